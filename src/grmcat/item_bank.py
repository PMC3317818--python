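"""Calibrated graded-response-model item banks.

An item bank is the first component of a computerized adaptive test: a
collection of polytomous items, each described by one discrimination
parameter ``a`` and ``K - 1`` ordered threshold parameters ``b`` on the
latent-trait scale.  The package ships the 22-item MASQ-AD (anhedonic
depression) bank as ``load_masq_ad_bank()``.

Parameterization contract: the thresholds refer to an *unscaled logistic*
link (no ``D = 1.7`` constant), and all parameters assume responses in
reverse-keyed orientation — higher category means more of the trait.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GRMItem",
    "ItemBank",
    "BankValidationError",
    "BankParseError",
    "load_bank",
    "save_bank",
    "load_masq_ad_bank",
]


class BankValidationError(ValueError):
    """An item or bank violates a structural invariant."""


class BankParseError(ValueError):
    """A bank file could not be parsed."""


@dataclass(frozen=True)
class GRMItem:
    """One polytomous item under the graded response model.

    Parameters
    ----------
    item_id : int
        1-based identifier, unique within a bank.
    a : float
        Discrimination (slope), strictly positive.
    b : tuple of float
        ``K - 1`` non-decreasing category thresholds on the latent scale.
    source_id : int, optional
        Item number in the source questionnaire (e.g. MASQ item 23).
    label : str
        Item wording.
    key : str
        ``"positive"`` or ``"negative"`` wording direction.  Positively
        worded items must be reverse-coded before scoring.
    """

    item_id: int
    a: float
    b: tuple[float, ...]
    source_id: int | None = None
    label: str = ""
    key: str = "negative"

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.b)
        object.__setattr__(self, "b", b)
        if not np.isfinite(self.a) or self.a <= 0:
            raise BankValidationError(
                f"item {self.item_id}: discrimination a={self.a!r} must be > 0"
            )
        if len(b) < 1:
            raise BankValidationError(
                f"item {self.item_id}: needs at least one threshold"
            )
        if any(b[i + 1] < b[i] for i in range(len(b) - 1)):
            raise BankValidationError(
                f"item {self.item_id}: thresholds {b} are not non-decreasing"
            )
        if self.key not in ("positive", "negative"):
            raise BankValidationError(
                f"item {self.item_id}: key must be 'positive' or 'negative', "
                f"got {self.key!r}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class ItemBank:
    """Ordered collection of :class:`GRMItem` sharing one category count."""

    items: tuple[GRMItem, ...]

    # cached parameter arrays for vectorized math
    a_array: np.ndarray = field(init=False, repr=False, compare=False)
    b_array: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        items = tuple(self.items)
        object.__setattr__(self, "items", items)
        if not items:
            raise BankValidationError("bank must contain at least one item")
        ids = [it.item_id for it in items]
        if len(set(ids)) != len(ids):
            raise BankValidationError(f"duplicate item ids in bank: {ids}")
        ks = {it.n_categories for it in items}
        if len(ks) != 1:
            raise BankValidationError(
                f"all items must share one category count, found {sorted(ks)}"
            )
        object.__setattr__(
            self, "a_array", np.array([it.a for it in items], dtype=float)
        )
        object.__setattr__(
            self, "b_array", np.array([it.b for it in items], dtype=float)
        )

    @property
    def n_categories(self) -> int:
        return self.items[0].n_categories

    @property
    def item_ids(self) -> list[int]:
        return [it.item_id for it in self.items]

    @property
    def keys(self) -> list[str]:
        return [it.key for it in self.items]

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[GRMItem]:
        return iter(self.items)

    def __getitem__(self, index: int) -> GRMItem:
        return self.items[index]

    def item_by_id(self, item_id: int) -> GRMItem:
        for it in self.items:
            if it.item_id == item_id:
                return it
        raise KeyError(f"no item with id {item_id}")

    def subset(self, item_ids: Sequence[int]) -> "ItemBank":
        """Sub-bank containing ``item_ids`` in the given order."""
        return ItemBank(tuple(self.item_by_id(i) for i in item_ids))

    def to_frame(self) -> pd.DataFrame:
        k = self.n_categories
        rows = []
        for it in self.items:
            row = {
                "item_id": it.item_id,
                "source_id": it.source_id,
                "label": it.label,
                "key": it.key,
                "a": it.a,
            }
            row.update({f"b{j + 1}": it.b[j] for j in range(k - 1)})
            rows.append(row)
        return pd.DataFrame(rows)


def _items_from_frame(df: pd.DataFrame, origin: str) -> ItemBank:
    b_cols = sorted(
        (c for c in df.columns if c.startswith("b") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    required = {"item_id", "a"}
    missing = required - set(df.columns)
    if missing or not b_cols:
        raise BankParseError(
            f"{origin}: missing required columns "
            f"{sorted(missing) + ([] if b_cols else ['b1..'])}"
        )
    items = []
    for idx, row in df.iterrows():
        try:
            b = tuple(float(row[c]) for c in b_cols)
            source = row.get("source_id")
            items.append(
                GRMItem(
                    item_id=int(row["item_id"]),
                    a=float(row["a"]),
                    b=b,
                    source_id=None if pd.isna(source) else int(source),
                    label=str(row.get("label", "")),
                    key=str(row.get("key", "negative")),
                )
            )
        except (TypeError, ValueError) as exc:
            if isinstance(exc, BankValidationError):
                raise
            raise BankParseError(f"{origin}: malformed row {idx}: {exc}") from exc
    return ItemBank(tuple(items))


def load_bank(path: str | Path, format: str | None = None) -> ItemBank:
    """Read a validated item bank from CSV or JSON.

    CSV column order is ``item_id,source_id,label,key,a,b1,...``; JSON is a
    list of objects with the same fields (``b`` as a list).  ``format`` is
    inferred from the suffix when omitted.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        try:
            df = pd.read_csv(path, float_precision="round_trip")
        except (pd.errors.ParserError, UnicodeDecodeError) as exc:
            raise BankParseError(f"{path}: {exc}") from exc
        return _items_from_frame(df, str(path))
    if fmt == "json":
        with open(path) as fh:
            payload = json.load(fh)
        records = payload["items"] if isinstance(payload, dict) else payload
        items = []
        for rec in records:
            items.append(
                GRMItem(
                    item_id=int(rec["item_id"]),
                    a=float(rec["a"]),
                    b=tuple(float(x) for x in rec["b"]),
                    source_id=rec.get("source_id"),
                    label=rec.get("label", ""),
                    key=rec.get("key", "negative"),
                )
            )
        return ItemBank(tuple(items))
    raise ValueError(f"unknown bank format {fmt!r}")


def save_bank(bank: ItemBank, path: str | Path, format: str | None = None) -> None:
    """Write ``bank`` to CSV or JSON; round-trips at full float precision."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        # shortest-repr floats + round_trip parsing make load(save(bank)) exact
        bank.to_frame().to_csv(path, index=False)
    elif fmt == "json":
        records = [
            {
                "item_id": it.item_id,
                "source_id": it.source_id,
                "label": it.label,
                "key": it.key,
                "a": it.a,
                "b": list(it.b),
            }
            for it in bank
        ]
        with open(path, "w") as fh:
            json.dump({"n_categories": bank.n_categories, "items": records}, fh, indent=1)
    else:
        raise ValueError(f"unknown bank format {fmt!r}")


def load_masq_ad_bank() -> ItemBank:
    """The packaged 22-item, 5-category MASQ-AD anhedonic depression bank."""
    ref = resources.files("grmcat.data").joinpath("masq_ad_table1.csv")
    with resources.as_file(ref) as p:
        return load_bank(p, format="csv")
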