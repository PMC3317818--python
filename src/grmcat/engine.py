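"""Post-hoc CAT simulation: replay complete response records adaptively.

Each respondent's full fixed-form record is fed through the adaptive
algorithm as if collected live: start at theta = 0, pick the not-yet-used
item with maximum Fisher information at the provisional estimate, reveal the
recorded response, re-estimate by MAP, and stop once the standard error
drops below the rule's threshold (checked only after at least one item) or
the pool is exhausted.

Because item selection depends only on the provisional estimate — never on
the stopping rule — the administration path under any SE threshold is a
prefix of the no-rule path.  ``simulate_cohort`` exploits this: callers that
sweep several rules over one cohort can compute the full path once per
respondent and truncate (see :func:`truncate_record`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .grm import bank_information
from .item_bank import ItemBank
from .scoring import ThetaEstimate, map_estimate

__all__ = [
    "StoppingRule",
    "CATRecord",
    "select_next_item",
    "run_cat_posthoc",
    "simulate_cohort",
    "truncate_record",
    "records_to_frame",
    "records_to_jsonl",
]


@dataclass(frozen=True)
class StoppingRule:
    """Terminate once SE(theta) < threshold, or never (``kind="none"``)."""

    kind: str = "none"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("none", "se_threshold"):
            raise ValueError(f"unknown stopping rule kind {self.kind!r}")
        if self.kind == "se_threshold":
            if self.threshold is None or self.threshold <= 0:
                raise ValueError("se_threshold rule needs threshold > 0")
        elif self.threshold is not None:
            raise ValueError("rule 'none' takes no threshold")

    @classmethod
    def none(cls) -> "StoppingRule":
        return cls(kind="none")

    @classmethod
    def se(cls, threshold: float) -> "StoppingRule":
        return cls(kind="se_threshold", threshold=threshold)

    def label(self) -> str:
        return "None" if self.kind == "none" else f"SE<{self.threshold:g}"


@dataclass(frozen=True)
class CATRecord:
    """Trace of one simulated adaptive administration.

    The SE trace is *typically* non-increasing (information is additive at a
    fixed theta) but may tick up slightly when the provisional estimate
    moves into a lower-information region, so no monotonicity is enforced.
    """

    respondent_id: int | str
    administered: tuple[int, ...]  # item ids in administration order
    responses: tuple[int, ...]
    trace: tuple[tuple[float, float], ...]  # (theta, se) after each item
    final: ThetaEstimate
    stop_reason: str  # precision_met | pool_exhausted | no_rule_complete

    def __post_init__(self) -> None:
        if len(set(self.administered)) != len(self.administered):
            raise ValueError("administered items contain duplicates")
        if len(self.trace) != len(self.administered):
            raise ValueError("trace length must equal number administered")

    @property
    def n_items(self) -> int:
        return len(self.administered)


def select_next_item(
    bank: ItemBank, remaining: Sequence[int], provisional_theta: float
) -> int:
    """Id of the remaining item with maximum information at the estimate.

    Ties broken by lowest item id for determinism.
    """
    remaining = sorted(remaining)
    if not remaining:
        raise RuntimeError("no items remaining to select from")
    sub = bank.subset(remaining)
    info = np.asarray(bank_information(sub, provisional_theta, total=False))
    return remaining[int(np.argmax(info))]


def run_cat_posthoc(
    bank: ItemBank,
    response_row,
    rule: StoppingRule,
    start_theta: float = 0.0,
    respondent_id: int | str = 0,
) -> CATRecord:
    """Replay one complete response row through the adaptive algorithm.

    ``response_row`` is aligned with ``bank`` order (categories ``0..K-1``,
    no missing values).  The stopping condition is evaluated only after each
    administration, so at least one item is always used.
    """
    row = np.asarray(response_row, dtype=float)
    if row.shape != (len(bank),):
        raise ValueError(f"need {len(bank)} responses, got shape {row.shape}")
    if np.any(~np.isfinite(row)):
        raise ValueError(
            f"respondent {respondent_id}: post-hoc CAT requires a complete row"
        )
    row = row.astype(int)
    pos = {it.item_id: j for j, it in enumerate(bank)}

    remaining = set(bank.item_ids)
    administered: list[int] = []
    responses: list[int] = []
    trace: list[tuple[float, float]] = []
    theta = float(start_theta)
    est = None
    stop_reason = None
    while remaining:
        nxt = select_next_item(bank, remaining, theta)
        remaining.discard(nxt)
        administered.append(nxt)
        responses.append(int(row[pos[nxt]]))
        est = map_estimate(bank.subset(administered), responses)
        theta = est.theta
        trace.append((est.theta, est.se))
        if rule.kind == "se_threshold" and est.se < rule.threshold:
            stop_reason = "precision_met"
            break
    if stop_reason is None:
        stop_reason = "no_rule_complete" if rule.kind == "none" else "pool_exhausted"
    return CATRecord(
        respondent_id=respondent_id,
        administered=tuple(administered),
        responses=tuple(responses),
        trace=tuple(trace),
        final=est,
        stop_reason=stop_reason,
    )


def truncate_record(full_record: CATRecord, rule: StoppingRule) -> CATRecord:
    """Derive the record under ``rule`` from a no-rule (full-path) record.

    Valid because selection is rule-independent: the rule only truncates the
    path at the first step whose SE beats the threshold.
    """
    if full_record.stop_reason != "no_rule_complete":
        raise ValueError("truncation requires a no-rule record")
    if rule.kind == "none":
        return full_record
    ses = np.array([se for _, se in full_record.trace])
    hits = np.nonzero(ses < rule.threshold)[0]
    if len(hits) == 0:
        stop = len(ses)
        reason = "pool_exhausted"
    else:
        stop = int(hits[0]) + 1
        reason = "precision_met"
    theta, se = full_record.trace[stop - 1]
    return CATRecord(
        respondent_id=full_record.respondent_id,
        administered=full_record.administered[:stop],
        responses=full_record.responses[:stop],
        trace=full_record.trace[:stop],
        final=ThetaEstimate(theta=theta, se=se, n_items=stop),
        stop_reason=reason,
    )


def simulate_cohort(
    data,
    bank_assignment: ItemBank | Mapping | Sequence[ItemBank],
    rule: StoppingRule,
    respondent_ids: Sequence | None = None,
) -> list[CATRecord]:
    """One post-hoc CAT record per respondent; deterministic given inputs.

    ``data`` is an (n, m) integer matrix aligned to the bank's item order.
    ``bank_assignment`` is a single bank for all respondents, or a per-
    respondent mapping/sequence (e.g. the cross-validation assignment where
    each respondent is scored with the bank fit on the other half).
    """
    data = np.asarray(data)
    n = data.shape[0]
    if respondent_ids is None:
        respondent_ids = list(range(n))

    def bank_for(i):
        if isinstance(bank_assignment, ItemBank):
            return bank_assignment
        if isinstance(bank_assignment, Mapping):
            return bank_assignment[respondent_ids[i]]
        return bank_assignment[i]

    records = []
    for i in range(n):
        records.append(
            run_cat_posthoc(
                bank_for(i), data[i], rule, respondent_id=respondent_ids[i]
            )
        )
    return records


def records_to_frame(records: Sequence[CATRecord]) -> pd.DataFrame:
    """Flat per-respondent summary (CSV-ready)."""
    return pd.DataFrame(
        {
            "respondent_id": [r.respondent_id for r in records],
            "n_items": [r.n_items for r in records],
            "final_theta": [r.final.theta for r in records],
            "final_se": [r.final.se for r in records],
            "stop_reason": [r.stop_reason for r in records],
        }
    )


def records_to_jsonl(records: Sequence[CATRecord], path: str | Path) -> None:
    """One JSON object per line, full administration trace included."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                json.dumps(
                    {
                        "respondent_id": r.respondent_id,
                        "administered": list(r.administered),
                        "responses": list(r.responses),
                        "trace": [[t, s] for t, s in r.trace],
                        "final": {
                            "theta": r.final.theta,
                            "se": r.final.se,
                            "n_items": r.final.n_items,
                        },
                        "stop_reason": r.stop_reason,
                    }
                )
                + "\n"
            )
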