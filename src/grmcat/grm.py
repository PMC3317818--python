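"""Graded response model (GRM) probabilities and information.

Samejima's GRM for an item with discrimination ``a`` and ordered thresholds
``b_1 <= ... <= b_{K-1}``:

    P*(X >= k | theta) = logistic(a * (theta - b_k)),   k = 1..K-1

with boundary conventions ``P*(X >= 0) = 1`` and ``P*(X >= K) = 0``; category
probabilities are the consecutive differences.  The link is an unscaled
logistic (no D = 1.7).

Expected (Fisher) item information is

    I(theta) = sum_k (W_k - W_{k+1})^2 / P_k,   W_k = a * P*_k (1 - P*_k)

with ``W_0 = W_K = 0``; test information is the sum over a bank's items.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit

from .item_bank import GRMItem, ItemBank

__all__ = [
    "cumulative_prob",
    "category_probabilities",
    "item_log_likelihood",
    "item_information",
    "test_information",
    "InformationCurve",
    "information_curve",
    "bank_category_probabilities",
    "bank_information",
]


def cumulative_prob(item: GRMItem, k: int, theta) -> np.ndarray | float:
    """P*(X >= k | theta) for boundary index ``k`` in ``1..K-1``.

    Strictly increasing in theta and equal to 0.5 at ``theta = b_k``.
    """
    if not 1 <= k <= len(item.b):
        raise IndexError(
            f"boundary index k={k} out of range 1..{len(item.b)} for item "
            f"{item.item_id}"
        )
    theta = np.asarray(theta, dtype=float)
    out = expit(item.a * (theta - item.b[k - 1]))
    return out if out.ndim else float(out)


def _cum_matrix(a: np.ndarray, b: np.ndarray, theta: np.ndarray) -> np.ndarray:
    """P* array of shape (..., m, K+1) incl. the P*_0 = 1 and P*_K = 0 pads."""
    # a: (m,), b: (m, K-1), theta broadcastable to (...,)
    z = a[:, None] * (theta[..., None, None] - b)  # (..., m, K-1)
    p = expit(z)
    shape = z.shape[:-1]
    ones = np.ones(shape + (1,))
    zeros = np.zeros(shape + (1,))
    return np.concatenate([ones, p, zeros], axis=-1)


def category_probabilities(item: GRMItem, theta) -> np.ndarray:
    """Probability of each of the K categories at ``theta``.

    Returns shape ``(K,)`` for scalar theta, ``theta.shape + (K,)`` otherwise.
    """
    arr = np.asarray(theta, dtype=float)
    scalar = arr.ndim == 0
    th = np.atleast_1d(arr)
    cum = _cum_matrix(np.array([item.a]), np.array([item.b]), th)[..., 0, :]
    probs = cum[..., :-1] - cum[..., 1:]
    return probs[0] if scalar else probs.reshape(arr.shape + (item.n_categories,))


def item_log_likelihood(item: GRMItem, response: int, theta) -> np.ndarray | float:
    """log P(X = response | theta); finite for interior theta."""
    k = int(response)
    if not 0 <= k <= len(item.b):
        raise ValueError(
            f"response {response} out of range 0..{len(item.b)} for item "
            f"{item.item_id}"
        )
    theta = np.asarray(theta, dtype=float)
    upper = expit(item.a * (theta - item.b[k - 1])) if k >= 1 else 1.0
    lower = expit(item.a * (theta - item.b[k])) if k <= len(item.b) - 1 else 0.0
    with np.errstate(divide="ignore"):
        out = np.log(np.maximum(upper - lower, 1e-300))
    return out if out.ndim else float(out)


def item_information(item: GRMItem, theta) -> np.ndarray | float:
    """Samejima expected Fisher information of one item at ``theta``."""
    out = bank_information(ItemBank((item,)), theta, total=False)[..., 0]
    return out if out.ndim else float(out)


def test_information(bank: ItemBank, theta) -> np.ndarray | float:
    """Sum of item informations over the bank (additive by local independence)."""
    out = bank_information(bank, theta, total=True)
    return out if out.ndim else float(out)


def bank_category_probabilities(bank: ItemBank, theta) -> np.ndarray:
    """Category probabilities for every bank item; shape (..., m, K)."""
    theta = np.asarray(theta, dtype=float)
    cum = _cum_matrix(bank.a_array, bank.b_array, theta)
    return cum[..., :-1] - cum[..., 1:]


def bank_information(bank: ItemBank, theta, total: bool = True) -> np.ndarray:
    """Item (or summed test) information for every bank item at ``theta``."""
    theta = np.asarray(theta, dtype=float)
    cum = _cum_matrix(bank.a_array, bank.b_array, theta)  # (..., m, K+1)
    w = bank.a_array[:, None] * cum * (1.0 - cum)  # W_0 = W_K = 0 automatically
    probs = cum[..., :-1] - cum[..., 1:]
    num = (w[..., :-1] - w[..., 1:]) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(probs > 1e-300, num / np.maximum(probs, 1e-300), 0.0)
    info = contrib.sum(axis=-1)  # (..., m)
    return info.sum(axis=-1) if total else info


@dataclass(frozen=True)
class InformationCurve:
    """Information evaluated on a theta grid (item- or test-level)."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape:
            raise ValueError("grid and values must have identical shape")
        if np.any(values < 0):
            raise ValueError("information must be non-negative")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)

    @property
    def peak_theta(self) -> float:
        return float(self.grid[int(np.argmax(self.values))])

    def to_csv(self, path: str | Path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.grid, self.values]),
            delimiter=",",
            header="theta,information",
            comments="",
        )


def information_curve(
    bank: ItemBank,
    lo: float = -4.0,
    hi: float = 4.0,
    n_points: int = 161,
) -> InformationCurve:
    """Test-information curve on an evenly spaced theta grid."""
    grid = np.linspace(lo, hi, n_points)
    return InformationCurve(grid=grid, values=np.asarray(test_information(bank, grid)))
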