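"""Latent-trait scoring: MAP estimates, full-test scores, keyed sum scores.

The trait is estimated by Maximum a Posteriori (MAP) under a standard-normal
prior: theta-hat maximizes ``log N(theta; 0, 1) + sum_i log P_{x_i}(theta)``.
The posterior is log-concave for the logistic GRM, so the mode is unique.
The reported standard error is the usual CAT stopping-rule quantity

    SE = [ I(theta-hat) + 1/prior_sd^2 ]^(-1/2)

i.e. expected test information at the mode plus the prior precision — not a
posterior SD.  With zero items administered this reduces to the prior:
theta-hat = 0, SE = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import expit

from .item_bank import ItemBank

__all__ = ["ThetaEstimate", "map_estimate", "full_test_estimate", "sum_score"]

_THETA_BOUNDS = (-6.0, 6.0)
_NEWTON_TOL = 1e-5
_MAX_NEWTON = 50


@dataclass(frozen=True)
class ThetaEstimate:
    """A MAP point estimate with its standard error."""

    theta: float
    se: float
    n_items: int
    method: str = "MAP"

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"se must be > 0, got {self.se}")
        if self.n_items < 0:
            raise ValueError(f"n_items must be >= 0, got {self.n_items}")


def _posterior_derivs(a, b, responses, theta, prior_mean, prior_var):
    """(f', f'') of the log posterior at theta; observed information."""
    k = responses
    kmax = b.shape[1]
    # boundary cumulative probabilities around each observed category
    p_up = np.where(k >= 1, expit(a * (theta - b[np.arange(len(a)), np.maximum(k - 1, 0)])), 1.0)
    p_lo = np.where(k <= kmax - 1, expit(a * (theta - b[np.arange(len(a)), np.minimum(k, kmax - 1)])), 0.0)
    p = np.maximum(p_up - p_lo, 1e-300)
    w_up = a * p_up * (1 - p_up)
    w_lo = a * p_lo * (1 - p_lo)
    dp = w_up - w_lo
    ddp = a**2 * (p_up * (1 - p_up) * (1 - 2 * p_up) - p_lo * (1 - p_lo) * (1 - 2 * p_lo))
    g = -(theta - prior_mean) / prior_var + np.sum(dp / p)
    h = -1.0 / prior_var + np.sum(ddp / p - (dp / p) ** 2)
    return g, h


def _log_posterior(a, b, responses, theta, prior_mean, prior_var):
    k = responses
    kmax = b.shape[1]
    idx = np.arange(len(a))
    p_up = np.where(k >= 1, expit(a * (theta - b[idx, np.maximum(k - 1, 0)])), 1.0)
    p_lo = np.where(k <= kmax - 1, expit(a * (theta - b[idx, np.minimum(k, kmax - 1)])), 0.0)
    p = np.maximum(p_up - p_lo, 1e-300)
    return -0.5 * (theta - prior_mean) ** 2 / prior_var + np.sum(np.log(p))


def map_estimate(
    items: ItemBank | None,
    responses: Sequence[int] | np.ndarray | None,
    prior_mean: float = 0.0,
    prior_sd: float = 1.0,
) -> ThetaEstimate:
    """MAP estimate of theta from responses to a (possibly empty) item set.

    ``items`` is a bank (or sub-bank) aligned element-wise with ``responses``
    (integer categories ``0..K-1``).  Safeguarded Newton iteration with a
    bracketed-search fallback on [-6, 6]; convergence ``|dtheta| < 1e-5``.
    """
    n_items = 0 if items is None else len(items)
    n_resp = 0 if responses is None else len(responses)
    if n_items != n_resp:
        raise ValueError(f"{n_resp} responses for {n_items} items")
    if n_items == 0:
        return ThetaEstimate(theta=prior_mean, se=prior_sd, n_items=0)

    responses = np.asarray(responses, dtype=int)
    kmax = items.n_categories - 1
    if responses.min() < 0 or responses.max() > kmax:
        raise ValueError(f"responses must lie in 0..{kmax}")

    a, b = items.a_array, items.b_array
    prior_var = prior_sd**2

    theta = prior_mean
    converged = False
    for _ in range(_MAX_NEWTON):
        g, h = _posterior_derivs(a, b, responses, theta, prior_mean, prior_var)
        step = -g / h if h < 0 else np.sign(g)  # force ascent if curvature degenerate
        step = float(np.clip(step, -1.0, 1.0))
        new = float(np.clip(theta + step, *_THETA_BOUNDS))
        if abs(new - theta) < _NEWTON_TOL:
            theta = new
            converged = True
            break
        theta = new
    if not converged:
        res = minimize_scalar(
            lambda t: -_log_posterior(a, b, responses, t, prior_mean, prior_var),
            bounds=_THETA_BOUNDS,
            method="bounded",
            options={"xatol": 1e-8},
        )
        theta = float(res.x)

    from .grm import test_information

    info = float(test_information(items, theta))
    se = 1.0 / np.sqrt(info + 1.0 / prior_var)
    return ThetaEstimate(theta=float(theta), se=float(se), n_items=len(items))


def full_test_estimate(bank: ItemBank, response_row) -> ThetaEstimate:
    """MAP estimate from the complete bank; requires a complete row."""
    row = np.asarray(response_row, dtype=float)
    if row.shape != (len(bank),):
        raise ValueError(
            f"full assessment needs {len(bank)} responses, got shape {row.shape}"
        )
    if np.any(~np.isfinite(row)):
        raise ValueError("full assessment requires a complete response row")
    return map_estimate(bank, row.astype(int))


def sum_score(response_row, key_vector: Sequence[str], n_categories: int = 5) -> int:
    """Keyed total score: positive items flipped (c -> K-1-c) then summed.

    ``response_row`` holds raw categories ``0..K-1``; after flipping the
    positively-worded items, a higher total means more of the trait.  For
    data already in reverse-keyed orientation pass all-``"negative"`` keys.
    """
    row = np.asarray(response_row, dtype=float)
    if np.any(~np.isfinite(row)):
        raise ValueError("sum score requires a complete response row")
    row = row.astype(int)
    keys = list(key_vector)
    if len(keys) != len(row):
        raise ValueError("one key per response required")
    kmax = n_categories - 1
    if row.min() < 0 or row.max() > kmax:
        raise ValueError(f"responses must lie in 0..{kmax}")
    flip = np.array([k == "positive" for k in keys])
    keyed = np.where(flip, kmax - row, row)
    return int(keyed.sum())
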