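"""GRM item-parameter estimation by marginal maximum likelihood (EM).

The latent trait is integrated out over a fixed quadrature approximation of
the standard-normal density (61 equally spaced nodes on [-5, 5] with
normalized normal weights).  The E-step computes each respondent's posterior
weight at every node; the M-step improves each item's expected complete-data
log-likelihood by quasi-Newton steps over (log a, b1, log threshold gaps) —
the gap parameterization keeps thresholds ordered at every iterate.  Partial
M-step maximization makes this a generalized EM, so the marginal
log-likelihood is non-decreasing across iterations.

Missing responses (NaN) are allowed here — they simply drop out of the
likelihood — but not in CAT simulation input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm

from .item_bank import GRMItem, ItemBank

__all__ = [
    "ResponseMatrix",
    "CalibrationResult",
    "CalibrationError",
    "fit_grm",
    "twofold_split",
    "cross_validated_banks",
]


class CalibrationError(ValueError):
    """Estimation is impossible for the given data."""


@dataclass(frozen=True)
class ResponseMatrix:
    """n x m matrix of integer categories 0..K-1 (NaN = missing)."""

    values: np.ndarray
    respondent_ids: tuple = ()
    item_ids: tuple = ()
    n_categories: int = 5

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > self.n_categories - 1):
            raise ValueError(
                f"categories must lie in 0..{self.n_categories - 1}"
            )
        if finite.size and np.any(finite != np.round(finite)):
            raise ValueError("categories must be integers")
        object.__setattr__(self, "values", vals)
        rids = tuple(self.respondent_ids) or tuple(range(vals.shape[0]))
        iids = tuple(self.item_ids) or tuple(range(1, vals.shape[1] + 1))
        if len(rids) != vals.shape[0] or len(iids) != vals.shape[1]:
            raise ValueError("id lengths must match matrix dimensions")
        object.__setattr__(self, "respondent_ids", rids)
        object.__setattr__(self, "item_ids", iids)

    @property
    def n_respondents(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return bool(np.all(np.isfinite(self.values)))

    def subset_rows(self, indices) -> "ResponseMatrix":
        idx = np.asarray(indices)
        return ResponseMatrix(
            values=self.values[idx],
            respondent_ids=tuple(self.respondent_ids[i] for i in idx),
            item_ids=self.item_ids,
            n_categories=self.n_categories,
        )

    @classmethod
    def from_csv(cls, path: str | Path, n_categories: int = 5) -> "ResponseMatrix":
        """External dialect: categories 1..K, missing token NA."""
        df = pd.read_csv(path, na_values=["NA"])
        rids = ()
        if "respondent_id" in df.columns:
            rids = tuple(df.pop("respondent_id"))
        return cls(
            values=df.to_numpy(dtype=float) - 1.0,
            respondent_ids=rids,
            item_ids=tuple(df.columns),
            n_categories=n_categories,
        )

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.values + 1.0, columns=[str(i) for i in self.item_ids])
        df.insert(0, "respondent_id", list(self.respondent_ids))
        df.to_csv(path, index=False, na_rep="NA")


@dataclass(frozen=True)
class CalibrationResult:
    bank: ItemBank
    log_likelihood_trace: tuple[float, ...]
    converged: bool
    n_iterations: int


def _item_tables(params: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """Category probabilities (Q, K) for one item's packed parameters."""
    a, b = _unpack(params)
    cum = expit(a * (nodes[:, None] - b[None, :]))
    cum = np.hstack([np.ones((len(nodes), 1)), cum, np.zeros((len(nodes), 1))])
    return cum[:, :-1] - cum[:, 1:]


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    gaps = np.maximum(np.diff(b), 1e-4)
    return np.concatenate([[np.log(a)], [b[0]], np.log(gaps)])


def _unpack(params: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(params[0]))
    b = params[1] + np.concatenate([[0.0], np.cumsum(np.exp(params[2:]))])
    return a, b


def _neg_expected_ll(params, counts, nodes):
    """(-f, -grad) of one item's expected complete-data log-likelihood."""
    a, b = _unpack(params)
    cum_in = expit(a * (nodes[:, None] - b[None, :]))  # (Q, K-1)
    cum = np.hstack([np.ones((len(nodes), 1)), cum_in, np.zeros((len(nodes), 1))])
    probs = np.maximum(cum[:, :-1] - cum[:, 1:], 1e-300)
    f = float(np.sum(counts * np.log(probs)))

    ratio = counts / probs  # (Q, K)
    # df/dP*_k = ratio[:, k] - ratio[:, k-1] for interior boundaries k=1..K-1
    g_qk = ratio[:, 1:] - ratio[:, :-1]  # (Q, K-1)
    s = cum_in * (1.0 - cum_in)
    df_da = float(np.sum(g_qk * (nodes[:, None] - b[None, :]) * s))
    df_db = -a * np.sum(g_qk * s, axis=0)  # (K-1,)

    grad = np.empty_like(params)
    grad[0] = a * df_da  # d/d log a
    grad[1] = df_db.sum()  # b1 shifts every threshold
    gaps = np.exp(params[2:])
    # gap j moves thresholds j+1..K-1
    tail = np.cumsum(df_db[::-1])[::-1]
    grad[2:] = gaps * tail[1:]
    return -f, -grad


def fit_grm(
    data: ResponseMatrix,
    n_categories: int | None = None,
    quadrature_points: int = 61,
    tol_params: float = 1e-3,
    tol_ll: float = 1e-7,
    max_iter: int = 500,
    min_n: int = 200,
) -> CalibrationResult:
    """Fit the graded response model to a response matrix.

    Every item must show every category at least once; items failing this
    have inestimable thresholds and raise :class:`CalibrationError` (collapse
    categories upstream if needed).
    """
    n_cat = n_categories or data.n_categories
    if data.n_respondents < min_n:
        raise CalibrationError(
            f"need at least {min_n} respondents, got {data.n_respondents}"
        )
    vals = data.values
    m = data.n_items
    for j in range(m):
        col = vals[:, j]
        col = col[np.isfinite(col)].astype(int)
        present = np.bincount(col, minlength=n_cat)
        if np.any(present == 0):
            missing_cats = np.nonzero(present == 0)[0].tolist()
            raise CalibrationError(
                f"item {data.item_ids[j]}: categories {missing_cats} never "
                "observed; thresholds are inestimable"
            )

    nodes = np.linspace(-5.0, 5.0, quadrature_points)
    log_w = norm.logpdf(nodes)
    log_w = log_w - logsumexp(log_w)

    # initial values: a = 1, thresholds from marginal cumulative logits
    params = []
    for j in range(m):
        col = vals[:, j]
        col = col[np.isfinite(col)].astype(int)
        p_ge = np.array([(col >= k).mean() for k in range(1, n_cat)])
        p_ge = np.clip(p_ge, 1e-3, 1 - 1e-3)
        # with a = 1 and theta = 0, P(X >= k) = expit(-b_k)
        b0 = np.sort(-np.log(p_ge / (1 - p_ge)))
        b0 = np.maximum.accumulate(b0 + np.arange(n_cat - 1) * 1e-4)
        params.append(_pack(1.0, b0))

    # per-item category indicator masks for fast expected counts
    cat_masks = []
    for j in range(m):
        col = vals[:, j]
        obs = np.isfinite(col)
        cat_masks.append((obs, np.where(obs, col, 0).astype(int)))

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        tables = [np.maximum(_item_tables(p, nodes), 1e-300) for p in params]
        log_tables = [np.log(t) for t in tables]
        loglik = np.zeros((data.n_respondents, len(nodes)))
        for j in range(m):
            obs, cats = cat_masks[j]
            contrib = log_tables[j][:, cats].T  # (n, Q)
            loglik[obs] += contrib[obs]
        joint = loglik + log_w[None, :]
        norm_c = logsumexp(joint, axis=1)
        trace.append(float(norm_c.sum()))
        post = np.exp(joint - norm_c[:, None])  # (n, Q)

        max_change = 0.0
        for j in range(m):
            obs, cats = cat_masks[j]
            counts = np.zeros((len(nodes), n_cat))
            pj = post[obs]
            cj = cats[obs]
            for k in range(n_cat):
                sel = cj == k
                if sel.any():
                    counts[:, k] = pj[sel].sum(axis=0)
            res = minimize(
                _neg_expected_ll,
                params[j],
                args=(counts, nodes),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 20},
            )
            new = res.x if res.fun <= _neg_expected_ll(params[j], counts, nodes)[0] else params[j]
            a_old, b_old = _unpack(params[j])
            a_new, b_new = _unpack(new)
            max_change = max(
                max_change,
                abs(a_new - a_old),
                float(np.max(np.abs(b_new - b_old))),
            )
            params[j] = new

        if len(trace) >= 2:
            rel = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-12)
        else:
            rel = np.inf
        if max_change < tol_params and rel < tol_ll:
            converged = True
            break

    items = []
    for j, p in enumerate(params):
        a, b = _unpack(p)
        iid = data.item_ids[j]
        items.append(
            GRMItem(
                item_id=int(iid) if str(iid).isdigit() else j + 1,
                a=a,
                b=tuple(b),
                label=str(iid),
            )
        )
    return CalibrationResult(
        bank=ItemBank(tuple(items)),
        log_likelihood_trace=tuple(trace),
        converged=converged,
        n_iterations=it,
    )


def twofold_split(n: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Random partition into two halves differing in size by at most one."""
    if n < 2:
        raise ValueError("need at least 2 respondents to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    half = n // 2
    return np.sort(perm[:half]), np.sort(perm[half:])


def cross_validated_banks(
    data: ResponseMatrix, seed: int, **fit_options
) -> tuple[ItemBank, ItemBank, list[ItemBank]]:
    """Two-fold cross-validation: each half calibrated separately.

    Returns ``(bank_a, bank_b, assignment)`` where ``assignment[i]`` is the
    bank estimated on the half respondent ``i`` does *not* belong to — the
    anti-overfitting device of the simulation design.
    """
    half_a, half_b = twofold_split(data.n_respondents, seed)
    bank_a = fit_grm(data.subset_rows(half_a), **fit_options).bank
    bank_b = fit_grm(data.subset_rows(half_b), **fit_options).bank
    in_a = np.zeros(data.n_respondents, dtype=bool)
    in_a[half_a] = True
    assignment = [bank_b if in_a[i] else bank_a for i in range(data.n_respondents)]
    return bank_a, bank_b, assignment
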