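"""Psychometric vetting battery for a polytomous item bank.

Before a scale's responses are trusted to drive an adaptive test, the IRT
assumptions behind it must be checked:

* **unidimensionality** — polychoric correlation matrix, principal-component
  variance proportions (first component >= 20%, first/second ratio >= 4);
* **local independence** — residual correlations after a one-factor
  (minres) extraction, flagged above 0.2, and Yen's Q3 on GRM residuals,
  banded moderate [0.24, 0.36] / large >= 0.37;
* **monotonicity** — Mokken scalability coefficients (item H >= 0.3) and
  rest-score regression checks;
* **parameter invariance** — ordinal-regression DIF with a McFadden
  pseudo-R-squared change of 0.02 as the effect-size cutoff.

All matrices are reported item-by-item; ``flags`` collects every threshold
exceedance in one flat list.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import multivariate_normal, norm

from .grm import bank_category_probabilities
from .item_bank import ItemBank

__all__ = [
    "ScreeningError",
    "Flag",
    "ScreeningReport",
    "polychoric_correlation",
    "polychoric_matrix",
    "pca_variance_ratio",
    "one_factor_residuals",
    "q3_matrix",
    "max_covariance",
    "mokken_scalability",
    "monotonicity_check",
    "dif_ordinal",
    "run_battery",
]

RESIDUAL_FLAG = 0.2
Q3_MODERATE = 0.24
Q3_LARGE = 0.37
MOKKEN_LOWER = 0.3
DIF_CUTOFF = 0.02
RECKASE_FIRST = 0.20
FIRST_SECOND_RATIO = 4.0


class ScreeningError(ValueError):
    pass


@dataclass(frozen=True)
class Flag:
    diagnostic: str
    items: tuple
    value: float
    threshold: float


@dataclass
class ScreeningReport:
    """Everything the battery computed, plus the flat flag list."""

    polychoric: np.ndarray | None = None
    pca_variance: np.ndarray | None = None
    residual_corr: np.ndarray | None = None
    q3: np.ndarray | None = None
    mokken_item_h: np.ndarray | None = None
    mokken_scale_h: float | None = None
    monotonicity_violations: np.ndarray | None = None
    dif: pd.DataFrame | None = None
    flags: list[Flag] = field(default_factory=list)

    def flags_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "diagnostic": [f.diagnostic for f in self.flags],
                "items": [",".join(str(i) for i in f.items) for f in self.flags],
                "value": [f.value for f in self.flags],
                "threshold": [f.threshold for f in self.flags],
            }
        )

    def to_json(self, path: str | Path) -> None:
        import json

        def arr(x):
            return None if x is None else np.asarray(x).tolist()

        payload = {
            "polychoric": arr(self.polychoric),
            "pca_variance": arr(self.pca_variance),
            "residual_corr": arr(self.residual_corr),
            "q3": arr(self.q3),
            "mokken_item_h": arr(self.mokken_item_h),
            "mokken_scale_h": self.mokken_scale_h,
            "monotonicity_violations": arr(self.monotonicity_violations),
            "dif": None if self.dif is None else self.dif.to_dict(orient="list"),
            "flags": [
                {
                    "diagnostic": f.diagnostic,
                    "items": list(f.items),
                    "value": f.value,
                    "threshold": f.threshold,
                }
                for f in self.flags
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


# --------------------------------------------------------------------------
# polychoric correlations


def _thresholds(col: np.ndarray, n_cat: int) -> np.ndarray:
    """Normal quantiles of cumulative category proportions (K-1 cuts)."""
    props = np.bincount(col, minlength=n_cat) / len(col)
    cum = np.cumsum(props)[:-1]
    cum = np.clip(cum, 1e-6, 1 - 1e-6)
    return norm.ppf(cum)


def polychoric_correlation(x: np.ndarray, y: np.ndarray, n_cat: int) -> float:
    """Two-step polychoric estimate for one ordinal pair.

    Step 1 fixes each variable's thresholds at normal quantiles of its
    marginal proportions; step 2 maximizes the bivariate-normal likelihood
    of the contingency table over the correlation alone.
    """
    tx = np.concatenate([[-np.inf], _thresholds(x, n_cat), [np.inf]])
    ty = np.concatenate([[-np.inf], _thresholds(y, n_cat), [np.inf]])
    table = np.zeros((n_cat, n_cat))
    for i in range(n_cat):
        xi = x == i
        for j in range(n_cat):
            table[i, j] = np.sum(xi & (y == j))

    finite_x = np.clip(tx, -8, 8)
    finite_y = np.clip(ty, -8, 8)
    grid = np.array(
        [[finite_x[i], finite_y[j]] for i in range(n_cat + 1) for j in range(n_cat + 1)]
    )

    def neg_ll(rho):
        mvn = multivariate_normal(mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]])
        cdf = mvn.cdf(grid).reshape(n_cat + 1, n_cat + 1)
        cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
        cell = np.maximum(cell, 1e-12)
        return -np.sum(table * np.log(cell))

    res = minimize_scalar(neg_ll, bounds=(-0.999, 0.999), method="bounded")
    return float(res.x)


def polychoric_matrix(data: np.ndarray, n_categories: int = 5) -> np.ndarray:
    """Pairwise two-step polychoric correlation matrix of an (n, m) matrix."""
    data = np.asarray(data).astype(int)
    n, m = data.shape
    for j in range(m):
        if len(np.unique(data[:, j])) < 2:
            raise ScreeningError(f"item {j + 1} has a single observed category")
    out = np.eye(m)
    for i in range(m):
        for j in range(i + 1, m):
            r = polychoric_correlation(data[:, i], data[:, j], n_categories)
            out[i, j] = out[j, i] = r
    return out


# --------------------------------------------------------------------------
# dimensionality


def pca_variance_ratio(corr: np.ndarray) -> tuple[np.ndarray, dict]:
    """Eigenvalue variance proportions of a correlation matrix plus flags.

    Non-PSD input (possible for pairwise polychorics) is smoothed by
    clipping negative eigenvalues, with a warning.
    """
    corr = np.asarray(corr, dtype=float)
    vals = np.linalg.eigvalsh(corr)[::-1]
    if vals[-1] < -1e-8:
        warnings.warn("correlation matrix not PSD; clipping negative eigenvalues")
        vals = np.maximum(vals, 0.0)
    props = vals / vals.sum()
    decision = {
        "first_proportion": float(props[0]),
        "first_ge_20pct": bool(props[0] >= RECKASE_FIRST),
        "first_second_ratio": float(props[0] / props[1]) if len(props) > 1 else np.inf,
        "ratio_ge_4": bool(len(props) > 1 and props[0] / props[1] >= FIRST_SECOND_RATIO),
    }
    return props, decision


def one_factor_residuals(corr: np.ndarray) -> tuple[np.ndarray, list[Flag]]:
    """Residual correlations after a least-squares one-factor extraction.

    Loadings minimize the off-diagonal squared residuals (minres); Heywood
    loadings are clipped to |lambda| <= 1 with a warning.  Off-diagonal
    residuals above 0.2 are flagged as possibly locally dependent.
    """
    corr = np.asarray(corr, dtype=float)
    m = corr.shape[0]
    if m < 3:
        raise ScreeningError("need at least 3 items for a one-factor model")
    vals, vecs = np.linalg.eigh(corr)
    lam0 = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
    if lam0.sum() < 0:
        lam0 = -lam0
    off = ~np.eye(m, dtype=bool)

    def loss(lam):
        resid = corr - np.outer(lam, lam)
        return 0.5 * np.sum(resid[off] ** 2)

    def grad(lam):
        resid = (corr - np.outer(lam, lam)) * off
        return -2.0 * resid @ lam

    res = minimize(loss, lam0, jac=grad, method="L-BFGS-B")
    lam = res.x
    if np.any(np.abs(lam) > 1.0):
        warnings.warn("Heywood case: one-factor loading clipped to |lambda| <= 1")
        lam = np.clip(lam, -1.0, 1.0)
    resid = corr - np.outer(lam, lam)
    np.fill_diagonal(resid, 0.0)
    flags = [
        Flag("residual_corr", (i + 1, j + 1), float(resid[i, j]), RESIDUAL_FLAG)
        for i in range(m)
        for j in range(i + 1, m)
        if resid[i, j] > RESIDUAL_FLAG
    ]
    return resid, flags


# --------------------------------------------------------------------------
# local dependence under the GRM


def q3_matrix(
    data: np.ndarray, bank: ItemBank, theta_hats: np.ndarray
) -> tuple[np.ndarray, list[Flag]]:
    """Yen's Q3: correlations of observed-minus-expected item scores.

    Expected scores use the GRM category probabilities at each respondent's
    estimate.  The diagonal is NaN.  Pairs in [0.24, 0.36] are flagged
    moderate, >= 0.37 large.  A mild negative bias of about -1/(m-1) is
    expected when the model holds.
    """
    data = np.asarray(data, dtype=float)
    theta_hats = np.asarray(theta_hats, dtype=float)
    if data.shape[0] != len(theta_hats):
        raise ScreeningError("one theta estimate per respondent required")
    probs = bank_category_probabilities(bank, theta_hats)  # (n, m, K)
    cats = np.arange(bank.n_categories)
    expected = (probs * cats).sum(axis=-1)
    resid = data - expected
    sd = resid.std(axis=0)
    m = data.shape[1]
    q3 = np.full((m, m), np.nan)
    ok = sd > 1e-12
    if np.any(~ok):
        warnings.warn("zero-variance residuals; affected pairs reported missing")
    sub = np.corrcoef(resid[:, ok], rowvar=False)
    idx = np.nonzero(ok)[0]
    for ii, i in enumerate(idx):
        for jj, j in enumerate(idx):
            if i != j:
                q3[i, j] = sub[ii, jj]
    flags = []
    for i in range(m):
        for j in range(i + 1, m):
            v = q3[i, j]
            if np.isnan(v):
                continue
            if abs(v) >= Q3_LARGE:
                flags.append(Flag("q3_large", (i + 1, j + 1), float(v), Q3_LARGE))
            elif abs(v) >= Q3_MODERATE:
                flags.append(Flag("q3_moderate", (i + 1, j + 1), float(v), Q3_MODERATE))
    return q3, flags


# --------------------------------------------------------------------------
# Mokken scalability


def max_covariance(x: np.ndarray, y: np.ndarray, n_cat: int) -> float:
    """Maximum covariance of two discrete variables given their marginals.

    Attained by the comonotone (maximally concordant) coupling: sort both
    marginal distributions and pair mass greedily from the top.
    """
    px = np.bincount(x, minlength=n_cat) / len(x)
    py = np.bincount(y, minlength=n_cat) / len(y)
    exy = 0.0
    i = j = 0
    remx = px.copy()
    remy = py.copy()
    while i < n_cat and j < n_cat:
        mass = min(remx[i], remy[j])
        exy += mass * i * j
        remx[i] -= mass
        remy[j] -= mass
        if remx[i] <= 1e-15:
            i += 1
        if remy[j] <= 1e-15:
            j += 1
    ex = np.dot(px, np.arange(n_cat))
    ey = np.dot(py, np.arange(n_cat))
    return float(exy - ex * ey)


def mokken_scalability(
    data: np.ndarray, n_categories: int = 5
) -> tuple[np.ndarray, np.ndarray, float, str]:
    """Loevinger-style H coefficients for polytomous items.

    ``H_ij = cov(X_i, X_j) / covmax(X_i, X_j)``; item and scale coefficients
    are ratio-of-sums aggregates.  Returns (item_h, pair_h, scale_h, band)
    with band one of unscalable/weak/moderate/strong (0.3/0.4/0.5 cuts).
    """
    data = np.asarray(data).astype(int)
    n, m = data.shape
    variances = data.var(axis=0)
    if np.any(variances == 0):
        warnings.warn("zero-variance items excluded from Mokken analysis")
        keep = variances > 0
        data = data[:, keep]
        m = data.shape[1]
    cov = np.cov(data, rowvar=False, ddof=0)
    covmax = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            covmax[i, j] = covmax[j, i] = max_covariance(
                data[:, i], data[:, j], n_categories
            )
    pair_h = np.full((m, m), np.nan)
    off = ~np.eye(m, dtype=bool)
    pair_h[off] = cov[off] / covmax[off]
    item_h = np.array(
        [cov[i, off[i]].sum() / covmax[i, off[i]].sum() for i in range(m)]
    )
    iu = np.triu_indices(m, 1)
    scale_h = float(cov[iu].sum() / covmax[iu].sum())
    band = (
        "strong"
        if scale_h >= 0.5
        else "moderate"
        if scale_h >= 0.4
        else "weak"
        if scale_h >= MOKKEN_LOWER
        else "unscalable"
    )
    return item_h, pair_h, scale_h, band


def monotonicity_check(
    data: np.ndarray, n_rest_groups: int = 5, min_group_size: int = 50
) -> np.ndarray:
    """Count rest-score monotonicity violations per item.

    Respondents are binned by rest score (total of all *other* items) into
    up to ``n_rest_groups`` quantile groups; small groups are merged.  Each
    item's mean score must be non-decreasing across groups; each decrease
    counts one violation.
    """
    data = np.asarray(data, dtype=float)
    n, m = data.shape
    violations = np.zeros(m, dtype=int)
    total = data.sum(axis=1)
    for j in range(m):
        rest = total - data[:, j]
        edges = np.quantile(rest, np.linspace(0, 1, n_rest_groups + 1)[1:-1])
        groups = np.searchsorted(edges, rest, side="right")
        means = []
        counts = []
        for g in np.unique(groups):
            sel = groups == g
            means.append(data[sel, j].mean())
            counts.append(sel.sum())
        # merge undersized bins into their left neighbour
        merged_means: list[float] = []
        merged_counts: list[int] = []
        for mu, c in zip(means, counts):
            if merged_counts and merged_counts[-1] < min_group_size:
                tot = merged_counts[-1] + c
                merged_means[-1] = (merged_means[-1] * merged_counts[-1] + mu * c) / tot
                merged_counts[-1] = tot
            else:
                merged_means.append(mu)
                merged_counts.append(c)
        violations[j] = sum(
            1 for a, b in zip(merged_means, merged_means[1:]) if b < a - 1e-12
        )
    return violations


# --------------------------------------------------------------------------
# differential item functioning


def _null_ordinal_ll(y: np.ndarray) -> float:
    """Max log-likelihood of the thresholds-only proportional-odds model.

    With no covariates the MLE fits the marginal category frequencies
    exactly, so the value is available in closed form.
    """
    counts = np.bincount(y)
    counts = counts[counts > 0]
    return float(np.sum(counts * np.log(counts / len(y))))


def dif_ordinal(
    data: np.ndarray,
    theta_hats: np.ndarray,
    group: np.ndarray,
    cutoff: float = DIF_CUTOFF,
) -> tuple[pd.DataFrame, list[Flag]]:
    """Ordinal-regression DIF screen with a McFadden delta-R2 effect size.

    Per item, proportional-odds models are compared: M0 ``item ~ theta``
    versus M1 ``item ~ theta + group + theta x group``.  The change in
    McFadden's pseudo-R2 (against the thresholds-only null) is the effect
    size; items at or above ``cutoff`` are flagged.  Non-converged items are
    reported indeterminate (NaN), not flagged.  A continuous covariate is
    entered linearly; categorical covariates are dummy-coded.
    """
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    data = np.asarray(data).astype(int)
    theta_hats = np.asarray(theta_hats, dtype=float)
    group = np.asarray(group)
    n, m = data.shape
    if group.dtype.kind in "OUSb" or len(np.unique(group)) <= 10:
        codes, levels = pd.factorize(group)
        if len(levels) < 2:
            raise ScreeningError("group covariate needs at least 2 levels")
        gcols = np.column_stack([(codes == k).astype(float) for k in range(1, len(levels))])
    else:
        gcols = (group.astype(float) - group.mean())[:, None]

    rows = []
    flags = []
    for j in range(m):
        y = data[:, j]
        # categories must be consecutive for OrderedModel
        y = pd.Series(y).astype("category").cat.codes.to_numpy()
        ll_null = _null_ordinal_ll(y)
        x0 = theta_hats[:, None]
        x1 = np.column_stack([x0, gcols, gcols * theta_hats[:, None]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                f0 = OrderedModel(y, x0, distr="logit").fit(method="bfgs", disp=False)
                f1 = OrderedModel(y, x1, distr="logit").fit(method="bfgs", disp=False)
            r2_0 = 1.0 - f0.llf / ll_null
            r2_1 = 1.0 - f1.llf / ll_null
            delta = max(r2_1 - r2_0, 0.0)
            rows.append({"item": j + 1, "delta_r2": delta, "converged": True})
            if delta >= cutoff:
                flags.append(Flag("dif", (j + 1,), float(delta), cutoff))
        except Exception:
            rows.append({"item": j + 1, "delta_r2": np.nan, "converged": False})
    return pd.DataFrame(rows), flags


# --------------------------------------------------------------------------
# the full battery


def run_battery(
    data: np.ndarray,
    bank: ItemBank,
    theta_hats: np.ndarray,
    dif_covariates: dict[str, np.ndarray] | None = None,
    n_categories: int = 5,
    polychoric: bool = True,
) -> ScreeningReport:
    """Run every screen and collect all flags in one report."""
    report = ScreeningReport()
    data = np.asarray(data).astype(int)

    if polychoric:
        report.polychoric = polychoric_matrix(data, n_categories)
        report.pca_variance, decision = pca_variance_ratio(report.polychoric)
        if not decision["first_ge_20pct"]:
            report.flags.append(
                Flag("pca_first_factor", (), decision["first_proportion"], RECKASE_FIRST)
            )
        if not decision["ratio_ge_4"]:
            report.flags.append(
                Flag("pca_ratio", (), decision["first_second_ratio"], FIRST_SECOND_RATIO)
            )
        resid, f = one_factor_residuals(report.polychoric)
        report.residual_corr = resid
        report.flags.extend(f)

    report.q3, f = q3_matrix(data, bank, theta_hats)
    report.flags.extend(f)

    item_h, _, scale_h, _ = mokken_scalability(data, n_categories)
    report.mokken_item_h = item_h
    report.mokken_scale_h = scale_h
    for j, h in enumerate(item_h):
        if h < MOKKEN_LOWER:
            report.flags.append(Flag("mokken_item_h", (j + 1,), float(h), MOKKEN_LOWER))

    report.monotonicity_violations = monotonicity_check(data)
    for j, v in enumerate(report.monotonicity_violations):
        if v > 0:
            report.flags.append(Flag("monotonicity", (j + 1,), float(v), 0.0))

    if dif_covariates:
        frames = []
        for name, cov in dif_covariates.items():
            df, f = dif_ordinal(data, theta_hats, cov)
            df.insert(0, "covariate", name)
            frames.append(df)
            report.flags.extend(f)
        report.dif = pd.concat(frames, ignore_index=True)
    return report
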