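"""Aggregate CAT records into efficiency and validity summaries.

Two table shapes come out of a stopping-rule sweep:

* a per-rule simulation summary — mean/SD of items administered, percentage
  of respondents using the whole pool, mean final SE, marginal reliability
  ``1 - mean(SE^2)`` (unit-variance trait), and the Pearson correlation of
  CAT estimates with full-test estimates;
* per-rule criterion-validity rows — Pearson r with a continuous criterion
  (Fisher-z 95% CI) or Mann-Whitney AUC against a binary diagnosis
  (Hanley-McNeil 95% CI), plus a sum-score reference row.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .engine import CATRecord, StoppingRule, simulate_cohort, truncate_record
from .item_bank import ItemBank
from .scoring import ThetaEstimate, full_test_estimate

__all__ = [
    "SimulationSummary",
    "ValiditySummary",
    "summarize_cat",
    "marginal_reliability",
    "criterion_correlation",
    "auc",
    "build_tables",
]


@dataclass(frozen=True)
class SimulationSummary:
    """One row of the per-stopping-rule efficiency table."""

    rule: StoppingRule
    n_respondents: int
    mean_items: float
    sd_items: float
    pct_all_items: float
    mean_se: float
    marginal_reliability: float
    r_with_full: float  # NaN when undefined (single respondent)


@dataclass(frozen=True)
class ValiditySummary:
    """One criterion-validity estimate with its 95% confidence interval."""

    rule_label: str
    criterion: str
    statistic: str  # pearson_r | auc
    estimate: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (self.ci_low - 1e-12 <= self.estimate <= self.ci_high + 1e-12):
            raise ValueError("estimate must lie inside its CI")


def marginal_reliability(se_values, prior_variance: float = 1.0) -> float:
    """``1 - mean(SE^2) / prior_variance``, floored at 0.

    A deliberately crude single-number reliability for a trait with known
    prior variance; exact only to the extent the SE is constant over theta.
    """
    se = np.asarray(se_values, dtype=float)
    if se.size == 0:
        raise ValueError("need at least one standard error")
    return float(max(0.0, 1.0 - np.mean(se**2) / prior_variance))


def summarize_cat(
    records: Sequence[CATRecord],
    full_estimates: Sequence[ThetaEstimate],
    rule: StoppingRule | None = None,
    pool_size: int | None = None,
) -> SimulationSummary:
    """Efficiency/fidelity summary of one rule's records.

    ``full_estimates`` must be aligned with ``records`` by respondent.
    ``pool_size`` (bank size) defaults to the largest administered count,
    which is exact whenever any respondent exhausted the pool.
    """
    if len(records) != len(full_estimates):
        raise ValueError("records and full estimates must align")
    if not records:
        raise ValueError("need at least one record")
    if rule is None:
        rule = (
            StoppingRule.none()
            if records[0].stop_reason == "no_rule_complete"
            else None
        )
    n_items = np.array([r.n_items for r in records], dtype=float)
    ses = np.array([r.final.se for r in records])
    cat_theta = np.array([r.final.theta for r in records])
    full_theta = np.array([e.theta for e in full_estimates])
    if pool_size is None:
        pool_size = int(max(r.n_items for r in records))
    if len(records) >= 2 and np.std(cat_theta) > 0 and np.std(full_theta) > 0:
        r_full = float(np.corrcoef(cat_theta, full_theta)[0, 1])
    else:
        warnings.warn("correlation with full test undefined; reporting NaN")
        r_full = float("nan")
    return SimulationSummary(
        rule=rule if rule is not None else StoppingRule.none(),
        n_respondents=len(records),
        mean_items=float(n_items.mean()),
        sd_items=float(n_items.std(ddof=0)),
        pct_all_items=float(100.0 * np.mean(n_items == pool_size)),
        mean_se=float(ses.mean()),
        marginal_reliability=marginal_reliability(ses),
        r_with_full=r_full,
    )


def criterion_correlation(
    theta_hats, criterion, rule_label: str = "", name: str = ""
) -> ValiditySummary:
    """Pearson r against a continuous criterion with a Fisher-z 95% CI."""
    x = np.asarray(theta_hats, dtype=float)
    y = np.asarray(criterion, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired one-dimensional inputs required")
    if len(x) < 4:
        raise ValueError("need n >= 4 for a confidence interval")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("missing values not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the variables")
    r = float(np.clip(np.corrcoef(x, y)[0, 1], -1.0, 1.0))
    if abs(r) >= 1.0 - 1e-12:  # degenerate: perfectly collinear
        r = float(np.sign(r))
        return ValiditySummary(rule_label, name, "pearson_r", r, r, r)
    z = np.arctanh(r)
    half = norm.ppf(0.975) / np.sqrt(len(x) - 3)
    return ValiditySummary(
        rule_label,
        name,
        "pearson_r",
        r,
        float(np.tanh(z - half)),
        float(np.tanh(z + half)),
    )


def auc(
    theta_hats, labels, rule_label: str = "", name: str = ""
) -> ValiditySummary:
    """Mann-Whitney AUC (ties count 1/2) with a Hanley-McNeil 95% CI."""
    x = np.asarray(theta_hats, dtype=float)
    y = np.asarray(labels).astype(int)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired one-dimensional inputs required")
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(x)  # midranks handle ties at 1/2
    a = (ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)
    a = float(a)
    q1 = a / (2.0 - a)
    q2 = 2.0 * a**2 / (1.0 + a)
    var = (a * (1 - a) + (n1 - 1) * (q1 - a**2) + (n0 - 1) * (q2 - a**2)) / (n1 * n0)
    half = norm.ppf(0.975) * np.sqrt(max(var, 0.0))
    return ValiditySummary(
        rule_label,
        name,
        "auc",
        a,
        float(max(0.0, a - half)),
        float(min(1.0, a + half)),
    )


def build_tables(
    data,
    bank_assignment,
    rules: Sequence[StoppingRule],
    criteria: Mapping[str, np.ndarray] | None = None,
    diagnosis=None,
    sum_scores=None,
    scoring_bank: ItemBank | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the stopping-rule sweep and assemble both summary tables.

    ``data`` is the (n, m) keyed response matrix; ``bank_assignment`` as in
    :func:`grmcat.engine.simulate_cohort`.  The full no-rule path is computed
    once per respondent; every SE rule is derived by truncation (selection is
    rule-independent).  ``criteria`` maps names to continuous columns;
    ``diagnosis`` is an optional binary column; ``sum_scores`` adds the
    traditional sum-score reference row to the validity table.

    Returns ``(simulation_table, validity_table)`` as DataFrames.
    """
    data = np.asarray(data)
    full_records = simulate_cohort(data, bank_assignment, StoppingRule.none())
    if scoring_bank is not None:
        full_ests = [full_test_estimate(scoring_bank, row) for row in data]
    else:
        full_ests = [r.final for r in full_records]

    sim_rows = []
    val_rows: list[ValiditySummary] = []

    def validity_for(scores, label):
        if criteria:
            for cname, col in criteria.items():
                val_rows.append(
                    criterion_correlation(scores, col, rule_label=label, name=cname)
                )
        if diagnosis is not None:
            val_rows.append(
                auc(scores, diagnosis, rule_label=label, name="diagnosis")
            )

    if sum_scores is not None:
        validity_for(np.asarray(sum_scores, dtype=float), "None: Sum score")

    for rule in rules:
        records = [truncate_record(r, rule) for r in full_records]
        summary = summarize_cat(records, full_ests, rule=rule, pool_size=data.shape[1])
        sim_rows.append(
            {
                "rule": rule.label(),
                "mean_items": summary.mean_items,
                "sd_items": summary.sd_items,
                "pct_all_items": summary.pct_all_items,
                "mean_se": summary.mean_se,
                "marginal_reliability": summary.marginal_reliability,
                "r_with_full": summary.r_with_full,
            }
        )
        theta = np.array([r.final.theta for r in records])
        label = rule.label() if rule.kind != "none" else "None: theta"
        validity_for(theta, label)

    sim_df = pd.DataFrame(sim_rows)
    val_df = pd.DataFrame(
        {
            "rule": [v.rule_label for v in val_rows],
            "criterion": [v.criterion for v in val_rows],
            "statistic": [v.statistic for v in val_rows],
            "estimate": [v.estimate for v in val_rows],
            "ci_low": [v.ci_low for v in val_rows],
            "ci_high": [v.ci_high for v in val_rows],
        }
    )
    return sim_df, val_df
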