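"""Synthetic cohorts: latent traits, GRM responses, criterion variables.

The generator stands in for the unavailable patient sample.  Latent traits
are drawn from a (mixture-of-)normal distribution, item responses are
sampled from the graded response model given each respondent's true theta,
and each continuous criterion is a linear-in-theta Gaussian calibrated to a
target population correlation with theta.  Criteria are tied to the *true*
trait, so the observed validity of any estimate of theta is attenuated by
measurement error — exactly the behaviour the evaluation module quantifies.

The default cohort mirrors the study population: n = 3,597 outpatients, 46%
with a depression diagnosis, a diagnosed/undiagnosed latent separation
calibrated so the true-trait AUC is 0.81 while the marginal trait variance
stays 1, and criteria named after the two companion MASQ scales (anxious
arousal r = 0.46, general distress r = 0.74).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .grm import _cum_matrix
from .item_bank import ItemBank, load_masq_ad_bank

__all__ = [
    "Group",
    "CohortSpec",
    "SyntheticCohort",
    "generate_cohort",
    "default_paper_cohort",
    "inject_local_dependence",
    "inject_dif",
    "reverse_item",
]


@dataclass(frozen=True)
class Group:
    """One mixture component of the latent-trait distribution."""

    label: str
    weight: float
    theta_mean: float
    theta_sd: float

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"group {self.label}: weight must be > 0")
        if self.theta_sd <= 0:
            raise ValueError(f"group {self.label}: theta_sd must be > 0")


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n: int
    bank: ItemBank
    groups: tuple[Group, ...] = (Group("all", 1.0, 0.0, 1.0),)
    criteria: tuple[tuple[str, float], ...] = ()  # (name, population r with theta)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        w = sum(g.weight for g in self.groups)
        if abs(w - 1.0) > 1e-9:
            raise ValueError(f"group weights must sum to 1, got {w}")
        for name, rho in self.criteria:
            if abs(rho) > 1.0:
                raise ValueError(f"criterion {name}: |rho| must be <= 1")

    @property
    def theta_mean(self) -> float:
        return sum(g.weight * g.theta_mean for g in self.groups)

    @property
    def theta_var(self) -> float:
        mu = self.theta_mean
        return sum(
            g.weight * (g.theta_sd**2 + (g.theta_mean - mu) ** 2) for g in self.groups
        )


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort; ``responses`` are reverse-keyed categories 0..K-1."""

    spec: CohortSpec
    theta_true: np.ndarray
    group_labels: np.ndarray
    responses: np.ndarray  # (n, m) int
    criteria: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def diagnosis(self) -> np.ndarray | None:
        """Binary indicator of the first group when the spec has two groups."""
        if len(self.spec.groups) < 2:
            return None
        return (self.group_labels == self.spec.groups[0].label).astype(int)

    def to_files(self, response_path: str | Path, meta_path: str | Path) -> None:
        """Responses as the calibration CSV dialect (1..K); truth separately.

        The truth file (theta, groups, criteria) is deliberately separate so
        a 'blind' pipeline can consume the responses alone.
        """
        df = pd.DataFrame(
            self.responses + 1, columns=[f"item{j}" for j in self.spec.bank.item_ids]
        )
        df.insert(0, "respondent_id", np.arange(len(df)))
        df.to_csv(response_path, index=False)
        meta = {
            "theta_true": self.theta_true.tolist(),
            "group_labels": self.group_labels.tolist(),
            "criteria": {c: self.criteria[c].tolist() for c in self.criteria.columns},
            "seed": self.spec.seed,
            "n": self.spec.n,
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh)


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Sample a cohort; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    weights = np.array([g.weight for g in spec.groups])
    idx = rng.choice(len(spec.groups), size=spec.n, p=weights)
    means = np.array([g.theta_mean for g in spec.groups])[idx]
    sds = np.array([g.theta_sd for g in spec.groups])[idx]
    theta = rng.normal(means, sds)
    labels = np.array([spec.groups[i].label for i in idx])

    bank = spec.bank
    # inverse-CDF sampling per item: X = #{k : u < P*(X>=k)}
    cum = _cum_matrix(bank.a_array, bank.b_array, theta)  # (n, m, K+1)
    u = rng.uniform(size=(spec.n, len(bank)))
    responses = (u[..., None] < cum[..., 1:-1]).sum(axis=-1).astype(int)

    sigma = np.sqrt(spec.theta_var)
    z = (theta - spec.theta_mean) / sigma
    crit = {}
    for name, rho in spec.criteria:
        noise = rng.normal(size=spec.n)
        crit[name] = rho * z + np.sqrt(max(0.0, 1.0 - rho**2)) * noise
    return SyntheticCohort(
        spec=spec,
        theta_true=theta,
        group_labels=labels,
        responses=responses,
        criteria=pd.DataFrame(crit),
    )


def _sample_item(item_a, item_b, theta, rng) -> np.ndarray:
    cum = _cum_matrix(np.array([item_a]), np.array([item_b]), np.asarray(theta))
    u = rng.uniform(size=(len(theta), 1))
    return (u < cum[:, 0, 1:-1]).sum(axis=-1).astype(int)


def inject_local_dependence(
    cohort: SyntheticCohort, item_pair: tuple[int, int], strength: float, seed: int
) -> np.ndarray:
    """Responses with a planted extra shared factor for one item pair.

    Both items are resampled with ``theta + strength * u`` where ``u`` is a
    shared standard-normal nuisance dimension — a controlled violation of
    local independence for validating the Q3/residual-correlation screens.
    Returns a modified copy of the response matrix.
    """
    rng = np.random.default_rng(seed)
    out = cohort.responses.copy()
    u = rng.normal(size=len(out))
    theta = cohort.theta_true + strength * u
    ids = cohort.spec.bank.item_ids
    for iid in item_pair:
        j = ids.index(iid)
        it = cohort.spec.bank[j]
        out[:, j] = _sample_item(it.a, np.array(it.b), theta, rng)
    return out


def inject_dif(
    cohort: SyntheticCohort, item_id: int, shift: float, group_label: str, seed: int
) -> np.ndarray:
    """Responses with one item's thresholds shifted by ``shift`` for a group.

    A positive shift makes the item uniformly harder to endorse for that
    group at equal theta — planted differential item functioning.  Returns a
    modified copy of the response matrix.
    """
    rng = np.random.default_rng(seed)
    out = cohort.responses.copy()
    sel = cohort.group_labels == group_label
    if not sel.any():
        raise ValueError(f"no respondents in group {group_label!r}")
    j = cohort.spec.bank.item_ids.index(item_id)
    it = cohort.spec.bank[j]
    out[sel, j] = _sample_item(
        it.a, np.array(it.b) + shift, cohort.theta_true[sel], rng
    )
    return out


def reverse_item(responses: np.ndarray, column: int, n_categories: int = 5) -> np.ndarray:
    """Responses with one column's keying flipped (c -> K-1-c)."""
    out = np.asarray(responses).copy()
    out[:, column] = n_categories - 1 - out[:, column]
    return out


def default_paper_cohort(
    n: int = 3597,
    depressed_weight: float = 0.46,
    target_auc: float = 0.81,
    seed: int = 0,
    bank: ItemBank | None = None,
) -> CohortSpec:
    """The study-population recipe: two diagnostic groups, unit trait variance.

    The diagnosed/undiagnosed mean separation delta and the common
    within-group SD sigma jointly satisfy (i) marginal Var(theta) = 1 and
    (ii) the normal-theory all-pairs AUC Phi(delta / (sigma*sqrt(2))) equals
    ``target_auc``:

        sigma^2 = 1 / (1 + 2 w (1-w) z^2),   delta = sigma * sqrt(2) * z,

    with z = Phi^{-1}(auc).  Criteria: anxious arousal (AA, rho = 0.46) and
    general distress (GD, rho = 0.74) against the true trait.
    """
    if bank is None:
        bank = load_masq_ad_bank()
    w = depressed_weight
    z = norm.ppf(target_auc)
    sigma2 = 1.0 / (1.0 + 2.0 * w * (1.0 - w) * z**2)
    sigma = float(np.sqrt(sigma2))
    delta = sigma * np.sqrt(2.0) * z
    # zero marginal mean: mu_dep - mu_non = delta, w*mu_dep + (1-w)*mu_non = 0
    mu_dep = (1.0 - w) * delta
    mu_non = -w * delta
    return CohortSpec(
        n=n,
        bank=bank,
        groups=(
            Group("depressed", w, float(mu_dep), sigma),
            Group("non_depressed", 1.0 - w, float(mu_non), sigma),
        ),
        criteria=(("AA", 0.46), ("GD", 0.74)),
        seed=seed,
    )
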