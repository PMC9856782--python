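"""Group comparison statistics.

Two layers of inference:

* **Regional FD tests** — per-region two-sample t-tests (Student by default,
  Welch optional) across the 68 regions, Benjamini-Hochberg FDR adjustment,
  and Cohen's d (pooled-SD) effect sizes.

* **Permutation network test** — group-level network properties (modularity
  Q, mean participation P, mean within-module z) admit no per-subject
  variance, so group differences are assessed by exchangeability: each
  iteration draws ``subsample`` subjects from each cohort, pools the
  2 x subsample subjects, re-splits them at random into two pseudo-groups,
  builds each pseudo-group's thresholded network and records the metric
  difference.  The observed full-group difference is compared one-tailed
  (direction taken from the observed sign) against the null, the empirical
  95th percentile serves as the critical value, and p-values are FDR
  adjusted across the metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .atlas import CohortFDMatrix
from .metrics import participation_coefficient, within_module_degree_z
from .modules import detect_modules
from .network import build_network

__all__ = [
    "RegionalComparisonTable",
    "PermutationResult",
    "bh_fdr",
    "cohens_d",
    "regional_fd_tests",
    "network_metrics",
    "permutation_network_test",
    "NETWORK_METRICS",
]

NETWORK_METRICS = ("modularity_q", "mean_participation", "mean_z")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, monotone, clipped to [0,1]."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def cohens_d(sample_a, sample_b) -> float:
    """(mean_a - mean_b) / pooled SD, pooling variances with n-1 weights."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per sample")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
    if pooled == 0:
        raise ValueError("zero pooled SD: effect size undefined")
    return float((a.mean() - b.mean()) / pooled)


@dataclass
class RegionalComparisonTable:
    """Per-region group comparison shaped like a clinical FD table.

    Columns: region_id, abbreviation, lobe, mean/sd per group, t, p, q
    (BH-adjusted), effect size (Cohen's d, group A minus group B).
    """

    table: pd.DataFrame
    alpha: float = 0.05

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["q"] < self.alpha]


def regional_fd_tests(
    cohort_a: CohortFDMatrix,
    cohort_b: CohortFDMatrix,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> RegionalComparisonTable:
    """Two-tailed t per region, BH-FDR across regions, Cohen's d effect sizes."""
    if cohort_a.values.shape[1] != cohort_b.values.shape[1]:
        raise ValueError("cohorts cover different region sets")
    if not cohort_a.region_table == cohort_b.region_table:
        raise ValueError("cohorts use different region tables")
    if cohort_a.n_subjects < 2 or cohort_b.n_subjects < 2:
        raise ValueError("need >= 2 subjects per group")
    a, b = cohort_a.values, cohort_b.values
    table = cohort_a.region_table
    t, p = sps.ttest_ind(a, b, axis=0, equal_var=equal_var)
    identical = a.std(axis=0) + b.std(axis=0) == 0
    d = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        # a cohort compared with itself is a legitimate null case: d = t = 0
        d[j] = 0.0 if identical[j] else cohens_d(a[:, j], b[:, j])
    t = np.where(identical, 0.0, t)
    p = np.where(identical, 1.0, p)
    q = bh_fdr(p)
    df = pd.DataFrame(
        {
            "region_id": np.arange(1, a.shape[1] + 1),
            "abbreviation": table.abbreviations,
            "lobe": table.lobes,
            f"mean_{cohort_a.group_label}": a.mean(axis=0),
            f"sd_{cohort_a.group_label}": a.std(axis=0, ddof=1),
            f"mean_{cohort_b.group_label}": b.mean(axis=0),
            f"sd_{cohort_b.group_label}": b.std(axis=0, ddof=1),
            "t": t,
            "p": p,
            "q": q,
            "effect_size": d,
        }
    )
    return RegionalComparisonTable(table=df, alpha=alpha)


def network_metrics(
    cohort: CohortFDMatrix | np.ndarray,
    threshold_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, float]:
    """Q, mean P and mean Z of one cohort's thresholded covariance network."""
    net = build_network(
        cohort if isinstance(cohort, CohortFDMatrix) else CohortFDMatrix(cohort),
        fraction=threshold_fraction,
    )
    part = detect_modules(net, seed=seed)
    return {
        "modularity_q": part.q,
        "mean_participation": float(participation_coefficient(net, part).mean()),
        "mean_z": float(within_module_degree_z(net, part).mean()),
    }


@dataclass
class PermutationResult:
    """Null distributions and decisions of the permutation network test."""

    observed_a: dict[str, float]
    observed_b: dict[str, float]
    observed_diff: dict[str, float]
    null: dict[str, np.ndarray]
    critical: dict[str, float]
    p: dict[str, float]
    q: dict[str, float]
    n_perm: int
    subsample: int
    seed: int
    alpha: float = 0.05
    significant: dict[str, bool] = field(init=False)

    def __post_init__(self):
        for metric, dist in self.null.items():
            if len(dist) != self.n_perm:
                raise ValueError(f"null for {metric} has length {len(dist)} != n_perm")
        self.significant = {m: self.q[m] < self.alpha for m in self.q}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for m in self.observed_a:
            rows.append(
                {
                    "metric": m,
                    "observed_a": self.observed_a[m],
                    "observed_b": self.observed_b[m],
                    "observed_diff": self.observed_diff[m],
                    "critical_95": self.critical[m],
                    "p": self.p[m],
                    "q": self.q[m],
                    "significant": self.significant[m],
                }
            )
        return pd.DataFrame(rows).set_index("metric")


def permutation_network_test(
    cohort_a: CohortFDMatrix,
    cohort_b: CohortFDMatrix,
    n_perm: int = 1000,
    subsample: int = 10,
    seed: int = 0,
    threshold_fraction: float = 0.2,
    alpha: float = 0.05,
) -> PermutationResult:
    """Pool-and-resplit permutation test of group network properties.

    Deterministic given ``seed``: the subject draws, the pseudo-group splits
    and the community-detection sweeps all derive from it.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    na, nb = cohort_a.n_subjects, cohort_b.n_subjects
    if subsample > na or subsample > nb:
        raise ValueError(
            f"subsample {subsample} exceeds a cohort size ({na}, {nb})"
        )
    ss = np.random.SeedSequence(seed)
    louvain_seed = int(ss.generate_state(1)[0] % (2**31))
    rng = np.random.default_rng(ss.spawn(1)[0])

    observed_a = network_metrics(cohort_a, threshold_fraction, seed=louvain_seed)
    observed_b = network_metrics(cohort_b, threshold_fraction, seed=louvain_seed)
    observed_diff = {m: observed_a[m] - observed_b[m] for m in NETWORK_METRICS}

    null = {m: np.empty(n_perm) for m in NETWORK_METRICS}
    for it in range(n_perm):
        take_a = rng.choice(na, size=subsample, replace=False)
        take_b = rng.choice(nb, size=subsample, replace=False)
        pool = np.vstack([cohort_a.values[take_a], cohort_b.values[take_b]])
        split = rng.permutation(2 * subsample)
        pseudo_a = pool[split[:subsample]]
        pseudo_b = pool[split[subsample:]]
        ma = network_metrics(pseudo_a, threshold_fraction, seed=louvain_seed)
        mb = network_metrics(pseudo_b, threshold_fraction, seed=louvain_seed)
        for m in NETWORK_METRICS:
            null[m][it] = ma[m] - mb[m]

    critical, p = {}, {}
    for m in NETWORK_METRICS:
        direction = 1.0 if observed_diff[m] >= 0 else -1.0
        signed_null = direction * null[m]
        critical[m] = float(np.percentile(signed_null, 95.0)) * direction
        exceed = int((signed_null >= direction * observed_diff[m]).sum())
        p[m] = (1 + exceed) / (n_perm + 1)
    q_vals = bh_fdr([p[m] for m in NETWORK_METRICS])
    q = {m: float(qv) for m, qv in zip(NETWORK_METRICS, q_vals)}
    return PermutationResult(
        observed_a=observed_a,
        observed_b=observed_b,
        observed_diff=observed_diff,
        null=null,
        critical=critical,
        p=p,
        q=q,
        n_perm=n_perm,
        subsample=subsample,
        seed=seed,
        alpha=alpha,
    )
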