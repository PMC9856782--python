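"""Model/results interface over the pipeline.

Two fitting objects in the statsmodels idiom:

* :class:`CovarianceNetworkModel` — one cohort's FD matrix in, and ``fit()``
  returns a :class:`CovarianceNetworkResults` carrying the correlation
  matrix, the thresholded network, the detected module partition, per-node
  metrics and the lobe-level connectivity report, with a ``summary()``.

* :class:`GroupComparisonModel` — two cohorts in; ``fit()`` runs the full
  contrast: each group's network results, the per-region t/FDR/effect-size
  table, lobe connectivity ratios, link counts and (optionally) the
  permutation test of Q / mean P / mean Z.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from .atlas import CohortFDMatrix, RegionTable, load_region_table
from .metrics import (
    LobeConnectivityReport,
    NodeMetrics,
    connectivity_ratio,
    lobe_connectivity,
    node_metrics,
)
from .modules import ModulePartition, detect_modules
from .network import (
    CovarianceNetwork,
    correlation_matrix,
    lobe_correlation_rates,
    proportional_threshold,
)
from .stats import (
    PermutationResult,
    RegionalComparisonTable,
    permutation_network_test,
    regional_fd_tests,
)

__all__ = [
    "CovarianceNetworkModel",
    "CovarianceNetworkResults",
    "GroupComparisonModel",
    "GroupComparisonResults",
]


class CovarianceNetworkModel:
    """Structural covariance network model for one cohort.

    Parameters
    ----------
    cohort : CohortFDMatrix
        Subjects x 68-region fractal dimension values.
    threshold_fraction : float
        Proportion of the strongest positive region pairs to retain (0.2).
    method : str
        Inter-regional correlation estimator, "pearson" or "spearman".
    intra_mode : str
        Headline intra-lobular reading, "weight" or "literal".
    seed : int
        Seed for the module-detection sweep order.
    """

    def __init__(
        self,
        cohort: CohortFDMatrix,
        threshold_fraction: float = 0.2,
        method: str = "pearson",
        intra_mode: str = "weight",
        seed: int = 0,
    ):
        self.cohort = cohort
        self.threshold_fraction = threshold_fraction
        self.method = method
        self.intra_mode = intra_mode
        self.seed = seed

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_label: str = "group",
        region_table: RegionTable | None = None,
        **kwargs,
    ) -> "CovarianceNetworkModel":
        """Build from a subjects x regions DataFrame (columns in table order)."""
        table = region_table or load_region_table()
        cohort = CohortFDMatrix(
            values=df.to_numpy(float),
            group_label=group_label,
            subject_ids=[str(s) for s in df.index],
            region_table=table,
        )
        return cls(cohort, **kwargs)

    def fit(self) -> "CovarianceNetworkResults":
        corr = correlation_matrix(self.cohort, method=self.method)
        net = proportional_threshold(
            corr,
            fraction=self.threshold_fraction,
            region_table=self.cohort.region_table,
        )
        part = detect_modules(net, seed=self.seed)
        return CovarianceNetworkResults(
            model=self,
            correlation=corr,
            network=net,
            partition=part,
            nodes=node_metrics(net, part),
            lobes=lobe_connectivity(
                net, self.cohort.region_table, mode=self.intra_mode
            ),
            lobe_correlation=lobe_correlation_rates(
                corr, self.cohort.region_table
            ),
        )


@dataclass
class CovarianceNetworkResults:
    """Fitted covariance network for one group."""

    model: CovarianceNetworkModel
    correlation: np.ndarray
    network: CovarianceNetwork
    partition: ModulePartition
    nodes: NodeMetrics
    lobes: LobeConnectivityReport
    lobe_correlation: dict[str, float]

    @property
    def group_label(self) -> str:
        return self.model.cohort.group_label

    def module_listing(self) -> pd.DataFrame:
        """Regions grouped by module, largest module first."""
        df = self.partition.to_dataframe(self.model.cohort.region_table)
        df["lobe"] = self.model.cohort.region_table.lobes
        df["hemisphere"] = self.model.cohort.region_table.hemispheres
        return df.sort_values(["module_id", "region_id"]).reset_index(drop=True)

    def summary(self) -> str:
        buf = StringIO()
        c = self.model.cohort
        print(f"Structural covariance network — group '{self.group_label}'", file=buf)
        print(
            f"  subjects: {c.n_subjects}   regions: {c.values.shape[1]}   "
            f"threshold: {self.model.threshold_fraction} "
            f"({self.network.n_edges_retained} edges)",
            file=buf,
        )
        print(
            f"  modules: {self.partition.n_modules} "
            f"(sizes {self.partition.module_sizes})   "
            f"Q = {self.partition.q:.4f}",
            file=buf,
        )
        print(
            f"  mean retained weight: {self.network.mean_retained_weight():.4f}",
            file=buf,
        )
        print("\nLobe connectivity (lobes as modules):", file=buf)
        print(self.lobes.table.round(4).to_string(), file=buf)
        return buf.getvalue()


class GroupComparisonModel:
    """Two-group contrast of regional FD and network properties."""

    def __init__(
        self,
        cohort_a: CohortFDMatrix,
        cohort_b: CohortFDMatrix,
        threshold_fraction: float = 0.2,
        method: str = "pearson",
        intra_mode: str = "weight",
        equal_var: bool = True,
        n_perm: int = 1000,
        subsample: int = 10,
        alpha: float = 0.05,
        seed: int = 0,
    ):
        self.cohort_a = cohort_a
        self.cohort_b = cohort_b
        self.threshold_fraction = threshold_fraction
        self.method = method
        self.intra_mode = intra_mode
        self.equal_var = equal_var
        self.n_perm = n_perm
        self.subsample = subsample
        self.alpha = alpha
        self.seed = seed

    def fit(self, permutation: bool = True) -> "GroupComparisonResults":
        common = dict(
            threshold_fraction=self.threshold_fraction,
            method=self.method,
            intra_mode=self.intra_mode,
            seed=self.seed,
        )
        res_a = CovarianceNetworkModel(self.cohort_a, **common).fit()
        res_b = CovarianceNetworkModel(self.cohort_b, **common).fit()
        regional = regional_fd_tests(
            self.cohort_a, self.cohort_b, equal_var=self.equal_var, alpha=self.alpha
        )
        perm = None
        if permutation:
            perm = permutation_network_test(
                self.cohort_a,
                self.cohort_b,
                n_perm=self.n_perm,
                subsample=self.subsample,
                seed=self.seed,
                threshold_fraction=self.threshold_fraction,
                alpha=self.alpha,
            )
        return GroupComparisonResults(
            model=self,
            results_a=res_a,
            results_b=res_b,
            regional=regional,
            ratios=connectivity_ratio(res_a.lobes, res_b.lobes),
            permutation=perm,
        )


@dataclass
class GroupComparisonResults:
    """Full two-group comparison output."""

    model: GroupComparisonModel
    results_a: CovarianceNetworkResults
    results_b: CovarianceNetworkResults
    regional: RegionalComparisonTable
    ratios: pd.DataFrame
    permutation: PermutationResult | None = None

    def summary(self) -> str:
        buf = StringIO()
        la, lb = self.results_a.group_label, self.results_b.group_label
        print(f"Group comparison: '{la}' vs '{lb}'", file=buf)
        sig = self.regional.significant()
        print(
            f"\nRegional FD: {len(sig)} of {len(self.regional.table)} regions "
            f"with q < {self.regional.alpha}",
            file=buf,
        )
        if len(sig):
            cols = ["abbreviation", "lobe", "t", "p", "q", "effect_size"]
            print(sig[cols].round(4).to_string(index=False), file=buf)
        print(
            f"\nModules: {la} {self.results_a.partition.n_modules} "
            f"(Q={self.results_a.partition.q:.4f})  "
            f"{lb} {self.results_b.partition.n_modules} "
            f"(Q={self.results_b.partition.q:.4f})",
            file=buf,
        )
        print(f"\nLobe connectivity ratios ({lb}/{la}, %):", file=buf)
        print(self.ratios.round(1).to_string(), file=buf)
        if self.permutation is not None:
            print(
                f"\nPermutation test ({self.permutation.n_perm} iterations, "
                f"subsample {self.permutation.subsample}):",
                file=buf,
            )
            print(self.permutation.to_frame().round(4).to_string(), file=buf)
        return buf.getvalue()
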