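"""Structural covariance network construction.

A group's network has one node per cortical region; the edge weight between
two regions is the across-subject Pearson correlation of their fractal
dimension values.  The dense 68x68 correlation matrix is then proportionally
thresholded: the strongest 20% of the 2278 unique region pairs are retained
(strictly positive values only), everything else — weaker edges, negative
correlations, and the diagonal — is set to zero.

Both a weighted view (retained correlation coefficients, used by the
modularity quality function) and a binary adjacency view (used by the
link-count metrics) are always carried.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .atlas import LOBES, CohortFDMatrix, RegionTable, load_region_table

__all__ = [
    "CovarianceNetwork",
    "correlation_matrix",
    "proportional_threshold",
    "build_network",
    "lobe_correlation_rates",
]

DEFAULT_THRESHOLD_FRACTION = 0.2


@dataclass
class CovarianceNetwork:
    """A proportionally thresholded covariance network.

    ``weights`` holds the retained correlation coefficients (zero elsewhere,
    zero diagonal); ``adjacency`` is the matching 0/1 mask.
    """

    weights: np.ndarray
    threshold_fraction: float
    region_table: RegionTable | None = None
    adjacency: np.ndarray = field(init=False)
    n_edges_retained: int = field(init=False)

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if not np.allclose(w, w.T):
            raise ValueError("weight matrix must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("diagonal must be zero")
        if np.any(w < 0):
            raise ValueError("retained weights must be positive")
        self.weights = w
        self.adjacency = (w > 0).astype(np.int8)
        self.n_edges_retained = int(self.adjacency.sum()) // 2

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def degree(self) -> np.ndarray:
        """Binary degree per node."""
        return self.adjacency.sum(axis=1).astype(int)

    def strength(self) -> np.ndarray:
        """Weighted degree per node (sum of retained correlation weights)."""
        return self.weights.sum(axis=1)

    def total_weight(self) -> float:
        """Sum of all matrix entries = 2m of the modularity quality function."""
        return float(self.weights.sum())

    def mean_retained_weight(self) -> float:
        if self.n_edges_retained == 0:
            return 0.0
        return float(self.weights.sum() / (2 * self.n_edges_retained))

    def edge_list(self) -> pd.DataFrame:
        rows, cols = np.nonzero(np.triu(self.weights, 1))
        names = (
            self.region_table.abbreviations
            if self.region_table is not None
            else [str(i + 1) for i in range(self.n_nodes)]
        )
        return pd.DataFrame(
            {
                "region_a": [names[i] for i in rows],
                "region_b": [names[j] for j in cols],
                "weight": self.weights[rows, cols],
            }
        )

    def save(self, prefix: str | Path) -> None:
        """Write <prefix>_weights.csv, <prefix>_edges.csv and a JSON sidecar."""
        prefix = Path(prefix)
        names = (
            self.region_table.abbreviations
            if self.region_table is not None
            else [str(i + 1) for i in range(self.n_nodes)]
        )
        pd.DataFrame(self.weights, index=names, columns=names).to_csv(
            f"{prefix}_weights.csv"
        )
        self.edge_list().to_csv(f"{prefix}_edges.csv", index=False)
        meta = {
            "threshold_fraction": self.threshold_fraction,
            "n_edges_retained": self.n_edges_retained,
            "n_nodes": self.n_nodes,
        }
        Path(f"{prefix}_meta.json").write_text(json.dumps(meta, indent=2))


def correlation_matrix(
    cohort: CohortFDMatrix | np.ndarray, method: str = "pearson"
) -> np.ndarray:
    """Inter-regional correlation of FD values across subjects.

    Pearson product-moment by default ("spearman" is available as a rank
    alternative).  Requires >= 3 subjects and nonzero variance in every
    region; a zero-variance region is named in the error.
    """
    values = cohort.values if isinstance(cohort, CohortFDMatrix) else np.asarray(cohort)
    if values.ndim != 2:
        raise ValueError("cohort values must be a 2D subjects x regions array")
    if values.shape[0] < 3:
        raise ValueError(f"need >= 3 subjects, got {values.shape[0]}")
    sds = values.std(axis=0)
    dead = np.flatnonzero(sds == 0)
    if dead.size:
        names = dead + 1
        if isinstance(cohort, CohortFDMatrix):
            names = [cohort.region_table.abbreviations[i] for i in dead]
        raise ValueError(f"zero-variance region(s): {list(names)}")
    if method == "pearson":
        corr = np.corrcoef(values, rowvar=False)
    elif method == "spearman":
        from scipy.stats import spearmanr

        corr, _ = spearmanr(values)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    corr = np.asarray(corr, dtype=float)
    np.fill_diagonal(corr, 1.0)
    return np.clip((corr + corr.T) / 2, -1.0, 1.0)


def proportional_threshold(
    matrix: np.ndarray,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    region_table: RegionTable | None = None,
) -> CovarianceNetwork:
    """Keep the strongest ``fraction`` of unique off-diagonal pairs.

    The quota is floor(fraction * n_pairs); only strictly positive values are
    eligible, so fewer edges are retained when positives run out.  Ties at
    the cutoff break by value descending, then (row, col) lexicographic.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValueError("input matrix must be square")
    if not np.allclose(matrix, matrix.T):
        raise ValueError("input matrix must be symmetric")
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    n = matrix.shape[0]
    rows, cols = np.triu_indices(n, k=1)
    vals = matrix[rows, cols]
    quota = int(np.floor(fraction * len(vals)))
    order = np.lexsort((cols, rows, -vals))  # value desc, then row, then col
    order = order[vals[order] > 0][:quota]
    weights = np.zeros_like(matrix)
    weights[rows[order], cols[order]] = vals[order]
    weights += weights.T
    return CovarianceNetwork(
        weights=weights, threshold_fraction=fraction, region_table=region_table
    )


def build_network(
    cohort: CohortFDMatrix,
    fraction: float = DEFAULT_THRESHOLD_FRACTION,
    method: str = "pearson",
) -> CovarianceNetwork:
    """correlation_matrix + proportional_threshold in one step."""
    return proportional_threshold(
        correlation_matrix(cohort, method=method),
        fraction=fraction,
        region_table=cohort.region_table,
    )


def lobe_correlation_rates(
    matrix: np.ndarray,
    region_table: RegionTable | None = None,
    network: CovarianceNetwork | None = None,
) -> dict[str, float]:
    """Mean within-lobe correlation per lobe.

    Computed on the dense pre-threshold correlation matrix by default;
    passing ``network`` instead averages over the *retained* within-lobe
    edges of the thresholded graph.
    """
    table = region_table or load_region_table()
    out = {}
    for lobe in LOBES:
        idx = table.lobe_indices(lobe)
        if network is not None:
            sub_w = network.weights[np.ix_(idx, idx)]
            sub_a = network.adjacency[np.ix_(idx, idx)]
            out[lobe] = float(sub_w.sum() / sub_a.sum()) if sub_a.sum() else 0.0
        else:
            sub = np.asarray(matrix)[np.ix_(idx, idx)]
            iu = np.triu_indices(len(idx), k=1)
            out[lobe] = float(sub[iu].mean())
    return out
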