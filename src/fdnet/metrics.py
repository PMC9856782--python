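"""Node- and lobe-level connectivity metrics.

Two classic roles-in-modules quantities, both evaluated on the binary
adjacency (edges are counted, not weighted):

* within-module degree z-score  Z_i = (K_i - mean K) / sd K, where K_i is
  node i's degree inside its own module and mean/sd are taken over that
  module's nodes (population sd, no n-1 correction; sd = 0 gives Z_i = 0);
* participation coefficient  P_i = 1 - sum_c (K_ci / K_i)^2, where K_ci is
  the number of node i's links landing in module c and K_i its total degree
  (K_i = 0 gives P_i = 0).  P_i is 0 when every link stays inside the node's
  own module and approaches 1 - 1/n_modules under uniform spread.

For lobe-level reporting the four anatomical lobes play the role of modules:
inter-lobular connectivity of a lobe is the mean P_i over its nodes, and
intra-lobular connectivity is reported in two modes — the literal mean Z_i
(identically 0 over a full module whenever sd > 0) and the mean retained
edge weight among within-lobe edges (the headline mode).  Link counts per
lobe split within-lobe edges into left/left, right/right and bilateral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import LOBES, RegionTable
from .modules import ModulePartition
from .network import CovarianceNetwork

__all__ = [
    "NodeMetrics",
    "LobeConnectivityReport",
    "within_module_degree_z",
    "participation_coefficient",
    "node_metrics",
    "lobe_connectivity",
    "link_counts",
    "connectivity_ratio",
]


def _labels_of(partition: ModulePartition | np.ndarray, n_nodes: int) -> np.ndarray:
    labels = (
        partition.assignment
        if isinstance(partition, ModulePartition)
        else np.asarray(partition, dtype=int)
    )
    if labels.shape != (n_nodes,):
        raise ValueError(f"partition covers {labels.size} nodes, network has {n_nodes}")
    return labels


def within_module_degree_z(
    network: CovarianceNetwork, partition: ModulePartition | np.ndarray
) -> np.ndarray:
    """Z_i per node on the binary adjacency restricted to each node's module."""
    labels = _labels_of(partition, network.n_nodes)
    adj = network.adjacency
    z = np.zeros(network.n_nodes)
    for module in np.unique(labels):
        mask = labels == module
        k_in = adj[np.ix_(mask, mask)].sum(axis=1).astype(float)
        sd = k_in.std()  # population sd
        if sd > 0:
            z[mask] = (k_in - k_in.mean()) / sd
    return z


def participation_coefficient(
    network: CovarianceNetwork, partition: ModulePartition | np.ndarray
) -> np.ndarray:
    """P_i per node from binary degrees; isolated nodes get P_i = 0."""
    labels = _labels_of(partition, network.n_nodes)
    adj = network.adjacency
    k_total = adj.sum(axis=1).astype(float)
    p = np.zeros(network.n_nodes)
    connected = k_total > 0
    frac_sq = np.zeros(network.n_nodes)
    for module in np.unique(labels):
        k_to_module = adj[:, labels == module].sum(axis=1).astype(float)
        frac_sq[connected] += (k_to_module[connected] / k_total[connected]) ** 2
    p[connected] = 1.0 - frac_sq[connected]
    return p


@dataclass
class NodeMetrics:
    """Per-node degree K_i, within-module z-score Z_i, participation P_i."""

    degree: np.ndarray
    z: np.ndarray
    p: np.ndarray

    def to_dataframe(self, region_table: RegionTable | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": np.arange(1, len(self.degree) + 1),
                "degree": self.degree,
                "z_within_module": self.z,
                "participation": self.p,
            }
        )
        if region_table is not None:
            df.insert(1, "abbreviation", region_table.abbreviations)
        return df


def node_metrics(
    network: CovarianceNetwork, partition: ModulePartition | np.ndarray
) -> NodeMetrics:
    return NodeMetrics(
        degree=network.degree(),
        z=within_module_degree_z(network, partition),
        p=participation_coefficient(network, partition),
    )


@dataclass
class LobeConnectivityReport:
    """Per-lobe connectivity summary (lobes as modules).

    ``table`` has one row per lobe with columns: intra (headline mode),
    intra_mean_z, intra_mean_weight, inter, links_L, links_R, links_B.
    """

    table: pd.DataFrame
    mode: str

    def lobe(self, name: str) -> pd.Series:
        return self.table.loc[name]


def link_counts(
    network: CovarianceNetwork, region_table: RegionTable
) -> pd.DataFrame:
    """For each lobe: within-lobe edges split by hemisphere (L, R, bilateral)."""
    hemi = region_table.hemispheres
    rows, cols = np.nonzero(np.triu(network.adjacency, 1))
    lobes = region_table.lobes
    out = []
    for lobe in LOBES:
        in_lobe = (lobes[rows] == lobe) & (lobes[cols] == lobe)
        h1, h2 = hemi[rows[in_lobe]], hemi[cols[in_lobe]]
        out.append(
            {
                "lobe": lobe,
                "links_L": int(((h1 == "L") & (h2 == "L")).sum()),
                "links_R": int(((h1 == "R") & (h2 == "R")).sum()),
                "links_B": int((h1 != h2).sum()),
            }
        )
    return pd.DataFrame(out).set_index("lobe")


def lobe_connectivity(
    network: CovarianceNetwork,
    region_table: RegionTable,
    mode: str = "weight",
) -> LobeConnectivityReport:
    """Intra-/inter-lobular connectivity with the 4 lobes as the partition.

    ``mode`` selects the headline intra-lobular reading: "weight" (mean
    retained within-lobe edge weight) or "literal" (mean within-lobe Z_i,
    identically ~0 whenever a lobe's degree sd is positive).  Both readings
    are always present in the table.
    """
    if mode not in ("weight", "literal"):
        raise ValueError(f"unknown intra-lobular mode {mode!r}")
    labels = region_table.lobe_partition()
    z = within_module_degree_z(network, labels)
    p = participation_coefficient(network, labels)
    counts = link_counts(network, region_table)
    rows = []
    for lobe in LOBES:
        idx = region_table.lobe_indices(lobe)
        sub_w = network.weights[np.ix_(idx, idx)]
        sub_a = network.adjacency[np.ix_(idx, idx)]
        mean_weight = float(sub_w.sum() / sub_a.sum()) if sub_a.sum() else 0.0
        mean_z = float(z[idx].mean())
        rows.append(
            {
                "lobe": lobe,
                "intra": mean_weight if mode == "weight" else mean_z,
                "intra_mean_z": mean_z,
                "intra_mean_weight": mean_weight,
                "inter": float(p[idx].mean()),
                "links_L": int(counts.loc[lobe, "links_L"]),
                "links_R": int(counts.loc[lobe, "links_R"]),
                "links_B": int(counts.loc[lobe, "links_B"]),
            }
        )
    return LobeConnectivityReport(table=pd.DataFrame(rows).set_index("lobe"), mode=mode)


def connectivity_ratio(
    report_a: LobeConnectivityReport, report_b: LobeConnectivityReport
) -> pd.DataFrame:
    """Per-lobe percentage ratios 100 * (group B / group A) of intra and inter."""
    if list(report_a.table.index) != list(report_b.table.index):
        raise ValueError("reports cover different lobes")
    out = {}
    for col in ("intra", "inter"):
        denom = report_a.table[col]
        if (denom == 0).any():
            bad = list(denom.index[denom == 0])
            raise ValueError(f"zero reference {col} connectivity in lobe(s) {bad}")
        out[f"{col}_ratio_pct"] = 100.0 * report_b.table[col] / denom
    return pd.DataFrame(out)
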