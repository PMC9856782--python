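"""Modularity and module detection on covariance networks.

Modularity of a partition on the weighted retained matrix A is Newman's

    Q = 1/(2m) * sum_ij [ A_ij - k_i k_j / (2m) ] * delta(c_i, c_j)

with k_i the weighted degree (sum of retained correlation coefficients at
node i) and 2m the total weight.  ``detect_modules`` maximizes Q with greedy
multi-level (Louvain) optimization, deterministic for a given seed; the
returned partition is relabeled so module 1 is the largest, module 2 the
second largest, and so on.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import CovarianceNetwork

__all__ = [
    "ModulePartition",
    "modularity",
    "detect_modules",
    "brute_force_modules",
]


@dataclass
class ModulePartition:
    """Node -> module assignment with its modularity Q on the source network.

    ``assignment`` holds 1-based module ids, contiguous, ordered so that
    module sizes are descending (ties broken by smallest member node).
    """

    assignment: np.ndarray
    q: float

    def __post_init__(self):
        a = np.asarray(self.assignment, dtype=int)
        if a.ndim != 1 or a.size == 0:
            raise ValueError("assignment must be a non-empty 1D array")
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(1, len(ids) + 1)):
            raise ValueError("module ids must be contiguous from 1")
        sizes = np.bincount(a)[1:]
        if np.any(np.diff(sizes) > 0):
            raise ValueError("modules must be ordered by size descending")
        self.assignment = a

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max())

    @property
    def module_sizes(self) -> list[int]:
        return np.bincount(self.assignment)[1:].tolist()

    def members(self, module_id: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == module_id)

    def to_dataframe(self, region_table=None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "region_id": np.arange(1, len(self.assignment) + 1),
                "module_id": self.assignment,
            }
        )
        if region_table is not None:
            df.insert(1, "abbreviation", region_table.abbreviations)
        return df


def _canonical_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel arbitrary module labels 1..k, sizes descending, ties by first member."""
    raw = np.asarray(raw)
    uniq = np.unique(raw)
    sizes = {u: int((raw == u).sum()) for u in uniq}
    first = {u: int(np.flatnonzero(raw == u)[0]) for u in uniq}
    order = sorted(uniq, key=lambda u: (-sizes[u], first[u]))
    mapping = {u: i + 1 for i, u in enumerate(order)}
    return np.array([mapping[u] for u in raw], dtype=int)


def make_partition(
    labels: np.ndarray, network: CovarianceNetwork
) -> ModulePartition:
    """Canonicalize raw labels and evaluate their modularity on the network."""
    labels = _canonical_labels(labels)
    part = ModulePartition(assignment=labels, q=0.0)
    part.q = modularity(network, part)
    return part


def modularity(
    network: CovarianceNetwork, partition: ModulePartition | np.ndarray
) -> float:
    """Newman modularity of a partition on the weighted retained matrix."""
    labels = (
        partition.assignment
        if isinstance(partition, ModulePartition)
        else np.asarray(partition, dtype=int)
    )
    if labels.shape != (network.n_nodes,):
        raise ValueError(
            f"partition covers {labels.size} nodes, network has {network.n_nodes}"
        )
    w = network.weights
    two_m = w.sum()
    if two_m == 0:
        raise ValueError("empty network: modularity undefined (2m = 0)")
    k = w.sum(axis=1)
    q = 0.0
    for module in np.unique(labels):
        mask = labels == module
        q += w[np.ix_(mask, mask)].sum() - k[mask].sum() ** 2 / two_m
    return float(q / two_m)


def detect_modules(network: CovarianceNetwork, seed: int = 0) -> ModulePartition:
    """Greedy multi-level (Louvain) Q maximization, deterministic given seed.

    Falls back to the single-module partition in the degenerate case where
    the optimizer returns a partition below the Q = 0 baseline.
    """
    if network.n_edges_retained == 0:
        raise ValueError("cannot detect modules on a network with no edges")
    graph = nx.from_numpy_array(network.weights)
    communities = nx.community.louvain_communities(
        graph, weight="weight", seed=int(seed)
    )
    labels = np.empty(network.n_nodes, dtype=int)
    for m, nodes in enumerate(communities, start=1):
        labels[list(nodes)] = m
    part = make_partition(labels, network)
    if part.q < 0.0:
        part = make_partition(np.ones(network.n_nodes, dtype=int), network)
    return part


def _set_partitions(n: int):
    """All set partitions of range(n) as label arrays (restricted growth strings)."""
    labels = np.zeros(n, dtype=int)

    def rec(i: int, k: int):
        if i == n:
            yield labels.copy()
            return
        for c in range(k + 1):
            labels[i] = c
            yield from rec(i + 1, max(k, c + 1))

    yield from rec(1, 1) if n > 1 else iter([labels.copy()])


def brute_force_modules(
    network: CovarianceNetwork, max_nodes: int = 10
) -> ModulePartition:
    """Exact maximum-Q partition by enumerating all set partitions.

    A test oracle: Bell(10) = 115975 partitions is the guard limit.  The
    first maximizer in canonical (restricted-growth) enumeration order is
    returned, which makes ties deterministic.
    """
    n = network.n_nodes
    if n > max_nodes:
        raise ValueError(f"{n} nodes exceeds brute-force guard {max_nodes}")
    if n == 1:
        # single node: the only partition; Q taken as 0 (no edges to score)
        return ModulePartition(assignment=np.array([1]), q=0.0)
    if network.n_edges_retained == 0:
        raise ValueError("cannot detect modules on a network with no edges")
    best_q, best = -np.inf, None
    for labels in _set_partitions(n):
        q = modularity(network, labels + 1)
        if q > best_q + 1e-15:
            best_q, best = q, labels + 1
    return make_partition(best, network)
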