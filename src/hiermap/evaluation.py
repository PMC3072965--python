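"""Partition comparison (normalized mutual information) and hierarchy summaries.

Partitions are compared through their contingency table: with n_x nodes in
module x of partition X, n_y in module y of Y, and n_xy jointly in both,

    H(X) = -sum_x (n_x/n) log2(n_x/n)
    I(X;Y) = sum_xy (n_xy/n) log2( n * n_xy / (n_x * n_y) )
    NMI(X,Y) = 2 I(X;Y) / (H(X) + H(Y))

(the Danon normalization), ranging from 0 for independent partitions to 1
for identical ones.  Two identical trivial one-module partitions score 1 by
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .codelength import HierarchicalPartition, plogp
from .flow import FlowField
from .network_io import NetworkValidationError


@dataclass
class PartitionComparison:
    """Contingency-table comparison of two flat partitions of the same nodes."""

    n: int
    counts: np.ndarray  # n_xy contingency matrix
    entropy_x: float
    entropy_y: float
    mutual_information: float
    nmi: float


def compare_partitions(part_x: Sequence[int], part_y: Sequence[int]) -> PartitionComparison:
    x = np.asarray(part_x, dtype=np.int64)
    y = np.asarray(part_y, dtype=np.int64)
    if x.shape != y.shape or x.ndim != 1 or len(x) == 0:
        raise NetworkValidationError("partitions must cover the same nonempty node set")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    n = len(x)
    kx, ky = xi.max() + 1, yi.max() + 1
    counts = np.zeros((kx, ky))
    np.add.at(counts, (xi, yi), 1.0)
    px = counts.sum(axis=1) / n
    py = counts.sum(axis=0) / n
    pxy = counts / n
    hx = float(-plogp(px).sum())
    hy = float(-plogp(py).sum())
    mask = pxy > 0
    mi = float((pxy[mask] * np.log2(pxy[mask] / np.outer(px, py)[mask])).sum())
    mi = max(mi, 0.0)
    if hx + hy == 0.0:
        nmi = 1.0  # two one-module partitions are identical
    else:
        nmi = 2.0 * mi / (hx + hy)
    return PartitionComparison(n, counts, hx, hy, mi, min(max(nmi, 0.0), 1.0))


def normalized_mutual_information(part_x: Sequence[int], part_y: Sequence[int]) -> float:
    """NMI of two flat partitions, in [0, 1]."""
    return compare_partitions(part_x, part_y).nmi


def level_slices(partition: HierarchicalPartition) -> tuple[list[int], list[int]]:
    """(top-level, finest-level) flat memberships of a hierarchy.

    The finest slice maps each node to its deepest containing module, so
    branches of different depth each contribute their own finest level.  On
    a depth-2 tree both slices coincide.
    """
    return partition.top_membership(), partition.finest_membership()


@dataclass
class HierarchyStatistics:
    """Summary of a multilevel partition."""

    n_modules: int  # internal vertices below the root, all levels
    n_large_modules: int  # modules holding more than 1% of all nodes
    average_depth: float  # per-node mean leaf depth (2.0 for flat partitions)
    average_finest_size: float  # per-node mean size of the node's finest module
    compression_gain_percent: float


def hierarchy_statistics(
    partition: HierarchicalPartition,
    flow: FlowField | None = None,
    two_level_bits: float | None = None,
    multilevel_bits: float | None = None,
) -> HierarchyStatistics:
    n = partition.n_nodes
    modules = [v for v in partition.vertices() if not v.is_leaf and v.path != ()]
    sizes = {v.path: len(v.leaf_ids()) for v in modules}
    n_large = sum(1 for s in sizes.values() if s > 0.01 * n)
    depths = partition.leaf_depths()
    avg_depth = sum(depths.values()) / n
    finest = partition.finest_membership()
    counts = np.bincount(np.asarray(finest))
    avg_finest = float(counts[np.asarray(finest)].mean())
    if two_level_bits is not None and multilevel_bits is not None and two_level_bits > 0:
        gain = max(0.0, 100.0 * (two_level_bits - multilevel_bits) / two_level_bits)
    else:
        gain = 0.0
    return HierarchyStatistics(len(modules), n_large, avg_depth, avg_finest, gain)
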