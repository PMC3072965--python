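"""Deterministic nested-clique test networks.

The flagship instance is a 27-node undirected, unweighted network of nine
triangles: within each group of three triangles, single links join the
triangles in a ring, and the three groups are themselves joined in a ring.
Every ring link attaches to a node that carries no other ring link, so the
degree sequence is 24 nodes of degree 3 and 3 nodes of degree 2 (total
degree 78).  This placement is the unique symmetric one consistent with the
network's known description lengths (4.75 bits unpartitioned, 3.57 bits over
the nine triangles, 3.48 bits for the three-group hierarchy), which is what
makes it useful as a worked example.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codelength import HierarchicalPartition
from .network_io import Network, NetworkValidationError


@dataclass(frozen=True)
class NestedCliqueSpec:
    """(clique size, branching per level, number of levels) of a nested-clique
    family; sibling blocks at every level are ring-linked through distinct
    previously-unused nodes."""

    clique_size: int = 3
    branching: int = 3
    levels: int = 3

    def __post_init__(self) -> None:
        if self.clique_size < 2 or self.branching < 2 or self.levels < 1:
            raise NetworkValidationError("clique_size, branching >= 2 and levels >= 1 required")


def nested_clique_network(spec: NestedCliqueSpec) -> Network:
    """Deterministic nested-clique network; ``(3, 3, 3)`` gives the 27-node
    fixture."""
    edges: list[tuple[int, int, float]] = []
    counter = 0

    def build(level: int) -> list[int]:
        """Construct one block; returns its still-free attachment nodes."""
        nonlocal counter
        if level == 1:
            nodes = list(range(counter, counter + spec.clique_size))
            counter += spec.clique_size
            for i, u in enumerate(nodes):
                for v in nodes[i + 1 :]:
                    edges.append((u, v, 1.0))
            return nodes
        free_lists = [build(level - 1) for _ in range(spec.branching)]
        if any(len(f) < 2 for f in free_lists):
            raise NetworkValidationError(
                "not enough unused nodes for ring links at this depth"
            )
        outs = [f.pop(0) for f in free_lists]
        ins = [f.pop(0) for f in free_lists]
        b = spec.branching
        for i in range(b):
            edges.append((outs[i], ins[(i + 1) % b], 1.0))
        return [node for f in free_lists for node in f]

    build(spec.levels)
    return Network(counter, directed=False, links=edges)


def _reference_tree(spec: NestedCliqueSpec) -> HierarchicalPartition:
    def nest(level: int, start: int) -> tuple[list, int]:
        if level == 1:
            nodes = list(range(start, start + spec.clique_size))
            return nodes, start + spec.clique_size
        children = []
        for _ in range(spec.branching):
            sub, start = nest(level - 1, start)
            children.append(sub)
        return children, start

    nested, n = nest(spec.levels, 0)
    return HierarchicalPartition.from_nested(nested, n_nodes=n)


def triangle_hierarchy_network() -> tuple[Network, HierarchicalPartition]:
    """The 27-node worked example and its reference three-level partition
    (3 groups x 3 triangles x 3 nodes)."""
    spec = NestedCliqueSpec(3, 3, 3)
    return nested_clique_network(spec), _reference_tree(spec)


def nested_clique_reference_partition(spec: NestedCliqueSpec) -> HierarchicalPartition:
    """The built-in hierarchy of a nested-clique network as a partition tree."""
    return _reference_tree(spec)
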