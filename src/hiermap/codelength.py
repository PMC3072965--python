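"""The two-level and hierarchical map equations.

A partition of the network is scored by the per-step description length, in
bits, of a random walker whose movements are encoded with one codebook per
module plus hierarchically nested index codebooks.  Each codebook's
contribution is its Shannon entropy weighted by its rate of use:

* an index codebook at any level holds codewords for entering each child
  module (rate: flow into that child) and, below the root, for exiting to the
  coarser level (rate: flow out of the vertex);
* a finest-level module codebook holds codewords for visiting each member
  node (rate: node visit rate) plus the exit codeword.

Logarithms are base 2 and ``0 log 0 = 0``: modules with zero flow contribute
nothing.  Minimizing the total over all hierarchical partitions yields the
optimal number of levels, modules per level, and memberships.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

from .flow import FlowField
from .network_io import NetworkValidationError


def plogp(x):
    """x * log2(x), elementwise, with 0 log 0 = 0."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    mask = x > 0
    out[mask] = x[mask] * np.log2(x[mask])
    return out if out.ndim else float(out)


class TreeVertex:
    """A vertex of a partition tree: a leaf (one node) or a module."""

    __slots__ = ("children", "node", "flow", "enter", "exit", "path")

    def __init__(self, node: int | None = None, children: list["TreeVertex"] | None = None):
        self.node = node
        self.children = children if children is not None else []
        self.flow = 0.0
        self.enter = 0.0
        self.exit = 0.0
        self.path: tuple[int, ...] = ()

    @property
    def is_leaf(self) -> bool:
        return self.node is not None

    def leaf_ids(self) -> list[int]:
        if self.is_leaf:
            return [self.node]
        out: list[int] = []
        stack = [self]
        while stack:
            v = stack.pop()
            if v.is_leaf:
                out.append(v.node)
            else:
                stack.extend(v.children)
        return out


class HierarchicalPartition:
    """Rooted tree whose leaves are network nodes and internal vertices modules.

    Invariants enforced at construction: every node appears in exactly one
    leaf; no internal vertex has a single child that is itself internal
    (chains are collapsed); every leaf sits at depth >= 2 (the root's children
    are modules, never bare nodes), so the degenerate one-module partition is
    root -> module -> all leaves.
    """

    def __init__(self, root: TreeVertex, n_nodes: int | None = None):
        self.root = root
        self._normalize()
        leaves = sorted(self.root.leaf_ids())
        if n_nodes is None:
            n_nodes = len(leaves)
        if leaves != list(range(n_nodes)):
            raise NetworkValidationError(
                "partition leaves must be exactly the node ids 0..n-1, each once"
            )
        self.n_nodes = n_nodes
        self._index()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_flat(cls, membership: Sequence[int]) -> "HierarchicalPartition":
        """Depth-2 tree from a node -> module-id assignment."""
        mods: dict[int, TreeVertex] = {}
        for node, m in enumerate(membership):
            mods.setdefault(m, TreeVertex(children=[])).children.append(TreeVertex(node=node))
        root = TreeVertex(children=[mods[m] for m in sorted(mods)])
        return cls(root)

    @classmethod
    def from_nested(cls, nested: list, n_nodes: int | None = None) -> "HierarchicalPartition":
        """Build from nested lists of node ids, e.g. ``[[0, 1], [[2], [3, 4]]]``."""

        def build(item) -> TreeVertex:
            if isinstance(item, (int, np.integer)):
                return TreeVertex(node=int(item))
            return TreeVertex(children=[build(c) for c in item])

        return cls(TreeVertex(children=[build(c) for c in nested]), n_nodes=n_nodes)

    def _normalize(self) -> None:
        """Collapse single-internal-child chains; wrap bare root leaves."""

        def collapse(v: TreeVertex) -> TreeVertex:
            while len(v.children) == 1 and not v.children[0].is_leaf:
                v.children = v.children[0].children
            v.children = [c if c.is_leaf else collapse(c) for c in v.children]
            return v

        if self.root.is_leaf:
            self.root = TreeVertex(children=[TreeVertex(children=[self.root])])
        collapse(self.root)
        if any(c.is_leaf for c in self.root.children):
            # leaves must live at depth >= 2: wrap everything in one module
            self.root = TreeVertex(children=[TreeVertex(children=self.root.children)])

    def _index(self) -> None:
        def walk(v: TreeVertex, path: tuple[int, ...]) -> None:
            v.path = path
            for i, c in enumerate(v.children):
                walk(c, path + (i,))

        walk(self.root, ())

    # -- queries ------------------------------------------------------------

    def vertices(self) -> Iterator[TreeVertex]:
        stack = [self.root]
        while stack:
            v = stack.pop()
            yield v
            stack.extend(v.children)

    def leaf_ids(self) -> list[int]:
        return self.root.leaf_ids()

    def leaf_depths(self) -> dict[int, int]:
        out: dict[int, int] = {}

        def walk(v: TreeVertex, d: int) -> None:
            if v.is_leaf:
                out[v.node] = d
            for c in v.children:
                walk(c, d + 1)

        walk(self.root, 0)
        return out

    def max_depth(self) -> int:
        return max(self.leaf_depths().values())

    def top_membership(self) -> list[int]:
        """Node -> index of its top-level module."""
        out = [0] * self.n_nodes
        for i, mod in enumerate(self.root.children):
            for node in mod.leaf_ids():
                out[node] = i
        return out

    def finest_membership(self) -> list[int]:
        """Node -> id of its deepest containing module (the parent of its leaf)."""
        out = [0] * self.n_nodes
        counter = 0

        def walk(v: TreeVertex) -> None:
            nonlocal counter
            my_id = counter
            has_direct = any(c.is_leaf for c in v.children)
            if has_direct:
                counter += 1
            for c in v.children:
                if c.is_leaf:
                    out[c.node] = my_id
                else:
                    walk(c)

        # root never holds leaves directly (invariant), ids stay per-module
        for mod in self.root.children:
            walk(mod)
        return out

    # -- annotation ---------------------------------------------------------

    def annotate(self, flow: FlowField) -> "HierarchicalPartition":
        """Cache flow, enter and exit rates on every vertex (in place)."""
        if sorted(self.leaf_ids()) != list(range(flow.n_nodes)):
            raise NetworkValidationError("partition and flow field cover different node sets")
        parent: dict[tuple[int, ...], TreeVertex] = {}
        leaf_path: dict[int, tuple[int, ...]] = {}
        for v in self.vertices():
            v.flow = v.enter = v.exit = 0.0
            parent[v.path] = v
            if v.is_leaf:
                leaf_path[v.node] = v.path
        for node, rate in enumerate(flow.node_rate):
            p = leaf_path[node]
            for depth in range(len(p) + 1):
                parent[p[:depth]].flow += rate
        for (u, v), f in zip(flow.directed_links, flow.link_flow):
            if u == v:
                continue
            pu, pv = leaf_path[u], leaf_path[v]
            shared = 0
            for a, b in zip(pu, pv):
                if a != b:
                    break
                shared += 1
            # vertices strictly between the meet and each leaf change membership
            for depth in range(shared + 1, len(pu)):
                parent[pu[:depth]].exit += f
            for depth in range(shared + 1, len(pv)):
                parent[pv[:depth]].enter += f
        return self


@dataclass
class CodelengthReport:
    """Total description length plus its per-codebook breakdown."""

    total_bits: float
    index_bits: float  # all index/subindex codebook terms
    module_bits: float  # finest-level module codebook terms
    terms: dict[tuple[int, ...], tuple[float, float]] = field(default_factory=dict)
    # vertex path -> (codebook use rate, weighted entropy in bits)
    num_levels: int = 2
    num_modules_per_level: dict[int, int] = field(default_factory=dict)


def _vertex_term(vertex: TreeVertex, node_rate: np.ndarray, is_root: bool) -> tuple[float, float]:
    """(use rate, weighted entropy) of one vertex's codebook.

    The codebook covers: enter rates of child modules, visit rates of direct
    child leaves, and (below the root) the vertex's own exit rate.
    """
    comps = [c.enter for c in vertex.children if not c.is_leaf]
    comps += [node_rate[c.node] for c in vertex.children if c.is_leaf]
    if not is_root:
        comps.append(vertex.exit)
    comps_arr = np.asarray(comps, dtype=float)
    use = comps_arr.sum()
    if use <= 0:
        return 0.0, 0.0
    bits = plogp(use) - plogp(comps_arr).sum()
    return use, float(bits)


def hierarchical_codelength(flow: FlowField, partition: HierarchicalPartition) -> CodelengthReport:
    """Evaluate the hierarchical map equation for a partition tree.

    Reduces exactly to :func:`two_level_codelength` on depth-2 trees.
    """
    if not flow.corrected:
        raise NetworkValidationError("codelength expects a corrected FlowField")
    partition.annotate(flow)
    total = index_bits = module_bits = 0.0
    terms: dict[tuple[int, ...], tuple[float, float]] = {}
    per_level: dict[int, int] = {}
    for v in partition.vertices():
        if v.is_leaf:
            continue
        if v.path:
            per_level[len(v.path)] = per_level.get(len(v.path), 0) + 1
        use, bits = _vertex_term(v, flow.node_rate, is_root=(v.path == ()))
        terms[v.path] = (use, bits)
        total += bits
        if any(not c.is_leaf for c in v.children) or v.path == ():
            index_bits += bits
        else:
            module_bits += bits
    return CodelengthReport(
        total_bits=total,
        index_bits=index_bits,
        module_bits=module_bits,
        terms=terms,
        num_levels=partition.max_depth(),
        num_modules_per_level=per_level,
    )


def two_level_codelength(flow: FlowField, modules) -> CodelengthReport:
    """Evaluate the two-level map equation for a flat partition.

    ``modules`` may be a membership sequence (node -> module id) or a depth-2
    :class:`HierarchicalPartition`.  With a single module the index term
    vanishes and the result is the entropy of the node visit rates.
    """
    if isinstance(modules, HierarchicalPartition):
        partition = modules
        if partition.max_depth() != 2:
            raise NetworkValidationError("two_level_codelength requires a depth-2 partition")
    else:
        membership = list(modules)
        if len(membership) != flow.n_nodes:
            raise NetworkValidationError("membership does not cover the node set")
        partition = HierarchicalPartition.from_flat(membership)
    return hierarchical_codelength(flow, partition)


def flat_codelength_terms(
    flow: FlowField, membership: Sequence[int]
) -> tuple[float, float, float]:
    """(total, index term, sum of module terms) of a flat partition, vectorized.

    Independent fast path used by the search and the exhaustive oracles; it
    agrees with :func:`two_level_codelength` to machine precision.
    """
    member = np.asarray(membership, dtype=np.int64)
    n_mod = int(member.max()) + 1
    src = np.fromiter((u for u, _ in flow.directed_links), dtype=np.int64, count=len(flow.link_flow))
    dst = np.fromiter((v for _, v in flow.directed_links), dtype=np.int64, count=len(flow.link_flow))
    mu, mv = member[src], member[dst]
    cross = mu != mv
    exit_rate = np.zeros(n_mod)
    enter_rate = np.zeros(n_mod)
    np.add.at(exit_rate, mu[cross], flow.link_flow[cross])
    np.add.at(enter_rate, mv[cross], flow.link_flow[cross])
    mod_flow = np.zeros(n_mod)
    np.add.at(mod_flow, member, flow.node_rate)
    index = float(plogp(enter_rate.sum()) - plogp(enter_rate).sum())
    module = float(
        plogp(exit_rate + mod_flow).sum() - plogp(exit_rate).sum() - plogp(flow.node_rate).sum()
    )
    return index + module, index, module
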