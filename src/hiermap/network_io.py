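"""Read and write networks and hierarchical partitions in plain-text formats.

Networks are held in a small immutable-ish container with contiguous 0-based
node ids; edge lists and Pajek ``.net`` files are supported on input, Pajek and
the community-detection ``.tree`` convention (module path, flow, name) on
output.  Pajek ids are 1-based and converted at the boundary.
"""

from __future__ import annotations

import shlex
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class NetworkParseError(ValueError):
    """Malformed input file; message names the offending line."""


class NetworkValidationError(ValueError):
    """Structurally valid file describing an invalid network."""


@dataclass
class Network:
    """A weighted, optionally directed network.

    Node ids are contiguous integers ``0..n_nodes-1``.  For undirected
    networks each link is stored once; duplicate ``(source, target)`` pairs
    are aggregated by summing weights at construction time.  Self-loops are
    kept: the random-walk dynamics are well defined for them and they count
    as within-module steps.
    """

    n_nodes: int
    directed: bool
    links: list[tuple[int, int, float]]
    node_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_nodes <= 0:
            raise NetworkValidationError("network must have at least one node")
        if not self.node_names:
            self.node_names = [str(i) for i in range(self.n_nodes)]
        aggregated: dict[tuple[int, int], float] = {}
        for s, t, w in self.links:
            if not (0 <= s < self.n_nodes and 0 <= t < self.n_nodes):
                raise NetworkValidationError(f"link ({s}, {t}) out of node range")
            if w <= 0:
                raise NetworkValidationError(f"non-positive weight {w} on link ({s}, {t})")
            if not self.directed and s > t:
                s, t = t, s
            key = (s, t)
            aggregated[key] = aggregated.get(key, 0.0) + float(w)
        self.links = [(s, t, w) for (s, t), w in sorted(aggregated.items())]

    @property
    def n_links(self) -> int:
        return len(self.links)

    def total_weight(self) -> float:
        return sum(w for _, _, w in self.links)

    def out_strength(self) -> list[float]:
        s = [0.0] * self.n_nodes
        for u, v, w in self.links:
            s[u] += w
            if not self.directed and v != u:
                s[v] += w
        return s

    def strength(self) -> list[float]:
        """Total strength: in+out for directed, incident weight for undirected
        (self-loops count twice, matching the degree convention)."""
        s = [0.0] * self.n_nodes
        for u, v, w in self.links:
            s[u] += w
            s[v] += w
        return s

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        for u, v, w in self.links:
            g.add_edge(u, v, weight=w)
        return g

    @classmethod
    def from_networkx(cls, g, directed: bool | None = None) -> "Network":
        import networkx as nx

        directed = g.is_directed() if directed is None else directed
        nodes = list(g.nodes())
        idx = {n: i for i, n in enumerate(nodes)}
        links = [
            (idx[u], idx[v], float(d.get("weight", 1.0))) for u, v, d in g.edges(data=True)
        ]
        if g.number_of_nodes() == 0:
            raise NetworkValidationError("empty graph")
        return cls(len(nodes), directed, links, [str(n) for n in nodes])


def read_edge_list(path: str | Path, directed: bool = False) -> Network:
    """Parse a whitespace-delimited ``src dst [weight]`` file.

    Labels may be arbitrary strings; they are remapped to contiguous 0-based
    ids in first-appearance order and kept in ``node_names``.
    """
    ids: dict[str, int] = {}
    links: list[tuple[int, int, float]] = []

    def nid(label: str) -> int:
        if label not in ids:
            ids[label] = len(ids)
        return ids[label]

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (2, 3):
                raise NetworkParseError(f"line {lineno}: expected 'src dst [weight]', got {raw!r}")
            try:
                w = float(parts[2]) if len(parts) == 3 else 1.0
            except ValueError:
                raise NetworkParseError(f"line {lineno}: bad weight {parts[2]!r}") from None
            if w <= 0:
                raise NetworkValidationError(f"line {lineno}: non-positive weight {w}")
            links.append((nid(parts[0]), nid(parts[1]), w))
    if not links:
        raise NetworkValidationError(f"{path}: no links found")
    return Network(len(ids), directed, links, list(ids))


def write_edge_list(network: Network, path: str | Path, names: bool = False) -> None:
    with open(path, "w") as fh:
        for u, v, w in network.links:
            a, b = (network.node_names[u], network.node_names[v]) if names else (u, v)
            if w == 1.0:
                fh.write(f"{a} {b}\n")
            else:
                fh.write(f"{a} {b} {w:.12g}\n")


def read_pajek(path: str | Path) -> Network:
    """Parse a Pajek ``.net`` file (``*Vertices`` + ``*Edges`` or ``*Arcs``)."""
    n = None
    names: list[str] = []
    links: list[tuple[int, int, float]] = []
    directed = None
    section = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise NetworkParseError(f"line {lineno}: bad *Vertices header")
                n = int(parts[1])
                names = [str(i + 1) for i in range(n)]
                section = "vertices"
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                if n is None:
                    raise NetworkParseError(f"line {lineno}: link section before *Vertices")
                directed = low.startswith("*arcs")
                section = "links"
                continue
            if line.startswith("*"):
                section = "skip"
                continue
            if section == "vertices":
                parts = shlex.split(line)
                try:
                    vid = int(parts[0])
                except (ValueError, IndexError):
                    raise NetworkParseError(f"line {lineno}: bad vertex line {raw!r}") from None
                if not 1 <= vid <= n:
                    raise NetworkValidationError(f"line {lineno}: vertex id {vid} out of range 1..{n}")
                if len(parts) > 1:
                    names[vid - 1] = parts[1]
            elif section == "links":
                parts = line.split()
                if len(parts) < 2:
                    raise NetworkParseError(f"line {lineno}: bad link line {raw!r}")
                try:
                    u, v = int(parts[0]), int(parts[1])
                    w = float(parts[2]) if len(parts) > 2 else 1.0
                except ValueError:
                    raise NetworkParseError(f"line {lineno}: bad link line {raw!r}") from None
                if not (1 <= u <= n and 1 <= v <= n):
                    raise NetworkValidationError(f"line {lineno}: vertex id out of range 1..{n}")
                if w <= 0:
                    raise NetworkValidationError(f"line {lineno}: non-positive weight {w}")
                links.append((u - 1, v - 1, w))
    if n is None:
        raise NetworkParseError(f"{path}: missing *Vertices section")
    if directed is None:
        raise NetworkParseError(f"{path}: missing *Edges/*Arcs section")
    if not links:
        raise NetworkValidationError(f"{path}: no links found")
    return Network(n, directed, links, names)


def write_pajek(network: Network, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"*Vertices {network.n_nodes}\n")
        for i, name in enumerate(network.node_names):
            fh.write(f'{i + 1} "{name}"\n')
        fh.write("*Arcs\n" if network.directed else "*Edges\n")
        for u, v, w in network.links:
            fh.write(f"{u + 1} {v + 1} {w:.12g}\n")


def write_tree(partition, flow, path: str | Path, network: Network | None = None) -> None:
    """Write a hierarchical partition in ``.tree`` format.

    One line per leaf node: colon-separated 1-based module path (siblings
    ordered by descending aggregate flow), the node visit rate, and the
    quoted node name.  A header comment records the total codelength.
    """
    from .codelength import hierarchical_codelength

    n = len(flow.node_rate)
    leaves = sorted(partition.leaf_ids())
    if leaves != list(range(n)):
        raise NetworkValidationError("partition leaves do not match the flow field's node set")
    report = hierarchical_codelength(flow, partition)
    names = network.node_names if network is not None else [str(i) for i in range(n)]
    lines: list[tuple[tuple[int, ...], int]] = []

    def rate_of(sub) -> float:
        return sum(flow.node_rate[i] for i in sub.leaf_ids())

    def walk(vertex, prefix: tuple[int, ...]) -> None:
        modules = [c for c in vertex.children if not c.is_leaf]
        direct = [c.node for c in vertex.children if c.is_leaf]
        ordered = sorted(modules, key=lambda m: (-rate_of(m), min(m.leaf_ids())))
        for k, m in enumerate(ordered, start=1):
            walk(m, prefix + (k,))
        for k, node in enumerate(
            sorted(direct, key=lambda i: (-flow.node_rate[i], i)), start=len(ordered) + 1
        ):
            lines.append((prefix + (k,), node))

    walk(partition.root, ())
    with open(path, "w") as fh:
        fh.write(f"# Codelength {report.total_bits:.9f} bits\n")
        for pathtuple, node in sorted(lines):
            fh.write(
                f'{":".join(map(str, pathtuple))} {flow.node_rate[node]:.9g} "{names[node]}"\n'
            )


def read_tree(path: str | Path, network: Network):
    """Read a ``.tree`` file back into a :class:`HierarchicalPartition`.

    Nodes are matched by the quoted name against ``network.node_names``.
    """
    from .codelength import HierarchicalPartition

    name_to_id = {name: i for i, name in enumerate(network.node_names)}
    entries: list[tuple[tuple[int, ...], int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = shlex.split(line)
            if len(parts) < 3:
                raise NetworkParseError(f"line {lineno}: expected 'path flow name'")
            try:
                pathtuple = tuple(int(x) for x in parts[0].split(":"))
            except ValueError:
                raise NetworkParseError(f"line {lineno}: bad module path {parts[0]!r}") from None
            name = parts[2]
            if name not in name_to_id:
                raise NetworkValidationError(f"line {lineno}: unknown node name {name!r}")
            entries.append((pathtuple, name_to_id[name]))
    if not entries:
        raise NetworkValidationError(f"{path}: no tree lines found")

    def build(items: list[tuple[tuple[int, ...], int]]):
        # items whose path has length 1 are direct leaves of this vertex
        leaves = [node for p, node in items if len(p) == 1]
        groups: dict[int, list[tuple[tuple[int, ...], int]]] = {}
        for p, node in items:
            if len(p) > 1:
                groups.setdefault(p[0], []).append((p[1:], node))
        children: list = list(leaves)
        for key in sorted(groups):
            children.append(build(groups[key]))
        return children

    nested = build(entries)
    return HierarchicalPartition.from_nested(nested, n_nodes=network.n_nodes)


def read_flat_partition(path: str | Path, n_nodes: int) -> list[int]:
    """Read a two-column ``node_id module_id`` file into a membership list."""
    membership = [-1] * n_nodes
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 2:
                raise NetworkParseError(f"line {lineno}: expected 'node_id module_id'")
            try:
                node, mod = int(parts[0]), int(parts[1])
            except ValueError:
                raise NetworkParseError(f"line {lineno}: bad ids {raw!r}") from None
            if not 0 <= node < n_nodes:
                raise NetworkValidationError(f"line {lineno}: node id {node} out of range")
            membership[node] = mod
    if any(m < 0 for m in membership):
        raise NetworkValidationError(f"{path}: not every node assigned a module")
    return membership


def write_flat_partition(membership: Sequence[int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for node, mod in enumerate(membership):
            fh.write(f"{node} {mod}\n")
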