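"""Synthetic three-level hierarchical benchmark networks.

Nodes have power-law degrees; coarse modules and the fine modules nested
inside them have power-law sizes.  Each node's links are split into three
stub pools — a fraction mu1 to other coarse modules, mu2 to other fine
modules within its coarse module, and the rest inside its fine module — and
each pool is matched configuration-model style with swap rewiring to remove
self-links, duplicate links, and pool-constraint violations.  The generator
keeps bookkeeping of the realized mixing fractions so its fidelity to the
targets is testable.

The analytic feasibility region: a three-level hierarchy is well defined
when link density within fine modules exceeds the density within coarse
modules (between fine ones), which in turn exceeds the density between
coarse modules.  With n_f-node fine and n_c-node coarse modules in an
N-node network this chain gives, for every admissible size combination,

    mu1 < mu2 * (N - n_c) / (n_c - n_f)        (coarse level distinguishable)
    mu1 < 1 - mu2 * n_c / (n_c - n_f)          (fine level distinguishable)

evaluated at the extreme sizes that make each line tightest.  The first
line rises from the origin and the second falls from one, so the region is
a wedge that is thin near mu2 = 0 and closes as mu2 grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .network_io import Network, NetworkValidationError


@dataclass(frozen=True)
class BenchmarkSpec:
    """Parameters of a hierarchical benchmark network.

    Defaults are the standard test conditions: 10,000 nodes, mean degree 20,
    maximum degree 100, degree exponent -2, coarse module sizes 400-4,000 and
    fine module sizes 10-100, both with size exponent -1.
    """

    n_nodes: int = 10_000
    avg_degree: float = 20.0
    max_degree: int = 100
    degree_exponent: float = -2.0
    coarse_size_range: tuple[int, int] = (400, 4_000)
    coarse_size_exponent: float = -1.0
    fine_size_range: tuple[int, int] = (10, 100)
    fine_size_exponent: float = -1.0
    mu1: float = 0.1
    mu2: float = 0.2
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0 <= self.mu1 and 0 <= self.mu2 and self.mu1 + self.mu2 <= 1):
            raise NetworkValidationError("need mu1, mu2 >= 0 and mu1 + mu2 <= 1")
        if self.fine_size_range[0] > self.fine_size_range[1] or (
            self.coarse_size_range[0] > self.coarse_size_range[1]
        ):
            raise NetworkValidationError("size ranges must be (min, max) with min <= max")
        if self.fine_size_range[1] > self.coarse_size_range[1]:
            raise NetworkValidationError("fine sizes must nest inside coarse sizes")
        if self.n_nodes < self.coarse_size_range[1]:
            raise NetworkValidationError("n_nodes must be at least the largest coarse size")
        if not 1 <= self.avg_degree <= self.max_degree:
            raise NetworkValidationError("need 1 <= avg_degree <= max_degree")


def mu1_feasibility_lines(spec: BenchmarkSpec, mu2: float) -> tuple[float, float]:
    """The two worst-case mu1 bound lines at a given mu2.

    Returns ``(coarse_line, fine_line)``: the hierarchy is well defined for
    ``0 <= mu1 < min(coarse_line, fine_line)``.  The coarse line rises with
    mu2 (with no links between fine modules of the same coarse module the
    coarse level does not exist); the fine line falls (too much flow between
    fine modules blurs them).
    """
    nf_min, nf_max = spec.fine_size_range
    nc_min, nc_max = spec.coarse_size_range
    if nf_max >= nc_min:
        raise NetworkValidationError(
            "feasibility lines need non-overlapping size ranges (nf_max < nc_min)"
        )
    coarse_line = mu2 * (spec.n_nodes - nc_max) / (nc_max - nf_min)
    fine_line = 1.0 - mu2 * nc_min / (nc_min - nf_max)
    return coarse_line, fine_line


def feasible_mu1_bounds(spec: BenchmarkSpec, mu2: float) -> tuple[float, float]:
    """(lower, upper) bounds on mu1 for a well-defined three-level hierarchy.

    A ``(mu2, mu1)`` pair is well defined iff ``lower < mu1 < upper`` (with
    mu1 = 0, disconnected coarse modules, allowed as the boundary case).
    The upper bound can be negative, meaning no mu1 is admissible at that
    mu2.
    """
    coarse_line, fine_line = mu1_feasibility_lines(spec, mu2)
    return 0.0, min(coarse_line, fine_line)


def is_well_defined(spec: BenchmarkSpec, mu2: float, mu1: float) -> bool:
    lower, upper = feasible_mu1_bounds(spec, mu2)
    return lower <= mu1 < upper


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _powerlaw_sample(rng, exponent: float, lo: float, hi: float, size: int) -> np.ndarray:
    """Continuous truncated power law p(x) ~ x**exponent on [lo, hi]."""
    u = rng.random(size)
    if np.isclose(exponent, -1.0):
        return lo * (hi / lo) ** u
    a = exponent + 1.0
    return (lo**a + u * (hi**a - lo**a)) ** (1.0 / a)


def _powerlaw_mean(lo: float, hi: float, exponent: float) -> float:
    if np.isclose(exponent, -1.0):
        return (hi - lo) / np.log(hi / lo)
    if np.isclose(exponent, -2.0):
        return np.log(hi / lo) / (1.0 / lo - 1.0 / hi)
    a1, a2 = exponent + 1.0, exponent + 2.0
    return ((hi**a2 - lo**a2) / a2) / ((hi**a1 - lo**a1) / a1)


def _solve_min_degree(avg: float, kmax: int, exponent: float) -> float:
    """Lower cutoff of the degree law that yields the requested mean."""
    lo, hi = 1.0, float(kmax) - 1e-9
    f = lambda k: _powerlaw_mean(k, kmax, exponent) - avg
    if f(lo) > 0 or f(hi) < 0:
        raise NetworkValidationError(
            f"avg_degree {avg} unreachable with max_degree {kmax} and exponent {exponent}"
        )
    return float(brentq(f, lo, hi))


def _tile_sizes(rng, total: int, lo: int, hi: int, exponent: float, max_tries: int = 10_000):
    """Sample sizes from the truncated power law until they sum to ``total``."""
    hi = min(hi, total)
    if lo > total:
        raise NetworkValidationError(f"cannot tile {total} nodes with minimum size {lo}")
    for _ in range(max_tries):
        sizes: list[int] = []
        while sum(sizes) < total:
            sizes.append(int(round(_powerlaw_sample(rng, exponent, lo, hi, 1)[0])))
            sizes[-1] = min(max(sizes[-1], lo), hi)
        excess = sum(sizes) - total
        if excess == 0:
            return sizes
        if sizes[-1] - excess >= lo:
            sizes[-1] -= excess
            return sizes
        remainder = total - sum(sizes[:-1])
        if lo <= remainder <= hi:
            sizes[-1] = remainder
            return sizes
    raise NetworkValidationError(f"could not tile {total} nodes with sizes in [{lo}, {hi}]")


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


@dataclass
class BenchmarkNetwork:
    """A generated benchmark instance with its planted truth and bookkeeping."""

    network: Network
    coarse_membership: list[int]
    fine_membership: list[int]
    realized_mu1: float
    realized_mu2: float
    spec: BenchmarkSpec = field(repr=False, default=None)


def _match_pool(
    rng,
    stubs: np.ndarray,
    edge_set: set[tuple[int, int]],
    constraint,
    max_passes: int = 300,
) -> list[tuple[int, int]]:
    """Pair stubs uniformly; swap-rewire violations; drop what cannot be fixed."""
    if len(stubs) < 2:
        return []
    stubs = stubs.copy()
    rng.shuffle(stubs)
    if len(stubs) % 2:
        stubs = stubs[:-1]
    a = stubs[0::2].copy()
    b = stubs[1::2].copy()

    def violations() -> np.ndarray:
        seen: set[tuple[int, int]] = set()
        bad = np.zeros(len(a), dtype=bool)
        for i, (u, v) in enumerate(zip(a, b)):
            if u == v or not constraint(u, v):
                bad[i] = True
                continue
            key = (min(u, v), max(u, v))
            if key in edge_set or key in seen:
                bad[i] = True
            else:
                seen.add(key)
        return bad

    for _ in range(max_passes):
        bad = violations()
        idx = np.flatnonzero(bad)
        if len(idx) == 0:
            break
        partners = rng.integers(0, len(a), size=len(idx))
        for i, j in zip(idx, partners):
            b[i], b[j] = b[j], b[i]
    bad = violations()
    edges = []
    for i in np.flatnonzero(~bad):
        u, v = int(a[i]), int(b[i])
        key = (min(u, v), max(u, v))
        edge_set.add(key)
        edges.append(key)
    return edges


def _is_graphical(degrees: np.ndarray) -> bool:
    """Erdos-Gallai test for an even-sum degree sequence."""
    d = np.sort(degrees)[::-1]
    if d.sum() % 2 or (d < 0).any():
        return False
    n = len(d)
    cum = np.cumsum(d)
    for k in range(1, n + 1):
        rhs = k * (k - 1) + np.minimum(d[k:], k).sum()
        if cum[k - 1] > rhs:
            return False
    return True


def _dense_module_graph(rng, nodes: np.ndarray, degrees: np.ndarray) -> list[tuple[int, int]]:
    """Simple graph on ``nodes`` with the exact given degree sequence.

    Havel-Hakimi construction followed by degree-preserving double-edge
    swaps.  Small fine modules are often near-complete under realistic
    mixing, where random stub matching sheds many duplicate pairs; this
    route is lossless whenever the sequence is graphical.
    """
    order = np.argsort(-degrees, kind="stable")
    remaining = [[int(degrees[i]), int(nodes[i])] for i in order if degrees[i] > 0]
    edges: list[tuple[int, int]] = []
    while remaining:
        remaining.sort(key=lambda t: -t[0])
        d, u = remaining.pop(0)
        if d > len(remaining):
            break  # not graphical; leftover stubs are dropped by the caller
        for rec in remaining[:d]:
            rec[0] -= 1
            edges.append((min(u, rec[1]), max(u, rec[1])))
        remaining = [r for r in remaining if r[0] > 0]
    # randomize while preserving degrees
    m = len(edges)
    if m > 1:
        present = set(edges)
        pair_idx = rng.integers(0, m, size=(10 * m, 2))
        for i, j in pair_idx:
            if i == j:
                continue
            (a, b), (c, d) = edges[i], edges[j]
            if len({a, b, c, d}) < 4:
                continue
            e1 = (min(a, d), max(a, d))
            e2 = (min(c, b), max(c, b))
            if e1 in present or e2 in present:
                continue
            present.discard(edges[i])
            present.discard(edges[j])
            present.add(e1)
            present.add(e2)
            edges[i], edges[j] = e1, e2
    return edges


def generate_hierarchical_benchmark(spec: BenchmarkSpec) -> BenchmarkNetwork:
    """Generate a benchmark network with planted coarse and fine partitions.

    The fine partition always refines the coarse one; with mu1 = mu2 = 0 the
    network is a disjoint union of fine modules.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_nodes

    coarse_sizes = _tile_sizes(
        rng, n, *spec.coarse_size_range, spec.coarse_size_exponent
    )
    fine_sizes: list[int] = []
    fine_coarse: list[int] = []  # coarse module of each fine module
    for c, size in enumerate(coarse_sizes):
        lo, hi = spec.fine_size_range
        for s in _tile_sizes(rng, size, lo, min(hi, size), spec.fine_size_exponent):
            fine_sizes.append(s)
            fine_coarse.append(c)
    n_fine = len(fine_sizes)

    kmin = _solve_min_degree(spec.avg_degree, spec.max_degree, spec.degree_exponent)
    degrees = np.round(
        _powerlaw_sample(rng, spec.degree_exponent, kmin, spec.max_degree, n)
    ).astype(int)
    degrees = np.clip(degrees, 1, spec.max_degree)

    d_between = rng.binomial(degrees, spec.mu1)
    p_mid = spec.mu2 / (1.0 - spec.mu1) if spec.mu1 < 1 else 0.0
    d_mid = rng.binomial(degrees - d_between, p_mid)
    d_fine = degrees - d_between - d_mid

    # place nodes into fine modules, largest-fit for high within-fine degrees
    capacity = np.asarray(fine_sizes, dtype=int).copy()
    sizes_arr = np.asarray(fine_sizes, dtype=int)
    fine_of_node = -np.ones(n, dtype=int)
    order = np.argsort(-d_fine, kind="stable")
    for node in order:
        ok = (capacity > 0) & (sizes_arr - 1 >= d_fine[node])
        if not ok.any():
            ok = capacity > 0  # place anywhere; the within-fine degree is clamped below
        choices = np.flatnonzero(ok)
        m = int(choices[rng.integers(len(choices))])
        fine_of_node[node] = m
        capacity[m] -= 1
    coarse_of_node = np.asarray(fine_coarse)[fine_of_node]
    coarse_node_count = np.bincount(coarse_of_node, minlength=len(coarse_sizes))

    # clamp stub counts to what the module geometry can accommodate; spilled
    # stubs cascade to the next-coarser active pool (dropped if none: with
    # mu1 = mu2 = 0 the network must stay a union of fine modules)
    has_mid, has_between = spec.mu2 > 0, spec.mu1 > 0
    overfull = d_fine > sizes_arr[fine_of_node] - 1
    spill = np.where(overfull, d_fine - (sizes_arr[fine_of_node] - 1), 0)
    d_fine -= spill
    if has_mid:
        d_mid += spill
    elif has_between:
        d_between += spill
    mid_room = coarse_node_count[coarse_of_node] - sizes_arr[fine_of_node]
    spill = np.maximum(d_mid - mid_room, 0)
    d_mid -= spill
    if has_between:
        d_between += spill

    edge_set: set[tuple[int, int]] = set()
    fine_edges: list[tuple[int, int]] = []
    mid_edges: list[tuple[int, int]] = []
    between_edges: list[tuple[int, int]] = []

    for m in range(n_fine):
        nodes = np.flatnonzero(fine_of_node == m)
        local = d_fine[nodes].copy()
        # spill stubs to the next active pool until the sequence is graphical
        while not _is_graphical(local):
            i = int(np.argmax(local))
            local[i] -= 1
            if has_mid:
                d_mid[nodes[i]] += 1
            elif has_between:
                d_between[nodes[i]] += 1
        d_fine[nodes] = local
        new_edges = _dense_module_graph(rng, nodes, local)
        edge_set.update(new_edges)
        fine_edges += new_edges

    for c in range(len(coarse_sizes)):
        nodes = np.flatnonzero(coarse_of_node == c)
        stubs = np.repeat(nodes, d_mid[nodes])
        if len(stubs) % 2:
            v = int(stubs[rng.integers(len(stubs))])
            d_mid[v] -= 1
            if has_between:
                d_between[v] += 1
            stubs = np.repeat(nodes, d_mid[nodes])
        mid_edges += _match_pool(
            rng, stubs, edge_set, lambda u, v: fine_of_node[u] != fine_of_node[v]
        )

    stubs = np.repeat(np.arange(n), d_between)
    between_edges += _match_pool(
        rng, stubs, edge_set, lambda u, v: coarse_of_node[u] != coarse_of_node[v]
    )

    all_edges = fine_edges + mid_edges + between_edges
    if not all_edges:
        raise NetworkValidationError("benchmark generation produced no links")
    total = len(all_edges)
    network = Network(
        n, directed=False, links=[(u, v, 1.0) for u, v in sorted(all_edges)]
    )
    return BenchmarkNetwork(
        network=network,
        coarse_membership=list(coarse_of_node),
        fine_membership=list(fine_of_node),
        realized_mu1=len(between_edges) / total,
        realized_mu2=len(mid_edges) / total,
        spec=spec,
    )
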