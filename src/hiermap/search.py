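"""Stochastic recursive minimization of the hierarchical map equation.

The flat core follows the aggregation scheme of Blondel et al.: starting from
singleton modules, nodes are moved in random sequential order to the
neighboring module giving the largest codelength decrease, the move phase is
repeated until no move helps, the network is rebuilt with modules as nodes,
and the cycle repeats.  Two refinements break the core's irreversible
merges — moving recursively-derived submodules between modules, and freeing
single nodes — and are alternated while they improve the result.

The multilevel search wraps the flat core in a recursion that adds index
codebooks where they pay for themselves: within each module it tries to
split the module's interior (finer levels), and above each partition it
tries to cluster the module aggregate (coarser levels), keeping extra levels
only when they strictly shorten the total description.  Flow is computed
once on the full network; all nested searches operate on exact aggregates of
node visit rates and boundary flows.

All randomness flows from the configured seed; identical seed and
configuration yield identical trees.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log2
from typing import Sequence

import numpy as np

from .codelength import (
    CodelengthReport,
    HierarchicalPartition,
    hierarchical_codelength,
    plogp,
    two_level_codelength,
)
from .flow import DEFAULT_TELEPORT_RATE, FlowField, network_flow
from .network_io import Network


@dataclass
class SearchConfig:
    """Knobs of the stochastic search.

    ``n_restarts`` full restarts are run and the shortest description kept;
    accuracy improves with repetition, so use as many as time allows.
    ``improvement_threshold`` (bits) absorbs floating-point noise when
    deciding whether a move or an extra hierarchical level truly helps.
    """

    seed: int = 1
    n_restarts: int = 100
    teleport_rate: float = DEFAULT_TELEPORT_RATE
    max_refine_rounds: int = 20
    improvement_threshold: float = 1e-10
    max_depth: int = 20

    def __post_init__(self) -> None:
        if self.n_restarts < 1:
            raise ValueError("n_restarts must be >= 1")
        if self.improvement_threshold < 0:
            raise ValueError("improvement_threshold must be >= 0")


def _f(x: float) -> float:
    return x * log2(x) if x > 0 else 0.0


@dataclass
class _SubNetwork:
    """A (sub)network in flow coordinates.

    ``node_flow`` holds visit rates (or, in index-level aggregates, module
    enter rates); ``exit_extra``/``enter_extra`` hold each node's flow to and
    from outside the subnetwork, which counts toward module boundaries but is
    not movable.  Self-loop flow is dropped: it never crosses a boundary.
    """

    node_flow: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    weight: np.ndarray  # link flow per directed edge
    exit_extra: np.ndarray
    enter_extra: np.ndarray

    _adj: list | None = None

    @property
    def n(self) -> int:
        return len(self.node_flow)

    def adjacency(self) -> list[list[tuple[int, float, float]]]:
        """Per node: (neighbor, flow out to it, flow in from it)."""
        if self._adj is None:
            pair: dict[tuple[int, int], list[float]] = {}
            for u, v, w in zip(self.src, self.dst, self.weight):
                u, v, w = int(u), int(v), float(w)
                key = (u, v) if u < v else (v, u)
                rec = pair.setdefault(key, [0.0, 0.0])
                rec[0 if u < v else 1] += w
            adj: list[list[tuple[int, float, float]]] = [[] for _ in range(self.n)]
            for (a, b), (w_ab, w_ba) in pair.items():
                adj[a].append((b, w_ab, w_ba))
                adj[b].append((a, w_ba, w_ab))
            self._adj = adj
        return self._adj


def _root_subnetwork(flow: FlowField) -> _SubNetwork:
    links = flow.directed_links
    keep = [k for k, (u, v) in enumerate(links) if u != v]
    src = np.array([links[k][0] for k in keep], dtype=np.int64)
    dst = np.array([links[k][1] for k in keep], dtype=np.int64)
    w = np.asarray(flow.link_flow, dtype=float)[keep]
    n = flow.n_nodes
    return _SubNetwork(
        np.asarray(flow.node_rate, dtype=float), src, dst, w, np.zeros(n), np.zeros(n)
    )


def _module_stats(subnet: _SubNetwork, member: np.ndarray, n_mod: int):
    mod_flow = np.bincount(member, weights=subnet.node_flow, minlength=n_mod)
    exit_rate = np.bincount(member, weights=subnet.exit_extra, minlength=n_mod)
    enter_rate = np.bincount(member, weights=subnet.enter_extra, minlength=n_mod)
    if len(subnet.src):
        mu, mv = member[subnet.src], member[subnet.dst]
        cross = mu != mv
        exit_rate += np.bincount(mu[cross], weights=subnet.weight[cross], minlength=n_mod)
        enter_rate += np.bincount(mv[cross], weights=subnet.weight[cross], minlength=n_mod)
    return mod_flow, enter_rate, exit_rate


def _local_cost(subnet: _SubNetwork, ctx_exit: float, member: np.ndarray) -> float:
    """Exact cost of a flat partition of ``subnet`` in its parent context.

    Sum of the vertex's index codebook term (entries: submodule enters plus
    the fixed context exit) and every submodule codebook term.  At the root
    (``ctx_exit = 0``, no extras) this equals the two-level codelength.
    """
    member = np.asarray(member, dtype=np.int64)
    n_mod = int(member.max()) + 1 if len(member) else 0
    mod_flow, enter, exit_ = _module_stats(subnet, member, n_mod)
    index = _f(ctx_exit + enter.sum()) - _f(ctx_exit) - plogp(enter).sum()
    modules = (
        plogp(exit_ + mod_flow).sum() - plogp(exit_).sum() - plogp(subnet.node_flow).sum()
    )
    return float(index + modules)


def _move_phase(
    subnet: _SubNetwork,
    ctx_exit: float,
    member: np.ndarray,
    rng: np.random.Generator,
    threshold: float,
    max_sweeps: int = 100,
) -> bool:
    """Greedy sequential node moves until a full sweep changes nothing."""
    n = subnet.n
    adj = subnet.adjacency()
    p = subnet.node_flow
    xx, ee = subnet.exit_extra, subnet.enter_extra
    mod_flow, enter, exit_ = (a.copy() for a in _module_stats(subnet, member, n))
    s_enter = float(enter.sum())
    counts = np.bincount(member, minlength=n)
    empty_ids = [m for m in range(n - 1, -1, -1) if counts[m] == 0]
    moved_any = False
    for _ in range(max_sweeps):
        moved = False
        for alpha in rng.permutation(n):
            alpha = int(alpha)
            nbrs = adj[alpha]
            if not nbrs:
                continue
            a = int(member[alpha])
            flows: dict[int, list[float]] = {}
            outtot = xx[alpha]
            intot = ee[alpha]
            for j, w_out, w_in in nbrs:
                m = int(member[j])
                rec = flows.setdefault(m, [0.0, 0.0])
                rec[0] += w_out
                rec[1] += w_in
                outtot += w_out
                intot += w_in
            out_a, in_a = flows.get(a, (0.0, 0.0))
            exit_a_new = exit_[a] - (outtot - out_a) + in_a
            enter_a_new = enter[a] - (intot - in_a) + out_a
            flow_a_new = mod_flow[a] - p[alpha]
            base_a = (
                -(_f(enter_a_new) - _f(enter[a]))
                - (_f(exit_a_new) - _f(exit_[a]))
                + (_f(exit_a_new + flow_a_new) - _f(exit_[a] + mod_flow[a]))
            )
            best_delta = 0.0
            best_mod = a
            candidates = sorted(flows)
            if counts[a] > 1 and empty_ids:
                # allow escape into a fresh module; enables in-place splits
                candidates.append(int(empty_ids[-1]))
            for b in candidates:
                if b == a:
                    continue
                out_b, in_b = flows.get(b, (0.0, 0.0))
                exit_b_new = exit_[b] + (outtot - out_b) - in_b
                enter_b_new = enter[b] + (intot - in_b) - out_b
                flow_b_new = mod_flow[b] + p[alpha]
                d_s = (enter_a_new + enter_b_new) - (enter[a] + enter[b])
                delta = (
                    _f(ctx_exit + s_enter + d_s)
                    - _f(ctx_exit + s_enter)
                    + base_a
                    - (_f(enter_b_new) - _f(enter[b]))
                    - (_f(exit_b_new) - _f(exit_[b]))
                    + (_f(exit_b_new + flow_b_new) - _f(exit_[b] + mod_flow[b]))
                )
                if delta < best_delta - 1e-15:
                    best_delta = delta
                    best_mod = b
            if best_mod != a and best_delta < -threshold:
                b = best_mod
                out_b, in_b = flows.get(b, (0.0, 0.0))
                exit_[a], enter[a], mod_flow[a] = exit_a_new, enter_a_new, flow_a_new
                exit_[b] = exit_[b] + (outtot - out_b) - in_b
                enter[b] = enter[b] + (intot - in_b) - out_b
                mod_flow[b] += p[alpha]
                s_enter = float(enter.sum())
                member[alpha] = b
                counts[a] -= 1
                counts[b] += 1
                if counts[b] == 1 and empty_ids and empty_ids[-1] == b:
                    empty_ids.pop()
                if counts[a] == 0:
                    empty_ids.append(a)
                moved = True
                moved_any = True
        if not moved:
            break
    return moved_any


def _compress(member: np.ndarray) -> tuple[np.ndarray, int]:
    uniq, inv = np.unique(member, return_inverse=True)
    return inv.astype(np.int64), len(uniq)


def _aggregate(
    subnet: _SubNetwork, member: np.ndarray, n_mod: int, node_flow: np.ndarray
) -> _SubNetwork:
    """Rebuild with modules as nodes; ``node_flow`` chooses the semantics
    (summed visit rates for same-level Louvain, enter rates for index levels)."""
    if len(subnet.src):
        mu, mv = member[subnet.src], member[subnet.dst]
        cross = mu != mv
        mu, mv, w = mu[cross], mv[cross], subnet.weight[cross]
        key = mu * n_mod + mv
        uniq, inv = np.unique(key, return_inverse=True)
        agg_w = np.bincount(inv, weights=w)
        src = (uniq // n_mod).astype(np.int64)
        dst = (uniq % n_mod).astype(np.int64)
    else:
        src = dst = np.zeros(0, dtype=np.int64)
        agg_w = np.zeros(0)
    exit_extra = np.bincount(member, weights=subnet.exit_extra, minlength=n_mod)
    enter_extra = np.bincount(member, weights=subnet.enter_extra, minlength=n_mod)
    return _SubNetwork(node_flow, src, dst, agg_w, exit_extra, enter_extra)


def _core(
    subnet: _SubNetwork,
    ctx_exit: float,
    rng: np.random.Generator,
    threshold: float,
    init: np.ndarray | None = None,
) -> np.ndarray:
    """Louvain-style core: move phases alternating with network rebuilds."""
    level = subnet
    member = np.arange(level.n) if init is None else np.asarray(init, dtype=np.int64).copy()
    member, _ = _compress(member)
    global_member = member.copy()
    while True:
        _move_phase(level, ctx_exit, member, rng, threshold)
        member, n_mod = _compress(member)
        global_member = member[global_member] if level is not subnet else member.copy()
        if n_mod == level.n:
            break
        mod_flow = np.bincount(member, weights=level.node_flow, minlength=n_mod)
        level = _aggregate(level, member, n_mod, mod_flow)
        member = np.arange(level.n)
    return global_member


def _extract(
    subnet: _SubNetwork, nodes: np.ndarray, node_flow: np.ndarray | None = None
) -> _SubNetwork:
    """Subnetwork induced by ``nodes``; boundary flow moves into the extras."""
    n = subnet.n
    local = -np.ones(n, dtype=np.int64)
    local[nodes] = np.arange(len(nodes))
    inside_src = local[subnet.src] >= 0
    inside_dst = local[subnet.dst] >= 0
    keep = inside_src & inside_dst
    exit_extra = subnet.exit_extra[nodes].copy()
    enter_extra = subnet.enter_extra[nodes].copy()
    out_mask = inside_src & ~inside_dst
    in_mask = ~inside_src & inside_dst
    if out_mask.any():
        exit_extra += np.bincount(
            local[subnet.src[out_mask]], weights=subnet.weight[out_mask], minlength=len(nodes)
        )
    if in_mask.any():
        enter_extra += np.bincount(
            local[subnet.dst[in_mask]], weights=subnet.weight[in_mask], minlength=len(nodes)
        )
    flow = subnet.node_flow[nodes] if node_flow is None else node_flow
    return _SubNetwork(
        flow.copy(),
        local[subnet.src[keep]],
        local[subnet.dst[keep]],
        subnet.weight[keep].copy(),
        exit_extra,
        enter_extra,
    )


def _split_recursively(
    subnet: _SubNetwork, ctx_exit: float, rng, threshold: float, depth: int = 0
) -> np.ndarray:
    """Finest units reachable by recursively re-running the core inside modules."""
    member = _core(subnet, ctx_exit, rng, threshold)
    member, n_mod = _compress(member)
    if n_mod <= 1 or n_mod == subnet.n or depth >= 20:
        return member
    out = np.zeros(subnet.n, dtype=np.int64)
    offset = 0
    _, enter, exit_ = _module_stats(subnet, member, n_mod)
    for m in range(n_mod):
        nodes = np.flatnonzero(member == m)
        if len(nodes) == 1:
            out[nodes] = offset
            offset += 1
            continue
        sub = _extract(subnet, nodes)
        sub_units = _split_recursively(sub, float(exit_[m]), rng, threshold, depth + 1)
        out[nodes] = sub_units + offset
        offset += int(sub_units.max()) + 1
    return out


def _refine_submodules(
    subnet: _SubNetwork, ctx_exit: float, member: np.ndarray, rng, threshold: float
) -> np.ndarray:
    """Submodule movements: recursively split each module, then let the
    resulting submodules move freely between modules."""
    member = np.asarray(member, dtype=np.int64)
    member, n_mod = _compress(member)
    units = np.zeros(subnet.n, dtype=np.int64)
    unit_module: list[int] = []
    _, _, exit_ = _module_stats(subnet, member, n_mod)
    for m in range(n_mod):
        nodes = np.flatnonzero(member == m)
        sub = _extract(subnet, nodes)
        sub_units = (
            _split_recursively(sub, float(exit_[m]), rng, threshold)
            if len(nodes) > 1
            else np.zeros(1, dtype=np.int64)
        )
        units[nodes] = sub_units + len(unit_module)
        unit_module.extend([m] * (int(sub_units.max()) + 1))
    n_units = len(unit_module)
    mod_flow_units = np.bincount(units, weights=subnet.node_flow, minlength=n_units)
    agg = _aggregate(subnet, units, n_units, mod_flow_units)
    refined = _core(agg, ctx_exit, rng, threshold, init=np.asarray(unit_module))
    return refined[units]


def _refine_single_nodes(
    subnet: _SubNetwork, ctx_exit: float, member: np.ndarray, rng, threshold: float
) -> np.ndarray:
    """Single-node movements: re-run the core from the current partition with
    every node individually movable."""
    return _core(subnet, ctx_exit, rng, threshold, init=np.asarray(member, dtype=np.int64))


def _search_flat(
    subnet: _SubNetwork, ctx_exit: float, rng, config: SearchConfig
) -> tuple[np.ndarray, float]:
    member = _core(subnet, ctx_exit, rng, config.improvement_threshold)
    best = _local_cost(subnet, ctx_exit, member)
    for _ in range(config.max_refine_rounds):
        cand = _refine_submodules(subnet, ctx_exit, member, rng, config.improvement_threshold)
        cand = _refine_single_nodes(subnet, ctx_exit, cand, rng, config.improvement_threshold)
        cost = _local_cost(subnet, ctx_exit, cand)
        if cost < best - config.improvement_threshold:
            member, best = cand, cost
        else:
            break
    member, _ = _compress(member)
    return member, best


def _flat_module_cost(subnet: _SubNetwork, ctx_exit: float) -> float:
    """Cost of describing the subnetwork with a single codebook (no split)."""
    return float(
        _f(ctx_exit + subnet.node_flow.sum()) - _f(ctx_exit) - plogp(subnet.node_flow).sum()
    )


def _build_tree(
    subnet: _SubNetwork, ctx_exit: float, rng, config: SearchConfig, depth: int = 0
) -> tuple[list, float]:
    """Recursive structure search.

    Returns ``(children, cost)`` where ``children`` is the nested child list
    of this vertex over subnet-local node indices (ints are leaves, lists are
    module vertices) and ``cost`` the exact description-length contribution
    of everything at or below this vertex's codebook.
    """
    flat_children = list(range(subnet.n))
    flat_cost = _flat_module_cost(subnet, ctx_exit)
    if subnet.n == 1 or depth >= config.max_depth:
        return flat_children, flat_cost
    member, _ = _search_flat(subnet, ctx_exit, rng, config)
    n_mod = int(member.max()) + 1
    if n_mod <= 1 or n_mod == subnet.n:
        return flat_children, flat_cost
    _, enter, exit_ = _module_stats(subnet, member, n_mod)

    sub_structs: list[list] = []
    sub_cost = 0.0
    for m in range(n_mod):
        nodes = np.flatnonzero(member == m)
        sub = _extract(subnet, nodes)
        struct, cost = _build_tree(sub, float(exit_[m]), rng, config, depth + 1)
        sub_structs.append(_translate(struct, nodes))
        sub_cost += cost

    agg = _aggregate(subnet, member, n_mod, enter.copy())
    agg_struct, agg_cost = _build_tree(agg, ctx_exit, rng, config, depth + 1)

    split_cost = agg_cost + sub_cost
    if split_cost < flat_cost - config.improvement_threshold:
        return _substitute(agg_struct, sub_structs), split_cost
    return flat_children, flat_cost


def _translate(struct: list, mapping: np.ndarray) -> list:
    return [int(mapping[c]) if isinstance(c, (int, np.integer)) else _translate(c, mapping) for c in struct]


def _substitute(agg_struct: list, sub_structs: list[list]) -> list:
    out: list = []
    for item in agg_struct:
        if isinstance(item, (int, np.integer)):
            out.append(sub_structs[int(item)])  # module vertex with its children
        else:
            out.append(_substitute(item, sub_structs))
    return out


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def core_partition(flow: FlowField, network: Network, rng: np.random.Generator) -> list[int]:
    """One run of the Louvain-style core from singleton modules."""
    subnet = _root_subnetwork(flow)
    return list(_compress(_core(subnet, 0.0, rng, 1e-10))[0])


def refine_submodules(
    flow: FlowField, network: Network, partition: Sequence[int], rng: np.random.Generator
) -> list[int]:
    """Submodule-movement refinement of a flat partition (never worse)."""
    subnet = _root_subnetwork(flow)
    return list(
        _compress(_refine_submodules(subnet, 0.0, np.asarray(partition), rng, 1e-10))[0]
    )


def refine_single_nodes(
    flow: FlowField, network: Network, partition: Sequence[int], rng: np.random.Generator
) -> list[int]:
    """Single-node-movement refinement of a flat partition (never worse)."""
    subnet = _root_subnetwork(flow)
    return list(
        _compress(_refine_single_nodes(subnet, 0.0, np.asarray(partition), rng, 1e-10))[0]
    )


def _restart_rngs(config: SearchConfig) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.n_restarts)]


def multilevel_search(
    network: Network,
    config: SearchConfig | None = None,
    two_level: bool = False,
    flow: FlowField | None = None,
) -> tuple[HierarchicalPartition, CodelengthReport]:
    """Best-of-``n_restarts`` (hierarchical) partition of a network.

    With ``two_level=True`` the search is constrained to a single module
    level.  The returned report is an exact re-evaluation of the winning
    tree by the codelength module.
    """
    config = config or SearchConfig()
    if flow is None:
        flow = network_flow(network, config.teleport_rate)
    subnet = _root_subnetwork(flow)
    best: tuple[HierarchicalPartition, CodelengthReport] | None = None
    for rng in _restart_rngs(config):
        if two_level:
            member, _ = _search_flat(subnet, 0.0, rng, config)
            partition = HierarchicalPartition.from_flat(list(member))
            report = two_level_codelength(flow, partition)
        else:
            struct, _ = _build_tree(subnet, 0.0, rng, config)
            partition = HierarchicalPartition.from_nested(struct, n_nodes=network.n_nodes)
            report = hierarchical_codelength(flow, partition)
        if best is None or report.total_bits < best[1].total_bits - config.improvement_threshold:
            best = (partition, report)
    assert best is not None
    return best


def two_level_search(
    network: Network, config: SearchConfig | None = None, flow: FlowField | None = None
) -> tuple[HierarchicalPartition, CodelengthReport]:
    """Best flat (two-level) partition; convenience wrapper."""
    return multilevel_search(network, config, two_level=True, flow=flow)


def compression_gain(network: Network, config: SearchConfig | None = None) -> float:
    """Percentage reduction of the multilevel codelength over the best
    two-level codelength, floored at zero."""
    config = config or SearchConfig()
    flow = network_flow(network, config.teleport_rate)
    _, two = multilevel_search(network, config, two_level=True, flow=flow)
    _, multi = multilevel_search(network, config, two_level=False, flow=flow)
    if two.total_bits <= 0:
        return 0.0
    return max(0.0, 100.0 * (two.total_bits - multi.total_bits) / two.total_bits)


# ---------------------------------------------------------------------------
# exhaustive oracle (small networks)
# ---------------------------------------------------------------------------


def all_memberships(n: int) -> np.ndarray:
    """Every set partition of ``range(n)`` as a membership matrix."""

    def rec(prefix: list[int], nxt: int):
        if len(prefix) == n:
            yield list(prefix)
            return
        for m in range(nxt + 1):
            prefix.append(m)
            yield from rec(prefix, max(nxt, m + 1))
            prefix.pop()

    return np.array(list(rec([], 0)), dtype=np.int64)


def exhaustive_two_level_minimum(flow: FlowField) -> tuple[float, np.ndarray]:
    """Minimum two-level codelength over all set partitions (Bell search).

    Vectorized direct evaluation; practical up to ~10 nodes.  Used as the
    independent optimality oracle for the stochastic search.
    """
    n = flow.n_nodes
    members = all_memberships(n)
    pcount = members.shape[0]
    links = [(u, v, w) for (u, v), w in zip(flow.directed_links, flow.link_flow) if u != v]
    node_rate = np.asarray(flow.node_rate, dtype=float)
    const = -plogp(node_rate).sum()
    if links:
        src = np.array([u for u, _, _ in links])
        dst = np.array([v for _, v, _ in links])
        w = np.array([wt for _, _, wt in links])
        mu = members[:, src]
        mv = members[:, dst]
        cross = mu != mv
        rows = np.repeat(np.arange(pcount), len(links)).reshape(pcount, len(links))
        exit_rate = np.zeros((pcount, n))
        enter_rate = np.zeros((pcount, n))
        wc = np.where(cross, w, 0.0)
        np.add.at(exit_rate, (rows, mu), wc)
        np.add.at(enter_rate, (rows, mv), wc)
    else:
        exit_rate = enter_rate = np.zeros((pcount, n))
    mod_flow = np.zeros((pcount, n))
    rows_n = np.repeat(np.arange(pcount), n).reshape(pcount, n)
    np.add.at(mod_flow, (rows_n, members), np.broadcast_to(node_rate, (pcount, n)))
    totals = (
        plogp(enter_rate.sum(axis=1))
        - plogp(enter_rate).sum(axis=1)
        - plogp(exit_rate).sum(axis=1)
        + plogp(exit_rate + mod_flow).sum(axis=1)
        + const
    )
    k = int(np.argmin(totals))
    return float(totals[k]), members[k]
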