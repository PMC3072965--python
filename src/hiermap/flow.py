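"""Random-walk flow on a network.

The description length of a partition depends only on the walker's stationary
node visit rates and per-link traversal rates.  For undirected networks these
follow in closed form from node strengths.  For directed networks the visit
rates are the stationary distribution of a walk with uniform teleportation at
rate tau (dangling nodes teleport uniformly), computed by power iteration;
the teleportation steps are then excluded from the described dynamics: each
link carries flow  p_source * (1 - tau) * w_link / s_out(source)  (zero for
dangling sources), all link flows are renormalized to sum to one, and the
node visit rate is replaced by the node's total link inflow.  After this
correction in- and outflow of a node need no longer be equal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_io import Network, NetworkValidationError

DEFAULT_TELEPORT_RATE = 0.15


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach the requested tolerance."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"power iteration did not converge within {max_iter} iterations "
            f"(L1 residual {residual:.3e})"
        )
        self.residual = residual


@dataclass
class FlowField:
    """Visit rates and link flows of the walker on one network.

    ``link_flow[k]`` is the traversal rate of ``directed_links[k]``; for an
    undirected network every stored link appears once per direction.  ``raw``
    fields keep the ergodic (teleportation-inclusive) rates.
    """

    node_rate: np.ndarray
    directed_links: list[tuple[int, int]]
    link_flow: np.ndarray
    teleport_rate: float
    corrected: bool
    raw_node_rate: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return len(self.node_rate)


def _directed_link_view(network: Network) -> tuple[list[tuple[int, int]], np.ndarray]:
    """Expand the stored links into per-direction (u, v, weight) arrays."""
    links: list[tuple[int, int]] = []
    weights: list[float] = []
    for u, v, w in network.links:
        if not network.directed and u == v:
            # undirected self-loop counts twice in strength; keep flow consistent
            links.append((u, v))
            weights.append(2.0 * w)
            continue
        links.append((u, v))
        weights.append(w)
        if not network.directed and u != v:
            links.append((v, u))
            weights.append(w)
    return links, np.asarray(weights, dtype=float)


def ergodic_visit_rates(
    network: Network,
    teleport_rate: float = DEFAULT_TELEPORT_RATE,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> FlowField:
    """Stationary visit rates of the (teleporting) random walker.

    Undirected networks use the closed form rate = strength / total strength
    and ignore ``teleport_rate``.  Directed networks run power iteration from
    the uniform distribution until the L1 change drops below ``tol``.
    """
    if network.n_nodes == 0:
        raise NetworkValidationError("empty network")
    n = network.n_nodes
    links, weights = _directed_link_view(network)

    if not network.directed:
        strength = np.asarray(network.strength(), dtype=float)
        total = strength.sum()
        if total <= 0:
            raise NetworkValidationError("network has no links")
        rate = strength / total
        # per-direction flow of link (u,v) is w/(2W); both directions are stored
        # in `weights`, which therefore already sums to the total strength
        flow = weights / weights.sum()
        return FlowField(rate, links, flow, teleport_rate, corrected=False)

    if not 0 <= teleport_rate < 1:
        raise NetworkValidationError("teleport_rate must lie in [0, 1)")
    src = np.fromiter((u for u, _ in links), dtype=np.int64, count=len(links))
    dst = np.fromiter((v for _, v in links), dtype=np.int64, count=len(links))
    out_strength = np.zeros(n)
    np.add.at(out_strength, src, weights)
    dangling = out_strength == 0
    rel_weight = weights / np.where(out_strength[src] > 0, out_strength[src], 1.0)

    p = np.full(n, 1.0 / n)
    residual = np.inf
    for _ in range(max_iter):
        follow = (1.0 - teleport_rate) * p
        new = np.zeros(n)
        np.add.at(new, dst, follow[src] * rel_weight)
        # teleportation + dangling mass spreads uniformly
        new += (teleport_rate + (1.0 - teleport_rate) * p[dangling].sum()) / n
        residual = np.abs(new - p).sum()
        p = new
        if residual < tol:
            break
    else:
        raise ConvergenceError(residual, max_iter)
    p /= p.sum()
    link_flow = p[src] * (1.0 - teleport_rate) * rel_weight
    link_flow[dangling[src]] = 0.0
    return FlowField(p, links, link_flow, teleport_rate, corrected=False)


def exclude_teleportation(network: Network, raw: FlowField) -> FlowField:
    """Drop teleportation steps from the described dynamics (directed case).

    Link flows are renormalized to sum to one and node visit rates become the
    total link inflow of each node.  For undirected networks teleportation
    plays no role and the field is returned unchanged apart from the flag.
    """
    if abs(raw.node_rate.sum() - 1.0) > 1e-8:
        raise NetworkValidationError("raw flow field is not normalized")
    if not network.directed:
        return FlowField(
            raw.node_rate.copy(),
            raw.directed_links,
            raw.link_flow.copy(),
            raw.teleport_rate,
            corrected=True,
            raw_node_rate=raw.node_rate.copy(),
        )
    total = raw.link_flow.sum()
    if total <= 0:
        raise NetworkValidationError("no link flow to renormalize (all nodes dangling?)")
    flow = raw.link_flow / total
    n = raw.n_nodes
    dst = np.fromiter((v for _, v in raw.directed_links), dtype=np.int64, count=len(flow))
    rate = np.zeros(n)
    np.add.at(rate, dst, flow)
    return FlowField(
        rate, raw.directed_links, flow, raw.teleport_rate, corrected=True,
        raw_node_rate=raw.node_rate.copy(),
    )


def network_flow(
    network: Network,
    teleport_rate: float = DEFAULT_TELEPORT_RATE,
    tol: float = 1e-12,
    max_iter: int = 10_000,
) -> FlowField:
    """Convenience: ergodic rates followed by the teleportation correction."""
    return exclude_teleportation(
        network, ergodic_visit_rates(network, teleport_rate, tol, max_iter)
    )


def module_boundary_rates(flow: FlowField, partition) -> dict[tuple[int, ...], tuple[float, float]]:
    """Enter and exit flow for every module vertex of a partition tree.

    Returns a mapping from the vertex's child-index path (root = ``()``) to
    ``(enter_rate, exit_rate)``: the summed link flow crossing into and out of
    the vertex's leaf set.  For undirected networks enter equals exit.
    """
    if not flow.corrected:
        raise NetworkValidationError("module_boundary_rates expects a corrected FlowField")
    annotated = partition.annotate(flow)
    return {v.path: (v.enter, v.exit) for v in annotated.vertices() if not v.is_leaf}
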