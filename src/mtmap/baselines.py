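"""Comparator target-search baselines and the control-effectiveness metric.

Control effectiveness of a pin set is the basin-weighted average phenotype
preference of the pinned network's attractors minus the same quantity for a
reference network (the unperturbed network by default, or the given-target-
only network for synergy-specific reporting).

SPS (systematic perturbation simulation) exhaustively evaluates every
candidate (node, pin value) added to the given perturbation and is the
brute-force oracle the merged-transition-map ranking is checked against.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .boolnet import BooleanNetwork, Perturbation, PhenotypeSpec, SignedGraph, apply_perturbation
from .dynamics import Attractor, estimate_basins, find_attractors, phenotype_preference
from .errors import ModelError

__all__ = [
    "ControlAssessment",
    "landscape_preference",
    "control_effectiveness",
    "sps_search",
    "minimal_fvs",
    "evaluate_pair_sets",
]


@dataclass
class ControlAssessment:
    pins: dict[str, int]
    effectiveness: float
    baseline_preference: float
    controlled_preference: float


def landscape_preference(
    net: BooleanNetwork,
    spec: PhenotypeSpec,
    n_samples: int = 10_000,
    seed: int | None = None,
    exhaustive_limit: int = 24,
) -> float:
    """Basin-weighted average phenotype preference over all attractors."""
    atts = find_attractors(net, exhaustive_limit=exhaustive_limit)
    basins = estimate_basins(net, atts, n_samples=n_samples, seed=seed)
    total = 0.0
    for a in atts:
        total += basins[a.id] * phenotype_preference(a, net, spec)
    return total


def control_effectiveness(
    net: BooleanNetwork,
    pins: Perturbation,
    spec: PhenotypeSpec,
    n_samples: int = 10_000,
    seed: int | None = None,
    reference: Perturbation | None = None,
    exhaustive_limit: int = 24,
) -> ControlAssessment:
    """Preference gain of pinning ``pins`` relative to the reference network
    (unperturbed unless ``reference`` pins, e.g. the given target alone, are
    supplied)."""
    if not pins.pins:
        raise ModelError("control_effectiveness requires a nonempty pin set")
    pins.validate(net)
    ref_net = net if reference is None else apply_perturbation(net, reference)
    baseline = landscape_preference(ref_net, spec, n_samples=n_samples, seed=seed, exhaustive_limit=exhaustive_limit)
    controlled = landscape_preference(
        apply_perturbation(net, pins), spec, n_samples=n_samples, seed=seed, exhaustive_limit=exhaustive_limit
    )
    return ControlAssessment(dict(pins.pins), controlled - baseline, baseline, controlled)


def sps_search(
    net: BooleanNetwork,
    given: tuple[str, int],
    spec: PhenotypeSpec,
    n_samples: int = 10_000,
    seed: int | None = None,
    reference: Perturbation | None = None,
    exhaustive_limit: int = 24,
) -> list[tuple[str, int, float]]:
    """Exhaustive two-node search: every non-marker candidate except the
    given target, both ON and OFF, ranked by control effectiveness
    (descending; ties by node name then pin value)."""
    g_node, g_val = given
    if g_node not in net.nodes:
        raise ModelError(f"given target {g_node!r} not in network")
    candidates = [n for n in net.nodes if n != g_node and n not in spec.markers]
    results = []
    for cand in candidates:
        for val in (0, 1):
            pins = Perturbation({g_node: g_val, cand: val})
            ca = control_effectiveness(
                net, pins, spec, n_samples=n_samples, seed=seed, reference=reference, exhaustive_limit=exhaustive_limit
            )
            results.append((cand, val, ca.effectiveness))
    results.sort(key=lambda r: (-round(r[2], 12), r[0], r[1]))
    return results


# ---------------------------------------------------------------------------
# feedback vertex set


def minimal_fvs(graph: SignedGraph | nx.DiGraph, exact_limit: int = 30) -> tuple[set[str], bool]:
    """Minimum feedback vertex set of the directed graph.

    Self-loop nodes are always included.  Exact branch-and-bound on cycles
    for graphs up to ``exact_limit`` nodes; a greedy max-degree heuristic
    above that.  Returns (node set, exact flag).
    """
    g = graph.structure() if isinstance(graph, SignedGraph) else nx.DiGraph(graph)
    fvs: set[str] = {u for u in g.nodes if g.has_edge(u, u)}
    core = g.copy()
    core.remove_nodes_from(fvs)
    _trim_acyclic(core)
    if core.number_of_nodes() == 0:
        return fvs, True
    if g.number_of_nodes() <= exact_limit:
        for k in range(core.number_of_nodes() + 1):
            found = _fvs_of_size(core, k)
            if found is not None:
                return fvs | found, True
    # greedy fallback: repeatedly delete the highest in*out degree node
    while True:
        _trim_acyclic(core)
        if core.number_of_nodes() == 0 or nx.is_directed_acyclic_graph(core):
            break
        node = max(core.nodes, key=lambda u: (core.in_degree(u) * core.out_degree(u), u))
        fvs.add(node)
        core.remove_node(node)
    return fvs, False


def _trim_acyclic(g: nx.DiGraph) -> None:
    """Remove nodes that cannot lie on any cycle (degree-0 ends, trivial SCCs)."""
    changed = True
    while changed:
        changed = False
        drop = [u for u in g.nodes if g.in_degree(u) == 0 or g.out_degree(u) == 0]
        if drop:
            g.remove_nodes_from(drop)
            changed = True


def _shortest_cycle(g: nx.DiGraph) -> list[str] | None:
    best: list[str] | None = None
    for u in sorted(g.nodes):
        # BFS from u back to u
        preds = {u: None}
        frontier = [u]
        found = None
        while frontier and found is None:
            nxt = []
            for a in frontier:
                for b in g.successors(a):
                    if b == u:
                        found = a
                        break
                    if b not in preds:
                        preds[b] = a
                        nxt.append(b)
                if found is not None:
                    break
            frontier = nxt
        if found is not None:
            cyc = [found]
            while preds[cyc[-1]] is not None:
                cyc.append(preds[cyc[-1]])
            cyc.reverse()
            if best is None or len(cyc) < len(best):
                best = cyc
                if len(best) <= 2:
                    break
    return best


def _fvs_of_size(g: nx.DiGraph, k: int) -> set[str] | None:
    """Depth-bounded search: every FVS must hit every cycle, so branch on
    the nodes of a shortest cycle."""
    h = g.copy()
    _trim_acyclic(h)
    if h.number_of_nodes() == 0 or nx.is_directed_acyclic_graph(h):
        return set()
    if k == 0:
        return None
    cyc = _shortest_cycle(h)
    if cyc is None:
        return set()
    for node in cyc:
        h2 = h.copy()
        h2.remove_node(node)
        sub = _fvs_of_size(h2, k - 1)
        if sub is not None:
            return sub | {node}
    return None


def evaluate_pair_sets(
    net: BooleanNetwork,
    suggested: set[str],
    spec: PhenotypeSpec,
    desired_attractor: Attractor,
    n_samples: int = 10_000,
    seed: int | None = None,
    reference: Perturbation | None = None,
    exhaustive_limit: int = 24,
) -> float:
    """Mean control effectiveness over all two-node pairs from ``suggested``,
    with pin values taken from the desired attractor's (minimum) state."""
    if len(suggested) < 2:
        raise ModelError("evaluate_pair_sets needs at least two suggested nodes")
    ref_state = desired_attractor.min_state()
    total = 0.0
    pairs = list(combinations(sorted(suggested), 2))
    for a, b in pairs:
        pins = Perturbation(
            {
                a: (ref_state >> net.index(a)) & 1,
                b: (ref_state >> net.index(b)) & 1,
            }
        )
        total += control_effectiveness(
            net, pins, spec, n_samples=n_samples, seed=seed, reference=reference, exhaustive_limit=exhaustive_limit
        ).effectiveness
    return total / len(pairs)
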