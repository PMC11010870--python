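"""Multi-stable motif detection, interconnecting nodes, conflict-pattern
census, degree-preserving randomization, and interaction-table curation.

A multi-stable motif is a strongly connected component of the signed
interaction graph whose projection onto the attractor states shows at least
two distinct patterns (for complex attractors every member state is
projected).  Interconnecting nodes between two motifs are the interior
nodes of k-shortest loopless directed paths between the motif node sets,
ranked by path coverage.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import islice
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .boolnet import BooleanNetwork, SignedGraph
from .dynamics import Attractor
from .errors import CapacityError, ModelError

__all__ = [
    "MultiStableMotif",
    "ConflictPair",
    "find_multistable_motifs",
    "interconnecting_nodes",
    "conflict_pair",
    "count_conflict_motif_pairs",
    "randomize_degree_preserving",
    "curate_interaction_network",
]


@dataclass
class MultiStableMotif:
    nodes: frozenset[str]
    stable_projections: frozenset[tuple[int, ...]]  # patterns in sorted-node order

    @property
    def sorted_nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.nodes))


@dataclass
class ConflictPair:
    motif_a: MultiStableMotif
    motif_b: MultiStableMotif
    interconnectors_ab: list[str]
    interconnectors_ba: list[str]
    sign_ab: int
    sign_ba: int


# ---------------------------------------------------------------------------
# motif detection


def find_multistable_motifs(
    net: BooleanNetwork,
    graph: SignedGraph,
    attractors: Sequence[Attractor],
    max_size: int = 4,
) -> list[MultiStableMotif]:
    """Minimal strongly connected motifs with >= 2 distinct stable patterns.

    Candidate motifs are the positive feedback loops (simple directed
    cycles of length <= ``max_size`` whose edge signs can multiply to +1;
    negative loops cannot hold alternative stable states).  A candidate is
    multi-stable when its projections onto the supplied attractor states
    (per state for complex attractors) contain at least two distinct
    patterns.  Mutually inhibiting motifs always sit inside one maximal
    SCC, so maximal-SCC decomposition cannot separate them; motifs are
    therefore reported as the node-disjoint minimal loops, accepted
    smallest-first.

    ``attractors`` should include the original landscape's attractors plus
    every attractor reachable from them once regulated, so that
    perturbation-induced alternative stable patterns are visible.
    """
    candidates = _positive_cycles(graph, max_size)
    multistable: list[MultiStableMotif] = []
    for nodes in candidates:
        names = tuple(sorted(nodes))
        idxs = [net.index(n) for n in names]
        projections = set()
        for att in attractors:
            for s in att.states:
                projections.add(tuple((s >> i) & 1 for i in idxs))
        if len(projections) >= 2:
            multistable.append(MultiStableMotif(frozenset(nodes), frozenset(projections)))
    # smallest loops first; composite loops overlapping an accepted motif
    # (e.g. the double-negative conflict loop spanning both motifs) drop out
    multistable.sort(key=lambda m: (len(m.nodes), m.sorted_nodes))
    accepted: list[MultiStableMotif] = []
    taken: set[str] = set()
    for m in multistable:
        if m.nodes & taken:
            continue
        accepted.append(m)
        taken |= m.nodes
    accepted.sort(key=lambda m: m.sorted_nodes)
    return accepted


# ---------------------------------------------------------------------------
# interconnecting nodes via k-shortest loopless paths


def _k_shortest_paths_between_sets(
    structure: nx.DiGraph, sources: frozenset[str], targets: frozenset[str], k: int
) -> list[list[str]]:
    """k shortest simple directed paths from any source to any target,
    sorted by length then lexicographically; interior nodes avoid both sets
    only by simplicity, not by construction."""
    paths: list[list[str]] = []
    for u in sorted(sources):
        for v in sorted(targets):
            if u == v or u not in structure or v not in structure:
                continue
            try:
                for p in islice(nx.shortest_simple_paths(structure, u, v), k):
                    paths.append(p)
            except nx.NetworkXNoPath:
                continue
    paths.sort(key=lambda p: (len(p), p))
    # deduplicate while preserving order
    seen: set[tuple[str, ...]] = set()
    out = []
    for p in paths:
        tp = tuple(p)
        if tp not in seen:
            seen.add(tp)
            out.append(p)
    return out[:k]


def _path_sign(graph: SignedGraph, path: Sequence[str]) -> int:
    """Net sign of a path: product of edge signs; 0 if any hop is dual-signed."""
    signs = graph.edge_signs()
    total = 1
    for u, v in zip(path, path[1:]):
        s = signs.get((u, v))
        if s is None:
            return 0
        if len(s) > 1:
            return 0
        total *= next(iter(s))
    return total


def interconnecting_nodes(
    graph: SignedGraph,
    a: MultiStableMotif | Iterable[str],
    b: MultiStableMotif | Iterable[str],
    k: int = 10,
) -> list[str]:
    """Interior nodes on k-shortest paths from motif ``a`` to motif ``b``,
    ranked by the number of covering paths, then by earliest (shortest)
    covering path, then by name.  Empty when no path exists."""
    if k < 1:
        raise ModelError("k must be >= 1")
    a_nodes = frozenset(a.nodes if isinstance(a, MultiStableMotif) else a)
    b_nodes = frozenset(b.nodes if isinstance(b, MultiStableMotif) else b)
    structure = graph.structure()
    paths = _k_shortest_paths_between_sets(structure, a_nodes, b_nodes, k)
    coverage: Counter[str] = Counter()
    first_len: dict[str, int] = {}
    for p in paths:
        for node in p[1:-1]:
            if node in a_nodes or node in b_nodes:
                continue
            coverage[node] += 1
            first_len.setdefault(node, len(p) - 1)
    return sorted(coverage, key=lambda n: (-coverage[n], first_len[n], n))


def conflict_pair(
    graph: SignedGraph, a: MultiStableMotif, b: MultiStableMotif, k: int = 10
) -> ConflictPair | None:
    """The pair record when both inter-motif directions are net-negative."""
    structure = graph.structure()
    best_ab = _best_connection_sign(graph, structure, a.nodes, b.nodes, k)
    best_ba = _best_connection_sign(graph, structure, b.nodes, a.nodes, k)
    if best_ab != -1 or best_ba != -1:
        return None
    return ConflictPair(
        a,
        b,
        interconnecting_nodes(graph, a, b, k),
        interconnecting_nodes(graph, b, a, k),
        best_ab,
        best_ba,
    )


def _best_connection_sign(graph, structure, src: frozenset[str], dst: frozenset[str], k: int) -> int:
    paths = _k_shortest_paths_between_sets(structure, src, dst, k)
    for p in paths:
        s = _path_sign(graph, p)
        if s != 0:
            return s
    return 0


# ---------------------------------------------------------------------------
# conflict-pattern census (pattern join)


def _positive_cycles(graph: SignedGraph, max_size: int) -> list[frozenset[str]]:
    """Node sets of simple directed cycles of length <= max_size whose edge
    signs can multiply to +1 (dual-signed edges can realize either sign)."""
    signs = graph.edge_signs()
    structure = graph.structure()
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for cyc in nx.simple_cycles(structure, length_bound=max_size):
        node_set = frozenset(cyc)
        if node_set in seen:
            continue
        hops = list(zip(cyc, cyc[1:] + cyc[:1]))
        sign_options = [signs[(u, v)] for u, v in hops]
        neg_fixed = sum(1 for s in sign_options if s == {-1})
        free = sum(1 for s in sign_options if len(s) > 1)
        # positive product achievable iff some choice yields an even negative count
        if free > 0 or neg_fixed % 2 == 0:
            seen.add(node_set)
            out.append(node_set)
    return sorted(out, key=lambda s: tuple(sorted(s)))


def _has_negative_connection(
    graph: SignedGraph, structure: nx.DiGraph, src: frozenset[str], dst: frozenset[str], max_path_len: int = 2
) -> bool:
    signs = graph.edge_signs()
    for u in src:
        for v in dst:
            s = signs.get((u, v))
            if s and -1 in s:
                return True
    if max_path_len >= 2:
        for u in src:
            for mid in structure.successors(u):
                if mid in src or mid in dst:
                    continue
                s1 = signs[(u, mid)]
                for v in structure.successors(mid):
                    if v not in dst:
                        continue
                    s2 = signs[(mid, v)]
                    if any(a * b == -1 for a in s1 for b in s2):
                        return True
    return False


def count_conflict_motif_pairs(
    graph: SignedGraph, max_motif_size: int = 3, max_pairs: int = 5_000_000
) -> int:
    """Census of conflicting positive-feedback pairs by pattern join.

    Counts unordered pairs of node-disjoint positive feedback loops (size
    <= ``max_motif_size``) connected by net-negative directed paths of
    length <= 2 in both directions.  Overlapping instances count
    separately.
    """
    if max_motif_size < 1:
        raise ModelError("max_motif_size must be >= 1")
    cycles = _positive_cycles(graph, max_motif_size)
    structure = graph.structure()
    if len(cycles) * (len(cycles) - 1) // 2 > max_pairs:
        raise CapacityError(f"too many positive loops ({len(cycles)}) for the pair census budget")
    count = 0
    for i in range(len(cycles)):
        for j in range(i + 1, len(cycles)):
            a, b = cycles[i], cycles[j]
            if a & b:
                continue
            if _has_negative_connection(graph, structure, a, b) and _has_negative_connection(graph, structure, b, a):
                count += 1
    return count


# ---------------------------------------------------------------------------
# degree-preserving randomization


def randomize_degree_preserving(
    graph: SignedGraph, swap_fraction: float = 0.3, seed: int | None = None, max_tries_factor: int = 200
) -> SignedGraph:
    """Double-edge swaps preserving in/out degree sequences exactly.

    Performs ``ceil(swap_fraction * |edges|)`` successful swaps: two edges
    (u -> x) and (v -> y) with distinct endpoints become (u -> y) and
    (v -> x); each sign travels with its source edge.  Swaps that would
    create self-loops or duplicate (source, target, sign) triples are
    rejected.
    """
    if not 0 < swap_fraction <= 1:
        raise ModelError("swap_fraction must be in (0, 1]")
    edges = sorted(graph.edges)
    if len(edges) < 2:
        raise ModelError("graph has too few edges to swap")
    rng = np.random.default_rng(seed)
    target_swaps = int(np.ceil(swap_fraction * len(edges)))
    edge_set = set(edges)
    done = 0
    tries = 0
    max_tries = max_tries_factor * max(target_swaps, 1)
    while done < target_swaps:
        if tries >= max_tries:
            raise ModelError(
                f"could not complete {target_swaps} degree-preserving swaps after {max_tries} attempts"
            )
        tries += 1
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (u, x, s1), (v, y, s2) = edges[int(i)], edges[int(j)]
        if u == v or x == y or u == y or v == x:
            continue
        new1, new2 = (u, y, s1), (v, x, s2)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[int(i)])
        edge_set.discard(edges[int(j)])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[int(i)], edges[int(j)] = new1, new2
        done += 1
    return SignedGraph(graph.nodes, frozenset(edge_set))


# ---------------------------------------------------------------------------
# curation of signed-directed interaction tables


REQUIRED_COLUMNS = ("source", "target", "sign", "is_directed")


def curate_interaction_network(
    tables: Sequence[pd.DataFrame],
    whitelist: set[tuple[str, str]] | None = None,
) -> SignedGraph:
    """Merge signed-directed interaction tables into one network.

    Rows without a sign (+1/-1) or not directed are dropped; an optional
    ``whitelist`` of (source, target) pairs (e.g. high-confidence
    cross-validation) further filters the edges.  The largest weakly
    connected component of the result is returned.
    """
    if not tables:
        raise ModelError("no interaction tables supplied")
    frames = []
    for t in tables:
        missing = [c for c in REQUIRED_COLUMNS if c not in t.columns]
        if missing:
            raise ModelError(f"interaction table missing required columns: {missing}")
        frames.append(t[list(REQUIRED_COLUMNS)])
    merged = pd.concat(frames, ignore_index=True)
    merged = merged.dropna(subset=["sign", "is_directed"])
    merged = merged[merged["is_directed"].astype(bool)]
    merged["sign"] = pd.to_numeric(merged["sign"], errors="coerce")
    merged = merged[merged["sign"].isin([1, -1])]
    if whitelist is not None:
        mask = merged.apply(lambda r: (r["source"], r["target"]) in whitelist, axis=1)
        merged = merged[mask]
    if merged.empty:
        raise ModelError("empty network after filtering unsigned/undirected interactions")
    g = nx.MultiDiGraph()
    edges = set()
    for _, r in merged.iterrows():
        edges.add((str(r["source"]), str(r["target"]), int(r["sign"])))
    for u, v, s in edges:
        g.add_edge(u, v, sign=s)
    comp = max(nx.weakly_connected_components(g), key=lambda c: (len(c), tuple(sorted(c))))
    kept = frozenset(e for e in edges if e[0] in comp and e[1] in comp)
    return SignedGraph(tuple(sorted(comp)), kept)
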