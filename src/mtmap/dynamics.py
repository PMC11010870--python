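"""Asynchronous update semantics, attractor identification and basins.

Updates are asynchronous: from a state, any single node whose rule value
differs from its current state may flip.  A state with no eligible flip is a
fixed point; attractors in general are the terminal strongly connected
components of the asynchronous state-transition graph (STG).

Attractor search first reduces the network by iterative constant-node
propagation (rules that simplify to constants are substituted into their
dependents until a fixed point), then enumerates the full STG of the
residual network and extracts terminal SCCs, re-expanding with the forced
assignments.  Every reported attractor is verified closed under the full
network's dynamics.

Basins of attraction are the expected fraction of initial states converging
to each attractor under uniformly random asynchronous trajectories.  In
exact mode (small state spaces) they are computed from absorption
probabilities of the induced Markov chain; otherwise they are estimated by
Monte-Carlo tracing from distinct uniformly sampled initial states.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
import sympy
from sympy import Symbol
from sympy.logic.boolalg import BooleanFalse, BooleanTrue, simplify_logic

from .boolnet import BooleanNetwork, PhenotypeSpec
from .errors import CapacityError, ModelError

__all__ = [
    "Attractor",
    "StateTransitionGraph",
    "async_successors",
    "build_reachable_stg",
    "reduce_by_constants",
    "find_attractors",
    "estimate_basins",
    "phenotype_preference",
    "exact_absorption",
    "random_trajectory",
]

DEFAULT_EXHAUSTIVE_LIMIT = 24
DEFAULT_STATE_BUDGET = 1 << 22


# ---------------------------------------------------------------------------
# STG construction


@dataclass
class StateTransitionGraph:
    """Reachable asynchronous STG: ``succ`` maps each state key to its
    successor keys (single-node flips).  States absent from ``succ`` values'
    expansion were not expanded (treated as absorbing by the caller)."""

    succ: dict[int, tuple[int, ...]]

    @property
    def states(self) -> set[int]:
        return set(self.succ)

    @property
    def n_edges(self) -> int:
        return sum(len(v) for v in self.succ.values())

    def fixed_points(self) -> set[int]:
        return {s for s, nxt in self.succ.items() if not nxt}


def async_successors(net: BooleanNetwork, state: int, funcs: Sequence[Callable[[int], int]] | None = None) -> set[int]:
    """All single-flip successors of ``state``; empty iff fixed point."""
    if funcs is None:
        funcs = net.compiled_rules()
    out = set()
    for i in range(net.n):
        if funcs[i](state) != (state >> i) & 1:
            out.add(state ^ (1 << i))
    return out


def _successor_closure(
    n: int,
    funcs: Sequence[Callable[[int], int]],
    seeds: Iterable[int],
    budget: int,
    absorbing: Callable[[int], bool] | None = None,
) -> dict[int, tuple[int, ...]]:
    succ: dict[int, tuple[int, ...]] = {}
    frontier = sorted(set(seeds))
    for s in frontier:
        succ[s] = ()
    while frontier:
        nxt: list[int] = []
        for s in frontier:
            if absorbing is not None and absorbing(s):
                succ[s] = ()
                continue
            out = []
            for i in range(n):
                if funcs[i](s) != (s >> i) & 1:
                    out.append(s ^ (1 << i))
            succ[s] = tuple(out)
            for t in out:
                if t not in succ:
                    if len(succ) >= budget:
                        raise CapacityError(f"state budget of {budget} states exceeded during STG construction")
                    succ[t] = ()
                    nxt.append(t)
        frontier = sorted(nxt)
    return succ


def build_reachable_stg(
    net: BooleanNetwork,
    seeds: Iterable[int],
    budget: int = DEFAULT_STATE_BUDGET,
    absorbing: Callable[[int], bool] | None = None,
) -> StateTransitionGraph:
    """BFS closure of ``seeds`` under asynchronous successors.

    States satisfying ``absorbing`` are kept but not expanded.  Raises
    :class:`CapacityError` when more than ``budget`` states are visited.
    """
    seeds = list(seeds)
    if not seeds:
        raise ModelError("build_reachable_stg requires at least one seed state")
    funcs = net.compiled_rules()
    return StateTransitionGraph(_successor_closure(net.n, funcs, seeds, budget, absorbing))


# ---------------------------------------------------------------------------
# constant-node reduction


def _as_constant(expr: sympy.Basic) -> int | None:
    if expr is sympy.true or isinstance(expr, BooleanTrue):
        return 1
    if expr is sympy.false or isinstance(expr, BooleanFalse):
        return 0
    return None


def reduce_by_constants(net: BooleanNetwork) -> tuple[BooleanNetwork | None, dict[str, int]]:
    """Iteratively propagate constant rules; returns (residual, forced).

    The residual network spans the nodes whose rules did not become
    constant (``None`` if all did); ``forced`` maps eliminated nodes to
    their forced values.  Attractors of the original network are exactly
    the attractors of the residual re-expanded with ``forced``.
    """
    rules = {n: net.rules[n] for n in net.nodes}
    forced: dict[str, int] = {}
    changed = True
    while changed:
        changed = False
        for name in net.nodes:
            if name in forced:
                continue
            expr = rules[name]
            if expr.free_symbols:
                expr = simplify_logic(expr)
                rules[name] = expr
            c = _as_constant(expr)
            if c is not None:
                forced[name] = c
                changed = True
        if changed:
            sub = {Symbol(k): (sympy.true if v else sympy.false) for k, v in forced.items()}
            for name in net.nodes:
                if name not in forced:
                    rules[name] = rules[name].subs(sub)
    residual_nodes = tuple(n for n in net.nodes if n not in forced)
    if not residual_nodes:
        return None, forced
    residual = BooleanNetwork(residual_nodes, {n: rules[n] for n in residual_nodes})
    return residual, forced


# ---------------------------------------------------------------------------
# attractors


@dataclass
class Attractor:
    """Terminal SCC of the asynchronous STG.

    ``states`` are full-network encoded state keys; ``kind`` is ``"point"``
    for a single fixed state and ``"complex"`` otherwise.
    """

    id: str
    states: frozenset[int]
    kind: str
    basin_fraction: float | None = None
    preference: float | None = None

    def min_state(self) -> int:
        return min(self.states)


def _terminal_sccs(succ: Mapping[int, tuple[int, ...]]) -> list[frozenset[int]]:
    g = nx.DiGraph()
    g.add_nodes_from(succ)
    for s, outs in succ.items():
        for t in outs:
            g.add_edge(s, t)
    sccs = list(nx.strongly_connected_components(g))
    cond = nx.condensation(g, scc=sccs)
    return [frozenset(sccs[c]) for c in cond.nodes if cond.out_degree(c) == 0]


def find_attractors(
    net: BooleanNetwork,
    exhaustive_limit: int = DEFAULT_EXHAUSTIVE_LIMIT,
    seeds: Iterable[int] | None = None,
    budget: int = DEFAULT_STATE_BUDGET,
) -> list[Attractor]:
    """Attractors as terminal SCCs of the (residual) asynchronous STG.

    After constant reduction the residual state space is enumerated
    exhaustively when it has at most ``exhaustive_limit`` free nodes;
    otherwise ``seeds`` (full-network states) must be supplied and the
    search is restricted to their reachable closure, which yields every
    attractor reachable from the seeds.
    """
    residual, forced = reduce_by_constants(net)
    if residual is None:
        key = net.dict_to_state(forced)
        atts = [Attractor("A0", frozenset({key}), "point")]
        _verify_closed(net, atts)
        return atts

    r_idx = {name: i for i, name in enumerate(residual.nodes)}
    funcs = residual.compiled_rules()
    if residual.n <= exhaustive_limit and residual.n <= 20:
        if seeds is None:
            seed_states: Iterable[int] = range(1 << residual.n)
        else:
            seed_states = {_project(net, residual, s) for s in seeds}
        succ = _successor_closure(residual.n, funcs, seed_states, budget)
    elif seeds is not None:
        seed_states = {_project(net, residual, s) for s in seeds}
        succ = _successor_closure(residual.n, funcs, seed_states, budget)
    else:
        raise CapacityError(
            f"residual network has {residual.n} free nodes (> limit {min(exhaustive_limit, 20)}); "
            "supply seed states for reachability-based search"
        )

    terminal = _terminal_sccs(succ)
    atts: list[Attractor] = []
    base = net.dict_to_state(forced)
    for comp in terminal:
        full_states = frozenset(_expand(net, residual, r_idx, base, s) for s in comp)
        kind = "point" if len(full_states) == 1 else "complex"
        atts.append(Attractor("", full_states, kind))
    atts.sort(key=lambda a: a.min_state())
    for i, a in enumerate(atts):
        a.id = f"A{i}"
    _verify_closed(net, atts)
    return atts


def _project(net: BooleanNetwork, residual: BooleanNetwork, full_state: int) -> int:
    key = 0
    for i, name in enumerate(residual.nodes):
        key |= ((full_state >> net.index(name)) & 1) << i
    return key


def _expand(net: BooleanNetwork, residual: BooleanNetwork, r_idx: Mapping[str, int], base: int, r_state: int) -> int:
    key = base
    for name, i in r_idx.items():
        key |= ((r_state >> i) & 1) << net.index(name)
    return key


def _verify_closed(net: BooleanNetwork, atts: Sequence[Attractor]) -> None:
    funcs = net.compiled_rules()
    for a in atts:
        for s in a.states:
            for t in async_successors(net, s, funcs):
                if t not in a.states:
                    raise ModelError(
                        f"attractor {a.id or '?'} not closed: {net.state_to_str(s)} -> {net.state_to_str(t)}"
                    )


# ---------------------------------------------------------------------------
# absorption analysis (shared with the merged transition map)


def exact_absorption(
    succ: Mapping[int, tuple[int, ...]],
    absorbing: Mapping[int, str],
    dests: Sequence[str],
) -> tuple[dict[int, np.ndarray], dict[int, int], list[int]]:
    """Absorption probabilities of the uniform-branch chain on ``succ``.

    Every transient state moves to a uniformly chosen successor; states in
    ``absorbing`` stop.  Returns ``(h, order, transient)`` where ``h[s]`` is
    the vector of absorption probabilities over ``dests`` for every state.
    """
    d_idx = {d: j for j, d in enumerate(dests)}
    transient = sorted(s for s in succ if s not in absorbing)
    t_idx = {s: i for i, s in enumerate(transient)}
    nt, k = len(transient), len(dests)
    h: dict[int, np.ndarray] = {}
    for s, d in absorbing.items():
        v = np.zeros(k)
        v[d_idx[d]] = 1.0
        h[s] = v
    if nt:
        rows, cols, vals = [], [], []
        R = np.zeros((nt, k))
        for s in transient:
            outs = succ[s]
            if not outs:
                raise ModelError(f"transient state {s} has no successors and is not absorbing (malformed segment)")
            p = 1.0 / len(outs)
            for t in outs:
                if t in absorbing:
                    R[t_idx[s], d_idx[absorbing[t]]] += p
                else:
                    rows.append(t_idx[s])
                    cols.append(t_idx[t])
                    vals.append(p)
        Q = sp.csc_matrix((vals, (rows, cols)), shape=(nt, nt))
        A = (sp.identity(nt, format="csc") - Q).tocsc()
        lu = spla.splu(A)
        H = lu.solve(R)
        for s in transient:
            h[s] = H[t_idx[s]]
    return h, t_idx, transient


def random_trajectory(
    n: int,
    funcs: Sequence[Callable[[int], int]],
    start: int,
    absorbing: Mapping[int, str],
    rng: np.random.Generator,
    step_budget: int,
) -> tuple[str | None, np.ndarray, int]:
    """One uniformly random asynchronous trajectory until absorption.

    Returns (destination id or None if censored, per-node flip counts,
    number of transitions)."""
    flips = np.zeros(n, dtype=np.int64)
    s = start
    steps = 0
    while s not in absorbing:
        eligible = [i for i in range(n) if funcs[i](s) != (s >> i) & 1]
        if not eligible:
            # fixed point outside the absorbing set: report as its own key
            return None, flips, steps
        if steps >= step_budget:
            return None, flips, steps
        i = eligible[int(rng.integers(len(eligible)))]
        s ^= 1 << i
        flips[i] += 1
        steps += 1
    return absorbing[s], flips, steps


# ---------------------------------------------------------------------------
# basins


def estimate_basins(
    net: BooleanNetwork,
    attractors: Sequence[Attractor],
    n_samples: int = 10_000,
    seed: int | None = None,
    step_budget: int | None = None,
    max_censored_fraction: float = 0.01,
) -> dict[str, float]:
    """Basin fractions for precomputed attractors; sets ``basin_fraction``.

    When the full state space has at most ``n_samples`` states the basin is
    computed exactly as the mean absorption probability over all initial
    states (uniform random asynchronous updating).  Otherwise ``n_samples``
    distinct initial states are sampled uniformly without replacement and a
    random trajectory is traced from each; trajectories exceeding the step
    budget are counted as censored, and more than ``max_censored_fraction``
    censored trajectories is an error.
    """
    if n_samples < 1:
        raise ModelError("n_samples must be >= 1")
    n = net.n
    absorbing: dict[int, str] = {}
    for a in attractors:
        for s in a.states:
            absorbing[s] = a.id
    dests = [a.id for a in attractors]

    if (1 << n) <= n_samples:
        funcs = net.compiled_rules()
        succ = _successor_closure(n, funcs, range(1 << n), budget=max(DEFAULT_STATE_BUDGET, 1 << n))
        h, _, _ = exact_absorption(succ, absorbing, dests)
        total = np.zeros(len(dests))
        for s in range(1 << n):
            total += h[s]
        fractions = total / float(1 << n)
    else:
        rng = np.random.default_rng(seed)
        if step_budget is None:
            step_budget = 10_000 * n
        funcs = net.compiled_rules()
        seen: set[int] = set()
        counts = np.zeros(len(dests))
        d_idx = {d: j for j, d in enumerate(dests)}
        censored = 0
        while len(seen) < n_samples:
            s = int(rng.integers(0, 1 << n)) if n < 63 else int(rng.integers(0, 2**62))
            if s in seen:
                continue
            seen.add(s)
            dest, _, _ = random_trajectory(n, funcs, s, absorbing, rng, step_budget)
            if dest is None:
                censored += 1
            else:
                counts[d_idx[dest]] += 1
        if censored > max_censored_fraction * n_samples:
            raise CapacityError(
                f"{censored}/{n_samples} trajectories did not reach a known attractor within "
                f"{step_budget} steps; attractor set may be incomplete"
            )
        converged = counts.sum()
        fractions = counts / converged if converged else counts
    out = {}
    for a, f in zip(attractors, fractions):
        a.basin_fraction = float(f)
        out[a.id] = float(f)
    return out


# ---------------------------------------------------------------------------
# phenotype preference


def phenotype_preference(att: Attractor, net: BooleanNetwork, spec: PhenotypeSpec) -> float:
    """Marker-weighted preference, averaged uniformly over attractor states."""
    spec.validate(net)
    vals = [spec.state_preference(net, s) for s in sorted(att.states)]
    pref = float(np.mean(vals))
    att.preference = pref
    return pref
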