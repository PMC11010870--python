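"""Merged transition map (MTM) construction, path-ensemble factorization,
weighted flipping frequencies, and signal-flow control-type selection.

The MTM merges two families of state-transition segments:

* **regulated** segments: from each attractor of the original (unperturbed)
  network, the reachable STG of the pinned network, absorbed at the pinned
  network's attractor states.  Segment seeds are the source attractor's
  states with the pinned values applied, so the pinned node never flips.
* **reversal** segments: from each attractor of the pinned network, the
  reachable STG of the original network (drug withdrawn), absorbed at the
  original attractor states.

Each (source, destination) pair of a segment is a *path ensemble*.  Branch
probabilities are uniform over a state's outgoing transitions, and the
ensemble's absorption probability and conditional expected per-node flip
counts are computed exactly by absorbing-Markov-chain first-step analysis,
which equals the probability-weighted sum over all transition paths (the
asynchronous STG contains cycles, so literal path enumeration diverges; the
chain analysis is the convergent closed form).

The weighted flipping frequency of a node is

    wff(n) = sum over ensembles of
             significance * P(absorb) * E[flips_n | absorbed] * PP * type

with PP the sign of the preference change (destination minus source), type
+1 for regulated and -1 for reversal ensembles, and significance the source
attractor's basin fraction on its own landscape.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boolnet import BooleanNetwork, Perturbation, PhenotypeSpec, SignedGraph, apply_perturbation
from .dynamics import (
    Attractor,
    build_reachable_stg,
    estimate_basins,
    exact_absorption,
    find_attractors,
    phenotype_preference,
)
from .errors import CapacityError, ModelError

__all__ = [
    "Segment",
    "MergedTransitionMap",
    "PathEnsemble",
    "TargetScore",
    "build_mtm",
    "transition_probabilities",
    "factorize_ensembles",
    "weighted_flipping_frequency",
    "rank_synergistic_targets",
    "flip_ratio",
    "signal_flow_influence",
    "determine_control_type",
]


@dataclass
class Segment:
    """One labeled sub-STG of the MTM."""

    label: str  # "regulated" | "reversal"
    source: Attractor  # attractor of the segment's source landscape
    seeds: dict[int, float]  # seed state -> weight (sums to 1)
    succ: dict[int, tuple[int, ...]]  # reachable STG, absorbing states unexpanded
    absorbing: dict[int, str]  # absorbing state -> destination attractor id


@dataclass
class MergedTransitionMap:
    net: BooleanNetwork
    pinned_net: BooleanNetwork
    perturbation: Perturbation
    original_attractors: list[Attractor]
    regulated_attractors: list[Attractor]
    segments: list[Segment]

    def attractor(self, label: str, aid: str) -> Attractor:
        pool = self.regulated_attractors if label == "regulated" else self.original_attractors
        for a in pool:
            if a.id == aid:
                return a
        raise ModelError(f"unknown attractor {aid!r} in {label} landscape")


@dataclass
class PathEnsemble:
    source: str  # source attractor id (its own landscape)
    dest: str  # destination attractor id (target landscape)
    label: str  # "regulated" | "reversal"
    p_absorb: float
    flips: dict[str, float]  # node -> E[flips | absorbed at dest]
    pp: int  # sign(pref(dest) - pref(source))
    type_sign: int  # +1 regulated, -1 reversal
    significance: float  # basin fraction of source on its own landscape


@dataclass
class TargetScore:
    node: str
    wff: float  # literal signed weighted flipping frequency
    desired_mass: float = 0.0  # flip mass on preference-increasing ensembles
    undesired_mass: float = 0.0  # flip mass on preference-decreasing ensembles
    decomposition: list[tuple[str, str, str, int, int, float]] = field(default_factory=list)
    control_type: str | None = None  # "ON" | "OFF"

    @property
    def conflict_score(self) -> float:
        """Net flip mass concentrated on undesired transitions.

        Nodes that flip mostly while the network slides toward worse
        phenotypes (state-conflict transmitters) score high; nodes that
        flip equally on desired transitions cancel out."""
        return self.undesired_mass - self.desired_mass


# ---------------------------------------------------------------------------
# MTM construction


def build_mtm(
    net: BooleanNetwork,
    pert: Perturbation,
    exhaustive_limit: int = 24,
    budget: int = 1 << 22,
) -> MergedTransitionMap:
    """Build all regulated and reversal segments of the merged map."""
    pert.validate(net)
    pinned = apply_perturbation(net, pert)
    orig_atts = find_attractors(net, exhaustive_limit=exhaustive_limit, budget=budget)
    # regulated attractors: reachable from the pinned originals (seeded search
    # keeps large models tractable and matches how the map is actually used)
    pin_seeds = {_apply_pin_to_state(net, pert, s) for a in orig_atts for s in a.states}
    try:
        reg_atts = find_attractors(pinned, exhaustive_limit=exhaustive_limit, budget=budget)
    except CapacityError:
        reg_atts = find_attractors(pinned, exhaustive_limit=exhaustive_limit, seeds=pin_seeds, budget=budget)

    reg_absorbing = {s: a.id for a in reg_atts for s in a.states}
    orig_absorbing = {s: a.id for a in orig_atts for s in a.states}

    segments: list[Segment] = []
    for a in orig_atts:
        mapped = Counter(_apply_pin_to_state(net, pert, s) for s in sorted(a.states))
        total = sum(mapped.values())
        seeds = {s: c / total for s, c in mapped.items()}
        stg = build_reachable_stg(pinned, seeds, budget=budget, absorbing=lambda s: s in reg_absorbing)
        segments.append(Segment("regulated", a, seeds, stg.succ, {s: d for s, d in reg_absorbing.items() if s in stg.succ}))
    for a in reg_atts:
        seeds = {s: 1.0 / len(a.states) for s in sorted(a.states)}
        stg = build_reachable_stg(net, seeds, budget=budget, absorbing=lambda s: s in orig_absorbing)
        segments.append(Segment("reversal", a, seeds, stg.succ, {s: d for s, d in orig_absorbing.items() if s in stg.succ}))
    return MergedTransitionMap(net, pinned, pert, orig_atts, reg_atts, segments)


def _apply_pin_to_state(net: BooleanNetwork, pert: Perturbation, state: int) -> int:
    for name, v in pert.pins.items():
        i = net.index(name)
        state = (state & ~(1 << i)) | ((1 if v else 0) << i)
    return state


def transition_probabilities(seg: Segment) -> dict[tuple[int, int], float]:
    """Uniform branch probabilities: each edge from s gets 1/outdegree(s)."""
    probs: dict[tuple[int, int], float] = {}
    for s, outs in seg.succ.items():
        if s in seg.absorbing or not outs:
            continue
        p = 1.0 / len(outs)
        for t in outs:
            probs[(s, t)] = p
    return probs


# ---------------------------------------------------------------------------
# factorization into path ensembles


def factorize_ensembles(
    mtm: MergedTransitionMap,
    spec: PhenotypeSpec,
    basins: dict[str, dict[str, float]] | None = None,
    n_samples: int = 10_000,
    seed: int | None = None,
) -> list[PathEnsemble]:
    """Factorize every segment into (source, dest) path ensembles.

    ``basins`` may carry precomputed fractions per landscape under keys
    ``"original"``/``"regulated"``; otherwise they are estimated here.
    Preferences of all attractors are computed (and cached on them).
    """
    net = mtm.net
    spec.validate(net)
    if basins is None:
        basins = {
            "original": estimate_basins(net, mtm.original_attractors, n_samples=n_samples, seed=seed),
            "regulated": estimate_basins(mtm.pinned_net, mtm.regulated_attractors, n_samples=n_samples, seed=seed),
        }
    for a in mtm.original_attractors + mtm.regulated_attractors:
        phenotype_preference(a, net, spec)

    ensembles: list[PathEnsemble] = []
    for seg in mtm.segments:
        src_landscape = "original" if seg.label == "regulated" else "regulated"
        dst_landscape = "regulated" if seg.label == "regulated" else "original"
        significance = basins[src_landscape].get(seg.source.id, 0.0)
        type_sign = 1 if seg.label == "regulated" else -1
        ensembles.extend(
            _segment_ensembles(mtm, seg, spec, significance, type_sign, dst_landscape)
        )
    return ensembles


def _segment_ensembles(
    mtm: MergedTransitionMap,
    seg: Segment,
    spec: PhenotypeSpec,
    significance: float,
    type_sign: int,
    dst_landscape: str,
) -> list[PathEnsemble]:
    net = mtm.net
    dest_ids = sorted({d for d in seg.absorbing.values()})
    if not dest_ids:
        raise ModelError(f"segment from {seg.source.id} ({seg.label}) reaches no absorbing attractor states")
    h, t_idx, transient = exact_absorption(seg.succ, seg.absorbing, dest_ids)

    # conditional expected flips: solve (I - Q) G_d = B_d per destination,
    # B_d[s, n] = sum over successors of (1/out) * [flip is node n] * h_d(s')
    nt = len(transient)
    n_nodes = net.n
    G: dict[str, np.ndarray] = {}
    if nt:
        rows, cols, vals = [], [], []
        for s in transient:
            outs = seg.succ[s]
            p = 1.0 / len(outs)
            for t in outs:
                if t not in seg.absorbing and t in t_idx:
                    rows.append(t_idx[s])
                    cols.append(t_idx[t])
                    vals.append(p)
        Q = sp.csc_matrix((vals, (rows, cols)), shape=(nt, nt))
        lu = spla.splu((sp.identity(nt, format="csc") - Q).tocsc())
        for j, d in enumerate(dest_ids):
            B = np.zeros((nt, n_nodes))
            for s in transient:
                outs = seg.succ[s]
                p = 1.0 / len(outs)
                for t in outs:
                    node_i = (s ^ t).bit_length() - 1
                    B[t_idx[s], node_i] += p * h[t][j]
            G[d] = lu.solve(B)

    out: list[PathEnsemble] = []
    src_pref = seg.source.preference
    for j, d in enumerate(dest_ids):
        p_abs = sum(w * h[s][j] for s, w in seg.seeds.items())
        if p_abs <= 1e-12:
            continue
        flips_vec = np.zeros(n_nodes)
        for s, w in seg.seeds.items():
            if s in t_idx:
                flips_vec += w * G[d][t_idx[s]]
        flips_vec /= p_abs
        dest_att = mtm.attractor(dst_landscape, d)
        dst_pref = dest_att.preference
        pp = int(np.sign(round(dst_pref - src_pref, 12)))
        out.append(
            PathEnsemble(
                source=seg.source.id,
                dest=d,
                label=seg.label,
                p_absorb=float(p_abs),
                flips={net.nodes[i]: float(flips_vec[i]) for i in range(n_nodes)},
                pp=pp,
                type_sign=type_sign,
                significance=float(significance),
            )
        )
    return out


# ---------------------------------------------------------------------------
# scoring and ranking


def weighted_flipping_frequency(ensembles: list[PathEnsemble], nodes: tuple[str, ...]) -> dict[str, TargetScore]:
    """Per-node weighted flipping statistics over all path ensembles.

    ``wff`` is the literal signed sum significance * p * E[flips] * PP *
    type; ``desired_mass``/``undesired_mass`` accumulate the unsigned flip
    mass significance * p * E[flips] split by the sign of the preference
    change, which is what the synergistic-target selection ranks on.
    """
    scores = {n: TargetScore(n, 0.0) for n in nodes}
    for e in ensembles:
        base = e.significance * e.p_absorb
        for n in nodes:
            mass = base * e.flips.get(n, 0.0)
            if mass == 0.0:
                continue
            scores[n].wff += mass * e.pp * e.type_sign
            if e.pp > 0:
                scores[n].desired_mass += mass
            elif e.pp < 0:
                scores[n].undesired_mass += mass
            scores[n].decomposition.append((e.label, e.source, e.dest, e.pp, e.type_sign, mass))
    return scores


RANKING_MODES = ("conflict", "undesired", "wff", "abs")


def rank_synergistic_targets(
    scores: dict[str, TargetScore],
    k: int = 5,
    exclude: set[str] | None = None,
    mode: str = "conflict",
) -> list[TargetScore]:
    """Rank candidate partner targets.

    ``mode`` selects the ranking functional:

    * ``"conflict"`` (default): net flip mass on preference-decreasing
      ensembles minus mass on preference-increasing ones — the node whose
      state flips are concentrated in the unwanted transitions, i.e. the
      conflict transmitter to stabilize;
    * ``"undesired"``: undesired-path flip mass alone;
    * ``"wff"``: the literal signed weighted flipping frequency,
      descending;
    * ``"abs"``: |wff|.

    Ties break lexicographically by node name.  Nodes in ``exclude`` (the
    given target, pinned inputs, phenotype markers) are dropped.
    """
    if k < 1:
        raise ModelError("k must be >= 1")
    exclude = exclude or set()
    cands = [s for n, s in scores.items() if n not in exclude]
    if not cands:
        raise ModelError("no eligible candidate nodes to rank")

    def keyval(s: TargetScore) -> float:
        if mode == "conflict":
            return s.conflict_score
        if mode == "undesired":
            return s.undesired_mass
        if mode == "wff":
            return s.wff
        if mode == "abs":
            return abs(s.wff)
        raise ModelError(f"unknown ranking mode {mode!r}; choose from {RANKING_MODES}")

    ranked = sorted(cands, key=lambda s: (-keyval(s), s.node))
    if all(s.desired_mass == 0.0 and s.undesired_mass == 0.0 for s in cands):
        raise ModelError("all candidate scores are zero; ranking is undetermined")
    return ranked[:k]


def flip_ratio(flips: np.ndarray | dict[str, float], transitions: int, nodes: tuple[str, ...] | None = None) -> dict[str, float]:
    """Per-node flip count divided by total transitions of one trajectory."""
    if transitions < 1:
        raise ModelError("flip ratio requires a trajectory with at least one transition")
    if isinstance(flips, dict):
        return {n: c / transitions for n, c in flips.items()}
    assert nodes is not None
    return {n: float(flips[i]) / transitions for i, n in enumerate(nodes)}


def sample_segment_trajectories(
    mtm: MergedTransitionMap,
    seg: Segment,
    n: int,
    rng: np.random.Generator,
    step_budget: int | None = None,
) -> list[tuple[str | None, np.ndarray, int]]:
    """Monte-Carlo trajectories through one segment: seeds drawn by weight,
    uniformly random eligible flips until an absorbing attractor state.

    Returns (destination attractor id, per-node flip counts, transitions)
    per trajectory; the independent stochastic oracle for the
    absorbing-chain factorization."""
    from .dynamics import random_trajectory

    dyn = mtm.pinned_net if seg.label == "regulated" else mtm.net
    funcs = dyn.compiled_rules()
    if step_budget is None:
        step_budget = 10_000 * dyn.n
    seeds = sorted(seg.seeds)
    probs = np.array([seg.seeds[s] for s in seeds])
    probs = probs / probs.sum()
    out = []
    for _ in range(n):
        start = seeds[int(rng.choice(len(seeds), p=probs))]
        out.append(random_trajectory(dyn.n, funcs, start, seg.absorbing, rng, step_budget))
    return out


def average_flip_ratios(
    mtm: MergedTransitionMap,
    n_samples: int = 2_000,
    seed: int | None = None,
    labels: tuple[str, ...] = ("regulated",),
    basins: dict[str, float] | None = None,
    dest_filter: "callable | None" = None,
) -> dict[str, float]:
    """Average per-node state-flipping ratio over sampled transition paths.

    Paths start from the source attractors of the selected segments
    (weighted by basin fraction when available) and run to an attractor of
    the segment's landscape; each path contributes its per-node flip count
    divided by its number of transitions.  Trivial (zero-transition) paths
    are skipped.  ``dest_filter(segment, dest_id)`` optionally restricts
    the statistic to particular path ensembles (e.g. undesired paths)."""
    rng = np.random.default_rng(seed)
    segs = [s for s in mtm.segments if s.label in labels]
    if not segs:
        raise ModelError("merged map has no segments with the requested labels")
    weights = np.array(
        [basins.get(s.source.id, 0.0) if basins else 1.0 for s in segs], dtype=float
    )
    if weights.sum() <= 0:
        weights = np.ones(len(segs))
    weights = weights / weights.sum()
    totals = np.zeros(mtm.net.n)
    count = 0
    for seg, w in zip(segs, weights):
        n_seg = int(round(n_samples * w))
        if n_seg == 0:
            continue
        for dest, flips, steps in sample_segment_trajectories(mtm, seg, n_seg, rng):
            if dest is None or steps == 0:
                continue
            if dest_filter is not None and not dest_filter(seg, dest):
                continue
            totals += flips / steps
            count += 1
    if count == 0:
        raise ModelError("no non-trivial transition paths were sampled")
    ratios = totals / count
    return {mtm.net.nodes[i]: float(ratios[i]) for i in range(mtm.net.n)}


# ---------------------------------------------------------------------------
# signal-flow analysis and control type


def signal_flow_influence(
    g: SignedGraph,
    source: str,
    value: int = 1,
    alpha: float = 0.5,
    max_len: int | None = None,
) -> dict[str, float]:
    """Damped signed path-sum influence of pinning ``source`` to ``value``.

    influence(t) = sum over path lengths L of alpha^L * sum over directed
    paths of length L from source to t of (product of edge signs) /
    (product of branch out-degrees along the path).  Computed by damped
    matrix powers; ``max_len`` defaults to the structural diameter.
    """
    if source not in g.nodes:
        raise ModelError(f"source node {source!r} not in graph")
    if value not in (-1, 1):
        value = 1 if value else -1
    nodes = list(g.nodes)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    W = np.zeros((n, n))
    outdeg = np.zeros(n)
    for u, v, s in g.edges:
        outdeg[idx[u]] += 1
    for u, v, s in g.edges:
        W[idx[u], idx[v]] += s / outdeg[idx[u]]
    if max_len is None:
        structure = g.structure()
        lengths = dict(nx.all_pairs_shortest_path_length(structure))
        max_len = max((d for src in lengths.values() for d in src.values()), default=1)
        max_len = max(max_len, 1)
    x = np.zeros(n)
    x[idx[source]] = float(value)
    acc = np.zeros(n)
    for _ in range(max_len):
        x = alpha * (x @ W)
        acc += x
    return {nodes[i]: float(acc[i]) for i in range(n)}


def determine_control_type(
    g: SignedGraph,
    given: tuple[str, int],
    candidate: str,
    alpha: float = 0.5,
    max_len: int | None = None,
) -> str:
    """Control type for a partner target: the opposite of its propagated
    tendency under the given perturbation (block the conflict channel)."""
    node, pin = given
    value = 1 if pin == 1 else -1
    infl = signal_flow_influence(g, node, value, alpha=alpha, max_len=max_len)
    if candidate not in infl:
        raise ModelError(f"candidate {candidate!r} not in graph")
    tendency = infl[candidate]
    if math.isclose(tendency, 0.0, abs_tol=1e-12):
        raise ModelError(
            f"signal-flow tendency of {candidate!r} is zero/undetermined; evaluate both pin types exhaustively"
        )
    return "OFF" if tendency > 0 else "ON"
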