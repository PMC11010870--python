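"""Merged transition map: segments, ensembles, scores, signal flow."""

import numpy as np
import pytest

from mtmap.boolnet import Perturbation, PhenotypeSpec, SignedGraph, derive_signed_graph, parse_bnet
from mtmap.dynamics import exact_absorption, find_attractors
from mtmap.errors import ModelError
from mtmap.fixtures import make_conflict_network
from mtmap.transition_map import (
    build_mtm,
    determine_control_type,
    factorize_ensembles,
    flip_ratio,
    rank_synergistic_targets,
    sample_segment_trajectories,
    signal_flow_influence,
    transition_probabilities,
    weighted_flipping_frequency,
)


@pytest.fixture(scope="module")
def conflict_mtm(conflict):
    mtm = build_mtm(conflict.network, Perturbation({conflict.target: conflict.target_pin}))
    ensembles = factorize_ensembles(mtm, conflict.phenotype, seed=7)
    return mtm, ensembles


class TestBuild:
    def test_toggle_pin_segments(self, toggle):
        mtm = build_mtm(toggle, Perturbation({"A": 1}))
        assert len(mtm.original_attractors) == 2 and len(mtm.regulated_attractors) == 1
        reg = [s for s in mtm.segments if s.label == "regulated"]
        target_state = toggle.str_to_state("10")
        for seg in reg:
            assert set(seg.absorbing) == {target_state}
        rev = [s for s in mtm.segments if s.label == "reversal"]
        assert len(rev) == 1 and set(rev[0].seeds) == {target_state}
        # the regulated attractor is also an original attractor: trivial reversal
        assert rev[0].absorbing == {target_state: "A0"}

    def test_stable_pin_gives_trivial_segments(self, toggle):
        # pinning B to its value in attractor (0,1) leaves that attractor intact
        mtm = build_mtm(toggle, Perturbation({"B": 1}))
        seg = next(s for s in mtm.segments if s.label == "regulated" and toggle.str_to_state("01") in s.seeds)
        assert set(seg.seeds) <= set(seg.absorbing)

    def test_conflict_reaches_two_regulated_attractors(self, conflict_mtm, conflict):
        mtm, _ = conflict_mtm
        assert len(mtm.regulated_attractors) == 2
        quiescent = next(a for a in mtm.original_attractors if min(a.states) == 0)
        seg = next(s for s in mtm.segments if s.label == "regulated" and s.source.id == quiescent.id)
        assert len(set(seg.absorbing.values())) == 2


class TestTransitionProbabilities:
    def test_uniform_branching(self, conflict_mtm):
        mtm, _ = conflict_mtm
        for seg in mtm.segments:
            probs = transition_probabilities(seg)
            out = {}
            for (s, _), p in probs.items():
                out.setdefault(s, []).append(p)
            for s, ps in out.items():
                assert all(p == ps[0] for p in ps)
                assert sum(ps) == pytest.approx(1.0)


class TestFactorization:
    def test_toggle_contested_absorption(self, toggle):
        """Hand-checkable two-branch case: from (0,0) both fixed points are
        reached with probability 1/2, flipping exactly the node that moves."""
        s00 = toggle.str_to_state("00")
        s10, s01 = toggle.str_to_state("10"), toggle.str_to_state("01")
        succ = {s00: (s10, s01), s10: (), s01: ()}
        h, t_idx, _ = exact_absorption(succ, {s10: "L", s01: "R"}, ["L", "R"])
        assert h[s00][0] == pytest.approx(0.5) and h[s00][1] == pytest.approx(0.5)

    def test_absorption_probabilities_sum_to_one(self, conflict_mtm):
        _, ensembles = conflict_mtm
        totals = {}
        for e in ensembles:
            totals[(e.label, e.source)] = totals.get((e.label, e.source), 0.0) + e.p_absorb
        for total in totals.values():
            assert total == pytest.approx(1.0, abs=1e-9)

    def test_pinned_target_never_flips_in_regulated_ensembles(self, conflict_mtm, conflict):
        _, ensembles = conflict_mtm
        for e in ensembles:
            if e.label == "regulated":
                assert e.flips[conflict.target] == 0.0

    def test_trivial_ensemble_zero_flips(self, toggle):
        # source attractor (0,1) already satisfies the pin B=1: identity path
        mtm = build_mtm(toggle, Perturbation({"B": 1}))
        ens = factorize_ensembles(mtm, PhenotypeSpec({"A": 1.0}), seed=0)
        trivial = [e for e in ens if all(v == 0.0 for v in e.flips.values())]
        assert trivial and all(e.p_absorb == pytest.approx(1.0) for e in trivial)

    def test_pp_signs_match_preference_differences(self, conflict_mtm):
        mtm, ensembles = conflict_mtm
        orig = {a.id: a.preference for a in mtm.original_attractors}
        reg = {a.id: a.preference for a in mtm.regulated_attractors}
        for e in ensembles:
            src = orig[e.source] if e.label == "regulated" else reg[e.source]
            dst = reg[e.dest] if e.label == "regulated" else orig[e.dest]
            assert e.pp == int(np.sign(round(dst - src, 9)))

    def test_expected_flips_match_monte_carlo(self, conflict_mtm, conflict):
        """Independent stochastic oracle: 10,000 sampled trajectories per
        contested segment agree with the absorbing-chain expectations
        within 3 standard errors."""
        mtm, ensembles = conflict_mtm
        rng = np.random.default_rng(123)
        net = conflict.network
        quiescent = next(a for a in mtm.original_attractors if min(a.states) == 0)
        seg = next(s for s in mtm.segments if s.label == "regulated" and s.source.id == quiescent.id)
        n = 10_000
        samples = sample_segment_trajectories(mtm, seg, n, rng)
        for e in ensembles:
            if e.label != "regulated" or e.source != quiescent.id:
                continue
            hits = [f for d, f, _ in samples if d == e.dest]
            p_hat = len(hits) / n
            se_p = np.sqrt(e.p_absorb * (1 - e.p_absorb) / n)
            assert abs(p_hat - e.p_absorb) <= 3 * se_p
            flips = np.array(hits)
            for i, node in enumerate(net.nodes):
                mean = flips[:, i].mean()
                se = flips[:, i].std(ddof=1) / np.sqrt(len(hits))
                assert abs(mean - e.flips[node]) <= 3 * se + 1e-9


class TestScores:
    def test_wff_equals_decomposition_sum(self, conflict_mtm, conflict):
        _, ensembles = conflict_mtm
        scores = weighted_flipping_frequency(ensembles, conflict.network.nodes)
        for s in scores.values():
            total = sum(pp * ts * mass for (_, _, _, pp, ts, mass) in s.decomposition)
            assert s.wff == pytest.approx(total)

    def test_all_neutral_phenotype_is_degenerate(self):
        # marker constant across every attractor of both landscapes: all pp = 0
        net = parse_bnet("A, !B\nB, !A\nC, 0")
        mtm = build_mtm(net, Perturbation({"A": 1}))
        ens = factorize_ensembles(mtm, PhenotypeSpec({"C": 1.0}), seed=0)
        assert all(e.pp == 0 for e in ens)
        scores = weighted_flipping_frequency(ens, net.nodes)
        with pytest.raises(ModelError, match="zero"):
            rank_synergistic_targets(scores, exclude={"C"})

    def test_single_ensemble_product(self):
        from mtmap.transition_map import PathEnsemble

        e = PathEnsemble("A0", "B0", "regulated", 1.0, {"X": 2.0}, 1, 1, 0.5)
        scores = weighted_flipping_frequency([e], ("X",))
        assert scores["X"].wff == pytest.approx(1.0)
        assert scores["X"].desired_mass == pytest.approx(1.0)

    def test_wff_permutation_equivariant(self, conflict):
        """Reordering node declarations must not change any node's score."""
        net = conflict.network
        from mtmap.boolnet import expression_to_bnet, parse_bnet

        text = {n: expression_to_bnet(net.rules[n]) for n in net.nodes}
        order = list(net.nodes)[::-1]
        permuted = parse_bnet("\n".join(f"{n}, {text[n]}" for n in order))
        for model in (net, permuted):
            mtm = build_mtm(model, Perturbation({conflict.target: conflict.target_pin}))
            ens = factorize_ensembles(mtm, conflict.phenotype, seed=3)
            scores = weighted_flipping_frequency(ens, model.nodes)
            if model is net:
                ref = {n: s.conflict_score for n, s in scores.items()}
            else:
                assert {n: pytest.approx(ref[n]) for n in ref} == {
                    n: s.conflict_score for n, s in scores.items()
                }

    def test_interconnect_tops_default_ranking(self, conflict_mtm, conflict):
        _, ensembles = conflict_mtm
        net = conflict.network
        scores = weighted_flipping_frequency(ensembles, net.nodes)
        ranked = rank_synergistic_targets(
            scores, k=5, exclude={conflict.target} | set(conflict.phenotype.markers)
        )
        assert ranked[0].node == conflict.interconnect

    def test_rank_requires_candidates(self, conflict_mtm, conflict):
        _, ensembles = conflict_mtm
        scores = weighted_flipping_frequency(ensembles, conflict.network.nodes)
        with pytest.raises(ModelError):
            rank_synergistic_targets(scores, exclude=set(conflict.network.nodes))


class TestFlipRatio:
    def test_direct_ratio(self):
        assert flip_ratio({"I": 2, "J": 1, "K": 1}, 4)["I"] == 0.5

    def test_hamming_one_path(self):
        assert flip_ratio({"I": 1}, 1)["I"] == 1.0

    def test_zero_length_rejected(self):
        with pytest.raises(ModelError):
            flip_ratio({"I": 0}, 0)


class TestSignalFlow:
    def test_chain_sign_propagation(self):
        g = SignedGraph(("P", "X", "Y"), frozenset({("P", "X", 1), ("X", "Y", -1)}))
        infl = signal_flow_influence(g, "P", 1)
        assert infl["X"] > 0 and infl["Y"] < 0

    def test_unreachable_node_zero(self):
        g = SignedGraph(("P", "X", "Z"), frozenset({("P", "X", 1)}))
        assert signal_flow_influence(g, "P", 1)["Z"] == 0.0

    def test_balanced_dual_paths_attenuate(self):
        """Two length-2 paths of opposite sign partially cancel versus a
        single path of the same length (explicit path-sum check)."""
        balanced = SignedGraph(
            ("P", "U", "V", "T"),
            frozenset({("P", "U", 1), ("P", "V", 1), ("U", "T", 1), ("V", "T", -1)}),
        )
        single = SignedGraph(
            ("P", "U", "T"),
            frozenset({("P", "U", 1), ("U", "T", 1)}),
        )
        b = abs(signal_flow_influence(balanced, "P", 1)["T"])
        s = abs(signal_flow_influence(single, "P", 1)["T"])
        assert b < s
        # explicit sum: alpha^2 * (1/2 - 1/2) = 0 for the balanced pair
        assert b == pytest.approx(0.0, abs=1e-12)

    def test_control_type_is_opposite_of_tendency(self):
        g = SignedGraph(("P", "X"), frozenset({("P", "X", -1)}))
        assert determine_control_type(g, ("P", 1), "X") == "ON"
        g2 = SignedGraph(("P", "X"), frozenset({("P", "X", 1)}))
        assert determine_control_type(g2, ("P", 1), "X") == "OFF"

    def test_zero_tendency_rejected(self):
        g = SignedGraph(("P", "X", "Z"), frozenset({("P", "X", 1)}))
        with pytest.raises(ModelError, match="undetermined"):
            determine_control_type(g, ("P", 1), "Z")

    def test_conflict_fixture_type_matches_sps_optimum(self, conflict):
        g = derive_signed_graph(conflict.network)
        ct = determine_control_type(g, (conflict.target, conflict.target_pin), conflict.interconnect)
        assert (1 if ct == "ON" else 0) == conflict.optimal_pair[conflict.interconnect]
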