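from __future__ import annotations

import math

import numpy as np
import pytest

from openmoa import (
    ActionPathSet,
    SignatureEntry,
    accumulate_edge_pscores,
    assign_action_pscores,
    constrained_shortest_paths,
    score_perturbation,
)
from openmoa.ingest import PPI, REGULATORY
from openmoa.pathweight import read_weighted_edges, write_weighted_edges

from bruteforce import (
    brute_constrained_shortest_paths,
    brute_score,
    csp_via_tf_append,
    random_scoring_case,
    random_typed_network,
)
from conftest import make_network


class TestConstrainedShortestPaths:
    def test_direct_regulation(self):
        net = make_network(regulatory=[("T", "G")])
        action = constrained_shortest_paths(net, "T", "G")
        assert action.paths == [(("T", "G", REGULATORY),)]
        assert action.m == 1 and action.length == 1

    def test_endpoint_without_incoming_regulation_is_unreachable(self):
        net = make_network(ppi=[("A", "B")], regulatory=[("A", "C")])
        assert constrained_shortest_paths(net, "A", "B") is None

    def test_unknown_node_error_names_it(self, chain_network):
        with pytest.raises(KeyError, match="NOPE"):
            constrained_shortest_paths(chain_network, "A", "NOPE")

    def test_start_equal_endpoint_rejected(self, chain_network):
        with pytest.raises(ValueError):
            constrained_shortest_paths(chain_network, "G", "G")

    def test_chain_path(self, chain_network):
        action = constrained_shortest_paths(chain_network, "A", "G")
        assert action.paths == [
            (("A", "B", PPI), ("B", "T", PPI), ("T", "G", REGULATORY))
        ]

    def test_unconstrained_shortcut_does_not_reduce_length(self):
        # S->G ppi is shorter but inadmissible; the constrained minimum
        # must still be found through the TF
        net = make_network(ppi=[("S", "G"), ("S", "T")], regulatory=[("T", "G")])
        action = constrained_shortest_paths(net, "S", "G")
        assert action.length == 2
        assert action.paths == [(("S", "T", PPI), ("T", "G", REGULATORY))]

    def test_max_len_truncates(self, chain_network):
        assert constrained_shortest_paths(chain_network, "A", "G", max_len=2) is None

    def test_parallel_edge_types_multiply_paths(self):
        # T-M ppi in parallel with T->M regulatory: two length-2 paths to G
        net = make_network(
            ppi=[("S", "T"), ("T", "M")],
            regulatory=[("T", "M"), ("M", "G"), ("T", "X")],
        )
        action = constrained_shortest_paths(net, "S", "M")
        assert action.m == 1  # final hop must be the regulatory edge
        assert action.paths == [(("S", "T", PPI), ("T", "M", REGULATORY))]
        # mid-path the same parallel pair yields two distinct edge sequences
        action = constrained_shortest_paths(net, "S", "G")
        assert action.m == 2
        assert {p[1][2] for p in action.paths} == {PPI, REGULATORY}

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        case = random_scoring_case(rng)
        if case is None:
            return
        net, start, endpoints = case
        for entry in endpoints:
            got = constrained_shortest_paths(net, start, entry.gene_id, max_len=6)
            expected = brute_constrained_shortest_paths(net, start, entry.gene_id, max_len=6)
            if expected is None:
                assert got is None
            else:
                assert got.paths == expected

    @pytest.mark.parametrize("seed", range(40))
    def test_equivalent_to_tf_then_append_formulation(self, seed):
        rng = np.random.default_rng(seed + 1000)
        case = random_scoring_case(rng)
        if case is None:
            return
        net, start, endpoints = case
        for entry in endpoints:
            got = constrained_shortest_paths(net, start, entry.gene_id, max_len=6)
            alt = csp_via_tf_append(net, start, entry.gene_id, max_len=6)
            assert (got.paths if got else None) == alt


def synthetic_action(fdr, m):
    paths = [
        ((f"N{i}", "T", PPI), ("T", "E", REGULATORY)) for i in range(m)
    ]
    return ActionPathSet("S", "E", paths, endpoint_fdr=fdr)


class TestPenaltyAssignment:
    @pytest.mark.parametrize(
        "fdr, m, expected",
        [(0.01, 1, 0.01), (0.04, 2, 0.2), (0.001, 3, 0.1)],
    )
    def test_even_split_is_mth_root(self, fdr, m, expected):
        scores = assign_action_pscores(synthetic_action(fdr, m))
        assert len(scores) == m + 1  # m first hops plus the shared final edge
        for value in scores.values():
            assert value == pytest.approx(expected, abs=1e-12)

    def test_shared_edge_assigned_once_per_action(self):
        scores = assign_action_pscores(synthetic_action(0.04, 2))
        assert scores[("T", "E", REGULATORY)] == pytest.approx(0.2, abs=1e-12)

    def test_empty_action_is_an_error(self):
        with pytest.raises(ValueError, match="m = 0"):
            assign_action_pscores(ActionPathSet("S", "E", [], 0.1))

    def test_fdr_out_of_range_is_an_error(self):
        with pytest.raises(ValueError):
            assign_action_pscores(synthetic_action(0.0, 1))


class TestAccumulation:
    def test_product_across_actions_and_confidence(self):
        net = make_network(ppi=[("S", "T")], regulatory=[("T", "E"), ("T", "F")])
        a1 = constrained_shortest_paths(net, "S", "E", endpoint_fdr=0.1)
        a2 = constrained_shortest_paths(net, "S", "F", endpoint_fdr=0.2)
        weighted = {w.key: w for w in accumulate_edge_pscores(net, [a1, a2])}
        shared = weighted[("S", "T", PPI)]
        assert 10.0**shared.log10_pscore == pytest.approx(0.02, abs=1e-12)
        assert shared.confidence == pytest.approx(0.98, abs=1e-12)
        assert shared.n_actions == 2

    def test_single_action_product_is_identity(self):
        net = make_network(ppi=[("S", "T")], regulatory=[("T", "E")])
        a = constrained_shortest_paths(net, "S", "E", endpoint_fdr=0.09)
        weighted = {w.key: w for w in accumulate_edge_pscores(net, [a])}
        for key in [("S", "T", PPI), ("T", "E", REGULATORY)]:
            assert 10.0**weighted[key].log10_pscore == pytest.approx(0.09, abs=1e-12)
            assert weighted[key].confidence == pytest.approx(0.91, abs=1e-12)

    def test_untouched_edges_have_zero_confidence(self):
        net = make_network(ppi=[("S", "T")], regulatory=[("T", "E"), ("X", "Y")])
        a = constrained_shortest_paths(net, "S", "E", endpoint_fdr=0.1)
        weighted = {w.key: w for w in accumulate_edge_pscores(net, [a])}
        assert weighted[("X", "Y", REGULATORY)].log10_pscore == 0.0
        assert weighted[("X", "Y", REGULATORY)].confidence == 0.0

    def test_thousand_actions_accumulate_without_underflow(self):
        net = make_network(regulatory=[("T", "E")])
        actions = [
            ActionPathSet("T", "E", [(("T", "E", REGULATORY),)], endpoint_fdr=0.5)
            for _ in range(1000)
        ]
        (weighted,) = accumulate_edge_pscores(net, actions)
        # exact in log space even though 0.5**1000 ~ 1e-302 underflows linearly
        assert weighted.log10_pscore == pytest.approx(1000 * math.log10(0.5), rel=1e-12)
        assert weighted.n_actions == 1000

    def test_confidence_consistent_with_log_field(self):
        net = make_network(regulatory=[("T", "E")])
        a = constrained_shortest_paths(net, "T", "E", endpoint_fdr=0.37)
        (w,) = accumulate_edge_pscores(net, [a])
        assert abs(w.confidence - (1.0 - 10.0**w.log10_pscore)) < 1e-12


class TestScorePerturbation:
    def test_unknown_start_is_an_error(self, chain_network):
        with pytest.raises(KeyError):
            score_perturbation(chain_network, "MISSING", [])

    def test_no_reachable_endpoint_scores_nothing(self, chain_network):
        endpoints = [SignatureEntry("B", 0.0, 0.5, 0.5)]  # B has no reg in-edge
        weighted = score_perturbation(chain_network, "A", endpoints)
        assert all(w.confidence == 0.0 for w in weighted)

    def test_single_endpoint_two_edge_path(self):
        net = make_network(ppi=[("S", "T")], regulatory=[("T", "E")])
        weighted = score_perturbation(net, "S", [SignatureEntry("E", 0, 0.05, 0.09)])
        scored = {w.key: w for w in weighted if w.n_actions > 0}
        assert set(scored) == {("S", "T", PPI), ("T", "E", REGULATORY)}
        for w in scored.values():
            assert w.confidence == pytest.approx(0.91, abs=1e-12)

    def test_endpoint_equal_to_start_is_skipped(self):
        net = make_network(ppi=[("S", "T")], regulatory=[("T", "E"), ("T", "S")])
        weighted = score_perturbation(net, "S", [SignatureEntry("S", 0, 0.01, 0.01)])
        assert all(w.n_actions == 0 for w in weighted)

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_naive_reimplementation(self, seed):
        rng = np.random.default_rng(seed + 2000)
        case = random_scoring_case(rng)
        if case is None:
            return
        net, start, endpoints = case
        weighted = score_perturbation(net, start, endpoints, max_len=6)
        expected = brute_score(net, start, endpoints, max_len=6)
        for w in weighted:
            ps, conf, n = expected[w.key]
            assert 10.0**w.log10_pscore == pytest.approx(ps, abs=1e-9)
            assert w.confidence == pytest.approx(conf, abs=1e-9)
            assert w.n_actions == n

    @pytest.mark.parametrize("seed", range(15))
    def test_action_order_invariance_is_bitwise(self, seed):
        rng = np.random.default_rng(seed + 3000)
        case = random_scoring_case(rng)
        if case is None:
            return
        net, start, endpoints = case
        forward = score_perturbation(net, start, endpoints, max_len=6)
        backward = score_perturbation(net, start, endpoints[::-1], max_len=6)
        assert forward == backward

    @pytest.mark.parametrize("seed", range(15))
    def test_adding_an_action_never_decreases_confidence(self, seed):
        rng = np.random.default_rng(seed + 4000)
        case = random_scoring_case(rng)
        if case is None or len(case[2]) < 2:
            return
        net, start, endpoints = case
        fewer = {w.key: w for w in score_perturbation(net, start, endpoints[:-1], max_len=6)}
        more = {w.key: w for w in score_perturbation(net, start, endpoints, max_len=6)}
        for key, w in more.items():
            assert w.confidence >= fewer[key].confidence
            assert w.log10_pscore <= fewer[key].log10_pscore

    @pytest.mark.parametrize("seed", range(15))
    def test_per_action_penalty_at_least_endpoint_fdr(self, seed):
        rng = np.random.default_rng(seed + 5000)
        case = random_scoring_case(rng)
        if case is None:
            return
        net, start, endpoints = case
        for entry in endpoints:
            action = constrained_shortest_paths(
                net, start, entry.gene_id, max_len=6, endpoint_fdr=entry.fdr
            )
            if action is None:
                continue
            for value in assign_action_pscores(action).values():
                assert value >= entry.fdr - 1e-15
                if action.m == 1:
                    assert value == pytest.approx(entry.fdr, rel=1e-12)
                else:
                    assert value > entry.fdr


def test_weighted_edge_table_round_trip(tmp_path):
    net = make_network(ppi=[("S", "T")], regulatory=[("T", "E")])
    weighted = score_perturbation(net, "S", [SignatureEntry("E", 0, 0.05, 0.09)])
    path = tmp_path / "weighted.tsv"
    write_weighted_edges(weighted, path)
    again = read_weighted_edges(path)
    assert [w.key for w in again] == [w.key for w in weighted]
    for a, b in zip(again, weighted):
        assert a.log10_pscore == pytest.approx(b.log10_pscore, rel=1e-11)
        assert a.n_actions == b.n_actions
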