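"""Similarity matrix, normal-fit thresholding and auxiliary scores."""

import numpy as np
import pandas as pd
import pytest

from mirlink.network import (
    AssociationNetwork,
    SimilarityMatrix,
    build_similarity_matrix,
    fit_threshold,
    meet_min,
    normal_cutoff,
    overlap_vs_similarity,
    tanimoto,
    threshold_network,
    vote_targets,
)
from mirlink.synthetic import make_association_scenario

from oracles import spearman_by_rank_formula


class TestBuildSimilarityMatrix:
    def test_identical_term_sets_score_one(self, seven_term_dag, seven_term_ic):
        terms = {"A1", "B1"}
        matrix = build_similarity_matrix(
            {"sm": terms}, {"mir": set(terms)}, seven_term_dag, seven_term_ic
        )
        assert matrix.scores.loc["sm", "mir"] == pytest.approx(1.0)

    def test_root_only_common_ancestor_scores_zero(self, seven_term_dag, seven_term_ic):
        matrix = build_similarity_matrix(
            {"sm": {"A1", "A2"}}, {"mir": {"B1", "B2"}}, seven_term_dag, seven_term_ic
        )
        assert matrix.scores.loc["sm", "mir"] == 0.0

    def test_empty_profiles_are_dropped(self, seven_term_dag, seven_term_ic):
        matrix = build_similarity_matrix(
            {"sm1": {"A1"}, "sm2": set()}, {"mir": {"A2"}},
            seven_term_dag, seven_term_ic,
        )
        assert list(matrix.scores.index) == ["sm1"]

    def test_planted_pairs_beat_background(self):
        """Planted pairs must exceed the 95th percentile of background scores."""
        for seed in (0, 1, 2):
            sc = make_association_scenario(seed=seed)
            matrix = build_similarity_matrix(
                sc.sm_profiles, sc.mirna_profiles, sc.dag, sc.ic_map
            )
            planted = set(sc.planted_pairs)
            planted_scores = [matrix.scores.loc[sm, mir] for sm, mir in planted]
            background = [
                matrix.scores.loc[sm, mir]
                for sm in matrix.scores.index
                for mir in matrix.scores.columns
                if (sm, mir) not in planted
            ]
            assert min(planted_scores) > np.percentile(background, 95)


class TestFitThreshold:
    def test_printed_fit_reproduces_cutoff(self):
        assert normal_cutoff(0.4882, 0.0965, 0.01) == pytest.approx(0.7127, abs=5e-5)

    def test_alpha_half_boundary_is_mu(self):
        assert normal_cutoff(0.3, 0.1, 0.4999999) == pytest.approx(0.3, abs=1e-6)

    def test_standard_normal_scores_give_z_cutoff(self):
        rng = np.random.default_rng(0)
        fit = fit_threshold(rng.normal(0, 1, 200_00), alpha=0.01)
        assert fit.cutoff == pytest.approx(2.3263, abs=0.05)

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        fit = fit_threshold(scores, 0.01)
        shifted = fit_threshold(scores + 0.25, 0.01)
        assert shifted.cutoff == pytest.approx(fit.cutoff + 0.25, abs=1e-12)
        scaled = fit_threshold(scores * 3.0, 0.01)
        assert scaled.cutoff - scaled.mu == pytest.approx(
            3.0 * (fit.cutoff - fit.mu), abs=1e-9
        )

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            fit_threshold([0.5, 0.5, 0.5])


class TestThresholdNetwork:
    def matrix3(self, values):
        return SimilarityMatrix(
            pd.DataFrame(values, index=["s1", "s2", "s3"], columns=["m1", "m2", "m3"])
        )

    def test_all_below_cutoff_gives_empty_network(self):
        fit = fit_threshold(np.linspace(0.1, 0.5, 9), 0.01)
        matrix = self.matrix3(np.full((3, 3), 0.2))
        assert len(threshold_network(matrix, fit).edges) == 0

    def test_cells_at_or_above_cutoff_become_edges(self):
        matrix = self.matrix3(
            [[0.9, 0.1, 0.1], [0.1, 0.85, 0.1], [0.1, 0.1, 0.1]]
        )
        fit = fit_threshold(matrix.flat(), alpha=0.05)
        net = threshold_network(matrix, fit)
        assert net.edge_set() == {("s1", "m1"), ("s2", "m2")}
        assert (net.edges["score"] >= fit.cutoff).all()

    def test_boundary_score_is_included(self):
        from mirlink.network import NormalFit

        matrix = self.matrix3(np.diag([0.7127, 0.0, 0.0]))
        fit = NormalFit(mu=0.4882, sigma=0.0965, alpha=0.01,
                        cutoff=normal_cutoff(0.4882, 0.0965, 0.01))
        net = threshold_network(matrix, fit)
        assert ("s1", "m1") in net.edge_set()

    def test_planted_scenario_edges_recovered(self):
        sc = make_association_scenario(seed=3)
        matrix = build_similarity_matrix(
            sc.sm_profiles, sc.mirna_profiles, sc.dag, sc.ic_map
        )
        net = threshold_network(matrix, fit_threshold(matrix.flat(), 0.01))
        assert net.edge_set() == set(sc.planted_pairs)


class TestOverlapScores:
    def test_meet_min_hand_and_boundary_values(self):
        assert meet_min({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(2 / 3)
        assert meet_min({"a"}, {"a"}) == 1.0
        assert meet_min({"a"}, {"b"}) == 0.0
        with pytest.raises(ValueError):
            meet_min(set(), {"a"})

    def test_meet_min_symmetric(self):
        assert meet_min({"a", "b"}, {"b", "c", "d"}) == meet_min(
            {"b", "c", "d"}, {"a", "b"}
        )

    def test_tanimoto_hand_and_boundary_values(self):
        assert tanimoto("1100", "1010") == pytest.approx(1 / 3)
        assert tanimoto("1011", "1011") == 1.0
        assert tanimoto("1100", "0011") == 0.0
        assert tanimoto("0000", "0000") == 0.0
        with pytest.raises(ValueError):
            tanimoto("110", "1100")

    def test_tanimoto_symmetric_in_unit_interval(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a = "".join(rng.choice(["0", "1"], 16))
            b = "".join(rng.choice(["0", "1"], 16))
            assert tanimoto(a, b) == tanimoto(b, a)
            assert 0.0 <= tanimoto(a, b) <= 1.0


class TestVoteTargets:
    tables = [
        {"miR-1": {"g1", "g2"}, "miR-2": {"g3"}},
        {"miR-1": {"g1"}, "miR-2": {"g4"}},
        {"miR-1": {"g1", "g5"}},
    ]

    def test_pair_in_two_tables_is_kept(self):
        out = vote_targets(self.tables, min_algorithms=2)
        assert "g2" not in out.get("miR-1", set())  # only 1 vote
        assert "g1" in out["miR-1"]  # 3 votes

    def test_pair_in_single_table_is_dropped(self):
        out = vote_targets(self.tables, min_algorithms=2)
        assert "miR-2" not in out  # g3, g4 each appear once

    def test_needs_at_least_two_tables(self):
        with pytest.raises(ValueError):
            vote_targets([self.tables[0]])


class TestOverlapVsSimilarity:
    def network(self, rows):
        return AssociationNetwork(
            edges=pd.DataFrame(rows, columns=["small_molecule", "mirna", "score"]),
            cutoff=0.0,
        )

    def test_perfect_monotone_counts_give_r_one(self):
        net = self.network(
            [("s1", "m1", 0.7), ("s2", "m2", 0.8), ("s3", "m3", 0.9)]
        )
        sm_targets = {"s1": {"a"}, "s2": {"a", "b"}, "s3": {"a", "b", "c"}}
        mir_targets = {m: {"a", "b", "c"} for m in ("m1", "m2", "m3")}
        report = overlap_vs_similarity(net, sm_targets, mir_targets)
        assert report["defined"] and report["r"] == pytest.approx(1.0)

    def test_constant_counts_are_flagged_undefined(self):
        net = self.network(
            [("s1", "m1", 0.7), ("s2", "m2", 0.8), ("s3", "m3", 0.9)]
        )
        targets = {k: {"a"} for k in ("s1", "s2", "s3", "m1", "m2", "m3")}
        report = overlap_vs_similarity(net, targets, targets)
        assert not report["defined"]

    def test_too_few_edges_undefined(self):
        net = self.network([("s1", "m1", 0.7)])
        report = overlap_vs_similarity(net, {"s1": {"a"}}, {"m1": {"a"}})
        assert not report["defined"]

    def test_matches_independent_rank_formula_on_hand_data(self):
        scores = [0.71, 0.74, 0.78, 0.80, 0.92]
        counts = [0, 2, 1, 5, 9]
        rows = [
            (f"s{i}", f"m{i}", s) for i, s in enumerate(scores)
        ]
        net = self.network(rows)
        sm_targets = {f"s{i}": {f"t{j}" for j in range(c)} for i, c in enumerate(counts)}
        mir_targets = {f"m{i}": {f"t{j}" for j in range(10)} for i in range(5)}
        report = overlap_vs_similarity(net, sm_targets, mir_targets)
        assert report["r"] == pytest.approx(
            spearman_by_rank_formula(counts, scores), abs=1e-12
        )
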