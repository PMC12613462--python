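"""FAHP weighting: closed forms, consistency diagnostics, recovery."""

import itertools

import numpy as np
import pytest

import fohi
from fohi.fahp import (
    FahpError,
    judgment_matrix_from_array,
    level_ids,
    principal_eigenvalue,
)
from fohi.simulate import expected_expert_panel


def brute_force_weights(unit_matrix: np.ndarray) -> np.ndarray:
    """Direct product/root/normalize evaluation of the weight formula."""
    n = unit_matrix.shape[0]
    gm = np.array([np.prod(unit_matrix[i]) ** (1.0 / n) for i in range(n)])
    return gm / gm.sum()


class TestBuildJudgmentMatrix:
    def test_paper_reciprocal_rule(self):
        votes = fohi.ExpertVotes("L", ["i", "j"], 23, {("i", "j"): 12})
        jm = fohi.build_judgment_matrix(votes)
        assert jm.count_matrix[0, 1] == 12
        assert jm.count_matrix[1, 0] == pytest.approx(23 / 12)
        assert jm.count_matrix[0, 0] == jm.count_matrix[1, 1] == 11.5
        assert jm.unit_matrix[0, 0] == 0.5

    def test_unanimous_count_clamped(self):
        votes = fohi.ExpertVotes("L", ["i", "j"], 23, {("i", "j"): 23})
        jm = fohi.build_judgment_matrix(votes)
        assert jm.count_matrix[0, 1] == 22.5
        assert jm.count_matrix[1, 0] == pytest.approx(23 / 22.5)
        # the pairwise product invariant of the reciprocal rule
        assert jm.count_matrix[0, 1] * jm.count_matrix[1, 0] == pytest.approx(23)

    def test_complement_mode(self):
        votes = fohi.ExpertVotes("L", ["i", "j"], 23, {("i", "j"): 12})
        jm = fohi.build_judgment_matrix(votes, mode="complement")
        assert jm.count_matrix[1, 0] == 11

    def test_count_out_of_range_rejected(self):
        votes = fohi.ExpertVotes("L", ["i", "j"], 23, {("i", "j"): 24})
        with pytest.raises((FahpError, fohi.simulate.SimulationError)):
            fohi.build_judgment_matrix(votes)

    def test_ratio_matrix_reciprocal(self):
        votes = fohi.generate_expert_panel(list("abcd"), [0.4, 0.3, 0.2, 0.1], 23, seed=2)
        for mode in ("ratio_reciprocal", "complement"):
            jm = fohi.build_judgment_matrix(votes, mode=mode)
            assert np.allclose(jm.ratio_matrix * jm.ratio_matrix.T, 1.0)
            assert (jm.count_matrix > 0).all()


class TestGeometricMeanWeights:
    def test_indifferent_matrix_gives_equal_weights(self):
        n = 23
        a = np.full((4, 4), n / 2.0)
        jm = judgment_matrix_from_array(list("abcd"), a, n)
        assert fohi.geometric_mean_weights(jm) == pytest.approx([0.25] * 4)

    def test_consistent_matrix_recovers_generating_weights(self):
        w = np.array([0.5, 0.3, 0.2])
        a = np.outer(w, 1.0 / w)  # a_ij = w_i / w_j
        jm = judgment_matrix_from_array(list("abc"), a, n_experts=1)
        assert fohi.geometric_mean_weights(jm) == pytest.approx(w, abs=1e-12)

    def test_matches_brute_force_formula(self):
        # 3x3 count matrix from pair counts 12, 15, 9 of 23 (paper mode)
        votes = fohi.ExpertVotes(
            "L", list("abc"), 23, {("a", "b"): 12, ("a", "c"): 15, ("b", "c"): 9}
        )
        jm = fohi.build_judgment_matrix(votes)
        assert fohi.geometric_mean_weights(jm) == pytest.approx(
            brute_force_weights(jm.unit_matrix), abs=1e-12
        )

    def test_scale_covariance_count_vs_unit_matrix(self, rng):
        a = np.exp(rng.normal(size=(5, 5)))
        jm_count = judgment_matrix_from_array(list("abcde"), a, n_experts=23)
        jm_unit = judgment_matrix_from_array(list("abcde"), a / 23, n_experts=1)
        assert fohi.geometric_mean_weights(jm_count) == pytest.approx(
            fohi.geometric_mean_weights(jm_unit), abs=1e-12
        )

    def test_diagonal_convention_cancels(self, rng):
        a = np.exp(rng.normal(size=(4, 4)))
        for diag in (0.5, 1.0, 11.5):
            b = a.copy()
            np.fill_diagonal(b, diag)
            jm = judgment_matrix_from_array(list("abcd"), b, n_experts=23)
            if diag == 0.5:
                ref = fohi.geometric_mean_weights(jm)
            else:
                assert fohi.geometric_mean_weights(jm) == pytest.approx(ref, abs=1e-12)

    @pytest.mark.parametrize("mode", ["ratio_reciprocal", "complement"])
    def test_relabeling_permutes_weights_identically(self, mode):
        votes = fohi.generate_expert_panel(list("abcd"), [0.4, 0.3, 0.2, 0.1], 23, seed=8)
        jm = fohi.build_judgment_matrix(votes, mode)
        w = dict(zip(jm.items, fohi.geometric_mean_weights(jm)))
        rename = {"a": "w", "b": "x", "c": "y", "d": "z"}
        votes_p = fohi.ExpertVotes(
            "L",
            [rename[i] for i in ("c", "a", "d", "b")],  # reordered item list
            23,
            {(rename[i], rename[j]): c for (i, j), c in votes.counts.items()},
        )
        jm_p = fohi.build_judgment_matrix(votes_p, mode)
        w_p = dict(zip(jm_p.items, fohi.geometric_mean_weights(jm_p)))
        for old, new in rename.items():
            assert w_p[new] == pytest.approx(w[old], abs=1e-12)


class TestConsistencyRatio:
    def test_consistent_matrix_gives_lambda_n_and_cr_zero(self):
        w = np.array([0.5, 0.3, 0.15, 0.05])
        a = np.outer(w, 1.0 / w)
        jm = judgment_matrix_from_array(list("abcd"), a, 1)
        res = fohi.consistency_ratio(jm)
        assert res.lambda_max == pytest.approx(4.0, abs=1e-8)
        assert res.cr == pytest.approx(0.0, abs=1e-8)
        assert res.passes_strict

    def test_two_items_cr_zero_by_convention(self):
        votes = fohi.ExpertVotes("L", ["i", "j"], 23, {("i", "j"): 20})
        res = fohi.consistency_ratio(fohi.build_judgment_matrix(votes))
        assert res.cr == 0.0

    def test_lambda_max_matches_eigenvalue_oracle(self, rng):
        # random reciprocal 4x4 instance vs numpy's full eigensolver
        upper = np.exp(rng.normal(size=6))
        r = np.ones((4, 4))
        idx = list(itertools.combinations(range(4), 2))
        for (i, j), v in zip(idx, upper):
            r[i, j] = v
            r[j, i] = 1.0 / v
        lam = principal_eigenvalue(r)
        oracle = max(np.linalg.eigvals(r).real)
        assert lam == pytest.approx(oracle, abs=1e-8)

    def test_non_reciprocal_matrix_rejected(self):
        jm = judgment_matrix_from_array(list("abc"), np.ones((3, 3)), 1)
        jm.ratio_matrix = np.array([[1.0, 2.0, 1.0], [1.0, 1.0, 1.0], [1.0, 1.0, 1.0]])
        with pytest.raises(FahpError, match="reciprocal"):
            fohi.consistency_ratio(jm)


class TestWeightTree:
    def test_levels_cover_top_and_multi_key_categories(self, fukuoka):
        assert level_ids(fukuoka) == ["top", "A", "B", "C"]

    def test_all_levels_normalized(self, weight_tree, fukuoka):
        assert sum(weight_tree.category_weights.values()) == pytest.approx(1.0)
        for c in fukuoka.categories:
            kis = [k.key_index_id for k in fukuoka.key_indices_of(c.category_id)]
            assert sum(weight_tree.key_index_weights[k] for k in kis) == pytest.approx(1.0)
        for k in fukuoka.key_indices:
            inds = fukuoka.indicators_of(k.key_index_id)
            assert sum(
                weight_tree.indicator_weights[i.indicator_id] for i in inds
            ) == pytest.approx(1.0)

    def test_indicator_weights_equal_within_key_index(self, weight_tree, fukuoka):
        for k in fukuoka.key_indices:
            inds = fukuoka.indicators_of(k.key_index_id)
            ws = {weight_tree.indicator_weights[i.indicator_id] for i in inds}
            assert len(ws) == 1

    def test_recovers_category_ordering_from_true_weights(self, fukuoka):
        # panel simulated from true top-level weights (EDI .225 < IDI .366 <
        # CDI .409); a large panel so the close CDI/IDI pair (preference
        # probability 0.528) is ordered by signal rather than by the draw
        from fohi.io import simulate_default_votes

        votes = simulate_default_votes(fukuoka, n_experts=2300, seed=11)
        tree = fohi.derive_weight_tree(votes, fukuoka, mode="complement")
        cw = tree.category_weights
        assert cw["C"] > cw["B"] > cw["A"]

    def test_indifferent_panel_gives_near_equal_weights(self):
        # all counts ~ n/2 at n_experts = 2000 -> weights ~ 1/n within 0.05
        items = list("abcde")
        votes = fohi.generate_expert_panel(items, [0.2] * 5, 2000, seed=4)
        jm = fohi.build_judgment_matrix(votes, mode="complement")
        w = fohi.geometric_mean_weights(jm)
        assert np.abs(w - 0.2).max() < 0.05

    def test_missing_level_reported(self, fukuoka):
        from fohi.io import simulate_default_votes

        votes = simulate_default_votes(fukuoka, n_experts=23, seed=11)
        del votes["B"]
        with pytest.raises(FahpError, match="B"):
            fohi.derive_weight_tree(votes, fukuoka)

    def test_item_mismatch_reported(self, fukuoka):
        from fohi.io import simulate_default_votes

        votes = simulate_default_votes(fukuoka, n_experts=23, seed=11)
        votes["top"] = fohi.generate_expert_panel(["X", "Y", "Z"], [1, 1, 1], 23, 0, "top")
        with pytest.raises(FahpError, match="top"):
            fohi.derive_weight_tree(votes, fukuoka)

    def test_effective_weights_sum_to_one(self, weight_tree, fukuoka):
        eff = fohi.effective_indicator_weights(weight_tree, fukuoka)
        assert sum(eff.values()) == pytest.approx(1.0)
        assert len(eff) == 34


class TestRecoveryConvergence:
    @pytest.mark.parametrize("mode", ["ratio_reciprocal", "complement"])
    def test_error_vs_noise_free_fixed_point_decreases(self, mode):
        """More experts -> weights closer to the noise-free fixed point."""
        items = list("abc")
        truth = np.array([0.409, 0.366, 0.225])
        seeds = {23: 101, 230: 102, 2300: 103}
        errors = []
        for n_experts, seed in seeds.items():
            votes = fohi.generate_expert_panel(items, truth, n_experts, seed)
            w = fohi.geometric_mean_weights(fohi.build_judgment_matrix(votes, mode))
            exp_votes = expected_expert_panel(items, truth, n_experts)
            w_inf = fohi.geometric_mean_weights(
                fohi.build_judgment_matrix(exp_votes, mode)
            )
            errors.append(np.abs(w - w_inf).sum())
        assert errors[0] > errors[1] > errors[2]

    def test_ordering_matches_truth_at_2300_experts(self):
        items = list("abc")
        truth = np.array([0.409, 0.366, 0.225])
        votes = fohi.generate_expert_panel(items, truth, 2300, seed=103)
        w = fohi.geometric_mean_weights(fohi.build_judgment_matrix(votes))
        assert w[0] > w[1] > w[2]
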