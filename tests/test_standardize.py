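"""Standardization: formula oracles, discrete scoring, imputation, pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fohi
from fohi.standardize import (
    StandardizationError,
    standardize_indicator,
)


def oracle_numeric(values: np.ndarray, reverse: bool) -> np.ndarray:
    """Independent composition of the three published formulas."""
    med = np.median(values)
    iqr = np.percentile(values, 75) - np.percentile(values, 25)
    scaled = (values - med) / iqr * 100.0
    score = (scaled - scaled.min()) / (scaled.max() - scaled.min()) * 100.0
    return 100.0 - score if reverse else score


class TestRobustScale:
    def test_declared_quantile_convention(self):
        # Q1=2, Q3=4, median=3 under linear interpolation
        out = fohi.robust_scale([1, 2, 3, 4, 5])
        assert out == pytest.approx([-100, -50, 0, 50, 100])

    def test_median_maps_to_zero(self):
        out = fohi.robust_scale([10, 20, 30])
        assert out[1] == 0.0

    def test_constant_vector_signals_degenerate_scale(self):
        with pytest.raises(StandardizationError, match="degenerate"):
            fohi.robust_scale([5, 5, 5, 5])

    def test_too_few_observed(self):
        with pytest.raises(StandardizationError):
            fohi.robust_scale([1.0])


class TestMinmaxRescale:
    def test_endpoints(self):
        out = fohi.minmax_rescale([-100, -50, 0, 50, 100])
        assert out == pytest.approx([0, 25, 50, 75, 100])

    def test_idempotent_on_full_span(self):
        x = np.array([0.0, 30.0, 100.0])
        once = fohi.minmax_rescale(x)
        assert fohi.minmax_rescale(once) == pytest.approx(once)

    def test_degenerate_range(self):
        with pytest.raises(StandardizationError, match="degenerate"):
            fohi.minmax_rescale([7, 7])


class TestReverseScore:
    def test_endpoints_and_linearity(self):
        assert fohi.reverse_score([0.0, 25.0, 100.0]) == pytest.approx([100, 75, 0])

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=10))
    def test_involution(self, xs):
        out = fohi.reverse_score(fohi.reverse_score(xs))
        assert out == pytest.approx(np.asarray(xs))

    def test_rejects_out_of_range(self):
        with pytest.raises(StandardizationError):
            fohi.reverse_score([120.0])


class TestScoreDiscrete:
    def test_binary_mapping(self):
        assert fohi.score_discrete(1, "binary") == 100.0
        assert fohi.score_discrete(0, "binary") == 0.0

    @pytest.mark.parametrize(
        "level,expected", [(1, 0.0), (2, 33.3), (3, 66.7), (4, 100.0)]
    )
    def test_four_level_proportional_scores(self, level, expected):
        assert fohi.score_discrete(level, "ordinal", 4) == expected

    def test_lowest_level_always_zero(self):
        for L in (2, 3, 5, 7):
            assert fohi.score_discrete(1, "ordinal", L) == 0.0

    def test_invalid_level_rejected(self):
        with pytest.raises(StandardizationError):
            fohi.score_discrete(5, "ordinal", 4)
        with pytest.raises(StandardizationError):
            fohi.score_discrete(2, "binary")


class TestImputeBroadcast:
    def test_mean_imputation(self):
        filled, mask = fohi.impute_monitoring([10.0, np.nan, 20.0, np.nan, np.nan])
        assert filled == pytest.approx([10, 15, 20, 15, 15])
        assert mask.tolist() == [False, True, False, True, True]

    def test_identity_when_complete(self):
        filled, mask = fohi.impute_monitoring([1.0, 2.0])
        assert filled == pytest.approx([1, 2])
        assert not mask.any()

    def test_single_observed_value(self):
        filled, _ = fohi.impute_monitoring([np.nan, 7.0, np.nan])
        assert filled == pytest.approx([7, 7, 7])

    def test_all_missing_rejected(self):
        with pytest.raises(StandardizationError):
            fohi.impute_monitoring([np.nan, np.nan])

    def test_broadcast(self):
        out = fohi.broadcast_regional({"r": 7.5}, {"m1": "r", "m2": "r"})
        assert out["m1"] == out["m2"] == 7.5

    def test_broadcast_missing_region_names_unit(self):
        with pytest.raises(StandardizationError, match="m9"):
            fohi.broadcast_regional({"r": 1.0}, {"m9": "s"})


class TestStandardizeTable:
    def test_numeric_indicators_attain_both_endpoints(self, standardized, fukuoka):
        for ind in fukuoka.indicators:
            if ind.value_kind != "numeric" or ind.coverage == "monitoring_sites":
                continue
            col = standardized.scores[ind.indicator_id]
            assert col.min() == pytest.approx(0.0, abs=1e-9)
            assert col.max() == pytest.approx(100.0, abs=1e-9)

    def test_all_scores_in_range_and_complete(self, standardized):
        assert not standardized.scores.isna().any().any()
        assert (standardized.scores.to_numpy() >= -1e-9).all()
        assert (standardized.scores.to_numpy() <= 100 + 1e-9).all()

    def test_higher_worse_best_performer_scores_100(self, raw_table, standardized):
        # A3.1 (unemployment) is reverse-scored: lowest raw value is best
        raw = raw_table.values["A3.1"]
        scores = standardized.scores["A3.1"]
        assert scores[raw.idxmin()] == pytest.approx(100.0)
        assert scores[raw.idxmax()] == pytest.approx(0.0)

    def test_imputed_units_share_transform_of_observed_mean(
        self, raw_table, standardized
    ):
        raw = raw_table.values["A1.2"]
        obs = raw.dropna()
        scores = standardized.scores["A1.2"]
        imputed_scores = scores[raw.isna()]
        assert imputed_scores.nunique() == 1
        expected = oracle_numeric(
            np.append(obs.to_numpy(), obs.mean()), reverse=True
        )[-1]
        assert imputed_scores.iloc[0] == pytest.approx(expected, abs=1e-10)
        prov = standardized.provenance["A1.2"]
        assert prov.n_imputed == 43

    def test_errors_annotated_with_indicator_id(self, fukuoka, raw_table):
        bad = raw_table.values.copy()
        bad.loc[bad.index[0], "B3.1"] = np.nan  # per-unit numeric can't be missing
        table = fohi.RawIndicatorTable(bad, fukuoka)
        with pytest.raises(StandardizationError, match="B3.1"):
            fohi.standardize_table(table)


def _numeric_def(reverse=False):
    from fohi.hierarchy import IndicatorDefinition

    return IndicatorDefinition(
        "X1.1", "x", "X1", "numeric",
        polarity="higher_worse" if reverse else "higher_better",
    )


# tie-free, well-conditioned vectors: quantile spread bounded away from 0
small_vectors = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False, width=32),
    min_size=3,
    max_size=8,
    unique=True,
).filter(lambda xs: np.percentile(xs, 75) - np.percentile(xs, 25) > 1e-2)


class TestPipelineProperties:
    @given(small_vectors, st.booleans())
    @settings(max_examples=200, deadline=None)
    def test_matches_independent_formula_composition(self, xs, reverse):
        """Pipeline = brute-force Eq-by-Eq composition on tie-free vectors."""
        col = pd.Series(xs, index=[f"u{i}" for i in range(len(xs))])
        scores, _ = standardize_indicator(col, _numeric_def(reverse))
        oracle = oracle_numeric(np.asarray(xs, dtype=float), reverse)
        assert scores.to_numpy() == pytest.approx(oracle, abs=1e-10)

    @given(small_vectors, st.floats(0.1, 100), st.floats(-1e3, 1e3))
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, xs, a, b):
        """x -> a*x + b (a>0) leaves final numeric scores unchanged."""
        x = np.asarray(xs, dtype=float)
        col = pd.Series(x)
        col2 = pd.Series(a * x + b)
        s1, _ = standardize_indicator(col, _numeric_def())
        s2, _ = standardize_indicator(col2, _numeric_def())
        assert s2.to_numpy() == pytest.approx(s1.to_numpy(), abs=1e-6)

    @given(small_vectors)
    @settings(max_examples=100, deadline=None)
    def test_negative_scale_flips_scores(self, xs):
        x = np.asarray(xs, dtype=float)
        s1, _ = standardize_indicator(pd.Series(x), _numeric_def())
        s2, _ = standardize_indicator(pd.Series(-x), _numeric_def())
        assert s2.to_numpy() == pytest.approx(100.0 - s1.to_numpy(), abs=1e-6)

    @given(small_vectors)
    @settings(max_examples=100, deadline=None)
    def test_x100_factor_is_absorbed_by_minmax(self, xs):
        """Omitting the x100 in robust scaling leaves final scores unchanged."""
        x = np.asarray(xs, dtype=float)
        med = np.median(x)
        iqr = np.percentile(x, 75) - np.percentile(x, 25)
        without_factor = (x - med) / iqr
        final = fohi.minmax_rescale(without_factor)
        s, _ = standardize_indicator(pd.Series(x), _numeric_def())
        assert s.to_numpy() == pytest.approx(final, abs=1e-8)

    @given(small_vectors)
    @settings(max_examples=100, deadline=None)
    def test_monotonicity(self, xs):
        # weak monotonicity: values indistinguishable after scaling may tie
        x = np.asarray(xs, dtype=float)
        order = np.argsort(x)
        s, _ = standardize_indicator(pd.Series(x), _numeric_def())
        assert (np.diff(s.to_numpy()[order]) >= -1e-9).all()
        s_rev, _ = standardize_indicator(pd.Series(x), _numeric_def(reverse=True))
        assert (np.diff(s_rev.to_numpy()[order]) <= 1e-9).all()


class TestDegenerateFallbacks:
    def test_iqr_zero_but_range_positive_uses_raw_minmax(self):
        x = pd.Series([1.0, 2.0, 2.0, 2.0, 2.0, 2.0, 2.0, 3.0])
        scores, prov = standardize_indicator(x, _numeric_def())
        assert prov.fallback == "minmax_raw"
        assert scores.min() == 0.0 and scores.max() == 100.0

    def test_constant_column_gets_midpoint(self):
        x = pd.Series([4.0] * 6)
        scores, prov = standardize_indicator(x, _numeric_def())
        assert prov.fallback == "constant_midpoint"
        assert (scores == 50.0).all()
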