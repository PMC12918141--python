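import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ubigen.formats_io import ValidationError
from ubigen.scoring_core import (
    ScoringConfig,
    breadth_subscore,
    compose_from_subscores,
    compose_scores,
    compute_subscores,
    level_subscore,
    minmax,
    sample_thresholds,
    variation_subscore,
)

from conftest import make_matrix


class TestSampleThresholds:
    def test_above_zero_is_zero(self):
        m = make_matrix({"g1": [0, 0], "g2": [0, 0], "g3": [0, 0], "g4": [10, 10]})
        assert sample_thresholds(m, "above_zero").tolist() == [0, 0]

    def test_median_uses_linear_interpolation(self):
        m = make_matrix({"g1": [1, 1], "g2": [2, 2], "g3": [3, 3], "g4": [4, 4]})
        assert sample_thresholds(m, "above_median").tolist() == [2.5, 2.5]

    def test_p95_of_1_to_100(self):
        m = make_matrix({f"g{i:03d}": [i, i] for i in range(1, 101)})
        # linear-interpolation quantile of 1..100 at 0.95 is 95.05
        assert sample_thresholds(m, "above_p95").tolist() == pytest.approx([95.05, 95.05])

    def test_thresholds_include_zeros(self):
        # the sample median is a property of ALL values, zeros included
        m = make_matrix({"g1": [0, 0], "g2": [0, 0], "g3": [6, 6]})
        assert sample_thresholds(m, "above_median").tolist() == [0, 0]


class TestBreadthSubscore:
    def test_sample_maximum_gene_scores_one(self):
        m = make_matrix({"g1": [9, 9], "g2": [1, 2], "g3": [0, 1]})
        assert breadth_subscore(m, "above_p95")["g1"] == 1.0

    def test_all_zero_gene_above_median_counts_zero_medians(self):
        # medians per sample are (0, 2); a zero gene meets the >= threshold
        # only where the median itself is 0 -> fraction 1/2
        m = make_matrix({"g1": [0, 0], "g2": [0, 2], "g3": [5, 9]})
        s = breadth_subscore(m, "above_median")
        assert s["g1"] == 0.5

    def test_all_zero_gene_above_zero_is_zero(self):
        m = make_matrix({"g1": [0, 0], "g2": [1, 1]})
        assert breadth_subscore(m, "above_zero")["g1"] == 0.0

    def test_above_p95_in_exactly_one_of_two_samples(self):
        m = make_matrix({"g1": [9, 1], "g2": [1, 9], "g3": [2, 2]})
        assert breadth_subscore(m, "above_p95")["g1"] == 0.5

    def test_invariant_under_per_sample_monotone_transform(self, rng):
        vals = rng.gamma(2.0, 10.0, size=(50, 6)) * (rng.random((50, 6)) > 0.3)
        m1 = make_matrix({f"g{i:02d}": list(vals[i]) for i in range(50)},
                         samples=[f"s{j}" for j in range(6)])
        transforms = [np.sqrt, np.log1p, lambda x: 2 * x, np.sqrt, np.cbrt, lambda x: x + 0]
        tvals = np.column_stack([t(vals[:, j]) for j, t in enumerate(transforms)])
        m2 = make_matrix({f"g{i:02d}": list(tvals[i]) for i in range(50)},
                         samples=[f"s{j}" for j in range(6)])
        for crit in ("above_p95", "above_median"):
            np.testing.assert_allclose(
                breadth_subscore(m1, crit).to_numpy(), breadth_subscore(m2, crit).to_numpy()
            )


class TestLevelSubscore:
    def test_median_excludes_zeros(self):
        m = make_matrix({"g1": [0, 4, 6]})
        assert level_subscore(m, "median")["g1"] == 5.0

    def test_all_zero_gene_gets_level_zero(self):
        m = make_matrix({"g1": [0, 0, 0], "g2": [1, 1, 1]})
        assert level_subscore(m, "median")["g1"] == 0.0
        assert level_subscore(m, "mean")["g1"] == 0.0

    def test_constant_mean(self):
        m = make_matrix({"g1": [2, 2, 2]})
        assert level_subscore(m, "mean")["g1"] == 2.0


class TestVariationSubscore:
    def test_constant_series_has_zero_qcv(self):
        m = make_matrix({"g1": [5, 5, 5, 5]})
        assert variation_subscore(m, "qcv")["g1"] == 0.0

    def test_qcv_of_1_to_5(self):
        m = make_matrix({"g1": [1, 2, 3, 4, 5]})
        # quartiles by linear interpolation: Q1=2, Q3=4, median 3
        assert variation_subscore(m, "qcv")["g1"] == pytest.approx(2 / 3)

    def test_sd_uses_n_minus_1(self):
        m = make_matrix({"g1": [1, 3]})
        assert variation_subscore(m, "sd")["g1"] == pytest.approx(math.sqrt(2))

    def test_single_positive_value_gives_zero_variation(self):
        m = make_matrix({"g1": [0, 0, 7], "g2": [1, 2, 3]})
        for crit in ("qcv", "iqr", "cv", "sd"):
            assert variation_subscore(m, crit)["g1"] == 0.0

    def test_undetected_gene_gets_dataset_maximum(self):
        m = make_matrix({"g1": [0, 0, 0], "g2": [1, 5, 9], "g3": [4, 5, 6]})
        v = variation_subscore(m, "sd")
        assert v["g1"] == max(v["g2"], v["g3"])

    def test_qcv_scale_invariant_iqr_scales(self):
        m1 = make_matrix({"g1": [1, 2, 3, 4, 8]})
        m2 = make_matrix({"g1": [7, 14, 21, 28, 56]})
        assert variation_subscore(m1, "qcv")["g1"] == pytest.approx(
            variation_subscore(m2, "qcv")["g1"]
        )
        assert 7 * variation_subscore(m1, "iqr")["g1"] == pytest.approx(
            variation_subscore(m2, "iqr")["g1"]
        )


class TestMinmax:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ((2, 4, 6), [0, 0.5, 1]),
            ((7, 7), [0.5, 0.5]),
            ((0, 1, 3), [0, 1 / 3, 1]),
        ],
    )
    def test_cases(self, values, expected):
        assert minmax(values).tolist() == pytest.approx(expected)


class TestCompose:
    def fixture_subscores(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "s_b": [1.0, 0.5, 0.0],
                "s_l_raw": [10.0, 5.0, 0.0],
                "s_v_raw": [0.0, 1.0, 2.0],
                "s_l": [1.0, 0.5, 0.0],
                "s_v": [0.0, 0.5, 1.0],
            },
            index=["gA", "gB", "gC"],
        )

    def test_three_gene_fixture(self):
        # raw composites (0.75, 0.25, -0.25) -> min-max -> (1.0, 0.5, 0.0)
        t = compose_from_subscores(self.fixture_subscores(), (0.5, 0.25, -0.25))
        assert t.scores.loc[["gA", "gB", "gC"]].tolist() == pytest.approx([1.0, 0.5, 0.0])
        assert t.ranks.loc[["gA", "gB", "gC"]].tolist() == [1, 2, 3]

    def test_percentile_is_le_fraction(self):
        t = compose_from_subscores(self.fixture_subscores(), (0.5, 0.25, -0.25))
        assert t.percentiles.loc["gA"] == 100.0
        assert t.percentiles.loc["gC"] == pytest.approx(100 / 3)

    def test_rank_ties_broken_by_gene_id(self):
        import pandas as pd

        sub = pd.DataFrame(
            {"s_b": [0.5, 0.5, 1.0], "s_l_raw": [1, 1, 2], "s_v_raw": [0, 0, 0],
             "s_l": [0.0, 0.0, 1.0], "s_v": [0.5, 0.5, 0.5]},
            index=["gZ", "gA", "gTop"],
        )
        t = compose_from_subscores(sub, (0.5, 0.25, -0.25))
        assert t.gene_ids == ["gTop", "gA", "gZ"]

    def test_invalid_weight_signs_rejected(self):
        with pytest.raises(ValidationError):
            ScoringConfig(weights=(0.5, 0.25, 0.25))
        with pytest.raises(ValidationError):
            ScoringConfig(weights=(0.0, 0.0, 0.0))

    @settings(max_examples=30, deadline=None)
    @given(scale=st.floats(min_value=0.05, max_value=20), seed=st.integers(0, 10_000))
    def test_scores_invariant_under_positive_weight_rescale(self, scale, seed):
        rng = np.random.default_rng(seed)
        vals = rng.gamma(1.5, 20, size=(30, 8)) * (rng.random((30, 8)) > 0.25)
        m = make_matrix({f"g{i:02d}": list(vals[i]) for i in range(30)},
                        samples=[f"s{j}" for j in range(8)])
        base = compose_scores(m, ScoringConfig())
        scaled = compose_scores(
            m, ScoringConfig(weights=(0.5 * scale, 0.25 * scale, -0.25 * scale))
        )
        np.testing.assert_allclose(base.scores.to_numpy(), scaled.scores.to_numpy(),
                                   atol=1e-12)
        assert base.gene_ids == scaled.gene_ids

    def test_monotone_in_breadth_and_antitone_in_variation(self):
        import pandas as pd

        sub = self.fixture_subscores()
        t0 = compose_from_subscores(sub, (0.5, 0.25, -0.25))
        up = sub.copy()
        up.loc["gB", "s_b"] = 0.9  # raise gB's breadth, others fixed
        t1 = compose_from_subscores(up, (0.5, 0.25, -0.25))
        assert t1.scores["gB"] >= t0.scores["gB"]
        worse = sub.copy()
        worse.loc["gB", "s_v"] = 1.0  # raise gB's variation, negative weight
        t2 = compose_from_subscores(worse, (0.5, 0.25, -0.25))
        assert t2.scores["gB"] <= t0.scores["gB"]


class TestEndpoints:
    def test_best_and_worst_profiles_hit_1_and_0(self):
        import pandas as pd

        sub = pd.DataFrame(
            {"s_b": [1.0, 0.0, 0.4], "s_l_raw": [9, 0, 3], "s_v_raw": [0, 9, 3],
             "s_l": [1.0, 0.0, 1 / 3], "s_v": [0.0, 1.0, 1 / 3]},
            index=["best", "worst", "mid"],
        )
        t = compose_from_subscores(sub, (0.5, 0.25, -0.25))
        assert t.scores["best"] == 1.0
        assert t.scores["worst"] == 0.0
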