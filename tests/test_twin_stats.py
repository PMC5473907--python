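import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from placentabold import twin_stats
from placentabold.errors import CollinearityError, ValidationError
from placentabold.paradigm import OxygenParadigm
from placentabold.synthetic import CohortSpec, generate_cohort
from placentabold.twin_stats import (
    CurveSet,
    fda_group_curves,
    friedman_test,
    group_difference_at,
    mixed_model_fit,
    pair_resampled_spearman,
)


class TestFriedman:
    def test_consistent_ordering_seven_pairs(self):
        blocks = np.column_stack([np.arange(7.0), np.arange(7.0) + 1.0])
        res = friedman_test(blocks)
        assert res["chi2"] == pytest.approx(7.0)
        assert res["p"] == pytest.approx(0.0082, abs=5e-4)

    def test_one_discordant_pair(self):
        blocks = np.column_stack([np.arange(7.0), np.arange(7.0) + 1.0])
        blocks[0] = blocks[0, ::-1]
        res = friedman_test(blocks)
        assert res["chi2"] == pytest.approx(25.0 / 7.0)
        assert res["p"] == pytest.approx(0.059, abs=1e-3)

    def test_all_tied_blocks(self):
        res = friedman_test(np.ones((5, 3)))
        assert res["chi2"] == pytest.approx(0.0)
        assert res["p"] == pytest.approx(1.0)

    def test_exhaustive_k2_closed_form(self):
        # for k=2 the statistic reduces to (2w - n)^2 / n where w counts
        # blocks preferring condition 1 -- enumerate all 2^7 patterns
        n = 7
        for pattern in itertools.product([0, 1], repeat=n):
            blocks = np.array([[0.0, 1.0] if b else [1.0, 0.0] for b in pattern])
            w = sum(pattern)
            expected = (2 * w - n) ** 2 / n
            assert friedman_test(blocks)["chi2"] == pytest.approx(expected)

    def test_matches_scipy_on_untied_data(self, rng):
        blocks = rng.normal(size=(9, 4))
        res = friedman_test(blocks)
        ref = stats.friedmanchisquare(*blocks.T)
        assert res["chi2"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_missing_values_rejected(self):
        blocks = np.ones((3, 2))
        blocks[0, 0] = np.nan
        with pytest.raises(ValidationError):
            friedman_test(blocks)


def _pairs_df(x, y):
    n = len(x) // 2
    return pd.DataFrame({"pair_id": np.repeat(np.arange(n), 2), "x": x, "y": y})


class TestPairResampledSpearman:
    def test_monotone_data_gives_r_one(self):
        x = np.arange(14.0)
        df = _pairs_df(x, 3.0 * x + 1.0)
        for seed in (0, 1, 99):
            res = pair_resampled_spearman(df, "x", "y", reps=1000, seed=seed)
            assert res["median_r"] == 1.0

    def test_independent_noise_stays_small(self):
        # one fixed null dataset; the resampled median must stay in the
        # stochastic band regardless of the resampling seed
        rng = np.random.default_rng(21)
        df = _pairs_df(rng.normal(size=14), rng.normal(size=14))
        meds = [
            pair_resampled_spearman(df, "x", "y", reps=200, seed=seed)["median_r"]
            for seed in range(10)
        ]
        assert np.all(np.abs(meds) < 0.5)

    def test_single_rep_reproducible(self):
        rng = np.random.default_rng(3)
        df = _pairs_df(rng.normal(size=14), rng.normal(size=14))
        a = pair_resampled_spearman(df, "x", "y", reps=1, seed=5)
        b = pair_resampled_spearman(df, "x", "y", reps=1, seed=5)
        assert a["median_r"] == b["median_r"] and a["median_p"] == b["median_p"]

    def test_median_stable_across_seeds_at_1000_reps(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=16)
        df = _pairs_df(x, x + rng.normal(scale=1.0, size=16))
        meds = [
            pair_resampled_spearman(df, "x", "y", reps=1000, seed=s)["median_r"]
            for s in range(4)
        ]
        assert max(meds) - min(meds) < 0.02

    def test_degenerate_reps_excluded(self):
        df = _pairs_df(np.repeat([1.0, 2.0, 3.0, 4.0], 2)[:8].repeat(1), np.arange(8.0))
        df["x"] = 1.0  # constant x in every rep
        with pytest.raises(ValidationError):
            pair_resampled_spearman(df, "x", "y", reps=10, seed=0)

    def test_too_few_pairs_rejected(self):
        df = _pairs_df(np.arange(6.0), np.arange(6.0))
        with pytest.raises(ValidationError):
            pair_resampled_spearman(df, "x", "y", reps=10, seed=0)


class TestMixedModel:
    @pytest.fixture()
    def table(self):
        rng = np.random.default_rng(17)
        n_pairs = 10
        ttp = rng.uniform(0.5, 4.0, 2 * n_pairs)
        mother = np.repeat([f"M{i}" for i in range(n_pairs)], 2)
        re = np.repeat(rng.normal(0, 50, n_pairs), 2)
        y = 3000.0 - 100.0 * ttp + re + rng.normal(0, 40, 2 * n_pairs)
        return pd.DataFrame({"mother_id": mother, "ttp": ttp, "weight": y})

    def test_zero_re_variance_equals_ols(self, table):
        res = mixed_model_fit(table, "weight", ["ttp"], "mother_id", re_variance=0)
        X = np.column_stack([np.ones(len(table)), table.ttp])
        beta = np.linalg.lstsq(X, table.weight.to_numpy(), rcond=None)[0]
        assert res["coefficients"]["intercept"] == pytest.approx(beta[0], abs=1e-6)
        assert res["coefficients"]["ttp"] == pytest.approx(beta[1], abs=1e-6)

    def test_recovers_generating_slope(self, table):
        res = mixed_model_fit(table, "weight", ["ttp"], "mother_id")
        est, se = res["coefficients"]["ttp"], res["se"]["ttp"]
        assert abs(est - (-100.0)) < 2 * se

    def test_cohort_generator_slope_recovery(self, paradigm):
        co = generate_cohort(CohortSpec(n_pairs=7, bw_ttp_slope=100.0), paradigm, seed=2)
        res = mixed_model_fit(co.records, "birth_weight", ["ttp_true"], "mother_id")
        est, se = res["coefficients"]["ttp_true"], res["se"]["ttp_true"]
        assert abs(est - (-100.0)) < 2 * se

    def test_duplicated_covariate_is_collinearity_error(self, table):
        table = table.assign(ttp2=table.ttp)
        with pytest.raises(CollinearityError) as exc:
            mixed_model_fit(table, "weight", ["ttp", "ttp2"], "mother_id")
        assert "ttp" in "".join(exc.value.fields)


def _curveset(t, curves_a, curves_b):
    curves = np.vstack([curves_a, curves_b])
    groups = np.array(["AGA"] * len(curves_a) + ["SGA"] * len(curves_b))
    return CurveSet(t=t, curves=curves, groups=groups)


class TestFDA:
    def test_identical_groups_flat_t(self, rng):
        t = np.arange(0, 30.001, 0.25)
        base = np.sin(t / 5.0)
        curves = np.tile(base, (3, 1)) + rng.normal(0, 1e-9, (3, len(t)))
        cs = _curveset(t, curves, curves)
        res = fda_group_curves(cs)
        assert np.nanmax(np.abs(res["t"])) < 1e-3
        assert np.nanmin(res["p"]) > 0.99

    def test_constant_offset_matches_welch_closed_form(self, rng):
        t = np.arange(0, 30.001, 0.25)
        n, d, s = 5, 2.0, 0.3
        offsets_a = rng.normal(0, s, n)
        offsets_b = rng.normal(d, s, n)
        curves_a = np.tile(t * 0.1, (n, 1)) + offsets_a[:, None]
        curves_b = np.tile(t * 0.1, (n, 1)) + offsets_b[:, None]
        res = fda_group_curves(_curveset(t, curves_a, curves_b))
        mid = len(res["grid"]) // 2
        se = np.sqrt(offsets_a.std(ddof=1) ** 2 / n + offsets_b.std(ddof=1) ** 2 / n)
        expected_t = (offsets_a.mean() - offsets_b.mean()) / se
        assert res["t"][mid] == pytest.approx(expected_t, abs=1e-6)

    def test_spline_reproduces_straight_line(self):
        t = np.arange(0, 30.001, 0.25)
        line = 2.0 - 0.4 * t
        res = fda_group_curves(_curveset(t, np.tile(line, (2, 1)), np.tile(line + 1, (2, 1))))
        np.testing.assert_allclose(res["mean"]["AGA"], 2.0 - 0.4 * res["grid"], atol=1e-8)

    def test_grid_shorter_than_knot_interval_rejected(self):
        t = np.arange(0, 1.0, 0.1)
        curves = np.ones((4, len(t)))
        with pytest.raises(ValidationError):
            fda_group_curves(_curveset(t, curves[:2], curves[2:]))


class TestGroupDifferenceAt:
    def test_identical_groups_p_near_one(self):
        t = np.arange(0, 30.001, 0.25)
        c = np.vstack([t * 0.1 + i * 1e-6 for i in range(2)])
        res = group_difference_at(_curveset(t, c, c.copy()), "value@t", t=15.0)
        assert res["p"] > 0.99

    def test_generated_slope_difference_detected(self, rng):
        t = np.arange(0, 30.001, 0.25)
        par = OxygenParadigm()
        ramp = np.clip(t - 10.0, 0.0, 5.0)  # slope 1 after onset
        curves_a = np.array([(1.0 + rng.normal(0, 0.2)) * ramp for _ in range(7)])
        curves_b = np.array([(0.0 + rng.normal(0, 0.2)) * ramp for _ in range(7)])
        res = group_difference_at(_curveset(t, curves_a, curves_b), "slope@t", t=12.0)
        assert res["p"] < 0.01

    def test_end_post_requires_paradigm(self):
        t = np.arange(0, 30.001, 0.25)
        c = np.ones((4, len(t)))
        with pytest.raises(ValidationError):
            group_difference_at(_curveset(t, c[:2], c[2:]), "end_post_value")

    def test_single_subject_group_rejected(self):
        t = np.arange(0, 30.001, 0.25)
        c = np.ones((3, len(t)))
        cs = CurveSet(t=t, curves=c, groups=np.array(["AGA", "AGA", "SGA"]))
        with pytest.raises(ValidationError):
            group_difference_at(cs, "value@t", t=5.0)
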