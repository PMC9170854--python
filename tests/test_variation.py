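"""CoV computation, square-root-law extrapolation and statistical tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from suvvar.framing import default_schedules, make_schedule
from suvvar.variation import (
    coefficient_of_variation,
    compare_table,
    cov_table,
    cross_estimate_matrix,
    estimate_at_full_length,
    extrapolate_cov,
    ks_normality,
    welch_t_test,
)


def synthetic_records(schedules, cov_of_rl, mean=100.0, seed=None, metrics=("Max3D",), spheres=(10,)):
    """Records whose per-RL populations have a prescribed CoV.

    With ``seed=None`` the populations are deterministic two-point sets
    realising the CoV exactly; with a seed they are Gaussian draws.
    """
    rng = np.random.default_rng(seed) if seed is not None else None
    rows = []
    for sched in schedules:
        target_cov = cov_of_rl(sched.rl_s) / 100.0
        n = sched.n_frames
        if rng is None:
            # zero-mean, unit-sample-SD pattern scaled to the target CoV
            if n % 2 == 0:
                x = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n)])
                x /= np.sqrt(n / (n - 1))
            else:
                x = np.array([1.0 if k % 2 == 0 else -1.0 for k in range(n - 1)] + [0.0])
            vals = mean * (1.0 + target_cov * x)
        else:
            vals = rng.normal(mean, mean * target_cov, size=n)
        for metric in metrics:
            for sphere in spheres:
                for k, v in enumerate(vals):
                    rows.append(
                        {
                            "sphere_id": sphere,
                            "metric": metric,
                            "rl_s": sched.rl_s,
                            "frame_index": k,
                            "value_kbq_ml": v,
                        }
                    )
    return pd.DataFrame(rows)


class TestCoV:
    def test_constant_sample_has_zero_cov(self):
        mean, sd, cov = coefficient_of_variation([5.0, 5.0, 5.0])
        assert (mean, sd, cov) == (5.0, 0.0, 0.0)

    def test_simple_sample(self):
        mean, sd, cov = coefficient_of_variation([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sd == pytest.approx(1.0)  # n-1 denominator
        assert cov == pytest.approx(50.0)

    @given(
        values=st.lists(st.floats(0.1, 1e4), min_size=2, max_size=30),
        scale=st.floats(0.01, 100.0),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_cov_is_scale_invariant(self, values, scale):
        arr = np.asarray(values)
        if arr.mean() == 0:
            return
        _, _, cov1 = coefficient_of_variation(arr)
        _, _, cov2 = coefficient_of_variation(arr * scale)
        assert cov2 == pytest.approx(cov1, rel=1e-9, abs=1e-9)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([1.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-1.0, 1.0])


class TestExtrapolation:
    def test_identity_at_equal_lengths(self):
        assert extrapolate_cov(7.3, 12.0, 12.0) == 7.3

    def test_quadrupling_time_halves_sd(self):
        assert extrapolate_cov(10.0, 10.0, 40.0) == pytest.approx(5.0)

    def test_worked_example_4s_to_150s(self):
        assert extrapolate_cov(30.0, 4.0, 150.0) == pytest.approx(30.0 * np.sqrt(4.0 / 150.0))
        assert extrapolate_cov(30.0, 4.0, 150.0) == pytest.approx(4.899, abs=1e-3)

    @given(sd=st.floats(0.01, 100), rl1=st.floats(1, 300), rl2=st.floats(1, 300))
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_round_trip_exact(self, sd, rl1, rl2):
        back = extrapolate_cov(extrapolate_cov(sd, rl1, rl2), rl2, rl1)
        assert back == pytest.approx(sd, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        for args in ((10, 0, 5), (10, 5, 0), (-1, 5, 5)):
            with pytest.raises(ValueError):
                extrapolate_cov(*args)


class TestFullLengthEstimation:
    def test_fourteen_estimates_per_cell(self):
        scheds = default_schedules()
        records = synthetic_records(scheds, lambda rl: 30.0 * np.sqrt(4.0 / rl), seed=1)
        agg = estimate_at_full_length(records, scheds, rl2_s=150.0)
        assert len(agg) == 1
        assert agg.iloc[0]["n_estimates"] == 14

    def test_exact_sqrt_law_collapses_to_single_value(self):
        """If every subset's CoV already satisfies the law, all 14
        extrapolations coincide and their SD is ~0."""
        scheds = default_schedules()
        records = synthetic_records(scheds, lambda rl: 30.0 * np.sqrt(4.0 / rl))
        table = cov_table(records, scheds, rl2_s=150.0)
        assert table["sd2_percent"].std() == pytest.approx(0.0, abs=1e-9)
        assert table["sd2_percent"].iloc[0] == pytest.approx(30.0 * np.sqrt(4.0 / 150.0), rel=1e-9)

    def test_noisy_sqrt_law_recovered_within_replicate_spread(self):
        scheds = default_schedules()
        records = synthetic_records(scheds, lambda rl: 30.0 * np.sqrt(4.0 / rl), seed=7)
        agg = estimate_at_full_length(records, scheds, rl2_s=150.0).iloc[0]
        truth = 30.0 * np.sqrt(4.0 / 150.0)  # ~4.899%
        assert abs(agg["mean_estimate"] - truth) <= 2.0 * agg["sd_estimate"]

    def test_missing_cell_is_reported(self):
        scheds = default_schedules()
        records = synthetic_records(scheds, lambda rl: 10.0, seed=2)
        broken = records[records["rl_s"] != 10.0]
        with pytest.raises(ValueError, match="10"):
            estimate_at_full_length(broken, scheds)


class TestCrossEstimation:
    def test_thirteen_estimates_per_target(self):
        scheds = default_schedules()
        records = synthetic_records(scheds, lambda rl: 30.0 * np.sqrt(4.0 / rl), seed=3)
        cross = cross_estimate_matrix(records, scheds)
        assert len(cross) == 14
        assert (cross["n_estimates"] == 13).all()

    def test_two_schedules_give_single_estimate(self):
        scheds = [make_schedule(150, 10), make_schedule(150, 30)]
        records = synthetic_records(scheds, lambda rl: 10.0, seed=4)
        cross = cross_estimate_matrix(records, scheds)
        assert (cross["n_estimates"] == 1).all()

    def test_reciprocal_extrapolations_algebraic_identity(self):
        # SD2(a->b) * SD2(b->a) = SD1(a) * SD1(b)
        sd_a, sd_b, rl_a, rl_b = 12.0, 5.0, 4.0, 30.0
        ab = extrapolate_cov(sd_a, rl_a, rl_b)
        ba = extrapolate_cov(sd_b, rl_b, rl_a)
        assert ab * ba == pytest.approx(sd_a * sd_b, rel=1e-12)


class TestKSNormality:
    def test_small_fitted_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, 2.0, 3.0, 4.0])

    def test_single_point_against_standard_normal(self):
        # ECDF jumps 0 -> 1 at 0 where the reference CDF is 0.5
        res = ks_normality([0.0], mean=0.0, sd=1.0)
        assert res.statistic == pytest.approx(0.5)

    def test_gaussian_samples_rarely_rejected(self):
        rejections = 0
        for seed in range(50):
            sample = np.random.default_rng(seed).normal(10.0, 2.0, size=200)
            if ks_normality(sample).reject:
                rejections += 1
        assert rejections <= 5  # >= 90% non-rejection

    def test_log_transform_requires_positive(self):
        with pytest.raises(ValueError):
            ks_normality([1.0, -2.0, 3.0, 4.0, 5.0], transform="log")

    def test_log_transform_runs_on_lognormal(self):
        sample = np.exp(np.random.default_rng(0).normal(0, 0.5, size=100))
        res = ks_normality(sample, transform="log")
        assert res.transform == "log"
        assert not res.reject


class TestWelch:
    def test_identical_samples(self):
        res = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_worked_example_against_hand_formula(self):
        a = np.array([1.0, 2, 3, 4, 5])
        b = np.array([2.0, 3, 4, 5, 6])
        res = welch_t_test(a, b)
        # independent hand computation of the Welch statistic and
        # Welch-Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1) / 5, b.var(ddof=1) / 5
        t_oracle = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df_oracle = (va + vb) ** 2 / (va**2 / 4 + vb**2 / 4)
        p_oracle = 2 * sps.t.sf(abs(t_oracle), df_oracle)
        assert res.statistic == pytest.approx(t_oracle)
        assert t_oracle == pytest.approx(-1.0)
        assert res.df == pytest.approx(8.0)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-9)
        assert res.p_value == pytest.approx(0.3466, abs=2e-4)

    def test_antisymmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        r1, r2 = welch_t_test(a, b), welch_t_test(b, a)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_sample_size_precondition(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1.0, 2.0])


class TestCompareTable:
    @staticmethod
    def estimates_frame(rng, sphere_scale=None):
        spheres = [10, 13, 17, 22, 28, 37]
        metrics = ["Max2D", "Max3D", "Mean2D", "Mean3D", "Peak"]
        rows = []
        for m in metrics:
            for s in spheres:
                loc = 5.0 if sphere_scale is None else sphere_scale.get(s, 5.0)
                for v in rng.normal(loc, 1.0, size=14):
                    rows.append({"metric": m, "sphere_id": s, "sd2_percent": v})
        return pd.DataFrame(rows)

    def test_emits_25_adjacent_and_60_metric_pair_tests(self):
        table = compare_table(self.estimates_frame(np.random.default_rng(0)))
        assert (table["family"] == "adjacent_spheres").sum() == 25
        assert (table["family"] == "metric_pairs").sum() == 60

    def test_identical_populations_not_significant(self):
        df = self.estimates_frame(np.random.default_rng(1))
        # make every population literally identical
        base = df[(df.metric == "Max2D") & (df.sphere_id == 10)]["sd2_percent"].to_numpy()
        df["sd2_percent"] = np.tile(base, len(df) // 14)
        table = compare_table(df)
        assert not table["significant"].any()

    def test_constructed_difference_detected(self):
        """A 4x noise difference between the 10 and 13 mm populations is
        flagged in >= 90% of seeds."""
        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            rng = np.random.default_rng(1000 + seed)
            df = self.estimates_frame(rng, sphere_scale={10: 20.0, 13: 5.0})
            table = compare_table(df)
            row = table[
                (table.family == "adjacent_spheres")
                & (table.metric_a == "Max3D")
                & (table.sphere_a == 10)
            ].iloc[0]
            hits += bool(row["significant"])
        assert hits >= 0.9 * n_seeds

    def test_incomplete_aggregates_rejected(self):
        df = self.estimates_frame(np.random.default_rng(2))
        df = df[~((df.metric == "Peak") & (df.sphere_id == 37))]
        with pytest.raises(ValueError):
            compare_table(df)
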