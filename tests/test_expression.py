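"""Expression mixing, sampling designs, assay error and fitness."""

import numpy as np
import pytest

import cortsim as cs
from cortsim.expression import express_matrix
from cortsim.population import ParameterSpec


def _truth(pop, n, seed):
    return cs.sample_population(pop, n, seed=seed).frame.to_numpy()


class TestExpressionMixing:
    def test_full_fidelity_reproduces_truth(self, default_pop, rng):
        truth = _truth(default_pop, 50, 1)
        expressed = express_matrix(
            truth, cs.ExpressionSpec(fidelity=1.0), default_pop, rng
        )
        np.testing.assert_allclose(expressed, truth, rtol=1e-12)

    def test_zero_fidelity_decorrelates(self, default_pop, rng):
        # expressed responses are unrelated to the truth at w=0
        truth = _truth(default_pop, 10_000, 2)
        expressed = express_matrix(
            truth, cs.ExpressionSpec(fidelity=0.0), default_pop, rng
        )
        r = np.corrcoef(np.log(truth[:, 3]), np.log(expressed[:, 3]))[0, 1]
        assert abs(r) < 0.05

    def test_variance_preserving_keeps_marginal_sd(self, default_pop, rng):
        # w^2 + (1 - w^2) = 1: expressed SD equals population SD
        truth = _truth(default_pop, 10_000, 3)
        expressed = express_matrix(
            truth,
            cs.ExpressionSpec(fidelity=0.6, mode="variance_preserving"),
            default_pop,
            rng,
        )
        log_m = np.log(expressed[:, 3])
        assert log_m.std(ddof=1) == pytest.approx(0.3, rel=0.05)
        t_ret = expressed[:, 5]
        assert t_ret.std(ddof=1) == pytest.approx(5.0, rel=0.05)

    def test_convex_mode_shrinks_variance(self, default_pop, rng):
        # convex blend shrinks marginal variance by w^2 + (1-w)^2
        w = 0.35
        truth = _truth(default_pop, 10_000, 4)
        expressed = express_matrix(
            truth, cs.ExpressionSpec(fidelity=w), default_pop, rng
        )
        shrink = np.sqrt(w**2 + (1 - w) ** 2)
        assert np.log(expressed[:, 3]).std(ddof=1) == pytest.approx(
            0.3 * shrink, rel=0.05
        )

    @pytest.mark.parametrize("mode", ["convex", "variance_preserving"])
    def test_correlation_structure_preserved(self, mode, rng):
        pop = cs.default_population().with_correlation(
            "time_to_max", "max_value", -0.6
        )
        truth = _truth(pop, 10_000, 5)
        expressed = express_matrix(
            truth, cs.ExpressionSpec(fidelity=0.5, mode=mode), pop, rng
        )
        r = np.corrcoef(expressed[:, 2], np.log(expressed[:, 3]))[0, 1]
        assert r == pytest.approx(-0.6, abs=0.06)

    def test_express_event_wrapper(self, default_pop, rng):
        p = cs.sample_population(default_pop, 1, seed=6).params_for(1)
        out = cs.express_event(p, cs.ExpressionSpec(fidelity=1.0), default_pop, rng)
        assert out == p

    def test_invalid_fidelity_rejected(self):
        with pytest.raises(ValueError):
            cs.ExpressionSpec(fidelity=1.5)
        with pytest.raises(ValueError):
            cs.ExpressionSpec(fidelity={"max_value": -0.1})
        with pytest.raises(ValueError):
            cs.ExpressionSpec(mode="other")


class TestSamplingTimes:
    def test_fixed_design_identical_across_individuals(self, rng):
        d = cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30))
        t = cs.sample_times(d, 8, rng)
        assert t.shape == (8, 3)
        np.testing.assert_array_equal(t, np.tile([1.0, 15.0, 30.0], (8, 1)))

    def test_uniform_random_support(self, rng):
        d = cs.SamplingDesign(kind="uniform_random", window=(1, 60), n_samples=3)
        t = cs.sample_times(d, 2000, rng)
        assert t.min() >= 1.0 and t.max() <= 60.0
        assert np.all(np.diff(t, axis=1) >= 0)

    def test_weighted_normal_mean(self, rng):
        d = cs.SamplingDesign(kind="weighted_normal", center=32.0, spread=9.0,
                              n_samples=1)
        t = cs.sample_times(d, 10_000, rng)
        assert t.mean() == pytest.approx(32.0, abs=0.3)
        assert t.min() >= 0.0

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError, match="window"):
            cs.SamplingDesign(kind="uniform_random", window=(10, 10))


class TestObserve:
    def test_exact_without_error(self, example_params, rng):
        curve = cs.build_curve(example_params)
        times = np.array([1.0, 15.5, 30.0])
        out = cs.observe(curve, times, cs.AssayModel(error_sd=0.0), rng)
        np.testing.assert_allclose(out, curve.value_at(times))

    def test_noise_sd_recovered(self, example_params):
        # 10,000 replicate measurements of one point: SD ~= error_sd
        curve = cs.build_curve(example_params)
        rng = np.random.default_rng(10)
        reps = np.concatenate(
            [
                cs.observe(curve, [30.0], cs.AssayModel(error_sd=2.0), rng)
                for _ in range(10_000)
            ]
        )
        assert reps.std(ddof=1) == pytest.approx(2.0, rel=0.05)
        assert reps.mean() == pytest.approx(float(curve.value_at(30.0)), abs=0.1)

    def test_flat_curve_all_baseline(self, rng):
        p = cs.ResponseParams(5, 1, 2, 5, 0, 1, 5)
        curve = cs.build_curve(p, t_end=60)
        out = cs.observe(curve, [0.0, 10.0, 59.5], cs.AssayModel(0.0), rng)
        np.testing.assert_allclose(out, 5.0)

    def test_floor_applied(self):
        p = cs.ResponseParams(0.1, 1, 2, 0.2, 0, 1, 0.1)
        curve = cs.build_curve(p, t_end=30)
        out = cs.observe(
            curve, [5.0] * 100, cs.AssayModel(error_sd=5.0),
            np.random.default_rng(3),
        )
        assert np.all(out >= 0.0)


class TestSimulateDataset:
    def test_shape_and_determinism(self, default_pop):
        cohort = cs.sample_population(default_pop, 10, seed=1)
        kwargs = dict(
            expr=cs.ExpressionSpec(fidelity=0.5),
            design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 30)),
            assay=cs.AssayModel(error_sd=1.0),
            n_events=2,
            seed=99,
        )
        a = cs.simulate_dataset(cohort, **kwargs)
        b = cs.simulate_dataset(cohort, **kwargs)
        assert len(a.observed) == 10 * 2 * 2
        assert a.observed.equals(b.observed)
        assert a.event_params.shape == (20, 9)
        assert a.event_curves is not None

    def test_zero_events_rejected(self, default_pop):
        cohort = cs.sample_population(default_pop, 2, seed=1)
        with pytest.raises(ValueError):
            cs.simulate_dataset(cohort, n_events=0)

    def test_perfect_fidelity_repeats_identically(self, default_pop):
        cohort = cs.sample_population(default_pop, 5, seed=2)
        ds = cs.simulate_dataset(
            cohort,
            expr=cs.ExpressionSpec(fidelity=1.0),
            design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
            assay=cs.AssayModel(error_sd=0.0),
            n_events=3,
            seed=3,
        )
        wide = ds.observed.pivot_table(
            index=["individual_id", "time_min"],
            columns="event_id",
            values="value",
        )
        np.testing.assert_allclose(wide[1], wide[2])
        np.testing.assert_allclose(wide[1], wide[3])


class TestFitness:
    def test_unmeasured_only_is_independent(self, default_pop):
        cohort = cs.sample_population(default_pop, 10_000, seed=4)
        fit = cs.assign_fitness(
            cohort, cs.FitnessSpec(unmeasured_share=1.0),
            np.random.default_rng(5),
        )
        r = np.corrcoef(np.log(cohort.frame["max_value"]), fit)[0, 1]
        assert abs(r) < 0.05

    def test_variance_share_becomes_r_squared(self, default_pop):
        cohort = cs.sample_population(default_pop, 10_000, seed=6)
        fit = cs.assign_fitness(
            cohort,
            cs.FitnessSpec(
                variance_share={"max_value": 0.8}, unmeasured_share=0.2
            ),
            np.random.default_rng(7),
        )
        x = np.log(cohort.frame["max_value"].to_numpy())
        r2 = np.corrcoef(x, fit)[0, 1] ** 2
        assert r2 == pytest.approx(0.80, abs=0.03)

    def test_pure_share_is_monotone_in_truth(self, default_pop):
        from scipy.stats import spearmanr

        cohort = cs.sample_population(default_pop, 500, seed=8)
        fit = cs.assign_fitness(
            cohort,
            cs.FitnessSpec(variance_share={"max_value": 1.0},
                           unmeasured_share=0.0),
            np.random.default_rng(9),
        )
        rho = spearmanr(cohort.frame["max_value"], fit).statistic
        assert rho == pytest.approx(1.0)

    def test_shares_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            cs.FitnessSpec(variance_share={"max_value": 0.5},
                           unmeasured_share=0.2)

    def test_zero_variance_share_param_rejected(self):
        base = cs.default_population()
        spec = base.replace({"baseline": ParameterSpec(5.0, 0.0)})
        cohort = cs.sample_population(spec, 100, seed=10)
        with pytest.raises(ValueError, match="zero variance"):
            cs.assign_fitness(
                cohort,
                cs.FitnessSpec(variance_share={"baseline": 0.5},
                               unmeasured_share=0.5),
                np.random.default_rng(11),
            )
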