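"""Repeatability statistics: ICC, AUC repeatability, profile repeatability."""

import numpy as np
import pytest

import cortsim as cs
from cortsim.population import ParameterSpec
from cortsim.repeatability import (
    auc_repeatability,
    event_aucs,
    icc,
    icc_bootstrap_ci,
    per_timepoint_icc,
    profile_repeatability,
    repeatability_report,
)


class TestICC:
    def test_perfect_repeatability(self):
        values = np.array([0.0, 0.0, 10.0, 10.0])
        groups = np.array([1, 1, 2, 2])
        assert icc(values, groups) == 1.0

    def test_duplicate_events_distinct_individuals(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=30)
        values = np.repeat(base, 3)
        groups = np.repeat(np.arange(30), 3)
        assert icc(values, groups) == 1.0

    def test_iid_values_near_zero(self):
        # no individual signal: R ~ 0
        rng = np.random.default_rng(1)
        values = rng.normal(size=400)
        groups = np.repeat(np.arange(200), 2)
        assert icc(values, groups) < 0.1

    def test_negative_estimate_clamped_with_warning(self):
        # anti-correlated within pairs drives the estimate negative
        values = np.array([1.0, -1.0, 2.0, -2.0, 1.5, -1.5])
        groups = np.array([1, 1, 2, 2, 3, 3])
        with pytest.warns(RuntimeWarning, match="clamped"):
            assert icc(values, groups) == 0.0

    def test_matches_pingouin_icc1(self):
        """Independent cross-check against pingouin's one-way ICC."""
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(2)
        n_ind, k = 25, 4
        truth = rng.normal(size=n_ind)
        values = (truth[:, None] + rng.normal(scale=0.7, size=(n_ind, k))).ravel()
        groups = np.repeat(np.arange(n_ind), k)
        ours = icc(values, groups)
        frame = pd.DataFrame(
            {
                "targets": groups,
                "raters": np.tile(np.arange(k), n_ind),
                "ratings": values,
            }
        )
        theirs = pg.intraclass_corr(
            frame, targets="targets", raters="raters", ratings="ratings"
        )
        icc1 = theirs.loc[theirs["Type"] == "ICC(1,1)", "ICC"].iloc[0]
        assert ours == pytest.approx(icc1, abs=1e-10)

    def test_requires_repeats(self):
        with pytest.raises(ValueError):
            icc(np.array([1.0, 2.0]), np.array([1, 2]))
        with pytest.raises(ValueError):
            icc(np.array([1.0, 2.0, 3.0]), np.array([1, 1, 1]))

    def test_bootstrap_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        truth = rng.normal(size=40)
        values = (truth[:, None] + rng.normal(scale=0.5, size=(40, 3))).ravel()
        groups = np.repeat(np.arange(40), 3)
        est = icc(values, groups)
        lo, hi = icc_bootstrap_ci(values, groups, n_boot=200, seed=4)
        assert 0.0 <= lo <= est <= hi <= 1.0


class TestAucRepeatability:
    def test_perfect_under_full_fidelity_no_noise(self, default_pop):
        cohort = cs.sample_population(default_pop, 15, seed=20)
        ds = cs.simulate_dataset(
            cohort,
            expr=cs.ExpressionSpec(fidelity=1.0),
            design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
            assay=cs.AssayModel(error_sd=0.0),
            n_events=2,
            seed=21,
        )
        for mode in ("ground", "increase"):
            for basis in ("full_curve", "observed_points", "windowed_curve"):
                assert auc_repeatability(ds, mode, basis) == pytest.approx(1.0)

    def test_observed_full_grid_equals_windowed(self, default_pop):
        # sampling every grid minute makes the observed-points AUC the
        # windowed-curve AUC exactly (same point set)
        cohort = cs.sample_population(default_pop, 8, seed=22)
        ds = cs.simulate_dataset(
            cohort,
            expr=cs.ExpressionSpec(fidelity=0.5),
            design=cs.SamplingDesign(
                kind="fixed", fixed_times=tuple(range(0, 61))
            ),
            assay=cs.AssayModel(error_sd=0.0),
            n_events=2,
            seed=23,
        )
        obs = event_aucs(ds, "ground", "observed_points")["auc"]
        win = event_aucs(ds, "ground", "windowed_curve")["auc"]
        np.testing.assert_allclose(obs, win, rtol=1e-12)

    def test_ground_exceeds_increase_with_repeatable_baseline(self):
        """Paired Monte-Carlo: with substantial, perfectly repeatable
        between-individual baseline variation, ground AUC carries an
        extra repeatable component that the increase AUC subtracts."""
        pop = cs.default_population().replace(
            {"baseline": ParameterSpec(8.0, 3.0)}
        )
        fid = {n: 0.6 for n in cs.PARAM_NAMES}
        fid["baseline"] = 1.0
        diffs = []
        for seed in range(1, 9):
            cohort = cs.sample_population(pop, 120, seed=seed)
            ds = cs.simulate_dataset(
                cohort,
                expr=cs.ExpressionSpec(fidelity=fid),
                design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
                assay=cs.AssayModel(error_sd=0.0),
                n_events=3,
                seed=seed + 10,
            )
            diffs.append(
                auc_repeatability(ds, "ground", "observed_points")
                - auc_repeatability(ds, "increase", "observed_points")
            )
        assert np.mean(diffs) > 0
        assert np.any(np.abs(diffs) > 1e-3)  # the two modes genuinely differ

    def test_requires_curves_for_curve_bases(self, small_dataset):
        stripped = cs.ObservedDataset(observed=small_dataset.observed.copy())
        with pytest.raises(ValueError, match="curves"):
            auc_repeatability(stripped, "ground", "full_curve")

    def test_single_point_event_rejected(self):
        obs = cs.ObservedDataset(
            observed=__import__("pandas").DataFrame(
                {
                    "individual_id": [1, 1, 2, 2],
                    "event_id": [1, 2, 1, 2],
                    "time_min": [30.0, 30.0, 30.0, 30.0],
                    "value": [1.0, 2.0, 3.0, 4.0],
                }
            )
        )
        with pytest.raises(ValueError, match="fewer than two"):
            auc_repeatability(obs, "ground", "observed_points")


class TestProfileRepeatability:
    def test_identical_profiles_within_individuals(self):
        import pandas as pd

        rows = []
        rng = np.random.default_rng(5)
        for ind in range(10):
            profile = rng.uniform(1, 20, size=3)
            for event in (1, 2):
                for t, v in zip((1.0, 15.0, 30.0), profile):
                    rows.append((ind, event, t, v))
        ds = cs.ObservedDataset(
            observed=pd.DataFrame(
                rows, columns=["individual_id", "event_id", "time_min", "value"]
            )
        )
        assert profile_repeatability(ds) == pytest.approx(1.0)

    def test_everyone_identical_is_undefined(self):
        import pandas as pd

        rows = [
            (ind, event, t, 5.0)
            for ind in range(4)
            for event in (1, 2)
            for t in (1.0, 15.0)
        ]
        ds = cs.ObservedDataset(
            observed=pd.DataFrame(
                rows, columns=["individual_id", "event_id", "time_min", "value"]
            )
        )
        with pytest.warns(RuntimeWarning, match="undefined"):
            assert np.isnan(profile_repeatability(ds))

    def test_mismatched_grids_rejected(self, default_pop):
        cohort = cs.sample_population(default_pop, 10, seed=30)
        ds = cs.simulate_dataset(
            cohort,
            design=cs.SamplingDesign(
                kind="uniform_random", window=(1, 60), n_samples=3
            ),
            n_events=2,
            seed=31,
        )
        with pytest.raises(ValueError, match="fixed time grid"):
            profile_repeatability(ds)

    def test_higher_fidelity_more_repeatable(self, default_pop):
        values = {}
        for fidelity in (0.0, 1.0):
            cohort = cs.sample_population(default_pop, 40, seed=32)
            ds = cs.simulate_dataset(
                cohort,
                expr=cs.ExpressionSpec(fidelity=fidelity),
                design=cs.SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
                assay=cs.AssayModel(error_sd=0.0),
                n_events=3,
                seed=33,
            )
            values[fidelity] = profile_repeatability(ds)
        assert values[1.0] > values[0.0]


class TestReport:
    def test_report_shape(self, small_dataset):
        report = repeatability_report(small_dataset)
        assert set(report.per_timepoint) == {1.0, 15.0, 30.0}
        assert len(report.auc) == 6
        assert report.n_individuals == 40
        assert report.n_events == 3
        for value in report.auc.values():
            assert 0.0 <= value <= 1.0

    def test_report_round_trips_json(self, small_dataset, tmp_path):
        import json

        report = repeatability_report(small_dataset)
        path = tmp_path / "report.json"
        report.to_json(path)
        loaded = json.loads(path.read_text())
        assert loaded["n_individuals"] == 40
        assert set(loaded["auc"]) == set(report.auc)

    def test_per_timepoint_keys_match_design(self, small_dataset):
        out = per_timepoint_icc(small_dataset)
        assert sorted(out) == [1.0, 15.0, 30.0]
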