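"""Simulation scenarios: study-design experiments built on the simulator.

Four parameterized, seeded pipelines that each return a tidy table of
sweep-cell outcomes:

* :func:`scenario_peak_timing_sweep` — how accurately a single 30-min
  sample estimates true maximum levels as the population's average peak
  timing and the between-individual SDs of maximum and speed vary.
* :func:`scenario_covariation` — how covariation between speed (time to
  maximum) and scope (maximum level) shapes what single-timepoint
  measures actually capture.
* :func:`scenario_fitness_detection` — power to detect a known
  glucocorticoid-fitness link under different amounts of between- and
  within-individual variation.
* :func:`scenario_sampling_schemes` — how alternative sampling-time
  designs recover a group difference in response speed.
"""

from __future__ import annotations

import math
import warnings
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .curves import DEFAULT_SMOOTH_SPAN, build_curves
from .expression import (
    ExpressionSpec,
    FitnessSpec,
    SamplingDesign,
    assign_fitness,
    express_matrix,
    sample_times,
)
from .population import (
    ParameterSpec,
    PopulationSpec,
    default_population,
    sample_population,
)

__all__ = [
    "scenario2_population",
    "scenario3_population",
    "scenario4_population",
    "scenario5_populations",
    "scenario_peak_timing_sweep",
    "scenario_covariation",
    "scenario_fitness_detection",
    "scenario_sampling_schemes",
    "default_schemes",
    "fit_group_curve",
]

_T_COL = "time_to_max"
_M_COL = "max_value"


def _child_seed(ss: np.random.SeedSequence) -> int:
    """A loggable 31-bit integer identifying a child stream."""
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def _r_squared(x: np.ndarray, y: np.ndarray) -> float:
    """R² of a simple linear regression of y on x."""
    vx = np.var(x)
    if vx == 0 or np.var(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


# ---------------------------------------------------------------------
# scenario populations


def scenario2_population(
    peak_mean: float, max_sd: float, speed_sd: float
) -> PopulationSpec:
    """Population for the single-trait accuracy sweep.

    Only maximum level (linear scale, mean 25 ng/µl) and time to maximum
    vary between individuals; every other parameter is identical across
    the population (SD 0), isolating the effect of the two swept SDs.
    """
    return PopulationSpec(
        params={
            "baseline": ParameterSpec(5.0, 0.0),
            "onset_delay": ParameterSpec(3.0, 0.0),
            "time_to_max": ParameterSpec(float(peak_mean), float(speed_sd)),
            "max_value": ParameterSpec(25.0, float(max_sd)),
            "plateau_duration": ParameterSpec(10.0, 0.0),
            "return_duration": ParameterSpec(30.0, 0.0),
            "end_value": ParameterSpec(6.0, 0.0),
        }
    )


def scenario3_population(
    correlation: float = 0.0,
    speed_sd: float = 2.0,
    max_sd: float = 1.0,
) -> PopulationSpec:
    """Population for the speed–scope covariation scenario.

    Average speed (time to maximum) is 30 min; maximum level is on the
    linear scale (mean 25 ng/µl) so the swept SDs are in ng/µl, and the
    requested correlation links time-to-max and maximum on the sampling
    scale. A negative correlation means faster responders reach higher
    values. Other parameters keep the package defaults.
    """
    spec = default_population().replace(
        {
            "time_to_max": ParameterSpec(30.0, float(speed_sd)),
            "max_value": ParameterSpec(25.0, float(max_sd)),
        }
    )
    return spec.with_correlation(_T_COL, _M_COL, float(correlation))


def scenario4_population(between_sd: float) -> PopulationSpec:
    """Default population with chosen log-scale SD of maximum level."""
    return default_population().replace(
        {"max_value": ParameterSpec(math.log(25.0), float(between_sd), "log")}
    )


def scenario5_populations(
    speed_reduction: float = 0.4,
) -> Tuple[PopulationSpec, PopulationSpec]:
    """Control and treatment populations for the sampling-scheme study.

    The treatment group reaches its maximum ``speed_reduction`` (40% by
    default, i.e. 12 min) faster than the control's 30-min average, with
    a proportionally shorter onset delay (hence a steeper initial
    slope); the two groups share the same maximum-level distribution.
    """
    control = default_population()
    factor = 1.0 - speed_reduction
    treatment = control.replace(
        {
            "time_to_max": ParameterSpec(30.0 * factor, 5.0),
            "onset_delay": ParameterSpec(3.0 * factor, 0.6),
        }
    )
    return control, treatment


# ---------------------------------------------------------------------
# scenario 2: accuracy of a single 30-min sample


def scenario_peak_timing_sweep(
    peak_means: Sequence[float] = (15.0, 30.0, 45.0),
    max_sd_grid: Sequence[float] = (1.0, 2.0, 4.0, 6.0, 8.0, 10.0, 12.0),
    speed_sd_grid: Sequence[float] = (1.0, 4.0, 8.0, 12.0, 16.0, 20.0),
    n: int = 200,
    sample_time: float = 30.0,
    seed: Optional[int] = None,
    reps: int = 1,
    fidelity: float = 0.8,
    error_sd: float = 1.0,
    t_end: int = 90,
) -> pd.DataFrame:
    """Sweep peak timing and between-individual SDs of maximum and speed.

    Per cell: ``n`` individuals, one expressed event each (moderate
    within-individual variability, small assay error), measured at
    ``sample_time``; records the R² of the observed value regressed on
    the true maximum. Returns tidy rows (scenario, peak_mean, max_sd,
    speed_sd, rep, seed, r2, n).
    """
    if not (len(peak_means) and len(max_sd_grid) and len(speed_sd_grid)):
        raise ValueError("sweep grids must be non-empty")
    expr = ExpressionSpec(fidelity=fidelity)
    master = np.random.SeedSequence(seed)
    rows = []
    for peak in peak_means:
        for max_sd in max_sd_grid:
            for speed_sd in speed_sd_grid:
                for rep in range(1, reps + 1):
                    child = master.spawn(1)[0]
                    rng = np.random.default_rng(child)
                    r2 = float("nan")
                    if max_sd <= 0:
                        warnings.warn(
                            "max_sd=0 cell: R² undefined (no variance in "
                            "true maximum); reported as missing",
                            RuntimeWarning,
                        )
                    else:
                        spec = scenario2_population(peak, max_sd, speed_sd)
                        cohort = sample_population(spec, n, rng)
                        expressed = express_matrix(
                            cohort.frame.to_numpy(), expr, spec, rng
                        )
                        curves = build_curves(expressed, t_end=t_end)
                        grid = np.arange(0, t_end + 1, dtype=float)
                        observed = np.array(
                            [np.interp(sample_time, grid, c) for c in curves]
                        )
                        observed = observed + rng.normal(
                            0.0, error_sd, size=n
                        )
                        observed = np.maximum(observed, 0.0)
                        true_max = cohort.frame[_M_COL].to_numpy()
                        r2 = _r_squared(true_max, observed)
                    rows.append(
                        {
                            "scenario": "peak_timing_sweep",
                            "peak_mean": peak,
                            "max_sd": max_sd,
                            "speed_sd": speed_sd,
                            "rep": rep,
                            "seed": _child_seed(child),
                            "r2": r2,
                            "n": n,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# scenario 3: covariation between speed and scope


def scenario_covariation(
    correlations: Sequence[float] = (-0.6, 0.0, 0.6),
    speed_sds: Sequence[float] = (2.0, 12.0),
    max_sds: Sequence[float] = (1.0, 10.0),
    times: Sequence[float] = tuple(range(0, 36)),
    reps: int = 50,
    n: int = 100,
    seed: Optional[int] = None,
    t_end: int = 90,
) -> pd.DataFrame:
    """Sweep speed–scope correlation and low/high variance combinations.

    Per (correlation, speed_sd, max_sd, rep): sample ``n`` individuals,
    express one event each, and — at every time in ``times`` — regress
    the noiseless expressed-curve value on the true time-to-max (speed)
    and, separately, on the true maximum. Returns tidy rows with
    ``target`` in {"speed", "max"} and the per-time R².
    """
    if np.any(np.abs(np.asarray(correlations)) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    expr = ExpressionSpec()
    master = np.random.SeedSequence(seed)
    times = np.asarray(times, dtype=float)
    rows = []
    for corr in correlations:
        for speed_sd in speed_sds:
            for max_sd in max_sds:
                spec = scenario3_population(corr, speed_sd, max_sd)
                for rep in range(1, reps + 1):
                    child = master.spawn(1)[0]
                    rng = np.random.default_rng(child)
                    cohort = sample_population(spec, n, rng)
                    expressed = express_matrix(
                        cohort.frame.to_numpy(), expr, spec, rng
                    )
                    curves = build_curves(expressed, t_end=t_end)
                    grid = np.arange(0, t_end + 1, dtype=float)
                    true_speed = cohort.frame[_T_COL].to_numpy()
                    true_max = cohort.frame[_M_COL].to_numpy()
                    values = np.vstack(
                        [np.interp(times, grid, c) for c in curves]
                    )
                    cseed = _child_seed(child)
                    for j, t in enumerate(times):
                        v = values[:, j]
                        for target, truth in (
                            ("speed", true_speed),
                            ("max", true_max),
                        ):
                            rows.append(
                                {
                                    "scenario": "covariation",
                                    "correlation": corr,
                                    "speed_sd": speed_sd,
                                    "max_sd": max_sd,
                                    "rep": rep,
                                    "seed": cseed,
                                    "time_min": float(t),
                                    "target": target,
                                    "r2": _r_squared(truth, v),
                                    "n": n,
                                }
                            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# scenario 4: detecting fitness links


def scenario_fitness_detection(
    between_sds: Sequence[float] = (0.02, 0.5),
    within_fidelities: Sequence[float] = (0.9, 0.5),
    n: int = 50,
    reps: int = 50,
    seed: Optional[int] = None,
    sample_time: float = 30.0,
    max_share: float = 0.8,
    error_sd: float = 1.0,
    t_end: int = 90,
) -> pd.DataFrame:
    """Power to detect a known fitness link under variance regimes.

    True maximum level (log scale) carries ``max_share`` of the fitness
    variance. Per replicate population: sample ``n`` individuals,
    observe one event at ``sample_time`` with assay error, regress
    fitness on the observed value and record the true and observed
    correlations plus a two-sided p < 0.05 detection flag.
    """
    if n < 3:
        raise ValueError("n must be >= 3")
    master = np.random.SeedSequence(seed)
    rows = []
    fit_spec = FitnessSpec(
        variance_share={"max_value": float(max_share)},
        unmeasured_share=1.0 - max_share,
    )
    grid = None
    for between_sd in between_sds:
        spec = scenario4_population(between_sd)
        for fidelity in within_fidelities:
            expr = ExpressionSpec(fidelity=fidelity)
            for rep in range(1, reps + 1):
                child = master.spawn(1)[0]
                rng = np.random.default_rng(child)
                cohort = sample_population(spec, n, rng)
                fitness = assign_fitness(cohort, fit_spec, rng).to_numpy()
                expressed = express_matrix(
                    cohort.frame.to_numpy(), expr, spec, rng
                )
                curves = build_curves(expressed, t_end=t_end)
                if grid is None or grid.size != curves.shape[1]:
                    grid = np.arange(0, t_end + 1, dtype=float)
                observed = np.array(
                    [np.interp(sample_time, grid, c) for c in curves]
                )
                observed = np.maximum(
                    observed + rng.normal(0.0, error_sd, size=n), 0.0
                )
                true_max_log = np.log(cohort.frame[_M_COL].to_numpy())
                res = stats.linregress(observed, fitness)
                rows.append(
                    {
                        "scenario": "fitness_detection",
                        "between_sd": between_sd,
                        "fidelity": fidelity,
                        "rep": rep,
                        "seed": _child_seed(child),
                        "true_corr": float(
                            np.corrcoef(true_max_log, fitness)[0, 1]
                        ),
                        "observed_corr": float(
                            np.corrcoef(observed, fitness)[0, 1]
                        ),
                        "p_value": float(res.pvalue),
                        "detected": bool(res.pvalue < 0.05),
                        "n": n,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# scenario 5: sampling-scheme design


def default_schemes() -> dict:
    """The five candidate sampling schemes for the design study."""
    return {
        "fixed_1_30_60": SamplingDesign(kind="fixed", fixed_times=(1, 30, 60)),
        "fixed_1_15_30": SamplingDesign(kind="fixed", fixed_times=(1, 15, 30)),
        "fixed_1_15_60": SamplingDesign(kind="fixed", fixed_times=(1, 15, 60)),
        "random": SamplingDesign(
            kind="uniform_random", window=(1.0, 60.0), n_samples=3
        ),
        "weighted": SamplingDesign(
            kind="weighted_normal", center=32.0, spread=9.0, n_samples=3
        ),
    }


_EDGE_SLOPE_WINDOW = 10.0  # minutes of fitted curve used for the boundary slope


def _boundary_slope(ft: np.ndarray, fv: np.ndarray, left: bool) -> float:
    if left:
        mask = ft <= ft[0] + _EDGE_SLOPE_WINDOW
    else:
        mask = ft >= ft[-1] - _EDGE_SLOPE_WINDOW
    if mask.sum() < 2:
        # fall back to the adjacent fitted segment
        mask = np.zeros_like(mask)
        mask[:2] = True
        if not left:
            mask = np.zeros_like(mask)
            mask[-2:] = True
    return float(np.polyfit(ft[mask], fv[mask], 1)[0])


def _extrapolate_edges(
    est: np.ndarray, grid: np.ndarray, ft: np.ndarray, fv: np.ndarray
) -> np.ndarray:
    est = est.copy()
    lo_mask = grid < ft[0]
    if lo_mask.any():
        slope = _boundary_slope(ft, fv, left=True)
        est[lo_mask] = fv[0] + slope * (grid[lo_mask] - ft[0])
    hi_mask = grid > ft[-1]
    if hi_mask.any():
        slope = _boundary_slope(ft, fv, left=False)
        est[hi_mask] = fv[-1] + slope * (grid[hi_mask] - ft[-1])
    return est


def fit_group_curve(
    times: np.ndarray,
    values: np.ndarray,
    grid: np.ndarray,
    frac: float = 0.4,
    n_boot: int = 0,
    rng: Optional[np.random.Generator] = None,
    groups: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Scatterplot-smoother estimate of a group's mean response curve.

    Locally weighted regression of pooled sample values on sampling
    time, evaluated on ``grid`` (linear interpolation between fitted
    points) and clamped at 0. Grid times outside the sampled range are
    extrapolated linearly along the boundary slope of the fitted curve
    (matching how a penalized-spline fit extends beyond its data) so
    schemes that never sample near t=0 are not credited with a flat
    baseline they did not measure. With ``n_boot > 0`` a pointwise 95%
    band is added by resampling individuals (``groups`` required).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)

    def _fit(t, v):
        sm = lowess(v, t, frac=frac, it=0, return_sorted=True)
        ft, idx = np.unique(sm[:, 0], return_index=True)
        fv = sm[idx, 1]
        est = np.interp(grid, ft, fv)
        est = _extrapolate_edges(est, grid, ft, fv)
        return np.clip(est, 0.0, None)

    out = pd.DataFrame({"time_min": grid, "estimate": _fit(times, values)})
    if n_boot > 0:
        if groups is None:
            raise ValueError("bootstrap band requires per-sample groups")
        groups = np.asarray(groups)
        uniq = np.unique(groups)
        rng = np.random.default_rng(rng)
        boots = np.empty((n_boot, grid.size))
        for b in range(n_boot):
            chosen = rng.choice(uniq, size=uniq.size, replace=True)
            masks = [groups == g for g in chosen]
            t = np.concatenate([times[m] for m in masks])
            v = np.concatenate([values[m] for m in masks])
            boots[b] = _fit(t, v)
        out["lower"] = np.quantile(boots, 0.025, axis=0)
        out["upper"] = np.quantile(boots, 0.975, axis=0)
    return out


def scenario_sampling_schemes(
    control_spec: Optional[PopulationSpec] = None,
    treatment_spec: Optional[PopulationSpec] = None,
    schemes: Optional[dict] = None,
    n_per_group: int = 20,
    n_samples: int = 3,
    seed: Optional[int] = None,
    reps: int = 1,
    eval_window: Tuple[float, float] = (0.0, 60.0),
    smooth_frac: float = 0.4,
    t_end: int = 120,
) -> pd.DataFrame:
    """Compare sampling schemes for detecting a group speed difference.

    Each individual is observed once, at ``n_samples`` scheme-generated
    times, directly from its *true* smoothed response curve (no assay
    error). Per scheme and replicate, a lowess group-curve estimate is
    compared with the true group-mean curve over ``eval_window``:
    records the mean absolute curve error per group and the estimated
    vs true between-group difference in the time of the curve maximum.
    """
    if control_spec is None or treatment_spec is None:
        c_def, t_def = scenario5_populations()
        control_spec = control_spec or c_def
        treatment_spec = treatment_spec or t_def
    if schemes is None:
        schemes = default_schemes()
    if not schemes:
        raise ValueError("schemes must be non-empty")
    master = np.random.SeedSequence(seed)
    lo, hi = eval_window
    grid = np.arange(lo, hi + 1, dtype=float)
    full_grid = np.arange(0, t_end + 1, dtype=float)
    rows = []
    for rep in range(1, reps + 1):
        rep_child = master.spawn(1)[0]
        rng = np.random.default_rng(rep_child)
        groups = {}
        for gname, spec in (
            ("control", control_spec),
            ("treatment", treatment_spec),
        ):
            cohort = sample_population(spec, n_per_group, rng)
            curves = build_curves(cohort.frame.to_numpy(), t_end=t_end)
            true_mean = curves.mean(axis=0)
            groups[gname] = (curves, np.interp(grid, full_grid, true_mean))
        true_peak = {
            g: grid[int(np.argmax(tm))] for g, (_, tm) in groups.items()
        }
        true_peak_diff = true_peak["control"] - true_peak["treatment"]
        for scheme_name, design in schemes.items():
            design = _with_n_samples(design, n_samples)
            cell = {}
            for gname, (curves, true_mean) in groups.items():
                times = sample_times(design, n_per_group, rng, t_end=t_end)
                vals = np.array(
                    [
                        np.interp(times[i], full_grid, curves[i])
                        for i in range(n_per_group)
                    ]
                )
                est = fit_group_curve(
                    times.ravel(), vals.ravel(), grid, frac=smooth_frac
                )["estimate"].to_numpy()
                cell[gname] = {
                    "mae": float(np.mean(np.abs(est - true_mean))),
                    "peak": float(grid[int(np.argmax(est))]),
                    "n_rows": times.size,
                }
            rows.append(
                {
                    "scenario": "sampling_schemes",
                    "scheme": scheme_name,
                    "rep": rep,
                    "seed": _child_seed(rep_child),
                    "mae_control": cell["control"]["mae"],
                    "mae_treatment": cell["treatment"]["mae"],
                    "mae_mean": 0.5
                    * (cell["control"]["mae"] + cell["treatment"]["mae"]),
                    "est_peak_control": cell["control"]["peak"],
                    "est_peak_treatment": cell["treatment"]["peak"],
                    "est_peak_diff": cell["control"]["peak"]
                    - cell["treatment"]["peak"],
                    "true_peak_diff": float(true_peak_diff),
                    "n_rows": cell["control"]["n_rows"]
                    + cell["treatment"]["n_rows"],
                }
            )
    return pd.DataFrame(rows)


def _with_n_samples(design: SamplingDesign, n_samples: int) -> SamplingDesign:
    if design.kind == "fixed":
        return design
    if design.n_samples == n_samples:
        return design
    from dataclasses import replace

    return replace(design, n_samples=n_samples)
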