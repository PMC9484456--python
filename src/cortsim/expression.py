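"""From true phenotypes to repeated observed responses.

Within-individual variation is modelled by *expression mixing*: each
realized response blends the individual's true parameters with a fresh
phenotype drawn from the same population distribution, so the population
covariance structure is preserved across expressed responses. The
expressed parameters are realized as a smoothed curve, sampled at
design-specified times, and perturbed with additive assay error. A
simple fitness value per individual can be generated from the true
parameters with user-chosen variance shares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .curves import (
    DEFAULT_SMOOTH_SPAN,
    DEFAULT_T_END,
    PARAM_NAMES,
    ResponseCurve,
    ResponseParams,
    build_curves,
    params_valid_mask,
)
from .population import Cohort, PopulationSpec, sample_truth_matrix

__all__ = [
    "ExpressionSpec",
    "SamplingDesign",
    "AssayModel",
    "FitnessSpec",
    "ObservedDataset",
    "express_event",
    "sample_times",
    "observe",
    "simulate_dataset",
    "assign_fitness",
    "DEFAULT_FIDELITY",
]

#: Default expression fidelity. Under convex mixing this yields an
#: expressed-trait repeatability of w^2 / (w^2 + (1-w)^2) ~= 0.22,
#: in line with field estimates for stress-induced glucocorticoids.
DEFAULT_FIDELITY = 0.35

_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class ExpressionSpec:
    """How strongly an expressed response tracks the true phenotype.

    ``fidelity`` is either a single weight ``w`` in [0, 1] applied to
    every parameter or a per-parameter mapping; ``w = 1`` reproduces the
    true value exactly, ``w = 0`` draws an unrelated response.

    ``mode="convex"`` mixes ``w*true + (1-w)*fresh`` (the literal
    blend; marginal variance shrinks by ``w^2 + (1-w)^2``).
    ``mode="variance_preserving"`` mixes
    ``mu + w*(true-mu) + sqrt(1-w^2)*(fresh-mu)``, keeping the
    population variance exact for every ``w``. Mixing happens on the
    sampling scale (log scale for log-flagged parameters).
    """

    fidelity: Union[float, Mapping[str, float]] = DEFAULT_FIDELITY
    mode: str = "convex"

    def __post_init__(self) -> None:
        if self.mode not in ("convex", "variance_preserving"):
            raise ValueError(f"unknown expression mode {self.mode!r}")
        w = self.weights()
        if np.any(w < 0) or np.any(w > 1):
            raise ValueError("fidelity weights must lie in [0, 1]")

    def weights(self) -> np.ndarray:
        """Per-parameter weight vector in canonical order."""
        if isinstance(self.fidelity, Mapping):
            unknown = set(self.fidelity) - set(PARAM_NAMES)
            if unknown:
                raise ValueError(f"unknown parameters: {sorted(unknown)}")
            return np.array(
                [
                    float(self.fidelity.get(n, 1.0))
                    for n in PARAM_NAMES
                ]
            )
        return np.full(len(PARAM_NAMES), float(self.fidelity))


@dataclass(frozen=True)
class SamplingDesign:
    """When blood samples are taken within one response event.

    kind="fixed": every individual is sampled at ``fixed_times``.
    kind="uniform_random": ``n_samples`` times drawn uniformly on
    ``window`` per individual.
    kind="weighted_normal": ``n_samples`` times drawn from
    Normal(center, spread), truncated to [0, t_end] by redraw —
    sampling weighted around the expected peak.
    """

    kind: str = "fixed"
    fixed_times: Sequence[float] = (1.0, 15.0, 30.0)
    window: Sequence[float] = (1.0, 60.0)
    center: float = 32.0
    spread: float = 9.0
    n_samples: Optional[int] = None

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform_random", "weighted_normal"):
            raise ValueError(f"unknown design kind {self.kind!r}")
        if self.kind == "fixed":
            if len(self.fixed_times) < 1:
                raise ValueError("fixed design needs at least one time")
        else:
            if self.samples_per_event < 1:
                raise ValueError("n_samples must be >= 1")
        if self.kind == "uniform_random":
            lo, hi = self.window
            if not hi > lo:
                raise ValueError("empty sampling window")
        if self.kind == "weighted_normal" and self.spread < 0:
            raise ValueError("spread must be >= 0")

    @property
    def samples_per_event(self) -> int:
        if self.kind == "fixed":
            return len(self.fixed_times)
        return int(self.n_samples if self.n_samples is not None else 3)


@dataclass(frozen=True)
class AssayModel:
    """Additive Gaussian measurement error with a detection floor."""

    error_sd: float = 0.0
    floor: float = 0.0

    def __post_init__(self) -> None:
        if self.error_sd < 0:
            raise ValueError("error_sd must be >= 0")


@dataclass(frozen=True)
class FitnessSpec:
    """Variance shares linking true parameters to a fitness value.

    ``variance_share[name]`` is the proportion of fitness variance
    contributed by that true parameter; ``unmeasured_share`` is the
    proportion from everything not simulated. Shares must sum to 1.
    """

    variance_share: Mapping[str, float] = field(default_factory=dict)
    unmeasured_share: float = 1.0

    def __post_init__(self) -> None:
        unknown = set(self.variance_share) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")
        shares = list(self.variance_share.values()) + [self.unmeasured_share]
        if any(s < 0 or s > 1 for s in shares):
            raise ValueError("variance shares must lie in [0, 1]")
        if abs(sum(shares) - 1.0) > 1e-9:
            raise ValueError("variance shares must sum to 1")


@dataclass
class ObservedDataset:
    """A simulated (or imported) repeated-measures hormone dataset.

    Attributes
    ----------
    observed : DataFrame
        Long table with columns ``individual_id, event_id, time_min,
        value`` — what an empirical study would record.
    true_params : DataFrame
        One row per individual: the true phenotype (natural scale).
    event_params : DataFrame
        One row per (individual, event): the expressed parameters.
    event_curves : DataFrame or None
        Long table of the full smoothed expressed curves (columns as
        ``observed``), when curves were retained.
    fitness : DataFrame or None
        ``individual_id, fitness`` when a fitness spec was supplied.
    """

    observed: pd.DataFrame
    true_params: Optional[pd.DataFrame] = None
    event_params: Optional[pd.DataFrame] = None
    event_curves: Optional[pd.DataFrame] = None
    fitness: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        required = {"individual_id", "event_id", "time_min", "value"}
        missing = required - set(self.observed.columns)
        if missing:
            raise ValueError(f"observed table missing columns {missing}")

    @property
    def n_individuals(self) -> int:
        return self.observed["individual_id"].nunique()

    @property
    def n_events(self) -> int:
        return self.observed.groupby("individual_id")["event_id"].nunique().max()

    @classmethod
    def from_csv(cls, observed_path, curves_path=None) -> "ObservedDataset":
        """Load a long-format observed table (and optional curves) from CSV."""
        observed = pd.read_csv(observed_path)
        curves = pd.read_csv(curves_path) if curves_path else None
        return cls(observed=observed, event_curves=curves)


# ---------------------------------------------------------------------
# expression mixing


def _mix_sampling_scale(
    true_s: np.ndarray,
    fresh_s: np.ndarray,
    weights: np.ndarray,
    mode: str,
    means: np.ndarray,
) -> np.ndarray:
    w = weights
    if mode == "convex":
        return w * true_s + (1.0 - w) * fresh_s
    # variance-preserving blend around the population mean
    return means + w * (true_s - means) + np.sqrt(1.0 - w**2) * (
        fresh_s - means
    )


def express_matrix(
    true_matrix: np.ndarray,
    spec: ExpressionSpec,
    pop: PopulationSpec,
    rng: np.random.Generator,
) -> np.ndarray:
    """Expressed (natural-scale) parameters for each row of true params.

    Draws one fresh phenotype per row with the population's rejection
    rules, mixes on the sampling scale, and rejection-resamples the
    fresh draw until the mixed row is itself physiologically valid.
    """
    true_matrix = np.asarray(true_matrix, dtype=float)
    n = true_matrix.shape[0]
    weights = spec.weights()
    log_mask = pop.log_mask
    true_s = true_matrix.copy()
    true_s[:, log_mask] = np.log(true_s[:, log_mask])

    out = np.empty_like(true_matrix)
    pending = np.arange(n)
    for _ in range(_MAX_ATTEMPTS):
        fresh = sample_truth_matrix(pop, len(pending), rng)
        fresh_s = fresh
        fresh_s[:, log_mask] = np.log(fresh_s[:, log_mask])
        mixed_s = _mix_sampling_scale(
            true_s[pending], fresh_s, weights, spec.mode, pop.means
        )
        mixed = mixed_s.copy()
        mixed[:, log_mask] = np.exp(mixed[:, log_mask])
        ok = params_valid_mask(mixed)
        out[pending[ok]] = mixed[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise RuntimeError(
        "could not express valid parameters within "
        f"{_MAX_ATTEMPTS} attempts; re-specify the population"
    )


def express_event(
    true_params: ResponseParams,
    spec: ExpressionSpec,
    pop: PopulationSpec,
    rng: np.random.Generator,
) -> ResponseParams:
    """One expressed response for an individual with the given truth."""
    mixed = express_matrix(
        true_params.to_array()[None, :], spec, pop, rng
    )
    return ResponseParams.from_array(mixed[0])


# ---------------------------------------------------------------------
# sampling designs and assay


def sample_times(
    design: SamplingDesign,
    n_individuals: int,
    rng: np.random.Generator,
    t_end: float = DEFAULT_T_END,
) -> np.ndarray:
    """Per-individual sorted sampling times, shape (n, samples_per_event)."""
    if n_individuals < 1:
        raise ValueError("n_individuals must be >= 1")
    k = design.samples_per_event
    if design.kind == "fixed":
        times = np.sort(np.asarray(design.fixed_times, dtype=float))
        if times[0] < 0 or times[-1] > t_end:
            raise ValueError("fixed times outside [0, t_end]")
        return np.tile(times, (n_individuals, 1))
    if design.kind == "uniform_random":
        lo, hi = design.window
        if lo < 0 or hi > t_end:
            raise ValueError("sampling window outside [0, t_end]")
        draws = rng.uniform(lo, hi, size=(n_individuals, k))
        return np.sort(draws, axis=1)
    # weighted_normal: truncate to [0, t_end] by redraw
    draws = rng.normal(design.center, design.spread, size=(n_individuals, k))
    bad = (draws < 0) | (draws > t_end)
    for _ in range(_MAX_ATTEMPTS):
        if not bad.any():
            break
        draws[bad] = rng.normal(design.center, design.spread, size=bad.sum())
        bad = (draws < 0) | (draws > t_end)
    else:
        raise RuntimeError("weighted design barely overlaps [0, t_end]")
    return np.sort(draws, axis=1)


def observe(
    event_curve: ResponseCurve,
    times,
    assay: AssayModel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Measure a curve at given times with additive assay error."""
    values = event_curve.value_at(times)
    if assay.error_sd > 0:
        values = values + rng.normal(0.0, assay.error_sd, size=values.shape)
    return np.maximum(values, assay.floor)


# ---------------------------------------------------------------------
# full simulation


def simulate_dataset(
    cohort: Cohort,
    expr: ExpressionSpec = ExpressionSpec(),
    design: SamplingDesign = SamplingDesign(),
    assay: AssayModel = AssayModel(),
    n_events: int = 1,
    seed: Optional[int] = None,
    t_end: int = DEFAULT_T_END,
    smooth_span: float = DEFAULT_SMOOTH_SPAN,
    keep_curves: bool = True,
    fitness: Optional[FitnessSpec] = None,
) -> ObservedDataset:
    """Simulate repeated observed responses for every cohort member.

    For each individual, ``n_events`` responses are expressed, realized
    as smoothed curves, and measured at design-generated times with
    assay error. Independent child RNG streams are spawned from ``seed``
    for expression, sampling times, assay noise and fitness, so e.g.
    changing the design leaves the expressed responses untouched.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    ss = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    rng_expr, rng_times, rng_assay, rng_fit = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n = cohort.n
    ids = cohort.frame.index.to_numpy()
    true_matrix = cohort.frame.to_numpy()

    rows = []
    curve_rows = []
    event_rows = []
    grid = np.arange(0, int(t_end) + 1, dtype=float)
    for event in range(1, n_events + 1):
        expressed = express_matrix(true_matrix, expr, cohort.spec, rng_expr)
        values = build_curves(expressed, t_end=t_end, smooth_span=smooth_span)
        times = sample_times(design, n, rng_times, t_end=t_end)
        for i in range(n):
            meas = np.interp(times[i], grid, values[i])
            if assay.error_sd > 0:
                meas = meas + rng_assay.normal(
                    0.0, assay.error_sd, size=meas.shape
                )
            meas = np.maximum(meas, assay.floor)
            rows.append(
                pd.DataFrame(
                    {
                        "individual_id": ids[i],
                        "event_id": event,
                        "time_min": times[i],
                        "value": meas,
                    }
                )
            )
        event_rows.append(
            pd.DataFrame(expressed, columns=list(PARAM_NAMES)).assign(
                individual_id=ids, event_id=event
            )
        )
        if keep_curves:
            curve_rows.append(
                pd.DataFrame(
                    {
                        "individual_id": np.repeat(ids, grid.size),
                        "event_id": event,
                        "time_min": np.tile(grid, n),
                        "value": values.ravel(),
                    }
                )
            )

    observed = pd.concat(rows, ignore_index=True)
    observed = observed.sort_values(
        ["individual_id", "event_id", "time_min"], kind="stable"
    ).reset_index(drop=True)
    event_params = pd.concat(event_rows, ignore_index=True)[
        ["individual_id", "event_id", *PARAM_NAMES]
    ]
    event_curves = (
        pd.concat(curve_rows, ignore_index=True).sort_values(
            ["individual_id", "event_id", "time_min"], kind="stable"
        ).reset_index(drop=True)
        if keep_curves
        else None
    )
    fitness_frame = None
    if fitness is not None:
        fit = assign_fitness(cohort, fitness, rng_fit)
        fitness_frame = fit.rename("fitness").reset_index()

    return ObservedDataset(
        observed=observed,
        true_params=cohort.frame.copy(),
        event_params=event_params,
        event_curves=event_curves,
        fitness=fitness_frame,
    )


def assign_fitness(
    cohort: Cohort,
    spec: FitnessSpec,
    rng: np.random.Generator,
) -> pd.Series:
    """Generate one fitness value per individual from true parameters.

    fitness_j = sum_i sqrt(v_i) * z_ij + sqrt(v_u) * eps_j, with z the
    cohort z-score of parameter i on its sampling scale and eps standard
    normal — so with uncorrelated parameters the asymptotic R² of
    fitness on true parameter i equals its variance share v_i.
    """
    sampling = cohort.sampling_scale()
    fitness = np.zeros(cohort.n)
    for name, share in spec.variance_share.items():
        if share == 0:
            continue
        col = sampling[name].to_numpy()
        sd = col.std(ddof=1)
        if sd == 0:
            raise ValueError(
                f"parameter {name!r} has zero variance in the cohort but a "
                "nonzero fitness share"
            )
        z = (col - col.mean()) / sd
        fitness += np.sqrt(share) * z
    fitness += np.sqrt(spec.unmeasured_share) * rng.standard_normal(cohort.n)
    return pd.Series(fitness, index=cohort.frame.index, name="fitness")
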