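"""Sampling "true" phenotypes from a correlated population distribution.

Each individual's seven response parameters are drawn jointly from a
multivariate normal distribution with user-specified means, SDs and a
7x7 correlation matrix. Parameters flagged ``scale="log"`` are sampled
on the natural-log scale inside the joint normal and exponentiated
afterwards, producing the right-skewed marginal typical of maximum
glucocorticoid levels while the correlation structure is honoured on
the sampling scale. Draws that violate the physiological constraints
(e.g. a negative onset delay, or a maximum below baseline) are rejected
and resampled per individual.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd

from .curves import PARAM_NAMES, ResponseParams, params_valid_mask

__all__ = [
    "ParameterSpec",
    "PopulationSpec",
    "Cohort",
    "sample_population",
    "default_population",
]

_MAX_ATTEMPTS = 1000
_PSD_TOL = 1e-8


@dataclass(frozen=True)
class ParameterSpec:
    """Marginal distribution of one parameter.

    ``mean`` and ``sd`` are interpreted on the sampling scale: raw units
    for ``scale="linear"``, natural-log units for ``scale="log"`` (the
    draw is exponentiated after sampling).
    """

    mean: float
    sd: float
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"unknown scale {self.scale!r}")


def _default_param_specs() -> Dict[str, ParameterSpec]:
    return {
        "baseline": ParameterSpec(5.0, 1.0),
        "onset_delay": ParameterSpec(3.0, 1.0),
        "time_to_max": ParameterSpec(30.0, 5.0),
        "max_value": ParameterSpec(math.log(25.0), 0.3, scale="log"),
        "plateau_duration": ParameterSpec(10.0, 3.0),
        "return_duration": ParameterSpec(30.0, 5.0),
        "end_value": ParameterSpec(6.0, 1.0),
    }


@dataclass
class PopulationSpec:
    """Joint distribution of the seven true response parameters.

    Attributes
    ----------
    params : dict
        One :class:`ParameterSpec` per parameter in
        :data:`~cortsim.curves.PARAM_NAMES`.
    correlation : ndarray
        7x7 symmetric correlation matrix on the sampling scale (unit
        diagonal, entries in [-1, 1], positive semidefinite up to a
        small repair tolerance). Rows/columns of zero-SD parameters
        must carry zero off-diagonal correlation.
    """

    params: Dict[str, ParameterSpec] = field(
        default_factory=_default_param_specs
    )
    correlation: np.ndarray = field(
        default_factory=lambda: np.eye(len(PARAM_NAMES))
    )

    def __post_init__(self) -> None:
        missing = set(PARAM_NAMES) - set(self.params)
        extra = set(self.params) - set(PARAM_NAMES)
        if missing:
            raise ValueError(f"missing parameter specs: {sorted(missing)}")
        if extra:
            raise ValueError(f"unknown parameter specs: {sorted(extra)}")
        corr = np.asarray(self.correlation, dtype=float)
        k = len(PARAM_NAMES)
        if corr.shape != (k, k):
            raise ValueError(f"correlation must be {k}x{k}")
        if not np.allclose(corr, corr.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(corr), 1.0, atol=1e-12):
            raise ValueError("correlation diagonal must be 1")
        if np.any(np.abs(corr) > 1 + 1e-12):
            raise ValueError("correlation entries must be in [-1, 1]")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -_PSD_TOL:
            raise ValueError(
                "correlation matrix is not positive semidefinite "
                f"(min eigenvalue {eigvals.min():.3g})"
            )
        if eigvals.min() < 0:
            # Repair tiny negative eigenvalues from config rounding.
            w, v = np.linalg.eigh(corr)
            corr = (v * np.clip(w, 0, None)) @ v.T
            d = np.sqrt(np.diag(corr))
            corr = corr / np.outer(d, d)
        for i, name in enumerate(PARAM_NAMES):
            if self.params[name].sd == 0:
                off = np.delete(corr[i], i)
                if np.any(off != 0):
                    raise ValueError(
                        f"parameter {name!r} has sd=0 but nonzero "
                        "off-diagonal correlation"
                    )
        self.correlation = corr

    # -- helpers -----------------------------------------------------
    @property
    def means(self) -> np.ndarray:
        """Mean vector on the sampling scale, in canonical order."""
        return np.array([self.params[n].mean for n in PARAM_NAMES])

    @property
    def sds(self) -> np.ndarray:
        """SD vector on the sampling scale, in canonical order."""
        return np.array([self.params[n].sd for n in PARAM_NAMES])

    @property
    def log_mask(self) -> np.ndarray:
        """Boolean mask of log-scale parameters, in canonical order."""
        return np.array(
            [self.params[n].scale == "log" for n in PARAM_NAMES]
        )

    def covariance(self) -> np.ndarray:
        """Covariance matrix on the sampling scale."""
        s = self.sds
        return self.correlation * np.outer(s, s)

    def replace(
        self,
        updates: Optional[Mapping[str, ParameterSpec]] = None,
        correlation: Optional[np.ndarray] = None,
    ) -> "PopulationSpec":
        """A copy with some parameter specs and/or correlation replaced."""
        params = dict(self.params)
        if updates:
            params.update(updates)
        corr = self.correlation if correlation is None else correlation
        return PopulationSpec(params=params, correlation=np.array(corr))

    def with_correlation(self, name_a: str, name_b: str, r: float):
        """A copy with one pairwise correlation set (both triangles)."""
        corr = np.array(self.correlation)
        i, j = PARAM_NAMES.index(name_a), PARAM_NAMES.index(name_b)
        corr[i, j] = corr[j, i] = r
        return self.replace(correlation=corr)


def default_population() -> PopulationSpec:
    """The package default population (uncorrelated parameters)."""
    return PopulationSpec()


@dataclass
class Cohort:
    """A sampled set of individuals with known true phenotypes.

    ``frame`` holds natural-scale parameter values (one row per
    individual, indexed by ``individual_id`` starting at 1).
    """

    frame: pd.DataFrame
    spec: PopulationSpec
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return len(self.frame)

    def params_for(self, individual_id: int) -> ResponseParams:
        """The true :class:`ResponseParams` of one individual."""
        return ResponseParams.from_array(
            self.frame.loc[individual_id].to_numpy()
        )

    def sampling_scale(self) -> pd.DataFrame:
        """Parameter values on the sampling scale (log where flagged)."""
        out = self.frame.copy()
        for name, mask in zip(PARAM_NAMES, self.spec.log_mask):
            if mask:
                out[name] = np.log(out[name])
        return out

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, lineterminator="\n")


def _draw_sampling_scale(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    cov = spec.covariance()
    # svd handles singular covariances (zero-SD parameters) gracefully.
    return rng.multivariate_normal(
        spec.means, cov, size=n, method="svd", check_valid="ignore"
    )


def sample_truth_matrix(
    spec: PopulationSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n valid natural-scale parameter rows (rejection-resampled).

    Low-level routine behind :func:`sample_population`; also used by the
    expression machinery to draw "fresh" responses with the identical
    rejection rules.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    out = np.empty((n, len(PARAM_NAMES)))
    pending = np.arange(n)
    rejected = 0
    for _ in range(_MAX_ATTEMPTS):
        draw = _draw_sampling_scale(spec, len(pending), rng)
        draw[:, spec.log_mask] = np.exp(draw[:, spec.log_mask])
        ok = params_valid_mask(draw)
        out[pending[ok]] = draw[ok]
        rejected += int((~ok).sum())
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:
        raise RuntimeError(
            "could not draw valid parameters within "
            f"{_MAX_ATTEMPTS} attempts; re-specify the population"
        )
    rate = rejected / (rejected + n)
    # Only flag the rate once enough draws have accrued for it to be a
    # property of the spec rather than small-sample noise.
    if rate > 0.5 and rejected + n >= 40:
        raise ValueError(
            f"rejection rate {rate:.0%} exceeds 50%; the population "
            "specification places most mass on invalid responses — "
            "re-specify means/SDs"
        )
    return out


def sample_population(
    spec: PopulationSpec, n: int, seed: Optional[int] = None
) -> Cohort:
    """Sample a cohort of ``n`` individuals with true phenotypes.

    Deterministic given ``(spec, n, seed)``. ``seed`` may be an int or a
    :class:`numpy.random.Generator`/``SeedSequence``.
    """
    rng = np.random.default_rng(seed)
    matrix = sample_truth_matrix(spec, n, rng)
    frame = pd.DataFrame(matrix, columns=list(PARAM_NAMES))
    frame.index = pd.RangeIndex(1, n + 1, name="individual_id")
    stored_seed = seed if isinstance(seed, (int, np.integer)) else None
    return Cohort(frame=frame, spec=spec, seed=stored_seed)
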