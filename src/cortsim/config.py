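"""Run configuration: YAML/JSON loading, validation and serialization.

A run config gathers every simulator knob in one document::

    seed: 1
    n_individuals: 20
    n_events: 3
    t_end: 120
    smooth_span: 0.3
    population:
      means: {baseline: 5, time_to_max: 30, max_value: 3.2189, ...}
      sds: {baseline: 1, ...}
      scales: {max_value: log}      # means/sds on the natural-log scale
      correlation:                  # full 7x7 matrix, or pair list:
        - [time_to_max, max_value, -0.6]
    expression: {fidelity: 0.35, mode: convex}
    design: {kind: fixed, fixed_times: [1, 15, 30]}
    assay: {error_sd: 1.0, floor: 0.0}
    fitness: {variance_share: {max_value: 0.8}, unmeasured_share: 0.2}

Every block is optional (documented defaults apply); unknown keys are
rejected with the offending path named.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import yaml

from .curves import DEFAULT_SMOOTH_SPAN, DEFAULT_T_END, PARAM_NAMES
from .expression import (
    DEFAULT_FIDELITY,
    AssayModel,
    ExpressionSpec,
    FitnessSpec,
    SamplingDesign,
)
from .population import ParameterSpec, PopulationSpec, default_population

__all__ = ["RunConfig", "load_config", "save_config", "config_to_dict"]


class ConfigError(ValueError):
    """A configuration document failed validation."""


@dataclass
class RunConfig:
    """Validated simulator configuration with defaults filled in."""

    population: PopulationSpec = field(default_factory=default_population)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)
    design: SamplingDesign = field(default_factory=SamplingDesign)
    assay: AssayModel = field(default_factory=lambda: AssayModel(error_sd=1.0))
    fitness: Optional[FitnessSpec] = None
    n_individuals: int = 20
    n_events: int = 1
    t_end: int = DEFAULT_T_END
    smooth_span: float = DEFAULT_SMOOTH_SPAN
    seed: Optional[int] = None


def _check_keys(block: dict, allowed, path: str) -> None:
    unknown = set(block) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} under {path!r}"
        )


def _parse_population(block: dict) -> PopulationSpec:
    _check_keys(block, {"means", "sds", "scales", "correlation"}, "population")
    base = default_population()
    means = block.get("means", {}) or {}
    sds = block.get("sds", {}) or {}
    scales = block.get("scales", {}) or {}
    for sub, name in (("means", means), ("sds", sds), ("scales", scales)):
        if not isinstance(name, dict):
            raise ConfigError(f"population.{sub} must be a mapping")
        _check_keys(name, PARAM_NAMES, f"population.{sub}")
    params = {}
    for name in PARAM_NAMES:
        old = base.params[name]
        params[name] = ParameterSpec(
            mean=float(means.get(name, old.mean)),
            sd=float(sds.get(name, old.sd)),
            scale=str(scales.get(name, old.scale)),
        )
    corr = np.eye(len(PARAM_NAMES))
    raw = block.get("correlation")
    if raw is not None:
        if (
            isinstance(raw, list)
            and raw
            and isinstance(raw[0], list)
            and len(raw[0]) == 3
            and isinstance(raw[0][0], str)
        ):
            for a, b, r in raw:
                for nm in (a, b):
                    if nm not in PARAM_NAMES:
                        raise ConfigError(
                            f"unknown parameter {nm!r} in population.correlation"
                        )
                r = float(r)
                if abs(r) > 1:
                    raise ConfigError(
                        f"population.correlation[{a},{b}] = {r} is outside "
                        "[-1, 1]"
                    )
                i, j = PARAM_NAMES.index(a), PARAM_NAMES.index(b)
                corr[i, j] = corr[j, i] = r
        else:
            corr = np.asarray(raw, dtype=float)
            if corr.shape != (len(PARAM_NAMES), len(PARAM_NAMES)):
                raise ConfigError(
                    "population.correlation must be a 7x7 matrix or a list "
                    "of [param_a, param_b, r] triples"
                )
            bad = np.argwhere(np.abs(corr) > 1 + 1e-12)
            if bad.size:
                i, j = bad[0]
                raise ConfigError(
                    f"population.correlation[{PARAM_NAMES[i]},"
                    f"{PARAM_NAMES[j]}] = {corr[i, j]} is outside [-1, 1]"
                )
    try:
        return PopulationSpec(params=params, correlation=corr)
    except ValueError as exc:
        raise ConfigError(f"population: {exc}") from exc


def _parse_expression(block: dict) -> ExpressionSpec:
    _check_keys(block, {"fidelity", "mode"}, "expression")
    fidelity = block.get("fidelity", DEFAULT_FIDELITY)
    if isinstance(fidelity, dict):
        _check_keys(fidelity, PARAM_NAMES, "expression.fidelity")
    try:
        return ExpressionSpec(
            fidelity=fidelity, mode=block.get("mode", "convex")
        )
    except ValueError as exc:
        raise ConfigError(f"expression: {exc}") from exc


def _parse_design(block: dict) -> SamplingDesign:
    _check_keys(
        block,
        {"kind", "fixed_times", "window", "center", "spread", "n_samples"},
        "design",
    )
    kwargs = dict(block)
    if "fixed_times" in kwargs:
        kwargs["fixed_times"] = tuple(float(t) for t in kwargs["fixed_times"])
    if "window" in kwargs:
        kwargs["window"] = tuple(float(t) for t in kwargs["window"])
    try:
        return SamplingDesign(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"design: {exc}") from exc


def _parse_assay(block: dict) -> AssayModel:
    _check_keys(block, {"error_sd", "floor"}, "assay")
    try:
        return AssayModel(
            error_sd=float(block.get("error_sd", 1.0)),
            floor=float(block.get("floor", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"assay: {exc}") from exc


def _parse_fitness(block: dict) -> FitnessSpec:
    _check_keys(block, {"variance_share", "unmeasured_share"}, "fitness")
    shares = block.get("variance_share", {}) or {}
    _check_keys(shares, PARAM_NAMES, "fitness.variance_share")
    try:
        return FitnessSpec(
            variance_share={k: float(v) for k, v in shares.items()},
            unmeasured_share=float(block.get("unmeasured_share", 0.0)),
        )
    except ValueError as exc:
        raise ConfigError(f"fitness: {exc}") from exc


_TOP_KEYS = {
    "population",
    "expression",
    "design",
    "assay",
    "fitness",
    "n_individuals",
    "n_events",
    "t_end",
    "smooth_span",
    "seed",
}


def parse_config(doc: Optional[dict]) -> RunConfig:
    """Validate a parsed YAML/JSON document into a :class:`RunConfig`."""
    doc = doc or {}
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "<root>")
    for key in ("population", "expression", "design", "assay", "fitness"):
        if key in doc and doc[key] is not None and not isinstance(doc[key], dict):
            raise ConfigError(f"{key} must be a mapping")
    cfg = RunConfig(
        population=_parse_population(doc.get("population") or {}),
        expression=_parse_expression(doc.get("expression") or {}),
        design=_parse_design(doc.get("design") or {}),
        assay=_parse_assay(doc.get("assay") or {}),
        fitness=(
            _parse_fitness(doc["fitness"])
            if doc.get("fitness") is not None
            else None
        ),
        n_individuals=int(doc.get("n_individuals", 20)),
        n_events=int(doc.get("n_events", 1)),
        t_end=int(doc.get("t_end", DEFAULT_T_END)),
        smooth_span=float(doc.get("smooth_span", DEFAULT_SMOOTH_SPAN)),
        seed=(None if doc.get("seed") is None else int(doc["seed"])),
    )
    if cfg.n_individuals < 1:
        raise ConfigError("n_individuals must be >= 1")
    if cfg.n_events < 1:
        raise ConfigError("n_events must be >= 1")
    if cfg.t_end <= 0:
        raise ConfigError("t_end must be positive")
    if not 0 < cfg.smooth_span <= 1:
        raise ConfigError("smooth_span must be in (0, 1]")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML (or JSON) configuration file."""
    with open(path, "r", encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"could not parse {path}: {exc}") from exc
    return parse_config(doc)


def config_to_dict(cfg: RunConfig) -> dict:
    """Canonical plain-dict form of a config (round-trips via YAML)."""
    pop = cfg.population
    out = {
        "population": {
            "means": {n: pop.params[n].mean for n in PARAM_NAMES},
            "sds": {n: pop.params[n].sd for n in PARAM_NAMES},
            "scales": {
                n: pop.params[n].scale
                for n in PARAM_NAMES
                if pop.params[n].scale != "linear"
            },
            "correlation": [
                [float(x) for x in row] for row in pop.correlation
            ],
        },
        "expression": {
            "fidelity": (
                dict(cfg.expression.fidelity)
                if isinstance(cfg.expression.fidelity, dict)
                else cfg.expression.fidelity
            ),
            "mode": cfg.expression.mode,
        },
        "design": {
            "kind": cfg.design.kind,
            "fixed_times": [float(t) for t in cfg.design.fixed_times],
            "window": [float(t) for t in cfg.design.window],
            "center": cfg.design.center,
            "spread": cfg.design.spread,
            "n_samples": cfg.design.samples_per_event,
        },
        "assay": {"error_sd": cfg.assay.error_sd, "floor": cfg.assay.floor},
        "n_individuals": cfg.n_individuals,
        "n_events": cfg.n_events,
        "t_end": cfg.t_end,
        "smooth_span": cfg.smooth_span,
        "seed": cfg.seed,
    }
    if cfg.fitness is not None:
        out["fitness"] = {
            "variance_share": dict(cfg.fitness.variance_share),
            "unmeasured_share": cfg.fitness.unmeasured_share,
        }
    return out


def save_config(cfg: RunConfig, path) -> None:
    """Write a config back to YAML in canonical form."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=True)
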