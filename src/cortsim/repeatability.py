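"""Repeatability statistics for repeated-measures hormone data.

Repeatability (the intraclass correlation, ICC) is the proportion of
total phenotypic variance attributable to differences among individuals.
This module computes:

* per-timepoint ICC — one estimate per designed sampling time;
* AUC repeatability — ICC of per-event areas under the curve, for both
  the ground (AUC_G, area above zero) and increase (AUC_I, area above
  the first sample) definitions, computed from three data bases: the
  full stored event curve, only the observed (downsampled) points, or
  the full curve windowed to the observed time range;
* profile repeatability — a variance-component summary of whole-profile
  consistency across matched fixed sampling times.

The ICC estimator is the one-way ANOVA ICC(1),
``R = (MS_B - MS_W) / (MS_B + (k - 1) MS_W)`` with ``k`` the harmonic
mean number of events per individual; negative variance-component
estimates are clamped to zero with a warning. A nonparametric bootstrap
(resampling individuals) provides optional confidence intervals.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .curves import auc as curve_auc
from .expression import ObservedDataset

__all__ = [
    "icc",
    "icc_bootstrap_ci",
    "per_timepoint_icc",
    "event_aucs",
    "auc_repeatability",
    "profile_repeatability",
    "repeatability_report",
    "RepeatabilityReport",
    "AUC_MODES",
    "AUC_BASES",
]

AUC_MODES = ("ground", "increase")
AUC_BASES = ("full_curve", "observed_points", "windowed_curve")


def icc(values, groups) -> float:
    """One-way ANOVA intraclass correlation of values grouped by individual.

    Parameters
    ----------
    values : array-like
        One measurement per row (e.g. one value per response event).
    groups : array-like
        Individual identifier per row.

    Returns
    -------
    float
        Repeatability in [0, 1]; negative estimates are clamped to 0
        (with a warning), and NaN is returned with a warning when the
        data carry no variance at all.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must align")
    _, inv = np.unique(groups, return_inverse=True)
    n_groups = inv.max() + 1 if inv.size else 0
    if n_groups < 2:
        raise ValueError("icc requires at least two individuals")
    counts = np.bincount(inv)
    if counts.max() < 2:
        raise ValueError(
            "icc requires repeated events for at least one individual"
        )
    sums = np.bincount(inv, weights=values)
    means = sums / counts
    grand = values.mean()
    ss_between = float(np.sum(counts * (means - grand) ** 2))
    ss_within = float(np.sum((values - means[inv]) ** 2))
    df_between = n_groups - 1
    df_within = values.size - n_groups
    if df_within == 0:
        raise ValueError("no within-individual degrees of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    k = len(counts) / np.sum(1.0 / counts)  # harmonic mean events/individual
    denom = ms_between + (k - 1) * ms_within
    if denom == 0:
        warnings.warn(
            "no variance between or within individuals; repeatability "
            "undefined",
            RuntimeWarning,
        )
        return float("nan")
    r = (ms_between - ms_within) / denom
    if r < 0:
        warnings.warn(
            f"negative repeatability estimate {r:.3g} clamped to 0",
            RuntimeWarning,
        )
        return 0.0
    return float(min(r, 1.0))


def icc_bootstrap_ci(
    values,
    groups,
    n_boot: int = 500,
    seed: Optional[int] = None,
    level: float = 0.95,
) -> Tuple[float, float]:
    """Percentile bootstrap CI for :func:`icc`, resampling individuals."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    rng = np.random.default_rng(seed)
    stats = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for _ in range(n_boot):
            chosen = rng.choice(uniq, size=uniq.size, replace=True)
            vs, gs = [], []
            for new_id, g in enumerate(chosen):
                mask = groups == g
                vs.append(values[mask])
                gs.append(np.full(mask.sum(), new_id))
            try:
                stats.append(icc(np.concatenate(vs), np.concatenate(gs)))
            except ValueError:
                continue
    alpha = (1.0 - level) / 2.0
    lo, hi = np.nanquantile(stats, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def per_timepoint_icc(dataset: ObservedDataset) -> Dict[float, float]:
    """ICC of measured values at each designed (shared) sampling time.

    Requires a fixed design: every event sampled at the same times.
    """
    obs = dataset.observed
    times = _matched_times(obs)
    out = {}
    for t in times:
        sub = obs[obs["time_min"] == t]
        out[float(t)] = icc(
            sub["value"].to_numpy(), sub["individual_id"].to_numpy()
        )
    return out


def _matched_times(obs: pd.DataFrame) -> np.ndarray:
    per_event = obs.groupby(["individual_id", "event_id"])["time_min"].apply(
        lambda s: tuple(np.sort(s.to_numpy()))
    )
    uniq = set(per_event)
    if len(uniq) != 1:
        raise ValueError(
            "events are not sampled on a shared fixed time grid"
        )
    return np.array(next(iter(uniq)))


def event_aucs(
    dataset: ObservedDataset, mode: str = "ground", basis: str = "observed_points"
) -> pd.DataFrame:
    """Per-event AUC on the chosen point set.

    basis="observed_points" integrates the downsampled measurements;
    "full_curve" integrates the stored smoothed event curve;
    "windowed_curve" integrates the stored curve restricted to
    [min observed time, max observed time] of that event.
    """
    if mode not in AUC_MODES:
        raise ValueError(f"unknown auc mode {mode!r}")
    if basis not in AUC_BASES:
        raise ValueError(f"unknown auc basis {basis!r}")
    if basis in ("full_curve", "windowed_curve"):
        if dataset.event_curves is None:
            raise ValueError(f"basis {basis!r} requires stored event curves")
    rows = []
    obs_groups = dataset.observed.groupby(["individual_id", "event_id"])
    curves = (
        dict(iter(dataset.event_curves.groupby(["individual_id", "event_id"])))
        if dataset.event_curves is not None
        else {}
    )
    for (ind, event), grp in obs_groups:
        if basis == "observed_points":
            t = grp["time_min"].to_numpy()
            v = grp["value"].to_numpy()
            order = np.argsort(t)
            t, v = t[order], v[order]
            if t.size < 2:
                raise ValueError(
                    f"event ({ind}, {event}) has fewer than two points"
                )
        else:
            curve = curves[(ind, event)]
            ct = curve["time_min"].to_numpy()
            cv = curve["value"].to_numpy()
            if basis == "windowed_curve":
                lo = grp["time_min"].min()
                hi = grp["time_min"].max()
                if not hi > lo:
                    raise ValueError(
                        f"event ({ind}, {event}) has a degenerate window"
                    )
                inside = (ct > lo) & (ct < hi)
                t = np.concatenate(([lo], ct[inside], [hi]))
                v = np.concatenate(
                    (
                        [np.interp(lo, ct, cv)],
                        cv[inside],
                        [np.interp(hi, ct, cv)],
                    )
                )
            else:
                t, v = ct, cv
        rows.append(
            {
                "individual_id": ind,
                "event_id": event,
                "auc": curve_auc((t, v), mode=mode),
            }
        )
    return pd.DataFrame(rows)


def auc_repeatability(
    dataset: ObservedDataset,
    mode: str = "ground",
    basis: str = "observed_points",
) -> float:
    """Repeatability (ICC across events) of per-event AUC."""
    aucs = event_aucs(dataset, mode=mode, basis=basis)
    return icc(aucs["auc"].to_numpy(), aucs["individual_id"].to_numpy())


def profile_repeatability(dataset: ObservedDataset) -> float:
    """Whole-profile repeatability over matched fixed sampling times.

    With every event sampled at the same times, let V_w be the mean over
    individuals of the per-timepoint within-individual variance averaged
    across timepoints, and V_a the across-individual variance component
    of the time-specific individual means (the raw variance of means
    minus its expected within-individual contribution V_w / k, clamped
    at zero), averaged across timepoints. Returns V_a / (V_a + V_w),
    which is ~0 when repeated profiles are unrelated within individuals
    and 1 when they repeat exactly.
    """
    obs = dataset.observed
    times = _matched_times(obs)
    pivot = obs.pivot_table(
        index=["individual_id", "event_id"],
        columns="time_min",
        values="value",
    )[times]
    ind = pivot.index.get_level_values("individual_id")
    # per-individual mean profile and within-individual variance per time
    means = pivot.groupby(ind).mean()
    within = pivot.groupby(ind).var(ddof=1)
    counts = pivot.groupby(ind).size()
    k = len(counts) / float((1.0 / counts).sum())  # harmonic mean events
    v_w = float(within.mean(axis=1).mean())
    v_raw = float(means.var(axis=0, ddof=1).mean())
    v_a = max(0.0, v_raw - v_w / k)
    if v_a + v_w == 0 or not np.isfinite(v_a + v_w):
        warnings.warn(
            "profile repeatability undefined (no variance)", RuntimeWarning
        )
        return float("nan")
    return v_a / (v_a + v_w)


@dataclass
class RepeatabilityReport:
    """All repeatability summaries for one dataset."""

    per_timepoint: Dict[float, float] = field(default_factory=dict)
    profile: float = float("nan")
    auc: Dict[str, float] = field(default_factory=dict)
    n_individuals: int = 0
    n_events: int = 0

    def to_dict(self) -> dict:
        return {
            "per_timepoint": {str(k): v for k, v in self.per_timepoint.items()},
            "profile": self.profile,
            "auc": self.auc,
            "n_individuals": self.n_individuals,
            "n_events": self.n_events,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, allow_nan=True)
            fh.write("\n")


def repeatability_report(dataset: ObservedDataset) -> RepeatabilityReport:
    """Per-timepoint, profile and all AUC repeatability variants.

    AUC bases requiring stored curves are skipped when the dataset has
    none (e.g. user-supplied field data).
    """
    aucs: Dict[str, float] = {}
    for mode in AUC_MODES:
        for basis in AUC_BASES:
            if basis != "observed_points" and dataset.event_curves is None:
                continue
            aucs[f"{mode}_{basis}"] = auc_repeatability(
                dataset, mode=mode, basis=basis
            )
    try:
        per_time = per_timepoint_icc(dataset)
        profile = profile_repeatability(dataset)
    except ValueError:
        per_time, profile = {}, float("nan")
    return RepeatabilityReport(
        per_timepoint=per_time,
        profile=profile,
        auc=aucs,
        n_individuals=dataset.n_individuals,
        n_events=int(dataset.n_events),
    )
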