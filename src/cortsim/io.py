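"""Dataset serialization: tidy CSV export/import.

All tables are written as UTF-8 CSV with '.' decimal separator,
newline-terminated rows and a fixed column order, so identical inputs
produce byte-identical files.
"""

from __future__ import annotations

import os
from typing import Dict

import pandas as pd

from .expression import ObservedDataset

__all__ = ["write_dataset", "read_dataset"]

_OBSERVED_COLS = ["individual_id", "event_id", "time_min", "value"]


def _write_csv(frame: pd.DataFrame, path: str) -> None:
    frame.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def write_dataset(dataset: ObservedDataset, out_dir) -> Dict[str, str]:
    """Write a dataset's tables to ``out_dir``; returns name -> path.

    Always writes ``observed.csv``; writes ``truth_individuals.csv``,
    ``truth_events.csv``, ``event_curves.csv`` and ``fitness.csv`` when
    the corresponding tables are present.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths: Dict[str, str] = {}

    observed = dataset.observed[_OBSERVED_COLS]
    path = os.path.join(out_dir, "observed.csv")
    _write_csv(observed, path)
    paths["observed"] = path

    if dataset.true_params is not None:
        path = os.path.join(out_dir, "truth_individuals.csv")
        _write_csv(dataset.true_params.reset_index(), path)
        paths["truth_individuals"] = path
    if dataset.event_params is not None:
        path = os.path.join(out_dir, "truth_events.csv")
        _write_csv(dataset.event_params, path)
        paths["truth_events"] = path
    if dataset.event_curves is not None:
        path = os.path.join(out_dir, "event_curves.csv")
        _write_csv(dataset.event_curves[_OBSERVED_COLS], path)
        paths["event_curves"] = path
    if dataset.fitness is not None:
        path = os.path.join(out_dir, "fitness.csv")
        _write_csv(dataset.fitness, path)
        paths["fitness"] = path
    return paths


def read_dataset(out_dir) -> ObservedDataset:
    """Load a dataset previously written by :func:`write_dataset`."""

    def _maybe(name):
        path = os.path.join(out_dir, name)
        return pd.read_csv(path) if os.path.exists(path) else None

    observed = pd.read_csv(os.path.join(out_dir, "observed.csv"))
    truth = _maybe("truth_individuals.csv")
    if truth is not None:
        truth = truth.set_index("individual_id")
    return ObservedDataset(
        observed=observed,
        true_params=truth,
        event_params=_maybe("truth_events.csv"),
        event_curves=_maybe("event_curves.csv"),
        fitness=_maybe("fitness.csv"),
    )
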