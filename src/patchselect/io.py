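"""Readers, writers and validation for datasets, designs and fit reports.

The on-disk dataset format is a long-format UTF-8 CSV with header
``replicate_id,strain,treatment,patch_id,substrate_id,resource,eggs`` — one
row per replicate x substrate.  Designs travel as YAML documents mapping a
treatment label to its distribution kind and per-patch substrate counts.
Fit and effect reports are JSON and embed the seeds and configuration needed
to regenerate them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .model import DesignError, ExperimentDesign, make_design, standard_designs
from .fit import COLUMNS, DataValidationError, EggCountDataset, FitResult

__all__ = [
    "read_dataset",
    "write_dataset",
    "read_designs",
    "write_designs",
    "load_designs",
    "write_fit_report",
]

logger = logging.getLogger(__name__)


def read_dataset(path: str | Path) -> EggCountDataset:
    """Read and validate a long-format egg-count CSV.

    Raises :class:`DataValidationError` naming offending rows for missing
    columns, non-integer or negative egg counts.  An empty file with a valid
    header yields an empty dataset with a warning.  Zero-egg replicates are
    flagged, never dropped.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, dtype={c: str for c in COLUMNS[:-1]})
    except pd.errors.EmptyDataError:
        raise DataValidationError(f"{path}: file has no header row") from None
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise DataValidationError(f"{path}: missing required columns {missing}")
    if frame.empty:
        logger.warning("%s: no data rows (header only)", path)
    data = EggCountDataset(frame)
    empty = data.zero_total_replicates()
    if empty:
        logger.warning("%s: %d replicate(s) with zero total eggs: %s", path, len(empty), empty[:5])
    return data


def write_dataset(data: EggCountDataset, path: str | Path) -> None:
    """Write the dataset as the canonical long-format CSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    data.frame.loc[:, list(COLUMNS)].to_csv(path, index=False)


def read_designs(path: str | Path) -> dict[str, ExperimentDesign]:
    """Load a design registry from YAML.

    Expected shape::

        6:2-uneven:
          distribution: uneven
          patches:
            - {A: 4, B: 0}
            - {A: 2, B: 2}
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or not doc:
        raise DesignError(f"{path}: expected a mapping of treatment labels to designs")
    registry = {}
    for label, body in doc.items():
        if not isinstance(body, dict) or "patches" not in body:
            raise DesignError(f"{path}: design {label!r} lacks a 'patches' list")
        comps = [(int(p.get("A", 0)), int(p.get("B", 0))) for p in body["patches"]]
        registry[str(label)] = make_design(
            str(label), comps, body.get("distribution", "even")
        )
    return registry


def write_designs(designs: Mapping[str, ExperimentDesign], path: str | Path) -> None:
    doc = {
        label: {
            "distribution": d.distribution_kind,
            "patches": [{"A": a, "B": b} for a, b in d.composition()],
        }
        for label, d in designs.items()
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_designs(source: str | Path | None = None) -> dict[str, ExperimentDesign]:
    """The built-in canonical designs, or a registry read from a YAML file."""
    if source is None:
        return standard_designs()
    return read_designs(source)


def write_fit_report(
    fit: FitResult, path: str | Path, extra: Mapping | None = None
) -> None:
    """Write a fit result (plus optional provenance) as JSON."""
    doc = fit.to_dict()
    if extra:
        doc.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")
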