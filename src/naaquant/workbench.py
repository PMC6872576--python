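"""Shared configuration, I/O and the end-to-end pipeline.

A run is described by a YAML config with nested sections (geometry,
kinetics, imaging, calcium, scoring, population, segmentation) whose
defaults are the study conditions of the simulator.  ``run_pipeline`` chains
simulate -> quantify -> lag -> score for a simulated field of view, writing
a TIFF stack for a representative cell, a tidy traces CSV, lag and score
JSONs, and a manifest that makes the run reproducible (config hash, package
version, seed, per-stage outputs).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .exceptions import ConfigurationError, InputError, PipelineError
from .quant import (
    CellScore,
    Trace,
    heterogeneity_trace,
    normalize_by_range,
    percent_positive,
    roi_mean_trace,
    score_cell,
)
from .simkit import (
    CalciumModel,
    FilamentRecord,
    ImagingConfig,
    KineticsConfig,
    NucleusGeometry,
    TimeLapse,
    iter_population,
)
from .temporal import estimate_lag

__all__ = [
    "ScoringConfig",
    "PopulationConfig",
    "SegmentationConfig",
    "RunConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "config_hash",
    "run_pipeline",
    "write_timelapse",
    "read_timelapse",
    "write_events_csv",
    "read_mask",
]

log = logging.getLogger("naaquant")

CHANNEL_ORDER = ("actin_probe", "calcium")


@dataclass(frozen=True)
class ScoringConfig:
    """Positive-cell calling and onset-detection parameters."""

    k: float = 5.0
    onset_threshold: float = 0.5
    sustain_frames: int = 2

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ConfigurationError("k must be positive")
        if not 0.0 <= self.onset_threshold <= 1.0:
            raise ConfigurationError("onset_threshold must lie in [0, 1]")
        if self.sustain_frames < 1:
            raise ConfigurationError("sustain_frames must be at least 1")


@dataclass(frozen=True)
class PopulationConfig:
    """Field-of-view composition for population runs."""

    n_cells: int = 1
    responder_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError("n_cells must be at least 1")
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ConfigurationError("responder_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SegmentationConfig:
    """EM pixel-classification parameters."""

    min_nucleolus_px: int = 200
    exclude_nucleolus: bool = False

    def __post_init__(self) -> None:
        if self.min_nucleolus_px < 1:
            raise ConfigurationError("min_nucleolus_px must be at least 1")


_SECTIONS = {
    "geometry": NucleusGeometry,
    "kinetics": KineticsConfig,
    "imaging": ImagingConfig,
    "calcium": CalciumModel,
    "scoring": ScoringConfig,
    "population": PopulationConfig,
    "segmentation": SegmentationConfig,
}


@dataclass
class RunConfig:
    """Validated, fully defaulted configuration of a pipeline run."""

    geometry: NucleusGeometry = field(default_factory=NucleusGeometry)
    kinetics: KineticsConfig = field(default_factory=KineticsConfig)
    imaging: ImagingConfig = field(default_factory=ImagingConfig)
    calcium: CalciumModel = field(default_factory=CalciumModel)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    population: PopulationConfig = field(default_factory=PopulationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    seed: int = 0
    outdir: str = "naa_run"


def _build_section(cls, data, section: str):
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"section '{section}' must be a mapping")
    valid = {f.name: f for f in dataclasses.fields(cls)}
    unknown = sorted(set(data) - set(valid))
    if unknown:
        raise ConfigurationError(f"unknown key(s) {unknown} in section '{section}'")
    kwargs = {}
    for name, value in data.items():
        if isinstance(value, list):
            value = tuple(value)
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"invalid section '{section}': {exc}") from exc


def build_config(data: Optional[dict]) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain mapping."""
    data = dict(data or {})
    unknown = sorted(set(data) - set(_SECTIONS) - {"seed", "outdir"})
    if unknown:
        raise ConfigurationError(f"unknown top-level key(s): {unknown}")
    kwargs = {}
    for section, cls in _SECTIONS.items():
        if section in data:
            kwargs[section] = _build_section(cls, data.pop(section), section)
    if "seed" in data:
        seed = data.pop("seed")
        if not isinstance(seed, int) or isinstance(seed, bool):
            raise ConfigurationError("seed must be an integer")
        kwargs["seed"] = seed
    if "outdir" in data:
        kwargs["outdir"] = str(data.pop("outdir"))
    return RunConfig(**kwargs)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run config; an empty file yields defaults."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigurationError(f"cannot parse {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ConfigurationError(f"config root in {path} must be a mapping")
    return build_config(data)


def _plain(obj):
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def config_to_dict(config: RunConfig) -> dict:
    return _plain(dataclasses.asdict(config))


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config), sort_keys=True))


def config_hash(config: RunConfig) -> str:
    canonical = yaml.safe_dump(config_to_dict(config), sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# File I/O


def write_timelapse(path, stack: TimeLapse) -> None:
    """Write a stack as one interleaved multi-page TIFF (axes TCYX) with
    channel names, frame times and pixel size in the shaped metadata."""
    names = [c for c in CHANNEL_ORDER if c in stack.channels]
    names += [c for c in stack.channels if c not in names]
    arr = np.stack([stack.channels[c] for c in names], axis=1).astype(np.float32)
    tifffile.imwrite(
        path,
        arr,
        metadata={
            "axes": "TCYX",
            "channel_names": names,
            "frame_times_s": [float(t) for t in stack.frame_times_s],
            "pixel_size_um": float(stack.pixel_size_um),
        },
    )


def read_timelapse(path) -> TimeLapse:
    """Read a stack written by :func:`write_timelapse` (or any TIFF with a
    TCYX / TYX layout; missing metadata falls back to unit frame times)."""
    with tifffile.TiffFile(path) as tf:
        arr = tf.asarray()
        meta = {}
        if tf.shaped_metadata:
            meta = dict(tf.shaped_metadata[0])
    if arr.ndim == 3:
        arr = arr[:, None, :, :]
    if arr.ndim != 4:
        raise InputError(f"cannot interpret TIFF with shape {arr.shape} as a stack")
    n_frames, n_channels = arr.shape[:2]
    names = meta.get("channel_names") or [f"channel_{i}" for i in range(n_channels)]
    times = meta.get("frame_times_s")
    times = np.asarray(times, float) if times is not None else np.arange(n_frames, dtype=float)
    pixel_size = float(meta.get("pixel_size_um", 1.0))
    channels = {name: arr[:, i].astype(float) for i, name in enumerate(names)}
    return TimeLapse(frame_times_s=times, channels=channels, pixel_size_um=pixel_size)


def write_events_csv(
    path, records: Sequence[FilamentRecord], cell_ids: Optional[Sequence] = None
) -> None:
    """Ground-truth nucleation events as CSV.  ``cell_ids`` (parallel to
    ``records``) adds a leading cell_id column for population runs."""
    rows = []
    for i, r in enumerate(records):
        row = {}
        if cell_ids is not None:
            row["cell_id"] = cell_ids[i]
        row.update(
            event_time_s=r.birth_time_s,
            origin_x_um=r.origin_um[0],
            origin_y_um=r.origin_um[1],
            direction_deg=np.degrees(np.arctan2(r.direction[1], r.direction[0])),
            lifetime_s=r.lifetime_s,
        )
        rows.append(row)
    cols = (["cell_id"] if cell_ids is not None else []) + [
        "event_time_s",
        "origin_x_um",
        "origin_y_um",
        "direction_deg",
        "lifetime_s",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_mask(path) -> np.ndarray:
    """Read a binary ROI mask from TIFF or PNG (nonzero = true)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
    if arr.ndim == 3:  # RGB(A) mask: any channel nonzero
        arr = arr.max(axis=-1)
    return np.asarray(arr) > 0


def traces_to_frame(cell_traces: Dict[int, Dict[str, Trace]]) -> pd.DataFrame:
    """Tidy long-format table of per-cell traces.

    ``cell_traces[cell_id]`` maps ``(kind, roi)`` labels of the form
    ``heterogeneity`` / ``calcium_nucleus`` / ``calcium_cytoplasm`` to traces.
    """
    rows = []
    for cell_id, traces in cell_traces.items():
        for label, tr in traces.items():
            if label == "heterogeneity":
                kind, roi = "heterogeneity", "nucleus"
            else:
                kind, _, roi = label.partition("_")
            for t, v in zip(tr.times_s, tr.values):
                rows.append(
                    {"time_s": t, "value": v, "kind": kind, "roi": roi, "cell_id": cell_id}
                )
    return pd.DataFrame(rows, columns=["time_s", "value", "kind", "roi", "cell_id"])


def frame_to_traces(df: pd.DataFrame) -> Dict[int, Dict[str, Trace]]:
    """Inverse of :func:`traces_to_frame`."""
    out: Dict[int, Dict[str, Trace]] = {}
    for (cell_id, kind, roi), grp in df.groupby(["cell_id", "kind", "roi"], sort=True):
        grp = grp.sort_values("time_s")
        label = "heterogeneity" if kind == "heterogeneity" else f"{kind}_{roi}"
        out.setdefault(cell_id, {})[label] = Trace(
            grp["time_s"].to_numpy(), grp["value"].to_numpy(), kind=kind
        )
    return out


def write_traces_csv(path, cell_traces: Dict[int, Dict[str, Trace]]) -> None:
    traces_to_frame(cell_traces).to_csv(path, index=False)


def read_traces_csv(path) -> Dict[int, Dict[str, Trace]]:
    return frame_to_traces(pd.read_csv(path, float_precision="round_trip"))


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    package_version: str
    seed: int
    outputs: Dict[str, str] = field(default_factory=dict)
    stages: Dict[str, str] = field(default_factory=dict)
    started: str = ""
    finished: str = ""

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _score_payload(score: CellScore, responder: bool) -> dict:
    return {
        "cell_id": score.cell_id,
        "positive": score.positive,
        "peak_raw_heterogeneity": score.peak_raw_heterogeneity,
        "baseline_mean": score.baseline_mean,
        "baseline_sd": score.baseline_sd,
        "true_responder": responder,
    }


def run_pipeline(config: RunConfig, outdir=None) -> RunManifest:
    """Execute simulate -> quantify -> lag -> score and write all outputs.

    Deterministic under the config seed: rerunning with the same config
    yields byte-identical traces CSV / JSON outputs.  On a stage failure the
    manifest is still written with the stage marked failed, and a
    :class:`~naaquant.exceptions.PipelineError` is raised.
    """
    out = Path(outdir or config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config_hash(config),
        package_version=__version__,
        seed=config.seed,
        started=datetime.now(timezone.utc).isoformat(),
    )
    save_config(config, out / "config.yaml")

    stage = "simulate"
    try:
        log.info("[%s] %d cell(s), responder fraction %.2f", stage,
                 config.population.n_cells, config.population.responder_fraction)
        nucleus = config.geometry.nucleus_mask()
        cytoplasm = config.geometry.cytoplasm_mask()
        stim = config.imaging.stimulus_time_s
        cell_traces: Dict[int, Dict[str, Trace]] = {}
        scores: List[CellScore] = []
        responders: List[bool] = []
        lags: List[dict] = []
        all_records: List[FilamentRecord] = []
        all_cell_ids: List[int] = []
        for i, stack, truth in iter_population(
            config.population.n_cells,
            config.population.responder_fraction,
            config.geometry,
            config.kinetics,
            config.imaging,
            config.calcium,
            seed=config.seed,
        ):
            if i == 0:
                write_timelapse(out / "stack.tif", stack)
            all_records.extend(truth.records)
            all_cell_ids.extend([i] * len(truth.records))
            responders.append(truth.responder)

            stage = "quantify"
            het = heterogeneity_trace(stack, nucleus)
            ca_nuc = roi_mean_trace(stack, nucleus)
            ca_cyt = roi_mean_trace(stack, cytoplasm)
            cell_traces[i] = {
                "heterogeneity": het,
                "calcium_nucleus": ca_nuc,
                "calcium_cytoplasm": ca_cyt,
            }

            stage = "lag"
            lr = estimate_lag(
                normalize_by_range(ca_nuc),
                normalize_by_range(het),
                threshold=config.scoring.onset_threshold,
                cytoplasm_trace=normalize_by_range(ca_cyt),
                sustain_frames=config.scoring.sustain_frames,
            )
            lags.append(
                {
                    "cell_id": i,
                    "lag_s": lr.lag_s,
                    "naa_onset_s": lr.naa_onset_s,
                    "calcium_onsets": lr.calcium_onsets,
                    "reason": lr.reason,
                }
            )

            stage = "score"
            scores.append(score_cell(het, stim, k=config.scoring.k, cell_id=i))
            stage = "simulate"

        stage = "write"
        write_events_csv(out / "events.csv", all_records, cell_ids=all_cell_ids)
        write_traces_csv(out / "traces.csv", cell_traces)
        finite = [l["lag_s"] for l in lags if l["lag_s"] is not None]
        (out / "lag.json").write_text(
            json.dumps(
                {
                    "cells": lags,
                    "median_lag_s": float(np.median(finite)) if finite else None,
                    "n_with_lag": len(finite),
                },
                indent=2,
            )
        )
        (out / "scores.json").write_text(
            json.dumps(
                {
                    "scores": [
                        _score_payload(s, r) for s, r in zip(scores, responders)
                    ],
                    "percent_positive": percent_positive(scores),
                },
                indent=2,
            )
        )
        manifest.outputs = {
            "stack": str(out / "stack.tif"),
            "events": str(out / "events.csv"),
            "traces": str(out / "traces.csv"),
            "lag": str(out / "lag.json"),
            "scores": str(out / "scores.json"),
        }
        for s in ("simulate", "quantify", "lag", "score", "write"):
            manifest.stages[s] = "ok"
    except Exception as exc:
        manifest.stages[stage] = f"failed: {exc}"
        manifest.finished = datetime.now(timezone.utc).isoformat()
        (out / "manifest.json").write_text(manifest.to_json())
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc

    manifest.finished = datetime.now(timezone.utc).isoformat()
    (out / "manifest.json").write_text(manifest.to_json())
    log.info("run complete: %s", out)
    return manifest
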