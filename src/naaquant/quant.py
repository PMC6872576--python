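"""Quantification of nuclear actin assembly (NAA) from two-channel time-lapses.

Nuclear F-actin formation is read out through the *spatial intensity
variance* of an F-actin probe (e.g. a nuclear actin chromobody) inside a
nuclear region of interest.  While the probe is unpolymerized it is
distributed homogeneously and the pixel-intensity variance is set by shot
noise alone; as filaments assemble, probe signal concentrates on bright
linear structures and the variance rises, peaking with filament mass and
relaxing back when the filaments depolymerize.  Calcium-sensor activity is
read out as a plain ROI mean.  Heterogeneity traces are min-max normalized
("normalized by the changing range") before onset analysis, and cells are
called NAA-positive when the post-stimulus variance peak exceeds a
baseline-derived threshold.

The module operates on any object exposing the :class:`~naaquant.simkit.TimeLapse`
interface (``frame_times_s``, ``channels``), simulated or imported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Iterable, Optional, Union

import numpy as np

from .exceptions import InputError

if TYPE_CHECKING:  # pragma: no cover - typing only
    from .simkit import TimeLapse

__all__ = [
    "Trace",
    "NormalizedTrace",
    "RoiMask",
    "CellScore",
    "spatial_heterogeneity",
    "heterogeneity_trace",
    "roi_mean_trace",
    "normalize_by_range",
    "score_cell",
    "percent_positive",
]


@dataclass
class Trace:
    """A time-indexed scalar series (heterogeneity or calcium intensity)."""

    times_s: np.ndarray
    values: np.ndarray
    kind: str = "heterogeneity"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times_s.ndim != 1 or self.values.ndim != 1:
            raise InputError("trace times and values must be 1-D")
        if self.times_s.size != self.values.size:
            raise InputError("trace times and values must have equal length")
        if self.times_s.size == 0:
            raise InputError("trace must contain at least one sample")
        if self.times_s.size > 1 and np.any(np.diff(self.times_s) <= 0):
            raise InputError("trace times must be strictly increasing")

    def __len__(self) -> int:
        return int(self.times_s.size)


@dataclass
class NormalizedTrace(Trace):
    """A trace min-max scaled to [0, 1].

    ``degenerate`` is set when the raw trace had zero range, in which case
    the values are all zeros (flat non-responder traces are expected inputs,
    not errors).
    """

    degenerate: bool = False


@dataclass
class RoiMask:
    """Binary region-of-interest mask (nucleus or cytoplasm)."""

    mask: np.ndarray
    label: str = "nucleus"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise InputError("ROI mask must be 2-D")
        if not self.mask.any():
            raise InputError("ROI mask must contain at least one true pixel")

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


MaskLike = Union[RoiMask, np.ndarray]


def _mask_array(mask: MaskLike, expected_shape=None) -> np.ndarray:
    m = mask.mask if isinstance(mask, RoiMask) else np.asarray(mask, dtype=bool)
    if not m.any():
        raise InputError("ROI mask is empty")
    if expected_shape is not None and m.shape != tuple(expected_shape):
        raise InputError(
            f"mask shape {m.shape} does not match frame shape {tuple(expected_shape)}"
        )
    return m


def _channel_frames(stack: "TimeLapse", channel: str) -> np.ndarray:
    try:
        return stack.channels[channel]
    except KeyError:
        raise InputError(
            f"channel {channel!r} not present; stack has {sorted(stack.channels)}"
        ) from None


def spatial_heterogeneity(image: np.ndarray, mask: MaskLike) -> float:
    """Spatial intensity variance of ``image`` over the ROI.

    Population variance (divide by N): this is a descriptive statistic of
    the full set of ROI pixels, not an estimate from a sample of them.
    """
    image = np.asarray(image, dtype=float)
    m = _mask_array(mask, image.shape)
    return float(np.var(image[m]))


def heterogeneity_trace(
    stack: "TimeLapse", mask: MaskLike, channel: str = "actin_probe"
) -> Trace:
    """Per-frame spatial intensity variance of the actin-probe channel."""
    frames = _channel_frames(stack, channel)
    m = _mask_array(mask, frames.shape[1:])
    values = frames[:, m].var(axis=1)
    return Trace(stack.frame_times_s, values, kind="heterogeneity")


def roi_mean_trace(
    stack: "TimeLapse", mask: MaskLike, channel: str = "calcium"
) -> Trace:
    """Per-frame mean intensity over the ROI (calcium readout)."""
    frames = _channel_frames(stack, channel)
    m = _mask_array(mask, frames.shape[1:])
    values = frames[:, m].mean(axis=1)
    return Trace(stack.frame_times_s, values, kind="calcium")


def normalize_by_range(trace: Trace) -> NormalizedTrace:
    """Min-max normalize a trace by its changing range.

    Non-degenerate output spans exactly [0, 1].  A zero-range trace maps to
    all zeros with ``degenerate=True``.
    """
    v = trace.values
    vmin = float(v.min())
    vmax = float(v.max())
    if vmax == vmin:
        return NormalizedTrace(
            trace.times_s, np.zeros_like(v), kind=trace.kind, degenerate=True
        )
    return NormalizedTrace(
        trace.times_s, (v - vmin) / (vmax - vmin), kind=trace.kind, degenerate=False
    )


@dataclass
class CellScore:
    """Per-cell NAA-positive call with the quantities behind it."""

    cell_id: Optional[object]
    positive: bool
    peak_raw_heterogeneity: float
    baseline_mean: float
    baseline_sd: float

    def __post_init__(self) -> None:
        if self.baseline_sd < 0:
            raise InputError("baseline_sd must be non-negative")


def score_cell(
    raw_trace: Trace,
    stimulus_time_s: float,
    k: float = 5.0,
    cell_id: Optional[object] = None,
) -> CellScore:
    """Call a cell NAA-positive from its raw heterogeneity trace.

    The baseline is every frame strictly before the stimulus; the cell is
    positive when the post-stimulus peak exceeds ``baseline_mean + k *
    baseline_sd``.  The rule is scale-covariant: rescaling the trace rescales
    peak, mean and sd together, leaving the decision unchanged.
    """
    t = raw_trace.times_s
    v = raw_trace.values
    pre = v[t < stimulus_time_s]
    if pre.size < 3:
        raise InputError(
            f"need >= 3 pre-stimulus frames to estimate a baseline, got {pre.size}"
        )
    post = v[t >= stimulus_time_s]
    if post.size == 0:
        raise InputError("trace has no post-stimulus frames")
    baseline_mean = float(pre.mean())
    baseline_sd = float(pre.std(ddof=1))
    peak = float(post.max())
    positive = peak > baseline_mean + k * baseline_sd
    return CellScore(cell_id, bool(positive), peak, baseline_mean, baseline_sd)


def percent_positive(scores: Iterable[CellScore]) -> float:
    """Percentage of NAA-positive cells among all scored cells."""
    scores = list(scores)
    if not scores:
        raise InputError("cannot compute a percentage from zero scores")
    return 100.0 * sum(1 for s in scores if s.positive) / len(scores)
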