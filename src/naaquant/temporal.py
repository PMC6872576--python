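"""Temporal ordering of calcium elevation and nuclear actin assembly.

The biological claim under test is one of order: calcium rises first, the
nuclear F-actin heterogeneity signal follows.  Onsets are defined as the
first *sustained* crossing of a threshold on the range-normalized trace
(default half-maximum held for two frames), with the crossing time linearly
interpolated between the bracketing frames.  The lag is then

    lag = onset(NAA heterogeneity) - onset(nuclear calcium)

so a positive lag means NAA follows the calcium transient.  The module also
provides the simulation-validation step: a rank correlation between
ground-truth filament mass and the heterogeneity trace, establishing the
spatial variance as a proxy for the amount of nuclear F-actin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Union

import numpy as np
from scipy.stats import spearmanr

from .exceptions import InputError
from .quant import NormalizedTrace, Trace, normalize_by_range

__all__ = [
    "OnsetResult",
    "LagResult",
    "ProxyValidation",
    "detect_onset",
    "estimate_lag",
    "validate_heterogeneity_proxy",
]


@dataclass
class OnsetResult:
    """Time of the first sustained threshold crossing, if any."""

    onset_time_s: Optional[float]
    threshold: float
    interpolated: bool = False

    @property
    def detected(self) -> bool:
        return self.onset_time_s is not None


@dataclass
class LagResult:
    """NAA onset relative to the calcium onset(s)."""

    lag_s: Optional[float]
    naa_onset_s: Optional[float]
    calcium_onsets: Dict[str, Optional[float]] = field(default_factory=dict)
    reason: Optional[str] = None


@dataclass
class ProxyValidation:
    """Spearman rank correlation between filament mass and heterogeneity."""

    spearman_rho: float
    n_frames: int
    undefined: bool = False


def _as_normalized(trace: Trace) -> NormalizedTrace:
    if isinstance(trace, NormalizedTrace):
        return trace
    return normalize_by_range(trace)


def detect_onset(
    trace: Trace, threshold: float = 0.5, sustain_frames: int = 2
) -> OnsetResult:
    """First time the normalized trace crosses ``threshold`` and stays above
    it for ``sustain_frames`` consecutive frames.

    The crossing time is linearly interpolated between the last sub-threshold
    frame and the first frame of the sustained excursion.  A degenerate
    (zero-range) trace yields an absent onset, not an error.  A raw
    :class:`~naaquant.quant.Trace` is normalized internally.
    """
    if sustain_frames < 1:
        raise InputError("sustain_frames must be at least 1")
    nt = _as_normalized(trace)
    if nt.degenerate:
        return OnsetResult(None, threshold)
    v = nt.values
    t = nt.times_s
    n = v.size
    above = v >= threshold
    idx = None
    for i in range(0, n - sustain_frames + 1):
        if above[i : i + sustain_frames].all():
            idx = i
            break
    if idx is None:
        return OnsetResult(None, threshold)
    if idx == 0:
        return OnsetResult(float(t[0]), threshold, interpolated=False)
    v0, v1 = v[idx - 1], v[idx]
    if v0 >= threshold or v1 == v0:
        # previous frame already at/above threshold (sustain failed there):
        # no well-defined crossing segment, report the frame time itself
        return OnsetResult(float(t[idx]), threshold, interpolated=False)
    frac = (threshold - v0) / (v1 - v0)
    onset = float(t[idx - 1] + frac * (t[idx] - t[idx - 1]))
    return OnsetResult(onset, threshold, interpolated=True)


def estimate_lag(
    calcium_trace: Trace,
    naa_trace: Trace,
    threshold: float = 0.5,
    cytoplasm_trace: Optional[Trace] = None,
    sustain_frames: int = 2,
) -> LagResult:
    """Lag between NAA onset and nuclear calcium onset on a shared time base.

    ``calcium_trace`` is the nuclear-compartment calcium trace (NAA is a
    nuclear event); a cytoplasmic trace may be supplied and its onset is
    reported alongside.  Positive lag means NAA follows calcium.
    """
    if not np.array_equal(calcium_trace.times_s, naa_trace.times_s):
        raise InputError("calcium and NAA traces must share the same time base")
    ca = detect_onset(calcium_trace, threshold, sustain_frames)
    naa = detect_onset(naa_trace, threshold, sustain_frames)
    onsets: Dict[str, Optional[float]] = {"nucleus": ca.onset_time_s}
    if cytoplasm_trace is not None:
        onsets["cytoplasm"] = detect_onset(
            cytoplasm_trace, threshold, sustain_frames
        ).onset_time_s
    if ca.onset_time_s is None or naa.onset_time_s is None:
        missing = []
        if ca.onset_time_s is None:
            missing.append("calcium")
        if naa.onset_time_s is None:
            missing.append("NAA")
        return LagResult(
            None, naa.onset_time_s, onsets, reason=f"no onset in: {', '.join(missing)}"
        )
    return LagResult(naa.onset_time_s - ca.onset_time_s, naa.onset_time_s, onsets)


def validate_heterogeneity_proxy(
    ground_truth_history, heterogeneity_trace
) -> ProxyValidation:
    """Spearman correlation of ground-truth filament mass per frame against
    the heterogeneity trace.

    Accepts a :class:`~naaquant.simkit.GroundTruth` (its ``total_length_um``)
    or a plain per-frame array, and a :class:`~naaquant.quant.Trace` or
    array.  If either series is constant the correlation is undefined and
    flagged rather than raised.
    """
    mass = np.asarray(
        getattr(ground_truth_history, "total_length_um", ground_truth_history),
        dtype=float,
    )
    het = np.asarray(
        getattr(heterogeneity_trace, "values", heterogeneity_trace), dtype=float
    )
    if mass.ndim != 1 or het.ndim != 1 or mass.size != het.size:
        raise InputError("filament mass and heterogeneity series must match in length")
    if mass.size < 2:
        raise InputError("need at least two frames")
    if np.ptp(mass) == 0 or np.ptp(het) == 0:
        return ProxyValidation(float("nan"), int(mass.size), undefined=True)
    rho = spearmanr(mass, het).statistic
    return ProxyValidation(float(rho), int(mass.size), undefined=False)
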