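"""Stochastic simulator of calcium-triggered nuclear actin assembly (NAA).

Generates synthetic two-channel nuclear time-lapse stacks: an F-actin probe
channel in which filaments nucleate stochastically and elongate inside a
circular nucleus, and a calcium-sensor channel following a phenomenological
transient.  The model:

* The nucleus is a 2-D disc (default diameter 10 um).
* Filament nucleation is a homogeneous Poisson process (default mean
  inter-arrival 20 s) that switches on a fixed latency after the stimulus
  (default 16 s, matching the observed delay between ionophore addition and
  the first polymerization).
* Filaments elongate at a constant rate (default 1.5 um/s), clamp at the
  nuclear boundary, and vanish after an exponentially distributed lifetime
  (default mean 50 s).
* Rendering is additive: a homogeneous background inside the nucleus plus a
  Gaussian-blurred line contribution per filament, with per-pixel Poisson
  shot noise.

Every simulation draws from a single seeded generator, so identical configs
and seeds give bit-identical stacks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .exceptions import ParameterError
from .quant import Trace

__all__ = [
    "NucleusGeometry",
    "KineticsConfig",
    "ImagingConfig",
    "CalciumModel",
    "Filament",
    "FilamentRecord",
    "TimeLapse",
    "GroundTruth",
    "PopulationResult",
    "sample_nucleation_times",
    "sample_filaments",
    "filament_state",
    "advance_filament",
    "render_frame",
    "simulate_calcium_trace",
    "simulate_timelapse",
    "simulate_population",
    "iter_population",
]

Vec2 = Tuple[float, float]

ORIGIN_MODES = ("uniform_interior", "inm_anchored")
NOISE_MODES = ("poisson", "none")


@dataclass(frozen=True)
class NucleusGeometry:
    """A circular nucleus embedded in a pixel grid.

    Physical coordinates are micrometres with the origin at the centre of
    the top-left pixel; pixel (row, col) has its centre at
    ``(x, y) = (col, row) * pixel_size_um``.  Mask membership is
    centre-in-disc.
    """

    center_um: Vec2 = (6.0, 6.0)
    diameter_um: float = 10.0
    pixel_size_um: float = 0.1
    image_shape: Tuple[int, int] = (120, 120)

    def __post_init__(self) -> None:
        if self.diameter_um <= 0:
            raise ParameterError("diameter_um must be positive")
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be positive")
        nrow, ncol = self.image_shape
        if nrow < 1 or ncol < 1:
            raise ParameterError("image_shape must be at least 1x1")
        cx, cy = self.center_um
        r = self.radius_um
        px = self.pixel_size_um
        if (
            cx - r < -0.5 * px
            or cy - r < -0.5 * px
            or cx + r > (ncol - 0.5) * px
            or cy + r > (nrow - 0.5) * px
        ):
            raise ParameterError("nucleus disc must lie fully inside the image")

    @property
    def radius_um(self) -> float:
        return 0.5 * self.diameter_um

    def pixel_centers_um(self) -> Tuple[np.ndarray, np.ndarray]:
        """(X, Y) coordinate arrays of pixel centres in micrometres."""
        nrow, ncol = self.image_shape
        x = np.arange(ncol) * self.pixel_size_um
        y = np.arange(nrow) * self.pixel_size_um
        return np.meshgrid(x, y)

    def nucleus_mask(self) -> np.ndarray:
        X, Y = self.pixel_centers_um()
        cx, cy = self.center_um
        return (X - cx) ** 2 + (Y - cy) ** 2 <= self.radius_um**2

    def cytoplasm_mask(self, margin_um: float = 0.3) -> np.ndarray:
        """Pixels at least ``margin_um`` outside the nuclear boundary."""
        X, Y = self.pixel_centers_um()
        cx, cy = self.center_um
        return (X - cx) ** 2 + (Y - cy) ** 2 > (self.radius_um + margin_um) ** 2

    def contains(self, point_um: Sequence[float], tol: float = 1e-9) -> bool:
        dx = point_um[0] - self.center_um[0]
        dy = point_um[1] - self.center_um[1]
        return dx * dx + dy * dy <= (self.radius_um + tol) ** 2

    def ray_exit_length(self, origin_um: Sequence[float], direction: Sequence[float]) -> float:
        """Distance from ``origin_um`` (inside the disc) along ``direction``
        (unit vector) to the nuclear boundary."""
        ox = origin_um[0] - self.center_um[0]
        oy = origin_um[1] - self.center_um[1]
        dx, dy = direction
        b = ox * dx + oy * dy
        c = ox * ox + oy * oy - self.radius_um**2
        disc = b * b - c
        if disc < 0:  # origin numerically outside; treat as on the boundary
            return 0.0
        return max(-b + math.sqrt(disc), 0.0)


@dataclass(frozen=True)
class KineticsConfig:
    """Filament nucleation/elongation/persistence parameters.

    ``nucleation_mean_interval_s`` may be ``inf`` to disable nucleation
    entirely (a non-responding cell).
    """

    growth_rate_um_s: float = 1.5
    nucleation_mean_interval_s: float = 20.0
    onset_latency_s: float = 16.0
    persistence_s: float = 50.0
    origin_mode: str = "uniform_interior"

    def __post_init__(self) -> None:
        if self.growth_rate_um_s <= 0:
            raise ParameterError("growth_rate_um_s must be positive")
        if not self.nucleation_mean_interval_s > 0:
            raise ParameterError("nucleation_mean_interval_s must be positive")
        if self.onset_latency_s < 0:
            raise ParameterError("onset_latency_s must be non-negative")
        if self.persistence_s <= 0:
            raise ParameterError("persistence_s must be positive")
        if self.origin_mode not in ORIGIN_MODES:
            raise ParameterError(f"origin_mode must be one of {ORIGIN_MODES}")


@dataclass(frozen=True)
class ImagingConfig:
    """Acquisition and rendering parameters for the synthetic microscope.

    Intensities are expected photon counts per pixel; with ``noise='poisson'``
    each pixel is an independent Poisson draw of its expectation (shot-noise
    limited detection).  ``conserve_total`` redistributes filament photons out
    of the diffuse background instead of adding them on top.
    """

    frame_interval_s: float = 3.0
    duration_s: float = 240.0
    stimulus_time_s: float = 60.0
    background_mean_photons: float = 100.0
    filament_gain_photons_per_um: float = 2000.0
    psf_sigma_um: float = 0.2
    noise: str = "poisson"
    conserve_total: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ParameterError("frame_interval_s must be positive")
        if self.duration_s <= self.frame_interval_s:
            raise ParameterError("duration_s must exceed frame_interval_s")
        if self.background_mean_photons < 0:
            raise ParameterError("background_mean_photons must be non-negative")
        if self.filament_gain_photons_per_um < 0:
            raise ParameterError("filament_gain_photons_per_um must be non-negative")
        if self.psf_sigma_um < 0:
            raise ParameterError("psf_sigma_um must be non-negative")
        if self.noise not in NOISE_MODES:
            raise ParameterError(f"noise must be one of {NOISE_MODES}")


@dataclass(frozen=True)
class CalciumModel:
    """Phenomenological calcium transient: difference of exponentials,
    scaled so its peak equals ``amplitude`` above baseline.  The nuclear
    compartment lags the cytoplasmic one by ``nuclear_delay_s``."""

    baseline: float = 50.0
    amplitude: float = 150.0
    rise_tau_s: float = 2.0
    decay_tau_s: float = 15.0
    nuclear_delay_s: float = 1.0

    def __post_init__(self) -> None:
        if self.baseline < 0:
            raise ParameterError("baseline must be non-negative")
        if self.amplitude < 0:
            raise ParameterError("amplitude must be non-negative")
        if self.rise_tau_s <= 0 or self.decay_tau_s <= 0:
            raise ParameterError("time constants must be positive")
        if self.rise_tau_s >= self.decay_tau_s:
            raise ParameterError(
                "rise_tau_s must be smaller than decay_tau_s (degenerate shape)"
            )
        if self.nuclear_delay_s < 0:
            raise ParameterError("nuclear_delay_s must be non-negative")


@dataclass(frozen=True)
class Filament:
    """A growing line segment inside the nucleus disc."""

    birth_time_s: float
    origin_um: Vec2
    direction: Vec2  # unit vector
    lifetime_s: float
    length_um: float = 0.0
    age_s: float = 0.0
    alive: bool = True

    def __post_init__(self) -> None:
        if self.length_um < 0:
            raise ParameterError("length_um must be non-negative")
        if self.lifetime_s <= 0:
            raise ParameterError("lifetime_s must be positive")
        norm = math.hypot(*self.direction)
        if not math.isclose(norm, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ParameterError("direction must be a unit vector")

    @property
    def tip_um(self) -> Vec2:
        ox, oy = self.origin_um
        dx, dy = self.direction
        return (ox + dx * self.length_um, oy + dy * self.length_um)


@dataclass(frozen=True)
class FilamentRecord:
    """Ground-truth record of one nucleation event."""

    birth_time_s: float
    origin_um: Vec2
    direction: Vec2
    lifetime_s: float


@dataclass
class TimeLapse:
    """Multi-channel frame stack with shared acquisition times."""

    frame_times_s: np.ndarray
    channels: dict
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
        if self.frame_times_s.ndim != 1 or self.frame_times_s.size == 0:
            raise ParameterError("frame_times_s must be a non-empty 1-D sequence")
        if self.frame_times_s.size > 1 and np.any(np.diff(self.frame_times_s) <= 0):
            raise ParameterError("frame_times_s must be strictly increasing")
        shapes = set()
        for name, frames in self.channels.items():
            frames = np.asarray(frames, dtype=float)
            if frames.ndim != 3 or frames.shape[0] != self.frame_times_s.size:
                raise ParameterError(
                    f"channel {name!r} must be (n_frames, H, W) matching frame times"
                )
            if np.any(frames < 0):
                raise ParameterError(f"channel {name!r} has negative intensities")
            self.channels[name] = frames
            shapes.add(frames.shape[1:])
        if len(shapes) > 1:
            raise ParameterError("all channels must share the same frame shape")

    @property
    def n_frames(self) -> int:
        return int(self.frame_times_s.size)

    def frame(self, channel: str, index: int) -> np.ndarray:
        return self.channels[channel][index]


@dataclass
class GroundTruth:
    """Everything the simulator knows that a microscope would not report."""

    records: List[FilamentRecord]
    nucleation_times_s: np.ndarray
    total_length_um: np.ndarray  # per frame
    calcium_nuclear: Trace  # noise-free model evaluation
    calcium_cytoplasmic: Trace
    responder: bool = True


# ---------------------------------------------------------------------------
# Stochastic kinetics


def sample_nucleation_times(
    duration_s: float,
    kinetics: KineticsConfig,
    stimulus_time_s: float = 0.0,
    seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Event times of the filament-nucleation Poisson process.

    The process is homogeneous with the configured mean inter-arrival time
    and starts at ``stimulus_time_s + onset_latency_s``; events are returned
    up to absolute time ``duration_s``.
    """
    if duration_s <= 0:
        raise ParameterError("duration_s must be positive")
    tau = kinetics.nucleation_mean_interval_s
    if rng is None:
        rng = np.random.default_rng(seed)
    start = stimulus_time_s + kinetics.onset_latency_s
    if not np.isfinite(tau) or start >= duration_s:
        return np.empty(0, dtype=float)
    chunks = []
    t = start
    while True:
        n = max(16, int((duration_s - t) / tau * 1.5) + 16)
        arrivals = t + np.cumsum(rng.exponential(tau, size=n))
        chunks.append(arrivals[arrivals <= duration_s])
        if arrivals[-1] > duration_s:
            break
        t = arrivals[-1]
    return np.concatenate(chunks)


def _sample_origin_direction(
    kinetics: KineticsConfig, geometry: NucleusGeometry, rng: np.random.Generator
) -> Tuple[Vec2, Vec2]:
    cx, cy = geometry.center_um
    r = geometry.radius_um
    if kinetics.origin_mode == "uniform_interior":
        rad = r * math.sqrt(rng.random())
        ang = rng.uniform(0.0, 2.0 * math.pi)
        origin = (cx + rad * math.cos(ang), cy + rad * math.sin(ang))
        phi = rng.uniform(0.0, 2.0 * math.pi)
    else:  # inm_anchored: origin on the boundary, direction into the disc
        ang = rng.uniform(0.0, 2.0 * math.pi)
        origin = (cx + r * math.cos(ang), cy + r * math.sin(ang))
        phi = ang + math.pi + rng.uniform(-0.5 * math.pi, 0.5 * math.pi)
    return origin, (math.cos(phi), math.sin(phi))


def sample_filaments(
    duration_s: float,
    kinetics: KineticsConfig,
    geometry: NucleusGeometry,
    stimulus_time_s: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> List[FilamentRecord]:
    """Draw a full filament history: nucleation times, origins, directions
    and exponential lifetimes (mean ``persistence_s``)."""
    if rng is None:
        rng = np.random.default_rng(seed)
    events = sample_nucleation_times(duration_s, kinetics, stimulus_time_s, rng=rng)
    records = []
    for t in events:
        origin, direction = _sample_origin_direction(kinetics, geometry, rng)
        lifetime = float(rng.exponential(kinetics.persistence_s))
        records.append(FilamentRecord(float(t), origin, direction, max(lifetime, 1e-9)))
    return records


def filament_state(
    record: FilamentRecord,
    time_s: float,
    kinetics: KineticsConfig,
    geometry: NucleusGeometry,
) -> Optional[Filament]:
    """Analytic state of a recorded filament at ``time_s``.

    Returns ``None`` before birth or after end-of-life (disappearance is
    instantaneous).  Equivalent to repeated :func:`advance_filament` steps.
    """
    age = time_s - record.birth_time_s
    if age < 0 or age > record.lifetime_s:
        return None
    clamp = geometry.ray_exit_length(record.origin_um, record.direction)
    length = min(kinetics.growth_rate_um_s * age, clamp)
    return Filament(
        birth_time_s=record.birth_time_s,
        origin_um=record.origin_um,
        direction=record.direction,
        lifetime_s=record.lifetime_s,
        length_um=length,
        age_s=age,
        alive=True,
    )


def advance_filament(
    filament: Filament,
    dt_s: float,
    kinetics: KineticsConfig,
    geometry: NucleusGeometry,
) -> Filament:
    """Advance a living filament by ``dt_s``: elongate at the configured
    rate, clamp the tip at the nuclear boundary, and mark the filament dead
    once its age exceeds its lifetime."""
    if dt_s < 0:
        raise ParameterError("dt_s must be non-negative")
    if not filament.alive:
        raise ParameterError("cannot advance a dead filament")
    if dt_s == 0:
        return filament
    clamp = geometry.ray_exit_length(filament.origin_um, filament.direction)
    new_length = min(filament.length_um + kinetics.growth_rate_um_s * dt_s, clamp)
    new_age = filament.age_s + dt_s
    return replace(
        filament,
        length_um=new_length,
        age_s=new_age,
        alive=new_age <= filament.lifetime_s,
    )


# ---------------------------------------------------------------------------
# Rendering


def _splat_segment(
    image: np.ndarray,
    filament: Filament,
    geometry: NucleusGeometry,
    gain_photons_per_um: float,
) -> None:
    """Deposit ``gain * length`` photons along the filament segment with
    bilinear sub-pixel weighting (in place)."""
    length = filament.length_um
    if length <= 0 or gain_photons_per_um <= 0:
        return
    px = geometry.pixel_size_um
    n = max(2, int(math.ceil(length / (0.25 * px))) + 1)
    s = np.linspace(0.0, length, n)
    ox, oy = filament.origin_um
    dx, dy = filament.direction
    x = (ox + dx * s) / px  # fractional column
    y = (oy + dy * s) / px  # fractional row
    w = np.full(n, gain_photons_per_um * length / n)
    c0 = np.floor(x).astype(int)
    r0 = np.floor(y).astype(int)
    fx = x - c0
    fy = y - r0
    nrow, ncol = image.shape
    for dr, dc, wt in (
        (0, 0, (1 - fy) * (1 - fx)),
        (0, 1, (1 - fy) * fx),
        (1, 0, fy * (1 - fx)),
        (1, 1, fy * fx),
    ):
        rr = r0 + dr
        cc = c0 + dc
        ok = (rr >= 0) & (rr < nrow) & (cc >= 0) & (cc < ncol)
        np.add.at(image, (rr[ok], cc[ok]), w[ok] * wt[ok])


def render_frame(
    filaments: Sequence[Filament],
    geometry: NucleusGeometry,
    imaging: ImagingConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Render one actin-probe frame.

    Expected intensity is the homogeneous background inside the nucleus
    (zero outside) plus each living filament's line contribution convolved
    with an isotropic Gaussian PSF; with ``noise='poisson'`` every pixel is
    an independent Poisson draw of its expectation.
    """
    mask = geometry.nucleus_mask()
    expectation = np.where(mask, imaging.background_mean_photons, 0.0)
    line = np.zeros(geometry.image_shape, dtype=float)
    total_photons = 0.0
    for fil in filaments:
        if fil is None or not fil.alive:
            continue
        _splat_segment(line, fil, geometry, imaging.filament_gain_photons_per_um)
        total_photons += imaging.filament_gain_photons_per_um * fil.length_um
    if imaging.psf_sigma_um > 0 and total_photons > 0:
        line = gaussian_filter(line, imaging.psf_sigma_um / geometry.pixel_size_um)
    if imaging.conserve_total and total_photons > 0:
        expectation = np.maximum(
            expectation - mask * (total_photons / mask.sum()), 0.0
        )
    expectation = expectation + line
    if imaging.noise == "poisson":
        if rng is None:
            rng = np.random.default_rng(imaging.seed)
        return rng.poisson(expectation).astype(float)
    return expectation


# ---------------------------------------------------------------------------
# Calcium


def simulate_calcium_trace(
    model: CalciumModel,
    frame_times: Sequence[float],
    stimulus_time_s: float,
    compartment: str = "nucleus",
) -> Trace:
    """Noise-free calcium-sensor trace for one compartment.

    Baseline before the stimulus; afterwards a difference-of-exponentials
    transient ``A * (exp(-t/tau_decay) - exp(-t/tau_rise))`` scaled so its
    peak equals ``amplitude``; the nuclear compartment is delayed by
    ``nuclear_delay_s``.  Returns to baseline asymptotically.
    """
    if compartment not in ("nucleus", "cytoplasm"):
        raise ParameterError("compartment must be 'nucleus' or 'cytoplasm'")
    t = np.asarray(frame_times, dtype=float)
    delay = model.nuclear_delay_s if compartment == "nucleus" else 0.0
    s = t - stimulus_time_s - delay
    tr, td = model.rise_tau_s, model.decay_tau_s
    peak_s = tr * td / (td - tr) * math.log(td / tr)
    peak = math.exp(-peak_s / td) - math.exp(-peak_s / tr)
    shape = np.zeros_like(s)
    m = s >= 0
    shape[m] = (np.exp(-s[m] / td) - np.exp(-s[m] / tr)) / peak
    return Trace(t, model.baseline + model.amplitude * shape, kind="calcium")


# ---------------------------------------------------------------------------
# Full simulations


def simulate_timelapse(
    geometry: NucleusGeometry = NucleusGeometry(),
    kinetics: KineticsConfig = KineticsConfig(),
    imaging: ImagingConfig = ImagingConfig(),
    calcium_model: CalciumModel = CalciumModel(),
) -> Tuple[TimeLapse, GroundTruth]:
    """Simulate one cell: a two-channel stack plus its ground truth.

    Frame count is ``floor(duration / interval) + 1`` (a frame at t=0).  The
    calcium channel renders the nuclear trace inside the disc and the
    cytoplasmic trace outside, so both compartment ROIs can be read from the
    same image.
    """
    rng = np.random.default_rng(imaging.seed)
    n_frames = int(math.floor(imaging.duration_s / imaging.frame_interval_s + 1e-9)) + 1
    times = np.arange(n_frames) * imaging.frame_interval_s

    records = sample_filaments(
        imaging.duration_s, kinetics, geometry, imaging.stimulus_time_s, rng=rng
    )
    ca_nuc = simulate_calcium_trace(calcium_model, times, imaging.stimulus_time_s, "nucleus")
    ca_cyt = simulate_calcium_trace(
        calcium_model, times, imaging.stimulus_time_s, "cytoplasm"
    )

    mask = geometry.nucleus_mask()
    actin = np.empty((n_frames,) + tuple(geometry.image_shape), dtype=float)
    calcium = np.empty_like(actin)
    total_length = np.zeros(n_frames)
    for i, t in enumerate(times):
        fils = [filament_state(r, t, kinetics, geometry) for r in records]
        fils = [f for f in fils if f is not None]
        total_length[i] = sum(f.length_um for f in fils)
        actin[i] = render_frame(fils, geometry, imaging, rng=rng)
        ca_expect = np.where(mask, ca_nuc.values[i], ca_cyt.values[i])
        if imaging.noise == "poisson":
            calcium[i] = rng.poisson(ca_expect).astype(float)
        else:
            calcium[i] = ca_expect

    stack = TimeLapse(
        frame_times_s=times,
        channels={"actin_probe": actin, "calcium": calcium},
        pixel_size_um=geometry.pixel_size_um,
    )
    truth = GroundTruth(
        records=records,
        nucleation_times_s=np.array([r.birth_time_s for r in records]),
        total_length_um=total_length,
        calcium_nuclear=ca_nuc,
        calcium_cytoplasmic=ca_cyt,
    )
    return stack, truth


@dataclass
class PopulationResult:
    """Simulated field of view: one stack + ground truth per cell."""

    stacks: List[TimeLapse]
    truths: List[GroundTruth]
    responders: np.ndarray  # bool per cell


def iter_population(
    n_cells: int,
    responder_fraction: float,
    geometry: NucleusGeometry = NucleusGeometry(),
    kinetics: KineticsConfig = KineticsConfig(),
    imaging: ImagingConfig = ImagingConfig(),
    calcium_model: CalciumModel = CalciumModel(),
    seed: int = 0,
) -> Iterator[Tuple[int, TimeLapse, GroundTruth]]:
    """Lazily simulate a population (memory-friendly for large fields).

    Responders use the given kinetics; non-responders have nucleation
    disabled.  Each cell gets an independent sub-seed derived from ``seed``.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be at least 1")
    if not 0.0 <= responder_fraction <= 1.0:
        raise ParameterError("responder_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    flags = rng.random(n_cells) < responder_fraction
    seeds = rng.integers(0, 2**31 - 1, size=n_cells)
    silent = replace(kinetics, nucleation_mean_interval_s=math.inf)
    for i in range(n_cells):
        cell_imaging = replace(imaging, seed=int(seeds[i]))
        cell_kinetics = kinetics if flags[i] else silent
        stack, truth = simulate_timelapse(geometry, cell_kinetics, cell_imaging, calcium_model)
        truth.responder = bool(flags[i])
        yield i, stack, truth


def simulate_population(
    n_cells: int,
    responder_fraction: float,
    geometry: NucleusGeometry = NucleusGeometry(),
    kinetics: KineticsConfig = KineticsConfig(),
    imaging: ImagingConfig = ImagingConfig(),
    calcium_model: CalciumModel = CalciumModel(),
    seed: int = 0,
) -> PopulationResult:
    """Materialized version of :func:`iter_population` (small populations)."""
    stacks: List[TimeLapse] = []
    truths: List[GroundTruth] = []
    for _, stack, truth in iter_population(
        n_cells, responder_fraction, geometry, kinetics, imaging, calcium_model, seed
    ):
        stacks.append(stack)
        truths.append(truth)
    return PopulationResult(
        stacks=stacks,
        truths=truths,
        responders=np.array([t.responder for t in truths], dtype=bool),
    )
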