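"""Unit and property tests for the NAA time-lapse simulator."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from naaquant.exceptions import ParameterError
from naaquant.simkit import (
    CalciumModel,
    Filament,
    ImagingConfig,
    KineticsConfig,
    NucleusGeometry,
    advance_filament,
    filament_state,
    iter_population,
    render_frame,
    sample_filaments,
    sample_nucleation_times,
    simulate_calcium_trace,
    simulate_population,
    simulate_timelapse,
)

NO_LATENCY = KineticsConfig(onset_latency_s=0.0)


# ---------------------------------------------------------------------------
# Nucleation process


class TestNucleation:
    def test_expected_event_count_matches_poisson_rate(self):
        # window T with mean inter-arrival tau -> E[count] = T / tau
        counts = [
            sample_nucleation_times(200.0, NO_LATENCY, 0.0, seed=s).size
            for s in range(3000)
        ]
        assert abs(np.mean(counts) - 10.0) < 0.25  # 4 sigma ~ 0.23

    def test_same_seed_reproduces_event_sequence(self, kinetics):
        a = sample_nucleation_times(500.0, kinetics, 0.0, seed=42)
        b = sample_nucleation_times(500.0, kinetics, 0.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_interarrival_mle_recovers_mean(self, kinetics):
        times = sample_nucleation_times(2.5e5, kinetics, 0.0, seed=1)
        gaps = np.diff(times)
        assert gaps.size >= 10_000
        assert abs(gaps.mean() - 20.0) / 20.0 < 0.02

    def test_interarrivals_pass_ks_against_exponential(self, kinetics):
        times = sample_nucleation_times(2.5e5, kinetics, 0.0, seed=2)
        gaps = np.diff(times)[:10_000]
        res = stats.kstest(gaps, "expon", args=(0.0, 20.0))
        assert res.pvalue > 0.01

    def test_events_start_after_stimulus_plus_latency(self, kinetics):
        times = sample_nucleation_times(400.0, kinetics, stimulus_time_s=30.0, seed=3)
        assert times.min() >= 30.0 + 16.0

    def test_infinite_mean_interval_yields_no_events(self):
        kin = KineticsConfig(nucleation_mean_interval_s=math.inf)
        assert sample_nucleation_times(500.0, kin, 0.0, seed=0).size == 0

    def test_nonpositive_mean_interval_rejected(self):
        with pytest.raises(ParameterError):
            KineticsConfig(nucleation_mean_interval_s=0.0)

    def test_nonpositive_duration_rejected(self, kinetics):
        with pytest.raises(ParameterError):
            sample_nucleation_times(0.0, kinetics, 0.0, seed=0)


# ---------------------------------------------------------------------------
# Filament kinematics


def _filament(**kw):
    base = dict(
        birth_time_s=0.0,
        origin_um=(6.0, 6.0),
        direction=(1.0, 0.0),
        lifetime_s=1e9,
    )
    base.update(kw)
    return Filament(**base)


class TestAdvanceFilament:
    def test_length_grows_at_configured_rate(self, kinetics, geometry):
        fil = advance_filament(_filament(), 2.0, kinetics, geometry)
        assert fil.length_um == pytest.approx(3.0)

    def test_zero_dt_is_identity(self, kinetics, geometry):
        fil = _filament()
        assert advance_filament(fil, 0.0, kinetics, geometry) is fil

    def test_tip_clamps_at_disc_boundary(self, kinetics, geometry):
        # from the centre of a 10 um disc any direction exits at the radius
        fil = advance_filament(_filament(), 100.0, kinetics, geometry)
        assert fil.length_um == pytest.approx(5.0)
        assert geometry.contains(fil.tip_um)

    def test_negative_dt_rejected(self, kinetics, geometry):
        with pytest.raises(ParameterError):
            advance_filament(_filament(), -1.0, kinetics, geometry)

    def test_dead_filament_cannot_advance(self, kinetics, geometry):
        dead = advance_filament(
            _filament(lifetime_s=1.0), 2.0, kinetics, geometry
        )
        assert not dead.alive
        with pytest.raises(ParameterError):
            advance_filament(dead, 1.0, kinetics, geometry)

    def test_stepping_matches_analytic_state(self, kinetics, geometry):
        records = sample_filaments(200.0, kinetics, geometry, 0.0, seed=5)
        assert records
        for rec in records[:5]:
            fil = filament_state(rec, rec.birth_time_s, kinetics, geometry)
            t = rec.birth_time_s
            while fil.alive and t < rec.birth_time_s + rec.lifetime_s:
                dt = 1.7
                t += dt
                fil = advance_filament(fil, dt, kinetics, geometry)
                ref = filament_state(rec, t, kinetics, geometry)
                if ref is not None:
                    assert fil.length_um == pytest.approx(ref.length_um, rel=1e-12)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_filament_tips_never_leave_nucleus(self, seed):
        geometry = NucleusGeometry()
        kinetics = KineticsConfig(origin_mode="inm_anchored" if seed % 2 else "uniform_interior")
        records = sample_filaments(150.0, kinetics, geometry, 0.0, seed=seed)
        for rec in records:
            for t in np.linspace(rec.birth_time_s, rec.birth_time_s + rec.lifetime_s, 7):
                fil = filament_state(rec, t, kinetics, geometry)
                if fil is not None:
                    assert geometry.contains(fil.origin_um)
                    assert geometry.contains(fil.tip_um)


# ---------------------------------------------------------------------------
# Rendering


class TestRenderFrame:
    def test_no_filaments_noise_free_is_uniform_background(self, geometry):
        imaging = ImagingConfig(noise="none")
        img = render_frame([], geometry, imaging)
        mask = geometry.nucleus_mask()
        assert np.all(img[mask] == imaging.background_mean_photons)
        assert np.all(img[~mask] == 0.0)

    def test_background_fano_factor_is_one(self, rng):
        # variance/mean of pure Poisson counts -> 1
        geometry = NucleusGeometry(pixel_size_um=0.05, image_shape=(240, 240))
        imaging = ImagingConfig(noise="poisson", background_mean_photons=100.0)
        img = render_frame([], geometry, imaging, rng=rng)
        vals = img[geometry.nucleus_mask()]
        assert vals.size >= 10_000
        assert vals.var() / vals.mean() == pytest.approx(1.0, abs=0.05)

    def test_filament_pixels_brighter_than_background(self, geometry):
        imaging = ImagingConfig(noise="none")
        fil = _filament(length_um=4.0)
        img = render_frame([fil], geometry, imaging)
        # pixels along the axis of the segment
        r = int(round(6.0 / geometry.pixel_size_um))
        c0 = int(round(6.5 / geometry.pixel_size_um))
        c1 = int(round(9.5 / geometry.pixel_size_um))
        assert np.all(img[r, c0:c1] > imaging.background_mean_photons)

    def test_total_intensity_increases_with_filament_mass(self, geometry):
        imaging = ImagingConfig(noise="none")
        totals = []
        for length in (0.0, 1.0, 2.5, 4.0, 4.9):
            fils = [_filament(length_um=length)] if length else []
            totals.append(render_frame(fils, geometry, imaging).sum())
        assert np.all(np.diff(totals) > 0)

    def test_conserve_total_keeps_summed_expectation(self, geometry):
        base = ImagingConfig(noise="none")
        conserving = dataclasses.replace(base, conserve_total=True)
        empty = render_frame([], geometry, base).sum()
        full = render_frame([_filament(length_um=3.0)], geometry, conserving).sum()
        assert full == pytest.approx(empty, rel=1e-6)


# ---------------------------------------------------------------------------
# Calcium transient


class TestCalciumTrace:
    times = np.arange(0.0, 200.0, 0.5)

    def test_baseline_before_stimulus(self, calcium_model):
        tr = simulate_calcium_trace(calcium_model, self.times, 50.0, "cytoplasm")
        assert np.all(tr.values[self.times < 50.0] == calcium_model.baseline)

    def test_peak_time_matches_double_exponential_formula(self, calcium_model):
        # argmax of exp(-t/td) - exp(-t/tr) is tr*td/(td-tr)*ln(td/tr)
        fine = np.arange(0.0, 100.0, 1e-3)
        tr = simulate_calcium_trace(calcium_model, fine, 0.0, "cytoplasm")
        t_peak = fine[np.argmax(tr.values)]
        tr_, td = calcium_model.rise_tau_s, calcium_model.decay_tau_s
        expected = tr_ * td / (td - tr_) * math.log(td / tr_)
        assert t_peak == pytest.approx(expected, abs=2e-3)
        assert tr.values.max() == pytest.approx(
            calcium_model.baseline + calcium_model.amplitude, rel=1e-6
        )

    def test_returns_to_baseline_asymptotically(self, calcium_model):
        tr = simulate_calcium_trace(calcium_model, np.array([0.0, 500.0]), 0.0, "nucleus")
        assert abs(tr.values[-1] - calcium_model.baseline) < 1e-6 * calcium_model.amplitude

    def test_nuclear_compartment_is_delayed(self, calcium_model):
        nuc = simulate_calcium_trace(calcium_model, self.times, 50.0, "nucleus")
        cyt = simulate_calcium_trace(calcium_model, self.times, 50.0, "cytoplasm")
        shift = int(round(calcium_model.nuclear_delay_s / 0.5))
        np.testing.assert_allclose(nuc.values[shift:], cyt.values[:-shift])

    def test_degenerate_taus_rejected(self):
        with pytest.raises(ParameterError):
            CalciumModel(rise_tau_s=15.0, decay_tau_s=2.0)


# ---------------------------------------------------------------------------
# Full simulation


class TestSimulateTimelapse:
    def test_frame_count_is_floor_duration_over_interval_plus_one(self, geometry, kinetics):
        imaging = ImagingConfig(duration_s=90.0, frame_interval_s=3.0)
        stack, _ = simulate_timelapse(geometry, kinetics, imaging)
        assert stack.n_frames == 31

    def test_no_nucleation_gives_flat_noise_free_heterogeneity(self, geometry):
        kin = KineticsConfig(nucleation_mean_interval_s=math.inf)
        imaging = ImagingConfig(duration_s=60.0, stimulus_time_s=10.0, noise="none")
        stack, truth = simulate_timelapse(geometry, kin, imaging)
        mask = geometry.nucleus_mask()
        variances = stack.channels["actin_probe"][:, mask].var(axis=1)
        assert np.all(variances == 0.0)
        assert truth.total_length_um.sum() == 0.0

    def test_identical_seeds_give_bit_identical_stacks(self, geometry, kinetics, fast_imaging):
        s1, _ = simulate_timelapse(geometry, kinetics, fast_imaging)
        s2, _ = simulate_timelapse(geometry, kinetics, fast_imaging)
        for ch in s1.channels:
            np.testing.assert_array_equal(s1.channels[ch], s2.channels[ch])

    def test_ground_truth_mass_reflects_recorded_filaments(self, geometry, kinetics, fast_imaging):
        stack, truth = simulate_timelapse(geometry, kinetics, fast_imaging)
        i = stack.n_frames - 1
        t = stack.frame_times_s[i]
        expected = sum(
            f.length_um
            for f in (filament_state(r, t, kinetics, geometry) for r in truth.records)
            if f is not None
        )
        assert truth.total_length_um[i] == pytest.approx(expected)


class TestPopulation:
    imaging = ImagingConfig(duration_s=60.0, stimulus_time_s=15.0, noise="none")

    def test_zero_fraction_gives_all_flat_actin_channels(self, geometry, kinetics):
        pop = simulate_population(5, 0.0, geometry, kinetics, self.imaging, seed=1)
        assert not pop.responders.any()
        for truth in pop.truths:
            assert len(truth.records) == 0

    def test_full_fraction_gives_events_in_every_cell(self, geometry):
        kin = KineticsConfig(nucleation_mean_interval_s=2.0, onset_latency_s=0.0)
        pop = simulate_population(5, 1.0, geometry, kin, self.imaging, seed=2)
        assert pop.responders.all()
        assert all(len(t.records) >= 1 for t in pop.truths)

    def test_responder_count_within_binomial_99_interval(self, geometry, kinetics):
        n, p = 200, 0.5
        count = sum(
            truth.responder
            for _, _, truth in iter_population(
                n, p, geometry, KineticsConfig(nucleation_mean_interval_s=math.inf),
                self.imaging, seed=3,
            )
        )
        lo = stats.binom.ppf(0.005, n, p)
        hi = stats.binom.ppf(0.995, n, p)
        assert lo <= count <= hi

    def test_invalid_population_parameters_rejected(self, geometry, kinetics):
        with pytest.raises(ParameterError):
            simulate_population(0, 0.5, geometry, kinetics, self.imaging)
        with pytest.raises(ParameterError):
            simulate_population(3, 1.5, geometry, kinetics, self.imaging)


class TestGeometryValidation:
    def test_disc_must_fit_inside_image(self):
        with pytest.raises(ParameterError):
            NucleusGeometry(center_um=(2.0, 6.0))

    def test_nonpositive_dimensions_rejected(self):
        with pytest.raises(ParameterError):
            NucleusGeometry(diameter_um=-1.0)
        with pytest.raises(ParameterError):
            NucleusGeometry(pixel_size_um=0.0)
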