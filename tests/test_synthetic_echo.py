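"""Tests for the synthetic A-scan generator and contact mechanics."""

import numpy as np
import pytest

from sonodent import (
    Inclusion,
    Indenter,
    LoadStep,
    PulseModel,
    TissuePhantom,
    deform,
    effective_modulus,
    make_pulse,
    shore_to_young,
    simulate_ascan,
    simulate_sweep,
    with_inclusion,
)
from sonodent.errors import (
    InvalidConfigurationError,
    InvalidInputError,
    InvalidLoadError,
    InvalidProtocolError,
)

from conftest import load_of

FS = 50e6


class TestMakePulse:
    def test_peak_amplitude_and_zero_mean(self, pulse):
        wave = make_pulse(pulse, FS)
        assert np.max(np.abs(wave)) == pytest.approx(1.0, abs=0)
        assert abs(wave.mean()) < 1e-6 * np.max(np.abs(wave))

    def test_zero_amplitude_gives_silence(self):
        wave = make_pulse(PulseModel(amplitude=0.0), FS)
        assert np.all(wave == 0.0)

    @pytest.mark.parametrize("bandwidth", [0.3, 0.6, 1.0])
    def test_spectrum_center_and_width(self, bandwidth):
        """Oracle: zero-padded DFT of the rendered waveform."""
        p = PulseModel(fractional_bandwidth=bandwidth)
        wave = make_pulse(p, FS)
        n_fft = 1 << 18
        spectrum = np.abs(np.fft.rfft(wave, n_fft))
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / FS)
        assert freqs[np.argmax(spectrum)] == pytest.approx(
            p.center_frequency, abs=2 * FS / wave.size
        )
        above = freqs[spectrum >= spectrum.max() * 10 ** (-6 / 20)]
        width = above.max() - above.min()
        assert width == pytest.approx(bandwidth * p.center_frequency, rel=0.05)

    def test_undersampling_rejected(self, pulse):
        with pytest.raises(InvalidConfigurationError):
            make_pulse(pulse, 9 * pulse.center_frequency)

    def test_invalid_bandwidth_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            PulseModel(fractional_bandwidth=1.5)


class TestDeform:
    def test_zero_load(self, soft_phantom, indenter):
        state = deform(soft_phantom, indenter, load_of(0.0))
        assert state.deformation_w == 0.0
        assert state.compressed_thickness_hi == soft_phantom.thickness_h

    def test_linear_arithmetic_oracle(self, soft_phantom, indenter):
        # w = (1 - nu^2) P / (2 a E) = 0.75 / (2 * 0.01 * 1e4)
        state = deform(soft_phantom, indenter, load_of(1.0))
        assert state.deformation_w == pytest.approx(3.75e-3, rel=1e-12)
        assert not state.bottomed_out

    def test_stiffening_reduces_depth_and_solves_force_balance(
        self, soft_phantom, indenter
    ):
        import dataclasses

        stiff = dataclasses.replace(soft_phantom, stiffening_beta=2.0)
        p = 1.0
        state = deform(stiff, indenter, load_of(p))
        w = state.deformation_w
        assert w < 3.75e-3
        k = 2 * indenter.contact_radius_a * stiff.youngs_modulus_e / 0.75
        residual = abs(p - k * w * (1 + 2.0 * w / stiff.thickness_h))
        assert residual < 1e-8 * p
        # independent oracle: dense grid search over w
        grid = np.linspace(0, 0.95 * stiff.thickness_h, 200_001)
        forces = k * grid * (1 + 2.0 * grid / stiff.thickness_h)
        w_grid = grid[np.argmin(np.abs(forces - p))]
        assert w == pytest.approx(w_grid, abs=grid[1])

    @pytest.mark.parametrize("beta", [0.0, 2.0])
    def test_monotone_in_load_and_modulus(self, indenter, beta):
        forces = np.linspace(0, 5, 11)
        moduli = [5e3, 10e3, 50e3]
        depth = {
            e: [
                deform(
                    TissuePhantom(0.03, 1540.0, e, stiffening_beta=beta),
                    indenter,
                    load_of(f),
                ).deformation_w
                for f in forces
            ]
            for e in moduli
        }
        for e in moduli:
            assert np.all(np.diff(depth[e]) >= 0)
        for f_idx in range(1, len(forces)):
            column = [depth[e][f_idx] for e in moduli]
            assert np.all(np.diff(column) < 0)

    def test_bottom_out_cap(self, soft_phantom, indenter):
        state = deform(soft_phantom, indenter, load_of(500.0))
        assert state.deformation_w == pytest.approx(
            0.95 * soft_phantom.thickness_h
        )
        assert state.bottomed_out

    def test_negative_force_rejected(self):
        with pytest.raises(InvalidLoadError):
            LoadStep("bad", applied_force_p=-1.0)

    def test_pressure_force_consistency_checked(self, soft_phantom, indenter):
        ok = LoadStep("p", applied_pressure=1e3,
                      applied_force_p=1e3 * indenter.contact_area)
        assert ok.resolve_force(indenter) == pytest.approx(0.31416, rel=1e-3)
        bad = LoadStep("p", applied_pressure=1e3, applied_force_p=1.0)
        with pytest.raises(InvalidLoadError):
            bad.resolve_force(indenter)


class TestEffectiveModulus:
    def test_homogeneous_limit(self, soft_phantom):
        phantom = with_inclusion(soft_phantom, 0.3, 0.3, 10e3)
        assert effective_modulus(phantom) == pytest.approx(10e3)

    def test_series_composite_arithmetic(self, soft_phantom):
        phantom = with_inclusion(soft_phantom, 0.3, 0.3, 1e6)
        expected = 1.0 / (0.7 / 10e3 + 0.3 / 1e6)
        assert effective_modulus(phantom) == pytest.approx(expected)
        assert expected == pytest.approx(14225.5, rel=1e-4)

    def test_vanishing_inclusion(self, soft_phantom):
        phantom = with_inclusion(soft_phantom, 0.3, 1e-9, 1e6)
        assert effective_modulus(phantom) == pytest.approx(10e3, rel=1e-4)

    def test_monotone_in_inclusion_modulus(self, soft_phantom):
        values = [
            effective_modulus(with_inclusion(soft_phantom, 0.3, 0.3, e_inc))
            for e_inc in [20e3, 50e3, 200e3, 1e6]
        ]
        assert np.all(np.diff(values) > 0)

    def test_requires_inclusion(self, soft_phantom):
        with pytest.raises(InvalidInputError):
            effective_modulus(soft_phantom)

    def test_inclusion_must_fit(self):
        with pytest.raises(InvalidConfigurationError):
            Inclusion(0.8, 0.3, 1e5)


class TestSimulateAscan:
    def _envelope_argmax_time(self, scan, t_min):
        """Oracle: argmax of the magnitude of the upsampled analytic signal."""
        from scipy.signal import hilbert, resample

        up = 10
        env = np.abs(hilbert(resample(scan.samples, scan.samples.size * up)))
        times = scan.time_origin + np.arange(env.size) / (scan.sampling_rate * up)
        env[times < t_min] = 0.0
        return times[np.argmax(env)]

    def test_back_echo_round_trip_time(self, soft_phantom, indenter, pulse):
        scan = simulate_ascan(soft_phantom, indenter, load_of(0.0), pulse)
        t_peak = self._envelope_argmax_time(scan, t_min=5e-6)
        expected = 2 * soft_phantom.thickness_h / soft_phantom.sound_speed_v
        half_period = 0.5 / pulse.center_frequency
        assert t_peak == pytest.approx(expected, abs=half_period)
        assert expected == pytest.approx(38.96e-6, rel=1e-3)

    @pytest.mark.parametrize("e_pa", [5e3, 10e3, 30e3, 60e3, 100e3])
    @pytest.mark.parametrize("force", [0.0, 0.5, 1.0, 1.5, 2.0])
    def test_echo_time_law_over_grid(self, indenter, pulse, e_pa, force):
        phantom = TissuePhantom(0.03, 1540.0, e_pa)
        state = deform(phantom, indenter, load_of(force))
        scan = simulate_ascan(phantom, indenter, load_of(force), pulse)
        t_peak = self._envelope_argmax_time(scan, t_min=5e-6)
        expected = 2 * state.compressed_thickness_hi / phantom.sound_speed_v
        assert t_peak == pytest.approx(
            expected, abs=0.5 / pulse.center_frequency
        )

    def test_record_covers_round_trip(self, soft_phantom, indenter):
        scan = simulate_ascan(soft_phantom, indenter, load_of(0.0))
        assert scan.duration >= 2 * soft_phantom.thickness_h / 1540.0

    def test_compression_advances_echo(self, soft_phantom, indenter):
        # pick the force that gives exactly w = 1 mm
        force = 1e-3 * 2 * 0.01 * 10e3 / 0.75
        base = simulate_ascan(soft_phantom, indenter, load_of(0.0))
        loaded = simulate_ascan(soft_phantom, indenter, load_of(force))
        shift = self._envelope_argmax_time(base, 5e-6) - self._envelope_argmax_time(
            loaded, 5e-6
        )
        assert shift == pytest.approx(2 * 1e-3 / 1540.0, rel=0.01)
        assert shift == pytest.approx(1.299e-6, rel=0.01)

    def test_noise_seeding_is_deterministic(self, soft_phantom, indenter):
        a = simulate_ascan(soft_phantom, indenter, load_of(1.0), snr_db=20, seed=7)
        b = simulate_ascan(soft_phantom, indenter, load_of(1.0), snr_db=20, seed=7)
        c = simulate_ascan(soft_phantom, indenter, load_of(1.0), snr_db=20, seed=8)
        assert np.array_equal(a.samples, b.samples)
        assert not np.array_equal(a.samples, c.samples)

    def test_noise_rms_matches_requested_snr(self, soft_phantom, indenter):
        clean = simulate_ascan(soft_phantom, indenter, load_of(0.0))
        noisy = simulate_ascan(soft_phantom, indenter, load_of(0.0),
                               snr_db=20, seed=3)
        rms = np.std(noisy.samples - clean.samples)
        expected = np.max(np.abs(clean.samples)) / 10 ** (20 / 20)
        assert rms == pytest.approx(expected, rel=0.05)

    def test_stiff_inclusion_reduces_deformation(self, soft_phantom, indenter):
        lesion = with_inclusion(soft_phantom, 0.3, 0.35, 100e3)
        for force in [0.5, 1.0, 2.0]:
            w_host = deform(soft_phantom, indenter, load_of(force)).deformation_w
            w_lesion = deform(lesion, indenter, load_of(force)).deformation_w
            assert w_lesion < w_host


class TestSimulateSweep:
    def test_eight_load_sweep_echo_times_non_increasing(
        self, soft_phantom, indenter
    ):
        loads = [load_of(float(f)) for f in range(0, 8)]
        scans = simulate_sweep(soft_phantom, indenter, loads)
        assert len(scans) == 8
        from scipy.signal import hilbert

        times = []
        for scan in scans:
            env = np.abs(hilbert(scan.samples))
            t = scan.times
            env[t < 5e-6] = 0.0
            times.append(t[np.argmax(env)])
        assert np.all(np.diff(times) <= 0)

    def test_rerun_is_bit_identical(self, soft_phantom, indenter):
        loads = [load_of(0.0), load_of(1.0)]
        first = simulate_sweep(soft_phantom, indenter, loads, snr_db=25, seed=1)
        second = simulate_sweep(soft_phantom, indenter, loads, snr_db=25, seed=1)
        for a, b in zip(first, second):
            assert np.array_equal(a.samples, b.samples)

    def test_single_load_protocol(self, soft_phantom, indenter):
        scans = simulate_sweep(soft_phantom, indenter, [load_of(0.0)])
        assert len(scans) == 1

    def test_empty_protocol_rejected(self, soft_phantom, indenter):
        with pytest.raises(InvalidProtocolError):
            simulate_sweep(soft_phantom, indenter, [])

    def test_baseline_must_be_lowest(self, soft_phantom, indenter):
        with pytest.raises(InvalidProtocolError):
            simulate_sweep(soft_phantom, indenter, [load_of(5.0), load_of(0.0)])


class TestShoreToYoung:
    def test_arithmetic_oracle(self):
        assert shore_to_young(0.0) == pytest.approx(0.1573e6, rel=1e-3)
        assert shore_to_young(30.0) == pytest.approx(1.142e6, rel=1e-3)

    def test_strictly_increasing(self):
        grid = np.linspace(0, 95, 96)
        values = [shore_to_young(s) for s in grid]
        assert np.all(np.diff(values) > 0)

    def test_singularity_rejected(self):
        with pytest.raises(InvalidInputError):
            shore_to_young(100.0)
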