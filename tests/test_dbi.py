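"""Windowed dynamical Bayesian inference of phase couplings."""

import numpy as np
import pytest

from phaseconn import (
    DbiConfig,
    PhaseOscillatorSpec,
    coupling_series,
    coupling_strength,
    coupling_surface,
    coupling_threshold,
    coupling_time,
    downsample_phase,
    extract_band_phase,
    fit_windows,
    generate_coupled_oscillators,
    mean_coefficients,
)
from phaseconn.dbi import basis_indices, n_basis


def oscillator_phases(coupling, seed, duration=120.0, noise=0.1, phase_fs=40.0):
    spec = PhaseOscillatorSpec(
        coupling=coupling, noise_sd_x=noise, noise_sd_p=noise,
        duration=duration, seed=seed,
    )
    osc = generate_coupled_oscillators(spec)
    pa, fs = downsample_phase(osc.phi_x, osc.fs, phase_fs)
    pb, _ = downsample_phase(osc.phi_p, osc.fs, phase_fs)
    return pa, pb, fs, spec


class TestBandPhase:
    def test_sinusoid_phase_slope(self):
        fs = 256.0
        t = np.arange(int(fs * 20)) / fs
        ph = extract_band_phase(np.sin(2 * np.pi * 8.0 * t), (3.5, 12.0), fs)
        slope = np.polyfit(t, ph, 1)[0]
        assert abs(slope - 2 * np.pi * 8.0) / (2 * np.pi * 8.0) < 0.01

    def test_amplitude_modulation_does_not_change_slope(self):
        fs = 256.0
        t = np.arange(int(fs * 20)) / fs
        carrier = np.sin(2 * np.pi * 8.0 * t)
        am = (1.0 + 0.5 * np.sin(2 * np.pi * 0.2 * t)) * carrier
        s1 = np.polyfit(t, extract_band_phase(carrier, (3.5, 12.0), fs), 1)[0]
        s2 = np.polyfit(t, extract_band_phase(am, (3.5, 12.0), fs), 1)[0]
        assert abs(s1 - s2) / s1 < 0.01

    def test_broadband_noise_slope_within_band(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(fs * 30))
        ph = extract_band_phase(x, (3.5, 12.0), fs)
        t = np.arange(x.size) / fs
        slope = np.polyfit(t, ph, 1)[0]
        assert 2 * np.pi * 3.5 < slope < 2 * np.pi * 12.0

    def test_invalid_band_error(self):
        with pytest.raises(ValueError):
            extract_band_phase(np.zeros(256), (12.0, 3.5), 256.0)


class TestWindowing:
    def test_window_count_is_floor_of_record_over_window(self):
        # 180 s record at 3 s windows, unity overlap -> 60 fits
        fs = 10.0
        t = np.arange(int(180 * fs)) / fs
        pa = 2 * np.pi * 0.7 * t          # well below the 10 Hz phase rate
        pb = 2 * np.pi * 1.1 * t + 0.01 * np.sin(t)
        cfg = DbiConfig(basis_order=1)
        fits = fit_windows(pa, pb, fs, cfg)
        assert len(fits) == 60

    def test_window_longer_than_record_error(self):
        with pytest.raises(ValueError, match="window"):
            fit_windows(np.arange(10.0), np.arange(10.0), 1.0, DbiConfig(window=30.0))

    def test_nonfinite_phases_error(self):
        bad = np.arange(200.0)
        bad[5] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_windows(bad, np.arange(200.0), 10.0)

    def test_half_overlap_doubles_windows(self):
        fs = 10.0
        t = np.arange(int(30 * fs)) / fs
        pa, pb = 2 * np.pi * 0.7 * t, 2 * np.pi * 1.1 * t + 0.01 * np.sin(t)
        full = fit_windows(pa, pb, fs, DbiConfig(basis_order=1, overlap=1.0))
        half = fit_windows(pa, pb, fs, DbiConfig(basis_order=1, overlap=0.5))
        assert len(half) == 2 * len(full) - 1

    def test_basis_size(self):
        assert n_basis(2) == 25
        assert len(basis_indices(1)) == 4


class TestInference:
    def test_uncoupled_deterministic_phase_is_linear(self):
        spec = PhaseOscillatorSpec(coupling=0.0, noise_sd_x=0.0, noise_sd_p=0.0,
                                   duration=10.0, seed=0)
        osc = generate_coupled_oscillators(spec)
        expect = osc.phi_p[0] + spec.omega_p * osc.times
        np.testing.assert_allclose(osc.phi_p, expect, rtol=1e-9)

    def test_natural_frequencies_recovered(self):
        pa, pb, fs, spec = oscillator_phases(0.0, seed=1)
        fits = fit_windows(pa, pb, fs)
        C = mean_coefficients(fits)
        assert abs(C[0, 0] - spec.omega_x) / spec.omega_x < 0.05
        assert abs(C[0, 1] - spec.omega_p) / spec.omega_p < 0.05

    def test_zero_coupling_strength_below_surrogate_threshold(self):
        """Cross-realisation surrogate pool: the genuine E = 0 strength is
        statistically indistinguishable from the null."""
        phases = [oscillator_phases(0.0, seed=10 + s, duration=60.0) for s in range(4)]
        null = []
        for i in range(4):
            for j in range(4):
                if i == j:
                    continue
                pa = phases[i][0]
                pb = phases[j][1]
                n = min(pa.size, pb.size)
                s = coupling_series(fit_windows(pa[:n], pb[:n], phases[0][2]))
                null.append(s.strength_a_to_b.mean())
        with pytest.warns(UserWarning):
            thr = coupling_threshold(np.asarray(null))
        genuine = coupling_series(fit_windows(phases[0][0], phases[0][1], phases[0][2]))
        assert genuine.strength_a_to_b.mean() < thr

    def test_strength_monotone_and_unidirectional(self):
        fwd, rev = {}, {}
        for E in (0.0, 5.0, 10.0):
            pa, pb, fs, _ = oscillator_phases(E, seed=3)
            s = coupling_series(fit_windows(pa, pb, fs))
            fwd[E] = s.strength_a_to_b.mean()
            rev[E] = s.strength_b_to_a.mean()
        assert fwd[0.0] < fwd[5.0] < fwd[10.0]
        # reverse direction stays at the uncoupled noise floor
        assert rev[10.0] < 2 * fwd[0.0]
        assert rev[10.0] < fwd[10.0] / 5

    def test_coupling_surface_matches_generating_function(self):
        pa, pb, fs, spec = oscillator_phases(10.0, seed=4, duration=200.0)
        fits = fit_windows(pa, pb, fs)
        grid, q = coupling_surface(mean_coefficients(fits), 2, "a_to_b")
        A, _ = np.meshgrid(grid, grid, indexing="ij")
        truth = spec.coupling * np.cos(A + spec.phase_shift)
        corr = np.corrcoef(q.ravel(), truth.ravel())[0, 1]
        assert corr > 0.9

    def test_driver_trajectory_independent_of_coupling(self):
        """Unidirectionality at the generator level: X's path is bit-identical
        whether or not it drives P."""
        a = generate_coupled_oscillators(PhaseOscillatorSpec(coupling=0.0, seed=9,
                                                             duration=30.0))
        b = generate_coupled_oscillators(PhaseOscillatorSpec(coupling=10.0, seed=9,
                                                             duration=30.0))
        np.testing.assert_array_equal(a.phi_x, b.phi_x)
        assert not np.array_equal(a.phi_p, b.phi_p)


class TestCouplingStrengthAndTime:
    def test_strength_of_manual_coefficients(self):
        from phaseconn.dbi import CouplingWindowFit

        K = n_basis(2)
        coeffs = np.zeros((K, 2))
        fit = CouplingWindowFit(0, 0.0, 3.0, coeffs.copy(), np.eye(2), 2)
        assert coupling_strength(fit, "a_to_b") == 0.0
        # single cross coefficient a -> |a|
        reps = basis_indices(2)
        j = next(i for i, (m, n) in enumerate(reps) if m != 0)
        coeffs[1 + 2 * j, 1] = -0.7
        fit = CouplingWindowFit(0, 0.0, 3.0, coeffs, np.eye(2), 2)
        assert np.isclose(coupling_strength(fit, "a_to_b"), 0.7)

    def test_surface_export_round_trip(self, tmp_path):
        from phaseconn.dbi import save_coupling_surface

        K = n_basis(2)
        coeffs = np.zeros((K, 2))
        coeffs[1, 1] = 2.0  # a single cross term in B's equation
        path = tmp_path / "surface.csv"
        save_coupling_surface(path, coeffs, 2, "a_to_b", n_grid=10)
        grid = np.loadtxt(path, delimiter=",", skiprows=1)
        assert grid.shape == (100, 3)
        _, q = coupling_surface(coeffs, 2, "a_to_b", n_grid=10)
        np.testing.assert_allclose(grid[:, 2], q.ravel())

    def test_coupling_time_trivia(self):
        assert coupling_time(np.array([1.0, 2.0, 3.0]), 0.5) == 100.0
        assert coupling_time(np.array([1.0, 0.0, 1.0, 0.0]), 0.5) == 50.0
        with pytest.raises(ValueError):
            coupling_time(np.array([]), 0.5)
        # strictly above: values equal to the threshold do not count
        assert coupling_time(np.array([0.5, 0.6]), 0.5) == 50.0

    def test_intermittent_coupling_detected_half_the_time(self):
        """Coupling switched on only in the second half of the record gives
        a coupling-time percentage near 50."""
        off = generate_coupled_oscillators(
            PhaseOscillatorSpec(coupling=0.0, duration=90.0, seed=6))
        on = generate_coupled_oscillators(
            PhaseOscillatorSpec(coupling=8.0, duration=90.0, seed=7))
        pa = np.concatenate([off.phi_x, off.phi_x[-1] + on.phi_x - on.phi_x[0]])
        pb = np.concatenate([off.phi_p, off.phi_p[-1] + on.phi_p - on.phi_p[0]])
        pa, fs = downsample_phase(pa, 256.0, 40.0)
        pb, _ = downsample_phase(pb, 256.0, 40.0)
        # independent windows: the statistic, not the between-window memory,
        # is under test here
        cfg = DbiConfig(propagation_constant=None)
        series = coupling_series(fit_windows(pa, pb, fs, cfg))
        null = generate_coupled_oscillators(
            PhaseOscillatorSpec(coupling=0.0, duration=90.0, seed=8))
        na, nfs = downsample_phase(null.phi_x, 256.0, 40.0)
        nb, _ = downsample_phase(null.phi_p, 256.0, 40.0)
        null_s = coupling_series(fit_windows(na, nb, nfs, cfg))
        thr = coupling_threshold(null_s.strength_a_to_b)
        pct = coupling_time(series.strength_a_to_b, thr)
        assert 30.0 <= pct <= 70.0


class TestPropagation:
    def test_none_gives_independent_windows(self):
        pa, pb, fs, _ = oscillator_phases(5.0, seed=8, duration=30.0)
        cfg = DbiConfig(propagation_constant=None)
        fits = fit_windows(pa, pb, fs, cfg)
        wlen = int(3.0 * fs)
        solo = fit_windows(pa[wlen : 2 * wlen + 1], pb[wlen : 2 * wlen + 1], fs, cfg)
        np.testing.assert_allclose(fits[1].coeffs, solo[0].coeffs, rtol=1e-8)

    def test_smaller_propagation_constant_smooths_trajectories(self):
        """The prior of each window is the previous posterior inflated by
        p^2 x diagonal: small p pins coefficients, large p lets them wander."""
        pa, pb, fs, _ = oscillator_phases(5.0, seed=12, duration=120.0)
        var = {}
        for p in (0.05, 0.5, 5.0):
            fits = fit_windows(pa, pb, fs, DbiConfig(propagation_constant=p))
            traj = np.array([f.coeffs for f in fits])
            var[p] = np.mean(np.var(traj, axis=0))
        assert var[0.05] < var[0.5] < var[5.0]

    def test_amplitude_invariance_through_band_phase(self, rng):
        fs = 256.0
        x = rng.standard_normal(int(fs * 40))
        y = rng.standard_normal(int(fs * 40))
        out = []
        for gain in (1.0, 4.0):
            pa, pfs = downsample_phase(
                extract_band_phase(gain * x, (3.5, 12.0), fs), fs, 40.0)
            pb, _ = downsample_phase(
                extract_band_phase(gain * y, (3.5, 12.0), fs), fs, 40.0)
            s = coupling_series(fit_windows(pa, pb, pfs))
            out.append((s.strength_a_to_b, s.strength_b_to_a))
        np.testing.assert_array_equal(out[0][0], out[1][0])
        np.testing.assert_array_equal(out[0][1], out[1][1])
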