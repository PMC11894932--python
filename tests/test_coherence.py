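"""Wavelet phase coherence and the wavelet mean field."""

import numpy as np
import pytest

from phaseconn import (
    TwoModeSpec,
    WaveletParams,
    band_average,
    extract_phase,
    generate_two_mode_pair,
    time_avg_wpc,
    time_localized_wpc,
    wavelet_mean_field,
    wavelet_transform,
)
from phaseconn.timefreq import TimeFreqRep

from conftest import make_phase_field


def brute_force_wpc(ph1, ph2, freqs, fs, cycles=10.0):
    """Direct loop over window sums; the independent oracle for the estimator."""
    nf, nt = ph1.shape
    values = np.zeros((nf, nt))
    valid = np.zeros((nf, nt), dtype=bool)
    for k in range(nf):
        w = max(int(round(cycles / freqs[k] * fs)), 1)
        lo = (w - 1) // 2
        for c in range(nt):
            start = c - lo
            if start < 0 or start + w > nt:
                continue
            acc = 0.0 + 0.0j
            for i in range(start, start + w):
                acc += np.exp(1j * (ph1[k, i] - ph2[k, i]))
            values[k, c] = abs(acc) / w
            valid[k, c] = True
    return values, valid


class TestTimeLocalizedWpc:
    def test_matches_brute_force_oracle(self, rng):
        ph1 = rng.uniform(-np.pi, np.pi, size=(3, 40))
        ph2 = rng.uniform(-np.pi, np.pi, size=(3, 40))
        freqs = np.array([4.0, 6.0, 9.0])
        f1 = make_phase_field(ph1, fs=10.0, freqs=freqs)
        f2 = make_phase_field(ph2, fs=10.0, freqs=freqs)
        tlc = time_localized_wpc(f1, f2)
        expect, evalid = brute_force_wpc(ph1, ph2, freqs, 10.0)
        np.testing.assert_array_equal(tlc.valid_mask, evalid)
        np.testing.assert_allclose(tlc.values[evalid], expect[evalid], atol=1e-12)

    def test_identical_phases_give_unity(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 200))
        f1 = make_phase_field(ph, fs=20.0)
        f2 = make_phase_field(ph.copy(), fs=20.0)
        tlc = time_localized_wpc(f1, f2)
        assert np.allclose(tlc.values[tlc.valid_mask], 1.0, atol=1e-12)

    def test_constant_phase_offset_gives_unity(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 200))
        tlc = time_localized_wpc(
            make_phase_field(ph, fs=20.0), make_phase_field(ph + 1.234, fs=20.0)
        )
        assert np.allclose(tlc.values[tlc.valid_mask], 1.0, atol=1e-12)

    def test_symmetry_exact(self, rng):
        a = make_phase_field(rng.uniform(-np.pi, np.pi, size=(2, 120)), fs=15.0)
        b = make_phase_field(rng.uniform(-np.pi, np.pi, size=(2, 120)), fs=15.0)
        ab = time_localized_wpc(a, b)
        ba = time_localized_wpc(b, a)
        np.testing.assert_array_equal(ab.values, ba.values)
        np.testing.assert_array_equal(ab.valid_mask, ba.valid_mask)

    def test_mismatched_grids_error(self, rng):
        a = make_phase_field(rng.uniform(size=(2, 50)), fs=10.0)
        b = make_phase_field(rng.uniform(size=(2, 60)), fs=10.0)
        with pytest.raises(ValueError, match="grid"):
            time_localized_wpc(a, b)

    def test_late_onset_shared_mode_detected(self):
        """The shared 11 Hz mode appears only in the second half: coherence
        there must be clearly higher than in the first half."""
        pair = generate_two_mode_pair(TwoModeSpec(duration=120.0, shared_onset=60.0, seed=0))
        params = WaveletParams(fs=256.0, fmin=9.0, fmax=13.0, voices_per_octave=8)
        p1 = extract_phase(wavelet_transform(pair.a, params))
        p2 = extract_phase(wavelet_transform(pair.b, params))
        tlc = time_localized_wpc(p1, p2)
        k11 = int(np.argmin(np.abs(tlc.freqs - 11.0)))
        row, ok = tlc.values[k11], tlc.valid_mask[k11]
        first = row[ok & (tlc.times < 60.0)].mean()
        second = row[ok & (tlc.times >= 60.0)].mean()
        assert second > 0.9
        assert second - first > 0.2


class TestTimeAveragedWpc:
    def test_constant_unity_field(self, rng):
        ph = rng.uniform(-np.pi, np.pi, size=(2, 300))
        tlc = time_localized_wpc(make_phase_field(ph, fs=20.0), make_phase_field(ph, fs=20.0))
        np.testing.assert_allclose(time_avg_wpc(tlc), 1.0, atol=1e-12)

    def test_empty_row_is_nan(self, rng):
        ph = rng.uniform(size=(2, 100))
        tlc = time_localized_wpc(make_phase_field(ph, fs=10.0), make_phase_field(ph, fs=10.0))
        tlc.valid_mask[0, :] = False
        assert np.isnan(time_avg_wpc(tlc)[0])

    def test_noise_coherence_tends_to_finite_window_bias(self):
        """Independent noise channels: the time-averaged coherence sits at
        the finite-window bias level set by the window length, and widening
        the window with the record (whole-record coherence) drives the bias
        down — the reason intersubject surrogates are subtracted from the
        10-cycle statistic rather than hoping longer records fix it."""
        params = WaveletParams(fs=64.0, fmin=6.0, fmax=10.0, voices_per_octave=4)
        rng = np.random.default_rng(11)

        def mean_bias(duration, cycles, n_pairs=100):
            total = 0.0
            for _ in range(n_pairs):
                x = rng.standard_normal(int(64 * duration))
                y = rng.standard_normal(int(64 * duration))
                p1 = extract_phase(wavelet_transform(x, params))
                p2 = extract_phase(wavelet_transform(y, params))
                spec = time_avg_wpc(time_localized_wpc(p1, p2, window_cycles=cycles))
                total += np.nanmean(spec)
            return total / n_pairs

        short_10 = mean_bias(12.0, 10)
        long_10 = mean_bias(40.0, 10)
        # fixed 10-cycle window: the bias level does not depend on record length
        assert abs(short_10 - long_10) < 0.05
        # window growing with the record: bias decreases with record length
        assert mean_bias(40.0, 60) < mean_bias(12.0, 18) < short_10

    def test_second_half_spectrum_peaks_at_11hz(self):
        pair = generate_two_mode_pair(TwoModeSpec(duration=120.0, shared_onset=60.0, seed=4))
        params = WaveletParams(fs=256.0, fmin=3.5, fmax=13.0, voices_per_octave=12)
        half = pair.a.size // 2
        p1 = extract_phase(wavelet_transform(pair.a[half:], params))
        p2 = extract_phase(wavelet_transform(pair.b[half:], params))
        spec = time_avg_wpc(time_localized_wpc(p1, p2))
        peak = params.freqs[np.nanargmax(spec)]
        assert abs(peak - 11.0) < 1.0


def _rep_from(coeffs, fs=10.0):
    nf, nt = coeffs.shape
    freqs = np.linspace(4, 10, nf)
    return TimeFreqRep(
        coeffs, freqs, np.arange(nt) / fs, np.ones((nf, nt), dtype=bool), None
    )


class TestMeanField:
    def test_identical_channels_full_synchrony(self, rng):
        base = rng.standard_normal((3, 500)) + 1j * rng.standard_normal((3, 500))
        mf = wavelet_mean_field([_rep_from(base.copy()) for _ in range(6)])
        np.testing.assert_allclose(mf.per_scale_coherence, 1.0, rtol=1e-12)
        assert np.isclose(mf.global_coherence(band=(4, 10)), 1.0)

    def test_single_channel_full_synchrony(self, rng):
        base = rng.standard_normal((2, 400)) + 1j * rng.standard_normal((2, 400))
        mf = wavelet_mean_field([_rep_from(base)])
        np.testing.assert_allclose(mf.per_scale_coherence, 1.0, rtol=1e-12)

    def test_independent_phases_scale_as_one_over_n(self, rng):
        n_ch, nt = 8, 8192
        reps = [
            _rep_from(np.exp(1j * rng.uniform(-np.pi, np.pi, size=(2, nt))))
            for _ in range(n_ch)
        ]
        mf = wavelet_mean_field(reps)
        np.testing.assert_allclose(mf.per_scale_coherence, 1.0 / n_ch, rtol=0.2)

    def test_grid_mismatch_error(self, rng):
        a = _rep_from(np.ones((2, 50), dtype=complex))
        b = _rep_from(np.ones((2, 60), dtype=complex))
        with pytest.raises(ValueError, match="grid"):
            wavelet_mean_field([a, b])


class TestBandAverage:
    def test_rows_outside_band_ignored(self):
        freqs = np.array([2.0, 4.0, 8.0, 16.0])
        vals = np.array([100.0, 1.0, 3.0, 100.0])
        assert band_average(freqs, vals, band=(3.5, 12.0)) == 2.0

    def test_empty_band_error(self):
        with pytest.raises(ValueError):
            band_average(np.array([1.0, 2.0]), np.array([1.0, 1.0]), band=(5.0, 6.0))


class TestAmplitudeRobustness:
    def test_wpc_bitwise_invariant_under_power_of_two_gain(self, small_params, rng):
        x = rng.standard_normal(64 * 12)
        y = rng.standard_normal(64 * 12)

        def wpc_of(a, b):
            p1 = extract_phase(wavelet_transform(a, small_params))
            p2 = extract_phase(wavelet_transform(b, small_params))
            return time_localized_wpc(p1, p2).values

        base = wpc_of(x, y)
        np.testing.assert_array_equal(wpc_of(4.0 * x, y), base)
        np.testing.assert_array_equal(wpc_of(x, 0.125 * y), base)

    def test_wpc_invariant_under_arbitrary_gain(self, small_params, rng):
        x = rng.standard_normal(64 * 12)
        y = rng.standard_normal(64 * 12)

        def wpc_of(a, b):
            p1 = extract_phase(wavelet_transform(a, small_params))
            p2 = extract_phase(wavelet_transform(b, small_params))
            return time_localized_wpc(p1, p2).values

        np.testing.assert_allclose(wpc_of(3.7 * x, y), wpc_of(x, y), atol=1e-9)
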