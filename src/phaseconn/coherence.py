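"""Wavelet phase coherence and the wavelet mean field.

Time-localised wavelet phase coherence (WPC) at frequency ``f`` and time
``t`` is the modulus of the mean unit phasor of the phase difference over a
centred window of 10 complete oscillations:

    WPC(t, f) = (f / n_cyc) * | integral_{t - n_cyc/2f}^{t + n_cyc/2f}
                                exp(1j * (phi1 - phi2)) ds |

It is 1 when the phase difference is constant over the window, 0 when the
difference drifts uniformly, and is by construction independent of the
amplitudes of the two signals.  Windows truncated by the record edge are
masked rather than shortened, to avoid inflating coherence at the edges.

The wavelet mean field averages unit-normalised wavelet transforms across
channels; the time-mean squared modulus of the mean field is the global
coherence, 1 for complete synchrony across channels and ~1/N for N
independent channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .timefreq import PhaseField, TimeFreqRep

__all__ = [
    "TimeLocalizedCoherence",
    "MeanField",
    "time_localized_wpc",
    "time_avg_wpc",
    "wavelet_mean_field",
    "band_average",
]


@dataclass
class TimeLocalizedCoherence:
    """WPC values on a (frequency x time) grid with a validity mask.

    ``valid_mask`` is True where the value is trustworthy: the full window
    lies inside the record, every phase in it is defined, and the centre
    cell is outside the cone of influence.
    """

    values: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    valid_mask: np.ndarray
    window_cycles: float = 10.0

    def window_seconds(self, freq: float) -> float:
        return self.window_cycles / freq


@dataclass
class MeanField:
    """Wavelet mean field r_sigma(t) and per-scale global coherence."""

    r: np.ndarray                   # complex, (frequency x time)
    freqs: np.ndarray
    times: np.ndarray
    n_channels: int
    per_scale_coherence: np.ndarray  # (frequency,) in [0, 1]

    def global_coherence(self, band: tuple[float, float] = (3.5, 12.0)) -> float:
        """Band-averaged global coherence, a scalar in [0, 1]."""
        return band_average(self.freqs, self.per_scale_coherence, band)


def time_localized_wpc(
    phase1: PhaseField,
    phase2: PhaseField,
    window_cycles: float = 10.0,
) -> TimeLocalizedCoherence:
    """Time-localised wavelet phase coherence between two phase fields.

    The two fields must share their (frequency, time) grid.  At each cell
    the modulus of the mean phasor of the phase difference is taken over a
    centred window of ``window_cycles`` periods of that row's frequency.
    """
    if not phase1.shares_grid(phase2):
        raise ValueError("phase fields do not share a (frequency, time) grid")
    fs = phase1.fs
    nf, nt = phase1.phases.shape
    z = np.exp(1j * (phase1.phases - phase2.phases))
    ok = phase1.defined_mask & phase2.defined_mask
    z = np.where(ok, z, 0.0)

    values = np.zeros((nf, nt))
    valid = np.zeros((nf, nt), dtype=bool)
    zero = np.zeros(1, dtype=complex)
    izero = np.zeros(1, dtype=np.int64)
    for k, f in enumerate(phase1.freqs):
        w = int(round(window_cycles / f * fs))
        w = max(w, 1)
        if w > nt:
            continue  # window exits the record everywhere: row fully masked
        cs = np.concatenate([zero, np.cumsum(z[k])])
        cnt = np.concatenate([izero, np.cumsum(ok[k].astype(np.int64))])
        m = np.abs(cs[w:] - cs[:-w]) / w
        full = (cnt[w:] - cnt[:-w]) == w  # no undefined phase inside window
        lo = (w - 1) // 2
        values[k, lo : lo + m.size] = m
        valid[k, lo : lo + m.size] = full
    coi = phase1.coi_mask & phase2.coi_mask
    valid &= coi
    return TimeLocalizedCoherence(values, phase1.freqs, phase1.times, valid, window_cycles)


def time_avg_wpc(tlc: TimeLocalizedCoherence) -> np.ndarray:
    """Time-averaged coherence spectrum: mean over unmasked columns per row.

    Rows with no valid cells yield NaN.
    """
    out = np.full(tlc.freqs.size, np.nan)
    for k in range(tlc.freqs.size):
        keep = tlc.valid_mask[k]
        if keep.any():
            out[k] = tlc.values[k, keep].mean()
    return out


def wavelet_mean_field(reps: list[TimeFreqRep]) -> MeanField:
    """Wavelet mean field across N channels.

    Each channel's transform is first divided, per scale, by the square
    root of the grand mean squared modulus across channels and time; the
    mean field is then the channel average of the normalised transforms,
    and the per-scale global coherence is the time-mean of |r|^2.
    """
    if len(reps) < 1:
        raise ValueError("need at least one channel")
    ref = reps[0]
    for rep in reps[1:]:
        if rep.coefficients.shape != ref.coefficients.shape or not np.allclose(
            rep.freqs, ref.freqs
        ):
            raise ValueError("channel transforms do not share a grid")
    W = np.stack([rep.coefficients for rep in reps])  # (N, F, T)
    norm = np.sqrt(np.mean(np.abs(W) ** 2, axis=(0, 2), keepdims=True))  # per scale
    norm = np.where(norm > 0, norm, 1.0)
    w = W / norm
    r = w.mean(axis=0)  # (F, T)
    per_scale = np.mean(np.abs(r) ** 2, axis=1)
    return MeanField(r, ref.freqs, ref.times, len(reps), per_scale)


def band_average(
    freqs: np.ndarray,
    values: np.ndarray,
    band: tuple[float, float] = (3.5, 12.0),
) -> float:
    """Mean over frequency rows inside ``band`` (inclusive), ignoring NaNs."""
    freqs = np.asarray(freqs)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not sel.any():
        raise ValueError("no frequency rows inside the requested band")
    vals = np.asarray(values, dtype=float)[..., sel]
    if np.all(np.isnan(vals)):
        return np.nan
    return float(np.nanmean(vals, axis=-1))
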