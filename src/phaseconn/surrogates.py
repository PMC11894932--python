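"""Intersubject surrogate nulls, effective coherence, coupling thresholds.

Genuine coherence between two probes can only exist within a subject.
Pairing probe 1 of subject i with probe 2 of subject j (i != j) therefore
yields an "apparent" coherence that is pure estimator bias: for n subjects
there are n**2 - n such cross pairings.  The per-frequency mean of this
pool is subtracted from each subject's actual coherence spectrum, negatives
are clipped to zero, and the band average gives the *effective* coherence —
one nonnegative scalar per subject and probe pair.

For coupling strengths (dynamical Bayesian inference), whose null values
run systematically higher, the 95th percentile of the surrogate pool is
used as a threshold instead of the mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .coherence import band_average, time_avg_wpc, time_localized_wpc, wavelet_mean_field
from .timefreq import PhaseField, TimeFreqRep

__all__ = [
    "SurrogatePool",
    "intersubject_pool",
    "actual_spectra",
    "effective_coherence",
    "coupling_threshold",
    "effective_global_coherence",
]


@dataclass
class SurrogatePool:
    """Null coherence spectra (or scalar coupling strengths) from cross-subject pairs."""

    values: np.ndarray          # (count, n_freq) spectra, or (count,) scalars
    freqs: np.ndarray | None
    pair: tuple[str, str]
    group: str | None = None
    n_subjects: int | None = None

    @property
    def count(self) -> int:
        return self.values.shape[0]

    def mean_spectrum(self) -> np.ndarray:
        """Per-frequency mean of the pool (the coherence threshold)."""
        return np.nanmean(self.values, axis=0)


def _truncate_to_shortest(fields: Sequence[PhaseField]) -> list[PhaseField]:
    lengths = {f.phases.shape[1] for f in fields}
    if len(lengths) == 1:
        return list(fields)
    n = min(lengths)
    warnings.warn(
        f"unequal record lengths; truncating all phase fields to {n} samples",
        UserWarning,
        stacklevel=3,
    )
    return [
        PhaseField(
            f.phases[:, :n], f.freqs, f.times[:n], f.coi_mask[:, :n], f.defined_mask[:, :n]
        )
        for f in fields
    ]


def intersubject_pool(
    subjects: Sequence[Mapping[str, PhaseField]],
    pair: tuple[str, str],
    group: str | None = None,
    window_cycles: float = 10.0,
) -> SurrogatePool:
    """Intersubject surrogate pool of time-averaged coherence spectra.

    Parameters
    ----------
    subjects : sequence of mappings
        One mapping per subject from probe label to its :class:`PhaseField`.
    pair : (probe, probe)
        The probe pair; probe 1 is taken from subject i, probe 2 from
        subject j, over all ordered pairs with i != j (``n**2 - n`` spectra).

    Records of unequal length are truncated to the shortest, with a warning.
    """
    n = len(subjects)
    if n < 3:
        raise ValueError("intersubject surrogates require at least 3 subjects")
    p, q = pair
    a = _truncate_to_shortest([s[p] for s in subjects])
    b = _truncate_to_shortest([s[q] for s in subjects])
    spectra = []
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            tlc = time_localized_wpc(a[i], b[j], window_cycles)
            spectra.append(time_avg_wpc(tlc))
    return SurrogatePool(np.asarray(spectra), a[0].freqs, pair, group, n)


def actual_spectra(
    subjects: Sequence[Mapping[str, PhaseField]],
    pair: tuple[str, str],
    window_cycles: float = 10.0,
) -> np.ndarray:
    """Within-subject (genuine) time-averaged coherence spectra, one row per subject."""
    p, q = pair
    out = []
    for s in subjects:
        tlc = time_localized_wpc(s[p], s[q], window_cycles)
        out.append(time_avg_wpc(tlc))
    return np.asarray(out)


def effective_coherence(
    actual: np.ndarray,
    pool: SurrogatePool,
    band: tuple[float, float] = (3.5, 12.0),
) -> float:
    """Surrogate-subtracted, clipped, band-averaged coherence.

    The per-frequency pool mean is subtracted from the actual spectrum,
    values below the surrogate level are set to zero, and the mean over the
    band is returned: one nonnegative scalar per subject and probe pair.
    """
    actual = np.asarray(actual, dtype=float)
    if pool.freqs is None or actual.shape != pool.freqs.shape:
        raise ValueError("actual spectrum and surrogate pool do not share a frequency grid")
    net = np.clip(actual - pool.mean_spectrum(), 0.0, None)
    return band_average(pool.freqs, net, band)


def coupling_threshold(pool: np.ndarray | SurrogatePool, percentile: float = 95.0) -> float:
    """Empirical percentile of a pool of surrogate coupling strengths.

    Uses linear interpolation between order statistics (the default
    convention in mainstream numerics), so e.g. the 95th percentile of
    {1, ..., 100} is 95.05.
    """
    values = pool.values if isinstance(pool, SurrogatePool) else np.asarray(pool, dtype=float)
    values = values.ravel()
    if values.size == 0:
        raise ValueError("empty surrogate pool")
    if values.size < 20:
        warnings.warn(
            f"only {values.size} null samples; at least 20 are recommended for a "
            "stable 95th percentile",
            UserWarning,
            stacklevel=2,
        )
    return float(np.percentile(values, percentile))


def effective_global_coherence(
    subject_reps: Sequence[Sequence[TimeFreqRep]],
    band: tuple[float, float] = (3.5, 12.0),
    n_surrogates: int = 19,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Surrogate-subtracted global coherence, one scalar per subject.

    The null level is estimated from surrogate "subjects" whose channels are
    drawn from distinct real subjects (the intersubject construction applied
    to the mean field): any global synchrony in such a composite is
    estimator bias.  The per-scale surrogate mean is subtracted before band
    averaging and negatives are clipped to zero.
    """
    rng = np.random.default_rng() if rng is None else rng
    n_sub = len(subject_reps)
    if n_sub < 3:
        raise ValueError("need at least 3 subjects")
    n_ch = len(subject_reps[0])
    freqs = subject_reps[0][0].freqs

    null = np.zeros((n_surrogates, freqs.size))
    for k in range(n_surrogates):
        donors = rng.permutation(n_sub)
        chans = [subject_reps[donors[c % n_sub]][c] for c in range(n_ch)]
        null[k] = wavelet_mean_field(chans).per_scale_coherence
    null_mean = null.mean(axis=0)

    out = np.empty(n_sub)
    for i, reps in enumerate(subject_reps):
        per_scale = wavelet_mean_field(list(reps)).per_scale_coherence
        net = np.clip(per_scale - null_mean, 0.0, None)
        out[i] = band_average(freqs, net, band)
    return out
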