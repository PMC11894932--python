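"""Shared fixtures: small wavelet grids, toy phase fields, a tiny cohort."""

import numpy as np
import pytest

from phaseconn import (
    CohortSpec,
    PhaseField,
    WaveletParams,
    extract_phase,
    generate_cohort,
    wavelet_transform,
)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_params():
    """Wavelet settings cheap enough for per-test transforms."""
    return WaveletParams(fs=64.0, fmin=3.0, fmax=14.0, voices_per_octave=8)


def make_phase_field(phases, fs=10.0, freqs=None):
    """Wrap a raw (freq x time) phase array in a fully valid PhaseField."""
    phases = np.atleast_2d(np.asarray(phases, dtype=float))
    nf, nt = phases.shape
    if freqs is None:
        freqs = np.linspace(4.0, 10.0, nf)
    times = np.arange(nt) / fs
    full = np.ones((nf, nt), dtype=bool)
    return PhaseField(phases, np.asarray(freqs, dtype=float), times, full.copy(), full.copy())


@pytest.fixture()
def phase_field_factory():
    return make_phase_field


def subject_phase_fields(recordings, channels, params):
    """Per-subject {label: PhaseField} dicts for the given channels."""
    out = []
    for rec in recordings:
        out.append(
            {ch: extract_phase(wavelet_transform(rec.channel(ch), params)) for ch in channels}
        )
    return out


@pytest.fixture()
def tiny_cohort():
    """Two-group cohort small enough for end-to-end tests (seconds, not minutes)."""
    spec = CohortSpec(
        n_per_group=(4, 3),
        channel_labels=("F3", "F4"),
        coupled_pairs=(("F3", "F4"),),
        group_effect=0.0,
        segment_count=2,
        segment_length=16.0,
        fs=64.0,
        seed=7,
    )
    return generate_cohort(spec)


def pytest_configure(config):
    import warnings

    warnings.filterwarnings(
        "ignore",
        message="record holds fewer than 30 cycles",
        category=UserWarning,
    )
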