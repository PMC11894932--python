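"""Synthetic inputs for every pipeline stage.

Three generators:

* :func:`generate_two_mode_pair` — a pair of signals, each the sum of a
  theta-like (~5.5 Hz) and an alpha-like (~11 Hz) non-autonomous mode with
  slowly drifting instantaneous frequency, plus independent white Gaussian
  noise.  The alpha mode is shared (identical phase) between channels only
  from ``shared_onset`` onwards, so phase coherence at 11 Hz should switch
  from its noise floor to near 1 at that time.

* :func:`generate_coupled_oscillators` — two phase oscillators with
  unidirectional coupling

      dphi_X/dt = omega_X + xi_X
      dphi_P/dt = omega_P + E * cos(phi_X + pi/2.5) + xi_P

  integrated by Euler-Maruyama at the signal sampling rate (the same
  discretisation the inference stage assumes).

* :func:`generate_cohort` — two groups of multichannel subjects in which
  designated probe pairs carry either a shared alpha mode or a directed
  phase coupling; the ``group_effect`` factor scales that structure down
  in group 2, emulating a connectivity deficit.  Mode variance is held
  constant across groups so that signal *power* carries no group
  information — only phase relations differ.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .pipeline_io import Recording

__all__ = [
    "TwoModeSpec",
    "PhaseOscillatorSpec",
    "CohortSpec",
    "TwoModePair",
    "OscillatorPair",
    "Cohort",
    "generate_two_mode_pair",
    "generate_coupled_oscillators",
    "generate_cohort",
]

Trajectory = Callable[[np.ndarray], np.ndarray]


def _default_theta(t: np.ndarray) -> np.ndarray:
    return 5.5 + 0.4 * np.sin(2 * np.pi * t / 47.0)


def _default_alpha(t: np.ndarray) -> np.ndarray:
    return 11.0 + 0.5 * np.sin(2 * np.pi * t / 71.0)


@dataclass(frozen=True)
class TwoModeSpec:
    """Two-mode, two-channel simulation settings (defaults are the study conditions)."""

    duration: float = 400.0
    fs: float = 256.0
    theta_freq_trajectory: Trajectory = _default_theta
    alpha_freq_trajectory: Trajectory = _default_alpha
    shared_onset: float = 200.0
    mode_amplitudes: tuple[float, float] = (1.0, 1.0)  # (theta, alpha)
    noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not 0 <= self.shared_onset <= self.duration:
            raise ValueError("shared_onset must lie within [0, duration]")
        t = np.linspace(0, self.duration, 1024)
        fmax = max(self.theta_freq_trajectory(t).max(), self.alpha_freq_trajectory(t).max())
        if self.fs <= 2 * fmax:
            raise ValueError(
                f"sampling theorem violated: fs = {self.fs} Hz <= 2 x max trajectory "
                f"frequency ({fmax:.3g} Hz)"
            )


@dataclass(frozen=True)
class PhaseOscillatorSpec:
    """Unidirectionally coupled phase-oscillator settings.

    omega_X, omega_P are natural frequencies in rad/s; E is the coupling
    amplitude; noise standard deviations are in rad/sqrt(s).
    """

    omega_x: float = 2 * np.pi * 5.0
    omega_p: float = 2 * np.pi * 8.0
    coupling: float = 0.0                    # E
    phase_shift: float = np.pi / 2.5
    noise_sd_x: float = 0.1
    noise_sd_p: float = 0.1
    duration: float = 200.0
    fs: float = 256.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("omega_x", "omega_p", "coupling", "noise_sd_x", "noise_sd_p",
                     "duration", "fs"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite parameter: {name}")
        if self.coupling < 0:
            raise ValueError("coupling amplitude E must be >= 0")
        for w in (self.omega_x, self.omega_p):
            if self.fs <= w / np.pi:  # fs above twice the natural frequency in Hz
                raise ValueError("fs must exceed omega/pi for both oscillators")


@dataclass(frozen=True)
class CohortSpec:
    """Two-group multichannel cohort settings."""

    n_per_group: tuple[int, int] = (13, 9)
    channel_labels: tuple[str, ...] = ("Fp1", "Fp2", "F3", "F4")
    coupled_pairs: tuple[tuple[str, str], ...] = (("F3", "F4"),)
    group_effect: float = 1.0
    segment_count: int = 1
    segment_length: float = 180.0
    fs: float = 256.0
    seed: int = 0
    mechanism: str = "shared_mode"   # or "phase_coupling"
    base_coupling: float = 0.9       # shared-mode weight (or E, for phase_coupling)
    noise_sd: float = 0.5
    group_names: tuple[str, str] = ("group1", "group2")

    def validate(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("duplicate channel labels")
        labels = set(self.channel_labels)
        for a, b in self.coupled_pairs:
            if a not in labels or b not in labels:
                raise ValueError(f"coupled pair ({a}, {b}) not within channel_labels")
        if not 0 <= self.group_effect <= 1:
            raise ValueError("group_effect must be in [0, 1]")
        if self.mechanism not in ("shared_mode", "phase_coupling"):
            raise ValueError("mechanism must be 'shared_mode' or 'phase_coupling'")
        if self.segment_count < 1:
            raise ValueError("segment_count must be >= 1")


@dataclass
class TwoModePair:
    a: np.ndarray
    b: np.ndarray
    times: np.ndarray
    fs: float
    alpha_phase: np.ndarray          # shared alpha phase trajectory (unwrapped)
    alpha_components: tuple[np.ndarray, np.ndarray]


@dataclass
class OscillatorPair:
    phi_x: np.ndarray                # unwrapped
    phi_p: np.ndarray
    times: np.ndarray
    fs: float

    @property
    def wrapped(self) -> tuple[np.ndarray, np.ndarray]:
        wrap = lambda p: np.angle(np.exp(1j * p))
        return wrap(self.phi_x), wrap(self.phi_p)

    @property
    def signals(self) -> tuple[np.ndarray, np.ndarray]:
        """Cosine projections, usable as observed signals."""
        return np.cos(self.phi_x), np.cos(self.phi_p)


@dataclass
class Cohort:
    recordings: list[Recording]
    metadata: pd.DataFrame
    spec: CohortSpec


def _phase_from_trajectory(freq: np.ndarray, fs: float, phase0: float) -> np.ndarray:
    """Unwrapped phase 2*pi*integral(f dt) by cumulative trapezoid."""
    inc = np.concatenate([[0.0], 0.5 * (freq[1:] + freq[:-1])]) / fs
    return phase0 + 2 * np.pi * np.cumsum(inc)


def generate_two_mode_pair(spec: TwoModeSpec) -> TwoModePair:
    """Simulate the two-channel, two-mode demonstration signal pair.

    Channel A carries the alpha mode only for t >= ``shared_onset``;
    channel B carries it throughout; the alpha-mode phase is identical
    across channels wherever both carry it.  Theta modes and the additive
    white Gaussian noise are independent between channels.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    t = np.arange(n) / spec.fs
    amp_theta, amp_alpha = spec.mode_amplitudes

    alpha_phase = _phase_from_trajectory(
        spec.alpha_freq_trajectory(t), spec.fs, rng.uniform(0, 2 * np.pi)
    )
    theta_a = _phase_from_trajectory(
        spec.theta_freq_trajectory(t), spec.fs, rng.uniform(0, 2 * np.pi)
    )
    theta_b = _phase_from_trajectory(
        spec.theta_freq_trajectory(t), spec.fs, rng.uniform(0, 2 * np.pi)
    )

    alpha_a = amp_alpha * np.where(t >= spec.shared_onset, np.cos(alpha_phase), 0.0)
    alpha_b = amp_alpha * np.cos(alpha_phase)
    a = amp_theta * np.cos(theta_a) + alpha_a + spec.noise_sd * rng.standard_normal(n)
    b = amp_theta * np.cos(theta_b) + alpha_b + spec.noise_sd * rng.standard_normal(n)
    return TwoModePair(a, b, t, spec.fs, alpha_phase, (alpha_a, alpha_b))


def generate_coupled_oscillators(spec: PhaseOscillatorSpec) -> OscillatorPair:
    """Integrate the unidirectional X -> P phase-oscillator pair.

    Euler-Maruyama at the sampling rate; phases are returned unwrapped
    (use ``.wrapped`` or ``.signals`` for wrapped phases / projections).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration * spec.fs))
    h = 1.0 / spec.fs
    sqh = np.sqrt(h)
    phi_x = np.empty(n)
    phi_p = np.empty(n)
    phi_x[0] = rng.uniform(0, 2 * np.pi)
    phi_p[0] = rng.uniform(0, 2 * np.pi)
    noise_x = spec.noise_sd_x * sqh * rng.standard_normal(n - 1)
    noise_p = spec.noise_sd_p * sqh * rng.standard_normal(n - 1)
    E, shift = spec.coupling, spec.phase_shift
    for k in range(n - 1):
        phi_x[k + 1] = phi_x[k] + h * spec.omega_x + noise_x[k]
        phi_p[k + 1] = (
            phi_p[k] + h * (spec.omega_p + E * np.cos(phi_x[k] + shift)) + noise_p[k]
        )
    t = np.arange(n) / spec.fs
    return OscillatorPair(phi_x, phi_p, t, spec.fs)


def _pair_components(labels: Sequence[str], pairs: Sequence[tuple[str, str]]):
    """Connected components of the coupled-pairs graph (shared-mode groups)."""
    comp: dict[str, int] = {}
    nxt = 0
    for a, b in pairs:
        ca, cb = comp.get(a), comp.get(b)
        if ca is None and cb is None:
            comp[a] = comp[b] = nxt
            nxt += 1
        elif ca is None:
            comp[a] = cb
        elif cb is None:
            comp[b] = ca
        elif ca != cb:
            for k, v in comp.items():
                if v == cb:
                    comp[k] = ca
    return comp


def _random_trajectory(
    rng: np.random.Generator,
    t: np.ndarray,
    center: float,
    center_sd: float,
    drift_amp: float,
) -> np.ndarray:
    """A subject/channel-specific instantaneous-frequency trajectory.

    Centre frequencies differ across individuals (e.g. the alpha peak
    varies by around half a hertz between children) and the slow drift has
    a random period and phase, so that distinct oscillators decohere over
    seconds — the property that keeps intersubject "apparent" coherence at
    its estimator-bias floor rather than near 1.
    """
    c = center + rng.normal(0, center_sd)
    period = rng.uniform(20.0, 60.0)
    phase = rng.uniform(0, 2 * np.pi)
    return c + drift_amp * np.sin(2 * np.pi * t / period + phase)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Simulate a two-group cohort with a controllable phase-coupling deficit.

    ``shared_mode`` mechanism: channels of a coupled pair mix a common
    alpha phase (weight w) with an independent one (weight sqrt(1 - w^2),
    keeping alpha variance constant); group 1 uses ``base_coupling``,
    group 2 ``base_coupling * group_effect``.  ``phase_coupling`` mechanism:
    the second channel of each pair is phase-driven by the first through a
    sin(phi_src - phi_tgt + pi/2.5) difference coupling whose amplitude
    (rad/s; values of ~5-15 give partial locking) is ``base_coupling``,
    scaled by ``group_effect`` in group 2.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_seg = spec.segment_count
    n = int(round(n_seg * spec.segment_length * spec.fs))
    t = np.arange(n) / spec.fs
    comp = _pair_components(spec.channel_labels, spec.coupled_pairs)
    driven = {b: a for a, b in spec.coupled_pairs}

    recordings: list[Recording] = []
    meta_rows = []
    sid = 0
    for g, (gname, n_sub) in enumerate(zip(spec.group_names, spec.n_per_group)):
        weight = spec.base_coupling * (1.0 if g == 0 else spec.group_effect)
        for _ in range(n_sub):
            sid += 1
            subject = f"S{sid:03d}"
            data = np.empty((len(spec.channel_labels), n))
            # one shared alpha phase per connected component of coupled pairs
            shared_phase = {
                c: _phase_from_trajectory(
                    _random_trajectory(rng, t, 11.0, 0.5, 0.5), spec.fs,
                    rng.uniform(0, 2 * np.pi),
                )
                for c in set(comp.values())
            }
            own_alpha = {
                ch: _phase_from_trajectory(
                    _random_trajectory(rng, t, 11.0, 0.5, 0.5), spec.fs,
                    rng.uniform(0, 2 * np.pi),
                )
                for ch in spec.channel_labels
            }
            for ci, ch in enumerate(spec.channel_labels):
                theta = np.cos(
                    _phase_from_trajectory(
                        _random_trajectory(rng, t, 5.5, 0.3, 0.4), spec.fs,
                        rng.uniform(0, 2 * np.pi),
                    )
                )
                if spec.mechanism == "shared_mode" and ch in comp:
                    w = weight
                    alpha = w * np.cos(shared_phase[comp[ch]]) + np.sqrt(
                        max(0.0, 1 - w ** 2)
                    ) * np.cos(own_alpha[ch])
                elif spec.mechanism == "phase_coupling" and ch in driven:
                    # driven channel: difference coupling to the driver's phase.
                    # A source-only term would modulate at the ~11 Hz driver
                    # frequency, placing FM sidebands outside every analysis
                    # band; the sin(phi_src - phi_tgt) form modulates at the
                    # slow beat frequency and is what same-band inference of
                    # directed coupling can actually resolve.
                    h = 1.0 / spec.fs
                    omega = 2 * np.pi * _random_trajectory(rng, t, 11.0, 0.5, 0.5)
                    src = own_alpha[driven[ch]]
                    ph = np.empty(n)
                    ph[0] = rng.uniform(0, 2 * np.pi)
                    for k in range(n - 1):
                        ph[k + 1] = ph[k] + h * (
                            omega[k] + weight * np.sin(src[k] - ph[k] + np.pi / 2.5)
                        )
                    alpha = np.cos(ph)
                else:
                    alpha = np.cos(own_alpha[ch])
                data[ci] = theta + alpha + spec.noise_sd * rng.standard_normal(n)
            rec = Recording(
                labels=list(spec.channel_labels),
                fs=spec.fs,
                data=data,
                meta={"subject": subject, "group": gname},
            )
            recordings.append(rec)
            meta_rows.append(
                {
                    "subject": subject,
                    "group": gname,
                    "age_months": int(rng.integers(40, 60)),
                    "n_segments": n_seg,
                    "segment_length_s": spec.segment_length,
                }
            )
    return Cohort(recordings, pd.DataFrame(meta_rows), spec)
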