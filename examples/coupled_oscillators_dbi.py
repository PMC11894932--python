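"""Recovering a unidirectional coupling function with Bayesian inference.

A phase oscillator X (5 Hz) drives P (8 Hz) through E*cos(phi_X + pi/2.5).
Windowed dynamical Bayesian inference on the two phase series should find
a forward coupling strength near E, a reverse strength at the noise floor,
and a coupling surface matching the generating function.
"""

import numpy as np

from phaseconn import (
    PhaseOscillatorSpec,
    coupling_series,
    coupling_surface,
    downsample_phase,
    fit_windows,
    generate_coupled_oscillators,
    mean_coefficients,
)

for E in (0.0, 5.0, 10.0):
    spec = PhaseOscillatorSpec(coupling=E, noise_sd_x=0.1, noise_sd_p=0.1,
                               duration=120.0, seed=1)
    osc = generate_coupled_oscillators(spec)
    phase_x, fs = downsample_phase(osc.phi_x, spec.fs, 40.0)
    phase_p, _ = downsample_phase(osc.phi_p, spec.fs, 40.0)
    fits = fit_windows(phase_x, phase_p, fs)
    series = coupling_series(fits)
    line = (f"E = {E:4.1f}:  X->P strength = {series.strength_a_to_b.mean():6.3f}   "
            f"P->X strength = {series.strength_b_to_a.mean():6.3f}")
    if E == 10.0:
        grid, q = coupling_surface(mean_coefficients(fits), 2, "a_to_b")
        A, _ = np.meshgrid(grid, grid, indexing="ij")
        corr = np.corrcoef(q.ravel(), (E * np.cos(A + np.pi / 2.5)).ravel())[0, 1]
        line += f"   surface corr vs E*cos(phi_X + pi/2.5) = {corr:.3f}"
    print(line)

print("Forward strength tracks E; the reverse direction stays at the E = 0")
print("noise floor, exposing the coupling's unidirectionality.")
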