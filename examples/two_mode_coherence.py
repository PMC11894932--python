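"""Time-localised wavelet phase coherence on a two-mode demonstration pair.

Two channels each carry a theta-like (~5.5 Hz) and an alpha-like (~11 Hz)
oscillation with slowly drifting frequency, plus independent noise.  The
alpha mode is shared between the channels only in the second half of the
record, so the 11 Hz coherence should jump at the onset — while the
first-half value shows the finite-window bias floor that the intersubject
surrogate subtraction exists to remove.
"""

import numpy as np

from phaseconn import (
    TwoModeSpec,
    WaveletParams,
    extract_phase,
    generate_two_mode_pair,
    time_localized_wpc,
    wavelet_transform,
)

spec = TwoModeSpec(duration=120.0, shared_onset=60.0, seed=0)
pair = generate_two_mode_pair(spec)

params = WaveletParams(fs=spec.fs, fmin=3.0, fmax=14.0, voices_per_octave=16)
phase_a = extract_phase(wavelet_transform(pair.a, params))
phase_b = extract_phase(wavelet_transform(pair.b, params))
tlc = time_localized_wpc(phase_a, phase_b)

k11 = int(np.argmin(np.abs(tlc.freqs - 11.0)))
row, ok = tlc.values[k11], tlc.valid_mask[k11]
first = row[ok & (tlc.times < spec.shared_onset)].mean()
second = row[ok & (tlc.times >= spec.shared_onset)].mean()

print(f"11 Hz time-localised WPC, first half  (no shared mode): {first:.3f}")
print(f"11 Hz time-localised WPC, second half (shared mode):    {second:.3f}")
print("The first-half value is the 10-cycle-window bias floor, not genuine")
print("coherence; the second-half value ~1 reflects the common alpha phase.")
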