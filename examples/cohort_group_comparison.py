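"""Effective coherence and group statistics on a synthetic two-group cohort.

Group 1 subjects share an alpha-band mode between F3 and F4; in group 2 the
shared structure is removed (group_effect = 0).  Intersubject surrogates
set the per-frequency "apparent coherence" threshold; what survives the
subtraction is compared between groups with the rank-sum test.
"""

import numpy as np

from phaseconn import (
    CohortSpec,
    WaveletParams,
    actual_spectra,
    cohens_d,
    effective_coherence,
    extract_phase,
    generate_cohort,
    intersubject_pool,
    rank_sum,
    wavelet_transform,
)

spec = CohortSpec(
    n_per_group=(13, 9),
    channel_labels=("F3", "F4"),
    coupled_pairs=(("F3", "F4"),),
    group_effect=0.0,          # coupling removed in group 2
    segment_length=32.0,
    fs=64.0,
    seed=2,
)
cohort = generate_cohort(spec)
params = WaveletParams(fs=spec.fs, fmin=3.5, fmax=12.0, voices_per_octave=12)

values = {}
for group in ("group1", "group2"):
    recs = [r for r in cohort.recordings if r.meta["group"] == group]
    subjects = [
        {ch: extract_phase(wavelet_transform(r.channel(ch), params))
         for ch in ("F3", "F4")}
        for r in recs
    ]
    pool = intersubject_pool(subjects, ("F3", "F4"))
    spectra = actual_spectra(subjects, ("F3", "F4"))
    values[group] = np.array([effective_coherence(s, pool) for s in spectra])
    print(f"{group}: n = {len(recs)}, surrogate pool = {pool.count} spectra, "
          f"median effective coherence = {np.median(values[group]):.4f}")

p = rank_sum(values["group1"], values["group2"])
d = cohens_d(values["group1"], values["group2"])
print(f"rank-sum P = {p:.4f}, Cohen's d = {d:.2f}")
print("Group 2's effective coherence collapses toward zero once the")
print("surrogate level is subtracted; the rank-sum test flags the deficit.")
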