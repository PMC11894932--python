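# phaseconn

Time-resolved, phase-based EEG connectivity analysis: continuous Morlet
wavelet transforms, time-localised wavelet phase coherence (WPC) with
intersubject-surrogate thresholding, global synchrony via the wavelet mean
field, and effective (directed) connectivity via windowed dynamical
Bayesian inference (DBI) of phase-coupling functions — plus the group
statistics and synthetic-data generators needed to exercise and calibrate
every stage.

## Who this is for

Researchers comparing resting-state EEG connectivity between groups
(e.g. clinical cohort vs controls) who need measures that are robust to
movement artefacts and faithful to the non-autonomous nature of neural
oscillations. All measures here depend on instantaneous *phase* only:
multiplying any channel by a positive constant changes no output.

## The measures

**Wavelet phase coherence.** With Morlet wavelet coefficients
`W(f, t)` (resolution parameter `ω_c = 4` cycles per envelope sigma,
log-spaced frequencies) and phases `φ = arg W`, the time-localised
coherence at `(t, f)` is the modulus of the mean unit phasor of the phase
difference over a centred window of 10 cycles:

    WPC(t, f) = (f/10) · | ∫_{t−5/f}^{t+5/f} e^{i(φ¹ − φ²)} ds |

1 means a constant phase difference (perfect coherence), 0 a uniformly
drifting one. Because short windows give unrelated signals substantial
apparent coherence, significance comes from *intersubject surrogates*: for
n subjects, the n² − n cross-subject pairings of the two probes (which
cannot share genuine coherence) set a per-frequency threshold; the mean is
subtracted, negatives are clipped, and the 3.5–12 Hz band average yields
one **effective coherence** per subject and probe pair.

**Coupling functions and coupling time.** Phases of two probes follow

    dφ_i/dt = Σ_k c_k^{(i)} Φ_k(φ_A, φ_B) + ξ_i

with `Φ` a second-order Fourier basis on the torus. A Gaussian posterior
over `c` is inferred in 3 s sliding windows (propagation constant 0.2
carries information between windows); the directional strength is the norm
of the cross-terms in the target's equation, and **coupling time** is the
percentage of windows whose strength exceeds the 95th percentile of the
intersubject surrogate pool. Group differences are assessed with rank-sum
tests, segment-shuffling repeats, Friedman/Kruskal–Wallis consistency
checks, Cohen's d, and a sensitivity (minimum-detectable-effect) analysis.

## Worked example

`examples/coupled_oscillators_dbi.py` simulates a 5 Hz phase oscillator X
unidirectionally driving an 8 Hz oscillator P through
`E·cos(φ_X + π/2.5)` and infers the coupling back from the phases:

```
E =  0.0:  X->P strength =  0.104   P->X strength =  0.095
E =  5.0:  X->P strength =  4.917   P->X strength =  0.096
E = 10.0:  X->P strength =  9.807   P->X strength =  0.097   surface corr vs E*cos(phi_X + pi/2.5) = 0.998
```

The forward strength recovers E to a few percent; the reverse direction
stays at the E = 0 noise floor (unidirectionality); the reconstructed
coupling surface correlates 0.998 with the generating function.

`examples/cohort_group_comparison.py` builds a 13-vs-9 synthetic cohort in
which group 2 lacks the shared F3–F4 alpha mode:

```
group1: n = 13, surrogate pool = 156 spectra, median effective coherence = 0.0371
group2: n = 9, surrogate pool = 72 spectra, median effective coherence = 0.0170
rank-sum P = 0.0043, Cohen's d = 1.42
```

The 156 surrogate spectra are the 13² − 13 cross-subject pairings; after
subtracting their mean, group 2's effective coherence collapses toward
zero and the rank-sum test flags the deficit. The other examples cover the
two-mode coherence demonstration, the sensitivity analysis (minimum
detectable d = 1.387 for 13 vs 9 at power 0.80), and the full
file-in/file-out pipeline.

A thin CLI wraps the same library calls:

```bash
phaseconn simulate --out cohort/ --n-per-group 13,9 --pairs F3-F4
phaseconn wpc cohort/S001.tsv --pairs F3-F4 --band 3.5:12
phaseconn dbi cohort/S001.tsv --pairs F3-F4 --window 3 --prop 0.2
phaseconn run --config cfg.yaml --out results/
```

## Layout

```
src/phaseconn/
  timefreq.py        Morlet wavelet transform, COI, phases, band power
  coherence.py       time-localised/averaged WPC, wavelet mean field
  surrogates.py      intersubject pools, effective coherence, thresholds
  dbi.py             windowed Bayesian inference of coupling functions
  group_stats.py     rank-sum, Friedman, Kruskal-Wallis, Cohen's d,
                     segment shuffles, sensitivity analysis, age regression
  synthetic_data.py  two-mode pairs, coupled oscillators, cohorts
  pipeline_io.py     recordings, EDF/delimited/.mat readers, preprocessing,
                     segmentation, the end-to-end pipeline
  cli.py             thin command-line interface
docs/methods.md      models, conventions, defaults, limitations
examples/            one narrative script per capability
```
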