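# cmcoherence

Corticomuscular and intermuscular coherence analysis for trial-based
EEG/EMG recordings, with a synthetic common-drive generator that provides
ground truth for every stage of the pipeline.

## The problem

During steady voluntary contraction, the motor cortex drives spinal
motoneurons through the corticospinal tract with an oscillatory component in
the beta band (15–30 Hz).  That shared drive makes the EEG over the motor
cortex coherent with the EMG of the active hand muscles (corticomuscular
coherence) and makes the EMGs of two muscles coherent with each other
(intermuscular coherence).  Changes in this coupling — for example after
motor practice — are a window on corticospinal plasticity.

This package implements the full estimation chain for such experiments:

1. **Preprocessing** — zero-phase 5–1000 Hz band-pass, average reference,
   full-wave rectification of EMG, extraction of per-trial hold-phase
   windows (0.85–2.85 s after ramp onset), per-segment demeaning and
   unit-variance normalization.
2. **Spectral estimation** — auto- and cross-spectra by averaging
   rectangular-taper periodograms over the L disjoint trial segments.
   Coherence is |f_xy(λ)|² / (f_xx(λ) f_yy(λ)), with the exact null
   confidence limit 1 − α^{1/(L−1)}.  The cumulant density q_xy(u) — the
   inverse transform of the cross-spectrum, a cross-correlogram analogue —
   localizes the corticospinal conduction delay (~11 ms) as its peak lag.
3. **Pooled inference** — segment-count-weighted pooling of spectra across
   subjects (equivalent to estimating on the union of all segments), and
   the extended χ² difference-of-coherence test: per frequency bin,
   z_i = tanh⁻¹√coh_i with var 1/(2n_i), X² = Σ w_i (z_i − z̄)² on k−1 df
   (threshold 3.84 for two groups at α = 0.05).
4. **Band statistics** — per-subject cumulated Σ ln coh over the beta band
   (31 bins at 0.5 Hz resolution), pre/post change tables ready for
   external mixed-model software, and Pearson correlations.
5. **Synthetic data** — sessions of 3 × 50 ramp-hold force-tracking trials
   (5.5 N, 3 s hold, 3 s rest, 2048 Hz) in which one EEG and two EMG
   channels receive a common band-limited drive with known gains and
   conduction delays.  In linear mode the model's coherence has a closed
   form, so estimator output can be checked against theory.

## Worked example

```python
import numpy as np
from cmcoherence import (
    DriveModelParams, ProtocolParams, PreprocessConfig,
    generate_session, preprocess, estimate_spectra, analyze,
    find_cumulant_peak, band_log_sum,
)

params = DriveModelParams(seed=42)          # beta-band drive, 11 ms delays
session = generate_session(params, ProtocolParams(), "S01", "pre")
cfg = PreprocessConfig(rectify_emg=False)   # linear-mode EMG
segs = preprocess(session, cfg, ("C4", "APB"))
res = analyze(estimate_spectra(segs))

band = (res.freqs_hz >= 15) & (res.freqs_hz <= 30)
print(f"L={segs.L} segments of T={segs.T} samples")
print(f"beta coherence mean {res.coh[band].mean():.3f} "
      f"(95% null limit {res.cl95:.4f})")
lag, q, sig = find_cumulant_peak(res, (-0.05, 0.05))
print(f"cumulant peak at {1e3 * lag:.2f} ms (significant: {sig})")
print(f"beta log-coherence sum {band_log_sum(res).value:.1f}")
```

prints

```
L=150 segments of T=4096 samples
beta coherence mean 0.153 (95% null limit 0.0199)
cumulant peak at 11.72 ms (significant: True)
beta log-coherence sum -63.4
```

The in-band coherence (~0.15 on average, ~0.2 at the band centre) matches
the generator's closed-form prediction; the cumulant peak recovers the
11 ms corticospinal delay; the band log-sum is the per-subject scalar used
for group comparisons.

A full simulated pre/post practice experiment (16 subjects, practice and
control sessions, all three channel pairs, TSV outputs and run log):

```bash
cmcoh run --out results/experiment --seed 1
```

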