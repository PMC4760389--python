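# Methods

This note documents the generative model, the estimator conventions, the
defaults and the numerical choices, in the package's own words.  No number
quoted here is asserted anywhere except where the tests or
`scripts/acceptance.py` compute it at run time.

## Generative model (synthetic sessions)

A single latent "common drive" c(t) stands in for the beta-band component
of the corticospinal output: white Gaussian noise, band-pass filtered to
[15, 30] Hz with a 4th-order Butterworth applied forward–backward (zero
phase), then re-standardized to zero mean and unit variance.  Zero phase
matters because any phase distortion would bias the cumulant peak used for
delay estimation.  The forward–backward pass squares the magnitude
response, so the drive PSD is |H(f)|⁴ normalized to unit total power; with
a 4th-order filter a few percent of the power sits in the skirts just
outside the corners, which is measured by the tests rather than idealized
away.

Channels:

- EEG (C4): `g_eeg · c(t) + noise`,
- EMG (APB, FDI), **linear mode**: `g_k · c(t − δ_k) + noise_k`,
- EMG, **modulation mode**: `(1 + m_k · c(t − δ_k)) · carrier_k(t)` with a
  broadband Gaussian carrier, the envelope clipped at zero (a warning is
  logged if more than 1% of samples clip),
- FORCE: ramp (0.5 s) – plateau (5.5 N, 3 s) – rest (3 s) template plus
  4 Hz low-passed tracking noise (SD 0.1 N).

The two EMG modes serve different purposes.  Linear mode admits the closed
form used for parameter recovery: with two-sided drive PSD S_c(f) and
white-noise PSD σ²/fs per channel,

    coh(f) = Π_{ch ∈ pair} g²_ch S_c(f) / (g²_ch S_c(f) + σ²_ch/fs),

implemented in `theoretical_coherence` with S_c(f) taken from the actual
filter response, and it is analyzed with rectification disabled —
full-wave rectifying a zero-mean linear mixture destroys the linear
coupling.  Modulation mode emulates an interference-pattern EMG whose
*envelope* carries the drive; that is the regime in which rectification is
physiologically meaningful, so it is the default for the end-to-end
simulated experiment, validated qualitatively (in-band coherence above the
null limit, increasing with modulation depth).

Defaults: sampling 2048 Hz; 3 blocks × 50 trials; conduction delays
11 ms for both muscles; unit noise SDs; gains 0.1, chosen once so that
beta-band coherence is near 0.2, the order of magnitude of real
corticomuscular coherence during steady contraction.
`gain_for_band_coherence` inverts the closed form at the band centre when
an experiment needs a specific coherence level.  Each session draws its
RNG stream from (seed, subject, condition, session label) via CRC-32 keys,
so regeneration is bit-identical and pre/post measurements differ only
where the model says they differ.

What the generator does *not* emulate: motor-unit spike trains and MUAP
shapes, 1/f EEG background, artifacts, volume conduction, or a full 64-
channel montage (average referencing is a logged no-op with one EEG
channel).  Passing tests therefore demonstrate correctness of the
estimator chain under a stationary Gaussian common-input model, not
robustness to real-world contamination.

## Preprocessing

Fixed stage order: band-pass filter → average reference → full-wave
rectification (EMG only) → window extraction → per-segment demean →
per-channel normalization.  The order is part of the contract because
rectification and normalization do not commute.

- Filter: 4th-order Butterworth band-pass 5–1000 Hz, forward–backward
  (zero phase), applied to EEG/EMG only; the low-pass corner is clipped
  below Nyquist with a warning if needed.
- Windows: [onset + 0.85 s, onset + 2.85 s), half-open in samples
  (T = 4096 at 2048 Hz); trials whose window leaves the record are dropped
  with a warning, and fewer than two usable trials is an error.
- Rectified EMG is demeaned per segment before spectral estimation:
  rectification introduces a large DC offset, and the spectral theory
  assumes zero-mean series.  This choice is toggleable
  (`demean_segments`).
- Normalization is per channel across all segments of a session (pooled
  variance 1), not per segment, preserving amplitude structure across
  trials.  Coherence is invariant to this scaling; it matters only for
  cumulant units.

## Spectral estimation

Disjoint segments (= trials), rectangular taper, no overlap.  This is the
classical trial-averaged periodogram scheme; it is kept deliberately
because the coherence null limit 1 − α^{1/(L−1)} is exact for it, whereas
tapering or overlap would change the effective degrees of freedom.
Densities follow the two-sided convention sampled at the non-negative DFT
bins (|X_k|²/(T·fs)); summing the two-sided spectrum times the bin width
fs/T reproduces the average segment variance to rounding error (a test
asserts 1e-9 relative).  Bins with zero auto-power are flagged undefined
rather than set to 0 or silently NaN.  Bin 0 is excluded from all band
statistics.

The cumulant density is the inverse DFT of the two-sided cross-spectrum,
scaled to the cross-covariance of the input series, with the convention
q(u) = cov(x(t), y(t+u)): a positive peak lag means the second channel
lags the first, so the EEG→EMG conduction delay appears at +11 ms.  Its
95% band uses the lag-independent asymptotic variance
(fs/T)² Σ_k f_xx f_yy / L, which a Monte-Carlo test confirms within 15%
(measured agreement is ~1%).

### Delay resolution

With a drive confined to 15–30 Hz the cumulant is an oscillatory wavelet,
and the location of its |q| maximum carries noise-driven jitter: at
realistic coherence (~0.2), Monte Carlo puts the peak-location SD near
0.9 ms even for an estimate pooled over 16 subjects × 150 trials — the
same ±1 ms scale as the 10–12 ms window such experiments report.  The
estimator itself is exact: in the noiseless limit and for a pure delay the
peak sits on the true lag to the sample.  The delay-recovery validation
therefore reports the mean pooled-peak lag over six replicate 16-subject
experiments, whose sampling SD (~0.4 ms) makes the check stable.

## Pooling and the difference-of-coherence test

Pooling operates on spectra with segment-count weights
Σ_i L_i f̂_i / Σ_i L_i, which is *identical* to averaging periodograms over
the union of all segments — a brute-force oracle the tests exploit (exact
to 1e-12).  Pooled coherence and the pooled cumulant are computed from the
pooled spectra, with confidence limits evaluated at n_total = Σ L_i.

The extended χ² test compares k independent pooled estimates per bin via
z_i = tanh⁻¹√coh_i, weight w_i = 2 n_i, X² = Σ w_i (z_i − z̄)² on k − 1 df.
The 1/(2n) variance is used without small-sample correction; calibration
is verified empirically instead: at 2 × 16 subjects and true in-band
coherence 0.2, the measured per-bin type-I error at the 3.84 threshold is
~0.06–0.07, within the accepted [0.03, 0.08] band (the transform is known
to run slightly liberal at finite n).  Coherence is clipped to 1 − 1e-12
before the transform; bins undefined in any group propagate NaN and are
never flagged.  Per-bin testing carries no multiple-comparison correction
across frequencies — band-level summaries are the job of the band
statistics.

## Band statistics

The per-subject scalar is Σ ln coh over the inclusive band bins (natural
log; the base is a documented choice, any base rescales all values
equally).  At 0.5 Hz resolution the 15–30 Hz band has exactly 31 bins.
Zero or undefined coherence inside the band raises with a pointer to the
offending frequencies rather than propagating −∞.  The pre/post table
demands exactly one pre and one post entry per (subject, session, pair)
and exports post − pre change scores; model fitting on those tables
(mixed models, ANOVA) is left to external statistics software by design.

## Problem sizes used in validation

The validation experiments default to the study conditions: L = 150 trials
of T = 4096 samples at 2048 Hz and 16 subjects per group.  The
Monte-Carlo replicate counts (100 for calibration and power, 6 pooled
replicates for delay recovery, 20 sessions for parameter recovery) were
chosen so each quantity's sampling error is small against the band it is
checked into.  Heavy Monte-Carlo loops sample the drive model directly as
hold-phase segments (`simulate_segment_set`), which is the same
statistical model as full session generation followed by window
extraction; the full session path (force protocol, filtering, windowing)
is exercised by the parameter-recovery experiment and the pipeline tests.

## Known limitations

- The closed-form coherence assumes the linear EMG mode; no closed form is
  claimed for modulation mode.
- The asymptotic cumulant band is lag-independent and ignores bin-to-bin
  correlation introduced by windowing; the Monte-Carlo check bounds the
  resulting error at the percent level under the model.
- EDF/BDF input relies on a trigger channel for trial onsets; recordings
  with event annotations instead are not parsed.
- Coherence bias at true coherence 0 is ≈ 1/L, so small-L records inflate
  band log-sums; compare records only at matched L (pooling handles this
  by weighting).
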