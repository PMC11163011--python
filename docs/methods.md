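# Methods

`cidn` re-creates, at desk scale, the full evaluation pipeline used when a
single-microphone deep-learning noise-reduction algorithm is developed for
cochlear-implant (CI) listeners: controlled speech-in-noise mixture
construction, two trainable enhancement architectures, objective
intelligibility/quality metrics, and the statistical machinery used on both
objective and behavioral scores.  This note records the models, the
parameter choices that matter, and the limits of what the synthetic
pipeline can demonstrate.

## Synthetic audio (synthgen)

Real experiments draw targets from read-speech corpora and maskers from
recorded noise.  The generators here are parametric stand-ins that keep the
statistical contrasts the algorithms exploit, with none of the download or
licensing burden:

* **Speech-like targets** — a harmonic source at f0 (60–400 Hz, 1/k
  harmonic roll-off, seeded random phases, 1% vibrato, low-level aspiration
  noise) filtered through second-order resonators at the formant centers,
  then gated by a syllabic envelope (raised-cosine bursts at 2–8 Hz, ~70%
  duty cycle, inter-syllable floor at −60 dB).  This yields harmonicity,
  formant structure, and strong amplitude modulation with genuine silent
  gaps — the three properties mask-based enhancement feeds on.
* **Speech-shaped stationary noise** — white Gaussian noise shaped in the
  frequency domain by a documented speech-weighted envelope (flat to 1 kHz,
  −6 dB/octave above, floored at −60 dB beyond 6 kHz).  The envelope is a
  configurable approximation of the standardized CCITT spectrum; a
  tabulated curve can be substituted.
* **Sparse environmental noise** — a Gaussian floor (σ = 0.02) plus
  Poisson-timed band-limited bursts (30–120 ms, 0.3–4 kHz, 8–18× floor
  amplitude).  At 2 events/s over 10 s the sample kurtosis exceeds 4;
  with no events it reverts to Gaussian (kurtosis ≈ 3).
* **N-talker babble** — a sum of pairwise-distinct talkers (f0 separated by
  ≥ 5 Hz), each RMS-equalized to 0.05 before summation.  No post-sum
  normalization is applied, so component additivity is exact and
  variance-additivity / asymptotic-stationarity properties are analyzable.

All generators are pure functions of (arguments, seed).

## Mixing (mixer)

The target is scaled so its *active speech level* — RMS over 50 ms,
half-overlapping frames whose energy is within 40 dB of the loudest frame —
sits at −29 dBFS.  This reading of the standard active-level anchor is an
approximation of the ITU-T P.56 measurement; both the anchor and the
activity threshold are arguments.  SNR is defined as target active level
minus overall RMS level of the noise after a seeded-offset crop, and the
noise gain is solved in closed form, so the achieved SNR equals the request
to float precision (the package contract allows 0.1 dB).  Mixtures are the
raw sample-wise sum, stored as float without a clipping guard, which keeps
`mixture − target − noise ≡ 0` exactly.

Two consequences worth knowing: with a gapped (speech-like) target the
mixture's SI-SDR sits ~0.5–1 dB *below* the nominal SNR, because SI-SDR
uses total rather than active energy; the SNR convention (active/overall)
is recorded in manifests so an overall/overall alternative can be selected.

Training manifests enforce equal SNR representation (each SNR appears
⌊n/k⌋ or ⌈n/k⌉ times per noise kind, remainder placed by seed).  The
behavioral plan enumerates the 13-condition grid — {unprocessed, RNN-style,
SepFormer-style} × {speech-shaped noise, two-talker babble} × {+5, +10 dB}
plus quiet — with disjoint sentence allocations.

## Time–frequency substrate (spectral)

Analysis: Hamming-windowed frames, window 512 samples, hop 256, FFT 512 at
16 kHz (32 ms / 16 ms).  Synthesis: weighted overlap-add with window-square
normalization, which is an exact inverse for any strictly positive window;
round-trip error is at float precision (contract ≤ 1e−6 relative).
Masks are hard-typed: any gain outside [0, 1] is a constructor error, never
a silent clip.  Mask application multiplies the noisy magnitude and reuses
the noisy phase — the standard choice for magnitude-mask enhancement; phase
estimation is out of scope.  The ideal ratio mask |S|/(|S|+|N|) (0/0 := 0)
is provided purely as a test oracle and performance upper bound.

## Recurrent enhancer (rnn_enhancer)

Features are add-one-log magnitudes, log(1+|X|), width 257 (one-sided bins;
a 512-wide two-sided variant is selectable).  The network is a stack of
bidirectional LSTM layers, each followed by a ReLU projection, with a
logistic output layer so the emitted gains lie in [0, 1] *architecturally*
(a ReLU-then-clamp output is selectable).  Reference-scale defaults are two
256-unit layers with 128-unit projections, learning rate 1e−4, 100 epochs;
the test scale is one 32-unit layer, 5 epochs, learning rate 3e−3 —
appropriate for ~300 Adam steps on 64 one-second mixtures.  The loss is the
mean squared error between the masked noisy magnitude and the clean
magnitude, computed in the linear-magnitude domain (a log-domain option
exists).  Training records per-epoch train/validation losses and restores
the best-validation parameters.  A causal (uni-directional) mode exists but
is not exercised by the benchmarks.

Because no deep-learning framework is part of the dependency set, both
models run on a small reverse-mode autodiff engine written for this package
(`autodiff.py`, float64, single-threaded), which makes training bit-for-bit
reproducible under a fixed seed.  Gradients of every composite operation
are tested against central differences.

## Dual-path separator (sepformer_lite)

A dimension-reduced implementation of the dual-path transformer separation
architecture: learned conv encoder (kernel 16, stride 8, ReLU latent),
per-frame layer norm + linear, chunking along time (50% overlap; chunk and
its overlap-add inverse are an exact pair pre-transformation), alternating
intra-chunk and inter-chunk pre-norm transformer blocks with sinusoidal
positional encodings, PReLU + linear, overlap-add, and two feed-forward
mask heads (ReLU clamped at 1) emitting foreground/background masks; a
bias-free transposed-conv decoder returns waveforms (a zero latent decodes
to exact silence).  Reference scale is 256 filters / chunk 250; the test
scale is 64 filters / chunk 50 with one intra and one inter block (~1e5
parameters), trained 5 epochs on 64 half-second mixtures.

Training uses the same MSE-on-spectra objective family as the enhancer,
applied between the foreground estimate's **complex** STFT and the clean
target's (differentiable STFT via DFT matrices); roles are fixed as
target/noise so no permutation-invariant loss is required, and a
negative-SI-SDR loss flag is available.  The complex — rather than
magnitude-only — difference is a deliberate design choice: here the decoder
synthesizes the waveform, so a magnitude-only loss leaves the output phase
entirely unconstrained and the held-out waveform SI-SDR flips sign from
seed to seed (observed −2.4 to +3.6 dB across seeds in development).  The
complex-spectrum MSE equals a windowed time-domain MSE by Parseval,
constrains the phase, and makes the tiny-scale benchmark stable (+1.8 to
+2.2 dB across seeds at 5 epochs, against the recurrent enhancer's >3 dB
with its noisy-phase resynthesis).  Mask-head biases are initialized at 0.5
so the clamped-ReLU heads start with live gradients in every unit; the
tiny-scale learning rate default is 3e-3.

## Metrics (metrics)

* **SI-SDR** from its defining projection: α = ⟨e, r⟩/⟨r, r⟩ after mean
  removal, 10·log10(‖αr‖²/‖e−αr‖²), capped at +140 dB when the error
  energy underflows.  Scale-invariance and the orthogonal-equal-energy →
  0 dB identity are exact.
* **STOI** re-implemented from the published pipeline: resample to 10 kHz,
  drop frames 40 dB below the loudest, 15 one-third-octave bands from
  150 Hz over 256-sample Hann frames (512-point FFT, 50% hop), 384 ms
  segments, per-segment normalization with the −15 dB clipping bound,
  per-unit linear correlation, global mean.  Constants are module-level
  and exposed for sensitivity work.
* **PESQ** is an adapter contract only: a conforming external backend can
  be registered; its scores are validated against [−0.5, 4.5]; with no
  backend the metric is reported as absent, which the evaluation grid and
  statistics handle by dropping the metric.

## Evaluation grid and nonparametric statistics (evalgrid)

`evaluate_grid` produces one row per item × processing × metric, scoring
the raw mixture for the unprocessed condition.  Paired comparisons use the
two-sided Wilcoxon signed-rank test (zero differences excluded; exact null
for n ≤ 25 without ties, else normal approximation with continuity
correction — the implementation delegates to the standard scipy routine and
is tested against a full sign-enumeration oracle).  Multiplicity over the
planned family (default 3 metrics × 2 maskers × 3 SNRs × 3 processing
pairs = 54) is controlled by Benjamini–Hochberg FDR without dependency
correction.

## Behavioral statistics (behavioral)

The intelligibility model is a linear mixed model on the raw percent scale
(a logit option is off by default): processing + SNR + masker +
processing:masker as sum-coded fixed effects and a participant random
intercept, fitted by REML (statsmodels MixedLM; a gradient-free fallback
handles zero-variance boundaries).  Quiet is excluded from this model (its
masker/SNR factors are undefined) and included in the quality model, which
is processing × masker with the same random-intercept structure.

* **Type-III tests** are joint Wald F tests per sum-coded term.
* **EMMs** are fixed-effect predictions averaged over a balanced reference
  grid, with delta-method SEs from the fixed-effect covariance.  On a
  balanced design with a model saturated in the grid factors, the EMM
  equals the raw cell mean exactly (asserted in tests).
* **Degrees of freedom**: rather than a Satterthwaite approximation, the
  package uses a containment-style rule — n_obs − n_participants for
  within-participant quantities (contrasts, F tests; 156 − 13 = 143 at the
  reference design) and n_participants − 1 for EMM intervals, whose
  variance is dominated by the participant-intercept component.  Simulation
  shows 95% EMM intervals then achieve ~96% empirical coverage at 13
  participants; a normal-approximation fallback would undercover (~93%).
* **Contrasts** are all pairwise EMM differences within each masker × SNR
  stratum, with a Tukey (studentized-range) family adjustment by default
  (none/BH selectable).
* **Stepwise AIC**: the improvement over unprocessed is modeled with
  masker + algorithm as base terms and demographics as candidates; a
  bidirectional search (single add/drop moves, maximum-likelihood fits,
  participant intercept retained) minimizes AIC and returns the full
  trace.  Known limitation: per-term AIC selection admits a null predictor
  whenever its likelihood-ratio statistic exceeds 2 — about a 16–20%
  chance per term — so with six candidate demographics the search retains
  at least one null term in well over half of replicates.  This is a
  property of AIC-based selection itself, not of the implementation.

The behavioral generator draws score(p, cell) = cell mean + participant
intercept + residual, truncated to [0, 100].  Default cell means are in the
range published for adult CI users on sentence recognition in noise
(mid-50s overall, ~15-point SNR effect, 12–21-point algorithm gains largest
in two-talker babble); default variance components (participant SD 15,
residual SD 12) imply the ~5.3-point EMM standard errors such studies
report at 13 participants.  Truncation shifts boundary-adjacent cell means
by up to ~1 point, which the parameter-recovery oracle accounts for
analytically (mean of the clipped normal).  What the generator does not
emulate: psychometric (binomial) score variance, floor/ceiling
compression beyond simple clipping, serial learning effects, or real
demographic structure — so passing tests certify the statistical machinery,
not any claim about real listeners.

## Problem sizes in the test and acceptance runs

Chosen so the full pipeline exercises every component on one CPU: learning
smoke runs use 64 training mixtures (1 s for the enhancer, 0.5 s for the
separator), 8 validation and 12 held-out items, 5 epochs; the demo pipeline
uses 64 mixtures across two noise kinds, a 2 masker × 3 SNR × 6 item
evaluation grid, and a 13-participant simulated behavioral table; the
statistical calibration uses 500 simulation replicates (recovery/coverage)
and 40–100 replicates for selection-rate estimates.  Reference-scale
settings (5590 mixtures per noise type, 100 epochs, 256-unit/256-filter
models) remain expressible through the same configs.

## Known limitations

* Synthetic talkers carry no phonetic content; STOI values on them are
  internally consistent but not comparable to corpus speech.
* The magnitude-domain separator loss bounds waveform SI-SDR (see above).
* PESQ is absent unless a licensed backend is registered.
* The mixed-model denominator-df rule is a documented approximation;
  exact Satterthwaite/Kenward–Roger df are not implemented.
* Exact Wilcoxon p-values require tie-free ranks; midrank ties fall back
  to the corrected normal approximation at any n.
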