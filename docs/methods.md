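# Methods

This note documents the models, numerical choices and known limitations of
`lcmem`, in the order the pipeline runs them.

## Behavioral model and scoring

Recognition follows the equal-variance Gaussian SDT model: new-item
familiarity ~ N(0, 1), old-item ~ N(d′, 1), "old" responses when familiarity
exceeds d′/2 + c.  Hence hit rate = Φ(d′/2 − c) and false-alarm rate =
Φ(−d′/2 − c), the identities the generator round-trip tests rely on.
Extreme observed rates are corrected by the 1/(2N) rule before the z
transform (a log-linear +0.5/+1 correction is available behind a flag;
1/(2N) is the default for its deterministic, widely cited lineage).  The
likelihood-ratio bias is β = exp(d′·c) exactly, and the implementation
asserts this identity rather than recomputing β from densities.

Recollection (choosing the correct name among three previously seen options)
is modelled as Bernoulli given a hit; its chance level is 1/3.  Two
recollection rates are reported: correct names / all old faces (raw) and
correct names / correctly recognized old faces.  The bias correction
regresses the raw recollection rate on β across subjects, separately per
valence, by ordinary least squares; residuals are re-centered at the sample
mean (the re-centering constant is not dictated by the procedure — the mean
keeps corrected rates on the original percentage scale and leaves group
medians interpretable).  A robust Huber-M variant is deliberately not the
default: OLS residuals are what enter the downstream group tests.  With
constant bias the slope is unidentifiable and the rates pass through
unchanged with a warning.

Wilcoxon signed-rank statistics use the normal approximation
Z = (W⁺ − n(n+1)/4 ± ½) / √(n(n+1)(2n+1)/24 − Σ(t³−t)/48), dropping zero
differences.  Note that the tie term matters even in "clean" situations: a
constant paired shift ties *all* absolute differences, so the maximal |Z|
for n pairs is larger than the no-tie closed form.

## Beat cleaning and HRV

Cleaning applies, per interval measured from the last kept beat:

1. rate bound: intervals implying > 200 bpm reject the beat (spurious
   detection); intervals implying < 25 bpm keep the beat but flag the
   interval as a gap (missed beats are a data hole, not a bad beat);
2. adaptive rule: intervals more than 13 % (configurable) *below* the
   running mean of the last 10 accepted intervals reject the beat.
   Intervals far above the mean are kept but excluded from the running mean.

The asymmetry (short ⇒ artifact, long ⇒ gap) is what makes the filter
idempotent: measuring every interval from the last kept beat means a second
pass sees exactly the interval sequence the first pass produced and rejects
nothing.  The 13 % default mirrors standard adaptive HRV filters; with
realistic R-R variability (CV ≈ 4–5 %) its false-rejection rate is below 1 %
per beat.

rMSSD is computed on raw accepted intervals only — never on the interpolated
series, which smooths successive differences — and skips differences
touching gaps or interval outliers.  The HRV series proper (successive R-R
differences, ms) is cubic-spline interpolated onto the working grid with
knots at the later beat of each difference pair.  A stage is unusable when
more than 10 % of grid points fall inside gaps.

ΔsAA = stage-end sample − stage-beginning sample on the seven-sample saliva
schedule (before bore, before baseline, before/after encoding, before/after
recollection, +30 min).  The pairing of samples to stages is configurable;
the default maps baseline → (pre-baseline, pre-encoding), encoding →
(pre, post encoding), consolidation → (post-encoding, pre-recollection),
recollection → (pre, post recollection).  Missing endpoints propagate to a
missing ΔsAA; zero is never imputed.

## Spectral estimation

Welch averaging with Hamming tapers, 20 % overlap (rounded to the nearest
sample), per-segment constant detrend, segment length 2·(bins − 1) samples,
giving `n_bins` one-sided bins on [0, fmax].  The default grid (90 bins on
0–0.5 Hz) requires a 1 Hz working rate, while BOLD is typically sampled at
TR = 2 s; inputs are therefore cubic-interpolated onto the working grid.
Interpolation cannot create information above the native Nyquist frequency —
bins beyond it contain only spectral images of the in-band content, and
because both series carry images of a *shared* latent those bins are
spuriously coherent.  The band-of-maximum-coherence search is therefore
restricted by default to frequencies below the smallest native Nyquist among
the inputs (0.25 Hz for TR = 2 s).

MSC is |P_AB|²/(P_AA·P_BB), clipped to [0, 1]; the phase is the
four-quadrant angle of P_AB = E[A·B*], positive when the first series leads.
With K averaged windows the MSC estimator is biased upward by roughly
(1 − C)²/K; recovery tests use series long enough (K ≳ 19) to keep this
below their tolerance, and readers of single-stage estimates at K ≈ 3–4
should expect that bias.  E[MSC] = 1/K for independent series with
non-overlapping windows is used as the null landmark throughout.

The band of maximum coherence is the 95 % percentile-bootstrap CI (5000
resamples, seeded) of the median per-subject argmax frequency; ties at the
argmax resolve to the lowest frequency.  Band summaries use the median MSC
and the circular median phase (the data angle minimizing total circular
distance) over in-band bins.  MSC rather than its square root is used for
"median coherence" everywhere, consistently.

AR(1) surrogates: lag-1 Yule–Walker fit (coefficient clipped into (−1, 1)
with a warning), redrawn with fresh Gaussian innovations and variance
matched to the original.  The null distribution collects band-median MSC
over `n_surrogates` independent surrogate pairs; p-values use the
(1 + exceedances)/(1 + n) convention.  Calibration at α = 0.05 over 1000
independent AR(1) pairs sits near 0.05 (asserted within [0.03, 0.07]).

Partial coherence comes from the inverse spectral matrix G = S⁻¹ per bin:
|G_ij|²/(G_ii·G_jj); near-singular bins are ridge-regularized with a
warning.  With an empty conditioning set this reduces exactly to MSC.

## Association statistics

Repeated-measures correlation uses the ANCOVA formulation (subject fixed
effects plus a common slope); r_rm carries the slope's sign,
df = N_obs − n_subjects − 1, and the p-value comes from the F test of the
common slope.  The bootstrap resamples *subjects* with replacement
(degenerate single-subject resamples are redrawn) and reports the percentile
CI — bootstrap for the interval, F test for the p, mirroring how both are
usually reported together.

Stage models are random-intercept linear mixed models fitted by maximum
likelihood (statsmodels performs the optimization; this package owns the
model construction, treatment coding with baseline as reference, and
post-processing).  statsmodels provides no Satterthwaite degrees of freedom;
the reported df is the residual approximation
n_obs − rank(X) − (n_groups − 1), adequate for the balanced designs the
pipeline produces but *not* a Satterthwaite replacement for badly unbalanced
data.  Singular fits (e.g. zero residual variance) fall back to OLS with a
warning.  Tukey contrasts use estimated marginal means (continuous
covariates at their sample mean) and the studentized-range distribution;
with two levels the adjusted p equals the unadjusted one.

The coherence-by-frequency model treats frequency as a continuous fixed
effect (bin centers), stage as a factor, and their interaction; the
Johnson–Neyman region of significance solves |t(f)| = t_crit analytically
(quadratic in f) and is verified in the tests against a dense grid of
pointwise tests.  Boundaries are equivariant under linear rescaling of the
moderator.  FDR adjustment is Benjamini–Hochberg step-up.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated:

* **Cohort**: TR = 2 s, four stages (baseline, encoding, consolidation,
  recollection), 360 samples per stage (12 min; the paradigm's stages run
  roughly 6–15 min).  Stage length and coupling bandwidth were fixed from a
  design analysis of the Welch argmax sampling distribution before any
  acceptance checks and not revisited.
* **Trials**: 45 old faces per valence, 23/22 new (emotional/neutral),
  per-valence (d′, c) and recollection probability; default βs reproduce a
  liberal emotional response bias.
* **Coupling**: a unit-variance latent built by zeroing all out-of-band bins
  of a white-noise spectrum (an exact zero-phase band-pass); the partner
  copy is phase-shifted in the frequency domain, so the shift is exact at
  every in-band bin with no group-delay distortion.  Mixing solves the MSC
  definition as a shared-power ratio in closed form (see the module
  docstring), with AR(1) channel noise (φ = 0.3 by default, roughly the
  lag-1 autocorrelation of denoised high-resolution BOLD).  Band center
  0.2 Hz and width 0.02 Hz emulate a narrowband respiratory-sinus-
  arrhythmia-like peak inside the HF-HRV band (0.15–0.4 Hz).
* **Beats**: the coupled HRV latent is written into the R-R *level* series
  pre-divided by the successive-difference filter H(f) = 1 − e^{−i2πfm}
  (m = mean R-R), so the pipeline's differencing restores it at the target
  phase; white per-beat jitter acts as the HRV-side noise channel, with its
  differenced PSD entering the same closed-form mixing solution.  Because
  the beat clock drifts with the cumulative jitter, the latent is evaluated
  at the actual beat times via a short fixed-point iteration — evaluating at
  nominal times would smear the phase by the accumulated drift.  Artifacts
  displace a random 2 % of beats toward their predecessor, the signature of
  spurious pulse detections.
* **sAA**: log-normal (non-negative, right-skewed), median 50 U/ml,
  between-subject spread 0.4 log-units, 12 % measurement noise.  Stage
  effects are persistent steps applied from the stage-end sample onward, so
  a +60 consolidation step raises ΔsAA_consolidation by 60 without
  contaminating the next stage's difference.  A latent arousal factor per
  subject × stage raises the sAA step and shrinks R-R variability together,
  inducing the negative within-subject ΔsAA–rMSSD association the analysis
  stage estimates.
* **Seeding**: one global seed expands through counter-based
  `SeedSequence` spawn keys (namespace, subject, stage), so any subset of
  the cohort regenerates identically.
* **Amplitude scale**: ROI BOLD series are unit-variance; no statistic in
  the pipeline depends on the absolute BOLD scale.

What the generator does *not* emulate: respiratory confounds and their
coupling to HRV (respiratory sinus arrhythmia is represented only as the
band-limited latent), scanner artifacts, motion, non-stationarity within a
stage, ectopic-beat morphology, or circadian sAA trends.  Passing tests
demonstrate that the estimators recover their own generative model, not that
the model captures every property of real physiological recordings.

## Problem sizes and determinism

Tests and the acceptance script use 6–20 subjects, 240–360 samples per stage
and 100–2000 bootstrap/surrogate replicates — sizes chosen so the full
validation runs comfortably on a laptop while keeping Monte-Carlo error well
inside the asserted tolerances.  Every stochastic step (generator, bootstrap,
surrogates) flows from an explicit seed; `run_all` is bit-reproducible given
the dataset and `RunConfig.seed`, and every output table carries the
configuration hash and seed.

## Known limitations

* The mixed-model df approximation (above) understates uncertainty for
  strongly unbalanced designs.
* Coherence estimates at single-stage lengths (K ≈ 3–4 windows) carry the
  (1 − C)²/K upward bias and a high-variance argmax; group-level medians are
  the intended unit of inference.
* The adaptive beat filter is causal and cannot distinguish a spurious beat
  adjacent to a genuine one from the genuine beat itself.
* Partial coherence assumes an invertible spectral matrix; heavy ridge use
  (warned) signals near-collinear inputs and should prompt a smaller
  conditioning set.
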