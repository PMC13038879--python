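# Methods

## Model and pipeline

The pipeline identifies recurring whole-brain connectivity states in
resting-state BOLD time series and quantifies how two groups (patients
vs. matched controls) differ in how they occupy, hold, and move between
those states.

The observation model is a K-state Gaussian hidden Markov model with a
full covariance matrix per state, fitted by expectation-maximization on
the z-scored ROI time series of all subjects concatenated along time.
A segment-lengths ledger accompanies the concatenated matrix: motion
scrubbing removes individual frames and splits a subject's recording
into continuous runs, and every recursion (forward-backward, Viterbi)
restarts at each segment boundary, so probability never flows across a
scrubbed gap or between two participants.

Stages, in order:

1. **Motion QC** — a subject is excluded when mean framewise
   displacement (FD) exceeds 0.2 mm or more than 20% of frames exceed
   FD 0.5 mm; for retained subjects, frames with FD > 0.5 mm are removed
   and the segment ledger is split at each removal.  The two printed
   exclusion criteria and the frame-level scrubbing are applied
   together: the source protocol says "excluded or scrubbed" without
   assigning subjects to either arm, and this combination honors both
   clauses while guaranteeing the segment ledger the HMM requires.
2. **Standardization** — per subject, per ROI: subtract the mean,
   divide by the population SD (ddof = 0; standardization is model
   input conditioning, not inference, and the choice is documented so
   tests can be exact).
3. **Model selection** — grid search over K (default 2-14) with
   multi-seed EM restarts (default 10; restart seeds are master_seed +
   0..9); per K the max-likelihood restart is kept and K is chosen at
   the global minimum of BIC = -2 logL + p ln(T), with T the total
   concatenated frame count and p = (K-1) + K(K-1) + KN + KN(N+1)/2.
   BIC ties break toward smaller K.
4. **Decoding** — per-segment Viterbi paths and forward-backward
   posteriors γ(t, k).
5. **Temporal metrics** — fractional occupancy from γ (FO_k = mean_t
   γ(t,k)); mean dwell time, switching rate, transition counts and
   per-subject transition probability matrices (TPMs, self-transitions
   included) from the hard Viterbi path.  The γ-for-FO / Viterbi-for-
   dwell split is the common convention where the source procedure lists
   both without assigning them; a one-hot γ makes FO equal Viterbi
   frequencies exactly, and the `fo_source` setting switches FO to the
   hard path.  Switching rate is defined as (within-segment
   state changes) / (within-segment frame pairs) — the source names the
   quantity without defining it, so this is a package decision.
6. **State connectivity** — per (subject, state): frames hard-assigned
   by Viterbi are pooled across segments; with ≥ 30 frames, a
   Ledoit-Wolf shrinkage covariance is estimated, converted to
   correlation, clipped to |r| ≤ 1 − 1e-7, Fisher z-transformed, and the
   diagonal zeroed; otherwise the matrix is marked missing and only
   available matrices enter group statistics.
7. **Network load** — each state's group-mean connectivity matrix is
   summarized per canonical network (mean over within-network ROI
   pairs); relative load is each network's deviation from the mean of
   the network averages, divided by |baseline| and capped at ±50%;
   networks ≥ 10% above baseline are High, ≤ −10% Low, the rest Neutral
   (the neutral band is configurable; no published threshold exists).
   The group-level mean of subject state-FC matrices is the default
   input; `netload_source: model` summarizes the fitted model's state
   covariances (as Fisher-z correlations) instead.
8. **Group statistics** — three separate families: edge-wise Welch
   t-tests with one Benjamini-Hochberg adjustment pooled across all
   states × edges; per-state FO/MDT/switching comparisons behind a
   normality gate (Shapiro-Wilk per group and median-centered Levene,
   both at α = 0.05: pass → Student's t, else Mann-Whitney U), with raw
   p reported and BH within each metric family (m = K) alongside;
   transition cells compared after the arcsine-square-root transform
   with BH across all K² directed cells.  Every comparison carries
   Cohen's d with equal-weight pooled SD, √((SD₁²+SD₂²)/2), and the
   rank-biserial correlation 1 − 2U/(n₁n₂) oriented so patients-larger
   is positive.
9. **Clinical correlations** — patients only, pairwise-complete,
   Pearson/Spearman by the same normality gate (overridable), two-sided
   uncorrected p, flagged exploratory.

## EM initialization

hmmlearn's default initialization clusters individual frames by k-means
on their values.  For connectivity-defined states — identical (zero)
means, different covariances — frame values carry almost no state
information, so that initialization is effectively random and EM restart
quality is poor.  `fit_hmm` instead summarizes non-overlapping
within-segment windows (12 frames) by their vectorized correlation
pattern, k-means-clusters the patterns (the restart seed drives the
clustering), and starts each state from the pooled moments of its
cluster's frames, with a uniform initial distribution and a
0.8-diagonal transition matrix.  This initialization made BIC model
selection stable across replicate cohorts where the frame-level
initialization selected a neighboring K in 2-4 of 10 replicates, and it
shortens EM runs.  When the data provide fewer windows than states the
code falls back to hmmlearn's initialization.

## Numerical choices

- EM convergence: gain in log-likelihood below `tol` (default 1e-4);
  maximum 500 iterations.  A fit is flagged `converged` only when the
  tolerance was actually reached, not when the iteration budget ran
  out.  Monotonicity of the EM log-likelihood is asserted on every fit
  (slack 1e-8 relative).
- Covariance floor: diagonal jitter of 1e-6 applied until the smallest
  eigenvalue clears 1e-8 (full covariances with few assigned frames are
  near-singular); the same constant feeds hmmlearn's `min_covar` and
  `covars_prior`.
- Fisher z clipping at |r| = 1 − 1e-7 (atanh diverges at ±1; duplicated
  ROIs then map to z ≈ 8.40 rather than infinity).
- State alignment across runs/models: states are compared by the strict
  lower triangle of their correlation (not covariance) matrices —
  connectivity patterns are scale-free — via the Hungarian assignment
  maximizing total Pearson similarity; full ties return the
  lowest-index assignment.
- BIC sample size is the total concatenated frame count; the free
  parameter count includes the initial distribution (K − 1).
- Internally states are 0-based; all emitted tables render them 1-based
  ("S1..SK").
- Degenerate guards: zero-variance ROI columns are errors naming subject
  and column; all-singleton segments give NaN switching rate; TPM rows
  with no outgoing transitions stay zero and are flagged, and group TPM
  averaging skips them (recording per-row contributing n); a BH family
  propagates NaN p-values as NaN q.

## Synthetic cohort generator

The generator exists because the study data this pipeline targets are
not public.  It emulates their structure: two arms of 100 subjects, 230
retained volumes at TR = 2 s, 142 ROIs over the seven canonical
networks, states defined by connectivity rather than amplitude, and a
disability score (MIDAS) coupled to one state's dwell time.

- **Emissions.**  Each state elevates a distinct subset of networks
  (the bit pattern of s + 1 over the networks, so signatures are unique
  and never empty) to within-network correlation `r_high` = 0.8; other
  networks sit at `r_low` = 0.05 with `r_cross` = 0.02 between networks;
  unit variances; zero means by default (a `mean_shift` option exists
  for decoding tests).  The contrast was chosen so that states are
  identifiable at the package's test scale (10 ROIs): with weaker
  blocks (e.g. 0.4 within), the Bayes-optimal per-frame accuracy at
  N = 10 is under 40% and no fitting procedure can recover the design —
  at the full 142-ROI scale, with ~20 ROIs per network, far weaker
  contrasts would remain identifiable, so the test-scale contrast
  errs on the separable side by design.
- **Dynamics.**  Control chain: self-transition 0.80 everywhere,
  off-diagonal uniform.  Patient chain: designated states get elevated
  self-transition (defaults 0.90 and 0.88 for the last two states —
  the "locked" states) and others reduced (0.72, 0.74 for the first two
  — depleted baseline states), reproducing the elevated-FO/MDT +
  reduced-baseline pattern.  Initial distributions are the chains'
  stationary distributions.
- **Motion.**  FD traces are |N(0.05, 0.03²)| with a 2% per-frame
  chance of a spike in (0.5, 1.0) mm — plausible values that guarantee
  the scrubbing path is exercised while subject-level exclusions stay
  rare.
- **Clinical coupling.**  MIDAS_i = max(0, round(α + β·MDT_i(s*) +
  ε_i)), ε ~ N(0, σ²) with σ = 9.2·√(1−r²); β is calibrated against the
  realized dwell-time sample so the latent Pearson correlation equals
  the target (default r = 0.38), and α centers the score at 18.8.
  Rounding and zero-truncation attenuate the realized correlation
  negligibly at these settings.  Other scales are drawn uncoupled from
  truncated normals matching the target population (VAS 5.6 ± 1.8,
  HIT-6 52.3 ± 9.0, SDS 49.8 ± 6.3, duration 6.6 ± 4.9 years) plus
  uniform 1-8 monthly headache days.
- **Seeds.**  Subject i uses `SeedSequence((master_seed, i))`; clinical
  noise uses `SeedSequence((master_seed, 2^20))`.  Cohorts are
  bit-reproducible and subjects independent.

What the generator does *not* emulate: hemodynamic autocorrelation,
physiological noise, spatial smoothness, scanner drift, site effects,
non-Markovian dwell-time distributions, and amplitude differences
between states.  Passing tests therefore demonstrate that the
*pipeline* recovers what this generative family encodes — they do not
certify performance on real BOLD data, where state separations are
weaker and emissions are not conditionally Gaussian.

## Problem sizes in the test suite

The default test/acceptance configuration is the "test scale": K = 4
states, 10 ROIs over 3 networks, T = 200 frames, 20 subjects per arm —
the full pipeline in seconds on one CPU.  Heavy checks use:

- Parameter recovery and K selection: null-chain cohorts (both arms
  share the control chain, so the generating TPM is unambiguous) with
  spike-free FD traces (scrubbing fragments subjects into ~200 segments
  and triples per-iteration EM cost; the scrubbing path has its own
  tests).  K selection runs the 2-8 grid with 2 restarts per K,
  EM tolerance 5e-2, 60 iterations, over 10 replicate cohorts.
- Calibration: 200 replicate cohorts (paths only) for null type-I
  error of the FO/MDT comparisons; 100 replicate 10-per-arm cohorts for
  edge-family FDR; 50 replicates for the designed self-transition
  difference; 100 replicates of 100 patients for clinical-coupling
  recovery.
- The dimensionality-reduction robustness check runs at N = 40
  (projection to 30 components, refits over K ± 2).

## Known limitations

- With N = 142 and K around 11, the full-covariance parameter count
  (~113k) exceeds typical concatenated frame counts; BIC at that scale
  rests on a likelihood that cannot be well conditioned.  The
  `pca_components` setting fits the HMM in a reduced space instead; the
  default follows the literal full-space procedure.
- One shared transition matrix is fitted to both groups (as in the
  source procedure); group TPM contrasts come from per-subject
  transition counting on the decoded paths, not from group-specific
  HMMs.
- The Ledoit-Wolf shrinkage intensity is estimated per (subject,
  state); matrices with few frames are strongly shrunk, which biases
  edge values toward zero differentially across states with different
  occupancy.
- `hmmlearn` reports the log-likelihood of the parameters from the
  penultimate M-step; at the default tolerance the discrepancy from the
  final parameters' likelihood is below the convergence gain and is
  ignored in BIC.
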