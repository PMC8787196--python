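# Methods

This note documents the models, estimators and design choices behind
`groomsyntax`, in the spirit of a statistical software methods appendix.
It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The data model

An **ethogram** is a frame-resolution categorical sequence over seven
actions: front leg cleaning (F), head grooming (H), abdomen grooming
(A), back leg cleaning (B), wing grooming (W), walking (Wk), standing
(S). F and H form the anterior motif; A, B, W the posterior motif; Wk
and S are non-grooming. Recordings default to 50,000 frames at 30 Hz
(27.78 min). A **bout** is a maximal run of one action; run-length
encoding makes bout-level self-transitions impossible by construction,
which is why the syntax representation has exactly 7 × 6 = 42 entries.

### Denoising

Automated frame classifiers produce isolated mislabeled frames. Grooming
bouts shorter than one complete leg sweep — 150 ms, i.e. under 5 frames
at 30 Hz (a 4-frame bout is 133 ms and is removed; a 5-frame bout is
167 ms and kept) — are treated as glitches. Frames of an eliminated bout
are absorbed by the *preceding* bout (the first bout, if short, merges
rightward), and adjacent same-action bouts are then re-merged.

Merging is **iterative, shortest-bout-first** (leftmost on ties), and
merged bouts are re-evaluated against the cutoff. This matters when a
glitch splits one real bout into sub-cutoff pieces: F(4 frames),
H(1), F(4) collapses to a single 9-frame F bout that now clears the
cutoff, rather than being discarded wholesale. The procedure is
idempotent and never changes the total frame count. Walking and standing
bouts are left untouched: the leg-sweep rationale applies to grooming
actions only. Applying the rule to all seven actions is a one-line
change, but short locomotor pauses are real behavior, not classifier
noise, so the default leaves them alone. A recording reduced to a single
still-short grooming bout is returned with a warning; there is nothing
principled left to merge it into.

## Feature families

* **Proportions** — fraction of frames per action; the
  grooming/walking/standing triplet is exposed for ternary-style
  summaries.
* **Progression** — the proportions recomputed in 10 equal contiguous
  windows (2.78 min each at the default length). When the frame count is
  not a multiple of 10, remainder frames go to the last window —
  deterministic and recorded here so feature vectors are bit-exactly
  reproducible.
* **Syntax** — per-fly bout-transition counts normalized per source
  action. Sources never observed get an all-zero row plus a missing
  flag. Statistical tests *exclude* missing-source flies per transition
  (imputation would manufacture zeros); classification imputes 0 by
  default (uniform 1/6 available via `impute="uniform"`). Syntax is
  computed at bout level, not frame level: frame-level counting is
  dominated by self-transitions, which the 42-dimensional no-self
  representation excludes by definition.
* **Duration histograms** — per action, 20 equal-width bins over
  [cutoff, category maximum], the maximum computed separately for
  grooming and non-grooming actions because walking and standing are
  much heavier-tailed. The upper edge defaults to the cohort-pooled
  per-category maximum (passed explicitly through
  `cohort_category_max`), making per-fly vectors comparable within a
  cohort; a fixed edge can be supplied instead.
* **Grooming half-time** — the time at which the cumulative count of
  grooming frames reaches 50% of the fly's total; NaN with a warning if
  the fly never grooms.

## Stereotypy

**Entropy rate.** `H = −Σ_i w_i Σ_{j≠i} p_ij ln p_ij`, natural
logarithm, `0·ln 0 ≡ 0`. The natural log is forced by the calibration
that H = 1 corresponds to a ≈ 37% (= e⁻¹) chance of predicting the next
action. Default weights `w_i` are empirical outgoing-transition
frequencies; stationary-distribution weighting (Cesàro-averaged power
iteration on the observed submatrix, robust to periodic chains) is
available by flag. Bounds: 0 ≤ H ≤ ln 6, with 0 iff every observed row
is deterministic and ln 6 iff every observed row is uniform over its six
allowed targets.

**Edit distance.** Unit-cost Levenshtein distance between
frame-resolution symbol sequences, computed via `edlib` (the two-letter
walking code is mapped to a single internal symbol first) and verified
in tests against a brute-force dynamic-programming oracle and the metric
axioms on exhaustive small-string sets. Distances are normalized by the
longer sequence length, so 0 means identical and 1 means maximally
different; summaries report minimum and median percent difference.

**Protocol.** Comparisons use the *first* continuous anterior (F/H) run
lasting at least 30 s — anterior runs because the two-action motif with
high mutual coupling is the best candidate for exhibiting sequence
stereotypy, 30 s so a repeat is long enough to show it. Designs:
within-fly across consecutive sessions, and between flies within each
fly's first session (all pairs; no truncation to a common length —
normalization handles unequal lengths). Flies or windows without a
qualifying run are skipped and counted in the log. For optogenetic
sessions, one run is extracted per stimulation window and windows act as
pseudo-sessions (Activation #1 vs #2 is the within-fly comparison).

## Group statistics

For each unordered group pair and each of the 42 transitions:

* **Location** — two-sided Wilcoxon rank-sum (Mann–Whitney) on per-fly
  transition probabilities; exact null distribution when both groups
  have ≤ 10 flies, normal approximation with tie correction otherwise.
* **Variance** — Levene's test centered at the median (the
  Brown–Forsythe variant), chosen for robustness on bounded, skewed
  proportions.
* **Durations** — per action, two-sample Kolmogorov–Smirnov on pooled
  bout durations; empty samples yield untestable rows that do not enter
  the correction family.

Each table is Holm step-down corrected as **one family** (all
transitions × all pairs — the most conservative reading of a
420-comparison design); significance is `p_adjusted < 0.05`. The Holm
implementation is six lines and is property-tested against statsmodels.

Calibration note: Brown–Forsythe p-values rely on an F approximation
whose far tail (where Holm operates) is anticonservative for very small,
coarse samples. The null-calibration simulation therefore uses 25 flies
per group and 5,000-frame recordings — comparable to the stock-line
cohort scale — where both test families hold family-wise error at the
nominal 5% level; with ~10 flies and very short recordings the variance
family can exceed it.

## The synthetic generator

The generator is a **semi-Markov chain**: bout actions follow a
transition matrix with zero diagonal; dwell times are drawn per action
from a log-normal truncated below at the 150 ms cutoff and converted to
frames by ceiling. Grooming actions use mode 0.6 s (σ = 0.45 log-s),
inside the 500–750 ms band where real grooming bout-duration
distributions peak; walking (mode 1.2 s, σ = 0.9) and standing (mode
1.0 s, σ = 1.0) are heavier-tailed. The log-normal family is a modeling
choice — only the histogram peaks are constrained by observation.

**Progression** is modeled as a sigmoid interpolation in bout-onset time
between an early anterior-biased matrix and a late posterior-biased one
(midpoint 400 s, steepness 120 s), with the diagonal re-zeroed and rows
renormalized after interpolation. This reproduces the
anterior-then-posterior progression qualitatively; the underlying
dust-depletion dynamics are not modeled.

**Groups** are divergence offsets on a base template. Offsets are
supplied row-balanced (mass removed from a motif target is explicitly
parked on named alternatives) because naive renormalization after
subtracting from a dominant entry largely cancels the intended effect.
Rows are clipped at zero and renormalized, so group matrices are always
row-stochastic with zero diagonal. **Per-fly heterogeneity** resamples
each matrix row from Dirichlet(κ · row) on its support; κ defaults to
150 (mild jitter, per-fly s.d. ≈ 0.03 on a 0.75 transition). The
variability presets use κ = 150 / 25 / 600 for stock-like / interbred /
isogenized groups. Preset divergences are illustrative magnitudes, not
fitted to any dataset: between-species effect sizes have not been
quantified numerically in the source material.

**Optogenetic sessions** replace the transition matrix with an
anterior-dominant one (P(F→H) = P(H→F) = 0.985; every other action
funnels ≈ 98.5% of its mass back into F/H) inside three 3-min
stimulation windows; bouts are truncated at window boundaries, since
stimulation onset interrupts ongoing behavior. Under this matrix
in-window frames are ≳ 95% anterior and 30-s continuous anterior runs
occur in nearly every window.

**Determinism.** All randomness flows from `numpy` `SeedSequence`
spawning, so population- and session-level outputs are bit-reproducible
for a fixed seed, and fixture generation writes byte-identical files.

### What the generator does and does not emulate

It reproduces the statistical structure the analyses consume:
bout-level syntax with motif coupling, dwell-time peaks, progression,
group differences, within-group jitter, and stimulation windows. It does
not model biomechanics, dust-level latent dynamics, learning across
sessions, sex differences, or individuality (per-fly traits stable
across days beyond the fixed per-fly matrix). Passing tests therefore
validate the *pipeline* — estimators, tests, protocols — under known
ground truth; they do not certify conclusions about real flies.

## Classification and embedding

Multinomial logistic regression with a light ridge penalty (C = 1), 42–
140 features and tens of flies being the regime where some shrinkage is
numerically prudent; features are z-scored with the scaler fit on
training folds only. Accuracy is the mean over 10 repeats of stratified
5-fold cross-validation (folds reduce with a warning when a class is
smaller than k). Chance level is the mean accuracy over label
permutations (default 100), reported with the 2.5–97.5 percentile band;
for balanced cohorts it converges to 1/n_classes. t-SNE (perplexity 10,
PCA initialization, fixed seed) is used for 2-D visualization only — no
quantitative claims are derived from the embedding.

## Problem sizes used in the checks

The packaged checks run on deliberately scaled synthetic cohorts chosen
as realistic study conditions: 13 flies per group (the per-genotype
recording scale), 50,000-frame recordings where per-fly estimation noise
matters (species classification, non-grooming classification,
progression), 10,000 frames where it does not (chance levels), 25 flies
per group × 5,000 frames × 200 replicates for null calibration, and
the equivalent of ~100,000 bouts for transition-matrix recovery, where
the max-abs error bound of 0.02 holds with a wide margin.

## Known limitations

* The semi-Markov generator's dwell truncation plus frame ceiling means
  simulated grooming bouts are never shorter than 5 frames; denoising is
  a near-no-op on clean simulated data (by design, glitch injection is
  trivial to add upstream).
* Brown–Forsythe calibration degrades for < ~15 flies per group with
  very short recordings (see above).
* Between-fly edit-distance comparisons use all pairs; matched-pair
  designs are not implemented.
* The anterior-run rule returns the *first* qualifying run; no
  alternative selection (longest, cleanest) is offered.
* Stationary-weight entropy falls back to source-frequency weights when
  the observed chain is ill-posed (e.g. absorbing targets), with a log
  message.
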