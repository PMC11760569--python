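# Methods

## The problem

Aging mouse colonies are usually summarized by a single mean growth curve,
which hides systematic heterogeneity: subgroups of animals that gain, lose,
or hold weight along distinct paths. In humanized-APOE colonies this
heterogeneity matters because weight change is a documented correlate of
Alzheimer's-risk biology. `apoetraj` discovers such weight trajectories from
irregular longitudinal weighings and validates them against independent
survival, plasma-biomarker, and body-composition measurements.

## The model

Each mouse contributes one variable-length sequence of visits. A discrete
hidden state `H_t ∈ {1..N}` (N = 10 by default) follows a first-order Markov
chain with initial law π and row-stochastic transition matrix `A = [a_ij]`.
Each visit emits the observed tuple:

- age `~ Normal(μ_age,i, σ²_age,i)`
- sex `~ Categorical(p_sex,i)` — re-emitted at every visit
- genotype `~ Categorical(p_geno,i)` — re-emitted at every visit
- weight `~ Normal(α_i + δ_i·[male] + φ_i·w_prev, σ²_w,i)`

The weight emission is first-order autoregressive on the previous *recorded*
weight, with a state-specific male intercept offset `δ_i` (the sex–weight
interaction). The first visit of a sequence has no predecessor and uses a
separate per-state Gaussian `(α0_i + δ0_i·[male], σ²_w0,i)`; this keeps short
sequences fully informative instead of discarding their first point.

Irregular spacing is handled structurally, not by imputation: every recorded
measurement is one Markov step, and age is an observed emission carrying the
time information. No data are imputed or resampled.

Because the autoregressive parent of each weight is observed, exact inference
on this chain reduces to forward–backward (and Viterbi) with the AR term
folded into the per-visit emission density — the chain specialization of
junction-tree inference. All recursions run in log space; categorical
probabilities are floored at 1e-12 before normalization and Gaussian
variances at 1e-3 (g² or months²), so densities stay finite.

### Fitting

Maximum likelihood by EM. The E-step is the exact forward–backward pass,
batched over padded sequences (a colony fit is a vectorized numpy
computation). The M-step is closed-form throughout: normalized expected
counts for π and A, responsibility-weighted frequencies for the
categoricals, weighted mean/variance for age, and responsibility-weighted
least squares of weight on `(1, [male], w_prev)` per state (a 3×3 normal
system with a 1e-9 ridge for degenerate designs). The log-likelihood trace
is therefore non-decreasing up to float tolerance; the test suite asserts
this at `1e-6·|LL|`.

Defaults follow the original protocol: 10 random restarts of up to 1,500
iterations each, keeping the restart with the highest final log-likelihood.
An optional early stop triggers when the relative improvement falls below
1e-8; in practice colony fits converge within a few hundred iterations.
States with near-zero total responsibility are re-seeded from a random
sequence segment with a logged warning.

Initialization matters. Emission centers come from jittered 1-D k-means on
all recorded weights with *within-cluster* variances; a diffuse pooled
variance makes the first E-step uninformative and EM then collapses into a
single near-random-walk state (`φ ≈ 1`), a strong local optimum. The
transition matrix starts sticky (diagonal 0.5–0.85) with Dirichlet jitter;
age and the categoricals start at pooled moments. All randomness in restart
`r` flows from the generator seeded with `[master_seed, r]`.

### Labeling and trajectory grouping

Likelihood is invariant to state permutation, so fitted states are relabeled
canonically: sorted ascending by the stationary weight level `α_i/(1−φ_i)`
(or `α_i` where `|φ_i| ≥ 1`), then named A, B, C, … This makes restarts and
platforms comparable; the letters themselves are arbitrary.

States with self-transition `a_ii > 0.3` (strict) are *ending* states. Each
mouse is assigned to the state occupied at its final visit — argmax of the
smoothed posterior by default (ties to the lower label), last Viterbi state
behind a flag. Mice terminating in an ending state form that state's
trajectory group; the rest are unassigned. Group curves are mean ± sample SD
per 1-month age bin (one value per mouse per bin so densely-weighed mice do
not dominate), with bins under 3 mice omitted. The phenotype call is the
percent weight change from the bin nearest 12 months (±1 month window; 12
months is middle age, the end of the growth phase) to the last curve bin:
≤ −5% loss, ≥ +5% gain, otherwise stable.

## Preprocessing

Exclusion rules run in a fixed order: breeders (diet change) → record-level
date sanity (measurement before birth / after death) → drop records under 5
months of age → exclude mice with monthly-normalized weight loss over 20%
between consecutive retained measurements → require ≥ 3 remaining records.
Record-level sanitation precedes mouse-level counting so the ≥3-point rule
applies to clean records. "Monthly" loss over a gap of Δ days is the observed
fractional loss scaled by 30.44/Δ; gaps under 15 days are not rate-tested
(short-gap noise would extrapolate to absurd monthly rates). A month is
30.44 days throughout. The exclusion report reconciles exactly: every input
mouse is retained or carries at least one reason.

## Post-hoc validation

- **Survival.** Time runs from birth to death, censoring at the last
  weighing for mice alive or of unknown fate; sacrificed mice are excluded
  (their endpoint reflects experiment scheduling). The Kaplan–Meier
  product-limit estimator and the K-sample log-rank test (hypergeometric
  variance, quadratic form on K−1 groups) are implemented in-package;
  `lifelines` is the independent oracle in tests only. Median survival is
  the first time S(t) ≤ 0.5.
- **Composition.** Pearson chi-square (no continuity correction) on the
  group × sex / genotype table, overall and pairwise.
- **Biomarkers / body composition.** Welch t-tests by default (the variant
  is not determined by the original description; pooled Student's t behind a
  flag). P-values are reported unadjusted, with a Holm-adjusted column
  always alongside. The adipose index is `fat/(fat+lean+free water)·100`.
- **Cross-sectional inference.** A single (age, weight, sex, genotype)
  observation gets a posterior over states by Bayes' rule with the
  first-visit weight Gaussian and, by default, the stationary distribution
  of the fitted transition matrix as prior (π behind a flag). Reducible
  chains fall back to the long-run occupancy `π·A^k` with a warning.

## The synthetic colony

The generator emulates the study conditions so the whole pipeline runs with
known ground truth: 1,196 mice, 45%/55% female/male, genotypes E3/3, E3/4,
E4/4 at 30/28/42%, first weighing uniform in 5–8 months, truncated-Gaussian
~monthly gaps (mean 1.0, sd 0.25, floor 0.5 months), observation window 5–28
months, 12% of later visits skipped (the first three are always recorded; a
skipped visit lengthens the gap without advancing the state chain). Five
archetype states are AR attractors at 18/23/29/36/48 g (female level; male
offsets 4–5 g at the attractor, AR slopes 0.55–0.6), with flow from the
stable and heavy states toward the loss and gain states, a genotype-coupled
entry distribution (the gain state enriched for E4/4), per-state constant
monthly death hazards (stable lowest at 0.012/month, gain highest at
0.045/month), and per-state biomarker means (gain highest). 5% of mice are
breeders; 55% carry an independent sacrifice time (uniform 8–26 months).
Birth dates are uniform over Nov 2018–Dec 2019 and all dates are written
ISO-8601; re-reading a written table reproduces ages to within date-rounding
(±0.02 months).

What the generator does **not** emulate: litter, cage and diet effects,
seasonal weighing gaps, measurement-device drift, and — importantly — any
direct age-emission structure: simulated ages come from the visit schedule,
not from the per-state age Gaussians. Passing tests therefore demonstrate
correct inference and recovery under the model's own assumptions, not
robustness to the violations real colonies exhibit.

Two reduced configurations exist for recovery testing, and their design is
deliberate. In `three_state_config` (levels 18/30/44 g, slopes 0.2–0.3,
sticky 0.85) and `five_state_config` (levels 18–50 g at 8 g spacing, slopes
0.35, sticky 0.80, male offsets 2–2.5 g) the age windows are identical
across states and initial states are uniform, so state occupancy carries no
age signal; separation is strong relative to the within-state sd so that the
generative structure is also the maximum-likelihood structure. This is not
cosmetic: because sex and genotype are re-emitted at every visit, a state
that goes sex-pure earns up to log 2 per visit, and under weak weight
separation EM will happily trade weight fit for sex purity (or segment age
when occupancy correlates with it). On the full study-like colony — where
occupancy does correlate with age — the fitted 10-state model indeed
produces age-localized, partly sex-segregated states; the trajectory groups
it derives still separate gain/loss/stable phenotypes, survival and
biomarkers, which is the analysis' actual deliverable.

## Problem sizes used in tests and the acceptance script

Inference correctness is checked against exhaustive path enumeration (240
random instances, N ≤ 4, k ≤ 6, tolerance 1e-10); EM monotonicity over 20
dataset×seed combinations; parameter recovery on 3-state colonies of 300
mice (~11 visits each, 10 seeds in tests, 5 in the acceptance script, each
fit 5 restarts × ≤300 iterations with early stopping); end-to-end recovery
on 5-archetype colonies of 600 mice; and the study-scale demonstration on a
1,196-mouse colony with the full 10-state, 10-restart protocol capped at 300
iterations (early stopping makes more iterations a no-op on this data).
These sizes were chosen as the smallest at which the statistical guarantees
are comfortably non-marginal.

## Known limitations

- Static covariates re-emitted per visit weight long sequences more; the
  conditional (covariate) formulation is a natural alternative the surface
  does not currently expose.
- One-step AR only; no continuous-time transition rescaling for very uneven
  gaps.
- The ending-state threshold 0.3 is inherited from the original protocol and
  is not adaptive; with very sticky fits every state can classify as ending,
  in which case no mice are unassigned.
- Survival validation assumes non-informative censoring at the last
  weighing; sacrifice decisions correlated with health would bias it.
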