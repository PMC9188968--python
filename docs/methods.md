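# Methods

## Observation model and inference

Each session is a timepoints × parcels matrix, z-scored per parcel within
session (divisor n−1). Sessions are concatenated in time and reduced by
PCA computed once on the concatenated matrix; the smallest m with
cumulative explained variance ≥ the threshold (default 0.75) is kept, and
component signs are fixed by making the largest-magnitude loading of each
component positive so fits are reproducible. State mean patterns can be
projected back to parcel space (`backproject`), giving activation maps in
standardized parcel units relative to the temporal average.

The hidden Markov model on the component scores has K states, each a
multivariate Gaussian with a state-specific mean and one full covariance
shared by all states. Only the mean drives state identity; the shared
covariance captures the group-level dependence between channels. Each
session is an independent chain: the initial distribution applies at every
session start and no transition is counted across session boundaries.

Inference is structured variational Bayes with conjugate factors:

* q(A_k·) and q(π): Dirichlet. Prior concentration 1 off-diagonal with a
  sticky diagonal parameterised by an expected dwell time d (default 5
  timepoints = 12 s at TR 2.4 s): diagonal concentration
  1 + (d−1)(K−1), so the prior-mean self-transition is 1 − 1/d.
* q(μ_k): Gaussian. Prior N(x̄, s² I) with s = 10 (weak on the
  standardized scale, where state means are O(1)).
* q(Λ) for the shared precision Λ = Σ⁻¹: Wishart. Prior degrees of
  freedom m + 2 and scale set so E[Λ] matches the inverse empirical
  covariance of the concatenated data. A `covariance_mode="fixed"`
  variant clamps Σ at the empirical estimate instead (both modes are
  provided because group-level analyses are run both ways in practice;
  inferred is the default).

The E-step runs exact scaled forward–backward recursions under the
expected-log parameters (digamma forms for the Dirichlet factors,
E[Λ] = νW and the multivariate-digamma log-determinant for the Wishart
factor), restarting the chain at every session boundary. The free energy
is F = −Σ_sessions log Z̃ + KL(q‖prior) summed over all factors, evaluated
after each E-step; coordinate updates guarantee it is non-increasing, and
the test suite asserts this with a relative slack of 1e-8. Convergence is
declared when the relative change falls below 1e-5 (default), capped at
500 iterations; a non-converged fit warns but still returns results.

Initialisation is seeded k-means (on a subsample of at most 10,000 rows)
for the means plus the empirical covariance and a sticky near-uniform
transition matrix; `n_init` independent initialisations (default 10) are
fitted and the lowest final free energy kept. Model order is chosen by
fitting each K in a candidate range (default 4..10) and taking the
free-energy argmin; the selection table is returned so users can override
the choice on substantive grounds (e.g. the smallest K that splits a
network of interest), which is how such choices are often made in
practice.

Decoding uses exact Viterbi with ties broken toward the lower state
index. Label switching between runs is resolved by Hungarian assignment
maximising total Pearson correlation between matched state means. States
absorbing fewer than one expected timepoint of total occupancy are
flagged as effectively eliminated; this affects reporting only, never the
fitted object.

## Dynamics summaries

Fractional occupancy is computed from the soft posteriors γ, averaged over
the timepoints of each task condition separately; fixation ('none')
timepoints never enter the denominators. Occupancy rows therefore lie on
the K-simplex exactly. Transition counts use the hard Viterbi path
(off-diagonal only), because probabilistic transition counting has no
agreed definition; the choice is recorded in output metadata. Change
scores are visit-2 minus visit-1 occupancy per paired subject and
condition.

Timepoint → condition assignment uses the acquisition-onset convention
with half-open block intervals [onset, onset+duration) and 0-based
indexing; an optional hemodynamic shift (default 0 s) delays the sampling
grid relative to the paradigm.

## Statistics

All tests are permutation-based, two-sided by default (one-sided variants
are available via `alternative`):

* unpaired: pooled-variance t, labels shuffled;
* paired: one-sample t on differences, signs flipped;
* correlation: Pearson r, one vector permuted;
* interaction: the unpaired test applied to per-subject change scores.

Whenever the permutation space fits within the requested number of
permutations (label splits, 2^n sign patterns, n! orders), it is
enumerated exhaustively and the p-value is exact and seed-independent;
otherwise p = (1 + b)/(1 + B) over B seeded Monte-Carlo permutations
(default B = 10,000). Mixed cross-sectional/longitudinal samples are
treated as independent units — the deliberate simplification of ignoring
that some subjects contribute two sessions.

BH-FDR is the step-up adjustment, monotone and capped at 1. NPC applies
one synchronised set of permutations to all partial correlation tests
(preserving their dependence), converts each permutation's statistics to
within-null p-values, combines them per declared family (Fisher
−2 Σ log p by default; Tippett min-p optional), and derives the joint p
from the combined null; family-wise error across families uses the
max-combined-statistic distribution from the same sweep. Families mirror
the analysis designs this pipeline targets: symptom variables aggregated
per state, or states aggregated per symptom variable.

Degenerate inputs raise informative errors rather than propagating NaNs:
constant parcels in standardization, zero pooled variance, all-zero
paired differences, constant correlation inputs, empty conditions in
occupancy, empty p-value sets in FDR.

## Synthetic cohort generator

The generator is the study-conditions oracle. Its defaults emulate a
mixed longitudinal trauma-therapy design: 96 sessions over five groups
(15 healthy trauma-exposed controls; 14 therapy pairs scanned before and
after treatment; 17 pre-only and 16 post-only therapy participants; 8
waiting-list pairs and 4 waiting-list pre-only), a pseudorandomised
40-block paradigm (20 trauma + 20 neutral blocks of 8 × 2 s pictures with
8 s fixation gaps; 16 min, 400 volumes at TR 2.4 s), and bounded
DSM-IV-style symptom-cluster scores (re-experiencing 0–12, avoidance
0–21, hyperarousal 0–18) linearly coupled to the true occupancy of a
target state with Gaussian noise, truncated to the scale bounds.

Ground-truth states are Gaussian with orthogonal mean directions (default
separation 2.0 in Mahalanobis-like units), one shared Wishart-sampled
covariance with identity mean, and sticky transitions with
self-persistence 0.8 (expected dwell 5 TR = 12 s, consistent with the
sticky prior). Group-level occupancy effects are planted by
exponentially tilting the transition column of the target state, with the
tilt weight solved numerically (Brent) so the stationary occupancy shifts
by exactly the requested amount (default ±0.05); emissions are untouched,
so planted effects are purely temporal. Where the emulated design leaves
effect sizes unspecified they are free parameters of `CohortDesign`,
documented as such.

Deliberately not emulated: hemodynamic convolution (the model operates on
BOLD directly, so states switch at TR resolution), scanner noise
structure (motion, physiological artefacts, drift), voxel-level imagery,
and the oddball target pictures embedded in real paradigms. Passing
tests therefore demonstrate correctness of the inference and statistics
under the stated generative assumptions, not robustness to fMRI
artefacts or HRF blurring.

## Problem sizes and numerical choices

Tests and the acceptance script use a reduced reference scenario — 20
sessions × 400 timepoints × 30 channels with 7 well-separated states —
chosen so the whole suite runs in well under an hour on one CPU while
leaving the recovery margins wide (typical state-mean RMSE ≈ 0.03 against
a 0.15 bound; transition MAE ≈ 0.005 against 0.05). Calibration checks
use 500 null simulations with 199 Monte-Carlo permutations (or exact
enumeration where attainable), so nominal α = 0.05 is exactly attainable
(10/200). Matrix solves use Cholesky factorizations throughout;
posterior covariances are symmetrised after inversion to suppress
round-off asymmetry; emission likelihood scaling subtracts per-timepoint
maxima before exponentiation.

## Known limitations

* The VB free energy is a bound, not the marginal likelihood; model-order
  selection by its argmin can be conservative on weakly separated states.
* PCA before HMM estimation can distort state geometry when the discarded
  variance is state-informative; the variance threshold is configurable.
* Exchangeability of the mixed sample is assumed by the unpaired tests;
  repeated subjects are treated as independent units by design.
* No covariate adjustment (age, gender, medication) is implemented.
* The generator's Markov-switching Gaussian data match the model family;
  real BOLD deviates from it, and performance numbers on synthetic
  cohorts are upper bounds in that respect.
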