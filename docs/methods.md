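# Methods

## The model

`relcurve` treats a behavioral task as a set of exchangeable trials.
Participant *i* has a latent proficiency *P<sub>i</sub>* (for binary
tasks, their true success probability), and a score formed from *L*
trials is a noisy estimate of it.  Reliability *R(L)* is defined as the
expected Pearson correlation, across participants, between scores
computed from two disjoint *L*-trial subsets — the internal-consistency
sense of reliability (consistency of the participants' ranking), not
absolute-score stability.

If trials are independent (no learning, no fatigue), the correlation of
two *L*-trial means follows the hyperbola

    R(L) = L / (L + C),

a reformulation of the Spearman–Brown prophecy in which the single
parameter *C* — the **convergence coefficient** — is the ratio of
single-trial error variance to true-score (between-participant)
variance.  Low *C* means few trials suffice to separate individuals;
high *C* (low between-participant variance, e.g. floor/ceiling effects)
means many.  The prophecy inverts to a planning rule,
`L = C·R/(1−R)`, so reaching R = 0.9 costs 2.25× the trials of R = 0.8.

## Estimating the curve

`splithalf.rl_curve` estimates *R(L)* by permutation: per resample two
disjoint *L*-column subsets are drawn, the **same columns for every
participant** (a split by trials, which preserves item effects), scores
are the means of non-missing outcomes, and the score vectors are
Pearson-correlated.  The default 1000 resamples per *L* were chosen as
the point where the mean stabilizes; the reported spread is the SD of
the correlation distribution.  Resamples with a constant score vector
have no defined correlation and are dropped (never imputed as zero,
which would bias the mean toward zero); the drop count is reported.
The default *L* grid is log-spaced from 2 to ⌊T/2⌋ with ≥ 10 points.

Test–retest reliability is the special split in which the two subsets
come from different sessions (one *L*-subset per session; within-session
sampling is without replacement).  `averaged_testretest` averages
per-day scores over disjoint day groups before correlating, which
suppresses day-specific state noise.  `curve_difference_test` compares
pooled and test–retest reliability at one *L* with a permutation null
built by shuffling session labels over trial columns (the same shuffle
for all participants, consistent with the shared-column split design);
the one-sided p-value uses add-one smoothing, so the smallest
reportable value is 1/(n_perm+1).

The mean split-half correlation at L = T/2, Spearman–Brown corrected
(2r/(1+r)), agrees with Cronbach's alpha on the full trial matrix; the
test suite checks this against an independent alpha implementation.

## Estimating C

Three estimators, which agree on well-behaved data:

* **direct** — nonlinear least squares of the hyperbola on the curve.
  Unweighted by default: the per-point SDs are strongly heteroscedastic
  but also strongly correlated between grid points, so 1/SD² weighting
  is exposed as an option rather than a default.
* **linearized** — OLS of 1/R on 1/L (`1/R = 1 + C/L`).  The intercept
  should equal 1 when trials are independent; deviation beyond its
  standard error flags learning or fatigue.  Points with R ≤ 0 are
  dropped with a warning (their reciprocal is meaningless).
* **mv** — binary tasks only.  The naive closed form
  `C = (E[P]−E[P]²)/Var(P) − 1` is biased downward when applied to
  finite-trial scores, because binomial sampling noise inflates the
  observed variance.  The law of total variance gives the corrected
  estimator

      C = (E[Z] − E[Z]² − Var(Z)) / (Var(Z) − (E[Z] − E[Z]²)/T),

  where *Z* is the score over all *T* trials.  The correction term is
  written with *T* (the total per-participant trial count) because *Z*
  averages all trials; in the split-half frame *T* = 2L.  When the
  denominator falls below 10⁻³ (configurable) the observed variance is
  at the binomial floor and a singularity error is raised instead of a
  wild estimate.  Var uses the unbiased (n−1) estimator throughout; at
  very small N the biased/unbiased choice shifts C visibly, which is
  one reason the planner warns below ~30 participants.

A note on power: under pooled *random* splits the linearized intercept
is only weakly sensitive to gentle drift.  A drift common to all
participants leaves rankings untouched, and participant-specific linear
drift enters each half only through the half's mean time value, whose
variance decays as 1/L — indistinguishable from trial noise.  The
diagnostic responds reliably once the violation produces strong
participant × time interactions (e.g. participant-specific acquisition
curves), which is what the test fixture uses.  Sequential
(first-half/second-half) splits would be more sensitive but are out of
scope.

## The synthetic generator

`simulate` draws proficiencies from Beta(α, β) — bounded in [0, 1] and
a good description of accuracy distributions on real task batteries —
and emits independent Bernoulli(P) trials.  For this model the ground
truth is exact: **C = α + β**, so every estimator can be scored against
a known answer (`ground_truth_c` also reports a large-N empirical value
from the mean/variance identity on exact proficiency draws; default
10⁶ draws, configurable).  Session-to-session state changes are
modeled as additive Gaussian perturbations of the proficiency per
session (clipped to [0, 1]; clipping rather than resampling is the
simplest contract and shifts the implied ceiling by < 0.003 at the
noise levels used).  Under this model the test–retest ceiling — the
infinite-trials limit of the test–retest curve — has the closed form
`Var(P)/(Var(P)+σ²)`, and the matched-L ratio
`r_across/√(r_within_a·r_within_b)` equals it at *every* L (the
finite-L attenuation cancels between numerator and denominator), which
is why `testretest_ceiling` reports the matched-L ratio as the
convergence value.

What the generator does **not** emulate: learning/fatigue beyond the
drift fixtures used for the intercept diagnostic, item heterogeneity
(all trials share the participant's P), non-Bernoulli outcomes, and
long-term true-ability drift.  Passing tests therefore certify the
estimators under exchangeable-trial conditions, not robustness to
violations of them.

## Error calibration and planning intervals

`calibration.build_surface` simulates beta-binomial experiments over a
(C, N, L) grid with α = β = C/2 and records the median and SD of the
percent error `100(Ĉ−C)/C` per cell, counting simulations discarded by
the denominator guard.  The symmetric-shapes choice is harmless: the
error distribution depends on the shapes essentially only through
α + β, which the suite spot-checks at C = 20.  MV cells draw scores
directly as Binomial(L, P)/L (identical in distribution to averaging a
trial matrix, far cheaper); curve-fit cells simulate full matrices.
Default test grids are reduced (coarse axes, ~100–1000 simulations per
cell); the full grids (C from 2–80 by 1, N 10–200 by 10, L 10–250 by
10, 1000 simulations) are a documented long-running mode of the
`calibrate` command.

`confidence_interval` interpolates the surface (bilinear in N and L,
nearest cell on the dense C axis), de-biases the point estimate by the
median error and inverts `Ĉ = C(1+e/100)` at normal quantiles:
`C_bound = Ĉ/(1+(median ± z·SD)/100)`.  A z-interval is what a
(median, SD) surface can support; at the calibrated operating points
the error distribution is close enough to Gaussian that nominal 95%
intervals cover the true C at ~95% (checked by a 500-pilot coverage
simulation at N = 50, T = 60, C = 10).  Queries outside the grid hull
are clipped to the nearest cells and flagged.

## Attenuation

`spearman_attenuation` implements `r_obs = r_true·√(R_a·R_b)`.
`correlate_at_reliability` subsamples each task to the trial counts its
fitted C requires per reliability level and reports the observed
correlation distribution together with the prediction, using the
reliabilities actually achieved by the integer trial counts (the
ceiling of `C·R/(1−R)` slightly overshoots the nominal level).  The
prediction uses the full-data correlation as `r_true`, which itself is
mildly attenuated (full data are reliable, not perfect), so predictions
at high levels sit a hair below the latent truth.

## Quality control

`apply_exclusions` implements three generic compliance criteria, each
at k = 2 group SDs: mean RT too fast, RT variability too low, and mean
same-response run length too long (computed on raw response codes when
available, otherwise on outcomes).  Two or more firing criteria exclude
a participant, unless their accuracy is within 0.5 SD below the group
mean (plausible performers are retained); the `strict_rt_sd` flag makes
the RT-variability criterion alone sufficient regardless of accuracy —
the bot-detection variant appropriate for recognition-memory tasks.
Group statistics are computed once, not iteratively re-estimated after
each exclusion.  For session comparisons, `session_outlier_filter`
drops participants whose between-session score change deviates more
than k = 2 SD from the mean change, taking the union over all pairwise
session comparisons.

## Numerical and design choices

* Scores are means over non-missing outcomes; a `min_trials` filter
  excludes participants with too few usable trials.  No imputation.
* Unbiased (n−1) sample variance everywhere across participants.  As a
  consequence the Bhatia–Davis bound `Var ≤ m(1−m)` holds only up to
  the factor n/(n−1), which is how the invariant is asserted.
* Trial indices are 0-based internally, 1-based in written reports.
* Long (tidy) CSV is canonical on disk; wide matrices convert via
  `TrialMatrix.from_wide`.  Duplicate (participant, session, form,
  trial) keys are an error, not a silent overwrite.
* All randomness flows through a single `numpy.random.Generator`;
  every CLI run logs its seed and writes its resolved configuration
  next to its outputs, so identical inputs + seed give byte-identical
  outputs.
* The direct fit starts from the median of the per-point moment
  solutions `C = L(1−R)/R` and is bounded to C > 0; an all-ones curve
  is reported as degenerate rather than returning C ≈ 0.

## Known limitations

* The exchangeability assumption excludes adaptive/staircase designs;
  ICC-style reliability variants are out of scope.
* The MV estimator applies to binary outcomes only; use the direct or
  linearized fits for RT-like or scalar measures.
* The mean split-half correlation of *structureless* data is centered
  on zero, but its per-dataset value at L near T/2 has an irreducible
  across-dataset SD of ≈ √(1/(2(N−1))) (≈ 0.07 at N = 100), because the
  realized between-participant variance of the empirical means
  fluctuates.  Single-dataset reliability values near ±0.1–0.2 at the
  largest half-lengths are therefore compatible with pure noise at
  typical cohort sizes; averaging curves over replications (whose grand
  mean is ≈ 0.003 in the suite's 30-replicate check) is the reliable
  null diagnostic.
* Planning intervals inherit the calibration grid: far outside its
  hull they are extrapolations and flagged as such.
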