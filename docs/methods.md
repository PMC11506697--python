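# Methods

## The model

`tractstage` estimates a data-driven trajectory of white-matter damage in
unilateral temporal lobe epilepsy (TLE) from cross-sectional, tract-level
diffusion MRI. The biomarkers are mean fractional anisotropy (FA) values in
the 20 JHU-atlas tracts (9 left/right pairs plus the two midline forceps).
Because FA falls as white matter is disrupted, and because damage in TLE is
organised around the epileptic focus, the pipeline works in a standardized,
focus-relative *abnormality* space and fits an event-based subtype-and-stage
model there.

### Normative abnormality z-scores

Per tract, FA is regressed on age and sex (OLS, sex coded M=0/F=1) in the
healthy controls only, so patient pathology cannot contaminate the normative
model. The residual SD uses the unbiased n − 3 denominator. A patient's
abnormality is

    z = −(FA_observed − FA_predicted(age, sex)) / residual SD,

the sign flip making "larger = more damaged" once, at the boundary, so the
progression model is agnostic to the raw biomarker's direction. Degenerate
tracts (residual SD ≈ 0) and FA cells that are missing or outside [0, 1] are
hard errors, not imputations: at 155 × 20 values, input should be clean.

Paired tracts are then relabelled ipsilateral/contralateral to each
patient's focus side (forceps unchanged). This is a pure per-row column
permutation computed after z-scoring; relabelling never re-standardizes.

### The linear z-score event model

Each of the 20 focus-relative ROIs carries a ladder of abnormality
thresholds, by default z ∈ {1, 2, 3} with an asymptote z_max = 5, giving
N = 60 events. A disease *sequence* S is a permutation of all 60 events in
which each ROI's thresholds appear in increasing order; a subject's *stage*
k ∈ {0, …, N} means the first k events have occurred. The expected
abnormality of biomarker b at stage k is the piecewise-linear curve through
(0, 0), (position of each of b's events, its threshold), and (N, z_max).
Three thresholds per ROI are the default because observed stage
distributions in tract-staging studies span many tens of stages (medians
near 16 with IQRs near 28), which a 20-event model cannot express.

Subjects are Gaussian around the trajectory with per-biomarker noise scale
sigma (default 1 — inputs are z-scores), and stage is latent with a uniform
prior over the N + 1 stages, so the subject marginal is

    log (1/(N+1)) Σ_k Π_b Normal(x_b; g_b(k), σ_b),

evaluated with log-sum-exp throughout.

### Fitting, uncertainty, subtypes, model order

*Point estimate.* Coordinate ascent over event positions: each event is
moved to its likelihood-optimal slot (within the slots its threshold ladder
allows) until no move improves. Multiple starts are used; the first is a
data-driven guess ordering events by cohort exceedance fraction (which is
always a valid sequence and typically lands near the basin of the optimum),
the rest are uniform random valid sequences. The per-event position scan
walks adjacent transpositions and updates only the two affected biomarker
trajectories, so a full sweep costs O(N · P · N) with a small constant.

*Uncertainty.* A Metropolis chain over valid sequences: the proposal swaps
two uniformly chosen positions and is re-proposed (counted, not rejected)
when the swap would break a threshold ladder; acceptance is the plain
likelihood ratio under a uniform prior over valid sequences. The chain's
positional density matrix (fraction of post-burn-in samples placing each
event at each position) is the positional-variance diagram's underlying
matrix; rows sum to 1 by construction.

*Subtypes.* C-subtype models are built hierarchically: fit C − 1, then try
to split each subtype's hard-assigned patients via seeded random
bipartitions refined by alternating refit/reassign rounds; the split with
the best total mixture likelihood is kept and mixture fractions are then
the MLE given fixed sequences (EM on fractions only). When no split is
feasible the largest subtype is duplicated — a redundant component that
model selection immediately penalizes away.

*Model order.* The number of subtypes is chosen with a cross-validation
information criterion: 10-fold subject-level splits (seeded, shuffled);
each held-out subject contributes the log of the fraction-weighted mixture
of its per-subtype stage marginals; CVIC(C) = −2 × summed held-out log
likelihood, minimized over C with ties broken toward the smaller C. One
hierarchical fit per fold yields every C ≤ C_max, so the CV cost is a
single path per fold.

*Staging.* Per patient, the subtype posterior is proportional to
fraction × subject marginal, and the reported stage posterior is the
posterior over stages conditional on the maximum-likelihood subtype; the ML
stage is its argmax with ties broken toward the smaller (less progressed)
stage. Stages are evaluated at integers only; continuous-time refinement is
out of scope.

### Association battery

ML stage is related to clinical variables with fixed nonparametric
conventions: Pearson chi-square without continuity correction for 2×2
categorical tables (this convention reproduces published TLE demographic
p-values exactly, e.g. 0.968 / 0.173 / 0.35 / 0.131; the Yates-corrected
variant is available behind a flag), two-sided Mann–Whitney U from the
tie-corrected normal approximation without continuity correction for group
comparisons (an exact-permutation option exists for n₁·n₂ ≤ 400), and
Spearman's rank correlation with the t-approximation p-value. Missing
clinical values are dropped pairwise and counted in the report. No
multiple-testing adjustment is applied; raw p-values are reported, with
p < 0.05 as the conventional significance remark.

At n₁ = n₂ = 8 with heavy ties, the uncorrected normal Mann–Whitney p and
an exhaustive permutation p agree to ~0.01 in the small-p regime; for
mid-range p the discreteness of the permutation distribution leaves an
irreducible gap of a few hundredths — a property of the approximation, not
of any implementation.

## The synthetic cohort generator

No tract-FA dataset ships with the package, so the generator inverts the
inference model with known ground truth. Defaults encode the study
conditions of a single-centre unilateral-TLE cohort:

| parameter | default | meaning |
|---|---|---|
| n_hc / n_patients | 270 / 155 | controls / patients |
| hs_fraction | 50/155 | hippocampal-sclerosis share |
| left_fraction | 107/155 | left-focus share |
| fa_baseline_mean | per tract, 0.40–0.58 | typical tract-level FA |
| fa_baseline_sd | 0.025 FA | control residual scale |
| age_slope | −0.0005 FA/yr | normative ageing effect |
| sex_offset | +0.005 FA (F) | normative sex effect |
| z_thresholds / z_max | {1,2,3} / 5 | event ladder per ROI |
| noise_sd | 1 z | subject noise around trajectory |
| stage_distribution | uniform on {0..60} | latent stage prior |

Patients get a latent stage and subtype, a lateralized abnormality vector
drawn around the planted sequence's trajectory, and FA values reconstructed
through the same age/sex baseline the normative model assumes
(FA = baseline − z · fa_baseline_sd), relabelled onto the sampled focus
side, clipped into (0, 1) (clipping is counted and is ~0 under defaults).
The default planted sequence is a fixed, clinically plausible ordering with
the ipsilateral uncinate fasciculus first and forceps/SLF/ATR early;
seed-random sequences and a maximally dissimilar "reversed pair" (a
biomarker-blocked ordering and its valid reversal, Kendall tau −0.93, the
bound threshold order permits) are available for separation experiments.

Clinical covariates are linear in stage plus Gaussian noise, floored at 0
and rounded: duration ≈ 10 + 0.24·stage ± 12 years and ASM count ≈
1.5 + 0.025·stage ± 1.5, calibrated once by Monte Carlo so that at n = 155
the stage–duration rank correlation centres near 0.33 and stage–ASM near
0.27 (the effect sizes such cohorts report). ASM counts are missing at a
~3% rate to exercise missing-data accounting. HS status is Bernoulli with
a logistic-in-stage probability (slope 0.06/stage, location calibrated so
the expected HS share equals hs_fraction), so HS patients occupy later
stages. Ages are uniform 18–70 and sex is balanced; exact demographic
medians/IQRs of any real cohort are deliberately not matched — only the
effect structure matters for recovery testing.

What the generator does *not* emulate: voxel-level DTI, scanner/site
effects, non-Gaussian or correlated biomarker noise, informative missing
data, and any real stage distribution (the beta option is a convenience).
Passing recovery tests therefore demonstrate internal consistency of the
estimator under its own assumptions, not performance on real data.

## Numerical choices and run sizes

- Stage densities are computed via the expanded Gaussian quadratic (one
  matrix product per sequence) and incremental updates under event swaps;
  incremental and full evaluations agree to ~1e−12 and are tested against
  brute-force oracles on small instances.
- Greedy defaults: 25 starts to convergence for final fits; cross-validated
  fits inside CVIC use 1 start (data-driven), 2 sweeps, 2 split attempts,
  and no MCMC — the package's desk-scale choice, recorded in every model
  file. MCMC default is 100,000 iterations with 10% burn-in; the packaged
  experiments and acceptance runs use 20,000, which is ample for the
  60-event posterior summaries reported here.
- Ties: ML stage and CVIC ties break toward the smaller value (less
  progression, simpler model). Sequence ties in the greedy scan keep the
  current position unless a strictly better slot exists (1e−9 margin).
- Degenerate inputs: empty cohorts give likelihood 0; single-sex control
  cohorts, zero-variance tracts, missing laterality, and malformed
  configurations raise named errors rather than propagating NaNs.
- Determinism: every stochastic step (generator, greedy starts, MCMC,
  CV splits, subsampled seeds) flows from one integer seed through
  `numpy.random.default_rng`; pipeline runs write SHA-256 hashes of every
  artifact, and identical configurations reproduce identical hashes.

## Known limitations

- The hierarchical splitter can lock onto stage-driven rather than
  subtype-driven bipartitions when subtypes are similar; more split
  attempts mitigate this at linear cost. Model-order selection results are
  reported as replicate frequencies for this reason.
- Stage is discrete and the trajectory piecewise-linear; sigmoidal or
  continuous-time variants are out of scope.
- The subtype posterior uses fitted point sequences, not the MCMC mixture,
  so subtype uncertainty is understated when chains overlap.
- With 60 events and 155 subjects the positional density has substantial
  spread; orderings should be read at the resolution of early/middle/late
  bands, not exact positions.
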