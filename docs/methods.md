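# Methods

`connpred` implements a connectome-based predictive framework that links
pretreatment whole-brain functional connectivity (FC) to multidimensional
treatment outcome in internalizing psychopathologies, and a synthetic-cohort
generator that emulates the statistical conditions that framework assumes.
This note documents the model, its tunable parameters, the numerical choices,
what the generator does and does not emulate, and known limitations.

## The predictive model

**Inputs.** Per participant: an FC edge vector (upper-triangle, i<j,
row-major vectorization of the region-by-region Pearson correlation matrix,
Fisher-z transformed by default) over a 442-region / nine-network atlas (400
cortical, 32 subcortical, 10 cerebellar; a 60-region layout with the same
nine networks serves fast runs), and eight clinical change scores
(post-treatment minus pre-treatment on BDI, HAMA, HAMD, PSWQ, LSAS, RUM and
the two ERQ subscales; percent change is an alternative outcome variant).

**Reduction and coupling.** Edges are z-scored with training-set statistics
and projected onto the top-k principal axes of the training correlation
matrix. The reduced scores X (n x k) and the standardized change scores Y
(n x 8) enter a regularized CCA: with sample covariances S_xx, S_yy, S_xy
(denominator n-1),

    C_xx = (1-c) S_xx + c I,  C_yy = (1-c) S_yy + c I,  c in [0, 1]
    K = C_xx^{-1/2} S_xy C_yy^{-1/2},  first singular triplet -> (w_x, w_y)

c = 0 is classical CCA; c = 1 is the SVD of the cross-covariance (a PLS-like
limit). The convex-interpolation form is what a c grid on [0, 1] implies;
both blocks share a single c. Only the first canonical pair is validated and
exported; higher singular values are computed but flagged non-validated.
`canonical_correlation_train` is reported as the Pearson correlation of the
training variates (it equals the leading singular value of K exactly at
c = 0; for c > 0 the singular value is not a correlation and can exceed 1 —
it is kept separately as a diagnostic).

**Sign convention.** CCA weights are defined up to a joint sign flip. Fitted
models are oriented so the symptom variate correlates non-negatively with
the row-mean of the standardized change scores on the training set (exact
zero falls back to making the largest-magnitude symptom weight positive).
This makes held-out scores poolable across folds and bootstrap replicates
alignable. PCA axes carry their own deterministic sign (largest-magnitude
element positive) so results are bit-reproducible.

## Validation and hyperparameter search

Three outer schemes: shuffled k-fold (default K=10), leave-one-diagnosis-out,
and leave-one-treatment-arm-out. Inside each outer training set, a 5-fold
grid search over c in {0, 0.05, ..., 1.0} and k in {10, 15, ..., min(100,
n_train-10)} picks the cell maximizing the Pearson correlation of the pooled
inner-held-out canonical score pairs — the same statistic the outer loop
reports, so the search optimizes the objective it is judged by. Ties break
toward larger c (more regularization) then smaller k (fewer components).
Requested k beyond what a training split supports is clamped to the feasible
maximum. Hyperparameters are re-searched independently per outer fold; the
selected model is fit once on the outer training rows and applied frozen to
the held-out rows (test rows never touch any training statistic; each fold
record carries a checksum of its training ids so leakage is assertable).

The prediction r is the Pearson correlation of the pooled held-out (u, v)
pairs across all participants — one scatter with n points — with per-fold
correlations also reported (for leave-one-arm-out, the per-arm values are
the quantities of interest). Pooling was chosen over averaging per-fold r
because the per-participant scatter is the natural summary of a single
cohort-wide prediction; both are available in the result object.

Inside the grid search, every cell of one inner fold shares that fold's
standardization and PCA at the largest feasible k: principal axes are
nested, so truncating the score matrix to k columns is exactly the k-column
fit, and the per-cell work reduces to small eigen/SVD problems. A test
asserts this fast path agrees with naively refitting each cell through the
public solver to 1e-8.

## Inference

**Permutation test.** Shuffles which participant's clinical row is paired
with which FC row, then reruns the *entire* nested validation (inner search
included) per shuffle, so the null distribution inherits the selection
effects of the grid search. p is the strict proportion of null r values
exceeding the observed one (no +1 correction by default; a flag enables the
(b+1)/(m+1) variant). 1000 permutations is the reporting default;
simulation tests use 99.

**Edge attribution.** Per-edge Pearson correlation with the brain variate u
from a full-cohort fit (hyperparameters from one 5-fold search on all data),
exact t-based two-sided p with n-2 df, Benjamini-Hochberg FDR at q < 0.05,
sign split, and counts per unordered network-pair cell (the tables behind
chord diagrams). Caveat: u is itself a linear combination of the tested
edges, so these tests are circular — under a pure-noise cohort the chance
of at least one BH discovery is high (~0.7 in simulation) even though the
*fraction* of noise edges flagged stays far below q (~0.001). The
attribution is therefore interpretive, ranking edges by their association
with the fitted variate, not a familywise-calibrated discovery procedure.

**Metric loadings.** Correlation of each change score with the symptom
variate v on the full cohort.

**Bootstrap stability.** Participant-level resampling with replacement;
each replicate refits at the full-fit (c, k) (no re-search), is sign-aligned
to the reference by the cosine of its symptom weights, and contributes
per-edge / per-metric loadings. Reported: sign-consistency against the
reference sign and 95% percentile CIs. Because replicates share data with
the reference, consistency under a null cohort is centered near 0.5 but
with dependence-induced spread; at n=181 over 95% of null edges fall in
[0.35, 0.65].

**Responder tiers.** Participants ranked by mean standardized change on a
chosen set of scales (direction configurable; "increase" matches the
orientation convention of v); top tertile vs rest compared on pooled
held-out v by the Mann-Whitney rank-sum statistic with a 10,000-draw
permutation p.

**Subset scans.** Network-restricted (within / between / both edge modes;
default both) and metric-restricted models rerun the standard validation
per subset; size-1 network models run across fold-split seeds, larger sizes
run every combination (subsampled above 200 per size, flagged in the
output). The identity restriction reproduces the full model bit-for-bit.

## The synthetic generator

One latent factor z ~ N(0,1) per participant drives both blocks:

    edges   = mu + a (gamma z) + N(0, sigma_b^2 I)
    metrics =      b (delta z) + N(0, sigma_y^2 I)

with unit-norm loadings a (supported on configurable network-pair cells,
first ceil(fraction * cell) edges in edge order, signs alternating +,-,+ so
both positive and negative contributions exist) and b (defaults dominated by
RUM, PSWQ, LSAS). The population correlation of the two sides' best
projections is rho* = gamma delta / sqrt((gamma^2+sigma_b^2)(delta^2+sigma_y^2)).
Six diagnosis categories and three treatment arms are assigned at fixed
proportions (deterministic largest-remainder counts, shuffled), optionally
with per-group mean shifts (scale 0.1 by default) — nuisance only, no
group-specific latent slope, which is what keeps cross-group generalization
achievable. Pre/post scale scores are synthesized around the change scores
from constant per-metric baselines (a baseline-SD knob exists; with constant
baselines the percent-change outcome is an affine rescaling of the
difference outcome).

**Default calibration.** gamma=6, sigma_b=1, delta=1, sigma_y=sqrt(107/37),
giving rho* = 0.5. The asymmetric split is deliberate: at n=181 by 1770
edges, PCA detects the planted direction only when the edge-side spike
gamma^2/sigma_b^2 clears the spiked-covariance (BBP) threshold
sqrt(p/n) ~ 3.1 with margin; the attenuating noise is placed on the
8-dimensional symptom side where estimation is stable. Under these
conditions 10-fold validation recovers a held-out r of ~0.44 +/- 0.06
against the planted 0.5 — the gap is subspace- and weight-estimation
attenuation, irreducible at this n. `SyntheticSpec.from_target_rho` solves
sigma_y for any other target. These values encode simulation conditions,
not claims about real effect sizes.

**What the generator does not emulate.** No fMRI physics, motion,
hemodynamics or scanner noise; no treatment mechanism (arms differ only by
nuisance shifts); a single factor (real brain-symptom covariance is likely
multi-factor); Gaussian noise with homogeneous variance; no missing data
(completers-only by construction); no site or scanner effects. Passing
recovery tests therefore demonstrates that the pipeline estimates what it
claims under its own assumptions — not that those assumptions hold in
clinical data.

A separate time-series generator exercises the FC-construction path: region
signals mix a shared per-network factor (weight 0.3 by default) with white
noise, giving block-structured expected correlation matrices.

## Numerical choices

- Covariance denominator n-1 throughout; standardization uses ddof=1 SDs.
- Inverse square roots by symmetric eigendecomposition with a relative
  eigenvalue floor of 1e-12 x (largest regularized eigenvalue); classical
  (c=0) solves on a singular block raise an advisory error rather than
  silently flooring.
- Correlations are clipped to +/-(1 - 1e-7) before the Fisher z transform.
- Zero-variance regions, edges, or metrics are hard errors naming the
  offending column — silent NaN propagation is the alternative failure mode.
- All randomness flows through named integer seeds (numpy Generator /
  SeedSequence); per-fold seeds are derived deterministically from the run
  seed, so identical inputs give byte-identical artifacts.
- Test-scale problem sizes: the 60-region nine-network layout (1770 edges)
  for study-scale simulations, a 30-region layout (435 edges) for unit
  tests, 99 permutations and 100-200 bootstrap replicates in simulations
  (1000 remains the reporting default). The acceptance script uses 99
  permutations and a single-cell grid for its permutation stage.

## Known limitations

- The full-fit attribution is circular (see above); a cross-validated
  variate option would trade interpretability for calibration and is left
  as an extension.
- Only the first canonical pair is validated; cohorts with several
  comparable latent factors would need the higher pairs.
- The percent-change outcome requires nonzero pre scores and is sensitive
  to small baselines; the difference outcome is the default for a reason.
- Leave-one-group-out folds inherit whatever confounding the group labels
  carry; the framework tests generalization, it does not adjust for
  group-level covariates.
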