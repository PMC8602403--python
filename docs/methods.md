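# Methods

## The data model

All analyses consume a validated per-cell table: unique cell id, tissue-
microarray spot, patient, response arm, timepoint, planar centroid (x, y),
a curated cell-type label, non-negative marker intensities, and a positive
cell area in pixels. Each spot belongs to exactly one (patient, arm,
timepoint). Coordinates are treated as abstract planar units — every
downstream statistic is either a ratio or compared within a spot, so no
micron conversion is performed. Column names in platform exports vary, so
readers take a column mapping onto the canonical names; marker intensities
are taken as given (no compensation or normalisation is attempted).

Bulk expression is a genes × spots matrix with an explicit transform state:
`raw_TPM` values are per-spot rescaled to one million and transformed as
log2(x + 1) exactly once. The +1 pseudo-count handles zero counts; the
state flag makes double transformation an error rather than a silent bug.

## SpatialScore

For a triplet (CT1 source, CT2 "right" target, CT3 "left" target), every
CT1 cell's score is the ratio of the distance to its nearest same-spot CT2
cell over the distance to its nearest same-spot CT3 cell. A cell is never
its own target. Distances never cross spot boundaries (cores are separate
pieces of tissue). CT1 cells in spots missing either target type are
excluded and counted, never given infinite or zero ratios. Nearest
neighbours come from a KD-tree; the test suite holds the KD-tree path to an
O(n²) brute-force oracle.

Aggregation pools cells: the arm mean is the mean over all of that arm's
scored cells, and per-patient values pool the patient's cells at a
timepoint. Standard errors are reported both over cells and over spot
means, because the two conventions answer different questions (precision of
the pooled mean vs between-core variability); per-spot means are also
emitted for spot-level plots and models.

### Random-sampling null

Per spot: replace the n CT1 cells with n non-CT1 cells drawn without
replacement, average their ratios, repeat 100 times. `quant` is the
percentage of random means *strictly* smaller than the measured CT1 mean
(ties have measure zero for continuous coordinates); the across-iteration
average of means is reported alongside. Only non-CT1 cells with defined
ratios enter the sampling pool — a spot's only CT2 cell, for instance, has
no distance to another CT2 cell — and spots whose pool is smaller than n,
or that lack either target, are skipped with a warning. Under complete
spatial randomness quant is uniform on [0, 100]; the acceptance suite
verifies this with a Kolmogorov–Smirnov test over 200 simulated spots.

## Cellular neighborhoods

Each cell's window is itself plus its w − 1 nearest same-spot neighbours
(default w = 10); the window's cell-type frequency vector is the feature.
Vectors are clustered with k-means (k-means++ initialisation, n_init = 10,
fixed seed; default k = 10), and each cell inherits the cluster of the
window centred on it. Full-batch k-means is the default for determinism; a
mini-batch flag exists for very large tables. Spots smaller than w use all
their cells rather than being dropped — dropping would bias small cores.
k-NN ties are broken by lowest row index; the composition is unaffected
when tied cells share a type. Frequencies (not counts) are clustered; at
fixed w the two differ by a constant factor. Choosing k automatically and
graph-based neighborhood definitions are out of scope.

## Expression scores

**PCA signature scores.** The per-spot score of a gene signature is the
first principal component of the spots × signature-genes submatrix of the
log2-TPM matrix, genes centred. PC1's sign is arbitrary, so the score is
oriented to correlate positively with the per-spot mean signature
expression; the orientation and PC1's explained-variance share are
reported. At least two signature genes must be present (missing symbols
are listed) and at least three spots are required.

**LASSO association.** Per-spot responses — the natural-log tumor-cell
percentage (+1 percentage-point pseudo-count) or the natural-log per-spot
SpatialScore — are regressed on per-spot log2 expression with an L1
penalty. Natural log for responses and covariates, log2 for expression:
the base affects only coefficient scale, not support recovery. For the
tumor model the log CD4⁺-frequency covariate enters unpenalised, handled by
Frisch–Waugh partialling-out (which leaves penalised coefficients exactly
unchanged) with the covariate coefficient recovered by least squares on the
residual. Predictors are standardised before penalisation and coefficients
rescaled back; folds are seeded random 6-fold splits, with an optional
patient-grouped split to avoid same-patient leakage across serial cores.
The regularisation strength uses the **1-SE rule**: the sparsest alpha
whose mean validation MSE is within one standard error of the minimum.
Plain CV-minimum selection (`alpha_rule="cv_min"`) is available, but at
realistic spot counts (tens of spots, hundreds of genes) it is known to
drag one to a few dozen spurious genes into the support; the 1-SE
convention (glmnet's `lambda.1se`) restores reliable support recovery and
is therefore the default.

**Fold-change phenotyping.** Per spot, the ratio of mean tumor-cell marker
intensity over mean reactive-CD4 intensity, plus the same ratio for cell
area; cores with fewer than five CD4⁺ T cells (tumor + reactive combined),
or with either population empty, are excluded and listed. The cohort
summary is the mean ± s.e.m. of per-spot ratios. Marker-positive subset
frequencies use explicit intensity thresholds standing in for manual
gating, with the denominator either all cells or a declared immune set.

## Inference and robustness

Group contrasts on repeated per-cell or per-spot measurements use a linear
mixed model with a patient random intercept, REML-fitted via statsmodels
MixedLM. Satterthwaite degrees of freedom are computed in-house (they are
not available in statsmodels): the contrast variance f(θ) = c'(X'V⁻¹X)⁻¹c
is differentiated numerically in θ = (τ², σ²), the observed REML
information is a numeric Hessian of the restricted log-likelihood (all
block operations use the closed-form rank-one inverses the random-intercept
structure allows), and df = 2f²/(∇f'A∇f). The implementation is verified
against R lme4 + lmerTest in the test suite (agreement to ≈4 decimals on
non-singular fits). A singular fit (no between-patient variance) falls back
to pooled OLS with a logged note; near the τ² = 0 boundary the profiled
likelihood is clamped to the boundary, which can make the computed df
differ from lmerTest's singular-fit convention (df = n − p) while leaving
the estimate, standard error and conclusion unchanged. Four-way
group/timepoint comparisons are Holm-Bonferroni adjusted; the two
biomarker contrasts (pre and post) are reported unadjusted because they
address independent questions.

Robustness of a contrast is assessed by (a) 100 random subsamples of a
fixed fraction of the observations (subsampling is over observations,
i.e. per-cell score measurements), refitting the mixed model each time and
reporting the share of iterations with p < 0.05; an iteration that empties
a group is redrawn and logged; (b) leave-one-patient-out refits, one per
patient, requiring at least three patients per group; and (c) per-iteration
bootstrap-coupled estimation of the mean difference: 5,000 seeded
resamples, percentile 95% CI. ROC analysis runs over per-patient scores;
orientation is auto-detected (low scores predicting response, as a
proximity biomarker behaves), the cutoff maximises Youden's J (the
criterion is surfaced in the report since the choice is conventional), and
the reported cutoff is the midpoint between the adjacent observed scores
the optimal threshold separates, so separable data yield a cutoff strictly
between the groups. Wilcoxon rank-sum and signed-rank tests are exact for
n ≤ 25 per group and normal-approximate above; an all-zero-difference
signed-rank input is flagged degenerate.

## The synthetic cohort generator

The generator emulates the statistical shape of a two-arm immunotherapy
imaging cohort: 7 patients per arm, two timepoints, two 0.6 mm circular
cores (radius 300 px at ~1 µm/px) per patient and timepoint, 1,000 cells
per core, and a seven-type vocabulary (reactive CD4 T, PD-1⁺ CD4 T, tumor,
Treg, CD8 T, M1 macrophage, other) with fixed proportions — the minimum
needed to exercise every stage.

**Spatial attraction.** Cells of non-source types are placed uniformly in
the disc. A source type with strengths θₐ toward anchor types a places each
cell, with probability θₐ/(1 + Σθ), at a random anchor cell plus a
displacement with planar density ∝ exp(−d/λ) (distance ~ Gamma(2, λ),
uniform angle, rejected back into the disc), and uniformly with the
remaining probability 1/(1 + Σθ). θ = 0 reduces *exactly* to complete
spatial randomness — the property the null-calibration tests rest on — and
θ is a single interpretable knob per pair. The Gamma(2, λ) distance (the
2-D reading of the exponential kernel) vanishes linearly at zero like a
true planted point process, keeping the distance-ratio's mean finite; an
exponential *distance* would put positive density at contact and give the
ratio an infinite mean in the left-attraction direction. λ defaults to
10 px — a displacement of about two cell diameters, the scale of direct
cell-cell interaction. This is a sampling recipe chosen for exactness and
speed, not a Gibbs process, and it is a test harness, not a claim about
tumor biology. A per-(arm, timepoint) attraction override lets one cohort
encode distinct spatial phenotypes (responders' effectors attracted to
tumor, nonresponders' to Tregs).

**Markers, sizes, expression.** Marker intensities are lognormal with
shared baselines; tumor-cell intensities are multiplied by configurable
fold-change factors (defaults 0.26 / 1.40 / 3.20 / 5.73 for CD7 / CD30 /
CD25 / Ki-67, with tumor cells generated larger), so the fold-change
estimator can be checked against known truth. Expression is generated on
the log scale: per-gene baseline + coefficient × spot covariate (log tumor
percentage or log SpatialScore) + arm/timepoint signature shifts + Gaussian
noise, giving a known sparse support for the LASSO to recover. Determinism
is per-entity: every spot and stream derives its RNG from the root seed
plus a stable CRC32 hash of its identity, so any subset of spots reproduces
bit-for-bit regardless of what else is generated.

**What the generator does not emulate** — segmentation error, marker
spillover, spatially varying cell density, realistic transcriptome
covariance, batch effects. Passing tests therefore demonstrate algorithmic
correctness and statistical calibration under the stated model, not
robustness to the artefacts of real imaging pipelines.

## Problem sizes and numerical choices

End-to-end checks run at desk scale, chosen so the full suite completes in
a couple of minutes: 200 spots × 300 cells for null calibration; 1,000
spots per θ level for attraction monotonicity (the θ = 2 → 5 mean gap is a
few hundredths, so strict ordering needs that many cores); 3 × 500 cells
for planted-region recovery; 64 spots × 300 genes for support recovery
(every support gene at R² ≈ 0.8); 1,000 replicates for mixed-model type-I
error and 500 for bootstrap coverage. k-means and LASSO seeds are fixed
arguments everywhere; KD-tree results are exact (verified against brute
force); quant uses strict inequality; Holm adjustment is the statsmodels
implementation.

## Known limitations

Distances are 2-D Euclidean within a core — no tissue masking, geodesics
or 3-D. The mixed model is a single random intercept per patient; nested
spot-within-patient or crossed structures are not modelled, matching the
repeated-measures design it serves. The ROC cutoff criterion (Youden's J)
is a convention, and per-patient ROC on ~14 patients has wide sampling
variability. The attraction simulator's θ is not calibrated to any
physical interaction strength; only its ordering and its exact θ = 0 null
are meaningful.
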