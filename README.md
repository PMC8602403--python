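# spatialscore

Spatial biomarkers from segmented multiplexed tissue imaging (CODEX,
Vectra/Opal), built around the **SpatialScore**: for every effector T cell
(CT1, e.g. a PD-1⁺ CD4⁺ T cell) in a tissue-microarray core,

```
r = d(CT1 → nearest tumor cell)  /  d(CT1 → nearest Treg)
```

the ratio of the Euclidean distance to its nearest "right" target (tumor,
CT2) over its nearest "left" target (Treg, CT3). Low scores mean effector
cells sit against the tumor — the immunologically favourable geometry; high
scores mean they sit against regulatory T cells. Because the score is a
ratio it is free of units and invariant to translating, rotating or
rescaling the coordinates.

The package is aimed at analysts of segmented single-cell imaging tables
(one row per cell: spot, patient, arm, timepoint, x/y, cell type, marker
intensities, size) and provides, as composable library functions plus a
thin CLI:

* **Cellular neighborhoods** — k-NN window composition vectors (window
  size 10: the index cell and its 9 nearest same-spot neighbours) clustered
  with k-means (k = 10 by default) into recurring local milieus, with
  per-spot CN frequency tables.
* **SpatialScore** — per-cell ratios, spot/patient/arm aggregates, and a
  random-sampling null: each spot's CT1 cells are replaced by an equal
  number of random non-CT1 cells, 100 times; `quant` is the percentage of
  random means below the measured mean (≈ 50 for random tissue, near 0 or
  100 for organised tissue).
* **Expression links** — per-spot PC1 gene-signature scores (IFN-γ-,
  TGF-β-style lists), and LASSO association of per-spot log expression with
  the log tumor-cell percentage (with an unpenalised CD4-frequency
  covariate) or the log SpatialScore; 6-fold cross-validation with the
  1-SE alpha rule, 1 percentage-point pseudo-counts before logs.
* **Phenotyping** — per-spot tumor-vs-reactive marker fold changes and
  cell-size ratios, excluding cores with fewer than 5 CD4⁺ T cells, and
  thresholded marker-positive subset frequencies.
* **Inference and robustness** — group contrasts by linear mixed model with
  a patient random intercept and Satterthwaite degrees of freedom
  (cross-checked against lme4/lmerTest), Holm-Bonferroni adjustment,
  Wilcoxon tests, 100-iteration subsampling, leave-one-patient-out
  exclusion, bootstrap-coupled effect-size estimation and ROC analysis with
  a Youden-J cutoff.
* **Synthetic cohorts** — a generator that plants tunable pairwise spatial
  attraction between cell types (strength θ, length-scale λ; θ = 0 is
  exactly complete spatial randomness), marker fold changes, and expression
  matrices with known sparse dependence on spatial covariates, so every
  stage is testable without patient data.

## Worked example

The numbered drivers under `analysis/` run the full study on a synthetic
14-patient cohort (two arms × two timepoints, two 0.6 mm cores per patient
and timepoint, 1,000 cells per core) in which responders' PD-1⁺ CD4 T cells
are attracted to tumor cells and nonresponders' to Tregs:

```bash
python analysis/01_simulate_cohort.py
python analysis/03_spatial_score.py
python analysis/05_robustness.py
```

prints, among other things:

```
group means (cells pooled):
nonresponder  post    1.141
              pre     1.134
responder     post    0.710
              pre     0.705
mean quant per arm: {'nonresponder': 74.9, 'responder': 30.2}
pretreatment contrast: estimate 0.429, df 354.3, p 0.000159
subsampling at 50%: 88% of iterations significant
subsampling at 75%: 100% of iterations significant
leave-one-patient-out: 100% of 14 iterations significant
per-patient ROC: AUC 0.939, cutoff 0.8271 (low_predicts_positive)
```

Read: responders' mean SpatialScore (0.70) sits well below nonresponders'
(1.13) before treatment; the mixed-model contrast puts the difference at
0.43 with p ≈ 1.6×10⁻⁴; the difference survives 50%/75% subsampling and
excluding any single patient; and a per-patient cutoff of ≈ 0.83 separates
the arms with AUC 0.94. The same calls work on real cell tables via
`spatialscore score --cells cells.tsv --ct1 "PD-1+ CD4 T" --ct2 tumor
--ct3 Treg --out out/`.

## Layout

```
src/spatialscore/   io, simulate, neighborhoods, scoring, expression, stats, cli
analysis/           numbered drivers reproducing the study narrative
tests/              unit, property and end-to-end acceptance tests
scripts/            acceptance.py
docs/methods.md     models, assumptions, parameter choices, limitations
```
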