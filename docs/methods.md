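# Methods

This note documents the models, conventions, and numerical choices behind
`cytofps`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Data model and panel

The unit of data is an event table: events × 28 channels for one
individual in one condition (`basal` or `stim`), with channels split into
7 QC channels (`Event_length`, the Gaussian acquisition parameters
`Center`/`Offset`/`Width`/`Residual`, and the DNA intercalators
`191Ir_DNA1`/`193Ir_DNA2`), 12 phenotyping markers (CD20, CD3, CD4, CD8a,
CD45RA, CD56, CD16, CD14, CD61, CD11c, CD123, HLA-DR), and 9 functional
markers (Caspase3, p-p38, p-Akt, p-cJun, p-NFkB, IkBa, CD120a, CD120b,
CD86).  Channels resolve by name (metal_marker dialect, configurable
alias map), so file column order never matters.  CD45 is deliberately not
part of the clustering panel: as a pan-leukocyte marker it carries no
between-subset contrast.

Marker channels are variance-stabilized with `asinh(x / cofactor)`,
cofactor 5 (the CyTOF convention; configurable).  QC channels are never
arcsinh-transformed — cleanup standardizes them instead.  The transform
is strictly increasing and invertible, so rank-based statistics downstream
are unaffected by the cofactor choice; only Gaussian-scale summaries
(means, mixture fits) depend on it.

File formats: FCS 3.0/3.1 list-mode float (own minimal codec, as no
suitable reader/writer is otherwise available in the dependency set) and
delimited text with a header row.  Only raw tables are persisted;
transformed tables are in-memory objects.

## Cleanup

Per sample, the QC matrix is mean-variance scaled (population SD) and a
two-component full-covariance Gaussian mixture is fit by EM
(k-means initialization under a caller seed, covariance ridge 1e-6, stop
when the relative log-likelihood gain drops below 1e-6 or after 200
steps; the per-step mean log-likelihood trace is retained and is
non-decreasing by EM monotonicity).  Events are assigned by maximum
posterior and the component with the smaller *mixing weight* is discarded
wholesale as doublets/debris.  Exactly equal weights resolve by keeping
the component with the larger total posterior mass.  A smaller weight
below 0.1% is still removed but flagged prominently in the report,
since it likely indicates an over-clean sample rather than real debris.

Fitting is per sample rather than pooled because acquisition artifacts
(clogs, doublet rates) are sample-specific; a pooled fit is available by
concatenating tables upstream.

## Clustering and annotation

Cleaned events from **all individuals and both conditions** are pooled
and clustered once, so every meta-cluster exists in both conditions and
paired stim-vs-basal features are well-defined.  Greedy farthest point
sampling picks k=49 representatives on the arcsinh-scale phenotyping
markers (unweighted Euclidean): the first pick is uniform under the run
seed (or fixed via `start`), each later pick maximizes the minimum
distance to the chosen set, ties to the lowest index, O(nk) time with a
single running min-distance array.  Clusters are the Voronoi cells of the
representatives; no Lloyd refinement is applied (FPS is used as a k-means
surrogate; a refinement pass could be added but changes the method).

Size filters use strictly-less-than semantics with boundary-inclusive
keep: clusters below 1/100,000 of all events are discarded, then
complete-linkage agglomeration of the surviving representatives is cut at
15 meta-clusters, and meta-clusters below 0.5% of all events are
discarded.  Both denominators are the pre-filter event total.  Because
thresholds like 1e-5 × 1e6 are float arithmetic, comparisons carry an
absolute slack of 1e-9 so exact boundaries behave as specified.

Meta-clusters are annotated from their median phenotyping profiles by a
fixed-priority rule table (Bc: CD20⁺HLA-DR⁺; CD4 Tc: CD3⁺CD4⁺, naive vs
memory by CD45RA; CD8 Tc: CD3⁺CD8⁺; NKc: CD56⁺CD3⁻; cM: CD14⁺CD61⁺;
mDc: CD11c⁺HLA-DR⁺CD14⁻; pDc: CD123⁺HLA-DR⁺CD11c⁻; otherwise
"unassigned").  A marker is called "hi" when the profile value exceeds
the midpoint of that marker's range across kept meta profiles.  The
midpoint was chosen over a median-of-profiles cut after direct
comparison: when fewer than half the metas express a marker, the median
sits inside the "lo" mode and sampling noise around it produces spurious
hi calls (observed as pure classical-monocyte metas annotated as B
cells); the midpoint separates the bimodal hi/lo structure of lineage
markers robustly.  A zero-spread marker is "lo" everywhere.

## Features

Per individual × kept meta-cluster × functional marker (arcsinh scale):

- `median_basal` — median over basal events;
- `q90_basal` — 90% quantile, linear interpolation between order
  statistics (h = 0.9·(n−1));
- `arcsinh_ratio` — median(stim) − median(basal); the difference of
  arcsinh medians is the standard phospho-cytometry "arcsinh ratio"
  (the arcsinh of a ratio of raw medians is a config-level alternative
  that was not adopted because it is undefined at zero medians).

Model variants: `basal` = medians + q90s (216 columns at 12 kept metas),
`ratio` = ratios (108), `combined` = union (324).  Column order is a pure
function of (kept metas, marker order, variant).  A cell backed by fewer
than `min_cells = 10` events in any contributing condition is treated as
missing, imputed with the cohort median of its column, and logged; the
pre-imputation matrix is kept so that cross-validation can re-impute
strictly inside each training set.

## Classification

The lasso-logistic objective is mean negative log-likelihood plus
λ‖β‖₁ over features standardized to zero mean and unit (population) SD,
intercept unpenalized; coefficients are reported on the standardized
scale.  The solver is proximal Newton: IRLS weights p(1−p) (floored at
1e-6), weighted least-squares subproblems solved by coordinate descent
with soft-thresholding (exact zeros), full-feature sweeps only when the
active set may grow, backtracking line search on the true objective so
every accepted step descends, and warm starts along the decreasing λ
path.  Stopping: relative objective decrease below 1e-9 per Newton step,
verified against a full-feature pass.  The solver is deterministic, so
classification results are seed-free given a feature table.

Double leave-one-out CV: the outer loop holds out each individual in
turn; the inner loop, on the remaining n−1 only, evaluates a 50-point
log-spaced λ grid from that training set's λ_max down to 1e-3·λ_max by
inner LOO mean binomial deviance (deviance is smoother than accuracy at
these n; exact ties resolve to the larger λ).  The grid top sits a hair
(1e-9, relative) above λ_max so the all-zero model is numerically exact
there.  Standardization, imputation references, λ selection, and the fit
all exclude the held-out row, which is directly asserted by a
perturbation test.  Predictions threshold at 0.5 (exactly 0.5 predicts
the control group); AUC is the Mann-Whitney rank statistic with ties
counted 1/2.  The reported coefficient set comes from a full-cohort refit
at the λ chosen by full-cohort LOO deviance (the union-over-folds
alternative would conflate fold-specific noise with the final model).

## Group comparisons

Per (kept meta, functional marker, condition) the per-individual medians
and 75th percentiles are compared between groups with two-sided
Mann-Whitney U tests: exact by enumeration when n₁·n₂ ≤ 400 with no
ties, otherwise the normal approximation with tie and continuity
corrections; fully tied inputs return p = 1.  P-values are reported raw —
deliberately no multiplicity correction, matching the exploratory framing
of this kind of screen; a Benjamini-Hochberg column is available behind a
flag.  These tests run on meta-cluster summaries (the automated analog of
manually gated subsets), so their rows are interpretable next to the
classifier's coefficients.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes, with
full ground truth:

- **Subsets.**  Eight annotatable subsets (Bc 4.3%, naive CD4 Tc 27.5%,
  memory CD4 Tc 32.5%, CD8 Tc 15.3%, NKc 5%, cM 5.7%, mDc 8.8%, pDc 1%;
  the family-level proportions follow the reported meta-cluster
  composition of such cohorts and are normalized to sum to one).  Lineage
  profiles are hi/lo templates realized as Gaussians on the arcsinh scale
  (hi 4.0, lo 0.5, SD 0.4) — separable but overlapping blobs.
- **Signaling.**  Functional markers are Gaussian on the arcsinh scale
  with subset-specific basal means (CD86 and the TNF receptors sit higher
  on antigen-presenting cells) and a TNF response added in the stim
  condition: IkBa down (degradation), p-NFkB and p-p38 up, strongest in
  the receptor-rich myeloid compartment, moderate in T cells.
- **Disease effects.**  The default scenario plants, in the RA group
  only, basal shifts of ±`effect_scale` arcsinh units: p-p38, IkBa,
  p-cJun up in memory CD4 T cells, p-cJun up in naive CD4 T cells,
  p-NFkB up and CD86 *down* in cM and mDc.  Scale 0 is the null
  configuration.
- **Individuals.**  Random intercepts per (individual, subset, functional
  marker), SD 0.2 arcsinh units, shared across that individual's two
  conditions — so the leave-one-out unit is a genuinely heterogeneous
  individual, and paired ratio features cancel the intercepts (which is
  why basal-only disease effects leave the ratio model uninformative).
- **Artifacts.**  A doublet-like population (fraction 8% by default)
  shifted +4 clean-SDs in every QC channel, with marker values resampled
  from independently scrambled subsets.
- Back-transform to raw scale: `sinh(v)·cofactor`, truncated at zero.
  Everything is driven by one `numpy` Generator seed; identical seeds
  give bit-identical cohorts.

What the generator does **not** emulate: mass-channel spillover,
barcoding/debarcoding errors, acquisition drift, non-Gaussian marker
shapes (bimodality within a subset), abundance differences between
groups, or correlated marker noise.  Passing recovery tests therefore
demonstrates that the pipeline's inference machinery is correct and
calibrated under its own assumptions — not that those assumptions hold
for any particular instrument run.

## Problem sizes in the test suite

The test and acceptance suites run cohorts of 40 individuals × 2
conditions at 600–4,000 events per sample (the acceptance script uses
2,000), sizes at which every statistical property under test — binomial
null calibration of the CV, Mann-Whitney p uniformity, subset-recovery
ARI, planted-effect recovery — is already stable, while the whole suite
completes on a single CPU in minutes.  The pipeline itself streams
assignment in bounded-memory chunks and has been exercised at
10⁶-event pools; nothing in it is specific to the test scale.

## Known limitations

- **Leave-one-out anti-learning under the null.**  When the data carry no
  signal, the inner loop correctly selects the all-zero model, whose
  intercept is the training-set log-odds: logit(19/39) when a case is
  held out, logit(20/39) when a control is — always on the wrong side of
  the 0.5 threshold.  A fully degenerate null cross-validation therefore
  reports accuracy (and AUC) near 0, not near 0.5; observed null-seed
  accuracies are bimodal at ~0 (all folds degenerate) and ~0.5-0.75
  (noise features selected).  This is a structural property of LOO with
  near-constant classifiers, well known in the small-sample CV
  literature; a strongly below-chance accuracy should be read as "no
  signal", not as an inverted classifier.  Permutation tests of the full
  pipeline are the calibrated alternative when a null reference is
  needed.

- FPS is sensitive to gross outliers (they are, by construction, far
  points); the QC cleanup stage is therefore load-bearing, and data with
  artifacts that are *not* separable in the QC channels will seed
  representatives on junk.
- The annotation rule table encodes one specific panel; other panels
  need their own rules.
- With n = 40 individuals, the CV accuracy estimate itself has a
  binomial SD of ≈ 0.08; differences between model variants smaller than
  that are not interpretable on a single cohort.
- The λ grid's lower bound (1e-3·λ_max) can truncate very dense models;
  it matches the sparsity regime these cohorts live in.
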