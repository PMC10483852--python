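# Methods

This note documents the statistical procedures, the synthetic-data
model, the defaults and the design choices behind `siglec15-tme`.

## Data model and conventions

Coordinates are continuous micrometres in image convention (origin
top-left, y downward); distances are Euclidean on nuclear centroids, and
areas are mm² (1 mm² = 10⁶ µm²). The imaged field defaults to
931 × 698 µm (≈ 0.65 mm²), three fields per patient. Binary marker
calls are the primary representation, matching what phenotyping software
exports; when a table carries only intensities, calls are derived with a
threshold-inclusive rule (intensity ≥ threshold ⇒ positive). Tissue
class (tumor/stroma) comes from tissue segmentation and is independent
of the phenotype gates; per-compartment tissue areas are required ROI
inputs because segmentation areas cannot be recovered from cell tables
alone (the generator emits them exactly).

Empty denominators (empty compartment, zero area, no reference cells,
no pairs in radius) always propagate as missing values, never as zero:
a patient with no TAMs has *undefined* — not 0% — Siglec-15 positivity
in the macrophage compartment.

## Phenotyping and quantification

Cells receive exactly one primary label by the first matching rule in
priority order tumor (CK⁺) > TAM (CD68⁺) > Treg (CD4⁺FoxP3⁺) >
Teff (CD4⁺FoxP3⁻) > CD8 T (CD8⁺), else `other`; marker co-positivity
handling is not fixed by convention in this field, so the order is
configurable. Siglec-15/PD-L1/CD163 ride along as sub-flags rather
than labels, so the labels always partition the cell set.

Patient-level percentages pool cells across ROIs rather than averaging
per-ROI percentages: pooling is robust to sparse ROIs where a
percentage would be computed over a handful of cells. Total-area
density is (tumor count + stroma count)/(tumor area + stroma area) and
therefore equals the area-weighted combination of the compartment
densities by construction. M2-ratio bands split the CD163⁺ fraction
among Siglec-15⁺ TAMs at 50% and 75%, lower-bound inclusive, reading
the printed interval notation (<50, 50–75, ≥75).

## Spatial statistics

The neighbor search uses a k-d tree with an inclusive radius (≤ r);
a cell in both the reference and target sets is never its own neighbor.
The tree search is validated bit-exactly against an exhaustive
all-pairs computation, which is kept as an independent reference
implementation.

The density normalization is deliberately two-mode. "Normalized to
tissue area" is ambiguous between the search-disc area and the ROI
tissue area; disc-area normalization (count / πr², averaged over
reference cells) makes values comparable across radii and estimates the
local target intensity, so it is the default, while `tissue` mode
(mean count / ROI tissue area) is exposed for sensitivity analyses.
For homogeneous Poisson targets the disc-mode mean is an unbiased
estimator of the target intensity for *interior* reference cells; no
edge correction is applied (none is standard for this statistic), and
an optional guard margin excludes reference cells within r of the ROI
border — the calibration experiment uses it, since border discs are
clipped and would bias the estimate low by ≈ 2% at r = 20 µm on this
field size.

Patient-level statistics pool reference cells across the patient's ROIs
(reference-cell-weighted) rather than averaging ROI values, so an ROI
with three reference cells cannot swamp one with three hundred.
Stratified comparisons default to paired Wilcoxon signed-rank across
patients with both strata defined (the strata are within-patient
subsets of the same tissue); an unpaired Mann-Whitney mode exists for
between-cohort use. With fewer than two usable patients the test is
reported as undefined. Two-sided α = 0.05 throughout; no
multiple-testing correction is applied across radii or features by
default (a Benjamini–Hochberg helper is provided as an opt-in
extension).

## Cutoffs, survival, immunotyping

The Youden cutoff maximizes J = sensitivity + specificity − 1 over the
observed feature values for predicting a binary outcome, ties broken
toward the smaller cutoff; "high" is always cutoff-inclusive, matching
the ≥1/≥5/≥25% fixed family. The outcome the original cutoffs were
tuned against is not recorded, so the default outcome is the DFS event
indicator over full follow-up (censoring ignored for the cutoff search
only) — a documented approximation, and the cutoff method/outcome are
configurable. The reference dichotomizations used throughout are
5% (tumor compartment) and 16% (macrophage compartment).

Kaplan–Meier, log-rank and Cox fitting delegate to `lifelines`.
Stepwise multivariate Cox is forward entry of every covariate with
univariate p < 0.05 and no removal step — the simplest rule consistent
with reporting only univariate-significant covariates in a joint model.
Constant covariates are dropped with a warning. Spatial-feature
survival stratification (e.g. CD8 density around Siglec-15⁺ tumor
cells) dichotomizes at the cohort median by default, configurable,
since no published rule exists for that split.

TMIT crosses Siglec-15 status (compartment cutoff above) with CD8
status. The CD8-high threshold is not published for the imaging-based
typing; the default is the cohort median of CD8 T-cell density in total
tissue area, and the interface accepts any per-patient scalar so an
expression-based feature can be substituted. The default group
contrast is CD8L_S15H vs CD8L_S15L (Mann-Whitney), with Kruskal–Wallis
across the four groups and a χ² test of the S15-high proportion between
CD8 groups.

## Synthetic cohort generator

The generator emulates the *structure* of an mfIHC cohort, not its
images. Per ROI, the tumor region is a union of disk-shaped nests
(count ~ max(1, Poisson(5)), radius ~ N(130, 30²) µm truncated at
20 µm) clipped to the frame; realized tumor/stroma areas are taken
exactly from this geometry, so they partition the frame. Baseline
cells are independent homogeneous Poisson processes per phenotype with
separate tumor/stroma intensities (cells/mm²); defaults plant an
immune-excluded pattern (CD8 T: 80 tumor / 250 stroma; TAM: 150/250;
Teff 75/150; Treg 25/50; tumor cells 2000/0; unlabeled stromal cells
100/500). Patient-level lognormal multipliers (σ_log = 0.35) add
between-patient heterogeneity, and a planted bimodal CD8 level
(P(high) = 0.5, ×2.5 intensity) gives the immunotyping a recoverable
CD8 axis.

Marker positivity probabilities are patient-level logit-normals sharing
a latent severity factor (loading 0.7 for Siglec-15). Their parameters
are calibrated analytically from pairs of quantile constraints chosen to
match published cohort rates: Siglec-15 in the tumor compartment
(µ = −4.785, σ = 1.852) gives ≈46% of patients positive at the 1%
cutoff and ≈16% high at 5%; the macrophage compartment (µ = −3.094,
σ = 2.342) gives ≈74% at 1% and ≈27% at 16%, hence ≈28% high in either
compartment; the CD163⁺ fraction among Siglec-15⁺ TAMs (µ = 1.848,
σ = 1.487) lands ≈11/20/69% in the <50 / 50–75 / ≥75% bands. These are
realism defaults, not acceptance claims; realized cohort rates vary
with n. (One visible approximation: the stroma compartment is CK⁻
cells and therefore includes TAMs, so its realized positivity rate runs
above the nominal CK⁻CD68⁻ parameter.)

Planted interactions use the simplest mechanisms with checkable first
moments: attraction is a Thomas-type cluster step (Poisson(strength)
offspring per flagged reference, isotropic Gaussian displacement of
scale σ; offspring falling outside the frame are discarded), exclusion
is independent distance-thinning (targets within σ of a flagged
reference kept with the configured retention probability). Defaults
plant the motifs this pipeline is designed to detect: CD8, Treg and TAM
attraction around Siglec-15⁺ TAMs/tumor cells, and CD8 exclusion
(retention 0.5 within 20 µm) around Siglec-15⁺PD-L1⁻ tumor cells.
The recovery experiments use strength 3 at σ = 10 µm for attraction
and retention 0.1 at σ = 20 µm for exclusion, with baseline target
intensities (150 and 400 cells/mm²) chosen analytically so the expected
per-disc counts separate the strata by many standard errors.

Survival follows an exponential proportional-hazards model over planted
per-patient binary features; defaults put HR 1.5 on macrophage-
compartment Siglec-15-high, 1.58 on T2–4 and 2.18 on N1–2 stage, with
baseline hazards 0.020/month (DFS) and 0.012/month (OS). Censoring is
independent exponential with its rate solved numerically
(E[c/(c + hᵢ)] = target, default 0.45); an infeasible target triggers a
warning with the achieved rate. A TAM-intensity multiplier (×1.6)
confined to planted CD8-low/Siglec-15-high patients provides the
recoverable immunotyping contrast. One seed produces one byte-identical
cohort.

What passing the recovery suite does **not** show about real data: the
generator has no segmentation error, no spectral bleed-through or
batch effects in marker calls, no cell-shape geometry, no spatially
varying intensity beyond the nest dichotomy, and independent censoring.
Effect sizes recovered here say nothing about power on cohorts with
weaker, correlated effects.

## Numerical choices and problem sizes

Radius comparisons, cutoff classifications and category bounds are
inclusive as stated above; density and proximity statistics are exact
arithmetic over tree-retrieved neighbor sets. Nest disks are
64-segment polygons; area and point-in-region tests use the same
polygons, so areas and tissue classes are mutually consistent. Cox
fits use lifelines defaults (Efron ties); times are simulated
continuous and rounded to 0.01 month.

The shipped experiments use: 50 random instances up to 2000 cells for
neighbor-oracle agreement; 500 ROIs at λ = 100/mm² (r = 40 µm, guard
margin) for intensity recovery; 200 replicates per interaction kind;
1000 null replicates (n = 200) for log-rank type-I error and 200
replicates (n = 500, HR 2.0) for Cox CI coverage; 100 instances for the
Youden oracle; and one 200-patient cohort for TMIT partition/contrast
recovery. The analysis drivers default to an 80-patient cohort. These
sizes keep the full suite around a minute while leaving Monte-Carlo
error well inside the asserted bands.

## Known limitations

- The spatial statistics are the bespoke radius statistics of this
  pipeline; Ripley's K/L, cross-PCF and nearest-neighbor G functions
  are intentionally out of scope.
- No edge correction beyond the optional guard margin; cross-ROI
  neighborhoods are never computed (ROIs are islands).
- Stepwise Cox has no removal step and inherits the usual caveats of
  stepwise selection; proportional-hazards diagnostics are limited.
- The Youden outcome convention and the spatial-feature dichotomization
  are documented defaults, not recovered choices of the original study.
- TCGA-expression-based immunotyping variants are supported only in the
  sense that any per-patient scalar can be supplied as the CD8 or
  Siglec-15 feature; no external data retrieval is included.
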