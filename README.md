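# siglec15-tme

Single-cell spatial analysis of Siglec-15 in the lung-adenocarcinoma
tumor immune microenvironment, packaged as a tested, reusable pipeline.
It is aimed at researchers working with multiplexed immunofluorescence
(mfIHC) cell tables — inForm-style exports with per-cell coordinates,
tissue class and marker calls — who want to go from raw cell tables to
compartment expression, spatial neighborhood statistics, survival
stratification and immunotyping without external services.

Because the original patient-level data are not publicly deposited, the
package ships a first-class synthetic-cohort generator with planted
ground truth (marker co-expression structure, cell–cell attraction and
exclusion, proportional-hazards outcomes), so every stage is validated
by recovery of known truth rather than by eyeballing.

## What it computes

**Phenotyping and quantification.** Cells are gated by marker logic
(tumor = CK⁺, TAM = CD68⁺, Treg = CD4⁺FoxP3⁺, Teff = CD4⁺FoxP3⁻,
CD8 T = CD8⁺; first matching rule wins) with Siglec-15 / PD-L1 / CD163
sub-flags. Expression compartments are TC = CK⁺ cells, MC = CD68⁺
cells, SC = CK⁻ cells. Per patient the pipeline reports
%-positive per compartment (cells pooled over ROIs), densities in
cells/mm² per tissue area (total / tumor / stroma), the
CD163⁺ fraction among Siglec-15⁺ TAMs (categorized <50% / 50–75% /
≥75%), and the joint TC×MC Siglec-15 high/low classification.

**Spatial statistics.** Each ROI is a bivariate planar marked point
pattern. For reference cells *R* (e.g. Siglec-15⁺ TAMs) and target
cells *T* (e.g. CD8 T cells), at radius *r* ∈ {20, 40, 60, 80} µm:

- *spatial density* = mean over reference cells of
  #{t ∈ T : ‖t − x‖ ≤ r} / (π r²), in cells/mm² (disc mode; a tissue
  mode dividing by ROI tissue area is also available);
- *proximity distance* = mean of all pair distances ≤ r, pooled over
  reference cells.

Strata (S15±, PD-L1± references) are compared across patients with
paired Wilcoxon tests at each radius.

**Survival and immunotyping.** Features are dichotomized at fixed
cutoffs (≥1 / ≥5 / ≥25%) or the Youden-optimal cutoff
(max J = sensitivity + specificity − 1, ties to the smaller value), then
analyzed with Kaplan–Meier/log-rank and univariate or stepwise
multivariate Cox regression (entry at univariate p < 0.05). TMIT
crosses Siglec-15 status with CD8 infiltration (cohort-median density
cutoff) into four groups (CD8^H/L × S15^H/L) with group contrasts and
four-curve survival.

## Worked example

Run the numbered analysis drivers from the repository root (about a
minute in total; `--out` defaults to `results/`):

```sh
python analysis/01_simulate_cohort.py --n-patients 80 --seed 11
python analysis/02_phenotype_quantify.py
python analysis/03_spatial_stats.py
python analysis/04_survival.py
python analysis/05_immunotyping.py
```

`01` writes an 80-patient, 240-ROI cohort (~300k cells) and reports the
planted Siglec-15-high fractions and achieved censoring. `02` prints,
among others:

```
Siglec-15 positivity in TC at 1% cutoff: 51% of patients
Siglec-15 positivity in MC at 1% cutoff: 76% of patients
M2-ratio categories: {'high': 0.68, 'intermediate': 0.24, 'low': 0.08}
```

i.e. Siglec-15 is more often positive in the macrophage compartment than
the tumor compartment, and predominantly expressed on CD163⁺ (M2-like)
TAMs — the structure the generator plants. `03` recovers the planted
spatial interactions, e.g. CD8 density around Siglec-15⁺ vs ⁻ TAMs:

```
r=  20 um  median   1199.1 vs    362.6 /mm^2  p=7.59e-14 (n=75)
```

and the reversed sign around Siglec-15⁺ tumor cells (55.5 vs
160.4 /mm² at 20 µm), where the generator plants CD8 exclusion. `04`
prints cutoffs and Cox results — with this seed the stepwise model
retains nodal stage (HR 2.26, 95% CI 1.20–4.25), and the median split on
CD8 density around S15⁺ tumor cells stratifies DFS at p = 0.044. `05`
reports the TMIT proportions and the planted TAM-density shift confined
to the CD8-low/S15-high group (medians 448.8 vs 223.6 /mm²,
p = 0.008).

As a library:

```python
from siglec15_tme.simulate import SimConfig, generate_cohort
from siglec15_tme.phenotyping import assign_phenotypes
from siglec15_tme.spatial import CellSelector, stratified_spatial_comparison

cohort = generate_cohort(SimConfig(n_patients=20, seed=1))
cells = assign_phenotypes(cohort.cells)
stats, tests = stratified_spatial_comparison(
    cells, cohort.rois,
    strata={"S15+ TAM": CellSelector("TAM", positive=("Siglec15",)),
            "S15- TAM": CellSelector("TAM", negative=("Siglec15",))},
    target=CellSelector("CD8T"),
)
```

A config-driven CLI wraps the same stages:
`siglec15-tme run-all --out results/run` (see
`siglec15_tme.pipeline.default_run_config` for the config schema).

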