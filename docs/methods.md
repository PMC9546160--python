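# Methods

## Scope and model

The package quantifies two things about cortical inhibitory
interneurons in a three-group postmortem design (control, SUDEP,
Alpers' syndrome; occipital, frontal and temporal cortex):

1. **Per-cell OXPHOS protein expression.** Somata are outlined by an
   intensity threshold on the 405 nm calcium-binding-protein channel;
   each cell's mean optical intensity is measured in four channels
   (CBP, COXI, NDUFB8, porin). Complex I/IV abundance is normalised to
   mitochondrial mass as the ratio of natural-log intensities,
   `r = ln I_marker / ln I_porin`, standardised against pooled control
   cells of the same region × subtype stratum, and binned at
   ±2 / −3 / −4 SD into `increased / normal / low / deficiency /
   severe_deficiency`.
2. **Neuronal density severity.** Densities `ND = count / area`
   (cells/mm²) per subject × region × subtype are standardised on the
   natural-log scale against control subjects of the same stratum and
   binned with the same edges into `increased / normal / mild_loss /
   moderate_loss / severe_loss`, with a `complete_loss` sentinel when
   a subtype has vanished (no z-score is defined at ND = 0). Group
   loss is summarised as `percent remaining = 100 × mean patient ND /
   mean control ND` using arithmetic group means of subject densities.

Key assumptions: cells (or subjects, for densities) are exchangeable
within a stratum; the control distribution of each metric is
approximately normal so that SD-unit bins are meaningful; mean soma
intensity is an adequate per-cell summary (no subcellular structure);
within-subject correlation of cells is ignored when pooling control
cells (see sensitivity modes below).

## Classification bins

The five bins are resolved as ordered half-open intervals with each
boundary assigned to the more extreme side: `z ≤ −4` severe, `−4 < z ≤
−3` deficiency, `−3 < z ≤ −2` low, `−2 < z < 2` normal, `z ≥ 2`
increased. This is the unique total partition of the real line that
honours the direction of every defining inequality (z < −4, z < −3,
z < −2, z > 2); the same convention (and code path) serves the density
grades. Non-finite z is a hard error, never silently binned.

## Ratio definition and log base

"Ratio of log-transformed intensities" is implemented literally as
`ln(I)/ln(I_porin)` (`ratio_mode="log_over_log"`, the default); a
`log_of_ratio` mode (`ln(I/I_porin)`) is provided because the phrase
admits both readings. Natural logarithms are used throughout. Under
`log_of_ratio` the base cancels in z-scores; under the default it does
not, so the base is fixed and documented rather than configurable.
Intensities must exceed a positivity guard (default 0; raise it for
noisy backgrounds) — guarded cells are flagged `excluded` with a
reason, never dropped silently, and are reported separately in
subject summaries.

## Control references

Expression references pool control *cells* within region × subtype
(default); a `per-subject` mode standardises against control subject
means as a sensitivity analysis for within-subject correlation.
Density references pool control *subjects* within region × subtype,
with a leave-one-out mode (`reference="loo"`) for judging control
self-calibration without self-inclusion shrinkage. A reference
requires n ≥ 2 and SD > 0; degenerate strata raise a named error. By
construction, pooled-mode control z-scores have mean 0 and SD 1
exactly within each stratum.

## Statistics layer

- Normality: Shapiro–Wilk plus a Q-Q summary (quantile correlation and
  maximum deviation); endpoints where any group rejects at alpha 0.05
  go to the rank-based family. The pipeline records each decision in
  `decision_trail.csv`.
- Linear-model endpoints: one-way OLS (`response ~ group`, no
  covariates by default since the emulated design is demographically
  matched) with all pairwise least-square-mean contrasts; family-wise
  adjustment uses the studentized-range distribution (Tukey–Kramer
  under imbalance). Unadjusted p-values come from the pooled-error t
  statistic, and adjusted ≥ unadjusted is enforced as an invariant.
- Rank-based endpoints: Kruskal–Wallis (tie-corrected H) with Dunn's
  post hoc; Dunn z statistics use pooled mean ranks with the tie
  correction to the rank variance. The adjustment family for Dunn is
  Holm by default (conservative and standard), configurable to any
  statsmodels `multipletests` method. Two-sample endpoints use
  Mann–Whitney U (exact enumeration for small tie-free samples).
- Cell-level intensity endpoints (porin, CBP) treat cells as
  observations, matching how such data are usually reported; this
  ignores within-subject correlation, so the per-subject reference
  mode above is the recommended companion check.
- Ordered binary outcomes (e.g. sex across ordered groups) use the
  Cochran–Armitage trend statistic with equally spaced scores; on a
  2×2 table it coincides algebraically with Pearson's χ² (1 df),
  which the tests verify.
- Alpha 0.05, two-sided, everywhere.

## Synthetic-data generator

The generator is the package's stand-in for a postmortem cohort and
defines the study conditions used by the tests:

- **Cohort**: 9 controls, 5 SUDEP, 14 patients; ages, sex ratios,
  postmortem intervals (h) and fixation durations (months) are
  normal/Bernoulli draws per group, patients skewing younger
  (location 10 y) to reflect childhood-predominant disease.
- **Per-cell intensities** are log-normal; channel log-locations
  default to 5.0 (arbitrary units) with scales 0.15–0.20. Patients
  get additive log shifts for porin (+0.4 in parvalbumin⁺ cells:
  raised mitochondrial mass) and CBP (−0.5 in parvalbumin⁺ cells:
  reduced parvalbumin expression).
- **Deficiency mixture**: each patient cell draws an NDUFB8 stratum
  from `{normal, low, deficient, severe}`; its COXI stratum copies
  the NDUFB8 stratum with probability 0.7 (combined complex I + IV
  deficiency) and is drawn independently otherwise. Default patient
  mixtures: parvalbumin⁺ 60/15/10/15% severe/deficient/low/normal;
  calretinin⁺ 20/25/25/30% (milder); SUDEP 85% normal with a small
  low tail; controls all normal.
- **Stratum placement** is specified in control-referenced z units
  (0 / −2.5 / −3.5 / −5) rather than raw log shifts: the generator
  samples the *ratio metric* directly from a normal at
  `μ_r + z_s·σ_r`, where `(μ_r, σ_r)` are the analytic control ratio
  moments, and back-computes the marker log-intensity as
  `r · ln I_porin`. This makes the planted-class → z-bin mapping exact
  by construction and independent of the patient porin shift —
  mirroring why the ratio normalisation exists. Deficient strata are
  narrow (0.25 z units) so classes are recoverable within binomial
  error; the normal stratum keeps the full control spread. A
  consequence: marker log-intensity marginals have slightly larger
  spread than the nominal channel scale (the ratio inherits porin
  variability), which is immaterial to the ratio-scale analysis.
- **Counts** are Poisson with mean `density × area` (default sampled
  area 4 mm² per subject × region × subtype). Control densities
  encode occipital parvalbumin⁺ enrichment (40/mm² occipital vs
  22/mm² elsewhere); patient multipliers plant the survival fractions
  0.15 (pv), 0.57 (cr), 0.30 (cb, sst, pyramidal); SUDEP 1.0.
- **Scenes**: 256×256 px fields at 0.5 µm/px; somata are disks
  (radius 4–7 µm) placed by rejection sampling (≥2 µm edge
  separation, 1,000 attempts per cell, failure is an error, never
  silent under-placement); the noise-free disk value per channel
  equals the cell's true intensity; additive Gaussian noise (SD 2
  a.u. against background 5 a.u.) is clipped at zero. Ground truth
  (label image, true intensities, true classes) accompanies every
  scene.
- **Determinism**: every output is bit-reproducible for a fixed seed;
  the pipeline splits one integer seed into order-stable sub-streams
  so adding a stage never perturbs earlier sampling.

What the generator does **not** emulate: optics (point-spread
function, channel bleed-through, autofluorescence), 3-D structure,
irregular soma shapes, touching cells, spatial density gradients or
necrotic lesions, per-region deficiency gradients, and
between-subject density heterogeneity beyond Poisson noise. Passing
tests therefore demonstrate correctness of the measurement and
classification machinery under the stated statistical structure, not
robustness to imaging artefacts or biological overdispersion.

## Segmentation choices

Threshold: Otsu on the 405 nm channel by default (the outlining
method is a free choice; Otsu is the standard parameter-free default)
with an absolute override, both echoed in run logs. A featureless
(constant) 405 nm image yields an empty labelling, not an error.
Connectivity: 8-connected components. Area gate 30–2,000 µm²
(plausible soma bounds, config-overridable). Border-touching cells
are kept by default (configurable). No hole-filling or watershed
splitting: overlapping somata are an acknowledged limitation of
threshold outlining. Thresholds are computed per image by default; a
fixed threshold can be shared across images of an experiment.

## Clinical table

The packaged fourteen-patient clinical table uses the `+` convention:
blank cells count as negative/unknown, so table-derived counts can
undershoot narrative counts (the developmental-delay column has 10
`+` marks although delay and/or regression is described for all
patients; the summariser reports the table-derived value). Ages parse
from `"2 m"` / `"4.0y"` to years (months/12). The onset bimodality
split defaults to 16 years, inclusive on the adolescent side, and is
a parameter because the split is descriptive, not defined.

## Problem sizes in tests

The test suite and acceptance script use: full default cohorts
(28 subjects, 8,400 cells) for classification checks; 10,000-cell
single-stratum tables for mixture-recovery checks; 20 rendered
256×256 scenes for segmentation fidelity; 1,000 null simulations
(3 groups × 10) for family-wise error and Kruskal–Wallis calibration;
10⁶ random z values for the partition property. These sizes give
Monte-Carlo error comfortably below the asserted tolerances while
keeping the default suite fast.

## Known limitations

- Cell-level inference for porin/CBP endpoints ignores within-subject
  correlation (anticonservative); use the per-subject modes to gauge
  sensitivity.
- The log-over-log ratio is scale-dependent (not invariant to
  rescaling intensity units); unit conventions must be consistent
  within an experiment. The `log_of_ratio` mode is scale-invariant in
  z.
- Threshold segmentation cannot split touching somata; planted scenes
  avoid overlap, real tissue does not.
- Density grading assumes Poisson-dominated count error; real
  stereology adds between-section and between-subject variance not
  modelled here.
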