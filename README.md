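# interneuron-profiler

Quantitative neuropathology of cortical inhibitory interneurons in
mitochondrial epilepsy. The package implements, as a tested and
reusable pipeline, the per-cell analysis used to characterise
parvalbumin⁺ and calretinin⁺ interneurons in postmortem neocortex from
Alpers' syndrome patients, SUDEP (epilepsy disease control) patients
and controls: soma segmentation on the 405 nm calcium-binding-protein
channel, per-cell OXPHOS protein quantification with z-score
classification against pooled controls, neuronal-density severity
grading, and the group-comparison statistics layer. Because postmortem
cohorts of this kind are not publicly distributable, a synthetic-data
generator with full ground truth stands in for the cohort; it is
first-class, tested code, and every downstream stage is validated
against the truth it plants.

Intended users: neuropathology and mitochondrial-disease researchers
who need a transparent, scriptable version of this analysis for their
own immunofluorescence or density data (both arms accept plain CSV
tables and multi-channel TIFFs), and methodologists studying the
behaviour of threshold segmentation and z-bin classification.

## The method

Each segmented interneuron yields mean optical intensities in four
channels: CBP (405 nm; parvalbumin or calretinin), COXI (488 nm,
complex IV), NDUFB8 (546 nm, complex I) and porin/VDAC1 (647 nm,
mitochondrial mass). Complex abundance is normalised to mitochondrial
mass by the ratio of log-transformed intensities,

```
r = ln(I_marker) / ln(I_porin),        marker ∈ {NDUFB8, COXI}
```

and standardised against the pooled control cells of the same
region × subtype stratum:

```
z = (r − mean_control r) / SD_control r
```

z-scores are binned into five expression levels — increased (z ≥ 2),
normal, low (z ≤ −2), deficiency (z ≤ −3), severe deficiency
(z ≤ −4) — giving per-patient deficiency profiles. Porin and CBP
intensities are analysed the same way on the natural-log scale.

Neuronal densities `ND = count / area` (cells/mm²) are graded with the
identical z-bins on log densities
(`z = [ln ND − mean_control ln ND] / SD_control ln ND`), with a
`complete_loss` sentinel where a subtype has vanished entirely, and
summarised at the group level as percent remaining,
`100 × mean(patient ND) / mean(control ND)`.

Group comparisons follow a recorded decision trail: Shapiro–Wilk (with
Q-Q summaries) chooses between a one-way linear model with
Tukey-adjusted least-square-mean contrasts and Kruskal–Wallis with
Dunn's post hoc (Holm-adjusted); two-sample endpoints use Mann–Whitney
U; ordered binary outcomes use the Cochran–Armitage χ² test for trend.
Alpha is 0.05, two-sided.

## Worked example

```python
from interneuron_profiler import synthetic as syn, oxphos as ox, density as de

cohort = syn.generate_cohort(syn.CohortSpec(seed=1))          # 9 / 5 / 14 subjects
cells = syn.generate_cell_intensity_table(syn.IntensityModel(seed=2), cohort)
classified = ox.classify_cells(ox.compute_ratios(cells))

pv = classified[(classified.group == "alpers") & (classified.subtype == "pv")]
print(pv["cat_ndufb8"].value_counts(normalize=True).round(3).to_string())

counts = syn.generate_counts(syn.default_density_rates(), 4.0, cohort, seed=3)
pct = de.percent_remaining_table(counts)
print(pct[pct.region == "occipital"][["subtype", "percent_remaining"]]
      .round(1).to_string(index=False))
```

prints

```
severe_deficiency    0.590
normal               0.158
deficiency           0.149
low                  0.099
increased            0.004
subtype  percent_remaining
     cb               26.6
     cr               60.3
     pv               14.6
    pyr               30.0
    sst               33.9
```

59% of the 2,100 patient parvalbumin⁺ cells are classified severely
NDUFB8-deficient — recovering the generator's planted 60% severe
stratum through the full ratio → reference → z → bin pipeline — and
the density arm recovers the planted survival fractions (15% of
parvalbumin⁺, 57% of calretinin⁺, ~30% of the other subtypes) within
Poisson sampling error.

The same analysis runs from the shell:

```sh
profiler run --seed 3 --out-dir run_out        # full pipeline + report
profiler synth --seed 1 --out-dir synth_out --n-scenes 2
profiler segment synth_out/scene_00.tiff       # Otsu on the 405 nm channel
profiler clinical                              # cohort feature counts
```

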