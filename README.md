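# isletmorph

Quantitative morphometry of pancreatic islets for the pathological
diagnosis of **adult non-neoplastic hyperinsulinemic hypoglycemia (ANHH)**,
also known as adult-onset nesidioblastosis.

ANHH is a diffuse, non-tumorous hyperplasia of pancreatic β-cells.  Its
histological diagnosis traditionally rests on qualitative minor criteria
such as "irregular shape of islets" and "lobulated islet structure", which
carry substantial interobserver variability — in a blind test, pathologists
identify ANHH slides at essentially chance level regardless of experience.
This package implements the quantitative alternative: measure every islet
in a whole-slide section and count the islets whose **circularity**

```
C = 4π · A / P²
```

(A = islet area, P = islet perimeter) falls below a diagnostic threshold,
normalised per cm² of pancreatic parenchyma.  C equals 1 for a perfect
circle and decreases toward 0 for lobulated outlines; the density of
low-circularity islets (C < 0.71) separates ANHH sections from controls
where islet counts, sizes and total areas do not.

## What the package provides

| module | contents |
|---|---|
| `isletmorph.geometry` | area, perimeter, maximum Feret diameter, circularity — from exact polygons and from calibrated label masks (sub-pixel smoothed-contour perimeter estimation) |
| `isletmorph.segmentation` | thresholding single-channel images into label masks, per-islet record extraction, parenchyma area in cm² |
| `isletmorph.morphometry` | per-specimen summaries (counts, densities, total areas, low-circularity counts, islet-cluster flags) and cytology fractions (enlarged nuclei ≥ 9 µm, recognizable nucleoli ≥ 1.5 µm) |
| `isletmorph.stats` | pooled (equal-variance) two-sample t-test from raw values **or** printed (mean, SE, n) summaries; the group-comparison table; the circularity-threshold scan; interobserver-accuracy statistics |
| `isletmorph.synthetic` | seeded generator of two-group cohorts with lobulated polar-contour islets, with an analytic circularity oracle, plus rendering to calibrated label images |
| `isletmorph.reference` | the published group-level summary statistics, shipped as analysis inputs |
| `isletmorph.cli` | `isletmorph simulate / measure / compare / scan-threshold / interobserver / report` |

## Worked example

Simulate a study-scale cohort (4 ANHH + 5 control specimens, calibrated to
the published group summaries), then compare the groups:

```bash
$ isletmorph simulate --preset table3_like --seed 1 --out demo
wrote cohort of 9 specimens to demo

$ isletmorph compare --islets demo/islets.csv --specimens demo/specimens.csv
measurement                 ANHH (n=4)            control (n=5)         P value
n_islets                    453 ± 143             372 ± 52.9            0.58
n_islets_per_cm2            223 ± 70.8            141 ± 21.7            0.256
total_islet_area_cm2        0.042 ± 0.0134        0.036 ± 0.00539       0.669
islet_area_fraction_pct     2.07 ± 0.665          1.37 ± 0.238          0.315
mean_max_diameter_um        105 ± 0.429           106 ± 1.9             0.701
n_low_circularity           91.5 ± 27.8           20 ± 3.56             0.0232
n_low_circularity_per_cm2   45.3 ± 14.2           7.51 ± 1.42           0.0199
```

Each row is group mean ± standard error over specimens with the pooled
two-tailed p.  The pattern mirrors the published finding: count, density,
area and diameter rows are non-significant, while the low-circularity
rows (count and per-cm² density at the 0.71 threshold) separate the groups
at p < 0.05.

The data-driven threshold selection scans candidate cut-offs 0.50–0.95 and
picks the one minimising the two-group p.  On a cohort with a separation
planted just below 0.71 it recovers the cut-off:

```bash
$ isletmorph simulate --preset planted_threshold --seed 1 --out planted
$ isletmorph scan-threshold --islets planted/islets.csv --specimens planted/specimens.csv
selected threshold 0.71 (p = 0.03664); minimal-p plateau: 0.71
```

Published summary triples are themselves valid inputs — the interobserver
blind-test statistics re-derive from the two printed rater-group summaries:

```bash
$ isletmorph interobserver --summaries raters.csv
experienced: 47.5% ± 6.12% (n=5)
less_experienced: 50.0% ± 8.63% (n=7)
overall: 49.0% ± 5.43% (n=12); p = 0.83
```

The same works in Python:

```python
from isletmorph import GroupSummary, pooled_ttest_from_summary

low_circ = pooled_ttest_from_summary(
    GroupSummary(mean=82.0, se=19.0, n=4),   # ANHH: islets with C < 0.71
    GroupSummary(mean=30.0, se=5.71, n=5),   # control
)
print(round(low_circ.p, 3))   # 0.023
```

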