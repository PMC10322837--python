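# lesionquant

Object-based quantification of murine lung histology: **percent tumor area
in H&E-stained sections** and **EdU/UHRF1 double-positive nuclei in
three-channel fluorescence fields**, with ground-truth simulators for
validating both pipelines end to end.

The package is aimed at researchers who quantify lung tumor burden from
brightfield H&E tiles and in-vivo proliferation (EdU incorporation) against
a nuclear marker (UHRF1) from immunofluorescence, and who want a scripted,
reproducible, fully tested alternative to an interactive CellProfiler-style
workflow.

## The two pipelines

**Tumor burden.** Hematoxylin and eosin are light-absorbing dyes, so their
contributions add linearly in optical-density space (Beer–Lambert):

    OD_c = −log10(I_c / W_c),      OD = d_H·v_H + d_E·v_E

where `I_c` is the transmitted intensity in channel `c`, `W_c` the white
reference, and `v_H`, `v_E` unit absorbance vectors. The pipeline converts
the RGB tile to OD, solves the per-pixel least-squares system for the stain
densities `d_H`, `d_E` (negative solutions clamped to 0), smooths, and
thresholds each density map independently with **global two-class Otsu**
(the histogram cut maximizing the between-class variance
`ω₀ω₁(μ₀−μ₁)²`). Dense basophilic lesions dominate the hematoxylin map and
airy eosinophilic parenchyma the eosin map; after connected-component
labeling, a minimum equivalent-diameter filter and disjointing of contested
pixels, the statistic is

    tumor_percent = 100 · tumor_px / (tumor_px + normal_px).

**Co-localization.** Each channel (Hoechst = all nuclei, FITC = EdU,
Cy5 = UHRF1) is segmented by smoothing → Otsu → labeling → typical-diameter
and border filtering. A nucleus is called marker-positive iff at least one
marker object's centroid (rounded half-away-from-zero) falls inside the
nucleus mask — the classic parent/child "relate by centroid" rule. A
nucleus positive for both markers is double-positive; the result reports
`pct_double_of_nuclei` and `pct_double_of_uhrf1` side by side.

**Simulators.** `make_he_tile` renders lesion blobs and parenchyma through
the Beer–Lambert model with a known per-pixel class map;
`make_fluor_field` places non-overlapping nuclei and draws (EdU+, UHRF1+)
labels from an explicit 2×2 joint table, so recovery of the true tumor
fraction and the true double-positive rate can be tested exactly.

## Worked example

```python
import lesionquant as lq

img, truth = lq.make_he_tile(lq.SynthHEParams(seed=42, target_tumor_fraction=0.30))
res = lq.quantify_tumor_burden(img)
print(f"true lesion fraction : {100 * truth.true_tumor_fraction:.2f}%")
print(f"estimated tumor area : {res.tumor_percent:.2f}% "
      f"({res.tumor_area_px} px in {res.n_lesions} lesions)")

ch, ctruth = lq.make_fluor_field(lq.SynthFluorParams(seed=42))
cres = lq.quantify_colocalization(ch["hoechst"], ch["edu"], ch["uhrf1"])
print(f"nuclei detected      : {cres.n_nuclei} (true {ctruth.n_nuclei})")
print(f"double-positive %    : {cres.pct_double_of_nuclei:.2f}% of nuclei")
```

prints

```
true lesion fraction : 30.30%
estimated tumor area : 30.36% (55178 px in 14 lesions)
nuclei detected      : 299 (true 300)
double-positive %    : 21.74% of nuclei
```

The tile was rendered with a true lesion share of 30.30% of tissue and the
pipeline reads back 30.36%; the fluorescence field carried 300 nuclei of
which 65 were truly double-positive, and the pipeline recovers 65 of the
299 nuclei it segments (21.74%).

## Command line

```sh
lesionquant simulate he --seed 5 --n-images 20 --out tiles/
lesionquant burden --input tiles/ --out burden.csv --save-masks masks/
lesionquant coloc --nuclei f_hoechst.tif --edu f_edu.tif --uhrf1 f_uhrf1.tif --out row.csv
lesionquant summarize --input burden.csv --group group --stat tumor_percent --out summary.csv
lesionquant config show
```

All defaults (stain vectors, diameters, smoothing, binning) are printed by
`config show` and overridable through a YAML file; every run writes a JSON
log with the config hash, seed and per-file status. Per-image/per-field
CSVs are designed to feed external group statistics (Kruskal–Wallis,
ANOVA); the package itself only aggregates mean/SD/min/max per group.

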