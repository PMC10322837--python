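# Methods

## Stain model

Both brightfield stains are treated as pure absorbers obeying the
Beer–Lambert law: transmitted intensity in channel `c` is
`I_c = W_c · 10^(−Σ_s d_s v_{s,c})`, with `W` the incident (white)
reference, `d_s ≥ 0` the dimensionless amount of stain `s` at the pixel and
`v_s` its unit absorbance vector. The optical-density transform inverts
this per channel, `OD_c = −log10(max(I_c, ε_c)/W_c)` clamped to ≥ 0, with
`ε_c = W_c/255` so an all-absorbing 8-bit pixel maps to a finite OD (~2.4)
rather than infinity. Unmixing solves the 3×2 least-squares system
`M d = OD` per pixel via the pseudoinverse and clamps negative components
to zero; clamping (rather than constrained optimization) is the standard
practice for OD unmixing and only activates where noise or off-model color
pushes the unconstrained solution slightly negative.

The default H&E basis is the Ruifrok–Johnston color-deconvolution pair
(hematoxylin (0.650, 0.704, 0.286), eosin (0.072, 0.990, 0.105), unit-
normalized). These are literature constants shipped as configuration —
they can and should be re-measured for a given scanner — not fitted values.

**Accuracy limits of the quantized round trip.** With float images the
render → OD → unmix loop is exact to ~1e−15. After 8-bit quantization the
OD error of a half-count step is `0.5/(I·ln 10)`, which stays below
0.02 OD only while the transmitted intensity exceeds ~11/255, i.e. while
the per-channel OD stays below ~1.4. Tissue-like pixels (one dominant
stain up to density 1 plus a co-stain up to 0.3) respect this; two
simultaneously saturated stains do not, and no unmixer could do better
there. The round-trip tests therefore sample the dominant+minor regime,
which is also exactly what the simulator renders.

## Thresholding conventions

Global two-class Otsu runs on a 256-bin histogram over the observed
[min, max] and returns a **bin edge**, the cut maximizing the
between-class variance `ω₀ω₁(μ₀−μ₁)²` with class means taken over bin
centers. Because bin centers are an affine function of the bin index, the
maximizing cut is found on exact integer index moments
(`(S₀N − SN₀)²/(N₀(N−N₀))` compared by cross-multiplication), which makes
the documented tie-break — the lowest qualifying threshold — deterministic
with no floating-point ambiguity. Binarization is strictly greater-than
(ties to background), so masks are bit-reproducible. A constant image has
no threshold and raises a degenerate-input error at the primitive level;
both pipelines catch it and emit an empty mask/label map with a warning.

## Objects

Connected components use 8-connectivity by default (CellProfiler-style
primary-object behavior; 4-connectivity available) and are labeled 1..n in
raster-scan order of each component's first pixel — scipy's labeling is
re-numbered to guarantee this. Object size is summarized by the equivalent
diameter `2·sqrt(area/π)`; the diameter filter keeps objects inside a
[min, max] range and optionally discards border-touching objects,
relabeling survivors consecutively. Coordinates are 0-based, row-major,
pixel centers at integer coordinates. No declumping runs by default — the
simulators produce non-touching objects, and splitting merged regions is a
policy choice best made per dataset; a distance-transform watershed
splitter is available behind a flag.

The parent/child relation is the centroid rule: a child object belongs to
the parent whose labeled region contains the child's centroid rounded half
away from zero; a background hit means "unrelated". Marker calling uses
marker objects as children and nuclei as parents (a reverse flag tests
nucleus centroids against marker objects instead), and a nucleus with two
or more related marker objects still counts once — positivity is boolean.

## Tumor-burden pipeline decisions

* Tumor = hematoxylin density, normal = eosin density (configurable): in
  these sections the lesions are dense and basophilic, the parenchyma airy
  and eosinophilic.
* Gaussian smoothing with σ = 1 px before thresholding suppresses
  quantization speckle; set to 0 to disable.
* Lesion mask objects below 5 px equivalent diameter are dropped
  (single-pixel noise); the normal-tissue mask is not size-filtered.
* Pixels claimed by both masks go to the class with the higher unmixed
  density, so areas are disjoint and the percentage is bounded by 100.
* `tumor_percent` is tumor/(tumor+normal) of detected tissue by default;
  a `percent_of_total` option divides by the full image area instead, for
  workflows that define burden against the whole field.

## Co-localization pipeline decisions

* Default typical diameter range (6, 40) px for every channel, matching
  the simulator's nucleus radii (5–8 px, i.e. diameters 10–16 px) with
  slack for blur.
* Border nuclei are discarded by default (partial cells bias calls);
  marker channels keep border objects since only their centroids matter.
* Both percentage conventions are always emitted
  (`pct_double_of_nuclei`, `pct_double_of_uhrf1`) because the appropriate
  denominator depends on the question being asked; reports must label
  which one they plot.

## Simulators: what they emulate, and what they do not

`make_he_tile` builds parenchyma as a thresholded smooth Gaussian random
field (default 40% airspace), lesions as unions of random disks
(radii 12–40 px) added until the lesion share of tissue reaches the
target, assigns mean optical densities (lesion: hematoxylin 0.90 +
eosin 0.15; parenchyma: eosin 0.45 + hematoxylin 0.08) with 5%
multiplicative texture, renders through the Beer–Lambert model and adds
Gaussian read noise (SD 2 on the 8-bit scale) before quantization. The
disk stream is seeded independently of the parenchyma and noise streams,
so raising the target fraction with a fixed seed *extends* the lesion set
without reshuffling anything else — this is what makes monotonicity of the
estimate testable. Default tiles are 512×512.

`make_fluor_field` rejection-samples non-overlapping nuclei (radii
5–8 px, ≥ 2 px edge clearance, kept a margin inside the border so blurred
disks never touch the edge), draws each nucleus's (EdU+, UHRF1+) pair from
the explicit joint table {both = p_both, edu-only = p_edu − p_both,
uhrf1-only = p_uhrf1 − p_both, neither}, subject to the Fréchet bounds,
and renders Hoechst/FITC/Cy5 disks with σ = 1 px blur, background 0.05 and
noise SD 0.01 on the normalized scale, quantized to 8 bits. Defaults:
1024×1024, 300 nuclei, marginals 0.40 (EdU) and 0.30 (UHRF1), joint 0.20.
Bounded retries (1000) end in a hard error — silently reducing density
would corrupt the ground truth.

Neither simulator attempts photorealism. Real sections add out-of-focus
light, stain variation between batches, touching and overlapping nuclei,
anisotropic lesion texture, folds and debris; none of these are modeled.
Passing recovery tests therefore demonstrates that the pipelines are
correct implementations of their stated algorithms and are unbiased under
the stated image-formation model — not that the defaults are optimal for
any particular scanner's output. The deterministic primitive layer
(thresholding, labeling, measurement, relation) is validated against
brute-force oracles independently of the simulators.

## Problem sizes and numerical choices

Recovery studies use 20 tiles (512×512) and 20 fields (1024×1024,
300 nuclei) — large enough that binomial noise on a 300-nucleus field
(SE ≈ 2.3 pp at p = 0.2) dominates segmentation error, and the whole
suite plus the acceptance script still complete in well under a minute.
All randomness flows from `numpy.random.SeedSequence` spawns of a single
seed; identical seeds give byte-identical images, masks and CSVs. CSV
numbers are written at full double precision with period decimal
separators, no locale handling.

## Known limitations

* The stain basis is global per image; no per-image basis estimation.
* No declumping by default means touching nuclei in real data would merge;
  enable the watershed splitter and tune `min_distance_px` for such data.
* `tumor_percent` is undefined (not 0) when no tissue is detected; batch
  outputs carry NaN there and the summarizer excludes and counts them.
* Percentages from fields with very few nuclei are noisy; the per-field
  CSVs deliberately carry raw counts so downstream statistics can weight
  fields properly.
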