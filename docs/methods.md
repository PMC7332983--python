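# Methods

This note documents the models, conventions and parameter choices behind
`punctascreen`, and what the synthetic benchmarks do and do not establish
about real data.

## Units and geometry

Images are 2-D arrays in (row, col) order with 0-based indices. Physical
calibration enters through a single `pixel_size_um` value (default
0.325 µm/px, plausible for a 20× widefield objective on a high-content
imager); every micrometre-denominated parameter is converted to pixels
through it. Two workflow parameters are deliberately pixel-denominated and
used as-is, matching how such assays are configured in practice: the
top-hat radius (10 px) and the pseudo-cell growth distance (50 px).

An object's **width** is its equivalent-circle diameter,
`2·sqrt(area/π)`. This makes min/max "width" gates well defined for
irregular connected components and lets the generator and the gates agree
by construction.

## Segmentation workflow

1. **Top-hat** (p62 channel): white top-hat with an exact circular
   structuring element of radius 10 px (pixel offsets with
   `dr² + dc² ≤ r²`), i.e. the image minus its grey opening, boundary mode
   reflect. This removes background structure wider than about twice the
   radius and is pointwise non-negative. The implementation
   (`scipy.ndimage.grey_opening`) is verified bit-exactly against a
   brute-force sliding min/max oracle in the tests.
2. **Nucleus segmentation** (DAPI channel): pixels above a local-mean
   threshold (window 401 px, offset 200 AU) are grouped with
   8-connectivity; components are kept iff their width is within the
   10–30 µm gate. The large window makes the local mean track the smooth
   background while ignoring nucleus-scale structure; the offset is half
   the synthetic nucleus amplitude, so the measured contour sits at the
   half-maximum edge. Both knobs are exposed for real data, where the
   "intensity above local threshold" is user-defined by nature.
3. **Punctum detection** (top-hat output by default; a flag allows the raw
   channel): local-mean window 25 px, offset 250 AU (half the synthetic
   punctum peak), width gate 0.5–1.0 µm. Because in-gate puncta are only
   1.5–3 px across, the area of a component is refined on a 4× finer grid:
   the intensity-minus-threshold surface is interpolated with cubic
   splines, and only the fine-grid region connected to the component's
   peak is counted. Without this refinement, pixel quantization biases the
   measured width by up to ±20 % at the small end of the gate and the
   boundary churn dominates the count error.
4. **Pseudo-whole cells**: every background pixel within 50 px (Euclidean,
   measured from the nucleus pixel set) of some nucleus is assigned to the
   *nearest* nucleus; exact ties go to the lower label id, so results are
   reproducible and fronts never merge. Implemented as per-label exact
   Euclidean distance transforms with a running argmin; verified
   bit-exactly against a brute-force nearest-seed oracle.
5. **Compartments and counting**: cytoplasm = cell minus nucleus, per
   label (a partition by construction); each detected punctum is assigned
   by the compartment containing its centroid (rounded to the nearest
   pixel). Centroid assignment is deterministic and conserves counts:
   nuclear + cytoplasmic + unassigned = total detected. Puncta are smaller
   than the uncertainty of compartment boundaries, so any-overlap
   assignment would only add ambiguity. Nuclei touching the image border
   are kept by default (configurable).

## Screen analysis

Well features are `cell_count` and the per-well sums of nuclear and
cytoplasmic puncta counts over all sites (per-cell means are also
emitted). Normalization divides every feature by the plate's
negative-control median, so 1 is the negative-control phenotype and the
transform is idempotent and invariant to uniform rescaling of the plate.

Hit calling uses bootstrap-aggregated decision trees (100 trees, seeded)
trained only on control wells: positive controls are the healthy
(rescued) phenotype, negative controls the impaired-flux phenotype.
Compound wells are scored, never trained on; the score is the ensemble
vote fraction and a well is a hit when it exceeds 0.5. The model reports
a stratified five-fold cross-validated misclassification error. A compound
is reported as a hit when either dose is called (per-well calls are also
emitted). "Ensemble-based tree classifier" admits several readings;
bagging of unconstrained trees is the most generic fully-reproducible one.

## Co-localization

Illumination correction divides by a heavily Gaussian-smoothed copy and
rescales to preserve the global mean; it assumes the gain field varies on
a scale larger than the smoothing kernel, which itself must exceed the
object scale. Alignment searches integer shifts within ±max_shift for the
maximum-correlation translation (smallest displacement wins ties) and
reports correlation before/after so degenerate pairs are visible.

For object overlap, each channel is thresholded (Otsu by default, manual
override available) and segmented. Because an auto-threshold can sit well
below an object's half-maximum, the width gate is applied to the
*half-maximum contour* of each component (peak above the sub-threshold
median background), making gating threshold-independent. All three
candidate overlap fractions are reported; the symmetric union (Jaccard)
fraction is the headline "percent co-localization" because it is bounded,
symmetric in the channels, and consistent with using total object pixels
as denominator. Costes-style significance testing is out of scope.

## Radial profiles

Rings radiate from the nucleus *boundary* (not its centre): ring k of a
cell is the set of pixels whose Euclidean distance to that cell's nucleus
lies in ((k−1)·2 µm, k·2 µm], restricted to pixels whose nearest nucleus
is that cell, so eight rings cover exactly 16 µm and the rings of one cell
partition its annulus. The perinuclear score is
`100 · inner4 / (inner4 + outer4)`; a cell is "perinuclear" when the score
exceeds 50 % (configurable, echoed in every output). Ring intensities are
raw integrated marker intensity — no background subtraction by default
(optional upstream), so a large uniform background biases every score
toward the ring-area ratio; high-contrast or background-subtracted marker
images are assumed. Microtubule density is the per-cell mean of
background-subtracted tubulin intensity, clipped at zero, with the modal
intensity outside all cells as the default background estimate.

## Flux cytometry

Per-event ratio mCherry/GFP (errors name offending rows when an intensity
is non-positive). The gate is the 99.5th percentile of the BafA1-treated
control population's ratio distribution — an assumption-free
operationalization of "the rightward base of the control curve"; the
quantile is configurable and recorded with every result. By construction
the gate passes ~0.5 % of control-like events, which bounds the
false-positive floor of the estimated autophagic percentage. Scatter-based
viability gating and spectral compensation are out of scope; events are
assumed pre-gated.

## Synthetic data

The generators emulate the statistical structure of the targeted assays,
with one shared intensity model (arbitrary units): base background 100,
seeded linear-plus-quadratic gradient of amplitude 20, additive Gaussian
noise (SD 5), nucleus amplitude 400 over background with 1 px edge
smoothing, punctum peak = signal-to-background ratio × 100 (default 5 →
peak 500). Threshold offsets in `SegmentationParams` default to half these
amplitudes, i.e. the workflow ships calibrated to its own simulator; on
real data the offsets are the user-defined quantities they are in any
high-content package.

* **Cell scenes**: non-overlapping axis-aligned elliptical nuclei (aspect
  ratio uniform in [1, 1.5], widths uniform in 10–30 µm), Poisson puncta
  per compartment (defaults 3 nuclear, 6 cytoplasmic per cell), punctum
  widths uniform in 0.5–1.0 µm rendered as Gaussian spots whose FWHM is
  the nominal width. Rendered spot mass matches the analytic Gaussian
  mass within 1 % (conservation check). Nuclear puncta are placed with an
  interior margin; cytoplasmic puncta in a 3–15 px band outside their own
  nucleus; inter-cell clearance guarantees each punctum is nearest its own
  nucleus, and minimum punctum separation keeps spots resolvable — the
  assay counts resolvable puncta, so unresolvable overlaps are not
  modelled. Placement failure raises an explicit error.
* **Screening plates**: 176 compounds × 2 doses (0.3 and 3.3 µM) plus 16
  negative- and 16 positive-control wells; 10 % true hits by default. A
  hit's puncta rates are pulled multiplicatively from the negative- toward
  the positive-control level (remaining-effect multiplier uniform in
  [0, 0.4]; half potency at the low dose); well-level log-normal rate
  noise (σ = 0.08), Poisson cell counts (mean 320/well) and Poisson count
  sums. Negative-control rates are 2.5 nuclear / 8 cytoplasmic puncta per
  cell; positive controls 1.0 / 1.5.
* **Radial scenes**: per cell, marker mass is split exactly between an
  inner (0–8 µm) and outer (8–16 µm) band as 20 Gaussian spots per band
  kept ≥1.5 µm from the band edges, so the true perinuclear fraction is
  exact before noise. The marker channel carries no base background (see
  above). Recovery runs use 10–16 µm nuclei so that full 16 µm annuli of
  several cells fit a 512² field.
* **Co-localization pairs**: n objects per channel; each B object is,
  independently with probability t, an exact copy of its A partner,
  otherwise placed disjointly. Truth records both the realized shared
  fraction (binomial around t) and the realized pixel-level union overlap
  of the half-maximum footprints.
* **Flow mixtures**: two log-normal components in (GFP, mCherry); basal
  events at median ratio 0.5 and autophagic events at median ratio 8,
  separated by far more than 4 pooled SDs of log-ratio, with the BafA1
  anchor population drawn from the basal component.

What passing these benchmarks does **not** show: robustness to realistic
optics (PSF tails, camera gain, saturation), touching nuclei (no watershed
splitting), unresolvable punctum clusters, autofluorescence structure, or
flow-cytometry artifacts (doublets, spillover). The synthetic conditions
are idealized precisely so that ground truth is exact.

## Benchmark problem sizes

The test suite and `scripts/acceptance.py` use: 100 (tests) / 40 (script)
seeded 768² scenes of 20 cells for count recovery; ten full simulated
plates for hit sensitivity/specificity plus 20 label permutations for the
chance-level check; nine perinuclear fractions × 20 cells for radial
recovery; five overlap levels × 10 (tests) / 5 (script) seeds of 200
objects for co-localization; 10⁵ anchor events and 10⁴-event samples at
fractions {0, 0.1, 0.3, 0.5} for flux. Oracle-equivalence checks run on
64² images where brute force is exact and fast.

## Known limitations

* Width gating near a gate boundary is inherently a coin flip for objects
  whose true width sits within the measurement resolution of the bound
  (~±0.02 µm for puncta); recovery criteria are therefore statistical.
* The per-label distance-transform approach to growth and rings is
  O(n_cells) full-image EDTs — fine for ≤ a few hundred cells, wasteful
  beyond.
* The flux gate's false-positive floor (1 − anchor quantile) is part of
  the method, not an error; estimated fractions for samples with little
  true signal are biased upward by that amount.
* `aggregate_wells` trusts the plate map for roles; there is no automatic
  toxicity filtering (the corresponding exclusions in practice are manual).
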