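# punctascreen

Quantitative image- and cytometry-analysis tools for autophagy phenotyping
in endothelial (and other adherent) cells. The package implements, as a
tested and reusable pipeline, the measurements a high-content p62 screen
needs:

* **Puncta segmentation** — white top-hat background removal, nucleus
  segmentation with 10–30 µm width gates, p62-punctum detection with
  0.5–1 µm width gates, pseudo-whole-cell construction by growing each
  nucleus 50 px, and per-cell nuclear/cytoplasmic puncta counting.
* **Screen analysis** — aggregation of per-cell records to whole-well
  features (`cell_count`, nuclear and cytoplasmic puncta sums),
  percent-of-negative-control plate normalization (negative-control median
  ≡ 1), and hit calling with a bagged decision-tree ensemble trained on the
  control wells.
* **Co-localization** — illumination correction, integer-shift channel
  alignment, pixel-based Pearson correlation, and object-overlap fractions
  (|A∩B|/|A|, |A∩B|/|B| and the union fraction |A∩B|/|A∪B|, reported as
  percent co-localization).
* **Radial profiles** — lysosome positioning as integrated marker
  intensity in eight concentric 2 µm rings around each nucleus; the
  perinuclear score is 100 · perinuclear/(perinuclear + cytoplasmic) with
  the inner four rings as "perinuclear", plus per-cell
  perinuclear/spread classification and microtubule-density readout.
* **Flux cytometry** — per-event mCherry/GFP ratios from a tandem
  mCherry-GFP-LC3 reporter, a ratio gate anchored at a high quantile of a
  Bafilomycin-A1-treated control population, and percent-autophagic
  estimation.
* **Synthetic scenes** — generators for microscopy fields, screening
  plates, co-localization pairs, radial scenes and flow-cytometry mixtures,
  all with exact ground truth, used throughout the test suite.

## Worked example

Simulate a field of 20 cells, segment it and count puncta per compartment:

```python
import punctascreen as ps

spec = ps.SceneSpec(field_size_px=(768, 768), n_cells=20, seed=1)
nuclei, puncta, truth = ps.generate_cell_scene(spec)

records, unassigned, masks = ps.segment_field(nuclei, puncta, ps.SegmentationParams())
detected = sum(r.total_puncta_count for r in records) + unassigned
print(f"cells found: {len(records)}")
print(f"puncta detected: {detected}  (ground truth: {truth.total_puncta})")
```

Output:

```
cells found: 20
puncta detected: 161  (ground truth: 166)
```

Twenty nuclei pass the 10–30 µm gate; 161 of the 166 rendered puncta are
detected and compartmentalized (the misses are spots whose measured width
falls marginally below the 0.5 µm gate). Per-cell records carry nuclear and
cytoplasmic counts, areas in px and µm², and mean compartment intensities.

A full screen runs from the command line:

```bash
punctascreen simulate --kind flow --seed 3 --autophagic-fraction 0.3 --out demo/
punctascreen flux --events demo/events.csv --out demo/flux/
```

Other subcommands: `segment`, `screen`, `coloc`, `radial`, `mtdensity` is
available as the radial module's `microtubule_density` function, and `run`
executes the whole segment → aggregate → normalize → classify pipeline
from a manifest plus plate map.

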