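"""Segmentation workflow: morphology oracles, width gates, compartments."""

import numpy as np
import pytest

from punctascreen import (
    ChannelImage,
    LabelMask,
    SceneSpec,
    SegmentationParams,
    ValidationError,
    compartmentalize,
    count_puncta_per_cell,
    detect_puncta,
    generate_cell_scene,
    grow_cells,
    segment_field,
    segment_nuclei,
    tophat_filter,
)
from conftest import render_disc, render_spot


def brute_force_tophat(pixels: np.ndarray, radius: int) -> np.ndarray:
    """White top-hat via explicit disk-neighborhood min then max."""
    offsets = [
        (dr, dc)
        for dr in range(-radius, radius + 1)
        for dc in range(-radius, radius + 1)
        if dr * dr + dc * dc <= radius * radius
    ]

    def slide(a, fn):
        p = np.pad(a, radius, mode="symmetric")
        stack = np.stack(
            [
                p[radius + dr : radius + dr + a.shape[0],
                  radius + dc : radius + dc + a.shape[1]]
                for dr, dc in offsets
            ]
        )
        return fn(stack, axis=0)

    return pixels - slide(slide(pixels, np.min), np.max)


def brute_force_growth(nuclei: np.ndarray, growth: int) -> np.ndarray:
    """Nearest-seed expansion with distance ties to the lower label."""
    seeds = [
        (r, c, nuclei[r, c])
        for r in range(nuclei.shape[0])
        for c in range(nuclei.shape[1])
        if nuclei[r, c] > 0
    ]
    out = np.zeros_like(nuclei)
    for r in range(nuclei.shape[0]):
        for c in range(nuclei.shape[1]):
            best_d, best_l = None, 0
            for sr, sc, lab in seeds:
                d = (r - sr) ** 2 + (c - sc) ** 2
                if best_d is None or d < best_d or (d == best_d and lab < best_l):
                    best_d, best_l = d, lab
            if best_d is not None and best_d <= growth * growth:
                out[r, c] = best_l
    return out


class TestTophat:
    def test_constant_image_maps_to_zero(self, params):
        img = ChannelImage(np.full((32, 32), 7.0), "x")
        assert np.array_equal(tophat_filter(img, params).pixels, np.zeros((32, 32)))

    def test_single_bright_pixel_preserved(self, params):
        pixels = np.zeros((32, 32))
        pixels[16, 16] = 9.0
        out = tophat_filter(ChannelImage(pixels, "x"), params).pixels
        assert out[16, 16] == 9.0
        assert np.count_nonzero(out) == 1

    def test_matches_brute_force_on_gradient_scene(self, params):
        rng = np.random.default_rng(0)
        pixels = rng.uniform(0, 30, (64, 64)) + np.linspace(0, 50, 64)[None, :]
        for _ in range(6):
            r, c = rng.integers(4, 60, 2)
            pixels[r, c] += 200
        out = tophat_filter(ChannelImage(pixels, "x"), params).pixels
        assert np.array_equal(out, brute_force_tophat(pixels, params.tophat_radius_px))
        assert (out >= 0).all()

    def test_radius_exceeding_image_rejected(self, params):
        with pytest.raises(ValidationError):
            tophat_filter(ChannelImage(np.zeros((12, 12)), "x"), params)


class TestNucleusGate:
    def test_three_separated_discs_give_three_labels(self, params):
        pixels = np.zeros((512, 512))
        for cc in (100, 250, 400):
            disc = render_disc((512, 512), 15.0).pixels
            pixels += np.roll(disc, cc - 256, axis=1)
        mask = segment_nuclei(ChannelImage(pixels, "DAPI"), params)
        assert mask.n_objects == 3

    @pytest.mark.parametrize(
        "diameter_um,expected", [(5.0, 0), (15.0, 1), (40.0, 0)]
    )
    def test_width_gate(self, params, diameter_um, expected):
        img = render_disc((256, 256), diameter_um)
        assert segment_nuclei(img, params).n_objects == expected

    def test_empty_image_gives_empty_mask(self, params):
        mask = segment_nuclei(ChannelImage(np.zeros((64, 64)), "DAPI"), params)
        assert mask.n_objects == 0


class TestPunctumGate:
    @pytest.mark.parametrize("width_um,expected", [(0.3, 0), (0.7, 1), (2.0, 0)])
    def test_width_gate(self, params, width_um, expected):
        img = render_spot((64, 64), width_um)
        assert detect_puncta(img, params).n_objects == expected

    def test_gate_monotonicity(self, params):
        """Widening the width gate never loses objects."""
        rng = np.random.default_rng(1)
        pixels = np.zeros((128, 128))
        for _ in range(12):
            r, c = rng.uniform(10, 118, 2)
            w = rng.uniform(0.3, 2.2)
            pixels += render_spot((128, 128), w, center=(r, c)).pixels
        img = ChannelImage(pixels, "Cy3")
        narrow = detect_puncta(img, params).n_objects
        wide_params = SegmentationParams(
            punctum_min_width_um=0.25, punctum_max_width_um=2.5
        )
        assert detect_puncta(img, wide_params).n_objects >= narrow


class TestGrowth:
    def test_single_nucleus_area_matches_distance_oracle(self, params):
        nuc = np.zeros((160, 160), dtype=np.int32)
        yy, xx = np.mgrid[0:160, 0:160]
        nuc[(yy - 80) ** 2 + (xx - 80) ** 2 <= 15**2] = 1
        cells = grow_cells(LabelMask(nuc, "nuclei"), params)
        from scipy import ndimage

        dist = ndimage.distance_transform_edt(nuc == 0)
        assert np.array_equal(cells.labels > 0, dist <= params.cell_growth_px)

    def test_empty_mask(self, params):
        cells = grow_cells(LabelMask(np.zeros((32, 32), dtype=np.int32), "nuclei"), params)
        assert cells.n_objects == 0

    def test_two_seeds_meet_without_merging(self, params):
        nuc = np.zeros((64, 64), dtype=np.int32)
        nuc[30:34, 2:6] = 1
        nuc[30:34, 58:62] = 2
        cells = grow_cells(LabelMask(nuc, "nuclei"), params)
        assert np.array_equal(cells.labels, brute_force_growth(nuc, params.cell_growth_px))
        assert set(np.unique(cells.labels)) >= {1, 2}


class TestCompartments:
    def test_nuclei_equal_cells_gives_empty_cytoplasm(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[10:20, 10:20] = 1
        cyto = compartmentalize(LabelMask(labels, "cells"), LabelMask(labels, "nuclei"))
        assert cyto.n_objects == 0

    def test_partition_identity(self, params):
        nuc = np.zeros((128, 128), dtype=np.int32)
        yy, xx = np.mgrid[0:128, 0:128]
        nuc[(yy - 40) ** 2 + (xx - 40) ** 2 <= 10**2] = 1
        nuc[(yy - 90) ** 2 + (xx - 90) ** 2 <= 8**2] = 2
        nuclei = LabelMask(nuc, "nuclei")
        cells = grow_cells(nuclei, params)
        cyto = compartmentalize(cells, nuclei)
        for k in (1, 2):
            cell_area = (cells.labels == k).sum()
            assert cell_area == (nuc == k).sum() + (cyto.labels == k).sum()
        assert not ((nuc > 0) & (cyto.labels > 0)).any()

    def test_shape_mismatch_and_inconsistent_nuclei_rejected(self):
        cells = LabelMask(np.ones((16, 16), dtype=np.int32), "cells")
        with pytest.raises(ValidationError):
            compartmentalize(cells, LabelMask(np.zeros((8, 8), dtype=np.int32), "nuclei"))
        bad_nuc = np.zeros((16, 16), dtype=np.int32)
        bad_nuc[0, 0] = 2  # cell label there is 1
        with pytest.raises(ValidationError):
            compartmentalize(cells, LabelMask(bad_nuc, "nuclei"))


class TestCounting:
    def test_counts_match_ground_truth_single_cell(self, params):
        spec = SceneSpec(
            field_size_px=(256, 256), n_cells=1,
            puncta_per_cell_nuclear=5.0, puncta_per_cell_cytoplasmic=7.0,
            punctum_width_range_um=(0.6, 0.9),  # safely inside the gate
            noise_sd=0.0, background_gradient_amplitude=0.0, seed=23,
        )
        nuclei, puncta, truth = generate_cell_scene(spec)
        records, unassigned, _ = segment_field(nuclei, puncta, params)
        assert len(records) == 1
        assert records[0].nuclear_puncta_count == truth.total_nuclear
        assert records[0].cytoplasmic_puncta_count == truth.total_cytoplasmic
        assert unassigned == 0

    def test_background_punctum_unassigned(self, params):
        puncta = np.zeros((64, 64), dtype=np.int32)
        puncta[5, 5] = 1  # far from any cell
        empty = LabelMask(np.zeros((64, 64), dtype=np.int32), "nuclei")
        records, unassigned = count_puncta_per_cell(
            LabelMask(puncta, "puncta"), empty, LabelMask(np.zeros((64, 64), dtype=np.int32), "cytoplasm")
        )
        assert records == [] and unassigned == 1

    def test_count_conservation(self, params):
        """nuclear + cytoplasmic + unassigned == total detected puncta."""
        spec = SceneSpec(field_size_px=(512, 512), n_cells=6, seed=31)
        nuclei, puncta, _ = generate_cell_scene(spec)
        records, unassigned, masks = segment_field(nuclei, puncta, params)
        assigned = sum(r.total_puncta_count for r in records)
        assert assigned + unassigned == masks["puncta"].n_objects

    def test_no_puncta_all_zero(self, params):
        nuc = np.zeros((64, 64), dtype=np.int32)
        nuc[20:40, 20:40] = 1
        nuclei = LabelMask(nuc, "nuclei")
        cells = grow_cells(nuclei, params)
        cyto = compartmentalize(cells, nuclei)
        records, unassigned = count_puncta_per_cell(
            LabelMask(np.zeros((64, 64), dtype=np.int32), "puncta"), nuclei, cyto
        )
        assert unassigned == 0
        assert records[0].total_puncta_count == 0
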