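"""Generator contracts: determinism, truth consistency, physical plausibility."""

import math

import numpy as np
import pandas as pd
import pytest

from punctascreen import (
    FlowSpec,
    PlacementError,
    PlateSpec,
    SceneSpec,
    ValidationError,
    generate_cell_scene,
    generate_coloc_pair,
    generate_flow_population,
    generate_radial_scene,
    generate_screen_plate,
)
from punctascreen.synthetic import FWHM_PER_SIGMA, spot_mass


class TestCellScene:
    def test_empty_scene_has_only_background(self):
        spec = SceneSpec(n_cells=0, noise_sd=0.0, seed=1)
        nuclei, puncta, truth = generate_cell_scene(spec)
        assert truth.cells == [] and truth.puncta == []
        assert truth.total_puncta == 0
        # No objects: both channels are the smooth background only.
        assert nuclei.pixels.max() - nuclei.pixels.min() <= spec.background_gradient_amplitude + 1e-9

    def test_truth_totals_equal_per_cell_sums(self):
        spec = SceneSpec(n_cells=5, seed=7)
        _, _, truth = generate_cell_scene(spec)
        assert truth.total_nuclear == sum(c.n_nuclear for c in truth.cells)
        assert truth.total_cytoplasmic == sum(c.n_cytoplasmic for c in truth.cells)
        assert len(truth.puncta) == truth.total_puncta
        per_cell = {c.cell_id: [0, 0] for c in truth.cells}
        for p in truth.puncta:
            per_cell[p.cell_id][0 if p.compartment == "nuclear" else 1] += 1
        for c in truth.cells:
            assert per_cell[c.cell_id] == [c.n_nuclear, c.n_cytoplasmic]

    def test_coordinates_inside_field(self):
        spec = SceneSpec(n_cells=6, seed=3)
        _, _, truth = generate_cell_scene(spec)
        rows, cols = spec.field_size_px
        for p in truth.puncta:
            assert 0 <= p.row < rows and 0 <= p.col < cols

    def test_determinism_bit_identical(self):
        spec = SceneSpec(n_cells=4, seed=42)
        n1, p1, _ = generate_cell_scene(spec)
        n2, p2, _ = generate_cell_scene(SceneSpec(n_cells=4, seed=42))
        assert np.array_equal(n1.pixels, n2.pixels)
        assert np.array_equal(p1.pixels, p2.pixels)

    def test_placement_failure_is_explicit(self):
        with pytest.raises(PlacementError):
            generate_cell_scene(SceneSpec(field_size_px=(128, 128), n_cells=30, seed=0))

    def test_punctum_mass_conservation(self):
        """Rendered intensity integrates to the analytic Gaussian mass (<1% off)."""
        spec = SceneSpec(
            n_cells=3, noise_sd=0.0, background_gradient_amplitude=0.0, seed=5
        )
        _, puncta, truth = generate_cell_scene(spec)
        rendered = puncta.pixels - puncta.pixels.min()
        total_mass = sum(
            spot_mass(p.width_um, p.amplitude, spec.pixel_size_um)
            for p in truth.puncta
        )
        # Background is 100 AU flat here; subtract it exactly.
        rendered_mass = float((puncta.pixels - 100.0).sum())
        assert rendered_mass == pytest.approx(total_mass, rel=0.01)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            SceneSpec(n_cells=-1)
        with pytest.raises(ValidationError):
            SceneSpec(nucleus_width_range_um=(30.0, 10.0))
        with pytest.raises(ValidationError):
            SceneSpec(noise_sd=-1.0)


class TestRadialScene:
    def test_extreme_fractions(self):
        spec = SceneSpec(
            field_size_px=(512, 512), n_cells=3,
            nucleus_width_range_um=(10.0, 16.0),
            noise_sd=0.0, background_gradient_amplitude=0.0, seed=2,
        )
        from scipy import ndimage

        for fraction in (0.0, 1.0):
            _, marker, truth = generate_radial_scene(fraction, spec)
            dist = ndimage.distance_transform_edt(truth.nucleus_labels == 0)
            inner = dist * spec.pixel_size_um <= 8.0
            inner_mass = marker.pixels[inner & (truth.nucleus_labels == 0)].sum()
            total = marker.pixels.sum()
            measured = inner_mass / total
            assert measured == pytest.approx(fraction, abs=0.01)

    def test_truth_records_fraction_per_cell(self):
        spec = SceneSpec(
            n_cells=2, nucleus_width_range_um=(10.0, 14.0), seed=9
        )
        _, _, truth = generate_radial_scene(0.7, spec)
        assert all(c.perinuclear_fraction == 0.7 for c in truth.cells)


class TestColocPair:
    def test_full_overlap_is_identical_object_set(self, noise_free_spec):
        a, b, truth = generate_coloc_pair(1.0, noise_free_spec, n_objects=50)
        assert truth.shared_fraction == 1.0
        assert truth.union_overlap_fraction == 1.0
        assert np.array_equal(a.pixels, b.pixels)

    def test_zero_overlap_disjoint(self, noise_free_spec):
        _, _, truth = generate_coloc_pair(0.0, noise_free_spec, n_objects=50)
        assert truth.shared_fraction == 0.0
        assert truth.union_overlap_fraction == 0.0
        assert not (truth.mask_a & truth.mask_b).any()

    def test_realized_overlap_within_binomial_error(self, noise_free_spec):
        """Shared-object count is Binomial(n, t): check a 4-sigma envelope."""
        _, _, truth = generate_coloc_pair(0.6, noise_free_spec, n_objects=200)
        se = math.sqrt(0.6 * 0.4 / 200)
        assert abs(truth.shared_fraction - 0.6) < 4 * se


class TestFlowPopulation:
    def test_zero_fraction_single_component(self):
        events, truth = generate_flow_population(
            FlowSpec(n_events=5000, autophagic_fraction=0.0, seed=1)
        )
        assert truth.n_autophagic == 0
        assert set(events["true_component"]) == {"basal"}

    def test_component_counts_within_sampling_error(self):
        events, truth = generate_flow_population(
            FlowSpec(n_events=10_000, autophagic_fraction=0.3, seed=4)
        )
        se = math.sqrt(0.3 * 0.7 / 10_000)
        assert abs(truth.autophagic_fraction - 0.3) < 4 * se
        assert (events["gfp"] > 0).all() and (events["mcherry"] > 0).all()

    def test_determinism(self):
        e1, _ = generate_flow_population(FlowSpec(n_events=1000, seed=7))
        e2, _ = generate_flow_population(FlowSpec(n_events=1000, seed=7))
        pd.testing.assert_frame_equal(e1, e2)

    def test_nonpositive_scale_rejected(self):
        from punctascreen import FlowComponent

        with pytest.raises(ValidationError):
            FlowComponent(1.0, 0.0, 1.0, 0.3)


class TestScreenPlate:
    def test_well_arithmetic(self):
        wells, _ = generate_screen_plate(PlateSpec(seed=0))
        compounds = wells[wells["role"] == "compound"]
        assert len(compounds) == 176 * 2
        assert (wells["role"] == "negative_control").sum() == 16
        assert (wells["role"] == "positive_control").sum() == 16

    def test_no_hits_means_negative_distribution(self):
        wells, truth = generate_screen_plate(
            PlateSpec(fraction_true_hits=0.0, seed=1)
        )
        assert not truth["is_hit"].any()
        assert (wells["effect_multiplier"][wells["role"] == "compound"] == 1.0).all()

    def test_null_effect_multiplier(self):
        wells, _ = generate_screen_plate(
            PlateSpec(fraction_true_hits=1.0, hit_multiplier_range=(1.0, 1.0), seed=2)
        )
        assert (wells["effect_multiplier"][wells["role"] == "compound"] == 1.0).all()

    def test_zero_control_wells_rejected(self):
        with pytest.raises(ValidationError):
            PlateSpec(n_negative_control_wells=0)
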