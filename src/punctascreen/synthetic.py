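"""Synthetic microscopy scenes, screening plates and cytometry populations.

Every generator in this module draws data with a fully known ground truth so
that the measurement code elsewhere in the package can be benchmarked against
what was actually rendered.  The generators emulate the statistical structure
of a widefield high-content p62 screen: fields of view with up to ~200 cells,
nuclei 10-30 um wide, diffraction-limited puncta 0.5-1 um wide, a smooth
background gradient and additive Gaussian pixel noise.

All randomness flows through :func:`numpy.random.default_rng` seeded from the
spec, so identical specs produce bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .core import (
    DEFAULT_PIXEL_SIZE_UM,
    ChannelImage,
    LabelMask,
    PlacementError,
    ValidationError,
    equivalent_diameter,
)

FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: Intensity model shared by all scene generators (arbitrary units).
BACKGROUND_BASE = 100.0
NUCLEUS_AMPLITUDE = 400.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Geometry, intensity and noise model of one synthetic field of view.

    ``signal_to_background`` sets the punctum peak amplitude as a multiple of
    the base background level (peak = ratio x 100 AU).  Puncta counts per
    cell are Poisson with the stated means; nucleus widths and punctum widths
    are uniform within their ranges.  Widths are full widths at half maximum
    and equal the equivalent-circle diameter the segmentation gates measure.
    """

    field_size_px: tuple[int, int] = (512, 512)
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    n_cells: int = 12
    nucleus_width_range_um: tuple[float, float] = (10.0, 30.0)
    punctum_width_range_um: tuple[float, float] = (0.5, 1.0)
    puncta_per_cell_nuclear: float = 3.0
    puncta_per_cell_cytoplasmic: float = 6.0
    background_gradient_amplitude: float = 20.0
    noise_sd: float = 5.0
    signal_to_background: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 0:
            raise ValidationError("n_cells must be >= 0")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")
        for name in ("nucleus_width_range_um", "punctum_width_range_um"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must satisfy 0 < min <= max")
        if self.nucleus_width_range_um[0] / self.pixel_size_um < 1.0:
            raise ValidationError("nucleus width below one pixel at this pixel size")
        for name in (
            "puncta_per_cell_nuclear",
            "puncta_per_cell_cytoplasmic",
            "background_gradient_amplitude",
            "noise_sd",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise ValidationError(f"{name} must be finite and non-negative")
        if self.signal_to_background <= 0:
            raise ValidationError("signal_to_background must be positive")

    @property
    def punctum_amplitude(self) -> float:
        return self.signal_to_background * BACKGROUND_BASE


@dataclass
class PlateSpec:
    """Layout and effect-size model of one synthetic screening plate.

    One well per compound x dose plus dedicated negative-control wells
    (impaired-flux phenotype, vehicle only) and positive-control wells
    (healthy phenotype).  True hits have their puncta rates pulled
    multiplicatively from the negative-control level toward the
    positive-control level; the multiplier is the remaining fraction of the
    disease effect (0 = full rescue, 1 = inactive).
    """

    n_compounds: int = 176
    doses_um: tuple[float, ...] = (0.3, 3.3)
    n_negative_control_wells: int = 16
    n_positive_control_wells: int = 16
    fraction_true_hits: float = 0.1
    hit_multiplier_range: tuple[float, float] = (0.0, 0.4)
    low_dose_effect: float = 0.5
    mean_cells_per_well: float = 320.0
    negative_rates: tuple[float, float] = (2.5, 8.0)  # (nuclear, cytoplasmic) per cell
    positive_rates: tuple[float, float] = (1.0, 1.5)
    well_noise_sd: float = 0.08  # log-normal sigma of well-to-well rate variation
    scene_overrides: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.doses_um):
            raise ValidationError("doses must be positive")
        if self.n_negative_control_wells < 1 or self.n_positive_control_wells < 1:
            raise ValidationError("at least one well of each control role is required")
        if not 0 <= self.fraction_true_hits <= 1:
            raise ValidationError("fraction_true_hits must be in [0, 1]")
        lo, hi = self.hit_multiplier_range
        if not (0 <= lo <= hi <= 1):
            raise ValidationError("hit_multiplier_range must satisfy 0 <= min <= max <= 1")


@dataclass
class FlowComponent:
    """Log-normal intensity model of one flow-cytometry subpopulation."""

    gfp_log_mean: float
    gfp_log_sd: float
    mcherry_log_mean: float
    mcherry_log_sd: float

    def __post_init__(self) -> None:
        if self.gfp_log_sd <= 0 or self.mcherry_log_sd <= 0:
            raise ValidationError("component scales must be positive")


@dataclass
class FlowSpec:
    """Two-component mCherry/GFP event mixture.

    The basal component models reporter at neutral pH (both fluorophores
    bright, low ratio); the autophagic component models autolysosomal
    reporter with quenched GFP (high ratio).  Defaults separate the two
    log-ratio distributions by well over four pooled standard deviations.
    """

    n_events: int = 10_000
    autophagic_fraction: float = 0.0
    basal: FlowComponent = field(
        default_factory=lambda: FlowComponent(
            math.log(1000.0), 0.25, math.log(500.0), 0.25
        )
    )
    autophagic: FlowComponent = field(
        default_factory=lambda: FlowComponent(
            math.log(125.0), 0.25, math.log(1000.0), 0.25
        )
    )
    sample_id: str = "sample"
    condition: str = "basal"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_events <= 0:
            raise ValidationError("n_events must be > 0")
        if not 0 <= self.autophagic_fraction <= 1:
            raise ValidationError("autophagic_fraction must be in [0, 1]")


# ---------------------------------------------------------------------------
# Ground truth containers
# ---------------------------------------------------------------------------


@dataclass
class PunctumTruth:
    cell_id: int
    compartment: str  # "nuclear" | "cytoplasmic"
    row: float
    col: float
    width_um: float
    amplitude: float


@dataclass
class CellTruth:
    cell_id: int
    center: tuple[float, float]
    width_param_um: float
    width_um: float  # equivalent-circle diameter of the drawn pixel area
    semi_axes_px: tuple[float, float]
    n_nuclear: int = 0
    n_cytoplasmic: int = 0
    perinuclear_fraction: float | None = None


@dataclass
class SceneTruth:
    """What the renderer actually drew; the oracle for every measurement test."""

    cells: list[CellTruth]
    puncta: list[PunctumTruth]
    nucleus_labels: np.ndarray
    pixel_size_um: float
    seed: int

    @property
    def total_nuclear(self) -> int:
        return sum(c.n_nuclear for c in self.cells)

    @property
    def total_cytoplasmic(self) -> int:
        return sum(c.n_cytoplasmic for c in self.cells)

    @property
    def total_puncta(self) -> int:
        return self.total_nuclear + self.total_cytoplasmic


@dataclass
class ColocObject:
    row: float
    col: float
    width_um: float
    shared: bool


@dataclass
class ColocTruth:
    objects_a: list[ColocObject]
    objects_b: list[ColocObject]
    shared_fraction: float
    union_overlap_fraction: float
    mask_a: np.ndarray
    mask_b: np.ndarray
    generating_overlap: float


@dataclass
class FlowTruth:
    n_events: int
    n_autophagic: int

    @property
    def autophagic_fraction(self) -> float:
        return self.n_autophagic / self.n_events


# ---------------------------------------------------------------------------
# Shared rendering helpers
# ---------------------------------------------------------------------------


def _background_field(shape: tuple[int, int], amplitude: float, rng) -> np.ndarray:
    """Smooth linear-plus-quadratic gradient in [base, base + amplitude]."""
    rows, cols = shape
    v, u = np.meshgrid(
        np.linspace(0.0, 1.0, rows), np.linspace(0.0, 1.0, cols), indexing="ij"
    )
    c = rng.uniform(-1.0, 1.0, size=4)
    g = c[0] * u + c[1] * v + c[2] * u * v + c[3] * u * u
    lo, hi = g.min(), g.max()
    if hi > lo:
        g = (g - lo) / (hi - lo)
    else:
        g = np.zeros(shape)
    return BACKGROUND_BASE + amplitude * g


def _add_gaussian_spot(
    image: np.ndarray, row: float, col: float, sigma_px: float, amplitude: float
) -> None:
    """Add a 2-D Gaussian of peak ``amplitude`` in place, truncated at 5 sigma."""
    radius = int(math.ceil(5.0 * sigma_px)) + 1
    r0 = max(int(math.floor(row)) - radius, 0)
    r1 = min(int(math.ceil(row)) + radius + 1, image.shape[0])
    c0 = max(int(math.floor(col)) - radius, 0)
    c1 = min(int(math.ceil(col)) + radius + 1, image.shape[1])
    rr = np.arange(r0, r1)[:, None] - row
    cc = np.arange(c0, c1)[None, :] - col
    image[r0:r1, c0:c1] += amplitude * np.exp(
        -(rr**2 + cc**2) / (2.0 * sigma_px**2)
    )


def spot_mass(width_um: float, amplitude: float, pixel_size_um: float) -> float:
    """Analytic integrated intensity of a rendered punctum (AU * px^2)."""
    sigma_px = width_um / pixel_size_um / FWHM_PER_SIGMA
    return amplitude * 2.0 * math.pi * sigma_px**2


def _place_nuclei(
    rng, spec: SceneSpec, clearance_px: float
) -> tuple[list[CellTruth], np.ndarray]:
    """Rejection-sample non-overlapping axis-aligned elliptical nuclei.

    ``clearance_px`` reserves an annulus around every nucleus (for
    cytoplasmic puncta or radial rings) that must stay inside the field and
    must not be contested by a neighbouring cell.
    """
    rows, cols = spec.field_size_px
    labels = np.zeros((rows, cols), dtype=np.int32)
    cells: list[CellTruth] = []
    placed: list[tuple[float, float, float]] = []  # (row, col, max semi-axis)
    max_attempts = 600 * max(spec.n_cells, 1)
    attempts = 0
    yy, xx = np.mgrid[0:rows, 0:cols]
    for cell_id in range(1, spec.n_cells + 1):
        width_um = rng.uniform(*spec.nucleus_width_range_um)
        aspect = rng.uniform(1.0, 1.5)
        radius_px = width_um / spec.pixel_size_um / 2.0
        a = radius_px * math.sqrt(aspect)  # row semi-axis
        b = radius_px / math.sqrt(aspect)
        r_max = max(a, b)
        margin = r_max + clearance_px + 2.0
        if 2 * margin >= min(rows, cols):
            raise PlacementError(
                f"field {spec.field_size_px} too small for a nucleus of "
                f"width {width_um:.1f} um plus {clearance_px:.0f} px clearance"
            )
        while True:
            attempts += 1
            if attempts > max_attempts:
                raise PlacementError(
                    f"could not place {spec.n_cells} non-overlapping cells in a "
                    f"{rows}x{cols} field after {max_attempts} attempts"
                )
            cr = rng.uniform(margin, rows - margin)
            cc = rng.uniform(margin, cols - margin)
            ok = all(
                math.hypot(cr - pr, cc - pc) >= r_max + pr_max + 2 * clearance_px + 4.0
                for pr, pc, pr_max in placed
            )
            if ok:
                break
        placed.append((cr, cc, r_max))
        inside = ((yy - cr) / a) ** 2 + ((xx - cc) / b) ** 2 <= 1.0
        labels[inside] = cell_id
        area = int(inside.sum())
        cells.append(
            CellTruth(
                cell_id=cell_id,
                center=(cr, cc),
                width_param_um=width_um,
                width_um=equivalent_diameter(area) * spec.pixel_size_um,
                semi_axes_px=(a, b),
            )
        )
    return cells, labels


def _render_nuclei_channel(labels: np.ndarray, spec: SceneSpec, rng) -> np.ndarray:
    img = _background_field(labels.shape, spec.background_gradient_amplitude, rng)
    body = ndimage.gaussian_filter((labels > 0).astype(float), sigma=1.0)
    img += NUCLEUS_AMPLITUDE * body
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=labels.shape)
    return np.clip(img, 0.0, None)


def _sample_position(
    rng,
    candidates: tuple[np.ndarray, np.ndarray],
    existing: list[tuple[float, float]],
    min_dist: float,
    max_tries: int = 200,
) -> tuple[float, float]:
    n = candidates[0].size
    if n == 0:
        raise PlacementError("no candidate pixels available for punctum placement")
    for _ in range(max_tries):
        k = int(rng.integers(n))
        row = candidates[0][k] + rng.uniform(-0.5, 0.5)
        col = candidates[1][k] + rng.uniform(-0.5, 0.5)
        if all(math.hypot(row - er, col - ec) >= min_dist for er, ec in existing):
            return row, col
    raise PlacementError("could not place punctum with the required separation")


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

#: Cytoplasmic puncta live in a band this many pixels outside the nucleus
#: boundary; combined with the inter-cell clearance it guarantees every
#: punctum is nearer to its own nucleus than to any neighbour.
CYTO_BAND_PX = (3.0, 15.0)


def generate_cell_scene(
    spec: SceneSpec,
) -> tuple[ChannelImage, ChannelImage, SceneTruth]:
    """Render one two-channel field: stained nuclei plus p62-like puncta.

    Returns the nuclei channel, the puncta channel and the ground truth.
    Raises :class:`PlacementError` when the requested number of cells cannot
    be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    clearance = CYTO_BAND_PX[1] + 2.0
    cells, labels = _place_nuclei(rng, spec, clearance_px=clearance)
    nuclei_px = _render_nuclei_channel(labels, spec, rng)

    puncta_img = _background_field(labels.shape, spec.background_gradient_amplitude, rng)
    puncta: list[PunctumTruth] = []
    positions: list[tuple[float, float]] = []
    # Distance maps for placement: inside each nucleus and outside all nuclei.
    dist_inside = ndimage.distance_transform_edt(labels > 0)
    dist_outside = ndimage.distance_transform_edt(labels == 0)
    max_w_px = spec.punctum_width_range_um[1] / spec.pixel_size_um
    for cell in cells:
        n_nuc = int(rng.poisson(spec.puncta_per_cell_nuclear))
        n_cyt = int(rng.poisson(spec.puncta_per_cell_cytoplasmic))
        own = labels == cell.cell_id
        margin_in = max_w_px / 2.0 + 2.0
        nuc_cand = np.nonzero(own & (dist_inside >= margin_in))
        # Pixels in the cytoplasmic band of this cell: outside every nucleus,
        # nearer to this nucleus than the band half-width.
        cyt_band = (
            (labels == 0)
            & (dist_outside >= CYTO_BAND_PX[0])
            & (dist_outside <= CYTO_BAND_PX[1])
        )
        own_dist = ndimage.distance_transform_edt(~own)
        cyt_cand = np.nonzero(cyt_band & (own_dist <= CYTO_BAND_PX[1]))
        for compartment, count, cand in (
            ("nuclear", n_nuc, nuc_cand),
            ("cytoplasmic", n_cyt, cyt_cand),
        ):
            for _ in range(count):
                width = rng.uniform(*spec.punctum_width_range_um)
                w_px = width / spec.pixel_size_um
                row, col = _sample_position(
                    rng, cand, positions, min_dist=w_px + max_w_px / 2.0 + 2.5
                )
                positions.append((row, col))
                sigma = w_px / FWHM_PER_SIGMA
                _add_gaussian_spot(puncta_img, row, col, sigma, spec.punctum_amplitude)
                puncta.append(
                    PunctumTruth(
                        cell_id=cell.cell_id,
                        compartment=compartment,
                        row=row,
                        col=col,
                        width_um=width,
                        amplitude=spec.punctum_amplitude,
                    )
                )
            if compartment == "nuclear":
                cell.n_nuclear = count
            else:
                cell.n_cytoplasmic = count
    if spec.noise_sd > 0:
        puncta_img += rng.normal(0.0, spec.noise_sd, size=labels.shape)
    puncta_img = np.clip(puncta_img, 0.0, None)

    truth = SceneTruth(
        cells=cells,
        puncta=puncta,
        nucleus_labels=labels,
        pixel_size_um=spec.pixel_size_um,
        seed=spec.seed,
    )
    nuclei = ChannelImage(nuclei_px, "DAPI", spec.pixel_size_um)
    marker = ChannelImage(puncta_img, "Cy3", spec.pixel_size_um)
    return nuclei, marker, truth


#: Marker spots of a radial scene are kept this far (um) away from the ring
#: boundaries at 0, 8 and 16 um so that spot tails do not leak across them.
_RADIAL_BANDS_UM = ((1.5, 6.5), (9.5, 14.5))
_RADIAL_SPOTS_PER_BAND = 20
_RADIAL_MASS_PER_CELL = 4.0e4
_RADIAL_SPOT_SIGMA_PX = 1.0


def generate_radial_scene(
    perinuclear_fraction: float, spec: SceneSpec
) -> tuple[ChannelImage, ChannelImage, SceneTruth]:
    """Render nuclei plus a lysosome-like marker with a known radial split.

    A fraction ``perinuclear_fraction`` of each cell's marker mass is placed
    in the inner 0-8 um annulus around the nucleus and the remainder in the
    outer 8-16 um annulus (before noise), so the true perinuclear fraction is
    exact by construction.
    """
    if not 0 <= perinuclear_fraction <= 1:
        raise ValidationError("perinuclear_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    outer_um = _RADIAL_BANDS_UM[1][1] + 1.5
    clearance = outer_um / spec.pixel_size_um
    cells, labels = _place_nuclei(rng, spec, clearance_px=clearance)
    nuclei_px = _render_nuclei_channel(labels, spec, rng)

    # The marker channel carries only the configurable gradient (no base
    # offset): the radial score integrates raw ring intensity, so a large
    # uniform background would bias every cell toward the ring-area ratio.
    marker = (
        _background_field(labels.shape, spec.background_gradient_amplitude, rng)
        - BACKGROUND_BASE
    )
    dist_outside = ndimage.distance_transform_edt(labels == 0) * spec.pixel_size_um
    for cell in cells:
        cell.perinuclear_fraction = perinuclear_fraction
        own_dist = (
            ndimage.distance_transform_edt(labels != cell.cell_id)
            * spec.pixel_size_um
        )
        for (lo, hi), share in zip(
            _RADIAL_BANDS_UM, (perinuclear_fraction, 1.0 - perinuclear_fraction)
        ):
            if share <= 0:
                continue
            cand = np.nonzero(
                (labels == 0)
                & (own_dist >= lo)
                & (own_dist <= hi)
                & (np.abs(dist_outside - own_dist) < 1e-9)
            )
            mass = share * _RADIAL_MASS_PER_CELL / _RADIAL_SPOTS_PER_BAND
            amplitude = mass / (2.0 * math.pi * _RADIAL_SPOT_SIGMA_PX**2)
            for _ in range(_RADIAL_SPOTS_PER_BAND):
                row, col = _sample_position(rng, cand, [], min_dist=0.0)
                _add_gaussian_spot(marker, row, col, _RADIAL_SPOT_SIGMA_PX, amplitude)
    if spec.noise_sd > 0:
        marker += rng.normal(0.0, spec.noise_sd, size=labels.shape)
    marker = np.clip(marker, 0.0, None)

    truth = SceneTruth(
        cells=cells,
        puncta=[],
        nucleus_labels=labels,
        pixel_size_um=spec.pixel_size_um,
        seed=spec.seed,
    )
    return (
        ChannelImage(nuclei_px, "DAPI", spec.pixel_size_um),
        ChannelImage(marker, "LAMP2", spec.pixel_size_um),
        truth,
    )


def generate_coloc_pair(
    target_overlap: float, spec: SceneSpec, n_objects: int = 200
) -> tuple[ChannelImage, ChannelImage, ColocTruth]:
    """Render two spot channels with a controlled object-overlap fraction.

    Each of the ``n_objects`` channel-B objects is, independently with
    probability ``target_overlap``, an exact copy of the corresponding
    channel-A object (same position and width); otherwise it is placed at a
    fresh location disjoint from every other object.  The truth records both
    the realized shared-object fraction and the realized pixel-level union
    overlap of the two half-maximum footprints.
    """
    if not 0 <= target_overlap <= 1:
        raise ValidationError("target_overlap must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.field_size_px
    max_w_px = spec.punctum_width_range_um[1] / spec.pixel_size_um
    min_sep = 2.0 * max_w_px + 4.0
    margin = max_w_px + 4.0

    def place(existing: list[tuple[float, float]]) -> tuple[float, float]:
        for _ in range(400):
            row = rng.uniform(margin, rows - margin)
            col = rng.uniform(margin, cols - margin)
            if all(math.hypot(row - r, col - c) >= min_sep for r, c in existing):
                return row, col
        raise PlacementError("could not place co-localization object")

    positions: list[tuple[float, float]] = []
    objects_a: list[ColocObject] = []
    shared_flags = rng.random(n_objects) < target_overlap
    widths = rng.uniform(*spec.punctum_width_range_um, size=n_objects)
    for i in range(n_objects):
        row, col = place(positions)
        positions.append((row, col))
        objects_a.append(ColocObject(row, col, float(widths[i]), bool(shared_flags[i])))
    objects_b: list[ColocObject] = []
    for obj in objects_a:
        if obj.shared:
            objects_b.append(ColocObject(obj.row, obj.col, obj.width_um, True))
        else:
            row, col = place(positions)
            positions.append((row, col))
            objects_b.append(ColocObject(row, col, obj.width_um, False))

    def render(objs: list[ColocObject]) -> tuple[np.ndarray, np.ndarray]:
        img = _background_field((rows, cols), spec.background_gradient_amplitude, rng)
        mask = np.zeros((rows, cols), dtype=bool)
        yy, xx = np.mgrid[0:rows, 0:cols]
        for obj in objs:
            w_px = obj.width_um / spec.pixel_size_um
            _add_gaussian_spot(
                img, obj.row, obj.col, w_px / FWHM_PER_SIGMA, spec.punctum_amplitude
            )
            # Half-maximum footprint: pixels within FWHM/2 of the centre.
            r = w_px / 2.0
            r0, r1 = max(int(obj.row - r) - 1, 0), min(int(obj.row + r) + 2, rows)
            c0, c1 = max(int(obj.col - r) - 1, 0), min(int(obj.col + r) + 2, cols)
            patch = (yy[r0:r1, c0:c1] - obj.row) ** 2 + (
                xx[r0:r1, c0:c1] - obj.col
            ) ** 2 <= r**2
            mask[r0:r1, c0:c1] |= patch
        if spec.noise_sd > 0:
            img += rng.normal(0.0, spec.noise_sd, size=(rows, cols))
        return np.clip(img, 0.0, None), mask

    img_a, mask_a = render(objects_a)
    img_b, mask_b = render(objects_b)
    union = np.count_nonzero(mask_a | mask_b)
    inter = np.count_nonzero(mask_a & mask_b)
    truth = ColocTruth(
        objects_a=objects_a,
        objects_b=objects_b,
        shared_fraction=float(np.mean(shared_flags)) if n_objects else 0.0,
        union_overlap_fraction=inter / union if union else 0.0,
        mask_a=mask_a,
        mask_b=mask_b,
        generating_overlap=target_overlap,
    )
    return (
        ChannelImage(img_a, "channel_a", spec.pixel_size_um),
        ChannelImage(img_b, "channel_b", spec.pixel_size_um),
        truth,
    )


def generate_flow_population(spec: FlowSpec) -> tuple[pd.DataFrame, FlowTruth]:
    """Sample a two-component (GFP, mCherry) event mixture.

    Returns an event table with columns ``sample_id, condition, gfp,
    mcherry, true_component`` and the truth with per-event membership counts.
    """
    rng = np.random.default_rng(spec.seed)
    is_auto = rng.random(spec.n_events) < spec.autophagic_fraction
    gfp = np.empty(spec.n_events)
    mch = np.empty(spec.n_events)
    for flag, comp in ((False, spec.basal), (True, spec.autophagic)):
        idx = np.nonzero(is_auto == flag)[0]
        gfp[idx] = rng.lognormal(comp.gfp_log_mean, comp.gfp_log_sd, size=idx.size)
        mch[idx] = rng.lognormal(
            comp.mcherry_log_mean, comp.mcherry_log_sd, size=idx.size
        )
    events = pd.DataFrame(
        {
            "sample_id": spec.sample_id,
            "condition": spec.condition,
            "gfp": gfp,
            "mcherry": mch,
            "true_component": np.where(is_auto, "autophagic", "basal"),
        }
    )
    return events, FlowTruth(n_events=spec.n_events, n_autophagic=int(is_auto.sum()))


# ---------------------------------------------------------------------------
# Screening plates
# ---------------------------------------------------------------------------


def _well_id(index: int) -> str:
    return f"W{index:03d}"


def generate_screen_plate(
    spec: PlateSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-well features for a full screening plate with known hits.

    Returns ``(wells, truth)``: ``wells`` has one row per well with columns
    ``plate_id, well_id, compound_id, dose_um, role, cell_count,
    nuclear_puncta_sum, cytoplasmic_puncta_sum``; ``truth`` has one row per
    compound with ``compound_id, is_hit, multiplier`` plus per-well effect
    multipliers merged in by ``well_id``.
    """
    rng = np.random.default_rng(spec.seed)
    neg_nuc, neg_cyt = spec.negative_rates
    pos_nuc, pos_cyt = spec.positive_rates

    is_hit = rng.random(spec.n_compounds) < spec.fraction_true_hits
    multipliers = np.where(
        is_hit, rng.uniform(*spec.hit_multiplier_range, size=spec.n_compounds), 1.0
    )
    high_dose = max(spec.doses_um)

    rows = []
    truth_rows = []
    idx = 0
    for role, count in (
        ("negative_control", spec.n_negative_control_wells),
        ("positive_control", spec.n_positive_control_wells),
    ):
        for _ in range(count):
            idx += 1
            rows.append((_well_id(idx), None, None, role, 1.0 if role == "negative_control" else 0.0))
    for c in range(spec.n_compounds):
        compound = f"CPD{c + 1:03d}"
        truth_rows.append(
            {
                "compound_id": compound,
                "is_hit": bool(is_hit[c]),
                "multiplier": float(multipliers[c]),
            }
        )
        for dose in spec.doses_um:
            idx += 1
            # Remaining fraction of the disease effect in this well: full
            # potency at the top dose, attenuated at lower doses.
            potency = 1.0 if dose == high_dose else spec.low_dose_effect
            m_eff = 1.0 - (1.0 - multipliers[c]) * potency
            rows.append((_well_id(idx), compound, dose, "compound", m_eff))

    out = []
    for well_id, compound, dose, role, m_eff in rows:
        rate_nuc = pos_nuc + m_eff * (neg_nuc - pos_nuc)
        rate_cyt = pos_cyt + m_eff * (neg_cyt - pos_cyt)
        cell_count = int(rng.poisson(spec.mean_cells_per_well))
        noise_nuc = rng.lognormal(0.0, spec.well_noise_sd)
        noise_cyt = rng.lognormal(0.0, spec.well_noise_sd)
        out.append(
            {
                "plate_id": "plate01",
                "well_id": well_id,
                "compound_id": compound,
                "dose_um": dose,
                "role": role,
                "cell_count": cell_count,
                "nuclear_puncta_sum": int(
                    rng.poisson(cell_count * rate_nuc * noise_nuc)
                ),
                "cytoplasmic_puncta_sum": int(
                    rng.poisson(cell_count * rate_cyt * noise_cyt)
                ),
                "effect_multiplier": m_eff,
            }
        )
    wells = pd.DataFrame(out)
    truth = pd.DataFrame(truth_rows)
    return wells, truth


def plate_scene_specs(
    spec: PlateSpec, base: SceneSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-well :class:`SceneSpec` table for rendering a (small) plate end to end.

    Returns ``(plan, truth)`` where ``plan`` has one row per well with the
    plate-map columns plus a ``scene_spec`` object column; puncta rates are
    scaled by the same effect model as :func:`generate_screen_plate`.
    """
    wells, truth = generate_screen_plate(spec)
    rng = np.random.default_rng(spec.seed + 1)
    neg_nuc, neg_cyt = spec.negative_rates
    pos_nuc, pos_cyt = spec.positive_rates
    specs = []
    for _, well in wells.iterrows():
        m = well["effect_multiplier"]
        specs.append(
            replace(
                base,
                puncta_per_cell_nuclear=pos_nuc + m * (neg_nuc - pos_nuc),
                puncta_per_cell_cytoplasmic=pos_cyt + m * (neg_cyt - pos_cyt),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    plan = wells[["plate_id", "well_id", "compound_id", "dose_um", "role"]].copy()
    plan["scene_spec"] = specs
    return plan, truth
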