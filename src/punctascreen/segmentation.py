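"""Image-analysis workflow of the puncta screen.

The stages mirror a high-content granularity workflow: white top-hat
background removal on the puncta channel, nucleus segmentation on the DAPI
channel with intensity-above-local-threshold and 10-30 um width gates,
punctum detection with 0.5-1 um width gates, pseudo-whole-cell construction
by growing each nucleus 50 px, nuclear/cytoplasmic compartmentalization and
per-cell puncta counting.

An object's "width" is its equivalent-circle diameter, ``2*sqrt(area/pi)``.
For objects only a few pixels across, the area of the above-threshold region
is refined on a sub-pixel grid (cubic interpolation of intensity minus
threshold) so that the measured width is not dominated by pixel quantization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    ChannelImage,
    LabelMask,
    ValidationError,
    equivalent_diameter,
)

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


@dataclass
class SegmentationParams:
    """Tunable parameters of the segmentation workflow.

    Width gates are in micrometres and converted through the image's pixel
    size; the top-hat radius and the cell growth distance are in pixels.
    The local thresholds are "intensity above local mean": a pixel is
    foreground when it exceeds the mean over the stated window plus an
    absolute offset.  Offsets are in the same arbitrary units as the image;
    the defaults are calibrated to the synthetic intensity model (nucleus
    amplitude 400 AU, punctum peak 500 AU), i.e. half the object amplitude,
    which places the measured contour at the half-maximum width.
    """

    tophat_radius_px: int = 10
    tophat_shape: str = "circle"
    nucleus_min_width_um: float = 10.0
    nucleus_max_width_um: float = 30.0
    punctum_min_width_um: float = 0.5
    punctum_max_width_um: float = 1.0
    cell_growth_px: int = 50
    nucleus_threshold_window_px: int = 401
    nucleus_threshold_offset: float = 200.0
    punctum_threshold_window_px: int = 25
    punctum_threshold_offset: float = 250.0
    punctum_subpixel_factor: int = 4
    include_border_objects: bool = True

    def __post_init__(self) -> None:
        if self.tophat_radius_px < 1:
            raise ValidationError("tophat_radius_px must be >= 1")
        if self.tophat_shape != "circle":
            raise ValidationError("only the circular top-hat element is supported")
        if self.cell_growth_px < 1:
            raise ValidationError("cell_growth_px must be >= 1")
        for window in (
            self.nucleus_threshold_window_px,
            self.punctum_threshold_window_px,
        ):
            if window < 3 or window % 2 == 0:
                raise ValidationError("threshold windows must be odd and >= 3")
        if not self.nucleus_min_width_um < self.nucleus_max_width_um:
            raise ValidationError("nucleus width gate must satisfy min < max")
        if not self.punctum_min_width_um < self.punctum_max_width_um:
            raise ValidationError("punctum width gate must satisfy min < max")
        if self.punctum_subpixel_factor < 1:
            raise ValidationError("punctum_subpixel_factor must be >= 1")


def disk_footprint(radius: int) -> np.ndarray:
    """Boolean disk: offsets with ``dr^2 + dc^2 <= radius^2``."""
    rr, cc = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return rr**2 + cc**2 <= radius**2


def tophat_filter(image: ChannelImage, params: SegmentationParams) -> ChannelImage:
    """White top-hat: image minus its morphological opening with a disk.

    Removes background structures wider than about twice the radius while
    preserving puncta; the result is pointwise non-negative.
    """
    radius = params.tophat_radius_px
    if 2 * radius + 1 > min(image.shape):
        raise ValidationError(
            f"top-hat radius {radius} px exceeds image extent {image.shape}"
        )
    footprint = disk_footprint(radius)
    opened = ndimage.grey_opening(image.pixels, footprint=footprint, mode="reflect")
    return ChannelImage(
        image.pixels - opened, image.channel_name, image.pixel_size_um
    )


def _local_mean_threshold(
    pixels: np.ndarray, window: int, offset: float
) -> np.ndarray:
    return ndimage.uniform_filter(pixels, size=window, mode="reflect") + offset


def _subpixel_area(
    pixels: np.ndarray,
    threshold: np.ndarray,
    labels: np.ndarray,
    label: int,
    region: tuple[slice, slice],
    factor: int,
) -> float:
    """Area (in original px^2) of the above-threshold region of one component,
    measured on a ``factor``-times finer grid via cubic interpolation.

    On the fine grid, only the connected region containing the component's
    peak is counted, so neighbouring objects in the same crop are excluded
    without clipping the contour of the object itself.
    """
    pad = 3
    r0 = max(region[0].start - pad, 0)
    r1 = min(region[0].stop + pad, pixels.shape[0])
    c0 = max(region[1].start - pad, 0)
    c1 = min(region[1].stop + pad, pixels.shape[1])
    excess = pixels[r0:r1, c0:c1] - threshold[r0:r1, c0:c1]
    component = labels[r0:r1, c0:c1] == label
    nr, nc = excess.shape
    # Sub-pixel sample centres: each fine sample represents 1/factor^2 px^2.
    fr = (np.arange(nr * factor) + 0.5) / factor - 0.5
    fc = (np.arange(nc * factor) + 0.5) / factor - 0.5
    grid = np.meshgrid(fr, fc, indexing="ij")
    fine_excess = ndimage.map_coordinates(excess, grid, order=3, mode="nearest")
    fine_labels, _ = ndimage.label(fine_excess > 0, structure=_EIGHT_CONNECTED)
    peak_flat = np.argmax(np.where(component, excess, -np.inf))
    pr, pc = np.unravel_index(peak_flat, excess.shape)
    fine_pr = int(np.clip(round((pr + 0.5) * factor - 0.5), 0, nr * factor - 1))
    fine_pc = int(np.clip(round((pc + 0.5) * factor - 0.5), 0, nc * factor - 1))
    target = fine_labels[fine_pr, fine_pc]
    if target == 0:
        return float(component.sum())
    return float(np.count_nonzero(fine_labels == target)) / factor**2


def _segment_by_width(
    image: ChannelImage,
    window: int,
    offset: float,
    min_width_um: float,
    max_width_um: float,
    subpixel_factor: int,
    include_border: bool,
    kind: str,
) -> LabelMask:
    pixels = image.pixels
    threshold = _local_mean_threshold(pixels, window, offset)
    binary = pixels > threshold
    labels, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    out = np.zeros_like(labels)
    next_id = 1
    regions = ndimage.find_objects(labels)
    for lab, region in enumerate(regions, start=1):
        if region is None:
            continue
        component = labels[region] == lab
        if not include_border:
            touches = (
                region[0].start == 0
                or region[1].start == 0
                or region[0].stop == pixels.shape[0]
                or region[1].stop == pixels.shape[1]
            )
            if touches:
                continue
        if subpixel_factor > 1:
            area_px = _subpixel_area(
                pixels, threshold, labels, lab, region, subpixel_factor
            )
        else:
            area_px = float(component.sum())
        width_um = equivalent_diameter(area_px) * image.pixel_size_um
        if min_width_um <= width_um <= max_width_um:
            out[region][component] = next_id
            next_id += 1
    return LabelMask(out, kind=kind)


def segment_nuclei(
    nuclei_channel: ChannelImage, params: SegmentationParams
) -> LabelMask:
    """Segment nuclei by intensity above local threshold with width gates.

    Connected components of pixels exceeding the local-mean threshold are
    retained iff their equivalent-circle diameter lies within the
    [min, max] nucleus width gate (default 10-30 um).
    """
    return _segment_by_width(
        nuclei_channel,
        params.nucleus_threshold_window_px,
        params.nucleus_threshold_offset,
        params.nucleus_min_width_um,
        params.nucleus_max_width_um,
        subpixel_factor=1,
        include_border=params.include_border_objects,
        kind="nuclei",
    )


def detect_puncta(
    puncta_channel: ChannelImage, params: SegmentationParams
) -> LabelMask:
    """Detect puncta by intensity above local background with width gates.

    The caller is expected to have applied :func:`tophat_filter` first
    (the detection threshold is relative to the residual local background).
    Components with equivalent-circle diameter within [min, max] punctum
    width (default 0.5-1.0 um) are retained.
    """
    return _segment_by_width(
        puncta_channel,
        params.punctum_threshold_window_px,
        params.punctum_threshold_offset,
        params.punctum_min_width_um,
        params.punctum_max_width_um,
        subpixel_factor=params.punctum_subpixel_factor,
        include_border=params.include_border_objects,
        kind="puncta",
    )


def grow_cells(nuclei: LabelMask, params: SegmentationParams) -> LabelMask:
    """Expand each nucleus outward into a pseudo-whole-cell territory.

    Every background pixel within ``cell_growth_px`` (Euclidean) of some
    nucleus is assigned to the nearest nucleus; distance ties are broken in
    favour of the lower label id.  Expansion fronts never merge and nucleus
    pixels keep their own label.
    """
    labels = nuclei.labels
    ids = nuclei.label_ids()
    if ids.size == 0:
        return LabelMask(np.zeros_like(labels), kind="cells")
    best_dist = np.full(labels.shape, np.inf)
    assigned = np.zeros_like(labels)
    for lab in ids:  # ascending: strict '<' leaves ties with the lower label
        dist = ndimage.distance_transform_edt(labels != lab)
        closer = dist < best_dist
        best_dist[closer] = dist[closer]
        assigned[closer] = lab
    cells = np.where(best_dist <= params.cell_growth_px, assigned, 0)
    return LabelMask(cells, kind="cells")


def compartmentalize(cells: LabelMask, nuclei: LabelMask) -> LabelMask:
    """Subtract the nuclear region from each cell to get the cytoplasm.

    For every label, nucleus and cytoplasm are disjoint and their union is
    the cell territory.
    """
    if cells.shape != nuclei.shape:
        raise ValidationError("cells and nuclei masks have different shapes")
    nuc = nuclei.labels
    inside = nuc > 0
    if not np.array_equal(cells.labels[inside], nuc[inside]):
        raise ValidationError("a nucleus pixel lies outside its own cell label")
    cytoplasm = np.where(inside, 0, cells.labels)
    return LabelMask(cytoplasm, kind="cytoplasm")


@dataclass
class CellRecord:
    """Per-cell measurements bridging pixels to well-level statistics."""

    cell_id: int
    nucleus_area_px: float
    nucleus_area_um2: float
    nuclear_puncta_count: int
    cytoplasmic_puncta_count: int
    mean_nuclear_intensity: float = float("nan")
    mean_cytoplasmic_intensity: float = float("nan")

    @property
    def total_puncta_count(self) -> int:
        return self.nuclear_puncta_count + self.cytoplasmic_puncta_count


def count_puncta_per_cell(
    puncta: LabelMask,
    nuclei: LabelMask,
    cytoplasm: LabelMask,
    intensity: ChannelImage | None = None,
    pixel_size_um: float | None = None,
) -> tuple[list[CellRecord], int]:
    """Assign each punctum to a compartment by its centroid and count per cell.

    Returns ``(records, n_unassigned)`` where ``n_unassigned`` counts puncta
    whose centroid falls outside every cell; no punctum is ever counted
    twice.  Mean compartment intensities are filled when ``intensity`` is
    given (its pixel size also supplies the area calibration).
    """
    if not (puncta.shape == nuclei.shape == cytoplasm.shape):
        raise ValidationError("puncta, nuclei and cytoplasm masks must share a shape")
    if pixel_size_um is None:
        pixel_size_um = intensity.pixel_size_um if intensity is not None else 1.0

    cell_ids = nuclei.label_ids()
    nuclear_counts = {int(k): 0 for k in cell_ids}
    cyto_counts = {int(k): 0 for k in cell_ids}
    unassigned = 0
    ids = puncta.label_ids()
    if ids.size:
        centroids = ndimage.center_of_mass(
            np.ones(puncta.shape), labels=puncta.labels, index=ids
        )
        for row, col in centroids:
            r = int(np.clip(round(row), 0, puncta.shape[0] - 1))
            c = int(np.clip(round(col), 0, puncta.shape[1] - 1))
            if nuclei.labels[r, c] > 0:
                nuclear_counts[int(nuclei.labels[r, c])] += 1
            elif cytoplasm.labels[r, c] > 0:
                cyto_counts[int(cytoplasm.labels[r, c])] += 1
            else:
                unassigned += 1

    records = []
    for k in cell_ids:
        k = int(k)
        nuc_mask = nuclei.labels == k
        area_px = float(nuc_mask.sum())
        if intensity is not None:
            cyt_mask = cytoplasm.labels == k
            mean_nuc = float(intensity.pixels[nuc_mask].mean()) if area_px else float("nan")
            mean_cyt = (
                float(intensity.pixels[cyt_mask].mean())
                if cyt_mask.any()
                else float("nan")
            )
        else:
            mean_nuc = mean_cyt = float("nan")
        records.append(
            CellRecord(
                cell_id=k,
                nucleus_area_px=area_px,
                nucleus_area_um2=area_px * pixel_size_um**2,
                nuclear_puncta_count=nuclear_counts[k],
                cytoplasmic_puncta_count=cyto_counts[k],
                mean_nuclear_intensity=mean_nuc,
                mean_cytoplasmic_intensity=mean_cyt,
            )
        )
    return records, unassigned


def segment_field(
    nuclei_channel: ChannelImage,
    puncta_channel: ChannelImage,
    params: SegmentationParams,
    apply_tophat: bool = True,
) -> tuple[list[CellRecord], int, dict[str, LabelMask]]:
    """Run the full per-field workflow and return records plus all masks.

    ``apply_tophat`` controls whether puncta detection runs on the top-hat
    output (default) or on the raw channel.
    """
    filtered = tophat_filter(puncta_channel, params) if apply_tophat else puncta_channel
    puncta = detect_puncta(filtered, params)
    nuclei = segment_nuclei(nuclei_channel, params)
    cells = grow_cells(nuclei, params)
    cytoplasm = compartmentalize(cells, nuclei)
    records, unassigned = count_puncta_per_cell(
        puncta, nuclei, cytoplasm, intensity=puncta_channel
    )
    masks = {
        "nuclei": nuclei,
        "cells": cells,
        "cytoplasm": cytoplasm,
        "puncta": puncta,
    }
    return records, unassigned, masks
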