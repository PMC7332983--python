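"""Two-channel co-localization: illumination correction, alignment,
pixel-based Pearson correlation and object-overlap fractions.

The object-overlap stage thresholds each channel (Otsu by default),
segments the above-threshold pixels into objects with the same width gating
used for puncta detection, and reports the three candidate overlap
fractions |A∩B|/|A|, |A∩B|/|B| and the symmetric union (Jaccard) fraction
|A∩B|/|A∪B|; the headline "percent co-localization" is 100x the union
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .core import ChannelImage, LabelMask, ValidationError, equivalent_diameter
from .segmentation import SegmentationParams, _subpixel_area, _EIGHT_CONNECTED


@dataclass
class ColocResult:
    pearson_r: float | None
    n_pixels_used: int
    overlap_fraction_a_in_b: float
    overlap_fraction_b_in_a: float
    union_overlap_fraction: float
    threshold_a: float
    threshold_b: float

    @property
    def percent_colocalization(self) -> float:
        return 100.0 * self.union_overlap_fraction


@dataclass
class AlignmentResult:
    image: ChannelImage
    shift: tuple[int, int]  # (d_row, d_col) applied to the moving image
    correlation_before: float
    correlation_after: float


def correct_illumination(
    image: ChannelImage, smoothing_scale_px: int
) -> ChannelImage:
    """Divide the image by its heavily smoothed version, preserving the mean.

    Removes smooth flat-field / gain artifacts of scale >= the smoothing
    scale while leaving objects (much smaller than that scale) intact.
    """
    if smoothing_scale_px < 3:
        raise ValidationError("smoothing_scale_px must be >= 3")
    smoothed = ndimage.gaussian_filter(image.pixels, sigma=smoothing_scale_px)
    if smoothed.min() <= 0:
        raise ValidationError(
            "smoothed illumination field contains non-positive values; "
            "cannot divide"
        )
    corrected = image.pixels / smoothed
    corrected *= image.pixels.mean() / corrected.mean()
    return ChannelImage(corrected, image.channel_name, image.pixel_size_um)


def _overlap_slices(shape, dr, dc):
    rows, cols = shape
    ref = (
        slice(max(dr, 0), rows + min(dr, 0)),
        slice(max(dc, 0), cols + min(dc, 0)),
    )
    mov = (
        slice(max(-dr, 0), rows + min(-dr, 0)),
        slice(max(-dc, 0), cols + min(-dc, 0)),
    )
    return ref, mov


def align_channels(
    reference: ChannelImage, moving: ChannelImage, max_shift_px: int
) -> AlignmentResult:
    """Find the integer translation of ``moving`` maximizing correlation.

    The search covers shifts within +/- ``max_shift_px``; among equally good
    shifts the smallest displacement wins.  Out-of-field pixels of the
    returned image are zero-filled and should be excluded from later
    statistics.
    """
    if reference.shape != moving.shape:
        raise ValidationError("reference and moving images have different shapes")
    if max_shift_px >= min(reference.shape):
        raise ValidationError("max_shift_px must be smaller than the image")
    ref = reference.pixels
    mov = moving.pixels

    def corr(dr: int, dc: int) -> float:
        s_ref, s_mov = _overlap_slices(ref.shape, dr, dc)
        a = ref[s_ref].ravel()
        b = mov[s_mov].ravel()
        if a.std() == 0 or b.std() == 0:
            return -np.inf
        return float(np.corrcoef(a, b)[0, 1])

    shifts = sorted(
        (
            (dr, dc)
            for dr in range(-max_shift_px, max_shift_px + 1)
            for dc in range(-max_shift_px, max_shift_px + 1)
        ),
        key=lambda s: (s[0] ** 2 + s[1] ** 2, s[0], s[1]),
    )
    best = (0, 0)
    best_r = -np.inf
    for dr, dc in shifts:
        r = corr(dr, dc)
        if r > best_r:
            best_r = r
            best = (dr, dc)
    dr, dc = best
    shifted = np.zeros_like(mov)
    s_ref, s_mov = _overlap_slices(ref.shape, dr, dc)
    shifted[s_ref] = mov[s_mov]
    return AlignmentResult(
        image=ChannelImage(shifted, moving.channel_name, moving.pixel_size_um),
        shift=best,
        correlation_before=corr(0, 0),
        correlation_after=best_r,
    )


def pearson_pixel_correlation(
    a: ChannelImage, b: ChannelImage, mask: LabelMask | None = None
) -> float:
    """Sample Pearson correlation of pixel intensities over the mask."""
    if a.shape != b.shape:
        raise ValidationError("channels have different shapes")
    if mask is not None:
        if mask.shape != a.shape:
            raise ValidationError("mask shape differs from the channels")
        select = mask.labels > 0
        x = a.pixels[select]
        y = b.pixels[select]
    else:
        x = a.pixels.ravel()
        y = b.pixels.ravel()
    if x.size < 2:
        raise ValidationError("need at least two pixels to correlate")
    if x.std() == 0 or y.std() == 0:
        raise ValidationError("zero variance in a channel; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def _object_pixels(
    image: ChannelImage,
    threshold: float,
    min_width_um: float,
    max_width_um: float,
    subpixel_factor: int,
) -> np.ndarray:
    """Boolean mask of pixels belonging to width-gated objects.

    Components are found at the detection threshold, but their width is the
    equivalent-circle diameter of the half-maximum contour (peak above the
    background level, estimated as the median of sub-threshold pixels), so
    the gate does not depend on where the auto-threshold happens to sit.
    """
    pixels = image.pixels
    thr = np.full(pixels.shape, threshold)
    binary = pixels > thr
    labels, _ = ndimage.label(binary, structure=_EIGHT_CONNECTED)
    below = pixels[~binary]
    background = float(np.median(below)) if below.size else 0.0
    keep = np.zeros(pixels.shape, dtype=bool)
    for lab, region in enumerate(ndimage.find_objects(labels), start=1):
        if region is None:
            continue
        component = labels[region] == lab
        peak = float(pixels[region][component].max())
        half_level = background + 0.5 * (peak - background)
        half_thr = np.broadcast_to(
            np.float64(max(half_level, threshold)), pixels.shape
        )
        if subpixel_factor > 1:
            area = _subpixel_area(pixels, half_thr, labels, lab, region, subpixel_factor)
        else:
            area = float(((pixels[region] > half_level) & component).sum())
        width_um = equivalent_diameter(area) * image.pixel_size_um
        if min_width_um <= width_um <= max_width_um:
            keep[region][component] = True
    return keep


def object_colocalization(
    a: ChannelImage,
    b: ChannelImage,
    params: SegmentationParams | None = None,
    threshold_a: float | None = None,
    threshold_b: float | None = None,
) -> ColocResult:
    """Object-overlap co-localization between two channels.

    Thresholds default to Otsu's method per channel; object width gates and
    the sub-pixel measurement factor come from ``params`` (punctum gates by
    default).  Raises when both object sets are empty (fractions undefined).
    """
    if a.shape != b.shape:
        raise ValidationError("channels have different shapes")
    params = params or SegmentationParams()
    thr_a = float(threshold_otsu(a.pixels)) if threshold_a is None else threshold_a
    thr_b = float(threshold_otsu(b.pixels)) if threshold_b is None else threshold_b
    mask_a = _object_pixels(
        a, thr_a, params.punctum_min_width_um, params.punctum_max_width_um,
        params.punctum_subpixel_factor,
    )
    mask_b = _object_pixels(
        b, thr_b, params.punctum_min_width_um, params.punctum_max_width_um,
        params.punctum_subpixel_factor,
    )
    n_a = int(mask_a.sum())
    n_b = int(mask_b.sum())
    if n_a == 0 and n_b == 0:
        raise ValidationError("no objects in either channel; overlap undefined")
    inter = int((mask_a & mask_b).sum())
    union = int((mask_a | mask_b).sum())
    try:
        r = pearson_pixel_correlation(a, b)
    except ValidationError:
        r = None
    return ColocResult(
        pearson_r=r,
        n_pixels_used=a.pixels.size,
        overlap_fraction_a_in_b=inter / n_a if n_a else 0.0,
        overlap_fraction_b_in_a=inter / n_b if n_b else 0.0,
        union_overlap_fraction=inter / union,
        threshold_a=thr_a,
        threshold_b=thr_b,
    )
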