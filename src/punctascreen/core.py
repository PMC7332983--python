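"""Core containers shared by every stage of the pipeline.

Conventions used throughout the package:

* images are 2-D ``float64`` arrays in (row, col) order with 0-based indices;
* physical calibration is carried by a single ``pixel_size_um`` value
  (micrometres per pixel) attached to each :class:`ChannelImage`;
* segmentations are integer label grids where ``0`` is background and
  object labels are consecutive positive integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default physical pixel size in micrometres per pixel, a plausible value
#: for a 20x widefield objective on a high-content imager.  Every parameter
#: denominated in micrometres is converted to pixels through this one value.
DEFAULT_PIXEL_SIZE_UM = 0.325


class ValidationError(ValueError):
    """An input violated a documented precondition."""


class PlacementError(RuntimeError):
    """The synthetic renderer could not place the requested objects."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""


@dataclass
class ChannelImage:
    """One 2-D fluorescence intensity field for a single stain.

    Parameters
    ----------
    pixels:
        Non-negative intensities, arbitrary units.
    channel_name:
        Stain / filter-set label, e.g. ``"DAPI"`` or ``"Cy3"``.
    pixel_size_um:
        Micrometres per pixel.
    """

    pixels: np.ndarray
    channel_name: str = ""
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValidationError(
                f"ChannelImage expects a 2-D array, got shape {self.pixels.shape}"
            )
        if not np.all(np.isfinite(self.pixels)):
            raise ValidationError("ChannelImage contains non-finite values")
        if self.pixel_size_um <= 0:
            raise ValidationError("pixel_size_um must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def um_to_px(self, micrometres: float) -> float:
        """Convert a physical length to pixels using this image's calibration."""
        return micrometres / self.pixel_size_um

    def px_to_um(self, pixels: float) -> float:
        return pixels * self.pixel_size_um


@dataclass
class LabelMask:
    """Integer-labelled segmentation; 0 is background.

    ``kind`` documents what the labels represent (``nuclei``, ``cells``,
    ``cytoplasm`` or ``puncta``).
    """

    labels: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValidationError("LabelMask expects a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValidationError("LabelMask labels must be integers")
        if self.labels.min() < 0:
            raise ValidationError("LabelMask labels must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def n_objects(self) -> int:
        return int(self.labels.max())

    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


def relabel_consecutive(labels: np.ndarray) -> np.ndarray:
    """Map positive labels to 1..n preserving their ascending order."""
    out = np.zeros_like(labels)
    for new, old in enumerate(np.unique(labels[labels > 0]), start=1):
        out[labels == old] = new
    return out


def equivalent_diameter(area: float) -> float:
    """Equivalent-circle diameter of an area: ``2 * sqrt(area / pi)``.

    This is the operational meaning of an object's "width" everywhere in the
    package; min/max width gates compare against this quantity.
    """
    return 2.0 * np.sqrt(area / np.pi)
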