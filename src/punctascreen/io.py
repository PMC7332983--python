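"""Readers, writers and run configuration.

TIFF images are read through :mod:`tifffile`; pixel size always comes from
the run configuration (TIFF metadata, when present, is reported but never
trusted).  Tables are plain CSV with a header row and stable column order.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .core import DEFAULT_PIXEL_SIZE_UM, ChannelImage, LabelMask, ValidationError
from .radial import RadialParams
from .segmentation import SegmentationParams


@dataclass
class ScreenSettings:
    n_trees: int = 100
    cv_folds: int = 5


@dataclass
class ColocSettings:
    smoothing_scale_px: int = 64
    max_shift_px: int = 10


@dataclass
class FluxSettings:
    anchor_quantile: float = 0.995
    bafa1_condition: str = "BafA1"


@dataclass
class RunConfig:
    """Everything a pipeline run needs; one seed reproduces the whole run."""

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    radial: RadialParams = field(default_factory=RadialParams)
    screen: ScreenSettings = field(default_factory=ScreenSettings)
    coloc: ColocSettings = field(default_factory=ColocSettings)
    flux: FluxSettings = field(default_factory=FluxSettings)
    output_dir: str = "results"
    log_level: str = "INFO"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, sub in (
            ("segmentation", SegmentationParams),
            ("radial", RadialParams),
            ("screen", ScreenSettings),
            ("coloc", ColocSettings),
            ("flux", FluxSettings),
        ):
            if key in data and isinstance(data[key], dict):
                block = dict(data[key])
                # YAML round-trips tuples as lists; dataclass fields accept both.
                data[key] = sub(**block)
        return cls(**data)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def read_image(
    path: str | Path,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    channel_map: dict[int, str] | None = None,
) -> ChannelImage | dict[str, ChannelImage]:
    """Read a single- or multi-channel TIFF as :class:`ChannelImage`.

    A 2-D file returns one image; a 3-D (page, row, col) file requires a
    ``channel_map`` of 1-based page index to channel name and returns a dict
    keyed by channel name.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    array = np.asarray(tifffile.imread(path))
    if array.ndim == 2:
        name = (channel_map or {}).get(1, path.stem)
        if array.min() < 0:
            raise ValidationError(f"negative intensities in {path}")
        return ChannelImage(array.astype(float), name, pixel_size_um)
    if array.ndim == 3:
        if not channel_map:
            raise ValidationError(
                f"{path} has {array.shape[0]} pages; provide a channel_map "
                "of page index (1-based) to channel name"
            )
        out = {}
        for page, name in channel_map.items():
            if not 1 <= page <= array.shape[0]:
                raise ValidationError(f"channel_map page {page} out of range for {path}")
            plane = array[page - 1]
            if plane.min() < 0:
                raise ValidationError(f"negative intensities in {path} page {page}")
            out[name] = ChannelImage(plane.astype(float), name, pixel_size_um)
        return out
    raise ValidationError(f"{path} is {array.ndim}-D; expected 2-D or 3-D TIFF")


def write_image(path: str | Path, image: ChannelImage) -> None:
    tifffile.imwrite(path, image.pixels.astype(np.float32))


def write_labels(path: str | Path, mask: LabelMask) -> None:
    tifffile.imwrite(path, mask.labels.astype(np.uint16))


def read_plate_map(path: str | Path) -> pd.DataFrame:
    plate_map = pd.read_csv(path)
    required = {"plate_id", "well_id", "role"}
    missing = required - set(plate_map.columns)
    if missing:
        raise ValidationError(f"plate map {path} is missing columns {sorted(missing)}")
    for column in ("compound_id", "dose_um"):
        if column not in plate_map.columns:
            plate_map[column] = None
    return plate_map


def write_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)
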