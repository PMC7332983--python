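"""End-to-end screen pipeline: segment -> aggregate -> normalize -> classify.

The manifest maps each imaged site to its two channel TIFFs; the plate map
assigns wells to compounds, doses and control roles.  Every output file
embeds the configuration hash and seed so a run is reproducible from one
number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from .core import PipelineError
from .io import RunConfig, read_image, write_table
from .screen import (
    aggregate_wells,
    call_hits,
    cell_records_to_frame,
    hits_per_compound,
    normalize_plate,
    train_hit_classifier,
)
from .segmentation import segment_field

logger = logging.getLogger("punctascreen")

MANIFEST_COLUMNS = ["plate_id", "well_id", "site", "nuclei_path", "puncta_path"]


def _stage(name: str, detail: str, exc: Exception) -> PipelineError:
    return PipelineError(f"stage '{name}' failed on {detail}: {exc}")


def run_pipeline(
    config: RunConfig,
    manifest: pd.DataFrame,
    plate_map: pd.DataFrame,
    out_dir: str | Path | None = None,
) -> dict:
    """Run the full screen analysis and (optionally) write the result bundle.

    Returns a dict with the per-cell table, well features, normalized wells,
    per-well and per-compound hit calls and the model report.
    """
    missing = [c for c in MANIFEST_COLUMNS if c not in manifest.columns]
    if missing:
        raise PipelineError(f"manifest is missing columns: {missing}")

    cell_frames = []
    for _, row in manifest.iterrows():
        detail = f"plate {row['plate_id']} well {row['well_id']} site {row['site']}"
        try:
            nuclei = read_image(row["nuclei_path"], config.pixel_size_um)
            puncta = read_image(row["puncta_path"], config.pixel_size_um)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage context
            raise _stage("read_image", detail, exc) from exc
        try:
            records, unassigned, _ = segment_field(nuclei, puncta, config.segmentation)
        except Exception as exc:  # noqa: BLE001
            raise _stage("segment", detail, exc) from exc
        logger.info(
            "%s: %d cells, %d unassigned puncta", detail, len(records), unassigned
        )
        cell_frames.append(
            cell_records_to_frame(
                records, row["plate_id"], row["well_id"], int(row["site"])
            )
        )
    cells = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else cell_records_to_frame([], "", "", 0)
    )

    try:
        wells = aggregate_wells(cells, plate_map)
    except Exception as exc:  # noqa: BLE001
        raise _stage("aggregate", "well aggregation", exc) from exc
    try:
        normalized = normalize_plate(wells)
    except Exception as exc:  # noqa: BLE001
        raise _stage("normalize", "plate normalization", exc) from exc
    try:
        classifier, cv_error = train_hit_classifier(
            normalized,
            n_trees=config.screen.n_trees,
            n_folds=config.screen.cv_folds,
            seed=config.seed,
        )
        per_well = call_hits(classifier, normalized)
        per_compound = hits_per_compound(per_well) if len(per_well) else pd.DataFrame(
            columns=["compound_id", "is_hit", "max_score"]
        )
    except Exception as exc:  # noqa: BLE001
        raise _stage("classify", "hit calling", exc) from exc

    report = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "cv_misclassification_error": cv_error,
        "n_trees": config.screen.n_trees,
        "cv_folds": config.screen.cv_folds,
        "n_cells": int(len(cells)),
        "n_wells": int(len(wells)),
        "n_hits": int((per_well["predicted_label"] == "hit").sum()) if len(per_well) else 0,
    }

    bundle = {
        "cells": cells,
        "wells": wells,
        "normalized_wells": normalized,
        "hit_calls": per_well,
        "hits_per_compound": per_compound,
        "model_report": report,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# config_hash={report['config_hash']} seed={config.seed}"
        for name in ("cells", "wells", "normalized_wells", "hit_calls", "hits_per_compound"):
            path = out / f"{name}.csv"
            with open(path, "w") as fh:
                fh.write(stamp + "\n")
                bundle[name].to_csv(fh, index=False)
        with open(out / "model_report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return bundle
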