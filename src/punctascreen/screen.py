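"""Well aggregation, percent-of-negative-control normalization and hit calling.

The data-analysis stage of the phenotypic screen: per-cell records are
aggregated to whole-well features (cell count plus nuclear and cytoplasmic
puncta sums over all imaged sites), every feature is divided by the plate's
negative-control median (so 1 = negative-control median, scale-free), and a
bootstrap-aggregated ensemble of decision trees trained on the two control
classes scores every compound well.  A compound well classified as
positive-control-like (rescued phenotype) is a hit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingClassifier
from sklearn.model_selection import StratifiedKFold, cross_val_predict
from sklearn.tree import DecisionTreeClassifier

from .core import ValidationError
from .segmentation import CellRecord

#: The well-level features used for normalization and classification.
FEATURES = ["cell_count", "nuclear_puncta_sum", "cytoplasmic_puncta_sum"]
NORM_FEATURES = [f + "_norm" for f in FEATURES]
PLATE_MAP_COLUMNS = ["plate_id", "well_id", "compound_id", "dose_um", "role"]
ROLES = {"negative_control", "positive_control", "compound"}


def cell_records_to_frame(
    records: list[CellRecord], plate_id: str, well_id: str, site: int
) -> pd.DataFrame:
    rows = [
        {
            "plate_id": plate_id,
            "well_id": well_id,
            "site": site,
            "cell_id": r.cell_id,
            "nucleus_area_px": r.nucleus_area_px,
            "nucleus_area_um2": r.nucleus_area_um2,
            "nuclear_puncta_count": r.nuclear_puncta_count,
            "cytoplasmic_puncta_count": r.cytoplasmic_puncta_count,
            "total_puncta_count": r.total_puncta_count,
            "mean_nuclear_intensity": r.mean_nuclear_intensity,
            "mean_cytoplasmic_intensity": r.mean_cytoplasmic_intensity,
        }
        for r in records
    ]
    columns = [
        "plate_id", "well_id", "site", "cell_id", "nucleus_area_px",
        "nucleus_area_um2", "nuclear_puncta_count", "cytoplasmic_puncta_count",
        "total_puncta_count", "mean_nuclear_intensity", "mean_cytoplasmic_intensity",
    ]
    return pd.DataFrame(rows, columns=columns)


def aggregate_wells(cell_records: pd.DataFrame, plate_map: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-cell records over sites to whole-well features.

    Every (plate_id, well_id) in ``cell_records`` must appear in the plate
    map; offenders are listed in the error.  Wells present in the plate map
    but with no cells get zero counts and are flagged.
    """
    missing = [c for c in PLATE_MAP_COLUMNS if c not in plate_map.columns]
    if missing:
        raise ValidationError(f"plate map is missing columns: {missing}")
    bad_roles = set(plate_map["role"]) - ROLES
    if bad_roles:
        raise ValidationError(f"unknown plate-map roles: {sorted(bad_roles)}")

    map_keys = set(zip(plate_map["plate_id"], plate_map["well_id"]))
    record_keys = set(zip(cell_records["plate_id"], cell_records["well_id"]))
    orphans = sorted(record_keys - map_keys)
    if orphans:
        raise ValidationError(
            f"cell records reference wells absent from the plate map: {orphans}"
        )

    grouped = (
        cell_records.groupby(["plate_id", "well_id"])
        .agg(
            cell_count=("cell_id", "size"),
            nuclear_puncta_sum=("nuclear_puncta_count", "sum"),
            cytoplasmic_puncta_sum=("cytoplasmic_puncta_count", "sum"),
        )
        .reset_index()
    )
    wells = plate_map.merge(grouped, on=["plate_id", "well_id"], how="left")
    wells["flagged_empty"] = wells["cell_count"].isna()
    for feature in FEATURES:
        wells[feature] = wells[feature].fillna(0).astype(int)
    # Whole-well per-cell averages, derivable but convenient downstream.
    with np.errstate(invalid="ignore", divide="ignore"):
        wells["nuclear_puncta_per_cell"] = np.where(
            wells["cell_count"] > 0,
            wells["nuclear_puncta_sum"] / wells["cell_count"],
            np.nan,
        )
        wells["cytoplasmic_puncta_per_cell"] = np.where(
            wells["cell_count"] > 0,
            wells["cytoplasmic_puncta_sum"] / wells["cell_count"],
            np.nan,
        )
    return wells


def normalize_plate(wells: pd.DataFrame) -> pd.DataFrame:
    """Divide every feature by the plate's negative-control median.

    After normalization the negative-control median of each feature is
    exactly 1; values are dimensionless and scale in (0, inf).  The
    operation is applied per plate and is idempotent on its own output.
    """
    for feature in FEATURES:
        if feature not in wells.columns:
            raise ValidationError(f"wells table is missing feature '{feature}'")
    out = []
    for plate_id, plate in wells.groupby("plate_id", sort=False):
        negatives = plate[plate["role"] == "negative_control"]
        if negatives.empty:
            raise ValidationError(f"plate '{plate_id}' has no negative-control wells")
        plate = plate.copy()
        for feature in FEATURES:
            median = float(negatives[feature].median())
            if median <= 0:
                raise ValidationError(
                    f"negative-control median of '{feature}' on plate "
                    f"'{plate_id}' is {median}; cannot normalize"
                )
            plate[feature + "_norm"] = plate[feature] / median
        out.append(plate)
    return pd.concat(out, ignore_index=True)


@dataclass
class HitClassifier:
    """A trained ensemble with its feature schema and CV diagnostics."""

    model: BaggingClassifier
    features: list[str]
    cv_misclassification_error: float


def train_hit_classifier(
    wells: pd.DataFrame,
    n_trees: int = 100,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[HitClassifier, float]:
    """Train bagged decision trees to separate the two control classes.

    Positive controls (healthy, rescued phenotype) are the positive class;
    negative controls (impaired flux, vehicle) the negative class.  Compound
    wells are never trained on.  Returns the classifier and its stratified
    ``n_folds``-fold cross-validated misclassification error.
    """
    for feature in NORM_FEATURES:
        if feature not in wells.columns:
            raise ValidationError(
                f"wells are not normalized: missing '{feature}' (run normalize_plate)"
            )
    controls = wells[wells["role"].isin(["negative_control", "positive_control"])]
    y = (controls["role"] == "positive_control").to_numpy()
    for label, count in (("positive_control", y.sum()), ("negative_control", (~y).sum())):
        if count < n_folds:
            raise ValidationError(
                f"class '{label}' has {count} wells; need >= {n_folds} for "
                f"{n_folds}-fold stratified CV"
            )
    X = controls[NORM_FEATURES].to_numpy(dtype=float)
    model = BaggingClassifier(
        estimator=DecisionTreeClassifier(random_state=seed),
        n_estimators=n_trees,
        random_state=seed,
    )
    cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    predicted = cross_val_predict(model, X, y, cv=cv)
    cv_error = float(np.mean(predicted != y))
    model.fit(X, y)
    clf = HitClassifier(
        model=model, features=list(NORM_FEATURES), cv_misclassification_error=cv_error
    )
    return clf, cv_error


def call_hits(classifier: HitClassifier, compound_wells: pd.DataFrame) -> pd.DataFrame:
    """Score compound wells; hit iff classified positive-control-like.

    ``score`` is the ensemble vote fraction for the rescued phenotype.
    """
    for feature in classifier.features:
        if feature not in compound_wells.columns:
            raise ValidationError(
                f"feature schema mismatch: compound wells lack '{feature}'"
            )
    wells = compound_wells[compound_wells["role"] == "compound"].copy()
    X = wells[classifier.features].to_numpy(dtype=float)
    if len(wells):
        scores = classifier.model.predict_proba(X)[:, list(classifier.model.classes_).index(True)]
    else:
        scores = np.zeros(0)
    wells["score"] = scores
    wells["predicted_label"] = np.where(scores > 0.5, "hit", "non_hit")
    columns = ["plate_id", "well_id", "compound_id", "dose_um", "predicted_label", "score"]
    return wells[[c for c in columns if c in wells.columns]].reset_index(drop=True)


def hits_per_compound(hit_calls: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-well calls: a compound is a hit if any dose is called."""
    return (
        hit_calls.assign(is_hit=hit_calls["predicted_label"] == "hit")
        .groupby("compound_id")
        .agg(is_hit=("is_hit", "any"), max_score=("score", "max"))
        .reset_index()
    )
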