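"""Ratiometric mCherry/GFP autophagic-flux analysis.

Cells expressing a tandem mCherry-GFP-LC3 reporter lose GFP (but not
mCherry) fluorescence when the reporter reaches the acidic lysosome, so a
high per-event mCherry/GFP ratio marks cells with active flux.  The gate
separating "high ratio" is anchored on a Bafilomycin-A1-treated control
population, in which lysosomal acidification is blocked and both
fluorophores stay bright: the gate sits at the rightward base of the BafA1
ratio distribution, operationalized as a high empirical quantile
(default 99.5%).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

REQUIRED_COLUMNS = ["gfp", "mcherry"]
MIN_ANCHOR_EVENTS = 100


def _validate_events(events: pd.DataFrame) -> None:
    for column in REQUIRED_COLUMNS:
        if column not in events.columns:
            raise ValidationError(f"event table is missing column '{column}'")
    bad = events.index[~(events["gfp"] > 0) | ~np.isfinite(events["gfp"])]
    if len(bad):
        raise ValidationError(
            f"non-positive GFP intensity in rows {list(bad[:10])}"
            + ("..." if len(bad) > 10 else "")
        )
    bad = events.index[~(events["mcherry"] > 0) | ~np.isfinite(events["mcherry"])]
    if len(bad):
        raise ValidationError(
            f"non-positive mCherry intensity in rows {list(bad[:10])}"
            + ("..." if len(bad) > 10 else "")
        )


@dataclass
class RatioGate:
    """An mCherry/GFP ratio threshold with its anchoring provenance."""

    gate_value: float
    anchor_condition: str = "BafA1"
    anchor_quantile: float = 0.995

    def __post_init__(self) -> None:
        if self.gate_value <= 0:
            raise ValidationError("gate_value must be positive")
        if not 0 < self.anchor_quantile < 1:
            raise ValidationError("anchor_quantile must be in (0, 1)")


def compute_ratios(events: pd.DataFrame) -> pd.Series:
    """Per-event mCherry/GFP ratio, order preserved."""
    _validate_events(events)
    return events["mcherry"] / events["gfp"]


def set_gate_from_bafa1(
    bafa1_events: pd.DataFrame,
    anchor_quantile: float = 0.995,
    anchor_condition: str = "BafA1",
) -> RatioGate:
    """Place the ratio gate at a high quantile of the BafA1 distribution."""
    if not 0 < anchor_quantile < 1:
        raise ValidationError("anchor_quantile must be in (0, 1)")
    if len(bafa1_events) < MIN_ANCHOR_EVENTS:
        raise ValidationError(
            f"need >= {MIN_ANCHOR_EVENTS} anchor events, got {len(bafa1_events)}"
        )
    ratios = compute_ratios(bafa1_events)
    gate = float(np.quantile(ratios.to_numpy(), anchor_quantile))
    return RatioGate(
        gate_value=gate,
        anchor_condition=anchor_condition,
        anchor_quantile=anchor_quantile,
    )


def fraction_autophagic(events: pd.DataFrame, gate: RatioGate) -> float:
    """Percentage of events with ratio above the gate, in [0, 100]."""
    if len(events) == 0:
        raise ValidationError("empty event table")
    ratios = compute_ratios(events)
    return 100.0 * float(np.mean(ratios.to_numpy() > gate.gate_value))


def analyze_flux(
    events: pd.DataFrame,
    bafa1_condition: str = "BafA1",
    anchor_quantile: float = 0.995,
) -> tuple[pd.DataFrame, RatioGate]:
    """Gate on the BafA1 condition, then score every (sample, condition).

    Returns a per-sample table with the autophagic percentage and the gate.
    """
    if "condition" not in events.columns:
        raise ValidationError("event table needs a 'condition' column")
    anchor = events[events["condition"] == bafa1_condition]
    if anchor.empty:
        raise ValidationError(f"no events with condition '{bafa1_condition}'")
    gate = set_gate_from_bafa1(anchor, anchor_quantile, bafa1_condition)
    rows = []
    for (sample_id, condition), group in events.groupby(
        ["sample_id", "condition"], sort=False
    ):
        rows.append(
            {
                "sample_id": sample_id,
                "condition": condition,
                "n_events": len(group),
                "percent_autophagic": fraction_autophagic(group, gate),
                "gate_value": gate.gate_value,
                "anchor_quantile": gate.anchor_quantile,
            }
        )
    return pd.DataFrame(rows), gate
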