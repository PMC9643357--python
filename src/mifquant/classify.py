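"""Marker positivity calls with calibrated thresholds and artifact corrections.

Positivity for the membrane markers (cd8 on green, cd66b on red) requires
the raw integrated density to exceed a calibrated threshold AND a
channel-ratio rule that removes cells whose band overlaps erythrocytes,
which fluoresce in several channels: green/red > 4 for cd8, red/green > 2
for cd66b.  All comparisons are strict, so exact boundary values are
negative.

The area-based route (alpha-SMA workflow) calls a cell positive when the
area of expansion-region pixels above a per-channel cutoff exceeds a
minimum (default 3 µm²), and discards cells whose expansion shows positive
area simultaneously in every erythrocyte-bleed channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fields import LabelMask, MultiChannelField
from .geometry import check_alignment

REASONS = ("below_threshold", "ratio_fail", "area_fail", "rbc_overlap_discard", "pass")


class CalibrationError(ValueError):
    """Too few negative-control cells to calibrate a threshold."""


@dataclass
class ClassifierConfig:
    cd8_rid_threshold: float | None = None
    cd66b_rid_threshold: float | None = None
    ratio_green_over_red_min: float = 4.0
    ratio_red_over_green_min: float = 2.0
    autofluor_quantile: float = 0.99
    min_negative_cells: int = 20
    alpha_sma_min_positive_area_um2: float = 3.0
    alpha_sma_channel: str = "green"
    pixel_classifier_thresholds: dict[str, float] = dc_field(default_factory=dict)
    rbc_discard_channels: tuple[str, ...] = ("green", "red", "farred")

    def __post_init__(self) -> None:
        if not (0 < self.autofluor_quantile < 1):
            raise ValueError("autofluor_quantile must lie in (0, 1)")
        for name in ("ratio_green_over_red_min", "ratio_red_over_green_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("cd8_rid_threshold", "cd66b_rid_threshold",
                     "alpha_sma_min_positive_area_um2"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class PositivityCall:
    cell_id: int
    marker: str
    positive: bool
    reason: str

    def __post_init__(self) -> None:
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.positive != (self.reason == "pass"):
            raise ValueError("positive must hold exactly when reason == 'pass'")


def calibrate_threshold(
    negative_rid_values: Iterable[float],
    quantile: float = 0.99,
    min_negatives: int = 20,
) -> float:
    """Empirical quantile (linear interpolation) of autofluorescence-only RIDs.

    Stands in for the by-eye comparison against autofluorescence-only cells:
    the threshold is the given quantile of the negative-control RID
    distribution, computed with the linear-interpolation convention
    (``numpy.quantile`` method 'linear').

    Raises :class:`CalibrationError` when fewer than ``min_negatives``
    values are supplied — set the threshold manually in that case.
    """
    vals = np.asarray(list(negative_rid_values), dtype=float)
    if vals.size < min_negatives:
        raise CalibrationError(
            f"only {vals.size} negative-control values (< {min_negatives}); "
            "supply the RID threshold manually"
        )
    if not (0 < quantile < 1):
        raise ValueError("quantile must lie in (0, 1)")
    return float(np.quantile(vals, quantile, method="linear"))


def _ratio(num: float, den: float) -> float:
    if den == 0:
        return math.inf if num > 0 else 0.0
    return num / den


def _classify_ratio_marker(
    cell_id: int, marker: str, rid_main: float, rid_other: float,
    threshold: float, ratio_min: float,
) -> PositivityCall:
    if not rid_main > threshold:
        return PositivityCall(cell_id, marker, False, "below_threshold")
    if not _ratio(rid_main, rid_other) > ratio_min:
        return PositivityCall(cell_id, marker, False, "ratio_fail")
    return PositivityCall(cell_id, marker, True, "pass")


def classify_cd8(row: Mapping, cfg: ClassifierConfig) -> PositivityCall:
    """cd8 call: rid_green > threshold AND green/red ratio > configured minimum.

    A zero red RID with nonzero green counts as an infinite ratio (passes);
    all comparisons are strict so boundary values are negative.
    """
    if cfg.cd8_rid_threshold is None:
        raise ValueError("cd8_rid_threshold not set; calibrate or supply one")
    return _classify_ratio_marker(
        int(row["cell_id"]), "cd8", float(row["rid_green"]), float(row["rid_red"]),
        cfg.cd8_rid_threshold, cfg.ratio_green_over_red_min,
    )


def classify_cd66b(row: Mapping, cfg: ClassifierConfig) -> PositivityCall:
    """cd66b call: mirror of :func:`classify_cd8` on the red channel."""
    if cfg.cd66b_rid_threshold is None:
        raise ValueError("cd66b_rid_threshold not set; calibrate or supply one")
    return _classify_ratio_marker(
        int(row["cell_id"]), "cd66b", float(row["rid_red"]), float(row["rid_green"]),
        cfg.cd66b_rid_threshold, cfg.ratio_red_over_green_min,
    )


def classify_markers(features: pd.DataFrame, cfg: ClassifierConfig) -> pd.DataFrame:
    """Apply the cd8 and cd66b rules to every row of a feature table.

    Returns a long table (cell_id, patient_id, field_id, marker, positive,
    reason) with one row per cell per marker.
    """
    calls = []
    for _, row in features.iterrows():
        for fn in (classify_cd8, classify_cd66b):
            c = fn(row, cfg)
            calls.append(
                {
                    "cell_id": c.cell_id,
                    "patient_id": row.get("patient_id", ""),
                    "field_id": row.get("field_id", ""),
                    "marker": c.marker,
                    "positive": c.positive,
                    "reason": c.reason,
                }
            )
    return pd.DataFrame(calls)


def positive_area_per_cell(
    field: MultiChannelField,
    expansion_mask: LabelMask,
    channel: str,
    cutoff: float,
) -> dict[int, float]:
    """Area (µm²) of expansion-region pixels strictly above ``cutoff``, per cell."""
    check_alignment(field, expansion_mask)
    img = field.channel(channel)
    labels = expansion_mask.labels
    n_max = int(labels.max()) + 1
    hot = (img > cutoff).ravel().astype(float)
    counts = np.bincount(labels.ravel(), weights=hot, minlength=n_max)
    px_area = field.pixel_size_um**2
    return {int(lab): float(counts[int(lab)] * px_area) for lab in expansion_mask.ids}


def classify_area_based(
    field: MultiChannelField,
    expansion_mask: LabelMask,
    cfg: ClassifierConfig,
    marker: str = "alpha_sma",
) -> list[PositivityCall]:
    """Pixel-classifier positivity: positive-pixel area must exceed the minimum.

    The pixel classifier is a global per-channel intensity cutoff
    (``cfg.pixel_classifier_thresholds``) standing in for an interactive
    thresholder.  A cell is positive iff its positive-pixel area is strictly
    greater than ``cfg.alpha_sma_min_positive_area_um2``.
    """
    channel = cfg.alpha_sma_channel
    if channel not in cfg.pixel_classifier_thresholds:
        raise ValueError(f"no pixel-classifier threshold configured for {channel!r}")
    areas = positive_area_per_cell(
        field, expansion_mask, channel, cfg.pixel_classifier_thresholds[channel]
    )
    calls = []
    for cid, area in sorted(areas.items()):
        if area > cfg.alpha_sma_min_positive_area_um2:
            calls.append(PositivityCall(cid, marker, True, "pass"))
        else:
            calls.append(PositivityCall(cid, marker, False, "area_fail"))
    return calls


def rbc_overlap_discard(
    field: MultiChannelField,
    expansion_mask: LabelMask,
    cfg: ClassifierConfig,
) -> set[int]:
    """Cells whose expansion shows positive area > 0 in *every* bleed channel.

    Erythrocytes fluoresce across channels, so a cell overlapping one shows
    classifier-positive pixels simultaneously in all of
    ``cfg.rbc_discard_channels``; only such cells are discarded.
    """
    per_channel = []
    for ch in cfg.rbc_discard_channels:
        if ch not in cfg.pixel_classifier_thresholds:
            raise ValueError(f"no pixel-classifier threshold configured for {ch!r}")
        per_channel.append(
            positive_area_per_cell(
                field, expansion_mask, ch, cfg.pixel_classifier_thresholds[ch]
            )
        )
    discarded = set()
    for cid in expansion_mask.ids:
        cid = int(cid)
        if all(areas.get(cid, 0.0) > 0 for areas in per_channel):
            discarded.add(cid)
    return discarded


def predicted_types(positivity: pd.DataFrame) -> pd.DataFrame:
    """Collapse marker calls to one predicted class per cell.

    cd8-positive -> 'cd8'; else cd66b-positive -> 'neutrophil'; else 'other'.
    Cells positive for both are labeled 'cd8' (double positives are not
    expected under the ratio rules, which are mutually exclusive for
    ratios > 1).
    """
    wide = positivity.pivot_table(
        index=["patient_id", "field_id", "cell_id"],
        columns="marker", values="positive", aggfunc="first",
    ).reset_index()
    for m in ("cd8", "cd66b"):
        if m not in wide:
            wide[m] = False
    wide["predicted_type"] = np.where(
        wide["cd8"].astype(bool), "cd8",
        np.where(wide["cd66b"].astype(bool), "neutrophil", "other"),
    )
    return wide[["patient_id", "field_id", "cell_id", "predicted_type"]]
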