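"""Nearest-neutrophil distances, touching/near binning and the group tests.

Per field of view, each cd8-positive cell is paired with its nearest
cd66b-positive cell by centroid-to-centroid Euclidean distance in µm
(the search never crosses fields).  Distances are binned into
``touching`` (< 10 µm), ``near`` ([10, 20) µm) or ``excluded``; granzyme-K
mean intensity is then normalized per patient by the mean over that
patient's near cells, and the pooled touching-vs-near comparison uses a
classical pooled-variance unpaired two-tailed t test (Welch optional).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

TOUCHING_MAX_UM = 10.0
NEAR_MAX_UM = 20.0

CATEGORIES = ("touching", "near", "excluded")


class EmptyGroupError(ValueError):
    """A comparison group is empty; carries the group name."""


def categorize(
    distance_um: float | None,
    touching_max_um: float = TOUCHING_MAX_UM,
    near_max_um: float = NEAR_MAX_UM,
) -> str:
    """Bin one nearest-neutrophil distance.

    < touching_max -> 'touching'; [touching_max, near_max) -> 'near';
    >= near_max or absent (None/NaN) -> 'excluded'.  Negative distances are
    an error.
    """
    if distance_um is None or (isinstance(distance_um, float) and math.isnan(distance_um)):
        return "excluded"
    if distance_um < 0:
        raise ValueError(f"distance must be >= 0, got {distance_um}")
    if distance_um < touching_max_um:
        return "touching"
    if distance_um < near_max_um:
        return "near"
    return "excluded"


def categorize_array(
    distances_um: np.ndarray,
    touching_max_um: float = TOUCHING_MAX_UM,
    near_max_um: float = NEAR_MAX_UM,
) -> np.ndarray:
    d = np.asarray(distances_um, dtype=float)
    if np.any(d[~np.isnan(d)] < 0):
        raise ValueError("distances must be >= 0")
    out = np.full(d.shape, "excluded", dtype=object)
    out[d < near_max_um] = "near"
    out[d < touching_max_um] = "touching"
    out[np.isnan(d)] = "excluded"
    return out


def nearest_neutrophil(
    cd8_cells: pd.DataFrame, neutrophils: pd.DataFrame
) -> pd.DataFrame:
    """Nearest cd66b+ cell for each query cell within one field of view.

    Inputs are tables with columns cell_id, centroid_x_um, centroid_y_um
    (both restricted to the same field).  Uses a k-d tree; distance ties are
    broken by the smaller neutrophil cell_id.  With zero neutrophils in the
    field, distances are absent (NaN) and ids are <NA>.
    """
    out = cd8_cells[["cell_id"]].copy()
    if neutrophils.empty:
        out["nearest_neutrophil_id"] = pd.array([pd.NA] * len(out), dtype="Int64")
        out["distance_um"] = np.nan
        return out
    npts = neutrophils[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    nids = neutrophils["cell_id"].to_numpy()
    qpts = cd8_cells[["centroid_x_um", "centroid_y_um"]].to_numpy(float)
    tree = cKDTree(npts)
    dist, idx = tree.query(qpts, k=1)

    # tie-break to the smallest neutrophil id among equidistant candidates
    best_ids = nids[idx].astype(np.int64)
    tol = 1e-9
    for i, (p, d) in enumerate(zip(qpts, dist)):
        cand = tree.query_ball_point(p, d + tol)
        if len(cand) > 1:
            cd = np.hypot(npts[cand, 0] - p[0], npts[cand, 1] - p[1])
            ties = [c for c, dd in zip(cand, cd) if abs(dd - d) <= tol]
            best_ids[i] = min(int(nids[c]) for c in ties)
    out["nearest_neutrophil_id"] = pd.array(best_ids, dtype="Int64")
    out["distance_um"] = dist
    return out


def build_proximity_table(
    features: pd.DataFrame,
    positivity: pd.DataFrame,
    *,
    gzmk_column: str = "mean_farred",
    touching_max_um: float = TOUCHING_MAX_UM,
    near_max_um: float = NEAR_MAX_UM,
    include_non_cd8: bool = False,
) -> pd.DataFrame:
    """Pair marker-positive cells with their nearest neutrophil, per field.

    ``features`` is a per-cell feature table (must carry centroids and
    ``gzmk_column``); ``positivity`` the long marker-call table from
    :func:`mifquant.classify.classify_markers`.  Rows are cd8+ cells (and,
    when ``include_non_cd8``, cells negative for both markers, flagged by
    ``is_cd8=False``) with nearest-neutrophil distance, category, and the
    raw granzyme-K mean intensity.
    """
    if touching_max_um >= near_max_um:
        raise ValueError("touching cutoff must be smaller than near cutoff")
    pos = positivity.pivot_table(
        index=["patient_id", "field_id", "cell_id"],
        columns="marker", values="positive", aggfunc="first",
    ).reset_index()
    for m in ("cd8", "cd66b"):
        if m not in pos:
            pos[m] = False
    merged = features.merge(pos, on=["patient_id", "field_id", "cell_id"], how="left")
    merged[["cd8", "cd66b"]] = merged[["cd8", "cd66b"]].fillna(False).astype(bool)

    frames = []
    for (pid, fid), grp in merged.groupby(["patient_id", "field_id"], sort=True):
        neut = grp[grp["cd66b"]]
        if include_non_cd8:
            queries = grp[~grp["cd66b"]]
        else:
            queries = grp[grp["cd8"]]
        if queries.empty:
            continue
        nn = nearest_neutrophil(queries, neut)
        block = queries[["cell_id", "patient_id", "field_id", "cd8"]].merge(
            nn, on="cell_id"
        )
        block["gzmk_mean"] = queries.set_index("cell_id").loc[
            block["cell_id"], gzmk_column
        ].to_numpy()
        frames.append(block)
    if not frames:
        return pd.DataFrame(
            columns=["cell_id", "patient_id", "field_id", "cd8",
                     "nearest_neutrophil_id", "distance_um", "category", "gzmk_mean"]
        )
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={"cd8": "is_cd8"})
    out["category"] = categorize_array(
        out["distance_um"].to_numpy(), touching_max_um, near_max_um
    )
    return out


def normalize_per_patient(proximity: pd.DataFrame) -> pd.DataFrame:
    """Divide each cell's granzyme-K intensity by its patient's near-cell mean.

    Adds ``gzmk_norm``.  Patients without any near-category cell cannot be
    normalized: their rows keep ``gzmk_norm = NaN`` and are flagged
    ``norm_excluded=True`` with a logged warning.  By construction the mean
    of ``gzmk_norm`` over each patient's near cells is exactly 1.
    """
    out = proximity.copy()
    out["gzmk_norm"] = np.nan
    out["norm_excluded"] = False
    for pid, grp in out.groupby("patient_id", sort=True):
        near = grp[grp["category"] == "near"]
        if near.empty:
            logger.warning(
                "patient %s has no 'near' cells; excluded from normalized analysis",
                pid,
            )
            out.loc[grp.index, "norm_excluded"] = True
            continue
        denom = near["gzmk_mean"].mean()
        out.loc[grp.index, "gzmk_norm"] = grp["gzmk_mean"] / denom
    return out


@dataclass(frozen=True)
class GroupComparison:
    """Two-group summary plus unpaired two-tailed t statistic."""

    group1: str
    group2: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    t: float
    p: float
    welch: bool

    def to_dict(self) -> dict:
        return {
            "group1": self.group1, "group2": self.group2,
            "n1": self.n1, "n2": self.n2,
            "mean1": self.mean1, "mean2": self.mean2,
            "sd1": self.sd1, "sd2": self.sd2,
            "t": self.t, "p": self.p, "welch": self.welch,
        }


def ttest_groups(
    values1: np.ndarray, values2: np.ndarray,
    name1: str = "group1", name2: str = "group2",
    welch: bool = False,
) -> GroupComparison:
    """Unpaired two-tailed t test (pooled variance by default, Welch by flag)."""
    a = np.asarray(values1, dtype=float)
    b = np.asarray(values2, dtype=float)
    for name, arr in ((name1, a), (name2, b)):
        if arr.size == 0:
            raise EmptyGroupError(f"group {name!r} is empty")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    return GroupComparison(
        group1=name1, group2=name2,
        n1=int(a.size), n2=int(b.size),
        mean1=float(a.mean()), mean2=float(b.mean()),
        sd1=float(a.std(ddof=1)) if a.size > 1 else 0.0,
        sd2=float(b.std(ddof=1)) if b.size > 1 else 0.0,
        t=float(res.statistic), p=float(res.pvalue), welch=welch,
    )


def touching_vs_near(
    normalized: pd.DataFrame, welch: bool = False
) -> GroupComparison:
    """Pooled touching-vs-near comparison of per-patient-normalized intensities.

    Cells are pooled across patients after normalization; rows without a
    normalized value (patients lacking near cells) are dropped first.
    """
    usable = normalized[~normalized["norm_excluded"] & normalized["gzmk_norm"].notna()]
    touching = usable.loc[usable["category"] == "touching", "gzmk_norm"].to_numpy()
    near = usable.loc[usable["category"] == "near", "gzmk_norm"].to_numpy()
    return ttest_groups(touching, near, "touching", "near", welch=welch)


def contact_comparison_cd8_vs_noncd8(
    proximity: pd.DataFrame,
    max_distance_um: float = TOUCHING_MAX_UM,
    welch: bool = False,
) -> GroupComparison:
    """Granzyme-K in cd8+ vs non-cd8 cells lying close to a neutrophil.

    Both groups are restricted to cells whose nearest neutrophil is below
    ``max_distance_um``; the comparison is on the raw granzyme-K mean
    intensity.  Requires a proximity table built with
    ``include_non_cd8=True`` so that non-cd8 rows exist.
    """
    close = proximity[proximity["distance_um"] < max_distance_um]
    cd8 = close.loc[close["is_cd8"], "gzmk_mean"].to_numpy()
    non = close.loc[~close["is_cd8"], "gzmk_mean"].to_numpy()
    return ttest_groups(cd8, non, "cd8_close", "non_cd8_close", welch=welch)
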