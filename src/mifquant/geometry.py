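"""Measurement-region construction: peri-nuclear bands and cell expansions.

The band ("ring" mode) is the set of background pixels whose center lies
within ``band_width_um`` (Euclidean, in physical µm) of a nucleus; the
"expansion" mode additionally includes the nucleus pixels themselves.
Pixels contested by neighboring nuclei are assigned to the nucleus whose
pixel set is nearest, with exact ties going to the smaller label — a
documented convention, deterministic and independent of label enumeration
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

from .fields import FieldIOError, LabelMask, MultiChannelField

logger = logging.getLogger(__name__)

BAND_MODES = ("ring", "expansion")


@dataclass
class BandParams:
    """Width (physical µm) and mode of the measurement region."""

    band_width_um: float = 1.0
    mode: str = "ring"

    def __post_init__(self) -> None:
        if not self.band_width_um > 0:
            raise ValueError(f"band_width_um must be > 0, got {self.band_width_um}")
        if self.mode not in BAND_MODES:
            raise ValueError(f"mode must be one of {BAND_MODES}, got {self.mode!r}")


def make_band_mask(
    nuclei: LabelMask, params: BandParams, pixel_size_um: float
) -> LabelMask:
    """Build the band (or expansion) label mask around each nucleus.

    Distances are Euclidean distance-transform distances in physical µm
    (axes scaled by the pixel size), measured from each background pixel
    center to the nearest pixel of the candidate nucleus.  A background
    pixel joins the band of the nucleus with the minimum such distance when
    that distance is <= ``band_width_um``; exact ties resolve to the smaller
    label.  The returned mask records each label's region area in µm².

    An empty nucleus mask yields an empty band mask.
    """
    if nuclei.kind != "nucleus":
        raise ValueError(f"expected a nucleus mask, got kind={nuclei.kind!r}")
    if not pixel_size_um > 0:
        raise ValueError("pixel_size_um must be > 0")
    labels = nuclei.labels
    out = np.zeros_like(labels)
    best = np.full(labels.shape, np.inf)

    pad = int(np.ceil(params.band_width_um / pixel_size_um)) + 1
    objects = ndi.find_objects(labels)
    ids = nuclei.ids
    for lab in ids:  # ids sorted ascending -> strict < keeps the smaller label on ties
        sl = objects[int(lab) - 1]
        if sl is None:
            continue
        win = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, labels.shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, labels.shape[1])),
        )
        this = labels[win] == lab
        d = ndi.distance_transform_edt(~this, sampling=pixel_size_um)
        cand = (d > 0) & (d <= params.band_width_um) & (labels[win] == 0)
        out_w, best_w = out[win], best[win]
        upd = cand & (d < best_w)
        out_w[upd] = lab
        best_w[upd] = d[upd]

    if params.mode == "expansion":
        out = np.where(labels > 0, labels, out)

    px_area = pixel_size_um**2
    counts = np.bincount(out.ravel(), minlength=int(labels.max()) + 1)
    areas = {int(lab): float(counts[int(lab)] * px_area) for lab in ids}
    return LabelMask(labels=out, kind=params.mode if params.mode == "expansion" else "band",
                     region_area_um2=areas)


def geometry_table(
    nuclei: LabelMask,
    band: LabelMask,
    pixel_size_um: float,
) -> pd.DataFrame:
    """Per-cell geometry: centroid (µm), nucleus/band areas (µm²), clipped flag.

    Centroids are nucleus centroids at pixel centers (pixel [i, j] center at
    x = j*px, y = i*px).  A cell is ``clipped`` when its nucleus or band
    region touches the image border, where the band may be truncated.
    """
    labels = nuclei.labels
    ids = nuclei.ids
    px = pixel_size_um
    px_area = px * px
    n_max = int(labels.max()) + 1

    nuc_counts = np.bincount(labels.ravel(), minlength=n_max)
    idx_r, idx_c = np.indices(labels.shape)
    sum_r = np.bincount(labels.ravel(), weights=idx_r.ravel(), minlength=n_max)
    sum_c = np.bincount(labels.ravel(), weights=idx_c.ravel(), minlength=n_max)

    border = np.zeros(labels.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    combined = np.where(band.labels > 0, band.labels, labels)
    clipped_ids = set(np.unique(combined[border])) - {0}

    rows = []
    for lab in ids:
        lab = int(lab)
        n = nuc_counts[lab]
        rows.append(
            {
                "cell_id": lab,
                "centroid_x_um": float(sum_c[lab] / n * px),
                "centroid_y_um": float(sum_r[lab] / n * px),
                "nucleus_area_um2": float(n * px_area),
                "band_area_um2": band.region_area_um2.get(lab, 0.0),
                "clipped": lab in clipped_ids,
            }
        )
    cols = ["cell_id", "centroid_x_um", "centroid_y_um",
            "nucleus_area_um2", "band_area_um2", "clipped"]
    return pd.DataFrame(rows, columns=cols)


def segment_nuclei_otsu(field: MultiChannelField, min_area_px: int = 9) -> LabelMask:
    """Reference nucleus segmenter for *synthetic* images only.

    Otsu threshold on the dapi channel + connected components, dropping
    specks below ``min_area_px``.  This is not suitable for real tissue —
    real pipelines should supply an externally produced label mask (e.g.
    from a trained star-convex model).
    """
    dapi = field.channel("dapi")
    if dapi.max() <= 0:
        return LabelMask(labels=np.zeros(dapi.shape, dtype=np.int32), kind="nucleus")
    thr = threshold_otsu(dapi)
    lab = cc_label(dapi > thr)
    counts = np.bincount(lab.ravel())
    keep = np.flatnonzero(counts >= min_area_px)
    keep = keep[keep > 0]
    remap = np.zeros(counts.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1, dtype=np.int32)
    return LabelMask(labels=remap[lab], kind="nucleus")


def check_alignment(field: MultiChannelField, mask: LabelMask) -> None:
    """Raise FieldIOError unless mask and field share a raster."""
    if mask.labels.shape != field.shape:
        raise FieldIOError(
            f"mask shape {mask.labels.shape} does not match field {field.shape}"
        )
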