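"""Per-cell intensity features: mean intensity and raw integrated density.

Both features are computed per channel over exactly the pixels of a cell's
measurement region (band or expansion).  Raw integrated density (RID) is
the plain sum of pixel values over the region, so RID = mean x n_pixels by
construction.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from skimage.filters import gaussian as _gaussian
from skimage.restoration import rolling_ball as _rolling_ball

from .fields import LabelMask, MultiChannelField
from .geometry import BandParams, check_alignment, geometry_table, make_band_mask

logger = logging.getLogger(__name__)


def preprocess_channel(
    img: np.ndarray,
    gaussian_sigma: float = 0.0,
    rolling_ball_radius: float = 0.0,
) -> np.ndarray:
    """Optional denoise / background-subtraction hook; both steps default off.

    Gaussian blur (sigma in pixels) followed by rolling-ball background
    subtraction (radius in pixels), clipped at zero.
    """
    out = np.asarray(img, dtype=np.float64)
    if gaussian_sigma > 0:
        out = _gaussian(out, sigma=gaussian_sigma, preserve_range=True)
    if rolling_ball_radius > 0:
        out = np.clip(out - _rolling_ball(out, radius=rolling_ball_radius), 0.0, None)
    return out


def quantify_cells(
    field: MultiChannelField,
    region_mask: LabelMask,
    expected_labels: Iterable[int] | None = None,
    *,
    gaussian_sigma: float = 0.0,
    rolling_ball_radius: float = 0.0,
) -> pd.DataFrame:
    """Per-cell, per-channel mean intensity and raw integrated density.

    One row per label with a nonzero region; columns ``mean_<channel>`` and
    ``rid_<channel>`` plus ``n_pixels``.  Labels listed in
    ``expected_labels`` but absent from the region mask are omitted with a
    logged warning (their region is empty).
    """
    check_alignment(field, region_mask)
    labels = region_mask.labels
    n_max = int(labels.max()) + 1
    counts = np.bincount(labels.ravel(), minlength=n_max)
    present = np.flatnonzero(counts)
    present = present[present > 0]

    if expected_labels is not None:
        missing = sorted(set(int(x) for x in expected_labels) - set(present.tolist()))
        if missing:
            logger.warning(
                "%d cell(s) omitted: empty measurement region (labels %s)",
                len(missing), missing[:20],
            )

    data: dict[str, np.ndarray] = {
        "cell_id": present.astype(np.int64),
        "n_pixels": counts[present].astype(np.int64),
    }
    flat_labels = labels.ravel()
    for name, chan in field.channels.items():
        img = preprocess_channel(chan, gaussian_sigma, rolling_ball_radius) \
            if (gaussian_sigma > 0 or rolling_ball_radius > 0) else chan
        sums = np.bincount(flat_labels, weights=img.ravel(), minlength=n_max)
        data[f"rid_{name}"] = sums[present]
        data[f"mean_{name}"] = sums[present] / counts[present]
    df = pd.DataFrame(data)
    df["patient_id"] = field.patient_id
    df["field_id"] = field.field_id
    return df


def build_feature_table(
    field: MultiChannelField,
    nuclei: LabelMask,
    band_params: BandParams | None = None,
    **preprocess_kwargs,
) -> tuple[pd.DataFrame, LabelMask]:
    """Geometry + intensity features over the band region, merged per cell.

    Returns the per-cell feature table (geometry columns, then one
    ``mean_``/``rid_`` pair per channel) and the band mask used, so the
    caller can reuse it (e.g. for area-based classification).
    """
    band_params = band_params or BandParams()
    check_alignment(field, nuclei)
    band = make_band_mask(nuclei, band_params, field.pixel_size_um)
    geom = geometry_table(nuclei, band, field.pixel_size_um)
    feats = quantify_cells(
        field, band, expected_labels=geom["cell_id"], **preprocess_kwargs
    )
    merged = geom.merge(feats.drop(columns=["patient_id", "field_id"]),
                        on="cell_id", how="inner")
    merged.insert(1, "patient_id", field.patient_id)
    merged.insert(2, "field_id", field.field_id)
    return merged, band
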