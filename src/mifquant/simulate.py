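"""Synthetic multi-channel tissue fields with known ground truth.

Generates fields of disk-shaped nuclei of three classes (cd8, neutrophil,
other).  Membrane marker signal is rendered on the analytic annulus of
width ``membrane_width_um`` around each nucleus: green for cd8 cells, red
for neutrophils.  The far-red channel carries a granzyme-K-like emission on
cd8 annuli whose magnitude is multiplied by ``gzmk_contact_fold`` for cd8
cells whose true nearest neutrophil lies within ``contact_radius_um``
(centroid-to-centroid).  Tissue autofluorescence is added over every cell
in green/red/farred, erythrocyte artifact disks bleed into configurable
channels without appearing in the label mask, and i.i.d. Gaussian noise
(clipped at zero) is applied last.

All randomness flows from a single integer seed; outputs are byte-identical
across runs for a fixed seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .fields import LabelMask, MultiChannelField, write_field

CELL_TYPES = ("cd8", "neutrophil", "other")


class PlacementError(RuntimeError):
    """Raised when nuclei cannot be placed without overlap in the given field."""


def _default_marker_intensity() -> dict[str, dict[str, tuple[float, float]]]:
    # per class -> channel -> (mean, sd) emission; dapi on the nucleus disk,
    # everything else on the membrane annulus
    return {
        "cd8": {"dapi": (200.0, 0.0), "green": (150.0, 0.0)},
        "neutrophil": {"dapi": (200.0, 0.0), "red": (150.0, 0.0)},
        "other": {"dapi": (200.0, 0.0)},
    }


def _default_rbc_intensity() -> dict[str, float]:
    return {"green": 120.0, "red": 120.0, "farred": 120.0}


@dataclass
class TissueSpec:
    """Generative parameters for one synthetic field.

    ``fraction_cd8 + fraction_neutrophil`` must not exceed 1; the remainder
    is the "other" class.  ``gzmk_contact_fold`` multiplies the far-red
    emission of cd8 cells in contact with a neutrophil (true centroid
    distance <= ``contact_radius_um``).
    """

    field_size_um: tuple[float, float] = (200.0, 200.0)  # (height, width)
    pixel_size_um: float = 0.1625
    n_cells: int = 100
    fraction_cd8: float = 0.3
    fraction_neutrophil: float = 0.3
    nucleus_radius_um: tuple[float, float] = (3.0, 0.3)  # (mean, sd)
    min_clearance_um: float = 0.0  # extra edge-to-edge spacing beyond non-overlap
    membrane_width_um: float = 1.0
    contact_radius_um: float = 10.0
    gzmk_base: float = 100.0
    gzmk_contact_fold: float = 1.0
    marker_intensity: dict = dc_field(default_factory=_default_marker_intensity)
    autofluorescence_level: float = 0.0
    n_rbc: int = 0
    rbc_intensity: dict = dc_field(default_factory=_default_rbc_intensity)
    rbc_radius_um: float = 3.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        h, w = self.field_size_um
        if not (h > 0 and w > 0):
            raise ValueError("field_size_um entries must be positive")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        if not (0 <= self.fraction_cd8 <= 1 and 0 <= self.fraction_neutrophil <= 1):
            raise ValueError("class fractions must lie in [0, 1]")
        if self.fraction_cd8 + self.fraction_neutrophil > 1 + 1e-12:
            raise ValueError("fraction_cd8 + fraction_neutrophil must be <= 1")
        mean_r, sd_r = self.nucleus_radius_um
        if mean_r <= 0 or sd_r < 0:
            raise ValueError("nucleus radius mean must be > 0 and sd >= 0")
        if self.min_clearance_um < 0:
            raise ValueError("min_clearance_um must be >= 0")
        for val, name in [
            (self.membrane_width_um, "membrane_width_um"),
            (self.contact_radius_um, "contact_radius_um"),
            (self.rbc_radius_um, "rbc_radius_um"),
        ]:
            if val <= 0:
                raise ValueError(f"{name} must be positive")
        for val, name in [
            (self.gzmk_base, "gzmk_base"),
            (self.gzmk_contact_fold, "gzmk_contact_fold"),
            (self.autofluorescence_level, "autofluorescence_level"),
            (self.noise_sd, "noise_sd"),
        ]:
            if val < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_rbc < 0:
            raise ValueError("n_rbc must be >= 0")
        for cls, chans in self.marker_intensity.items():
            if cls not in CELL_TYPES:
                raise ValueError(f"unknown cell class {cls!r} in marker_intensity")
            for ch, (m, s) in chans.items():
                if m < 0 or s < 0:
                    raise ValueError(f"marker_intensity[{cls}][{ch}] must be >= 0")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TissueSpec":
        d = dict(d)
        if "field_size_um" in d:
            d["field_size_um"] = tuple(d["field_size_um"])
        if "nucleus_radius_um" in d:
            d["nucleus_radius_um"] = tuple(d["nucleus_radius_um"])
        if "marker_intensity" in d:
            d["marker_intensity"] = {
                cls: {ch: tuple(v) for ch, v in chans.items()}
                for cls, chans in d["marker_intensity"].items()
            }
        spec = cls(**d)
        spec.validate()
        return spec


@dataclass(frozen=True)
class Placement:
    """One nucleus: centroid in µm (x, y), radius in µm, cell class."""

    centroid_um: tuple[float, float]
    radius_um: float
    cell_type: str


def place_nuclei(
    spec: TissueSpec,
    seed: int | None = None,
    max_attempts_per_cell: int = 2000,
) -> list[Placement]:
    """Place ``spec.n_cells`` non-overlapping disks fully inside the field.

    Disks are placed by rejection sampling; center distances strictly exceed
    the sum of radii.  Cell classes are drawn i.i.d. with the spec's class
    fractions.  Deterministic for a fixed seed.

    Raises
    ------
    PlacementError
        If a disk cannot be placed after ``max_attempts_per_cell`` draws —
        the field is too crowded for ``n_cells``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    h, w = spec.field_size_um
    mean_r, sd_r = spec.nucleus_radius_um
    p_other = 1.0 - spec.fraction_cd8 - spec.fraction_neutrophil
    types = rng.choice(
        CELL_TYPES, size=spec.n_cells,
        p=[spec.fraction_cd8, spec.fraction_neutrophil, max(p_other, 0.0)],
    )

    centers = np.empty((0, 2))
    radii = np.empty(0)
    for i in range(spec.n_cells):
        for _ in range(max_attempts_per_cell):
            r = float(rng.normal(mean_r, sd_r)) if sd_r > 0 else mean_r
            r = max(r, 0.25 * mean_r)  # guard against nonphysical tiny/negative draws
            if 2 * r >= min(h, w):
                continue
            x = rng.uniform(r, w - r)
            y = rng.uniform(r, h - r)
            if centers.size:
                d = np.hypot(centers[:, 0] - x, centers[:, 1] - y)
                if np.any(d <= radii + r + spec.min_clearance_um):
                    continue
            centers = np.vstack([centers, [x, y]])
            radii = np.append(radii, r)
            break
        else:
            raise PlacementError(
                f"could not place nucleus {i + 1}/{spec.n_cells} after "
                f"{max_attempts_per_cell} attempts; field "
                f"{h}x{w} um is too crowded"
            )
    return [
        Placement(centroid_um=(float(cx), float(cy)), radius_um=float(r), cell_type=str(t))
        for (cx, cy), r, t in zip(centers, radii, types)
    ]


def nearest_neutrophil_distances(placement: list[Placement]) -> np.ndarray:
    """Brute-force (all-pairs) nearest-neutrophil centroid distance per cell.

    For neutrophils the nearest *other* neutrophil is used.  Cells with no
    eligible neutrophil get ``nan``.
    """
    n = len(placement)
    out = np.full(n, np.nan)
    neut_idx = [i for i, p in enumerate(placement) if p.cell_type == "neutrophil"]
    if not neut_idx:
        return out
    pts = np.array([p.centroid_um for p in placement])
    npts = pts[neut_idx]
    d = cdist(pts, npts)
    for i in range(n):
        row = d[i].copy()
        if placement[i].cell_type == "neutrophil":
            row[np.array(neut_idx) == i] = np.inf
        m = row.min()
        out[i] = m if np.isfinite(m) else np.nan
    return out


def _disk_window(
    shape: tuple[int, int], cx: float, cy: float, r_um: float, px: float
) -> tuple[tuple[slice, slice], np.ndarray]:
    """Bounding window and per-pixel centroid distances (µm) for a disk."""
    r0 = max(0, int(np.floor((cy - r_um) / px)))
    r1 = min(shape[0] - 1, int(np.ceil((cy + r_um) / px)))
    c0 = max(0, int(np.floor((cx - r_um) / px)))
    c1 = min(shape[1] - 1, int(np.ceil((cx + r_um) / px)))
    yy = np.arange(r0, r1 + 1) * px
    xx = np.arange(c0, c1 + 1) * px
    d = np.hypot(yy[:, None] - cy, xx[None, :] - cx)
    return (slice(r0, r1 + 1), slice(c0, c1 + 1)), d


def render_field(
    spec: TissueSpec,
    placement: list[Placement] | None = None,
    *,
    seed: int | None = None,
    patient_id: str = "P0",
    field_id: str = "F0",
) -> tuple[MultiChannelField, LabelMask, pd.DataFrame]:
    """Rasterize a placement into channels, a label mask, and ground truth.

    Pixel centers sit at integer multiples of the pixel size (pixel [i, j]
    is at (x, y) = (j*px, i*px)); a pixel belongs to a disk iff its center
    is within the disk radius of the centroid.

    Returns the field, the 16-bit-safe nucleus label mask (cell_id = row
    order in the placement, starting at 1), and the ground-truth table with
    columns cell_id, cell_type, centroid_x_um, centroid_y_um,
    nucleus_radius_um, true_gzmk_emission, true_nearest_neutrophil_distance_um,
    is_contact.
    """
    spec.validate()
    if placement is None:
        placement = place_nuclei(spec, seed=seed)
    rng = np.random.default_rng((spec.seed if seed is None else seed) + 1)
    px = spec.pixel_size_um
    h_um, w_um = spec.field_size_um
    shape = (int(round(h_um / px)), int(round(w_um / px)))
    channels = {c: np.zeros(shape) for c in ("dapi", "green", "red", "farred")}
    labels = np.zeros(shape, dtype=np.int32)

    dists = nearest_neutrophil_distances(placement)

    # Draw all per-cell emissions up front in a fixed order for determinism.
    emissions: list[dict[str, float]] = []
    for p in placement:
        em = {}
        for ch, (mean, sd) in spec.marker_intensity.get(p.cell_type, {}).items():
            val = float(rng.normal(mean, sd)) if sd > 0 else mean
            em[ch] = max(val, 0.0)
        emissions.append(em)

    rows = []
    for i, p in enumerate(placement):
        cid = i + 1
        cx, cy = p.centroid_um
        r = p.radius_um
        sl, d = _disk_window(shape, cx, cy, r + spec.membrane_width_um, px)
        nucleus = d <= r
        annulus = (d > r) & (d <= r + spec.membrane_width_um)
        whole = d <= r + spec.membrane_width_um
        labels[sl][nucleus] = cid

        em = emissions[i]
        if "dapi" in em:
            channels["dapi"][sl][nucleus] += em["dapi"]
        for ch, val in em.items():
            if ch != "dapi":
                channels[ch][sl][annulus] += val
        if spec.autofluorescence_level > 0:
            for ch in ("green", "red", "farred"):
                channels[ch][sl][whole] += spec.autofluorescence_level

        is_contact = bool(
            p.cell_type == "cd8"
            and np.isfinite(dists[i])
            and dists[i] <= spec.contact_radius_um
        )
        gzmk = 0.0
        if p.cell_type == "cd8":
            gzmk = spec.gzmk_base * (spec.gzmk_contact_fold if is_contact else 1.0)
            channels["farred"][sl][annulus] += gzmk
        rows.append(
            {
                "cell_id": cid,
                "cell_type": p.cell_type,
                "centroid_x_um": cx,
                "centroid_y_um": cy,
                "nucleus_radius_um": r,
                "true_gzmk_emission": gzmk,
                "true_nearest_neutrophil_distance_um": dists[i],
                "is_contact": is_contact,
            }
        )

    for _ in range(spec.n_rbc):
        cx = rng.uniform(0, w_um)
        cy = rng.uniform(0, h_um)
        sl, d = _disk_window(shape, cx, cy, spec.rbc_radius_um, px)
        disk = d <= spec.rbc_radius_um
        for ch, val in spec.rbc_intensity.items():
            channels[ch][sl][disk] += val

    if spec.noise_sd > 0:
        for ch in channels:
            channels[ch] += rng.normal(0.0, spec.noise_sd, size=shape)
            np.clip(channels[ch], 0.0, None, out=channels[ch])

    field = MultiChannelField(
        channels=channels,
        pixel_size_um=px,
        patient_id=patient_id,
        field_id=field_id,
    )
    truth = pd.DataFrame(rows)
    if truth.empty:
        truth = pd.DataFrame(
            columns=[
                "cell_id", "cell_type", "centroid_x_um", "centroid_y_um",
                "nucleus_radius_um", "true_gzmk_emission",
                "true_nearest_neutrophil_distance_um", "is_contact",
            ]
        )
    return field, LabelMask(labels=labels, kind="nucleus"), truth


def simulate_field(
    spec: TissueSpec,
    *,
    seed: int | None = None,
    patient_id: str = "P0",
    field_id: str = "F0",
) -> tuple[MultiChannelField, LabelMask, pd.DataFrame]:
    """Place nuclei and render in one call (the common entry point)."""
    placement = place_nuclei(spec, seed=seed)
    return render_field(
        spec, placement, seed=seed, patient_id=patient_id, field_id=field_id
    )


def write_simulation(
    outdir: str | Path,
    field: MultiChannelField,
    mask: LabelMask,
    truth: pd.DataFrame,
    spec: TissueSpec | None = None,
) -> dict[str, Path]:
    """Write field TIFF (+ sidecar), label TIFF, ground-truth CSV and spec JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = f"{field.patient_id}_{field.field_id}" if field.field_id else "field"
    paths = {
        "image": outdir / f"{stem}.tif",
        "mask": outdir / f"{stem}_labels.tif",
        "truth": outdir / f"{stem}_ground_truth.csv",
    }
    write_field(field, paths["image"], mask=mask, mask_path=paths["mask"])
    truth.to_csv(paths["truth"], index=False)
    if spec is not None:
        paths["spec"] = outdir / f"{stem}_spec.json"
        paths["spec"].write_text(json.dumps(spec.to_dict(), indent=2))
    return paths


def sample_cell_table(
    spec: TissueSpec,
    rng: np.random.Generator,
    *,
    patient_id: str = "P0",
    field_id: str = "F0",
    mean_noise_sd: float | None = None,
) -> pd.DataFrame:
    """Sample a per-cell feature table directly from the generative model.

    Skips rasterization: positions come from :func:`place_nuclei`, the
    measured per-cell granzyme-K mean intensity is the true emission plus
    autofluorescence plus Gaussian error of sd ``mean_noise_sd`` (default
    ``spec.noise_sd``, i.e. treating the pixel noise sd as the sd of the
    band mean), clipped at zero.  Intended for statistical calibration
    experiments where rendering thousands of fields would be wasteful.
    """
    seed = int(rng.integers(0, 2**31 - 1))
    placement = place_nuclei(spec, seed=seed)
    dists = nearest_neutrophil_distances(placement)
    sd = spec.noise_sd if mean_noise_sd is None else mean_noise_sd
    rows = []
    for i, p in enumerate(placement):
        is_contact = bool(
            p.cell_type == "cd8"
            and np.isfinite(dists[i])
            and dists[i] <= spec.contact_radius_um
        )
        gzmk = 0.0
        if p.cell_type == "cd8":
            gzmk = spec.gzmk_base * (spec.gzmk_contact_fold if is_contact else 1.0)
        meas = gzmk + spec.autofluorescence_level
        if sd > 0:
            meas += float(rng.normal(0.0, sd))
        rows.append(
            {
                "cell_id": i + 1,
                "patient_id": patient_id,
                "field_id": field_id,
                "cell_type": p.cell_type,
                "centroid_x_um": p.centroid_um[0],
                "centroid_y_um": p.centroid_um[1],
                "gzmk_mean": max(meas, 0.0),
                "true_nearest_neutrophil_distance_um": dists[i],
                "is_contact": is_contact,
            }
        )
    return pd.DataFrame(rows)
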