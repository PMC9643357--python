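"""Containers for multi-channel fields and label masks, with TIFF round-trip I/O.

A field is a set of named 2D intensity rasters sharing one grid plus the
physical pixel size; a label mask is an integer raster aligned to it
(0 = background).  Images are stored as multi-page TIFF (one page per
channel) with a JSON sidecar recording channel order, pixel size and
field/patient identifiers, so a written field round-trips losslessly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

CHANNEL_ORDER = ("dapi", "green", "red", "farred")

MASK_KINDS = frozenset({"nucleus", "band", "expansion"})


class FieldIOError(ValueError):
    """Raised on malformed field/mask input (missing channel, shape mismatch...)."""


@dataclass
class MultiChannelField:
    """Named 2D intensity channels over one pixel grid.

    Parameters
    ----------
    channels:
        Mapping of channel name to a 2D non-negative float raster. All
        channels must share the same shape.
    pixel_size_um:
        Physical edge length of one pixel in micrometres (> 0).
    patient_id, field_id:
        Free-form identifiers carried through every per-cell table.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    patient_id: str = ""
    field_id: str = ""

    def __post_init__(self) -> None:
        if not self.channels:
            raise FieldIOError("field must contain at least one channel")
        shapes = {name: np.asarray(arr).shape for name, arr in self.channels.items()}
        first = next(iter(shapes.values()))
        if len(first) != 2:
            raise FieldIOError(f"channels must be 2D, got shape {first}")
        for name, shp in shapes.items():
            if shp != first:
                raise FieldIOError(
                    f"channel {name!r} has shape {shp}, expected {first}"
                )
        if not (self.pixel_size_um > 0):
            raise FieldIOError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.channels = {k: np.asarray(v, dtype=np.float64) for k, v in self.channels.items()}

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.channels[name]
        except KeyError:
            raise FieldIOError(
                f"channel {name!r} not present (have {sorted(self.channels)})"
            ) from None


@dataclass
class LabelMask:
    """Integer-labeled raster aligned to a field; 0 is background.

    ``kind`` records what the labeled region represents: the segmented
    nucleus, the peri-nuclear band (ring) or the whole-cell expansion
    (nucleus plus ring).  ``region_area_um2`` optionally records the
    physical area covered by each label.
    """

    labels: np.ndarray
    kind: str = "nucleus"
    region_area_um2: dict[int, float] = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FieldIOError(f"label mask must be 2D, got ndim={self.labels.ndim}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise FieldIOError(f"label mask must be integer, got {self.labels.dtype}")
        if self.labels.min() < 0:
            raise FieldIOError("label mask contains negative labels")
        if self.kind not in MASK_KINDS:
            raise FieldIOError(f"unknown mask kind {self.kind!r}")

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]


def write_field(
    field: MultiChannelField,
    image_path: str | Path,
    mask: LabelMask | None = None,
    mask_path: str | Path | None = None,
) -> None:
    """Write a field as multi-page TIFF + JSON sidecar, and optionally its mask.

    Page order follows :data:`CHANNEL_ORDER` for known channels, then any
    remaining channels alphabetically; the order actually written is recorded
    in the sidecar ``<image_path>.json``.
    """
    image_path = Path(image_path)
    known = [c for c in CHANNEL_ORDER if c in field.channels]
    extra = sorted(set(field.channels) - set(known))
    order = known + extra
    stack = np.stack([field.channels[c] for c in order])
    tifffile.imwrite(image_path, stack, photometric="minisblack")
    sidecar = {
        "channels": order,
        "pixel_size_um": field.pixel_size_um,
        "patient_id": field.patient_id,
        "field_id": field.field_id,
    }
    image_path.with_suffix(image_path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )
    if mask is not None:
        if mask_path is None:
            raise ValueError("mask_path required when mask is given")
        if mask.labels.max() > np.iinfo(np.uint16).max:
            raise FieldIOError("label mask exceeds 16-bit range")
        tifffile.imwrite(Path(mask_path), mask.labels.astype(np.uint16))


def read_field(
    image_path: str | Path,
    mask_path: str | Path | None = None,
    *,
    channel_names: list[str] | None = None,
    pixel_size_um: float | None = None,
    patient_id: str | None = None,
    field_id: str | None = None,
    mask_kind: str = "nucleus",
) -> tuple[MultiChannelField, LabelMask | None]:
    """Read a multi-page TIFF field (and optional label mask).

    Metadata defaults come from the JSON sidecar written by
    :func:`write_field`; explicit keyword arguments override it.  Raises
    :class:`FieldIOError` on missing channels, declared/actual channel-count
    mismatch, nonpositive pixel size, or mask/field dimension mismatch.
    """
    image_path = Path(image_path)
    stack = tifffile.imread(image_path)
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise FieldIOError(f"expected a stack of 2D pages, got ndim={stack.ndim}")

    sidecar_path = image_path.with_suffix(image_path.suffix + ".json")
    meta: Mapping = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())

    names = channel_names if channel_names is not None else meta.get("channels")
    if names is None:
        raise FieldIOError("channel names not declared and no sidecar found")
    if len(names) != stack.shape[0]:
        raise FieldIOError(
            f"declared {len(names)} channels but image has {stack.shape[0]} pages"
        )
    px = pixel_size_um if pixel_size_um is not None else meta.get("pixel_size_um")
    if px is None:
        raise FieldIOError("pixel_size_um not declared and no sidecar found")

    fld = MultiChannelField(
        channels={n: stack[i] for i, n in enumerate(names)},
        pixel_size_um=float(px),
        patient_id=patient_id if patient_id is not None else meta.get("patient_id", ""),
        field_id=field_id if field_id is not None else meta.get("field_id", ""),
    )
    mask = None
    if mask_path is not None:
        raw = tifffile.imread(Path(mask_path))
        if raw.ndim != 2:
            raise FieldIOError(f"label mask must be 2D, got ndim={raw.ndim}")
        if raw.shape != fld.shape:
            raise FieldIOError(
                f"mask shape {raw.shape} does not match field shape {fld.shape}"
            )
        mask = LabelMask(labels=raw.astype(np.int64), kind=mask_kind)
    return fld, mask
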