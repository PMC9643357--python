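"""End-to-end pipeline: simulate/ingest -> band -> quantify -> classify ->
proximity -> normalized contact comparison, driven by one YAML config and
one seed.

Every run writes per-cell features, positivity calls, the proximity table,
a summary JSON and a manifest (config hash + seed + versions); rerunning
with the same config and seed reproduces identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import ClassifierConfig, calibrate_threshold, classify_markers
from .fields import read_field
from .geometry import BandParams
from .proximity import (
    EmptyGroupError,
    build_proximity_table,
    normalize_per_patient,
    touching_vs_near,
)
from .quantify import build_feature_table
from .simulate import TissueSpec, simulate_field

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and context."""


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class FieldInput:
    image: Path
    mask: Path
    patient_id: str
    field_id: str
    pixel_size_um: float | None = None


@dataclass
class PipelineConfig:
    """Validated run configuration.

    Exactly one of ``simulate`` (a :class:`TissueSpec` plus cohort layout)
    or ``inputs`` (external TIFF fields + label masks) drives the run.
    """

    output_dir: Path
    seed: int = 0
    simulate: TissueSpec | None = None
    n_fields: int = 1
    n_patients: int = 1
    inputs: list[FieldInput] = dc_field(default_factory=list)
    band: BandParams = dc_field(default_factory=BandParams)
    classify: ClassifierConfig = dc_field(default_factory=ClassifierConfig)
    touching_max_um: float = 10.0
    near_max_um: float = 20.0
    welch: bool = False
    log_level: str = "INFO"
    raw: dict = dc_field(default_factory=dict)

    def validate(self) -> None:
        if self.touching_max_um <= 0 or self.near_max_um <= 0:
            raise ConfigError("distance cutoffs must be positive")
        if self.touching_max_um >= self.near_max_um:
            raise ConfigError(
                f"touching cutoff ({self.touching_max_um}) must be smaller than "
                f"near cutoff ({self.near_max_um})"
            )
        if (self.simulate is None) == (not self.inputs):
            # exactly one source required
            if self.simulate is None:
                raise ConfigError("config must define either 'simulate' or 'inputs'")
            raise ConfigError("config cannot define both 'simulate' and 'inputs'")
        if self.simulate is not None:
            self.simulate.validate()
            if self.n_fields < 1 or self.n_patients < 1:
                raise ConfigError("n_fields and n_patients must be >= 1")
        for inp in self.inputs:
            for p in (inp.image, inp.mask):
                if not Path(p).exists():
                    raise ConfigError(f"input file does not exist: {p}")


def load_config(path: str | Path, overrides: dict | None = None) -> PipelineConfig:
    """Parse a YAML pipeline config; ``overrides`` (CLI flags) win over the file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    return config_from_dict(raw)


def config_from_dict(raw: dict) -> PipelineConfig:
    sim_cfg = raw.get("simulate")
    sim = None
    n_fields = 1
    n_patients = 1
    if sim_cfg is not None:
        sim_cfg = dict(sim_cfg)
        n_fields = int(sim_cfg.pop("n_fields", 1))
        n_patients = int(sim_cfg.pop("n_patients", 1))
        sim = TissueSpec.from_dict(sim_cfg)
    inputs = [
        FieldInput(
            image=Path(i["image"]), mask=Path(i["mask"]),
            patient_id=str(i.get("patient_id", "P0")),
            field_id=str(i.get("field_id", f"F{k}")),
            pixel_size_um=i.get("pixel_size_um"),
        )
        for k, i in enumerate(raw.get("inputs", []))
    ]
    band_cfg = raw.get("band", {})
    cls_cfg = dict(raw.get("classify", {}))
    cls_cfg.setdefault("pixel_classifier_thresholds", {})
    prox = raw.get("proximity", {})
    cfg = PipelineConfig(
        output_dir=Path(raw.get("output_dir", "mifquant_out")),
        seed=int(raw.get("seed", 0)),
        simulate=sim,
        n_fields=n_fields,
        n_patients=n_patients,
        inputs=inputs,
        band=BandParams(**band_cfg),
        classify=ClassifierConfig(**cls_cfg),
        touching_max_um=float(prox.get("touching_max_um", 10.0)),
        near_max_um=float(prox.get("near_max_um", 20.0)),
        welch=bool(prox.get("welch", False)),
        log_level=str(raw.get("log_level", "INFO")),
        raw=raw,
    )
    cfg.validate()
    return cfg


def _config_hash(cfg: PipelineConfig) -> str:
    canon = json.dumps(cfg.raw, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()


def _gather_fields(cfg: PipelineConfig):
    """Yield (field, nucleus mask, ground truth or None) per configured field."""
    if cfg.simulate is not None:
        k = 0
        for p in range(cfg.n_patients):
            for f in range(cfg.n_fields):
                yield simulate_field(
                    cfg.simulate,
                    seed=cfg.seed + 1000 * k,
                    patient_id=f"P{p}",
                    field_id=f"F{f}",
                )
                k += 1
    else:
        for inp in cfg.inputs:
            field, mask = read_field(
                inp.image, inp.mask,
                pixel_size_um=inp.pixel_size_um,
                patient_id=inp.patient_id, field_id=inp.field_id,
            )
            if mask is None:
                raise ConfigError(f"no mask for input field {inp.field_id}")
            yield field, mask, None


def calibrate_from_truth(
    features: pd.DataFrame,
    truth: pd.DataFrame,
    cfg: ClassifierConfig,
) -> ClassifierConfig:
    """Fill unset RID thresholds from ground-truth autofluorescence-only cells.

    Negative controls are the simulator's 'other' cells (they carry only
    autofluorescence in green/red/farred), pooled per patient across fields;
    the threshold applied to every patient is the maximum per-patient
    quantile so a single config serves the cohort.
    """
    merged = features.merge(
        truth[["patient_id", "field_id", "cell_id", "cell_type"]],
        on=["patient_id", "field_id", "cell_id"],
    )
    negatives = merged[merged["cell_type"] == "other"]
    if negatives.empty:
        raise ConfigError(
            "no autofluorescence-only cells available to calibrate thresholds"
        )
    out = ClassifierConfig(**{**cfg.__dict__})
    for attr, col in (("cd8_rid_threshold", "rid_green"),
                      ("cd66b_rid_threshold", "rid_red")):
        if getattr(out, attr) is None:
            per_patient = [
                calibrate_threshold(
                    grp[col], cfg.autofluor_quantile, cfg.min_negative_cells
                )
                for _, grp in negatives.groupby("patient_id")
            ]
            setattr(out, attr, max(per_patient))
    return out


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle to ``cfg.output_dir``.

    Outputs: features.csv, positivity.csv, proximity.csv, ground_truth.csv
    (simulated runs), summary.json, manifest.json.  Returns the summary
    dict.  Any stage error is re-raised as :class:`PipelineError` naming
    the stage.
    """
    cfg.validate()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    feature_frames, truth_frames = [], []
    stage = "ingest/simulate"
    try:
        for field, mask, truth in _gather_fields(cfg):
            stage = f"quantify ({field.patient_id}/{field.field_id})"
            feats, _band = build_feature_table(field, mask, cfg.band)
            feature_frames.append(feats)
            if truth is not None:
                t = truth.copy()
                t.insert(0, "patient_id", field.patient_id)
                t.insert(1, "field_id", field.field_id)
                truth_frames.append(t)

        stage = "pool"
        features = pd.concat(feature_frames, ignore_index=True)
        truth_all = (
            pd.concat(truth_frames, ignore_index=True) if truth_frames else None
        )

        stage = "classify"
        cls_cfg = cfg.classify
        if cls_cfg.cd8_rid_threshold is None or cls_cfg.cd66b_rid_threshold is None:
            if truth_all is None:
                raise ConfigError(
                    "RID thresholds must be supplied for external inputs"
                )
            cls_cfg = calibrate_from_truth(features, truth_all, cls_cfg)
        positivity = classify_markers(features, cls_cfg)

        stage = "proximity"
        prox = build_proximity_table(
            features, positivity,
            touching_max_um=cfg.touching_max_um, near_max_um=cfg.near_max_um,
        )
        normed = normalize_per_patient(prox)

        stage = "touching_vs_near"
        try:
            comparison = touching_vs_near(normed, welch=cfg.welch).to_dict()
        except EmptyGroupError as exc:
            logger.warning("touching-vs-near comparison skipped: %s", exc)
            comparison = {"skipped": str(exc)}
    except (ConfigError, PipelineError):
        raise
    except Exception as exc:  # noqa: BLE001 - annotate with stage context
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    features.to_csv(outdir / "features.csv", index=False)
    positivity.to_csv(outdir / "positivity.csv", index=False)
    normed.to_csv(outdir / "proximity.csv", index=False)
    if truth_all is not None:
        truth_all.to_csv(outdir / "ground_truth.csv", index=False)

    counts = normed["category"].value_counts().to_dict() if len(normed) else {}
    summary = {
        "n_cells": int(len(features)),
        "n_cd8_rows": int(len(normed)),
        "category_counts": {k: int(v) for k, v in counts.items()},
        "cd8_rid_threshold": cls_cfg.cd8_rid_threshold,
        "cd66b_rid_threshold": cls_cfg.cd66b_rid_threshold,
        "touching_vs_near": comparison,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2))

    manifest = {
        "config_sha256": _config_hash(cfg),
        "seed": cfg.seed,
        "mifquant_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "outputs": sorted(
            p.name for p in outdir.iterdir() if p.suffix in {".csv", ".json"}
        ),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return summary
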