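"""Configuration-driven orchestration of the full analysis.

A validated `RunConfig` (YAML/JSON) names the input source — an EDF
directory, a columnar-text cohort directory, or a synthetic preset — and the
analysis settings; `run_pipeline` builds the model, fits it, and writes a
machine-readable report plus CSV tables and BrainNet exports.  Runs are
deterministic given the config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import __version__
from .io import DEFAULT_CHANNELS, read_columnar, read_edf
from .model import DEFAULT_REPORT_BANDS, BrainConnectivityModel
from .preprocess import FilterSpec
from .synth import CohortSpec, generate_cohort, load_cohort, paper_contrast_spec
from .wpd import BandDefinition, DEFAULT_BANDS, WaveletSpec, band_leaf_map

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("osaconnect")

DEFAULT_BAND_EDGES = {b.name: [b.f_low, b.f_high] for b in DEFAULT_BANDS}


class FilterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    notch: float = 50.0
    notch_q: float = 30.0
    band: tuple[float, float] = (0.5, 35.0)
    butter_order: int = 4
    zero_phase: bool = True

    def to_spec(self) -> FilterSpec:
        return FilterSpec(
            notch_freq=self.notch,
            notch_q=self.notch_q,
            band_low=self.band[0],
            band_high=self.band[1],
            butter_order=self.butter_order,
            zero_phase=self.zero_phase,
        )


class WaveletConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    family: str = "db4"
    level: int = 5
    boundary: str = "periodization"

    def to_spec(self) -> WaveletSpec:
        return WaveletSpec(
            family=self.family, level=self.level, boundary_mode=self.boundary
        )


class SynthConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    preset: Literal["paper_contrast"] = "paper_contrast"
    n_osa: int = 10
    n_healthy: int = 10
    duration_s: float = 300.0


class RunConfig(BaseModel):
    """Validated run configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    input_kind: Literal["edf_dir", "columnar_dir", "synth"] = "synth"
    input_dir: Optional[str] = None
    synth: SynthConfig = Field(default_factory=SynthConfig)
    channels: list[str] = Field(default_factory=lambda: list(DEFAULT_CHANNELS))
    filter: FilterConfig = Field(default_factory=FilterConfig)
    wavelet: WaveletConfig = Field(default_factory=WaveletConfig)
    bands: dict[str, tuple[float, float]] = Field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_BAND_EDGES.items()}
    )
    report_bands: list[str] = Field(default_factory=lambda: list(DEFAULT_REPORT_BANDS))
    epoch_seconds: float = 30.0
    edge_threshold: float = 0.0
    fisher_z: bool = False
    group_map: dict[str, str] = Field(default_factory=dict)
    output_dir: str = "osaconnect_out"
    seed: int = 0

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if self.input_kind in ("edf_dir", "columnar_dir") and not self.input_dir:
            raise ValueError(f"input_kind={self.input_kind} requires input_dir")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")
        if self.edge_threshold < 0:
            raise ValueError("edge_threshold must be >= 0")
        band_defs = self.band_definitions()
        # overlapping bands (and malformed edges) rejected before any I/O
        band_leaf_map(200.0, self.wavelet.level, band_defs)
        names = {b.name for b in band_defs}
        for rb in self.report_bands:
            if rb not in names:
                raise ValueError(f"report band {rb!r} not among defined bands")
        for g in self.group_map.values():
            if g not in ("OSA", "HEALTHY"):
                raise ValueError(f"group_map values must be OSA/HEALTHY, got {g!r}")
        return self

    def band_definitions(self) -> tuple[BandDefinition, ...]:
        return tuple(
            BandDefinition(name, lo, hi) for name, (lo, hi) in self.bands.items()
        )

    def analysis_hash(self) -> str:
        """Hash of the settings that determine per-subject computations."""
        payload = json.dumps(
            {
                "channels": self.channels,
                "filter": self.filter.model_dump(),
                "wavelet": self.wavelet.model_dump(),
                "bands": {k: list(v) for k, v in self.bands.items()},
                "epoch_seconds": self.epoch_seconds,
                "fisher_z": self.fisher_z,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return RunConfig.model_validate(raw or {})


def _load_recordings(cfg: RunConfig):
    if cfg.input_kind == "synth":
        spec = paper_contrast_spec(
            n_osa=cfg.synth.n_osa,
            n_healthy=cfg.synth.n_healthy,
            duration_s=cfg.synth.duration_s,
            seed=cfg.seed,
        )
        subjects, manifest = generate_cohort(spec)
        return [s.recording for s in subjects], manifest
    in_dir = Path(cfg.input_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"input_dir {in_dir} does not exist")
    recs = []
    if cfg.input_kind == "columnar_dir":
        if (in_dir / "manifest.json").exists():
            recs, manifest = load_cohort(in_dir)
            recs = [r.select(cfg.channels) if set(cfg.channels) != set(r.channel_labels) else r for r in recs]
            return recs, manifest
        paths = sorted(in_dir.glob("*.tsv"))
        for p in paths:
            recs.append(read_columnar(p).select(cfg.channels))
    else:
        for p in sorted(in_dir.glob("*.edf")):
            recs.append(read_edf(p, cfg.channels))
    if not recs:
        raise FileNotFoundError(f"no recordings found in {in_dir}")
    return recs, None


def run_pipeline(cfg: RunConfig):
    """Execute ingest -> preprocess -> WPD -> connectivity -> stats -> exports.

    Returns the fitted :class:`~osaconnect.model.BrainConnectivityResults`
    and writes ``report.json``, CSV tables, per-subject matrices and
    BrainNet files under ``cfg.output_dir``.
    """
    recordings, manifest = _load_recordings(cfg)
    for rec in recordings:
        if rec.subject_id in cfg.group_map:
            rec.group_label = cfg.group_map[rec.subject_id]

    model = BrainConnectivityModel(
        recordings,
        groups=cfg.group_map or None,
        filter_spec=cfg.filter.to_spec(),
        wavelet_spec=cfg.wavelet.to_spec(),
        bands=cfg.band_definitions(),
        epoch_seconds=cfg.epoch_seconds,
        edge_threshold=cfg.edge_threshold,
        fisher_z=cfg.fisher_z,
    )
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = model.fit(
        report_bands=cfg.report_bands,
        cache_dir=out / "cache",
        cache_key=cfg.analysis_hash(),
    )
    for sid, err in results.failures.items():
        log.warning("subject %s failed: %s", sid, err)

    results.subject_table().to_csv(out / "subject_table.csv", index=False)
    results.group_summary_table().to_csv(out / "group_summaries.csv", index=False)
    tests = {}
    if len(results.groups_present()) == 2:
        test_tabs = []
        for feature in ("mean_pos_r", "mean_abs_coeff"):
            tab = results.band_test_table(feature)
            test_tabs.append(tab)
            tests[feature] = {
                row["band"]: {
                    "U": row["U"],
                    "z": row["z"],
                    "p": row["p"],
                    "method": row["method"],
                    "significant": bool(row["significant"]),
                }
                for _, row in tab.iterrows()
            }
        pd.concat(test_tabs).to_csv(out / "band_tests.csv", index=False)
        results.export_brainnet(out / "brainnet")
        tmaps = {
            band: {
                "labels": tm.labels,
                "t": [None if not np.isfinite(v) else float(v) for v in tm.t],
                "df": [None if not np.isfinite(v) else float(v) for v in tm.df],
            }
            for band, tm in results.degree_tmaps().items()
        }
    else:
        tmaps = {}

    mat_dir = out / "matrices"
    mat_dir.mkdir(exist_ok=True)
    for sid, by_band in results.subject_matrices.items():
        for band, m in by_band.items():
            np.savetxt(
                mat_dir / f"{sid}_{band}.csv",
                m.r,
                delimiter=",",
                header=",".join(m.channel_labels),
                comments="",
            )

    report = {
        "software": {"name": "osaconnect", "version": __version__},
        "config": json.loads(cfg.model_dump_json()),
        "analysis_hash": cfg.analysis_hash(),
        "n_subjects": len(results.subject_ids),
        "failures": results.failures,
        "group_summaries": [
            {
                "band": s.band,
                "group": s.group,
                "min_pos_r": s.min_pos_r,
                "max_pos_r": s.max_pos_r,
                "empty": s.empty,
            }
            for s in results.group_summaries()
        ],
        "band_tests": tests,
        "degree_tmaps": tmaps,
    }
    if manifest is not None:
        report["cohort_manifest"] = {
            k: v for k, v in manifest.items() if k == "spec"
        }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return results
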