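"""End-to-end orchestration: simulate/load -> filter -> structure -> trends -> classify.

Every stage reads and writes plain delimited/JSON files in one run
directory, so the composed stages and :func:`run_pipeline` produce
byte-identical outputs under a fixed seed. A manifest records the
config, seed, library versions and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .classify import ClassifierConfig, run_classifier
from .errors import ConfigError
from .filtering import FilterConfig, apply_filters
from .kinematics import build_feature_table
from .simulate import generate_study
from .structure import fit_swarm_ellipsoid, summarize_group, summarize_replicates
from .tracks import read_tracks, write_tracks
from .trends import compare_models, fit_mixed_speed_density, fit_quadratic

__all__ = ["RunConfig", "run_pipeline", "stage_simulate", "stage_filter",
           "stage_structure", "stage_trends", "stage_classify"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Validated configuration for one pipeline run."""

    output_dir: str = "run"
    seed: int = 0
    input_path: str | None = None  # delimited track table; None -> synthetic study
    synthetic: dict = field(default_factory=dict)  # kwargs for generate_study
    filter: FilterConfig = field(default_factory=FilterConfig)
    confidence: float = 0.90
    volume_convention: str = "ellipsoid"
    track_core_fraction: float = 0.5
    classifier: ClassifierConfig | None = field(default_factory=ClassifierConfig)
    run_trends: bool = True

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
        if "filter" in raw and isinstance(raw["filter"], dict):
            f = dict(raw["filter"])
            for key in ("time_window", "x_range", "z_range"):
                if key in f:
                    f[key] = tuple(f[key])
            try:
                raw["filter"] = FilterConfig(**f)
            except TypeError as exc:
                raise ConfigError(f"filter section: {exc}") from exc
        if "classifier" in raw and isinstance(raw["classifier"], dict):
            try:
                raw["classifier"] = ClassifierConfig(**raw["classifier"])
            except TypeError as exc:
                raise ConfigError(f"classifier section: {exc}") from exc
        return cls(**raw)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def _dump_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=2, default=float) + "\n")


def stage_simulate(config: RunConfig, outdir: Path) -> Path:
    """Generate the synthetic study and write tracks.csv + ground_truth.csv."""
    kwargs = dict(config.synthetic)
    tracks, truth = generate_study(np.random.default_rng(config.seed), **kwargs)
    path = outdir / "tracks.csv"
    write_tracks(tracks, path)
    truth.table().to_csv(outdir / "ground_truth.csv", index=False)
    _dump_json(
        {
            "volume_law": truth.volume_law,
            "volumes_by_group": truth.volumes_by_group,
            "speeds_by_group": truth.speeds_by_group,
            "seed": config.seed,
        },
        outdir / "ground_truth.json",
    )
    return path


def stage_filter(tracks_csv: Path, config: RunConfig, outdir: Path) -> Path:
    """Apply the four-stage swarming filter; write tracks_filtered.csv."""
    tracks = read_tracks(tracks_csv)
    kept = apply_filters(tracks, config.filter)
    out = outdir / "tracks_filtered.csv"
    write_tracks(kept, out)
    return out


def stage_structure(filtered_csv: Path, config: RunConfig, outdir: Path) -> tuple[Path, Path, Path]:
    """Per-replicate ellipsoid fits, group summaries and core feature table."""
    tracks = read_tracks(filtered_csv)
    by_rep: dict[tuple[int, str], list] = {}
    for tr in tracks:
        key = (tr.group_code if tr.group_code is not None else -1, tr.replicate_id)
        by_rep.setdefault(key, []).append(tr)
    if not by_rep:
        from .errors import DegenerateSwarmError

        raise DegenerateSwarmError("no tracks survived filtering; cannot fit swarm structure")
    summaries = []
    ellipsoids = {}
    core_tracks = []
    for (code, rep), rep_tracks in sorted(by_rep.items()):
        ell = fit_swarm_ellipsoid(rep_tracks, config.confidence, config.volume_convention)
        ellipsoids[f"{code}|{rep}"] = ell.to_dict()
        summaries.append(
            summarize_group(
                rep_tracks,
                ell,
                track_core_fraction=config.track_core_fraction,
                frame_rate=config.filter.frame_rate,
                replicate_id=rep,
                group_code=code,
            )
        )
        for tr in rep_tracks:
            if ell.track_is_core(tr, config.track_core_fraction):
                masked = tr.with_mask(ell.contains(tr.xyz))
                if masked is not None:
                    core_tracks.append(masked)
    summary_df = pd.DataFrame([s.to_row() for s in summaries])
    summary_path = outdir / "group_summary.csv"
    summary_df.to_csv(summary_path, index=False)
    summarize_replicates(summaries).to_csv(outdir / "group_summary_agg.csv", index=False)
    ell_path = outdir / "ellipsoids.json"
    _dump_json(ellipsoids, ell_path)
    features = build_feature_table(core_tracks, frame_rate=config.filter.frame_rate)
    feat_path = outdir / "core_features.csv"
    features.to_csv(feat_path, index=False)
    return summary_path, ell_path, feat_path


def stage_trends(summary_csv: Path, config: RunConfig, outdir: Path) -> Path:
    """Quadratic volume law, AIC model comparison and the speed-density
    mixed model, from the replicate-level group summary."""
    rows = pd.read_csv(summary_csv)
    out: dict[str, Any] = {}
    by_group = rows.groupby("group_code")["volume_cm3"].mean()
    x = by_group.index.to_numpy(float)
    y = by_group.to_numpy(float)
    if np.unique(x).size >= 3:
        quad = fit_quadratic(x, y)
        out["quadratic_volume"] = {
            "a": quad.a, "b": quad.b, "c": quad.c, "r2": quad.r2, "aic": quad.aic,
        }
    if np.unique(x).size >= 5:
        comp = compare_models(x, y)
        out["model_comparison"] = {"entries": comp.entries, "skipped": comp.skipped,
                                   "winner": comp.winner}
    ok = rows["speed_mps"].notna()
    if ok.sum() >= 5 and rows.loc[ok, "replicate_id"].nunique() >= 1:
        # Cohort grouping: replicate ids of the form <group>_<cohort> share a
        # random intercept per cohort (the study's independent rearing
        # cohorts); other id shapes fall back to one group per replicate id.
        cohort = rows.loc[ok, "replicate_id"].astype(str).str.split("_").str[-1]
        mm = fit_mixed_speed_density(
            rows.loc[ok, "density_per_cm3"].to_numpy(),
            rows.loc[ok, "speed_mps"].to_numpy(),
            cohort.to_numpy(),
        )
        out["mixed_speed_density"] = {
            "intercept": mm.intercept,
            "slope": mm.slope,
            "slope_se": mm.slope_se,
            "random_intercept_var": mm.random_intercept_var,
            "pseudo_r2": mm.pseudo_r2,
            "aic": mm.aic,
            "n_obs": mm.n_obs,
            "n_groups": mm.n_groups,
            "fallback_ols": mm.fallback_ols,
        }
    path = outdir / "trends.json"
    _dump_json(out, path)
    return path


def stage_classify(features_csv: Path, config: RunConfig, outdir: Path) -> Path:
    """Train and evaluate the OSR classifier on the core feature table."""
    table = pd.read_csv(features_csv)
    cfg = config.classifier or ClassifierConfig()
    report = run_classifier(table, cfg)
    path = outdir / "classifier_report.json"
    path.write_text(report.to_json() + "\n")
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage in order and write a deterministic manifest.

    Stage errors propagate with the stage name; downstream stages are
    skipped. Returns the manifest dict.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "swarmkin_version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "stages": {},
    }
    stage = "simulate/load"
    try:
        if config.input_path is None:
            tracks_csv = stage_simulate(config, outdir)
        else:
            tracks_csv = Path(config.input_path)
        n_in = pd.read_csv(tracks_csv)["track_id"].nunique()
        manifest["stages"]["input"] = {"tracks": int(n_in)}

        stage = "filter"
        filtered_csv = stage_filter(tracks_csv, config, outdir)
        n_kept = pd.read_csv(filtered_csv)["track_id"].nunique() if filtered_csv.stat().st_size else 0
        manifest["stages"]["filter"] = {"tracks_in": int(n_in), "tracks_out": int(n_kept)}

        stage = "structure"
        summary_csv, ell_path, feat_csv = stage_structure(filtered_csv, config, outdir)
        summary = pd.read_csv(summary_csv)
        manifest["stages"]["structure"] = {
            "replicates": int(len(summary)),
            "groups": int(summary["group_code"].nunique()),
            "core_feature_rows": int(len(pd.read_csv(feat_csv))),
        }

        if config.run_trends:
            stage = "trends"
            stage_trends(summary_csv, config, outdir)
            manifest["stages"]["trends"] = {"done": True}

        if config.classifier is not None:
            stage = "classify"
            report_path = stage_classify(feat_csv, config, outdir)
            rep = json.loads(report_path.read_text())
            manifest["stages"]["classify"] = {
                "accuracy": rep["accuracy"],
                "n_train": rep["n_train"],
                "n_test": rep["n_test"],
            }
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc

    blob = json.dumps(manifest, sort_keys=True, default=float)
    manifest["manifest_hash"] = hashlib.sha256(blob.encode()).hexdigest()
    _dump_json(manifest, outdir / "manifest.json")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj
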