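"""End-to-end orchestration: flatten -> ratio -> features -> type / SAPs.

A single :class:`RunConfig` (loadable from YAML) drives both pipelines;
every stage's effective parameters are echoed into the output report so a
run is self-describing, and all randomness flows from the configured seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import celltyper, features, flatten, saps, stack_io

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Inputs, parameters and seeds for a pipeline run."""

    stack_path: str | None = None
    labels_path: str | None = None
    types_csv: str | None = None
    frame_paths: list[str] = field(default_factory=list)  # time series for SAPs
    channel_map: dict[str, int] = field(
        default_factory=lambda: {"nadph": 0, "fad": 1, "shg": 2}
    )
    voxel_size: tuple[float, float, float] | None = None
    reference_z: float = 10.0
    integer_shift: bool = False
    ratio_floor: float | None = None
    nucleus_quantile: float = 0.2
    min_cell_voxels: int = features.MIN_CELL_VOXELS
    classifier_kinds: list[str] = field(default_factory=lambda: list(celltyper.CLASSIFIER_KINDS))
    test_frac: float = 0.25
    umap_n_neighbors: int = 15
    void_min_volume_um3: float = 0.5
    void_min_sphericity: float = 0.5
    gating_radius_um: float = 2.0
    seed: int = 42
    out_dir: str = "runs"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def validate(self, require_stack: bool = True) -> None:
        paths = {"stack_path": self.stack_path, "labels_path": self.labels_path}
        if self.types_csv:
            paths["types_csv"] = self.types_csv
        for i, p in enumerate(self.frame_paths):
            paths[f"frame_paths[{i}]"] = p
        for name, p in paths.items():
            if p is None:
                if require_stack and name in ("stack_path", "labels_path") and not self.frame_paths:
                    raise ConfigError(f"config field {name!r} is required but missing")
                continue
            if not Path(p).exists():
                raise ConfigError(f"config field {name!r}: path does not exist: {p}")


def _stage(name: str):
    """Decorator-free stage wrapper: times the call and tags errors."""
    class _Ctx:
        def __init__(self):
            self.t0 = 0.0

        def __enter__(self):
            self.t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc is not None:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2f s", name, dt)
            return False

    return _Ctx()


def _load_and_flatten(config: RunConfig, path: str):
    stack = stack_io.read_stack(
        path, config.channel_map, voxel_size=config.voxel_size
    )
    with _stage("detect_basement_membrane"):
        surface = flatten.detect_basement_membrane(stack)
    with _stage("flatten"):
        flat = flatten.flatten_stack(
            stack, surface, reference_z=config.reference_z, integer_shift=config.integer_shift
        )
    return stack, surface, flat


def run_typing_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Flatten, extract features, embed, and train/evaluate classifiers.

    Writes ``features.csv``, ``embedding.csv`` and ``report.json`` into
    the output directory and returns the report dict.  Deterministic for
    a fixed config.
    """
    config.validate()
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    stack, surface, flat = _load_and_flatten(config, config.stack_path)
    labels = stack_io.read_labels(config.labels_path, config.types_csv)
    with _stage("flatten_labels"):
        labels_flat = flatten.flatten_labels(labels, surface, reference_z=config.reference_z)
    with _stage("ratio"):
        ratio = features.compute_ratio_volume(flat, floor=config.ratio_floor)
    with _stage("features"):
        table = features.build_feature_table(
            flat,
            ratio,
            labels_flat,
            reference_z=config.reference_z,
            min_voxels=config.min_cell_voxels,
            nucleus_quantile=config.nucleus_quantile,
        )
    table.to_csv(out / "features.csv", index=False)

    with _stage("umap"):
        coords = celltyper.embed_umap(table, n_neighbors=config.umap_n_neighbors)
    emb = table[["cell_id"]].copy()
    emb["umap_1"], emb["umap_2"] = coords[:, 0], coords[:, 1]
    emb.to_csv(out / "embedding.csv", index=False)

    report: dict = {"config": _jsonable(asdict(config)), "n_cells": int(len(table)), "classifiers": {}}
    if table["cell_type"].notna().any():
        train_idx, test_idx = celltyper.split_train_test(
            table, test_frac=config.test_frac, seed=config.seed
        )
        report["split"] = {"train": train_idx.tolist(), "test": test_idx.tolist()}
        for kind in config.classifier_kinds:
            with _stage(f"train_{kind}"):
                model = celltyper.train_classifier(kind, table.iloc[train_idx], seed=config.seed)
                rep = celltyper.evaluate_classifier(model, table.iloc[test_idx])
            report["classifiers"][kind] = json.loads(rep.to_json())
    (out / "report.json").write_text(json.dumps(report, indent=2))
    return report


def run_sap_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> dict:
    """Detect voids per frame, link them over time, and report fractions.

    Works on ``frame_paths`` (a time series) or on the single
    ``stack_path``; writes ``voids.csv``, ``tracks.csv`` and
    ``fractions.json``.
    """
    config.validate(require_stack=not config.frame_paths)
    out = Path(out_dir or config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    paths = config.frame_paths or [config.stack_path]
    labels = stack_io.read_labels(config.labels_path, config.types_csv)
    secretory = [
        int(k) for k, t in labels.type_of.items() if t == "secretory"
    ] or [int(i) for i in labels.ids()]
    if not secretory:
        raise saps.SapError("no cells")

    params = saps.VoidParams(
        min_volume_um3=config.void_min_volume_um3,
        min_sphericity=config.void_min_sphericity,
        low_af_quantile=config.nucleus_quantile,
    )
    per_frame: list[list[saps.VoidCall]] = []
    fractions = {}
    voxel_size = None
    for frame, path in enumerate(paths):
        _, surface, flat = _load_and_flatten(config, path)
        voxel_size = flat.voxel_size
        labels_flat = flatten.flatten_labels(labels, surface, reference_z=config.reference_z)
        calls: list[saps.VoidCall] = []
        with _stage(f"detect_voids_frame{frame}"):
            for cell in secretory:
                mask = labels_flat.mask(cell)
                if not mask.any():
                    continue
                try:
                    nucleus = features.estimate_nucleus(
                        flat, mask, quantile=config.nucleus_quantile
                    )
                except features.FeatureError:
                    nucleus = None
                calls.extend(
                    saps.detect_voids(flat, mask, nucleus, cell_id=cell, params=params, frame=frame)
                )
        per_frame.append(calls)
        fractions[f"frame_{frame}"] = saps.sap_fraction(secretory, calls)

    all_calls = [c for calls in per_frame for c in calls]
    saps.calls_to_frame(all_calls).to_csv(out / "voids.csv", index=False)
    tracks = saps.track_voids(
        per_frame, gating_radius_um=config.gating_radius_um, voxel_size=voxel_size
    )
    saps.tracks_to_frame(tracks).to_csv(out / "tracks.csv", index=False)
    result = {"config": _jsonable(asdict(config)), "fractions": fractions, "n_tracks": len(tracks)}
    (out / "fractions.json").write_text(json.dumps(result, indent=2))
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
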