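"""Reproducible pipeline: simulate -> preprocess -> spta/map -> decode -> evaluate.

A run is driven by a YAML config plus a seed; every stage writes its outputs
under the run directory and the run ends with a manifest (config echo, seed,
per-file SHA-256 checksums), so identical config + seed reproduce identical
metric tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import evaluation, spta, synth

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger("limbdecode")


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Full configuration of one pipeline run."""

    seed: int
    out_dir: str
    n_datasets: int = 13
    n_trials: int = 40
    n_units: int = 34
    trial_jitter: int = 5
    folds: int = 4
    facilitation: str | None = "grouped"
    targets: tuple[str, ...] = ("emg", "kinematics")
    decoders: tuple[str, ...] = ("kf", "ukf")
    ann_hidden: int = 20
    ann_lr: float = 0.2
    ann_epochs: int = 2000
    ukf_alpha: float = 1.0
    ukf_kappa: float | None = None
    raw_differences: bool = False
    zero_phase: bool = False
    session_overrides: dict = field(default_factory=dict)

    def session_config(self) -> synth.SessionConfig:
        return synth.SessionConfig(
            n_trials=self.n_trials, n_units=self.n_units, **self.session_overrides
        )

    def decoder_config(self, target: str) -> evaluation.DecoderConfig:
        return evaluation.DecoderConfig(
            target=target,
            decoders=tuple(self.decoders),
            folds=self.folds,
            ann_hidden=self.ann_hidden,
            ann_lr=self.ann_lr,
            ann_epochs=self.ann_epochs,
            ukf_alpha=self.ukf_alpha,
            ukf_kappa=self.ukf_kappa,
            raw_differences=self.raw_differences,
            zero_phase=self.zero_phase,
        )


_REQUIRED_KEYS = ("seed", "out_dir")


def load_config(path: str | Path) -> PipelineConfig:
    """Read a YAML config; missing mandatory keys raise naming the key."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in _REQUIRED_KEYS:
        if key not in raw:
            raise PipelineError(f"config missing required key {key!r}")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise PipelineError(f"unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages in order and return the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }
    stage = "simulate"
    try:
        t0 = time.time()
        log.info("stage %s: %d datasets", stage, config.n_datasets)
        sessions = synth.generate_study(
            config.session_config(),
            config.seed,
            n_datasets=config.n_datasets,
            trial_jitter=config.trial_jitter,
            facilitation=config.facilitation,
        )
        files = {}
        for s in sessions:
            files.update(
                {f"{s.dataset_id}/{k}": v for k, v in synth.save_session(s, out / "sessions").items()}
            )
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}

        stage = "spta"
        t0 = time.time()
        log.info("stage %s", stage)
        spta_tables = []
        first = sessions[0]
        rect = first.emg.copy()
        rect.values = np.abs(rect.values)
        table = spta.scan_pairs(first.spikes, rect)
        table.insert(0, "dataset", first.dataset_id)
        spta_tables.append(table)
        spta_path = out / "spta_features.csv"
        pd.concat(spta_tables, ignore_index=True).to_csv(spta_path, index=False)
        files["spta_features"] = str(spta_path)

        stage = "map"
        density_rows = []
        linkage_rows = []
        for view in ("horizontal", "coronal"):
            maps = {}
            for m in synth.MUSCLES:
                flags = (
                    table[table["muscle"] == m]
                    .set_index("unit")["accepted"]
                    .reindex(first.spikes.unit_ids)
                    .fillna(False)
                    .to_numpy()
                )
                dm = spta.compute_density_map(first.spikes.coords, flags, view=view)
                maps[m] = dm
                density_rows.append(
                    {"view": view, "muscle": m, "max_raw": dm.raw.max()}
                )
            labels, Z, _ = spta.cluster_density_maps(maps)
            for a, b, h, n in Z:
                linkage_rows.append(
                    {"view": view, "i": int(a), "j": int(b), "height": h, "size": int(n)}
                )
            linkage_rows.append(
                {"view": view, "i": -1, "j": -1,
                 "height": float("nan"), "size": len(labels)}
            )
        dens_path = out / "density_summary.csv"
        pd.DataFrame(density_rows).to_csv(dens_path, index=False)
        link_path = out / "linkage.csv"
        pd.DataFrame(linkage_rows).to_csv(link_path, index=False)
        files["density_summary"] = str(dens_path)
        files["linkage"] = str(link_path)
        manifest["stages"]["spta+map"] = {"seconds": round(time.time() - t0, 2)}

        stage = "decode+evaluate"
        t0 = time.time()
        log.info("stage %s", stage)
        summaries = {}
        for target in config.targets:
            cfg = config.decoder_config(target)
            metrics = evaluation.cross_validate_study(
                sessions, cfg, seed=config.seed
            )
            mpath = out / f"metrics_{target}.csv"
            metrics.to_csv(mpath, index=False)
            files[f"metrics_{target}"] = str(mpath)
            if {"kf", "ukf"} <= set(config.decoders):
                summaries[target] = {
                    metric: evaluation.compare_decoders(metrics, metric=metric)
                    for metric in ("CC", "SNR")
                }
        sum_path = out / "comparison.json"
        sum_path.write_text(json.dumps(summaries, indent=1))
        files["comparison"] = str(sum_path)
        manifest["stages"][stage] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    manifest["files"] = {
        k: {"path": v, "sha256": _sha256(Path(v))} for k, v in files.items()
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
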