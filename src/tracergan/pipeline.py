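"""End-to-end orchestration: synth -> prepare -> train -> translate ->
evaluate -> compare, driven by one YAML config and a single global seed.

The global seed fans out to per-stage seeds (seed + stage index) so any
stage can be rerun independently and the whole run is reproducible
bit-for-bit in single-threaded execution. Intermediate images are NIfTI,
tabular outputs CSV, and a JSON manifest records the config hash, seeds and
file inventory of every stage.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .metrics import SimilarityReport, evaluate_pairs
from .pet_io import (Tracer, pair_subsets, rescale_to_unit, resample_volume,
                     slice_axial, split_participants, write_nifti)
from .phantom import PhantomParams, make_dataset, write_dataset
from .stats import compare_models
from .training import TrainConfig, train, translate

__all__ = ["PipelineConfig", "RunManifest", "run_all", "StageError"]

STAGES = ("synth", "prepare", "train_cyclegan", "train_pix2pix",
          "translate", "evaluate", "compare")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    out_dir: str = "run"
    seed: int = 0
    participants: int = 6
    fbb_subsets: int = 4
    fdg_subsets: int = 6
    train_fraction: float = 0.75
    pairs_per_participant: int = 3
    matrix: int = 64
    central_slices: int | None = None   # restrict to central axial slices
    misalignment_max_voxels: float = 0.0
    noise_sd_fbb: float = 0.06
    noise_sd_fdg: float = 0.03
    epochs: int = 10
    batch_size: int = 8
    levels: int = 3
    base_filters: int = 8
    learning_rate: float = 2e-4
    log_level: str = "info"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical(self) -> str:
        return yaml.safe_dump(self.__dict__, sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical().encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    files: dict           # stage -> list of paths (relative to out_dir)
    version: str
    timestamps: dict
    summary: dict = field(default_factory=dict)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2,
                                         default=str))


def _volume_slices(vol, pid, subset, tracer, central: int | None):
    slices = slice_axial(vol, participant_id=pid, subset_index=subset,
                         tracer=tracer)
    if central:
        depth = len(slices)
        lo = (depth - central) // 2
        slices = slices[lo:lo + central]
    return slices


def _prepare_split(cfg: PipelineConfig, tree: dict, ids: list, seed: int):
    """Resample subset volumes, draw per-participant pairs, cut slices."""
    a_slices, b_slices, n_volumes = [], [], 0
    matrix = (cfg.matrix,) * 3
    for k, pid in enumerate(sorted(ids)):
        node = tree[pid]
        fbb = [resample_volume(rescale_to_unit(r), matrix)
               for r in node[Tracer.FBB]]
        fdg = [resample_volume(rescale_to_unit(r), matrix)
               for r in node[Tracer.FDG]]
        pairs = pair_subsets(fbb, fdg, cfg.pairs_per_participant,
                             seed=seed + k, participant_id=pid)
        for pr in pairs:
            n_volumes += 1
            a_slices.extend(_volume_slices(pr.fbb, pid, pr.fbb_subset_index,
                                           Tracer.FBB, cfg.central_slices))
            b_slices.extend(_volume_slices(pr.fdg, pid, pr.fdg_subset_index,
                                           Tracer.FDG, cfg.central_slices))
    return a_slices, b_slices, n_volumes


def _save_stack(slices, path: Path) -> None:
    arr = np.stack([s.values for s in slices], axis=-1)
    write_nifti(arr, path)


def run_all(config: PipelineConfig | str | Path) -> RunManifest:
    """Execute every stage for both model modes; returns the run manifest."""
    cfg = (config if isinstance(config, PipelineConfig)
           else PipelineConfig.from_yaml(config))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = {stage: cfg.seed + i for i, stage in enumerate(STAGES)}
    files: dict = {s: [] for s in STAGES}
    timestamps: dict = {}
    summary: dict = {}

    def _stamp(stage):
        timestamps[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    # ---- synth ------------------------------------------------------------
    stage = "synth"
    try:
        params = PhantomParams(
            matrix=(cfg.matrix,) * 3,
            misalignment_max_voxels=cfg.misalignment_max_voxels,
            noise_sd_fbb=cfg.noise_sd_fbb, noise_sd_fdg=cfg.noise_sd_fdg)
        tree = make_dataset(cfg.participants, cfg.fbb_subsets,
                            cfg.fdg_subsets, params=params,
                            seed=seeds[stage])
        synth_dir = out / "synth"
        manifest_csv = write_dataset(tree, synth_dir)
        files[stage] = [str(p.relative_to(out))
                        for p in sorted(synth_dir.rglob("*")) if p.is_file()]
        _stamp(stage)
    except Exception as e:                                    # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- prepare ----------------------------------------------------------
    stage = "prepare"
    try:
        split = split_participants(sorted(tree), cfg.train_fraction,
                                   seed=seeds[stage])
        train_a, train_b, n_train_vol = _prepare_split(
            cfg, tree, sorted(split.train_ids), seeds[stage])
        val_a, val_b, n_val_vol = _prepare_split(
            cfg, tree, sorted(split.val_ids), seeds[stage] + 1000)
        prep = out / "prepare"
        prep.mkdir(exist_ok=True)
        for name, sl in (("train_FBB", train_a), ("train_FDG", train_b),
                         ("val_FBB", val_a), ("val_FDG", val_b)):
            _save_stack(sl, prep / f"{name}.nii.gz")
        split_df = pd.DataFrame(
            {"participant_id": sorted(tree),
             "split": ["train" if p in split.train_ids else "val"
                       for p in sorted(tree)]})
        split_df.to_csv(prep / "split.csv", index=False)
        files[stage] = [str(p.relative_to(out)) for p in sorted(prep.iterdir())]
        summary["n_train_participants"] = len(split.train_ids)
        summary["n_val_participants"] = len(split.val_ids)
        summary["n_train_subset_volumes"] = n_train_vol
        summary["n_val_subset_volumes"] = n_val_vol
        summary["n_train_slices"] = len(train_a)
        summary["n_val_slices"] = len(val_a)
        _stamp(stage)
    except Exception as e:                                    # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- train both modes -------------------------------------------------
    results = {}
    for mode in ("cyclegan", "pix2pix"):
        stage = f"train_{mode}"
        try:
            tdir = out / stage
            tdir.mkdir(exist_ok=True)
            tc = TrainConfig(mode=mode, epochs=cfg.epochs,
                             batch_size=cfg.batch_size, levels=cfg.levels,
                             base_filters=cfg.base_filters,
                             learning_rate=cfg.learning_rate,
                             seed=seeds[stage],
                             loss_log=str(tdir / "loss_history.csv"))
            results[mode] = train(train_a, train_b, tc)
            from .networks import save_checkpoint

            save_checkpoint(results[mode].G_A, tdir / "G_A.npz")
            files[stage] = [str(p.relative_to(out))
                            for p in sorted(tdir.iterdir())]
            _stamp(stage)
        except Exception as e:                                # noqa: BLE001
            raise StageError(stage, e) from e

    # ---- translate ---------------------------------------------------------
    stage = "translate"
    try:
        tdir = out / "translate"
        tdir.mkdir(exist_ok=True)
        generated = {}
        for mode in ("cyclegan", "pix2pix"):
            generated[mode] = translate(results[mode].G_A, val_a)
            _save_stack(generated[mode], tdir / f"generated_FDG_{mode}.nii.gz")
        files[stage] = [str(p.relative_to(out)) for p in sorted(tdir.iterdir())]
        _stamp(stage)
    except Exception as e:                                    # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- evaluate ----------------------------------------------------------
    stage = "evaluate"
    try:
        edir = out / "evaluate"
        edir.mkdir(exist_ok=True)
        reports = {}
        for mode in ("cyclegan", "pix2pix"):
            rep = evaluate_pairs(generated[mode], val_b, model=mode)
            rep.to_csv(edir / f"report_{mode}.csv")
            reports[mode] = rep
            agg = rep.aggregates
            summary[f"{mode}_ssim_mean"] = agg["ssim_mean"]
            summary[f"{mode}_ssim_sd"] = agg["ssim_sd"]
            summary[f"{mode}_psnr_mean"] = agg["psnr_mean"]
            summary[f"{mode}_psnr_sd"] = agg["psnr_sd"]
        files[stage] = [str(p.relative_to(out)) for p in sorted(edir.iterdir())]
        _stamp(stage)
    except Exception as e:                                    # noqa: BLE001
        raise StageError(stage, e) from e

    # ---- compare -----------------------------------------------------------
    stage = "compare"
    try:
        table = compare_models(reports["cyclegan"], reports["pix2pix"])
        table.to_csv(out / "comparison.csv", index=False)
        files[stage] = ["comparison.csv"]
        summary["comparison"] = table[
            ["metric", "t_statistic", "p_value", "significant", "higher"]
        ].to_dict("records")
        _stamp(stage)
    except Exception as e:                                    # noqa: BLE001
        raise StageError(stage, e) from e

    manifest = RunManifest(config_hash=cfg.config_hash, seeds=seeds,
                           files=files, version=__version__,
                           timestamps=timestamps, summary=summary)
    manifest.write(out / "manifest.json")
    return manifest
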