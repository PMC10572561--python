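"""End-to-end experiment orchestration: simulate → train → evaluate.

An experiment is described by one YAML/dict config; each stage writes its
outputs (NIfTI volumes, manifest and history CSVs, JSON reports) plus a
resolved copy of the config into the output directory, so a run can be
replayed exactly from what is on disk.  The CLI subcommands are thin
wrappers over the ``run_*`` functions here.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from . import phantom as ph
from .errors import ConfigError, DataError
from .evaluate import axial_psnr_profile, fid, EvalReport
from .features import ConvFeatureEncoder
from .losses import make_loss_config
from .networks import (DiscriminatorSpec, GeneratorSpec, load_checkpoint,
                       save_checkpoint)
from .suv import rois_from_label_map, suv_error_table
from .train import TrainConfig, fit, translate

__all__ = ["load_config", "run_simulate", "run_train", "run_evaluate"]

DEFAULTS = {
    "seed": 0,
    "phantom": {"n_subjects": 6, "n_slices": 48, "slice_shape": [32, 32],
                "psf_sigma": 0.8, "poisson_scale": 200.0,
                "gaussian_sigma": 0.0, "degradation": None},
    "times": {"t_early": 14.0, "t_late": 52.0},
    "split": {"train": 4, "val": 1, "test": 1},
    "loss": "lsgan+l1",
    "train": {"epochs": 10, "batch_size": 4, "lr0": 2e-4,
              "lr_decay_base": 0.98, "checkpoint_every": 0},
    "network": {"n_down": 3, "base_channels": 16, "channel_cap": 128,
                "norm_kind": "instance", "residual": True,
                "d_layers": 2, "d_base_channels": 16},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in (override or {}).items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    """Read an experiment config (YAML path or dict) over the defaults."""
    if isinstance(path_or_dict, dict):
        user = path_or_dict
    else:
        if not os.path.exists(path_or_dict):
            raise DataError(f"no such config file: {path_or_dict}")
        with open(path_or_dict) as fh:
            user = yaml.safe_load(fh) or {}
    cfg = _merge(DEFAULTS, user)
    t = cfg["times"]
    if not 0 <= t["t_early"] < t["t_late"]:
        raise ConfigError(
            f"need 0 <= t_early < t_late, got {t['t_early']}, {t['t_late']}")
    make_loss_config(cfg["loss"])  # fail fast on bad names
    if "out_dir" not in cfg:
        raise ConfigError("config must set out_dir")
    return cfg


def _write_resolved(cfg: dict, out_dir: str, stage: str) -> None:
    with open(os.path.join(out_dir, f"config_{stage}.yaml"), "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def _subject_ids(n: int) -> list:
    return [f"sub-{i + 1:02d}" for i in range(n)]


def run_simulate(cfg: dict) -> pd.DataFrame:
    """Generate the paired phantom dataset on disk; returns the manifest."""
    out_dir = cfg["out_dir"]
    os.makedirs(out_dir, exist_ok=True)
    p = cfg["phantom"]
    t = cfg["times"]
    base = ph.default_phantom_spec(
        n_slices=int(p["n_slices"]), slice_shape=tuple(p["slice_shape"]),
        seed=int(cfg["seed"]), psf_sigma=float(p["psf_sigma"]),
        poisson_scale=float(p["poisson_scale"]),
        gaussian_sigma=float(p["gaussian_sigma"]),
        degradation=p.get("degradation"))
    subjects = _subject_ids(int(p["n_subjects"]))
    counts = (cfg["split"]["train"], cfg["split"]["val"], cfg["split"]["test"])
    assignment = pio.split_subjects(subjects, counts=counts,
                                    seed=int(cfg["seed"]))
    rows = []
    for i, sid in enumerate(subjects):
        spec = ph.vary_spec(base, seed=int(cfg["seed"]) * 1000 + i + 1)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(cfg["seed"]),
                                   spawn_key=(1, i)))
        early, late, lab = ph.simulate_pair(
            spec, t["t_early"], t["t_late"], rng=rng, subject_id=sid)
        paths = {k: os.path.join(out_dir, f"{sid}_{k}.nii.gz")
                 for k in ("early", "late", "labels")}
        pio.write_nifti(early, paths["early"])
        pio.write_nifti(late, paths["late"])
        pio.write_nifti(pio.ImageStack(lab.astype(np.float64),
                                       spacing=early.spacing,
                                       subject_id=sid), paths["labels"])
        rows.append({"subject_id": sid, "split": assignment[sid],
                     "early_path": paths["early"],
                     "late_path": paths["late"],
                     "labels_path": paths["labels"],
                     "t_early": t["t_early"], "t_late": t["t_late"],
                     "n_slices": early.n_slices})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    with open(os.path.join(out_dir, "phantom_organs.json"), "w") as fh:
        json.dump([o.name for o in base.organs], fh)
    _write_resolved(cfg, out_dir, "simulate")
    return manifest


def _read_manifest(cfg: dict) -> pd.DataFrame:
    mpath = os.path.join(cfg["out_dir"], "manifest.csv")
    if not os.path.exists(mpath):
        raise DataError(f"no manifest at {mpath}; run simulate first")
    return pd.read_csv(mpath)


def _global_norm_params(cfg: dict) -> pio.NormParams:
    """One normalization range for the whole experiment, computed over the
    union of early and delayed stacks of the TRAINING split only (so the
    held-out subjects never leak into the intensity scale)."""
    manifest = _read_manifest(cfg)
    lo, hi = np.inf, -np.inf
    for _, row in manifest[manifest["split"] == "train"].iterrows():
        for key in ("early_path", "late_path"):
            vox = pio.read_nifti(row[key]).voxels
            lo = min(lo, float(vox.min()))
            hi = max(hi, float(vox.max()))
    if not hi > lo:
        raise DataError("degenerate intensity range in training split")
    return pio.NormParams(lo, hi)


def _load_split(cfg: dict, split: str, params: pio.NormParams | None = None):
    """(samples, per-subject stacks) for one split, normalized with the
    dataset-level params (computed from the training split if not given)."""
    manifest = _read_manifest(cfg)
    if params is None:
        params = _global_norm_params(cfg)
    samples, per_subject = [], []
    for _, row in manifest[manifest["split"] == split].iterrows():
        early = pio.read_nifti(row["early_path"])
        late = pio.read_nifti(row["late_path"])
        samples.extend(pio.pair_slices(early, late, params))
        per_subject.append({"row": row, "early": early, "late": late,
                            "params": params})
    return samples, per_subject


def _network_specs(cfg: dict):
    n = cfg["network"]
    p = cfg["phantom"]
    rows, cols = (int(s) for s in p["slice_shape"])
    gen = GeneratorSpec(rows=rows, cols=cols, n_down=int(n["n_down"]),
                        base_channels=int(n["base_channels"]),
                        channel_cap=int(n["channel_cap"]),
                        norm_kind=n["norm_kind"],
                        residual=bool(n.get("residual", False)))
    disc = DiscriminatorSpec(n_layers=int(n["d_layers"]),
                             base_channels=int(n["d_base_channels"]),
                             channel_cap=int(n["channel_cap"]),
                             norm_kind=n["norm_kind"])
    return gen, disc


def run_train(cfg: dict, verbose: bool = False):
    """Train on the train split; writes generator checkpoint + history CSV."""
    out_dir = cfg["out_dir"]
    params = _global_norm_params(cfg)
    train_samples, _ = _load_split(cfg, "train", params)
    if not train_samples:
        raise DataError("train split is empty")
    val_samples, _ = _load_split(cfg, "val", params)
    gen_spec, disc_spec = _network_specs(cfg)
    tc = cfg["train"]
    config = TrainConfig(batch_size=int(tc["batch_size"]),
                         lr0=float(tc["lr0"]),
                         lr_decay_base=float(tc["lr_decay_base"]),
                         epochs=int(tc["epochs"]),
                         loss=make_loss_config(cfg["loss"]),
                         seed=int(cfg["seed"]),
                         checkpoint_every=int(tc.get("checkpoint_every", 0)))
    G, history = fit(train_samples, config, generator_spec=gen_spec,
                     discriminator_spec=disc_spec,
                     val_samples=val_samples or None,
                     checkpoint_dir=out_dir, verbose=verbose)
    history.to_csv(os.path.join(out_dir, "history.csv"), index=False)
    save_checkpoint(os.path.join(out_dir, "generator.npz"), G,
                    seed=int(cfg["seed"]),
                    extra={"loss": cfg["loss"],
                           "norm": {"lo": params.lo, "hi": params.hi},
                           "train": {k: (v if not hasattr(v, "item") else
                                         float(v)) for k, v in tc.items()}})
    _write_resolved(cfg, out_dir, "train")
    return G, history


def run_evaluate(cfg: dict, split: str = "test") -> dict:
    """Translate the held-out split and compute FID, the axial PSNR profile
    and the organ SUV error table.  Writes JSON + CSV reports."""
    out_dir = cfg["out_dir"]
    ckpt = os.path.join(out_dir, "generator.npz")
    if not os.path.exists(ckpt):
        raise DataError(f"no generator checkpoint at {ckpt}; train first")
    G, _meta = load_checkpoint(ckpt)
    _samples, per_subject = _load_split(cfg, split)
    if not per_subject:
        raise DataError(f"split {split!r} is empty")
    with open(os.path.join(out_dir, "phantom_organs.json")) as fh:
        organ_names = json.load(fh)

    encoder = ConvFeatureEncoder()
    gen_slices, real_slices = [], []
    profiles, suv_tables = [], []
    for item in per_subject:
        early, late, params = item["early"], item["late"], item["params"]
        gen = translate(G, early, params,
                        time_post_injection=late.time_post_injection)
        gen_n, _ = pio.normalize(gen, params)
        late_n, _ = pio.normalize(late, params)
        early_n, _ = pio.normalize(early, params)
        prof = axial_psnr_profile(early_n.voxels, gen_n.voxels, late_n.voxels)
        prof.insert(0, "subject_id", early.subject_id)
        profiles.append(prof)
        gen_slices.extend(gen_n.voxels)
        real_slices.extend(late_n.voxels)
        labels = pio.read_nifti(item["row"]["labels_path"]).voxels.astype(int)
        rois = rois_from_label_map(labels, organ_names)
        table = suv_error_table(gen, late, rois)
        table.insert(0, "subject_id", early.subject_id)
        suv_tables.append(table)

    profile = pd.concat(profiles, ignore_index=True)
    suv_table = pd.concat(suv_tables, ignore_index=True)
    report = EvalReport(
        fid=fid(real_slices, gen_slices, encoder),
        psnr_per_slice=list(profile["psnr_gen"]),
        baseline_psnr_per_slice=list(profile["psnr_early"]),
        axial_profile=profile, encoder_identity=encoder.identity,
        extras={"split": split, "n_slices": len(profile),
                "n_subjects": len(per_subject)})
    profile.to_csv(os.path.join(out_dir, "axial_profile.csv"), index=False)
    suv_table.to_csv(os.path.join(out_dir, "suv_report.csv"), index=False)
    out = report.to_dict()
    out["suv_mean_absolute_error_by_organ"] = {
        organ: float(g["absolute_error"].mean())
        for organ, g in suv_table.groupby("organ")}
    with open(os.path.join(out_dir, "eval_report.json"), "w") as fh:
        json.dump(out, fh, indent=2)
    _write_resolved(cfg, out_dir, "evaluate")
    return out
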