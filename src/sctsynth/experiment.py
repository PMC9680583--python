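"""End-to-end experiment driver: phantoms -> preprocessing -> unpaired
training -> MRI-to-CT translation -> image metrics (and optionally gamma
analysis on surrogate doses), with a single JSON summary.

Every stage derives its randomness from the experiment seed, so a config +
seed fully determines the summary.  A stage failure aborts the run with
the stage name; logs written up to that point are left in place.
"""

from __future__ import annotations

import dataclasses
import json
import os
from contextlib import contextmanager
from typing import List, Tuple

import numpy as np

from .config import ExperimentConfig
from .containers import HUVolume, MRVolume
from .evaluation import gamma_grid_report, metric_report
from .io import Manifest, ManifestRow, write_volume
from .phantom import generate_phantom_pair, surrogate_dose
from .training import TranslationModel, build_slice_dataset, fit, translate

__all__ = ["run_experiment"]


@contextmanager
def _stage(name: str):
    try:
        yield
    except Exception as exc:
        raise RuntimeError(f"experiment stage '{name}' failed: {exc}") from exc


def _generate_subjects(cfg: ExperimentConfig
                       ) -> List[Tuple[str, HUVolume, MRVolume, str]]:
    spec = cfg.phantom_spec()
    out = []
    for i in range(cfg.n_subjects):
        split = "test" if i >= cfg.n_subjects - cfg.n_test else "train"
        ct, mri = generate_phantom_pair(spec, i)
        out.append((f"{i:03d}", ct, mri, split))
    return out


def run_experiment(cfg: ExperimentConfig) -> dict:
    os.makedirs(cfg.out_dir, exist_ok=True)
    with _stage("phantom"):
        subjects = _generate_subjects(cfg)
        data_dir = os.path.join(cfg.out_dir, "data")
        os.makedirs(data_dir, exist_ok=True)
        rows = []
        for sid, ct, mri, split in subjects:
            ct_path = os.path.join(data_dir, f"ct_{sid}.nii.gz")
            mri_path = os.path.join(data_dir, f"mri_{sid}.nii.gz")
            write_volume(ct, ct_path)
            write_volume(mri, mri_path)
            rows.append(ManifestRow(sid, ct_path, mri_path, split))
        Manifest(rows).write(os.path.join(data_dir, "manifest.tsv"))

    with _stage("preprocess"):
        train_pairs = [(ct, mri) for _, ct, mri, split in subjects
                       if split == "train"]
        mri_pool, ct_pool = build_slice_dataset(train_pairs,
                                                size=cfg.slice_size)

    with _stage("train"):
        model = fit(cfg.train, mri_pool, ct_pool, cfg.out_dir)

    results = {}
    with _stage("translate"):
        scts = {}
        for sid, ct, mri, split in subjects:
            if split != "test":
                continue
            sct = translate(model, mri)
            write_volume(sct, os.path.join(cfg.out_dir, f"sct_{sid}.nii.gz"))
            scts[sid] = (ct, sct)

    with _stage("evaluate"):
        for sid, (ct, sct) in scts.items():
            rep = metric_report(ct, sct, ct.body_mask)
            entry = {"metrics": rep.as_dict()}
            if cfg.run_gamma:
                entry["gamma"] = [g.as_dict()
                                  for g in _gamma_on_surrogates(ct, sct,
                                                                cfg.prescription)]
            results[sid] = entry

    summary = {
        "seed": cfg.seed,
        "model_kind": cfg.train.model_kind,
        "config": cfg.to_flat_dict(),
        "results": results,
        "mean": _mean_metrics(results),
    }
    with open(os.path.join(cfg.out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary


def _gamma_on_surrogates(ct: HUVolume, sct: HUVolume, prescription: float):
    """Gamma grid between the CT-based and sCT-based surrogate doses,
    both scaled by the CT dose's normalisation (same delivery)."""
    from .containers import DoseGrid
    ref_raw = surrogate_dose(ct, prescription=prescription, normalize=False)
    ev_raw = surrogate_dose(sct, prescription=prescription, normalize=False)
    nz, ny, nx = ref_raw.dose.shape
    center = ref_raw.dose[nz // 2, ny // 2, nx // 2]
    scale = prescription / center if center > 0 else 0.0
    ref = DoseGrid(ref_raw.dose * scale, ref_raw.spacing, prescription)
    ev = DoseGrid(ev_raw.dose * scale, ev_raw.spacing, prescription)
    return gamma_grid_report(ref, ev)


def _mean_metrics(results: dict) -> dict:
    if not results:
        return {}
    keys = ("mae_hu", "psnr_db", "ssim")
    return {k: float(np.mean([r["metrics"][k] for r in results.values()]))
            for k in keys}
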