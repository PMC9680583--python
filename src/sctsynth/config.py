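"""Flat experiment configuration with validation.

A single key: value file (YAML mapping of scalars) drives an end-to-end
experiment.  Every training hyperparameter has a named key whose default is
the full-scale protocol value (loss weights alpha=10, beta=5, lambda=1,
eta=1, tau=0.07; learning rate 2e-4 over 200 epochs decaying from 100;
286-pad/256-crop augmentation).  Unknown keys and cross-field invariant
violations are rejected with the offending key named.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Tuple

import yaml

from .losses import LossWeights
from .phantom import PhantomSpec, default_tissue_table, monotone_tissue_table
from .training import TrainConfig

__all__ = ["ExperimentConfig", "validate_config", "load_config_file"]

_WEIGHT_KEYS = ("alpha", "beta", "lambda1", "lambda2",
                "eta1", "eta2", "eta3", "eta4", "tau")
_TRAIN_KEYS = ("model_kind", "epochs", "lr0", "decay_start_epoch", "batch_size",
               "pad_to", "crop_to", "rotation_deg", "hflip", "base_filters",
               "n_res_blocks", "n_downsamples", "feature_layer_ids",
               "dis_base_filters", "dis_n_layers", "head_hidden_dim",
               "head_out_dim", "n_patches", "nce_reduction", "identity_nce",
               "checkpoint_every", "adam_beta1", "adam_beta2")


@dataclass(frozen=True)
class ExperimentConfig:
    """Resolved end-to-end experiment settings (phantoms -> training ->
    translation -> evaluation)."""
    seed: int = 0
    data_dir: Optional[str] = None
    out_dir: str = "run"
    verbosity: int = 1
    # phantom generation
    n_subjects: int = 4
    n_test: int = 1
    grid_shape: Tuple[int, int, int] = (32, 64, 64)
    shape_jitter: float = 0.08
    monotone_phantom: bool = False
    slice_size: int = 240
    # evaluation
    run_gamma: bool = False
    prescription: float = 50.0
    # training (flattened TrainConfig + LossWeights)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self):
        if not 1 <= self.n_test < self.n_subjects:
            raise ValueError("n_test must satisfy 1 <= n_test < n_subjects")
        div = 2 ** self.train.n_downsamples
        if self.slice_size % div:
            raise ValueError(f"slice_size must be divisible by {div}")

    def phantom_spec(self) -> PhantomSpec:
        table = monotone_tissue_table() if self.monotone_phantom \
            else default_tissue_table()
        return PhantomSpec(n_subjects=self.n_subjects,
                           grid_shape=tuple(self.grid_shape),
                           seed=self.seed, shape_jitter=self.shape_jitter,
                           tissue_table=tuple(table),
                           require_contrast_inversion=not self.monotone_phantom)

    def to_flat_dict(self) -> dict:
        out = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)
               if f.name != "train"}
        out["grid_shape"] = list(self.grid_shape)
        for k in _TRAIN_KEYS:
            out[k] = getattr(self.train, k)
        out["feature_layer_ids"] = list(self.train.feature_layer_ids)
        for k in _WEIGHT_KEYS:
            out[k] = getattr(self.train.weights, k)
        out["train_seed"] = self.train.seed
        return out


def validate_config(raw: dict) -> ExperimentConfig:
    """Build an :class:`ExperimentConfig` from a flat key-value mapping,
    filling defaults, checking types and naming any unknown key."""
    raw = dict(raw or {})
    exp_keys = {f.name for f in dataclasses.fields(ExperimentConfig)} - {"train"}
    known = exp_keys | set(_TRAIN_KEYS) | set(_WEIGHT_KEYS) | {"train_seed"}
    unknown = sorted(set(raw) - known)
    if unknown:
        raise KeyError(f"unknown config keys: {unknown}")

    weight_kwargs = {k: float(raw.pop(k)) for k in _WEIGHT_KEYS if k in raw}
    train_kwargs = {k: raw.pop(k) for k in _TRAIN_KEYS if k in raw}
    if "feature_layer_ids" in train_kwargs:
        train_kwargs["feature_layer_ids"] = tuple(
            train_kwargs["feature_layer_ids"])
    train_seed = raw.pop("train_seed", raw.get("seed", 0))
    try:
        weights = LossWeights(**weight_kwargs)
        train = TrainConfig(weights=weights, seed=int(train_seed), **train_kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid training configuration: {exc}") from exc
    if "grid_shape" in raw:
        raw["grid_shape"] = tuple(int(v) for v in raw["grid_shape"])
    return ExperimentConfig(train=train, **raw)


def load_config_file(path: str) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key: value mapping")
    return validate_config(raw)
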