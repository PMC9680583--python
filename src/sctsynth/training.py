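"""Unpaired training of the three translation model kinds.

The harness is shared: the same data shuffling (MRI and CT pools shuffled
independently each epoch, so pairs mix subjects and anatomical positions),
augmentation (pad, random crop, small rotation, horizontal flip), Adam
optimizer and two-phase learning-rate schedule (constant, then linear decay
to zero) drive whichever objective the model kind selects.  Each step runs
one generator update (projection heads included for the contrastive terms)
followed by one update per discriminator.

All randomness derives from the config seed through ``numpy`` seed
sequences, so identical configs reproduce identical loss logs and
checkpoint-resume continues a run bit-compatibly.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .containers import AIR_HU, CT_BOUNDS, HUVolume, MRVolume, NormalizedImage
from .losses import (
    DiscriminatorLossReport, GeneratorLossReport, LossWeights,
    cut_generator_objective, cyclecut_generator_objective,
    cyclegan_generator_objective, discriminator_objective, l1_mean,
    lsgan_dis_loss, lsgan_gen_loss, patchnce_loss,
)
from .nn import (
    Adam, DiscriminatorSpec, GeneratorSpec, PatchDiscriminator,
    ProjectionHeads, ProjectionHeadSpec, ResnetGenerator, Tensor,
    encoder_features, project_features, sample_patch_locations,
)

__all__ = [
    "TrainConfig", "TranslationModel", "augment", "unpaired_sampler",
    "lr_schedule", "train_step", "fit", "translate",
    "save_checkpoint", "load_checkpoint", "build_slice_dataset",
]

MODEL_KINDS = ("cyclegan", "cut", "cyclecut")
LOG_COLUMNS = ("epoch", "step", "model_kind", "lr", "component", "value")


@dataclass(frozen=True)
class TrainConfig:
    """Model kind, architecture sizes, loss weights and schedule.

    Defaults are the full-scale protocol (200 epochs, lr 2e-4 decaying from
    epoch 100, 286-pad/256-crop augmentation, 64-filter networks); tests
    shrink the architecture and slice size, not the protocol's structure.
    """
    model_kind: str = "cyclecut"
    epochs: int = 200
    lr0: float = 2e-4
    decay_start_epoch: int = 100
    batch_size: int = 1
    pad_to: int = 286
    crop_to: int = 256
    rotation_deg: float = 5.0
    hflip: bool = True
    seed: int = 0
    weights: LossWeights = field(default_factory=LossWeights)
    # network sizes
    base_filters: int = 64
    n_res_blocks: int = 9
    n_downsamples: int = 2
    feature_layer_ids: Tuple[int, ...] = ()
    dis_base_filters: int = 64
    dis_n_layers: int = 3
    head_hidden_dim: int = 256
    head_out_dim: int = 256
    n_patches: int = 256
    nce_reduction: str = "mean_locations"
    #: semantics of the CUT identity NCE term: compare CT against G(CT)
    identity_nce: str = "g_of_ct"
    checkpoint_every: int = 0   # 0 -> final checkpoint only
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"model_kind must be one of {MODEL_KINDS}")
        if not 0 < self.decay_start_epoch <= self.epochs:
            raise ValueError("decay_start_epoch must lie in (0, epochs]")
        if self.crop_to > self.pad_to:
            raise ValueError("crop_to must not exceed pad_to")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.identity_nce != "g_of_ct":
            raise ValueError("identity_nce supports only 'g_of_ct'")

    def generator_spec(self) -> GeneratorSpec:
        return GeneratorSpec(base_filters=self.base_filters,
                             n_res_blocks=self.n_res_blocks,
                             n_downsamples=self.n_downsamples,
                             feature_layer_ids=tuple(self.feature_layer_ids))

    def discriminator_spec(self) -> DiscriminatorSpec:
        return DiscriminatorSpec(base_filters=self.dis_base_filters,
                                 n_layers=self.dis_n_layers)

    def head_spec(self) -> ProjectionHeadSpec:
        return ProjectionHeadSpec(hidden_dim=self.head_hidden_dim,
                                  out_dim=self.head_out_dim)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @staticmethod
    def from_dict(d: dict) -> "TrainConfig":
        d = dict(d)
        if isinstance(d.get("weights"), dict):
            d["weights"] = LossWeights(**d["weights"])
        if "feature_layer_ids" in d:
            d["feature_layer_ids"] = tuple(d["feature_layer_ids"])
        return TrainConfig(**d)


def _derive_seed(*parts: int) -> int:
    """Stable child seed below 2**31 from integer path components."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# data pipeline
# ---------------------------------------------------------------------------

def augment(image: NormalizedImage, seed: int, pad_to: int = 286,
            crop_to: int = 256, rotation_deg: float = 5.0,
            hflip: bool = True) -> NormalizedImage:
    """Pad with the normalised background (-1), random-crop, rotate within
    +/- ``rotation_deg`` degrees, and horizontally flip with probability 1/2.
    Deterministic given ``seed``."""
    if crop_to > pad_to:
        raise ValueError("crop_to must not exceed pad_to")
    rng = np.random.default_rng(seed)
    px = image.pixels
    h, w = px.shape
    if pad_to < max(h, w):
        raise ValueError("pad_to smaller than the stored slice")
    canvas = np.full((pad_to, pad_to), -1.0)
    oy, ox = (pad_to - h) // 2, (pad_to - w) // 2
    canvas[oy:oy + h, ox:ox + w] = px
    cy = int(rng.integers(0, pad_to - crop_to + 1))
    cx = int(rng.integers(0, pad_to - crop_to + 1))
    out = canvas[cy:cy + crop_to, cx:cx + crop_to]
    if rotation_deg > 0:
        angle = float(rng.uniform(-rotation_deg, rotation_deg))
        out = ndimage.rotate(out, angle, order=1, reshape=False,
                             mode="constant", cval=-1.0)
        out = np.clip(out, -1.0, 1.0)
    if hflip and rng.uniform() < 0.5:
        out = out[:, ::-1]
    return NormalizedImage(np.ascontiguousarray(out),
                           image.source_min, image.source_max)


def unpaired_sampler(mri_slices: Sequence, ct_slices: Sequence,
                     seed: int) -> List[Tuple]:
    """One epoch of unpaired (MRI, CT) pairs: both pools are shuffled
    independently; the epoch length is the larger pool (the smaller pool
    cycles), so every slice of the larger pool appears exactly once."""
    if len(mri_slices) == 0 or len(ct_slices) == 0:
        raise ValueError("both slice pools must be non-empty")
    rng = np.random.default_rng(seed)
    n = max(len(mri_slices), len(ct_slices))
    mri_idx = _cycled_shuffle(len(mri_slices), n, rng)
    ct_idx = _cycled_shuffle(len(ct_slices), n, rng)
    return [(mri_slices[i], ct_slices[j]) for i, j in zip(mri_idx, ct_idx)]


def _cycled_shuffle(pool: int, n: int, rng: np.random.Generator) -> np.ndarray:
    reps = []
    total = 0
    while total < n:
        reps.append(rng.permutation(pool))
        total += pool
    return np.concatenate(reps)[:n]


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Constant ``lr0`` through ``decay_start_epoch``, then linear decay
    reaching zero at the final epoch boundary."""
    if not 1 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [1, {cfg.epochs}]")
    if epoch <= cfg.decay_start_epoch:
        return cfg.lr0
    return cfg.lr0 * (cfg.epochs - epoch) / (cfg.epochs - cfg.decay_start_epoch)


def build_slice_dataset(subjects: Sequence[Tuple[HUVolume, MRVolume]],
                        size: int = 240, match_histograms: bool = True
                        ) -> Tuple[List[NormalizedImage], List[NormalizedImage]]:
    """Preprocess subject volumes into pooled normalised slices.

    MRI volumes are histogram-matched to the first subject's scan (the
    intensity-standardisation step), both modalities are masked and sliced
    axially, and the slices are returned as two pools (MRI, CT).
    """
    from .phantom import histogram_match, slice_dataset
    if len(subjects) == 0:
        raise ValueError("no subjects")
    reference = subjects[0][1]
    mri_pool, ct_pool = [], []
    for ct, mri in subjects:
        if match_histograms:
            mri = histogram_match(mri, reference)
        ct_pool.extend(slice_dataset(ct, size=size))
        mri_pool.extend(slice_dataset(mri, size=size))
    return mri_pool, ct_pool


# ---------------------------------------------------------------------------
# model bundle
# ---------------------------------------------------------------------------

class TranslationModel:
    """Networks + optimizers for one model kind.

    ``gen_a`` maps MRI -> CT (the direction every kind trains); cycle kinds
    add the reverse generator ``gen_b`` and a second discriminator.
    Contrastive kinds attach per-encoder-layer projection heads.
    """

    def __init__(self, cfg: TrainConfig):
        self.cfg = cfg
        rng = np.random.default_rng(_derive_seed(cfg.seed, 0xA11))
        gspec, dspec, hspec = (cfg.generator_spec(), cfg.discriminator_spec(),
                               cfg.head_spec())
        self.layer_ids = gspec.resolved_feature_layers()
        self.gen_a = ResnetGenerator(gspec, rng=rng)
        self.dis_ct = PatchDiscriminator(dspec, rng=rng)
        self.gen_b = self.dis_mri = self.heads_a = self.heads_b = None
        if cfg.model_kind in ("cyclegan", "cyclecut"):
            self.gen_b = ResnetGenerator(gspec, rng=rng)
            self.dis_mri = PatchDiscriminator(dspec, rng=rng)
        if cfg.model_kind in ("cut", "cyclecut"):
            self.heads_a = ProjectionHeads(gspec, hspec, rng=rng)
        if cfg.model_kind == "cyclecut":
            self.heads_b = ProjectionHeads(gspec, hspec, rng=rng)
        self.opt_g = Adam(self._gen_params(), lr=cfg.lr0,
                          beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
        self.opt_d = Adam(self._dis_params(), lr=cfg.lr0,
                          beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)

    def _named_modules(self):
        mods = {"gen_a": self.gen_a, "dis_ct": self.dis_ct,
                "gen_b": self.gen_b, "dis_mri": self.dis_mri,
                "heads_a": self.heads_a, "heads_b": self.heads_b}
        return {k: v for k, v in mods.items() if v is not None}

    def _gen_params(self) -> dict:
        out = {}
        for name in ("gen_a", "gen_b", "heads_a", "heads_b"):
            mod = getattr(self, name)
            if mod is not None:
                out.update({f"{name}/{k}": p for k, p in mod.parameters().items()})
        return out

    def _dis_params(self) -> dict:
        out = {}
        for name in ("dis_ct", "dis_mri"):
            mod = getattr(self, name)
            if mod is not None:
                out.update({f"{name}/{k}": p for k, p in mod.parameters().items()})
        return out

    def state_dict(self) -> dict:
        return {f"{mname}/{k}": v for mname, mod in self._named_modules().items()
                for k, v in mod.state_dict().items()}

    def load_state_dict(self, state: dict) -> None:
        for mname, mod in self._named_modules().items():
            prefix = f"{mname}/"
            sub = {k[len(prefix):]: v for k, v in state.items()
                   if k.startswith(prefix)}
            mod.load_state_dict(sub)

    def set_lr(self, lr: float) -> None:
        self.opt_g.lr = lr
        self.opt_d.lr = lr


# ---------------------------------------------------------------------------
# one optimisation step
# ---------------------------------------------------------------------------

def _nce_term(gen, heads, feats_in: dict, output: Tensor, cfg: TrainConfig,
              seed: int):
    """PatchNCE between captured input features and the output re-encoded
    by the same encoder, through that generator's projection heads."""
    feats_out = encoder_features(gen, output, tuple(feats_in))
    locs = sample_patch_locations(feats_in, cfg.n_patches, seed)
    stack_in = project_features(heads, feats_in, locs)
    stack_out = project_features(heads, feats_out, locs)
    return patchnce_loss(stack_in, stack_out, cfg.weights.tau,
                         reduction=cfg.nce_reduction)


def _check_finite(parts: dict) -> None:
    for name, val in parts.items():
        v = val.item() if isinstance(val, Tensor) else float(val)
        if not np.isfinite(v):
            raise FloatingPointError(f"non-finite loss component {name!r}: {v}")


def train_step(model: TranslationModel, mri: np.ndarray, ct: np.ndarray,
               step_seed: int
               ) -> Tuple[GeneratorLossReport, DiscriminatorLossReport]:
    """One generator update followed by one update per discriminator.

    ``mri`` and ``ct`` are augmented 2D arrays in [-1, 1] at the training
    input size.  Returns float-valued loss reports for logging.
    """
    cfg = model.cfg
    w = cfg.weights
    x_mri = Tensor(np.asarray(mri, dtype=np.float32)[None, None])
    x_ct = Tensor(np.asarray(ct, dtype=np.float32)[None, None])
    kind = cfg.model_kind
    # terms whose weight is zero are neither computed nor reported
    parts = {}
    fakes = {}

    if kind == "cut":
        sct, feats_mri = model.gen_a(x_mri, capture=model.layer_ids)
        parts["adversarial_a"] = lsgan_gen_loss(model.dis_ct(sct))
        if w.lambda1 > 0:
            parts["nce_1"] = _nce_term(model.gen_a, model.heads_a, feats_mri,
                                       sct, cfg, _derive_seed(step_seed, 1))
        if w.lambda2 > 0:
            idt, feats_ct = model.gen_a(x_ct, capture=model.layer_ids)
            parts["nce_2"] = _nce_term(model.gen_a, model.heads_a, feats_ct,
                                       idt, cfg, _derive_seed(step_seed, 2))
        gen_report = cut_generator_objective(
            {"nce_1": 0.0, "nce_2": 0.0, **parts}, w)
        fakes = {"sct": sct}
    else:
        is_ccut = kind == "cyclecut"
        etas = (w.eta1, w.eta2, w.eta3, w.eta4) if is_ccut else (0,) * 4
        capture = model.layer_ids if is_ccut else ()
        sct, feats_mri_a = model.gen_a(x_mri, capture=capture) if capture \
            else (model.gen_a(x_mri), None)
        smri, feats_ct_b = model.gen_b(x_ct, capture=capture) if capture \
            else (model.gen_b(x_ct), None)
        parts["adversarial_a"] = lsgan_gen_loss(model.dis_ct(sct))
        parts["adversarial_b"] = lsgan_gen_loss(model.dis_mri(smri))
        if w.alpha > 0 or etas[3] > 0:
            cyc_mri, feats_sct_b = model.gen_b(sct, capture=capture) if capture \
                else (model.gen_b(sct), None)
        if w.alpha > 0 or etas[1] > 0:
            cyc_ct, feats_smri_a = model.gen_a(smri, capture=capture) if capture \
                else (model.gen_a(smri), None)
        if w.alpha > 0:
            parts["cycle_mri"] = l1_mean(cyc_mri, x_mri)
            parts["cycle_ct"] = l1_mean(cyc_ct, x_ct)
        if w.beta > 0:
            parts["identity_ct"] = l1_mean(model.gen_a(x_ct), x_ct)
            parts["identity_mri"] = l1_mean(model.gen_b(x_mri), x_mri)
        if etas[0] > 0:
            parts["nce_1"] = _nce_term(model.gen_a, model.heads_a, feats_mri_a,
                                       sct, cfg, _derive_seed(step_seed, 1))
        if etas[1] > 0:
            parts["nce_2"] = _nce_term(model.gen_a, model.heads_a, feats_smri_a,
                                       cyc_ct, cfg, _derive_seed(step_seed, 2))
        if etas[2] > 0:
            parts["nce_3"] = _nce_term(model.gen_b, model.heads_b, feats_ct_b,
                                       smri, cfg, _derive_seed(step_seed, 3))
        if etas[3] > 0:
            parts["nce_4"] = _nce_term(model.gen_b, model.heads_b, feats_sct_b,
                                       cyc_mri, cfg, _derive_seed(step_seed, 4))
        filler = {k: 0.0 for k in ("cycle_mri", "cycle_ct", "identity_ct",
                                   "identity_mri", "nce_1", "nce_2", "nce_3",
                                   "nce_4")}
        full_parts = {**filler, **parts}
        gen_report = cyclecut_generator_objective(full_parts, w) if is_ccut \
            else cyclegan_generator_objective(
                {k: full_parts[k] for k in
                 ("adversarial_a", "adversarial_b", "cycle_mri", "cycle_ct",
                  "identity_ct", "identity_mri")}, w)
        fakes = {"sct": sct, "smri": smri}

    _check_finite(parts)
    model.opt_g.zero_grad()
    gen_report.total.backward()
    model.opt_g.step()
    # restrict the logged report to the terms actually computed
    gen_report = GeneratorLossReport(total=gen_report.total, components=parts)

    d_parts = {"d_a": lsgan_dis_loss(model.dis_ct(x_ct),
                                     model.dis_ct(fakes["sct"].detach()))}
    if model.dis_mri is not None:
        d_parts["d_b"] = lsgan_dis_loss(model.dis_mri(x_mri),
                                        model.dis_mri(fakes["smri"].detach()))
    dis_report = discriminator_objective(kind, d_parts)
    _check_finite(d_parts)
    model.opt_d.zero_grad()
    dis_report.total.backward()
    model.opt_d.step()

    return (GeneratorLossReport(total=gen_report.total.item(),
                                components={k: v.item() if isinstance(v, Tensor)
                                            else float(v)
                                            for k, v in parts.items()}),
            DiscriminatorLossReport(total=dis_report.total.item(),
                                    components={k: v.item() for k, v
                                                in dis_report.components.items()}))


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(path: str, model: TranslationModel, epoch: int) -> None:
    """Single-file, self-describing checkpoint: architecture config,
    network weights, optimizer moments and step counters."""
    meta = {"version": CHECKPOINT_VERSION, "epoch": epoch,
            "config": model.cfg.to_dict()}
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    for tag, opt in (("opt_g", model.opt_g), ("opt_d", model.opt_d)):
        st = opt.state_dict()
        arrays[f"{tag}/t"] = np.asarray(st["t"])
        arrays.update({f"{tag}/m/{k}": v for k, v in st["m"].items()})
        arrays.update({f"{tag}/v/{k}": v for k, v in st["v"].items()})
    os.makedirs(os.path.dirname(os.path.abspath(path)), exist_ok=True)
    with open(path, "wb") as fh:
        np.savez(fh, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)


def load_checkpoint(path: str) -> Tuple[TranslationModel, int]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
        cfg = TrainConfig.from_dict(meta["config"])
        model = TranslationModel(cfg)
        model.load_state_dict({k[len("param/"):]: data[k] for k in data.files
                               if k.startswith("param/")})
        for tag, opt in (("opt_g", model.opt_g), ("opt_d", model.opt_d)):
            st = {"t": int(data[f"{tag}/t"]),
                  "m": {k[len(f"{tag}/m/"):]: data[k] for k in data.files
                        if k.startswith(f"{tag}/m/")},
                  "v": {k[len(f"{tag}/v/"):]: data[k] for k in data.files
                        if k.startswith(f"{tag}/v/")}}
            opt.load_state_dict(st)
    return model, int(meta["epoch"])


# ---------------------------------------------------------------------------
# the training loop
# ---------------------------------------------------------------------------

def fit(cfg: TrainConfig, mri_slices: Sequence[NormalizedImage],
        ct_slices: Sequence[NormalizedImage], out_dir: str,
        resume_from: Optional[str] = None) -> TranslationModel:
    """Train for ``cfg.epochs`` epochs over pooled normalised slices.

    Writes a tab-separated loss log (one row per step and component) and a
    final self-describing checkpoint under ``out_dir``; ``resume_from``
    continues a run from a saved checkpoint, reproducing the uninterrupted
    run exactly because every per-step seed derives from (seed, epoch, step).
    """
    if len(mri_slices) == 0 or len(ct_slices) == 0:
        raise ValueError("training requires non-empty MRI and CT slice pools")
    os.makedirs(out_dir, exist_ok=True)
    if resume_from is not None:
        model, start_epoch = load_checkpoint(resume_from)
        if model.cfg != cfg:
            raise ValueError("resume checkpoint config differs from cfg")
    else:
        model, start_epoch = TranslationModel(cfg), 0
    log_path = os.path.join(out_dir, "loss_log.tsv")
    mode = "a" if (resume_from is not None and os.path.exists(log_path)) else "w"
    with open(log_path, mode) as log:
        if mode == "w":
            log.write("\t".join(LOG_COLUMNS) + "\n")
        for epoch in range(start_epoch + 1, cfg.epochs + 1):
            lr = lr_schedule(epoch, cfg)
            model.set_lr(lr)
            pairs = unpaired_sampler(mri_slices, ct_slices,
                                     _derive_seed(cfg.seed, 0xE, epoch))
            for step, (mri_img, ct_img) in enumerate(pairs):
                aug_kw = dict(pad_to=cfg.pad_to, crop_to=cfg.crop_to,
                              rotation_deg=cfg.rotation_deg, hflip=cfg.hflip)
                mri_aug = augment(mri_img,
                                  _derive_seed(cfg.seed, epoch, step, 0),
                                  **aug_kw).pixels
                ct_aug = augment(ct_img,
                                 _derive_seed(cfg.seed, epoch, step, 1),
                                 **aug_kw).pixels
                gen_rep, dis_rep = train_step(
                    model, mri_aug, ct_aug,
                    _derive_seed(cfg.seed, epoch, step, 2))
                for name, val in {**gen_rep.components, "total": gen_rep.total,
                                  **{f"dis_{k}": v for k, v
                                     in dis_rep.components.items()},
                                  "dis_total": dis_rep.total}.items():
                    log.write(f"{epoch}\t{step}\t{cfg.model_kind}\t{lr:.8g}\t"
                              f"{name}\t{val:.10g}\n")
            if cfg.checkpoint_every and epoch % cfg.checkpoint_every == 0:
                save_checkpoint(os.path.join(out_dir, f"checkpoint_ep{epoch:04d}.npz"),
                                model, epoch)
        save_checkpoint(os.path.join(out_dir, "checkpoint_final.npz"),
                        model, cfg.epochs)
    return model


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def translate(model: TranslationModel, mri: MRVolume) -> HUVolume:
    """Translate an MRI volume to synthetic CT in Hounsfield Units.

    Each axial slice is normalised with the volume's own bounds, padded to
    the generator's divisibility requirement (background fill -1), run
    through the MRI->CT generator, cropped back and mapped to HU with the
    fixed CT window.  Outside the body mask the sCT is exactly -1024 HU.
    """
    gen = model.gen_a
    div = 2 ** gen.spec.n_downsamples
    vox = mri.voxels
    lo, hi = float(vox.min()), float(vox.max())
    if not hi > lo:
        raise ValueError("constant MRI volume cannot be translated")
    nz, ny, nx = vox.shape
    py = (-ny) % div
    px = (-nx) % div
    out = np.full(vox.shape, AIR_HU)
    ct_lo, ct_hi = CT_BOUNDS
    for z in range(nz):
        if mri.body_mask is not None and not mri.body_mask[z].any():
            continue
        norm = 2.0 * (vox[z] - lo) / (hi - lo) - 1.0
        padded = np.pad(norm, ((0, py), (0, px)), mode="constant",
                        constant_values=-1.0)
        pred = gen(Tensor(padded[None, None])).data[0, 0]
        pred = pred[:ny, :nx]
        out[z] = np.clip(0.5 * (pred + 1.0) * (ct_hi - ct_lo) + ct_lo,
                         ct_lo, ct_hi)
    if mri.body_mask is not None:
        out[~mri.body_mask] = AIR_HU
        return HUVolume(out, mri.spacing, mri.body_mask)
    return HUVolume(out, mri.spacing, None)
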