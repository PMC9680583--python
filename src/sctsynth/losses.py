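"""Loss terms and model objectives for the three translation frameworks.

Every term is a pure function usable two ways: fed plain numpy arrays it
returns a float (as the unit tests do), fed autodiff ``Tensor`` objects it
returns a ``Tensor`` on the training tape.  The three composite objectives
are

* cycleGAN:  L = L_adv_A + L_adv_B + alpha * (L_cycle_MRI + L_cycle_CT)
  + beta * (L_identity_CT + L_identity_MRI)
* CUT:       L = L_adv_A + lambda1 * PatchNCE(MRI, sCT)
  + lambda2 * PatchNCE(CT, G(CT))        (the identity NCE term)
* cycleCUT:  the cycleGAN objective plus four PatchNCE terms weighted by
  eta1..eta4, one per generator application in the two cycles.

Adversarial terms are least-squares (LSGAN) on sigmoid patch scores; the
PatchNCE term is a temperature-scaled cross-entropy that pulls an output
patch toward the input patch at the same location against all other
locations of the same image ("internal" negatives).
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np

from .nn.autodiff import Tensor, as_tensor
from .nn.ops import cross_entropy_diag
from .nn.networks import FeatureStack

__all__ = [
    "LossWeights", "GeneratorLossReport", "DiscriminatorLossReport",
    "lsgan_gen_loss", "lsgan_dis_loss", "l1_mean", "nce_cross_entropy",
    "patchnce_loss", "cyclegan_generator_objective", "cut_generator_objective",
    "cyclecut_generator_objective", "discriminator_objective",
]


@dataclass(frozen=True)
class LossWeights:
    """Objective weights; defaults are the standard values for this family:
    cycle weight alpha = 10, identity weight beta = 5, unit NCE weights and
    contrastive temperature tau = 0.07."""
    alpha: float = 10.0
    beta: float = 5.0
    lambda1: float = 1.0
    lambda2: float = 1.0
    eta1: float = 1.0
    eta2: float = 1.0
    eta3: float = 1.0
    eta4: float = 1.0
    tau: float = 0.07

    def __post_init__(self):
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be non-negative")
        if self.tau <= 0:
            raise ValueError("tau must be positive")


@dataclass
class GeneratorLossReport:
    total: object                 # float or Tensor
    components: dict              # name -> float or Tensor

    def as_floats(self) -> dict:
        out = {k: _val(v) for k, v in self.components.items()}
        out["total"] = _val(self.total)
        return out


@dataclass
class DiscriminatorLossReport:
    total: object
    components: dict

    def as_floats(self) -> dict:
        out = {k: _val(v) for k, v in self.components.items()}
        out["total"] = _val(self.total)
        return out


def _val(x) -> float:
    return x.item() if isinstance(x, Tensor) else float(x)


def _mean_sq(t: Tensor) -> Tensor:
    return (t * t).mean()


def _as_score_tensor(scores) -> Tensor:
    """Accept a score map, a list of score maps, or a Tensor."""
    if isinstance(scores, Tensor):
        return scores
    if isinstance(scores, (list, tuple)):
        if len(scores) == 0:
            raise ValueError("empty score input")
        arr = np.concatenate([np.ravel(np.asarray(s, dtype=float)) for s in scores])
    else:
        arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("empty score input")
    return Tensor(arr)


def lsgan_gen_loss(d_scores):
    """Least-squares generator loss: mean of (1 - D(G(x)))^2 over items and
    patch locations."""
    was_plain = not isinstance(d_scores, Tensor)
    s = _as_score_tensor(d_scores)
    out = _mean_sq(1.0 - s)
    return out.item() if was_plain else out


def lsgan_dis_loss(d_real, d_fake):
    """Least-squares discriminator loss: mean of
    [(1 - D(real))^2 + D(fake)^2] / 2."""
    was_plain = not (isinstance(d_real, Tensor) or isinstance(d_fake, Tensor))
    r = _as_score_tensor(d_real)
    f = _as_score_tensor(d_fake)
    out = (_mean_sq(1.0 - r) + _mean_sq(f)) * 0.5
    return out.item() if was_plain else out


def l1_mean(a, b):
    """Mean absolute elementwise difference (cycle and identity losses)."""
    was_plain = not (isinstance(a, Tensor) or isinstance(b, Tensor))
    ta, tb = as_tensor(a), as_tensor(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    out = (ta - tb).abs().mean()
    return out.item() if was_plain else out


def nce_cross_entropy(pos_sim: float, neg_sims, tau: float) -> float:
    """Temperature-scaled contrastive cross-entropy for one query patch:

        -log[ exp(pos/tau) / (exp(pos/tau) + sum_n exp(neg_n/tau)) ]

    evaluated with a log-sum-exp guard so similarities at the extremes of
    [-1, 1] with tau = 0.07 stay finite.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    logits = np.concatenate([[pos_sim], np.ravel(neg_sims)]) / tau
    m = logits.max()
    lse = m + np.log(np.exp(logits - m).sum())
    return float(lse - logits[0])


def d_nce_cross_entropy_dpos(pos_sim: float, neg_sims, tau: float) -> float:
    """Analytic derivative of :func:`nce_cross_entropy` w.r.t. ``pos_sim``:
    (softmax weight of the positive - 1) / tau."""
    logits = np.concatenate([[pos_sim], np.ravel(neg_sims)]) / tau
    m = logits.max()
    p = np.exp(logits - m)
    return float((p[0] / p.sum() - 1.0) / tau)


def patchnce_loss(stack_in: FeatureStack, stack_out: FeatureStack, tau: float,
                  reduction: str = "mean_locations"):
    """Patchwise contrastive loss between an input and an output feature stack.

    For each layer l and sampled location s the positive similarity is
    zhat_l^s . z_l^s and the negatives are zhat_l^s . z_l^n for every other
    sampled location n of the same layer of the same image.  The per-layer
    value is the mean cross-entropy over locations ("mean_locations", the
    default, which keeps the magnitude independent of the patch count) or
    the raw sum over locations ("sum_locations"); layers are summed.

    The two stacks must carry identical location-index records — a silent
    misalignment would corrupt training.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    if reduction not in ("mean_locations", "sum_locations"):
        raise ValueError(f"unknown reduction {reduction!r}")
    if stack_in.layer_ids() != stack_out.layer_ids():
        raise ValueError("feature stacks have different layer ids")
    plain = True
    total = None
    for lid in stack_in.layer_ids():
        loc_in = np.asarray(stack_in.locations[lid])
        loc_out = np.asarray(stack_out.locations[lid])
        if not np.array_equal(loc_in, loc_out):
            raise ValueError(f"location records differ at layer {lid}")
        z = stack_in.features[lid]
        zhat = stack_out.features[lid]
        plain = plain and not (isinstance(z, Tensor) or isinstance(zhat, Tensor))
        z, zhat = as_tensor(z), as_tensor(zhat)
        if z.shape != zhat.shape:
            raise ValueError(f"feature dimensions differ at layer {lid}")
        logits = (zhat @ z.T) * (1.0 / tau)
        term = cross_entropy_diag(logits)
        if reduction == "sum_locations":
            term = term * float(z.shape[0])
        total = term if total is None else total + term
    if total is None:
        raise ValueError("empty feature stacks")
    return total.item() if plain else total


def _require(parts: dict, keys, model: str) -> None:
    missing = [k for k in keys if k not in parts]
    if missing:
        raise KeyError(f"{model} objective missing components: {missing}")


_CYCLEGAN_KEYS = ("adversarial_a", "adversarial_b", "cycle_mri", "cycle_ct",
                  "identity_ct", "identity_mri")


def cyclegan_generator_objective(parts: dict, w: LossWeights) -> GeneratorLossReport:
    _require(parts, _CYCLEGAN_KEYS, "cycleGAN")
    total = (parts["adversarial_a"] + parts["adversarial_b"]
             + w.alpha * (parts["cycle_mri"] + parts["cycle_ct"])
             + w.beta * (parts["identity_ct"] + parts["identity_mri"]))
    return GeneratorLossReport(total=total,
                               components={k: parts[k] for k in _CYCLEGAN_KEYS})


def cut_generator_objective(parts: dict, w: LossWeights) -> GeneratorLossReport:
    keys = ("adversarial_a", "nce_1", "nce_2")
    _require(parts, keys, "CUT")
    total = (parts["adversarial_a"] + w.lambda1 * parts["nce_1"]
             + w.lambda2 * parts["nce_2"])
    return GeneratorLossReport(total=total,
                               components={k: parts[k] for k in keys})


def cyclecut_generator_objective(parts: dict, w: LossWeights) -> GeneratorLossReport:
    keys = _CYCLEGAN_KEYS + ("nce_1", "nce_2", "nce_3", "nce_4")
    _require(parts, keys, "cycleCUT")
    base = cyclegan_generator_objective(parts, w)
    total = (base.total + w.eta1 * parts["nce_1"] + w.eta2 * parts["nce_2"]
             + w.eta3 * parts["nce_3"] + w.eta4 * parts["nce_4"])
    return GeneratorLossReport(total=total,
                               components={k: parts[k] for k in keys})


def discriminator_objective(model_kind: str, parts: dict) -> DiscriminatorLossReport:
    """Sum of the LSGAN discriminator terms present for the model kind:
    one discriminator for CUT, two for cycleGAN and cycleCUT."""
    expected = {"cut": ("d_a",), "cyclegan": ("d_a", "d_b"),
                "cyclecut": ("d_a", "d_b")}
    if model_kind not in expected:
        raise ValueError(f"unknown model kind {model_kind!r}")
    keys = expected[model_kind]
    _require(parts, keys, model_kind)
    extra = set(parts) - set(keys)
    if extra:
        raise KeyError(f"{model_kind} discriminator got unexpected components: "
                       f"{sorted(extra)}")
    total = parts[keys[0]]
    for k in keys[1:]:
        total = total + parts[k]
    return DiscriminatorLossReport(total=total,
                                   components={k: parts[k] for k in keys})
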