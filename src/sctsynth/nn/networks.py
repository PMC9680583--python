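"""Generator, discriminator and projection-head architectures.

The generator is the resnet encoder–decoder used across this translation
family: a wide 7x7 input convolution, ``n_downsamples`` stride-2
convolutions, a stack of residual blocks (the encoder tail), then a
mirrored decoder ending in a tanh so outputs live in (-1, 1).  The encoder
half doubles as the feature extractor for patchwise contrastive learning:
layer 0 is the input image itself, deeper layers are the activations after
each encoder block.

The discriminator is a patch classifier: three stride-2 convolutions
followed by a 1-channel convolution and a sigmoid, so it emits a grid of
per-patch realness scores in (0, 1).

Decoder upsampling uses nearest-neighbour resize + 3x3 convolution rather
than transposed convolution; resize-conv avoids checkerboard artifacts and
has a simpler exact adjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor
from . import ops
from .layers import Conv2d, InstanceNorm2d, MLPHead, Module

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "ProjectionHeadSpec",
    "ResnetGenerator", "PatchDiscriminator", "ProjectionHeads",
    "FeatureStack", "sample_patch_locations", "encoder_features",
    "project_features",
]


@dataclass(frozen=True)
class GeneratorSpec:
    in_channels: int = 1
    out_channels: int = 1
    base_filters: int = 64
    n_res_blocks: int = 9
    n_downsamples: int = 2
    feature_layer_ids: tuple = ()   # empty -> default set

    def __post_init__(self):
        if self.n_downsamples < 1:
            raise ValueError("n_downsamples must be >= 1")
        ids = self.resolved_feature_layers()
        if list(ids) != sorted(set(ids)):
            raise ValueError("feature_layer_ids must be strictly increasing")
        if ids and ids[-1] > self.n_encoder_layers():
            raise ValueError(
                f"feature layer id {ids[-1]} exceeds last encoder layer "
                f"{self.n_encoder_layers()}")

    def n_encoder_layers(self) -> int:
        """Index of the deepest encoder layer (input image is layer 0)."""
        return 1 + self.n_downsamples + self.n_res_blocks

    def resolved_feature_layers(self) -> tuple:
        if self.feature_layer_ids:
            return tuple(self.feature_layer_ids)
        mid_res = 1 + self.n_downsamples + (self.n_res_blocks + 1) // 2
        ids = list(range(1 + self.n_downsamples + 1)) + [mid_res]
        return tuple(sorted(set(ids)))

    def layer_channels(self, layer_id: int) -> int:
        if layer_id == 0:
            return self.in_channels
        if layer_id == 1:
            return self.base_filters
        d = min(layer_id - 1, self.n_downsamples)
        return self.base_filters * 2 ** d


@dataclass(frozen=True)
class DiscriminatorSpec:
    in_channels: int = 1
    base_filters: int = 64
    n_layers: int = 3   # stride-2 downsampling convolutions


@dataclass(frozen=True)
class ProjectionHeadSpec:
    hidden_dim: int = 256
    out_dim: int = 256


class _ResBlock(Module):
    def __init__(self, ch: int, *, rng):
        self.conv1 = Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng)
        self.norm1 = InstanceNorm2d(ch)
        self.conv2 = Conv2d(ch, ch, 3, pad=1, pad_mode="reflect", rng=rng)
        self.norm2 = InstanceNorm2d(ch)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.norm1(self.conv1(x)).relu()
        h = self.norm2(self.conv2(h))
        return x + h


class _UpBlock(Module):
    def __init__(self, in_ch: int, out_ch: int, *, rng):
        self.conv = Conv2d(in_ch, out_ch, 3, pad=1, pad_mode="reflect", rng=rng)
        self.norm = InstanceNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(ops.upsample_nearest2x(x))).relu()


class ResnetGenerator(Module):
    def __init__(self, spec: GeneratorSpec, *, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        self.in_conv = Conv2d(spec.in_channels, f, 7, pad=3,
                              pad_mode="reflect", rng=rng)
        self.in_norm = InstanceNorm2d(f)
        downs = []
        ch = f
        for _ in range(spec.n_downsamples):
            downs.append(Conv2d(ch, ch * 2, 3, stride=2, pad=1, rng=rng))
            downs.append(InstanceNorm2d(ch * 2))
            ch *= 2
        self.downs = downs
        self.res_blocks = [_ResBlock(ch, rng=rng) for _ in range(spec.n_res_blocks)]
        ups = []
        for _ in range(spec.n_downsamples):
            ups.append(_UpBlock(ch, ch // 2, rng=rng))
            ch //= 2
        self.ups = ups
        self.out_conv = Conv2d(ch, spec.out_channels, 7, pad=3,
                               pad_mode="reflect", rng=rng)

    def _check_size(self, x: Tensor) -> None:
        div = 2 ** self.spec.n_downsamples
        h, w = x.shape[2], x.shape[3]
        if h % div or w % div:
            raise ValueError(
                f"input {h}x{w} not divisible by {div}; pad to "
                f"{-(-h // div) * div}x{-(-w // div) * div}")

    def encode(self, x: Tensor, capture: tuple = ()) -> tuple:
        """Run the encoder; returns (deepest activation, captured feature maps)."""
        self._check_size(x)
        feats = {}
        layer_id = 0
        if layer_id in capture:
            feats[layer_id] = x
        h = self.in_norm(self.in_conv(x)).relu()
        layer_id += 1
        if layer_id in capture:
            feats[layer_id] = h
        for i in range(0, len(self.downs), 2):
            h = self.downs[i + 1](self.downs[i](h)).relu()
            layer_id += 1
            if layer_id in capture:
                feats[layer_id] = h
        for block in self.res_blocks:
            h = block(h)
            layer_id += 1
            if layer_id in capture:
                feats[layer_id] = h
        return h, feats

    def decode(self, h: Tensor) -> Tensor:
        for up in self.ups:
            h = up(h)
        return self.out_conv(h).tanh()

    def __call__(self, x: Tensor, capture: tuple = ()):
        h, feats = self.encode(x, capture)
        out = self.decode(h)
        if capture:
            return out, feats
        return out


class PatchDiscriminator(Module):
    def __init__(self, spec: DiscriminatorSpec, *, rng: np.random.Generator):
        self.spec = spec
        f = spec.base_filters
        layers = [Conv2d(spec.in_channels, f, 4, stride=2, pad=1, rng=rng)]
        ch = f
        for _ in range(spec.n_layers - 1):
            layers.append(Conv2d(ch, ch * 2, 4, stride=2, pad=1, rng=rng))
            layers.append(InstanceNorm2d(ch * 2))
            ch *= 2
        self.layers = layers
        self.out_conv = Conv2d(ch, 1, 3, pad=1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.layers[0](x).leaky_relu(0.2)
        i = 1
        while i < len(self.layers):
            h = self.layers[i + 1](self.layers[i](h)).leaky_relu(0.2)
            i += 2
        return self.out_conv(h).sigmoid()


class ProjectionHeads(Module):
    """One independent two-layer MLP head per selected encoder layer."""

    def __init__(self, gen_spec: GeneratorSpec, head_spec: ProjectionHeadSpec,
                 *, rng: np.random.Generator):
        self.layer_ids = gen_spec.resolved_feature_layers()
        self.heads = [
            MLPHead(gen_spec.layer_channels(lid), head_spec.hidden_dim,
                    head_spec.out_dim, rng=rng)
            for lid in self.layer_ids
        ]

    def head_for(self, layer_id: int) -> MLPHead:
        return self.heads[self.layer_ids.index(layer_id)]


@dataclass
class FeatureStack:
    """Projected, unit-norm feature vectors at sampled spatial locations,
    keyed by encoder layer id, with the location record used to draw them."""
    features: dict   # layer_id -> (S, D) Tensor
    locations: dict  # layer_id -> int array of flat spatial indices

    def layer_ids(self):
        return tuple(sorted(self.features))


def sample_patch_locations(feature_maps: dict, n_patches: int, seed: int) -> dict:
    """Uniform sample (without replacement) of flat spatial indices per layer.

    The returned record must be reused for the paired input/output stacks so
    positives align by construction.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    rng = np.random.default_rng(seed)
    record = {}
    for lid in sorted(feature_maps):
        fmap = feature_maps[lid]
        total = fmap.shape[2] * fmap.shape[3]
        record[lid] = rng.choice(total, size=min(n_patches, total), replace=False)
    return record


def encoder_features(gen: ResnetGenerator, image: Tensor, layer_ids) -> dict:
    """Raw activation grids of the requested encoder layers (0 = the input)."""
    layer_ids = tuple(layer_ids)
    for lid in layer_ids:
        if lid < 0 or lid > gen.spec.n_encoder_layers():
            raise ValueError(f"invalid encoder layer id {lid}")
    _, feats = gen.encode(image, capture=layer_ids)
    return feats


def project_features(heads: ProjectionHeads, feature_maps: dict,
                     locations: dict) -> FeatureStack:
    features = {}
    for lid, fmap in feature_maps.items():
        gathered = ops.gather_locations(fmap, locations[lid])
        features[lid] = heads.head_for(lid)(gathered)
    return FeatureStack(features=features,
                        locations={k: np.asarray(v) for k, v in locations.items()})
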