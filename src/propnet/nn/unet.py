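"""The progressive multi-resolution registration U-net.

A standard 3D U-net with two extensions that enable progressive training:

* *input heads*: at every resolution level the 2-channel input pair is
  average-pooled to that level's grid and passed through one convolution
  matching the level's feature count; a summation node adds it to the pooled
  features from the level above, so coarse levels see the images even while
  the finer levels are still inactive;
* *output heads*: every decoder level (and the bottleneck) ends in a
  1x1x1 convolution to the three displacement components, zero-initialized so
  the untrained network predicts the identity transform.  Heads are resized
  trilinearly to the full-resolution grid and combined by a weighted sum
  whose weights follow the progressive schedule.

Displacements are expressed in full-resolution voxel units at every head.
Encoder/decoder blocks are two 3x3x3 convolutions with batch normalization
and ReLU; downsampling is 2x max pooling, decoder upsampling is trilinear
followed by concatenation with the skip connection.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from propnet.errors import ConfigError, InputError
from propnet.nn import autodiff as ad


@dataclass
class UNetConfig:
    levels: int = 5
    input_size: tuple[int, int, int] = (128, 128, 128)
    base_features: int = 32
    feature_cap: int = 256
    input_channels: int = 2
    output_channels: int = 3
    conv_kernel: int = 3
    bn_ema_decay: float = 0.99

    def __post_init__(self):
        self.input_size = tuple(int(n) for n in np.broadcast_to(self.input_size, (3,)))
        if self.levels < 2:
            raise ConfigError("need >= 2 resolution levels")
        div = 2 ** (self.levels - 1)
        if any(n % div for n in self.input_size):
            raise ConfigError(
                f"input size {self.input_size} not divisible by 2^(levels-1)={div}"
            )

    def features(self, level: int) -> int:
        """Feature count at resolution level (0 = finest)."""
        return min(self.base_features * 2**level, self.feature_cap)


def init_params(cfg: UNetConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    """He-initialized weights; output heads and all biases start at zero."""
    params: dict[str, np.ndarray] = {}

    def conv(name, k, cin, cout, zero=False):
        if zero:
            w = np.zeros((k, k, k, cin, cout), dtype=np.float32)
        else:
            std = np.sqrt(2.0 / (k**3 * cin))
            w = rng.normal(0.0, std, size=(k, k, k, cin, cout)).astype(np.float32)
        params[f"{name}.w"] = w
        params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)

    def bn(name, c):
        params[f"{name}.gamma"] = np.ones(c, dtype=np.float32)
        params[f"{name}.beta"] = np.zeros(c, dtype=np.float32)

    k = cfg.conv_kernel
    for lvl in range(cfg.levels):
        f = cfg.features(lvl)
        cin = cfg.input_channels if lvl == 0 else cfg.features(lvl - 1)
        conv(f"enc{lvl}.conv1", k, cin, f)
        bn(f"enc{lvl}.bn1", f)
        conv(f"enc{lvl}.conv2", k, f, f)
        bn(f"enc{lvl}.bn2", f)
        if lvl > 0:
            conv(f"inhead{lvl}", k, cfg.input_channels, cin)
    for lvl in range(cfg.levels - 1):
        f = cfg.features(lvl)
        cin = cfg.features(lvl + 1) + f  # upsampled + skip
        conv(f"dec{lvl}.conv1", k, cin, f)
        bn(f"dec{lvl}.bn1", f)
        conv(f"dec{lvl}.conv2", k, f, f)
        bn(f"dec{lvl}.bn2", f)
    for lvl in range(cfg.levels):
        conv(f"outhead{lvl}", 1, cfg.features(lvl), cfg.output_channels, zero=True)
    return params


def init_bn_stats(params: dict[str, np.ndarray]) -> dict[str, ad.BNStat]:
    return {
        name[: -len(".gamma")]: ad.BNStat(arr.shape[0])
        for name, arr in params.items()
        if name.endswith(".gamma")
    }


def forward_graph(cfg: UNetConfig, params: dict[str, ad.Tensor],
                  bn_stats: dict[str, ad.BNStat], x: np.ndarray,
                  alphas, training: bool) -> ad.Tensor:
    """Build the forward graph; returns the full-resolution field tensor.

    ``x`` is the ``(D, H, W, 2)`` image pair, ``alphas`` the per-level output
    weights ordered coarsest -> finest.
    """
    if x.shape != cfg.input_size + (cfg.input_channels,):
        raise InputError(
            f"input shape {x.shape} does not match configured "
            f"{cfg.input_size + (cfg.input_channels,)}"
        )
    alphas = np.asarray(alphas, dtype=np.float64)
    if alphas.shape != (cfg.levels,):
        raise InputError(f"need {cfg.levels} level weights, got {alphas.shape}")

    p = params
    decay = cfg.bn_ema_decay

    def block(prefix, h):
        h = ad.conv3d(h, p[f"{prefix}.conv1.w"], p[f"{prefix}.conv1.b"])
        h = ad.batchnorm(h, p[f"{prefix}.bn1.gamma"], p[f"{prefix}.bn1.beta"],
                         bn_stats[f"{prefix}.bn1"], training, decay)
        h = ad.relu(h)
        h = ad.conv3d(h, p[f"{prefix}.conv2.w"], p[f"{prefix}.conv2.b"])
        h = ad.batchnorm(h, p[f"{prefix}.bn2.gamma"], p[f"{prefix}.bn2.beta"],
                         bn_stats[f"{prefix}.bn2"], training, decay)
        return ad.relu(h)

    xt = ad.Tensor(x.astype(np.float32))
    pooled_inputs = [xt]
    for _ in range(cfg.levels - 1):
        pooled_inputs.append(ad.avgpool2(pooled_inputs[-1]))

    skips = []
    h = block("enc0", xt)
    skips.append(h)
    for lvl in range(1, cfg.levels):
        down = ad.maxpool2(h)
        head = ad.conv3d(pooled_inputs[lvl], p[f"inhead{lvl}.w"], p[f"inhead{lvl}.b"])
        h = block(f"enc{lvl}", ad.add(down, head))
        skips.append(h)

    heads: list[ad.Tensor] = [None] * cfg.levels
    heads[cfg.levels - 1] = ad.conv3d(
        h, p[f"outhead{cfg.levels - 1}.w"], p[f"outhead{cfg.levels - 1}.b"]
    )
    g = h
    for lvl in range(cfg.levels - 2, -1, -1):
        target = tuple(n // 2**lvl for n in cfg.input_size)
        g = ad.resize_linear(g, target)
        g = ad.concat(g, skips[lvl])
        g = block(f"dec{lvl}", g)
        heads[lvl] = ad.conv3d(g, p[f"outhead{lvl}.w"], p[f"outhead{lvl}.b"])

    full = [
        ad.resize_linear(heads[lvl], cfg.input_size)
        if heads[lvl].data.shape[:3] != cfg.input_size else heads[lvl]
        for lvl in range(cfg.levels)
    ]
    # alphas are coarsest-first; heads list is finest-first
    return ad.weighted_sum(full, list(alphas[::-1]))
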