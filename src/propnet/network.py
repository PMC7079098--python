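"""Progressive training schedule, losses, training loop, and propagation.

The registration network maps a (moving, fixed) image pair to a dense
displacement field on the fixed grid; a spatial transformer then pulls the
moving (pretreatment) CTV mask through the field.  Training is supervised by
any convex combination of

* an *overlap* term — one minus the soft Dice between the warped moving mask
  and the target mask, and
* a *deformation* term — the mean squared 3-vector error between the
  predicted and true displacement fields,

with the three study presets (1,0) overlap, (0,1) deformation, (1,1) hybrid.

Resolution levels are activated coarse-to-fine: the coarsest output head
carries all the weight for N iterations, then linearly hands over to the
next level across M iterations, after which the grown network trains for 2N
iterations before the next hand-over, and so on.  With 5 levels, N=1000 and
M=2000 the schedule completes exactly at iteration 15000.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Iterator, Optional

import numpy as np
from scipy import ndimage

from propnet.errors import (
    ConfigError,
    InputError,
    ShapeError,
    TrainingDivergenceError,
)
from propnet.nn import autodiff as ad
from propnet.nn.unet import UNetConfig, forward_graph, init_bn_stats, init_params
from propnet.phantom import TrainingSample
from propnet.transforms import DisplacementField, _grid_points
from propnet.volume import Volume3D

__all__ = [
    "UNetConfig",
    "ProgressiveSchedule",
    "LossWeights",
    "OptimizerSettings",
    "ModelState",
    "level_weights",
    "forward",
    "stl_warp",
    "overlap_loss",
    "dvf_loss",
    "total_loss",
    "train",
    "propagate",
]


@dataclass
class ProgressiveSchedule:
    """Coarse-to-fine activation timeline.

    ``N`` iterations on the coarsest level, ``M``-iteration linear ramps
    between adjacent levels, ``plateau_multiplier * N`` iterations on each
    intermediate plateau.
    """

    N: int = 1000
    M: int = 2000
    plateau_multiplier: int = 2

    def __post_init__(self):
        if self.N < 1 or self.M < 1:
            raise ConfigError("schedule lengths must be >= 1")

    def total_length(self, levels: int) -> int:
        """Iteration index at which the finest level first holds weight 1."""
        return self.N + self.M + (levels - 2) * (self.plateau_multiplier * self.N + self.M)


@dataclass
class LossWeights:
    """Weights of the overlap and deformation terms, each in [0, 1]."""

    k_overlap: float = 1.0
    k_dvf: float = 1.0

    def __post_init__(self):
        if self.k_overlap == 0 and self.k_dvf == 0:
            raise ConfigError("at least one loss weight must be nonzero")
        if not (0 <= self.k_overlap <= 1 and 0 <= self.k_dvf <= 1):
            raise ConfigError("loss weights must lie in [0, 1]")

    PRESETS = {
        "overlap": (1.0, 0.0),
        "deformation": (0.0, 1.0),
        "hybrid": (1.0, 1.0),
    }

    @classmethod
    def from_preset(cls, name: str) -> "LossWeights":
        try:
            ko, kd = cls.PRESETS[name]
        except KeyError:
            raise ConfigError(
                f"unknown loss preset {name!r}; choose from {sorted(cls.PRESETS)}"
            ) from None
        return cls(k_overlap=ko, k_dvf=kd)


@dataclass
class OptimizerSettings:
    """Plain SGD with momentum; no weight decay, no learning-rate schedule."""

    learning_rate: float = 0.01
    momentum: float = 0.5


@dataclass
class ModelState:
    """Everything needed to reproduce the network's forward pass."""

    config: UNetConfig
    params: dict
    bn_stats: dict
    iteration: int = 0
    alphas: Optional[np.ndarray] = None  # level weights used at inference
    loss_log: list = dc_field(default_factory=list)

    @classmethod
    def initialize(cls, config: UNetConfig, rng: np.random.Generator) -> "ModelState":
        params = init_params(config, rng)
        return cls(config=config, params=params, bn_stats=init_bn_stats(params))

    def inference_alphas(self) -> np.ndarray:
        if self.alphas is not None:
            return np.asarray(self.alphas, dtype=np.float64)
        a = np.zeros(self.config.levels)
        a[-1] = 1.0
        return a

    # -- checkpointing ------------------------------------------------------
    def save(self, path) -> None:
        cfg = {
            k: getattr(self.config, k)
            for k in ("levels", "input_size", "base_features", "feature_cap",
                      "input_channels", "output_channels", "conv_kernel",
                      "bn_ema_decay")
        }
        arrays = {f"param/{k}": v for k, v in self.params.items()}
        for name, st in self.bn_stats.items():
            arrays[f"bn/{name}/mean"] = st.mean
            arrays[f"bn/{name}/var"] = st.var
            arrays[f"bn/{name}/init"] = np.asarray(st.initialized)
        arrays["meta/iteration"] = np.asarray(self.iteration)
        arrays["meta/alphas"] = self.inference_alphas()
        arrays["meta/config"] = np.frombuffer(
            json.dumps(cfg).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "ModelState":
        with np.load(path) as z:
            cfg = json.loads(bytes(z["meta/config"].tobytes()).decode())
            cfg["input_size"] = tuple(cfg["input_size"])
            config = UNetConfig(**cfg)
            params = {
                k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")
            }
            bn_stats = init_bn_stats(params)
            for name, st in bn_stats.items():
                st.mean = z[f"bn/{name}/mean"]
                st.var = z[f"bn/{name}/var"]
                st.initialized = bool(z[f"bn/{name}/init"])
            return cls(
                config=config, params=params, bn_stats=bn_stats,
                iteration=int(z["meta/iteration"]),
                alphas=np.asarray(z["meta/alphas"]),
            )


# ---------------------------------------------------------------------------
# Progressive level weights
# ---------------------------------------------------------------------------

def level_weights(s: ProgressiveSchedule, iteration: int, levels: int) -> np.ndarray:
    """Per-level output weights (coarsest -> finest) at a training step.

    Nonnegative, summing to one, piecewise linear in the iteration with at
    most two adjacent nonzero entries; once the schedule has run out, all
    weight sits on the finest level.
    """
    if iteration < 0:
        raise ConfigError("iteration must be >= 0")
    w = np.zeros(levels)
    t = iteration
    for k in range(levels - 1):
        plateau = s.N if k == 0 else s.plateau_multiplier * s.N
        if t < plateau:
            w[k] = 1.0
            return w
        t -= plateau
        if t < s.M:
            frac = t / s.M
            w[k] = 1.0 - frac
            w[k + 1] = frac
            return w
        t -= s.M
    w[levels - 1] = 1.0
    return w


# ---------------------------------------------------------------------------
# Losses (plain-number forms)
# ---------------------------------------------------------------------------

def overlap_loss(pred: np.ndarray, truth: np.ndarray, eps: float = 1e-5) -> float:
    """One minus the (soft) Dice overlap of a [0,1] prediction and a mask."""
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ShapeError("overlap operands must share the grid")
    if pred.min() < 0 or pred.max() > 1 or truth.min() < 0 or truth.max() > 1:
        raise InputError("overlap operands must have values in [0, 1]")
    inter = float((pred * truth).sum())
    denom = float(pred.sum() + truth.sum()) + eps
    return 1.0 - 2.0 * inter / denom


def _field_array(f) -> np.ndarray:
    return f.u if isinstance(f, DisplacementField) else np.asarray(f, dtype=np.float64)


def dvf_loss(pred, truth) -> float:
    """Mean over voxels of the squared 3-vector displacement difference."""
    p, t = _field_array(pred), _field_array(truth)
    if p.shape != t.shape:
        raise ShapeError("field operands must share the grid")
    diff = p - t
    return float((diff * diff).sum()) / (diff.size // 3)


def total_loss(w: LossWeights, overlap: float, dvf: float) -> float:
    return w.k_overlap * overlap + w.k_dvf * dvf


# ---------------------------------------------------------------------------
# Forward pass, spatial transformer
# ---------------------------------------------------------------------------

def _image_array(v) -> np.ndarray:
    return v.data if isinstance(v, Volume3D) else np.asarray(v)


def forward(state: ModelState, moving, fixed, alphas=None) -> DisplacementField:
    """Inference forward pass: image pair -> dense field in voxel units.

    Deterministic: uses the exponential-moving-average normalization
    statistics and (by default) the model's stored level weights.
    """
    m, f = _image_array(moving), _image_array(fixed)
    for arr in (m, f):
        if arr.shape != state.config.input_size:
            raise InputError(
                f"image shape {arr.shape} != configured {state.config.input_size}"
            )
        if arr.min() < 0 or arr.max() > 1:
            raise InputError("network inputs must be normalized to [0, 1]")
    if alphas is None:
        alphas = state.inference_alphas()
    x = np.stack([m, f], axis=-1).astype(np.float32)
    params_t = {k: ad.Tensor(v) for k, v in state.params.items()}
    with ad.no_grad():
        out = forward_graph(state.config, params_t, state.bn_stats, x,
                            alphas, training=False)
    u = out.data.astype(np.float64).transpose(3, 0, 1, 2)
    return DisplacementField(u)


def stl_warp(mask_or_probs: np.ndarray, field: DisplacementField,
             mode: str = "infer") -> np.ndarray:
    """Spatial-transformer warp of a mask (or soft probability map).

    ``infer`` uses nearest-neighbor sampling (binary in, binary out),
    ``train`` uses trilinear sampling so the warp is differentiable in the
    field.  Both follow the pull convention with zero outside the grid.
    """
    m = np.asarray(mask_or_probs, dtype=np.float64)
    if m.shape != field.grid_size:
        raise ShapeError("mask grid does not match the field grid")
    if mode == "infer":
        pts = _grid_points(m.shape) + field.u
        return ndimage.map_coordinates(m, pts, order=0, mode="grid-constant",
                                       cval=0.0)
    if mode == "train":
        ft = ad.Tensor(field.u.transpose(1, 2, 3, 0))
        with ad.no_grad():
            return ad.warp_trilinear(m, ft).data
    raise ConfigError(f"unknown stl_warp mode {mode!r}")


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def train(state: ModelState, data: Iterable[TrainingSample],
          schedule: ProgressiveSchedule, weights: LossWeights,
          opt: OptimizerSettings = OptimizerSettings(),
          iterations: int = 0,
          log_every: int = 1) -> ModelState:
    """Stochastic gradient descent with momentum over a training-sample stream.

    Batch size is one; per-iteration level weights come from the progressive
    schedule; normalization statistics are tracked as exponential moving
    averages for inference.  Appends ``(iteration, total, overlap, dvf)``
    rows to ``state.loss_log`` and returns the (mutated) state.

    Raises :class:`TrainingDivergenceError` carrying the last finite state if
    the loss becomes non-finite.
    """
    if iterations == 0:
        return state
    cfg = state.config
    params_t = {k: ad.Tensor(v.copy(), requires_grad=True)
                for k, v in state.params.items()}
    velocity = {k: np.zeros_like(v) for k, v in state.params.items()}
    it_stream: Iterator[TrainingSample] = iter(data)

    last_alphas = state.inference_alphas()
    for step in range(state.iteration, state.iteration + iterations):
        sample = next(it_stream)
        alphas = level_weights(schedule, step, cfg.levels)
        last_alphas = alphas
        x = np.stack(
            [sample.moving_image.data, sample.fixed_image.data], axis=-1
        ).astype(np.float32)
        field_t = forward_graph(cfg, params_t, state.bn_stats, x, alphas,
                                training=True)
        terms, ws = [], []
        lo = ld = 0.0
        if weights.k_overlap > 0:
            warped = ad.warp_trilinear(
                sample.moving_mask.data.astype(np.float32), field_t
            )
            lo_t = ad.soft_dice_loss(warped, sample.target_mask.data)
            terms.append(lo_t)
            ws.append(weights.k_overlap)
            lo = float(lo_t.data)
        if weights.k_dvf > 0:
            truth = sample.target_field.u.transpose(1, 2, 3, 0)
            ld_t = ad.field_mse_loss(field_t, truth)
            terms.append(ld_t)
            ws.append(weights.k_dvf)
            ld = float(ld_t.data)
        loss_t = ad.weighted_sum(terms, ws)
        total = float(loss_t.data)
        if not np.isfinite(total):
            state.iteration = step
            state.params = {k: t.data for k, t in params_t.items()}
            raise TrainingDivergenceError(
                f"non-finite loss at iteration {step}", state=state
            )
        ad.backward(loss_t)
        for name, t in params_t.items():
            if t.grad is None:
                continue
            v = velocity[name]
            v *= opt.momentum
            v += t.grad
            t.data -= opt.learning_rate * v
            t.grad = None
        if step % log_every == 0:
            state.loss_log.append((step, total, lo, ld))

    state.params = {k: t.data for k, t in params_t.items()}
    state.iteration += iterations
    state.alphas = last_alphas
    return state


def propagate(state: ModelState, pre_image: Volume3D, pre_mask: Volume3D,
              fraction_image: Volume3D) -> tuple[Volume3D, DisplacementField]:
    """Propagate a pretreatment CTV mask onto a fraction image.

    One inference forward pass followed by the nearest-neighbor spatial
    transformer warp; returns the binary mask on the fraction grid and the
    predicted displacement field.
    """
    if not pre_mask.is_mask:
        raise InputError("pre_mask must be a binary mask")
    field = forward(state, pre_image, fraction_image)
    warped = stl_warp(pre_mask.data, field, mode="infer").astype(np.uint8)
    mask = fraction_image.copy_with(warped, is_mask=True)
    return mask, field
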