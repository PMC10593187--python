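"""Factories for the six learned functions: generators G_AB/G_BA,
discriminators D_A/D_B and temporal predictors P_A/P_B.

Exact layer structures are not prescribed, so these are configurable
approximations with the established roles: a residual encoder--decoder
generator, a patch-level convolutional discriminator, and a
generator-style predictor over channel-concatenated input frames. The
default "tiny" profile (base width 16, 2 residual blocks) trains on CPU
at 32x32.

All factories are pure given ``(config, seed)``: parameters are
byte-identical across calls. Networks consume/produce frames on the
model scale ``[-1, 1]``; a bounded output activation guarantees every
generated frame is representable on the 12-bit scale after rescaling.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, List, Optional, Sequence, Union

import numpy as np

from recyclect import nn

__all__ = [
    "GeneratorConfig",
    "DiscriminatorConfig",
    "PredictorConfig",
    "GeneratorFn",
    "DiscriminatorFn",
    "PredictorFn",
    "ModelSet",
    "make_generator",
    "make_discriminator",
    "make_predictor",
    "make_model_set",
    "save_checkpoint",
    "load_checkpoint",
]

Frame = Union[np.ndarray, nn.Tensor]


@dataclass(frozen=True)
class GeneratorConfig:
    """Residual translation net predicting a bounded correction to its input.

    The tiny profile keeps the whole stack at full resolution
    (``n_downsample=0``): noise corrections are pixel-level and do not
    survive an encoder--decoder bottleneck at 32x32. Downsampling stages
    (stride-2 conv down, nearest-neighbour up) are available for larger
    frames.
    """

    image_size: int = 32
    base_width: int = 16
    n_res_blocks: int = 2
    n_downsample: int = 0
    head_gain: float = 0.1  # small head init -> near-identity at start

    @property
    def downsample_factor(self) -> int:
        return 2**self.n_downsample


@dataclass(frozen=True)
class DiscriminatorConfig:
    """Patch classifier over fixed band-split features.

    The tiny CPU profile needs a discriminator that becomes informative
    within a few hundred updates, so the default front end is fixed (not
    learned): a box low-pass channel (intensity content) and a clamped
    |Laplacian| channel (local noise amplitude; the clamp saturates
    anatomical edges identically for real and translated frames so only
    flat-region texture carries gradient). ``n_layers=1`` makes each patch
    score a logistic read-out pooled over ``kernel``² feature pixels —
    pooling is what turns the weak per-pixel dose signal into a confident
    per-patch one.
    """

    base_width: int = 16
    n_layers: int = 1  # learnable convs; 1 = pooled logistic scorer
    kernel: int = 15
    stride: int = 8
    hp_cap: float = 0.3  # clamp on the |Laplacian| channel (model units)
    lowpass_kernel: int = 5
    fixed_front: bool = True  # False: raw intensity input only


@dataclass(frozen=True)
class PredictorConfig:
    w: int = 2
    base_width: int = 16
    head_gain: float = 0.1


def _check_divisible(size: int, factor: int, what: str) -> None:
    if size % factor:
        raise ValueError(
            f"{what} size {size} is not divisible by the downsampling factor {factor}"
        )


def _to4d(frame: Frame) -> tuple:
    """Lift a frame to (N, C, H, W); remember how to undo it."""
    t = frame if isinstance(frame, nn.Tensor) else nn.Tensor(np.asarray(frame, float))
    if t.data.ndim == 2:
        h, w = t.data.shape
        return t.reshape(1, 1, h, w), "2d"
    if t.data.ndim == 4:
        return t, "4d"
    raise ValueError(f"frames must be 2D or 4D (N,C,H,W); got {t.data.ndim} axes")


def _from4d(y: nn.Tensor, kind: str, was_tensor: bool) -> Frame:
    if kind == "2d":
        y = y.reshape(y.data.shape[2], y.data.shape[3])
    return y if was_tensor else y.data


class _ResBlock(nn.Module):
    def __init__(self, width: int, rng: np.random.Generator):
        self.conv1 = nn.Conv2d(width, width, 3, rng=rng)
        self.conv2 = nn.Conv2d(width, width, 3, rng=rng)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        return self.conv2(nn.relu(self.conv1(x))) + x


class _GeneratorNet(nn.Module):
    """Residual encoder-decoder predicting a bounded correction to its input."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.base_width
        self.stem = nn.Conv2d(1, w, 3, rng=rng)
        self.down = []
        for _ in range(cfg.n_downsample):
            self.down.append(nn.Conv2d(w, 2 * w, 3, stride=2, rng=rng))
            w *= 2
        self.blocks = [_ResBlock(w, rng) for _ in range(cfg.n_res_blocks)]
        self.up = []
        for _ in range(cfg.n_downsample):
            self.up.append(nn.Conv2d(w, w // 2, 3, rng=rng))
            w //= 2
        self.head = nn.Conv2d(w, 1, 3, rng=rng, gain=cfg.head_gain)

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.stem(x))
        for layer in self.down:
            h = nn.relu(layer(h))
        for block in self.blocks:
            h = block(h)
        for layer in self.up:
            h = nn.relu(layer(nn.upsample_nearest2(h)))
        return nn.hardtanh(x + self.head(h))


class GeneratorFn:
    """Callable frame -> frame on model-scale arrays; output in [-1, 1]."""

    kind = "generator"

    def __init__(self, module: _GeneratorNet, config: GeneratorConfig, seed: int):
        self.module = module
        self.config = config
        self.seed = seed

    @property
    def parameter_count(self) -> int:
        return self.module.n_parameters()

    def __call__(self, frame: Frame) -> Frame:
        x4, kind = _to4d(frame)
        _check_divisible(x4.data.shape[2], self.config.downsample_factor, "image height")
        _check_divisible(x4.data.shape[3], self.config.downsample_factor, "image width")
        return _from4d(self.module(x4), kind, isinstance(frame, nn.Tensor))


#: Discrete Laplacian used by the fixed high-pass discriminator front end.
_LAPLACIAN = np.array([[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]])


class _DiscriminatorNet(nn.Module):
    def __init__(self, cfg: DiscriminatorConfig, rng: np.random.Generator):
        self.cfg = cfg
        # fixed (non-learned) front end; requires_grad stays False
        self._lap = nn.Tensor(_LAPLACIAN[None, None])
        kb = cfg.lowpass_kernel
        self._box = nn.Tensor(np.full((1, 1, kb, kb), 1.0 / (kb * kb)))
        c = 2 if cfg.fixed_front else 1
        if cfg.n_layers == 1:
            self.convs = [
                nn.Conv2d(c, 1, cfg.kernel, stride=cfg.stride, pad=cfg.kernel // 2, rng=rng)
            ]
        else:
            convs = [
                nn.Conv2d(
                    c, cfg.base_width, cfg.kernel, stride=cfg.stride, pad=cfg.kernel // 2, rng=rng
                )
            ]
            for _ in range(cfg.n_layers - 2):
                convs.append(nn.Conv2d(cfg.base_width, cfg.base_width, 3, rng=rng))
            convs.append(nn.Conv2d(cfg.base_width, 1, 3, rng=rng))
            self.convs = convs

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        if self.cfg.fixed_front:
            hp = nn.hardtanh(
                nn.absolute(nn.conv2d(x, self._lap, None, pad=1)), 0.0, self.cfg.hp_cap
            ) * (1.0 / self.cfg.hp_cap)
            lo = nn.conv2d(x, self._box, None, pad=self.cfg.lowpass_kernel // 2)
            x = nn.concat_channels([lo, hp])
        for conv in self.convs[:-1]:
            x = nn.leaky_relu(conv(x))
        return nn.sigmoid(self.convs[-1](x))


class DiscriminatorFn:
    """Callable frame -> patch score map with values strictly in (0, 1)."""

    kind = "discriminator"

    def __init__(self, module: _DiscriminatorNet, config: DiscriminatorConfig, seed: int):
        self.module = module
        self.config = config
        self.seed = seed

    def receptive_field(self) -> int:
        """Receptive field of one output score via the standard recurrence."""
        rf, jump = 1, 1
        specs = []
        if self.config.fixed_front:
            # parallel box/Laplacian branches: the wider one bounds the RF
            specs.append((max(self.config.lowpass_kernel, 3), 1))
        specs += [(c.weight.data.shape[2], c.stride) for c in self.module.convs]
        for k, s in specs:
            rf += (k - 1) * jump
            jump *= s
        return rf

    def __call__(self, frame: Frame) -> Frame:
        x4, kind = _to4d(frame)
        y = self.module(x4)
        if kind == "2d":
            y = y.reshape(y.data.shape[2], y.data.shape[3])
        return y if isinstance(frame, nn.Tensor) else y.data


class _PredictorNet(nn.Module):
    def __init__(self, cfg: PredictorConfig, rng: np.random.Generator):
        self.cfg = cfg
        w = cfg.base_width
        self.conv1 = nn.Conv2d(cfg.w, w, 3, rng=rng)
        self.conv2 = nn.Conv2d(w, w, 3, rng=rng)
        self.head = nn.Conv2d(w, 1, 3, rng=rng, gain=cfg.head_gain)

    def forward(self, stacked: nn.Tensor, last: nn.Tensor) -> nn.Tensor:
        h = nn.relu(self.conv1(stacked))
        h = nn.relu(self.conv2(h))
        # near-persistence at init: predict the last frame plus a correction
        return nn.hardtanh(last + self.head(h))


class PredictorFn:
    """Callable (w ordered frames) -> next frame; consumes exactly w frames."""

    kind = "predictor"

    def __init__(self, module: _PredictorNet, config: PredictorConfig, seed: int):
        self.module = module
        self.config = config
        self.seed = seed

    @property
    def w(self) -> int:
        return self.config.w

    def __call__(self, frames: Sequence[Frame]) -> Frame:
        frames = list(frames)
        if len(frames) != self.config.w:
            raise ValueError(
                f"predictor expects exactly w={self.config.w} frames, got {len(frames)}"
            )
        was_tensor = any(isinstance(f, nn.Tensor) for f in frames)
        lifted = [_to4d(f) for f in frames]
        kind = lifted[0][1]
        stacked = nn.concat_channels([t for t, _ in lifted])
        y = self.module(stacked, lifted[-1][0])
        return _from4d(y, kind, was_tensor)


# ---------------------------------------------------------------------------
# factories
# ---------------------------------------------------------------------------

def make_generator(config: GeneratorConfig = GeneratorConfig(), seed: int = 0) -> GeneratorFn:
    """Freshly initialised generator; deterministic for a fixed seed.

    Raises at construction if ``config.image_size`` is not divisible by
    the downsampling factor.
    """
    _check_divisible(config.image_size, config.downsample_factor, "configured image")
    rng = np.random.default_rng(seed)
    return GeneratorFn(_GeneratorNet(config, rng), config, seed)


def make_discriminator(
    config: DiscriminatorConfig = DiscriminatorConfig(), seed: int = 0
) -> DiscriminatorFn:
    rng = np.random.default_rng(seed)
    return DiscriminatorFn(_DiscriminatorNet(config, rng), config, seed)


def make_predictor(config: PredictorConfig = PredictorConfig(), seed: int = 0) -> PredictorFn:
    if config.w < 1:
        raise ValueError(f"predictor window w must be >= 1, got {config.w}")
    rng = np.random.default_rng(seed)
    return PredictorFn(_PredictorNet(config, rng), config, seed)


@dataclass
class ModelSet:
    """The networks of one experiment; predictors present only for RecycleGAN."""

    g_ab: GeneratorFn
    g_ba: GeneratorFn
    d_a: DiscriminatorFn
    d_b: DiscriminatorFn
    p_a: Optional[PredictorFn] = None
    p_b: Optional[PredictorFn] = None

    def named(self) -> dict:
        out = {"g_ab": self.g_ab, "g_ba": self.g_ba, "d_a": self.d_a, "d_b": self.d_b}
        if self.p_a is not None:
            out["p_a"] = self.p_a
        if self.p_b is not None:
            out["p_b"] = self.p_b
        return out


def make_model_set(
    seed: int,
    gen_config: GeneratorConfig = GeneratorConfig(),
    disc_config: DiscriminatorConfig = DiscriminatorConfig(),
    pred_config: Optional[PredictorConfig] = PredictorConfig(),
    with_predictors: bool = True,
) -> ModelSet:
    """Build all networks from one master seed (stable per-network offsets)."""
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(6)]
    return ModelSet(
        g_ab=make_generator(gen_config, seeds[0]),
        g_ba=make_generator(gen_config, seeds[1]),
        d_a=make_discriminator(disc_config, seeds[2]),
        d_b=make_discriminator(disc_config, seeds[3]),
        p_a=make_predictor(pred_config, seeds[4]) if with_predictors else None,
        p_b=make_predictor(pred_config, seeds[5]) if with_predictors else None,
    )


# ---------------------------------------------------------------------------
# checkpoints: one archive with all parameters + JSON config sidecar
# ---------------------------------------------------------------------------

def save_checkpoint(models: ModelSet, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays, meta = {}, {}
    for name, fn in models.named().items():
        for i, arr in enumerate(fn.module.state_arrays()):
            arrays[f"{name}__{i:03d}"] = arr
        meta[name] = {
            "kind": fn.kind,
            "seed": fn.seed,
            "config": dataclasses.asdict(fn.config),
        }
    np.savez_compressed(path, **arrays)
    if path.suffix != ".npz":
        path = path.with_name(path.name + ".npz")
    path.with_name(path.name + ".json").write_text(json.dumps(meta, indent=1))
    return path


def load_checkpoint(path) -> ModelSet:
    """Rebuild a :class:`ModelSet` with bit-identical behaviour."""
    path = Path(path)
    meta = json.loads(path.with_name(path.name + ".json").read_text())
    factories = {
        "generator": (make_generator, GeneratorConfig),
        "discriminator": (make_discriminator, DiscriminatorConfig),
        "predictor": (make_predictor, PredictorConfig),
    }
    fns = {}
    with np.load(path) as npz:
        for name, info in meta.items():
            factory, cfg_cls = factories[info["kind"]]
            fn = factory(cfg_cls(**info["config"]), seed=info["seed"])
            keys = sorted(k for k in npz.files if k.startswith(f"{name}__"))
            fn.module.load_state_arrays([npz[k] for k in keys])
            fns[name] = fn
    return ModelSet(
        g_ab=fns["g_ab"],
        g_ba=fns["g_ba"],
        d_a=fns["d_a"],
        d_b=fns["d_b"],
        p_a=fns.get("p_a"),
        p_b=fns.get("p_b"),
    )
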