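"""Loss terms for the spatial (CycleGAN) and spatiotemporal (RecycleGAN)
unpaired-translation objectives.

All image-difference reductions are the *mean over pixels* of a frame, and
per-sequence terms then average over the contributing time indices. The λ
defaults are λ=10 (cycle), λ_rx=0.5, λ_ry=50 (recycle), λ_τx=1, λ_τy=100
(recurrent).

Every loss here is generic over plain NumPy arrays (evaluation, unit
tests) and :class:`recyclect.nn.Tensor` (differentiable training path):
feed NumPy in, get a float out; feed Tensors in, get a scalar Tensor.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Union

import numpy as np

from recyclect import nn
from recyclect.sequence import PhaseSequence, frame_window

__all__ = [
    "EPS",
    "LossWeights",
    "LossBreakdown",
    "adversarial_loss",
    "lsgan_loss",
    "cycle_consistency_loss",
    "identity_loss",
    "recurrent_loss",
    "recycle_loss",
    "cyclegan_objective",
    "recyclegan_objective",
]

#: Discriminator scores are clamped to ``[EPS, 1-EPS]`` before logs.
EPS = 1e-7

Frame = Union[np.ndarray, "nn.Tensor"]
SeqLike = Union[PhaseSequence, Sequence[Frame]]


@dataclass(frozen=True)
class LossWeights:
    """λ coefficients of both objectives (defaults are the published ones)."""

    lambda_cycle: float = 10.0
    lambda_rx: float = 0.5
    lambda_ry: float = 50.0
    lambda_tau_x: float = 1.0
    lambda_tau_y: float = 100.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} must be nonnegative")


@dataclass
class LossBreakdown:
    """Total objective value plus its per-term decomposition."""

    objective: str
    total: float
    terms: Dict[str, float] = field(default_factory=dict)

    def to_record(self) -> Dict[str, float]:
        """Flat record (for CSV/JSON-lines step logging)."""
        rec = {"objective": self.objective, "total": self.total}
        rec.update(self.terms)
        return rec

    def to_json(self) -> str:
        return json.dumps(self.to_record())


# ---------------------------------------------------------------------------
# generic scalar helpers (NumPy or Tensor)
# ---------------------------------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, nn.Tensor)


def _mean_sq_diff(x: Frame, y: Frame):
    """Mean over pixels of (x - y)^2."""
    if _is_t(x) or _is_t(y):
        return nn.square(nn.as_tensor(x) - nn.as_tensor(y)).mean()
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.mean((x - y) ** 2))


def _mean_abs_diff(x: Frame, y: Frame):
    if _is_t(x) or _is_t(y):
        return nn.absolute(nn.as_tensor(x) - nn.as_tensor(y)).mean()
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return float(np.mean(np.abs(x - y)))


def _mean_over(values: list):
    """Mean of a list of scalars (floats and/or scalar Tensors)."""
    total = values[0]
    for v in values[1:]:
        total = total + v
    return total * (1.0 / len(values)) if _is_t(total) else total / len(values)


def _mean_log(scores: Sequence, one_minus: bool = False):
    """Mean of log(s) (or log(1-s)) over every entry of every score map."""
    if len(scores) == 0:
        raise ValueError("empty discriminator score list")
    tensorish = any(_is_t(s) for s in scores)
    if tensorish:
        total, count = None, 0
        for s in scores:
            st = nn.as_tensor(s)
            if st.data.ndim == 0:
                st = st.reshape(1)
            val = (1.0 - st) if one_minus else st
            term = nn.log(nn.clamp(val, EPS, 1.0 - EPS)).sum()
            total = term if total is None else total + term
            count += st.data.size
        return total * (1.0 / count)
    flat = np.concatenate([np.atleast_1d(np.asarray(s, float)).ravel() for s in scores])
    val = 1.0 - flat if one_minus else flat
    return float(np.mean(np.log(np.clip(val, EPS, 1.0 - EPS))))


# ---------------------------------------------------------------------------
# component losses
# ---------------------------------------------------------------------------

def adversarial_loss(d_real: Sequence, d_fake: Sequence):
    """Printed (log-likelihood) GAN value: E[log D(real)] + E[log(1 - D(fake))].

    Score maps are flattened: every entry counts as an independent score.
    The discriminator maximises this value; the generator minimises the
    fake term. Scores are clamped to ``[EPS, 1-EPS]`` before logs.
    """
    return _mean_log(d_real) + _mean_log(d_fake, one_minus=True)


def lsgan_loss(d_real: Sequence, d_fake: Sequence):
    """Least-squares alternative (off by default; practical stabiliser)."""
    if len(d_real) == 0 or len(d_fake) == 0:
        raise ValueError("empty discriminator score list")
    real_terms = [_mean_sq_diff(s, np.ones(np.shape(getattr(s, "data", s)))) for s in d_real]
    fake_terms = [_mean_sq_diff(s, np.zeros(np.shape(getattr(s, "data", s)))) for s in d_fake]
    return -(_mean_over(real_terms) + _mean_over(fake_terms))


def cycle_consistency_loss(a: Frame, a_reconstructed: Frame, b: Frame, b_reconstructed: Frame):
    """Mean-L1 of both cycle reconstructions:
    mean|G_BA(G_AB(a)) - a| + mean|G_AB(G_BA(b)) - b|.
    """
    return _mean_abs_diff(a, a_reconstructed) + _mean_abs_diff(b, b_reconstructed)


def identity_loss(a: Frame, g_ba_a: Frame, b: Frame, g_ab_b: Frame):
    """Optional identity-mapping term (not part of either printed objective)."""
    return _mean_abs_diff(a, g_ba_a) + _mean_abs_diff(b, g_ab_b)


def _frames_and_looped(seq: SeqLike, looped: Optional[bool]) -> tuple:
    if isinstance(seq, PhaseSequence):
        return list(seq.frames), seq.looped
    if looped is None:
        raise ValueError("pass looped= when giving a bare frame list")
    return list(seq), looped


def _window(frames: list, looped: bool, t: int, w: int) -> list:
    """Chronological window of length ``w`` ending at 1-based phase ``t``."""
    T = len(frames)
    if looped:
        return [frames[(t - w + k) % T] for k in range(w)]
    return frames[t - w : t]


def _prediction_targets(T: int, looped: bool, w: int) -> List[int]:
    """1-based window-end indices t whose target frame t+1 is available."""
    if looped:
        return list(range(1, T + 1))
    ts = list(range(w, T))
    if not ts:
        raise ValueError(
            f"non-looped sequence of {T} frames too short for window w={w} "
            f"plus a prediction target"
        )
    return ts


def recurrent_loss(seq: SeqLike, predictor: Callable, w: int = 2, looped: Optional[bool] = None):
    """Temporal-prediction loss L_τ(P): mean over valid t of the per-pixel
    mean squared error between frame t+1 and P(window ending at t).

    Looped sequences contribute all T targets (indices wrap); non-looped
    sequences contribute t = w..T-1.
    """
    frames, looped = _frames_and_looped(seq, looped)
    T = len(frames)
    errs = []
    for t in _prediction_targets(T, looped, w):
        target = frames[t % T]  # 1-based t+1 -> 0-based t, wrapped
        pred = predictor(_window(frames, looped, t, w))
        errs.append(_mean_sq_diff(target, pred))
    return _mean_over(errs)


def recycle_loss(
    seq: SeqLike,
    g_fwd: Callable,
    g_bwd: Callable,
    predictor_target: Callable,
    w: int = 2,
    looped: Optional[bool] = None,
):
    """Cross-domain spatiotemporal loss L_r: translate the window
    frame-by-frame with ``g_fwd``, predict the next translated frame with
    the target-domain predictor, map back with ``g_bwd``, and penalise the
    per-pixel mean squared error against the true frame t+1; averaged over
    valid t.

    With identity generators this reduces exactly to :func:`recurrent_loss`.
    """
    frames, looped = _frames_and_looped(seq, looped)
    T = len(frames)
    errs = []
    for t in _prediction_targets(T, looped, w):
        target = frames[t % T]
        translated = [g_fwd(f) for f in _window(frames, looped, t, w)]
        back = g_bwd(predictor_target(translated))
        errs.append(_mean_sq_diff(target, back))
    return _mean_over(errs)


# ---------------------------------------------------------------------------
# full objectives
# ---------------------------------------------------------------------------

def _as_float(x) -> float:
    return x.item() if _is_t(x) else float(x)


def cyclegan_objective(batch: dict, models, weights: LossWeights) -> LossBreakdown:
    """Value of the spatial objective on an unpaired batch.

    ``batch`` maps ``"a"`` and ``"b"`` to lists of frames; ``models``
    exposes ``g_ab``, ``g_ba``, ``d_a``, ``d_b``.
    total = gan_AB + gan_BA + λ·cycle.
    """
    frames_a, frames_b = list(batch.get("a", ())), list(batch.get("b", ()))
    if not frames_a or not frames_b:
        raise ValueError("batch must contain frames from both domains")
    fake_b = [models.g_ab(a) for a in frames_a]
    fake_a = [models.g_ba(b) for b in frames_b]
    gan_ab = _as_float(
        adversarial_loss([models.d_b(b) for b in frames_b], [models.d_b(f) for f in fake_b])
    )
    gan_ba = _as_float(
        adversarial_loss([models.d_a(a) for a in frames_a], [models.d_a(f) for f in fake_a])
    )
    cyc_a = _mean_over([_mean_abs_diff(a, models.g_ba(f)) for a, f in zip(frames_a, fake_b)])
    cyc_b = _mean_over([_mean_abs_diff(b, models.g_ab(f)) for b, f in zip(frames_b, fake_a)])
    cycle = _as_float(cyc_a + cyc_b)
    terms = {"gan_AB": gan_ab, "gan_BA": gan_ba, "cycle": cycle}
    total = gan_ab + gan_ba + weights.lambda_cycle * cycle
    return LossBreakdown(objective="cyclegan", total=total, terms=terms)


def recyclegan_objective(
    batch: dict, models, weights: LossWeights, w: int = 2
) -> LossBreakdown:
    """Value of the spatiotemporal objective on ordered sequences.

    ``batch`` maps ``"a"`` / ``"b"`` to lists of :class:`PhaseSequence`;
    ``models`` additionally exposes predictors ``p_a``, ``p_b``.
    total = gan_AB + gan_BA + λ_rx·L_r(G_AB→P_B→G_BA on A)
          + λ_ry·L_r(G_BA→P_A→G_AB on B) + λ_τx·L_τ(P_A) + λ_τy·L_τ(P_B).
    """
    seqs_a, seqs_b = list(batch.get("a", ())), list(batch.get("b", ()))
    if not seqs_a or not seqs_b:
        raise ValueError("batch must contain sequences from both domains")
    frames_a = [f for s in seqs_a for f in (s.frames if isinstance(s, PhaseSequence) else s)]
    frames_b = [f for s in seqs_b for f in (s.frames if isinstance(s, PhaseSequence) else s)]
    gan_ab = _as_float(
        adversarial_loss(
            [models.d_b(b) for b in frames_b], [models.d_b(models.g_ab(a)) for a in frames_a]
        )
    )
    gan_ba = _as_float(
        adversarial_loss(
            [models.d_a(a) for a in frames_a], [models.d_a(models.g_ba(b)) for b in frames_b]
        )
    )
    recycle_x = _as_float(
        _mean_over([recycle_loss(s, models.g_ab, models.g_ba, models.p_b, w) for s in seqs_a])
    )
    recycle_y = _as_float(
        _mean_over([recycle_loss(s, models.g_ba, models.g_ab, models.p_a, w) for s in seqs_b])
    )
    recurrent_x = _as_float(_mean_over([recurrent_loss(s, models.p_a, w) for s in seqs_a]))
    recurrent_y = _as_float(_mean_over([recurrent_loss(s, models.p_b, w) for s in seqs_b]))
    terms = {
        "gan_AB": gan_ab,
        "gan_BA": gan_ba,
        "recycle_x": recycle_x,
        "recycle_y": recycle_y,
        "recurrent_x": recurrent_x,
        "recurrent_y": recurrent_y,
    }
    total = (
        gan_ab
        + gan_ba
        + weights.lambda_rx * recycle_x
        + weights.lambda_ry * recycle_y
        + weights.lambda_tau_x * recurrent_x
        + weights.lambda_tau_y * recurrent_y
    )
    return LossBreakdown(objective="recyclegan", total=total, terms=terms)
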