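"""Data model and I/O for temporally ordered 2D CT image sequences.

A :class:`PhaseSequence` holds the frames of one slice over the cardiac
phases, together with its intensity-scale convention and whether the phase
axis is cyclic ("looped video" of one heart beat).

Intensity conventions
---------------------
Two storage scales are supported, linked by a fixed affine map:

* ``raw12bit`` — integers in ``[0, 4095]`` (12-bit CT detector scale).
* ``hu``      — Hounsfield units with ``raw = HU + 1024``, clamped to the
  12-bit range.

A third scale, ``model``, denotes network input/output in ``[-1, 1]``; it
is never written to disk.

Phase indices are 1-based at every user-facing boundary (``t = 1..T``),
mirroring the usual cardiac-phase numbering.
"""

from __future__ import annotations

import enum
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, List, Sequence

import numpy as np

__all__ = [
    "RAW_MAX",
    "HU_OFFSET",
    "SequenceError",
    "SequenceIOError",
    "ShapeMismatchError",
    "DoseDomain",
    "IntensityWindow",
    "PhaseSequence",
    "hu_to_raw",
    "raw_to_hu",
    "to_model_scale",
    "from_model_scale",
    "frame_window",
    "load_sequence",
    "save_sequence",
]

#: Maximum representable raw 12-bit intensity.
RAW_MAX = 4095

#: Fixed offset of the raw scale relative to Hounsfield units.
HU_OFFSET = 1024

_VALID_SCALES = ("raw12bit", "hu", "model")
_VALID_DOMAINS = ("low_dose", "full_dose", "denoised", "clean")


class SequenceError(ValueError):
    """Contract violation on a phase sequence."""


class SequenceIOError(SequenceError):
    """Typed I/O error for sequence reading/writing."""


class ShapeMismatchError(SequenceError):
    """Frames of a sequence do not share one shape."""


class DoseDomain(str, enum.Enum):
    """The two unpaired training domains: A = low dose, B = full dose."""

    A = "low_dose"
    B = "full_dose"

    @property
    def label(self) -> str:
        return self.value


@dataclass(frozen=True)
class IntensityWindow:
    """Display window in HU, used only for PNG export."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise SequenceError(
                f"window lower bound {self.lower} must be < upper bound {self.upper}"
            )


@dataclass
class PhaseSequence:
    """Ordered frames of one slice over cardiac phases ``t = 1..T``.

    Parameters
    ----------
    frames
        List of 2D arrays, all with identical shape, in chronological
        phase order.
    intensity_scale
        One of ``"raw12bit"``, ``"hu"``, ``"model"``.
    looped
        If true, phase ``T`` is temporally followed by phase 1.
    domain_label
        One of ``"low_dose"``, ``"full_dose"``, ``"denoised"``, ``"clean"``.
    """

    frames: List[np.ndarray]
    intensity_scale: str
    looped: bool = False
    domain_label: str = "low_dose"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.frames:
            raise SequenceError("a phase sequence needs at least one frame")
        self.frames = [np.asarray(f) for f in self.frames]
        shape0 = self.frames[0].shape
        for t, f in enumerate(self.frames, start=1):
            if f.ndim != 2:
                raise ShapeMismatchError(f"frame {t} is not 2D (shape {f.shape})")
            if f.shape != shape0:
                raise ShapeMismatchError(
                    f"frame {t} has shape {f.shape}, expected {shape0}"
                )
        if self.intensity_scale not in _VALID_SCALES:
            raise SequenceError(
                f"unknown intensity_scale {self.intensity_scale!r}; "
                f"expected one of {_VALID_SCALES}"
            )
        if self.domain_label not in _VALID_DOMAINS:
            raise SequenceError(
                f"unknown domain_label {self.domain_label!r}; "
                f"expected one of {_VALID_DOMAINS}"
            )
        if self.intensity_scale == "raw12bit":
            lo = min(float(f.min()) for f in self.frames)
            hi = max(float(f.max()) for f in self.frames)
            if lo < 0 or hi > RAW_MAX:
                raise SequenceError(
                    f"raw12bit values must lie in [0, {RAW_MAX}]; "
                    f"observed range [{lo}, {hi}]"
                )

    @property
    def phase_count(self) -> int:
        return len(self.frames)

    @property
    def frame_shape(self) -> tuple:
        return self.frames[0].shape

    def frame(self, t: int) -> np.ndarray:
        """Return the frame at 1-based phase index ``t``."""
        if not 1 <= t <= self.phase_count:
            raise SequenceError(
                f"phase index {t} out of range 1..{self.phase_count}"
            )
        return self.frames[t - 1]

    def stack(self) -> np.ndarray:
        """Frames stacked on a leading phase axis, shape ``(T, H, W)``."""
        return np.stack(self.frames, axis=0)

    def with_frames(self, frames: Iterable[np.ndarray], **changes) -> "PhaseSequence":
        """Copy carrying new frames (and optional metadata changes)."""
        return replace(self, frames=list(frames), **changes)


def hu_to_raw(hu: np.ndarray) -> np.ndarray:
    """Map HU to the raw 12-bit scale, ``raw = HU + 1024``, clamped."""
    return np.clip(np.asarray(hu, dtype=np.float64) + HU_OFFSET, 0, RAW_MAX)


def raw_to_hu(raw: np.ndarray) -> np.ndarray:
    """Inverse of :func:`hu_to_raw` (no clamping needed)."""
    return np.asarray(raw, dtype=np.float64) - HU_OFFSET


def to_model_scale(frame: np.ndarray) -> np.ndarray:
    """Affine map of a raw 12-bit frame to the network scale ``[-1, 1]``.

    ``x -> x / 2047.5 - 1``. Out-of-range values are clamped with a
    warning rather than raising, so a stray value never aborts training.
    """
    x = np.asarray(frame, dtype=np.float64)
    if x.size and (x.min() < 0 or x.max() > RAW_MAX):
        warnings.warn(
            "frame values outside [0, 4095] clamped before model scaling",
            stacklevel=2,
        )
        x = np.clip(x, 0, RAW_MAX)
    return x / (RAW_MAX / 2.0) - 1.0


def from_model_scale(frame: np.ndarray) -> np.ndarray:
    """Map ``[-1, 1]`` model output back to the raw 12-bit scale (float)."""
    y = np.asarray(frame, dtype=np.float64)
    return np.clip((y + 1.0) * (RAW_MAX / 2.0), 0, RAW_MAX)


def frame_window(seq: PhaseSequence, t: int, w: int) -> List[np.ndarray]:
    """The ``w`` chronologically ordered frames ending at phase ``t``.

    On a looped sequence indices wrap modulo ``T`` (the predecessors of
    phase 1 are phases ``T, T-1, ...``). On a non-looped sequence ``t``
    must satisfy ``t >= w``.
    """
    T = seq.phase_count
    if w < 1:
        raise SequenceError(f"window length must be >= 1, got {w}")
    if not 1 <= t <= T:
        raise SequenceError(f"phase index {t} out of range 1..{T}")
    if seq.looped:
        return [seq.frames[(t - w + k) % T] for k in range(w)]
    if t < w:
        raise SequenceError(
            f"window of length {w} ending at phase {t} runs off the start "
            f"of a non-looped sequence"
        )
    return seq.frames[t - w : t]


# ---------------------------------------------------------------------------
# I/O: NIfTI (via nibabel) and a compressed array archive with a JSON sidecar
# ---------------------------------------------------------------------------

_FORMATS = ("nifti", "array_archive")


def _meta_dict(seq: PhaseSequence) -> dict:
    return {
        "intensity_scale": seq.intensity_scale,
        "looped": bool(seq.looped),
        "domain_label": seq.domain_label,
        "phase_count": seq.phase_count,
    }


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_sequence(seq: PhaseSequence, path, format: str = "array_archive") -> Path:
    """Write a sequence to disk; the result round-trips bit-exactly.

    ``nifti`` stores frames as a 3D volume with phase on the last axis;
    ``array_archive`` is an ``.npz`` with one array per phase. Both carry
    a JSON sidecar (``<name>.json``) holding scale/looped/domain metadata.
    """
    if format not in _FORMATS:
        raise SequenceIOError(f"unknown format {format!r}; expected one of {_FORMATS}")
    if seq.intensity_scale is None or seq.intensity_scale not in _VALID_SCALES:
        raise SequenceIOError("intensity_scale must be set before saving")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "nifti":
        import nibabel as nib

        # (H, W, T): phase is the last (slowest) axis.
        vol = np.stack(seq.frames, axis=-1)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        nib.save(img, str(path))
    else:
        arrays = {f"phase_{t:03d}": f for t, f in enumerate(seq.frames, start=1)}
        np.savez_compressed(path, **arrays)
        if path.suffix != ".npz":
            path = path.with_name(path.name + ".npz")
    _sidecar_path(path).write_text(json.dumps(_meta_dict(seq), indent=1))
    return path


def load_sequence(path, format: str = "array_archive") -> PhaseSequence:
    """Read a sequence written by :func:`save_sequence`.

    For NIfTI the last (slowest) axis is interpreted as phase/time.
    Integer intensities are preserved bit-exactly.
    """
    if format not in _FORMATS:
        raise SequenceIOError(f"unknown format {format!r}; expected one of {_FORMATS}")
    path = Path(path)
    if not path.exists():
        raise SequenceIOError(f"no such file: {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise SequenceIOError(
            f"metadata sidecar {sidecar.name} missing; scale metadata is "
            f"required and never defaulted"
        )
    meta = json.loads(sidecar.read_text())
    if format == "nifti":
        import nibabel as nib

        img = nib.load(str(path))
        vol = np.asanyarray(img.dataobj)
        if vol.ndim != 3:
            raise SequenceIOError(
                f"expected a 3D (H, W, phase) NIfTI, got {vol.ndim} axes"
            )
        frames = [vol[..., t] for t in range(vol.shape[-1])]
    else:
        with np.load(path) as npz:
            keys = sorted(npz.files)
            frames = [npz[k] for k in keys]
    seq = PhaseSequence(
        frames=frames,
        intensity_scale=meta["intensity_scale"],
        looped=bool(meta["looped"]),
        domain_label=meta["domain_label"],
    )
    if seq.phase_count != int(meta["phase_count"]):
        raise SequenceIOError(
            f"phase axis length {seq.phase_count} disagrees with sidecar "
            f"phase_count {meta['phase_count']}"
        )
    return seq


def export_png(seq: PhaseSequence, directory, window: IntensityWindow) -> List[Path]:
    """Lossy 8-bit PNG export for visual inspection only (never an input)."""
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, f in enumerate(seq.frames, start=1):
        hu = raw_to_hu(f) if seq.intensity_scale == "raw12bit" else np.asarray(f, float)
        img = np.clip((hu - window.lower) / (window.upper - window.lower), 0, 1)
        out = directory / f"phase_{t:03d}.png"
        iio.imwrite(out, (img * 255).astype(np.uint8))
        paths.append(out)
    return paths
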