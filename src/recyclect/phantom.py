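"""Synthetic dynamic cardiac phantom: paired full-dose/low-dose 8-phase
looped sequences with a beating "heart", static lungs/body, and a flat
contrast-filled "aorta" disc for ROI noise measurements.

The anatomy is deliberately desk-scale (concentric smooth shapes at
32-128 px): the contract under test is spatiotemporal denoising, not
anatomic fidelity. Clean, full-dose and low-dose renderings of one
phantom share the geometry exactly, so paired PSNR/SSIM against the
clean reference are well defined even though *training* never uses the
pairing.

Noise model: additive Gaussian in HU with quantum-noise-motivated
1/sqrt(dose) scaling, sigma(dose) = full_dose_sigma / sqrt(dose_fraction)
(so the default 20% dose carries sqrt(5) times the full-dose noise), plus
an optional small smoothing to mimic reconstruction-kernel correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from recyclect.metrics import ROISpec
from recyclect.sequence import HU_OFFSET, RAW_MAX, PhaseSequence, hu_to_raw

__all__ = [
    "AnatomyHU",
    "MotionParams",
    "NoiseModel",
    "PhantomParams",
    "CohortRanges",
    "PhantomRecord",
    "PhantomPair",
    "generate_phantom",
    "generate_cohort",
    "make_roi_fixture",
    "default_roi",
    "blood_pool_mask",
    "soft_tissue_mask",
]

COHORT_LABELS = ("cohort0", "cohort1")


@dataclass(frozen=True)
class AnatomyHU:
    background: float = -1000.0
    lung: float = -800.0
    soft_tissue: float = 40.0
    myocardium: float = 45.0
    blood_baseline: float = 45.0
    #: arterial enhancement above baseline; clinically 200-350 HU
    enhancement: float = 300.0


@dataclass(frozen=True)
class MotionParams:
    """Chamber radii in normalised units (frame spans [-1, 1])."""

    r_end_diastole: float = 0.34
    r_end_systole: float = 0.22
    wall_thickness: float = 0.09

    def radius(self, t: int, phase_count: int) -> float:
        """Smooth periodic radius; phase 1 is end-diastole, loop-consistent."""
        phase = 2.0 * np.pi * (t - 1) / phase_count
        amp = (self.r_end_diastole - self.r_end_systole) / 2.0
        mid = (self.r_end_diastole + self.r_end_systole) / 2.0
        return float(mid + amp * np.cos(phase))


@dataclass(frozen=True)
class NoiseModel:
    kind: str = "gaussian_quantum"
    full_dose_sigma: float = 32.0  # HU; calibrated so selection thresholds hold
    smooth_width: float = 0.0  # pixels; >0 mimics reconstruction correlation

    def __post_init__(self):
        if self.kind != "gaussian_quantum":
            raise ValueError(f"unknown noise model kind {self.kind!r}")
        if self.full_dose_sigma <= 0:
            raise ValueError("full_dose_sigma must be positive")

    def sigma(self, dose_fraction: float) -> float:
        return self.full_dose_sigma / np.sqrt(dose_fraction)


@dataclass(frozen=True)
class PhantomParams:
    image_size: int = 32
    phase_count: int = 8
    anatomy: AnatomyHU = field(default_factory=AnatomyHU)
    motion: MotionParams = field(default_factory=MotionParams)
    cohort_label: str = "cohort0"
    dose_fraction: float = 0.2
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0

    # fixed scene layout (normalised [-1, 1] coordinates, (y, x))
    body_axes: Tuple[float, float] = (0.8, 0.9)
    lung_center_y: float = -0.15
    lung_center_x: float = 0.45
    lung_axes: Tuple[float, float] = (0.3, 0.22)
    heart_center: Tuple[float, float] = (0.25, 0.0)
    aorta_center: Tuple[float, float] = (-0.5, 0.0)
    aorta_radius: float = 0.2

    def __post_init__(self):
        if self.phase_count < 2:
            raise ValueError("phase_count must be >= 2")
        if not 0.0 < self.dose_fraction <= 1.0:
            raise ValueError("dose_fraction must lie in (0, 1]")
        m = self.motion
        if min(m.r_end_diastole, m.r_end_systole) <= 0:
            raise ValueError("chamber radii must be positive")
        if m.r_end_systole - m.wall_thickness <= 0.02:
            raise ValueError("end-systolic blood pool collapses: wall too thick")
        cy, cx = self.heart_center
        if abs(cy) + m.r_end_diastole > self.body_axes[0] or abs(cx) + m.r_end_diastole > self.body_axes[1]:
            raise ValueError("heart geometry exceeds the body outline")
        ay, ax = self.aorta_center
        if abs(ay) + self.aorta_radius > 1.0 or abs(ax) + self.aorta_radius > 1.0:
            raise ValueError("aorta geometry exceeds the frame")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _grid(size: int) -> Tuple[np.ndarray, np.ndarray]:
    c = (np.arange(size) + 0.5) / size * 2.0 - 1.0
    return np.meshgrid(c, c, indexing="ij")  # (Y, X)


def _smooth_disc(Y, X, cy, cx, ry, rx, edge) -> np.ndarray:
    """Soft-edged ellipse indicator in [0, 1]; edge in normalised units."""
    d = np.sqrt(((Y - cy) / ry) ** 2 + ((X - cx) / rx) ** 2) - 1.0
    # signed distance approx in normalised units along the minor axis
    d = d * min(ry, rx)
    t = np.clip(0.5 - d / edge, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)  # smoothstep


def _render_layers(params: PhantomParams, t: int) -> List[Tuple[np.ndarray, float]]:
    S = params.image_size
    Y, X = _grid(S)
    edge = 1.5 * (2.0 / S)
    a = params.anatomy
    r = params.motion.radius(t, params.phase_count)
    r_blood = r - params.motion.wall_thickness
    hy, hx = params.heart_center
    ay, ax = params.aorta_center
    return [
        (_smooth_disc(Y, X, 0.0, 0.0, *params.body_axes, edge=edge), a.soft_tissue),
        (
            _smooth_disc(
                Y, X, params.lung_center_y, -params.lung_center_x, *params.lung_axes, edge=edge
            ),
            a.lung,
        ),
        (
            _smooth_disc(
                Y, X, params.lung_center_y, params.lung_center_x, *params.lung_axes, edge=edge
            ),
            a.lung,
        ),
        (_smooth_disc(Y, X, hy, hx, r, r, edge=edge), a.myocardium),
        (
            _smooth_disc(Y, X, hy, hx, r_blood, r_blood, edge=edge),
            a.blood_baseline + a.enhancement,
        ),
        (
            _smooth_disc(Y, X, ay, ax, params.aorta_radius, params.aorta_radius, edge=edge),
            a.blood_baseline + a.enhancement,
        ),
    ]


def _render_clean_hu(params: PhantomParams, t: int) -> np.ndarray:
    hu = np.full((params.image_size, params.image_size), params.anatomy.background)
    for alpha, value in _render_layers(params, t):
        hu = hu * (1.0 - alpha) + value * alpha
    return hu


def blood_pool_mask(params: PhantomParams, t: int) -> np.ndarray:
    """Strict interior of the contrast-filled chamber at phase ``t``
    (pixels whose clean HU equals the blood value exactly)."""
    return _render_layers(params, t)[4][0] >= 1.0


def soft_tissue_mask(params: PhantomParams, t: int = 1) -> np.ndarray:
    """Flat soft-tissue pixels: inside the body, outside every other layer."""
    layers = _render_layers(params, t)
    inside = layers[0][0] >= 1.0
    for alpha, _ in layers[1:]:
        inside &= alpha <= 0.0
    return inside


def _sequence_from_hu(
    frames_hu: List[np.ndarray], domain: str, params: PhantomParams
) -> PhaseSequence:
    frames = [hu_to_raw(f) for f in frames_hu]
    return PhaseSequence(
        frames=frames,
        intensity_scale="raw12bit",
        looped=True,
        domain_label=domain,
        meta={"phantom": dataclasses.asdict(params)},
    )


def generate_phantom(
    params: PhantomParams,
) -> Tuple[PhaseSequence, PhaseSequence, PhaseSequence]:
    """Render one phantom as (clean, full_dose, low_dose) looped sequences.

    All three share geometry exactly (pixelwise aligned); the noisy pair
    differs from clean only by the additive noise realisations. Output
    frames are on the raw 12-bit scale, clamped to [0, 4095]. Deterministic
    for fixed ``params`` (including ``params.seed``).
    """
    rng = np.random.default_rng(params.seed)
    clean_hu = [_render_clean_hu(params, t) for t in range(1, params.phase_count + 1)]

    def noisy(dose: float) -> List[np.ndarray]:
        sigma = params.noise.sigma(dose)
        out = []
        for f in clean_hu:
            noise = rng.normal(0.0, sigma, size=f.shape)
            if params.noise.smooth_width > 0:
                noise = gaussian_filter(noise, params.noise.smooth_width)
            out.append(f + noise)
        return out

    full_hu = noisy(1.0)
    low_hu = noisy(params.dose_fraction)
    return (
        _sequence_from_hu(clean_hu, "clean", params),
        _sequence_from_hu(full_hu, "full_dose", params),
        _sequence_from_hu(low_hu, "low_dose", params),
    )


def default_roi(params: PhantomParams) -> ROISpec:
    """Largest centred square safely inside the flat aorta disc."""
    S = params.image_size
    cy = int(round((params.aorta_center[0] + 1.0) / 2.0 * S))
    cx = int(round((params.aorta_center[1] + 1.0) / 2.0 * S))
    r_px = params.aorta_radius / 2.0 * S
    half = int(np.floor(r_px / np.sqrt(2.0))) - 2  # inset clears the soft edge
    half = max(half, 1)
    return ROISpec(row0=cy - half, col0=cx - half, height=2 * half, width=2 * half)


def make_roi_fixture(params: PhantomParams) -> Tuple[PhaseSequence, ROISpec]:
    """A full-dose sequence plus an ROI lying entirely inside the flat
    aorta, for ROI-STD calibration tests (noise SD there ==
    ``params.noise.full_dose_sigma`` up to sampling error)."""
    _, full, _ = generate_phantom(params)
    return full, default_roi(params)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRanges:
    """Sampling ranges for per-phantom anatomy variation.

    ``cohort1`` chamber radii are offset by ``cohort_radius_offset``
    relative to ``cohort0`` — a purely structural analog of the paper's
    per-gender reporting, with no biological meaning claimed.
    """

    r_end_diastole: Tuple[float, float] = (0.31, 0.37)
    systole_ratio: Tuple[float, float] = (0.6, 0.72)
    wall_thickness: Tuple[float, float] = (0.08, 0.10)
    enhancement: Tuple[float, float] = (200.0, 350.0)
    cohort_radius_offset: float = -0.03

    def __post_init__(self):
        for name in ("r_end_diastole", "systole_ratio", "wall_thickness", "enhancement"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"degenerate range for {name}: ({lo}, {hi})")


@dataclass
class PhantomRecord:
    pair_id: int
    cohort_label: str
    params: PhantomParams
    clean: PhaseSequence
    full_dose: PhaseSequence
    low_dose: PhaseSequence


@dataclass
class PhantomPair:
    pair_id: int
    members: Dict[str, PhantomRecord]


def _draw_params(
    pair_id: int,
    cohort: str,
    ranges: CohortRanges,
    base: PhantomParams,
    rng: np.random.Generator,
    seed: int,
) -> PhantomParams:
    r_ed = rng.uniform(*ranges.r_end_diastole)
    if cohort == COHORT_LABELS[1]:
        r_ed += ranges.cohort_radius_offset
    r_es = r_ed * rng.uniform(*ranges.systole_ratio)
    wall = rng.uniform(*ranges.wall_thickness)
    enh = rng.uniform(*ranges.enhancement)
    return dataclasses.replace(
        base,
        cohort_label=cohort,
        seed=seed,
        motion=MotionParams(r_end_diastole=r_ed, r_end_systole=r_es, wall_thickness=wall),
        anatomy=dataclasses.replace(base.anatomy, enhancement=enh),
    )


def generate_cohort(
    n_pairs: int,
    param_ranges: CohortRanges = CohortRanges(),
    master_seed: int = 0,
    base_params: PhantomParams = PhantomParams(),
) -> List[PhantomPair]:
    """Generate ``n_pairs`` phantom pairs (one member per cohort label).

    Anatomy is drawn reproducibly from ``param_ranges``; every phantom
    gets a distinct seed derived from ``master_seed``. With ``n_pairs=9``
    the result feeds :func:`recyclect.training.build_cv_folds` directly.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    ss = np.random.SeedSequence(master_seed)
    children = ss.spawn(2 * n_pairs)
    pairs: List[PhantomPair] = []
    idx = 0
    for pair_id in range(1, n_pairs + 1):
        members: Dict[str, PhantomRecord] = {}
        for cohort in COHORT_LABELS:
            child = children[idx]
            idx += 1
            seed = int(child.generate_state(1)[0])
            rng = np.random.default_rng(child)
            params = _draw_params(pair_id, cohort, param_ranges, base_params, rng, seed)
            clean, full, low = generate_phantom(params)
            members[cohort] = PhantomRecord(
                pair_id=pair_id,
                cohort_label=cohort,
                params=params,
                clean=clean,
                full_dose=full,
                low_dose=low,
            )
        pairs.append(PhantomPair(pair_id=pair_id, members=members))
    return pairs
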