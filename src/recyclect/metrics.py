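"""Quantitative evaluation: MSE, PSNR, SSIM, ROI standard deviation,
noise-based frame selection, and report aggregation.

Conventions
-----------
* Paired metrics operate on the raw 12-bit scale; PSNR's MAX defaults to
  4095.
* SSIM is the product of luminance, contrast and structure terms computed
  globally over the frame (single window); a sliding-window variant is
  available behind ``windowed=True``. Moments use the population (``ddof=0``)
  estimator.
* ROI STD is the sample (``ddof=1``) standard deviation of the HU values
  in a 0-based half-open rectangle; it is translation invariant, so raw
  and HU inputs give the same value.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import uniform_filter

from recyclect.sequence import RAW_MAX, PhaseSequence

__all__ = [
    "SSIMConstants",
    "ROISpec",
    "SelectionCriteria",
    "MetricReport",
    "mse",
    "psnr",
    "ssim",
    "roi_std",
    "select_low_full_frames",
    "evaluate_sequence",
]


@dataclass(frozen=True)
class SSIMConstants:
    """Stabilising constants; defaults follow the standard convention
    c1=(k1 L)^2, c2=(k2 L)^2, c3=c2/2 with k1=0.01, k2=0.03, L=4095."""

    c1: float = (0.01 * RAW_MAX) ** 2
    c2: float = (0.03 * RAW_MAX) ** 2
    c3: float = (0.03 * RAW_MAX) ** 2 / 2

    def __post_init__(self):
        if min(self.c1, self.c2, self.c3) <= 0:
            raise ValueError("SSIM constants must be positive")

    @classmethod
    def from_k(cls, k1: float = 0.01, k2: float = 0.03, L: float = RAW_MAX) -> "SSIMConstants":
        c2 = (k2 * L) ** 2
        return cls(c1=(k1 * L) ** 2, c2=c2, c3=c2 / 2)


@dataclass(frozen=True)
class ROISpec:
    """Rectangle (row0, col0, height, width), 0-based, half-open."""

    row0: int
    col0: int
    height: int
    width: int

    def __post_init__(self):
        if self.row0 < 0 or self.col0 < 0 or self.height < 1 or self.width < 1:
            raise ValueError(f"invalid ROI {self}")
        if self.height * self.width < 2:
            raise ValueError("ROI area must be at least 2 pixels")

    def slices(self) -> Tuple[slice, slice]:
        return (
            slice(self.row0, self.row0 + self.height),
            slice(self.col0, self.col0 + self.width),
        )

    def check_inside(self, shape: Tuple[int, int]) -> None:
        if self.row0 + self.height > shape[0] or self.col0 + self.width > shape[1]:
            raise ValueError(f"ROI {self} exceeds frame shape {shape}")


@dataclass(frozen=True)
class SelectionCriteria:
    """Noise thresholds for training-frame selection.

    A phase qualifies as full dose if its aorta-ROI STD is below
    ``full_dose_max_std`` (default 39 HU), as low dose if above
    ``low_dose_min_std`` (default 59 HU), and is kept only inside a run of
    at least ``min_consecutive`` (default 3) consecutive qualifying phases.
    """

    full_dose_max_std: float = 39.0
    low_dose_min_std: float = 59.0
    min_consecutive: int = 3
    looped: bool = False

    def __post_init__(self):
        if not self.full_dose_max_std < self.low_dose_min_std:
            raise ValueError("full-dose threshold must lie below low-dose threshold")
        if self.min_consecutive < 1:
            raise ValueError("min_consecutive must be >= 1")


def _check_pair(x: np.ndarray, y: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    return x, y


def mse(x: np.ndarray, y: np.ndarray) -> float:
    """Mean squared error (1/mn) sum (x - y)^2; symmetric."""
    x, y = _check_pair(x, y)
    return float(np.mean((x - y) ** 2))


def psnr(x: np.ndarray, y: np.ndarray, max_value: float = float(RAW_MAX)) -> float:
    """10 log10(MAX^2 / MSE) in dB; identical frames give +inf, never raise."""
    m = mse(x, y)
    if m == 0.0:
        return float("inf")
    return float(10.0 * np.log10(max_value**2 / m))


def _ssim_terms(x, y, c: SSIMConstants) -> float:
    mu_x, mu_y = np.mean(x), np.mean(y)
    var_x, var_y = np.var(x), np.var(y)
    cov = np.mean((x - mu_x) * (y - mu_y))
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c.c1) / (mu_x**2 + mu_y**2 + c.c1)
    con = (2 * sd_x * sd_y + c.c2) / (var_x + var_y + c.c2)
    struct = (cov + c.c3) / (sd_x * sd_y + c.c3)
    return float(lum * con * struct)


def ssim(
    x: np.ndarray,
    y: np.ndarray,
    constants: SSIMConstants = SSIMConstants(),
    windowed: bool = False,
    window: int = 8,
) -> float:
    """Structural similarity l*c*s, globally per frame by default.

    The classical l*c*s decomposition is used (contrast term
    ``2 sd_x sd_y`` in the numerator). With ``windowed=True``, terms are
    computed in a uniform sliding window and mean-pooled, for
    comparability with common toolkits.
    """
    x, y = _check_pair(x, y)
    if not windowed:
        return _ssim_terms(x, y, constants)
    mu_x = uniform_filter(x, window)
    mu_y = uniform_filter(y, window)
    var_x = np.maximum(uniform_filter(x * x, window) - mu_x**2, 0.0)
    var_y = np.maximum(uniform_filter(y * y, window) - mu_y**2, 0.0)
    cov = uniform_filter(x * y, window) - mu_x * mu_y
    sd_x, sd_y = np.sqrt(var_x), np.sqrt(var_y)
    c = constants
    lum = (2 * mu_x * mu_y + c.c1) / (mu_x**2 + mu_y**2 + c.c1)
    con = (2 * sd_x * sd_y + c.c2) / (var_x + var_y + c.c2)
    struct = (cov + c.c3) / (sd_x * sd_y + c.c3)
    return float(np.mean(lum * con * struct))


def roi_std(frame: np.ndarray, roi: ROISpec) -> float:
    """Sample standard deviation (n-1 denominator) inside the ROI, in HU."""
    frame = np.asarray(frame, dtype=np.float64)
    roi.check_inside(frame.shape)
    values = frame[roi.slices()]
    return float(np.std(values, ddof=1))


def _qualifying_runs(qualifies: np.ndarray, min_run: int, looped: bool) -> List[int]:
    """Indices belonging to a run of >= min_run consecutive True entries.

    Runs may wrap around the end when ``looped``.
    """
    n = len(qualifies)
    if not qualifies.any():
        return []
    if qualifies.all():
        return list(range(n)) if n >= min_run else []
    if looped:
        # rotate so the scan starts at a False entry; runs then never wrap
        start = int(np.argmin(qualifies))
        order = [(start + i) % n for i in range(n)]
    else:
        order = list(range(n))
    selected: List[int] = []
    run: List[int] = []
    for idx in order:
        if qualifies[idx]:
            run.append(idx)
        else:
            if len(run) >= min_run:
                selected.extend(run)
            run = []
    if len(run) >= min_run:
        selected.extend(run)
    return sorted(selected)


def select_low_full_frames(
    per_phase_stds: Sequence[float], criteria: SelectionCriteria = SelectionCriteria()
) -> Tuple[List[int], List[int]]:
    """Classify phases into (low-dose, full-dose) training candidates.

    A phase is kept for a class only if it sits in a run of at least
    ``min_consecutive`` consecutive phases all satisfying that class's
    threshold (full dose: STD < max; low dose: STD > min). Runs may wrap
    when ``criteria.looped``. Returned phase indices are 1-based and the
    two lists are disjoint by construction of the thresholds.
    """
    stds = np.asarray(list(per_phase_stds), dtype=np.float64)
    if len(stds) < criteria.min_consecutive:
        raise ValueError(
            f"need at least {criteria.min_consecutive} phases, got {len(stds)}"
        )
    low = _qualifying_runs(stds > criteria.low_dose_min_std, criteria.min_consecutive, criteria.looped)
    full = _qualifying_runs(stds < criteria.full_dose_max_std, criteria.min_consecutive, criteria.looped)
    return [i + 1 for i in low], [i + 1 for i in full]


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """Per-frame and aggregate results for one evaluated sequence."""

    per_frame: List[Dict[str, float]]
    provenance: Dict[str, object] = field(default_factory=dict)

    def _column(self, key: str) -> np.ndarray:
        return np.asarray([row[key] for row in self.per_frame if key in row], float)

    def aggregate(self, key: str) -> Dict[str, float]:
        col = self._column(key)
        if col.size == 0:
            raise KeyError(f"no per-frame values for {key!r}")
        finite = col[np.isfinite(col)]
        mean = float(np.mean(col)) if finite.size == col.size else float("inf")
        sd = float(np.std(finite, ddof=1)) if finite.size > 1 else 0.0
        return {"mean": mean, "sd": sd, "n": int(col.size)}

    def _numeric_keys(self) -> List[str]:
        keys = sorted({k for row in self.per_frame for k in row if k != "phase"})
        return [
            k
            for k in keys
            if all(
                isinstance(row[k], (int, float, np.floating, np.integer))
                for row in self.per_frame
                if k in row
            )
        ]

    def aggregates(self) -> Dict[str, Dict[str, float]]:
        return {k: self.aggregate(k) for k in self._numeric_keys()}

    def subgroup_aggregates(self, group_key: str) -> Dict[str, Dict[str, Dict[str, float]]]:
        """Aggregates recomputed within each value of a grouping column."""
        groups = sorted({str(row[group_key]) for row in self.per_frame if group_key in row})
        out: Dict[str, Dict[str, Dict[str, float]]] = {}
        for g in groups:
            sub = MetricReport(
                per_frame=[r for r in self.per_frame if str(r.get(group_key)) == g],
                provenance=self.provenance,
            )
            out[g] = sub.aggregates()
        return out

    def to_json(self, path=None) -> str:
        payload = json.dumps(
            {
                "provenance": self.provenance,
                "aggregates": self.aggregates(),
                "per_frame": self.per_frame,
            },
            indent=1,
            default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def to_csv(self, path) -> Path:
        path = Path(path)
        keys = ["phase"] + sorted(
            {k for row in self.per_frame for k in row if k != "phase"}
        )
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            for row in self.per_frame:
                writer.writerow(row)
        return path


def evaluate_sequence(
    candidate: PhaseSequence,
    reference: Optional[PhaseSequence] = None,
    roi: Optional[ROISpec] = None,
    constants: SSIMConstants = SSIMConstants(),
    provenance: Optional[dict] = None,
) -> MetricReport:
    """Evaluate a sequence against a clean reference and/or via ROI STD.

    With a reference, per-phase MSE/PSNR/SSIM are computed; without one
    (clinical-style data) an ROI is required and per-phase ROI STDs are
    reported instead. Both may be combined.
    """
    if reference is None and roi is None:
        raise ValueError("need a reference sequence and/or an ROI")
    if reference is not None and reference.phase_count != candidate.phase_count:
        raise ValueError(
            f"candidate has {candidate.phase_count} phases, reference "
            f"{reference.phase_count}"
        )
    rows: List[Dict[str, float]] = []
    for t in range(1, candidate.phase_count + 1):
        row: Dict[str, float] = {"phase": t}
        frame = candidate.frame(t)
        if reference is not None:
            ref = reference.frame(t)
            row["mse"] = mse(frame, ref)
            row["psnr"] = psnr(frame, ref)
            row["ssim"] = ssim(frame, ref, constants)
        if roi is not None:
            row["roi_std"] = roi_std(frame, roi)
        rows.append(row)
    return MetricReport(per_frame=rows, provenance=dict(provenance or {}))
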