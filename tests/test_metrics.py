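import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recyclect.metrics import (
    MetricReport,
    ROISpec,
    SelectionCriteria,
    SSIMConstants,
    evaluate_sequence,
    mse,
    psnr,
    roi_std,
    select_low_full_frames,
    ssim,
)
from recyclect.sequence import PhaseSequence


# --- independent reference implementations (explicit loops, no reuse) ----

def ref_mse(x, y):
    m, n = x.shape
    acc = 0.0
    for i in range(m):
        for j in range(n):
            acc += (x[i, j] - y[i, j]) ** 2
    return acc / (m * n)


def ref_psnr(x, y, max_value=4095.0):
    m = ref_mse(x, y)
    if m == 0:
        return float("inf")
    return 10.0 * math.log10(max_value**2 / m)


def ref_ssim(x, y, c1, c2, c3):
    n = x.size
    mu_x = float(sum(x.ravel())) / n
    mu_y = float(sum(y.ravel())) / n
    var_x = sum((v - mu_x) ** 2 for v in x.ravel()) / n
    var_y = sum((v - mu_y) ** 2 for v in y.ravel()) / n
    cov = sum((v - mu_x) * (w - mu_y) for v, w in zip(x.ravel(), y.ravel())) / n
    sx, sy = math.sqrt(var_x), math.sqrt(var_y)
    lum = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
    con = (2 * sx * sy + c2) / (var_x + var_y + c2)
    s = (cov + c3) / (sx * sy + c3)
    return lum * con * s


def ref_run_scan(qualifies, min_run, looped):
    """Brute-force run scan: for every index, check whether it belongs to
    any run of >= min_run consecutive qualifying entries."""
    n = len(qualifies)
    selected = set()
    for start in range(n):
        for length in range(min_run, n + 1):
            idxs = [(start + k) % n for k in range(length)]
            if not looped and start + length > n:
                continue
            if all(qualifies[i] for i in idxs):
                selected.update(idxs)
    return sorted(selected)


class TestMSE:
    def test_identical(self, rng):
        x = rng.uniform(0, 4095, (5, 5))
        assert mse(x, x) == 0.0

    def test_hand_value(self):
        x = np.zeros((2, 2))
        y = np.zeros((2, 2))
        y[0, 0] = 4.0
        assert mse(x, y) == pytest.approx(4.0)

    def test_symmetry_and_reference(self, rng):
        x = rng.uniform(0, 4095, (4, 4))
        y = rng.uniform(0, 4095, (4, 4))
        assert mse(x, y) == pytest.approx(mse(y, x), rel=1e-15)
        assert mse(x, y) == pytest.approx(ref_mse(x, y), rel=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            mse(np.zeros((2, 2)), np.zeros((3, 3)))


class TestPSNR:
    def test_zero_db_case(self):
        x = np.zeros((4, 4))
        y = np.full((4, 4), 4095.0)
        assert psnr(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_identical_gives_inf(self):
        x = np.ones((3, 3))
        assert psnr(x, x) == float("inf")

    def test_one_pixel_case(self):
        x = np.zeros((2, 2))
        y = np.zeros((2, 2))
        y[1, 1] = 4095.0
        # MSE = 4095^2/4 -> PSNR = 10 log10 4 = 6.0206 dB
        assert psnr(x, y) == pytest.approx(10 * math.log10(4.0), abs=1e-9)

    def test_monotone_decreasing_in_mse(self, rng):
        x = np.zeros((8, 8))
        noise = rng.normal(0, 1, (8, 8))
        values = [psnr(x, s * noise) for s in (1, 2, 4, 8)]
        assert all(a > b for a, b in zip(values, values[1:]))

    @pytest.mark.parametrize("trial", range(100))
    def test_agrees_with_reference(self, trial):
        rng = np.random.default_rng(trial)
        x = rng.uniform(0, 4095, (6, 6))
        y = rng.uniform(0, 4095, (6, 6))
        assert psnr(x, y) == pytest.approx(ref_psnr(x, y), rel=1e-9)


class TestSSIM:
    def test_identity_is_one(self, rng):
        x = rng.uniform(0, 4095, (8, 8))
        assert ssim(x, x) == pytest.approx(1.0, abs=1e-12)

    def test_constant_frames_luminance_only(self):
        x = np.zeros((4, 4))
        y = np.full((4, 4), 4095.0)
        c = SSIMConstants()
        expected = c.c1 / (4095.0**2 + c.c1)
        assert ssim(x, y) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(1.0e-4, rel=2e-2)

    def test_symmetry(self, rng):
        x = rng.uniform(0, 4095, (8, 8))
        y = rng.uniform(0, 4095, (8, 8))
        assert ssim(x, y) == pytest.approx(ssim(y, x), rel=1e-12)

    @pytest.mark.parametrize("trial", range(100))
    def test_agrees_with_reference(self, trial):
        rng = np.random.default_rng(1000 + trial)
        x = rng.uniform(0, 4095, (6, 6))
        y = rng.uniform(0, 4095, (6, 6))
        c = SSIMConstants()
        assert ssim(x, y) == pytest.approx(ref_ssim(x, y, c.c1, c.c2, c.c3), rel=1e-9)

    def test_range(self, rng):
        for trial in range(20):
            x = rng.uniform(0, 4095, (5, 5))
            y = rng.uniform(0, 4095, (5, 5))
            assert -1.0 <= ssim(x, y) <= 1.0

    def test_constants_derivation(self):
        c = SSIMConstants.from_k(k1=0.01, k2=0.03, L=4095)
        assert c.c1 == pytest.approx((0.01 * 4095) ** 2)
        assert c.c3 == pytest.approx(c.c2 / 2)

    def test_windowed_mode_close_to_global_on_stationary_noise(self, rng):
        x = rng.normal(1000, 30, (32, 32))
        y = x + rng.normal(0, 10, (32, 32))
        g = ssim(x, y)
        w = ssim(x, y, windowed=True)
        assert abs(g - w) < 0.2


class TestRoiStd:
    def test_constant_region_zero(self):
        frame = np.full((6, 6), 100.0)
        assert roi_std(frame, ROISpec(1, 1, 3, 3)) == 0.0

    def test_hand_value(self):
        frame = np.array([[0.0, 2.0], [0.0, 2.0]])
        assert roi_std(frame, ROISpec(0, 0, 2, 2)) == pytest.approx(math.sqrt(4.0 / 3.0))

    def test_translation_invariant(self, rng):
        frame = rng.uniform(0, 100, (8, 8))
        roi = ROISpec(2, 2, 4, 4)
        assert roi_std(frame + 500.0, roi) == pytest.approx(roi_std(frame, roi), rel=1e-12)

    def test_roi_outside_frame(self):
        with pytest.raises(ValueError):
            roi_std(np.zeros((4, 4)), ROISpec(2, 2, 4, 4))

    def test_area_minimum(self):
        with pytest.raises(ValueError):
            ROISpec(0, 0, 1, 1)


LOW_PHASE_STDS = {1: 60.12, 2: 62.35, 3: 58.17, 4: 49.34, 5: 45.06, 6: 51.09, 19: 65.61, 20: 66.56}
FULL_PHASE_STDS = {8: 31.09, 9: 29.01, 10: 36.84, 11: 34.17, 12: 35.27, 13: 35.33, 14: 38.39, 15: 39.59}


def twenty_phase_stds():
    """A 20-phase STD profile embedding the published low/full-dose values;
    unlisted transition phases sit between the two thresholds."""
    stds = {**LOW_PHASE_STDS, **FULL_PHASE_STDS, 7: 45.0, 16: 45.0, 17: 50.0, 18: 55.0}
    return [stds[t] for t in range(1, 21)]


class TestFrameSelection:
    def test_published_profile_non_looped(self):
        crit = SelectionCriteria(looped=False)
        low, full = select_low_full_frames(twenty_phase_stds(), crit)
        # qualifying low runs {1,2} and {19,20} are both shorter than 3
        assert low == []
        # phase 15 (STD 39.59) misses the <39 threshold; run 8..14 qualifies
        assert full == [8, 9, 10, 11, 12, 13, 14]

    def test_published_profile_looped(self):
        crit = SelectionCriteria(looped=True)
        low, full = select_low_full_frames(twenty_phase_stds(), crit)
        assert sorted(low) == [1, 2, 19, 20]  # wrap run 19,20,1,2 of length 4

    def test_all_full_dose(self):
        low, full = select_low_full_frames([30.0] * 8, SelectionCriteria())
        assert low == [] and full == list(range(1, 9))

    def test_outputs_disjoint_random(self, rng):
        crit = SelectionCriteria(looped=True)
        for _ in range(50):
            stds = rng.uniform(20, 80, size=12)
            low, full = select_low_full_frames(stds, crit)
            assert not set(low) & set(full)

    @pytest.mark.parametrize("looped", [False, True])
    def test_brute_force_oracle_agreement(self, looped):
        rng = np.random.default_rng(7 if looped else 8)
        crit = SelectionCriteria(looped=looped)
        for _ in range(1000):
            n = int(rng.integers(3, 25))
            stds = rng.uniform(20, 80, size=n)
            low, full = select_low_full_frames(stds, crit)
            exp_low = [i + 1 for i in ref_run_scan(stds > 59.0, 3, looped)]
            exp_full = [i + 1 for i in ref_run_scan(stds < 39.0, 3, looped)]
            assert low == exp_low
            assert full == exp_full

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            SelectionCriteria(full_dose_max_std=60, low_dose_min_std=59)

    def test_too_short_input(self):
        with pytest.raises(ValueError):
            select_low_full_frames([70.0, 70.0], SelectionCriteria())


class TestEvaluateSequence:
    def _seq(self, frames, scale="raw12bit"):
        return PhaseSequence(frames=frames, intensity_scale=scale, looped=True)

    def test_identity_candidate(self, rng):
        frames = [rng.uniform(0, 4095, (8, 8)) for _ in range(4)]
        seq = self._seq(frames)
        report = evaluate_sequence(seq, reference=self._seq([f.copy() for f in frames]))
        for row in report.per_frame:
            assert row["psnr"] == float("inf")
            assert row["ssim"] == pytest.approx(1.0, abs=1e-12)

    def test_roi_only_constant(self):
        frames = [np.full((8, 8), 1000.0) for _ in range(3)]
        report = evaluate_sequence(self._seq(frames), roi=ROISpec(1, 1, 4, 4))
        assert all(row["roi_std"] == 0.0 for row in report.per_frame)

    def test_needs_reference_or_roi(self):
        seq = self._seq([np.zeros((4, 4))])
        with pytest.raises(ValueError):
            evaluate_sequence(seq)

    def test_known_noise_roi_std(self, rng):
        sigma, n = 50.0, 32 * 32
        frames = [1000.0 + rng.normal(0, sigma, (32, 32)) for _ in range(8)]
        frames = [np.clip(f, 0, 4095) for f in frames]
        report = evaluate_sequence(self._seq(frames), roi=ROISpec(0, 0, 32, 32))
        mean_std = np.mean([row["roi_std"] for row in report.per_frame])
        tol = 3 * sigma / math.sqrt(2 * (n - 1))
        assert abs(mean_std - sigma) < tol

    def test_aggregates_match_recomputation(self, rng):
        frames = [rng.uniform(0, 4095, (8, 8)) for _ in range(4)]
        ref = [rng.uniform(0, 4095, (8, 8)) for _ in range(4)]
        report = evaluate_sequence(self._seq(frames), reference=self._seq(ref))
        agg = report.aggregate("psnr")
        per = [row["psnr"] for row in report.per_frame]
        assert agg["mean"] == pytest.approx(np.mean(per), rel=1e-12)
        assert agg["sd"] == pytest.approx(np.std(per, ddof=1), rel=1e-12)

    def test_csv_and_json_roundtrip(self, tmp_path, rng):
        frames = [rng.uniform(0, 4095, (4, 4)) for _ in range(2)]
        report = evaluate_sequence(self._seq(frames), roi=ROISpec(0, 0, 3, 3))
        report.to_csv(tmp_path / "r.csv")
        report.to_json(tmp_path / "r.json")
        import json

        payload = json.loads((tmp_path / "r.json").read_text())
        assert "roi_std" in payload["aggregates"]
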