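import numpy as np
import pytest

from recyclect.losses import LossWeights
from recyclect.networks import make_generator, GeneratorConfig
from recyclect.phantom import PhantomParams, generate_cohort, generate_phantom
from recyclect.sequence import PhaseSequence
from recyclect.training import (
    FoldPlan,
    TrainingConfig,
    TrainingHistory,
    build_cv_folds,
    denoise_sequence,
    default_lr_grid,
    finalize_and_evaluate,
    learning_rate_search,
    train_cyclegan,
    train_recyclegan,
)


@pytest.fixture(scope="module")
def tiny_cohort():
    base = PhantomParams(image_size=32, phase_count=8)
    return generate_cohort(3, master_seed=42, base_params=base)


def tiny_dataset(cohort):
    return {
        "a": [p.members[c].low_dose for p in cohort for c in p.members],
        "b": [p.members[c].full_dose for p in cohort for c in p.members],
    }


class TestConfig:
    def test_lr_range_enforced(self):
        with pytest.raises(ValueError):
            TrainingConfig(learning_rate=0.01)
        TrainingConfig(learning_rate=0.01, allow_lr_outside_range=True)

    def test_objective_validated(self):
        with pytest.raises(ValueError):
            TrainingConfig(objective="pix2pix")


class TestTrainCycleGAN:
    def test_epochs_zero_noop(self, tiny_cohort):
        cfg = TrainingConfig(objective="cyclegan", epochs=0, seed=1)
        models, history = train_cyclegan(tiny_dataset(tiny_cohort), cfg)
        assert history.records == []
        fresh = train_cyclegan(tiny_dataset(tiny_cohort), cfg)[0]
        for a, b in zip(models.g_ab.module.state_arrays(), fresh.g_ab.module.state_arrays()):
            np.testing.assert_array_equal(a, b)

    def test_empty_domain_rejected(self, tiny_cohort):
        cfg = TrainingConfig(objective="cyclegan")
        with pytest.raises(ValueError):
            train_cyclegan({"a": [], "b": tiny_dataset(tiny_cohort)["b"]}, cfg)

    def test_wrong_objective_rejected(self, tiny_cohort):
        with pytest.raises(ValueError):
            train_cyclegan(tiny_dataset(tiny_cohort), TrainingConfig(objective="recyclegan"))

    def test_determinism_and_breakdown_consistency(self, tiny_cohort):
        cfg = TrainingConfig(objective="cyclegan", epochs=1, max_steps=6, seed=3)
        data = tiny_dataset(tiny_cohort)
        m1, h1 = train_cyclegan(data, cfg)
        m2, h2 = train_cyclegan(data, cfg)
        assert [r["total"] for r in h1.records] == [r["total"] for r in h2.records]
        for a, b in zip(m1.g_ab.module.state_arrays(), m2.g_ab.module.state_arrays()):
            np.testing.assert_array_equal(a, b)
        lam = cfg.weights.lambda_cycle
        for rec in h1.records:
            assert rec["total"] == pytest.approx(
                rec["gan_AB"] + rec["gan_BA"] + lam * rec["cycle"], rel=1e-10
            )


class TestTrainRecycleGAN:
    def test_epochs_zero_noop(self, tiny_cohort):
        cfg = TrainingConfig(objective="recyclegan", epochs=0, seed=1)
        models, history = train_recyclegan(tiny_dataset(tiny_cohort), cfg)
        assert history.records == []
        assert models.p_a is not None

    def test_all_lambda_zero_pure_adversarial(self, tiny_cohort):
        weights = LossWeights(lambda_rx=0, lambda_ry=0, lambda_tau_x=0, lambda_tau_y=0)
        cfg = TrainingConfig(
            objective="recyclegan", epochs=1, max_steps=3, seed=2, weights=weights
        )
        models, history = train_recyclegan(tiny_dataset(tiny_cohort), cfg)
        # predictors receive no gradient: parameters must stay at init
        from recyclect.training import _make_models

        fresh = _make_models(cfg, with_predictors=True)
        for a, b in zip(models.p_a.module.state_arrays(), fresh.p_a.module.state_arrays()):
            np.testing.assert_array_equal(a, b)
        # but generators did move
        moved = any(
            not np.array_equal(a, b)
            for a, b in zip(
                models.g_ab.module.state_arrays(), fresh.g_ab.module.state_arrays()
            )
        )
        assert moved

    def test_too_short_non_looped_sequences_rejected(self):
        frames = [np.zeros((32, 32)) for _ in range(2)]
        seq = PhaseSequence(frames=frames, intensity_scale="raw12bit", looped=False)
        cfg = TrainingConfig(objective="recyclegan", window_w=2)
        with pytest.raises(ValueError):
            train_recyclegan({"a": [seq], "b": [seq]}, cfg)

    def test_breakdown_consistency(self, tiny_cohort):
        cfg = TrainingConfig(objective="recyclegan", epochs=1, max_steps=3, seed=5)
        _, history = train_recyclegan(tiny_dataset(tiny_cohort), cfg)
        w = cfg.weights
        for rec in history.records:
            expected = (
                rec["gan_AB"]
                + rec["gan_BA"]
                + w.lambda_rx * rec["recycle_x"]
                + w.lambda_ry * rec["recycle_y"]
                + w.lambda_tau_x * rec["recurrent_x"]
                + w.lambda_tau_y * rec["recurrent_y"]
            )
            assert rec["total"] == pytest.approx(expected, rel=1e-10)


class TestDenoiseSequence:
    def test_identity_generator_round_trip(self, tiny_cohort):
        low = tiny_cohort[0].members["cohort0"].low_dose
        ident = lambda x: x  # noqa: E731
        out = denoise_sequence(ident, low)
        assert out.domain_label == "denoised"
        assert out.looped == low.looped
        assert out.phase_count == low.phase_count
        for f, g in zip(low.frames, out.frames):
            assert np.max(np.abs(f - g)) <= 0.5 + 1e-9  # rescale rounding only

    def test_model_scale_input_rejected(self):
        seq = PhaseSequence(frames=[np.zeros((4, 4))], intensity_scale="model")
        g = make_generator(GeneratorConfig(image_size=4, n_downsample=0), seed=0)
        with pytest.raises(ValueError):
            denoise_sequence(g, seq)


class _FakeModels:
    def __init__(self, g_ab):
        self.g_ab = g_ab


class TestLearningRateSearch:
    def _val_set(self):
        clean, _, low = generate_phantom(PhantomParams(image_size=32, seed=13))
        return [(low, clean)]

    def test_single_element_grid(self):
        val = self._val_set()
        best, table = learning_rate_search(lambda r: _FakeModels(lambda x: x), [1e-4], val)
        assert best == 1e-4
        assert set(table) == {1e-4}

    def test_argmax_by_construction(self):
        # mock train_fn: each rate yields a denoiser blending a known
        # fraction of the way toward clean, so the PSNR ordering is forced
        alpha_by_rate = {1e-5: 0.3, 1e-4: 0.6, 1e-3: 0.0}
        clean, _, low = generate_phantom(PhantomParams(image_size=32, seed=14))
        val = [(low, clean)]
        from recyclect.sequence import to_model_scale

        pairs = [(to_model_scale(f), to_model_scale(c)) for f, c in zip(low.frames, clean.frames)]

        def fake_train(rate):
            alpha = alpha_by_rate[rate]

            def g(x):
                for lo_f, cl_f in pairs:
                    if np.array_equal(x, lo_f):
                        return alpha * cl_f + (1 - alpha) * lo_f
                raise AssertionError("unexpected input frame")

            return _FakeModels(g)

        best, table = learning_rate_search(fake_train, list(alpha_by_rate), val)
        assert best == 1e-4
        assert table[1e-4] > table[1e-5] > table[1e-3]

    def test_tie_breaks_toward_smaller_rate(self):
        val = self._val_set()
        ident = lambda rate: _FakeModels(lambda x: x)  # same PSNR for all rates
        best, _ = learning_rate_search(ident, [1e-4, 1e-5], val)
        assert best == 1e-5

    def test_failed_rates_excluded(self):
        val = self._val_set()

        def flaky(rate):
            if rate > 5e-5:
                raise RuntimeError("diverged")
            return _FakeModels(lambda x: x)

        best, table = learning_rate_search(flaky, [1e-5, 1e-4], val)
        assert best == 1e-5
        assert np.isnan(table[1e-4])

    def test_all_failed_errors(self):
        def dead(rate):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            learning_rate_search(dead, [1e-5], self._val_set())

    def test_empty_grid(self):
        with pytest.raises(ValueError):
            learning_rate_search(lambda r: None, [], self._val_set())

    def test_default_grid_spans_published_range(self):
        grid = default_lr_grid()
        assert len(grid) == 8
        assert grid[0] == pytest.approx(5.00e-6)
        assert grid[-1] == pytest.approx(1.26e-3)


class TestCVFolds:
    def test_published_assignments(self):
        folds = build_cv_folds(list(range(1, 10)))
        f1 = folds[0]
        assert f1.test_pair == 1
        assert f1.validation_pair == 8
        assert f1.train_pairs == (2, 3, 4, 5, 6, 7, 9)
        f9 = folds[8]
        assert f9.test_pair == 9
        assert f9.validation_pair == 5

    def test_full_table(self):
        expected_val = {1: 8, 2: 9, 3: 2, 4: 6, 5: 3, 6: 7, 7: 4, 8: 1, 9: 5}
        for fold in build_cv_folds(list(range(1, 10))):
            assert fold.validation_pair == expected_val[fold.fold_id]
            assert fold.test_pair == fold.fold_id
            assert len(fold.train_pairs) == 7

    def test_partition_property(self):
        folds = build_cv_folds(list(range(1, 10)))
        tests = [f.test_pair for f in folds]
        assert sorted(tests) == list(range(1, 10))
        for f in folds:
            union = set(f.train_pairs) | {f.validation_pair, f.test_pair}
            assert union == set(range(1, 10))

    def test_wrong_pair_count(self):
        with pytest.raises(ValueError):
            build_cv_folds(list(range(8)))

    def test_fold_plan_disjointness_enforced(self):
        with pytest.raises(ValueError):
            FoldPlan(fold_id=1, train_pairs=(1, 2), validation_pair=2, test_pair=3)


class TestFinalizeAndEvaluate:
    def _fold(self):
        return FoldPlan(fold_id=1, train_pairs=(2,), validation_pair=1, test_pair=1)

    def test_identity_denoiser_equals_noisy_baseline(self, tiny_cohort):
        from recyclect.metrics import psnr as psnr_fn

        fold = FoldPlan(fold_id=1, train_pairs=(3,), validation_pair=2, test_pair=1)
        cfg = TrainingConfig(objective="cyclegan")
        report = finalize_and_evaluate(fold, cfg, tiny_cohort, denoiser=lambda s: s)
        rec = tiny_cohort[0].members["cohort0"]
        expected = psnr_fn(rec.low_dose.frames[0], rec.clean.frames[0])
        row = [r for r in report.per_frame if r["cohort"] == "cohort0" and r["phase"] == 1][0]
        assert row["psnr"] == pytest.approx(expected, rel=1e-12)

    def test_clean_oracle_denoiser(self, tiny_cohort):
        fold = FoldPlan(fold_id=1, train_pairs=(3,), validation_pair=2, test_pair=1)
        cfg = TrainingConfig(objective="cyclegan")
        by_id = {p.pair_id: p for p in tiny_cohort}

        def oracle(seq):
            for rec in by_id[1].members.values():
                if seq is rec.low_dose:
                    return rec.clean
            raise AssertionError

        report = finalize_and_evaluate(fold, cfg, tiny_cohort, denoiser=oracle)
        assert all(r["psnr"] == float("inf") for r in report.per_frame)
        assert all(r["ssim"] == pytest.approx(1.0) for r in report.per_frame)

    def test_subgroup_aggregates_structure(self, tiny_cohort):
        fold = FoldPlan(fold_id=1, train_pairs=(3,), validation_pair=2, test_pair=1)
        report = finalize_and_evaluate(
            fold, TrainingConfig(), tiny_cohort, denoiser=lambda s: s
        )
        sub = report.subgroup_aggregates("cohort")
        assert set(sub) == {"cohort0", "cohort1"}
        for agg in sub.values():
            assert "psnr" in agg and "ssim" in agg


class TestHistory:
    def test_monotone_step_counter_enforced(self):
        from recyclect.losses import LossBreakdown

        h = TrainingHistory()
        bd = LossBreakdown(objective="cyclegan", total=0.0, terms={})
        h.append(1, bd, 0, "abc")
        with pytest.raises(ValueError):
            h.append(1, bd, 0, "abc")

    def test_records_carry_seed_and_config(self):
        from recyclect.losses import LossBreakdown

        h = TrainingHistory()
        h.append(1, LossBreakdown(objective="cyclegan", total=0.0, terms={}), 7, "cfg")
        assert h.records[0]["seed"] == 7
        assert h.records[0]["config"] == "cfg"
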