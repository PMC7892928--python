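"""Splits and the training loop: partitioning, stratification, bookkeeping."""

import numpy as np
import pytest

from triseg.exceptions import ConfigError, SplitError
from triseg.losses import LossConfig
from triseg.nn import NetworkConfig
from triseg.patches import AugmentConfig, SamplerConfig
from triseg.phantoms import generate_cohort
from triseg.training import (
    SplitPlan,
    TrainConfig,
    make_holdout,
    make_kfold,
    prepare_subjects,
    train_ensemble,
    train_orientation,
)

from .conftest import small_spec


def _ids(cohort):
    return {s.subject_id for s in cohort}


class TestHoldout:
    def test_worked_example_10_subjects(self, small_cohort):
        plan = make_holdout(small_cohort, (0.5, 0.25, 0.25), seed=0)
        assert len(plan.train) == 6 and len(plan.validation) == 3 and len(plan.test) == 3
        # stratified: patients (4) split 2/1/1, controls (8) split 4/2/2
        pats = [s.subject_id for s in small_cohort if s.group == "patient"]
        assert sum(p in plan.train for p in pats) == 2
        assert sum(p in plan.validation for p in pats) == 1
        assert sum(p in plan.test for p in pats) == 1

    def test_partition_property_random_cohorts(self):
        rng = np.random.default_rng(0)
        for trial in range(100):
            n_c = int(rng.integers(3, 20))
            n_p = int(rng.integers(3, 20))
            cohort = [
                type("S", (), {"subject_id": f"s{i}", "group": g})()
                for i, g in enumerate(["control"] * n_c + ["patient"] * n_p)
            ]
            plan = make_holdout(cohort, (0.6, 0.2, 0.2), seed=trial)
            union = set(plan.train) | set(plan.validation) | set(plan.test)
            assert union == _ids(cohort)
            assert len(plan.train) + len(plan.validation) + len(plan.test) == len(cohort)

    def test_seeded_and_seed_sensitive(self, small_cohort):
        a = make_holdout(small_cohort, seed=3)
        b = make_holdout(small_cohort, seed=3)
        c = make_holdout(small_cohort, seed=4)
        assert a == b
        assert a != c

    def test_bad_fractions(self, small_cohort):
        with pytest.raises(SplitError):
            make_holdout(small_cohort, (0.5, 0.3, 0.3))

    def test_empty_role_detected(self, small_cohort):
        # 1 subject per stratum cannot fill three roles
        one = [small_cohort[0]]
        with pytest.raises(SplitError):
            make_holdout(one, (0.34, 0.33, 0.33))

    def test_overlap_guard(self):
        with pytest.raises(SplitError):
            SplitPlan(train=("a", "b"), validation=("b",), test=("c",)).validate()


class TestKFold:
    def test_test_sets_partition_cohort(self, small_cohort):
        for k in (2, 3, 4):
            plans = make_kfold(small_cohort, k, seed=1)
            assert len(plans) == k
            tests = [set(p.test) for p in plans]
            assert set().union(*tests) == _ids(small_cohort)
            assert sum(len(t) for t in tests) == len(small_cohort)
            for p in plans:
                assert set(p.train) == _ids(small_cohort) - set(p.test)
                assert p.validation == ()

    def test_stratified_fold_balance(self, small_cohort):
        plans = make_kfold(small_cohort, 4, seed=2)
        for p in plans:
            pats = sum(1 for s in small_cohort if s.group == "patient" and s.subject_id in p.test)
            assert pats == 1  # 4 patients over 4 folds

    def test_errors(self, small_cohort):
        with pytest.raises(SplitError):
            make_kfold(small_cohort, 1)
        with pytest.raises(SplitError):
            make_kfold(small_cohort, 99)

    def test_property_random_cohorts(self):
        rng = np.random.default_rng(5)
        for trial in range(50):
            n = int(rng.integers(4, 25))
            k = int(rng.integers(2, min(n, 6) + 1))
            cohort = [
                type("S", (), {"subject_id": f"s{i}", "group": rng.choice(["a", "b"])})()
                for i in range(n)
            ]
            plans = make_kfold(cohort, k, seed=trial)
            tests = [set(p.test) for p in plans]
            assert set().union(*tests) == _ids(cohort)
            assert sum(map(len, tests)) == n
            sizes = sorted(map(len, tests))
            assert sizes[-1] - sizes[0] <= 2  # near-equal folds (<=1 per stratum)


class TestConfigValidation:
    def test_loss_head_mismatch(self):
        cfg = TrainConfig(
            loss=LossConfig(kind="dice"),
            network=NetworkConfig(output_mode="softmax_2ch"),
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_boundary_horizon_too_short(self):
        cfg = TrainConfig(epochs=20, loss=LossConfig(kind="boundary", total_epochs=10))
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_patch_must_fit_network_depth(self):
        cfg = TrainConfig(
            loss=LossConfig(kind="dice"),
            network=NetworkConfig(depth=5, output_mode="sigmoid_1ch"),
            sampler=SamplerConfig(patch_size=(16, 16)),
        )
        with pytest.raises(ConfigError):
            cfg.validate()


class TestTrainingLoop:
    def test_history_bookkeeping(self, tiny_ensemble, tiny_train_config):
        _, history, plan, _ = tiny_ensemble
        assert len(history) == 3 * tiny_train_config.epochs
        for rec in history:
            assert rec["orientation"] in ("sagittal", "coronal", "axial")
            assert 1 <= rec["epoch"] <= tiny_train_config.epochs
            assert np.isfinite(rec["train_loss"])
            assert np.isfinite(rec["val_dice"])  # validation subjects present
            # only training subjects ever drawn from
            assert set(rec["subjects_used"]) <= set(plan.train)

    def test_ensemble_has_three_distinct_models(self, tiny_ensemble):
        models, _, _, _ = tiny_ensemble
        assert set(models) == {"sagittal", "coronal", "axial"}
        ws = [models[o].parameters()[0].value for o in ("sagittal", "coronal", "axial")]
        assert not np.array_equal(ws[0], ws[1])

    def test_training_is_deterministic(self, small_cohort, tiny_train_config):
        from triseg.nn import build_network

        subjects = prepare_subjects(small_cohort)
        plan = make_holdout(small_cohort, (0.5, 0.25, 0.25), seed=1)
        outs = []
        for _ in range(2):
            model = build_network(tiny_train_config.network)
            model, hist = train_orientation(model, subjects, plan, "axial", tiny_train_config)
            outs.append((model, hist))
        a, b = outs
        assert [r["train_loss"] for r in a[1]] == [r["train_loss"] for r in b[1]]
        assert all(
            np.array_equal(pa.value, pb.value)
            for pa, pb in zip(a[0].parameters(), b[0].parameters())
        )

    def test_epochs_use_distinct_patch_streams(self, small_cohort, tiny_train_config):
        """Seeding by [seed, orientation, epoch] must not repeat draws across epochs."""
        from triseg.training import _draw_batch

        subjects = prepare_subjects(small_cohort)
        ids = [s.subject_id for s in small_cohort]
        x1, _, _ = _draw_batch(subjects, ids, "axial", tiny_train_config,
                               np.random.default_rng([7, 2, 1]), 8)
        x2, _, _ = _draw_batch(subjects, ids, "axial", tiny_train_config,
                               np.random.default_rng([7, 2, 2]), 8)
        assert not np.array_equal(x1, x2)

    def test_no_training_subjects_rejected(self, small_cohort, tiny_train_config):
        from triseg.nn import build_network

        subjects = prepare_subjects(small_cohort)
        plan = SplitPlan(train=(), validation=(), test=tuple(subjects))
        with pytest.raises(ConfigError):
            train_orientation(build_network(tiny_train_config.network), subjects, plan,
                              "axial", tiny_train_config)

    def test_boundary_loss_records_alpha(self, small_cohort):
        cfg = TrainConfig(
            epochs=2,
            patches_per_epoch=16,
            batch_size=8,
            loss=LossConfig(kind="boundary", total_epochs=2),
            sampler=SamplerConfig(patch_size=(16, 16), augment=AugmentConfig(enabled=False)),
            network=NetworkConfig(base_width=2, depth=2, output_mode="softmax_2ch", seed=0),
            val_patches=8,
            seed=3,
        )
        from triseg.nn import build_network

        subjects = prepare_subjects(small_cohort)
        plan = make_holdout(small_cohort, (0.5, 0.25, 0.25), seed=1)
        _, hist = train_orientation(build_network(cfg.network), subjects, plan, "sagittal", cfg)
        assert [r["alpha"] for r in hist] == [1.0, 0.0]
        assert all(np.isfinite(r["train_loss"]) for r in hist)

    def test_patient_only_training_possible(self):
        """Resected cohorts still train: empty sides never break sampling."""
        cohort = generate_cohort(0, 2, small_spec(), seed=11)
        subjects = prepare_subjects(cohort)
        ids = [s.subject_id for s in cohort]
        plan = SplitPlan(train=tuple(ids), validation=(), test=())
        cfg = TrainConfig(
            epochs=1,
            patches_per_epoch=8,
            batch_size=4,
            loss=LossConfig(kind="dice"),
            sampler=SamplerConfig(patch_size=(16, 16), augment=AugmentConfig(enabled=False)),
            network=NetworkConfig(base_width=2, depth=2, output_mode="sigmoid_1ch", seed=0),
            seed=5,
        )
        from triseg.nn import build_network

        _, hist = train_orientation(build_network(cfg.network), subjects, plan, "coronal", cfg)
        assert np.isfinite(hist[0]["train_loss"])
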