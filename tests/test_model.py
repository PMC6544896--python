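"""Residual-network regression: encoding, training, block selection,
bootstrap ensembling and prediction semantics."""

import numpy as np
import pandas as pd
import pytest

from camopt.model import (
    VisibilityEnsemble,
    encode,
    encode_frame,
    predict,
    predict_members,
    select_block_count,
    train_ensemble,
    train_model,
)
from camopt.nnet import TrainingConfig
from camopt.observer import (
    ObserverGroundTruth,
    SimulationConfig,
    generate_dataset,
    true_log_rt_batch,
)
from conftest import FAST_TRAINING


def constant_trials(n=300, rt=1000.0, n_participants=3):
    rng = np.random.default_rng(0)
    return pd.DataFrame(
        {
            "participant_id": rng.integers(1, n_participants + 1, n),
            "environment": "forest",
            "chromacy": "trichromat",
            "r": rng.integers(0, 256, n),
            "g": rng.integers(0, 256, n),
            "b": rng.integers(0, 256, n),
            "occlusion": rng.uniform(0.25, 0.5, n),
            "rt_ms": rt,
            "success": True,
        }
    )


class TestEncoding:
    def test_one_hot_and_scaling(self):
        v = encode((255, 255, 255), 0.375, participant_id=3, n_participants=10)
        assert v.shape == (14,)
        assert tuple(v[:3]) == (1.0, 1.0, 1.0)
        assert v[3] == 0.375
        hot = v[4:]
        assert hot[2] == 1.0 and hot.sum() == 1.0

    def test_unknown_participant_rejected(self):
        with pytest.raises(ValueError):
            encode((0, 0, 0), 0.3, participant_id=11, n_participants=10)

    def test_frame_encoding_matches_scalar(self):
        df = constant_trials(20)
        X = encode_frame(df, n_participants=3)
        for i, row in df.iterrows():
            v = encode(
                (row.r, row.g, row.b), row.occlusion,
                participant_id=row.participant_id, n_participants=3,
            )
            assert np.allclose(X[i], v)


class TestTraining:
    def test_constant_rt_is_learned_to_high_precision(self):
        df = constant_trials(300)
        m = train_model(
            df, n_blocks=2, split_seed=0, init_seed=1,
            n_participants=3, config=FAST_TRAINING,
        )
        rmse = np.sqrt(m.validation_mse)
        assert rmse < 1e-3  # log-RT units

    def test_requires_100_successful_trials(self):
        df = constant_trials(120)
        df.loc[df.index[:30], "success"] = False
        with pytest.raises(ValueError, match="100"):
            train_model(df, 2, 0, 1, n_participants=3)

    def test_deterministic_given_seeds(self, tiny_trials):
        kw = dict(
            n_blocks=2, split_seed=3, init_seed=4,
            n_participants=3, config=FAST_TRAINING,
        )
        m1 = train_model(tiny_trials, **kw)
        m2 = train_model(tiny_trials, **kw)
        assert m1.validation_mse == m2.validation_mse
        X = encode_frame(tiny_trials.head(20), 3)
        assert np.array_equal(m1.predict_log_rt(X), m2.predict_log_rt(X))

    def test_unit_change_rescales_predictions_exactly(self, tiny_trials):
        kw = dict(
            n_blocks=2, split_seed=3, init_seed=4,
            n_participants=3, config=FAST_TRAINING,
        )
        m_ms = train_model(tiny_trials, **kw)
        in_s = tiny_trials.copy()
        in_s["rt_ms"] = in_s["rt_ms"] / 1000.0
        m_s = train_model(in_s, **kw)
        X = encode_frame(tiny_trials.head(50), 3)
        ratio = np.exp(m_ms.predict_log_rt(X)) / np.exp(m_s.predict_log_rt(X))
        assert np.allclose(ratio, 1000.0, rtol=1e-9)


class TestBlockSelection:
    def test_single_candidate_is_returned(self, tiny_trials):
        best, table = select_block_count(
            tiny_trials, candidates=(4,), seed=0,
            n_participants=3, config=FAST_TRAINING,
        )
        assert best == 4 and list(table["n_blocks"]) == [4]

    def test_winner_is_argmin_of_logged_table(self, tiny_trials):
        best, table = select_block_count(
            tiny_trials, candidates=(2, 4), seed=0,
            n_participants=3, config=FAST_TRAINING,
        )
        assert best == int(table.loc[table["validation_mse"].idxmin(), "n_blocks"])

    def test_ties_break_to_smallest(self, monkeypatch):
        import camopt.model as mod

        class Fake:
            validation_mse = 0.5

        monkeypatch.setattr(mod, "train_model", lambda *a, **k: Fake())
        best, table = mod.select_block_count(pd.DataFrame(), candidates=(6, 2, 4))
        assert best == 2
        assert (table["validation_mse"] == 0.5).all()

    def test_empty_candidates_rejected(self, tiny_trials):
        with pytest.raises(ValueError):
            select_block_count(tiny_trials, candidates=())


class TestEnsemble:
    def test_member_count_and_seed_determinism(self, tiny_ensemble, tiny_trials):
        assert tiny_ensemble.n_boot == 3
        again = train_ensemble(
            tiny_trials, n_boot=3, base_seed=7, n_blocks=2,
            n_participants=3, condition=("forest", "trichromat"),
            config=FAST_TRAINING,
        )
        cols = np.array([(10, 20, 30), (200, 100, 0)], dtype=np.uint8)
        assert np.array_equal(
            predict_members(tiny_ensemble, cols, 0.375),
            predict_members(again, cols, 0.375),
        )

    def test_requires_at_least_two_members(self, tiny_trials):
        with pytest.raises(ValueError):
            train_ensemble(tiny_trials, n_boot=1)

    def test_member_order_is_exchangeable(self, tiny_ensemble):
        cols = np.array([(5, 50, 200)], dtype=np.uint8)
        p1, se1 = predict(tiny_ensemble, cols, 0.375)
        rev = VisibilityEnsemble(
            models=list(reversed(tiny_ensemble.models)),
            condition=tiny_ensemble.condition,
            n_participants=tiny_ensemble.n_participants,
        )
        p2, se2 = predict(rev, cols, 0.375)
        assert np.allclose(p1, p2) and np.allclose(se1, se2)

    def test_bootstrap_se_shrinks_with_training_set_size(self):
        gt = ObserverGroundTruth(sigma=0.2, n_participants=2)
        rng = np.random.default_rng(11)
        cols = rng.integers(0, 256, (50, 3), dtype=np.uint8)
        ses = []
        for n_trials in (300, 3000):
            cfg = SimulationConfig(
                environments=("forest",), chromacies=("trichromat",),
                n_participants=2, n_trials=n_trials,
            )
            df = generate_dataset(cfg, gt, seed=9)
            ens = train_ensemble(
                df, n_boot=6, base_seed=1, n_blocks=2,
                n_participants=2, config=FAST_TRAINING,
            )
            _, se = predict(ens, cols, 0.375)
            ses.append(se.mean())
        assert ses[1] < ses[0]


class TestPrediction:
    def test_uniform_weights_equal_explicit_participant_average(self, tiny_ensemble):
        cols = np.array([(12, 120, 200), (70, 80, 40)], dtype=np.uint8)
        uniform = predict_members(tiny_ensemble, cols, 0.375)
        per_part = []
        for p in range(3):
            w = np.zeros(3)
            w[p] = 1.0
            per_part.append(
                np.log(predict_members(tiny_ensemble, cols, 0.375, w))
            )
        explicit = np.exp(np.mean(per_part, axis=0))
        assert np.allclose(uniform, explicit, rtol=1e-9)

    def test_degenerate_weights_select_single_participant(self, tiny_ensemble):
        cols = np.array([(12, 120, 200)], dtype=np.uint8)
        w = np.array([0.0, 1.0, 0.0])
        got = predict_members(tiny_ensemble, cols, 0.375, w)[0, 0]
        X = encode((12, 120, 200), 0.375, participant_id=2, n_participants=3)
        direct = np.exp(tiny_ensemble.models[0].predict_log_rt(X[None, :])[0])
        assert got == pytest.approx(direct, rel=1e-12)

    def test_invalid_weights_rejected(self, tiny_ensemble):
        cols = np.array([(1, 2, 3)], dtype=np.uint8)
        with pytest.raises(ValueError):
            predict_members(tiny_ensemble, cols, 0.375, np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            predict_members(tiny_ensemble, cols, 0.375, np.array([0.7, 0.2, 0.2]))

    def test_identical_members_have_zero_se(self, tiny_ensemble):
        clone = VisibilityEnsemble(
            models=[tiny_ensemble.models[0]] * 3,
            condition=tiny_ensemble.condition,
            n_participants=3,
        )
        _, se = predict(clone, np.array([(9, 9, 90)], dtype=np.uint8), 0.375)
        assert np.allclose(se, 0.0)

    def test_single_model_prediction_has_zero_se(self, tiny_ensemble):
        point, se = predict(
            tiny_ensemble.models[0], np.array([(9, 9, 90)], dtype=np.uint8), 0.375
        )
        assert point.shape == (1,) and se[0] == 0.0


class TestFunctionRecovery:
    def test_noise_free_recovery_below_005_log_units(self):
        # sigma=0: the ensemble should reproduce the generator's mean
        # log RT on held-out colours almost exactly
        gt = ObserverGroundTruth(sigma=0.0)
        cfg = SimulationConfig(
            environments=("forest",), chromacies=("trichromat",),
            n_participants=10, n_trials=300,
        )
        df = generate_dataset(cfg, gt, seed=3)
        ens = train_ensemble(
            df, n_boot=3, base_seed=7, n_blocks=2, n_participants=10,
            condition=("forest", "trichromat"),
        )
        rng = np.random.default_rng(11)
        held_out = rng.integers(0, 256, (400, 3), dtype=np.uint8)
        point, _ = predict(ens, held_out, 0.375)
        mu = true_log_rt_batch(held_out, 0.375, 0, "forest", "trichromat", gt)
        rmse = np.sqrt(np.mean((np.log(point) - mu) ** 2))
        assert rmse < 0.05
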