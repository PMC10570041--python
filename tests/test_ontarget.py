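"""Transfer-learning on-target model: encoders, freezing, baselines, CV."""

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import Ridge

from guidevar import ontarget as on
from guidevar._rnn import init_lstm_params, lstm_backward, lstm_forward
from guidevar.errors import (
    FrozenViolationError,
    InsufficientDataError,
    UncalibratedModelError,
    UnknownKindError,
)
from guidevar.seqfeat import MONO_ORDER, Spacer

from conftest import random_spacer


def test_lstm_backprop_matches_numerical_gradient():
    rng = np.random.default_rng(0)
    params = init_lstm_params(3, 4, rng)
    X = rng.normal(size=(4, 5, 3))
    w = rng.normal(size=4)

    def loss(p):
        h, _ = lstm_forward(p, X)
        return float(np.sum((h @ w) ** 2))

    h, cache = lstm_forward(params, X)
    grads = lstm_backward(params, cache, 2 * np.outer(h @ w, w))
    eps = 1e-6
    for k in params:
        it = np.nditer(params[k], flags=["multi_index"])
        for _ in it:
            idx = it.multi_index
            orig = params[k][idx]
            params[k][idx] = orig + eps
            lp = loss(params)
            params[k][idx] = orig - eps
            lm = loss(params)
            params[k][idx] = orig
            num = (lp - lm) / (2 * eps)
            assert grads[k][idx] == pytest.approx(num, rel=1e-3, abs=1e-7)


class TestSpacerOnehot:
    def test_shape_and_padding(self):
        X = on.spacers_to_onehot([Spacer("A" * 20), Spacer("C" * 19)])
        assert X.shape == (2, 20, 4)
        assert X[0].sum() == 20
        assert X[1, 0].sum() == 0  # PAM-distal pad step for the 19-mer
        assert X[1].sum() == 19

    def test_channel_order(self):
        X = on.spacers_to_onehot([Spacer("G" * 20)])
        assert X[0, :, MONO_ORDER.index("G")].sum() == 20


class TestPretrainEncoder:
    def test_planted_task_learnable(self, pretrain_task, trained_encoders):
        """Held-out embeddings carry the planted position-1..5 signal."""
        sp, y = pretrain_task["spacers"], pretrain_task["y"]
        enc = trained_encoders[0]
        head = Ridge().fit(enc.encode(sp[:600]), y[:600])
        rho = spearmanr(head.predict(enc.encode(sp[600:])), y[600:]).statistic
        assert rho > 0.5

    def test_deterministic_digest(self):
        rng = np.random.default_rng(1)
        sp = [random_spacer(rng) for _ in range(120)]
        y = rng.normal(size=120)
        a = on.pretrain_encoder(sp, y, hidden=8, epochs=20, seed=5)
        b = on.pretrain_encoder(sp, y, hidden=8, epochs=20, seed=5)
        assert a.digest() == b.digest()

    def test_too_few_examples(self):
        rng = np.random.default_rng(2)
        sp = [random_spacer(rng) for _ in range(10)]
        with pytest.raises(InsufficientDataError):
            on.pretrain_encoder(sp, np.zeros(10))


class TestFineTune:
    def _data(self, pretrain_task, n=400):
        return pretrain_task["spacers"][:n], pretrain_task["y"][:n]

    def test_feature_dims(self, pretrain_task, trained_encoders):
        sp, y = self._data(pretrain_task)
        emb_dim = sum(e.embedding_dim for e in trained_encoders)
        for features, extra in [("none", 0), ("mono", 80), ("di", 304), ("mono+di", 384)]:
            model = on.GuideVarOnRegressor(
                encoders=trained_encoders, features=features,
                hidden_layer_sizes=(16,), max_iter=30, random_state=0,
            ).fit(sp, y)
            assert model.n_features_in_ == emb_dim + extra

    def test_freezing_contract_digests(self, pretrain_task, trained_encoders):
        sp, y = self._data(pretrain_task)
        before = tuple(e.digest() for e in trained_encoders)
        model = on.GuideVarOnRegressor(
            encoders=trained_encoders, features="none",
            hidden_layer_sizes=(16,), max_iter=50, random_state=0,
        ).fit(sp, y)
        after = tuple(e.digest() for e in trained_encoders)
        assert before == after == model.encoder_digests_

    def test_unfrozen_encoder_rejected(self, pretrain_task, trained_encoders):
        sp, y = self._data(pretrain_task, 100)
        e1, e2 = trained_encoders
        import dataclasses

        thawed = dataclasses.replace(e1, frozen=False)
        with pytest.raises(FrozenViolationError):
            on.GuideVarOnRegressor(encoders=(thawed, e2)).fit(sp, y)

    def test_predictions_calibrated_to_unit_interval(self, pretrain_task, trained_encoders):
        sp, y = self._data(pretrain_task)
        model = on.GuideVarOnRegressor(
            encoders=trained_encoders, features="mono",
            hidden_layer_sizes=(16,), max_iter=100, random_state=0,
        ).fit(sp, y)
        scores = model.predict(pretrain_task["spacers"][400:])
        assert ((scores >= 0) & (scores <= 1)).all()
        # ranking tracks the planted truth
        rho = spearmanr(scores, pretrain_task["y"][400:]).statistic
        assert rho > 0.6

    def test_unfitted_predict_raises(self, trained_encoders):
        model = on.GuideVarOnRegressor(encoders=trained_encoders)
        with pytest.raises(UncalibratedModelError):
            model.predict([Spacer("A" * 20)])

    def test_transfer_beats_random_encoders(self, pretrain_task, trained_encoders):
        """Pretrained frozen encoders outperform random frozen encoders
        when the fine-tune target shares the pretraining structure."""
        sp, y = pretrain_task["spacers"], pretrain_task["y"]
        train_s, train_y = sp[:300], y[:300]
        test_s, test_y = sp[600:], y[600:]
        diffs = []
        for seed in range(5):
            pre = on.GuideVarOnRegressor(
                encoders=trained_encoders, features="none",
                hidden_layer_sizes=(16,), max_iter=150, random_state=seed,
            ).fit(train_s, train_y)
            rand_encs = (
                on.SourceEncoder.random(hidden=24, seed=100 + seed),
                on.SourceEncoder.random(hidden=24, seed=200 + seed),
            )
            rnd = on.GuideVarOnRegressor(
                encoders=rand_encs, features="none",
                hidden_layer_sizes=(16,), max_iter=150, random_state=seed,
            ).fit(train_s, train_y)
            rho_pre = spearmanr(pre.predict(test_s), test_y).statistic
            rho_rnd = spearmanr(rnd.predict(test_s), test_y).statistic
            diffs.append(rho_pre - rho_rnd)
        assert np.mean(diffs) > 0

    def test_di_features_capture_planted_dinucleotide_signal(self):
        """Adding dinucleotide features helps when the signal is dinucleotide-borne."""
        rng = np.random.default_rng(9)
        spacers = [random_spacer(rng) for _ in range(500)]
        y = np.array([s.sequence.count("TG") + 0.5 * s.sequence.count("CA")
                      for s in spacers], dtype=float)
        encs = (
            on.SourceEncoder.random(hidden=8, seed=1),
            on.SourceEncoder.random(hidden=8, seed=2),
        )
        res = {}
        for features in ("none", "di"):
            model = on.GuideVarOnRegressor(
                encoders=encs, features=features,
                hidden_layer_sizes=(32,), max_iter=200, random_state=0,
            ).fit(spacers[:350], y[:350])
            res[features] = spearmanr(model.predict(spacers[350:]), y[350:]).statistic
        assert res["di"] > res["none"]


class TestBaselines:
    def test_linear_recovers_linear_target(self):
        rng = np.random.default_rng(3)
        spacers = [random_spacer(rng) for _ in range(300)]
        w = rng.normal(size=80)
        y = on.sequence_features(spacers, "mono") @ w
        model = on.train_baseline(spacers, y, kind="linear", features="mono")
        rho = spearmanr(model.predict(spacers), y).statistic
        assert rho > 0.99

    def test_all_kinds_smoke(self, pretrain_task):
        sp, y = pretrain_task["spacers"][:200], pretrain_task["y"][:200]
        for kind in on.BASELINE_KINDS:
            model = on.train_baseline(sp, y, kind=kind, seed=1)
            scores = model.predict(sp[:20])
            assert scores.shape == (20,)
            assert ((scores >= 0) & (scores <= 1)).all()

    def test_unknown_kind(self):
        with pytest.raises(UnknownKindError):
            on.train_baseline([Spacer("A" * 20)] * 50, np.zeros(50), kind="mlp")

    def test_too_few_examples(self):
        with pytest.raises(InsufficientDataError):
            on.train_baseline([Spacer("A" * 20)] * 10, np.zeros(10), kind="gbt")


class _Oracle(BaseEstimator, RegressorMixin):
    """Predicts the planted truth exactly (upper bound for CV)."""

    def __init__(self, f=None):
        self.f = f

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.array([self.f(s) for s in X])


class _Random(BaseEstimator, RegressorMixin):
    def __init__(self, seed=0):
        self.seed = seed

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.random.default_rng(self.seed).normal(size=len(X))


class TestCrossValidate:
    def test_oracle_upper_bound(self, pretrain_task):
        sp, y = pretrain_task["spacers"][:200], pretrain_task["y"][:200]
        res = on.cross_validate(sp, y, _Oracle(pretrain_task["f"]), k=4, repeats=2, seed=0)
        assert all(r == pytest.approx(1.0) for r in res["per_fold"])

    def test_random_predictor_near_zero(self, pretrain_task):
        sp, y = pretrain_task["spacers"][:300], pretrain_task["y"][:300]
        res = on.cross_validate(sp, y, _Random(seed=3), k=5, repeats=4, seed=0)
        assert abs(res["mean"]) < 0.15

    def test_fold_assignment_deterministic(self, pretrain_task):
        sp, y = pretrain_task["spacers"][:120], pretrain_task["y"][:120]
        a = on.cross_validate(sp, y, _Oracle(pretrain_task["f"]), k=3, repeats=2, seed=5)
        b = on.cross_validate(sp, y, _Oracle(pretrain_task["f"]), k=3, repeats=2, seed=5)
        assert a["per_fold"] == b["per_fold"]


def test_efficiency_from_zscores_orientation():
    z_hf = np.array([-6.0, 0.0])
    z_lz = np.array([-4.0, 0.0])
    y = on.efficiency_from_zscores(z_hf, z_lz)
    assert y[0] == pytest.approx(5.0)  # strong dropout -> high efficiency
    assert y[0] > y[1]
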