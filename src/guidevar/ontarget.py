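"""On-target efficiency prediction for high-fidelity Cas9 variants.

The predictor ("GuideVar-on") is a two-step transfer-learning model:

1. *Pretraining*: two BiLSTM sequence encoders are trained as regressors on
   large source screens (one wild-type SpCas9 task, one HF1-style task);
   their temporary readout heads are discarded and the recurrent parameters
   are frozen.
2. *Fine-tuning*: the concatenated final-state embeddings of the two frozen
   encoders, optionally joined with flattened mononucleotide (80) and/or
   dinucleotide (304) one-hot features, feed a small dense network trained
   on the variant-efficiency target (the negated mean of the HiFi and LZ3
   dropout Z-scores, so that higher = more efficient).

Predictions are min-max calibrated to [0, 1] using the training targets.
Conventional baselines (linear, RBF-SVR, random forest, gradient-boosted
trees) on the same sequence features and a repeated k-fold cross-validation
harness are provided for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from ._rnn import bilstm_embed, init_lstm_params, params_digest, train_bilstm_regressor
from .errors import (
    FrozenViolationError,
    InsufficientDataError,
    UncalibratedModelError,
    UnknownKindError,
)
from .seqfeat import MONO_ORDER, Spacer, encode_di, encode_mono, validate_spacer

FEATURE_CONFIGS = ("none", "mono", "di", "mono+di")


def _as_spacers(X: Sequence) -> list[Spacer]:
    return [x if isinstance(x, Spacer) else validate_spacer(str(x)) for x in X]


def spacers_to_onehot(spacers: Sequence[Spacer]) -> np.ndarray:
    """One-hot input tensor (N, 20, 4); time axis runs 5'->3' (PAM-distal
    first), channels in A/T/C/G order; 19-nt spacers zero-pad the first step."""
    X = np.zeros((len(spacers), 20, 4))
    for n, s in enumerate(spacers):
        for pos in range(1, len(s) + 1):
            X[n, 20 - pos, MONO_ORDER.index(s.base_at(pos))] = 1.0
    return X


def sequence_features(spacers: Sequence[Spacer], features: str) -> np.ndarray:
    """Flattened mono (80) and/or di (304) one-hot features per config."""
    if features not in FEATURE_CONFIGS:
        raise UnknownKindError(f"feature config {features!r} not in {FEATURE_CONFIGS}")
    blocks = []
    if features in ("mono", "mono+di"):
        blocks.append(np.stack([encode_mono(s).ravel() for s in spacers]))
    if features in ("di", "mono+di"):
        blocks.append(np.stack([encode_di(s).ravel() for s in spacers]))
    if not blocks:
        return np.zeros((len(spacers), 0))
    return np.concatenate(blocks, axis=1).astype(float)


@dataclass
class EfficiencyDataset:
    """Spacers paired with a variant-efficiency target (higher = better)."""

    spacers: list[Spacer]
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        if len(self.spacers) != len(self.y):
            raise InsufficientDataError("one target value per spacer required")


def efficiency_from_zscores(z_hifi, z_lz3) -> np.ndarray:
    """Variant-efficiency target: negated mean of the two variant Z-scores.

    Strongly negative dropout Z-scores indicate efficient knockout, so the
    negation orients the target as higher = more efficient.
    """
    return -(np.asarray(z_hifi, dtype=float) + np.asarray(z_lz3, dtype=float)) / 2.0


@dataclass
class SourceEncoder:
    """A frozen BiLSTM sequence encoder transferred from a source screen."""

    fwd: dict
    bwd: dict
    hidden: int
    task_tag: str = ""
    frozen: bool = True
    _digest: str = field(default="", repr=False)

    def __post_init__(self) -> None:
        if not self._digest:
            self._digest = params_digest(self.fwd, self.bwd)

    @property
    def embedding_dim(self) -> int:
        return 2 * self.hidden

    def digest(self) -> str:
        return params_digest(self.fwd, self.bwd)

    def encode(self, spacers: Sequence[Spacer]) -> np.ndarray:
        return bilstm_embed(self.fwd, self.bwd, spacers_to_onehot(spacers))

    @classmethod
    def random(cls, hidden: int = 32, seed: int = 0, task_tag: str = "random") -> "SourceEncoder":
        """Randomly initialized (untrained) encoder; transfer-benefit control."""
        rng = np.random.default_rng(seed)
        return cls(
            fwd=init_lstm_params(4, hidden, rng),
            bwd=init_lstm_params(4, hidden, rng),
            hidden=hidden,
            task_tag=task_tag,
        )


def pretrain_encoder(
    spacers: Sequence[Spacer],
    y: Sequence[float],
    hidden: int = 32,
    epochs: int = 300,
    lr: float = 0.02,
    patience: int = 10,
    seed: int = 0,
    task_tag: str = "",
) -> SourceEncoder:
    """Pretrain a BiLSTM encoder on a source (spacer, efficiency) task.

    The temporary linear readout is discarded; the returned encoder is
    frozen.  Deterministic under a fixed seed.  Requires >= 100 examples.
    """
    spacers = _as_spacers(spacers)
    if len(spacers) < 100:
        raise InsufficientDataError(
            f"pretraining needs >= 100 examples, got {len(spacers)}"
        )
    X = spacers_to_onehot(spacers)
    fwd, bwd, _head = train_bilstm_regressor(
        X, np.asarray(y, dtype=float), hidden=hidden, epochs=epochs, lr=lr,
        patience=patience, seed=seed,
    )
    return SourceEncoder(fwd=fwd, bwd=bwd, hidden=hidden, task_tag=task_tag)


class GuideVarOnRegressor(BaseEstimator, RegressorMixin):
    """Transfer-learning on-target efficiency model (dense head fine-tuning).

    Parameters
    ----------
    encoders : tuple of two SourceEncoder
        Frozen source encoders whose embeddings feed the head.
    features : {"none", "mono", "di", "mono+di"}
        Additional flattened sequence features appended to the embeddings.
    hidden_layer_sizes, max_iter, alpha, random_state
        Dense-head (``sklearn.neural_network.MLPRegressor``) settings.

    Fitted attributes end in an underscore; ``predict`` returns scores
    min-max calibrated to [0, 1] (higher = more efficient).
    """

    def __init__(
        self,
        encoders=None,
        features: str = "mono+di",
        hidden_layer_sizes=(128, 32),
        max_iter: int = 500,
        alpha: float = 1e-4,
        random_state: int = 0,
    ):
        self.encoders = encoders
        self.features = features
        self.hidden_layer_sizes = hidden_layer_sizes
        self.max_iter = max_iter
        self.alpha = alpha
        self.random_state = random_state

    def _validate_encoders(self) -> tuple[SourceEncoder, SourceEncoder]:
        if self.encoders is None or len(self.encoders) != 2:
            raise InsufficientDataError("two source encoders are required")
        for enc in self.encoders:
            if not enc.frozen:
                raise FrozenViolationError(
                    f"encoder {enc.task_tag!r} is not marked frozen"
                )
        return tuple(self.encoders)

    def _features(self, spacers: Sequence[Spacer]) -> np.ndarray:
        e1, e2 = self._validate_encoders()
        blocks = [e1.encode(spacers), e2.encode(spacers)]
        seq = sequence_features(spacers, self.features)
        if seq.shape[1]:
            blocks.append(seq)
        return np.concatenate(blocks, axis=1)

    def fit(self, X: Sequence, y: Sequence[float]) -> "GuideVarOnRegressor":
        spacers = _as_spacers(X)
        y = np.asarray(y, dtype=float)
        e1, e2 = self._validate_encoders()
        digests_before = (e1.digest(), e2.digest())
        F = self._features(spacers)
        self.head_ = MLPRegressor(
            hidden_layer_sizes=self.hidden_layer_sizes,
            max_iter=self.max_iter,
            alpha=self.alpha,
            random_state=self.random_state,
        )
        self.head_.fit(F, y)
        digests_after = (e1.digest(), e2.digest())
        if digests_before != digests_after:
            raise FrozenViolationError("encoder parameters changed during fine-tuning")
        self.encoder_digests_ = digests_after
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        self.n_features_in_ = F.shape[1]
        return self

    def _calibrate(self, raw: np.ndarray) -> np.ndarray:
        if not hasattr(self, "y_min_"):
            raise UncalibratedModelError("model has no calibration bounds; call fit")
        span = self.y_max_ - self.y_min_
        if span == 0:
            return np.clip(np.zeros_like(raw) + 0.5, 0.0, 1.0)
        return np.clip((raw - self.y_min_) / span, 0.0, 1.0)

    def predict(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "head_"):
            raise UncalibratedModelError("model is not fitted")
        return self._calibrate(self.head_.predict(self._features(_as_spacers(X))))


_BASELINES = {
    "linear": lambda seed: LinearRegression(),
    "svr_rbf": lambda seed: SVR(kernel="rbf"),
    "random_forest": lambda seed: RandomForestRegressor(
        n_estimators=200, random_state=seed
    ),
    "gbt": lambda seed: GradientBoostingRegressor(random_state=seed),
}

BASELINE_KINDS = tuple(_BASELINES)


class BaselineOnRegressor(BaseEstimator, RegressorMixin):
    """Conventional-ML on-target baseline on flattened sequence features.

    Same predict contract as :class:`GuideVarOnRegressor` (min-max
    calibrated [0, 1] scores).
    """

    def __init__(self, kind: str = "gbt", features: str = "mono+di", random_state: int = 0):
        self.kind = kind
        self.features = features
        self.random_state = random_state

    def fit(self, X: Sequence, y: Sequence[float]) -> "BaselineOnRegressor":
        if self.kind not in _BASELINES:
            raise UnknownKindError(
                f"kind {self.kind!r} not in {sorted(_BASELINES)}"
            )
        spacers = _as_spacers(X)
        y = np.asarray(y, dtype=float)
        F = sequence_features(spacers, self.features)
        if F.shape[1] == 0:
            raise UnknownKindError("baselines require sequence features ('none' invalid)")
        self.model_ = _BASELINES[self.kind](self.random_state)
        self.model_.fit(F, y)
        self.y_min_, self.y_max_ = float(y.min()), float(y.max())
        return self

    def predict(self, X: Sequence) -> np.ndarray:
        if not hasattr(self, "model_"):
            raise UncalibratedModelError("model is not fitted")
        raw = self.model_.predict(sequence_features(_as_spacers(X), self.features))
        span = self.y_max_ - self.y_min_
        if span == 0:
            return np.full_like(raw, 0.5)
        return np.clip((raw - self.y_min_) / span, 0.0, 1.0)


def train_baseline(
    spacers: Sequence,
    y: Sequence[float],
    kind: str = "gbt",
    features: str = "mono+di",
    seed: int = 0,
) -> BaselineOnRegressor:
    """Fit one conventional baseline; requires >= 50 examples."""
    if kind not in _BASELINES:
        raise UnknownKindError(f"kind {kind!r} not in {sorted(_BASELINES)}")
    if len(spacers) < 50:
        raise InsufficientDataError("baseline training needs >= 50 examples")
    return BaselineOnRegressor(kind=kind, features=features, random_state=seed).fit(
        spacers, y
    )


def fine_tune(
    encoders,
    dataset: EfficiencyDataset,
    features: str = "mono+di",
    hidden_layer_sizes=(128, 32),
    max_iter: int = 500,
    seed: int = 0,
) -> GuideVarOnRegressor:
    """Convenience wrapper fitting :class:`GuideVarOnRegressor` on a dataset."""
    model = GuideVarOnRegressor(
        encoders=encoders,
        features=features,
        hidden_layer_sizes=hidden_layer_sizes,
        max_iter=max_iter,
        random_state=seed,
    )
    return model.fit(dataset.spacers, dataset.y)


def predict_on(model, spacers: Sequence) -> np.ndarray:
    """Predict calibrated on-target scores in [0, 1] for a batch of spacers."""
    return model.predict(spacers)


def cross_validate(
    spacers: Sequence,
    y: Sequence[float],
    estimator,
    k: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> dict:
    """Repeated k-fold CV; metric is held-out Spearman correlation.

    Splits are re-drawn each repeat from a seeded stream, so fold assignment
    is reproducible under a fixed seed.
    """
    spacers = _as_spacers(spacers)
    y = np.asarray(y, dtype=float)
    if len(spacers) < k:
        raise InsufficientDataError(f"need at least k={k} examples")
    per_fold = []
    for rep in range(repeats):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        for train_idx, test_idx in kf.split(y):
            model = clone(estimator)
            model.fit([spacers[i] for i in train_idx], y[train_idx])
            pred = model.predict([spacers[i] for i in test_idx])
            per_fold.append(float(spearmanr(pred, y[test_idx]).statistic))
    arr = np.asarray(per_fold)
    return {"per_fold": per_fold, "mean": float(arr.mean()), "sd": float(arr.std(ddof=1))}
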