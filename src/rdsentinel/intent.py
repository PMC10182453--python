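"""Session-intent prediction: RD-concerned vs news-concerned vs other.

The classifier follows the two-branch architecture: an LSTM encodes the
per-query feature sequence; its final hidden state is concatenated with
the 38-dim session vector and passed through a one-hidden-layer MLP with
ReLU into a 3-way softmax, trained with cross-entropy and Adam, with early
stopping on validation loss.

Also provided: the 8:1:1 labeled-data split, the standard macro-F1 /
accuracy / per-class-F1 evaluation, and Fleiss' kappa agreement for the
three-annotator labeling protocol (with majority-vote consolidation).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import accuracy_score, f1_score
from statsmodels.stats.inter_rater import fleiss_kappa

from ._nn import Adam, LSTMMLPNet, pad_sequences
from .features import SessionFeatures
from .intent_labels import INTENT_NAMES, as_intent_index

__all__ = [
    "IntentModelConfig",
    "IntentPrediction",
    "IntentMetrics",
    "IntentClassifier",
    "split_811",
    "train_intent",
    "predict_intent",
    "evaluate_intent",
    "AgreementResult",
    "annotation_agreement",
]


@dataclass(frozen=True)
class IntentModelConfig:
    """Hyperparameters of the intent model; defaults are desk-scale."""

    recurrent_hidden_size: int = 64
    mlp_hidden_size: int = 64
    learning_rate: float = 1e-3
    max_epochs: int = 200
    patience: int = 20
    seed: int = 0
    class_weighting: bool = False

    def __post_init__(self):
        if self.recurrent_hidden_size < 1 or self.mlp_hidden_size < 1:
            raise ValueError("hidden sizes must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")


@dataclass(frozen=True)
class IntentPrediction:
    probabilities: np.ndarray
    label: int

    @property
    def label_name(self) -> str:
        return INTENT_NAMES[self.label]


@dataclass(frozen=True)
class IntentMetrics:
    macro_f1: float
    accuracy: float
    per_class_f1: tuple[float, float, float]


def _unpack(X):
    """Accept SessionFeatures objects or (seq, vec) pairs."""
    seqs, vecs = [], []
    for item in X:
        if isinstance(item, SessionFeatures):
            seqs.append(np.asarray(item.query_sequence, dtype=float))
            vecs.append(np.asarray(item.session_vector, dtype=float))
        else:
            seq, vec = item
            seqs.append(np.asarray(seq, dtype=float))
            vecs.append(np.asarray(vec, dtype=float))
    return seqs, np.stack(vecs)


class IntentClassifier(ClassifierMixin, BaseEstimator):
    """LSTM + MLP session-intent classifier (classes RD=0, NEWS=1, OTHER=2).

    Sequences are processed at their natural length; batches are padded and
    padded steps are masked out of both the recurrence and the gradients.
    Features are standardized on the training set.  Training is
    reproducible: the seed controls initialization and batch order.
    """

    def __init__(
        self,
        hidden_size: int = 64,
        mlp_hidden: int = 64,
        learning_rate: float = 1e-3,
        max_epochs: int = 200,
        patience: int = 20,
        batch_size: int = 64,
        seed: int = 0,
        class_weighting: bool = False,
    ):
        self.hidden_size = hidden_size
        self.mlp_hidden = mlp_hidden
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.batch_size = batch_size
        self.seed = seed
        self.class_weighting = class_weighting

    # -- helpers -----------------------------------------------------------

    def _standardize_seqs(self, seqs):
        return [(s - self.seq_mean_) / self.seq_scale_ for s in seqs]

    def _standardize_vecs(self, vecs):
        return (vecs - self.vec_mean_) / self.vec_scale_

    def _batch_loss(self, seqs, vecs, y, weights):
        x_seq, mask = pad_sequences(seqs)
        loss, _, _ = self.net_.loss_and_grads(x_seq, mask, vecs, y, weights)
        return loss

    # -- estimator API -----------------------------------------------------

    def fit(self, X, y, X_val=None, y_val=None):
        seqs, vecs = _unpack(X)
        y = np.array([as_intent_index(v) for v in y])
        self.classes_ = np.arange(3)

        all_steps = np.concatenate(seqs, axis=0)
        self.seq_mean_ = all_steps.mean(axis=0)
        self.seq_scale_ = np.maximum(all_steps.std(axis=0), 1e-8)
        self.vec_mean_ = vecs.mean(axis=0)
        self.vec_scale_ = np.maximum(vecs.std(axis=0), 1e-8)
        seqs = self._standardize_seqs(seqs)
        vecs = self._standardize_vecs(vecs)

        weights = None
        if self.class_weighting:
            counts = np.maximum(np.bincount(y, minlength=3), 1)
            weights = len(y) / (3.0 * counts)

        if X_val is not None:
            vseqs, vvecs = _unpack(X_val)
            vseqs = self._standardize_seqs(vseqs)
            vvecs = self._standardize_vecs(vvecs)
            vy = np.array([as_intent_index(v) for v in y_val])

        self.net_ = LSTMMLPNet(
            input_dim=seqs[0].shape[1],
            vec_dim=vecs.shape[1],
            hidden_size=self.hidden_size,
            mlp_hidden=self.mlp_hidden,
            seed=self.seed,
        )
        opt = Adam(self.net_.params, lr=self.learning_rate)
        rng = np.random.default_rng(self.seed)

        best_loss = np.inf
        best_params = self.net_.copy_params()
        best_epoch = 0
        since_best = 0
        self.history_ = []
        n = len(seqs)
        for epoch in range(1, self.max_epochs + 1):
            order = rng.permutation(n)
            train_loss = 0.0
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                x_seq, mask = pad_sequences([seqs[i] for i in idx])
                loss, grads, _ = self.net_.loss_and_grads(
                    x_seq, mask, vecs[idx], y[idx], weights
                )
                opt.step(grads)
                train_loss += loss * len(idx)
            train_loss /= n
            if X_val is not None:
                monitored = self._batch_loss(vseqs, vvecs, vy, weights)
            else:
                monitored = self._batch_loss(seqs, vecs, y, weights)
            self.history_.append(
                {"epoch": epoch, "train_loss": train_loss, "val_loss": monitored}
            )
            if monitored < best_loss - 1e-9:
                best_loss = monitored
                best_params = self.net_.copy_params()
                best_epoch = epoch
                since_best = 0
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.net_.set_params_(best_params)
        self.best_epoch_ = best_epoch
        self.n_iter_ = len(self.history_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        seqs, vecs = _unpack(X)
        seqs = self._standardize_seqs(seqs)
        vecs = self._standardize_vecs(vecs)
        x_seq, mask = pad_sequences(seqs)
        probs, _ = self.net_.forward(x_seq, mask, vecs)
        return probs

    def predict(self, X) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=1)


def predict_intent(classifier: IntentClassifier, features) -> IntentPrediction:
    """Predict one session's intent from its features."""
    probs = classifier.predict_proba([features])[0]
    return IntentPrediction(probabilities=probs, label=int(np.argmax(probs)))


def split_811(n: int, seed: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random 8:1:1 index split (train, validation, test)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(0.8 * n)
    n_val = int(0.1 * n)
    return (
        order[:n_train],
        order[n_train : n_train + n_val],
        order[n_train + n_val :],
    )


@dataclass
class IntentTrainResult:
    classifier: IntentClassifier
    splits: tuple[np.ndarray, np.ndarray, np.ndarray]
    test_metrics: IntentMetrics
    history: list = field(default_factory=list)


def train_intent(
    features: Sequence, labels: Sequence, config: IntentModelConfig | None = None
) -> IntentTrainResult:
    """Train the intent model on labeled sessions with an 8:1:1 split.

    Raises if any intent class is absent from the training split (a
    different seed reshuffles the split).
    """
    config = config or IntentModelConfig()
    y = np.array([as_intent_index(v) for v in labels])
    tr, va, te = split_811(len(y), config.seed)
    present = set(y[tr])
    if present != {0, 1, 2}:
        missing = [INTENT_NAMES[c] for c in sorted({0, 1, 2} - present)]
        raise ValueError(
            f"intent class(es) {missing} absent from the training split; "
            "try a different seed"
        )
    clf = IntentClassifier(
        hidden_size=config.recurrent_hidden_size,
        mlp_hidden=config.mlp_hidden_size,
        learning_rate=config.learning_rate,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=config.seed,
        class_weighting=config.class_weighting,
    )
    feats = list(features)
    clf.fit(
        [feats[i] for i in tr],
        y[tr],
        X_val=[feats[i] for i in va],
        y_val=y[va],
    )
    y_pred = clf.predict([feats[i] for i in te])
    return IntentTrainResult(
        classifier=clf,
        splits=(tr, va, te),
        test_metrics=evaluate_intent(y[te], y_pred),
        history=clf.history_,
    )


def evaluate_intent(y_true, y_pred) -> IntentMetrics:
    """Macro-F1 (unweighted mean of the 3 class F1s), accuracy, per-class F1."""
    y_true = np.array([as_intent_index(v) for v in y_true])
    y_pred = np.array([as_intent_index(v) for v in y_pred])
    per_class = f1_score(y_true, y_pred, labels=[0, 1, 2], average=None,
                         zero_division=0)
    return IntentMetrics(
        macro_f1=float(per_class.mean()),
        accuracy=float(accuracy_score(y_true, y_pred)),
        per_class_f1=tuple(float(v) for v in per_class),
    )


@dataclass(frozen=True)
class AgreementResult:
    """Inter-annotator agreement plus majority-vote consolidation."""

    kappa: float
    consolidated: tuple
    tie_indices: tuple[int, ...]


def annotation_agreement(labels) -> AgreementResult:
    """Fleiss' kappa over items each labeled by the same number of raters.

    ``labels`` is an (n_items, n_raters) table of intent labels.  The
    consolidated label is the majority vote; items with no majority get
    ``None`` and are listed for adjudication.
    """
    arr = np.array([[as_intent_index(v) for v in row] for row in labels])
    n_items, n_raters = arr.shape
    table = np.zeros((n_items, 3))
    for c in range(3):
        table[:, c] = (arr == c).sum(axis=1)
    kappa = float(fleiss_kappa(table))
    consolidated = []
    ties = []
    for i in range(n_items):
        top = int(np.argmax(table[i]))
        if table[i, top] * 2 > n_raters:
            consolidated.append(top)
        else:
            consolidated.append(None)
            ties.append(i)
    return AgreementResult(
        kappa=kappa, consolidated=tuple(consolidated), tie_indices=tuple(ties)
    )
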