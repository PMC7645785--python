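"""Person identification from hand-localization error maps.

A small convolutional classifier treats the 2 x 5 x 20 error map like a
two-channel image and learns to name the subject it came from.  The
architecture is deliberately tiny — one 3 x 3 convolution with 13
filters, batch normalization, ReLU, dropout, one fully connected layer
and softmax — trained with cross-entropy under stochastic gradient
descent with momentum (initial learning rate 0.01, inputs reshuffled
every epoch, 350 epochs by default).

If maps are idiosyncratic and stable, a classifier trained on one or two
sessions identifies subjects from a held-out later session well above
the 1/n chance level; if the idiosyncratic component is removed, test
accuracy falls back to chance.

`ErrorMapClassifier` follows the scikit-learn estimator contract
(``fit`` / ``predict`` / ``predict_proba`` / ``score``,
``get_params`` / ``set_params``), so it composes with sklearn model
selection; :func:`identification_protocol` wraps the session-split
experiments around it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.exceptions import NotFittedError

from ._cnn import SmallConvNet
from .error_maps import ErrorMap

__all__ = ["ErrorMapClassifier", "IdentificationResult", "identification_protocol", "evaluate"]


@dataclass
class IdentificationResult:
    """Outcome of one identification run."""

    accuracy: float
    n_correct: int
    n_test: int
    predictions: list = field(default_factory=list)  # (true, predicted) per map
    train_sessions: tuple = ()
    test_session: object = None
    seed: int | None = None
    config: dict = field(default_factory=dict)
    train_accuracy: float | None = None

    @property
    def chance(self) -> float:
        classes = {t for t, _ in self.predictions}
        return 1.0 / len(classes) if classes else float("nan")

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "n_correct": self.n_correct,
            "n_test": self.n_test,
            "train_accuracy": self.train_accuracy,
            "predictions": [[str(t), str(p)] for t, p in self.predictions],
            "train_sessions": [str(s) for s in self.train_sessions],
            "test_session": str(self.test_session),
            "seed": self.seed,
            "config": self.config,
        }


class ErrorMapClassifier(ClassifierMixin, BaseEstimator):
    """Convolutional person-identification classifier for error maps.

    Parameters
    ----------
    kernel_size, n_filters : int
        Convolution geometry; 3 and 13 by default (fixed task choices).
    dropout : float
        Dropout rate after the ReLU, default 0.5.
    learning_rate, momentum : float
        SGD-with-momentum hyperparameters (0.01, 0.9).
    epochs : int
        Training epochs, default 350 (the appropriate range for
        training-set sizes here is roughly 250-500).
    batch_size : int or None
        Mini-batch size; None means min(128, n_samples).
    input_shape : tuple
        Expected per-map shape, default (2, 5, 20).
    random_state : int or None
        Seeds initialization, per-epoch shuffling and dropout masks;
        a fixed value makes training bit-reproducible.

    Attributes
    ----------
    classes_ : ndarray
        Sorted class labels seen in ``fit``.
    loss_curve_ : list of float
        Mean cross-entropy per epoch.
    net_ : SmallConvNet
        The fitted network.
    """

    def __init__(
        self,
        kernel_size: int = 3,
        n_filters: int = 13,
        dropout: float = 0.5,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        epochs: int = 350,
        batch_size: int | None = None,
        input_shape: tuple = (2, 5, 20),
        random_state: int | None = None,
    ):
        self.kernel_size = kernel_size
        self.n_filters = n_filters
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.epochs = epochs
        self.batch_size = batch_size
        self.input_shape = input_shape
        self.random_state = random_state

    # ---- data marshalling ---------------------------------------------

    def _as_images(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        c, h, w = self.input_shape
        if X.ndim == 2 and X.shape[1] == c * h * w:
            X = X.reshape(-1, c, h, w)
        if X.ndim != 4 or X.shape[1:] != (c, h, w):
            raise ValueError(
                f"expected maps of shape {self.input_shape} "
                f"(or flattened to {c * h * w}), got {X.shape}"
            )
        if not np.all(np.isfinite(X)):
            raise ValueError("maps contain non-finite values")
        return X

    def fit(self, X, y):
        """Train on maps X (n, 2, 5, 20) with subject labels y."""
        X = self._as_images(X)
        y = np.asarray(y)
        if len(y) != len(X):
            raise ValueError("X and y lengths differ")
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        n = len(X)
        onehot = np.eye(len(self.classes_))[y_idx]

        rng = np.random.default_rng(self.random_state)
        self.net_ = SmallConvNet(
            input_shape=self.input_shape,
            n_classes=len(self.classes_),
            kernel_size=self.kernel_size,
            n_filters=self.n_filters,
            dropout=self.dropout,
            rng=rng,
        )
        batch = self.batch_size or min(128, n)
        self.loss_curve_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, batch):
                sel = order[start : start + batch]
                losses.append(
                    self.net_.train_step(
                        X[sel], onehot[sel], self.learning_rate, self.momentum, rng
                    )
                )
            self.loss_curve_.append(float(np.mean(losses)))
        self.n_features_in_ = int(np.prod(self.input_shape))
        return self

    def predict_proba(self, X) -> np.ndarray:
        if not hasattr(self, "net_"):
            raise NotFittedError("call fit before predict")
        return self.net_.predict_proba(self._as_images(X))

    def predict(self, X) -> np.ndarray:
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def evaluate(model: ErrorMapClassifier, X_test, y_test) -> IdentificationResult:
    """Score a fitted classifier on held-out maps."""
    y_test = np.asarray(y_test)
    if len(y_test) == 0:
        raise ValueError("empty test set")
    unknown = set(y_test) - set(model.classes_)
    if unknown:
        raise ValueError(f"test labels not seen in training: {sorted(map(str, unknown))}")
    pred = model.predict(X_test)
    n_correct = int((pred == y_test).sum())
    return IdentificationResult(
        accuracy=n_correct / len(y_test),
        n_correct=n_correct,
        n_test=len(y_test),
        predictions=list(zip(y_test.tolist(), pred.tolist())),
    )


def _stack_session(maps: dict[tuple, ErrorMap], subjects, sessions):
    X, y = [], []
    for ses in sessions:
        for sid in subjects:
            if (sid, ses) not in maps:
                raise ValueError(f"subject {sid!r} is missing session {ses!r}")
            X.append(maps[(sid, ses)].errors)
            y.append(sid)
    return np.stack(X), np.asarray(y)


def identification_protocol(
    maps: dict[tuple, ErrorMap],
    train_sessions,
    test_session,
    seed: int | None = None,
    **classifier_kwargs,
) -> IdentificationResult:
    """Run one train/test session split of the identification experiment.

    ``maps`` is keyed by (subject_id, session).  The classifier is
    trained on all subjects' maps from ``train_sessions`` and must
    identify each subject from their single ``test_session`` map.  Any
    split is supported — e.g. (1, 2) -> 3, 1 -> 2, (1, 2, 3) -> 4 —
    as long as the test session is disjoint from training.
    """
    train_sessions = tuple(
        train_sessions if isinstance(train_sessions, (list, tuple)) else [train_sessions]
    )
    if test_session in train_sessions:
        raise ValueError("test session overlaps training sessions")
    subjects = sorted({sid for sid, _ in maps}, key=str)
    X_train, y_train = _stack_session(maps, subjects, train_sessions)
    X_test, y_test = _stack_session(maps, subjects, [test_session])

    clf = ErrorMapClassifier(random_state=seed, **classifier_kwargs)
    clf.fit(X_train, y_train)
    result = evaluate(clf, X_test, y_test)
    train_acc = float((clf.predict(X_train) == y_train).mean())
    result.train_sessions = train_sessions
    result.test_session = test_session
    result.seed = seed
    result.train_accuracy = train_acc
    result.config = clf.get_params()
    return result
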