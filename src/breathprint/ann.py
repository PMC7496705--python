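"""ANN scoring of breath patterns on [-1, 1], with data-scaling options.

The classifier is a one-hidden-layer network with tanh activations on both
the hidden and the output layer, trained by full-batch Adam on the squared
error between the scalar output and the +-1 class labels (case = +1,
control = -1). The saturating output unit guarantees every score lies in
(-1, 1) by construction, matching the device software's contract of a
per-breath value on [-1, 1] that is later thresholded.

Four data-scaling options are supported; parameters are always estimated on
training data only and re-applied as-is to held-out data:

- ``none``: identity.
- ``zscore_fiber``: per-feature standardization (applied at the stacked
  tensor level before the Tucker fit when used in the full pipeline).
- ``minmax_feature``: per-feature min-max to [0, 1]; constant features -> 0.
- ``unit_norm_per_measurement``: each row scaled to unit L2 norm (no fitted
  parameters); zero rows stay zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

SCALING_OPTIONS = ("none", "zscore_fiber", "minmax_feature", "unit_norm_per_measurement")

#: Options that act on the stacked tensor (pre-Tucker) in the full pipeline.
TENSOR_LEVEL_OPTIONS = ("zscore_fiber",)


class FeatureScaler(TransformerMixin, BaseEstimator):
    """Pure feature-matrix scaling transform with train-only parameters."""

    def __init__(self, option: str = "none"):
        self.option = option

    def fit(self, X, y=None):
        X = self._check(X)
        if self.option in ("none", "unit_norm_per_measurement"):
            self.params_ = {}
        elif self.option == "zscore_fiber":
            self.params_ = {"mean": X.mean(axis=0), "sd": X.std(axis=0)}
        elif self.option == "minmax_feature":
            self.params_ = {"min": X.min(axis=0), "range": np.ptp(X, axis=0)}
        else:
            raise ValueError(f"unknown scaling option {self.option!r}")
        return self

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "params_")
        X = self._check(X)
        if self.option == "none":
            return X
        if self.option == "unit_norm_per_measurement":
            norms = np.linalg.norm(X, axis=1, keepdims=True)
            return np.divide(X, norms, out=np.zeros_like(X), where=norms > 0)
        if self.option == "zscore_fiber":
            sd = self.params_["sd"]
            out = (X - self.params_["mean"]) / np.where(sd > 0, sd, 1.0)
            return np.where(sd > 0, out, 0.0)
        rng_ = self.params_["range"]
        out = (X - self.params_["min"]) / np.where(rng_ > 0, rng_, 1.0)
        return np.where(rng_ > 0, out, 0.0)

    @staticmethod
    def _check(X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if not np.isfinite(X).all():
            raise ValueError("non-finite entries in feature matrix")
        return X


def apply_scaling(features, option: str, fitted_params: dict | None = None):
    """Scale a feature matrix; returns (scaled, fitted_params).

    With ``fitted_params`` absent the parameters are estimated from the
    given matrix (training use); otherwise they are applied as-is (test use).
    """
    scaler = FeatureScaler(option)
    if fitted_params is None:
        scaler.fit(features)
    else:
        scaler.params_ = fitted_params
    return scaler.transform(features), scaler.params_


@dataclass(frozen=True)
class MLPConfig:
    """Training configuration for the scoring network."""

    hidden_units: int = 8
    epochs: int = 300
    learning_rate: float = 0.02
    alpha: float = 1e-3  # L2 penalty on weights
    seed: int = 0

    def __post_init__(self):
        if self.hidden_units < 1:
            raise ValueError("hidden_units must be >= 1")


class BreathNet(BaseEstimator):
    """One-hidden-layer tanh network scoring samples on (-1, 1).

    Trained with full-batch Adam on mean squared error against +-1 labels
    plus an L2 weight penalty; deterministic given ``random_state``.
    Fitted attributes: ``coefs_`` (W1, w2), ``intercepts_`` (b1, b2),
    ``loss_curve_``.
    """

    def __init__(
        self,
        hidden_units: int = 8,
        epochs: int = 300,
        learning_rate: float = 0.02,
        alpha: float = 1e-3,
        random_state: int = 0,
    ):
        self.hidden_units = hidden_units
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.alpha = alpha
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        if not set(np.unique(y)) <= {-1.0, 1.0}:
            raise ValueError("labels must be +-1 (case=+1, control=-1)")
        if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == -1).sum()) < 2:
            raise ValueError("need at least 2 samples of each class")

        n, d = X.shape
        h = self.hidden_units
        rng = np.random.default_rng(self.random_state)
        # Glorot-style init
        W1 = rng.normal(0.0, np.sqrt(2.0 / (d + h)), size=(d, h))
        b1 = np.zeros(h)
        w2 = rng.normal(0.0, np.sqrt(2.0 / (h + 1)), size=h)
        b2 = 0.0

        params = [W1, b1, w2, np.array([b2])]
        m_t = [np.zeros_like(p) for p in params]
        v_t = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        lr, alpha = self.learning_rate, self.alpha

        losses = []
        for step in range(1, self.epochs + 1):
            H = np.tanh(X @ params[0] + params[1])
            z = H @ params[2] + params[3][0]
            out = np.tanh(z)
            err = out - y
            loss = float(np.mean(err**2)) + alpha * (
                float((params[0] ** 2).sum()) + float((params[2] ** 2).sum())
            )
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "training diverged (non-finite loss); reduce learning_rate"
                )
            losses.append(loss)

            dz = 2.0 * err * (1.0 - out**2) / n
            g_w2 = H.T @ dz + 2.0 * alpha * params[2]
            g_b2 = np.array([dz.sum()])
            dH = np.outer(dz, params[2]) * (1.0 - H**2)
            g_W1 = X.T @ dH + 2.0 * alpha * params[0]
            g_b1 = dH.sum(axis=0)

            for i, g in enumerate((g_W1, g_b1, g_w2, g_b2)):
                m_t[i] = beta1 * m_t[i] + (1 - beta1) * g
                v_t[i] = beta2 * v_t[i] + (1 - beta2) * g**2
                mhat = m_t[i] / (1 - beta1**step)
                vhat = v_t[i] / (1 - beta2**step)
                params[i] = params[i] - lr * mhat / (np.sqrt(vhat) + eps)

        self.coefs_ = (params[0], params[2])
        self.intercepts_ = (params[1], float(params[3][0]))
        self.loss_curve_ = losses
        self.n_features_in_ = d
        return self

    def decision_function(self, X) -> np.ndarray:
        check_is_fitted(self, "coefs_")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape}"
            )
        W1, w2 = self.coefs_
        b1, b2 = self.intercepts_
        return np.tanh(np.tanh(X @ W1 + b1) @ w2 + b2)

    # scores on [-1, 1] are the primary output of this estimator
    predict = decision_function


@dataclass
class TrainedClassifier:
    """Scaling option (with fitted params) plus the trained network."""

    config: MLPConfig
    scaling_option: str
    scaler: FeatureScaler
    net: BreathNet

    @property
    def training_log(self) -> list[float]:
        return self.net.loss_curve_

    def predict(self, features: np.ndarray) -> np.ndarray:
        return self.net.predict(self.scaler.transform(features))


def train_mlp(features, labels, config: MLPConfig = MLPConfig(),
              scaling_option: str = "none") -> TrainedClassifier:
    """Fit the scaler (train data only) and the scoring network."""
    scaler = FeatureScaler(scaling_option).fit(features)
    net = BreathNet(
        hidden_units=config.hidden_units,
        epochs=config.epochs,
        learning_rate=config.learning_rate,
        alpha=config.alpha,
        random_state=config.seed,
    ).fit(scaler.transform(features), labels)
    return TrainedClassifier(
        config=config, scaling_option=scaling_option, scaler=scaler, net=net
    )


def predict(classifier: TrainedClassifier, features) -> np.ndarray:
    """Scores in [-1, 1] for a feature matrix; pure function."""
    return classifier.predict(np.asarray(features, dtype=float))


def select_model(candidates: list, cv_results: list[dict]) -> int:
    """Index of the best candidate by CV accuracy.

    Ties broken by higher AUC, then fewer hidden units, then the canonical
    scaling-option order. ``candidates`` holds (scaling_option, MLPConfig)
    pairs; ``cv_results`` dicts with 'accuracy' and 'auc'.
    """
    if not candidates:
        raise ValueError("empty candidate list")
    if len(candidates) != len(cv_results):
        raise ValueError("candidates and cv_results must align")

    def key(i: int):
        option, cfg = candidates[i]
        res = cv_results[i]
        return (
            -res["accuracy"],
            -res["auc"],
            cfg.hidden_units,
            SCALING_OPTIONS.index(option),
            i,
        )

    return min(range(len(candidates)), key=key)
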