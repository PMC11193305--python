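"""Direct LVDdI regression with a densely connected network.

The regressor maps a subject's representative pulse waveform (or its
harmonic powers) to the left ventricular diastolic diameter index
(mm/m^2). The network is a small dense net: each block consumes the
concatenation of ALL preceding block outputs,

    Output^{n+1} = G(Output^1, Output^2, ..., Output^n),

where the block operator G is batch normalization, ReLU activation, then
an affine map. Two hidden blocks of 128 and 32 units feed a single
output unit; a dropout layer sits between the two hidden blocks.
Training minimizes mean squared error with Adam (learning rate 0.001,
rho1 0.9, rho2 0.999, delta 1e-8) over 100 epochs with batches of 128
samples and a 10% validation split carved from the training data.

Targets are standardized internally during training (predictions are
mapped back), which conditions the optimization without changing the
model class; reported MSE is on the original mm/m^2 scale.

Regression quality is summarized by MAPE and the derived accuracy
(1 - MAPE), by Bland-Altman agreement against the measured values, and
by thresholding the predicted LVDdI into an LVE/non-LVE classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import PredictionSet, POSITIVE_LABEL
from .screening import label_lve
from .synthetic import LVDDI_THRESHOLDS

__all__ = [
    "DenseNetConfig",
    "DenseNetRegressor",
    "BlandAltmanSummary",
    "train_regressor",
    "predict_lvddi",
    "mape_accuracy",
    "bland_altman",
    "regression_as_classifier",
]


@dataclass
class DenseNetConfig:
    """Architecture and Adam training recipe of the dense net.

    ``adam_epsilon_alt`` records a second, epsilon-like constant that
    sometimes accompanies published Adam settings alongside the
    numerical-stability constant ``adam_delta``; it has no defined role
    in the update rule and is not used.
    """

    hidden_sizes: tuple = (128, 32)
    dropout_rate: float = 0.2
    dense_connectivity: bool = True
    learning_rate: float = 0.001
    adam_rho1: float = 0.9
    adam_rho2: float = 0.999
    adam_delta: float = 1e-8
    adam_epsilon_alt: float = 0.001   # recorded, unused
    epochs: int = 100
    batch_size: int = 128
    validation_fraction: float = 0.10
    prediction_floor: float = 0.1     # mm/m^2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(h <= 0 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be positive")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


class _Block:
    """One G block: batch normalization -> ReLU -> affine."""

    def __init__(self, dim_in: int, dim_out: int, rng: np.random.Generator):
        self.gamma = np.ones(dim_in)
        self.beta = np.zeros(dim_in)
        self.running_mean = np.zeros(dim_in)
        self.running_var = np.ones(dim_in)
        self.W = rng.normal(0.0, np.sqrt(2.0 / dim_in), size=(dim_in, dim_out))
        self.b = np.zeros(dim_out)
        self._cache = None

    @property
    def n_parameters(self) -> int:
        return self.gamma.size + self.beta.size + self.W.size + self.b.size

    def parameters(self):
        return [self.gamma, self.beta, self.W, self.b]

    def forward(self, x: np.ndarray, training: bool, bn_eps: float,
                bn_momentum: float = 0.1) -> np.ndarray:
        if training and x.shape[0] > 1:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = (1 - bn_momentum) * self.running_mean + bn_momentum * mean
            self.running_var = (1 - bn_momentum) * self.running_var + bn_momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + bn_eps)
        x_hat = (x - mean) * inv_std
        z = self.gamma * x_hat + self.beta
        r = np.maximum(z, 0.0)
        out = r @ self.W + self.b
        if training:
            self._cache = (x_hat, inv_std, z, r)
        return out

    def backward(self, grad_out: np.ndarray):
        """Returns (grad_x, [d_gamma, d_beta, dW, db])."""
        x_hat, inv_std, z, r = self._cache
        m = grad_out.shape[0]
        dW = r.T @ grad_out
        db = grad_out.sum(axis=0)
        dr = grad_out @ self.W.T
        dz = dr * (z > 0)
        d_gamma = (dz * x_hat).sum(axis=0)
        d_beta = dz.sum(axis=0)
        dx_hat = dz * self.gamma
        if m > 1:
            dx = (inv_std / m) * (
                m * dx_hat
                - dx_hat.sum(axis=0)
                - x_hat * (dx_hat * x_hat).sum(axis=0)
            )
        else:
            dx = dx_hat * inv_std
        return dx, [d_gamma, d_beta, dW, db]


class DenseNetRegressor:
    """Densely connected feed-forward regressor (see module docstring)."""

    BN_EPS = 1e-5

    def __init__(self, n_features: int, config: DenseNetConfig):
        self.config = config
        self.n_features = n_features
        rng = np.random.default_rng(config.seed)
        dims_out = list(config.hidden_sizes) + [1]
        self.blocks: list[_Block] = []
        concat_dim = n_features
        prev_dim = n_features
        for dim_out in dims_out:
            dim_in = concat_dim if config.dense_connectivity else prev_dim
            self.blocks.append(_Block(dim_in, dim_out, rng))
            concat_dim += dim_out
            prev_dim = dim_out
        self._rng = rng
        self.y_mean = 0.0
        self.y_sd = 1.0
        self.fitted = False

    @property
    def n_parameters(self) -> int:
        return sum(b.n_parameters for b in self.blocks)

    def _forward(self, X: np.ndarray, training: bool):
        outputs = [X]
        dropout_scales = [None] * (len(self.blocks) + 1)
        for i, block in enumerate(self.blocks):
            if self.config.dense_connectivity:
                inp = np.concatenate(outputs, axis=1)
            else:
                inp = outputs[-1]
            out = block.forward(inp, training, self.BN_EPS)
            # dropout between the 1st and 2nd hidden blocks
            if i == 0 and training and self.config.dropout_rate > 0:
                keep = 1.0 - self.config.dropout_rate
                mask = (self._rng.uniform(size=out.shape) < keep) / keep
                out = out * mask
                dropout_scales[1] = mask
            outputs.append(out)
        return outputs, dropout_scales

    def _backward(self, outputs, dropout_scales, grad_pred):
        grads_on_outputs = [np.zeros_like(o) for o in outputs]
        grads_on_outputs[-1] = grad_pred
        param_grads = [None] * len(self.blocks)
        for i in range(len(self.blocks) - 1, -1, -1):
            g_out = grads_on_outputs[i + 1]
            if dropout_scales[i + 1] is not None:
                g_out = g_out * dropout_scales[i + 1]
            g_in, pgrads = self.blocks[i].backward(g_out)
            param_grads[i] = pgrads
            if self.config.dense_connectivity:
                offset = 0
                for j in range(i + 1):
                    width = outputs[j].shape[1]
                    grads_on_outputs[j] = grads_on_outputs[j] + g_in[:, offset:offset + width]
                    offset += width
            else:
                grads_on_outputs[i] = grads_on_outputs[i] + g_in
        return param_grads

    def fit(self, X, y) -> pd.DataFrame:
        """Train with Adam on MSE; returns the per-epoch loss history."""
        cfg = self.config
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if len(X) < 10:
            raise ValueError("need at least 10 training subjects")
        if X.shape[1] != self.n_features:
            raise ValueError("feature dimension mismatch")

        self.y_mean = float(y.mean())
        self.y_sd = float(y.std()) or 1.0
        y_std = (y - self.y_mean) / self.y_sd

        n = len(X)
        split_rng = np.random.default_rng(cfg.seed + 1)
        perm = split_rng.permutation(n)
        n_val = int(round(cfg.validation_fraction * n))
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        X_tr, y_tr = X[tr_idx], y_std[tr_idx]
        X_val, y_val = X[val_idx], y_std[val_idx]

        params = [p for blk in self.blocks for p in blk.parameters()]
        m_state = [np.zeros_like(p) for p in params]
        v_state = [np.zeros_like(p) for p in params]
        t = 0
        history = []
        epoch_rng = np.random.default_rng(cfg.seed + 2)
        scale = self.y_sd ** 2  # back to mm/m^2 squared for reporting

        for epoch in range(cfg.epochs):
            order = epoch_rng.permutation(len(X_tr))
            batch_losses = []
            for start in range(0, len(X_tr), cfg.batch_size):
                idx = order[start:start + cfg.batch_size]
                xb, yb = X_tr[idx], y_tr[idx]
                outputs, drop = self._forward(xb, training=True)
                pred = outputs[-1].ravel()
                err = pred - yb
                loss = float(np.mean(err ** 2))
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"training diverged at epoch {epoch}: non-finite loss")
                batch_losses.append((loss, len(idx)))
                grad_pred = (2.0 * err / len(idx)).reshape(-1, 1)
                pgrads = self._backward(outputs, drop, grad_pred)
                flat_grads = [g for blk_g in pgrads for g in blk_g]
                t += 1
                lr_t = cfg.learning_rate * (
                    np.sqrt(1 - cfg.adam_rho2 ** t) / (1 - cfg.adam_rho1 ** t))
                for p, g, ms, vs in zip(params, flat_grads, m_state, v_state):
                    ms *= cfg.adam_rho1
                    ms += (1 - cfg.adam_rho1) * g
                    vs *= cfg.adam_rho2
                    vs += (1 - cfg.adam_rho2) * g ** 2
                    p -= lr_t * ms / (np.sqrt(vs) + cfg.adam_delta)
            train_mse = scale * sum(l * w for l, w in batch_losses) / len(X_tr)
            if len(X_val):
                val_pred = self._predict_standardized(X_val)
                val_mse = scale * float(np.mean((val_pred - y_val) ** 2))
            else:
                val_mse = np.nan
            history.append({"epoch": epoch, "train_mse": train_mse,
                            "val_mse": val_mse})

        self.fitted = True
        return pd.DataFrame(history)

    def _predict_standardized(self, X: np.ndarray) -> np.ndarray:
        outputs, _ = self._forward(np.asarray(X, dtype=float), training=False)
        return outputs[-1].ravel()

    def predict(self, X) -> np.ndarray:
        """Predicted LVDdI (mm/m^2), clamped at the configured positive floor."""
        if not self.fitted:
            raise RuntimeError("model is not trained")
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_features:
            raise ValueError(
                f"input length mismatch: expected {self.n_features}, got {X.shape[1]}")
        pred = self._predict_standardized(X) * self.y_sd + self.y_mean
        return np.maximum(pred, self.config.prediction_floor)


def train_regressor(X_train, y_train, config: DenseNetConfig):
    """Fit a dense net on (waveforms, LVDdI targets); returns (model, history)."""
    X = np.asarray(X_train, dtype=float)
    model = DenseNetRegressor(X.shape[1], config)
    history = model.fit(X, y_train)
    return model, history


def predict_lvddi(model: DenseNetRegressor, waveforms) -> np.ndarray:
    return model.predict(waveforms)


def mape_accuracy(y, y_hat) -> tuple[float, float]:
    """Mean absolute percentage error (percent) and accuracy = 1 - MAPE.

    MAPE = (100%/n) * sum |(y_hat - y)/y|; accuracy is returned as a
    fraction (1 corresponds to MAPE of 0%) and can be negative when
    MAPE exceeds 100%.
    """
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    if np.any(y == 0):
        raise ValueError("measured values must be nonzero (relative error)")
    mape = 100.0 * float(np.mean(np.abs((y_hat - y) / y)))
    return mape, 1.0 - mape / 100.0


@dataclass
class BlandAltmanSummary:
    """Agreement between measured and predicted values."""

    means: np.ndarray       # per-pair (y + y_hat) / 2
    differences: np.ndarray  # per-pair y_hat - y
    mean_difference: float
    sd_difference: float
    lower_limit: float
    upper_limit: float
    fraction_within_limits: float


def bland_altman(y, y_hat) -> BlandAltmanSummary:
    """Bland-Altman agreement: mean bias and 95% limits (mean +/- 1.96 SD)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if len(y) != len(y_hat) or len(y) < 2:
        raise ValueError("need at least two pairs of equal length")
    diffs = y_hat - y
    means = (y + y_hat) / 2.0
    mean_diff = float(diffs.mean())
    sd_diff = float(diffs.std(ddof=1))
    lower = mean_diff - 1.96 * sd_diff
    upper = mean_diff + 1.96 * sd_diff
    within = float(np.mean((diffs >= lower) & (diffs <= upper)))
    return BlandAltmanSummary(means, diffs, mean_diff, sd_diff,
                              lower, upper, within)


def regression_as_classifier(pred_lvddi, sexes, subject_ids=None,
                             y_true=None) -> PredictionSet:
    """Threshold predicted LVDdI into LVE/non-LVE labels with a ROC score.

    Labels inherit the strict sex-specific thresholds. The continuous
    score is the signed margin (predicted LVDdI minus the subject's
    sex-specific threshold) squashed by a logistic so male and female
    subjects share one score axis in [0, 1]; the squashing is monotone
    and therefore leaves the ROC curve unchanged.
    """
    pred = np.asarray(pred_lvddi, dtype=float)
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be finite")
    sexes = np.asarray(sexes)
    thresholds = np.array([LVDDI_THRESHOLDS[s] for s in sexes])
    margins = pred - thresholds
    scores = 1.0 / (1.0 + np.exp(-margins))
    labels = np.array([label_lve(v, s) for v, s in zip(pred, sexes)],
                      dtype=object)
    if subject_ids is None:
        subject_ids = np.arange(len(pred)).astype(str)
    if y_true is None:
        y_true = np.full(len(pred), "", dtype=object)
    return PredictionSet(
        subject_ids=np.asarray(subject_ids),
        y_true=np.asarray(y_true, dtype=object),
        y_pred=labels,
        scores=scores,
    )
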