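"""GRU sequence classifier over feature windows (GRU-S).

A single gated-recurrent-unit layer reads each 2 s feature window timestep
by timestep; its final hidden state feeds a stack of five ReLU dense
layers with two dropout layers, then a softmax output over the four status
classes.  The gating is the standard update/reset formulation

    z_t = sigmoid(x_t Wxz + h_{t-1} Whz + bz)          (update: keep old)
    r_t = sigmoid(x_t Wxr + h_{t-1} Whr + br)          (reset)
    n_t = tanh(x_t Wxn + (r_t * h_{t-1}) Whn + bn)     (candidate)
    h_t = z_t * h_{t-1} + (1 - z_t) * n_t

The network, backpropagation through time and the Adam optimizer are
implemented directly in NumPy: the model is small enough (tens of
thousands of parameters) to train on one CPU in minutes at cohort scale.
Gradients are exercised against finite differences in the test suite.

Everything the source protocol leaves unstated — layer widths, dropout
rate and placement, optimizer, epoch budget — is a configurable default
here, not a measured value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .features import Window, window_labels, window_tensor
from .records import StatusLabel, ValidationError

__all__ = ["GruConfig", "GruClassifier", "build_model", "train", "predict"]

_CLIP = 60.0  # sigmoid pre-activation clip against overflow


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -_CLIP, _CLIP)))


@dataclass(frozen=True)
class GruConfig:
    """Hyperparameters of the GRU classifier.

    ``dense_layers`` defaults to five hidden widths with dropout after the
    1st and 3rd (1-based positions in the dense stack); ``recurrent_units``
    is the GRU state size.  ``class_weighting`` switches on
    inverse-frequency class weights in the cross-entropy loss for
    imbalanced data (off by default).  ``validation_fraction`` of windows
    is held out (seeded) for the per-epoch validation curve.
    """

    recurrent_units: int = 64
    dense_layers: tuple[int, ...] = (128, 64, 32, 16, 8)
    dropout_rate: float = 0.2
    dropout_positions: tuple[int, ...] = (1, 3)
    n_classes: int = 4
    activation_hidden: str = "relu"
    epochs: int = 10
    batch_size: int = 64
    learning_rate: float = 1e-3
    seed: int = 0
    class_weighting: bool = False
    validation_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.recurrent_units < 1 or any(w < 1 for w in self.dense_layers):
            raise ValueError("layer widths must be positive")
        if not self.dense_layers:
            raise ValueError("at least one dense layer is required")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        bad = [p for p in self.dropout_positions
               if not 1 <= p <= len(self.dense_layers)]
        if bad:
            raise ValueError(
                f"dropout_positions {bad} outside the dense stack "
                f"(1..{len(self.dense_layers)})"
            )
        if self.activation_hidden != "relu":
            raise ValueError("only the 'relu' hidden activation is supported")
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate <= 0:
            raise ValueError("invalid training hyperparameters")
        if not 0.0 <= self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in [0, 1)")


class GruClassifier:
    """Four-class status classifier over (n, window_len, n_channels) tensors.

    Usage::

        clf = GruClassifier(GruConfig(seed=1)).fit(X_train, y_train)
        labels, probs = clf.predict(X_test)

    ``fit`` standardizes channels (mean/sd estimated from the training
    tensor) and records a per-epoch training/validation history.  All
    randomness (init, shuffling, dropout, validation split) derives from
    ``config.seed``, so (seed, data, config) fully determine the result on
    one platform.
    """

    def __init__(self, config: GruConfig | None = None):
        self.config = config or GruConfig()
        self.params: dict[str, np.ndarray] | None = None
        self.n_channels: int | None = None
        self.scaler_mean: np.ndarray | None = None
        self.scaler_sd: np.ndarray | None = None
        self.history: dict[str, list[float]] = {}

    # -- construction -------------------------------------------------------

    def build(self, n_channels: int) -> "GruClassifier":
        """Initialize weights (Glorot-uniform, seeded) for a channel count."""
        if n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        cfg = self.config
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=cfg.seed, spawn_key=(0,))
        )

        def glorot(fan_in, fan_out, shape):
            lim = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-lim, lim, shape)

        u, c = cfg.recurrent_units, n_channels
        p = {
            "Wx": glorot(c, u, (c, 3 * u)),
            "Wh": glorot(u, u, (u, 3 * u)),
            "b": np.zeros(3 * u),
        }
        widths = [u, *cfg.dense_layers]
        for i, (din, dout) in enumerate(zip(widths[:-1], widths[1:])):
            p[f"W{i}"] = glorot(din, dout, (din, dout))
            p[f"b{i}"] = np.zeros(dout)
        p["Wo"] = glorot(widths[-1], cfg.n_classes, (widths[-1], cfg.n_classes))
        p["bo"] = np.zeros(cfg.n_classes)
        self.params = p
        self.n_channels = n_channels
        return self

    @property
    def n_parameters(self) -> int:
        if self.params is None:
            raise RuntimeError("model not built")
        return int(sum(v.size for v in self.params.values()))

    # -- forward ------------------------------------------------------------

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        if self.scaler_mean is None:
            return X
        return (X - self.scaler_mean) / self.scaler_sd

    def _forward(self, X: np.ndarray, dropout_rng=None,
                 cache: dict | None = None) -> np.ndarray:
        """Logits for a standardized batch (B, T, C).

        ``dropout_rng`` set -> training mode (inverted dropout);
        ``cache`` dict collects intermediates for backprop.
        """
        p = self.params
        cfg = self.config
        B, T, _ = X.shape
        u = cfg.recurrent_units
        h = np.zeros((B, u))
        steps = []
        for t in range(T):
            x = X[:, t, :]
            zr = _sigmoid(x @ p["Wx"][:, : 2 * u] + h @ p["Wh"][:, : 2 * u]
                          + p["b"][: 2 * u])
            z, r = zr[:, :u], zr[:, u:]
            n_pre = (x @ p["Wx"][:, 2 * u:] + (r * h) @ p["Wh"][:, 2 * u:]
                     + p["b"][2 * u:])
            n = np.tanh(n_pre)
            h_new = z * h + (1.0 - z) * n
            if cache is not None:
                steps.append((x, h, z, r, n))
            h = h_new
        a = h
        dense = []
        for i in range(len(cfg.dense_layers)):
            pre = a @ p[f"W{i}"] + p[f"b{i}"]
            out = np.maximum(pre, 0.0)
            mask = None
            if dropout_rng is not None and cfg.dropout_rate > 0 and \
                    (i + 1) in cfg.dropout_positions:
                keep = 1.0 - cfg.dropout_rate
                mask = (dropout_rng.random(out.shape) < keep) / keep
                out = out * mask
            if cache is not None:
                dense.append((a, pre, mask))
            a = out
        logits = a @ p["Wo"] + p["bo"]
        if cache is not None:
            cache["steps"] = steps
            cache["dense"] = dense
            cache["last_hidden"] = h
            cache["dense_out"] = a
        return logits

    @staticmethod
    def _softmax(logits: np.ndarray) -> np.ndarray:
        e = np.exp(logits - logits.max(axis=1, keepdims=True))
        return e / e.sum(axis=1, keepdims=True)

    # -- backward -----------------------------------------------------------

    def _backward(self, X: np.ndarray, dlogits: np.ndarray,
                  cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        cfg = self.config
        u = cfg.recurrent_units
        g = {k: np.zeros_like(v) for k, v in p.items()}

        g["Wo"] = cache["dense_out"].T @ dlogits
        g["bo"] = dlogits.sum(axis=0)
        da = dlogits @ p["Wo"].T
        for i in reversed(range(len(cfg.dense_layers))):
            a_in, pre, mask = cache["dense"][i]
            if mask is not None:
                da = da * mask
            dpre = da * (pre > 0)
            g[f"W{i}"] = a_in.T @ dpre
            g[f"b{i}"] = dpre.sum(axis=0)
            da = dpre @ p[f"W{i}"].T

        dh = da
        Whz, Whr, Whn = p["Wh"][:, :u], p["Wh"][:, u:2 * u], p["Wh"][:, 2 * u:]
        for x, h_prev, z, r, n in reversed(cache["steps"]):
            dz = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            g["Wx"][:, 2 * u:] += x.T @ dn_pre
            g["Wh"][:, 2 * u:] += (r * h_prev).T @ dn_pre
            g["b"][2 * u:] += dn_pre.sum(axis=0)
            dq = dn_pre @ Whn.T
            dr = dq * h_prev
            dh_prev += dq * r
            dz_pre = dz * z * (1.0 - z)
            dr_pre = dr * r * (1.0 - r)
            g["Wx"][:, :u] += x.T @ dz_pre
            g["Wx"][:, u:2 * u] += x.T @ dr_pre
            g["Wh"][:, :u] += h_prev.T @ dz_pre
            g["Wh"][:, u:2 * u] += h_prev.T @ dr_pre
            g["b"][:u] += dz_pre.sum(axis=0)
            g["b"][u:2 * u] += dr_pre.sum(axis=0)
            dh_prev += dz_pre @ Whz.T + dr_pre @ Whr.T
            dh = dh_prev
        return g

    def _loss_grad(self, logits: np.ndarray, y: np.ndarray,
                   class_weights: np.ndarray | None):
        """Mean (weighted) cross-entropy and its gradient w.r.t. logits."""
        B = len(y)
        probs = self._softmax(logits)
        w = np.ones(B) if class_weights is None else class_weights[y]
        wsum = w.sum()
        logp = np.log(np.clip(probs[np.arange(B), y], 1e-12, None))
        loss = float(-(w * logp).sum() / wsum)
        dlogits = probs.copy()
        dlogits[np.arange(B), y] -= 1.0
        dlogits *= (w / wsum)[:, None]
        return loss, dlogits, probs

    # -- training -----------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GruClassifier":
        """Train on an (n, T, C) tensor and integer labels.

        Requires at least one window of every class.  Records
        ``history['loss'/'accuracy'/'val_loss'/'val_accuracy']`` per epoch
        (training metrics are running minibatch averages).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=np.int64)
        if X.ndim != 3 or len(X) != len(y):
            raise ValueError("X must be (n, window_len, n_channels) matching y")
        cfg = self.config
        present = np.unique(y)
        missing = [StatusLabel(c).label_name for c in range(cfg.n_classes)
                   if c not in present]
        if missing:
            raise ValidationError(
                f"training data lack classes: {', '.join(missing)}"
            )
        if self.params is None:
            self.build(X.shape[2])
        elif X.shape[2] != self.n_channels:
            raise ValueError(
                f"got {X.shape[2]} channels, model built for {self.n_channels}"
            )

        flat = X.reshape(-1, X.shape[2])
        self.scaler_mean = flat.mean(axis=0)
        self.scaler_sd = np.clip(flat.std(axis=0), 1e-8, None)
        Xs = self._standardize(X)

        ss = np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,))
        shuffle_rng, dropout_rng, split_rng = map(
            np.random.default_rng, ss.spawn(3)
        )

        n = len(y)
        idx = split_rng.permutation(n)
        n_val = int(round(cfg.validation_fraction * n))
        val_idx, tr_idx = idx[:n_val], idx[n_val:]
        if len(tr_idx) == 0:
            raise ValueError("validation split leaves no training windows")
        Xtr, ytr = Xs[tr_idx], y[tr_idx]
        Xval, yval = Xs[val_idx], y[val_idx]

        class_weights = None
        if cfg.class_weighting:
            counts = np.bincount(ytr, minlength=cfg.n_classes).astype(float)
            counts[counts == 0] = 1.0
            class_weights = len(ytr) / (cfg.n_classes * counts)

        adam_m = {k: np.zeros_like(v) for k, v in self.params.items()}
        adam_v = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        step = 0

        self.history = {"loss": [], "accuracy": [],
                        "val_loss": [], "val_accuracy": []}
        for _ in range(cfg.epochs):
            order = shuffle_rng.permutation(len(ytr))
            ep_loss = ep_correct = ep_weight = 0.0
            for lo in range(0, len(order), cfg.batch_size):
                sel = order[lo: lo + cfg.batch_size]
                xb, yb = Xtr[sel], ytr[sel]
                cache: dict = {}
                logits = self._forward(xb, dropout_rng=dropout_rng, cache=cache)
                loss, dlogits, probs = self._loss_grad(logits, yb, class_weights)
                if not np.isfinite(loss):
                    raise FloatingPointError("non-finite training loss")
                grads = self._backward(xb, dlogits, cache)
                step += 1
                lr_t = cfg.learning_rate * \
                    np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
                for k, v in self.params.items():
                    adam_m[k] = b1 * adam_m[k] + (1 - b1) * grads[k]
                    adam_v[k] = b2 * adam_v[k] + (1 - b2) * grads[k] ** 2
                    v -= lr_t * adam_m[k] / (np.sqrt(adam_v[k]) + eps)
                ep_loss += loss * len(yb)
                ep_correct += float((probs.argmax(axis=1) == yb).sum())
                ep_weight += len(yb)
            self.history["loss"].append(ep_loss / ep_weight)
            self.history["accuracy"].append(ep_correct / ep_weight)
            if len(yval):
                vl, va = self._evaluate(Xval, yval, class_weights)
                self.history["val_loss"].append(vl)
                self.history["val_accuracy"].append(va)
        return self

    def _evaluate(self, Xs, y, class_weights, batch: int = 2048):
        losses, correct = 0.0, 0.0
        for lo in range(0, len(y), batch):
            xb, yb = Xs[lo: lo + batch], y[lo: lo + batch]
            logits = self._forward(xb)
            loss, _, probs = self._loss_grad(logits, yb, class_weights)
            losses += loss * len(yb)
            correct += float((probs.argmax(axis=1) == yb).sum())
        return losses / len(y), correct / len(y)

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X: np.ndarray, batch: int = 2048) -> np.ndarray:
        if self.params is None:
            raise RuntimeError("model not built/trained")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_channels:
            raise ValueError(
                f"channel mismatch: expected (n, window_len, "
                f"{self.n_channels}) input, got shape {X.shape}"
            )
        Xs = self._standardize(X)
        out = [self._softmax(self._forward(Xs[lo: lo + batch]))
               for lo in range(0, len(Xs), batch)]
        return np.concatenate(out) if out else np.zeros((0, self.config.n_classes))

    def predict(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(labels, probabilities): argmax class per window and the softmax."""
        probs = self.predict_proba(X)
        return probs.argmax(axis=1).astype(np.int64), probs

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Archive config + scaler + weights (.npz with embedded JSON config)."""
        if self.params is None:
            raise RuntimeError("nothing to save: model not built")
        meta = {
            "config": asdict(self.config),
            "n_channels": self.n_channels,
            "history": self.history,
        }
        np.savez(
            path,
            __meta__=np.array(json.dumps(meta)),
            scaler_mean=self.scaler_mean if self.scaler_mean is not None
            else np.array([]),
            scaler_sd=self.scaler_sd if self.scaler_sd is not None
            else np.array([]),
            **{f"param_{k}": v for k, v in self.params.items()},
        )

    @classmethod
    def load(cls, path) -> "GruClassifier":
        with np.load(path, allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
            cfg = meta["config"]
            for key in ("dense_layers", "dropout_positions"):
                cfg[key] = tuple(cfg[key])
            model = cls(GruConfig(**cfg))
            model.n_channels = meta["n_channels"]
            model.history = meta["history"]
            model.params = {
                k[len("param_"):]: data[k] for k in data.files
                if k.startswith("param_")
            }
            if data["scaler_mean"].size:
                model.scaler_mean = data["scaler_mean"]
                model.scaler_sd = data["scaler_sd"]
        return model


# -- thin functional surface over the estimator ------------------------------

def build_model(cfg: GruConfig, n_channels: int) -> GruClassifier:
    """Construct an untrained, weight-initialized classifier."""
    return GruClassifier(cfg).build(n_channels)


def train(model: GruClassifier, train_windows: list[Window]) -> GruClassifier:
    """Train a classifier on a list of labelled windows."""
    return model.fit(window_tensor(train_windows), window_labels(train_windows))


def predict(model: GruClassifier, windows: list[Window]):
    """Per-window (StatusLabel, probability 4-vector) pairs."""
    labels, probs = model.predict(window_tensor(windows))
    return [(StatusLabel(int(l)), p) for l, p in zip(labels, probs)]
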