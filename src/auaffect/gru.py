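"""Minimal seeded GRU sequence regressor on numpy.

One recurrent GRU layer over a short (5-step) sequence followed by a single
linear output unit.  The cell follows the common convention

    z_t = sigmoid(x_t Wz + h_{t-1} Uz + bz)            (update gate)
    r_t = sigmoid(x_t Wr + h_{t-1} Ur + br)            (reset gate)
    c_t = phi(x_t Wc + (r_t * h_{t-1}) Uc + bc)        (candidate)
    h_t = z_t * h_{t-1} + (1 - z_t) * c_t

with a configurable candidate activation phi (tanh, relu, or identity for
"none"); the gate activations stay sigmoid.  Input dropout and recurrent
dropout use inverted masks shared across time steps, redrawn per batch, one
mask per gate use — active only during training.

Gradients are computed by backpropagation through time and are checked
against central finite differences in the test suite.  Optimization is Adam
on mean-absolute-error loss.
"""

from __future__ import annotations

import math
from typing import Callable

import numpy as np

_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    # name -> (phi(a), dphi/da expressed from (a, phi(a)))
    "tanh": (np.tanh, lambda a, c: 1.0 - c * c),
    "relu": (lambda a: np.maximum(a, 0.0), lambda a, c: (a > 0.0).astype(a.dtype)),
    "none": (lambda a: a, lambda a, c: np.ones_like(a)),
}

PARAM_NAMES = ("Wz", "Wr", "Wc", "Uz", "Ur", "Uc", "bz", "br", "bc", "wo", "bo")


def _sigmoid(a: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * a))  # numerically stable logistic


def _glorot(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    limit = math.sqrt(6.0 / sum(shape))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return q * np.sign(np.diag(r))


def gru_param_count(n_features: int, hidden_units: int) -> int:
    """Closed-form parameter count: 3 gate blocks plus the linear head."""
    h, k = hidden_units, n_features
    return 3 * (h * k + h * h + h) + h + 1


class GRURegressor:
    """GRU layer + linear unit; plain-numpy parameters, Adam training."""

    def __init__(
        self,
        n_features: int,
        hidden_units: int,
        activation: str = "tanh",
        dropout: float = 0.0,
        recurrent_dropout: float = 0.0,
        output_bias_init: float = 0.0,
        rng: np.random.Generator | None = None,
    ) -> None:
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.n_features = int(n_features)
        self.hidden_units = int(hidden_units)
        self.activation = activation
        self.dropout = float(dropout)
        self.recurrent_dropout = float(recurrent_dropout)
        k, h = self.n_features, self.hidden_units
        self.params: dict[str, np.ndarray] = {
            "Wz": _glorot(rng, (k, h)),
            "Wr": _glorot(rng, (k, h)),
            "Wc": _glorot(rng, (k, h)),
            "Uz": _orthogonal(rng, h),
            "Ur": _orthogonal(rng, h),
            "Uc": _orthogonal(rng, h),
            "bz": np.zeros(h),
            "br": np.zeros(h),
            "bc": np.zeros(h),
            "wo": _glorot(rng, (h, 1))[:, 0],
            "bo": np.array(float(output_bias_init)),
        }

    # -- forward / backward -------------------------------------------------

    def _draw_masks(self, batch: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Inverted dropout masks, one per gate use, shared across time steps."""
        masks: dict[str, np.ndarray] = {}
        for g in ("z", "r", "c"):
            if self.dropout > 0.0:
                keep = 1.0 - self.dropout
                masks[f"in_{g}"] = rng.binomial(1, keep, size=(batch, self.n_features)) / keep
            if self.recurrent_dropout > 0.0:
                keep = 1.0 - self.recurrent_dropout
                masks[f"rec_{g}"] = rng.binomial(1, keep, size=(batch, self.hidden_units)) / keep
        return masks

    def forward(
        self, X: np.ndarray, masks: dict[str, np.ndarray] | None = None
    ) -> tuple[np.ndarray, dict]:
        """Run the sequence; X is (batch, T, n_features).  Returns (y, cache)."""
        X = np.asarray(X, dtype=float)
        batch, T, k = X.shape
        if k != self.n_features:
            raise ValueError(f"expected {self.n_features} features, got {k}")
        p = self.params
        phi, _ = _ACTIVATIONS[self.activation]
        ones_in = np.ones((batch, k))
        ones_rec = np.ones((batch, self.hidden_units))
        m = masks or {}
        mi = {g: m.get(f"in_{g}", ones_in) for g in ("z", "r", "c")}
        mr = {g: m.get(f"rec_{g}", ones_rec) for g in ("z", "r", "c")}
        h = np.zeros((batch, self.hidden_units))
        steps = []
        for t in range(T):
            x = X[:, t, :]
            az = (x * mi["z"]) @ p["Wz"] + (h * mr["z"]) @ p["Uz"] + p["bz"]
            ar = (x * mi["r"]) @ p["Wr"] + (h * mr["r"]) @ p["Ur"] + p["br"]
            z, r = _sigmoid(az), _sigmoid(ar)
            hc = h * mr["c"]
            ac = (x * mi["c"]) @ p["Wc"] + (r * hc) @ p["Uc"] + p["bc"]
            c = phi(ac)
            h_new = z * h + (1.0 - z) * c
            steps.append({"x": x, "h_prev": h, "z": z, "r": r, "ac": ac, "c": c, "hc": hc})
            h = h_new
        y = h @ p["wo"] + p["bo"]
        cache = {"steps": steps, "h_last": h, "mi": mi, "mr": mr}
        return y, cache

    def backward(self, cache: dict, dy: np.ndarray) -> dict[str, np.ndarray]:
        """BPTT: gradient of the loss w.r.t. every parameter given dL/dy."""
        p = self.params
        _, dphi = _ACTIVATIONS[self.activation]
        mi, mr = cache["mi"], cache["mr"]
        g = {name: np.zeros_like(p[name]) for name in PARAM_NAMES}
        g["wo"] = cache["h_last"].T @ dy
        g["bo"] = np.array(dy.sum())
        dh = np.outer(dy, p["wo"])
        for st in reversed(cache["steps"]):
            x, h_prev = st["x"], st["h_prev"]
            z, r, c, ac, hc = st["z"], st["r"], st["c"], st["ac"], st["hc"]
            dz = dh * (h_prev - c)
            dc = dh * (1.0 - z)
            dh_prev = dh * z
            dac = dc * dphi(ac, c)
            g["bc"] += dac.sum(axis=0)
            g["Wc"] += (x * mi["c"]).T @ dac
            g["Uc"] += (r * hc).T @ dac
            d_rhc = dac @ p["Uc"].T
            dr = d_rhc * hc
            dh_prev += d_rhc * r * mr["c"]
            dar = dr * r * (1.0 - r)
            g["br"] += dar.sum(axis=0)
            g["Wr"] += (x * mi["r"]).T @ dar
            g["Ur"] += (h_prev * mr["r"]).T @ dar
            dh_prev += (dar @ p["Ur"].T) * mr["r"]
            daz = dz * z * (1.0 - z)
            g["bz"] += daz.sum(axis=0)
            g["Wz"] += (x * mi["z"]).T @ daz
            g["Uz"] += (h_prev * mr["z"]).T @ daz
            dh_prev += (daz @ p["Uz"].T) * mr["z"]
            dh = dh_prev
        return g

    # -- training -----------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Inference (dropout off)."""
        y, _ = self.forward(X, masks=None)
        return y

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int,
        batch_size: int,
        learning_rate: float,
        rng: np.random.Generator,
    ) -> list[float]:
        """Adam / MAE training loop; returns the per-epoch mean training loss."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n = X.shape[0]
        mstate = {k: np.zeros_like(v) for k, v in self.params.items()}
        vstate = {k: np.zeros_like(v) for k, v in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-7
        step = 0
        history: list[float] = []
        for _ in range(int(epochs)):
            order = rng.permutation(n)
            losses = []
            for lo in range(0, n, batch_size):
                idx = order[lo : lo + batch_size]
                xb, yb = X[idx], y[idx]
                masks = self._draw_masks(len(idx), rng)
                pred, cache = self.forward(xb, masks)
                resid = pred - yb
                losses.append(float(np.abs(resid).mean()))
                dy = np.sign(resid) / len(idx)
                grads = self.backward(cache, dy)
                step += 1
                corr = math.sqrt(1.0 - b2**step) / (1.0 - b1**step)
                for name in PARAM_NAMES:
                    mstate[name] = b1 * mstate[name] + (1 - b1) * grads[name]
                    vstate[name] = b2 * vstate[name] + (1 - b2) * grads[name] ** 2
                    self.params[name] -= (
                        learning_rate * corr * mstate[name] / (np.sqrt(vstate[name]) + eps)
                    )
            history.append(float(np.mean(losses)) if losses else float("nan"))
        return history

    # -- persistence helpers -------------------------------------------------

    def n_params(self) -> int:
        return int(sum(v.size for v in self.params.values()))

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for name in PARAM_NAMES:
            w = np.asarray(weights[name], dtype=float)
            if w.shape != self.params[name].shape:
                raise ValueError(f"weight {name}: shape {w.shape} != {self.params[name].shape}")
            self.params[name] = w.copy()
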