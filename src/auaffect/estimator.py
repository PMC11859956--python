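"""GRU-based valence and arousal regressors.

Separate models are trained for the two affect dimensions; each maps a
5-frame x 17-AU intensity window to a real-valued rating.  The published
hyperparameters differ between the two targets and are the per-target
defaults of :class:`ModelConfig`; the recurrent width (not published) is a
package choice of 32 units in a single layer.

"activation none" for the arousal model is interpreted as an identity
candidate activation inside the GRU cell; the update/reset gates keep their
sigmoid activations.  Predictions are clipped to the output scale's bounds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace, asdict
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

from ._errors import ConfigError, DataFormatError, EmptyInputError, NotFittedError
from .aucore import (
    AUWindow,
    ContinuousSession,
    MODEL_AUS,
    RatedEpisode,
    Scale,
    convert_rating,
)
from .gru import GRURegressor, gru_param_count


class Target(Enum):
    VALENCE = "valence"
    AROUSAL = "arousal"


#: Published training hyperparameters, per target.
_TARGET_DEFAULTS = {
    Target.VALENCE: dict(
        activation="relu",
        dropout=0.530,
        recurrent_dropout=0.266,
        learning_rate=1.23e-5,
        batch_size=48,
    ),
    Target.AROUSAL: dict(
        activation="none",
        dropout=0.680,
        recurrent_dropout=0.301,
        learning_rate=1.01e-5,
        batch_size=32,
    ),
}


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one affect model.

    Use :meth:`for_target` to obtain the published per-target defaults;
    ``hidden_units`` (GRU width) defaults to 32, a package-level choice.
    """

    target: Target
    hidden_units: int = 32
    activation: str = "relu"
    dropout: float = 0.0
    recurrent_dropout: float = 0.0
    learning_rate: float = 1e-3
    batch_size: int = 32
    epochs: int = 100
    loss: str = "mean_absolute_error"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be a positive integer")
        if self.activation not in ("relu", "none", "tanh"):
            raise ConfigError(f"unknown activation {self.activation!r}")
        for name in ("dropout", "recurrent_dropout"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ConfigError(f"{name} must lie in [0, 1), got {v}")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be a positive integer")
        if self.epochs < 0:
            raise ConfigError("epochs must be >= 0")
        if self.loss != "mean_absolute_error":
            raise ConfigError("only mean_absolute_error loss is supported")

    @classmethod
    def for_target(cls, target: Target, **overrides) -> "ModelConfig":
        """Published defaults for the given target, with optional overrides."""
        kw = dict(_TARGET_DEFAULTS[target], target=target, epochs=100)
        kw.update(overrides)
        return cls(**kw)

    def replace(self, **changes) -> "ModelConfig":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["target"] = self.target.value
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        d["target"] = Target(d["target"])
        return cls(**d)


class AffectEstimator:
    """A (possibly trained) GRU regressor for one affect dimension."""

    def __init__(
        self,
        config: ModelConfig,
        output_scale: Scale = Scale.FIVE,
        n_features: int = len(MODEL_AUS),
    ) -> None:
        self.config = config
        self.output_scale = output_scale
        self.n_features = int(n_features)
        self.fitted = False
        rng = np.random.default_rng(config.seed)
        mid = 0.5 * (output_scale.lo + output_scale.hi)
        # Output bias starts at mid-scale so early training works on structure
        # rather than climbing toward the label mean.
        self._net = GRURegressor(
            n_features=self.n_features,
            hidden_units=config.hidden_units,
            activation=config.activation,
            dropout=config.dropout,
            recurrent_dropout=config.recurrent_dropout,
            output_bias_init=mid,
            rng=rng,
        )

    # -- low-level array interface ------------------------------------------

    def fit_arrays(self, X: np.ndarray, y: np.ndarray, seed: int | None = None) -> "AffectEstimator":
        """Train on raw arrays X (n, 5, n_features), y (n,).  Seeded, in place."""
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise DataFormatError(
                f"X must be (n, steps, {self.n_features}), got {X.shape}"
            )
        if X.shape[0] == 0:
            raise EmptyInputError("no training samples")
        rng = np.random.default_rng(self.config.seed if seed is None else seed)
        self.training_history = self._net.fit(
            X,
            y,
            epochs=self.config.epochs,
            batch_size=self.config.batch_size,
            learning_rate=self.config.learning_rate,
            rng=rng,
        )
        self.fitted = True
        return self

    def predict_arrays(self, X: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise NotFittedError("estimator must be trained before predicting")
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[2] != self.n_features:
            raise DataFormatError(f"X must be (n, steps, {self.n_features}), got {X.shape}")
        y = self._net.predict(X)
        return np.clip(y, self.output_scale.lo, self.output_scale.hi)

    def n_params(self) -> int:
        return self._net.n_params()

    def with_input_dropped(self, index: int) -> "AffectEstimator":
        """An unfitted copy with input column ``index`` genuinely removed.

        The copy re-creates this estimator's seeded initialization and then
        deletes the corresponding input-weight row of every gate, leaving all
        other parameters identical.  Paired retrains of the full and the
        narrowed model therefore share common random numbers (weight draws
        and shuffle order), so their error difference isolates the effect of
        the removed column; used by drop-column importance.
        """
        if not 0 <= index < self.n_features:
            raise ConfigError(f"input index {index} out of range")
        est = AffectEstimator(self.config, self.output_scale, self.n_features)
        for name in ("Wz", "Wr", "Wc"):
            est._net.params[name] = np.delete(est._net.params[name], index, axis=0)
        est._net.n_features -= 1
        est.n_features -= 1
        return est

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "output_scale": self.output_scale.name,
            "n_features": self.n_features,
            "fitted": self.fitted,
        }
        (d / "config.json").write_text(json.dumps(meta, indent=2))
        np.savez(d / "weights.npz", **self._net.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "AffectEstimator":
        d = Path(directory)
        meta = json.loads((d / "config.json").read_text())
        config = ModelConfig.from_dict(meta["config"])  # re-validates invariants
        est = cls(config, output_scale=Scale[meta["output_scale"]], n_features=meta["n_features"])
        with np.load(d / "weights.npz") as w:
            est._net.set_weights({k: w[k] for k in w.files})
        est.fitted = bool(meta["fitted"])
        return est


# ---------------------------------------------------------------------------
# Episode-level API
# ---------------------------------------------------------------------------

def build(config: ModelConfig, output_scale: Scale = Scale.FIVE, n_features: int = len(MODEL_AUS)) -> AffectEstimator:
    """Construct an unfitted estimator for the given configuration.

    The architecture is a single GRU layer of ``config.hidden_units`` over
    the 5 x n_features input sequence plus one linear output unit; its
    parameter count equals :func:`auaffect.gru.gru_param_count`.
    """
    return AffectEstimator(config, output_scale=output_scale, n_features=n_features)


def episodes_to_arrays(
    episodes: Sequence[RatedEpisode],
    target: Target,
    output_scale: Scale,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack episode windows and labels; labels are converted to output_scale."""
    if not episodes:
        raise EmptyInputError("empty episode list")
    scales = {e.valence.scale for e in episodes}
    if len(scales) != 1:
        raise DataFormatError("episodes mix rating scales")
    (scale,) = scales
    X = np.stack([e.window.matrix for e in episodes])
    labels = []
    for e in episodes:
        r = e.valence if target is Target.VALENCE else e.arousal
        if scale is not output_scale:
            if scale is Scale.FIVE and output_scale is Scale.NINE:
                r = convert_rating(r)
            else:
                raise DataFormatError(
                    f"cannot convert labels from {scale.name} to {output_scale.name}"
                )
        labels.append(r.value)
    return X, np.array(labels, dtype=float)


def train(
    est: AffectEstimator,
    episodes: Sequence[RatedEpisode],
    seed: int | None = None,
) -> AffectEstimator:
    """Train the estimator on rated episodes (labels chosen by config.target)."""
    X, y = episodes_to_arrays(episodes, est.config.target, est.output_scale)
    return est.fit_arrays(X, y, seed=seed)


def predict(est: AffectEstimator, window: AUWindow | np.ndarray) -> float:
    """Predict one rating from one window, clipped to the output scale."""
    matrix = window.matrix if isinstance(window, AUWindow) else np.asarray(window, dtype=float)
    if matrix.ndim != 2:
        raise DataFormatError(f"window must be 2-D, got shape {matrix.shape}")
    return float(est.predict_arrays(matrix[None, :, :])[0])


def predict_session(est: AffectEstimator, session: ContinuousSession) -> np.ndarray:
    """Per-second predictions: a pure map of ``predict`` over the windows."""
    if len(session) == 0:
        return np.empty(0)
    X = np.stack([w.matrix for w in session.windows])
    return est.predict_arrays(X)
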