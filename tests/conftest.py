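import numpy as np
import pytest

from auaffect.aucore import MODEL_AUS, AUFrame, AUWindow, RatedEpisode, Rating, Scale
from auaffect.estimator import ModelConfig, Target


def make_frame(timestamp: float, value: float = 0.5, **au_overrides) -> AUFrame:
    """An AUFrame with every model AU at `value`, overridable per AU (au12=...)."""
    intensities = {a: value for a in MODEL_AUS}
    for key, v in au_overrides.items():
        intensities[int(key.removeprefix("au"))] = v
    return AUFrame(timestamp=timestamp, intensities=intensities)


def make_window(rng: np.random.Generator | None = None, fill: float | None = None) -> AUWindow:
    if fill is not None:
        return AUWindow(matrix=np.full((5, len(MODEL_AUS)), fill))
    rng = rng or np.random.default_rng(0)
    return AUWindow(matrix=rng.uniform(0, 5, size=(5, len(MODEL_AUS))))


def make_episode(
    pid: str, valence: float, arousal: float, rng: np.random.Generator
) -> RatedEpisode:
    return RatedEpisode(
        participant_id=pid,
        window=make_window(rng),
        valence=Rating(valence, Scale.FIVE),
        arousal=Rating(arousal, Scale.FIVE),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture
def fast_config():
    """Small, quick-to-train configuration for pipeline tests."""

    def _make(target: Target = Target.VALENCE, **overrides) -> ModelConfig:
        kw = dict(
            hidden_units=16,
            epochs=20,
            learning_rate=1e-2,
            dropout=0.0,
            recurrent_dropout=0.0,
            seed=0,
        )
        kw.update(overrides)
        return ModelConfig.for_target(target, **kw)

    return _make
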