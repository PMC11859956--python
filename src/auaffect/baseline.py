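"""Category/AU-based dimensional baseline (FaceReader-style arithmetic).

Valence is derived from the intensities of the seven emotion categories:
the intensity of 'happy' minus the intensity of the strongest negative
category (sad, angry, scared, disgusted); surprised is treated as
valence-neutral.  Arousal is derived from 19 AU activation values (AUs 1-27
per the enumeration below, plus one minus the AU 43 activation): each value
is corrected by subtracting its rolling mean over the trailing 60 s (over
the whole history while less than 60 s has elapsed), and arousal is the mean
of the five highest corrected values.

Only the dimensional arithmetic is implemented here — the category and AU
classifiers that produce the inputs are outside this package's scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import DataFormatError, EmptyInputError

CATEGORIES = ("happy", "sad", "angry", "scared", "disgusted", "surprised", "neutral")
NEGATIVE_CATEGORIES = ("sad", "angry", "scared", "disgusted")

#: The 19 activation keys used for arousal: 18 AUs plus the inverse of AU 43.
BASELINE_AUS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 24, 25, 26, 27)
ACTIVATION_KEYS: tuple[str, ...] = tuple(f"AU{a:02d}" for a in BASELINE_AUS) + ("inv43",)

ROLLING_WINDOW_S = 60.0
TOP_K = 5


@dataclass(frozen=True)
class CategoryFrame:
    """Per-frame intensities of the six basic emotions plus neutral, in [0, 1]."""

    timestamp: float
    intensities: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.intensities)
        if missing:
            raise DataFormatError(f"missing emotion categories: {sorted(missing)}")
        for k in CATEGORIES:
            v = self.intensities[k]
            if not 0.0 <= v <= 1.0:
                raise DataFormatError(f"category {k!r} intensity {v} outside [0, 1]")


@dataclass(frozen=True)
class ActivationFrame:
    """Per-frame activation values of the 19 baseline AU keys, in [0, 1]."""

    timestamp: float
    activations: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(ACTIVATION_KEYS) - set(self.activations)
        if missing:
            raise DataFormatError(f"missing activation keys: {sorted(missing)}")
        for k in ACTIVATION_KEYS:
            v = self.activations[k]
            if not 0.0 <= v <= 1.0:
                raise DataFormatError(f"activation {k!r} value {v} outside [0, 1]")

    def vector(self) -> np.ndarray:
        return np.array([self.activations[k] for k in ACTIVATION_KEYS], dtype=float)


def baseline_valence(frame: CategoryFrame) -> float:
    """happy minus the strongest of {sad, angry, scared, disgusted}; in [-1, 1]."""
    i = frame.intensities
    return float(i["happy"] - max(i[k] for k in NEGATIVE_CATEGORIES))


def corrected_activations(
    series: Sequence[ActivationFrame], t: float
) -> dict[str, float]:
    """Current activations minus their rolling mean over the trailing 60 s.

    The mean is taken over frames with timestamp in the half-open window
    (t - 60, t]; while the analysis is under 60 s old this reduces to the
    mean over the whole history up to t.
    """
    past = [f for f in series if t - ROLLING_WINDOW_S < f.timestamp <= t]
    if not past:
        raise EmptyInputError(f"no activation frames at or before t={t} within the window")
    current = min(past, key=lambda f: abs(f.timestamp - t))
    mean = np.mean([f.vector() for f in past], axis=0)
    corr = current.vector() - mean
    return dict(zip(ACTIVATION_KEYS, corr.tolist()))


def baseline_arousal(series: Sequence[ActivationFrame], t: float) -> float:
    """Mean of the five highest corrected activation values at time t."""
    corr = np.array(list(corrected_activations(series, t).values()))
    top = np.sort(corr)[-TOP_K:]
    return float(top.mean())


def score_series(
    category_frames: Sequence[CategoryFrame],
    activation_frames: Sequence[ActivationFrame],
) -> pd.DataFrame:
    """Per-timestamp baseline valence and arousal for aligned input series."""
    if len(category_frames) != len(activation_frames):
        raise DataFormatError("category and activation series must be aligned")
    rows = []
    for cf, af in zip(category_frames, activation_frames):
        rows.append(
            {
                "timestamp": cf.timestamp,
                "valence": baseline_valence(cf),
                "arousal": baseline_arousal(activation_frames, af.timestamp),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_category_table(path: str | Path) -> list[CategoryFrame]:
    df = pd.read_csv(path, skipinitialspace=True)
    for col in ("timestamp",) + CATEGORIES:
        if col not in df.columns:
            raise DataFormatError(f"category table {path} missing column {col!r}")
    return [
        CategoryFrame(
            timestamp=float(row.timestamp),
            intensities={k: float(getattr(row, k)) for k in CATEGORIES},
        )
        for row in df.itertuples(index=False)
    ]


def read_activation_table(path: str | Path) -> list[ActivationFrame]:
    df = pd.read_csv(path, skipinitialspace=True)
    for col in ("timestamp",) + ACTIVATION_KEYS:
        if col not in df.columns:
            raise DataFormatError(f"activation table {path} missing column {col!r}")
    return [
        ActivationFrame(
            timestamp=float(row.timestamp),
            activations={k: float(getattr(row, k)) for k in ACTIVATION_KEYS},
        )
        for row in df.itertuples(index=False)
    ]


def write_category_table(frames: Sequence[CategoryFrame], path: str | Path) -> None:
    pd.DataFrame(
        [{"timestamp": f.timestamp, **{k: f.intensities[k] for k in CATEGORIES}} for f in frames]
    ).to_csv(path, index=False)


def write_activation_table(frames: Sequence[ActivationFrame], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"timestamp": f.timestamp, **{k: f.activations[k] for k in ACTIVATION_KEYS}}
            for f in frames
        ]
    ).to_csv(path, index=False)
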