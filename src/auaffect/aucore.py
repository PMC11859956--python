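"""Domain types, AU table I/O, 1-second windowing and rating-scale conversion.

The estimation pipeline works on facial action-unit (AU) intensity time
series as produced by OpenFace 2.x: one row per video frame with the AU
intensity columns ``AUxx_r`` on a 0-5 scale, a tracking ``success`` flag and
a tracking ``confidence``.  Seventeen AUs enter the model; the model input
unit is a 5-frame x 17-AU matrix covering one second of video (five frames
sampled at equal intervals).

Two rating scales coexist: per-episode ordinal ratings on 1-5 and per-second
real-valued ratings on 1-9.  ``convert_rating`` maps the former onto the
latter with the affine rule I' = 2I - 1, which fixes both endpoints
(1 -> 1, 5 -> 9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import (
    DataFormatError,
    DomainError,
    EmptyInputError,
    InsufficientCoverageError,
)

#: The 17 action units used by the estimation model, ascending FACS id.
MODEL_AUS: tuple[int, ...] = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 45)

#: OpenFace intensity column names for the model AUs, in model column order.
AU_COLUMNS: tuple[str, ...] = tuple(f"AU{a:02d}_r" for a in MODEL_AUS)

#: Number of frames sampled per 1-second window.
FRAMES_PER_WINDOW = 5

#: Offsets (seconds) of the sampled frames within a window: equal intervals
#: over [0, 1] with inclusive endpoints.
WINDOW_OFFSETS: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0)

_REQUIRED_META = ("frame", "timestamp", "confidence", "success")


class Scale(Enum):
    """Rating scale: FIVE is the ordinal 1-5 scale, NINE the real 1-9 scale."""

    FIVE = (1.0, 5.0)
    NINE = (1.0, 9.0)

    @property
    def lo(self) -> float:
        return self.value[0]

    @property
    def hi(self) -> float:
        return self.value[1]


@dataclass(frozen=True)
class Rating:
    """A valence or arousal rating on a declared scale."""

    value: float
    scale: Scale

    def __post_init__(self) -> None:
        if not (self.scale.lo <= self.value <= self.scale.hi):
            raise DomainError(
                f"rating {self.value} outside scale bounds "
                f"[{self.scale.lo}, {self.scale.hi}]"
            )


@dataclass(frozen=True)
class AUFrame:
    """One timestamped vector of AU intensities for a single tracked face."""

    timestamp: float
    intensities: Mapping[int, float]
    confidence: float = 1.0
    success: bool = True

    def __post_init__(self) -> None:
        if set(self.intensities) != set(MODEL_AUS):
            missing = set(MODEL_AUS) - set(self.intensities)
            extra = set(self.intensities) - set(MODEL_AUS)
            raise DataFormatError(
                f"AUFrame must carry exactly the 17 model AUs; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )
        for au, v in self.intensities.items():
            if not math.isfinite(v) or v < 0:
                raise DataFormatError(f"AU{au:02d} intensity {v!r} is not finite and >= 0")

    def vector(self) -> np.ndarray:
        """Intensities as a length-17 array in ascending AU-id order."""
        return np.array([self.intensities[a] for a in MODEL_AUS], dtype=float)


@dataclass(frozen=True)
class AUWindow:
    """A 5-frame x 17-AU matrix covering one second; the model's input unit."""

    matrix: np.ndarray
    start_time: float = 0.0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (FRAMES_PER_WINDOW, len(MODEL_AUS)):
            raise DataFormatError(
                f"window matrix must be {FRAMES_PER_WINDOW}x{len(MODEL_AUS)}, got {m.shape}"
            )
        if not np.all(np.isfinite(m)):
            raise DataFormatError("window matrix contains non-finite entries")
        object.__setattr__(self, "matrix", m)


@dataclass(frozen=True)
class RatedEpisode:
    """One peak-second AU window paired with its episode-level ratings."""

    participant_id: str
    window: AUWindow
    valence: Rating
    arousal: Rating

    def __post_init__(self) -> None:
        if self.valence.scale is not self.arousal.scale:
            raise DataFormatError("valence and arousal must share one rating scale")


@dataclass(frozen=True)
class ContinuousSession:
    """Per-second AU windows with per-second valence/arousal ratings (1-9)."""

    participant_id: str
    windows: Sequence[AUWindow]
    valence_series: Sequence[Rating]
    arousal_series: Sequence[Rating]

    def __post_init__(self) -> None:
        n = len(self.windows)
        if len(self.valence_series) != n or len(self.arousal_series) != n:
            raise DataFormatError(
                "windows, valence_series and arousal_series must have equal length"
            )

    def __len__(self) -> int:
        return len(self.windows)


# ---------------------------------------------------------------------------
# AU table I/O (OpenFace 2.x CSV dialect)
# ---------------------------------------------------------------------------

def read_au_table(
    path: str | Path,
    min_confidence: float = 0.0,
    require_success: bool = True,
) -> list[AUFrame]:
    """Read an OpenFace-dialect AU intensity CSV into timestamp-ordered frames.

    Rows with ``success == 0`` (when ``require_success``) or with confidence
    below ``min_confidence`` are dropped.  Only the 17 model AU columns are
    retained; extra columns are ignored and whitespace after commas is
    tolerated.

    Raises
    ------
    DataFormatError
        If a required column is absent (the message names it).
    EmptyInputError
        If no rows survive the filter.
    """
    df = pd.read_csv(path, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in _REQUIRED_META + AU_COLUMNS:
        if col not in df.columns:
            raise DataFormatError(f"AU table {path} is missing required column {col!r}")
    if require_success:
        df = df[df["success"].astype(int) != 0]
    if min_confidence > 0.0:
        df = df[df["confidence"].astype(float) >= min_confidence]
    if df.empty:
        raise EmptyInputError(f"AU table {path}: no rows left after filtering")
    df = df.sort_values("timestamp", kind="stable")
    frames = [
        AUFrame(
            timestamp=float(row.timestamp),
            intensities={a: float(getattr(row, c)) for a, c in zip(MODEL_AUS, AU_COLUMNS)},
            confidence=float(row.confidence),
            success=bool(int(row.success)),
        )
        for row in df.itertuples(index=False)
    ]
    return frames


def write_au_table(frames: Iterable[AUFrame], path: str | Path) -> None:
    """Write frames as an OpenFace-dialect CSV (consumed by ``read_au_table``)."""
    rows = []
    for i, f in enumerate(frames):
        row: dict[str, float] = {
            "frame": i + 1,
            "timestamp": f.timestamp,
            "confidence": f.confidence,
            "success": int(f.success),
        }
        row.update({c: f.intensities[a] for a, c in zip(MODEL_AUS, AU_COLUMNS)})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Windowing
# ---------------------------------------------------------------------------

def extract_window(frames: Sequence[AUFrame], start_time: float) -> AUWindow:
    """Sample a 5x17 window from ``frames`` covering [start_time, start_time+1].

    The five rows are the frames nearest in time to start_time + {0, .25, .5,
    .75, 1.0} s (no interpolation: rows are authentic observed frames; ties
    go to the earlier frame).  A target whose nearest frame is farther away
    than one typical inter-frame interval indicates a coverage gap.
    """
    if not frames:
        raise EmptyInputError("no frames given")
    ts = np.array([f.timestamp for f in frames], dtype=float)
    if len(ts) < 2:
        raise InsufficientCoverageError("need more than one frame to cover 1 s")
    # Typical spacing; tolerate jitter by allowing one full interval of slack.
    spacing = float(np.median(np.diff(np.sort(ts))))
    max_gap = max(spacing, 1e-9)
    rows = []
    for off in WINDOW_OFFSETS:
        target = start_time + off
        d = np.abs(ts - target)
        idx = int(np.argmin(d))  # argmin takes the first minimum: earlier frame wins ties
        if d[idx] > max_gap + 1e-12:
            raise InsufficientCoverageError(
                f"no frame within {max_gap:.4f} s of target t={target:.4f} s"
            )
        rows.append(frames[idx].vector())
    return AUWindow(matrix=np.vstack(rows), start_time=float(start_time))


def select_peak_segment(frames: Sequence[AUFrame]) -> float:
    """Start time of the 1-s segment where expression is most prominent.

    The criterion is the mean over in-window frames of the total (summed over
    the 17 AUs) intensity; candidate starts are the frame timestamps whose
    window [t, t+1] fits inside the series.  Ties break to the earliest start.
    """
    if not frames:
        raise EmptyInputError("no frames given")
    ts = np.array([f.timestamp for f in frames], dtype=float)
    totals = np.array([float(sum(f.intensities.values())) for f in frames])
    if ts[-1] - ts[0] < 1.0:
        raise InsufficientCoverageError(
            f"series spans {ts[-1] - ts[0]:.3f} s; need at least 1 s"
        )
    best_start, best_score = None, -np.inf
    for t0 in ts:
        if t0 + 1.0 > ts[-1] + 1e-12:
            break
        mask = (ts >= t0 - 1e-12) & (ts <= t0 + 1.0 + 1e-12)
        score = float(totals[mask].mean())
        if score > best_score + 1e-12:
            best_score, best_start = score, float(t0)
    assert best_start is not None
    return best_start


def frames_to_rated_episode(
    frames: Sequence[AUFrame],
    participant_id: str,
    valence: Rating,
    arousal: Rating,
) -> RatedEpisode:
    """Pick the peak 1-s segment of an episode and window it."""
    start = select_peak_segment(frames)
    return RatedEpisode(
        participant_id=participant_id,
        window=extract_window(frames, start),
        valence=valence,
        arousal=arousal,
    )


# ---------------------------------------------------------------------------
# Rating-scale conversion
# ---------------------------------------------------------------------------

def convert_rating(r: Rating) -> Rating:
    """Map a 1-5 rating I onto the 1-9 scale with I' = 2I - 1."""
    if r.scale is not Scale.FIVE:
        raise DomainError("convert_rating expects a rating on the 1-5 scale")
    return Rating(value=2.0 * r.value - 1.0, scale=Scale.NINE)


def invert_rating(r: Rating) -> Rating:
    """Inverse of :func:`convert_rating`: I = (I' + 1) / 2."""
    if r.scale is not Scale.NINE:
        raise DomainError("invert_rating expects a rating on the 1-9 scale")
    return Rating(value=(r.value + 1.0) / 2.0, scale=Scale.FIVE)
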