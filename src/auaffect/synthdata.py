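"""Seeded synthetic AU/affect data with known ground truth.

Real rated facial-expression corpora in this domain are request-only, so
every other module is exercised against generated data whose AU -> affect
mapping is planted and therefore recoverable:

* ``generate_riken_like`` emulates a rated-episode corpus: per participant,
  25 four-second episodes covering every combination of five valence and
  five arousal levels (1-5), each with a 1-s onset ramp, 2-s hold and 1-s
  offset.  AU trajectories follow

      AU(t) = baseline + ramp(t) * (effect_matrix . affect_deviation
                                    + participant_effect) + noise

  with affect_deviation = (valence - 3, arousal - 3) and intensities
  truncated at 0 (the OpenFace _r scale is non-negative).

* ``generate_session_like`` emulates a continuously rated session: smooth
  latent valence/arousal trajectories on the 1-9 scale (low-frequency
  sinusoids with seeded random phases, held constant within each second),
  the same linear AU emission, per-second windows and noisy ratings.

* ``generate_category_series`` builds emotion-category and AU-activation
  series (with optional step events) for the dimensional baseline.

The default effect matrix loads valence mainly on AUs 12, 6, 4 and 1 and
arousal on AUs 4, 6, 17 and 7, echoing which AUs are known to matter for
each dimension, so importance analyses on synthetic data should single out
these AUs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataFormatError
from .aucore import (
    AUFrame,
    ContinuousSession,
    MODEL_AUS,
    RatedEpisode,
    Rating,
    Scale,
    extract_window,
    frames_to_rated_episode,
    write_au_table,
)
from .baseline import (
    ACTIVATION_KEYS,
    ActivationFrame,
    CATEGORIES,
    CategoryFrame,
)

#: (valence coefficient, arousal coefficient) per AU; unlisted AUs are inert.
DEFAULT_EFFECTS: dict[int, tuple[float, float]] = {
    12: (0.4, 0.0),   # lip corner puller: smiling, positive valence
    6: (0.4, 0.4),    # cheek raiser: Duchenne smiles and facial tension
    4: (-0.4, 0.4),   # brow lowerer: negative valence, high arousal
    1: (0.4, 0.0),    # inner brow raiser
    17: (0.0, 0.4),   # chin raiser
    7: (0.0, 0.4),    # lid tightener
}

DEFAULT_BASELINE = 1.0  # neutral-face intensity on the 0-5 _r scale

RIKEN_LEVELS = (1, 2, 3, 4, 5)
EPISODE_DURATION_S = 4.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of the synthetic study."""

    n_participants: int = 24
    effect_matrix: Mapping[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    baseline_au: Mapping[int, float] = field(
        default_factory=lambda: {a: DEFAULT_BASELINE for a in MODEL_AUS}
    )
    noise_sd: float = 0.3
    participant_sd: float = 0.2
    rating_noise_sd: float = 0.25
    frame_rate: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        for name in ("noise_sd", "participant_sd", "rating_noise_sd"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ConfigError(f"{name} must be finite and >= 0")
        bad = set(self.effect_matrix) - set(MODEL_AUS)
        if bad:
            raise ConfigError(f"effect_matrix refers to non-model AUs {sorted(bad)}")
        coefs = np.array(list(self.effect_matrix.values()), dtype=float).reshape(-1, 2)
        if coefs.size == 0 or not (np.any(coefs[:, 0]) and np.any(coefs[:, 1])):
            raise ConfigError("effect_matrix needs a nonzero coefficient per target")

    def coefficient_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(valence, arousal) coefficient vectors over the 17 AUs, model order."""
        cv = np.array([self.effect_matrix.get(a, (0.0, 0.0))[0] for a in MODEL_AUS])
        ca = np.array([self.effect_matrix.get(a, (0.0, 0.0))[1] for a in MODEL_AUS])
        return cv, ca

    def baseline_vector(self) -> np.ndarray:
        return np.array([self.baseline_au.get(a, DEFAULT_BASELINE) for a in MODEL_AUS])


@dataclass(frozen=True)
class EpisodeFrames:
    """A full 4-s episode trajectory with its episode-level ratings."""

    participant_id: str
    episode_id: str
    valence: Rating
    arousal: Rating
    frames: Sequence[AUFrame]


def ramp(t: float) -> float:
    """Onset/hold/offset envelope: 0->1 over [0,1], 1 over [1,3], 1->0 over [3,4]."""
    if t <= 0 or t >= EPISODE_DURATION_S:
        return 0.0
    if t < 1.0:
        return t
    if t <= 3.0:
        return 1.0
    return EPISODE_DURATION_S - t


def _frames_from_matrix(times: np.ndarray, mat: np.ndarray) -> list[AUFrame]:
    return [
        AUFrame(
            timestamp=float(t),
            intensities=dict(zip(MODEL_AUS, row.tolist())),
        )
        for t, row in zip(times, mat)
    ]


def generate_riken_like(spec: GeneratorSpec) -> dict[str, list[EpisodeFrames]]:
    """Rated episodes grouped by participant: 25 per participant, 5x5 grid."""
    rng = np.random.default_rng(spec.seed)
    cv, ca = spec.coefficient_vectors()
    base = spec.baseline_vector()
    n_frames = int(EPISODE_DURATION_S * spec.frame_rate) + 1
    times = np.arange(n_frames) / spec.frame_rate
    ramps = np.array([ramp(t) for t in times])
    out: dict[str, list[EpisodeFrames]] = {}
    for p in range(spec.n_participants):
        pid = f"P{p:02d}"
        participant_effect = rng.normal(0.0, spec.participant_sd, size=len(MODEL_AUS))
        episodes: list[EpisodeFrames] = []
        for v in RIKEN_LEVELS:
            for a in RIKEN_LEVELS:
                dev = cv * (v - 3.0) + ca * (a - 3.0)
                signal = base + ramps[:, None] * (dev + participant_effect)[None, :]
                noise = rng.normal(0.0, spec.noise_sd, size=signal.shape)
                mat = np.maximum(signal + noise, 0.0)
                episodes.append(
                    EpisodeFrames(
                        participant_id=pid,
                        episode_id=f"v{v}a{a}",
                        valence=Rating(float(v), Scale.FIVE),
                        arousal=Rating(float(a), Scale.FIVE),
                        frames=_frames_from_matrix(times, mat),
                    )
                )
        out[pid] = episodes
    return out


def to_rated_episodes(
    episodes_by_participant: Mapping[str, Sequence[EpisodeFrames]],
) -> dict[str, list[RatedEpisode]]:
    """Window each raw episode at its peak 1-s segment."""
    return {
        pid: [
            frames_to_rated_episode(e.frames, e.participant_id, e.valence, e.arousal)
            for e in eps
        ]
        for pid, eps in episodes_by_participant.items()
    }


def generate_session_like(
    spec: GeneratorSpec, duration: float, participant_id: str = "S00"
) -> tuple[ContinuousSession, np.ndarray, np.ndarray]:
    """A continuously rated session plus its latent per-second trajectories.

    Returns (session, latent_valence, latent_arousal); stored ratings equal
    the latent values plus seeded Gaussian rating noise, clipped to [1, 9].
    """
    n_seconds = int(duration)
    if n_seconds < 3:
        raise ConfigError("duration must be at least 3 s")
    rng = np.random.default_rng(spec.seed)
    secs = np.arange(n_seconds) + 0.5

    def latent() -> np.ndarray:
        f = rng.uniform(0.004, 0.03, size=2)
        phase = rng.uniform(0.0, 2.0 * np.pi, size=2)
        tr = 5.0 + 2.2 * np.sin(2 * np.pi * f[0] * secs + phase[0]) + 1.2 * np.sin(
            2 * np.pi * f[1] * secs + phase[1]
        )
        return np.clip(tr, 1.0, 9.0)

    lat_v, lat_a = latent(), latent()
    cv, ca = spec.coefficient_vectors()
    base = spec.baseline_vector()
    fr = spec.frame_rate
    n_frames = int(n_seconds * fr) + 1
    times = np.arange(n_frames) / fr
    sec_idx = np.minimum(times.astype(int), n_seconds - 1)
    # Deviations on the 1-5 scale equivalent: (x - 5) / 2 spans the same +/-2.
    dev = (
        cv[None, :] * ((lat_v[sec_idx] - 5.0) / 2.0)[:, None]
        + ca[None, :] * ((lat_a[sec_idx] - 5.0) / 2.0)[:, None]
    )
    mat = np.maximum(base[None, :] + dev + rng.normal(0.0, spec.noise_sd, dev.shape), 0.0)
    frames = _frames_from_matrix(times, mat)
    windows = [extract_window(frames, float(i)) for i in range(n_seconds)]
    v_noise = rng.normal(0.0, spec.rating_noise_sd, n_seconds)
    a_noise = rng.normal(0.0, spec.rating_noise_sd, n_seconds)
    v_ratings = [
        Rating(float(np.clip(x, 1.0, 9.0)), Scale.NINE) for x in lat_v + v_noise
    ]
    a_ratings = [
        Rating(float(np.clip(x, 1.0, 9.0)), Scale.NINE) for x in lat_a + a_noise
    ]
    session = ContinuousSession(
        participant_id=participant_id,
        windows=windows,
        valence_series=v_ratings,
        arousal_series=a_ratings,
    )
    return session, lat_v, lat_a


def generate_category_series(
    spec: GeneratorSpec,
    duration: float,
    frame_rate: float = 5.0,
    constant: float | None = None,
    steps: Sequence[tuple[float, str, float]] = (),
) -> tuple[list[CategoryFrame], list[ActivationFrame]]:
    """Seeded category/activation series for the dimensional baseline.

    ``constant`` freezes every value at the given level; ``steps`` is a list
    of (time, key, delta) events added to all frames with timestamp >= time
    (keys from the category names or activation keys).  Values stay in [0, 1].
    """
    rng = np.random.default_rng(spec.seed)
    n = int(duration * frame_rate)
    times = np.arange(n) / frame_rate

    def series(keys: Sequence[str]) -> dict[str, np.ndarray]:
        out = {}
        for k in keys:
            if constant is not None:
                vals = np.full(n, float(constant))
            else:
                level = rng.uniform(0.05, 0.35)
                amp = rng.uniform(0.0, 0.15)
                f = rng.uniform(0.005, 0.05)
                phase = rng.uniform(0, 2 * np.pi)
                vals = level + amp * np.sin(2 * np.pi * f * times + phase)
            for t0, key, delta in steps:
                if key == k:
                    vals = vals + delta * (times >= t0)
            out[k] = np.clip(vals, 0.0, 1.0)
        return out

    cat = series(CATEGORIES)
    act = series(ACTIVATION_KEYS)
    cat_frames = [
        CategoryFrame(timestamp=float(t), intensities={k: float(cat[k][i]) for k in CATEGORIES})
        for i, t in enumerate(times)
    ]
    act_frames = [
        ActivationFrame(
            timestamp=float(t), activations={k: float(act[k][i]) for k in ACTIVATION_KEYS}
        )
        for i, t in enumerate(times)
    ]
    return cat_frames, act_frames


# ---------------------------------------------------------------------------
# Dataset I/O (OpenFace-dialect AU CSVs + ratings CSV)
# ---------------------------------------------------------------------------

def write_dataset(
    episodes_by_participant: Mapping[str, Sequence[EpisodeFrames]], out_dir: str | Path
) -> None:
    """One AU CSV per episode under ``au/`` plus a ``ratings.csv`` index."""
    d = Path(out_dir)
    (d / "au").mkdir(parents=True, exist_ok=True)
    rows = []
    for pid in sorted(episodes_by_participant):
        for e in episodes_by_participant[pid]:
            write_au_table(e.frames, d / "au" / f"{pid}_{e.episode_id}.csv")
            rows.append(
                {
                    "participant_id": pid,
                    "episode_id": e.episode_id,
                    "valence": e.valence.value,
                    "arousal": e.arousal.value,
                    "scale": e.valence.scale.name,
                }
            )
    pd.DataFrame(rows).to_csv(d / "ratings.csv", index=False)


def read_dataset(in_dir: str | Path) -> dict[str, list[EpisodeFrames]]:
    """Inverse of :func:`write_dataset`."""
    from .aucore import read_au_table

    d = Path(in_dir)
    ratings_path = d / "ratings.csv"
    if not ratings_path.exists():
        raise DataFormatError(f"no ratings.csv under {d}")
    df = pd.read_csv(ratings_path)
    for col in ("participant_id", "episode_id", "valence", "arousal", "scale"):
        if col not in df.columns:
            raise DataFormatError(f"ratings table missing column {col!r}")
    out: dict[str, list[EpisodeFrames]] = {}
    for row in df.itertuples(index=False):
        scale = Scale[str(row.scale)]
        frames = read_au_table(d / "au" / f"{row.participant_id}_{row.episode_id}.csv")
        out.setdefault(str(row.participant_id), []).append(
            EpisodeFrames(
                participant_id=str(row.participant_id),
                episode_id=str(row.episode_id),
                valence=Rating(float(row.valence), scale),
                arousal=Rating(float(row.arousal), scale),
                frames=frames,
            )
        )
    return out
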