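"""Leave-one-out cross-validation and correlation-based group inference.

Per participant, agreement between actual and estimated ratings is measured
with Pearson's r.  Group-level inference Fisher-transforms the
per-participant coefficients (z = atanh r, variance-stabilizing) and applies
a one-sample t-test against zero; paired comparisons between two methods use
a paired t-test on the z values.  LOOCV holds out one participant per fold
and retrains both affect models on the remaining participants.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, DataFormatError, DegenerateSampleError, DomainError
from .aucore import RatedEpisode, Scale
from .estimator import ModelConfig, Target, build, episodes_to_arrays

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ParticipantResult:
    participant_id: str
    r_valence: float
    r_arousal: float
    n_pairs: int


@dataclass(frozen=True)
class GroupInference:
    """One-sample t-test on Fisher-z coefficients: t = mean/(sd/sqrt(n))."""

    mean_r: float
    mean_z: float
    t_stat: float
    df: int
    p_two_sided: float
    cohens_d: float


def pearson_r(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Pearson product-moment correlation between two equal-length series."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise DataFormatError("series must be 1-D and of equal length")
    if len(a) < 3:
        raise DegenerateSampleError("need at least 3 pairs for a correlation")
    da, dp = a - a.mean(), p - p.mean()
    sa, sp = float(np.sqrt((da * da).sum())), float(np.sqrt((dp * dp).sum()))
    if sa == 0.0 or sp == 0.0:
        raise DegenerateSampleError("correlation undefined: a series has zero variance")
    return float((da * dp).sum() / (sa * sp))


def fisher_z(r: float) -> float:
    """Fisher transformation z = atanh(r); requires |r| < 1."""
    if not -1.0 < r < 1.0:
        raise DomainError(f"fisher_z requires |r| < 1, got {r}")
    return math.atanh(r)


def one_sample_t(zs: Sequence[float]) -> GroupInference:
    """One-sample t-test of the z values against zero (two-sided p)."""
    z = np.asarray(zs, dtype=float)
    if len(z) < 2:
        raise DegenerateSampleError("need at least 2 values for a t-test")
    sd = float(z.std(ddof=1))
    if sd == 0.0:
        raise DegenerateSampleError("t undefined: sample standard deviation is zero")
    mean = float(z.mean())
    n = len(z)
    t = mean / (sd / math.sqrt(n))
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return GroupInference(
        mean_r=float(np.tanh(mean)),
        mean_z=mean,
        t_stat=t,
        df=df,
        p_two_sided=p,
        cohens_d=mean / sd,
    )


def paired_t(zs_a: Sequence[float], zs_b: Sequence[float]) -> GroupInference:
    """Paired t-test: one-sample test on the element-wise differences a - b."""
    a = np.asarray(zs_a, dtype=float)
    b = np.asarray(zs_b, dtype=float)
    if a.shape != b.shape:
        raise DataFormatError("paired samples must have equal length")
    return one_sample_t(a - b)


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

def _default_configs(
    configs: Mapping[Target, ModelConfig] | None,
) -> dict[Target, ModelConfig]:
    if configs is None:
        return {t: ModelConfig.for_target(t) for t in Target}
    out = dict(configs)
    for t in Target:
        if t not in out:
            raise ConfigError(f"missing configuration for target {t.value}")
        if out[t].target is not t:
            raise ConfigError(f"configuration for {t.value} has target {out[t].target.value}")
    return out


def loocv_folds(participant_ids: Sequence[str]) -> list[tuple[int, str, list[str]]]:
    """Fold plan: (fold index, held-out participant, training participants)."""
    pids = sorted(participant_ids)
    return [(i, pid, [q for q in pids if q != pid]) for i, pid in enumerate(pids)]


def loocv(
    episodes_by_participant: Mapping[str, Sequence[RatedEpisode]],
    configs: Mapping[Target, ModelConfig] | None = None,
    seed: int = 0,
    output_scale: Scale = Scale.FIVE,
) -> tuple[list[ParticipantResult], dict[Target, GroupInference]]:
    """Leave-one-participant-out evaluation of both affect models.

    Each fold trains fresh valence and arousal estimators (seed = ``seed`` +
    fold index, so folds are independent yet reproducible) on every other
    participant and predicts the held-out participant's episodes.
    Participants whose actual ratings have zero variance for a target are
    excluded from that target's inference with a warning.
    """
    cfgs = _default_configs(configs)
    pids = sorted(episodes_by_participant)
    if len(pids) < 3:
        raise DataFormatError("LOOCV needs at least 3 participants")
    for pid in pids:
        if len(episodes_by_participant[pid]) < 3:
            raise DataFormatError(f"participant {pid} has fewer than 3 episodes")

    results: list[ParticipantResult] = []
    zs: dict[Target, list[float]] = {t: [] for t in Target}
    for fold, pid, train_pids in loocv_folds(pids):
        train_eps = [e for q in train_pids for e in episodes_by_participant[q]]
        test_eps = list(episodes_by_participant[pid])
        rs: dict[Target, float] = {}
        for target in Target:
            cfg = cfgs[target].replace(seed=seed + fold)
            est = build(cfg, output_scale=output_scale)
            Xtr, ytr = episodes_to_arrays(train_eps, target, output_scale)
            est.fit_arrays(Xtr, ytr, seed=seed + fold)
            Xte, yte = episodes_to_arrays(test_eps, target, output_scale)
            pred = est.predict_arrays(Xte)
            try:
                rs[target] = pearson_r(yte, pred)
                zs[target].append(fisher_z(rs[target]))
            except DegenerateSampleError:
                logger.warning(
                    "participant %s: degenerate %s ratings or predictions; "
                    "excluded from inference",
                    pid,
                    target.value,
                )
                rs[target] = float("nan")
        results.append(
            ParticipantResult(
                participant_id=pid,
                r_valence=rs[Target.VALENCE],
                r_arousal=rs[Target.AROUSAL],
                n_pairs=len(test_eps),
            )
        )
    inference = {t: one_sample_t(zs[t]) for t in Target}
    return results, inference


def session_correlations(
    actual: Sequence[float], predicted: Sequence[float]
) -> float:
    """Alias of :func:`pearson_r` for per-second session series."""
    return pearson_r(actual, predicted)


# ---------------------------------------------------------------------------
# Report I/O
# ---------------------------------------------------------------------------

def results_frame(results: Sequence[ParticipantResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "r_valence": r.r_valence,
                "r_arousal": r.r_arousal,
                "n_pairs": r.n_pairs,
            }
            for r in results
        ]
    )


def inference_dict(inference: Mapping[Target, GroupInference]) -> dict:
    return {
        t.value: {
            "mean_r": gi.mean_r,
            "mean_z": gi.mean_z,
            "t_stat": gi.t_stat,
            "df": gi.df,
            "p_two_sided": gi.p_two_sided,
            "cohens_d": gi.cohens_d,
        }
        for t, gi in inference.items()
    }


def write_report(
    results: Sequence[ParticipantResult],
    inference: Mapping[Target, GroupInference],
    out_dir: str | Path,
) -> None:
    """Write per-participant CSV and group-inference JSON under ``out_dir``."""
    import json

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    results_frame(results).to_csv(d / "participants.csv", index=False)
    (d / "inference.json").write_text(json.dumps(inference_dict(inference), indent=2))


def write_predictions(
    rows: Sequence[tuple[str, str, float, float, str]], path: str | Path
) -> None:
    """Dump predictions: columns participant_id, unit_id, actual, predicted, target."""
    pd.DataFrame(
        rows, columns=["participant_id", "unit_id", "actual", "predicted", "target"]
    ).to_csv(path, index=False)
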