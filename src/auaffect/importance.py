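"""Drop-column feature importance with relative-error normalization.

For each of the 17 AUs the model is retrained from scratch on the remaining
16 input columns (true removal — the input is narrower, not zero-masked) and
the mean absolute prediction error is recomputed under the same protocol.
The relative importance of AU a is

    (error_without_a - baseline_error) / baseline_error

so a positive value means removal hurts (the AU carries signal) and a
negative value means removal helps (the AU behaves as noise).  Normalizing
by the baseline error removes the influence of the error's magnitude.

Each narrowed model shares the seeded initialization of the full model with
one input-weight row deleted (common random numbers), so the paired error
difference reflects the removed column rather than retraining noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigError, DataFormatError, DegenerateSampleError
from .aucore import MODEL_AUS, RatedEpisode, Scale
from .estimator import AffectEstimator, ModelConfig, Target, build, episodes_to_arrays


@dataclass(frozen=True)
class ImportanceReport:
    target: Target
    baseline_error: float
    per_au: Mapping[int, float]
    protocol: str = "holdout"

    def __post_init__(self) -> None:
        if set(self.per_au) != set(MODEL_AUS):
            raise DataFormatError("per_au must cover exactly the 17 model AUs")


def _holdout_split(pids: Sequence[str], test_fraction: float) -> tuple[list[str], list[str]]:
    """Deterministic participant-level split: every k-th participant held out."""
    k = max(2, round(1.0 / test_fraction))
    test = [p for i, p in enumerate(pids) if i % k == 0]
    train = [p for p in pids if p not in test]
    return train, test


def _build_for_columns(
    config: ModelConfig,
    output_scale: Scale,
    n_features: int,
    drop_index: int | None,
    seed: int,
) -> AffectEstimator:
    """Full-width estimator, or its common-random-numbers narrowed copy."""
    est = build(config.replace(seed=seed), output_scale=output_scale, n_features=n_features)
    if drop_index is not None:
        est = est.with_input_dropped(drop_index)
    return est


def drop_column_importance(
    episodes_by_participant: Mapping[str, Sequence[RatedEpisode]],
    config: ModelConfig,
    target: Target | None = None,
    seed: int = 0,
    protocol: str = "holdout",
    test_fraction: float = 0.25,
    output_scale: Scale = Scale.FIVE,
) -> ImportanceReport:
    """Relative drop-column importance of each of the 17 AUs.

    ``protocol="holdout"`` evaluates errors on a deterministic
    participant-level holdout split (fast default); ``protocol="loocv"``
    pools absolute errors over leave-one-participant-out folds (18x the
    training cost).  The same seed policy is applied to the full model and
    every column-dropped retrain so differences reflect the removed column.
    """
    target = target if target is not None else config.target
    if config.target is not target:
        config = config.replace(target=target)
    if protocol not in ("holdout", "loocv"):
        raise ConfigError(f"unknown protocol {protocol!r}")
    pids = sorted(episodes_by_participant)
    if len(pids) < 2:
        raise DataFormatError("importance analysis needs at least 2 participants")

    # Pre-assemble per-participant arrays once; columns dropped by slicing.
    arrays = {
        pid: episodes_to_arrays(list(eps), target, output_scale)
        for pid, eps in episodes_by_participant.items()
    }

    n_total = len(MODEL_AUS)

    def protocol_error(drop_index: int | None) -> float:
        keep = [i for i in range(n_total) if i != drop_index]
        if protocol == "holdout":
            train_p, test_p = _holdout_split(pids, test_fraction)
            Xtr = np.concatenate([arrays[p][0][:, :, keep] for p in train_p])
            ytr = np.concatenate([arrays[p][1] for p in train_p])
            Xte = np.concatenate([arrays[p][0][:, :, keep] for p in test_p])
            yte = np.concatenate([arrays[p][1] for p in test_p])
            est = _build_for_columns(config, output_scale, n_total, drop_index, seed)
            est.fit_arrays(Xtr, ytr, seed=seed)
            return float(np.abs(est.predict_arrays(Xte) - yte).mean())
        abs_errors: list[np.ndarray] = []
        for fold, pid in enumerate(pids):
            Xtr = np.concatenate([arrays[p][0][:, :, keep] for p in pids if p != pid])
            ytr = np.concatenate([arrays[p][1] for p in pids if p != pid])
            Xte, yte = arrays[pid][0][:, :, keep], arrays[pid][1]
            est = _build_for_columns(config, output_scale, n_total, drop_index, seed + fold)
            est.fit_arrays(Xtr, ytr, seed=seed + fold)
            abs_errors.append(np.abs(est.predict_arrays(Xte) - yte))
        return float(np.concatenate(abs_errors).mean())

    baseline_error = protocol_error(None)
    if baseline_error == 0.0:
        raise DegenerateSampleError(
            "baseline error is zero; relative importance is undefined"
        )
    per_au: dict[int, float] = {}
    for j, au in enumerate(MODEL_AUS):
        per_au[au] = (protocol_error(j) - baseline_error) / baseline_error
    return ImportanceReport(
        target=target, baseline_error=baseline_error, per_au=per_au, protocol=protocol
    )


def report_frame(report: ImportanceReport) -> pd.DataFrame:
    return pd.DataFrame(
        [{"au_id": au, "importance": report.per_au[au]} for au in MODEL_AUS]
    )


def write_report(report: ImportanceReport, out_dir: str | Path) -> None:
    """Write per-AU CSV plus a JSON with baseline error and settings."""
    import json

    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    report_frame(report).to_csv(d / "importance.csv", index=False)
    (d / "importance.json").write_text(
        json.dumps(
            {
                "target": report.target.value,
                "baseline_error": report.baseline_error,
                "protocol": report.protocol,
                "per_au": {str(k): v for k, v in report.per_au.items()},
            },
            indent=2,
        )
    )
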