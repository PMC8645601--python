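"""Reaction-time calibration from the 0-back target-detection task.

Each participant's mean and SD of simple reaction time define an
individualized half-window ``max(multiplier * SD, floor)`` used by the
rate-of-overlap metric to decide whether a block-2 response repeats a
block-1 response.  Runs are pooled by default (the two runs bracket the
segmentation blocks and serve as a fatigue control; a per-run comparison
is available for sensitivity analysis).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import RtCalibration
from .stats import StatResult, wilcoxon_signed_rank

#: half-window multiplier applied to the per-participant RT SD
DEFAULT_MULTIPLIER = 0.25
#: fallback floor: one frame of a 50 Hz video, in seconds
DEFAULT_FLOOR_S = 0.02


def compare_runs(
    trials: pd.DataFrame,
    groups: dict[str, str] | None = None,
) -> dict[str, StatResult]:
    """Wilcoxon signed-rank on per-participant mean RT, run 1 vs run 2.

    Participants missing either run are excluded with a warning.  Returns
    one result per group when a participant -> group mapping is given,
    else a single pooled result under key ``"all"``.
    """
    means = (
        trials.groupby(["participant_id", "run"])["latency_ms"].mean().unstack("run")
    )
    missing = means.index[means.isna().any(axis=1)]
    if len(missing):
        warnings.warn(
            f"excluding {len(missing)} participant(s) missing a 0-back run: "
            f"{sorted(missing)}"
        )
        means = means.dropna()
    if groups is None:
        return {"all": wilcoxon_signed_rank(means[1], means[2], comparison="rt_run1_vs_run2")}
    out: dict[str, StatResult] = {}
    labels = means.index.map(groups)
    for g in sorted(set(labels)):
        sub = means[labels == g]
        out[g] = wilcoxon_signed_rank(
            sub[1], sub[2], comparison="rt_run1_vs_run2", group=g
        )
    return out


def calibrate(
    trials: pd.DataFrame,
    *,
    multiplier: float = DEFAULT_MULTIPLIER,
    floor_s: float = DEFAULT_FLOOR_S,
    pool_runs: bool = True,
    target_only: bool = False,
) -> dict[str, RtCalibration]:
    """Per-participant RT mean/SD and matching half-window.

    SD is the sample SD (n-1) over all retained trials pooled across runs
    (``pool_runs=False`` returns one calibration per participant x run,
    keyed ``"pid/run"``, for sensitivity analysis).  ``target_only``
    restricts to target trials.  Participants with fewer than two trials
    raise a :class:`ValueError`.
    """
    if floor_s <= 0:
        raise ValueError("floor_s must be > 0")
    t = trials[trials["is_target"]] if target_only else trials
    out: dict[str, RtCalibration] = {}
    keys = ["participant_id"] if pool_runs else ["participant_id", "run"]
    for key, g in t.groupby(keys, sort=True):
        lat = g["latency_ms"].to_numpy(dtype=float)
        pid = key[0] if not pool_runs else (key if isinstance(key, str) else key[0])
        label = pid if pool_runs else f"{key[0]}/{key[1]}"
        if len(lat) < 2:
            raise ValueError(
                f"participant {label}: {len(lat)} retained trial(s); "
                "calibration needs >= 2"
            )
        sd = float(np.std(lat, ddof=1))
        out[label] = RtCalibration(
            participant_id=str(pid),
            mean_ms=float(lat.mean()),
            sd_ms=sd,
            n_trials=len(lat),
            half_window_s=max(multiplier * sd / 1000.0, floor_s),
        )
    return out
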