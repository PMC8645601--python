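"""Within-subject segmentation metrics: grain size (TBR) and consistency (ROO).

TBR (time between responses) is the mean gap in seconds between a
participant's successive button presses in one video and block — the
inverse proxy for segmentation grain size.  Leading and trailing video
time is ignored by construction: with n responses the mean of the n-1
successive gaps equals (t_last - t_first) / (n - 1).

ROO (rate of overlap) is the percentage of block-2 responses for which a
block-1 response exists within an individualized window: |t1 - t2| <=
half_window, with the half-window derived from the participant's 0-back
reaction-time SD (see :mod:`eventseg.rt`).  Matching is an existence test
by default — one block-1 response may match several block-2 responses; a
one-to-one greedy variant and the reverse anchoring direction are
available for sensitivity analysis.

Undefined values (too few responses) propagate as NaN, never as zero.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import RtCalibration, VideoMeta, video_map


def compute_tbr(times: Sequence[float]) -> float:
    """Mean successive gap in seconds; NaN with fewer than two responses."""
    t = np.sort(np.asarray(times, dtype=float))
    if len(t) < 2:
        return math.nan
    return float(np.diff(t).mean())


def compute_roo(
    block1: Sequence[float],
    block2: Sequence[float],
    half_window_s: float,
    *,
    direction: str = "block2",
    one_to_one: bool = False,
) -> float:
    """Percentage of anchor-block responses matched in the other block.

    ``direction="block2"`` (default) anchors on block 2 and searches block
    1; ``"block1"`` reverses.  The window boundary is inclusive.  NaN when
    the anchor block is empty.
    """
    if not half_window_s > 0:
        raise ValueError("half_window_s must be > 0")
    if direction == "block2":
        anchors, pool = np.asarray(block2, float), np.asarray(block1, float)
    elif direction == "block1":
        anchors, pool = np.asarray(block1, float), np.asarray(block2, float)
    else:
        raise ValueError(f"unknown direction {direction!r}")
    if len(anchors) == 0:
        return math.nan
    if len(pool) == 0:
        return 0.0
    if not one_to_one:
        diffs = np.abs(anchors[:, None] - pool[None, :])
        matched = (diffs <= half_window_s).any(axis=1)
        return 100.0 * matched.mean()
    # greedy one-to-one: anchors in time order claim the nearest unused pool response
    used = np.zeros(len(pool), dtype=bool)
    n_matched = 0
    for a in np.sort(anchors):
        d = np.abs(pool - a)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= half_window_s:
            used[j] = True
            n_matched += 1
    return 100.0 * n_matched / len(anchors)


def consistency_table(
    responses: pd.DataFrame,
    videos: Iterable[VideoMeta],
    calibrations: Mapping[str, RtCalibration],
    *,
    direction: str = "block2",
    one_to_one: bool = False,
    floor_frames: int = 1,
) -> pd.DataFrame:
    """Participant x video table of TBR per block, pooled TBR and ROO.

    The matching half-window is the participant's calibrated
    ``half_window_s``, floored at ``floor_frames`` frames of the video at
    hand so that a degenerate RT SD of zero can never make matching
    impossible.  Undefined metrics are NaN with the response counts kept,
    so exclusions stay countable downstream.
    """
    vmap = video_map(videos)
    rows = []
    grouped = responses.groupby(["participant_id", "video_id"], sort=True)
    for (pid, vid), g in grouped:
        video = vmap[vid]
        b1 = g.loc[g["block"] == 1, "time_s"].to_numpy()
        b2 = g.loc[g["block"] == 2, "time_s"].to_numpy()
        tbr_b1 = compute_tbr(b1)
        tbr_b2 = compute_tbr(b2)
        defined = [v for v in (tbr_b1, tbr_b2) if not math.isnan(v)]
        calib = calibrations.get(pid)
        if calib is not None:
            half_window = max(calib.half_window_s, floor_frames / video.frame_rate_hz)
            roo = compute_roo(b1, b2, half_window,
                              direction=direction, one_to_one=one_to_one)
        else:
            half_window, roo = math.nan, math.nan
        rows.append(
            {
                "participant_id": pid,
                "group": g["group"].iloc[0],
                "video_id": vid,
                "style": video.style,
                "difficulty": video.difficulty,
                "duration_s": video.duration_s,
                "n_b1": len(b1),
                "n_b2": len(b2),
                "tbr_b1_s": tbr_b1,
                "tbr_b2_s": tbr_b2,
                "tbr_s": float(np.mean(defined)) if defined else math.nan,
                "half_window_s": half_window,
                "roo_pct": roo,
            }
        )
    return pd.DataFrame(rows)


def summarize_participants(table: pd.DataFrame) -> pd.DataFrame:
    """Per-participant unweighted means over defined video-level values.

    Adds responses per video (mean over video x block), the response rate
    per second, per-level means for the style and block factors, and the
    count of undefined video-level values excluded from each mean.
    """
    out = []
    for pid, g in table.groupby("participant_id", sort=True):
        n_videos = len(g)
        n_resp = g["n_b1"].sum() + g["n_b2"].sum()
        watched_s = 2 * g["duration_s"].sum()
        per_style = {
            f"tbr_s_{s}": sub["tbr_s"].mean()
            for s, sub in g.groupby("style")
        }
        per_style.update(
            {f"roo_pct_{s}": sub["roo_pct"].mean() for s, sub in g.groupby("style")}
        )
        out.append(
            {
                "participant_id": pid,
                "group": g["group"].iloc[0],
                "n_videos": n_videos,
                "tbr_s": g["tbr_s"].mean(),
                "tbr_s_b1": g["tbr_b1_s"].mean(),
                "tbr_s_b2": g["tbr_b2_s"].mean(),
                "roo_pct": g["roo_pct"].mean(),
                "responses_per_video": n_resp / (2 * n_videos),
                "response_rate_per_s": n_resp / watched_s,
                "n_undefined_tbr": int(g["tbr_s"].isna().sum()),
                "n_undefined_roo": int(g["roo_pct"].isna().sum()),
                **per_style,
            }
        )
    df = pd.DataFrame(out)
    if df.empty or df[["tbr_s", "roo_pct"]].isna().all().all():
        # all-undefined cohort: still return the frame so counts survive
        return df
    return df


def retest_reliability(summary: pd.DataFrame) -> tuple[float, float, int]:
    """Pearson r between per-participant mean TBR in block 1 and block 2."""
    from scipy.stats import pearsonr

    paired = summary[["tbr_s_b1", "tbr_s_b2"]].dropna()
    if len(paired) < 3:
        return math.nan, math.nan, len(paired)
    r, p = pearsonr(paired["tbr_s_b1"], paired["tbr_s_b2"])
    return float(r), float(p), len(paired)
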