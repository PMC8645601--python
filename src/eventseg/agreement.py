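"""Group agreement on boundary placement: afv profiles, threshold, n-bound.

The added frame value (afv) of video frame ``f`` (at time ``t_f = f /
frame_rate``) counts how many response units gave at least one button
press in the trailing one-second bin ``(t_f - bin_width, t_f]``.  A unit
is a participant x block pair by default — responses of the two blocks
are summarized, so the maximal afv is twice the group size; the stricter
``units="participant"`` mode collapses blocks so the maximum is the group
size.  Within a bin each unit contributes at most once.

Agreed boundaries are maximal contiguous runs of frames whose afv
strictly exceeds the threshold mean + 2 SD, where mean and SD are taken
over the nonzero bins only.  Their count is n-bound, the per-video,
per-group index of within-group agreement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ValidationError, VideoMeta

UNIT_MODES = ("participant_block", "participant")


@dataclass
class AfvProfile:
    """Per-frame agreement counts for one video and group."""

    video_id: str
    group: str
    counts: np.ndarray  # int, length n_frames
    bin_width_s: float
    n_units: int
    frame_rate_hz: float
    nonzero_mean: float = math.nan
    nonzero_sd: float = math.nan
    threshold: float = math.nan  # NaN when < 2 nonzero bins

    @property
    def n_frames(self) -> int:
        return len(self.counts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": np.arange(self.n_frames),
                "time_s": np.arange(self.n_frames) / self.frame_rate_hz,
                "afv": self.counts,
            }
        )


@dataclass(frozen=True)
class Boundary:
    start_frame: int
    end_frame: int  # inclusive
    peak_frame: int
    peak_afv: int


@dataclass
class BoundarySet:
    """Agreed boundaries of one video x group and their count (n-bound)."""

    video_id: str
    group: str
    frame_rate_hz: float
    threshold: float
    boundaries: list[Boundary] = field(default_factory=list)

    @property
    def n_bound(self) -> int:
        return len(self.boundaries)

    def intervals_s(self) -> list[tuple[float, float]]:
        return [
            (b.start_frame / self.frame_rate_hz, b.end_frame / self.frame_rate_hz)
            for b in self.boundaries
        ]

    def to_frame(self) -> pd.DataFrame:
        fps = self.frame_rate_hz
        return pd.DataFrame(
            [
                {
                    "video_id": self.video_id,
                    "group": self.group,
                    "start_frame": b.start_frame,
                    "end_frame": b.end_frame,
                    "start_s": b.start_frame / fps,
                    "end_s": b.end_frame / fps,
                    "peak_s": b.peak_frame / fps,
                    "peak_afv": b.peak_afv,
                }
                for b in self.boundaries
            ],
            columns=[
                "video_id", "group", "start_frame", "end_frame",
                "start_s", "end_s", "peak_s", "peak_afv",
            ],
        )


def compute_afv(
    responses: pd.DataFrame,
    video: VideoMeta,
    *,
    group: str | None = None,
    bin_width_s: float = 1.0,
    units: str = "participant_block",
) -> AfvProfile:
    """Per-frame agreement profile for one video x group.

    ``responses`` must already be restricted to a single video and group
    (``group`` only labels the output unless given and checked).  A frame
    at time t_f counts a unit if that unit has any response t with
    ``t_f - bin_width < t <= t_f``; bins before ``bin_width`` seconds are
    truncated at video onset by construction.
    """
    if units not in UNIT_MODES:
        raise ValueError(f"units must be one of {UNIT_MODES}")
    if len(responses):
        if (responses["video_id"] != video.video_id).any():
            raise ValidationError("responses from a different video")
        if (responses["time_s"] > video.duration_s).any() or (responses["time_s"] < 0).any():
            raise ValidationError("response beyond video duration")
        group_labels = responses["group"].unique()
        if group is not None and set(group_labels) - {group}:
            raise ValidationError("responses from a different group")
        group = group or group_labels[0]
    group = group or "unknown"

    n_frames = video.n_frames
    frame_times = video.frame_times()
    counts = np.zeros(n_frames, dtype=int)
    if units == "participant_block":
        keys = ["participant_id", "block"]
        participants = responses["participant_id"].nunique() if len(responses) else 0
        n_units = 2 * participants
    else:
        keys = ["participant_id"]
        n_units = responses["participant_id"].nunique() if len(responses) else 0

    for _, g in responses.groupby(keys, sort=False) if len(responses) else []:
        mark = np.zeros(n_frames, dtype=bool)
        for t in g["time_s"].to_numpy(dtype=float):
            # frames with t <= t_f < t + bin_width  <=>  t in (t_f - w, t_f]
            lo = int(np.searchsorted(frame_times, t, side="left"))
            hi = int(np.searchsorted(frame_times, t + bin_width_s, side="left"))
            mark[lo:hi] = True
        counts += mark

    profile = AfvProfile(
        video_id=video.video_id,
        group=group,
        counts=counts,
        bin_width_s=bin_width_s,
        n_units=n_units,
        frame_rate_hz=video.frame_rate_hz,
    )
    compute_threshold(profile)
    return profile


def compute_threshold(
    profile: AfvProfile, *, sd_over_nonzero: bool = True
) -> float:
    """Mean + 2 SD over nonzero bins; NaN (no boundaries) with < 2 nonzero bins.

    Zero bins are excluded from the mean per the agreement procedure; by
    default the SD is taken over the same nonzero bins
    (``sd_over_nonzero=False`` uses all bins for the SD, the alternative
    reading).  Updates the profile in place and returns the threshold.
    """
    counts = np.asarray(profile.counts)
    nonzero = counts[counts > 0]
    if len(nonzero) < 2:
        profile.nonzero_mean = float(nonzero.mean()) if len(nonzero) else math.nan
        profile.nonzero_sd = math.nan
        profile.threshold = math.nan
        return profile.threshold
    mean = float(nonzero.mean())
    sd = float(np.std(nonzero if sd_over_nonzero else counts, ddof=1))
    profile.nonzero_mean = mean
    profile.nonzero_sd = sd
    profile.threshold = mean + 2.0 * sd
    return profile.threshold


#: minimal duration a supra-threshold run must span to count as a peak.
#: Quantization blips a few frames wide are not discernible peaks on an
#: agreement profile; at coarse resolutions (<= 5 frames/s) every run counts.
DEFAULT_MIN_PEAK_WIDTH_S = 0.2


def detect_boundaries(
    profile: AfvProfile, *, min_peak_width_s: float = DEFAULT_MIN_PEAK_WIDTH_S
) -> BoundarySet:
    """Maximal contiguous runs of frames with afv strictly above threshold.

    Each sufficiently wide run is one agreed boundary: a run must span at
    least ``min_peak_width_s`` (converted to frames, minimum one frame, so
    profiles binned at <= 1 / min_peak_width_s frames/s keep every run).
    The peak frame is the earliest argmax within the run.  An undefined
    threshold (flat or empty profile) yields n_bound = 0.
    """
    bset = BoundarySet(
        video_id=profile.video_id,
        group=profile.group,
        frame_rate_hz=profile.frame_rate_hz,
        threshold=profile.threshold,
    )
    if math.isnan(profile.threshold):
        return bset
    above = profile.counts > profile.threshold
    if not above.any():
        return bset
    min_frames = max(1, int(round(min_peak_width_s * profile.frame_rate_hz)))
    padded = np.concatenate(([False], above, [False]))
    d = np.diff(padded.astype(int))
    run_starts = np.flatnonzero(d == 1)
    run_ends = np.flatnonzero(d == -1) - 1
    for s, e in zip(run_starts, run_ends):
        if e - s + 1 < min_frames:
            continue
        seg = profile.counts[s : e + 1]
        peak_off = int(np.argmax(seg))
        bset.boundaries.append(
            Boundary(
                start_frame=int(s),
                end_frame=int(e),
                peak_frame=int(s + peak_off),
                peak_afv=int(seg[peak_off]),
            )
        )
    return bset


@dataclass
class RefereeOverlap:
    """Descriptive overlap of one rater's responses with agreed boundaries."""

    video_id: str
    group: str
    overlap_fraction: dict  # block -> fraction of responses hitting a boundary
    repetition_rate: float  # block-1 vs block-2 same-bin match rate
    n_responses: dict  # block -> count


def referee_overlap(
    referee_responses: pd.DataFrame,
    boundaries: BoundarySet,
    video: VideoMeta,
    *,
    bin_width_s: float = 1.0,
) -> RefereeOverlap:
    """Overlap of a designated rater's responses with a group's boundaries.

    A response at time t occupies the frames of its trailing bin
    ``[t, t + bin_width)`` (the frames whose bin contains it); it overlaps
    when any of those frames falls inside an agreed-boundary run.  Also
    reports the rater's block-1 vs block-2 repetition rate (existence
    match within ``bin_width_s``).  The rater must be excluded from the
    group profile upstream.  NaN fractions when a block has no responses.
    """
    frame_times = video.frame_times()
    intervals = [(b.start_frame, b.end_frame) for b in boundaries.boundaries]

    def hits(t: float) -> bool:
        lo = int(np.searchsorted(frame_times, t, side="left"))
        hi = int(np.searchsorted(frame_times, t + bin_width_s, side="left"))
        return any(s < hi and e >= lo for s, e in intervals)

    frac: dict = {}
    n_resp: dict = {}
    by_block = {
        b: referee_responses.loc[referee_responses["block"] == b, "time_s"].to_numpy()
        for b in (1, 2)
    }
    for b, times in by_block.items():
        n_resp[b] = len(times)
        frac[b] = float(np.mean([hits(t) for t in times])) if len(times) else math.nan
    b1, b2 = by_block[1], by_block[2]
    if len(b2) and len(b1):
        rep = float(
            np.mean([(np.abs(b1 - t) <= bin_width_s).any() for t in b2])
        )
    elif len(b2):
        rep = 0.0
    else:
        rep = math.nan
    return RefereeOverlap(
        video_id=video.video_id,
        group=boundaries.group,
        overlap_fraction=frac,
        repetition_rate=rep,
        n_responses=n_resp,
    )
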