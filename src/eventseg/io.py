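"""Domain types, CSV readers/writers and validation for segmentation datasets.

All tabular interchange is plain CSV (UTF-8, comma-separated, mandatory
header, ``.`` decimal).  Times are seconds from video onset; frame ``i``
(0-based) of a video running at ``frame_rate_hz`` occurs at ``i /
frame_rate_hz`` seconds.  Response logs are long-format, one button press
per row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

GROUPS = ("expert", "control")
STYLES = ("ITF", "WT")
DIFFICULTIES = ("easy", "difficult")
MARKERS = ("head", "left_hand", "right_hand", "pelvis", "left_foot", "right_foot")

RESPONSE_COLUMNS = ["participant_id", "group", "video_id", "block", "time_s"]
RT_COLUMNS = ["participant_id", "run", "latency_ms", "is_target", "correct"]
VIDEO_COLUMNS = ["video_id", "style", "difficulty", "duration_s", "frame_rate_hz"]
TRAJECTORY_COLUMNS = ["video_id", "marker", "frame", "x", "y", "z"]

#: recordable latency window of the target-detection task, in ms
RT_MIN_MS = 100.0
RT_MAX_MS = 1500.0


class SchemaError(ValueError):
    """A file is missing required columns or cannot be parsed."""


class ValidationError(ValueError):
    """A row violates a domain invariant (bounds, references, contiguity)."""


@dataclass(frozen=True)
class VideoMeta:
    """Metadata of one stimulus video."""

    video_id: str
    style: str
    difficulty: str
    duration_s: float
    frame_rate_hz: float

    def __post_init__(self) -> None:
        if self.style not in STYLES:
            raise ValidationError(f"unknown style {self.style!r} for {self.video_id}")
        if self.difficulty not in DIFFICULTIES:
            raise ValidationError(
                f"unknown difficulty {self.difficulty!r} for {self.video_id}"
            )
        if not self.duration_s > 0 or not self.frame_rate_hz > 0:
            raise ValidationError(f"non-positive duration/frame rate for {self.video_id}")
        if self.duration_s * self.frame_rate_hz < 1:
            raise ValidationError(f"{self.video_id}: fewer than one frame")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


@dataclass(frozen=True)
class RtCalibration:
    """Per-participant reaction-time statistics and the derived matching window.

    ``half_window_s`` is the half-width of the response-matching window used
    by the rate-of-overlap metric: ``max(multiplier * sd_ms / 1000, floor)``.
    """

    participant_id: str
    mean_ms: float
    sd_ms: float
    n_trials: int
    half_window_s: float

    def __post_init__(self) -> None:
        if self.sd_ms < 0:
            raise ValidationError("sd_ms must be >= 0")
        if not self.half_window_s > 0:
            raise ValidationError("half_window_s must be > 0")


@dataclass
class Trajectory:
    """Tracked 3-D positions (meters) of one body marker over one video."""

    video_id: str
    marker: str
    positions: np.ndarray  # shape (n_frames, 3)
    frame_rate_hz: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.marker not in MARKERS:
            raise ValidationError(f"unknown marker {self.marker!r}")
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError("positions must have shape (n_frames, 3)")
        if self.frame_rate_hz <= 0:
            raise ValidationError("frame_rate_hz must be > 0")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class LoadReport:
    """Structured account of everything a loader excluded or collapsed.

    Loaders never drop a row silently: every exclusion carries the row
    number (0-based, data rows), the reason and the offending value.
    """

    source: str
    n_loaded: int = 0
    exclusions: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    def exclude(self, row: int, reason: str, value=None) -> None:
        self.exclusions.append({"row": int(row), "reason": reason, "value": value})

    @property
    def n_excluded(self) -> int:
        return len(self.exclusions)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, default=str))


def _require_columns(df: pd.DataFrame, required: Sequence[str], source: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{source}: missing column(s) {missing}")


def _read_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8")
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: empty file without header")
    _require_columns(df, required, str(path))
    return df


def read_videos(path) -> list[VideoMeta]:
    df = _read_csv(path, VIDEO_COLUMNS)
    return [
        VideoMeta(
            video_id=str(r.video_id),
            style=str(r.style),
            difficulty=str(r.difficulty),
            duration_s=float(r.duration_s),
            frame_rate_hz=float(r.frame_rate_hz),
        )
        for r in df.itertuples()
    ]


def video_map(videos: Iterable[VideoMeta]) -> dict[str, VideoMeta]:
    return {v.video_id: v for v in videos}


def read_responses(
    path,
    videos: Iterable[VideoMeta],
    *,
    strict: bool = True,
) -> tuple[pd.DataFrame, LoadReport]:
    """Load and validate a long-format response log.

    Returns the canonically sorted response table (columns
    ``participant_id, group, video_id, block, time_s``) and a
    :class:`LoadReport`.  Out-of-bounds times raise a
    :class:`ValidationError` naming the row when ``strict`` (default), or
    are excluded into the report otherwise.  Duplicate timestamps within a
    participant x video x block (button bounce) are collapsed to one event
    with a warning.
    """
    vmap = video_map(videos)
    df = _read_csv(path, RESPONSE_COLUMNS)
    report = LoadReport(source=str(path))
    df = df[RESPONSE_COLUMNS].copy()

    time_s = pd.to_numeric(df["time_s"], errors="coerce")
    bad_time = time_s.isna() & df["time_s"].notna()
    if bad_time.any():
        rows = df.index[bad_time].tolist()
        raise SchemaError(f"{path}: non-numeric time_s in row(s) {rows}")
    df["time_s"] = time_s.astype(float)
    df["block"] = pd.to_numeric(df["block"], errors="raise").astype(int)
    for col in ("participant_id", "group", "video_id"):
        df[col] = df[col].astype(str)

    unknown_group = ~df["group"].isin(GROUPS)
    if unknown_group.any():
        raise ValidationError(
            f"{path}: unknown group label(s) {sorted(df.loc[unknown_group, 'group'].unique())}"
        )
    unknown_video = ~df["video_id"].isin(vmap)
    if unknown_video.any():
        raise ValidationError(
            f"{path}: unknown video_id(s) {sorted(df.loc[unknown_video, 'video_id'].unique())}"
        )
    if not df["block"].isin((1, 2)).all():
        raise ValidationError(f"{path}: block must be 1 or 2")

    durations = df["video_id"].map({k: v.duration_s for k, v in vmap.items()})
    out_of_bounds = (df["time_s"] < 0) | (df["time_s"] > durations)
    if out_of_bounds.any():
        rows = df.index[out_of_bounds].tolist()
        if strict:
            raise ValidationError(
                f"{path}: time_s outside [0, duration] in row(s) {rows}"
            )
        for row in rows:
            report.exclude(row, "time_s outside [0, video duration]", df.at[row, "time_s"])
        df = df.loc[~out_of_bounds]

    df = df.sort_values(RESPONSE_COLUMNS[:4] + ["time_s"], kind="mergesort")
    dup = df.duplicated(subset=["participant_id", "video_id", "block", "time_s"])
    if dup.any():
        report.warnings.append(
            f"collapsed {int(dup.sum())} duplicate timestamp(s) within participant x video x block"
        )
        df = df.loc[~dup]
    df = df.reset_index(drop=True)
    report.n_loaded = len(df)
    return df, report


def read_rt_trials(path) -> tuple[pd.DataFrame, LoadReport]:
    """Load 0-back reaction-time trials; latencies outside the recordable
    100-1500 ms window are excluded and counted in the report."""
    df = _read_csv(path, RT_COLUMNS)
    report = LoadReport(source=str(path))
    df = df[RT_COLUMNS].copy()
    latency = pd.to_numeric(df["latency_ms"], errors="coerce")
    bad = latency.isna() & df["latency_ms"].notna()
    if bad.any():
        raise SchemaError(f"{path}: non-numeric latency_ms in row(s) {df.index[bad].tolist()}")
    df["latency_ms"] = latency.astype(float)
    df["participant_id"] = df["participant_id"].astype(str)
    df["run"] = pd.to_numeric(df["run"], errors="raise").astype(int)
    df["is_target"] = df["is_target"].astype(bool)
    df["correct"] = df["correct"].astype(bool)
    if not df["run"].isin((1, 2)).all():
        raise ValidationError(f"{path}: run must be 1 or 2")

    out = (df["latency_ms"] < RT_MIN_MS) | (df["latency_ms"] > RT_MAX_MS)
    for row in df.index[out]:
        report.exclude(row, "latency outside recordable 100-1500 ms window",
                       df.at[row, "latency_ms"])
    df = df.loc[~out].reset_index(drop=True)
    report.n_loaded = len(df)
    return df, report


def read_trajectories(path) -> list[Trajectory]:
    """Load marker trajectories; per video x marker the frame indices must
    form the contiguous range 0..F-1."""
    df = _read_csv(path, TRAJECTORY_COLUMNS)
    if "frame_rate_hz" not in df.columns:
        raise SchemaError(f"{path}: missing column(s) ['frame_rate_hz']")
    out: list[Trajectory] = []
    for (vid, marker), g in df.groupby(["video_id", "marker"], sort=True):
        if marker not in MARKERS:
            raise ValidationError(f"{path}: unknown marker {marker!r} for video {vid}")
        g = g.sort_values("frame")
        frames = g["frame"].to_numpy(dtype=int)
        expected = np.arange(len(frames))
        if not np.array_equal(frames, expected):
            missing = sorted(set(expected) - set(frames))
            first = missing[0] if missing else int(frames[0])
            raise ValidationError(
                f"{path}: non-contiguous frames for video {vid}, marker {marker} "
                f"(first problem at frame {first})"
            )
        rates = g["frame_rate_hz"].unique()
        if len(rates) != 1:
            raise ValidationError(f"{path}: mixed frame rates for {vid}/{marker}")
        out.append(
            Trajectory(
                video_id=str(vid),
                marker=str(marker),
                positions=g[["x", "y", "z"]].to_numpy(dtype=float),
                frame_rate_hz=float(rates[0]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers (exact round-trip counterparts of the readers)

def write_videos(videos: Iterable[VideoMeta], path) -> None:
    pd.DataFrame([asdict(v) for v in videos], columns=VIDEO_COLUMNS).to_csv(
        path, index=False
    )


def write_responses(df: pd.DataFrame, path) -> None:
    df[RESPONSE_COLUMNS].to_csv(path, index=False)


def write_rt_trials(df: pd.DataFrame, path) -> None:
    df[RT_COLUMNS].to_csv(path, index=False)


def write_trajectories(trajectories: Iterable[Trajectory], path) -> None:
    frames = []
    for t in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "video_id": t.video_id,
                    "marker": t.marker,
                    "frame": np.arange(t.n_frames),
                    "x": t.positions[:, 0],
                    "y": t.positions[:, 1],
                    "z": t.positions[:, 2],
                    "frame_rate_hz": t.frame_rate_hz,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# dataset manifest

MANIFEST_KEYS = ("responses", "rt_trials", "videos")


def read_manifest(path) -> dict:
    """Read a JSON/YAML manifest binding the dataset file paths.

    Required keys: ``responses``, ``rt_trials``, ``videos``; optional:
    ``trajectories``, ``referee_id``.  Relative paths resolve against the
    manifest's directory.
    """
    path = Path(path)
    text = path.read_text()
    manifest = yaml.safe_load(text)
    if not isinstance(manifest, Mapping):
        raise SchemaError(f"{path}: manifest must be a mapping")
    missing = [k for k in MANIFEST_KEYS if k not in manifest]
    if missing:
        raise SchemaError(f"{path}: manifest missing key(s) {missing}")
    resolved = dict(manifest)
    for key in (*MANIFEST_KEYS, "trajectories"):
        if key in resolved and resolved[key] is not None:
            resolved[key] = str((path.parent / resolved[key]).resolve())
    return resolved
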