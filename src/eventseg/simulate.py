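"""Synthetic segmentation-experiment generator with known ground truth.

Emulates the study design end to end: 12 stimulus videos (six ~51 s ITF,
six ~71 s WT, half easy / half difficult), two experimental blocks, an
expert-like group that shares one ground-truth boundary set per video and
a control-like group whose members carry individual boundary sets, plus
0-back reaction-time trials and marker trajectories with speed bursts at
the ground-truth boundaries.

Response mechanism per participant and video: each boundary of the
participant's set is kept with a persistent probability ``grain_q``
(drawn once per participant from a Beta distribution — the same kept-set
applies to both blocks, which is what produces high block-to-block grain
reliability); kept boundaries are detected per block with ``p_detect``
and answered with latency ``Normal(mu_lat_s, sigma_lat_s)``; idiosyncratic
presses arrive as a Poisson process of rate ``lambda_idio``.  Because the
control group uses the identical rate parameters (only the boundary sets
differ), expected response counts are analytically matched across groups
and grain size carries no group signal — agreement (n-bound) does.

All randomness flows from one master seed; per-participant/video/block
streams are derived by stable hashing of identifiers, so output is
independent of iteration order and byte-identical across runs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .io import (
    MARKERS,
    Trajectory,
    VideoMeta,
    write_responses,
    write_rt_trials,
    write_trajectories,
    write_videos,
)

SHARE_MODES = ("shared_set", "individual_sets")


@dataclass
class GroupParams:
    """Generative parameters of one participant group."""

    name: str
    n_participants: int
    share_mode: str = "shared_set"
    p_detect: float = 0.75
    mu_lat_s: float = 0.4
    sigma_lat_s: float = 0.3
    lambda_idio: float = 0.05  # idiosyncratic presses per second
    grain_alpha: float = 1.2  # Beta parameters of the persistent keep rate
    grain_beta: float = 0.6  # wide spread: grain varies hugely across observers

    def __post_init__(self) -> None:
        if self.share_mode not in SHARE_MODES:
            raise ValueError(f"share_mode must be one of {SHARE_MODES}")
        if not 0 <= self.p_detect <= 1:
            raise ValueError("p_detect must be in [0, 1]")


@dataclass
class RtParams:
    mu_ms: float = 385.0
    sd_ms: float = 120.0
    n_trials_per_run: int = 10  # targets per 0-back run


@dataclass
class KinematicsParams:
    enabled: bool = True
    burst_amp: float = 3.0  # peak speed of a boundary burst, m/s
    burst_width_s: float = 0.25  # Gaussian sigma of the burst
    baseline_speed: float = 0.3  # slow wandering between bursts, m/s
    noise_sd_m: float = 0.002  # positional jitter, m


@dataclass
class SimConfig:
    """Full generative configuration; the defaults are the study conditions."""

    n_videos_per_style: int = 6
    itf_duration_s: float = 51.0
    wt_duration_s: float = 71.0
    frame_rate_hz: float = 50.0
    n_boundaries: int = 10
    min_gap_s: float = 2.0
    expert: GroupParams = field(
        default_factory=lambda: GroupParams("expert", 24, "shared_set")
    )
    control: GroupParams = field(
        default_factory=lambda: GroupParams("control", 29, "individual_sets")
    )
    rt: RtParams = field(default_factory=RtParams)
    kinematics: KinematicsParams = field(default_factory=KinematicsParams)
    seed: int = 0

    def videos(self) -> list[VideoMeta]:
        out = []
        for style, dur in (("ITF", self.itf_duration_s), ("WT", self.wt_duration_s)):
            for i in range(self.n_videos_per_style):
                half = self.n_videos_per_style // 2
                out.append(
                    VideoMeta(
                        video_id=f"{style.lower()}{i + 1:02d}",
                        style=style,
                        difficulty="easy" if i < half else "difficult",
                        duration_s=dur,
                        frame_rate_hz=self.frame_rate_hz,
                    )
                )
        return out

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        for key, typ in (("expert", GroupParams), ("control", GroupParams),
                         ("rt", RtParams), ("kinematics", KinematicsParams)):
            if key in d and isinstance(d[key], dict):
                d[key] = typ(**d[key])
        return cls(**d)


def _stream(seed: int, *keys) -> np.random.Generator:
    """Derive an order-independent RNG stream from the master seed and IDs."""
    digest = hashlib.blake2b(
        ("|".join(str(k) for k in (seed, *keys))).encode(), digest_size=8
    ).digest()
    return np.random.default_rng(int.from_bytes(digest, "big"))


def sample_boundaries(
    rng: np.random.Generator, k: int, duration_s: float, min_gap_s: float,
    edge_s: float = 1.0,
) -> np.ndarray:
    """K boundary times, uniform subject to a minimal gap, clear of the edges.

    Uses the order-statistics construction (uniform draws in the
    gap-reduced interval plus deterministic offsets), which is exact and
    needs no rejection.  Raises when the packing is infeasible.
    """
    if k == 0:
        return np.array([])
    usable = duration_s - 2 * edge_s
    slack = usable - (k - 1) * min_gap_s
    if slack < 0:
        raise ValueError(
            f"cannot place {k} boundaries with gap {min_gap_s} s in "
            f"{duration_s} s (usable {usable} s)"
        )
    u = np.sort(rng.uniform(0.0, slack, size=k))
    return edge_s + u + np.arange(k) * min_gap_s


def generate_ground_truth(config: SimConfig, video: VideoMeta) -> np.ndarray:
    """Shared ground-truth boundary times of one video."""
    rng = _stream(config.seed, "truth", video.video_id)
    return sample_boundaries(
        rng, config.n_boundaries, video.duration_s, config.min_gap_s
    )


def _participant_boundaries(
    config: SimConfig, gp: GroupParams, pid: str, video: VideoMeta,
    truth: np.ndarray,
) -> np.ndarray:
    if gp.share_mode == "shared_set":
        return truth
    rng = _stream(config.seed, "bset", pid, video.video_id)
    return sample_boundaries(
        rng, config.n_boundaries, video.duration_s, config.min_gap_s
    )


def generate_participant_responses(
    boundaries: np.ndarray,
    gp: GroupParams,
    kept_mask: np.ndarray,
    block: int,
    rng: np.random.Generator,
    duration_s: float,
) -> np.ndarray:
    """Response times of one participant x video x block.

    ``kept_mask`` is the participant's persistent boundary selection (the
    same mask is applied in both blocks); detection and latency noise are
    re-drawn per block, and idiosyncratic Poisson presses are appended.
    """
    kept = boundaries[kept_mask] if len(boundaries) else boundaries
    detected = kept[rng.random(len(kept)) < gp.p_detect]
    times = detected + rng.normal(gp.mu_lat_s, gp.sigma_lat_s, size=len(detected))
    n_idio = rng.poisson(gp.lambda_idio * duration_s)
    idio = rng.uniform(0.0, duration_s, size=n_idio)
    all_times = np.clip(np.concatenate([times, idio]), 0.0, duration_s)
    return np.unique(np.sort(all_times))


@dataclass
class Dataset:
    """In-memory synthetic dataset with its generative ground truth."""

    responses: pd.DataFrame
    rt_trials: pd.DataFrame
    videos: list
    trajectories: list | None
    ground_truth: dict
    config: SimConfig

    def write(self, out_dir) -> dict:
        """Write all CSVs, ground_truth.json, a manifest and provenance."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_videos(self.videos, out / "videos.csv")
        write_responses(self.responses, out / "responses.csv")
        write_rt_trials(self.rt_trials, out / "rt_trials.csv")
        manifest = {
            "videos": "videos.csv",
            "responses": "responses.csv",
            "rt_trials": "rt_trials.csv",
        }
        if self.trajectories:
            write_trajectories(self.trajectories, out / "trajectories.csv")
            manifest["trajectories"] = "trajectories.csv"
        (out / "ground_truth.json").write_text(
            json.dumps(self.ground_truth, indent=2, sort_keys=True)
        )
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (out / "provenance.json").write_text(
            json.dumps(
                {
                    "config": self.config.as_dict(),
                    "seed": self.config.seed,
                    "package": "eventseg",
                    "version": __version__,
                },
                indent=2,
                sort_keys=True,
            )
        )
        return manifest


def _truncated_normal(rng, mu, sd, lo, hi, n) -> np.ndarray:
    out = np.empty(0)
    while len(out) < n:
        draw = rng.normal(mu, sd, size=2 * (n - len(out)) + 8)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


def _generate_rt_trials(config: SimConfig, participants: list[tuple[str, str]]) -> pd.DataFrame:
    rows = []
    for pid, _group in participants:
        for run in (1, 2):
            rng = _stream(config.seed, "rt", pid, run)
            lat = _truncated_normal(
                rng, config.rt.mu_ms, config.rt.sd_ms, 100.0, 1500.0,
                config.rt.n_trials_per_run,
            )
            for v in lat:
                rows.append(
                    {
                        "participant_id": pid,
                        "run": run,
                        "latency_ms": float(v),
                        "is_target": True,
                        "correct": True,
                    }
                )
    return pd.DataFrame(rows)


def _generate_trajectories(config: SimConfig, videos, truths) -> list[Trajectory]:
    kp = config.kinematics
    out = []
    for video in videos:
        n_frames = video.n_frames
        t = np.arange(n_frames) / video.frame_rate_hz
        for m_idx, marker in enumerate(MARKERS):
            rng = _stream(config.seed, "traj", video.video_id, marker)
            # speed profile: slow baseline + Gaussian bursts at boundaries
            speed = kp.baseline_speed * (1.2 + np.sin(2 * np.pi * 0.05 * t + m_idx))
            for b in truths[video.video_id]:
                amp = kp.burst_amp * (0.7 + 0.6 * rng.random())
                speed = speed + amp * np.exp(-0.5 * ((t - b) / kp.burst_width_s) ** 2)
            heading = 2 * np.pi * 0.02 * t + rng.uniform(0, 2 * np.pi)
            dt = 1.0 / video.frame_rate_hz
            x = np.cumsum(speed * np.cos(heading)) * dt
            y = np.cumsum(speed * np.sin(heading)) * dt
            z = 0.9 + 0.05 * np.sin(2 * np.pi * 0.1 * t + m_idx)
            pos = np.column_stack([x, y, z]) + rng.normal(
                0.0, kp.noise_sd_m, size=(n_frames, 3)
            )
            out.append(
                Trajectory(
                    video_id=video.video_id,
                    marker=marker,
                    positions=pos,
                    frame_rate_hz=video.frame_rate_hz,
                )
            )
    return out


def generate_cohort(config: SimConfig, out_dir=None) -> Dataset:
    """Generate the full synthetic dataset (and optionally write it).

    Returns responses, 0-back RT trials, video metadata, marker
    trajectories (when enabled) and a ground-truth record (per-video
    boundary times, per-participant grain rates) for recovery scoring.
    """
    videos = config.videos()
    truths = {v.video_id: generate_ground_truth(config, v) for v in videos}

    participants: list[tuple[str, str, GroupParams]] = []
    for gp, prefix in ((config.expert, "E"), (config.control, "C")):
        for i in range(gp.n_participants):
            participants.append((f"{prefix}{i + 1:02d}", gp.name, gp))

    grain_q = {
        pid: float(
            _stream(config.seed, "grain", pid).beta(gp.grain_alpha, gp.grain_beta)
        )
        for pid, _g, gp in participants
    }

    rows = []
    for pid, group, gp in participants:
        for video in videos:
            truth = truths[video.video_id]
            bset = _participant_boundaries(config, gp, pid, video, truth)
            kept_rng = _stream(config.seed, "kept", pid, video.video_id)
            kept_mask = kept_rng.random(len(bset)) < grain_q[pid]
            for block in (1, 2):
                rng = _stream(config.seed, "resp", pid, video.video_id, block)
                times = generate_participant_responses(
                    bset, gp, kept_mask, block, rng, video.duration_s
                )
                for ts in times:
                    rows.append(
                        {
                            "participant_id": pid,
                            "group": group,
                            "video_id": video.video_id,
                            "block": block,
                            "time_s": float(ts),
                        }
                    )
    responses = pd.DataFrame(
        rows, columns=["participant_id", "group", "video_id", "block", "time_s"]
    ).sort_values(
        ["participant_id", "group", "video_id", "block", "time_s"], kind="mergesort"
    ).reset_index(drop=True)

    rt_trials = _generate_rt_trials(config, [(p, g) for p, g, _ in participants])
    trajectories = (
        _generate_trajectories(config, videos, truths)
        if config.kinematics.enabled
        else None
    )
    ground_truth = {
        "boundaries_s": {vid: list(map(float, ts)) for vid, ts in truths.items()},
        "grain_q": grain_q,
        "groups": {pid: g for pid, g, _ in participants},
        "seed": config.seed,
    }
    dataset = Dataset(
        responses=responses,
        rt_trials=rt_trials,
        videos=videos,
        trajectories=trajectories,
        ground_truth=ground_truth,
        config=config,
    )
    if out_dir is not None:
        dataset.write(out_dir)
    return dataset
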