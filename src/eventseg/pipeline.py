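"""Orchestration: run calibration -> metrics -> agreement -> stats -> kinematics.

:func:`analyze` consumes either an in-memory synthetic :class:`Dataset`
or a dataset manifest on disk and produces a :class:`ResultBundle` whose
contents are deterministic given inputs and configuration.
:func:`save_bundle` serializes every table to CSV/JSON (figures are
rendered separately by :mod:`eventseg.plotting`, always alongside their
underlying data).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agreement, kinematics as kin, metrics, rt, stats
from .io import (
    LoadReport,
    read_manifest,
    read_responses,
    read_rt_trials,
    read_trajectories,
    read_videos,
    video_map,
)

log = logging.getLogger("eventseg")


@dataclass
class RunConfig:
    """Analysis switches; echoed verbatim into every output bundle."""

    bin_width_s: float = 1.0
    units: str = "participant_block"  # or "participant"
    window_multiplier: float = 0.25
    floor_frames: int = 1
    roo_direction: str = "block2"
    one_to_one: bool = False
    sd_over_nonzero: bool = True
    min_peak_width_s: float = 0.2
    kinematics_signal: str = "speed_derivative"
    smooth_s: float = 0.1
    referee_id: str | None = None
    permutation_shifts: int = 199
    permutation_seed: int = 0
    run_kinematics: bool = True

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ResultBundle:
    config: RunConfig
    videos: list
    calibrations: dict
    rt_run_comparison: dict
    consistency: pd.DataFrame
    participants: pd.DataFrame
    profiles: dict  # (video_id, group) -> AfvProfile
    boundary_sets: dict  # (video_id, group) -> BoundarySet
    nbound: pd.DataFrame  # per video: n_bound_expert, n_bound_control
    stat_results: dict
    referee: list = field(default_factory=list)
    kinematics_overlap: pd.DataFrame | None = None
    load_reports: list = field(default_factory=list)


def _per_video_group_table(consistency: pd.DataFrame, nbound: pd.DataFrame) -> pd.DataFrame:
    """Per video x group means of TBR/ROO joined with n-bound (videos as cases)."""
    agg = (
        consistency.groupby(["video_id", "group", "style", "difficulty"], sort=True)[
            ["tbr_s", "roo_pct"]
        ]
        .mean()
        .reset_index()
    )
    return agg.merge(nbound, on=["video_id", "group"], how="left")


def analyze(dataset, config: RunConfig | None = None) -> ResultBundle:
    """Run the full pipeline on a dataset (manifest path or Dataset object)."""
    config = config or RunConfig()
    reports: list[LoadReport] = []

    if isinstance(dataset, (str, Path)):
        manifest = read_manifest(dataset)
        videos = read_videos(manifest["videos"])
        responses, rep = read_responses(manifest["responses"], videos)
        reports.append(rep)
        rt_trials, rep = read_rt_trials(manifest["rt_trials"])
        reports.append(rep)
        trajectories = (
            read_trajectories(manifest["trajectories"])
            if manifest.get("trajectories")
            else None
        )
        if config.referee_id is None and manifest.get("referee_id"):
            config = dataclasses.replace(config, referee_id=str(manifest["referee_id"]))
    else:
        videos = dataset.videos
        responses = dataset.responses
        rt_trials = dataset.rt_trials
        trajectories = dataset.trajectories

    vmap = video_map(videos)
    log.info("analyze: %d responses, %d videos", len(responses), len(videos))

    # --- stage 1: RT calibration -------------------------------------------
    groups = (
        responses.drop_duplicates("participant_id")
        .set_index("participant_id")["group"]
        .to_dict()
    )
    min_frame_s = 1.0 / max(v.frame_rate_hz for v in videos)
    calibrations = rt.calibrate(
        rt_trials,
        multiplier=config.window_multiplier,
        floor_s=config.floor_frames * min_frame_s,
    )
    rt_runs = rt.compare_runs(rt_trials, groups=groups)

    # --- stage 2: within-subject metrics -----------------------------------
    consistency = metrics.consistency_table(
        responses,
        videos,
        calibrations,
        direction=config.roo_direction,
        one_to_one=config.one_to_one,
        floor_frames=config.floor_frames,
    )
    participants = metrics.summarize_participants(consistency)
    retest_r, retest_p, retest_n = metrics.retest_reliability(participants)

    # --- stage 3: group agreement ------------------------------------------
    profiles: dict = {}
    boundary_sets: dict = {}
    nbound_rows = []
    for video in videos:
        for group in sorted(responses["group"].unique()):
            sub = responses[
                (responses["video_id"] == video.video_id)
                & (responses["group"] == group)
            ]
            if config.referee_id is not None:
                sub = sub[sub["participant_id"] != config.referee_id]
            profile = agreement.compute_afv(
                sub, video, group=group,
                bin_width_s=config.bin_width_s, units=config.units,
            )
            agreement.compute_threshold(profile, sd_over_nonzero=config.sd_over_nonzero)
            bset = agreement.detect_boundaries(
                profile, min_peak_width_s=config.min_peak_width_s
            )
            profiles[(video.video_id, group)] = profile
            boundary_sets[(video.video_id, group)] = bset
            nbound_rows.append(
                {"video_id": video.video_id, "group": group, "n_bound": bset.n_bound}
            )
    nbound = pd.DataFrame(nbound_rows)

    # --- stage 4: inferential layer ----------------------------------------
    stat_results: dict = {
        "rt_run_comparison": {g: r.as_dict() for g, r in rt_runs.items()},
        "retest_reliability": {"r": retest_r, "p": retest_p, "n": retest_n},
    }
    n_tests = 0
    for metric in ("tbr_s", "roo_pct"):
        try:
            stat_results[f"{metric}_group"] = stats.compare_participants(
                participants, metric, "group"
            ).as_dict()
            n_tests += 1
        except ValueError as e:
            stat_results[f"{metric}_group"] = {"error": str(e)}
    for metric in ("tbr_s", "roo_pct"):
        for factor in ("style", "block"):
            if factor == "block" and metric == "roo_pct":
                continue  # ROO is itself a block-1-vs-2 comparison
            for group in (None, "expert", "control"):
                key = f"{metric}_{factor}_{group or 'all'}"
                try:
                    stat_results[key] = stats.compare_participants(
                        participants, metric, factor, group=group
                    ).as_dict()
                    n_tests += 1
                except (ValueError, KeyError) as e:
                    stat_results[key] = {"error": str(e)}

    wide = nbound.pivot(index="video_id", columns="group", values="n_bound")
    if {"expert", "control"} <= set(wide.columns) and len(wide) >= 2:
        stat_results["nbound_group_anova"] = stats.videos_as_cases_anova(
            wide["expert"], wide["control"]
        ).as_dict()
        n_tests += 1

    cases = _per_video_group_table(consistency, nbound)
    for group in sorted(cases["group"].unique()):
        sub = cases[cases["group"] == group]
        for factor in ("style", "difficulty"):
            if sub[factor].nunique() != 2 or len(sub) < 4:
                continue
            res = stats.style_difficulty_manova(sub, factor, group=group)
            stat_results[f"manova_{factor}_{group}"] = {
                k: (v.as_dict() if isinstance(v, stats.StatResult) else v)
                for k, v in res.items()
                if v is not None
            }
            n_tests += res["n_tests"]
    stat_results["n_tests_run"] = n_tests

    # --- stage 5: referee + kinematics overlays ----------------------------
    referee = []
    if config.referee_id is not None:
        for video in videos:
            ref = responses[
                (responses["participant_id"] == config.referee_id)
                & (responses["video_id"] == video.video_id)
            ]
            if ref.empty:
                continue
            for group in sorted(responses["group"].unique()):
                ov = agreement.referee_overlap(
                    ref, boundary_sets[(video.video_id, group)], video,
                    bin_width_s=config.bin_width_s,
                )
                referee.append(ov)

    kinematics_overlap = None
    if trajectories and config.run_kinematics:
        rng = np.random.default_rng(config.permutation_seed)
        tables = []
        by_video: dict = {}
        for traj in trajectories:
            by_video.setdefault(traj.video_id, []).append(traj)
        for vid, trajs in sorted(by_video.items()):
            profs = [
                kin.compute_acceleration(
                    t, smoothing_window_s=config.smooth_s,
                    signal=config.kinematics_signal,
                )
                for t in trajs
            ]
            for group in sorted(responses["group"].unique()):
                bset = boundary_sets.get((vid, group))
                if bset is None:
                    continue
                tables.append(
                    kin.boundary_accel_overlap(
                        bset, profs, n_shifts=config.permutation_shifts, rng=rng,
                        bin_width_s=config.bin_width_s,
                    )
                )
        if tables:
            kinematics_overlap = pd.concat(tables, ignore_index=True)

    return ResultBundle(
        config=config,
        videos=videos,
        calibrations=calibrations,
        rt_run_comparison=rt_runs,
        consistency=consistency,
        participants=participants,
        profiles=profiles,
        boundary_sets=boundary_sets,
        nbound=nbound,
        stat_results=stat_results,
        referee=referee,
        kinematics_overlap=kinematics_overlap,
        load_reports=reports,
    )


def save_bundle(bundle: ResultBundle, out_dir) -> Path:
    """Serialize the bundle: metric tables, afv/boundary files, stats JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "run_config.json").write_text(json.dumps(bundle.config.as_dict(), indent=2))

    pd.DataFrame(
        [dataclasses.asdict(c) for c in bundle.calibrations.values()]
    ).to_csv(out / "calibrations.csv", index=False)
    bundle.consistency.to_csv(out / "consistency.csv", index=False)
    bundle.participants.to_csv(out / "participants.csv", index=False)
    bundle.nbound.to_csv(out / "nbound.csv", index=False)

    for (vid, group), profile in bundle.profiles.items():
        df = profile.to_frame()
        df["threshold"] = profile.threshold
        df.to_csv(out / f"afv_{vid}_{group}.csv", index=False)
    boundary_frames = [b.to_frame() for b in bundle.boundary_sets.values()]
    if boundary_frames:
        pd.concat(boundary_frames, ignore_index=True).to_csv(
            out / "boundaries.csv", index=False
        )

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, float) and math.isnan(o):
            return None
        return str(o)

    (out / "stats.json").write_text(
        json.dumps(bundle.stat_results, indent=2, default=_default)
    )
    if bundle.referee:
        (out / "referee_overlap.json").write_text(
            json.dumps(
                [dataclasses.asdict(r) for r in bundle.referee],
                indent=2, default=_default,
            )
        )
    if bundle.kinematics_overlap is not None:
        bundle.kinematics_overlap.to_csv(out / "kinematics_overlap.csv", index=False)
    for i, rep in enumerate(bundle.load_reports):
        rep.to_json(out / f"load_report_{i}.json")
    return out
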