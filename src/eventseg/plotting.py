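"""Figures for the analysis report; every figure's data is also saved as CSV."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_afv(profile, boundary_set, ax=None):
    """Agreement-profile overlay: afv dots, threshold line, marked runs."""
    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3))
    df = profile.to_frame()
    ax.plot(df["time_s"], df["afv"], ".", ms=2, color="tab:blue", label="afv")
    if not np.isnan(profile.threshold):
        ax.axhline(profile.threshold, color="red", lw=1,
                   label="threshold (mean + 2 SD of nonzero bins)")
    for i, b in enumerate(boundary_set.boundaries):
        fps = boundary_set.frame_rate_hz
        ax.axvspan(b.start_frame / fps, (b.end_frame + 1) / fps,
                   color="orange", alpha=0.3,
                   label="agreed boundary" if i == 0 else None)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("afv")
    ax.set_title(
        f"{profile.video_id} / {profile.group}  "
        f"(n-bound = {boundary_set.n_bound}, units = {profile.n_units})"
    )
    ax.legend(loc="upper right", fontsize=7)
    return ax


def plot_group_comparison(nbound: pd.DataFrame, ax=None):
    """Per-video n-bound by group, paired across videos."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    wide = nbound.pivot(index="video_id", columns="group", values="n_bound")
    x = np.arange(len(wide.columns))
    for vid, row in wide.iterrows():
        ax.plot(x, row.values, "o-", alpha=0.5, label=vid)
    ax.set_xticks(x, wide.columns)
    ax.set_ylabel("n-bound")
    ax.set_title("agreed boundaries per video")
    return ax


def render_report(bundle, out_dir) -> list[Path]:
    """Render all figures for a result bundle; returns the written paths.

    Sections whose inputs are absent (e.g. no kinematics) are skipped
    without error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for (vid, group), profile in bundle.profiles.items():
        fig, ax = plt.subplots(figsize=(10, 3))
        plot_afv(profile, bundle.boundary_sets[(vid, group)], ax=ax)
        path = out / f"afv_{vid}_{group}.png"
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    if len(bundle.nbound):
        fig, ax = plt.subplots(figsize=(4, 4))
        plot_group_comparison(bundle.nbound, ax=ax)
        path = out / "nbound_groups.png"
        fig.tight_layout()
        fig.savefig(path, dpi=110)
        plt.close(fig)
        written.append(path)
    if bundle.kinematics_overlap is not None:
        path = out / "kinematics_overlap.csv"
        bundle.kinematics_overlap.to_csv(path, index=False)
        written.append(path)
    return written
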