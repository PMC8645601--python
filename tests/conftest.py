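import numpy as np
import pandas as pd
import pytest

from eventseg.io import VideoMeta


@pytest.fixture
def video_50fps() -> VideoMeta:
    return VideoMeta("v1", "WT", "easy", duration_s=30.0, frame_rate_hz=50.0)


@pytest.fixture
def videos_small() -> list[VideoMeta]:
    return [
        VideoMeta("v1", "WT", "easy", 30.0, 50.0),
        VideoMeta("v2", "ITF", "difficult", 20.0, 50.0),
    ]


def make_responses(rows) -> pd.DataFrame:
    """rows: (participant_id, group, video_id, block, time_s) tuples."""
    return pd.DataFrame(
        rows, columns=["participant_id", "group", "video_id", "block", "time_s"]
    )


def make_rt_trials(latencies_by_pid: dict, run: int = 1) -> pd.DataFrame:
    rows = []
    for pid, lats in latencies_by_pid.items():
        for lat in lats:
            rows.append(
                {
                    "participant_id": pid,
                    "run": run,
                    "latency_ms": float(lat),
                    "is_target": True,
                    "correct": True,
                }
            )
    return pd.DataFrame(rows)


def random_response_df(rng, video, n_participants, rate_per_s, group="expert"):
    rows = []
    for i in range(n_participants):
        for block in (1, 2):
            n = rng.poisson(rate_per_s * video.duration_s)
            for t in np.sort(rng.uniform(0, video.duration_s, n)):
                rows.append((f"P{i}", group, video.video_id, block, float(t)))
    return make_responses(rows)
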