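import math

import numpy as np
import pandas as pd
import pytest

from eventseg import agreement
from eventseg.io import ValidationError, VideoMeta

from conftest import make_responses, random_response_df


def brute_force_afv(responses, video, bin_width_s=1.0, units="participant_block"):
    """Triple loop over (frame, unit, response); the definitional oracle."""
    n_frames = video.n_frames
    counts = np.zeros(n_frames, dtype=int)
    if units == "participant_block":
        unit_of = lambda r: (r.participant_id, r.block)
    else:
        unit_of = lambda r: r.participant_id
    by_unit = {}
    for r in responses.itertuples():
        by_unit.setdefault(unit_of(r), []).append(r.time_s)
    for f in range(n_frames):
        t_f = f / video.frame_rate_hz
        for times in by_unit.values():
            if any(t_f - bin_width_s < t <= t_f for t in times):
                counts[f] += 1
    return counts


def profile_from_counts(counts, fps=1.0):
    p = agreement.AfvProfile(
        video_id="v", group="expert", counts=np.asarray(counts, dtype=int),
        bin_width_s=1.0, n_units=int(np.max(counts, initial=0)), frame_rate_hz=fps,
    )
    agreement.compute_threshold(p)
    return p


class TestAfv:
    def test_forced_single_bin(self):
        # 3 participants, one response at t=10.0 in both blocks, 50 fps:
        # counts = 6 exactly on frames with t_f in [10, 11), 0 elsewhere
        video = VideoMeta("v1", "WT", "easy", 30.0, 50.0)
        rows = [
            (p, "expert", "v1", b, 10.0) for p in ("a", "b", "c") for b in (1, 2)
        ]
        profile = agreement.compute_afv(make_responses(rows), video)
        t = video.frame_times()
        expected = np.where((t >= 10.0) & (t < 11.0), 6, 0)
        np.testing.assert_array_equal(profile.counts, expected)
        assert profile.n_units == 6

    def test_no_responses_all_zero_no_boundaries(self, video_50fps):
        profile = agreement.compute_afv(
            make_responses([]).astype({"time_s": float}), video_50fps
        )
        assert profile.counts.sum() == 0
        assert math.isnan(profile.threshold)
        assert agreement.detect_boundaries(profile).n_bound == 0

    def test_response_beyond_duration_rejected(self, video_50fps):
        rows = make_responses([("a", "expert", "v1", 1, 31.0)])
        with pytest.raises(ValidationError):
            agreement.compute_afv(rows, video_50fps)

    def test_within_bin_dedup_counts_unit_once(self):
        video = VideoMeta("v1", "WT", "easy", 10.0, 10.0)
        rows = make_responses(
            [("a", "expert", "v1", 1, 5.0), ("a", "expert", "v1", 1, 5.3)]
        )
        profile = agreement.compute_afv(rows, video)
        assert profile.counts.max() == 1

    @pytest.mark.parametrize("units", ["participant_block", "participant"])
    def test_matches_brute_force_on_random_instances(self, units):
        rng = np.random.default_rng(1234)
        for i in range(25):
            fps = float(rng.integers(10, 51))
            video = VideoMeta("v1", "WT", "easy", float(rng.uniform(5, 30)), fps)
            df = random_response_df(rng, video, int(rng.integers(1, 7)), 0.3)
            got = agreement.compute_afv(df, video, units=units).counts
            np.testing.assert_array_equal(got, brute_force_afv(df, video, units=units))

    def test_counts_capped_by_units_and_conservation(self, video_50fps):
        rng = np.random.default_rng(7)
        df = random_response_df(rng, video_50fps, 5, 0.2)
        profile = agreement.compute_afv(df, video_50fps)
        assert profile.counts.max() <= profile.n_units == 10
        # a lone response away from video edges covers exactly fps*bin frames
        lone = make_responses([("z", "expert", "v1", 1, 14.2)])
        p = agreement.compute_afv(lone, video_50fps)
        assert p.counts.sum() == round(video_50fps.frame_rate_hz * 1.0)


class TestThreshold:
    def test_hand_case(self):
        p = profile_from_counts([0, 0, 2, 2, 2, 8])
        assert p.nonzero_mean == pytest.approx(3.5)
        assert p.nonzero_sd == pytest.approx(3.0)
        assert p.threshold == pytest.approx(9.5)
        assert agreement.detect_boundaries(p).n_bound == 0  # the 8 is sub-threshold

    def test_flat_nonzero_profile_has_no_boundaries(self):
        p = profile_from_counts([3, 3, 3, 3])
        assert p.threshold == pytest.approx(3.0)
        assert agreement.detect_boundaries(p).n_bound == 0

    def test_single_nonzero_bin_undefined(self):
        p = profile_from_counts([0, 5, 0])
        assert math.isnan(p.threshold)
        assert agreement.detect_boundaries(p).n_bound == 0

    def test_matches_independent_sd_routine(self):
        rng = np.random.default_rng(99)
        counts = rng.poisson(3, 500)
        p = profile_from_counts(counts)
        nz = counts[counts > 0]
        assert p.threshold == pytest.approx(
            float(np.mean(nz)) + 2 * float(pd.Series(nz).std())
        )

    def test_sd_over_all_bins_variant(self):
        counts = [0, 0, 2, 2, 2, 8]
        p = profile_from_counts(counts)
        agreement.compute_threshold(p, sd_over_nonzero=False)
        assert p.threshold == pytest.approx(3.5 + 2 * np.std(counts, ddof=1))


class TestBoundaries:
    def test_two_disjoint_runs(self):
        counts = [1] * 23
        counts[5] = counts[6] = 9
        counts[15] = 9  # two supra-threshold runs split by sub-threshold frames
        p = profile_from_counts(counts)
        assert 1 < p.threshold < 9
        bset = agreement.detect_boundaries(p)
        assert bset.n_bound == 2
        assert [(b.start_frame, b.end_frame) for b in bset.boundaries] == [(5, 6), (15, 15)]

    def test_peak_frame_earliest_argmax(self):
        counts = [0] + [1] * 10 + [9, 9, 9] + [1] * 10
        p = profile_from_counts(counts)
        bset = agreement.detect_boundaries(p)
        assert bset.n_bound == 1
        assert bset.boundaries[0].peak_frame == 11  # earliest frame of the tied peak
        assert bset.boundaries[0].peak_afv == 9

    def test_equals_run_length_encoding_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            counts = rng.poisson(2, 200)
            p = profile_from_counts(counts)
            bset = agreement.detect_boundaries(p)
            if math.isnan(p.threshold):
                assert bset.n_bound == 0
                continue
            above = "".join("1" if c > p.threshold else "0" for c in counts)
            n_runs = len([r for r in above.split("0") if r])
            assert bset.n_bound == n_runs

    def test_min_peak_width_filters_subframe_blips(self):
        # at 50 fps a 3-frame (60 ms) excursion is not a discernible peak
        counts = np.ones(300)
        counts[100:103] = 9
        counts[200:220] = 9
        p = profile_from_counts(counts, fps=50.0)
        bset = agreement.detect_boundaries(p, min_peak_width_s=0.2)
        assert [(b.start_frame, b.end_frame) for b in bset.boundaries] == [(200, 219)]
        # coarse profiles (1 frame/s) keep every run
        coarse = [1] * 23
        coarse[5] = coarse[15] = 9
        p1 = profile_from_counts(coarse, fps=1.0)
        assert agreement.detect_boundaries(p1, min_peak_width_s=0.2).n_bound == 2

    def test_invariant_to_participant_and_block_relabeling(self, video_50fps):
        rng = np.random.default_rng(17)
        df = random_response_df(rng, video_50fps, 5, 0.25)
        base = agreement.detect_boundaries(
            agreement.compute_afv(df, video_50fps)
        ).n_bound
        relabeled = df.copy()
        relabeled["participant_id"] = relabeled["participant_id"].map(
            lambda s: "X" + s
        )
        relabeled["block"] = 3 - relabeled["block"]
        again = agreement.detect_boundaries(
            agreement.compute_afv(relabeled, video_50fps)
        ).n_bound
        assert base == again

    def test_frame_rate_doubling_regression(self):
        # quantization robustness: frozen n_bound at 25 and 50 fps on a fixture
        rng = np.random.default_rng(2024)
        rows = []
        for p in range(6):
            for b in (1, 2):
                for t in rng.uniform(0, 30, 8):
                    rows.append((f"p{p}", "expert", "v1", b, float(t)))
        df = make_responses(rows)
        nb = {}
        for fps in (25.0, 50.0):
            video = VideoMeta("v1", "WT", "easy", 30.0, fps)
            nb[fps] = agreement.detect_boundaries(
                agreement.compute_afv(df, video)
            ).n_bound
        assert abs(nb[25.0] - nb[50.0]) <= 1


class TestRefereeOverlap:
    def _boundaries(self, video):
        counts = np.ones(video.n_frames)
        counts[500:560] = 20  # 10.0-11.18 s at 50 fps
        counts[1000:1060] = 20
        p = agreement.AfvProfile("v1", "expert", counts.astype(int), 1.0, 20,
                                 video.frame_rate_hz)
        agreement.compute_threshold(p)
        return agreement.detect_boundaries(p)

    def test_referee_at_peaks_full_overlap(self, video_50fps):
        bset = self._boundaries(video_50fps)
        ref = make_responses(
            [("T4", "expert", "v1", b, t) for b in (1, 2) for t in (10.0, 20.0)]
        )
        ov = agreement.referee_overlap(ref, bset, video_50fps)
        assert ov.overlap_fraction[1] == 1.0
        assert ov.overlap_fraction[2] == 1.0
        assert ov.repetition_rate == 1.0

    def test_referee_far_from_boundaries_zero_overlap(self, video_50fps):
        bset = self._boundaries(video_50fps)
        ref = make_responses([("T4", "expert", "v1", 1, 25.0)])
        ov = agreement.referee_overlap(ref, bset, video_50fps)
        assert ov.overlap_fraction[1] == 0.0
        assert math.isnan(ov.overlap_fraction[2])
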