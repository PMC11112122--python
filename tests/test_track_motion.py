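"""Track classification: movement flags, segmentation, per-track metrics,
per-axon aggregation. The segmentation rules are checked against an
independent brute-force enumerator."""

import numpy as np
import pytest

from axotraffic.errors import InputError
from axotraffic.track_motion import (
    AxonRecord,
    TrackMotionConfig,
    binarize_motion,
    classify_cohort,
    classify_track,
    segment_states,
    segments_to_interval_labels,
    summarize_axon,
)

from conftest import make_track, random_integer_track


def oracle_segments(flags, signs, min_run, min_pause):
    """Brute-force enumerator of the written segmentation rules:
    maximal constant-flag blocks, moving blocks split at sign reversals,
    5-frame cutoffs for runs and pauses, the rest oscillation."""
    out = []
    n = len(flags)
    i = 0
    while i < n:
        j = i
        while j < n and flags[j] == flags[i]:
            j += 1
        if flags[i]:
            k = i
            while k < j:
                l = k
                while l < j and signs[l] == signs[k]:
                    l += 1
                if l - k >= min_run:
                    out.append(("run", int(signs[k]), k, l))
                else:
                    out.append(("oscillation", 0, k, l))
                k = l
        else:
            if j - i >= min_pause:
                out.append(("pause", 0, i, j))
            else:
                out.append(("oscillation", 0, i, j))
        i = j
    return out


def as_tuples(segments, cfg):
    out = []
    for s in segments:
        if s.state == "run":
            sign = cfg.anterograde_sign if s.direction == "anterograde" else -cfg.anterograde_sign
        else:
            sign = 0
        out.append((s.state, sign, s.start_frame, s.end_frame))
    return out


class TestBinarize:
    def test_constant_track_has_no_movement(self, cfg):
        flags, signs = binarize_motion(make_track([5.0] * 180), cfg)
        assert len(flags) == 179 and not flags.any() and not signs.any()

    def test_monotone_track_all_moving_positive(self, cfg):
        flags, signs = binarize_motion(make_track(np.arange(21.0)), cfg)
        assert flags.all() and (signs == 1).all() and len(flags) == 20

    def test_matches_elementwise_comparison(self, cfg):
        rng = np.random.default_rng(7)
        for _ in range(50):
            t = random_integer_track(rng, 40)
            flags, signs = binarize_motion(t, cfg)
            dx = np.diff(t.x_px)
            assert np.array_equal(flags, np.abs(dx) > 0.5)
            assert np.array_equal(signs, np.where(np.abs(dx) > 0.5, np.sign(dx), 0))

    def test_noncontiguous_frames_rejected(self, cfg):
        t = make_track(np.arange(25.0))
        object.__setattr__(t, "frames", np.concatenate([t.frames[:10], t.frames[10:] + 5]))
        with pytest.raises(InputError, match="contiguous"):
            binarize_motion(t, cfg)


class TestSegmentation:
    def test_short_move_then_long_dwell(self, cfg):
        flags = np.array([True] * 4 + [False] * 10)
        signs = np.array([1] * 4 + [0] * 10)
        segs = segment_states(flags, signs, cfg)
        assert [(s.state, s.n_intervals) for s in segs] == [("oscillation", 4), ("pause", 10)]

    def test_long_unidirectional_movement_is_one_run(self, cfg):
        flags = np.ones(20, bool)
        signs = np.ones(20, int)
        segs = segment_states(flags, signs, cfg)
        assert len(segs) == 1
        (s,) = segs
        assert s.state == "run" and s.direction == "anterograde" and s.n_intervals == 20

    def test_equals_bruteforce_on_random_sequences(self, cfg):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 60))
            signs = rng.choice([-1, 0, 0, 1], size=n)
            flags = signs != 0
            got = as_tuples(segment_states(flags, signs, cfg), cfg)
            assert got == oracle_segments(flags, signs, cfg.min_run_frames, cfg.min_pause_frames)

    def test_tiling_no_gaps_no_overlaps(self, cfg):
        rng = np.random.default_rng(13)
        for _ in range(200):
            t = random_integer_track(rng, int(rng.integers(20, 80)))
            m = classify_track(t, cfg)
            spans = sorted((s.start_frame, s.end_frame) for s in m.segments)
            assert spans[0][0] == 0 and spans[-1][1] == t.n_frames - 1
            assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))
            assert sum(s.n_intervals for s in m.segments) == t.n_frames - 1


class TestClassifyTrack:
    def test_steady_run_distance_and_speed(self, cfg):
        # +1 px/frame for 20 frames at 0.175 um/px and 1 s/frame
        m = classify_track(make_track(np.arange(21.0)), cfg)
        assert not m.is_stationary
        assert m.n_runs_antero == 1 and m.n_runs_retro == 0
        assert m.mean_run_distance_antero_um == pytest.approx(3.5)
        assert m.mean_speed_antero_um_s == pytest.approx(0.175)

    def test_net_threshold_is_0875_um(self, cfg):
        assert cfg.net_disp_threshold_um == pytest.approx(0.875)

    def test_mobile_below_net_threshold_is_none(self, cfg):
        # a 9-frame run out (+9 px) and a 5-frame run back (-5 px): net +4 px
        x = np.concatenate([np.arange(10.0), np.arange(8.0, 3.0, -1.0), [4.0] * 10])
        m = classify_track(make_track(x), cfg)
        assert not m.is_stationary
        assert m.net_displacement_um == pytest.approx(4 * 0.175)
        assert m.net_direction == "none"

    def test_net_direction_at_threshold(self, cfg):
        x = np.concatenate([np.arange(6.0), [5.0] * 15])  # +5 px exactly
        m = classify_track(make_track(x), cfg)
        assert m.net_direction == "anterograde"

    def test_stationary_track(self, cfg):
        m = classify_track(make_track([3.0] * 30), cfg)
        assert m.is_stationary and m.pause_durations_s == [] and m.net_direction == "none"

    def test_short_track_rejected(self, cfg):
        with pytest.raises(InputError, match="minimum"):
            classify_track(make_track(np.arange(10.0)), cfg)

    def test_mirroring_swaps_directions(self, cfg):
        rng = np.random.default_rng(17)
        for _ in range(100):
            t = random_integer_track(rng, 60)
            m = classify_track(t, cfg)
            mm = classify_track(make_track(-t.x_px), cfg)
            assert (m.n_runs_antero, m.n_runs_retro) == (mm.n_runs_retro, mm.n_runs_antero)
            assert mm.net_displacement_um == pytest.approx(-m.net_displacement_um)
            assert mm.mean_speed_antero_um_s == pytest.approx(m.mean_speed_retro_um_s, nan_ok=True)
            assert mm.mean_run_distance_antero_um == pytest.approx(m.mean_run_distance_retro_um, nan_ok=True)
            assert m.pause_durations_s == mm.pause_durations_s

    def test_anterograde_sign_flip_relabels(self, cfg):
        t = make_track(np.arange(21.0))
        m_plus = classify_track(t, cfg)
        m_minus = classify_track(t, TrackMotionConfig(anterograde_sign=-1))
        assert m_plus.n_runs_antero == 1 and m_minus.n_runs_retro == 1
        assert m_minus.net_displacement_um == pytest.approx(-m_plus.net_displacement_um)


class TestAxonAggregation:
    def test_pct_stationary(self, cfg):
        tracks = [make_track([0.0] * 25, track_id=f"s{i}") for i in range(4)] + [
            make_track(np.arange(25.0), track_id=f"m{i}") for i in range(6)
        ]
        metrics = [classify_track(t, cfg) for t in tracks]
        s = summarize_axon(metrics, kymo_length_um=35.0, cfg=cfg)
        assert s.pct_stationary == pytest.approx(40.0)

    def test_vesicle_density(self, cfg):
        metrics = [classify_track(make_track([0.0] * 25, track_id=f"t{i}"), cfg) for i in range(7)]
        s = summarize_axon(metrics, kymo_length_um=35.0, cfg=cfg)
        assert s.vesicles_per_10um == pytest.approx(2.0)

    def test_empty_axon_flagged(self, cfg):
        s = summarize_axon([], kymo_length_um=30.0, cfg=cfg, axon_id="empty")
        assert s.n_tracks == 0 and np.isnan(s.pct_stationary)

    def test_cohort_is_order_invariant(self, cfg):
        rng = np.random.default_rng(23)
        recs = []
        for i in range(5):
            tracks = tuple(
                random_integer_track(rng, 40) for _ in range(6)
            )
            tracks = tuple(
                type(t)(track_id=f"t{j}", frames=t.frames, x_px=t.x_px, axon_id=f"a{i}")
                for j, t in enumerate(tracks)
            )
            recs.append(AxonRecord(axon_id=f"a{i}", tracks=tracks, kymo_length_um=50.0))
        fwd, _ = classify_cohort(recs, cfg)
        rev, _ = classify_cohort(list(reversed(recs)), cfg)
        assert fwd.equals(rev)

    def test_cohort_empty(self, cfg):
        table, rej = classify_cohort([], cfg)
        assert table.empty and rej == []

    def test_cohort_matches_summarize(self, cfg):
        tracks = tuple(
            make_track(np.arange(30.0) + i, track_id=f"t{i}", axon_id="ax") for i in range(3)
        )
        table, _ = classify_cohort([AxonRecord("ax", tracks, 40.0)], cfg)
        direct = summarize_axon([classify_track(t, cfg) for t in tracks], 40.0, cfg, axon_id="ax")
        assert table.loc[0, "mean_speed_antero_um_s"] == pytest.approx(direct.mean_speed_antero_um_s)
        assert table.loc[0, "vesicles_per_10um"] == pytest.approx(direct.vesicles_per_10um)


def test_interval_labels_tile(cfg):
    rng = np.random.default_rng(29)
    t = random_integer_track(rng, 50)
    m = classify_track(t, cfg)
    labels = segments_to_interval_labels(m.segments, t.n_frames - 1)
    assert len(labels) == 49
    assert set(labels) <= {"run-antero", "run-retro", "pause", "oscillation"}
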