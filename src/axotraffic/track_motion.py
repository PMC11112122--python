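"""Run/pause/oscillation classification of kymograph particle tracks.

A track is an ordered list of (frame, x) positions of one organelle along an
axon. Movement is scored between consecutive frames: an interval counts as
"movement" when the x coordinate changes by more than ``movement_eps_px``
(0.5 px, so integer-pixel tracker output reproduces an exact changed /
stayed-the-same test while tolerating sub-pixel floats). Maximal blocks of
moving intervals are split at displacement-sign reversals; moving blocks of
at least ``min_run_frames`` intervals in a single direction are *runs*,
non-moving blocks of at least ``min_pause_frames`` intervals are *pauses*,
and everything below those cutoffs is *oscillation*. A track with no runs is
completely *stationary*. Runs carry a distance (sum of |dx| converted to um)
and a mean speed; pauses carry durations and are only reported for mobile
tracks. Net displacement (end minus start) is classified anterograde or
retrograde only for mobile tracks moving at least ``net_disp_threshold_px``
pixels (5 px = 0.875 um at the default 0.175 um/px calibration).

Per-axon aggregation averages over the tracks of one axon; group-level
statistics (with n = axons) live in :mod:`axotraffic.stats`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, ParameterError

__all__ = [
    "TrackMotionConfig",
    "Track",
    "Segment",
    "TrackMetrics",
    "AxonSummary",
    "AxonRecord",
    "binarize_motion",
    "segment_states",
    "classify_track",
    "summarize_axon",
    "classify_cohort",
    "segments_to_interval_labels",
    "DEFAULT_PIXEL_SIZE_UM",
    "DEFAULT_FRAME_INTERVAL_S",
    "DEFAULT_MIN_RUN_FRAMES",
    "DEFAULT_MIN_PAUSE_FRAMES",
]

DEFAULT_PIXEL_SIZE_UM = 0.175
DEFAULT_FRAME_INTERVAL_S = 1.0
DEFAULT_MIN_RUN_FRAMES = 5
DEFAULT_MIN_PAUSE_FRAMES = 5


@dataclass(frozen=True)
class TrackMotionConfig:
    """Calibration and cutoffs for track classification.

    ``anterograde_sign`` maps the sign of increasing x (arc-length
    coordinate of the kymograph) onto transport direction: +1 means
    increasing x points away from the soma.
    """

    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    min_run_frames: int = DEFAULT_MIN_RUN_FRAMES
    min_pause_frames: int = DEFAULT_MIN_PAUSE_FRAMES
    net_disp_threshold_px: float = 5.0
    movement_eps_px: float = 0.5
    min_track_frames: int = 20
    anterograde_sign: int = 1
    # "unweighted": per-track speed = mean of per-run mean speeds;
    # "duration_weighted": total run distance / total run time.
    speed_average: Literal["unweighted", "duration_weighted"] = "unweighted"

    def __post_init__(self) -> None:
        if self.min_run_frames < 1 or self.min_pause_frames < 1:
            raise ParameterError("run/pause cutoffs must be >= 1 frame")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ParameterError("calibration must be positive")
        if self.anterograde_sign not in (-1, 1):
            raise ParameterError("anterograde_sign must be +1 or -1")

    @property
    def net_disp_threshold_um(self) -> float:
        return self.net_disp_threshold_px * self.pixel_size_um


@dataclass(frozen=True)
class Track:
    """Ordered (frame, x_px) samples for one organelle on one axon."""

    track_id: str
    frames: np.ndarray  # int, strictly increasing, contiguous
    x_px: np.ndarray
    axon_id: str = ""

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=np.int64)
        x = np.asarray(self.x_px, dtype=np.float64)
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "x_px", x)
        if frames.ndim != 1 or frames.shape != x.shape:
            raise InputError(f"track {self.track_id}: frames/x shape mismatch")
        if len(frames) < 2:
            raise InputError(f"track {self.track_id}: needs >= 2 samples")
        if np.any(np.diff(frames) <= 0):
            raise InputError(f"track {self.track_id}: frames must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class Segment:
    """A classified interval of one track.

    ``start_frame``/``end_frame`` are frame indices; the segment covers the
    ``end_frame - start_frame`` inter-frame intervals between them.
    """

    state: Literal["run", "pause", "oscillation"]
    direction: Literal["anterograde", "retrograde", "none"]
    start_frame: int
    end_frame: int
    duration_s: float
    distance_um: float | None = None  # runs only
    mean_speed_um_s: float | None = None  # runs only

    @property
    def n_intervals(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class TrackMetrics:
    """Per-track classification result."""

    track_id: str
    axon_id: str
    is_stationary: bool
    segments: list[Segment]
    n_runs_antero: int
    n_runs_retro: int
    mean_run_distance_antero_um: float
    mean_run_distance_retro_um: float
    mean_speed_antero_um_s: float
    mean_speed_retro_um_s: float
    pause_durations_s: list[float]
    net_displacement_um: float
    net_direction: Literal["anterograde", "retrograde", "none"]


@dataclass
class AxonSummary:
    """Per-axon aggregates over its accepted tracks."""

    axon_id: str
    n_tracks: int
    kymo_length_um: float
    vesicles_per_10um: float
    pct_stationary: float
    mean_pause_s: float
    mean_net_displacement_um: float
    mean_speed_antero_um_s: float
    median_speed_antero_um_s: float
    mean_speed_retro_um_s: float
    median_speed_retro_um_s: float
    mean_run_distance_antero_um: float
    median_run_distance_antero_um: float
    mean_run_distance_retro_um: float
    median_run_distance_retro_um: float
    n_net_antero: int
    n_net_retro: int
    n_net_none: int
    pct_net_antero: float
    pct_net_retro: float
    pct_net_none: float


@dataclass(frozen=True)
class AxonRecord:
    """One axon's tracks plus the kymograph metadata needed to aggregate."""

    axon_id: str
    tracks: tuple[Track, ...]
    kymo_length_um: float


def binarize_motion(track: Track, cfg: TrackMotionConfig) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval movement flags and displacement signs.

    Returns ``(flags, signs)`` of length ``n_frames - 1``: ``flags[i]`` is
    True iff ``|x[i+1] - x[i]| > movement_eps_px``; ``signs[i]`` is the sign
    of the displacement (0 for non-moving intervals).
    """
    if np.any(np.diff(track.frames) != 1):
        raise InputError(
            f"track {track.track_id}: frames must be contiguous (gap-filling would bias pause statistics)"
        )
    dx = np.diff(track.x_px)
    flags = np.abs(dx) > cfg.movement_eps_px
    signs = np.where(flags, np.sign(dx).astype(np.int64), 0)
    return flags, signs


def _maximal_blocks(values: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of maximal constant-value blocks."""
    n = len(values)
    if n == 0:
        return []
    changes = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], changes))
    ends = np.concatenate((changes, [n]))
    return list(zip(starts.tolist(), ends.tolist()))


def _direction(sign: int, cfg: TrackMotionConfig) -> str:
    return "anterograde" if sign * cfg.anterograde_sign > 0 else "retrograde"


def segment_states(
    flags: np.ndarray, signs: np.ndarray, cfg: TrackMotionConfig
) -> list[Segment]:
    """Tile the track's intervals into run / pause / oscillation segments.

    Maximal moving blocks are first split at displacement-sign reversals so
    every run has a single direction; the resulting moving (sub)blocks of
    >= ``min_run_frames`` intervals become runs, non-moving blocks of
    >= ``min_pause_frames`` become pauses, and all remaining blocks become
    oscillation. Distances and speeds are filled in by ``classify_track``.
    """
    segments: list[Segment] = []
    dt = cfg.frame_interval_s
    for start, end in _maximal_blocks(flags):
        if flags[start]:
            # moving: split at sign reversals
            for s2, e2 in _maximal_blocks(signs[start:end]):
                a, b = start + s2, start + e2
                sign = int(signs[a])
                if b - a >= cfg.min_run_frames:
                    segments.append(
                        Segment("run", _direction(sign, cfg), a, b, (b - a) * dt)
                    )
                else:
                    segments.append(Segment("oscillation", "none", a, b, (b - a) * dt))
        else:
            if end - start >= cfg.min_pause_frames:
                segments.append(Segment("pause", "none", start, end, (end - start) * dt))
            else:
                segments.append(Segment("oscillation", "none", start, end, (end - start) * dt))
    return segments


def segments_to_interval_labels(segments: Sequence[Segment], n_intervals: int) -> np.ndarray:
    """Expand a segment list into one label per inter-frame interval.

    Labels are ``run-antero``, ``run-retro``, ``pause`` or ``oscillation``,
    the same vocabulary the synthetic ground truth uses.
    """
    labels = np.empty(n_intervals, dtype=object)
    for seg in segments:
        if seg.state == "run":
            lab = "run-antero" if seg.direction == "anterograde" else "run-retro"
        else:
            lab = seg.state
        labels[seg.start_frame : seg.end_frame] = lab
    if any(l is None for l in labels):
        raise AssertionError("segments do not tile the track")
    return labels


def classify_track(track: Track, cfg: TrackMotionConfig) -> TrackMetrics:
    """Classify one track and compute its per-track statistics.

    Raises :class:`InputError` for tracks shorter than ``min_track_frames``
    (the tracker's own minimum); ``classify_cohort`` catches and logs these.
    """
    if track.n_frames < cfg.min_track_frames:
        raise InputError(
            f"track {track.track_id}: {track.n_frames} frames < minimum {cfg.min_track_frames}"
        )
    flags, signs = binarize_motion(track, cfg)
    segments = segment_states(flags, signs, cfg)

    px, dt = cfg.pixel_size_um, cfg.frame_interval_s
    dx = np.diff(track.x_px)
    out: list[Segment] = []
    for seg in segments:
        if seg.state == "run":
            dist = float(np.sum(np.abs(dx[seg.start_frame : seg.end_frame]))) * px
            out.append(
                replace(seg, distance_um=dist, mean_speed_um_s=dist / seg.duration_s)
            )
        else:
            out.append(seg)
    segments = out

    runs = [s for s in segments if s.state == "run"]
    is_stationary = len(runs) == 0
    antero = [s for s in runs if s.direction == "anterograde"]
    retro = [s for s in runs if s.direction == "retrograde"]

    def _mean_dist(rr: list[Segment]) -> float:
        return float(np.mean([s.distance_um for s in rr])) if rr else float("nan")

    def _mean_speed(rr: list[Segment]) -> float:
        if not rr:
            return float("nan")
        if cfg.speed_average == "duration_weighted":
            return float(sum(s.distance_um for s in rr) / sum(s.duration_s for s in rr))
        return float(np.mean([s.mean_speed_um_s for s in rr]))

    pauses = (
        [] if is_stationary else [s.duration_s for s in segments if s.state == "pause"]
    )

    net_px = float(track.x_px[-1] - track.x_px[0])
    net_um = net_px * px * cfg.anterograde_sign
    if is_stationary or abs(net_px) < cfg.net_disp_threshold_px:
        net_direction = "none"
    else:
        net_direction = _direction(int(np.sign(net_px)), cfg)

    return TrackMetrics(
        track_id=track.track_id,
        axon_id=track.axon_id,
        is_stationary=is_stationary,
        segments=segments,
        n_runs_antero=len(antero),
        n_runs_retro=len(retro),
        mean_run_distance_antero_um=_mean_dist(antero),
        mean_run_distance_retro_um=_mean_dist(retro),
        mean_speed_antero_um_s=_mean_speed(antero),
        mean_speed_retro_um_s=_mean_speed(retro),
        pause_durations_s=pauses,
        net_displacement_um=net_um,
        net_direction=net_direction,
    )


def _nanmean(values: list[float]) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.mean(vals)) if vals else float("nan")


def _nanmedian(values: list[float]) -> float:
    vals = [v for v in values if not np.isnan(v)]
    return float(np.median(vals)) if vals else float("nan")


def summarize_axon(
    metrics: Sequence[TrackMetrics], kymo_length_um: float, cfg: TrackMotionConfig, axon_id: str = ""
) -> AxonSummary:
    """Aggregate one axon's track metrics.

    Directional speed/distance aggregates average the per-track means over
    tracks that have runs in that direction; the pause aggregate averages
    per-track mean pause durations over mobile tracks with pauses. Mobile
    tracks alone enter the net-displacement class percentages.
    """
    if kymo_length_um <= 0:
        raise ParameterError("kymo_length_um must be positive")
    n = len(metrics)
    if n == 0:
        return AxonSummary(
            axon_id=axon_id, n_tracks=0, kymo_length_um=kymo_length_um,
            vesicles_per_10um=0.0, pct_stationary=float("nan"),
            mean_pause_s=float("nan"), mean_net_displacement_um=float("nan"),
            mean_speed_antero_um_s=float("nan"), median_speed_antero_um_s=float("nan"),
            mean_speed_retro_um_s=float("nan"), median_speed_retro_um_s=float("nan"),
            mean_run_distance_antero_um=float("nan"), median_run_distance_antero_um=float("nan"),
            mean_run_distance_retro_um=float("nan"), median_run_distance_retro_um=float("nan"),
            n_net_antero=0, n_net_retro=0, n_net_none=0,
            pct_net_antero=float("nan"), pct_net_retro=float("nan"), pct_net_none=float("nan"),
        )
    if not axon_id:
        axon_id = metrics[0].axon_id
    mobile = [m for m in metrics if not m.is_stationary]
    pause_means = [float(np.mean(m.pause_durations_s)) for m in mobile if m.pause_durations_s]
    net_counts = {"anterograde": 0, "retrograde": 0, "none": 0}
    for m in mobile:
        net_counts[m.net_direction] += 1
    n_mobile = len(mobile)
    sp_a = [m.mean_speed_antero_um_s for m in metrics]
    sp_r = [m.mean_speed_retro_um_s for m in metrics]
    rd_a = [m.mean_run_distance_antero_um for m in metrics]
    rd_r = [m.mean_run_distance_retro_um for m in metrics]
    return AxonSummary(
        axon_id=axon_id,
        n_tracks=n,
        kymo_length_um=kymo_length_um,
        vesicles_per_10um=n / kymo_length_um * 10.0,
        pct_stationary=100.0 * sum(m.is_stationary for m in metrics) / n,
        mean_pause_s=_nanmean(pause_means),
        mean_net_displacement_um=_nanmean([m.net_displacement_um for m in mobile]),
        mean_speed_antero_um_s=_nanmean(sp_a),
        median_speed_antero_um_s=_nanmedian(sp_a),
        mean_speed_retro_um_s=_nanmean(sp_r),
        median_speed_retro_um_s=_nanmedian(sp_r),
        mean_run_distance_antero_um=_nanmean(rd_a),
        median_run_distance_antero_um=_nanmedian(rd_a),
        mean_run_distance_retro_um=_nanmean(rd_r),
        median_run_distance_retro_um=_nanmedian(rd_r),
        n_net_antero=net_counts["anterograde"],
        n_net_retro=net_counts["retrograde"],
        n_net_none=net_counts["none"],
        pct_net_antero=100.0 * net_counts["anterograde"] / n_mobile if n_mobile else float("nan"),
        pct_net_retro=100.0 * net_counts["retrograde"] / n_mobile if n_mobile else float("nan"),
        pct_net_none=100.0 * net_counts["none"] / n_mobile if n_mobile else float("nan"),
    )


def classify_cohort(
    axons: Iterable[AxonRecord], cfg: TrackMotionConfig
) -> tuple[pd.DataFrame, list[dict]]:
    """Classify every axon's tracks and tabulate per-axon summaries.

    Returns ``(table, rejections)``: one row per axon sorted by axon_id, and
    a log of tracks rejected (too short / malformed) with reasons. Output is
    independent of input ordering.
    """
    rows = []
    rejections: list[dict] = []
    for rec in sorted(axons, key=lambda r: r.axon_id):
        accepted: list[TrackMetrics] = []
        for track in rec.tracks:
            try:
                accepted.append(classify_track(track, cfg))
            except InputError as exc:
                rejections.append(
                    {"axon_id": rec.axon_id, "track_id": track.track_id, "reason": str(exc)}
                )
        summary = summarize_axon(accepted, rec.kymo_length_um, cfg, axon_id=rec.axon_id)
        rows.append(vars(summary))
    table = pd.DataFrame(rows)
    if not table.empty:
        table = table.sort_values("axon_id").reset_index(drop=True)
    return table, rejections
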