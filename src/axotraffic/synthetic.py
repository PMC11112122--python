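"""Synthetic counterparts of the study's microscopy data, with ground truth.

Everything the real experiments obtained by imaging is emulated here so the
full pipeline can be exercised offline against known generative parameters:

* endolysosome tracks on a kymograph (state-switching run/pause/oscillation
  model at 0.175 um/px and 1 s/frame over 180 frames),
* rendered kymograph images (Gaussian bumps plus noise),
* periodic membrane-skeleton (MPS) intensity profiles (~190 nm lattice at
  30 nm/px),
* STED-like AIS images bearing F-actin patches,
* plateau-shaped AIS marker intensity profiles (AnkG/TRIM46-like),
* linearly coupled two-channel particle intensity tables.

The default trafficking preset (`wt_preset`) encodes the wild-type medians
reported for cultured hippocampal neurons — 56% stationary organelles,
16.4 s median pause, anterograde runs of 5.88 um at 0.43 um/s, retrograde
runs of 8.71 um at 0.48 um/s — as the medians of log-normal generative
distributions, so round-trip recovery by the classifier is testable.

Every generator is deterministic given its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import BoundsError, ParameterError
from .kymograph import Kymograph
from .track_motion import (
    DEFAULT_FRAME_INTERVAL_S,
    DEFAULT_MIN_PAUSE_FRAMES,
    DEFAULT_MIN_RUN_FRAMES,
    DEFAULT_PIXEL_SIZE_UM,
    Track,
)

__all__ = [
    "LogNormalSpec",
    "MotionModelParams",
    "TrackTruth",
    "GroundTruth",
    "KymographRenderParams",
    "wt_preset",
    "svbp_ko_preset",
    "ttl_ko_preset",
    "simulate_tracks",
    "render_kymograph",
    "simulate_mps_profile",
    "simulate_ais_image",
    "simulate_ais_marker_profile",
    "simulate_coloc_table",
]


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal distribution parameterized by its median and log-sd.

    The paper-style presets put the reported median here directly; sigma
    (dimensionless log-sd, default 0.25) sets the within-genotype spread.
    """

    median: float
    sigma: float = 0.25

    def __post_init__(self) -> None:
        if self.median <= 0:
            raise ParameterError("distribution median must be > 0")
        if self.sigma < 0:
            raise ParameterError("sigma must be >= 0")

    def sample(self, rng: np.random.Generator) -> float:
        return float(self.median * np.exp(self.sigma * rng.standard_normal()))


@dataclass(frozen=True)
class MotionModelParams:
    """Generative parameters for the organelle trafficking simulator."""

    n_particles: int
    p_stationary: float
    run_length_um: Mapping[str, LogNormalSpec]
    run_speed_um_s: Mapping[str, LogNormalSpec]
    pause_duration_s: LogNormalSpec
    p_retrograde_run: float
    oscillation_rate: float = 1.0
    n_frames: int = 180
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_stationary, self.p_retrograde_run):
            if not 0.0 <= p <= 1.0:
                raise ParameterError("probabilities must lie in [0, 1]")
        if self.n_particles < 0:
            raise ParameterError("n_particles must be >= 0")
        if self.n_frames < 20:
            raise ParameterError("n_frames must be >= 20")
        if self.oscillation_rate < 0:
            raise ParameterError("oscillation_rate must be >= 0")
        for key in ("anterograde", "retrograde"):
            if key not in self.run_length_um or key not in self.run_speed_um_s:
                raise ParameterError(f"missing '{key}' distribution spec")


@dataclass
class TrackTruth:
    """Per-track ground truth emitted alongside the simulated positions."""

    track_id: str
    states: np.ndarray  # (n_frames-1,) labels: run-antero|run-retro|pause|oscillation
    runs: list[dict]  # direction, distance_um, speed_um_s, n_intervals
    pauses_s: list[float]
    stationary: bool


@dataclass
class GroundTruth:
    tracks: dict[str, TrackTruth] = field(default_factory=dict)


@dataclass(frozen=True)
class KymographRenderParams:
    """Rendering parameters for turning tracks into a kymograph image."""

    psf_sigma_px: float = 1.2
    particle_amplitude: float = 1000.0
    background: float = 100.0
    noise_sigma: float = 0.0
    space_px: int = 512
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ParameterError("noise_sigma must be >= 0")
        if self.space_px < 1:
            raise ParameterError("space_px must be >= 1")


def wt_preset(n_particles: int = 20, seed: int = 0, n_frames: int = 180) -> MotionModelParams:
    """Wild-type trafficking preset (reported cohort medians as generative medians)."""
    return MotionModelParams(
        n_particles=n_particles,
        p_stationary=0.56,
        run_length_um={"anterograde": LogNormalSpec(5.88), "retrograde": LogNormalSpec(8.71)},
        run_speed_um_s={"anterograde": LogNormalSpec(0.43), "retrograde": LogNormalSpec(0.48)},
        pause_duration_s=LogNormalSpec(16.4),
        p_retrograde_run=0.55,
        oscillation_rate=1.0,
        n_frames=n_frames,
        seed=seed,
    )


def svbp_ko_preset(n_particles: int = 20, seed: int = 0, n_frames: int = 180) -> MotionModelParams:
    """SVBP-knockout-like preset (more stationary, longer pauses, short slow retro runs)."""
    return MotionModelParams(
        n_particles=n_particles,
        p_stationary=0.61,
        run_length_um={"anterograde": LogNormalSpec(5.88), "retrograde": LogNormalSpec(6.11)},
        run_speed_um_s={"anterograde": LogNormalSpec(0.43), "retrograde": LogNormalSpec(0.43)},
        pause_duration_s=LogNormalSpec(19.5),
        p_retrograde_run=0.45,
        oscillation_rate=1.0,
        n_frames=n_frames,
        seed=seed,
    )


def ttl_ko_preset(n_particles: int = 20, seed: int = 0, n_frames: int = 180) -> MotionModelParams:
    """TTL-knockout-like preset (most stationary, short retrograde runs)."""
    return MotionModelParams(
        n_particles=n_particles,
        p_stationary=0.69,
        run_length_um={"anterograde": LogNormalSpec(5.88), "retrograde": LogNormalSpec(6.14)},
        run_speed_um_s={"anterograde": LogNormalSpec(0.43), "retrograde": LogNormalSpec(0.48)},
        pause_duration_s=LogNormalSpec(16.7),
        p_retrograde_run=0.55,
        oscillation_rate=1.0,
        n_frames=n_frames,
        seed=seed,
    )


def _sample_run(rng: np.random.Generator, p: MotionModelParams, direction: str) -> tuple[float, int]:
    """Draw (speed um/s, duration frames) for one run; enforces the detection floor.

    Speeds are resampled until they move at least one pixel per frame (so the
    rounded track changes every frame of the run) and lengths until the run
    lasts at least the classifier's minimum run duration.
    """
    dt, px = p.frame_interval_s, p.pixel_size_um
    v_floor = px / dt
    for _ in range(1000):
        v = p.run_speed_um_s[direction].sample(rng)
        if v >= v_floor:
            break
    else:
        raise ParameterError(f"run speed spec for {direction} cannot reach {v_floor} um/s")
    for _ in range(1000):
        length = p.run_length_um[direction].sample(rng)
        n = int(round(length / (v * dt)))
        if n >= DEFAULT_MIN_RUN_FRAMES:
            return v, n
    raise ParameterError(f"run length spec for {direction} cannot reach {DEFAULT_MIN_RUN_FRAMES} frames")


def _sample_pause(rng: np.random.Generator, p: MotionModelParams) -> int:
    for _ in range(1000):
        d = p.pause_duration_s.sample(rng)
        if d >= DEFAULT_MIN_PAUSE_FRAMES * p.frame_interval_s:
            return max(DEFAULT_MIN_PAUSE_FRAMES, int(round(d / p.frame_interval_s)))
    raise ParameterError("pause duration spec cannot reach the 5 s support floor")


def _mobile_blocks(rng: np.random.Generator, p: MotionModelParams, n_intervals: int) -> list[dict]:
    """Alternating pause/run block sequence, with optional jitter episodes.

    Oscillation episodes (1-4 frames of alternating +-1 px jitter) are only
    inserted immediately before a run, ending with the sign opposite to the
    run's, so ground-truth labels coincide with the classifier's rules even
    where a jitter episode touches a run.
    """
    # expected blocks per track, used to convert the episode rate to a
    # per-run insertion probability
    exp_run = p.run_length_um["retrograde"].median / (
        p.run_speed_um_s["retrograde"].median * p.frame_interval_s
    )
    exp_pause = p.pause_duration_s.median / p.frame_interval_s
    exp_runs = max(1.0, n_intervals / (exp_run + exp_pause))
    p_osc = min(1.0, p.oscillation_rate / exp_runs)

    blocks: list[dict] = []
    total = 0
    next_is_run = bool(rng.random() < 0.5)
    while total < n_intervals:
        if next_is_run:
            direction = "retrograde" if rng.random() < p.p_retrograde_run else "anterograde"
            sign = -1 if direction == "retrograde" else 1
            if rng.random() < p_osc:
                k = int(rng.integers(1, 5))
                blocks.append({"kind": "osc", "n": k, "end_sign": -sign})
                total += k
            v, n = _sample_run(rng, p, direction)
            blocks.append({"kind": "run", "n": n, "sign": sign, "v": v})
            total += n
        else:
            n = _sample_pause(rng, p)
            blocks.append({"kind": "pause", "n": n})
            total += n
        next_is_run = not next_is_run
    # truncate to the imaging window, as a finite movie would
    out: list[dict] = []
    remaining = n_intervals
    for b in blocks:
        if remaining == 0:
            break
        n = min(b["n"], remaining)
        out.append({**b, "n": n})
        remaining -= n
    return out


def _realize_track(
    rng: np.random.Generator, p: MotionModelParams, blocks: list[dict], track_id: str
) -> tuple[Track, TrackTruth]:
    dt, px = p.frame_interval_s, p.pixel_size_um
    x = [float(rng.uniform(50.0, 450.0))]
    states: list[str] = []
    runs: list[dict] = []
    pauses: list[float] = []
    for b in blocks:
        n = b["n"]
        if b["kind"] == "pause":
            x.extend([x[-1]] * n)
            # a pause cut below the cutoff by the window end reads as oscillation
            lab = "pause" if n >= DEFAULT_MIN_PAUSE_FRAMES else "oscillation"
            states.extend([lab] * n)
            if lab == "pause":
                pauses.append(n * dt)
        elif b["kind"] == "run":
            step = b["sign"] * b["v"] * dt / px  # px per frame, |step| >= 1
            for _ in range(n):
                x.append(x[-1] + step)
            if n >= DEFAULT_MIN_RUN_FRAMES:
                direction = "anterograde" if b["sign"] > 0 else "retrograde"
                states.extend([f"run-{'antero' if b['sign'] > 0 else 'retro'}"] * n)
                runs.append(
                    {
                        "direction": direction,
                        "distance_um": n * b["v"] * dt,
                        "speed_um_s": b["v"],
                        "n_intervals": n,
                    }
                )
            else:
                states.extend(["oscillation"] * n)
        else:  # oscillation episode: alternating +-1 px, fixed end sign
            end_sign = b["end_sign"]
            deltas = [end_sign * (1 if (n - 1 - i) % 2 == 0 else -1) for i in range(n)]
            for d in deltas:
                x.append(x[-1] + d)
            states.extend(["oscillation"] * n)
    xr = np.round(np.asarray(x))
    frames = np.arange(p.n_frames, dtype=np.int64)
    track = Track(track_id=track_id, frames=frames, x_px=xr)
    truth = TrackTruth(
        track_id=track_id,
        states=np.asarray(states, dtype=object),
        runs=runs,
        pauses_s=pauses,
        stationary=len(runs) == 0,
    )
    return track, truth


def simulate_tracks(params: MotionModelParams) -> tuple[list[Track], GroundTruth]:
    """Simulate organelle tracks on the integer pixel grid, with ground truth.

    Stationary particles (probability ``p_stationary``) keep a constant
    position. Mobile particles alternate runs and pauses drawn from the
    per-direction distribution specs, with optional sub-cutoff jitter
    episodes. Positions are simulated continuously and rounded to integer
    pixels, matching what a kymograph tracker emits.
    """
    rng = np.random.default_rng(params.seed)
    tracks: list[Track] = []
    truth = GroundTruth()
    n_int = params.n_frames - 1
    for i in range(params.n_particles):
        tid = f"track{i:04d}"
        if rng.random() < params.p_stationary:
            x0 = round(float(rng.uniform(50.0, 450.0)))
            track = Track(
                tid, np.arange(params.n_frames, dtype=np.int64), np.full(params.n_frames, float(x0))
            )
            tt = TrackTruth(
                tid,
                states=np.asarray(["pause"] * n_int, dtype=object),
                runs=[],
                pauses_s=[n_int * params.frame_interval_s],
                stationary=True,
            )
        else:
            blocks = _mobile_blocks(rng, params, n_int)
            track, tt = _realize_track(rng, params, blocks, tid)
        tracks.append(track)
        truth.tracks[tid] = tt
    return tracks, truth


def render_kymograph(
    tracks: list[Track],
    rp: KymographRenderParams,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S,
) -> Kymograph:
    """Render tracks into a (time, space) image: one Gaussian bump per particle
    per frame over a flat background, plus seeded Gaussian noise."""
    n_frames = max(int(t.frames.max()) for t in tracks) + 1 if tracks else 0
    for t in tracks:
        if t.x_px.min() < 0 or t.x_px.max() >= rp.space_px:
            raise BoundsError(f"track {t.track_id} exceeds the spatial extent [0, {rp.space_px})")
    grid = np.arange(rp.space_px, dtype=np.float64)
    img = np.full((n_frames, rp.space_px), rp.background, dtype=np.float64)
    for t in tracks:
        for f, xp in zip(t.frames, t.x_px):
            img[int(f)] += rp.particle_amplitude * np.exp(
                -0.5 * ((grid - xp) / rp.psf_sigma_px) ** 2
            )
    if rp.noise_sigma > 0:
        rng = np.random.default_rng(rp.seed)
        img += rng.normal(0.0, rp.noise_sigma, size=img.shape)
    return Kymograph(
        matrix=img,
        pixel_size_um=pixel_size_um,
        frame_interval_s=frame_interval_s,
        source_id="synthetic",
    )


def simulate_mps_profile(
    spacing_nm: float = 190.0,
    px_nm: float = 30.0,
    length_um: float = 10.0,
    peak_sigma_nm: float = 35.0,
    noise_frac: float = 0.1,
    seed: int = 0,
):
    """Periodic membrane-skeleton intensity profile.

    A lattice of Gaussian peaks at regular spacing; the lattice constant is
    snapped to the sampling grid (190 nm at 30 nm/px renders as 6 px =
    180 nm), so the noiseless profile has exactly periodic maxima.
    ``noise_frac`` scales additive Gaussian noise relative to peak amplitude.
    """
    from .ais import IntensityProfile  # local import: ais also imports nothing from here

    if spacing_nm <= 2 * px_nm:
        raise ParameterError("lattice spacing must exceed 2 pixels (Nyquist)")
    length_nm = length_um * 1000.0
    if length_nm < 10 * spacing_nm:
        raise ParameterError("profile must cover at least 10 lattice periods")
    spacing_px = int(round(spacing_nm / px_nm))
    n = int(round(length_nm / px_nm))
    x = np.arange(n, dtype=np.float64)
    centers = np.arange(spacing_px // 2, n, spacing_px, dtype=np.float64)
    sig_px = peak_sigma_nm / px_nm
    values = np.exp(-0.5 * ((x[:, None] - centers[None, :]) / sig_px) ** 2).sum(axis=1)
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_frac * rng.standard_normal(n)
    return IntensityProfile(values=values, px_nm=px_nm, origin=f"synthetic-mps-{spacing_nm:g}nm")


def simulate_ais_image(
    n_patches: int,
    patch_sigma_px: float = 2.0,
    amplitude: float = 1000.0,
    image_shape: tuple[int, int] = (48, 240),
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, list[dict]]:
    """STED-like AIS image with ``n_patches`` Gaussian blobs and ground truth.

    Blob centers are drawn with a margin of 4 sigma from the borders and a
    pairwise separation of at least 8 sigma; an over-packed request raises.
    """
    if n_patches < 0 or patch_sigma_px <= 0 or noise_sigma < 0:
        raise ParameterError("invalid patch image parameters")
    h, w = image_shape
    margin = 4.0 * patch_sigma_px
    min_sep = 8.0 * patch_sigma_px
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise ParameterError("patches do not fit inside the image")
    rng = np.random.default_rng(seed)
    centers: list[tuple[float, float]] = []
    attempts = 0
    while len(centers) < n_patches:
        if attempts > 10000:
            raise ParameterError(f"cannot pack {n_patches} patches into {image_shape}")
        attempts += 1
        cy = float(rng.uniform(margin, h - margin))
        cx = float(rng.uniform(margin, w - margin))
        if all(np.hypot(cy - y0, cx - x0) >= min_sep for y0, x0 in centers):
            centers.append((cy, cx))
    yy, xx = np.mgrid[0:h, 0:w]
    img = np.zeros((h, w), dtype=np.float64)
    for cy, cx in centers:
        img += amplitude * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * patch_sigma_px**2))
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    truth = [
        {"centroid": (cy, cx), "sigma_px": patch_sigma_px, "amplitude": amplitude}
        for cy, cx in centers
    ]
    return img, truth


def simulate_ais_marker_profile(
    true_length_um: float,
    px_um: float = 0.09,
    edge_sigma_um: float = 0.5,
    noise_frac: float = 0.0,
    seed: int = 0,
):
    """Plateau-shaped AIS marker profile with error-function edges.

    The plateau of extent ``true_length_um`` sits between flanking baseline
    stretches; ``edge_sigma_um`` sets the edge softness (0 gives a sharp
    rectangle). Intensity is normalized to a plateau height of 1 before
    noise is added.
    """
    from scipy.special import erf

    from .ais import IntensityProfile

    if edge_sigma_um < 0 or noise_frac < 0 or px_um <= 0:
        raise ParameterError("invalid marker-profile parameters")
    if edge_sigma_um > 0 and true_length_um <= 4 * edge_sigma_um:
        raise ParameterError("plateau must be longer than 4 edge sigmas")
    pad_um = max(5.0, 0.25 * true_length_um)
    total = true_length_um + 2 * pad_um
    n = int(round(total / px_um))
    x = np.arange(n) * px_um
    a, b = pad_um, pad_um + true_length_um
    if edge_sigma_um == 0:
        values = ((x >= a) & (x <= b)).astype(np.float64)
    else:
        s = edge_sigma_um * np.sqrt(2.0)
        values = 0.5 * (erf((x - a) / s) - erf((x - b) / s))
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        values = values + noise_frac * rng.standard_normal(n)
    return IntensityProfile(values=values, px_nm=px_um * 1000.0, origin="synthetic-ais-marker")


def simulate_coloc_table(
    n: int = 815,
    slope: float = 1578.0,
    intercept: float = 4156.0,
    noise_sigma: float = 0.0,
    seed: int = 0,
    x_range: tuple[float, float] = (1.0, 60.0),
) -> pd.DataFrame:
    """Paired particle intensities with a linear channel coupling.

    Defaults reproduce the fitted relation between detection-channel and
    second-channel integrated densities (y = 1578 x + 4156) over n = 815
    particles; ``noise_sigma`` is additive Gaussian noise on y.
    """
    if n < 3:
        raise ParameterError("need at least 3 particles")
    if noise_sigma < 0:
        raise ParameterError("noise_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    x = rng.uniform(x_range[0], x_range[1], size=n)
    y = slope * x + intercept
    if noise_sigma > 0:
        y = y + rng.normal(0.0, noise_sigma, size=n)
    return pd.DataFrame(
        {"particle_id": np.arange(n), "integdens_a": x, "integdens_b": y}
    )
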