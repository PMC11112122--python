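"""Axon-initial-segment structural metrics.

Three independent measurements on AIS imaging data:

* **MPS periodicity** — normalized autocorrelation of a longitudinal
  F-actin intensity profile (STED, 30 nm pixels). The membrane-associated
  periodic skeleton shows up as a side peak near 190 nm.
* **F-actin patches** — blob detection on STED images inside a manually
  drawn AIS mask: smooth, threshold relative to the ROI dynamic range
  (``pa_thre``), 8-connected components, discard components small relative
  to the median candidate area (``area_thre``); patch size in pixels
  (30 x 30 nm) and density per 10 um.
* **AIS length** — extent of an AnkG/TRIM46 marker intensity profile,
  measured between the outermost crossings of a threshold fraction
  (default 0.33) of the smoothed, background-subtracted maximum.

The ``pa_thre``/``area_thre`` semantics and the 0.33 length criterion are
conventions of this package (the cited upstream scripts do not define them
publicly); both are configurable and documented in the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, uniform_filter1d
from scipy.signal import find_peaks
from skimage.measure import label as sk_label
from skimage.measure import regionprops

from .errors import DegenerateInputError, InputError, ParameterError

__all__ = [
    "IntensityProfile",
    "AutocorrCurve",
    "Patch",
    "PatchDetectParams",
    "AISExtent",
    "autocorrelate_profile",
    "average_autocorr",
    "estimate_period",
    "detect_patches",
    "patch_stats",
    "measure_ais_length",
]

BACKGROUND_PERCENTILE = 10.0  # robust background: 10th percentile of ROI intensities


@dataclass
class IntensityProfile:
    """Calibrated 1D intensity signal; ``px_nm`` is the sample spacing in nm."""

    values: np.ndarray
    px_nm: float
    origin: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or len(self.values) < 2:
            raise ParameterError("profile needs >= 2 samples")
        if self.px_nm <= 0:
            raise ParameterError("sample spacing must be > 0")

    @property
    def px_um(self) -> float:
        return self.px_nm / 1000.0


@dataclass
class AutocorrCurve:
    """Normalized autocorrelation: value 1 at lag 0, |values| <= 1."""

    lags_nm: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lags_nm = np.asarray(self.lags_nm, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)

    @property
    def lag_step_nm(self) -> float:
        return float(self.lags_nm[1] - self.lags_nm[0])


@dataclass
class Patch:
    """One detected F-actin patch (pixel units; STED pixels are 30 x 30 nm)."""

    centroid: tuple[float, float]  # (y, x)
    area_px: int
    mean_intensity: float


@dataclass(frozen=True)
class PatchDetectParams:
    """Detection thresholds. ``pa_thre`` is the intensity threshold as a
    fraction of the ROI dynamic range above background; ``area_thre``
    discards components smaller than that fraction of the median candidate
    component area."""

    pa_thre: float = 0.6
    area_thre: float = 0.7
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.pa_thre <= 1) or not (0 < self.area_thre <= 1):
            raise ParameterError("thresholds must lie in (0, 1]")
        if self.smoothing_sigma_px < 0:
            raise ParameterError("smoothing sigma must be >= 0")


@dataclass
class AISExtent:
    """AIS extent along the neurite, in um from the profile origin."""

    start_um: float
    end_um: float
    threshold_fraction: float
    detected: bool = True

    @property
    def length_um(self) -> float:
        return self.end_um - self.start_um


def autocorrelate_profile(p: IntensityProfile, max_lag_nm: float) -> AutocorrCurve:
    """Mean-subtracted, variance-normalized autocorrelation up to ``max_lag_nm``.

    Uses the biased estimator (sum of lagged products over N, normalized by
    the lag-0 value), so the curve starts at exactly 1 and stays within
    [-1, 1].
    """
    v = p.values - p.values.mean()
    c0 = float(np.dot(v, v))
    if c0 == 0:
        raise DegenerateInputError("constant profile has no autocorrelation")
    max_lag_px = int(round(max_lag_nm / p.px_nm))
    max_lag_px = min(max_lag_px, len(v) - 1)
    if len(v) < 2 * max_lag_px:
        raise ParameterError("profile too short for the requested maximum lag")
    vals = np.array([np.dot(v[: len(v) - k], v[k:]) for k in range(max_lag_px + 1)])
    return AutocorrCurve(lags_nm=np.arange(max_lag_px + 1) * p.px_nm, values=vals / c0)


def average_autocorr(curves: Sequence[AutocorrCurve]) -> tuple[AutocorrCurve, np.ndarray]:
    """Pointwise mean curve and per-lag s.e.m. across identically gridded curves."""
    if not curves:
        raise InputError("no curves to average")
    lags = curves[0].lags_nm
    for c in curves[1:]:
        if len(c.lags_nm) != len(lags) or not np.allclose(c.lags_nm, lags):
            raise InputError("autocorrelation curves have mismatched lag grids")
    stack = np.vstack([c.values for c in curves])
    mean = stack.mean(axis=0)
    sem = (
        stack.std(axis=0, ddof=1) / np.sqrt(len(curves))
        if len(curves) > 1
        else np.zeros_like(mean)
    )
    return AutocorrCurve(lags_nm=lags.copy(), values=mean), sem


def estimate_period(curve: AutocorrCurve, min_prominence: float = 0.3) -> float | None:
    """Lag (nm) of the first prominent autocorrelation side peak, or None.

    The first local maximum beyond lag 0 with prominence at least
    ``min_prominence`` is taken as the lattice period; a curve without one
    (e.g. from white noise) yields None rather than an exception.
    """
    peaks, _ = find_peaks(curve.values, prominence=min_prominence)
    peaks = peaks[peaks > 0]
    if len(peaks) == 0:
        return None
    return float(curve.lags_nm[peaks[0]])


def detect_patches(
    image: np.ndarray,
    roi_mask: np.ndarray | None,
    params: PatchDetectParams = PatchDetectParams(),
) -> list[Patch]:
    """Detect bright patches inside an ROI.

    Pipeline: Gaussian smooth -> threshold at background + pa_thre * (ROI
    max - background), background being the ROI's 10th intensity percentile
    -> 8-connected components -> discard components with area below
    area_thre * median candidate area. ``mean_intensity`` is measured on
    the unsmoothed image. (The colocalization module uses the underlying
    implementation to also obtain the label image of kept patches.)
    """
    return _detect_patches_impl(image, roi_mask, params)[0]


def _detect_patches_impl(
    image: np.ndarray,
    roi_mask: np.ndarray | None,
    params: PatchDetectParams,
) -> tuple[list[Patch], np.ndarray]:
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise InputError("image must be 2D")
    if roi_mask is None:
        roi_mask = np.ones(image.shape, dtype=bool)
    else:
        roi_mask = np.asarray(roi_mask, dtype=bool)
        if roi_mask.shape != image.shape:
            raise InputError("ROI mask shape must match the image")
    if not roi_mask.any():
        raise InputError("empty ROI")
    roi_vals = image[roi_mask]
    background = float(np.percentile(roi_vals, BACKGROUND_PERCENTILE))
    smoothed = (
        gaussian_filter(image, params.smoothing_sigma_px)
        if params.smoothing_sigma_px > 0
        else image
    )
    roi_max = float(smoothed[roi_mask].max())
    if roi_max <= background:
        return [], np.zeros(image.shape, dtype=np.int32)
    thr = background + params.pa_thre * (roi_max - background)
    binary = (smoothed >= thr) & roi_mask
    labels = sk_label(binary, connectivity=2)
    props = regionprops(labels, intensity_image=image)
    if not props:
        return [], labels
    areas = np.array([p.area for p in props])
    min_area = params.area_thre * float(np.median(areas))
    kept = [p for p in props if p.area >= min_area]
    out_labels = np.zeros_like(labels)
    patches = []
    for new_id, p in enumerate(kept, start=1):
        out_labels[labels == p.label] = new_id
        patches.append(
            Patch(
                centroid=(float(p.centroid[0]), float(p.centroid[1])),
                area_px=int(p.area),
                mean_intensity=float(p.intensity_mean),
            )
        )
    return patches, out_labels


def patch_stats(patches: Sequence[Patch], roi_length_um: float) -> tuple[float, float]:
    """(median patch area in px, patches per 10 um of AIS)."""
    if roi_length_um <= 0:
        raise ParameterError("roi_length_um must be > 0")
    density = len(patches) / roi_length_um * 10.0
    if not patches:
        return float("nan"), density
    return float(np.median([p.area_px for p in patches])), density


def measure_ais_length(
    p: IntensityProfile,
    smoothing_um: float = 1.0,
    threshold_fraction: float = 0.33,
) -> AISExtent:
    """AIS extent from a marker intensity profile.

    The profile is smoothed with a rolling mean of width ``smoothing_um``
    (0 disables smoothing), background-subtracted (10th percentile) and
    normalized to its maximum; start/end are the outermost crossings of
    ``threshold_fraction``, localized to sub-pixel precision by linear
    interpolation. A profile that never exceeds the threshold returns a
    flagged no-AIS result instead of raising.
    """
    if not (0 < threshold_fraction < 1):
        raise ParameterError("threshold_fraction must lie in (0, 1)")
    px_um = p.px_um
    vals = p.values
    if smoothing_um > 0:
        w = max(1, int(round(smoothing_um / px_um)))
        vals = uniform_filter1d(vals.astype(np.float64), size=w, mode="nearest")
    background = float(np.percentile(vals, BACKGROUND_PERCENTILE))
    peak = float(vals.max())
    if peak <= background:
        return AISExtent(0.0, 0.0, threshold_fraction, detected=False)
    norm = (vals - background) / (peak - background)
    above = norm >= threshold_fraction
    if not above.any():
        return AISExtent(0.0, 0.0, threshold_fraction, detected=False)
    i0 = int(np.argmax(above))
    i1 = len(norm) - 1 - int(np.argmax(above[::-1]))

    def _cross(i_below: int, i_above: int) -> float:
        # linear interpolation of the crossing between two samples
        y0, y1 = norm[i_below], norm[i_above]
        if y1 == y0:
            return float(i_above)
        return i_below + (threshold_fraction - y0) / (y1 - y0) * (i_above - i_below)

    start = _cross(i0 - 1, i0) if i0 > 0 else 0.0
    end = _cross(i1 + 1, i1) if i1 < len(norm) - 1 else float(len(norm) - 1)
    return AISExtent(start * px_um, end * px_um, threshold_fraction)
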