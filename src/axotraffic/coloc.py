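"""Two-channel particle-intensity correlation (Lysotracker vs Magic Red).

Particles are detected on the detection channel (A) only; the detected
footprints are then used to measure background-subtracted integrated
density in both channels, and the paired intensities are summarized by an
ordinary least-squares regression of B on A plus Spearman's rank
correlation. The reference dataset behind the defaults reported
y = 1578 x + 4156 with Spearman r = 0.9258 over 815 particles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ais import PatchDetectParams, _detect_patches_impl
from .errors import DegenerateInputError, InputError
from .stats import median_ci  # noqa: F401  (re-exported convenience)

__all__ = ["RegressionResult", "detect_particles_2ch", "correlate"]


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    spearman_r: float
    n: int


def detect_particles_2ch(
    image_a: np.ndarray,
    image_b: np.ndarray,
    params: PatchDetectParams = PatchDetectParams(pa_thre=0.2, area_thre=0.2, smoothing_sigma_px=1.0),
) -> pd.DataFrame:
    """Detect particles on channel A; measure integrated density in both.

    Integrated density = sum of background-subtracted intensities over the
    particle footprint; background per channel = median intensity outside
    all detected footprints. Returns a table with columns ``particle_id``,
    ``integdens_a``, ``integdens_b``.
    """
    image_a = np.asarray(image_a, dtype=np.float64)
    image_b = np.asarray(image_b, dtype=np.float64)
    if image_a.shape != image_b.shape:
        raise InputError("channel images must have the same shape")
    patches, labels = _detect_patches_impl(image_a, None, params)
    if not patches:
        return pd.DataFrame(columns=["particle_id", "integdens_a", "integdens_b"])
    outside = labels == 0
    bg_a = float(np.median(image_a[outside])) if outside.any() else 0.0
    bg_b = float(np.median(image_b[outside])) if outside.any() else 0.0
    rows = []
    for pid in range(1, len(patches) + 1):
        fp = labels == pid
        rows.append(
            {
                "particle_id": pid - 1,
                "integdens_a": float(np.sum(image_a[fp] - bg_a)),
                "integdens_b": float(np.sum(image_b[fp] - bg_b)),
            }
        )
    return pd.DataFrame(rows)


def correlate(table: pd.DataFrame) -> RegressionResult:
    """OLS regression of channel B on channel A plus Spearman correlation.

    Spearman uses midranks for ties. Requires >= 3 paired rows and nonzero
    variance in both columns.
    """
    a = np.asarray(table["integdens_a"], dtype=np.float64)
    b = np.asarray(table["integdens_b"], dtype=np.float64)
    if len(a) < 3:
        raise InputError("need at least 3 particles for correlation")
    if np.var(a) == 0 or np.var(b) == 0:
        raise DegenerateInputError("zero variance in an intensity column")
    fit = sps.linregress(a, b)
    rho = sps.spearmanr(a, b).statistic
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        spearman_r=float(rho),
        n=len(a),
    )
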