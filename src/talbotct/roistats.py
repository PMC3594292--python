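"""ROI contrast-to-noise analysis with standard-error propagation.

The three-ROI protocol: region 1 covers the target feature (e.g. solid
tumor), region 2 the surrounding reference tissue, and region 3 a
homogeneous area probing pure image noise -- kept separate because tissue
heterogeneity inside an ROI would otherwise masquerade as noise.  The
statistic is

    CNR = |mean_1 - mean_2| / sd_3

with uncertainty from first-order error propagation using the standard
errors of the two means (s_i / sqrt(n_i)) and of the noise estimate
(s_3 / sqrt(2 (n_3 - 1)), the large-sample SE of a sample sd):

    sigma_CNR^2 = (SE_1^2 + SE_2^2) / s_3^2 + CNR^2 (SE_s3 / s_3)^2

The relative contrast gain is the ratio of the phase-image CNR to the
attenuation-image CNR of the same feature, with the uncertainties combined
in quadrature on the relative scale.  A gain is reported as undefined when
the attenuation CNR is not significant (its uncertainty is of the same
order as the value itself).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np


class ROIRole(str, Enum):
    TARGET = "target"
    REFERENCE = "reference"
    NOISE = "noise"


@dataclass(frozen=True)
class ROISpec:
    """Circular ROI: center in mm from image center, area in mm^2."""

    center_mm: tuple
    area_mm2: float
    role: ROIRole = ROIRole.TARGET

    def __post_init__(self):
        if not self.area_mm2 > 0:
            raise ValueError("ROI area must be positive")

    @property
    def radius_mm(self) -> float:
        return math.sqrt(self.area_mm2 / math.pi)


@dataclass(frozen=True)
class ROIStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("ROI must contain at least 2 pixels")
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @property
    def se_mean(self) -> float:
        return self.sd / math.sqrt(self.n)

    @property
    def se_sd(self) -> float:
        return self.sd / math.sqrt(2.0 * (self.n - 1))


@dataclass(frozen=True)
class CNRResult:
    cnr: float
    sigma: float


@dataclass(frozen=True)
class GainResult:
    gain: float
    sigma: float

    @property
    def rounded_gain(self) -> int:
        return round(self.gain)


def roi_mask(shape: tuple, roi: ROISpec, pixel_size_um: float) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the ROI circle."""
    ny, nx = shape
    px_mm = pixel_size_um * 1e-3
    cx = roi.center_mm[0] / px_mm + nx // 2
    cy = roi.center_mm[1] / px_mm + ny // 2
    r_px = roi.radius_mm / px_mm
    if (
        cx - r_px < -0.5
        or cx + r_px > nx - 0.5
        or cy - r_px < -0.5
        or cy + r_px > ny - 0.5
    ):
        raise ValueError("ROI extends outside the image")
    Y, X = np.ogrid[:ny, :nx]
    return (X - cx) ** 2 + (Y - cy) ** 2 <= r_px**2


def roi_stats(image: np.ndarray, roi: ROISpec, pixel_size_um: float) -> ROIStats:
    """Mean and sample sd (n-1 denominator) of the pixels inside the ROI."""
    mask = roi_mask(image.shape, roi, pixel_size_um)
    vals = np.asarray(image, dtype=float)[mask]
    if vals.size < 2:
        raise ValueError("ROI covers fewer than 2 pixel centers")
    return ROIStats(mean=float(vals.mean()), sd=float(vals.std(ddof=1)), n=int(vals.size))


def propagate_cnr(stats1: ROIStats, stats2: ROIStats, stats3: ROIStats) -> float:
    """First-order uncertainty of the CNR (see module docstring)."""
    if not stats3.sd > 0:
        raise ValueError("noise ROI has zero sd")
    c = abs(stats1.mean - stats2.mean) / stats3.sd
    var = (stats1.se_mean**2 + stats2.se_mean**2) / stats3.sd**2
    var += c**2 * (stats3.se_sd / stats3.sd) ** 2
    return math.sqrt(var)


def cnr(stats1: ROIStats, stats2: ROIStats, stats3: ROIStats) -> CNRResult:
    """CNR = |mean_1 - mean_2| / sd_3 with propagated uncertainty."""
    if not stats3.sd > 0:
        raise ValueError("noise ROI has zero sd; CNR undefined")
    value = abs(stats1.mean - stats2.mean) / stats3.sd
    return CNRResult(cnr=value, sigma=propagate_cnr(stats1, stats2, stats3))


def undefined_gain_guard(result: CNRResult) -> bool:
    """True when the CNR is not significant (sigma >= cnr, boundary in)."""
    return result.sigma >= result.cnr


def contrast_gain(cnr_phase: CNRResult, cnr_atten: CNRResult) -> GainResult:
    """Relative contrast gain: phase CNR over attenuation CNR.

    Raises when the attenuation CNR is zero; callers should consult
    :func:`undefined_gain_guard` first and suppress the gain when the
    attenuation CNR is consistent with zero.
    """
    if not cnr_atten.cnr > 0:
        raise ValueError("attenuation CNR must be positive for a gain")
    gain = cnr_phase.cnr / cnr_atten.cnr
    sigma = gain * math.sqrt(
        (cnr_atten.sigma / cnr_atten.cnr) ** 2
        + (cnr_phase.sigma / cnr_phase.cnr) ** 2
    )
    return GainResult(gain=gain, sigma=sigma)
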