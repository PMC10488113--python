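"""Histogram-based local thresholding of fluorescence channels.

A channel is segmented by subtracting a box-mean background estimate and
thresholding the residual at ``t = c * sigma + m``, where ``sigma`` is the
standard deviation and ``m`` the (integer-binned) mode of the residual.
Pixels with residual >= t are signal.  Locality enters through the
box-mean subtraction; ``sigma`` and ``m`` default to global statistics of
the residual (a per-box sigma variant is available via ``local_sigma``).

Binary post-processing: subtraction of the lipofuscin autofluorescence
mask and a majority (median) filter of radius 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .image import require_same_grid

#: Channel-specific multipliers for the threshold t = c * sigma + m.
DEFAULT_C_FACTORS = {
    "DAPI": 2.0,
    "RyR": 3.0,
    "WGA": 1.0,
    "dextran": 0.5,
    "SERCA": 2.0,
    "lipofuscin": 4.0,
}

#: Smallest meaningful mean-filter box (µm); below this the background
#: estimate starts tracking the signal itself.
MIN_BOX_SIZE_UM = 10.0


@dataclass
class ThresholdConfig:
    """Configuration of :func:`local_threshold` for one channel.

    ``box_size_um = None`` means the whole-image mean is subtracted.
    ``threshold_on`` selects whether the threshold is applied to the
    residual (default) or to the original intensities; ``local_sigma``
    switches sigma from a global to a per-box statistic.
    """

    c_factor: float = 1.0
    box_size_um: Optional[float] = None
    apply_median: bool = True
    median_radius_px: int = 1
    local_sigma: bool = False
    threshold_on: str = "residual"

    def __post_init__(self) -> None:
        if self.c_factor <= 0:
            raise ValueError("c_factor must be positive")
        if self.box_size_um is not None and self.box_size_um < MIN_BOX_SIZE_UM:
            raise ValueError(f"box_size_um must be >= {MIN_BOX_SIZE_UM} µm or None")
        if self.median_radius_px < 1:
            raise ValueError("median_radius_px must be >= 1")
        if self.threshold_on not in ("residual", "original"):
            raise ValueError("threshold_on must be 'residual' or 'original'")

    @classmethod
    def for_channel(cls, role: str, **kwargs) -> "ThresholdConfig":
        c = kwargs.pop("c_factor", DEFAULT_C_FACTORS.get(role, 1.0))
        return cls(c_factor=c, **kwargs)


@dataclass
class ThresholdResult:
    """Binary mask plus the statistics that produced it."""

    mask: np.ndarray
    threshold: float
    sigma: float
    mode: float
    degenerate: bool = False

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.mask, dtype=dtype)


def _integer_mode(residual: np.ndarray) -> float:
    """Mode of the residual on a histogram with bin width 1 intensity unit.

    Residuals are rounded to the nearest integer; ties between equally
    populated bins break toward the smallest bin value.
    """
    vals = np.rint(residual.ravel()).astype(np.int64)
    uniq, counts = np.unique(vals, return_counts=True)
    return float(uniq[np.argmax(counts)])  # first argmax = smallest value


def local_threshold(
    channel: np.ndarray, config: ThresholdConfig, pixel_size_um: float = 0.1
) -> ThresholdResult:
    """Threshold one intensity channel at ``t = c * sigma + m``.

    Returns a :class:`ThresholdResult`; ``result.mask`` is True where the
    pixel is signal (residual >= t, with >= so pixels exactly at t count
    as signal).  A constant image has sigma = m = t = 0, yielding an
    all-signal mask flagged ``degenerate``.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("channel is empty")
    img = channel.astype(np.float64, copy=False)

    box_px = None
    if config.box_size_um is not None:
        box_px = int(round(config.box_size_um / pixel_size_um))
        if box_px >= min(img.shape):
            box_px = None  # clamp to whole-image mean
    if box_px is None:
        background = img.mean()
    else:
        background = ndi.uniform_filter(img, size=box_px, mode="reflect")
    residual = img - background

    m = _integer_mode(residual)
    if config.local_sigma:
        size = box_px if box_px is not None else min(img.shape)
        mean_r = ndi.uniform_filter(residual, size=size, mode="reflect")
        mean_r2 = ndi.uniform_filter(residual**2, size=size, mode="reflect")
        sigma = np.sqrt(np.clip(mean_r2 - mean_r**2, 0.0, None))
        sigma_scalar = float(sigma.mean())
    else:
        sigma = residual.std()
        sigma_scalar = float(sigma)

    t = config.c_factor * sigma + m
    target = residual if config.threshold_on == "residual" else img
    mask = target >= t

    degenerate = sigma_scalar == 0.0
    if degenerate:
        warnings.warn(
            "zero-variance residual: threshold is degenerate and the mask "
            "marks every pixel at or above the mode",
            RuntimeWarning,
            stacklevel=2,
        )
    t_scalar = float(np.mean(t))
    return ThresholdResult(mask=mask, threshold=t_scalar, sigma=sigma_scalar,
                           mode=m, degenerate=degenerate)


def subtract_lipofuscin(mask: np.ndarray, lipofuscin_mask: np.ndarray) -> np.ndarray:
    """Remove autofluorescent lipofuscin pixels from a signal mask."""
    mask = np.asarray(mask, dtype=bool)
    lipofuscin_mask = np.asarray(lipofuscin_mask, dtype=bool)
    require_same_grid(mask, lipofuscin_mask)
    return mask & ~lipofuscin_mask


def median_filter_binary(mask: np.ndarray, radius_px: int = 1) -> np.ndarray:
    """Majority filter over the (2r+1)x(2r+1) square neighborhood.

    Borders are handled by reflection; the odd window size makes ties
    impossible.
    """
    if radius_px < 1:
        raise ValueError("radius_px must be >= 1")
    mask = np.asarray(mask, dtype=bool)
    filtered = ndi.median_filter(
        mask.astype(np.uint8), size=2 * radius_px + 1, mode="reflect"
    )
    return filtered.astype(bool)
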