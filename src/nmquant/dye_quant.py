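"""Mask-based intensity quantification for vital-dye assays.

Covers three measurement styles that share one masking convention
(mean automatic thresholding of a reference channel, applied to the
quantified channel):

* dye uptake/clearance time series — drift-corrected, max-projected,
  rolling-ball background-subtracted signal measured under the mask at each
  time point, reported as ΔF relative to the first point;
* single-channel baselines — the red-channel mean under a green-channel
  mask on a central-slice max projection, with no background subtraction;
* ratiometric readouts — red/green mean ratio under a green-derived mask,
  with background subtraction only where the protocol applies it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation
from skimage.restoration import rolling_ball
from scipy import ndimage

from .core_io import MovieStack

__all__ = [
    "DyeTimeSeries",
    "rolling_ball_subtract",
    "mean_threshold_mask",
    "masked_mean",
    "dye_timeseries",
    "baseline_dye_intensity",
    "ratiometric_ratio",
    "fit_uptake",
    "fit_clearance",
]


def rolling_ball_subtract(image: np.ndarray, radius_px: int = 50) -> np.ndarray:
    """Subtract a rolling-ball background (ball radius in pixels).

    The background is the surface traced by a ball of the given radius
    rolled under the intensity landscape — equivalently a grayscale opening
    with a spherical structuring element — so features narrower than the
    ball survive subtraction at full height. Output is clipped at zero.
    A radius at or above the smallest image dimension degenerates to
    global-minimum subtraction with a warning.
    """
    image = np.asarray(image, dtype=np.float64)
    if radius_px < 1:
        raise ValueError("rolling-ball radius must be >= 1 px")
    if radius_px >= min(image.shape):
        warnings.warn(
            f"rolling-ball radius {radius_px} >= smallest image dimension "
            f"{min(image.shape)}; subtracting the global minimum instead",
            stacklevel=2,
        )
        return image - image.min()
    background = rolling_ball(image, radius=radius_px)
    return np.clip(image - background, 0.0, None)


def mean_threshold_mask(image: np.ndarray) -> tuple[np.ndarray, float]:
    """Mean automatic threshold: pixels strictly above the image mean.

    A constant image yields an empty mask (warned, and detectable via
    ``mask.any()``); quantification routines refuse empty masks.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.size == 0:
        raise ValueError("cannot threshold an empty image")
    threshold = float(image.mean())
    mask = image > threshold
    if not mask.any():
        warnings.warn(
            "mean threshold produced an empty mask (constant image?)",
            stacklevel=2,
        )
    return mask, threshold


def masked_mean(signal: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of ``signal`` over the True pixels of ``mask``."""
    signal = np.asarray(signal, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    if signal.shape != mask.shape:
        raise ValueError("signal and mask shapes differ")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(signal[mask].mean())


@dataclass
class DyeTimeSeries:
    """Masked-mean dye intensity over time; ΔF is relative to the first point."""

    t_s: np.ndarray
    mean_intensity: np.ndarray
    dF: np.ndarray
    phase: str = "uptake"

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=np.float64)
        self.mean_intensity = np.asarray(self.mean_intensity, dtype=np.float64)
        self.dF = np.asarray(self.dF, dtype=np.float64)
        if not (self.t_s.shape == self.mean_intensity.shape == self.dF.shape):
            raise ValueError("t, intensity and dF must have equal length")
        if self.t_s.size and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time points must be strictly increasing")


def dye_timeseries(
    movie: MovieStack,
    t_s: Sequence[float],
    bg_radius: int = 50,
    reference_channel: int = 0,
    signal_channel: int = 1,
    register: bool = True,
    phase: str = "uptake",
) -> DyeTimeSeries:
    """Dye intensity per time point from a two-channel stack series.

    Per time point: rigid drift correction against the first time point
    (estimated on the reference-channel projection, applied to both
    channels), max projection across z, rolling-ball background subtraction
    of the signal channel, mean-threshold mask from the reference channel,
    masked mean of the signal. One volume per time point.
    """
    if not movie.has_channels or movie.data.shape[-1] < 2:
        raise ValueError("a two-channel movie (reference + signal) is required")
    t_s = np.asarray(list(t_s), dtype=float)
    if t_s.size != movie.n_volumes:
        raise ValueError(
            f"{t_s.size} time points for {movie.n_volumes} volumes"
        )

    ref_proj0 = movie.data[0, :, :, :, reference_channel].max(axis=0)
    means = np.empty(t_s.size)
    for i in range(t_s.size):
        ref = movie.data[i, :, :, :, reference_channel].max(axis=0)
        sig = movie.data[i, :, :, :, signal_channel].max(axis=0)
        if register and i > 0 and np.ptp(ref) > 0 and np.ptp(ref_proj0) > 0:
            shift, _, _ = phase_cross_correlation(
                ref_proj0, ref, upsample_factor=10, normalization=None
            )
            if np.any(shift != 0):
                ref = ndimage.shift(ref, shift, order=1, mode="nearest")
                sig = ndimage.shift(sig, shift, order=1, mode="nearest")
        sig = rolling_ball_subtract(sig, bg_radius)
        mask, _ = mean_threshold_mask(ref)
        means[i] = masked_mean(sig, mask)
    return DyeTimeSeries(t_s, means, means - means[0], phase=phase)


def baseline_dye_intensity(
    stack: MovieStack,
    n_central_slices: int = 2,
    reference_channel: int = 0,
    signal_channel: int = 1,
    volume: int = 0,
) -> float:
    """Baseline dye readout from a single two-channel z-stack.

    The ``n_central_slices`` most central z planes (those spanning the cell
    bodies) are max-projected; a mean-threshold mask from the reference
    (green) channel selects the cells and the signal (red) channel is
    averaged under it. No background subtraction, matching the
    single-wavelength dye protocol.
    """
    if not stack.has_channels or stack.data.shape[-1] < 2:
        raise ValueError("a two-channel stack is required")
    n_z = stack.data.shape[1]
    if n_central_slices < 1 or n_central_slices > n_z:
        raise ValueError(
            f"n_central_slices={n_central_slices} with only {n_z} z planes"
        )
    lo = (n_z - n_central_slices) // 2
    sl = slice(lo, lo + n_central_slices)
    ref = stack.data[volume, sl, :, :, reference_channel].max(axis=0)
    sig = stack.data[volume, sl, :, :, signal_channel].max(axis=0)
    mask, _ = mean_threshold_mask(ref)
    return masked_mean(sig, mask)


def ratiometric_ratio(
    red: np.ndarray,
    green: np.ndarray,
    bg_subtract: bool = True,
    bg_radius: int = 50,
) -> float:
    """Red/green masked-mean intensity ratio.

    The mask always comes from the green channel (mean threshold). With
    ``bg_subtract`` both channels are rolling-ball corrected before masking
    and measuring (the cumulative-oxidation reporter protocol); without it
    the raw channels are ratioed (the potentiometric-dye protocol).
    """
    red = np.asarray(red, dtype=np.float64)
    green = np.asarray(green, dtype=np.float64)
    if red.shape != green.shape:
        raise ValueError("red and green shapes differ")
    if bg_subtract:
        red = rolling_ball_subtract(red, bg_radius)
        green = rolling_ball_subtract(green, bg_radius)
    mask, _ = mean_threshold_mask(green)
    if not mask.any():
        raise ValueError("green channel produced an empty mask")
    denom = masked_mean(green, mask)
    if denom == 0:
        raise ZeroDivisionError("green masked mean is zero")
    return masked_mean(red, mask) / denom


# ---------------------------------------------------------------------------
# Saturation / washout model fits


def _uptake_model(t: np.ndarray, Imax: float, tau: float) -> np.ndarray:
    return Imax * (1.0 - np.exp(-t / tau))


def _clearance_model(t: np.ndarray, I0: float, f: float, tau: float) -> np.ndarray:
    return I0 * (f + (1.0 - f) * np.exp(-t / tau))


def fit_uptake(series: DyeTimeSeries) -> tuple[float, float]:
    """Fit ``I(t) = Imax·(1 - exp(-t/tau))`` to the ΔF series.

    Returns (Imax, tau_s).
    """
    t = series.t_s - series.t_s[0]
    y = series.dF
    Imax0 = max(float(y.max()), 1e-9)
    tau0 = max(float(t[-1]) / 3.0, 1e-9)
    popt, _ = curve_fit(
        _uptake_model, t, y, p0=(Imax0, tau0),
        bounds=([0, 1e-12], [np.inf, np.inf]), maxfev=10_000,
    )
    return float(popt[0]), float(popt[1])


def fit_clearance(series: DyeTimeSeries) -> tuple[float, float, float]:
    """Fit ``I(t) = I0·(f + (1-f)·exp(-t/tau))`` to the intensity series.

    Returns (I0, retained_fraction, tau_s).
    """
    t = series.t_s - series.t_s[0]
    y = series.mean_intensity
    I0 = max(float(y[0]), 1e-9)
    f0 = float(np.clip(y[-1] / I0, 0.0, 1.0))
    tau0 = max(float(t[-1]) / 3.0, 1e-9)
    popt, _ = curve_fit(
        _clearance_model, t, y, p0=(I0, f0, tau0),
        bounds=([0, 0, 1e-12], [np.inf, 1, np.inf]), maxfev=10_000,
    )
    return float(popt[0]), float(popt[1]), float(popt[2])
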