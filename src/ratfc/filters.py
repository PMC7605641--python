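"""Spatial Gaussian smoothing and temporal band-pass filtering.

Smoothing is isotropic in millimetres (per-axis sigma adapts to the
voxel size); the temporal filter is a Butterworth band-pass applied
forward-backward (zero phase), so the effective attenuation is the
squared one-pass magnitude response.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage, signal

from ratfc.io_core import ValidationError, Volume4D

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def gaussian_smooth(vol: Volume4D, fwhm_mm: float) -> Volume4D:
    """Smooth each frame with an isotropic (in mm) Gaussian kernel.

    sigma per axis = fwhm / (voxel_size * 2*sqrt(2 ln 2)); reflective
    boundaries; fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValidationError("FWHM must be nonnegative")
    if fwhm_mm == 0:
        return vol.with_data(vol.data.copy())
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / vol.voxel_size_mm
    out = ndimage.gaussian_filter(vol.data, sigma=[*sigma_vox, 0.0], mode="reflect")
    return vol.with_data(out)


def smooth_frame(frame: np.ndarray, fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Gaussian-smooth a single 3D frame (same convention as above)."""
    if fwhm_mm == 0:
        return frame.copy()
    sigma_vox = fwhm_mm * FWHM_TO_SIGMA / np.asarray(voxel_size_mm, dtype=float)
    return ndimage.gaussian_filter(frame, sigma=sigma_vox, mode="reflect")


def butter_bandpass(low_hz: float, high_hz: float, tr_s: float, order: int = 4):
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValidationError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < Nyquist {nyq}")
    return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs)


def bandpass(vol: Volume4D, low_hz: float = 0.01, high_hz: float = 0.1,
             order: int = 4) -> Volume4D:
    """Zero-phase Butterworth band-pass of every voxel time course.

    The per-voxel mean is removed before filtering and restored after, so
    the output keeps the baseline image while fluctuations outside the
    band are suppressed.
    """
    t = vol.n_frames
    min_len = 3 * order
    if t < min_len:
        raise ValidationError(f"time series too short: {t} frames < minimum {min_len}")
    b, a = butter_bandpass(low_hz, high_hz, vol.tr_s, order)
    mean = vol.data.mean(axis=3, keepdims=True)
    demeaned = vol.data - mean
    padlen = min(3 * (max(len(a), len(b)) - 1) * order, t - 1)
    filtered = signal.filtfilt(b, a, demeaned, axis=3, padtype="odd", padlen=padlen)
    return vol.with_data(filtered + mean)


def bandpass_array(x: np.ndarray, tr_s: float, low_hz: float = 0.01,
                   high_hz: float = 0.1, order: int = 4, axis: int = -1) -> np.ndarray:
    """Zero-phase band-pass of a bare array along ``axis`` (mean preserved)."""
    b, a = butter_bandpass(low_hz, high_hz, tr_s, order)
    n = x.shape[axis]
    if n < 3 * order:
        raise ValidationError(f"time series too short: {n} < {3 * order}")
    mean = x.mean(axis=axis, keepdims=True)
    padlen = min(3 * (max(len(a), len(b)) - 1) * order, n - 1)
    return signal.filtfilt(b, a, x - mean, axis=axis, padtype="odd", padlen=padlen) + mean
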