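"""Raw two-wavelength intensities -> five-region oxyhemoglobin series.

The chain is: optical density relative to a pre-task baseline, motion
correction by Savitzky-Golay smoothing-replacement, zero-phase bandpass
(0.01-0.1 Hz), modified Beer-Lambert conversion to (dHbO2, dHbR), optional
short-separation systemic regression, and unweighted averaging of the long
channels assigned to each region.  Every step is linear, so the whole chain
obeys superposition; filtering is applied on optical density, before the
Beer-Lambert step.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .datatypes import ChannelInfo, RawRecording, ROITimeSeries
from .optics import DEFAULT_DPF, extinction_matrix

__all__ = [
    "intensity_to_od",
    "correct_motion_sg",
    "bandpass",
    "mbll",
    "regress_short_channels",
    "average_rois",
    "PreprocessConfig",
    "preprocess_recording",
]


def intensity_to_od(raw: RawRecording, baseline_s: Optional[tuple[float, float]] = None) -> np.ndarray:
    """Convert raw intensity to change in optical density.

    dOD(t) = -ln(I(t) / Ibar) per channel and wavelength, where Ibar is the
    mean intensity over the baseline interval (seconds).  Returns an array
    with the same (T, n_channels, 2) shape as ``raw.intensity``.
    """
    if baseline_s is None:
        baseline_s = raw.baseline_s
    lo, hi = baseline_s
    i0 = int(round(lo * raw.sampling_rate_hz))
    i1 = int(round(hi * raw.sampling_rate_hz))
    if not (0 <= i0 < i1 <= raw.n_samples):
        raise ValueError(
            f"baseline interval {baseline_s} s outside recording of {raw.duration_s:.1f} s"
        )
    ibar = raw.intensity[i0:i1].mean(axis=0)
    return -np.log(raw.intensity / ibar)


def correct_motion_sg(series: np.ndarray, sampling_rate_hz: float, window_s: float = 3.0, polyorder: int = 3) -> np.ndarray:
    """Motion correction by Savitzky-Golay smoothing-replacement.

    The signal is replaced by its local polynomial fit, which suppresses
    sample-isolated spikes while passing polynomials of degree <= polyorder
    unchanged.  Operates along axis 0 of any array shape.
    """
    series = np.asarray(series, dtype=float)
    nwin = int(round(window_s * sampling_rate_hz))
    if nwin % 2 == 0:
        nwin += 1
    nwin = max(nwin, polyorder + 2 + ((polyorder + 2) % 2 == 0))
    if nwin % 2 == 0:
        nwin += 1
    if nwin > series.shape[0]:
        raise ValueError(
            f"Savitzky-Golay window ({nwin} samples) longer than series ({series.shape[0]})"
        )
    return signal.savgol_filter(series, nwin, polyorder, axis=0)


def bandpass(series: np.ndarray, sampling_rate_hz: float, low_hz: float = 0.01, high_hz: float = 0.1, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth bandpass (forward-backward filtering).

    Defaults to the 0.01-0.1 Hz hemodynamic band.  Rejects DC entirely and
    preserves in-band amplitudes to within a few percent.
    """
    series = np.asarray(series, dtype=float)
    nyq = sampling_rate_hz / 2.0
    if not 0 < low_hz < high_hz < nyq:
        raise ValueError(f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz")
    sos = signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=sampling_rate_hz, output="sos")
    padlen = 3 * (2 * order + 1)
    if series.shape[0] <= 3 * padlen:
        raise ValueError(
            f"series of {series.shape[0]} samples too short for order-{order} zero-phase filter"
        )
    return signal.sosfiltfilt(sos, series, axis=0)


def mbll(
    od690: np.ndarray,
    od830: np.ndarray,
    distance_mm: float,
    dpf: tuple[float, float] = DEFAULT_DPF,
    extinction: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer-Lambert inversion to concentration changes.

    Solves, sample-wise,

        dOD_lambda = (eps_HbO,lambda * dHbO + eps_HbR,lambda * dHbR) * d * DPF_lambda

    for the two chromophores.  Distances in mm, concentrations in uM, OD in
    natural-log units.

    Returns ``(dHbO2, dHbR)`` arrays of the same shape as the inputs.
    """
    if distance_mm <= 0:
        raise ValueError("distance must be positive")
    if extinction is None:
        extinction = extinction_matrix()
    extinction = np.asarray(extinction, dtype=float)
    if np.linalg.cond(extinction) > 1e8:
        raise ValueError("extinction matrix is singular or nearly so")
    # A[lambda, chromophore] includes pathlength per wavelength
    A = extinction * (distance_mm * np.asarray(dpf)[:, None])
    Ainv = np.linalg.inv(A)
    od = np.stack([np.asarray(od690, float), np.asarray(od830, float)], axis=-1)
    conc = od @ Ainv.T
    return conc[..., 0], conc[..., 1]


def regress_short_channels(
    long_hbo: np.ndarray,
    short_hbo: np.ndarray,
    enabled: bool = False,
) -> np.ndarray:
    """Systemic-physiology removal by short-separation regression.

    When enabled, each long-channel series (columns of ``long_hbo``) is
    replaced by its residual after least-squares projection onto the best
    correlated short channel plus an intercept.  Disabled (the default) it is
    the identity, since applying the correction is an analysis choice.
    """
    long_hbo = np.asarray(long_hbo, dtype=float)
    if not enabled:
        return long_hbo.copy()
    short_hbo = np.atleast_2d(np.asarray(short_hbo, dtype=float))
    if short_hbo.shape[0] == long_hbo.shape[0]:
        pass
    elif short_hbo.shape[1] == long_hbo.shape[0]:
        short_hbo = short_hbo.T
    if short_hbo.size == 0 or short_hbo.shape[1] == 0:
        raise ValueError("short-channel regression enabled but no short channels present")
    out = np.empty_like(long_hbo)
    for j in range(long_hbo.shape[1]):
        y = long_hbo[:, j]
        # pick the short channel most correlated with this long channel
        cors = [
            abs(np.corrcoef(y, short_hbo[:, k])[0, 1]) if np.std(short_hbo[:, k]) > 0 else 0.0
            for k in range(short_hbo.shape[1])
        ]
        k = int(np.argmax(cors))
        X = np.column_stack([np.ones_like(y), short_hbo[:, k]])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        out[:, j] = y - X @ beta
    return out


def average_rois(
    channel_hbo: np.ndarray,
    channels: list[ChannelInfo],
    sampling_rate_hz: float,
    roi_labels: Optional[tuple[str, ...]] = None,
) -> ROITimeSeries:
    """Unweighted mean of each region's long channels, sample-wise.

    ``channel_hbo`` is (T, n_channels) including short channels, which are
    excluded from the averages.
    """
    if roi_labels is None:
        seen = []
        for c in channels:
            if c.kind == "long" and c.roi_label not in seen:
                seen.append(c.roi_label)
        roi_labels = tuple(seen)
    cols = []
    for roi in roi_labels:
        idx = [i for i, c in enumerate(channels) if c.kind == "long" and c.roi_label == roi]
        if not idx:
            raise ValueError(f"region {roi} has no long channels")
        cols.append(channel_hbo[:, idx].mean(axis=1))
    return ROITimeSeries(sampling_rate_hz, np.column_stack(cols), roi_labels)


@dataclass
class PreprocessConfig:
    """Parameters of the intensity -> ROI dHbO2 chain."""

    sg_window_s: float = 3.0
    sg_polyorder: int = 3
    band_hz: tuple[float, float] = (0.01, 0.1)
    dpf: tuple[float, float] = DEFAULT_DPF
    baseline_s: Optional[tuple[float, float]] = None
    short_channel_regression: bool = False
    motion_correction: bool = True
    bandpass_filter: bool = True
    crop_to_task: bool = True  # drop the baseline interval from the output


def preprocess_recording(
    raw: RawRecording,
    config: PreprocessConfig = PreprocessConfig(),
    roi_labels: Optional[tuple[str, ...]] = None,
) -> tuple[ROITimeSeries, np.ndarray]:
    """Full chain from a raw recording to the ROI oxyhemoglobin series.

    Returns ``(roi_series, channel_hbr)`` — deoxyhemoglobin is computed and
    returned per channel but not propagated into the network analysis.
    """
    od = intensity_to_od(raw, config.baseline_s)
    if config.motion_correction:
        od = correct_motion_sg(od, raw.sampling_rate_hz, config.sg_window_s, config.sg_polyorder)
    if config.bandpass_filter:
        od = bandpass(od, raw.sampling_rate_hz, *config.band_hz)

    T, nch, _ = od.shape
    hbo = np.empty((T, nch))
    hbr = np.empty((T, nch))
    for i, ch in enumerate(raw.channels):
        hbo[:, i], hbr[:, i] = mbll(
            od[:, i, 0], od[:, i, 1], ch.source_detector_distance_mm, config.dpf
        )

    long_idx = raw.long_channels()
    short_idx = raw.short_channels()
    corrected = regress_short_channels(
        hbo[:, long_idx], hbo[:, short_idx] if short_idx else np.empty((T, 0)),
        enabled=config.short_channel_regression,
    )
    full = hbo.copy()
    full[:, long_idx] = corrected
    roi = average_rois(full, raw.channels, raw.sampling_rate_hz, roi_labels)
    if config.crop_to_task:
        base = config.baseline_s if config.baseline_s is not None else raw.baseline_s
        i1 = int(round(base[1] * raw.sampling_rate_hz))
        roi = ROITimeSeries(roi.sampling_rate_hz, roi.values[i1:], roi.roi_labels)
        hbr = hbr[i1:]
    return roi, hbr
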