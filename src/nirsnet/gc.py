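"""Directed-network estimation: windows in, edge tables out.

`SpectralGC` is the model object: construct it from an ROI time series (or a
whole study dataset via :func:`first_window_networks`), call ``fit()`` and
get back per-window :class:`~nirsnet.datatypes.DirectedNetwork` objects with
a tidy edge table and a ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import DirectedNetwork, ROITimeSeries, StudyDataset
from .spectral import (
    SpectralWindowing,
    band_average_gc,
    estimate_cross_spectrum,
    pairwise_gc_spectrum,
    resample_to_rate,
)

logger = logging.getLogger(__name__)

__all__ = [
    "select_window_length",
    "segment_windows",
    "pairwise_directed_network",
    "SpectralGC",
    "SpectralGCResults",
    "first_window_networks",
    "surrogate_threshold",
]


def segment_windows(series: ROITimeSeries, windowing: SpectralWindowing) -> list[np.ndarray]:
    """Contiguous nonoverlapping windows starting at sample 0 (task onset);
    the trailing remainder shorter than one window is discarded."""
    n_win_samples = int(round(windowing.window_s * series.sampling_rate_hz))
    if series.n_samples < n_win_samples:
        raise ValueError(
            f"series of {series.duration_s:.1f} s shorter than one "
            f"{windowing.window_s:.0f} s window"
        )
    n_windows = series.n_samples // n_win_samples
    return [
        series.values[k * n_win_samples : (k + 1) * n_win_samples]
        for k in range(n_windows)
    ]


def select_window_length(
    series: ROITimeSeries,
    candidates: Sequence[float],
    min_s: float = 50.0,
    alpha: float = 0.05,
    pass_fraction: float = 0.9,
    analysis_rate_hz: Optional[float] = 1.25,
) -> float:
    """Smallest candidate window length whose segments look stationary.

    For each candidate the series is cut into nonoverlapping windows and an
    augmented Dickey-Fuller test is run per (ROI, window) segment, on the
    decimated (analysis-rate) segment so the unit-root regression is not
    swamped by oversampling.  The smallest candidate for which at least
    ``pass_fraction`` of segments reject the unit root at ``alpha`` wins.
    """
    from statsmodels.tsa.stattools import adfuller

    candidates = sorted(candidates)
    if any(c < min_s for c in candidates):
        raise ValueError(f"all candidates must be >= {min_s} s")
    if candidates[-1] > series.duration_s:
        raise ValueError("candidate window exceeds series duration")

    if analysis_rate_hz is not None and analysis_rate_hz < series.sampling_rate_hz:
        x, fs = resample_to_rate(series.values, series.sampling_rate_hz, analysis_rate_hz)
    else:
        x, fs = series.values, series.sampling_rate_hz

    rates = {}
    for w in candidates:
        nwin = int(round(w * fs))
        n_windows = x.shape[0] // nwin
        n_pass = n_total = 0
        for k in range(n_windows):
            seg = x[k * nwin : (k + 1) * nwin]
            for r in range(seg.shape[1]):
                y = seg[:, r]
                n_total += 1
                if np.std(y) < 1e-14:
                    continue
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    p = adfuller(y, autolag="AIC")[1]
                if p < alpha:
                    n_pass += 1
        rates[w] = n_pass / max(n_total, 1)
        if rates[w] >= pass_fraction:
            return float(w)
    raise ValueError(
        "no candidate window passed the stationarity screen; pass rates: "
        + ", ".join(f"{w} s: {r:.2f}" for w, r in rates.items())
    )


def pairwise_directed_network(
    window: np.ndarray,
    sampling_rate_hz: float,
    windowing: SpectralWindowing = SpectralWindowing(),
    band_hz: tuple[float, float] = (0.01, 0.07),
    roi_labels: Optional[tuple[str, ...]] = None,
    window_index: int = 0,
) -> DirectedNetwork:
    """Band-averaged bivariate Granger causality for every ordered ROI pair.

    Runs cross-spectrum -> Wilson factorization -> Geweke decomposition ->
    band average per pair.  Pairs whose factorization fails to converge are
    flagged invalid rather than raising.
    """
    x = np.asarray(window, float)
    R = x.shape[1]
    if R < 2:
        raise ValueError("need at least two regions")
    if roi_labels is None:
        roi_labels = tuple(f"R{i}" for i in range(R))
    y, fs = resample_to_rate(x, sampling_rate_hz, windowing.analysis_rate_hz)
    cs = estimate_cross_spectrum(y, fs, windowing)
    edges = np.full((R, R), np.nan)
    valid = np.zeros((R, R), bool)
    n_clipped = 0
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            gc = pairwise_gc_spectrum(cs, i, j)
            if gc.valid:
                edges[i, j] = band_average_gc(gc, band_hz)
                valid[i, j] = True
                n_clipped += gc.n_clipped
            else:
                logger.warning("factorization did not converge for pair %s->%s",
                               roi_labels[i], roi_labels[j])
    net = DirectedNetwork(roi_labels, edges, valid, band_hz, window_index)
    net.n_clipped_bins = n_clipped  # bookkeeping for diagnostics
    return net


@dataclass
class SpectralGCResults:
    """Fitted directed networks for the windows of one series."""

    networks: list[DirectedNetwork]
    roi_labels: tuple[str, ...]
    band_hz: tuple[float, float]
    windowing: SpectralWindowing

    def edge_table(self) -> pd.DataFrame:
        rows = []
        for net in self.networks:
            for i, src in enumerate(net.roi_labels):
                for j, dst in enumerate(net.roi_labels):
                    if i == j:
                        continue
                    rows.append(
                        dict(window=net.window_index, source=src, target=dst,
                             gc=net.edges[i, j], valid=bool(net.valid[i, j]))
                    )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        tab = self.edge_table()
        mean_edges = tab.groupby(["source", "target"])["gc"].mean().reset_index()
        lines = [
            "Spectral Granger causality results",
            "==================================",
            f"windows: {len(self.networks)}   window length: {self.windowing.window_s} s",
            f"band: {self.band_hz[0]}-{self.band_hz[1]} Hz   "
            f"edges/window: {self.networks[0].n_edges if self.networks else 0}",
            "",
            "Mean band GC (nats) over windows:",
            mean_edges.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class SpectralGC:
    """Nonparametric spectral Granger-causality model for one ROI series.

    Parameters
    ----------
    series : ROITimeSeries
        The (T, R) oxyhemoglobin series.
    windowing : SpectralWindowing
        Window length, sub-segmentation, taper and padding parameters.
    band_hz : (float, float)
        Neurovascular band over which GC spectra are averaged.
    first_window_only : bool
        Analyze only the first window of the series (the convention used for
        trial-level networks) instead of all nonoverlapping windows.
    """

    def __init__(
        self,
        series: ROITimeSeries,
        windowing: SpectralWindowing = SpectralWindowing(),
        band_hz: tuple[float, float] = (0.01, 0.07),
        first_window_only: bool = False,
    ):
        self.series = series
        self.windowing = windowing
        self.band_hz = band_hz
        self.first_window_only = first_window_only

    def fit(self) -> SpectralGCResults:
        windows = segment_windows(self.series, self.windowing)
        if self.first_window_only:
            windows = windows[:1]
        nets = [
            pairwise_directed_network(
                w, self.series.sampling_rate_hz, self.windowing, self.band_hz,
                self.series.roi_labels, window_index=k,
            )
            for k, w in enumerate(windows)
        ]
        return SpectralGCResults(nets, self.series.roi_labels, self.band_hz, self.windowing)


def first_window_networks(
    study: StudyDataset,
    windowing: SpectralWindowing = SpectralWindowing(),
    band_hz: tuple[float, float] = (0.01, 0.07),
) -> pd.DataFrame:
    """One directed network per trial record, from the first analysis window.

    Trials shorter than one window are skipped with a logged warning.
    Returns a long-format table (subject, group, condition, trial, source,
    target, gc, valid).
    """
    rows = []
    nwin = windowing.window_s
    for rec in study.records:
        if rec.roi_series.duration_s < nwin - 1e-9:
            logger.warning(
                "trial %s/%s/%d of %.1f s shorter than the %.0f s window; skipped",
                rec.subject_id, rec.condition, rec.trial_index,
                rec.roi_series.duration_s, nwin,
            )
            continue
        res = SpectralGC(rec.roi_series, windowing, band_hz, first_window_only=True).fit()
        net = res.networks[0]
        for i, src in enumerate(net.roi_labels):
            for j, dst in enumerate(net.roi_labels):
                if i == j:
                    continue
                rows.append(dict(
                    subject=rec.subject_id, group=rec.group, condition=rec.condition,
                    trial=rec.trial_index, source=src, target=dst,
                    gc=net.edges[i, j], valid=bool(net.valid[i, j]),
                    score=rec.score,
                ))
    return pd.DataFrame(rows)


def surrogate_threshold(
    series: np.ndarray,
    sampling_rate_hz: float,
    source: int,
    target: int,
    windowing: SpectralWindowing = SpectralWindowing(),
    band_hz: tuple[float, float] = (0.01, 0.07),
    n_surrogates: int = 200,
    quantile: float = 0.95,
    seed: int = 0,
    min_shift_s: float = 5.0,
    window_start_s: float = 0.0,
) -> float:
    """Circular-shift surrogate null threshold for one edge of one window.

    ``series`` is the full (T, R) recording the analysis window was cut
    from.  Each surrogate re-extracts the source channel from a randomly
    shifted position along the series (circularly, with the wrap seam kept
    outside the extracted stretch whenever the series is longer than the
    window), destroying source-target alignment while preserving the source
    autospectrum without introducing a discontinuity.  Returns the
    ``quantile`` of the surrogate band-GC distribution.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(series, float)
    y, fs = resample_to_rate(x[:, [source, target]], sampling_rate_hz, windowing.analysis_rate_hz)
    T = y.shape[0]
    nwin = int(round(windowing.window_s * fs))
    i0 = int(round(window_start_s * fs))
    if i0 + nwin > T:
        raise ValueError("window extends past the series")
    target_win = y[i0 : i0 + nwin, 1]
    min_shift = max(int(round(min_shift_s * fs)), 1)
    # contiguous source stretches at least min_shift away from the window
    allowed = [u for u in range(0, T - nwin + 1) if abs(u - i0) >= min_shift]
    vals = np.empty(n_surrogates)
    src_ext = np.concatenate([y[:, 0], y[:, 0]])  # circular fallback
    for k in range(n_surrogates):
        if allowed:
            u = int(rng.choice(allowed))
        else:
            u = (i0 + int(rng.integers(min_shift, T - min_shift))) % T
        surr = np.column_stack([src_ext[u : u + nwin], target_win])
        cs = estimate_cross_spectrum(surr, fs, windowing)
        gc = pairwise_gc_spectrum(cs, 0, 1)
        vals[k] = band_average_gc(gc, band_hz) if gc.valid else np.nan
    return float(np.nanquantile(vals, quantile))
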