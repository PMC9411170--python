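"""Core data containers shared across the pipeline.

The containers deliberately stay thin: numpy arrays plus metadata, with
validation in ``__post_init__``.  Anything tabular (edge tables, CoV tables,
statistics output) lives in pandas DataFrames produced by the relevant
module.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: Canonical region-of-interest ordering used throughout the package:
#: left/right prefrontal cortex, left/right primary motor cortex,
#: supplementary motor area.
DEFAULT_ROIS: tuple[str, ...] = ("LPFC", "RPFC", "LPMC", "RPMC", "SMA")

#: Source-detector separation (mm) below which a channel is treated as a
#: short-separation (scalp/systemic) channel.
SHORT_CHANNEL_CUTOFF_MM: float = 15.0


@dataclass
class ChannelInfo:
    """Metadata for one fNIRS measurement channel.

    Parameters
    ----------
    channel_id : str
        Unique identifier (e.g. ``"S1-D3"``).
    source_detector_distance_mm : float
        Source-detector separation.  Long channels are 30-40 mm; short
        (systemic) channels ~8 mm.
    roi_label : str or None
        Region assignment for long channels; ``None`` for short channels.
    """

    channel_id: str
    source_detector_distance_mm: float
    roi_label: Optional[str] = None
    short_cutoff_mm: float = SHORT_CHANNEL_CUTOFF_MM

    @property
    def kind(self) -> str:
        return "short" if self.source_detector_distance_mm < self.short_cutoff_mm else "long"

    def __post_init__(self) -> None:
        if self.source_detector_distance_mm <= 0:
            raise ValueError(
                f"channel {self.channel_id}: nonpositive source-detector distance"
            )
        if self.kind == "long" and self.roi_label is None:
            raise ValueError(f"long channel {self.channel_id} lacks an ROI label")


@dataclass
class RawRecording:
    """Two-wavelength raw intensity recording.

    ``intensity`` has shape (T, n_channels, 2) with the last axis ordered as
    ``wavelengths_nm`` (default 690, 830 nm).  Intensities are in arbitrary
    detector units and must be strictly positive (their log is taken when
    converting to optical density).
    """

    sampling_rate_hz: float
    channels: list[ChannelInfo]
    intensity: np.ndarray
    wavelengths_nm: tuple[float, float] = (690.0, 830.0)
    baseline_s: tuple[float, float] = (0.0, 60.0)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 3 or self.intensity.shape[1:] != (len(self.channels), 2):
            raise ValueError(
                "intensity must have shape (T, n_channels, 2); got "
                f"{self.intensity.shape} for {len(self.channels)} channels"
            )
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        bad = np.argwhere(self.intensity <= 0)
        if bad.size:
            t, c, w = bad[0]
            raise ValueError(
                f"nonpositive intensity at sample {t}, channel "
                f"{self.channels[c].channel_id}, wavelength {self.wavelengths_nm[w]} nm"
            )

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def long_channels(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.kind == "long"]

    def short_channels(self) -> list[int]:
        return [i for i, c in enumerate(self.channels) if c.kind == "short"]


@dataclass
class ROITimeSeries:
    """Oxyhemoglobin concentration change per region of interest.

    ``values`` has shape (T, R) in micromolar units, one column per label in
    ``roi_labels``.
    """

    sampling_rate_hz: float
    values: np.ndarray
    roi_labels: tuple[str, ...] = DEFAULT_ROIS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = tuple(self.roi_labels)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.roi_labels):
            raise ValueError(
                f"values must be (T, {len(self.roi_labels)}); got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ROI series contains non-finite samples")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_rois(self) -> int:
        return self.values.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz


@dataclass
class DirectedNetwork:
    """Band-averaged directed Granger-causality network for one window.

    ``edges`` is an (R, R) array with ``edges[i, j]`` the causal influence of
    region i onto region j (nats); the diagonal is NaN and never reported.
    ``valid`` marks edges whose spectral factorization converged.
    """

    roi_labels: tuple[str, ...]
    edges: np.ndarray
    valid: np.ndarray
    band_hz: tuple[float, float] = (0.01, 0.07)
    window_index: int = 0

    def __post_init__(self) -> None:
        r = len(self.roi_labels)
        self.edges = np.asarray(self.edges, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.edges.shape != (r, r) or self.valid.shape != (r, r):
            raise ValueError("edges/valid must be square (R, R) arrays")
        np.fill_diagonal(self.edges, np.nan)
        np.fill_diagonal(self.valid, False)

    @property
    def n_edges(self) -> int:
        r = len(self.roi_labels)
        return r * (r - 1)

    def edge_dict(self) -> dict[str, float]:
        """Edges as ``{"SRC->DST": value}`` in row-major (source, target) order."""
        out = {}
        for i, src in enumerate(self.roi_labels):
            for j, dst in enumerate(self.roi_labels):
                if i != j:
                    out[f"{src}->{dst}"] = float(self.edges[i, j])
        return out


def edge_names(roi_labels=DEFAULT_ROIS) -> list[str]:
    """Ordered names of the R(R-1) directed edges (20 for the 5-ROI montage)."""
    return [
        f"{src}->{dst}"
        for i, src in enumerate(roi_labels)
        for j, dst in enumerate(roi_labels)
        if i != j
    ]


@dataclass
class StudyRecord:
    """One trial of one subject under one simulator condition."""

    subject_id: str
    group: str  # "expert" | "novice"
    condition: str  # "physical" | "vr"
    trial_index: int
    roi_series: ROITimeSeries
    score: float
    raw: Optional[RawRecording] = None


@dataclass
class StudyDataset:
    """All trials of a factorial skill x simulator study, plus ground truth
    (when synthetic).  ``ground_truth[(group, condition)]`` stores the
    generative network for that design cell; empty for real data."""

    records: list[StudyRecord]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.records:
            raise ValueError("StudyDataset needs at least one record")
        labels = self.records[0].roi_series.roi_labels
        rates = {r.roi_series.sampling_rate_hz for r in self.records}
        if any(r.roi_series.roi_labels != labels for r in self.records):
            raise ValueError("records disagree on ROI ordering")
        if len(rates) != 1:
            raise ValueError("records disagree on sampling rate")
        counts: dict[tuple[str, str], int] = {}
        for r in self.records:
            counts[(r.subject_id, r.condition)] = counts.get((r.subject_id, r.condition), 0) + 1
        if len(set(counts.values())) > 1:
            raise ValueError("unequal trial counts across (subject, condition)")

    @property
    def roi_labels(self) -> tuple[str, ...]:
        return self.records[0].roi_series.roi_labels

    @property
    def n_trials(self) -> int:
        first = self.records[0]
        return sum(
            1
            for r in self.records
            if r.subject_id == first.subject_id and r.condition == first.condition
        )
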