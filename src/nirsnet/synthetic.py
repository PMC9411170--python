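"""Ground-truth-known synthetic data for every pipeline stage.

The generative model mirrors the analysis assumptions, so each stage can be
validated by parameter recovery:

* directed couplings are vector-autoregressive (VAR) coefficients acting on
  a slow grid (default 0.5 Hz, i.e. 2-s interregional delays) whose AR
  self-memory concentrates power in the 0.01-0.1 Hz hemodynamic band; the
  realization is band-limited-interpolated to the instrument rate;
* raw intensities follow the Beer-Lambert forward model that the
  preprocessing chain inverts, with optional drifts, motion spikes and a
  shared systemic (Mayer-wave) component that also feeds the
  short-separation channels;
* behavior scores are a linear read-out of selected ground-truth couplings
  plus Gaussian noise;
* a full 2 (skill) x 2 (simulator) factorial study with repeated trials is
  assembled from per-cell networks whose couplings carry the configured
  main and interaction effects.

For every generated design cell, the population band-averaged Granger
causality is available in closed form from the VAR coefficients — the
oracle downstream estimators are judged against.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np
from scipy import signal

from .datatypes import (
    DEFAULT_ROIS,
    ChannelInfo,
    RawRecording,
    ROITimeSeries,
    StudyDataset,
    StudyRecord,
    edge_names,
)
from .optics import DEFAULT_DPF, extinction_matrix
from .spectral import parametric_gc_spectrum

__all__ = [
    "GroundTruthNetwork",
    "default_network",
    "simulate_var",
    "simulate_var_network",
    "population_gc_matrix",
    "default_montage",
    "ArtifactModel",
    "RawSynthesis",
    "synthesize_raw_intensity",
    "simulate_behavior_scores",
    "StudyDesign",
    "generate_study",
]


@dataclass
class GroundTruthNetwork:
    """A stationary VAR ground truth on the slow grid.

    ``coupling`` is (R, R, p); ``coupling[i, j, k-1]`` is the lag-k weight of
    region j's past on region i (row = driven region).  ``slow_rate_hz`` is
    the grid the VAR runs on; one lag at the default 0.5 Hz is a 2-s
    interregional delay, and the AR self-memory keeps most spectral power
    inside the hemodynamic band.
    """

    rois: tuple[str, ...] = DEFAULT_ROIS
    coupling: Optional[np.ndarray] = None
    noise_cov: Optional[np.ndarray] = None
    band_hz: tuple[float, float] = (0.01, 0.1)
    slow_rate_hz: float = 0.5

    def __post_init__(self) -> None:
        R = len(self.rois)
        if self.coupling is None:
            self.coupling = np.zeros((R, R, 1))
        self.coupling = np.asarray(self.coupling, float)
        if self.coupling.ndim == 2:
            self.coupling = self.coupling[:, :, None]
        if self.coupling.shape[:2] != (R, R):
            raise ValueError(f"coupling must be ({R}, {R}, p)")
        if self.noise_cov is None:
            self.noise_cov = np.eye(R)
        self.noise_cov = np.asarray(self.noise_cov, float)
        rad = self.spectral_radius()
        if rad >= 1.0:
            raise ValueError(
                f"VAR is non-stationary: companion spectral radius {rad:.4f} >= 1"
            )
        try:
            np.linalg.cholesky(self.noise_cov)
        except np.linalg.LinAlgError:
            raise ValueError("noise_cov must be symmetric positive definite")

    @property
    def order(self) -> int:
        return self.coupling.shape[2]

    def spectral_radius(self) -> float:
        R, _, p = self.coupling.shape
        comp = np.zeros((R * p, R * p))
        for k in range(p):
            comp[:R, k * R : (k + 1) * R] = self.coupling[:, :, k]
        if p > 1:
            comp[R:, : R * (p - 1)] = np.eye(R * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(comp))))


#: Directed edges present in the default ground truth (source, target).
DEFAULT_TRUE_EDGES = (
    ("RPFC", "SMA"),
    ("LPMC", "SMA"),
    ("SMA", "LPFC"),
    ("RPFC", "LPMC"),
    ("LPMC", "RPFC"),
)


def default_network(
    rois: tuple[str, ...] = DEFAULT_ROIS,
    self_coupling: float = 0.6,
    cross_coupling: float = 0.25,
    edges: tuple[tuple[str, str], ...] = DEFAULT_TRUE_EDGES,
    extra: Optional[dict[tuple[str, str], float]] = None,
) -> GroundTruthNetwork:
    """The package's reference 5-region ground truth: lag-1 self-memory on
    every region plus directed couplings on a sparse edge set."""
    R = len(rois)
    A = np.zeros((R, R, 1))
    np.fill_diagonal(A[:, :, 0], self_coupling)
    idx = {r: i for i, r in enumerate(rois)}
    for src, dst in edges:
        A[idx[dst], idx[src], 0] = cross_coupling
    if extra:
        for (src, dst), delta in extra.items():
            A[idx[dst], idx[src], 0] += delta
    return GroundTruthNetwork(rois, A, np.eye(R))


def unidirectional_pair(
    coupling: float = 1.4,
    self_coupling: float = 0.6,
    labels: tuple[str, str] = ("X", "Y"),
) -> GroundTruthNetwork:
    """Strong unidirectional two-region benchmark (X drives Y at one slow-grid
    lag, population band GC ~2 nats at the defaults) used to validate
    direction recovery from single analysis windows."""
    A = np.zeros((2, 2, 1))
    A[0, 0, 0] = A[1, 1, 0] = self_coupling
    A[1, 0, 0] = coupling
    return GroundTruthNetwork(labels, A, np.eye(2))


def simulate_var(
    coeffs: np.ndarray,
    noise_cov: np.ndarray,
    n_samples: int,
    rng: np.random.Generator,
    burn_in: int = 500,
) -> np.ndarray:
    """Draw one realization of a VAR(p) process (rows of ``coeffs`` index the
    driven variable), discarding ``burn_in`` initial samples."""
    coeffs = np.asarray(coeffs, float)
    if coeffs.ndim == 2:
        coeffs = coeffs[:, :, None]
    R, _, p = coeffs.shape
    L = np.linalg.cholesky(np.asarray(noise_cov, float))
    total = n_samples + burn_in
    e = rng.standard_normal((total, R)) @ L.T
    x = np.zeros((total, R))
    for t in range(p, total):
        acc = e[t].copy()
        for k in range(p):
            acc += coeffs[:, :, k] @ x[t - 1 - k]
        x[t] = acc
    return x[burn_in:]


def simulate_var_network(
    net: GroundTruthNetwork,
    n_samples: int,
    sampling_rate_hz: float,
    seed: Union[int, np.random.Generator] = 0,
    burn_in: int = 500,
    hbo_scale_um: float = 0.5,
    noise_floor_sd_um: float = 0.01,
) -> ROITimeSeries:
    """Simulate an ROI oxyhemoglobin series from a ground-truth network.

    The VAR runs on the slow grid; the realization is band-limited
    interpolated (Fourier resampling) to ``sampling_rate_hz``, scaled to
    ``hbo_scale_um`` micromolar per innovation unit, and a small white
    measurement-noise floor is added (the instrument noise a real recording
    always carries; it keeps estimated spectra full rank).
    """
    if n_samples <= 100 * net.order:
        raise ValueError(f"n_samples must exceed 100 * VAR order ({100 * net.order})")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sampling_rate_hz < net.slow_rate_hz:
        raise ValueError("output rate below the generative grid rate")
    if abs(sampling_rate_hz - net.slow_rate_hz) < 1e-12:
        y = simulate_var(net.coupling, net.noise_cov, n_samples, rng,
                         burn_in=max(burn_in, 100 * net.order))
    else:
        # simulate with generous margins and keep the center: Fourier
        # resampling assumes periodicity, so edges must be discarded
        margin = 32
        n_slow = int(np.ceil(n_samples * net.slow_rate_hz / sampling_rate_hz)) + 2 * margin
        x = simulate_var(net.coupling, net.noise_cov, n_slow, rng,
                         burn_in=max(burn_in, 100 * net.order))
        n_up = int(round(n_slow * sampling_rate_hz / net.slow_rate_hz))
        up = signal.resample(x, n_up, axis=0)
        start = int(round(margin * sampling_rate_hz / net.slow_rate_hz))
        y = up[start : start + n_samples]
        if y.shape[0] < n_samples:  # pragma: no cover - defensive
            raise RuntimeError("internal margin bookkeeping error")
    y = y * hbo_scale_um
    if noise_floor_sd_um > 0:
        y = y + noise_floor_sd_um * rng.standard_normal(y.shape)
    return ROITimeSeries(sampling_rate_hz, y, net.rois)


def population_gc_matrix(
    net: GroundTruthNetwork,
    band_hz: tuple[float, float] = (0.01, 0.07),
    n_freqs: int = 101,
) -> np.ndarray:
    """Closed-form population band-averaged GC for every ordered pair.

    ``out[i, j]`` is the causal influence of region i on region j computed
    from the VAR transfer function on a dense in-band grid.  Frequencies are
    physical (Hz); band-limited interpolation to a higher instrument rate is
    a common invertible filter and leaves these values unchanged in the
    passband.
    """
    R = len(net.rois)
    freqs = np.linspace(band_hz[0], band_hz[1], n_freqs)
    out = np.full((R, R), np.nan)
    for i in range(R):
        for j in range(R):
            if i == j:
                continue
            if R == 2:
                gc = parametric_gc_spectrum(
                    net.coupling, net.noise_cov, freqs, net.slow_rate_hz, i, j
                )
            else:
                gc = parametric_gc_spectrum(
                    net.coupling, net.noise_cov, freqs, net.slow_rate_hz, i, j
                )
            out[i, j] = float(np.mean(gc.values))
    return out


# ---------------------------------------------------------------------------
# Raw-intensity forward model
# ---------------------------------------------------------------------------

def default_montage(
    rois: tuple[str, ...] = DEFAULT_ROIS,
    n_long_per_roi: int = 5,
    n_short: int = 8,
) -> list[ChannelInfo]:
    """A montage shaped like the instrument's: 25 long channels (5 per
    region, 30-40 mm) and 8 short (~8 mm) channels."""
    distances = [30.0, 32.0, 35.0, 38.0, 40.0]
    channels = []
    for roi in rois:
        for k in range(n_long_per_roi):
            channels.append(
                ChannelInfo(f"{roi}-L{k + 1}", distances[k % len(distances)], roi)
            )
    for k in range(n_short):
        channels.append(ChannelInfo(f"SS{k + 1}", 8.0, None))
    return channels


@dataclass
class ArtifactModel:
    """Amplitudes of the nuisance components of raw recordings.

    drift is a per-channel slow baseline wander in optical density; spikes
    are exponentially decaying motion excursions; the systemic component is
    a shared Mayer-wave (~0.095 Hz) plus very-low-frequency oscillation, in
    micromolar, reaching every channel including the short ones.
    """

    drift_amplitude_od: float = 0.0
    spike_rate_per_min: float = 0.0
    spike_amplitude_od: float = 0.05
    systemic_amplitude_um: float = 0.0
    short_noise_um: float = 0.02

    @classmethod
    def realistic(cls) -> "ArtifactModel":
        return cls(drift_amplitude_od=0.01, spike_rate_per_min=0.5,
                   systemic_amplitude_um=0.15)


@dataclass
class RawSynthesis:
    """A synthesized raw recording plus its generative bookkeeping."""

    recording: RawRecording
    od_truth: np.ndarray  # (T_total, n_channels, 2) OD actually applied
    channel_hbo: np.ndarray  # (T_total, n_channels) uM, neural+systemic
    roi_series: ROITimeSeries  # the neural truth (task period)
    spike_times_s: dict[str, list[float]] = field(default_factory=dict)


def synthesize_raw_intensity(
    roi_series: ROITimeSeries,
    montage: Optional[list[ChannelInfo]] = None,
    artifacts: Optional[ArtifactModel] = None,
    seed: Union[int, np.random.Generator] = 0,
    rest_duration_s: float = 60.0,
    dpf: tuple[float, float] = DEFAULT_DPF,
    hbr_ratio: float = -1.0 / 3.0,
    source_intensity: float = 1.0,
) -> RawSynthesis:
    """Beer-Lambert forward model: ROI oxyhemoglobin -> raw intensities.

    A rest (baseline) period of zero neural signal is prepended; long
    channels carry their region's signal, short channels only systemic
    physiology and noise.  Deoxyhemoglobin is coupled as ``hbr_ratio`` times
    oxyhemoglobin.  Intensity is I0 * exp(-dOD) and is strictly positive.

    With ``artifacts=None`` (all nuisance terms off) the preprocessing chain
    (baseline OD, Beer-Lambert inversion, region averaging; filters
    disabled) recovers ``roi_series`` exactly up to numerical round-off.
    """
    if montage is None:
        montage = default_montage(roi_series.roi_labels)
    if artifacts is None:
        artifacts = ArtifactModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    fs = roi_series.sampling_rate_hz
    roi_index = {r: i for i, r in enumerate(roi_series.roi_labels)}
    for roi in roi_series.roi_labels:
        if not any(c.kind == "long" and c.roi_label == roi for c in montage):
            raise ValueError(f"montage assigns no long channel to region {roi}")

    n_rest = int(round(rest_duration_s * fs))
    T_task = roi_series.n_samples
    T = n_rest + T_task
    t = np.arange(T) / fs
    nch = len(montage)

    ext = extinction_matrix()
    if np.linalg.cond(ext) > 1e8:
        raise ValueError("extinction matrix not invertible")

    # shared systemic physiology (uM): Mayer wave + very-low-frequency drift
    if artifacts.systemic_amplitude_um > 0:
        ph = rng.uniform(0, 2 * np.pi, size=2)
        systemic = artifacts.systemic_amplitude_um * (
            np.sin(2 * np.pi * 0.095 * t + ph[0]) + 0.7 * np.sin(2 * np.pi * 0.04 * t + ph[1])
        )
    else:
        systemic = np.zeros(T)

    hbo = np.zeros((T, nch))
    od = np.zeros((T, nch, 2))
    spike_times: dict[str, list[float]] = {}
    for c, ch in enumerate(montage):
        if ch.kind == "long":
            neural = np.zeros(T)
            neural[n_rest:] = roi_series.values[:, roi_index[ch.roi_label]]
        else:
            neural = artifacts.short_noise_um * rng.standard_normal(T)
        hbo[:, c] = neural + systemic
        hbr = hbr_ratio * hbo[:, c]
        conc = np.stack([hbo[:, c], hbr], axis=-1)  # (T, 2) uM
        for w in range(2):
            od[:, c, w] = (
                (ext[w, 0] * conc[:, 0] + ext[w, 1] * conc[:, 1])
                * ch.source_detector_distance_mm
                * dpf[w]
            )
        # nuisance terms in OD, identical at both wavelengths
        nuis = np.zeros(T)
        if artifacts.drift_amplitude_od > 0:
            slope = rng.uniform(-1, 1)
            nuis += artifacts.drift_amplitude_od * (
                slope * (t / t[-1] - 0.5) + 0.5 * np.sin(2 * np.pi * 0.004 * t + rng.uniform(0, 2 * np.pi))
            )
        if artifacts.spike_rate_per_min > 0:
            n_spikes = rng.poisson(artifacts.spike_rate_per_min * t[-1] / 60.0)
            times = np.sort(rng.uniform(5.0, t[-1] - 5.0, size=n_spikes))
            spike_times[ch.channel_id] = list(times)
            tau = 0.5  # s, decay constant of a motion excursion
            for ts in times:
                mask = t >= ts
                nuis[mask] += artifacts.spike_amplitude_od * np.exp(-(t[mask] - ts) / tau)
        od[:, c, :] += nuis[:, None]

    intensity = source_intensity * np.exp(-od)
    rec = RawRecording(
        sampling_rate_hz=fs,
        channels=montage,
        intensity=intensity,
        baseline_s=(0.0, rest_duration_s),
    )
    return RawSynthesis(rec, od, hbo, roi_series, spike_times)


def simulate_behavior_scores(
    edge_truth: np.ndarray,
    weights: dict[str, float],
    intercept: float,
    noise_sd: float,
    seed: Union[int, np.random.Generator] = 0,
    edge_labels: Optional[list[str]] = None,
) -> np.ndarray:
    """Linear behavioral read-out of ground-truth couplings.

    ``edge_truth`` is (n_trials, n_edges) of population band GC per edge;
    ``weights`` maps edge names (``"SRC->DST"``) to linear weights.  Returns
    intercept + sum(w * edge) + N(0, noise_sd) per trial.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    edge_truth = np.atleast_2d(np.asarray(edge_truth, float))
    if edge_labels is None:
        edge_labels = edge_names()
    unknown = set(weights) - set(edge_labels)
    if unknown:
        raise ValueError(f"weights refer to unknown edges: {sorted(unknown)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = np.array([weights.get(e, 0.0) for e in edge_labels])
    mean = intercept + edge_truth @ w
    return mean + noise_sd * rng.standard_normal(mean.shape)


# ---------------------------------------------------------------------------
# Full factorial study
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """A 2 (skill) x 2 (simulator) repeated-trials design.

    Effects are expressed as per-edge coupling offsets applied with effects
    coding (expert = +1, novice = -1; physical = +1, vr = -1); e.g. a skill
    offset of 0.1 on an edge moves its coupling +0.1 for experts and -0.1
    for novices.  The same subjects perform both simulator conditions.
    """

    n_experts: int = 7
    n_novices: int = 6
    n_trials: int = 5
    trial_duration_s: float = 300.0
    rest_duration_s: float = 60.0
    sampling_rate_hz: float = 25.0
    base_network: Optional[GroundTruthNetwork] = None
    skill_effects: dict[str, float] = field(default_factory=lambda: {"RPFC->SMA": 0.08, "LPMC->SMA": 0.08})
    simulator_effects: dict[str, float] = field(default_factory=lambda: {"RPFC->LPMC": 0.08})
    interaction_effects: dict[str, float] = field(default_factory=lambda: {"LPMC->RPFC": 0.08})
    behavior_weights: dict[str, float] = field(default_factory=lambda: {"RPFC->SMA": 21.0})
    behavior_intercept: float = 60.0
    behavior_noise_sd: Union[float, dict[str, float]] = 8.0
    include_raw: bool = True
    artifacts: Optional[ArtifactModel] = None
    subject_sd: float = 0.0  # between-subject coupling jitter (per edge)
    seed: int = 0
    min_trial_s: float = 54.0

    def __post_init__(self) -> None:
        if self.n_trials < 2:
            raise ValueError("n_trials must be >= 2 (trial variability is undefined otherwise)")
        if self.n_experts < 1 or self.n_novices < 1:
            raise ValueError("each group needs at least one subject")
        if self.trial_duration_s < self.min_trial_s:
            raise ValueError(
                f"trial duration {self.trial_duration_s} s below the analysis "
                f"window of {self.min_trial_s} s"
            )
        if self.base_network is None:
            self.base_network = default_network()

    def noise_sd_for(self, group: str) -> float:
        if isinstance(self.behavior_noise_sd, dict):
            return float(self.behavior_noise_sd[group])
        return float(self.behavior_noise_sd)


def _cell_network(design: StudyDesign, group: str, condition: str) -> GroundTruthNetwork:
    skill = 1.0 if group == "expert" else -1.0
    sim = 1.0 if condition == "physical" else -1.0
    base = design.base_network
    idx = {r: i for i, r in enumerate(base.rois)}
    A = base.coupling.copy()
    for eff, code in ((design.skill_effects, skill), (design.simulator_effects, sim),
                      (design.interaction_effects, skill * sim)):
        for name, delta in eff.items():
            src, dst = name.split("->")
            A[idx[dst], idx[src], 0] += code * delta
    return GroundTruthNetwork(base.rois, A, base.noise_cov.copy(), base.band_hz, base.slow_rate_hz)


def generate_study(design: StudyDesign) -> StudyDataset:
    """Assemble the full factorial dataset; deterministic given the seed.

    Each design cell gets its ground-truth network (base couplings plus
    coded effects); each trial is an independent VAR realization; scores are
    the linear behavioral read-out of the cell's population band GC.  The
    per-cell networks and their closed-form band-GC matrices are stored in
    ``StudyDataset.ground_truth``.
    """
    root = np.random.SeedSequence(design.seed)
    band = (0.01, 0.07)
    cells = {}
    for group in ("expert", "novice"):
        for condition in ("physical", "vr"):
            net = _cell_network(design, group, condition)
            cells[(group, condition)] = {
                "network": net,
                "band_gc": population_gc_matrix(net, band),
            }

    labels = design.base_network.rois
    enames = edge_names(labels)
    n_task = int(round(design.trial_duration_s * design.sampling_rate_hz))
    records = []
    subjects = [("expert", f"E{k + 1}") for k in range(design.n_experts)] + [
        ("novice", f"N{k + 1}") for k in range(design.n_novices)
    ]
    streams = root.spawn(len(subjects))
    for (group, sid), subj_seq in zip(subjects, streams):
        cond_streams = subj_seq.spawn(2)
        for condition, cond_seq in zip(("physical", "vr"), cond_streams):
            cell = cells[(group, condition)]
            gc_truth = cell["band_gc"]
            edge_vec = np.array([
                gc_truth[labels.index(e.split("->")[0]), labels.index(e.split("->")[1])]
                for e in enames
            ])
            trial_streams = cond_seq.spawn(design.n_trials)
            for trial, tr_seq in enumerate(trial_streams):
                rng = np.random.default_rng(tr_seq)
                roi = simulate_var_network(
                    cell["network"], n_task, design.sampling_rate_hz, seed=rng
                )
                score = float(simulate_behavior_scores(
                    edge_vec[None, :], design.behavior_weights,
                    design.behavior_intercept, design.noise_sd_for(group),
                    seed=rng, edge_labels=enames,
                )[0])
                raw = None
                if design.include_raw:
                    raw = synthesize_raw_intensity(
                        roi, artifacts=design.artifacts, seed=rng,
                        rest_duration_s=design.rest_duration_s,
                    ).recording
                records.append(StudyRecord(sid, group, condition, trial, roi, score, raw))
    return StudyDataset(records, ground_truth=cells)
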