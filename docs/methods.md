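# Methods

`nirsnet` implements a complete brain-behavior analysis for two-wavelength
continuous-wave fNIRS: raw optical intensities are converted to regional
oxyhemoglobin (HbO₂) series, directed functional connectivity between the
five regions (LPFC, RPFC, LPMC, RPMC, SMA) is estimated per analysis window
by nonparametric spectral Granger causality, trial-to-trial variability is
summarized as coefficients of variation, and the link to task performance is
assessed with factorial effect tests under FDR control, backward-elimination
regression, and recursive path analysis. A synthetic-data generator with
closed-form ground truth makes each stage testable by parameter recovery.

## Preprocessing

The chain is: change in optical density ΔOD(t) = −ln(I(t)/Ī) against the
mean intensity of the pre-task rest (default: the first 60 s); motion
correction by Savitzky–Golay smoothing-replacement (default 3-s window,
polynomial order 3 — the signal is replaced by its local polynomial fit, so
polynomials up to the order pass unchanged while sample-scale excursions are
damped); zero-phase 3rd-order Butterworth bandpass at 0.01–0.1 Hz; modified
Beer–Lambert inversion per channel,

    ΔOD_λ = (ε_HbO,λ ΔHbO₂ + ε_HbR,λ ΔHbR) · d · DPF_λ,

with source–detector distance d (mm), differential pathlength factors
(6.4, 5.8) at (690, 830) nm, and the standard compiled hemoglobin extinction
table (natural-log convention, µM·mm units); and finally the unweighted mean
of each region's long (30–40 mm) channels. Filtering happens on optical
density, before the Beer–Lambert step; every step after the logarithm is
linear, so the chain obeys superposition. Short-separation (~8 mm) channels
carry only scalp/systemic physiology; regressing them out of the long
channels is implemented but disabled by default, since whether to apply it
is an analysis choice. Deoxyhemoglobin is computed and returned but not
propagated into the network analysis.

## Spectral Granger causality

Each ROI series is cut into nonoverlapping 54-s windows starting at task
onset (trailing remainder dropped). 54 s sits above the 50-s floor
suggested by stationarity screening of this class of signals; an augmented
Dickey–Fuller screen over candidate lengths is available
(`select_window_length`) but the fixed default is used unless selection is
requested. The screen's power is inherently limited on 50–60-s windows of
smooth hemodynamic-band signals (the unit-root test sees ~25–70 effective
samples), which is why it is a screen, not a gate.

Within a window the cross-spectral density matrix S(f) is estimated by
averaging tapered, zero-padded sub-segment periodogram outer products
(Welch/STFT estimator): Hann-tapered sub-segments of 16 s at 87.5% overlap,
linearly detrended, zero-padded to a 0.005-Hz grid. Dense overlap is
deliberate: a 54-s window yields only 2 segments at the textbook 50%
overlap, which leaves the spectral matrix too noisy for factorization-based
causality (direction recovery was near chance in simulation); at 87.5%
overlap the estimator uses nearly all of the window's effective spectral
degrees of freedom. Before estimation the window is decimated to an
analysis rate of 1.25 Hz (identical polyphase filter on every channel —
Granger causality is invariant under common invertible filtering in the
passband), which keeps the factorization well conditioned while retaining
at least 64 samples per window.

The spectral matrix is factorized with Wilson's iterative minimum-phase
algorithm, S(f) = H(f) Σ H(f)*, operating on the uniform two-sided density
(interior-frequency doubling of the one-sided estimate is undone first; the
algorithm requires smoothness across DC and Nyquist). A per-channel
diagonal ridge of 1e-8 times each channel's mean power keeps nearly
singular spectra factorizable without breaking scale invariance. The
iteration stops at a relative update below 1e-9 or when it plateaus (rough
finite-sample spectra impose a lag-truncation floor); the result carries an
honest `converged` flag based on the reconstruction residual
max_f ‖S − HΣH*‖/‖S‖ (default threshold 1e-2) plus the residual itself.
On analytic VAR spectra the residual reaches ~1e-13.

For every ordered region pair the 2×2 submatrix of S is refactorized
(bivariate, not conditional, causality) and the Geweke decomposition is
evaluated:

    f_{s→t}(f) = ln [ S_tt(f) / ( S_tt(f) − (Σ_ss − Σ_st²/Σ_tt) |H_ts(f)|² ) ]

with S_tt taken from the factorization model itself so that density
conventions cancel. Negative values (finite-sample artifacts) are clipped
to zero and counted. The scalar edge weight is the unweighted mean of
f_{s→t} over grid frequencies in the neurovascular band 0.01–0.07 Hz
(endpoints inclusive; 13 bins at the default grid). Five regions give
exactly 20 directed edges per window; trial-level networks use the first
window of each trial.

Significance of a single edge can be calibrated with time-shift surrogates:
the source channel is re-extracted from a shifted position along the full
trial (seam kept outside the window), preserving its autospectrum while
destroying source-target alignment. Within-window circular shifts are a
fallback when no longer series exists; they slightly under-disperse the
null for band-limited signals because the wrap seam injects broadband
power.

## Synthetic ground truth

The generator mirrors the analysis assumptions. Directed couplings are
lag-1 VAR coefficients on a slow grid (default 0.5 Hz, i.e. 2-s
interregional delays — a plausible neurovascular latency), with AR(1)
self-memory 0.6 per region concentrating ~75% of spectral power below
0.1 Hz. The realization is Fourier-interpolated to the instrument rate
(default 25 Hz; simulated with 32-slow-sample margins because Fourier
resampling is circular), scaled to 0.5 µM per innovation unit, and a small
white measurement-noise floor (0.01 µM) is added — the instrument noise any
real recording carries, which also keeps estimated spectra full rank. A
hard 0.1-Hz low-pass is deliberately NOT applied: the minimum-phase
factorization is global over frequency, and truncating the spectrum makes
the in-band transfer estimates ill-conditioned (direction recovery dropped
from ~97% to ~71% in simulation when a 0.1-Hz low-pass was added). This is
also a caution about the method on heavily band-limited real data.

The population band causality of any generated network is available in
closed form from the VAR transfer function H(f) = (I − A e^{−iωΔ})⁻¹,
evaluated on a dense in-band grid — the oracle all estimator tests compare
against. Because pairwise causality is computed on two-region subprocesses,
the oracle for the five-region network correctly shows nonzero values on
indirect routes (e.g. a RPFC→SMA→LPFC chain induces pairwise RPFC→LPFC
causality); that is a property of bivariate Granger causality, not an
error.

The factorial study mirrors the protocol: 7 experts and 6 novices, each
performing 5 trials of up to 300 s (after a 60-s rest) in both a physical
and a VR simulator, at 25 Hz. Skill, simulator and interaction effects are
coupling offsets applied with effects coding (expert/physical = +1); the
defaults put skill effects on RPFC→SMA and LPMC→SMA, a simulator effect on
RPFC→LPMC and an interaction on LPMC→RPFC (offset 0.08 on a base coupling
of 0.25, chosen so every design cell stays comfortably stationary —
companion spectral radius ≤ 0.93). Behavior scores are a linear read-out of
the cell's population band causality (default: intercept 60, weight 21 on
RPFC→SMA, Gaussian noise SD 8, echoing the magnitude of performance scores
and their reported association), with optional group-specific noise for
variability studies. Raw intensities follow the Beer–Lambert forward model
over a 25-long/8-short channel montage, with optional baseline drift,
exponentially decaying motion spikes, and a shared Mayer-wave (~0.095 Hz)
plus very-low-frequency systemic component that also feeds the short
channels. With artifacts off, the preprocessing chain inverts the forward
model exactly (round-trip error ~1e-15).

A strong unidirectional two-region benchmark (`unidirectional_pair`,
coupling 1.4, population band causality ≈ 2 nats) is the reference
configuration for single-window direction recovery. Single 54-s windows of
0.01–0.1 Hz signal carry only ~3–6 effective spectral degrees of freedom in
the causality band, so single-window edge estimates are intrinsically noisy
(null edges average ~0.1–0.4 nats of estimator bias); at realistic coupling
strengths direction recovery from one window is closer to 60–80%, and
reliable inference requires the trial/window averaging the statistics stage
performs. This is a genuine limitation of short-window spectral causality,
not of the implementation — the estimator converges to the oracle as the
window grows (2% relative error at 2^14 samples).

## Statistics

The factorial stage runs, per dependent variable (each edge, each edge CoV,
the score, the score CoV), a two-factor between-subject linear model with
interaction, effects coding and Type-III sums of squares — the
between-subject effect tests a point-and-click MANOVA reports — with
partial η² = SS_effect/(SS_effect + SS_error). Repeated trials are reduced
to subject-by-condition means by default (`trial-as-replicate` is
available). Shapiro–Wilk normality and Levene variance screens are
advisory. p-values are adjusted across the 20 edges within each effect by
Benjamini–Hochberg step-up FDR at q = 0.05 (the implementation is
cross-checked against a literal step-up oracle). Estimated marginal means
with model-based standard errors feed effect plots.

Brain-behavior regression is backward elimination: refit OLS, drop the
predictor with the largest p-value while it exceeds the removal threshold
0.1, recording the elimination trace. With pure-noise predictors each
survives the final check with probability ≈ 0.1, so the expected
"only-the-true-predictor" rate with two noise covariates is ≈ 0.81 — a
property of the procedure worth remembering when reading its output. When
a small study has fewer trials than predictors, the pipeline pre-screens
edges by absolute correlation with the score before elimination (logged).

The path analysis is a recursive (acyclic) model — skill and simulator
codes → five mediator edges → score — estimated equation-wise by OLS;
estimates are unstandardized, C.R. = Estimate/S.E. is referred to the
standard normal (structural-equation software convention), and the arrow
table mirrors the Dependent/Independent/Estimate/S.E./C.R./P layout, with
BH adjustment across arrows. A 2-S.E. interval around each estimate covers
the truth at the theoretical ~95% rate; note that requiring *every* arrow
of a 15-arrow model to be covered simultaneously succeeds in only ~half of
replicates — coverage is a per-arrow property.

## Problem sizes used in validation

The test suite and `scripts/acceptance.py` validate on: 20 seeds × 2^14
samples for estimator-vs-oracle agreement; 200 windows × 200 surrogates for
null calibration; 100 windows for direction recovery; 200 replicates for
factorial type-I uniformity; 1,000 random vectors for the FDR cross-check;
100 runs for backward elimination; 50 replicates (n = 500) for path
recovery plus 100 null replicates for C.R. calibration. Study-level tests
use reduced designs (2–3 subjects per group, 2–3 trials of 54–120 s at
5 Hz); the full-protocol design remains the generator default.

## Known limitations

- Bivariate (not conditional) causality: indirect routes produce genuine
  pairwise edges; no claim of direct anatomical coupling is implied.
- Single-window edge estimates at 54 s are bias-dominated for weak
  couplings; group statistics, not single windows, carry the inference.
- The Wilson factorization degrades on spectra that are numerically zero
  over much of the frequency axis; the analysis-rate decimation and the
  generator's noise floor both exist to avoid that regime, and sharply
  band-limited real data will inherit the same difficulty.
- The ADF-based window screen has limited power on smooth signals at
  candidate lengths of 50–60 s; it cannot certify stationarity, only flag
  gross violations.
- Behavior scores are modeled as a linear function of population couplings
  plus noise; no trial-level neural-behavioral coupling is simulated.
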