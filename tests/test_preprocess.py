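"""Preprocessing chain: optical density, motion correction, filtering,
Beer-Lambert inversion, region averaging."""

import numpy as np
import pytest

from nirsnet.datatypes import ChannelInfo, RawRecording
from nirsnet.optics import extinction_matrix
from nirsnet.preprocess import (
    PreprocessConfig,
    average_rois,
    bandpass,
    correct_motion_sg,
    intensity_to_od,
    mbll,
    preprocess_recording,
    regress_short_channels,
)
from nirsnet.synthetic import (
    ArtifactModel,
    default_network,
    simulate_var_network,
    synthesize_raw_intensity,
)


def _flat_recording(T=300, fs=10.0, level=2.0):
    ch = [ChannelInfo("C1", 30.0, "LPFC")]
    intensity = np.full((T, 1, 2), level)
    return RawRecording(fs, ch, intensity, baseline_s=(0.0, 5.0))


class TestIntensityToOD:
    def test_constant_intensity_gives_zero_od(self):
        od = intensity_to_od(_flat_recording())
        assert np.allclose(od, 0.0)

    def test_e_fold_drop_gives_unit_od(self):
        raw = _flat_recording()
        raw.intensity[100, 0, 0] = 2.0 * np.exp(-1)
        od = intensity_to_od(raw, baseline_s=(0.0, 5.0))
        assert od[100, 0, 0] == pytest.approx(1.0, abs=1e-6)

    def test_baseline_mean_is_zero(self):
        rng = np.random.default_rng(0)
        raw = _flat_recording()
        raw.intensity *= np.exp(rng.normal(0, 0.01, raw.intensity.shape))
        od = intensity_to_od(raw)
        # mean OD over baseline equals -ln of the geometric-mean ratio, ~0
        assert np.abs(od[:50].mean(axis=0)).max() < 1e-3

    def test_nonpositive_intensity_rejected(self):
        raw = _flat_recording()
        with pytest.raises(ValueError, match="nonpositive"):
            raw.intensity[5, 0, 1] = 0.0
            RawRecording(raw.sampling_rate_hz, raw.channels, raw.intensity)

    def test_baseline_outside_recording_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            intensity_to_od(_flat_recording(), baseline_s=(0.0, 1000.0))


class TestSavitzkyGolay:
    def test_cubic_polynomial_passes_unchanged(self):
        t = np.linspace(0, 10, 251)
        x = 0.3 * t**3 - t**2 + 2 * t - 5
        out = correct_motion_sg(x[:, None], sampling_rate_hz=25.0, window_s=3.0, polyorder=3)
        assert np.allclose(out[:, 0], x, atol=1e-9)

    def test_constant_series_unchanged(self):
        x = np.full((200, 2), 3.14)
        out = correct_motion_sg(x, 25.0)
        assert np.allclose(out, x)

    def test_spike_attenuated(self):
        x = np.zeros(500)
        x[250] = 1.0
        out = correct_motion_sg(x[:, None], sampling_rate_hz=25.0, window_s=3.0, polyorder=3)
        assert np.abs(out[250, 0]) < 0.2  # >= 80% reduction

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            correct_motion_sg(np.zeros((10, 1)), 25.0, window_s=3.0)


class TestBandpass:
    def test_passband_sinusoid_preserved(self):
        fs, T = 10.0, 6000
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = bandpass(x[:, None], fs)[:, 0]
        mid = slice(T // 4, 3 * T // 4)
        ratio = np.abs(y[mid]).max() / np.abs(x[mid]).max()
        assert 0.95 < ratio < 1.05

    def test_stopband_sinusoid_attenuated(self):
        fs, T = 10.0, 6000
        t = np.arange(T) / fs
        x = np.sin(2 * np.pi * 0.5 * t)
        y = bandpass(x[:, None], fs)[:, 0]
        assert np.abs(y[T // 4 : -T // 4]).max() < 0.05

    def test_dc_rejected(self):
        y = bandpass(np.full((5000, 1), 7.0), 10.0)
        assert np.abs(y).max() < 1e-6

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass(np.zeros((5000, 1)), 10.0, low_hz=0.1, high_hz=0.01)


class TestMBLL:
    def test_zero_od_gives_zero_concentration(self):
        hbo, hbr = mbll(np.zeros(10), np.zeros(10), 30.0)
        assert np.allclose(hbo, 0) and np.allclose(hbr, 0)

    def test_default_pathlength_factors(self):
        from nirsnet.optics import DEFAULT_DPF

        assert DEFAULT_DPF == (6.4, 5.8)

    def test_forward_inverse_identity(self, rng):
        # forward model through the extinction matrix, then invert
        conc = rng.normal(0, 0.5, (100, 2))  # (HbO, HbR) in uM
        ext = extinction_matrix()
        d, dpf = 35.0, (6.4, 5.8)
        od = (conc @ ext.T) * d * np.asarray(dpf)
        hbo, hbr = mbll(od[:, 0], od[:, 1], d)
        assert np.allclose(hbo, conc[:, 0], rtol=1e-9)
        assert np.allclose(hbr, conc[:, 1], rtol=1e-9)

    def test_singular_extinction_rejected(self):
        with pytest.raises(ValueError, match="singular|invertible"):
            mbll(np.zeros(5), np.zeros(5), 30.0, extinction=np.ones((2, 2)))


class TestShortChannelRegression:
    def test_disabled_is_identity(self, rng):
        x = rng.normal(size=(100, 3))
        out = regress_short_channels(x, rng.normal(size=(100, 1)), enabled=False)
        assert np.array_equal(out, x)

    def test_long_equals_short_gives_zero_residual(self, rng):
        s = rng.normal(size=100)
        out = regress_short_channels(s[:, None], s[:, None], enabled=True)
        assert np.abs(out).max() < 1e-10

    def test_systemic_component_removed(self, rng):
        neural = rng.normal(size=2000)
        systemic = np.sin(2 * np.pi * 0.1 * np.arange(2000) / 10.0)
        long = (neural + 0.7 * systemic)[:, None]
        out = regress_short_channels(long, systemic[:, None], enabled=True)
        assert abs(np.corrcoef(out[:, 0], systemic)[0, 1]) <= 0.05

    def test_enabled_without_short_channels_rejected(self, rng):
        with pytest.raises(ValueError, match="no short"):
            regress_short_channels(rng.normal(size=(50, 1)), np.empty((50, 0)), enabled=True)


class TestAverageROIs:
    def test_identical_channels_average_to_themselves(self, rng):
        x = rng.normal(size=100)
        chans = [ChannelInfo("a", 30.0, "LPFC"), ChannelInfo("b", 32.0, "LPFC")]
        roi = average_rois(np.column_stack([x, x]), chans, 10.0)
        assert np.allclose(roi.values[:, 0], x)

    def test_two_channel_arithmetic(self):
        chans = [ChannelInfo("a", 30.0, "LPFC"), ChannelInfo("b", 32.0, "LPFC")]
        data = np.array([[1.0, 3.0], [2.0, 4.0], [0.0, -2.0]])
        roi = average_rois(data, chans, 10.0)
        assert np.allclose(roi.values[:, 0], [2.0, 3.0, -1.0])

    def test_short_channels_excluded(self, rng):
        chans = [ChannelInfo("a", 30.0, "LPFC"), ChannelInfo("ss", 8.0)]
        x = rng.normal(size=(50, 2))
        roi = average_rois(x, chans, 10.0)
        assert np.allclose(roi.values[:, 0], x[:, 0])

    def test_empty_roi_rejected(self, rng):
        chans = [ChannelInfo("a", 30.0, "LPFC")]
        with pytest.raises(ValueError, match="SMA"):
            average_rois(np.zeros((10, 1)), chans, 10.0, roi_labels=("SMA",))


class TestEndToEnd:
    def test_artifact_free_round_trip(self):
        """Forward Beer-Lambert model then the inverse chain recovers the
        ROI series to numerical precision (filters off, artifacts off)."""
        net = default_network()
        roi = simulate_var_network(net, int(90 * 10), 10.0, seed=5)
        syn = synthesize_raw_intensity(roi, artifacts=None, seed=1, rest_duration_s=20.0)
        cfg = PreprocessConfig(motion_correction=False, bandpass_filter=False,
                               baseline_s=(0.0, 20.0))
        rec, _ = preprocess_recording(syn.recording, cfg)
        rel = np.max(np.abs(rec.values - roi.values)) / np.max(np.abs(roi.values))
        assert rel < 1e-6

    def test_od_bookkeeping_matches_generator(self):
        net = default_network()
        roi = simulate_var_network(net, 600, 10.0, seed=3)
        syn = synthesize_raw_intensity(roi, artifacts=None, seed=2, rest_duration_s=10.0)
        od = intensity_to_od(syn.recording, (0.0, 10.0))
        # long channels have zero baseline signal, so the baseline-mean
        # normalization cancels exactly; short channels carry noise
        long_idx = syn.recording.long_channels()
        assert np.max(np.abs(od[:, long_idx] - syn.od_truth[:, long_idx])) < 1e-10

    def test_chain_is_linear_from_od(self, rng):
        """Superposition through SG -> bandpass -> Beer-Lambert -> averaging."""
        fs, T = 10.0, 1200
        chans = [ChannelInfo("a", 30.0, "LPFC"), ChannelInfo("b", 32.0, "LPFC")]

        def chain(od):
            od = correct_motion_sg(od, fs)
            od = bandpass(od, fs)
            hbo = np.empty((T, 2))
            for i, ch in enumerate(chans):
                hbo[:, i], _ = mbll(od[:, i, 0], od[:, i, 1], ch.source_detector_distance_mm)
            return average_rois(hbo, chans, fs).values

        a = rng.normal(0, 0.01, (T, 2, 2))
        b = rng.normal(0, 0.01, (T, 2, 2))
        lhs = chain(a + b)
        rhs = chain(a) + chain(b)
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    def test_motion_spike_attenuated_by_declared_order(self):
        """A spike in raw intensity is damped by the motion-correction step
        applied on optical density before the Beer-Lambert conversion."""
        net = default_network()
        roi = simulate_var_network(net, 900, 10.0, seed=9)
        art = ArtifactModel(spike_rate_per_min=4.0, spike_amplitude_od=0.2)
        syn = synthesize_raw_intensity(roi, artifacts=art, seed=4, rest_duration_s=20.0)
        base = PreprocessConfig(motion_correction=False, bandpass_filter=False,
                                baseline_s=(0.0, 20.0))
        sg = PreprocessConfig(motion_correction=True, bandpass_filter=False,
                              baseline_s=(0.0, 20.0))
        raw_out, _ = preprocess_recording(syn.recording, base)
        sg_out, _ = preprocess_recording(syn.recording, sg)
        dev_raw = np.max(np.abs(raw_out.values - roi.values))
        dev_sg = np.max(np.abs(sg_out.values - roi.values))
        assert dev_sg < 0.75 * dev_raw

    def test_spikes_visible_at_seeded_times(self):
        net = default_network()
        roi = simulate_var_network(net, 3000, 10.0, seed=11)
        art = ArtifactModel(spike_rate_per_min=2.0, spike_amplitude_od=0.3)
        syn = synthesize_raw_intensity(roi, artifacts=art, seed=5, rest_duration_s=30.0)
        od = intensity_to_od(syn.recording, (0.0, 30.0))
        fs = syn.recording.sampling_rate_hz
        ids = [ch.channel_id for ch in syn.recording.channels]
        found = total = 0
        for cid, times in syn.spike_times_s.items():
            c = ids.index(cid)
            for ts in times:
                total += 1
                i = int(round(ts * fs)) + 1
                # onset jump of the exponential excursion: ~spike amplitude
                if od[i, c, 0] - od[i - 4, c, 0] > 0.15:
                    found += 1
        assert total > 0 and found >= 0.9 * total
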