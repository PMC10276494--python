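"""Optical chain: OD conversion, motion detection/correction, band-pass,
Beer-Lambert inversion, block averaging, ROI means."""

import numpy as np
import pytest

from cortimuscle import fnirs
from cortimuscle.errors import ConfigurationError, ParameterError, ValidationError
from cortimuscle.montage import default_montage
from cortimuscle.paradigm import TaskParadigm
from cortimuscle.recordings import RawIntensitySeries
from cortimuscle.simulate import band_limited_noise, inject_artifacts


def _od(x, rate=10.0, **kw):
    """Wrap a 1-D trace as a single-channel dual-wavelength OD series."""
    return fnirs.OpticalDensitySeries(np.repeat(x[:, None, None], 2, axis=2),
                                      rate=rate, **kw)


class TestIntensityToOD:
    def test_constant_intensity_gives_zero(self):
        raw = RawIntensitySeries(np.full((100, 2, 2), 1.3))
        od = fnirs.intensity_to_od(raw)
        assert np.abs(od.dod).max() < 1e-12

    def test_exact_inverse_relation(self, rng):
        x = 0.01 * rng.standard_normal((200, 1, 2))
        raw = RawIntensitySeries(np.exp(-x))
        od = fnirs.intensity_to_od(raw)
        shift = np.log(np.exp(-x).mean(axis=0))
        assert np.allclose(od.dod, x + shift, atol=1e-12)
        assert np.abs(od.dod.mean(axis=0)).max() < 1e-3

    def test_nonpositive_intensity_names_channel(self):
        samples = np.ones((50, 2, 2))
        samples[7, 1, 0] = 0.0
        raw = RawIntensitySeries(samples, channel_ids=np.array([3, 9]))
        with pytest.raises(ValidationError, match="channel 9"):
            fnirs.intensity_to_od(raw)


class TestMotionDetection:
    def test_clean_sinusoid_empty_mask(self):
        t = np.arange(6000) / 10.0
        od = _od(0.01 * np.sin(2 * np.pi * 0.05 * t))
        assert not fnirs.detect_motion_artifacts(od).any()

    @pytest.mark.parametrize("kind", ["spike", "step"])
    def test_injected_artifact_flagged(self, kind):
        rng = np.random.default_rng(5)
        clean = 0.002 * band_limited_noise(rng, 6000, 10.0, (0.01, 0.1))
        dirty, _ = inject_artifacts(clean[:, None, None], 10.0,
                                    [(100.0, kind, 10 * clean.std())])
        od = fnirs.OpticalDensitySeries(np.repeat(dirty, 2, axis=2), rate=10.0)
        mask = fnirs.detect_motion_artifacts(od)
        sl = slice(int((100.0 - 1.0) * 10), int((100.0 + 1.0) * 10))
        assert mask[sl, 0].any()
        assert mask[:, 0].mean() < 0.2  # not flagging the whole record

    def test_window_too_short_rejected(self):
        od = _od(np.zeros(100))
        with pytest.raises(ParameterError, match="window"):
            fnirs.detect_motion_artifacts(od, window=0.05)


class TestSplineCorrect:
    def test_empty_mask_identity(self, rng):
        od = _od(0.01 * rng.standard_normal(500))
        mask = np.zeros((500, 1), dtype=bool)
        out = fnirs.spline_correct(od, mask)
        assert np.array_equal(out.dod, od.dod)

    def test_spike_rmse_halved(self):
        rng = np.random.default_rng(20)
        clean = 0.002 * band_limited_noise(rng, 6000, 10.0, (0.01, 0.1))
        dirty, _ = inject_artifacts(clean[:, None, None], 10.0,
                                    [(200.0, "spike", 10 * clean.std())])
        od = fnirs.OpticalDensitySeries(np.repeat(dirty, 2, axis=2), rate=10.0)
        corr = fnirs.spline_correct(od, fnirs.detect_motion_artifacts(od))
        rmse_unc = np.sqrt(np.mean((dirty[:, 0, 0] - clean) ** 2))
        rmse_cor = np.sqrt(np.mean((corr.dod[:, 0, 0] - clean) ** 2))
        assert rmse_cor <= 0.5 * rmse_unc

    def test_step_discontinuity_mostly_removed(self):
        rng = np.random.default_rng(12)
        clean = 0.002 * band_limited_noise(rng, 6000, 10.0, (0.01, 0.1))
        h = 10 * clean.std()
        dirty, _ = inject_artifacts(clean[:, None, None], 10.0, [(300.0, "step", h)])
        od = fnirs.OpticalDensitySeries(np.repeat(dirty, 2, axis=2), rate=10.0)
        corr = fnirs.spline_correct(od, fnirs.detect_motion_artifacts(od))
        err = corr.dod[:, 0, 0] - clean
        mask = fnirs.detect_motion_artifacts(od)[:, 0]
        runs = np.flatnonzero(mask)
        a, b = runs.min(), runs.max() + 1
        disc = abs(err[b:b + 20].mean() - err[a - 20:a].mean())
        assert disc < 0.1 * h

    def test_flagged_segment_at_record_start_anchors_one_sided(self):
        rng = np.random.default_rng(13)
        clean = 0.002 * band_limited_noise(rng, 2000, 10.0, (0.01, 0.1))
        dirty = clean.copy()
        dirty[:15] += 0.05  # artifact touching the first sample
        od = _od(dirty)
        mask = np.zeros((2000, 1), dtype=bool)
        mask[:20, 0] = True
        corr = fnirs.spline_correct(od, mask)
        assert np.all(np.isfinite(corr.dod))
        # anchored to the following clean level, not the contaminated one
        assert abs(corr.dod[:20, 0, 0].mean() - clean[20:40].mean()) < 0.01

    def test_bad_smoothing_rejected(self):
        od = _od(np.zeros(100))
        with pytest.raises(ParameterError):
            fnirs.spline_correct(od, np.zeros((100, 1), bool), smoothing=1.5)


class TestBandpass:
    @pytest.mark.parametrize("freq,check", [
        (1.0, lambda g: g <= 0.1),    # cardiac tone: >= 20 dB down
        (0.05, lambda g: 0.9 <= g <= 1.0),
    ])
    def test_tone_gains(self, freq, check):
        t = np.arange(20000) / 10.0
        od = _od(np.sin(2 * np.pi * freq * t))
        out = fnirs.bandpass_hemodynamic(od).dod[5000:15000, 0, 0]
        gain = np.sqrt(np.mean(out ** 2) / 0.5)
        assert check(gain)

    def test_zero_in_zero_out(self):
        out = fnirs.bandpass_hemodynamic(_od(np.zeros(4000)))
        assert np.abs(out.dod).max() < 1e-12

    def test_zero_phase(self):
        from scipy.signal import correlate
        t = np.arange(20000) / 10.0
        x = np.sin(2 * np.pi * 0.05 * t)
        y = fnirs.bandpass_hemodynamic(_od(x)).dod[:, 0, 0]
        sl = slice(5000, 15000)
        xc = correlate(y[sl], x[sl], mode="same")
        assert np.argmax(np.abs(xc)) == len(xc) // 2

    def test_idempotent_within_tolerance(self):
        rng = np.random.default_rng(3)
        x = band_limited_noise(rng, 6000, 10.0, (0.03, 0.06))
        once = fnirs.bandpass_hemodynamic(_od(x))
        twice = fnirs.bandpass_hemodynamic(once)
        sl = slice(1000, 5000)
        p1 = np.mean(once.dod[sl, 0, 0] ** 2)
        p2 = np.mean(twice.dod[sl, 0, 0] ** 2)
        assert abs(p2 - p1) / p1 < 0.01

    def test_short_record_warns(self):
        with pytest.warns(UserWarning, match="shorter than three"):
            fnirs.bandpass_hemodynamic(_od(np.zeros(1000)))


class TestBeerLambert:
    def test_known_concentrations_recovered(self, montage):
        dhbo2 = np.full((10, 63), 1.0)
        dhbr = np.full((10, 63), -0.3)
        dod = fnirs.forward_beer_lambert(dhbo2, dhbr, montage)
        od = fnirs.OpticalDensitySeries(dod, rate=10.0, channel_ids=montage.channel_ids)
        hb = fnirs.od_to_hemoglobin(od, montage)
        assert np.abs(hb.dhbo2 - 1.0).max() < 1e-9
        assert np.abs(hb.dhbr + 0.3).max() < 1e-9

    def test_zero_od_zero_concentration(self, montage):
        od = fnirs.OpticalDensitySeries(np.zeros((5, 63, 2)), rate=10.0,
                                        channel_ids=montage.channel_ids)
        hb = fnirs.od_to_hemoglobin(od, montage)
        assert np.abs(hb.dhbo2).max() == 0.0

    def test_separation_linearity(self, montage, rng):
        dod = 0.01 * rng.standard_normal((20, 63, 2))
        od = fnirs.OpticalDensitySeries(dod, rate=10.0, channel_ids=montage.channel_ids)
        hb1 = fnirs.od_to_hemoglobin(od, montage)
        wide = default_montage()
        wide.separation_cm = 6.0
        hb2 = fnirs.od_to_hemoglobin(od, wide)
        assert np.allclose(hb2.dhbo2, hb1.dhbo2 / 2.0)

    def test_unknown_wavelengths_rejected(self):
        with pytest.raises(ConfigurationError):
            fnirs.extinction_matrix((700.0, 900.0))


class TestBlockAverage:
    def test_constant_series_zero_amplitude(self, paradigm):
        hb = fnirs.HemoglobinSeries(np.full((3700, 1), 2.0), np.zeros((3700, 1)), rate=10.0)
        est = fnirs.block_average_hrf(hb, paradigm)
        assert est.channel_amplitude[1] == 0.0

    def test_boxcar_recovered_exactly(self, paradigm):
        t = np.arange(3700) / 10.0
        box = 0.5 * ((t >= 30.0) & (t < 360.0))
        hb = fnirs.HemoglobinSeries(box[:, None], np.zeros((3700, 1)), rate=10.0)
        est = fnirs.block_average_hrf(hb, paradigm)
        assert est.channel_amplitude[1] == pytest.approx(0.5, abs=1e-12)

    def test_window_exceeding_record_rejected(self, paradigm):
        hb = fnirs.HemoglobinSeries(np.zeros((100, 1)), np.zeros((100, 1)), rate=10.0)
        with pytest.raises(ValidationError):
            fnirs.block_average_hrf(hb, paradigm)


class TestROIAverage:
    def test_identical_channels_pass_through(self, montage, rng):
        x = rng.standard_normal(100)
        hb = fnirs.HemoglobinSeries(np.tile(x[:, None], (1, 63)), np.zeros((100, 63)),
                                    rate=10.0, channel_ids=montage.channel_ids)
        roi = fnirs.roi_average(hb, montage)
        for label in roi.roi_labels:
            assert np.allclose(roi.roi(label), x)

    def test_antisymmetric_pair_cancels(self, rng):
        montage = default_montage().subset([5, 6])
        x = rng.standard_normal(100)
        hb = fnirs.HemoglobinSeries(np.column_stack([x, -x]), np.zeros((100, 2)),
                                    rate=10.0, channel_ids=montage.channel_ids)
        roi = fnirs.roi_average(hb, montage)
        assert np.abs(roi.roi("lPFC")).max() < 1e-12

    def test_lpfc_uses_exactly_its_channels(self, montage):
        dhbo2 = np.zeros((50, 63))
        for ch in (5, 6, 7, 18):
            dhbo2[:, ch - 1] = 1.0
        hb = fnirs.HemoglobinSeries(dhbo2, np.zeros_like(dhbo2), rate=10.0,
                                    channel_ids=montage.channel_ids)
        roi = fnirs.roi_average(hb, montage)
        assert np.allclose(roi.roi("lPFC"), 1.0)
        for other in roi.roi_labels:
            if other != "lPFC":
                assert np.abs(roi.roi(other)).max() == 0.0

    def test_empty_roi_names_it(self, montage):
        hb = fnirs.HemoglobinSeries(np.zeros((50, 4)), np.zeros((50, 4)), rate=10.0,
                                    channel_ids=np.array([5, 6, 7, 18]))
        with pytest.raises(ValidationError, match="rPFC"):
            fnirs.roi_average(hb, montage)


class TestPruning:
    def test_nonpositive_and_unstable_channels_dropped(self, rng):
        samples = np.abs(rng.uniform(0.9, 1.1, (100, 3, 2)))
        samples[5, 1, 0] = 0.0
        samples[:, 2, 1] = np.abs(rng.uniform(0.0, 3.0, 100)) + 1e-6
        raw = RawIntensitySeries(samples, channel_ids=np.array([1, 2, 3]))
        assert fnirs.prune_channels(raw) == {2, 3}
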