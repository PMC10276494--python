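"""PSI and magnitude-squared coherence between ROI dHbO2 and muscle envelopes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import coherence as scipy_coherence
from scipy.signal import hilbert

from cortimuscle import coupling as cp
from cortimuscle.emg import EnvelopeSeries
from cortimuscle.errors import ValidationError
from cortimuscle.fnirs import ROISeries
from cortimuscle.paradigm import TaskParadigm
from cortimuscle.simulate import band_limited_noise


class TestAnalysisWindow:
    def test_index_arithmetic(self, paradigm):
        x = np.arange(3700, dtype=float)
        out = cp.select_analysis_window(x, 10.0, 0.0, paradigm)
        assert out[0] == 600 and out[-1] == 1199 and len(out) == 600

    def test_window_length_fixed_regardless_of_onset(self):
        for rest in (10.0, 30.0, 50.0):
            par = TaskParadigm(rest_pre=rest, task=200.0, rest_post=0.0)
            x = np.zeros(int(par.total * 10))
            assert len(cp.select_analysis_window(x, 10.0, 0.0, par)) == 600

    def test_pure_function(self, paradigm):
        x = np.arange(3700, dtype=float)
        a = cp.select_analysis_window(x, 10.0, 0.0, paradigm)
        b = cp.select_analysis_window(x, 10.0, 0.0, paradigm)
        assert np.array_equal(a, b)

    def test_insufficient_coverage_rejected(self, paradigm):
        with pytest.raises(ValidationError):
            cp.select_analysis_window(np.zeros(800), 10.0, 0.0, paradigm)


class TestAlignPair:
    def _roi(self, x, rate=10.0, t0=0.0):
        return ROISeries(x[:, None], ("rM1",), rate, t0)

    def _env(self, y, rate=10.0, t0=0.0):
        return EnvelopeSeries(y[:, None], rate, ("lBB",), t0=t0, units="%MVC")

    def test_identical_grids_pass_through_demeaned(self, rng):
        x = rng.standard_normal(600)
        y = np.abs(rng.standard_normal(600))
        xo, yo, rate, t0 = cp.align_pair(self._roi(x), self._env(y))
        assert np.allclose(xo[:, 0], x - x.mean())
        assert abs(yo[:, 0].mean()) < 1e-10

    def test_rate_mismatch_instructs_regeneration(self, rng):
        x = rng.standard_normal(600)
        with pytest.raises(ValidationError, match="regenerate"):
            cp.align_pair(self._roi(x), self._env(np.abs(x), rate=5.0))

    def test_fractional_offset_rejected(self, rng):
        x = rng.standard_normal(600)
        with pytest.raises(ValidationError, match="multiple"):
            cp.align_pair(self._roi(x), self._env(np.abs(x), t0=0.25))

    def test_whole_sample_offset_accepted(self, rng):
        x = rng.standard_normal(600)
        xo, yo, _, t0 = cp.align_pair(self._roi(x), self._env(np.abs(x), t0=0.5))
        assert len(xo) == len(yo) == 595
        assert t0 == 0.5


class TestInstantaneousPhase:
    def test_cosine_phase_velocity(self):
        t = np.arange(6000) / 10.0
        ph = cp.instantaneous_phase(np.cos(2 * np.pi * 0.05 * t), 10.0)
        dphi = np.diff(np.unwrap(ph.theta[500:5500]))
        assert np.abs(dphi.mean() - 2 * np.pi * 0.05 / 10.0) / (2 * np.pi * 0.005) < 0.01

    def test_quadrature_offset(self):
        t = np.arange(6000) / 10.0
        c = cp.instantaneous_phase(np.cos(2 * np.pi * 0.05 * t), 10.0)
        s = cp.instantaneous_phase(np.sin(2 * np.pi * 0.05 * t), 10.0)
        d = np.angle(np.exp(1j * (c.theta - s.theta)))[500:5500]
        assert np.abs(d - np.pi / 2).max() < 0.05

    def test_phase_in_range(self, rng):
        x = band_limited_noise(rng, 1000, 10.0, (0.01, 0.1))
        ph = cp.instantaneous_phase(x, 10.0)
        assert (ph.theta > -np.pi).all() and (ph.theta <= np.pi).all()
        assert ph.in_band

    def test_broadband_input_flagged(self, rng):
        ph = cp.instantaneous_phase(rng.standard_normal(1000), 10.0)
        assert not ph.in_band


class TestPSI:
    def test_identical_phases_give_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, 600)
        assert cp.psi(th, th).psi == pytest.approx(1.0)

    def test_constant_offset_gives_one(self, rng):
        th = rng.uniform(-np.pi, np.pi, 600)
        assert cp.psi(th + 0.7, th).psi == pytest.approx(1.0)

    def test_self_synchronization_exact(self, rng):
        x = band_limited_noise(rng, 600, 10.0, (0.01, 0.1))
        th = np.angle(hilbert(x))
        assert cp.psi(th, th).psi == pytest.approx(1.0, abs=1e-12)

    def test_uniform_phases_below_monte_carlo_null(self):
        rng = np.random.default_rng(77)
        null = [np.hypot(np.cos(d).mean(), np.sin(d).mean())
                for d in rng.uniform(-np.pi, np.pi, (2000, 600))]
        q95 = np.quantile(null, 0.95)
        observed = cp.psi(np.random.default_rng(5).uniform(-np.pi, np.pi, 600),
                          np.zeros(600)).psi
        assert observed < q95
        assert q95 == pytest.approx(np.sqrt(-np.log(0.05) / 600), rel=0.1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            cp.psi(np.zeros(10), np.zeros(11))

    @given(st.floats(-10, 10))
    @settings(deadline=None, max_examples=25)
    def test_offset_invariance(self, offset):
        rng = np.random.default_rng(3)
        tx = rng.uniform(-np.pi, np.pi, 200)
        ty = rng.uniform(-np.pi, np.pi, 200)
        assert cp.psi(tx + offset, ty).psi == pytest.approx(cp.psi(tx, ty).psi, abs=1e-9)


class TestCoherence:
    def test_exact_scaled_copy_is_unity(self, rng):
        x = rng.standard_normal(600)
        coh = cp.coherence_spectrum(x, 3.0 * x, 10.0)
        assert np.abs(1.0 - coh.cxy[coh.frequencies > 0]).max() < 1e-10

    def test_segment_count(self, rng):
        coh = cp.coherence_spectrum(rng.standard_normal(600), rng.standard_normal(600), 10.0)
        assert coh.n_segments == 11
        assert coh.frequencies[1] == pytest.approx(0.1)

    def test_too_few_segments_rejected(self, rng):
        with pytest.raises(ValidationError, match="2 segments"):
            cp.coherence_spectrum(rng.standard_normal(140), rng.standard_normal(140), 10.0)

    def test_matches_scipy_welch(self, rng):
        """Independent-route check against scipy's Welch coherence with the
        same taper, segmentation and overlap."""
        x = rng.standard_normal(1000)
        y = 0.5 * x + rng.standard_normal(1000)
        coh = cp.coherence_spectrum(x, y, 10.0)
        f, cxy = scipy_coherence(x, y, fs=10.0, window="hann", nperseg=100,
                                 noverlap=50, detrend="constant")
        assert np.allclose(coh.frequencies, f)
        assert np.allclose(coh.cxy, cxy, atol=1e-10)

    def test_independent_noise_below_null(self):
        rng = np.random.default_rng(11)
        null = []
        for _ in range(300):
            a, b = rng.standard_normal((2, 600))
            null.append(cp.band_average_coherence(cp.coherence_spectrum(a, b, 10.0)))
        q95 = np.quantile(null, 0.95)
        a, b = np.random.default_rng(999).standard_normal((2, 600))
        assert cp.band_average_coherence(cp.coherence_spectrum(a, b, 10.0)) < q95

    def test_scale_invariance(self, rng):
        x, y = rng.standard_normal((2, 600))
        c1 = cp.coherence_spectrum(x, y, 10.0).cxy
        c2 = cp.coherence_spectrum(4.0 * x, 0.1 * y, 10.0).cxy
        assert np.allclose(c1, c2, atol=1e-12)

    def test_delayed_copy_near_unity_in_band(self, rng):
        x = band_limited_noise(rng, 2000, 10.0, (0.01, 0.1))
        coh = cp.coherence_spectrum(x[:-2], x[2:], 10.0)
        assert cp.band_average_coherence(coh) > 0.95


class TestBandAverage:
    def _result(self, freqs, cxy):
        return cp.CoherenceResult(np.asarray(freqs), np.asarray(cxy), 5, 100)

    def test_flat_spectrum(self):
        res = self._result([0.0, 0.1, 0.2], [0.9, 0.4, 0.4])
        assert cp.band_average_coherence(res) == pytest.approx(0.4)

    def test_two_bin_average(self):
        res = self._result([0.0, 0.05, 0.1, 0.15], [1.0, 0.2, 0.6, 0.9])
        assert cp.band_average_coherence(res) == pytest.approx(0.4)

    def test_matches_enumeration(self, rng):
        freqs = np.arange(0, 0.55, 0.0333)
        cxy = rng.uniform(0, 1, freqs.size)
        res = self._result(freqs, cxy)
        manual = [c for f, c in zip(freqs, cxy) if 0.0 < f and 0.01 <= f <= 0.1 + 1e-9]
        assert cp.band_average_coherence(res) == pytest.approx(np.mean(manual))

    def test_empty_band_rejected(self):
        res = self._result([0.0, 0.5, 1.0], [1.0, 0.5, 0.2])
        with pytest.raises(ValidationError):
            cp.band_average_coherence(res)


class TestPairsAndGroups:
    def test_lbb_pairs_with_right_rois(self):
        pairs = cp.contralateral_pairs(["lBB"], ["rPFC", "rPMC", "rSMA", "rM1", "lPFC"])
        assert {p.roi for p in pairs} == {"rPFC", "rPMC", "rSMA", "rM1"}

    def test_no_ipsilateral_pairs(self):
        muscles = ["lUT", "rUT", "lMD", "rMD", "lBB", "rBB", "lTB", "rTB"]
        rois = ["lPFC", "rPFC", "lPMC", "rPMC", "lSMA", "rSMA", "lM1", "rM1"]
        pairs = cp.contralateral_pairs(muscles, rois)
        assert len(pairs) == 32
        assert all(p.muscle[0] != p.roi[0] for p in pairs)

    def test_unlabeled_side_rejected(self):
        with pytest.raises(ValidationError, match="prefix"):
            cp.contralateral_pairs(["BB"], ["rPFC"])

    def test_group_level_single_subject_sd_flagged(self):
        import pandas as pd
        df = pd.DataFrame({"muscle": ["lBB"], "roi": ["rM1"], "coherence_band": [0.4]})
        out = cp.group_level(df)
        assert out["mean"].iloc[0] == 0.4
        assert np.isnan(out["sd"].iloc[0])
        assert out["n_subjects"].iloc[0] == 1

    def test_group_level_matches_enumeration(self):
        import pandas as pd
        df = pd.DataFrame({"muscle": ["lBB"] * 2, "roi": ["rM1"] * 2,
                           "coherence_band": [0.2, 0.4]})
        out = cp.group_level(df)
        assert out["mean"].iloc[0] == pytest.approx(0.3)
        assert out["sd"].iloc[0] == pytest.approx(np.std([0.2, 0.4], ddof=1))
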