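"""Forward simulator for coupled fNIRS + sEMG recordings with analytically
known coupling.

The generative model:

* A zero-mean latent oscillation s(t), band-limited to the hemodynamic
  band (0.01-0.1 Hz, flat spectrum), shared by all cortical channels and
  by every muscle envelope.
* Channel dHbO2 = latent + per-channel band-limited noise (sized so the
  pairwise in-band correlation hits the target r*) + physiological
  nuisances (Mayer ~0.1 Hz, respiration ~0.3 Hz, cardiac ~1 Hz sinusoids
  with per-subject random phase), linear drift, broadband white noise and
  a boxcar task response convolved with a gamma-shaped impulse response.
  dHbR is an anti-correlated scaled copy (-ratio * dHbO2) plus noise.
  The modified Beer-Lambert forward model maps concentrations to dOD, and
  intensity I = I0 * exp(-dOD); motion artifacts (spikes, baseline steps)
  are injected into dOD after the ground truth is stored.
* Muscle envelope e(t) = baseline + g * s(t) + band-limited noise at
  10 Hz, kept positive by softplus clipping, then multiplied onto a
  unit-RMS 10-400 Hz band-limited carrier at 2000 Hz.  An MVC trial is a
  3 s plateau at a configurable multiple of the task envelope mean.

Under this additive construction the magnitude-squared coherence between
the latent and the envelope is the closed form

    gamma^2(f) = g^2 S_s(f) / (g^2 S_s(f) + S_n(f))

flat across the shared band.  The *measured* pair (ROI-mean dHbO2,
envelope) is additionally diluted by the per-channel in-band noise implied
by r* < 1; ``theoretical_coherence`` implements the general closed form
(the spec case is recovered with ``include_fnirs_noise=False``), and
``gain_for_band_coherence`` inverts it to choose g for a target value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConfigurationError, ValidationError
from .fnirs import HEMODYNAMIC_BAND, forward_beer_lambert
from .montage import Montage, default_montage
from .paradigm import TaskParadigm
from .recordings import MUSCLES, EMGRecording, RawIntensitySeries

_LATENT_STREAM = 101
_FNIRS_STREAM = 202
_EMG_STREAM = 303
_MVC_STREAM = 404


@dataclass
class SimulationScenario:
    """All knobs of the generative model (units in field comments)."""

    seed: int = 0
    duration: float = 370.0                 # s
    fnirs_rate: float = 10.0                # Hz
    emg_rate: float = 2000.0                # Hz
    roi_signal_band: tuple[float, float] = HEMODYNAMIC_BAND
    latent_sd: float = 0.1                  # uM, in-band hemodynamic oscillation
    inter_channel_correlation: float = 0.6  # target pairwise r* within/between ROIs
    coupling_gain: float | dict[str, float] = 1.0  # per muscle (envelope units per unit latent)
    mayer_amp: float = 0.05                 # uM at ~0.1 Hz
    resp_amp: float = 0.05                  # uM at ~0.3 Hz
    cardiac_amp: float = 0.1                # uM at ~1.0 Hz
    white_sd: float = 0.02                  # uM broadband per channel
    drift_slope: float = 5e-4               # uM/s baseline drift scale
    task_response_amplitude: float = 0.2    # uM boxcar plateau
    hbr_ratio: float = 1.0 / 3.0            # dHbR = -ratio * dHbO2 + noise
    hbr_noise_sd: float = 0.005             # uM
    i0: float = 1.0                         # baseline intensity, arbitrary units
    artifact_spec: list[tuple[float, str, float]] = field(default_factory=list)
    env_baseline: float = 0.5               # mV resting envelope level
    env_latent_sd: float = 0.05             # mV envelope swing per unit coupling gain
    env_noise_sd: float = 0.05              # mV band-limited envelope noise
    mvc_multiple: float = 4.0               # MVC plateau / task envelope mean
    mvc_duration: float = 3.0               # s
    softplus_beta: float = 0.02             # mV softness of the positivity clip
    quantize_output: bool = True            # store signals at ADC (single) precision

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError("duration must be > 0 s")
        if not -1.0 < self.inter_channel_correlation < 1.0:
            raise ValidationError("|inter_channel_correlation| must be < 1")
        for name in ("mayer_amp", "resp_amp", "cardiac_amp", "white_sd",
                     "env_noise_sd", "latent_sd", "env_latent_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for g in (self.coupling_gain.values() if isinstance(self.coupling_gain, dict)
                  else [self.coupling_gain]):
            if g < 0:
                raise ValidationError("coupling gains must be >= 0")

    def gain(self, muscle: str) -> float:
        if isinstance(self.coupling_gain, dict):
            return float(self.coupling_gain.get(muscle, 0.0))
        return float(self.coupling_gain)


@dataclass
class LatentSeries:
    series: np.ndarray  # unit-variance, zero-mean, band-limited, 10 Hz
    rate: float
    warn_short: bool = False


@dataclass
class GroundTruth:
    """Simulator record: latent signals, injected artifacts, analytic targets."""

    latent: LatentSeries | None = None
    dhbo2: np.ndarray | None = None          # [time, channel], pre-artifact, uM
    dhbr: np.ndarray | None = None
    envelope: np.ndarray | None = None       # [time@10Hz, muscle], post-clip, mV
    envelope_preclip: np.ndarray | None = None
    clipped_fraction: dict[str, float] = field(default_factory=dict)
    artifacts: list[dict] = field(default_factory=list)
    gamma2_band: dict[tuple[str, str], float] = field(default_factory=dict)
    psi_regime: dict[tuple[str, str], str] = field(default_factory=dict)
    mvc_plateau: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for pair, g2 in self.gamma2_band.items():
            if not 0.0 <= g2 <= 1.0:
                raise ValidationError(f"gamma^2* for {pair} outside [0, 1]: {g2}")

    def table(self) -> pd.DataFrame:
        rows = [
            {"muscle": m, "roi": r, "gamma2_band": g2,
             "psi_regime": self.psi_regime.get((m, r), "")}
            for (m, r), g2 in sorted(self.gamma2_band.items())
        ]
        return pd.DataFrame(rows)


def band_limited_noise(rng: np.random.Generator, n: int, rate: float,
                       band: tuple[float, float], size: int | None = None) -> np.ndarray:
    """Zero-mean, unit-SD series with a flat spectrum confined to ``band``.

    Synthesized in the Fourier domain: i.i.d. complex coefficients on the
    in-band bins, zero elsewhere.  Returns shape [n] (size=None) or [n, size].
    """
    k = 1 if size is None else int(size)
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    mask = (freqs >= band[0]) & (freqs <= band[1]) & (freqs > 0)
    if not mask.any():
        raise ValidationError(
            f"{n} samples at {rate} Hz cannot resolve the {band} Hz band"
        )
    spec = np.zeros((k, freqs.size), dtype=complex)
    m = int(mask.sum())
    spec[:, mask] = rng.standard_normal((k, m)) + 1j * rng.standard_normal((k, m))
    x = np.fft.irfft(spec, n=n, axis=1)
    x -= x.mean(axis=1, keepdims=True)
    x /= x.std(axis=1, keepdims=True)
    return x[0] if size is None else x.T


def generate_latent_oscillation(scenario: SimulationScenario) -> LatentSeries:
    """The shared band-limited latent oscillation at the fNIRS rate."""
    n = int(round(scenario.duration * scenario.fnirs_rate))
    warn_short = scenario.duration < 2.0 / scenario.roi_signal_band[0]
    if warn_short:
        warnings.warn(
            f"duration {scenario.duration} s is too short to resolve "
            f"{scenario.roi_signal_band[0]} Hz well", stacklevel=2,
        )
    rng = np.random.default_rng([scenario.seed, _LATENT_STREAM])
    s = band_limited_noise(rng, n, scenario.fnirs_rate, scenario.roi_signal_band)
    return LatentSeries(series=s, rate=scenario.fnirs_rate, warn_short=warn_short)


def _task_response(n: int, rate: float, paradigm: TaskParadigm, amplitude: float) -> np.ndarray:
    """Boxcar over the task interval convolved with a gamma-shaped kernel."""
    if amplitude == 0:
        return np.zeros(n)
    t = np.arange(n) / rate
    box = ((t >= paradigm.onset) & (t < paradigm.onset + paradigm.task)).astype(float)
    tk = np.arange(0, 30.0, 1.0 / rate)
    kernel = tk ** 2 * np.exp(-tk / 2.0)  # gamma(k=3, theta=2), peak ~4 s
    kernel /= kernel.sum()
    return amplitude * np.convolve(box, kernel)[:n]


def inject_artifacts(dod: np.ndarray, rate: float,
                     artifact_spec: list[tuple[float, str, float]],
                     spike_width: float = 0.5) -> tuple[np.ndarray, list[dict]]:
    """Add spike/step artifacts (OD units) to a [time, ...] dOD array.

    A ``spike`` is a Hanning-shaped pulse of ``spike_width`` seconds; a
    ``step`` is a permanent baseline shift from its onset.  Returns the
    contaminated array and annotations with the affected interval.
    """
    out = dod.copy()
    n = dod.shape[0]
    notes: list[dict] = []
    for t_art, kind, mag in artifact_spec:
        i = int(round(t_art * rate))
        if not 0 <= i < n:
            raise ValidationError(f"artifact time {t_art} s outside record")
        if kind == "spike":
            w = max(3, int(round(spike_width * rate)))
            pulse = mag * np.hanning(w)
            a = max(0, i - w // 2)
            b = min(n, a + w)
            shaped = pulse[: b - a]
            out[a:b] += shaped.reshape(-1, *([1] * (dod.ndim - 1)))
            notes.append({"time": t_art, "type": "spike", "magnitude": mag,
                          "start": a / rate, "end": b / rate})
        elif kind == "step":
            out[i:] += mag
            notes.append({"time": t_art, "type": "step", "magnitude": mag,
                          "start": i / rate, "end": min(n, i + 1) / rate})
        else:
            raise ValidationError(f"unknown artifact type {kind!r}")
    return out, notes


def synthesize_fnirs(scenario: SimulationScenario, montage: Montage,
                     latent: LatentSeries,
                     paradigm: TaskParadigm | None = None,
                     ) -> tuple[RawIntensitySeries, GroundTruth]:
    """Forward-simulate dual-wavelength intensities for every montage channel."""
    rng = np.random.default_rng([scenario.seed, _FNIRS_STREAM])
    n = latent.series.size
    rate = scenario.fnirs_rate
    t = np.arange(n) / rate
    n_ch = montage.n_channels

    r = scenario.inter_channel_correlation
    if r <= 0:
        shared = np.zeros(n)
        sigma_w = 1.0
    else:
        shared = latent.series
        sigma_w = float(np.sqrt((1.0 - r) / r))
    own = band_limited_noise(rng, n, rate, scenario.roi_signal_band, size=n_ch)

    phases = rng.uniform(0, 2 * np.pi, size=3)
    nuisance = (
        scenario.mayer_amp * np.sin(2 * np.pi * 0.1 * t + phases[0])
        + scenario.resp_amp * np.sin(2 * np.pi * 0.3 * t + phases[1])
        + scenario.cardiac_amp * np.sin(2 * np.pi * 1.0 * t + phases[2])
    )
    task = _task_response(n, rate, paradigm or TaskParadigm(), scenario.task_response_amplitude)
    drift = scenario.drift_slope * (t - t.mean())[:, None] * rng.uniform(-1.5, 1.5, n_ch)
    white = scenario.white_sd * rng.standard_normal((n, n_ch))

    dhbo2 = (scenario.latent_sd * (shared[:, None] + sigma_w * own)
             + nuisance[:, None] + task[:, None] + drift + white)
    dhbr = -scenario.hbr_ratio * dhbo2 + scenario.hbr_noise_sd * rng.standard_normal((n, n_ch))

    dod = forward_beer_lambert(dhbo2, dhbr, montage,
                               wavelengths_nm=montage.wavelengths_nm)
    dod, notes = inject_artifacts(dod, rate, scenario.artifact_spec)
    intensity = scenario.i0 * np.exp(-dod)
    if np.any(~np.isfinite(intensity)) or np.any(intensity <= 0):
        raise ConfigurationError("simulated intensity not strictly positive")
    if scenario.quantize_output:
        intensity = intensity.astype(np.float32).astype(np.float64)

    raw = RawIntensitySeries(intensity, rate=rate, t0=0.0,
                             channel_ids=montage.channel_ids.copy(),
                             wavelengths_nm=montage.wavelengths_nm)
    truth = GroundTruth(latent=latent, dhbo2=dhbo2, dhbr=dhbr, artifacts=notes)
    return raw, truth


def _softplus(x: np.ndarray, beta: float) -> np.ndarray:
    return beta * np.logaddexp(0.0, x / beta)


def synthesize_emg(scenario: SimulationScenario, latent: LatentSeries,
                   muscles: tuple[str, ...] = MUSCLES,
                   ) -> tuple[EMGRecording, EMGRecording, GroundTruth]:
    """Simulate the task sEMG recording and an MVC trial.

    Returns (task recording, MVC trial recording, ground-truth part with
    the latent envelopes and per-muscle clipping diagnostics).
    """
    rng = np.random.default_rng([scenario.seed, _EMG_STREAM])
    n10 = latent.series.size
    factor = int(round(scenario.emg_rate / scenario.fnirs_rate))
    n_hi = n10 * factor
    n_m = len(muscles)

    noise = band_limited_noise(rng, n10, scenario.fnirs_rate,
                               scenario.roi_signal_band, size=n_m)
    gains = np.array([scenario.gain(m) for m in muscles])
    e_raw = (scenario.env_baseline
             + scenario.env_latent_sd * gains[None, :] * latent.series[:, None]
             + scenario.env_noise_sd * noise)
    e = _softplus(e_raw, scenario.softplus_beta)
    clipped = {m: float((e_raw[:, i] < 0).mean()) for i, m in enumerate(muscles)}
    worst = max(clipped.values())
    if worst > 0.01:
        warnings.warn(
            f"envelope clipped below zero for {worst:.1%} of samples; analytic "
            "coherence is computed pre-clipping and will be biased", stacklevel=2,
        )

    sos = sps.butter(4, (10.0, 400.0), btype="bandpass", fs=scenario.emg_rate, output="sos")
    carrier = sps.sosfiltfilt(sos, rng.standard_normal((n_hi, n_m)), axis=0)
    carrier /= np.sqrt((carrier ** 2).mean(axis=0, keepdims=True))
    emg = carrier * np.repeat(e, factor, axis=0)
    if scenario.quantize_output:
        emg = emg.astype(np.float32).astype(np.float64)
    task_rec = EMGRecording(emg, rate=scenario.emg_rate, t0=0.0, muscle_labels=muscles)

    # MVC trial: constant plateau at mvc_multiple x task envelope mean
    rng_mvc = np.random.default_rng([scenario.seed, _MVC_STREAM])
    n_trial = int(round(scenario.mvc_duration * scenario.emg_rate))
    plateau = {m: scenario.mvc_multiple * float(e[:, i].mean()) for i, m in enumerate(muscles)}
    carrier_trial = sps.sosfiltfilt(sos, rng_mvc.standard_normal((n_trial, n_m)), axis=0)
    carrier_trial /= np.sqrt((carrier_trial ** 2).mean(axis=0, keepdims=True))
    trial = carrier_trial * np.array([plateau[m] for m in muscles])[None, :]
    if scenario.quantize_output:
        trial = trial.astype(np.float32).astype(np.float64)
    mvc_rec = EMGRecording(trial, rate=scenario.emg_rate, t0=0.0, muscle_labels=muscles)

    truth = GroundTruth(latent=latent, envelope=e, envelope_preclip=e_raw,
                        clipped_fraction=clipped, mvc_plateau=plateau)
    return task_rec, mvc_rec, truth


# ---------------------------------------------------------------------------
# analytic coupling targets
# ---------------------------------------------------------------------------

def fnirs_dilution(scenario: SimulationScenario, n_roi_channels: int = 1) -> float:
    """In-band signal fraction of the ROI-mean dHbO2 under the channel model.

    The ROI mean carries the latent plus 1/K of the per-channel band noise
    (variance latent^2 (1-r)/r) and of the in-band share of the white noise.
    """
    r = scenario.inter_channel_correlation
    if r <= 0:
        return 0.0
    k = max(1, n_roi_channels)
    band_lo, band_hi = scenario.roi_signal_band
    sig = scenario.latent_sd ** 2
    chan_band = sig * (1.0 - r) / r
    white_inband = scenario.white_sd ** 2 * (band_hi - band_lo) / (scenario.fnirs_rate / 2.0)
    return sig / (sig + (chan_band + white_inband) / k)


def theoretical_coherence(scenario: SimulationScenario, muscle: str,
                          montage: Montage | None = None, roi: str | None = None,
                          include_fnirs_noise: bool = True,
                          freqs: np.ndarray | None = None,
                          ) -> float | tuple[float, np.ndarray]:
    """Closed-form band-averaged magnitude-squared coherence for a pair.

    Envelope side: gamma^2 = g^2 S_s / (g^2 S_s + S_n) with flat in-band
    spectra (g absorbs the envelope latent scale).  With
    ``include_fnirs_noise=True`` the value is multiplied by the fNIRS-side
    in-band signal fraction of the ROI mean; with ``False`` the pure
    additive-noise envelope formula is returned.
    """
    g2ss = (scenario.gain(muscle) * scenario.env_latent_sd) ** 2
    sn = scenario.env_noise_sd ** 2
    if g2ss == 0.0:
        env = 0.0
    elif sn == 0.0:
        env = 1.0
    else:
        env = g2ss / (g2ss + sn)
    if include_fnirs_noise:
        k = len(montage.roi_channels(roi)) if (montage is not None and roi is not None) else 1
        env *= fnirs_dilution(scenario, k)
    if freqs is None:
        return env
    lo, hi = scenario.roi_signal_band
    spectrum = np.where((freqs >= lo) & (freqs <= hi), env, 0.0)
    return env, spectrum


def gain_for_band_coherence(target: float, scenario: SimulationScenario,
                            montage: Montage | None = None, roi: str | None = None,
                            include_fnirs_noise: bool = True) -> float:
    """Invert the closed form: the gain g giving band coherence ``target``."""
    if not 0.0 <= target < 1.0:
        raise ValidationError("target coherence must be in [0, 1)")
    if target == 0.0:
        return 0.0
    d = 1.0
    if include_fnirs_noise:
        k = len(montage.roi_channels(roi)) if (montage is not None and roi is not None) else 1
        d = fnirs_dilution(scenario, k)
    env_target = target / d
    if env_target >= 1.0:
        raise ValidationError(
            f"target {target} unreachable: fNIRS-side dilution caps coherence at {d:.3f}"
        )
    return float(np.sqrt(env_target / (1.0 - env_target)) *
                 scenario.env_noise_sd / scenario.env_latent_sd)


# ---------------------------------------------------------------------------
# one-call subject simulation
# ---------------------------------------------------------------------------

@dataclass
class SubjectData:
    intensity: RawIntensitySeries
    emg: EMGRecording
    mvc_trial: EMGRecording
    truth: GroundTruth
    montage: Montage
    paradigm: TaskParadigm


def simulate_subject(scenario: SimulationScenario,
                     montage: Montage | None = None,
                     paradigm: TaskParadigm | None = None,
                     muscles: tuple[str, ...] = MUSCLES) -> SubjectData:
    """Simulate one subject's synchronized fNIRS + sEMG session."""
    montage = montage if montage is not None else default_montage()
    paradigm = paradigm if paradigm is not None else TaskParadigm()
    latent = generate_latent_oscillation(scenario)
    raw, truth_f = synthesize_fnirs(scenario, montage, latent, paradigm)
    emg, mvc_trial, truth_e = synthesize_emg(scenario, latent, muscles)

    truth = GroundTruth(
        latent=latent, dhbo2=truth_f.dhbo2, dhbr=truth_f.dhbr,
        envelope=truth_e.envelope, envelope_preclip=truth_e.envelope_preclip,
        clipped_fraction=truth_e.clipped_fraction, artifacts=truth_f.artifacts,
        mvc_plateau=truth_e.mvc_plateau,
    )
    rois = montage.roi_labels
    for m in muscles:
        g = scenario.gain(m)
        if g == 0.0:
            regime = "independent"
        elif scenario.env_noise_sd == 0.0:
            regime = "locked"
        else:
            regime = "partial"
        for roi in rois:
            if m[0] == roi[0]:
                continue
            truth.gamma2_band[(m, roi)] = theoretical_coherence(
                scenario, m, montage=montage, roi=roi)
            truth.psi_regime[(m, roi)] = regime
    truth.validate()
    return SubjectData(raw, emg, mvc_trial, truth, montage, paradigm)
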