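"""sEMG processing: band-pass, rectification, RMS envelope, MVC normalization.

The chain follows standard surface-EMG practice: second-order Butterworth
band-pass 10-400 Hz (zero-phase), full-wave rectification, root-mean-square
amplitude over non-overlapping 100 ms windows, and normalization to the
peak envelope of a maximal-voluntary-contraction (MVC) trial, yielding an
envelope in % MVC.  With 100 ms windows the envelope is natively 10 Hz and
lands on the hemodynamic sampling grid without further resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import ParameterError, ValidationError
from .recordings import EMGRecording
from .timebase import window_indices

EMG_BAND = (10.0, 400.0)
RMS_WINDOW_S = 0.1
MVC_SMOOTH_S = 0.5


@dataclass
class EnvelopeSeries:
    """Per-muscle RMS envelope, [time, muscle].

    ``units`` is ``"mV"`` before MVC normalization and ``"%MVC"`` after.
    """

    envelope: np.ndarray
    rate: float
    muscle_labels: tuple[str, ...]
    t0: float = 0.0
    window: float = RMS_WINDOW_S
    units: str = "mV"

    def __post_init__(self) -> None:
        self.envelope = np.asarray(self.envelope, dtype=float)
        if np.any(self.envelope < 0):
            raise ValidationError("RMS envelope must be non-negative")
        self.muscle_labels = tuple(self.muscle_labels)

    @property
    def n_samples(self) -> int:
        return self.envelope.shape[0]

    def muscle(self, label: str) -> np.ndarray:
        return self.envelope[:, self.muscle_labels.index(label)]


def bandpass_emg(raw: EMGRecording, band: tuple[float, float] = EMG_BAND,
                 order: int = 2) -> EMGRecording:
    """Zero-phase second-order Butterworth band-pass, 10-400 Hz."""
    if raw.rate <= 2 * band[1]:
        raise ParameterError(
            f"EMG rate {raw.rate} Hz puts the {band[1]} Hz band edge at/above Nyquist"
        )
    sos = signal.butter(order, band, btype="bandpass", fs=raw.rate, output="sos")
    padlen = min(raw.n_samples - 1, int(round(3.0 * raw.rate / band[0])))
    filtered = signal.sosfiltfilt(sos, raw.samples, axis=0, padlen=padlen)
    return EMGRecording(filtered, rate=raw.rate, t0=raw.t0,
                        muscle_labels=raw.muscle_labels,
                        mvc_reference=raw.mvc_reference)


def rectify(filtered: EMGRecording) -> EMGRecording:
    """Full-wave rectification (elementwise absolute value)."""
    return EMGRecording(np.abs(filtered.samples), rate=filtered.rate, t0=filtered.t0,
                        muscle_labels=filtered.muscle_labels,
                        mvc_reference=filtered.mvc_reference)


def rms_envelope(rec: EMGRecording, window: float = RMS_WINDOW_S) -> EnvelopeSeries:
    """RMS over non-overlapping windows of ``window`` seconds.

    The RMS of the rectified signal equals the RMS of the filtered signal
    (squaring removes sign).  An incomplete trailing window is dropped; the
    output rate is 1/window (10 Hz at the default 100 ms).
    """
    w = int(round(window * rec.rate))
    if w < 2:
        raise ParameterError(f"window {window} s is shorter than 2 samples at {rec.rate} Hz")
    n_win = rec.n_samples // w
    if n_win < 1:
        raise ValidationError(
            f"record of {rec.n_samples} samples is shorter than one {window} s window"
        )
    x = rec.samples[: n_win * w]
    env = np.sqrt((x.reshape(n_win, w, -1) ** 2).mean(axis=1))
    return EnvelopeSeries(env, rate=1.0 / window, muscle_labels=rec.muscle_labels,
                          t0=rec.t0, window=window, units="mV")


def compute_mvc(mvc_trial: EMGRecording, window: float = RMS_WINDOW_S,
                smooth: float = MVC_SMOOTH_S) -> dict[str, float]:
    """Per-muscle MVC reference: peak of a 0.5 s moving average of the RMS
    envelope of the (band-passed) MVC trial."""
    if mvc_trial.duration < 1.0:
        raise ValidationError(f"MVC trial of {mvc_trial.duration:.2f} s is shorter than 1 s")
    env = rms_envelope(bandpass_emg(mvc_trial), window=window)
    k = max(1, int(round(smooth * env.rate)))
    kernel = np.ones(k) / k
    ref: dict[str, float] = {}
    for mi, m in enumerate(env.muscle_labels):
        smoothed = np.convolve(env.envelope[:, mi], kernel, mode="valid")
        peak = float(smoothed.max()) if smoothed.size else float(env.envelope[:, mi].max())
        if peak <= 0:
            raise ValidationError(f"MVC undefined for {m}: all-zero trial")
        ref[m] = peak
    return ref


def mvc_normalize(envelope: EnvelopeSeries, mvc_reference: dict[str, float]) -> EnvelopeSeries:
    """Express the envelope in % MVC per muscle."""
    scale = np.empty(len(envelope.muscle_labels))
    for mi, m in enumerate(envelope.muscle_labels):
        if m not in mvc_reference:
            raise ValidationError(f"no MVC reference for muscle {m}")
        if mvc_reference[m] <= 0:
            raise ValidationError(f"MVC reference for {m} must be > 0, got {mvc_reference[m]}")
        scale[mi] = mvc_reference[m]
    return EnvelopeSeries(100.0 * envelope.envelope / scale, rate=envelope.rate,
                          muscle_labels=envelope.muscle_labels, t0=envelope.t0,
                          window=envelope.window, units="%MVC")


def activation_summary(envelope: EnvelopeSeries, window: tuple[float, float]) -> dict[str, float]:
    """Mean envelope per muscle over the half-open [start, end) window (absolute s)."""
    sl = window_indices(window[0], window[1], envelope.t0, envelope.rate, envelope.n_samples)
    mean = envelope.envelope[sl].mean(axis=0)
    return {m: float(v) for m, v in zip(envelope.muscle_labels, mean)}


def process_emg(raw: EMGRecording, mvc_trial: EMGRecording | None = None,
                window: float = RMS_WINDOW_S) -> EnvelopeSeries:
    """Full chain: band-pass -> rectify -> RMS envelope -> % MVC.

    The MVC reference comes from ``mvc_trial`` if given, else from the
    recording's own ``mvc_reference`` header.
    """
    env = rms_envelope(rectify(bandpass_emg(raw)), window=window)
    if mvc_trial is not None:
        ref = compute_mvc(mvc_trial, window=window)
    elif raw.mvc_reference:
        ref = raw.mvc_reference
    else:
        raise ValidationError("no MVC trial or reference available for normalization")
    return mvc_normalize(env, ref)
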