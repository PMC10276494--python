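"""Corticomuscular coupling: phase synchronization index and
magnitude-squared coherence between each cortical ROI's dHbO2 and the
contralateral muscle's % MVC envelope.

Phase synchronization index (PSI)::

    PSI = sqrt( <cos theta_xy(t)>_t^2 + <sin theta_xy(t)>_t^2 )
    theta_xy(t) = n*theta_x(t) - m*theta_y(t),  n = m = 1

where theta are instantaneous phases of the band-limited signals after the
Hilbert transform.  PSI is the resultant length of the phase-difference
distribution: 1 for perfect locking, ~0 for independent phases.

Magnitude-squared coherence::

    C_xy(f) = |P_xy(f)|^2 / (P_xx(f) * P_yy(f))

with Welch-averaged auto/cross spectra over Hanning-tapered segments of
100 samples with 50% overlap.  At the 10 Hz grid a 100-sample segment is
10 s, i.e. a 0.1 Hz frequency resolution; with DC excluded the 0.01-0.1 Hz
band average then rests on the single 0.1 Hz bin, so a longer diagnostic
segment (default 300 samples, 0.033 Hz resolution) is reported alongside.

Both statistics are computed on the 30-90 s-after-onset analysis window
and aggregated across subjects per (muscle, contralateral ROI) pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .emg import EnvelopeSeries
from .errors import ParameterError, ValidationError
from .fnirs import HEMODYNAMIC_BAND, ROISeries, _bandpass_sos, _filtfilt
from .paradigm import TaskParadigm
from .timebase import check_aligned, window_indices

ANALYSIS_WINDOW = (30.0, 90.0)  # seconds after task onset
SEGMENT_SAMPLES = 100
SEGMENT_SAMPLES_LONG = 300
ROI_SIDES = {"l": "left", "r": "right"}


@dataclass
class PhaseSeries:
    """Instantaneous phase in (-pi, pi] of a band-limited signal."""

    theta: np.ndarray
    rate: float
    source: str = ""
    band: tuple[float, float] = HEMODYNAMIC_BAND
    band_power_fraction: float = 1.0

    @property
    def in_band(self) -> bool:
        return self.band_power_fraction >= 0.8


@dataclass(frozen=True)
class CouplingPair:
    muscle: str
    roi: str

    def __post_init__(self) -> None:
        if self.muscle[0] not in ROI_SIDES or self.roi[0] not in ROI_SIDES:
            raise ValidationError(f"labels must carry an l/r side prefix: {self}")
        if self.muscle[0] == self.roi[0]:
            raise ValidationError(
                f"{self.muscle}-{self.roi} is ipsilateral; coupling pairs are contralateral"
            )


@dataclass
class PSIResult:
    psi: float
    n_samples: int
    pair: CouplingPair | None = None


@dataclass
class CoherenceResult:
    frequencies: np.ndarray
    cxy: np.ndarray
    n_segments: int
    segment_samples: int
    pair: CouplingPair | None = None


def select_analysis_window(values: np.ndarray, rate: float, t0: float,
                           paradigm: TaskParadigm,
                           window: tuple[float, float] = ANALYSIS_WINDOW) -> np.ndarray:
    """Extract the half-open [onset+start, onset+end) interval."""
    onset = t0 + paradigm.onset
    sl = window_indices(onset + window[0], onset + window[1], t0, rate, values.shape[0])
    return values[sl]


def align_pair(roi_series: ROISeries, envelope: EnvelopeSeries) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Put both modalities on a common grid and demean them.

    Returns ``(x, y, rate, t0)`` where x is the [time, ROI] dHbO2 block and
    y the [time, muscle] envelope block over their common time span.
    """
    if abs(roi_series.rate - envelope.rate) > 1e-9:
        raise ValidationError(
            f"rate mismatch ({roi_series.rate} vs {envelope.rate} Hz): regenerate the "
            f"envelope with a window of {1.0 / roi_series.rate} s"
        )
    rate = roi_series.rate
    check_aligned(roi_series.t0, envelope.t0, rate)
    start = max(roi_series.t0, envelope.t0)
    end = min(roi_series.t0 + roi_series.values.shape[0] / rate,
              envelope.t0 + envelope.n_samples / rate)
    if end <= start:
        raise ValidationError("series do not overlap in time")
    xs = window_indices(start, end, roi_series.t0, rate, roi_series.values.shape[0])
    ys = window_indices(start, end, envelope.t0, rate, envelope.n_samples)
    x = roi_series.values[xs] - roi_series.values[xs].mean(axis=0)
    y = envelope.envelope[ys] - envelope.envelope[ys].mean(axis=0)
    return x, y, rate, start


def band_power_fraction(x: np.ndarray, rate: float,
                        band: tuple[float, float] = HEMODYNAMIC_BAND) -> float:
    f, p = sps.periodogram(x, fs=rate, detrend="constant")
    total = p[1:].sum()
    if total <= 0:
        return 1.0
    sel = (f >= band[0]) & (f <= band[1])
    return float(p[sel].sum() / total)


def instantaneous_phase(x: np.ndarray, rate: float,
                        band: tuple[float, float] = HEMODYNAMIC_BAND,
                        source: str = "") -> PhaseSeries:
    """Phase of the analytic signal of a band-limited, demeaned series."""
    x = np.asarray(x, dtype=float)
    frac = band_power_fraction(x - x.mean(), rate, band)
    theta = np.angle(sps.hilbert(x - x.mean()))
    return PhaseSeries(theta, rate=rate, source=source, band=band,
                       band_power_fraction=frac)


def bandlimit(x: np.ndarray, rate: float,
              band: tuple[float, float] = HEMODYNAMIC_BAND, order: int = 3) -> np.ndarray:
    """Zero-phase Butterworth band-pass of a 1-D/2-D series (time on axis 0)."""
    sos = _bandpass_sos(rate, band, order)
    return _filtfilt(np.asarray(x, dtype=float), sos, rate, band[0])


def psi(theta_x: PhaseSeries | np.ndarray, theta_y: PhaseSeries | np.ndarray,
        n: int = 1, m: int = 1, pair: CouplingPair | None = None) -> PSIResult:
    """Phase synchronization index of the phase difference n*theta_x - m*theta_y."""
    tx = theta_x.theta if isinstance(theta_x, PhaseSeries) else np.asarray(theta_x, float)
    ty = theta_y.theta if isinstance(theta_y, PhaseSeries) else np.asarray(theta_y, float)
    if tx.shape != ty.shape:
        raise ValidationError(f"phase series lengths differ: {tx.shape} vs {ty.shape}")
    if tx.size < 2:
        raise ValidationError("PSI needs at least 2 samples")
    d = n * tx - m * ty
    value = float(np.hypot(np.cos(d).mean(), np.sin(d).mean()))
    return PSIResult(psi=min(value, 1.0), n_samples=tx.size, pair=pair)


def coherence_spectrum(x: np.ndarray, y: np.ndarray, rate: float,
                       segment: int = SEGMENT_SAMPLES, overlap: float = 0.5,
                       pair: CouplingPair | None = None) -> CoherenceResult:
    """Welch magnitude-squared coherence with Hanning-tapered segments.

    Auto- and cross-spectra are averaged over segments of ``segment``
    samples with the given fractional overlap; each segment is demeaned
    before tapering.  Requires at least two segments (single-segment
    coherence is identically 1 and meaningless).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("coherence inputs must be equal-length 1-D series")
    step = segment - int(round(overlap * segment))
    if step < 1:
        raise ParameterError(f"overlap {overlap} leaves no advance between segments")
    n_seg = (x.size - segment) // step + 1 if x.size >= segment else 0
    if n_seg < 2:
        raise ValidationError(
            f"{x.size} samples give {n_seg} segment(s) of {segment}; "
            "coherence needs at least 2 segments"
        )
    win = sps.windows.hann(segment, sym=False)
    pxx = np.zeros(segment // 2 + 1)
    pyy = np.zeros(segment // 2 + 1)
    pxy = np.zeros(segment // 2 + 1, dtype=complex)
    for k in range(n_seg):
        xs = x[k * step: k * step + segment]
        ys = y[k * step: k * step + segment]
        fx = np.fft.rfft((xs - xs.mean()) * win)
        fy = np.fft.rfft((ys - ys.mean()) * win)
        pxx += np.abs(fx) ** 2
        pyy += np.abs(fy) ** 2
        pxy += fx * np.conj(fy)
    with np.errstate(divide="ignore", invalid="ignore"):
        cxy = np.abs(pxy / n_seg) ** 2 / (pxx / n_seg * (pyy / n_seg))
    cxy = np.where((pxx > 0) & (pyy > 0), cxy, np.nan)
    freqs = np.fft.rfftfreq(segment, d=1.0 / rate)
    return CoherenceResult(freqs, np.clip(cxy, 0.0, 1.0), n_segments=n_seg,
                           segment_samples=segment, pair=pair)


def band_average_coherence(result: CoherenceResult,
                           band: tuple[float, float] = HEMODYNAMIC_BAND,
                           exclude_dc: bool = True) -> float:
    """Unweighted mean coherence over grid frequencies inside the band
    (endpoints inclusive; the DC bin is excluded for demeaned inputs)."""
    tol = 1e-9
    sel = (result.frequencies >= band[0] - tol) & (result.frequencies <= band[1] + tol)
    if exclude_dc:
        sel &= result.frequencies > tol
    vals = result.cxy[sel]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValidationError(
            f"band {band} Hz does not intersect the coherence frequency grid "
            f"(resolution {result.frequencies[1]:.4f} Hz)"
        )
    return float(vals.mean())


def contralateral_pairs(muscles: list[str] | tuple[str, ...],
                        rois: list[str] | tuple[str, ...]) -> list[CouplingPair]:
    """All (muscle, ROI) pairs on opposite body sides."""
    for lbl in list(muscles) + list(rois):
        if not lbl or lbl[0] not in ROI_SIDES:
            raise ValidationError(f"label {lbl!r} lacks an l/r side prefix")
    return [CouplingPair(m, r) for m in muscles for r in rois if m[0] != r[0]]


def couple_subject(roi_series: ROISeries, envelope: EnvelopeSeries,
                   paradigm: TaskParadigm,
                   window: tuple[float, float] = ANALYSIS_WINDOW,
                   segment: int = SEGMENT_SAMPLES,
                   segment_long: int = SEGMENT_SAMPLES_LONG,
                   with_spectra: bool = False):
    """PSI and coherence for every contralateral (muscle, ROI) pair.

    PSI inputs are band-limited to the hemodynamic band before the Hilbert
    transform (the analytic signal is computed on the full record, the
    30-90 s window extracted afterwards so filter/Hilbert edges never touch
    it).  Coherence inputs are the demeaned but unfiltered window; the
    scalar is the 0.01-0.1 Hz band average at the 100-sample segment
    (headline) and at a longer diagnostic segment.
    """
    x, y, rate, t0 = align_pair(roi_series, envelope)
    pairs = contralateral_pairs(list(envelope.muscle_labels), list(roi_series.roi_labels))
    # phases from the full aligned record
    xb = bandlimit(x, rate)
    yb = bandlimit(y, rate)
    theta_x = np.angle(sps.hilbert(xb, axis=0))
    theta_y = np.angle(sps.hilbert(yb, axis=0))
    rows = []
    spectra_rows = []
    for p in pairs:
        ri = roi_series.roi_labels.index(p.roi)
        mi = envelope.muscle_labels.index(p.muscle)
        th_m = select_analysis_window(theta_y[:, mi], rate, t0, paradigm, window)
        th_r = select_analysis_window(theta_x[:, ri], rate, t0, paradigm, window)
        ps = psi(th_m, th_r, pair=p)
        xm = select_analysis_window(y[:, mi], rate, t0, paradigm, window)
        xr = select_analysis_window(x[:, ri], rate, t0, paradigm, window)
        coh = coherence_spectrum(xm, xr, rate, segment=segment, pair=p)
        coh_long = coherence_spectrum(xm, xr, rate, segment=segment_long, pair=p)
        rows.append({
            "muscle": p.muscle,
            "roi": p.roi,
            "psi": ps.psi,
            "coherence_band": band_average_coherence(coh),
            "coherence_band_long": band_average_coherence(coh_long),
            "n_segments": coh.n_segments,
            "n_samples": ps.n_samples,
        })
        if with_spectra:
            for f, c in zip(coh.frequencies, coh.cxy):
                spectra_rows.append({"muscle": p.muscle, "roi": p.roi,
                                     "frequency_hz": float(f), "coherence": float(c)})
    df = pd.DataFrame(rows)
    if with_spectra:
        return df, pd.DataFrame(spectra_rows)
    return df


def group_level(values: pd.DataFrame, value_col: str = "coherence_band") -> pd.DataFrame:
    """Mean, sample SD and subject count per (muscle, ROI) pair.

    SD is NaN (flagged) for single-subject pairs, never silently zero.
    """
    def agg(g: pd.Series) -> pd.Series:
        return pd.Series({
            "mean": g.mean(),
            "sd": g.std(ddof=1) if len(g) > 1 else np.nan,
            "n_subjects": len(g),
        })

    out = (values.groupby(["muscle", "roi"])[value_col].apply(agg).unstack()
           .reset_index())
    out["n_subjects"] = out["n_subjects"].astype(int)
    return out
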