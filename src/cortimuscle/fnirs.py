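"""fNIRS processing: optical density, motion correction, band-pass, the
modified Beer-Lambert inversion, block-averaged response amplitudes and
ROI averaging.

Chain (mirroring standard continuous-wave fNIRS practice):

1. ``intensity_to_od`` — dOD(t) = -ln(I(t) / mean(I)) per channel/wavelength.
2. ``detect_motion_artifacts`` + ``spline_correct`` — flag windows whose
   signal excursion is implausible for hemodynamics and subtract a
   smoothing-spline fit of each flagged segment (head-movement spikes and
   baseline steps).
3. ``bandpass_hemodynamic`` — zero-phase Butterworth band-pass 0.01-0.1 Hz,
   removing drift, Mayer waves (~0.1 Hz edge), respiration (~0.3 Hz) and
   cardiac (~1 Hz) components.
4. ``od_to_hemoglobin`` — solve the modified Beer-Lambert law
   dOD(lambda) = [eps_HbO2(lambda) dHbO2 + eps_HbR(lambda) dHbR] * d * DPF(lambda)
   per channel and sample for the chromophore concentration changes (uM).
5. ``block_average_hrf`` — task response amplitude as plateau mean minus
   baseline mean; ``roi_average`` — mean dHbO2 over each ROI's channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.interpolate import make_smoothing_spline

from .errors import ConfigurationError, ParameterError, ValidationError
from .montage import Montage
from .paradigm import TaskParadigm
from .recordings import RawIntensitySeries
from .timebase import window_indices

# Extinction coefficients in cm^-1 * uM^-1 for (HbO2, HbR), from the
# standard compiled absorption tables for adult tissue spectroscopy.
EXTINCTION_UM_CM: dict[float, tuple[float, float]] = {
    740.0: (0.4383e-3, 1.1589e-3),
    850.0: (1.0697e-3, 0.7861e-3),
}

DEFAULT_DPF = 6.0
HEMODYNAMIC_BAND = (0.01, 0.1)


@dataclass
class OpticalDensitySeries:
    dod: np.ndarray  # [time, channel, wavelength]
    rate: float
    t0: float = 0.0
    channel_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    wavelengths_nm: tuple[float, float] = (740.0, 850.0)
    artifact_mask: np.ndarray | None = None  # [time, channel] bool
    warn_short: bool = False

    def __post_init__(self) -> None:
        self.dod = np.asarray(self.dod, dtype=float)
        if not np.all(np.isfinite(self.dod)):
            raise ValidationError("optical density contains non-finite values")
        if len(self.channel_ids) == 0:
            self.channel_ids = np.arange(1, self.dod.shape[1] + 1)
        if self.artifact_mask is not None and self.artifact_mask.shape[0] != self.dod.shape[0]:
            raise ValidationError("artifact mask length does not match series")

    @property
    def n_samples(self) -> int:
        return self.dod.shape[0]


@dataclass
class HemoglobinSeries:
    """Chromophore concentration changes in uM, [time, channel]."""

    dhbo2: np.ndarray
    dhbr: np.ndarray
    rate: float
    t0: float = 0.0
    channel_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.dhbo2 = np.asarray(self.dhbo2, dtype=float)
        self.dhbr = np.asarray(self.dhbr, dtype=float)
        if self.dhbo2.shape != self.dhbr.shape:
            raise ValidationError("dHbO2 and dHbR shapes differ")
        if len(self.channel_ids) == 0:
            self.channel_ids = np.arange(1, self.dhbo2.shape[1] + 1)

    @property
    def n_samples(self) -> int:
        return self.dhbo2.shape[0]


@dataclass
class HRFEstimate:
    """Plateau-minus-baseline response amplitude per channel and ROI (uM)."""

    channel_amplitude: dict[int, float]
    roi_amplitude: dict[str, float]
    baseline_window: tuple[float, float]
    plateau_window: tuple[float, float]


@dataclass
class ROISeries:
    """Mean dHbO2 per ROI, [time, ROI], uM."""

    values: np.ndarray
    roi_labels: tuple[str, ...]
    rate: float
    t0: float = 0.0

    def roi(self, label: str) -> np.ndarray:
        return self.values[:, self.roi_labels.index(label)]


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def intensity_to_od(raw: RawIntensitySeries) -> OpticalDensitySeries:
    """Convert intensity to optical-density changes about the record mean."""
    bad = np.argwhere(raw.samples <= 0)
    if bad.size:
        t, c, w = bad[0]
        raise ValidationError(
            f"nonpositive intensity at sample {t}, channel {raw.channel_ids[c]} "
            f"(wavelength index {w}); cannot form optical density"
        )
    ref = raw.samples.mean(axis=0, keepdims=True)
    dod = -np.log(raw.samples / ref)
    return OpticalDensitySeries(dod, rate=raw.rate, t0=raw.t0,
                                channel_ids=raw.channel_ids.copy(),
                                wavelengths_nm=raw.wavelengths_nm)


def detect_motion_artifacts(
    od: OpticalDensitySeries,
    window: float = 0.5,
    mask_expand: float = 1.0,
    std_thresh: float = 20.0,
    amp_thresh: float = 5.0,
) -> np.ndarray:
    """Flag samples whose local excursion is implausibly fast.

    Within every sliding interval of length ``window`` seconds the
    max-minus-min excursion of each channel (summed over wavelengths'
    worst case) is compared against ``std_thresh`` times the robust SD of
    the channel's sample-to-sample change and against the absolute
    ``amp_thresh`` (OD units).  Flagged intervals are expanded by
    ``mask_expand`` seconds on each side.  Returns a [time, channel] mask.
    """
    if min(window, mask_expand) < 0 or std_thresh <= 0 or amp_thresh <= 0:
        raise ParameterError("detection parameters must be positive")
    w = int(round(window * od.rate))
    if w < 2:
        raise ParameterError(f"window {window} s is shorter than 2 samples at {od.rate} Hz")
    n, n_ch, n_wl = od.dod.shape
    mask = np.zeros((n, n_ch), dtype=bool)
    expand = int(round(mask_expand * od.rate))
    for ci in range(n_ch):
        flagged = np.zeros(n, dtype=bool)
        for wi in range(n_wl):
            x = od.dod[:, ci, wi]
            d = np.diff(x)
            sigma_d = 1.4826 * np.median(np.abs(d - np.median(d))) if d.size else 0.0
            hi = ndimage.maximum_filter1d(x, size=w, mode="nearest")
            lo = ndimage.minimum_filter1d(x, size=w, mode="nearest")
            exc = hi - lo
            thresh = max(std_thresh * sigma_d, 0.0)
            flagged |= (exc > thresh) & (sigma_d > 0) | (exc > amp_thresh)
        if expand > 0 and flagged.any():
            flagged = ndimage.binary_dilation(flagged, structure=np.ones(2 * expand + 1, bool))
        mask[:, ci] = flagged
    return mask


def _segments(mask_1d: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as half-open (start, stop) index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask_1d.astype(int), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def _level(x: np.ndarray) -> float:
    return float(np.mean(x))


def _trend_at(x: np.ndarray, idx: np.ndarray, at: float) -> float:
    """Local linear fit of x[idx] evaluated at sample position ``at``.

    Captures the slow hemodynamic slope so level comparisons across a
    masked gap are not biased by the signal drifting during the gap.
    """
    if idx.size < 3:
        return float(np.mean(x[idx]))
    coef = np.polyfit(idx.astype(float), x[idx], 1)
    return float(np.polyval(coef, at))


def spline_correct(
    od: OpticalDensitySeries,
    artifact_mask: np.ndarray,
    smoothing: float = 0.99,
    anchor_window: float = 1.0,
) -> OpticalDensitySeries:
    """Subtract a smoothing-spline fit of each flagged segment.

    Within every flagged run the trace is replaced by its residual about a
    flexible smoothing spline (parameter ``smoothing`` = p in (0,1), csaps
    convention, mapped to the penalty weight lam = (1-p)/p * dt^3), then
    re-anchored to the level of the neighbouring clean data.  If the level
    on the far side of the gap disagrees with the near side by more than an
    adaptive threshold (a baseline step), all subsequent samples are
    shifted to restore continuity; otherwise clean data are left untouched.
    """
    if not 0 < smoothing < 1:
        raise ParameterError(f"smoothing must be in (0, 1), got {smoothing}")
    if not artifact_mask.any():
        return OpticalDensitySeries(od.dod.copy(), od.rate, od.t0,
                                    od.channel_ids.copy(), od.wavelengths_nm,
                                    artifact_mask=artifact_mask)
    dt = 1.0 / od.rate
    lam = (1.0 - smoothing) / smoothing * dt**3
    wlen = max(2, int(round(anchor_window * od.rate)))
    out = od.dod.copy()
    n = od.n_samples
    for ci in range(od.dod.shape[1]):
        runs = _segments(artifact_mask[:, ci])
        if not runs:
            continue
        for wi in range(od.dod.shape[2]):
            x = out[:, ci, wi]
            # adaptive step threshold: spread of window-mean differences at
            # the anchor lag across the whole record
            means = np.convolve(x, np.ones(wlen) / wlen, mode="valid")
            lag = 2 * wlen
            if len(means) > lag:
                dm = means[lag:] - means[:-lag]
                step_thresh = 5.0 * 1.4826 * np.median(np.abs(dm - np.median(dm)))
            else:
                step_thresh = np.inf
            for (a, b) in runs:
                seg = x[a:b]
                t = np.arange(a, b) * dt
                if b - a >= 4:
                    spl = make_smoothing_spline(t, seg, lam=lam)
                    resid = seg - spl(t)
                else:
                    resid = np.zeros_like(seg)
                # anchor level from the near clean side
                if a > 0:
                    anchor = _level(x[max(0, a - wlen):a])
                elif b < n:
                    anchor = _level(x[b:min(n, b + wlen)])
                else:
                    anchor = _level(seg)
                x[a:b] = anchor + resid
                # step handling: shift the far side if its level is
                # inconsistent with the near side beyond the adaptive
                # threshold; both levels are local linear-trend estimates
                # extrapolated to the gap centre so the slow hemodynamic
                # slope across the gap does not masquerade as a step
                if a > 0 and b < n:
                    centre = 0.5 * (a + b)
                    before_idx = np.arange(max(0, a - 3 * wlen), a)
                    after_idx = np.arange(b, min(n, b + 3 * wlen))
                    jump = (_trend_at(x, after_idx, centre)
                            - _trend_at(x, before_idx, centre))
                    if np.isfinite(step_thresh) and abs(jump) > step_thresh:
                        x[b:] -= jump
            out[:, ci, wi] = x
    return OpticalDensitySeries(out, od.rate, od.t0, od.channel_ids.copy(),
                                od.wavelengths_nm, artifact_mask=artifact_mask)


def _bandpass_sos(rate: float, band: tuple[float, float] = HEMODYNAMIC_BAND, order: int = 3):
    return signal.butter(order, band, btype="bandpass", fs=rate, output="sos")


def _filtfilt(x: np.ndarray, sos: np.ndarray, rate: float, low_edge: float) -> np.ndarray:
    n = x.shape[0]
    padlen = min(n - 1, int(round(3.0 * rate / low_edge)))
    return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)


def bandpass_hemodynamic(
    od: OpticalDensitySeries,
    band: tuple[float, float] = HEMODYNAMIC_BAND,
    order: int = 3,
) -> OpticalDensitySeries:
    """Zero-phase Butterworth band-pass to the hemodynamic band (0.01-0.1 Hz)."""
    if od.rate < 1.0:
        raise ParameterError(f"rate {od.rate} Hz too low for a {band[1]} Hz band edge")
    warn_short = od.n_samples / od.rate < 3.0 / band[0]
    if warn_short:
        warnings.warn(
            f"record of {od.n_samples / od.rate:.0f} s is shorter than three "
            f"time constants of the {band[0]} Hz edge; band-pass transients may dominate",
            stacklevel=2,
        )
    sos = _bandpass_sos(od.rate, band, order)
    filtered = _filtfilt(od.dod, sos, od.rate, band[0])
    return OpticalDensitySeries(filtered, od.rate, od.t0, od.channel_ids.copy(),
                                od.wavelengths_nm, artifact_mask=od.artifact_mask,
                                warn_short=warn_short)


def extinction_matrix(wavelengths_nm: tuple[float, float],
                      table: dict[float, tuple[float, float]] | None = None) -> np.ndarray:
    """2x2 matrix of extinction coefficients (rows: wavelengths; cols HbO2, HbR)."""
    table = table or EXTINCTION_UM_CM
    try:
        rows = [table[float(w)] for w in wavelengths_nm]
    except KeyError as exc:
        raise ConfigurationError(
            f"no extinction coefficients tabulated for {exc.args[0]} nm"
        ) from None
    return np.asarray(rows, dtype=float)


def od_to_hemoglobin(
    od: OpticalDensitySeries,
    montage: Montage,
    dpf: tuple[float, float] = (DEFAULT_DPF, DEFAULT_DPF),
    extinction: np.ndarray | None = None,
) -> HemoglobinSeries:
    """Invert the modified Beer-Lambert law per channel and sample."""
    E = extinction if extinction is not None else extinction_matrix(od.wavelengths_nm)
    if E.shape != (2, 2):
        raise ConfigurationError(f"extinction matrix must be 2x2, got {E.shape}")
    d = montage.separation_cm
    if d <= 0 or min(dpf) <= 0:
        raise ConfigurationError("separation and DPF must be positive")
    A = E * (d * np.asarray(dpf)[:, None])  # effective 2x2 system matrix
    if np.linalg.cond(A) > 1e6:
        raise ConfigurationError(
            f"effective Beer-Lambert matrix is ill-conditioned (cond={np.linalg.cond(A):.2e})"
        )
    # dod: [T, C, 2]; solve A @ conc = dod for each (t, c)
    conc = np.einsum("ij,tcj->tci", np.linalg.inv(A), od.dod)
    return HemoglobinSeries(conc[:, :, 0], conc[:, :, 1], rate=od.rate, t0=od.t0,
                            channel_ids=od.channel_ids.copy())


def forward_beer_lambert(
    dhbo2: np.ndarray,
    dhbr: np.ndarray,
    montage: Montage,
    dpf: tuple[float, float] = (DEFAULT_DPF, DEFAULT_DPF),
    extinction: np.ndarray | None = None,
    wavelengths_nm: tuple[float, float] = (740.0, 850.0),
) -> np.ndarray:
    """Forward model: concentrations (uM) -> dOD, shape [time, channel, wavelength]."""
    E = extinction if extinction is not None else extinction_matrix(wavelengths_nm)
    A = E * (montage.separation_cm * np.asarray(dpf)[:, None])
    conc = np.stack([dhbo2, dhbr], axis=-1)  # [T, C, 2]
    return np.einsum("ij,tcj->tci", A, conc)


def block_average_hrf(
    hb: HemoglobinSeries,
    paradigm: TaskParadigm,
    montage: Montage | None = None,
    baseline: tuple[float, float] = (-5.0, 0.0),
    plateau: tuple[float, float] = (10.0, 100.0),
) -> HRFEstimate:
    """Response amplitude: plateau mean minus baseline mean of dHbO2.

    Windows are in seconds relative to task onset; defaults are the last
    5 s of the pre-task rest and 10-100 s after onset.
    """
    onset = paradigm.onset + hb.t0
    base = window_indices(onset + baseline[0], onset + baseline[1], hb.t0, hb.rate, hb.n_samples)
    plat = window_indices(onset + plateau[0], onset + plateau[1], hb.t0, hb.rate, hb.n_samples)
    amp = hb.dhbo2[plat].mean(axis=0) - hb.dhbo2[base].mean(axis=0)
    channel_amplitude = {int(ch): float(a) for ch, a in zip(hb.channel_ids, amp)}
    roi_amplitude: dict[str, float] = {}
    if montage is not None:
        for roi in montage.roi_labels:
            chans = [c for c in montage.roi_channels(roi) if c in channel_amplitude]
            if chans:
                roi_amplitude[roi] = float(np.mean([channel_amplitude[c] for c in chans]))
    return HRFEstimate(channel_amplitude, roi_amplitude,
                       baseline_window=baseline, plateau_window=plateau)


def roi_average(
    hb: HemoglobinSeries,
    montage: Montage,
    exclude_channels: set[int] | None = None,
) -> ROISeries:
    """Per-time mean dHbO2 over each ROI's (surviving) channels."""
    exclude = exclude_channels or set()
    present = {int(c): i for i, c in enumerate(hb.channel_ids)}
    labels = montage.roi_labels
    cols = []
    for roi in labels:
        chans = [c for c in montage.roi_channels(roi) if c in present and c not in exclude]
        if not chans:
            raise ValidationError(f"ROI {roi!r} has no surviving channels")
        cols.append(hb.dhbo2[:, [present[c] for c in chans]].mean(axis=1))
    return ROISeries(np.column_stack(cols), roi_labels=tuple(labels), rate=hb.rate, t0=hb.t0)


def prune_channels(raw: RawIntensitySeries, cv_thresh: float = 0.5) -> set[int]:
    """Channels unusable for Beer-Lambert inversion.

    A channel is dropped when any wavelength shows nonpositive samples or an
    intensity coefficient of variation above ``cv_thresh``.
    """
    bad: set[int] = set()
    mean = raw.samples.mean(axis=0)
    sd = raw.samples.std(axis=0)
    for ci, ch in enumerate(raw.channel_ids):
        if np.any(raw.samples[:, ci, :] <= 0):
            bad.add(int(ch))
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(mean[ci] > 0, sd[ci] / mean[ci], np.inf)
        if np.any(cv > cv_thresh):
            bad.add(int(ch))
    return bad
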