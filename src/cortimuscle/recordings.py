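"""Raw recording containers and their on-disk formats.

Signals travel as self-describing tabular text: ``#``-prefixed header lines
declare the sampling rate, start time and column labels, followed by one
CSV row per sample.  The format is diffable and round-trips float64 values
losslessly (shortest-repr formatting).  A minimal reader for the
HDF5-based SNIRF container is provided as an optional input dialect for
the optical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .montage import Montage

MUSCLES: tuple[str, ...] = ("lUT", "rUT", "lMD", "rMD", "lBB", "rBB", "lTB", "rTB")


@dataclass
class RawIntensitySeries:
    """Dual-wavelength light intensity, shape [time, channel, wavelength]."""

    samples: np.ndarray
    rate: float = 10.0
    t0: float = 0.0
    channel_ids: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    wavelengths_nm: tuple[float, float] = (740.0, 850.0)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[2] != 2:
            raise ValidationError(
                f"intensity samples must be [time, channel, 2], got {self.samples.shape}"
            )
        if self.rate <= 0:
            raise ValidationError(f"rate must be > 0 Hz, got {self.rate}")
        if len(self.channel_ids) == 0:
            self.channel_ids = np.arange(1, self.samples.shape[1] + 1)
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        if len(self.channel_ids) != self.samples.shape[1]:
            raise ValidationError("channel_ids length does not match sample matrix")
        neg = np.argwhere(self.samples < 0)
        if neg.size:
            t, c, w = neg[0]
            raise ValidationError(
                f"negative intensity at sample {t}, channel {self.channel_ids[c]}, "
                f"wavelength index {w}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


@dataclass
class EMGRecording:
    """Raw surface EMG in mV, shape [time, muscle]."""

    samples: np.ndarray
    rate: float = 2000.0
    t0: float = 0.0
    muscle_labels: tuple[str, ...] = MUSCLES
    mvc_reference: dict[str, float] | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValidationError(f"EMG samples must be [time, muscle], got {self.samples.shape}")
        if self.rate <= 0:
            raise ValidationError(f"rate must be > 0 Hz, got {self.rate}")
        self.muscle_labels = tuple(self.muscle_labels)
        unknown = [m for m in self.muscle_labels if m not in MUSCLES]
        if unknown:
            raise ValidationError(
                f"unknown muscle labels {unknown}; allowed: {list(MUSCLES)}"
            )
        if len(self.muscle_labels) != self.samples.shape[1]:
            raise ValidationError("muscle_labels length does not match sample matrix")
        if self.mvc_reference is not None:
            for m, v in self.mvc_reference.items():
                if m in self.muscle_labels and not v > 0:
                    raise ValidationError(f"mvc_reference for {m} must be > 0, got {v}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate


# ---------------------------------------------------------------------------
# tabular text IO
# ---------------------------------------------------------------------------

def _is_single(values: np.ndarray) -> bool:
    return bool(np.all(values == values.astype(np.float32)))


def _write_samples(fh, values: np.ndarray, columns: list[str]) -> None:
    """Write the sample block, declaring single precision when lossless.

    Single-precision data are emitted as %.9g (shortest unique float32
    decimals) and restored bit-exactly through a float32 cast on read;
    anything else is written at full float64 repr.
    """
    if _is_single(values):
        fh.write("# precision: single\n")
        fh.write(",".join(columns) + "\n")
        np.savetxt(fh, values, fmt="%.9g", delimiter=",")
    else:
        fh.write("# precision: double\n")
        pd.DataFrame(values, columns=columns).to_csv(fh, index=False)


def _restore_precision(values: np.ndarray, meta: dict[str, str]) -> np.ndarray:
    if meta.get("precision") == "single":
        return values.astype(np.float32).astype(np.float64)
    return values


def _parser_precision(meta: dict[str, str]) -> str | None:
    # single-precision files are restored through a float32 cast, which
    # absorbs 1-ulp parser differences; the slow round-trip parser is only
    # needed for full float64 payloads
    return None if meta.get("precision") == "single" else "round_trip"


def _read_header(path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n_header = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_header += 1
            body = line[1:].strip()
            if ":" in body:
                key, val = body.split(":", 1)
                meta[key.strip()] = val.strip()
    return meta, n_header


def write_intensity(path, series: RawIntensitySeries) -> None:
    wl = series.wavelengths_nm
    cols = [f"ch{ch:02d}_{int(w)}" for ch in series.channel_ids for w in wl]
    flat = series.samples.reshape(series.n_samples, -1)
    with open(path, "w") as fh:
        fh.write("# format: cortimuscle-intensity v1\n")
        fh.write(f"# rate_hz: {series.rate!r}\n")
        fh.write(f"# t0_s: {series.t0!r}\n")
        fh.write(f"# wavelengths_nm: {wl[0]!r},{wl[1]!r}\n")
        _write_samples(fh, flat, cols)


def read_intensity_recording(path, montage: Montage) -> RawIntensitySeries:
    """Read and validate a dual-wavelength intensity file against a montage."""
    meta, n_header = _read_header(path)
    for key in ("rate_hz", "t0_s", "wavelengths_nm"):
        if key not in meta:
            raise FormatError(f"intensity file missing header '{key}'")
    try:
        rate = float(meta["rate_hz"])
        t0 = float(meta["t0_s"])
        wls = tuple(float(x) for x in meta["wavelengths_nm"].split(","))
    except ValueError as exc:
        raise FormatError(f"malformed intensity header: {exc}") from None
    df = pd.read_csv(path, skiprows=n_header, float_precision=_parser_precision(meta))
    # parse columns chNN_WWW
    chan_wl: dict[int, dict[int, str]] = {}
    for col in df.columns:
        try:
            ch_part, wl_part = col.split("_")
            ch = int(ch_part[2:])
            wl = int(wl_part)
        except (ValueError, IndexError):
            raise FormatError(f"unrecognized intensity column {col!r}") from None
        chan_wl.setdefault(ch, {})[wl] = col
    file_channels = sorted(chan_wl)
    missing = [int(c) for c in montage.channel_ids if c not in chan_wl]
    extra = [c for c in file_channels if c not in set(montage.channel_ids.tolist())]
    if missing or extra:
        raise ValidationError(
            f"channel/montage mismatch: missing channels {missing}, unexpected {extra}"
        )
    wl_int = tuple(int(w) for w in wls)
    n = len(df)
    samples = np.empty((n, montage.n_channels, 2))
    for ci, ch in enumerate(montage.channel_ids):
        for wi, w in enumerate(wl_int):
            if w not in chan_wl[int(ch)]:
                raise ValidationError(f"channel {ch} missing wavelength {w} nm column")
            samples[:, ci, wi] = df[chan_wl[int(ch)][w]].to_numpy()
    samples = _restore_precision(samples, meta)
    return RawIntensitySeries(samples, rate=rate, t0=t0,
                              channel_ids=montage.channel_ids.copy(), wavelengths_nm=wls)


def write_emg(path, rec: EMGRecording) -> None:
    with open(path, "w") as fh:
        fh.write("# format: cortimuscle-emg v1\n")
        fh.write(f"# rate_hz: {rec.rate!r}\n")
        fh.write(f"# t0_s: {rec.t0!r}\n")
        if rec.mvc_reference:
            ref = ",".join(f"{m}={rec.mvc_reference[m]!r}" for m in rec.muscle_labels
                           if m in rec.mvc_reference)
            fh.write(f"# mvc_reference: {ref}\n")
        _write_samples(fh, rec.samples, list(rec.muscle_labels))


def read_emg_recording(path) -> EMGRecording:
    """Read and validate an sEMG file."""
    meta, n_header = _read_header(path)
    for key in ("rate_hz", "t0_s"):
        if key not in meta:
            raise FormatError(f"EMG file missing header '{key}'")
    try:
        rate = float(meta["rate_hz"])
        t0 = float(meta["t0_s"])
    except ValueError as exc:
        raise FormatError(f"malformed EMG header: {exc}") from None
    if rate <= 0:
        raise ValidationError(f"EMG rate must be > 0 Hz, got {rate}")
    mvc = None
    if "mvc_reference" in meta:
        mvc = {}
        for item in meta["mvc_reference"].split(","):
            m, v = item.split("=")
            mvc[m.strip()] = float(v)
    df = pd.read_csv(path, skiprows=n_header, float_precision=_parser_precision(meta))
    labels = tuple(df.columns)
    samples = _restore_precision(df.to_numpy(dtype=float), meta)
    return EMGRecording(samples, rate=rate, t0=t0,
                        muscle_labels=labels, mvc_reference=mvc)


# ---------------------------------------------------------------------------
# SNIRF (minimal dialect)
# ---------------------------------------------------------------------------

def read_snirf(path, montage: Montage) -> RawIntensitySeries:
    """Read continuous-wave intensity from a SNIRF (HDF5) file.

    Minimal dialect: ``/nirs/data1/dataTimeSeries`` with a measurement list
    whose (sourceIndex, detectorIndex) pairs identify channels in montage
    order and wavelengthIndex selects the wavelength.  Only regular time
    grids are accepted.
    """
    import h5py

    with h5py.File(path, "r") as f:
        data = f["/nirs/data1/dataTimeSeries"][()]
        time = f["/nirs/data1/time"][()]
        wl = tuple(float(w) for w in f["/nirs/probe/wavelengths"][()])
        n_meas = data.shape[1]
        pairs = []
        for i in range(1, n_meas + 1):
            ml = f[f"/nirs/data1/measurementList{i}"]
            pairs.append(
                (int(ml["sourceIndex"][()]), int(ml["detectorIndex"][()]),
                 int(ml["wavelengthIndex"][()]))
            )
    dt = np.diff(time)
    if dt.size and (dt.max() - dt.min()) > 1e-6 * dt.mean():
        raise FormatError("SNIRF time grid is not regular")
    rate = 1.0 / float(dt.mean()) if dt.size else 10.0
    # channels = unique (source, detector) pairs in first-appearance order
    sd_order: list[tuple[int, int]] = []
    for s, d, _ in pairs:
        if (s, d) not in sd_order:
            sd_order.append((s, d))
    if len(sd_order) != montage.n_channels:
        raise ValidationError(
            f"SNIRF file has {len(sd_order)} channels, montage declares {montage.n_channels}"
        )
    samples = np.empty((data.shape[0], montage.n_channels, 2))
    for col, (s, d, w) in enumerate(pairs):
        ci = sd_order.index((s, d))
        samples[:, ci, w - 1] = data[:, col]
    return RawIntensitySeries(samples, rate=rate, t0=float(time[0]),
                              channel_ids=montage.channel_ids.copy(),
                              wavelengths_nm=wl)
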