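"""Channel montage: optode geometry and channel-to-ROI assignment.

The default montage encodes the 63-channel, dual-wavelength (740/850 nm,
3 cm source-detector separation) layout with eight cortical regions of
interest (prefrontal cortex, premotor cortex, supplementary motor area and
primary motor cortex, per hemisphere).  ROI membership follows the standard
probabilistic-registration channel table for this layout:

=====  ====================
ROI    channels
=====  ====================
lPFC   5, 6, 7, 18
rPFC   23, 59, 60, 61
lPMC   1, 2, 26
rPMC   40, 42, 43
lSMA   12, 13, 29, 30
rSMA   37, 38, 39, 41
lM1    14, 25, 31, 32
rM1    44, 45, 46, 48
=====  ====================

30 channels carry an ROI label; the remaining 33 are measured but belong to
no ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

N_CHANNELS = 63
DEFAULT_SEPARATION_CM = 3.0
DEFAULT_WAVELENGTHS_NM = (740.0, 850.0)

ROI_CHANNELS: dict[str, tuple[int, ...]] = {
    "lPFC": (5, 6, 7, 18),
    "rPFC": (23, 59, 60, 61),
    "lPMC": (1, 2, 26),
    "rPMC": (40, 42, 43),
    "lSMA": (12, 13, 29, 30),
    "rSMA": (37, 38, 39, 41),
    "lM1": (14, 25, 31, 32),
    "rM1": (44, 45, 46, 48),
}

ROI_ORDER: tuple[str, ...] = ("lPFC", "rPFC", "lPMC", "rPMC", "lSMA", "rSMA", "lM1", "rM1")


@dataclass
class Montage:
    """Channel geometry plus channel->ROI map.

    ``roi_of`` maps a channel id to its ROI label; channels without an ROI
    are absent from the map.  A channel belongs to at most one ROI.
    """

    channel_ids: np.ndarray
    source_ids: np.ndarray
    detector_ids: np.ndarray
    separation_cm: float = DEFAULT_SEPARATION_CM
    wavelengths_nm: tuple[float, float] = DEFAULT_WAVELENGTHS_NM
    roi_of: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.channel_ids = np.asarray(self.channel_ids, dtype=int)
        self.source_ids = np.asarray(self.source_ids, dtype=int)
        self.detector_ids = np.asarray(self.detector_ids, dtype=int)
        self.validate()

    # -- invariants -------------------------------------------------------
    def validate(self) -> None:
        if self.separation_cm <= 0:
            raise ValidationError(f"separation must be > 0 cm, got {self.separation_cm}")
        lo, hi = self.wavelengths_nm
        if not (lo < hi):
            raise ValidationError(f"wavelength pair must be strictly increasing, got {self.wavelengths_nm}")
        if not (600.0 < lo < 1000.0 and 600.0 < hi < 1000.0):
            raise ValidationError(f"wavelengths must lie in (600, 1000) nm, got {self.wavelengths_nm}")
        if len(np.unique(self.channel_ids)) != len(self.channel_ids):
            raise ValidationError("duplicate channel ids in montage")
        known = set(self.channel_ids.tolist())
        for ch, roi in self.roi_of.items():
            if ch not in known:
                raise ValidationError(f"ROI {roi!r} references unknown channel {ch}")

    # -- queries ----------------------------------------------------------
    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    @property
    def roi_labels(self) -> tuple[str, ...]:
        present = set(self.roi_of.values())
        return tuple(r for r in ROI_ORDER if r in present) + tuple(
            sorted(present - set(ROI_ORDER))
        )

    def roi_channels(self, roi: str) -> list[int]:
        return [ch for ch, r in sorted(self.roi_of.items()) if r == roi]

    def channel_index(self, channel_id: int) -> int:
        idx = np.flatnonzero(self.channel_ids == channel_id)
        if idx.size == 0:
            raise ValidationError(f"channel {channel_id} not in montage")
        return int(idx[0])

    def subset(self, channel_ids: list[int]) -> "Montage":
        """Restrict the montage to a subset of channels (order preserved)."""
        idx = [self.channel_index(ch) for ch in channel_ids]
        return Montage(
            channel_ids=self.channel_ids[idx],
            source_ids=self.source_ids[idx],
            detector_ids=self.detector_ids[idx],
            separation_cm=self.separation_cm,
            wavelengths_nm=self.wavelengths_nm,
            roi_of={ch: r for ch, r in self.roi_of.items() if ch in set(channel_ids)},
        )


def _roi_map(overrides: dict[str, list[int]] | None) -> dict[int, str]:
    table = {k: tuple(v) for k, v in overrides.items()} if overrides else dict(ROI_CHANNELS)
    roi_of: dict[int, str] = {}
    for roi, chans in table.items():
        for ch in chans:
            if ch in roi_of:
                raise ValidationError(
                    f"channel {ch} assigned to both {roi_of[ch]!r} and {roi!r}"
                )
            roi_of[ch] = roi
    return roi_of


def default_montage(roi_overrides: dict[str, list[int]] | None = None) -> Montage:
    """The 63-channel default montage with the standard ROI table."""
    ch = np.arange(1, N_CHANNELS + 1)
    # Source/detector bookkeeping: deterministic plumbing (the exact optode
    # grid is irrelevant to every computation downstream of the montage).
    src = (ch - 1) // 3 + 1
    det = (ch - 1) % 24 + 1
    return Montage(
        channel_ids=ch,
        source_ids=src,
        detector_ids=det,
        roi_of=_roi_map(roi_overrides),
    )


def load_montage(path=None) -> Montage:
    """Load a montage from CSV; ``None`` yields the default montage.

    Columns: channel, source, detector, separation_cm, wl1_nm, wl2_nm, roi
    (roi empty or 'none' for unassigned channels).  Omitted columns fall
    back to the defaults (3 cm, 740/850 nm, default ROI table).
    """
    if path is None:
        return default_montage()
    df = pd.read_csv(path, comment="#")
    if "channel" not in df.columns:
        raise ValidationError("montage file must have a 'channel' column")
    ch = df["channel"].to_numpy(dtype=int)
    src = df["source"].to_numpy(dtype=int) if "source" in df else (ch - 1) // 3 + 1
    det = df["detector"].to_numpy(dtype=int) if "detector" in df else (ch - 1) % 24 + 1
    sep = float(df["separation_cm"].iloc[0]) if "separation_cm" in df else DEFAULT_SEPARATION_CM
    if "wl1_nm" in df and "wl2_nm" in df:
        wls = (float(df["wl1_nm"].iloc[0]), float(df["wl2_nm"].iloc[0]))
    else:
        wls = DEFAULT_WAVELENGTHS_NM
    if "roi" in df.columns:
        roi_of: dict[int, str] = {}
        seen: dict[int, str] = {}
        for c, r in zip(ch, df["roi"].fillna("none")):
            r = str(r).strip()
            if r and r.lower() != "none" and r != "nan":
                if c in seen:
                    raise ValidationError(f"channel {c} assigned to two ROIs")
                seen[int(c)] = r
                roi_of[int(c)] = r
    else:
        roi_of = {c: r for c, r in _roi_map(None).items() if c in set(ch.tolist())}
    return Montage(ch, src, det, sep, wls, roi_of)


def write_montage(path, montage: Montage) -> None:
    rows = []
    for i, ch in enumerate(montage.channel_ids):
        rows.append(
            {
                "channel": int(ch),
                "source": int(montage.source_ids[i]),
                "detector": int(montage.detector_ids[i]),
                "separation_cm": montage.separation_cm,
                "wl1_nm": montage.wavelengths_nm[0],
                "wl2_nm": montage.wavelengths_nm[1],
                "roi": montage.roi_of.get(int(ch), "none"),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
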