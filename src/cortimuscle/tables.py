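"""Labeled time-series tables for derived signals (ROI dHbO2, envelopes, ...).

Same self-describing text convention as the raw recordings: ``#`` header
lines for rate/t0/units, then one CSV row per sample with labeled columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import FormatError
from .recordings import _read_header


def write_timeseries(path, values: np.ndarray, columns: list[str], rate: float,
                     t0: float = 0.0, units: str = "", kind: str = "timeseries") -> None:
    with open(path, "w") as fh:
        fh.write(f"# format: cortimuscle-{kind} v1\n")
        fh.write(f"# rate_hz: {rate!r}\n")
        fh.write(f"# t0_s: {t0!r}\n")
        if units:
            fh.write(f"# units: {units}\n")
        pd.DataFrame(np.asarray(values), columns=columns).to_csv(fh, index=False)


def read_timeseries(path) -> tuple[np.ndarray, list[str], float, float, str]:
    """Returns (values, columns, rate, t0, units)."""
    meta, n_header = _read_header(path)
    if "rate_hz" not in meta or "t0_s" not in meta:
        raise FormatError(f"{path}: missing rate_hz/t0_s header")
    df = pd.read_csv(path, skiprows=n_header, float_precision="round_trip")
    return (df.to_numpy(dtype=float), list(df.columns),
            float(meta["rate_hz"]), float(meta["t0_s"]), meta.get("units", ""))
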