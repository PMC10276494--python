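"""Shared-clock time bookkeeping.

Both modalities carry an absolute start time ``t0`` on one synchronized
clock.  All analysis windows are specified in seconds and converted to
sample indices by rounding half-up; intervals are half-open ``[start, end)``
so boundary samples are never double counted.
"""

from __future__ import annotations

import math

from .errors import ValidationError


def sample_index(t: float, t0: float, rate: float) -> int:
    """Index of the sample at absolute time ``t`` (round half-up)."""
    return int(math.floor((t - t0) * rate + 0.5))


def window_indices(start: float, end: float, t0: float, rate: float, n: int) -> slice:
    """Slice of samples covering the half-open interval [start, end) seconds.

    Raises if the interval is not fully covered by the ``n`` available samples.
    """
    i0 = sample_index(start, t0, rate)
    i1 = sample_index(end, t0, rate)
    if i0 < 0 or i1 > n:
        raise ValidationError(
            f"window [{start}, {end}) s exceeds record "
            f"(t0={t0}, rate={rate}, n={n})"
        )
    if i1 <= i0:
        raise ValidationError(f"empty window [{start}, {end}) s")
    return slice(i0, i1)


def check_aligned(t0_a: float, t0_b: float, rate: float, tol: float = 1e-6) -> None:
    """Require the t0 offset between two series to be a whole number of samples."""
    offset = (t0_b - t0_a) * rate
    if abs(offset - round(offset)) > tol * rate:
        raise ValidationError(
            f"t0 offset {t0_b - t0_a} s is not a multiple of the sample period "
            f"1/{rate} s; regenerate the series on a shared grid"
        )
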