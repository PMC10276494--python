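"""Functional connectivity from dHbO2: Pearson correlation between channels
with Fisher-z aggregation to ROI level.

The ROI-level value for a region pair (A, B) is the inverse Fisher
transform of the mean z over all cross-region channel pairs — averaging in
z-space is variance-stabilizing and is *not* the same as averaging the
correlation coefficients directly (tanh is concave on r > 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fnirs import HemoglobinSeries
from .montage import Montage
from .timebase import window_indices

_CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """Symmetric ROI x ROI functional-connectivity matrix.

    Cells are back-transformed mean-z correlations; ``n_pairs`` counts the
    channel pairs entering each cell.  Undefined cells (no valid pairs) are
    NaN and flagged in ``defined``.
    """

    values: np.ndarray
    n_pairs: np.ndarray
    roi_labels: tuple[str, ...]
    window: tuple[float, float] | None = None

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    def cell(self, roi_a: str, roi_b: str) -> float:
        i, j = self.roi_labels.index(roi_a), self.roi_labels.index(roi_b)
        return float(self.values[i, j])


def channel_fc(
    hb: HemoglobinSeries,
    window: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Pearson correlation of dHbO2 over a window.

    Returns ``(r, valid)``: the [channel, channel] correlation matrix (unit
    diagonal) and a boolean validity vector; zero-variance channels get NaN
    rows/columns and ``valid=False``.
    """
    if window is not None:
        sl = window_indices(window[0], window[1], hb.t0, hb.rate, hb.n_samples)
        x = hb.dhbo2[sl]
    else:
        x = hb.dhbo2
    if x.shape[0] < 30:
        raise ValidationError(f"FC window of {x.shape[0]} samples is below the 30-sample minimum")
    sd = x.std(axis=0)
    valid = sd > 0
    r = np.full((x.shape[1], x.shape[1]), np.nan)
    if valid.any():
        sub = np.corrcoef(x[:, valid], rowvar=False)
        sub = np.atleast_2d(sub)
        ii = np.flatnonzero(valid)
        r[np.ix_(ii, ii)] = sub
    np.fill_diagonal(r, np.where(valid, 1.0, np.nan))
    return r, valid


def fisher_z(r: np.ndarray | float) -> np.ndarray | float:
    """z = atanh(r); |r| >= 1 is clipped to +/-(1 - 1e-7) with a warning."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) >= 1.0):
        warnings.warn("correlation at or beyond +/-1 clipped before Fisher transform",
                      stacklevel=2)
        r_arr = np.clip(r_arr, -_CLIP, _CLIP)
    z = np.arctanh(r_arr)
    return float(z) if np.isscalar(r) else z


def inverse_fisher(z: np.ndarray | float) -> np.ndarray | float:
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) else out


def roi_fc(
    r_matrix: np.ndarray,
    montage: Montage,
    channel_ids: np.ndarray | None = None,
    valid: np.ndarray | None = None,
    window: tuple[float, float] | None = None,
) -> FCMatrix:
    """Aggregate a channel correlation matrix to ROI level in z-space.

    Off-diagonal cells average all cross-region channel pairs; diagonal
    cells average all distinct within-region pairs.  ROI pairs with no
    valid channel pair are NaN (flagged, never silent zeros).
    """
    channel_ids = np.asarray(channel_ids if channel_ids is not None
                             else np.arange(1, r_matrix.shape[0] + 1))
    if valid is None:
        valid = ~np.isnan(np.diagonal(r_matrix))
    pos = {int(c): i for i, c in enumerate(channel_ids)}
    labels = montage.roi_labels
    k = len(labels)
    values = np.full((k, k), np.nan)
    n_pairs = np.zeros((k, k), dtype=int)
    members = {
        roi: [pos[c] for c in montage.roi_channels(roi) if c in pos and valid[pos[c]]]
        for roi in labels
    }
    for i, ra in enumerate(labels):
        for j in range(i, k):
            rb = labels[j]
            if i == j:
                idx = members[ra]
                pairs = [(a, b) for ai, a in enumerate(idx) for b in idx[ai + 1:]]
            else:
                pairs = [(a, b) for a in members[ra] for b in members[rb] if a != b]
            if not pairs:
                continue
            rs = np.array([r_matrix[a, b] for a, b in pairs])
            rs = rs[~np.isnan(rs)]
            if rs.size == 0:
                continue
            values[i, j] = values[j, i] = inverse_fisher(np.mean(fisher_z(rs)))
            n_pairs[i, j] = n_pairs[j, i] = rs.size
    return FCMatrix(values, n_pairs, tuple(labels), window=window)
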