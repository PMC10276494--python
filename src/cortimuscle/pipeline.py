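"""Per-subject pipeline conveniences chaining the stage operations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import connectivity, coupling, emg as emg_mod, fnirs
from .montage import Montage
from .paradigm import TaskParadigm
from .recordings import EMGRecording, RawIntensitySeries


@dataclass
class FnirsDerived:
    od: fnirs.OpticalDensitySeries
    artifact_mask: np.ndarray
    od_corrected: fnirs.OpticalDensitySeries
    od_filtered: fnirs.OpticalDensitySeries
    hb: fnirs.HemoglobinSeries
    roi: fnirs.ROISeries
    hrf: fnirs.HRFEstimate
    pruned_channels: set[int]


def preprocess_fnirs_subject(raw: RawIntensitySeries, montage: Montage,
                             paradigm: TaskParadigm,
                             motion_params: dict | None = None,
                             spline_smoothing: float = 0.99) -> FnirsDerived:
    """intensity -> OD -> motion correction -> band-pass -> MBLL -> ROI/HRF."""
    pruned = fnirs.prune_channels(raw)
    od = fnirs.intensity_to_od(raw)
    mask = fnirs.detect_motion_artifacts(od, **(motion_params or {}))
    od_corr = fnirs.spline_correct(od, mask, smoothing=spline_smoothing)
    od_filt = fnirs.bandpass_hemodynamic(od_corr)
    hb = fnirs.od_to_hemoglobin(od_filt, montage)
    roi = fnirs.roi_average(hb, montage, exclude_channels=pruned)
    hrf = fnirs.block_average_hrf(hb, paradigm, montage=montage)
    return FnirsDerived(od, mask, od_corr, od_filt, hb, roi, hrf, pruned)


def preprocess_emg_subject(raw: EMGRecording, mvc_trial: EMGRecording,
                           paradigm: TaskParadigm) -> tuple[emg_mod.EnvelopeSeries, dict[str, float]]:
    """raw sEMG -> %MVC envelope + task-window activation summary."""
    env = emg_mod.process_emg(raw, mvc_trial=mvc_trial)
    onset = env.t0 + paradigm.onset
    activation = emg_mod.activation_summary(
        env, (onset + coupling.ANALYSIS_WINDOW[0], onset + coupling.ANALYSIS_WINDOW[1]))
    return env, activation


def fc_subject(derived: FnirsDerived, montage: Montage, paradigm: TaskParadigm,
               window: tuple[float, float] | None = None) -> connectivity.FCMatrix:
    """ROI functional connectivity over the task interval (default window)."""
    hb = derived.hb
    if window is None:
        onset = hb.t0 + paradigm.onset
        window = (onset, onset + paradigm.task)
    r, valid = connectivity.channel_fc(hb, window=window)
    pruned = derived.pruned_channels
    for i, ch in enumerate(hb.channel_ids):
        if int(ch) in pruned:
            valid[i] = False
    return connectivity.roi_fc(r, montage, channel_ids=hb.channel_ids,
                               valid=valid, window=window)


def fc_long_table(fc: connectivity.FCMatrix, subject: str = "") -> pd.DataFrame:
    rows = []
    labels = fc.roi_labels
    for i, a in enumerate(labels):
        for j in range(i, len(labels)):
            rows.append({"subject": subject, "roi_a": a, "roi_b": labels[j],
                         "r": fc.values[i, j], "n_pairs": int(fc.n_pairs[i, j])})
    return pd.DataFrame(rows)
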