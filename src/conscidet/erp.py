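"""Condition-averaged waveforms and ERP component amplitudes.

Four components are quantified as region-of-interest window means of the
condition-averaged waveform:

* P300 — parietal ROI (P7, P3, PZ, P4, P8), 250–400 ms, deviant stimuli;
* CNV  — frontal ROI (FP1, FP2, F7, F3, FZ, F4, F8), 800–1000 ms, deviants;
* N400 — parietal ROI, 380–420 ms, incorrect-novel minus correct-novel;
* P600 — frontal ROI, 650–750 ms, incorrect-novel minus correct-novel.

Amplitudes are window means only; no peak picking or latency estimation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import ROI1, ROI2, EpochSet


@dataclass(frozen=True)
class ComponentSpec:
    name: str
    roi: tuple[str, ...]
    window_ms: tuple[float, float]
    kind: str                      # {"single", "difference"}
    conditions: tuple[str, ...]    # stimulus types involved


COMPONENT_SPECS = (
    ComponentSpec("P300", ROI1, (250.0, 400.0), "single", ("deviant",)),
    ComponentSpec("CNV", ROI2, (800.0, 1000.0), "single", ("deviant",)),
    ComponentSpec("N400", ROI1, (380.0, 420.0), "difference",
                  ("incorrect_novel", "correct_novel")),
    ComponentSpec("P600", ROI2, (650.0, 750.0), "difference",
                  ("incorrect_novel", "correct_novel")),
)


def average_waveform(ep: EpochSet, stimulus_type: str | None = None,
                     mode: str | None = None) -> np.ndarray:
    """Pointwise mean over trials matching the condition (channels × time)."""
    m = ep.mask(stimulus_type=stimulus_type, mode=mode)
    if not m.any():
        raise ValueError(
            f"no trials match stimulus_type={stimulus_type!r}, mode={mode!r}")
    return ep.data[m].mean(axis=0)


def roi_window_mean(waveform: np.ndarray, channel_names, times_ms,
                    roi, window_ms) -> float:
    """Mean over ROI channels then over window samples (inclusive ends)."""
    channel_names = tuple(channel_names)
    idx = [channel_names.index(ch) for ch in roi]
    times_ms = np.asarray(times_ms)
    lo, hi = window_ms
    m = (times_ms >= lo - 1e-9) & (times_ms <= hi + 1e-9)
    if not m.any():
        raise ValueError(f"window {window_ms} contains no samples")
    return float(waveform[np.ix_(idx, np.nonzero(m)[0])].mean())


def component_amplitudes(ep: EpochSet, subject_id: str = "S1",
                         specs=COMPONENT_SPECS) -> pd.DataFrame:
    """One amplitude per (mode × component); difference components are
    incorrect-novel minus correct-novel window means.

    Conditions absent from the data yield a warning and no row.
    """
    modes = list(dict.fromkeys(ep.labels["mode"]))
    modality = ep.labels["modality"].iloc[0] if len(ep.labels) else "unknown"
    rows = []
    for mode in modes:
        for spec in specs:
            counts = [int(ep.mask(stimulus_type=st, mode=mode).sum())
                      for st in spec.conditions]
            if any(c == 0 for c in counts):
                warnings.warn(
                    f"{spec.name}/{mode}: missing condition(s) "
                    f"{[st for st, c in zip(spec.conditions, counts) if c == 0]}"
                    "; row omitted")
                continue
            means = [roi_window_mean(
                         average_waveform(ep, stimulus_type=st, mode=mode),
                         ep.channel_names, ep.times_ms, spec.roi,
                         spec.window_ms)
                     for st in spec.conditions]
            amp = means[0] if spec.kind == "single" else means[0] - means[1]
            rows.append((subject_id, modality, mode, spec.name, amp,
                         sum(counts)))
    return pd.DataFrame(rows, columns=["subject_id", "modality", "mode",
                                       "component", "amplitude_uv",
                                       "n_trials_used"])
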