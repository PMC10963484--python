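"""Continuous-EEG preprocessing: band-pass + notch filtering, mastoid
re-referencing, epoching with baseline correction, ocular-artifact
regression, and amplitude-based trial rejection.

Filters are applied forward-backward (zero phase) so that component
latencies are not shifted.  The amplitude rejection rule is strict
("exceeding ±75 µV"): samples at exactly the threshold are retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (EOG_CHANNELS, LABEL_COLUMNS, MASTOIDS, EpochSet,
                         Recording)


@dataclass(frozen=True)
class PreprocessConfig:
    bandpass_hz: tuple[float, float] = (0.1, 20.0)
    notch_hz: float = 50.0
    notch_q: float = 30.0
    epoch_window_ms: tuple[float, float] = (-200.0, 1000.0)
    baseline_window_ms: tuple[float, float] = (-200.0, 0.0)
    reject_threshold_uv: float = 75.0
    artifact_method: str = "eog_regression"    # {eog_regression, none}

    def __post_init__(self) -> None:
        lo, hi = self.bandpass_hz
        if not 0 <= lo < hi:
            raise ValueError("bandpass must satisfy 0 <= low < high")
        e0, e1 = self.epoch_window_ms
        b0, b1 = self.baseline_window_ms
        if not (e0 <= b0 < b1 <= e1):
            raise ValueError("baseline window must lie inside the epoch window")
        if self.reject_threshold_uv <= 0:
            raise ValueError("reject threshold must be positive")
        if self.artifact_method not in ("eog_regression", "none"):
            raise ValueError(f"unknown artifact_method {self.artifact_method!r}")

    def with_(self, **kwargs) -> "PreprocessConfig":
        return replace(self, **kwargs)


def filter_recording(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
                     ) -> Recording:
    """Zero-phase 4th-order band-pass plus 50 Hz notch (Q=30).

    The notch is applied to EEG channels only; EOG channels are band-passed
    but not notched.  Signal length is preserved.
    """
    fs = rec.sampling_rate_hz
    lo, hi = cfg.bandpass_hz
    if hi >= fs / 2:
        raise ValueError(f"band edge {hi} Hz >= Nyquist ({fs / 2} Hz)")
    sos = signal.butter(2, (lo, hi), btype="bandpass", fs=fs, output="sos")
    out = rec.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    if cfg.notch_hz and cfg.notch_hz < fs / 2:
        b, a = signal.iirnotch(cfg.notch_hz, cfg.notch_q, fs=fs)
        eeg = [i for i, ch in enumerate(rec.channel_names)
               if ch not in EOG_CHANNELS]
        out.data[eeg] = signal.filtfilt(b, a, out.data[eeg], axis=1)
    return out


def rereference(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
                ) -> Recording:
    """Re-reference every non-EOG channel to the mastoid average (M1+M2)/2."""
    for m in MASTOIDS:
        if m not in rec.channel_names:
            raise ValueError(f"mastoid channel {m} missing; cannot re-reference")
    ref = 0.5 * (rec.channel("M1") + rec.channel("M2"))
    out = rec.copy()
    for i, ch in enumerate(rec.channel_names):
        if ch not in EOG_CHANNELS:
            out.data[i] -= ref
    return out


def extract_epochs(rec: Recording, cfg: PreprocessConfig = PreprocessConfig()
                   ) -> EpochSet:
    """Cut one baseline-corrected trial per event.

    Window endpoints are inclusive on the native sample grid, so a
    (−200, +1000) ms window at 1000 Hz yields 1201 samples.  Events whose
    window extends past either end of the recording are skipped and logged.
    """
    fs = rec.sampling_rate_hz
    w0, w1 = cfg.epoch_window_ms
    off0 = int(round(w0 * fs / 1000.0))
    off1 = int(round(w1 * fs / 1000.0))
    n_times = off1 - off0 + 1
    times_ms = (np.arange(off0, off1 + 1)) * 1000.0 / fs

    trials, rows, log = [], [], []
    for idx, ev in enumerate(rec.events):
        center = int(round(ev.onset_ms * fs / 1000.0))
        a, b = center + off0, center + off1 + 1
        if a < 0 or b > rec.n_samples:
            log.append({"event_index": idx, "reason": "edge",
                        "onset_ms": ev.onset_ms})
            continue
        trials.append(rec.data[:, a:b])
        rows.append((idx, ev.onset_ms, ev.stimulus_type, ev.mode, ev.block,
                     ev.modality))
    if not trials:
        raise ValueError("no events fit inside the recording")
    data = np.stack(trials)
    labels = pd.DataFrame(rows, columns=LABEL_COLUMNS)
    ep = EpochSet(data, rec.channel_names, fs, times_ms, labels, log)
    return baseline_correct(ep, cfg)


def baseline_correct(ep: EpochSet, cfg: PreprocessConfig = PreprocessConfig()
                     ) -> EpochSet:
    """Subtract the per-trial per-channel mean over the baseline window.

    This is a projection: applying it twice equals applying it once.
    """
    m = ep.time_mask(*cfg.baseline_window_ms)
    base = ep.data[:, :, m].mean(axis=2, keepdims=True)
    return EpochSet(ep.data - base, ep.channel_names, ep.sampling_rate_hz,
                    ep.times_ms, ep.labels.copy(), list(ep.rejection_log))


def remove_ocular_artifacts(ep: EpochSet,
                            cfg: PreprocessConfig = PreprocessConfig()
                            ) -> EpochSet:
    """Regress each EEG channel on VEOG/HEOG and subtract the fit.

    Coefficients are estimated by least squares pooled over all retained
    samples of all trials.  A pluggable stand-in for component-based
    artifact removal; with ``artifact_method == "none"`` this is the
    identity.
    """
    if cfg.artifact_method == "none":
        return ep
    for ch in EOG_CHANNELS:
        if ch not in ep.channel_names:
            raise ValueError(f"EOG channel {ch} missing; cannot regress")
    veog = ep.data[:, ep.index("VEOG"), :].ravel()
    heog = ep.data[:, ep.index("HEOG"), :].ravel()
    X = np.column_stack([veog, heog])
    Xd = X - X.mean(axis=0)
    if np.allclose(Xd.std(axis=0), 0):
        warnings.warn("EOG channels have zero variance; skipping regression")
        return ep
    eog_idx = ep.indices(EOG_CHANNELS)
    eeg_idx = np.array([i for i in range(len(ep.channel_names))
                        if i not in eog_idx])
    n_tr, _, n_t = ep.data.shape
    Y = ep.data[:, eeg_idx, :].transpose(1, 0, 2).reshape(len(eeg_idx), -1).T
    Y0 = Y - Y.mean(axis=0)
    # coefficients from demeaned data; the subtracted contribution uses the
    # raw EOG so an exactly proportional channel is zeroed out
    beta, *_ = np.linalg.lstsq(Xd, Y0, rcond=None)
    cleaned = (Y - X @ beta).T.reshape(len(eeg_idx), n_tr, n_t).transpose(1, 0, 2)
    out = ep.data.copy()
    out[:, eeg_idx, :] = cleaned
    return EpochSet(out, ep.channel_names, ep.sampling_rate_hz, ep.times_ms,
                    ep.labels.copy(), list(ep.rejection_log))


def reject_epochs(ep: EpochSet, cfg: PreprocessConfig = PreprocessConfig()
                  ) -> EpochSet:
    """Drop trials in which any scalp-EEG sample strictly exceeds the
    threshold magnitude; mastoid and EOG channels are not tested."""
    scalp = ep.indices(ep.scalp_names)
    peak = np.abs(ep.data[:, scalp, :]).max(axis=(1, 2))
    keep = peak <= cfg.reject_threshold_uv
    log = list(ep.rejection_log)
    for i in np.nonzero(~keep)[0]:
        log.append({"event_index": int(ep.labels["event_index"].iloc[i]),
                    "reason": "amplitude",
                    "peak_uv": float(peak[i])})
    if not keep.any():
        raise ValueError(
            f"all {ep.n_trials} trials exceed ±{cfg.reject_threshold_uv} µV; "
            "check scaling or threshold")
    return EpochSet(ep.data[keep], ep.channel_names, ep.sampling_rate_hz,
                    ep.times_ms, ep.labels.loc[keep].reset_index(drop=True),
                    log)


def preprocess_recording(rec: Recording,
                         cfg: PreprocessConfig = PreprocessConfig()
                         ) -> EpochSet:
    """Full chain: filter → re-reference → epoch/baseline → EOG regression →
    amplitude rejection (rejection last, maximizing retained trials)."""
    rec = filter_recording(rec, cfg)
    rec = rereference(rec, cfg)
    ep = extract_epochs(rec, cfg)
    ep = remove_ocular_artifacts(ep, cfg)
    return reject_epochs(ep, cfg)
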