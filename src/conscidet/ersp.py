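"""Event-related spectral perturbation (ERD/ERS) analysis.

Per-trial short-time Fourier power P(t, f) = |F(t, f)|² is computed with a
fixed 200 ms Hann window hopped every 50 ms, the mean baseline power
R̄(f) over pre-stimulus frames is subtracted per trial and per frequency
(subtraction convention, raw µV² — not the dB ratio convention), and the
baseline-corrected maps are averaged across trials.  Negative corrected
power is event-related desynchronization (ERD), positive is
synchronization (ERS).

Frequency bins are spaced 1 Hz apart by zero-padding each 200 ms frame to
one second.  A 200 ms window cannot genuinely resolve structure below
~5 Hz; lower bins are retained but should be read as axis coverage, not
resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .containers import EpochSet

STFT_WINDOW_MS = 200.0
STFT_HOP_MS = 50.0
FREQ_RANGE_HZ = (1.0, 20.0)

#: named band/window presets used throughout: FZ theta-ERS and alpha-ERD
THETA_PRESET = ((4.0, 7.0), (200.0, 400.0))
ALPHA_PRESET = ((8.0, 13.0), (400.0, 1000.0))


@dataclass(frozen=True)
class BandWindowSpec:
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    channel: str = "FZ"

    @classmethod
    def theta(cls, channel: str = "FZ") -> "BandWindowSpec":
        return cls(*THETA_PRESET, channel)

    @classmethod
    def alpha(cls, channel: str = "FZ") -> "BandWindowSpec":
        return cls(*ALPHA_PRESET, channel)


@dataclass
class ERSPMap:
    """Trial-averaged time-frequency map for one channel."""

    power: np.ndarray          # (n_frames, n_freqs) baseline-corrected, µV²
    raw_power: np.ndarray      # (n_frames, n_freqs) before baseline removal
    baseline: np.ndarray       # (n_freqs,) mean R̄(f) across trials
    times_ms: np.ndarray       # frame centers
    freqs_hz: np.ndarray
    channel: str
    n_trials: int
    trial_averaged: bool = True


def _frame_centers(times_ms: np.ndarray, fs: float) -> np.ndarray:
    """Centers of fully supported frames, hopped every STFT_HOP_MS."""
    half = STFT_WINDOW_MS / 2.0
    t0, t1 = times_ms[0] + half, times_ms[-1] - half
    n = int(np.floor((t1 - t0) / STFT_HOP_MS + 1e-9)) + 1
    return t0 + STFT_HOP_MS * np.arange(n)


def compute_ersp(ep: EpochSet, channel: str = "FZ") -> ERSPMap:
    """Baseline-corrected STFT power map, averaged over trials.

    The baseline R̄(f) is, per trial, the mean raw power over frames whose
    centers fall in (−200, 0] ms; frames with partial support are never
    formed.
    """
    fs = ep.sampling_rate_hz
    x = ep.data[:, ep.index(channel), :]           # (trials, times)
    win_n = int(round(STFT_WINDOW_MS * fs / 1000.0))
    n_fft = int(round(fs))                         # 1 Hz bin spacing
    win = windows.hann(win_n, sym=True)

    centers = _frame_centers(ep.times_ms, fs)
    starts = np.round((centers - STFT_WINDOW_MS / 2.0 - ep.times_ms[0])
                      * fs / 1000.0).astype(int)
    frames = np.stack([x[:, s:s + win_n] for s in starts], axis=1)
    spec = np.fft.rfft(frames * win, n=n_fft, axis=2)
    power = np.abs(spec) ** 2                      # (trials, frames, freqs)

    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)
    fmask = (freqs >= FREQ_RANGE_HZ[0] - 1e-9) & (freqs <= FREQ_RANGE_HZ[1] + 1e-9)
    power = power[:, :, fmask]
    freqs = freqs[fmask]

    base_frames = (centers > -STFT_WINDOW_MS - 1e-9) & (centers <= 1e-9)
    if not base_frames.any():
        raise ValueError("no baseline frames; epoch must cover the pre-stimulus "
                         "interval")
    baseline = power[:, base_frames, :].mean(axis=1)        # per trial, (f,)
    corrected = power - baseline[:, None, :]
    return ERSPMap(power=corrected.mean(axis=0),
                   raw_power=power.mean(axis=0),
                   baseline=baseline.mean(axis=0),
                   times_ms=centers, freqs_hz=freqs, channel=channel,
                   n_trials=x.shape[0])


def band_window_power(m: ERSPMap, spec: BandWindowSpec) -> float:
    """Mean baseline-corrected power over the band × window bins (µV²)."""
    fm = (m.freqs_hz >= spec.band_hz[0] - 1e-9) & \
         (m.freqs_hz <= spec.band_hz[1] + 1e-9)
    tm = (m.times_ms >= spec.window_ms[0] - 1e-9) & \
         (m.times_ms <= spec.window_ms[1] + 1e-9)
    if not fm.any() or not tm.any():
        raise ValueError(f"no bins inside band {spec.band_hz} Hz × window "
                         f"{spec.window_ms} ms")
    return float(m.power[np.ix_(tm, fm)].mean())


def classify_erd_ers(value: float) -> str:
    """Sign convention: positive → ERS, negative → ERD, zero → null."""
    if not np.isfinite(value):
        raise ValueError("band-window power must be finite")
    if value > 0:
        return "ERS"
    if value < 0:
        return "ERD"
    return "null"


def band_summaries(ep: EpochSet, channel: str = "FZ",
                   by=("mode", "stimulus_type")):
    """Theta/alpha band-window powers per condition, as a tidy table."""
    import pandas as pd

    groups = ep.labels.groupby(list(by)).groups
    rows = []
    for key, idx in groups.items():
        key = key if isinstance(key, tuple) else (key,)
        sub = EpochSet(ep.data[np.asarray(idx)], ep.channel_names,
                       ep.sampling_rate_hz, ep.times_ms,
                       ep.labels.loc[np.asarray(idx)].reset_index(drop=True))
        m = compute_ersp(sub, channel)
        theta = band_window_power(m, BandWindowSpec.theta(channel))
        alpha = band_window_power(m, BandWindowSpec.alpha(channel))
        rows.append((*key, theta, classify_erd_ers(theta),
                     alpha, classify_erd_ers(alpha), sub.n_trials))
    return pd.DataFrame(rows, columns=[*by, "theta_power_uv2", "theta_label",
                                       "alpha_power_uv2", "alpha_label",
                                       "n_trials"])
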