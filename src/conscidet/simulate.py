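"""Synthetic EEG generation for configurable subject profiles.

The generator produces continuous 32-channel recordings that carry the
signatures the downstream analysis looks for:

* 1/f ("pink") background noise with a shared-across-channels component,
* phase-locked ERP components added as raised-cosine (Hann) bumps in the
  standard analysis windows (P300, novelty P3, N400/P600 effects) and a
  slow negative ramp for the CNV, with mode-dependent amplitudes,
* non-phase-locked theta/alpha rhythms at FZ whose power is modulated
  inside the theta (200–400 ms) and alpha (400–1000 ms) analysis windows
  (event-related synchronization / desynchronization),
* blink artifacts on VEOG that propagate to the frontal leads.

A "conscious" profile grades its effects active > passive > breathing; an
"unconscious" profile injects no stimulus-locked structure at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .containers import MONTAGE_32, ROI1, ROI2, Recording
from .paradigm import EventSequence

# ---------------------------------------------------------------------------
# component geometry (ms, relative to stimulus onset)

P300_WINDOW = (250.0, 400.0)
NOVELTY_P3_WINDOW = (250.0, 500.0)
N400_WINDOW = (380.0, 420.0)
P600_WINDOW = (650.0, 750.0)
CNV_RAMP = (600.0, 1000.0)            # linear ramp from 0 to full amplitude
THETA_WINDOW = (200.0, 400.0)
ALPHA_WINDOW = (400.0, 1000.0)
THETA_BAND = (4.0, 7.0)
ALPHA_BAND = (8.0, 13.0)

#: standing deviation of the ongoing FZ rhythms that ERS/ERD modulates (µV);
#: chosen so the rhythms dominate the 1/f background inside their bands,
#: as frontal theta/alpha do in real recordings
THETA_RHYTHM_SD_UV = 6.0
ALPHA_RHYTHM_SD_UV = 8.0
#: fraction of background noise power shared across channels
SHARED_NOISE_FRACTION = 0.5
#: cosine ramp length for the ERS/ERD envelopes (ms), kept inside the window
ERS_RAMP_MS = 50.0
BLINK_DURATION_MS = 300.0

# topographic weights: full weight on the generating region, partial spread
# to neighbours, small leakage elsewhere; zero on mastoids and EOG
def _weights(full, partial, partial_w=0.5, leak=0.1):
    w = {}
    for ch in MONTAGE_32:
        if ch in ("M1", "M2", "VEOG", "HEOG"):
            w[ch] = 0.0
        elif ch in full:
            w[ch] = 1.0
        elif ch in partial:
            w[ch] = partial_w
        else:
            w[ch] = leak
    return w

PARIETAL_WEIGHTS = _weights(ROI1, ("CP3", "CP4", "TP7", "TP8", "O1", "OZ", "O2"))
FRONTAL_WEIGHTS = _weights(ROI2, ("FT7", "FC3", "FC4", "FT8"))
BLINK_WEIGHTS = {"VEOG": 1.0, "FP1": 0.45, "FP2": 0.45, "F7": 0.2, "F3": 0.2,
                 "FZ": 0.2, "F4": 0.2, "F8": 0.2, "HEOG": 0.05}


@dataclass(frozen=True)
class ModeEffects:
    """Stimulus-locked effect sizes for one task mode.

    Amplitudes are the peak values of the injected templates in µV; the
    corresponding window-mean amplitudes recovered by the ERP analysis are
    peak/2 for a Hann bump spanning its window exactly.  Gains are
    fractional power changes of the FZ rhythms inside their windows.
    """

    p300_uv: float = 0.0          # Hann bump, 250–400 ms, parietal, deviants
    novelty_p3_uv: float = 0.0    # Hann bump, 250–500 ms, parietal, novels
    cnv_uv: float = 0.0           # ramp endpoint at 1000 ms, frontal, deviants
    n400_uv: float = 0.0          # Hann bump, 380–420 ms, parietal, incorrect novels
    p600_uv: float = 0.0          # Hann bump, 650–750 ms, frontal, incorrect novels
    theta_ers_gain: float = 0.0   # fractional theta power increase, 200–400 ms
    alpha_erd_gain: float = 0.0   # fractional alpha power decrease, 400–1000 ms

    def magnitudes(self) -> dict:
        return {k: abs(getattr(self, k)) for k in
                ("p300_uv", "novelty_p3_uv", "cnv_uv", "n400_uv", "p600_uv",
                 "theta_ers_gain", "alpha_erd_gain")}


@dataclass(frozen=True)
class SubjectProfile:
    """Generator parameters for one synthetic subject."""

    label: str = "conscious"              # {conscious, unconscious}
    modality: str = "visual"
    effects: dict = field(default_factory=dict)   # mode -> ModeEffects
    noise_sd: float = 10.0                # background sd per channel, µV
    pink_exponent: float = 1.0            # beta in 1/f^beta power spectrum
    blink_rate_per_min: float = 10.0
    blink_amplitude_uv: float = 100.0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.label not in ("conscious", "unconscious"):
            raise ValueError(f"unknown label {self.label!r}")
        effs = {m: e for m, e in self.effects.items()}
        if self.label == "unconscious":
            vals = [e.magnitudes() for e in effs.values()]
            if vals and any(v != vals[0] for v in vals[1:]):
                raise ValueError(
                    "unconscious profile must have identical effects across modes")
        else:
            order = [m for m in ("active", "passive", "breathing") if m in effs]
            for a, b in zip(order, order[1:]):
                ma, mb = effs[a].magnitudes(), effs[b].magnitudes()
                for k in ma:
                    if ma[k] + 1e-12 < mb[k]:
                        raise ValueError(
                            f"conscious profile: |{k}| must be non-increasing "
                            f"from {a} to {b}")

    def effects_for(self, mode: str) -> ModeEffects:
        try:
            return self.effects[mode]
        except KeyError:
            raise KeyError(f"profile has no effects for mode {mode!r}") from None

    def with_(self, **kwargs) -> "SubjectProfile":
        return replace(self, **kwargs)


def conscious_profile(modality: str = "visual", **overrides) -> SubjectProfile:
    """Default conscious subject.

    Peak amplitudes are set so that the window-mean component amplitudes in
    the active mode land near the grand-average values reported for healthy
    subjects under the visual paradigm (e.g. a 9.3 µV P300 bump yields a
    4.65 µV window mean), with passive effects intermediate and breathing
    effects strongly reduced.
    """
    if modality == "visual":
        effects = {
            "active": ModeEffects(9.3, 9.6, -2.3, -4.8, 6.4, 0.8, 0.5),
            "passive": ModeEffects(7.7, 4.2, -0.5, -3.0, 1.8, 0.6, 0.4),
            "breathing": ModeEffects(2.6, 1.7, -0.1, -1.2, 0.6, 0.2, 0.15),
        }
    elif modality == "auditory":
        effects = {
            "active": ModeEffects(2.7, 6.0, -5.1, -9.8, 1.8, 0.8, 0.5),
            "passive": ModeEffects(1.9, 1.3, -2.3, -3.1, 0.9, 0.6, 0.4),
            "breathing": ModeEffects(0.1, 1.2, -1.3, -3.0, 0.2, 0.2, 0.15),
        }
    else:
        raise ValueError(f"unknown modality {modality!r}")
    return SubjectProfile(label="conscious", modality=modality,
                          effects=effects, **overrides)


def unconscious_profile(modality: str = "visual", **overrides) -> SubjectProfile:
    """Subject with no stimulus-locked structure in any mode."""
    null = ModeEffects()
    effects = {m: null for m in ("active", "passive", "breathing")}
    return SubjectProfile(label="unconscious", modality=modality,
                          effects=effects, **overrides)


# ---------------------------------------------------------------------------
# waveform primitives

def hann_bump(times_ms: np.ndarray, window: tuple[float, float],
              peak: float) -> np.ndarray:
    """Raised-cosine bump of given peak spanning exactly `window` (ms)."""
    lo, hi = window
    out = np.zeros_like(times_ms, dtype=float)
    m = (times_ms >= lo) & (times_ms <= hi)
    out[m] = peak * 0.5 * (1.0 - np.cos(2.0 * np.pi * (times_ms[m] - lo) / (hi - lo)))
    return out


def cnv_ramp(times_ms: np.ndarray, amplitude: float,
             ramp: tuple[float, float] = CNV_RAMP) -> np.ndarray:
    """Slow ramp from 0 at ramp start to `amplitude` at ramp end."""
    lo, hi = ramp
    out = np.zeros_like(times_ms, dtype=float)
    m = (times_ms >= lo) & (times_ms <= hi)
    out[m] = amplitude * (times_ms[m] - lo) / (hi - lo)
    out[times_ms > hi] = amplitude
    return out


def pink_noise(n_samples: int, n_series: int, exponent: float,
               rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f^exponent noise, one row per series."""
    n_fft = int(2 ** np.ceil(np.log2(max(n_samples, 2))))
    freqs = np.fft.rfftfreq(n_fft)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal((n_series, freqs.size))
                  + 1j * rng.standard_normal((n_series, freqs.size)))
    spec[:, 0] = 0.0
    x = np.fft.irfft(spec, n=n_fft, axis=1)[:, :n_samples]
    x -= x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_noise(n_samples: int, band: tuple[float, float], fs: float,
                rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian noise."""
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n_samples))
    sd = x.std()
    return x / sd if sd > 0 else x


def _ers_envelope(n_samples: int, fs: float, onsets_ms: np.ndarray,
                  window: tuple[float, float], scale: float) -> np.ndarray:
    """Amplitude envelope that is 1 outside the per-event windows and
    `scale` inside, with cosine ramps of ERS_RAMP_MS kept inside the window."""
    env = np.ones(n_samples)
    if scale == 1.0:
        return env
    ramp_n = max(int(round(ERS_RAMP_MS * fs / 1000.0)), 1)
    ramp_up = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_n) / ramp_n))
    for onset in onsets_ms:
        a = int(round((onset + window[0]) * fs / 1000.0))
        b = int(round((onset + window[1]) * fs / 1000.0))
        if a >= n_samples:
            continue
        b = min(b, n_samples)
        seg = np.full(b - a, scale)
        k = min(ramp_n, len(seg) // 2)
        if k > 0:
            seg[:k] = 1.0 + (scale - 1.0) * ramp_up[:k]
            seg[-k:] = scale - (scale - 1.0) * ramp_up[:k]
        env[a:b] = seg
    return env


def blink_template(fs: float, amplitude: float) -> np.ndarray:
    n = int(round(BLINK_DURATION_MS * fs / 1000.0))
    return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / n))


# ---------------------------------------------------------------------------

def _component_snippet(profile: SubjectProfile, mode: str, stimulus_type: str,
                       times_ms: np.ndarray) -> np.ndarray | None:
    """Phase-locked (channels × samples) template for one event class."""
    eff = profile.effects_for(mode)
    parts: list[tuple[np.ndarray, dict]] = []
    if stimulus_type == "deviant":
        if eff.p300_uv:
            parts.append((hann_bump(times_ms, P300_WINDOW, eff.p300_uv),
                          PARIETAL_WEIGHTS))
        if eff.cnv_uv:
            parts.append((cnv_ramp(times_ms, eff.cnv_uv), FRONTAL_WEIGHTS))
    elif stimulus_type in ("correct_novel", "incorrect_novel"):
        if eff.novelty_p3_uv:
            parts.append((hann_bump(times_ms, NOVELTY_P3_WINDOW,
                                    eff.novelty_p3_uv), PARIETAL_WEIGHTS))
        if stimulus_type == "incorrect_novel":
            if eff.n400_uv:
                parts.append((hann_bump(times_ms, N400_WINDOW, eff.n400_uv),
                              PARIETAL_WEIGHTS))
            if eff.p600_uv:
                parts.append((hann_bump(times_ms, P600_WINDOW, eff.p600_uv),
                              FRONTAL_WEIGHTS))
    if not parts:
        return None
    snippet = np.zeros((len(MONTAGE_32), len(times_ms)))
    for wave, weights in parts:
        w = np.array([weights[ch] for ch in MONTAGE_32])
        snippet += w[:, None] * wave[None, :]
    return snippet


def synthesize_recording(seq: EventSequence, profile: SubjectProfile,
                         seed: int) -> Recording:
    """Render an event sequence into a continuous synthetic recording.

    Deterministic for fixed (sequence, profile, seed).
    """
    if len(seq) == 0:
        raise ValueError("cannot synthesize a recording from an empty sequence")
    for mode in {e.mode for e in seq}:
        profile.effects_for(mode)       # raises if a mode is uncovered

    fs = seq.sampling_rate_hz
    rng = np.random.default_rng(seed)
    onsets = seq.onsets_ms()
    duration_ms = onsets[-1] + 1500.0   # covers the last +1000 ms epoch
    n_samples = int(round(duration_ms * fs / 1000.0))
    n_ch = len(MONTAGE_32)

    # --- background: shared + private pink noise ---------------------------
    shared = pink_noise(n_samples, 1, profile.pink_exponent, rng)[0]
    private = pink_noise(n_samples, n_ch, profile.pink_exponent, rng)
    a = np.sqrt(SHARED_NOISE_FRACTION)
    b = np.sqrt(1.0 - SHARED_NOISE_FRACTION)
    data = profile.noise_sd * (a * shared[None, :] + b * private)

    # --- phase-locked components ------------------------------------------
    snip_n = int(round(1000.0 * fs / 1000.0)) + 1
    snip_times = np.arange(snip_n) * 1000.0 / fs
    cache: dict[tuple[str, str], np.ndarray | None] = {}
    for ev in seq:
        key = (ev.mode, ev.stimulus_type)
        if key not in cache:
            cache[key] = _component_snippet(profile, ev.mode, ev.stimulus_type,
                                            snip_times)
        snippet = cache[key]
        if snippet is None:
            continue
        i0 = int(round(ev.onset_ms * fs / 1000.0))
        i1 = min(i0 + snip_n, n_samples)
        data[:, i0:i1] += snippet[:, :i1 - i0]

    # --- non-phase-locked FZ rhythms with ERS/ERD modulation ---------------
    # rhythm amplitude tracks the background level so that a silent
    # profile (noise_sd -> 0) yields a silent recording
    fz = MONTAGE_32.index("FZ")
    rhythm_scale = profile.noise_sd / 10.0
    theta = (THETA_RHYTHM_SD_UV * rhythm_scale
             * _band_noise(n_samples, THETA_BAND, fs, rng))
    alpha = (ALPHA_RHYTHM_SD_UV * rhythm_scale
             * _band_noise(n_samples, ALPHA_BAND, fs, rng))
    by_mode: dict[str, list[float]] = {}
    for ev in seq:
        by_mode.setdefault(ev.mode, []).append(ev.onset_ms)
    theta_env = np.ones(n_samples)
    alpha_env = np.ones(n_samples)
    for mode, mode_onsets in by_mode.items():
        eff = profile.effects_for(mode)
        mo = np.asarray(mode_onsets)
        if eff.theta_ers_gain:
            s = np.sqrt(1.0 + eff.theta_ers_gain)
            e = _ers_envelope(n_samples, fs, mo, THETA_WINDOW, s)
            theta_env = np.where(e != 1.0, e, theta_env)
        if eff.alpha_erd_gain:
            s = np.sqrt(max(1.0 - eff.alpha_erd_gain, 0.0))
            e = _ers_envelope(n_samples, fs, mo, ALPHA_WINDOW, s)
            alpha_env = np.where(e != 1.0, e, alpha_env)
    data[fz] += theta * theta_env + alpha * alpha_env

    # --- blinks -------------------------------------------------------------
    n_blinks = rng.poisson(profile.blink_rate_per_min * duration_ms / 60000.0)
    if n_blinks > 0 and profile.blink_amplitude_uv > 0:
        template = blink_template(fs, profile.blink_amplitude_uv)
        starts = np.sort(rng.integers(0, max(n_samples - len(template), 1),
                                      size=n_blinks))
        for ch, w in BLINK_WEIGHTS.items():
            ci = MONTAGE_32.index(ch)
            for s0 in starts:
                s1 = min(s0 + len(template), n_samples)
                data[ci, s0:s1] += w * template[:s1 - s0]

    return Recording(data, MONTAGE_32, fs, seq)
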