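"""Time-frequency (ERD/ERS) analysis against an independent oracle."""

import numpy as np
import pytest
from scipy.signal import windows

import conscidet as cd
from conscidet.containers import MONTAGE_32
from conscidet.ersp import BandWindowSpec

from conftest import make_epochs


def oracle_ersp(x, times_ms, fs):
    """Independent frame-by-frame windowed periodogram with subtraction
    baseline; plain Python loops and the full complex FFT."""
    win_n = int(round(0.2 * fs))
    n_fft = int(round(fs))
    win = windows.hann(win_n, sym=True)
    half = 100.0
    centers = []
    t = times_ms[0] + half
    while t <= times_ms[-1] - half + 1e-9:
        centers.append(t)
        t += 50.0
    freqs = np.arange(n_fft) * fs / n_fft
    keep = [i for i, f in enumerate(freqs) if 1.0 - 1e-9 <= f <= 20.0 + 1e-9]
    maps = []
    for trial in x:
        rows = []
        for c in centers:
            s = int(round((c - half - times_ms[0]) * fs / 1000.0))
            frame = trial[s:s + win_n] * win
            spec = np.fft.fft(frame, n=n_fft)
            rows.append([abs(spec[i]) ** 2 for i in keep])
        rows = np.array(rows)
        base = np.array([c <= 1e-9 and c > -200.0 - 1e-9 for c in centers])
        rbar = rows[base].mean(axis=0)
        maps.append(rows - rbar)
    return np.mean(maps, axis=0), np.array(centers), freqs[keep]


def test_zero_epochs_give_zero_map():
    ep = make_epochs(np.zeros((3, 32, 301)))
    m = cd.compute_ersp(ep, "FZ")
    assert np.abs(m.power).max() == 0.0


def test_stationary_tone_cancels_against_its_baseline():
    """A 10 Hz tone spanning the whole epoch (baseline included) leaves a
    near-null subtraction-corrected map at 10 Hz.  At 1000 Hz the 50 ms
    hop is a whole number of samples, so every frame sees an identical
    tone power and the cancellation is exact."""
    fs = 1000.0
    times = (np.arange(1201) - 200) * 1000.0 / fs
    tone = 5.0 * np.sin(2 * np.pi * 10.0 * times / 1000.0)
    data = np.zeros((2, 32, 1201))
    data[:, MONTAGE_32.index("FZ"), :] = tone
    m = cd.compute_ersp(make_epochs(data, fs=fs), "FZ")
    i10 = np.argmin(np.abs(m.freqs_hz - 10.0))
    raw = m.raw_power[:, i10].max()
    assert np.abs(m.power[:, i10]).max() < 1e-6 * raw


def test_burst_matches_independent_periodogram_oracle():
    """A 10 Hz burst confined to 400-1000 ms: implementation equals the
    loop-based oracle to numerical precision, and the alpha band-window
    summary is positive (ERS)."""
    fs = 250.0
    rng = np.random.default_rng(0)
    times = (np.arange(301) - 50) * 1000.0 / fs
    data = rng.normal(scale=0.5, size=(4, 32, 301))
    burst = (times >= 400) & (times <= 1000)
    data[:, MONTAGE_32.index("FZ"), burst] += \
        6.0 * np.sin(2 * np.pi * 10.0 * times[burst] / 1000.0)
    ep = make_epochs(data, fs=fs)
    m = cd.compute_ersp(ep, "FZ")
    exp_map, exp_t, exp_f = oracle_ersp(data[:, MONTAGE_32.index("FZ"), :],
                                        times, fs)
    assert np.allclose(m.times_ms, exp_t)
    assert np.allclose(m.freqs_hz, exp_f)
    scale = np.abs(exp_map).max()
    assert np.abs(m.power - exp_map).max() < 1e-6 * scale
    assert cd.band_window_power(m, BandWindowSpec.alpha()) > 0


def test_band_window_power_on_synthetic_maps():
    ep = make_epochs(np.zeros((2, 32, 301)))
    m = cd.compute_ersp(ep, "FZ")
    assert cd.band_window_power(m, BandWindowSpec.theta()) == 0.0
    m.power = np.full_like(m.power, 3.25)
    assert cd.band_window_power(m, BandWindowSpec.theta()) == \
        pytest.approx(3.25)
    with pytest.raises(ValueError):
        cd.band_window_power(m, BandWindowSpec((50.0, 60.0), (0.0, 100.0)))


def test_missing_channel_raises():
    ep = make_epochs(np.zeros((2, 32, 301)))
    with pytest.raises(KeyError):
        cd.compute_ersp(ep, "XY")


@pytest.mark.parametrize("value,label", [(1.5, "ERS"), (-0.2, "ERD"),
                                         (0.0, "null")])
def test_erd_ers_sign_convention(value, label):
    assert cd.classify_erd_ers(value) == label
    with pytest.raises(ValueError):
        cd.classify_erd_ers(float("nan"))


def test_white_noise_power_scales_with_variance():
    """Total raw STFT power is linear in input variance."""
    fs = 250.0
    rng = np.random.default_rng(1)
    base = rng.normal(size=(6, 32, 301))
    totals = []
    for scale in (1.0, 2.0, 3.0):
        m = cd.compute_ersp(make_epochs(base * scale, fs=fs), "FZ")
        totals.append(m.raw_power.sum())
    assert totals[1] / totals[0] == pytest.approx(4.0, rel=1e-9)
    assert totals[2] / totals[0] == pytest.approx(9.0, rel=1e-9)


def test_theta_ers_and_alpha_erd_signs_recovered(conscious_epochs):
    """The generator's frontal theta gain (+) and alpha loss (−) appear
    with the right signs in the FZ band-window summaries (active mode,
    all stimuli pooled)."""
    active = conscious_epochs.select(mode="active")
    m = cd.compute_ersp(active, "FZ")
    theta = cd.band_window_power(m, BandWindowSpec.theta())
    alpha = cd.band_window_power(m, BandWindowSpec.alpha())
    assert theta > 0 and cd.classify_erd_ers(theta) == "ERS"
    assert alpha < 0 and cd.classify_erd_ers(alpha) == "ERD"


def test_mode_contrast_weakens_in_breathing(conscious_epochs):
    """Frontal theta-ERS and alpha-ERD magnitudes shrink from the active
    to the breathing mode."""
    summaries = {}
    for mode in ("active", "breathing"):
        m = cd.compute_ersp(conscious_epochs.select(mode=mode), "FZ")
        summaries[mode] = (cd.band_window_power(m, BandWindowSpec.theta()),
                           cd.band_window_power(m, BandWindowSpec.alpha()))
    assert abs(summaries["active"][0]) > abs(summaries["breathing"][0])
    assert abs(summaries["active"][1]) > abs(summaries["breathing"][1])
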