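"""Preprocessing chain: filter response, referencing, epoching, EOG
regression, amplitude rejection."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sg

import conscidet as cd
from conscidet.containers import MONTAGE_32
from conscidet.preprocess import PreprocessConfig
from conscidet.simulate import blink_template

from conftest import make_epochs


def _recording_from(data, fs=250.0, events=None, config=None):
    config = config or cd.ParadigmConfig(sampling_rate_hz=fs)
    events = events or []
    return cd.Recording(data, MONTAGE_32, fs, cd.EventSequence(events, config))


def _sine_recording(freq, fs=1000.0, seconds=20.0):
    t = np.arange(int(fs * seconds)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return _recording_from(np.tile(x, (len(MONTAGE_32), 1)), fs=fs)


def test_passband_sinusoid_preserved():
    """10 Hz sits in the passband; the forward-backward pass squares the
    ~3% single-pass droop from the 20 Hz edge, so ~6% total is expected."""
    rec = _sine_recording(10.0)
    out = cd.filter_recording(rec, PreprocessConfig())
    mid = slice(5000, 15000)   # avoid edge transients
    ratio = out.data[0, mid].std() / rec.data[0, mid].std()
    assert ratio == pytest.approx(1.0, abs=0.08)


def test_notch_kills_line_frequency():
    rec = _sine_recording(50.0)
    out = cd.filter_recording(rec, PreprocessConfig())
    mid = slice(5000, 15000)
    assert out.data[0, mid].std() < 0.1 * rec.data[0, mid].std()


def test_filter_response_attenuates_drift_and_line():
    """The realized transfer function (forward-backward, so magnitude
    squared) is checked directly at 0.01 Hz and 50 Hz."""
    fs = 1000.0
    cfg = PreprocessConfig()
    sos = sg.butter(2, cfg.bandpass_hz, btype="bandpass", fs=fs, output="sos")
    for freq, bound in ((0.01, 0.5), (50.0, 0.1)):
        w, h = sg.sosfreqz(sos, worN=[freq], fs=fs)
        assert np.abs(h[0]) ** 2 < bound


def test_cutoff_above_nyquist_rejected():
    rec = _sine_recording(5.0, fs=30.0, seconds=5.0)
    with pytest.raises(ValueError):
        cd.filter_recording(rec, PreprocessConfig())


def test_rereference_identity_and_shift():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(len(MONTAGE_32), 500))
    i_m1, i_m2 = MONTAGE_32.index("M1"), MONTAGE_32.index("M2")
    data[i_m1] = data[i_m2] = 0.0
    rec = _recording_from(data.copy())
    out = cd.rereference(rec)
    assert np.array_equal(out.data, data)

    data[i_m1] = data[i_m2] = 3.0
    out = cd.rereference(_recording_from(data.copy()))
    fz = MONTAGE_32.index("FZ")
    assert np.allclose(out.data[fz], data[fz] - 3.0)


def test_rereference_preserves_channel_differences():
    rng = np.random.default_rng(1)
    rec = _recording_from(rng.normal(size=(len(MONTAGE_32), 300)))
    out = cd.rereference(rec)
    pz, fz = MONTAGE_32.index("PZ"), MONTAGE_32.index("FZ")
    assert np.allclose(out.data[pz] - out.data[fz],
                       rec.data[pz] - rec.data[fz])


def test_missing_mastoid_raises():
    names = tuple(ch if ch != "M1" else "MX" for ch in MONTAGE_32)
    rec = cd.Recording(np.zeros((32, 100)), names, 250.0,
                       cd.EventSequence([], cd.ParadigmConfig()))
    with pytest.raises(ValueError, match="M1"):
        cd.rereference(rec)


def test_epoch_window_sample_count():
    """(−200, +1000) ms inclusive at 1000 Hz is 1201 samples."""
    fs = 1000.0
    cfg = cd.ParadigmConfig(sampling_rate_hz=fs)
    events = [cd.paradigm.Event(1000.0 * (i + 1), "standard", "active", 0,
                                "visual") for i in range(3)]
    data = np.full((len(MONTAGE_32), 6000), 3.0)
    rec = _recording_from(data, fs=fs, events=events, config=cfg)
    ep = cd.extract_epochs(rec)
    assert ep.data.shape == (3, 32, 1201)
    assert ep.times_ms[0] == -200.0 and ep.times_ms[-1] == 1000.0
    # constant channel is annihilated by baseline correction
    assert np.abs(ep.data).max() < 1e-9


def test_edge_events_skipped_and_logged():
    fs = 250.0
    events = [cd.paradigm.Event(t, "standard", "active", 0, "visual")
              for t in (10.0, 2000.0, 3950.0)]
    rec = _recording_from(np.zeros((32, 1000)), fs=fs, events=events)
    ep = cd.extract_epochs(rec)
    assert ep.n_trials == 1
    assert sorted(e["reason"] for e in ep.rejection_log) == ["edge", "edge"]


def test_baseline_correction_is_projection():
    rng = np.random.default_rng(2)
    ep = make_epochs(rng.normal(size=(4, 32, 301)))
    once = cd.baseline_correct(ep)
    twice = cd.baseline_correct(once)
    assert np.allclose(once.data, twice.data)
    m = once.time_mask(-200.0, 0.0)
    assert np.abs(once.data[:, :, m].mean(axis=2)).max() < 1e-9


def test_eog_regression_removes_proportional_artifact():
    rng = np.random.default_rng(3)
    n_tr, n_t = 5, 301
    data = np.zeros((n_tr, 32, n_t))
    veog = rng.normal(size=(n_tr, n_t))
    data[:, MONTAGE_32.index("VEOG"), :] = veog
    data[:, MONTAGE_32.index("FP1"), :] = 0.3 * veog
    ep = make_epochs(data)
    out = cd.remove_ocular_artifacts(ep)
    assert np.abs(out.data[:, MONTAGE_32.index("FP1"), :]).max() < 1e-9


def test_eog_regression_leaves_independent_eeg_untouched():
    rng = np.random.default_rng(4)
    data = rng.normal(size=(6, 32, 301))
    ep = make_epochs(data)
    out = cd.remove_ocular_artifacts(ep)
    fz = MONTAGE_32.index("FZ")
    resid = out.data[:, fz, :] - data[:, fz, :]
    assert resid.std() < 0.1 * data[:, fz, :].std()


def test_eog_regression_attenuates_blinks():
    """A template blink propagated to FP1 is mostly removed."""
    rng = np.random.default_rng(5)
    fs = 250.0
    n_tr, n_t = 10, 301
    data = rng.normal(scale=1.0, size=(n_tr, 32, n_t))
    tpl = blink_template(fs, 100.0)
    sl = slice(100, 100 + len(tpl))
    data[:, MONTAGE_32.index("VEOG"), sl] += tpl
    data[:, MONTAGE_32.index("FP1"), sl] += 0.45 * tpl
    ep = make_epochs(data, fs=fs)
    out = cd.remove_ocular_artifacts(ep)
    fp1 = MONTAGE_32.index("FP1")
    before = np.sqrt((data[:, fp1, sl] ** 2).mean())
    after = np.sqrt((out.data[:, fp1, sl] ** 2).mean())
    assert after < 0.2 * before


def test_zero_variance_eog_warns_and_is_identity():
    ep = make_epochs(np.zeros((3, 32, 301)))
    with pytest.warns(UserWarning, match="zero variance"):
        out = cd.remove_ocular_artifacts(ep)
    assert np.array_equal(out.data, ep.data)


def test_rejection_boundary_is_strict():
    data = np.zeros((3, 32, 301))
    data[0, MONTAGE_32.index("CZ"), 150] = 75.0     # exactly at threshold
    data[1, MONTAGE_32.index("CZ"), 150] = 80.0     # exceeds
    data[2, MONTAGE_32.index("VEOG"), 150] = 500.0  # EOG not tested
    ep = make_epochs(data)
    out = cd.reject_epochs(ep)
    assert out.n_trials == 2
    assert out.rejection_log[-1]["reason"] == "amplitude"
    kept = set(out.labels["event_index"])
    assert kept == {0, 2}


def test_rejection_is_idempotent_and_conserves_counts():
    rng = np.random.default_rng(6)
    data = rng.normal(scale=18.0, size=(20, 32, 301))
    ep = make_epochs(data)
    once = cd.reject_epochs(ep)
    twice = cd.reject_epochs(once)
    assert once.n_trials == twice.n_trials
    n_amp = sum(1 for e in once.rejection_log if e["reason"] == "amplitude")
    assert once.n_trials + n_amp == ep.n_trials
    assert 0 < once.n_trials < 20   # at sd 30 some but not all trials pass


def test_all_trials_rejected_raises():
    ep = make_epochs(np.full((3, 32, 301), 100.0))
    ep = cd.EpochSet(ep.data, ep.channel_names, ep.sampling_rate_hz,
                     ep.times_ms, ep.labels)   # skip baseline correction
    with pytest.raises(ValueError, match="exceed"):
        cd.reject_epochs(ep)
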