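"""File formats: European Data Format (EDF) for continuous EEG, a
tab-separated events sidecar, and an array container for epoched data.

The EDF writer emits plain EDF (16-bit, one-second data records, signals
padded with zeros to a whole record); reading goes through MNE's EDF
reader.  Events travel in a BIDS-events-like TSV with columns
``onset_ms  stimulus_type  mode  block  modality``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSet, Recording
from .paradigm import Event, EventSequence, ParadigmConfig

EVENTS_COLUMNS = ("onset_ms", "stimulus_type", "mode", "block", "modality")


# ---------------------------------------------------------------------------
# events TSV

def write_events_tsv(path, events: EventSequence) -> None:
    df = pd.DataFrame(
        [(e.onset_ms, e.stimulus_type, e.mode, e.block, e.modality)
         for e in events], columns=EVENTS_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path, config: ParadigmConfig | None = None,
                    sampling_rate_hz: float | None = None) -> EventSequence:
    df = pd.read_csv(path, sep="\t")
    missing = set(EVENTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"events file lacks columns {sorted(missing)}")
    onsets = df["onset_ms"].to_numpy(dtype=float)
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("event onsets must be strictly increasing")
    events = [Event(float(r.onset_ms), str(r.stimulus_type), str(r.mode),
                    int(r.block), str(r.modality))
              for r in df.itertuples()]
    if config is None:
        config = ParadigmConfig()
        if sampling_rate_hz is not None:
            config = config.with_(sampling_rate_hz=sampling_rate_hz)
    return EventSequence(events, config)


# ---------------------------------------------------------------------------
# EDF

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")
    if len(b) > width:
        raise ValueError(f"field {text!r} longer than {width} bytes")
    return b.ljust(width)


def write_edf(path, rec: Recording) -> None:
    """Write a recording as plain EDF (µV, 16-bit, 1 s records).

    The last record is zero-padded; physical scaling is chosen per channel
    from the data range, so the quantization step is |range|/65535.
    """
    fs = rec.sampling_rate_hz
    spr = int(round(fs))                      # samples per 1 s record
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_ch = len(rec.channel_names)
    n_rec = int(np.ceil(rec.n_samples / spr))
    padded = np.zeros((n_ch, n_rec * spr))
    padded[:, :rec.n_samples] = rec.data

    pmax = np.maximum(np.abs(padded).max(axis=1), 1e-6)
    pmax = np.ceil(pmax * 10) / 10            # round up to 0.1 µV
    dmax = 32767
    header = b"".join([
        _pad("0", 8), _pad("synthetic subject", 80), _pad("synthetic rec", 80),
        _pad("01.01.20", 8), _pad("00.00.00", 8),
        _pad(str(256 * (n_ch + 1)), 8), _pad("", 44),
        _pad(str(n_rec), 8), _pad("1", 8), _pad(str(n_ch), 4),
    ])
    fields = [
        [_pad(ch, 16) for ch in rec.channel_names],
        [_pad("AgAgCl electrode", 80)] * n_ch,
        [_pad("uV", 8)] * n_ch,
        [_pad(f"{-p:.1f}", 8) for p in pmax],
        [_pad(f"{p:.1f}", 8) for p in pmax],
        [_pad(str(-dmax), 8)] * n_ch,
        [_pad(str(dmax), 8)] * n_ch,
        [_pad("", 80)] * n_ch,
        [_pad(str(spr), 8)] * n_ch,
        [_pad("", 32)] * n_ch,
    ]
    scale = dmax / pmax
    digital = np.clip(np.rint(padded * scale[:, None]), -dmax, dmax
                      ).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        for f in fields:
            fh.write(b"".join(f))
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path, events_path=None, config: ParadigmConfig | None = None
             ) -> Recording:
    """Load an EDF recording (µV) plus its events sidecar."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6               # MNE returns volts
    names = tuple(raw.ch_names)
    fs = float(raw.info["sfreq"])
    if events_path is not None:
        events = read_events_tsv(events_path, config=config,
                                 sampling_rate_hz=fs)
    else:
        events = EventSequence([], config or ParadigmConfig())
    return Recording(np.ascontiguousarray(data), names, fs, events)


# ---------------------------------------------------------------------------
# epoch container: npz array + labels TSV + JSON metadata

def save_epochs(directory, ep: EpochSet, stem: str = "epochs") -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / f"{stem}.npz", data=ep.data, times_ms=ep.times_ms)
    ep.labels.to_csv(directory / f"{stem}_labels.tsv", sep="\t", index=False)
    meta = {"channel_names": list(ep.channel_names),
            "sampling_rate_hz": ep.sampling_rate_hz,
            "rejection_log": ep.rejection_log}
    (directory / f"{stem}.json").write_text(json.dumps(meta, indent=1))


def load_epochs(directory, stem: str = "epochs") -> EpochSet:
    directory = Path(directory)
    arrays = np.load(directory / f"{stem}.npz")
    labels = pd.read_csv(directory / f"{stem}_labels.tsv", sep="\t")
    meta = json.loads((directory / f"{stem}.json").read_text())
    return EpochSet(arrays["data"], tuple(meta["channel_names"]),
                    float(meta["sampling_rate_hz"]), arrays["times_ms"],
                    labels, meta.get("rejection_log", []))
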