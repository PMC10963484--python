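"""In-memory containers shared across the pipeline: continuous recordings
and epoched data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .paradigm import EventSequence

#: 32-channel cap: 28 scalp electrodes on the 10/20 layout plus the two
#: mastoid reference electrodes and the vertical/horizontal EOG leads.
MONTAGE_32 = (
    "FP1", "FP2", "F7", "F3", "FZ", "F4", "F8",
    "FT7", "FC3", "FC4", "FT8",
    "T7", "C3", "CZ", "C4", "T8",
    "TP7", "CP3", "CP4", "TP8",
    "P7", "P3", "PZ", "P4", "P8",
    "O1", "OZ", "O2",
    "M1", "M2", "VEOG", "HEOG",
)

MASTOIDS = ("M1", "M2")
EOG_CHANNELS = ("VEOG", "HEOG")
#: scalp EEG channels (everything except mastoids and EOG)
SCALP_CHANNELS = tuple(ch for ch in MONTAGE_32
                       if ch not in MASTOIDS + EOG_CHANNELS)

ROI1 = ("P7", "P3", "PZ", "P4", "P8")          # parietal
ROI2 = ("FP1", "FP2", "F7", "F3", "FZ", "F4", "F8")  # frontal
REQUIRED_CHANNELS = tuple(dict.fromkeys(ROI1 + ROI2))


@dataclass
class Recording:
    """Continuous multi-channel EEG in microvolts plus its event stream."""

    data: np.ndarray                      # (n_channels, n_samples), µV
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    events: EventSequence

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 2:
            raise ValueError("data must be (channels, samples)")
        if self.data.shape[0] != len(self.channel_names):
            raise ValueError("channel count does not match data")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("channel names must be unique")
        missing = [ch for ch in REQUIRED_CHANNELS if ch not in self.channel_names]
        if missing:
            raise ValueError(f"missing required channels: {missing}")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in recording") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names])

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.index(name)]

    @property
    def scalp_names(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_names
                     if ch not in MASTOIDS + EOG_CHANNELS)

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.channel_names,
                         self.sampling_rate_hz, self.events)


LABEL_COLUMNS = ("event_index", "onset_ms", "stimulus_type", "mode", "block",
                 "modality")


@dataclass
class EpochSet:
    """Baseline-corrected trials (trials × channels × samples, µV) with
    per-trial labels and a log of dropped trials."""

    data: np.ndarray                      # (n_trials, n_channels, n_times)
    channel_names: tuple[str, ...]
    sampling_rate_hz: float
    times_ms: np.ndarray                  # shared time axis, ms re onset
    labels: pd.DataFrame                  # one row per retained trial
    rejection_log: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, channels, times)")
        if self.data.shape[1] != len(self.channel_names):
            raise ValueError("channel count mismatch")
        if self.data.shape[2] != len(self.times_ms):
            raise ValueError("time axis mismatch")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels must have one row per trial")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in epochs") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names])

    @property
    def scalp_names(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channel_names
                     if ch not in MASTOIDS + EOG_CHANNELS)

    def mask(self, stimulus_type: str | None = None, mode: str | None = None,
             block: int | None = None) -> np.ndarray:
        m = np.ones(self.n_trials, dtype=bool)
        if stimulus_type is not None:
            m &= (self.labels["stimulus_type"] == stimulus_type).to_numpy()
        if mode is not None:
            m &= (self.labels["mode"] == mode).to_numpy()
        if block is not None:
            m &= (self.labels["block"] == block).to_numpy()
        return m

    def select(self, **kwargs) -> "EpochSet":
        m = self.mask(**kwargs)
        return EpochSet(self.data[m], self.channel_names,
                        self.sampling_rate_hz, self.times_ms,
                        self.labels.loc[m].reset_index(drop=True),
                        list(self.rejection_log))

    def time_mask(self, start_ms: float, stop_ms: float) -> np.ndarray:
        """Boolean mask of samples with start <= t <= stop (inclusive)."""
        return (self.times_ms >= start_ms - 1e-9) & (self.times_ms <= stop_ms + 1e-9)
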