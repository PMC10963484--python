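"""Stimulus paradigm definition and event-sequence generation.

The paradigm is a multi-stage oddball/novelty design: frequent standard
stimuli, rare deviant stimuli, and two kinds of novel stimuli (correct /
incorrect) that always follow a deviant after a fixed gap.  Blocks are run
in three task modes — active (count the target), passive (no task), and
breathing (attend to breathing, ignore stimuli) — under a visual or an
auditory modality.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

STIMULUS_TYPES = ("standard", "deviant", "correct_novel", "incorrect_novel")
MODES = ("active", "passive", "breathing")
MODALITIES = ("visual", "auditory")

#: silent lead-in before the first stimulus of each block (ms); long enough
#: for the pre-stimulus baseline of the first epoch.
BLOCK_LEAD_IN_MS = 1000.0
#: gap between the end of one block and the start of the next (ms).
INTER_BLOCK_GAP_MS = 2000.0


class PairingInfeasibleError(ValueError):
    """Raised when a block requests more novel stimuli than deviants."""


@dataclass(frozen=True)
class ParadigmConfig:
    """Stimulus counts, timing, and block structure of one paradigm run.

    Defaults follow the published protocol: six blocks (two per mode),
    each with 200 standard / 50 deviant / 25 correct-novel / 25
    incorrect-novel stimuli of 600 ms duration, novels trailing their
    deviant by 600 ms, and other inter-stimulus intervals drawn uniformly
    from 600–1000 ms, recorded at 1000 Hz.
    """

    modality: str = "visual"
    modes: tuple[str, ...] = ("active", "passive", "breathing")
    blocks_per_mode: int = 2
    n_standard: int = 200
    n_deviant: int = 50
    n_correct_novel: int = 25
    n_incorrect_novel: int = 25
    stimulus_duration_ms: float = 600.0
    deviant_to_novel_gap_ms: float = 600.0
    isi_range_ms: tuple[float, float] = (600.0, 1000.0)
    sampling_rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")
        if not self.modes or any(m not in MODES for m in self.modes):
            raise ValueError(f"modes must be a non-empty subset of {MODES}")
        for name in ("blocks_per_mode", "n_standard", "n_deviant",
                     "n_correct_novel", "n_incorrect_novel"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.stimulus_duration_ms <= 0 or self.deviant_to_novel_gap_ms <= 0:
            raise ValueError("durations must be positive")
        lo, hi = self.isi_range_ms
        if lo > hi or lo < 0:
            raise ValueError("isi_range_ms must satisfy 0 <= min <= max")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def n_blocks(self) -> int:
        return self.blocks_per_mode * len(self.modes)

    @property
    def n_novel(self) -> int:
        return self.n_correct_novel + self.n_incorrect_novel

    @property
    def events_per_block(self) -> int:
        return self.n_standard + self.n_deviant + self.n_novel

    def with_(self, **kwargs) -> "ParadigmConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class Event:
    onset_ms: float
    stimulus_type: str
    mode: str
    block: int
    modality: str


@dataclass
class EventSequence:
    """Timed stimulus stream for a whole multi-block run."""

    events: list[Event]
    config: ParadigmConfig = field(repr=False, default_factory=ParadigmConfig)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    @property
    def sampling_rate_hz(self) -> float:
        return self.config.sampling_rate_hz

    def onsets_ms(self) -> np.ndarray:
        return np.array([e.onset_ms for e in self.events])

    def count(self, stimulus_type: str | None = None, mode: str | None = None,
              block: int | None = None) -> int:
        return sum(
            1 for e in self.events
            if (stimulus_type is None or e.stimulus_type == stimulus_type)
            and (mode is None or e.mode == mode)
            and (block is None or e.block == block)
        )

    def validate(self) -> None:
        onsets = self.onsets_ms()
        if np.any(np.diff(onsets) <= 0):
            raise ValueError("event onsets must be strictly increasing")
        cfg = self.config
        expected = {
            "standard": cfg.n_standard,
            "deviant": cfg.n_deviant,
            "correct_novel": cfg.n_correct_novel,
            "incorrect_novel": cfg.n_incorrect_novel,
        }
        for b in range(cfg.n_blocks):
            for st, n in expected.items():
                got = self.count(stimulus_type=st, block=b)
                if got != n:
                    raise ValueError(
                        f"block {b}: expected {n} {st} events, found {got}")
        # every novel must trail a deviant by exactly stimulus + gap
        pair_gap = cfg.stimulus_duration_ms + cfg.deviant_to_novel_gap_ms
        for i, e in enumerate(self.events):
            if e.stimulus_type.endswith("novel"):
                if i == 0 or self.events[i - 1].stimulus_type != "deviant":
                    raise ValueError(f"novel event {i} not preceded by a deviant")
                gap = e.onset_ms - self.events[i - 1].onset_ms
                if abs(gap - pair_gap) > 1.0:
                    raise ValueError(
                        f"novel event {i}: deviant→novel gap {gap} != {pair_gap}")


def generate_event_sequence(config: ParadigmConfig, seed: int) -> EventSequence:
    """Generate a randomized, pairing-consistent event sequence.

    Within each block the presentation order is randomized subject to the
    constraint that each novel stimulus immediately follows a deviant at a
    fixed gap (stimulus duration + deviant-to-novel gap).  Onsets are
    rounded to the nearest millisecond.  Deterministic for a fixed seed.
    """
    if config.n_novel > config.n_deviant:
        raise PairingInfeasibleError(
            f"{config.n_novel} novel stimuli per block cannot each be paired "
            f"with one of {config.n_deviant} deviants")
    rng = np.random.default_rng(seed)
    pair_gap = config.stimulus_duration_ms + config.deviant_to_novel_gap_ms

    events: list[Event] = []
    t = 0.0
    block = 0
    for mode in config.modes:
        for _ in range(config.blocks_per_mode):
            # presentation units: a unit is either a lone stimulus or a
            # (deviant, novel) pair welded at the fixed gap
            units: list[tuple[str, ...]] = []
            novel_types = (["correct_novel"] * config.n_correct_novel
                           + ["incorrect_novel"] * config.n_incorrect_novel)
            rng.shuffle(novel_types)
            units += [("deviant", nt) for nt in novel_types]
            units += [("deviant",)] * (config.n_deviant - config.n_novel)
            units += [("standard",)] * config.n_standard
            order = rng.permutation(len(units))

            t += BLOCK_LEAD_IN_MS
            for idx in order:
                unit = units[idx]
                onset = round(t)
                events.append(Event(onset, unit[0], mode, block, config.modality))
                if len(unit) == 2:
                    onset2 = round(t + pair_gap)
                    events.append(Event(onset2, unit[1], mode, block,
                                        config.modality))
                    t = onset2
                t += (config.stimulus_duration_ms
                      + rng.uniform(*config.isi_range_ms))
            t += INTER_BLOCK_GAP_MS
            block += 1

    seq = EventSequence(events, config)
    seq.validate()
    return seq
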