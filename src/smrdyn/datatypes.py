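"""Core data containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The nine motor-cortex channels common to both recording montages.
ANALYSIS_CHANNELS = ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4")

#: Reference channels for relative-phase vectors: symmetric about the
#: midline, surrounding C3/Cz/C4.
REFERENCE_CHANNELS = ("FC3", "FC4", "CP3", "CP4")

#: Extra frontal channel carried by the synthetic montage.
FRONTAL_CHANNEL = "AFz"


def wrap_phase(a):
    """Wrap angles to the half-open interval (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    return -(np.mod(np.pi - a, 2.0 * np.pi) - np.pi)


@dataclass(frozen=True)
class BandDefinition:
    """A named analysis frequency band [low, high] in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ValueError(f"invalid band edges ({self.low}, {self.high})")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: Analysis bands: alpha plus three beta sub-bands.
DEFAULT_BANDS = (
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("lower_beta", 13.0, 16.0),
    BandDefinition("mid_beta", 16.0, 20.0),
    BandDefinition("upper_beta", 20.0, 30.0),
)

BAND_BY_NAME = {b.name: b for b in DEFAULT_BANDS}


@dataclass(frozen=True)
class ParadigmSpec:
    """Trial timing of the cue-guided motor-imagery paradigm.

    All times are seconds relative to fixation-cross onset.  The baseline
    window is fixed to the 1.5 s immediately preceding the cue.
    """

    trial_length: float = 8.0
    cue_onset: float = 1.5
    cue_offset: float = 3.5
    mi_window: tuple[float, float] = (1.5, 8.0)
    sampling_rate: float = 250.0

    def __post_init__(self):
        if not 0 <= self.cue_onset < self.cue_offset <= self.trial_length:
            raise ValueError("require 0 <= cue_onset < cue_offset <= trial_length")
        if self.sampling_rate <= 60.0:
            raise ValueError(
                f"sampling rate {self.sampling_rate} Hz too low: must exceed "
                "60 Hz (twice the highest analysis frequency of 30 Hz)"
            )

    @property
    def baseline_window(self) -> tuple[float, float]:
        return (self.cue_onset - 1.5, self.cue_onset)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_length * self.sampling_rate))


@dataclass(frozen=True)
class Event:
    """A trial marker inside a continuous recording."""

    onset_sample: int
    condition: str
    trial_index: int


@dataclass
class EEGRecording:
    """Continuous multichannel EEG with trial events.

    Attributes
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Amplitude in microvolts.
    channel_labels : tuple of str
    sampling_rate : float
    events : list of Event
    participant : dict
        Free-form metadata (id, group, age, gender, ...).
    artifact_trials : frozenset of int
        Trial indices that received an injected artifact (generator
        ground truth; empty for real data).
    """

    signal: np.ndarray
    channel_labels: tuple
    sampling_rate: float
    events: list = field(default_factory=list)
    participant: dict = field(default_factory=dict)
    artifact_trials: frozenset = frozenset()

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.signal.ndim != 2:
            raise ValueError("signal must be 2-D (channels x samples)")
        if self.signal.shape[0] != len(self.channel_labels):
            raise ValueError("one label per channel row required")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


@dataclass
class TrialSet:
    """Segmented trials: trials x channels x samples, time anchored at 0 s.

    ``time_axis`` runs from 0 (fixation-cross onset) using 0-based sample
    indexing; windows are half-open ``[start, end)`` throughout.
    """

    data: np.ndarray
    channel_labels: tuple
    sampling_rate: float
    conditions: np.ndarray
    participant: dict = field(default_factory=dict)
    band: BandDefinition | None = None
    artifact_flags: np.ndarray | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        self.conditions = np.asarray(self.conditions)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("one label per channel required")
        if self.data.shape[0] != len(self.conditions):
            raise ValueError("one condition label per trial required")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None

    def select_condition(self, condition: str) -> "TrialSet":
        mask = self.conditions == condition
        flags = self.artifact_flags[mask] if self.artifact_flags is not None else None
        return replace(
            self,
            data=self.data[mask],
            conditions=self.conditions[mask],
            artifact_flags=flags,
        )

    def window_slice(self, start: float, end: float) -> slice:
        """Half-open sample slice covering [start, end) seconds."""
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(end * self.sampling_rate - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_samples))


@dataclass
class FeatureSeries:
    """Per-trial-set feature time course (band power or PLV).

    ``values`` keeps the trials x channels x samples layout; a trial- or
    channel-averaged series uses a singleton axis.
    """

    values: np.ndarray
    sampling_rate: float
    feature_name: str
    band: BandDefinition | None = None
    channel_labels: tuple | None = None
    baseline_corrected: bool = False
    valid_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be 3-D (trials x channels x samples)")

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    @property
    def time_axis(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate

    def window_slice(self, start: float, end: float) -> slice:
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(end * self.sampling_rate - 1e-9))
        return slice(max(i0, 0), min(i1, self.n_samples))
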