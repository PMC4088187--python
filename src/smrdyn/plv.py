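"""Across-trial phase-locking value (PLV) time courses.

The instantaneous phase of each band-filtered trial is taken as the angle
of its analytic signal.  For a channel pair the PLV at time ``t`` is the
modulus of the across-trial mean unit phasor of the phase difference::

    PLV_t = | (1/N) * sum_n exp(j * theta(t, n)) |

with ``N`` trials; 0 means no locking, 1 perfect locking.  PLV is computed
for every unordered pair of the nine motor channels (36 pairs) and
averaged, and separately for the three frontal-to-primary-motor pairs
(frontal-C3, frontal-Cz, frontal-C4) as an M1-SMA coupling estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy.signal import hilbert

from smrdyn.datatypes import (
    ANALYSIS_CHANNELS,
    BandDefinition,
    FeatureSeries,
    TrialSet,
    wrap_phase,
)

logger = logging.getLogger(__name__)

#: Phase samples closer than this (s) to a trial edge are excluded from
#: segment means (Hilbert transform edge effects).
EDGE_EXCLUSION_S = 0.25

#: Default stand-in for the supplementary-motor-area electrode; the nominal
#: frontal-midline site is absent from the common montage, so the overlying
#: fronto-central channel is used and kept configurable.
DEFAULT_FRONTAL = "FCz"

M1_CHANNELS = ("C3", "Cz", "C4")


@dataclass
class PhaseTrialSet:
    """Instantaneous phase per trial/channel/sample, wrapped to (-pi, pi]."""

    phases: np.ndarray  # trials x channels x samples
    channel_labels: tuple
    sampling_rate: float
    band: BandDefinition | None = None

    def __post_init__(self):
        self.phases = np.asarray(self.phases, dtype=float)
        self.channel_labels = tuple(self.channel_labels)
        if self.phases.ndim != 3:
            raise ValueError("phases must be 3-D (trials x channels x samples)")

    @property
    def n_trials(self) -> int:
        return self.phases.shape[0]

    @property
    def n_samples(self) -> int:
        return self.phases.shape[2]

    def channel_index(self, label: str) -> int:
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel label {label!r}") from None


def instantaneous_phase(trials: TrialSet) -> PhaseTrialSet:
    """Analytic-signal phase of every (band-filtered) trial and channel."""
    if trials.band is None:
        logger.warning(
            "computing instantaneous phase of a trial set without band "
            "metadata; input may be broadband"
        )
    analytic = hilbert(trials.data, axis=-1)
    return PhaseTrialSet(
        phases=wrap_phase(np.angle(analytic)),
        channel_labels=trials.channel_labels,
        sampling_rate=trials.sampling_rate,
        band=trials.band,
    )


def _plv_from_diff(diff: np.ndarray) -> np.ndarray:
    """PLV time course from a (trials x samples) phase-difference array."""
    return np.abs(np.exp(1j * diff).mean(axis=0))


def _valid_window(phases: PhaseTrialSet) -> tuple[float, float]:
    dur = phases.n_samples / phases.sampling_rate
    return (EDGE_EXCLUSION_S, dur - EDGE_EXCLUSION_S)


def plv_timecourse(phases: PhaseTrialSet, pair: tuple[str, str]) -> FeatureSeries:
    """Across-trial PLV time course for one channel pair."""
    if phases.n_trials < 2:
        raise ValueError("PLV needs at least 2 trials")
    i = phases.channel_index(pair[0])
    j = phases.channel_index(pair[1])
    diff = phases.phases[:, i, :] - phases.phases[:, j, :]
    plv = _plv_from_diff(diff)
    return FeatureSeries(
        values=plv[None, None, :],
        sampling_rate=phases.sampling_rate,
        feature_name="plv",
        band=phases.band,
        channel_labels=(f"{pair[0]}-{pair[1]}",),
        valid_window=_valid_window(phases),
    )


def mean_pairwise_plv(
    phases: PhaseTrialSet, channels: tuple = ANALYSIS_CHANNELS
) -> FeatureSeries:
    """Mean PLV over all unordered pairs of the given channels (36 for 9)."""
    if phases.n_trials < 2:
        raise ValueError("PLV needs at least 2 trials")
    idx = [phases.channel_index(c) for c in channels]
    pairs = list(combinations(idx, 2))
    acc = np.zeros(phases.n_samples)
    for i, j in pairs:
        acc += _plv_from_diff(phases.phases[:, i, :] - phases.phases[:, j, :])
    plv = acc / len(pairs)
    return FeatureSeries(
        values=plv[None, None, :],
        sampling_rate=phases.sampling_rate,
        feature_name="plv",
        band=phases.band,
        channel_labels=("mean_pairwise",),
        valid_window=_valid_window(phases),
    )


def m1_sma_plv(
    phases: PhaseTrialSet, frontal: str = DEFAULT_FRONTAL
) -> FeatureSeries:
    """Mean PLV of the three frontal-to-M1 pairs."""
    if phases.n_trials < 2:
        raise ValueError("PLV needs at least 2 trials")
    fi = phases.channel_index(frontal)
    acc = np.zeros(phases.n_samples)
    for c in M1_CHANNELS:
        ci = phases.channel_index(c)
        acc += _plv_from_diff(phases.phases[:, fi, :] - phases.phases[:, ci, :])
    plv = acc / len(M1_CHANNELS)
    return FeatureSeries(
        values=plv[None, None, :],
        sampling_rate=phases.sampling_rate,
        feature_name="plv",
        band=phases.band,
        channel_labels=(f"{frontal}-M1",),
        valid_window=_valid_window(phases),
    )
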