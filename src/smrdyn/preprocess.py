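"""Pre-processing: common average reference, segmentation, artifact
rejection, and zero-phase band filtering.

Order of application follows the analysis convention: CAR on the continuous
recording, segmentation into trials, amplitude-threshold rejection on the
nine analysis channels, then band filtering.  Windows are half-open
``[start, end)`` with 0-based sample indexing.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
from scipy.signal import butter, sosfiltfilt

from smrdyn.datatypes import (
    ANALYSIS_CHANNELS,
    BandDefinition,
    EEGRecording,
    ParadigmSpec,
    TrialSet,
)

logger = logging.getLogger(__name__)

#: Amplitude-rejection threshold (uV): trials exceeding +-80 uV are dropped.
REJECTION_THRESHOLD_UV = 80.0


def apply_car(
    recording: EEGRecording, channels: tuple = ANALYSIS_CHANNELS
) -> EEGRecording:
    """Re-reference the given channels to their common average.

    At every sample, the mean over the referenced channels becomes zero;
    channels outside the set are left untouched.
    """
    if len(channels) < 2:
        raise ValueError("common average reference needs at least 2 channels")
    idx = [recording.channel_index(c) for c in channels]
    signal = recording.signal.copy()
    signal[idx] -= signal[idx].mean(axis=0, keepdims=True)
    return replace(recording, signal=signal)


def segment_trials(recording: EEGRecording, paradigm: ParadigmSpec) -> TrialSet:
    """Slice ``[onset, onset + trial_length)`` around each event.

    Events whose window would run past the end of the recording are dropped
    with a warning.
    """
    n = paradigm.n_samples
    slices, conditions = [], []
    for ev in recording.events:
        if ev.onset_sample + n > recording.n_samples or ev.onset_sample < 0:
            logger.warning(
                "dropping truncated trial %d (onset %d, needs %d of %d samples)",
                ev.trial_index,
                ev.onset_sample,
                n,
                recording.n_samples,
            )
            continue
        slices.append(recording.signal[:, ev.onset_sample : ev.onset_sample + n])
        conditions.append(ev.condition)
    data = (
        np.stack(slices)
        if slices
        else np.empty((0, recording.n_channels, n))
    )
    flags = None
    if recording.artifact_trials:
        flags = np.array(
            [
                ev.trial_index in recording.artifact_trials
                for ev in recording.events
                if ev.onset_sample + n <= recording.n_samples and ev.onset_sample >= 0
            ]
        )
    return TrialSet(
        data=data,
        channel_labels=recording.channel_labels,
        sampling_rate=recording.sampling_rate,
        conditions=np.array(conditions, dtype=object),
        participant=dict(recording.participant),
        artifact_flags=flags,
    )


def reject_artifacts(
    trials: TrialSet,
    threshold: float = REJECTION_THRESHOLD_UV,
    channels: tuple = ANALYSIS_CHANNELS,
) -> tuple[TrialSet, int]:
    """Drop every trial whose amplitude strictly exceeds ``threshold`` uV.

    The criterion is evaluated on the analysis channels only; a sample at
    exactly the threshold is kept.  Surviving trials keep their order and
    their samples are untouched.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    idx = [trials.channel_index(c) for c in channels]
    bad = np.any(np.abs(trials.data[:, idx, :]) > threshold, axis=(1, 2))
    n_rejected = int(bad.sum())
    if n_rejected == trials.n_trials and trials.n_trials > 0:
        logger.warning("all %d trials rejected at +-%g uV", trials.n_trials, threshold)
    keep = ~bad
    flags = trials.artifact_flags[keep] if trials.artifact_flags is not None else None
    kept = replace(
        trials,
        data=trials.data[keep],
        conditions=trials.conditions[keep],
        artifact_flags=flags,
    )
    return kept, n_rejected


def _band_sos(band: BandDefinition, fs: float, order: int = 4):
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} upper edge {band.high} Hz >= Nyquist {nyq} Hz"
        )
    return butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass(trials: TrialSet, band: BandDefinition, order: int = 4) -> TrialSet:
    """Zero-phase Butterworth band-pass of every trial and channel.

    Forward-backward application cancels the group delay; the effective
    roll-off (~48 dB/octave for the default 4th order) comfortably exceeds
    20 dB one octave outside the passband.
    """
    sos = _band_sos(band, trials.sampling_rate, order)
    if trials.n_trials == 0:
        raise ValueError("cannot filter an empty trial set")
    data = sosfiltfilt(sos, trials.data, axis=-1)
    return replace(trials, data=data, band=band)
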