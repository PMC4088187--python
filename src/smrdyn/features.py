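"""Band-power features: sliding-window RMS amplitude, pre-cue baselining,
channel averaging, and 2-s segment means."""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from smrdyn.datatypes import ANALYSIS_CHANNELS, FeatureSeries, TrialSet

#: Default sliding RMS window (s); matches the 2-s segment resolution.
RMS_WINDOW_S = 1.0

#: Segment boundaries (s) used for group comparison.
SEGMENTS = ((0.0, 2.0), (2.0, 4.0), (4.0, 6.0), (6.0, 8.0))


def _sliding_mean(x: np.ndarray, half: int) -> np.ndarray:
    """Centered moving average along the last axis with truncated edges."""
    n = x.shape[-1]
    csum = np.cumsum(x, axis=-1)
    csum = np.concatenate([np.zeros(x.shape[:-1] + (1,)), csum], axis=-1)
    i = np.arange(n)
    lo = np.maximum(i - half, 0)
    hi = np.minimum(i + half + 1, n)
    return (csum[..., hi] - csum[..., lo]) / (hi - lo)


def band_power(trials: TrialSet, window: float = RMS_WINDOW_S) -> FeatureSeries:
    """Time-resolved band power as sliding-window RMS amplitude.

    Per trial and channel the band-filtered signal is squared, averaged in
    a centered window of ``window`` seconds (truncated at the trial edges),
    and square-rooted.  ``window`` equal to one sample period reduces to
    ``|x(t)|``.
    """
    n_win = int(round(window * trials.sampling_rate))
    if n_win < 1:
        raise ValueError("window must cover at least one sample")
    if n_win > trials.n_samples:
        raise ValueError(
            f"window of {n_win} samples exceeds trial length {trials.n_samples}"
        )
    half = (n_win - 1) // 2
    rms = np.sqrt(_sliding_mean(trials.data**2, half))
    return FeatureSeries(
        values=rms,
        sampling_rate=trials.sampling_rate,
        feature_name="bandpower",
        band=trials.band,
        channel_labels=trials.channel_labels,
    )


def baseline_correct(
    series: FeatureSeries, baseline_window: tuple[float, float] = (0.0, 1.5)
) -> FeatureSeries:
    """Subtract each trial/channel's scalar mean over the baseline window.

    Negative corrected values indicate desynchronization (ERD), positive
    ones synchronization (ERS).
    """
    sl = series.window_slice(*baseline_window)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline window contains no samples")
    baseline = series.values[..., sl].mean(axis=-1, keepdims=True)
    return replace(
        series, values=series.values - baseline, baseline_corrected=True
    )


def average_channels(
    series: FeatureSeries, channels: tuple = ANALYSIS_CHANNELS
) -> FeatureSeries:
    """Average the series over the given channels into a single channel."""
    if series.channel_labels is None:
        raise ValueError("series carries no channel labels")
    try:
        idx = [series.channel_labels.index(c) for c in channels]
    except ValueError as e:
        raise KeyError(f"channel missing from series: {e}") from None
    values = series.values[:, idx, :].mean(axis=1, keepdims=True)
    return replace(series, values=values, channel_labels=("mean",))


def segment_means(
    series: FeatureSeries, segments: tuple = SEGMENTS
) -> np.ndarray:
    """Reduce a series to per-segment scalar means.

    Trials (and any remaining channels) are averaged first; each segment
    mean is then taken over its half-open window, restricted to the
    series' ``valid_window`` when one is set (used to exclude filter /
    Hilbert edge artifacts).
    """
    end_needed = max(e for _, e in segments)
    if series.n_samples < int(np.floor(end_needed * series.sampling_rate)):
        raise ValueError(
            f"series of {series.n_samples} samples does not cover "
            f"[0, {end_needed}) s"
        )
    mean_series = series.values.mean(axis=(0, 1))
    valid = np.ones(series.n_samples, dtype=bool)
    if series.valid_window is not None:
        sl = series.window_slice(*series.valid_window)
        valid[:] = False
        valid[sl] = True
    out = np.empty(len(segments))
    for i, (start, end) in enumerate(segments):
        sl = series.window_slice(start, end)
        m = valid[sl]
        if not m.any():
            raise ValueError(f"segment [{start}, {end}) has no valid samples")
        out[i] = mean_series[sl][m].mean()
    return out


def baseline_power(
    trials: TrialSet,
    baseline_window: tuple[float, float] = (0.0, 1.5),
    window: float = RMS_WINDOW_S,
    channels: tuple = ANALYSIS_CHANNELS,
) -> float:
    """Absolute pre-cue band power: un-baselined RMS averaged over the
    baseline window, the analysis channels, and all trials."""
    series = band_power(trials, window=window)
    series = average_channels(series, channels)
    sl = series.window_slice(*baseline_window)
    if sl.stop - sl.start < 1:
        raise ValueError("baseline window contains no samples")
    return float(series.values[..., sl].mean())
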