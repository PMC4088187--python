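"""Phase-pattern dynamics: relative phase vectors, the instantaneous
instability index, global phase synchronization (GPS) episodes, circular
episode patterns, and pooled K-means labeling.

Per sample, each motor channel's phase is referenced to the circular mean
phase of the four channels surrounding the primary motor sites::

    Phi_i(t) = wrap(theta_i(t) - theta_R(t)),   R = {FC3, FC4, CP3, CP4}

The instability index at each sample is

    I(t) = sum_i d_i(t)^2,
    d_i(t) = (1/N) * sum_h (1 - cos(Phi_i(t) - Phi_h(t)))

so identical phases give I = 0 and I depends only on pairwise phase
differences.  GPS episodes are maximal runs where I stays strictly below a
percentile threshold (50th by default) of the pooled I values; each episode
is summarized by the per-channel circular mean of Phi over its samples, and
the pooled episode patterns are clustered (K-means on the cos/sin
embedding, K = 6) into a discrete symbol sequence per participant and
condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from smrdyn.datatypes import (
    ANALYSIS_CHANNELS,
    REFERENCE_CHANNELS,
    wrap_phase,
)
from smrdyn.plv import PhaseTrialSet

logger = logging.getLogger(__name__)

DEFAULT_K = 6
GPS_PERCENTILE = 50.0

#: Resultant lengths below this flag a degenerate (antipodal) circular mean.
_RESULTANT_TOL = 1e-9


def relative_phase(
    phases: PhaseTrialSet,
    channels: tuple = ANALYSIS_CHANNELS,
    references: tuple = REFERENCE_CHANNELS,
) -> np.ndarray:
    """Relative phase Phi: (trials x channels x samples), wrapped.

    The reference phase is the circular mean (angle of the summed unit
    phasors) of the reference channels; plain arithmetic averaging of
    wrapped angles would be ill-defined at the wrap point.
    """
    ch_idx = [phases.channel_index(c) for c in channels]
    ref_idx = [phases.channel_index(c) for c in references]
    ref_phasor = np.exp(1j * phases.phases[:, ref_idx, :]).sum(axis=1)
    theta_r = np.angle(ref_phasor)
    return wrap_phase(phases.phases[:, ch_idx, :] - theta_r[:, None, :])


def instability_index(rel: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Instability index I and per-channel dissimilarities d.

    ``rel`` is (channels x samples) or (trials x channels x samples);
    returns ``(I, d)`` with the channel axis reduced in ``I``.
    """
    rel = np.asarray(rel, dtype=float)
    if rel.shape[-2] < 2:
        raise ValueError("instability index needs at least 2 channels")
    # d_i = 1 - (1/N) sum_h cos(Phi_i - Phi_h); expand via phasors:
    # sum_h cos(Phi_i - Phi_h) = cos(Phi_i) * sum_h cos(Phi_h)
    #                          + sin(Phi_i) * sum_h sin(Phi_h)
    n = rel.shape[-2]
    c, s = np.cos(rel), np.sin(rel)
    sc = c.sum(axis=-2, keepdims=True)
    ss = s.sum(axis=-2, keepdims=True)
    d = 1.0 - (c * sc + s * ss) / n
    i = (d**2).sum(axis=-2)
    return i, d


@dataclass(frozen=True)
class GPSEpisode:
    """Half-open sample interval of one stable-phase episode."""

    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def gps_threshold(pooled_i: np.ndarray, percentile: float = GPS_PERCENTILE) -> float:
    """Linear-interpolation percentile of the pooled instability values."""
    pooled_i = np.asarray(pooled_i, dtype=float)
    if pooled_i.size == 0:
        raise ValueError("empty instability series")
    return float(np.percentile(pooled_i, percentile))


def gps_segment(
    i_series: np.ndarray,
    percentile: float = GPS_PERCENTILE,
    threshold: float | None = None,
) -> list[GPSEpisode]:
    """Maximal runs where I(t) stays strictly below the threshold.

    When ``threshold`` is given (e.g. computed from a pooled series across
    trials), the percentile argument is ignored.  A constant series yields
    no episodes (no sample is strictly below its own percentile).
    """
    i_series = np.asarray(i_series, dtype=float)
    if i_series.ndim != 1 or i_series.size == 0:
        raise ValueError("instability series must be non-empty and 1-D")
    if threshold is None:
        threshold = gps_threshold(i_series, percentile)
    below = i_series < threshold
    if not below.any():
        logger.warning("no samples below GPS threshold %g; zero episodes", threshold)
        return []
    padded = np.concatenate([[False], below, [False]]).astype(int)
    d = np.diff(padded)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [GPSEpisode(int(a), int(b)) for a, b in zip(starts, ends)]


def gps_patterns(
    rel: np.ndarray, episodes: list[GPSEpisode]
) -> tuple[np.ndarray, np.ndarray]:
    """Circular-mean phase pattern of each episode.

    ``rel`` is (channels x samples).  Returns ``(patterns, degenerate)``:
    patterns is (n_episodes x channels) wrapped angles via the
    four-quadrant arctangent of summed sines/cosines; channels whose
    resultant vanishes (antipodal samples) get angle 0 and set the
    episode's degenerate flag.
    """
    rel = np.asarray(rel, dtype=float)
    patterns = np.empty((len(episodes), rel.shape[0]))
    degenerate = np.zeros(len(episodes), dtype=bool)
    for g, ep in enumerate(episodes):
        if ep.length < 1 or ep.start < 0 or ep.end > rel.shape[1]:
            raise ValueError(f"episode {g} empty or outside the series")
        seg = rel[:, ep.start : ep.end]
        ssin = np.sin(seg).sum(axis=1)
        scos = np.cos(seg).sum(axis=1)
        resultant = np.hypot(ssin, scos) / ep.length
        bad = resultant < _RESULTANT_TOL
        xi = np.arctan2(ssin, scos)
        xi[bad] = 0.0
        patterns[g] = wrap_phase(xi)
        degenerate[g] = bool(bad.any())
    return patterns, degenerate


def embed_patterns(patterns: np.ndarray) -> np.ndarray:
    """Map angle patterns (M x N) to the (M x 2N) cos/sin embedding."""
    return np.concatenate([np.cos(patterns), np.sin(patterns)], axis=1)


def cluster_patterns(
    pooled_patterns: np.ndarray,
    k: int = DEFAULT_K,
    seed: int = 0,
    n_init: int = 10,
) -> tuple[KMeans, np.ndarray]:
    """K-means labeling of pooled episode patterns.

    Patterns are pooled across every participant and condition and
    clustered once, so the resulting symbol alphabet ``{0..k-1}`` is shared
    — a prerequisite for comparing hidden-Markov dynamics across
    participants.  Returns the fitted model and the pooled label sequence
    (to be split back per participant in episode order by the caller).
    """
    pooled_patterns = np.asarray(pooled_patterns, dtype=float)
    if pooled_patterns.shape[0] < k:
        raise ValueError(
            f"need at least {k} pooled patterns, got {pooled_patterns.shape[0]}"
        )
    model = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = model.fit_predict(embed_patterns(pooled_patterns))
    return model, labels
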