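"""End-to-end orchestration: recordings -> trials -> feature tables,
GPS symbol sequences, and group classification."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from smrdyn import features as feat
from smrdyn import phasedyn
from smrdyn.datatypes import (
    ANALYSIS_CHANNELS,
    DEFAULT_BANDS,
    BandDefinition,
    EEGRecording,
    ParadigmSpec,
    TrialSet,
)
from smrdyn.markov import DEFAULT_STATE_CANDIDATES, LOOResult, loo_classify
from smrdyn.plv import (
    DEFAULT_FRONTAL,
    instantaneous_phase,
    m1_sma_plv,
    mean_pairwise_plv,
)
from smrdyn.preprocess import (
    REJECTION_THRESHOLD_UV,
    apply_car,
    bandpass,
    reject_artifacts,
    segment_trials,
)
from smrdyn.simulate import CONDITIONS

logger = logging.getLogger(__name__)

SEGMENT_LABELS = ("0-2", "2-4", "4-6", "6-8")


def preprocess_recording(
    recording: EEGRecording,
    paradigm: ParadigmSpec,
    threshold: float = REJECTION_THRESHOLD_UV,
) -> tuple[TrialSet, int]:
    """CAR -> segmentation -> amplitude rejection for one recording."""
    rec = apply_car(recording)
    trials = segment_trials(rec, paradigm)
    return reject_artifacts(trials, threshold=threshold)


def _meta_row(trials: TrialSet) -> dict:
    meta = trials.participant
    return {
        "participant": meta.get("participant_id", "?"),
        "group": meta.get("group", "?"),
        "age": meta.get("age", np.nan),
        "gender": meta.get("gender", "?"),
        "n_trials": trials.n_trials,
    }


def bandpower_table(
    trial_sets: list[TrialSet],
    paradigm: ParadigmSpec,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    conditions: tuple = CONDITIONS,
) -> pd.DataFrame:
    """Long-format relative band power per participant/condition/band/segment.

    Per cell: band filter, sliding RMS, per-trial pre-cue baselining,
    nine-channel average, trial average, 2-s segment means.
    """
    rows = []
    for trials in trial_sets:
        base = _meta_row(trials)
        for condition in conditions:
            sub = trials.select_condition(condition)
            if sub.n_trials == 0:
                logger.warning(
                    "participant %s has no %s trials", base["participant"], condition
                )
                continue
            for band in bands:
                filtered = bandpass(sub, band)
                series = feat.band_power(filtered)
                series = feat.baseline_correct(series, paradigm.baseline_window)
                series = feat.average_channels(series)
                seg = feat.segment_means(series)
                bl = feat.baseline_power(filtered, paradigm.baseline_window)
                for label, value in zip(SEGMENT_LABELS, seg):
                    rows.append(
                        {
                            **base,
                            "condition": condition,
                            "band": band.name,
                            "segment": label,
                            "feature": "bandpower",
                            "value": value,
                        }
                    )
                rows.append(
                    {
                        **base,
                        "condition": condition,
                        "band": band.name,
                        "segment": "baseline",
                        "feature": "baseline_power",
                        "value": bl,
                    }
                )
    return pd.DataFrame(rows)


def plv_table(
    trial_sets: list[TrialSet],
    paradigm: ParadigmSpec,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    conditions: tuple = CONDITIONS,
    frontal: str = DEFAULT_FRONTAL,
) -> pd.DataFrame:
    """Long-format baselined PLV (regions MC and M1-SMA) per segment, plus
    the time-mean baseline PLV level per cell."""
    rows = []
    for trials in trial_sets:
        base = _meta_row(trials)
        for condition in conditions:
            sub = trials.select_condition(condition)
            if sub.n_trials < 2:
                logger.warning(
                    "participant %s: fewer than 2 %s trials; PLV skipped",
                    base["participant"],
                    condition,
                )
                continue
            for band in bands:
                phases = instantaneous_phase(bandpass(sub, band))
                for region, series in (
                    ("MC", mean_pairwise_plv(phases)),
                    ("M1-SMA", m1_sma_plv(phases, frontal=frontal)),
                ):
                    sl = series.window_slice(*paradigm.baseline_window)
                    baseline_level = float(series.values[..., sl].mean())
                    corrected = feat.baseline_correct(
                        series, paradigm.baseline_window
                    )
                    seg = feat.segment_means(corrected)
                    for label, value in zip(SEGMENT_LABELS, seg):
                        rows.append(
                            {
                                **base,
                                "condition": condition,
                                "band": band.name,
                                "segment": label,
                                "feature": f"plv_{region}",
                                "value": value,
                            }
                        )
                    rows.append(
                        {
                            **base,
                            "condition": condition,
                            "band": band.name,
                            "segment": "baseline",
                            "feature": f"baseline_plv_{region}",
                            "value": baseline_level,
                        }
                    )
    return pd.DataFrame(rows)


@dataclass
class GPSResult:
    """Per-participant/condition symbol sequences plus episode bookkeeping."""

    sequences: dict  # (participant, condition) -> np.ndarray of symbols
    episodes: pd.DataFrame  # participant, condition, trial, start_s, end_s, label
    iii: dict  # (participant, condition) -> concatenated instability series
    k: int


def gps_sequences(
    trial_sets: list[TrialSet],
    band: BandDefinition,
    k: int = phasedyn.DEFAULT_K,
    percentile: float = phasedyn.GPS_PERCENTILE,
    seed: int = 0,
    conditions: tuple = CONDITIONS,
) -> GPSResult:
    """Phase-dynamics front end shared across the cohort.

    Per participant and condition: band filter, relative phase, instability
    index per trial; the GPS threshold is the given percentile of that
    participant/condition's pooled instability values; episodes from each
    trial are summarized by circular-mean patterns and concatenated in
    trial order.  Patterns from *all* participants and conditions are
    pooled into one K-means fit so symbol identities are shared.
    """
    entries = []  # (participant, condition, trial, episode list, patterns)
    iii = {}
    pooled = []
    for trials in trial_sets:
        pid = trials.participant.get("participant_id", "?")
        for condition in conditions:
            sub = trials.select_condition(condition)
            if sub.n_trials == 0:
                continue
            phases = instantaneous_phase(bandpass(sub, band))
            rel = phasedyn.relative_phase(phases)
            i_all, _ = phasedyn.instability_index(rel)
            iii[(pid, condition)] = i_all.ravel()
            threshold = phasedyn.gps_threshold(i_all.ravel(), percentile)
            for trial in range(sub.n_trials):
                eps = phasedyn.gps_segment(i_all[trial], threshold=threshold)
                if not eps:
                    continue
                patterns, _ = phasedyn.gps_patterns(rel[trial], eps)
                entries.append((pid, condition, trial, eps, patterns))
                pooled.append(patterns)
    if not pooled:
        raise ValueError("no GPS episodes found in any trial")
    pooled_patterns = np.concatenate(pooled)
    _, labels = phasedyn.cluster_patterns(pooled_patterns, k=k, seed=seed)

    sequences: dict = {}
    ep_rows = []
    pos = 0
    fs = trial_sets[0].sampling_rate
    for pid, condition, trial, eps, patterns in entries:
        lab = labels[pos : pos + len(eps)]
        pos += len(eps)
        key = (pid, condition)
        sequences.setdefault(key, []).append(lab)
        for ep, symbol in zip(eps, lab):
            ep_rows.append(
                {
                    "participant": pid,
                    "condition": condition,
                    "trial": trial,
                    "start_s": ep.start / fs,
                    "end_s": ep.end / fs,
                    "label": int(symbol),
                }
            )
    sequences = {key: np.concatenate(parts) for key, parts in sequences.items()}
    return GPSResult(
        sequences=sequences, episodes=pd.DataFrame(ep_rows), iii=iii, k=k
    )


def classify_groups(
    gps: GPSResult,
    participants: pd.DataFrame,
    condition: str,
    candidates: tuple[int, ...] = DEFAULT_STATE_CANDIDATES,
    seed: int = 0,
    **fit_kwargs,
) -> LOOResult:
    """Leave-one-out group classification for one condition's sequences."""
    group_of = dict(
        zip(participants["participant_id"], participants["group"])
    )
    pids, seqs, groups = [], [], []
    for (pid, cond), seq in sorted(gps.sequences.items()):
        if cond != condition or len(seq) == 0:
            continue
        pids.append(pid)
        seqs.append(seq)
        groups.append(group_of[pid])
    result = loo_classify(
        seqs, groups, n_symbols=gps.k, candidates=candidates, seed=seed, **fit_kwargs
    )
    for fold, pid in zip(result.folds, pids):
        fold["participant"] = pid
    return result
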