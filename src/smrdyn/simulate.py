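"""Synthetic two-group motor-imagery EEG cohorts.

The generator produces continuous multichannel recordings whose band-limited
oscillators have controllable baseline amplitude, imagery-locked amplitude
suppression (ERD), inter-channel phase coupling, and phase-pattern switching
dynamics, riding on a 1/f noise floor.  Every knob maps monotonically onto
the downstream measurement it is meant to drive, which is what makes the
analysis stack testable without recorded data.

Generative model, per participant and band:

* a shared base phase ``phi(t) = 2*pi*f_c*t + random walk`` (narrowband
  carrier with slow drift);
* per-channel phase offsets taken from the currently active template of a
  :class:`PatternTemplateBank`; the active template follows a Markov chain
  with exponential holding times of mean ``1/switch_rate`` seconds, drawn
  once per participant and condition and frozen across that condition's
  trials (so across-trial phase locking is governed purely by jitter);
* per-trial, per-channel von Mises phase jitter whose concentration is a
  monotone map of ``plv_target`` (``plv_target=1`` means zero jitter);
* an amplitude envelope that drops by the fraction ``erd_depth`` inside the
  imagery window, with a 0.5 s raised-cosine ramp.

Templates in the default bank are channel permutations of one base offset
pattern, so all templates share the same instantaneous instability value and
switching-rate effects are not confounded by between-template level shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from smrdyn.datatypes import (
    ANALYSIS_CHANNELS,
    DEFAULT_BANDS,
    FRONTAL_CHANNEL,
    BandDefinition,
    EEGRecording,
    Event,
    ParadigmSpec,
    wrap_phase,
)

DEFAULT_MONTAGE = ANALYSIS_CHANNELS + (FRONTAL_CHANNEL,)
CONDITIONS = ("hand", "feet")

#: Duration of the raised-cosine ERD onset ramp (s).
_ERD_RAMP_S = 0.5
#: Injected artifact: square transient amplitude (uV) and duration (s).
_ARTIFACT_AMP_UV = 100.0
_ARTIFACT_DUR_S = 0.2


def _per_band(value, bands) -> dict:
    """Broadcast a scalar or per-band mapping to a {band_name: float} dict."""
    if isinstance(value, dict):
        missing = [b.name for b in bands if b.name not in value]
        if missing:
            raise ValueError(f"missing band entries: {missing}")
        return {b.name: float(value[b.name]) for b in bands}
    return {b.name: float(value) for b in bands}


@dataclass(frozen=True)
class ParticipantProfile:
    """Generative parameters for one synthetic participant.

    ``baseline_amp``, ``erd_depth`` and ``plv_target`` accept either a
    scalar (applied to every band) or a ``{band_name: value}`` mapping.
    """

    participant_id: str
    group: str
    age: float
    gender: str
    n_trials_per_condition: int
    baseline_amp: object = 5.0
    erd_depth: object = 0.4
    plv_target: object = 0.6
    switch_rate: float = 4.0
    noise_amp: float = 2.0
    artifact_fraction: float = 0.0

    def __post_init__(self):
        if self.group not in ("A", "B"):
            raise ValueError("group must be 'A' or 'B'")
        if self.gender not in ("F", "M"):
            raise ValueError("gender must be 'F' or 'M'")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")
        if self.switch_rate <= 0:
            raise ValueError("switch_rate must be > 0")
        if not 0.0 <= self.artifact_fraction <= 1.0:
            raise ValueError("artifact_fraction must be in [0, 1]")
        for name, bounded in (("erd_depth", True), ("plv_target", True)):
            vals = getattr(self, name)
            vals = vals.values() if isinstance(vals, dict) else [vals]
            for v in vals:
                if bounded and not 0.0 <= float(v) <= 1.0:
                    raise ValueError(f"{name} values must lie in [0, 1]")


@dataclass(frozen=True)
class PatternTemplateBank:
    """Ground-truth phase-offset templates and their switching chain."""

    templates: np.ndarray  # (n_templates, n_channels) radians
    transition_matrix: np.ndarray  # row-stochastic, no self-transitions needed

    def __post_init__(self):
        t = np.asarray(self.templates, dtype=float)
        m = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "templates", wrap_phase(t))
        object.__setattr__(self, "transition_matrix", m)
        if t.ndim != 2:
            raise ValueError("templates must be 2-D")
        if m.shape != (t.shape[0], t.shape[0]):
            raise ValueError("transition matrix shape must match template count")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("transition matrix rows must sum to 1")
        if np.any(m < 0):
            raise ValueError("transition probabilities must be non-negative")

    @property
    def n_templates(self) -> int:
        return self.templates.shape[0]


def default_template_bank(
    n_templates: int = 6, n_channels: int = len(DEFAULT_MONTAGE)
) -> PatternTemplateBank:
    """Bank of ``n_templates`` cyclic channel permutations of one pattern.

    Permuting channel offsets leaves the multiset of pairwise phase
    differences over the analysis channels unchanged, so every template has
    the same instability-index level; the frontal channel keeps offset 0.
    """
    base = wrap_phase(0.7 * np.arange(len(ANALYSIS_CHANNELS)))
    templates = np.zeros((n_templates, n_channels))
    for k in range(n_templates):
        templates[k, : len(ANALYSIS_CHANNELS)] = np.roll(base, k)
    if n_templates == 1:
        m = np.ones((1, 1))
    else:
        # uniform jumps to any *other* template
        m = np.full((n_templates, n_templates), 1.0 / (n_templates - 1))
        np.fill_diagonal(m, 0.0)
    return PatternTemplateBank(templates, m)


def _plv_to_kappa(plv_target: float) -> float:
    """Monotone map from target coupling in [0, 1) to von Mises concentration."""
    return 4.0 * plv_target / (1.0 - plv_target)


def _template_sequence(
    bank: PatternTemplateBank,
    n_samples: int,
    fs: float,
    switch_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-sample active-template indices from an exponential-holding chain."""
    seq = np.empty(n_samples, dtype=np.intp)
    state = int(rng.integers(bank.n_templates))
    pos = 0
    while pos < n_samples:
        dwell = max(1, int(round(rng.exponential(1.0 / switch_rate) * fs)))
        seq[pos : pos + dwell] = state
        pos += dwell
        state = int(rng.choice(bank.n_templates, p=bank.transition_matrix[state]))
    return seq


def _erd_envelope(paradigm: ParadigmSpec, depth: float) -> np.ndarray:
    """Fractional amplitude retained at each trial sample: 1 -> 1 - depth."""
    t = np.arange(paradigm.n_samples) / paradigm.sampling_rate
    start, end = paradigm.mi_window
    ramp = np.clip((t - start) / _ERD_RAMP_S, 0.0, 1.0)
    g = 0.5 * (1.0 - np.cos(np.pi * ramp))  # raised cosine 0 -> 1
    g[(t < start) | (t >= end)] = 0.0
    # re-apply the ramp only inside the window
    inside = (t >= start) & (t < end)
    g[~inside] = 0.0
    return 1.0 - depth * g


def _pink_noise(shape, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f (power) noise along the last axis."""
    n = shape[-1]
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** -0.5  # amplitude ~ f^-1/2 => power ~ 1/f
    spec = (
        rng.standard_normal(shape[:-1] + (len(freqs),))
        + 1j * rng.standard_normal(shape[:-1] + (len(freqs),))
    ) * scale
    x = np.fft.irfft(spec, n=n, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_participant(
    profile: ParticipantProfile,
    paradigm: ParadigmSpec | None = None,
    templates: PatternTemplateBank | None = None,
    seed: int | np.random.SeedSequence = 0,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    montage: tuple = DEFAULT_MONTAGE,
    gap_s: float = 1.0,
) -> EEGRecording:
    """Simulate one participant's continuous recording with trial events.

    Trials of the two conditions are interleaved in random order and
    separated by ``gap_s`` seconds of noise-only signal.  Identical
    ``(profile, seed)`` pairs give bit-identical output.
    """
    paradigm = paradigm or ParadigmSpec()
    templates = templates if templates is not None else default_template_bank(
        n_channels=len(montage)
    )
    if templates.templates.shape[1] != len(montage):
        raise ValueError("template bank channel count must match montage")
    if len(montage) < 10 or any(c not in montage for c in ANALYSIS_CHANNELS):
        raise ValueError(
            "montage must contain the nine analysis channels plus a frontal channel"
        )
    fs = paradigm.sampling_rate
    for band in bands:
        if band.high * 2.0 >= fs:
            raise ValueError(
                f"sampling rate {fs} Hz too low for band "
                f"{band.name} ({band.low}-{band.high} Hz); need fs > {2 * band.high} Hz"
            )

    rng = np.random.default_rng(seed)
    amps = _per_band(profile.baseline_amp, bands)
    depths = _per_band(profile.erd_depth, bands)
    couplings = _per_band(profile.plv_target, bands)

    n_trial = paradigm.n_samples
    n_gap = int(round(gap_s * fs))
    n_cond_trials = profile.n_trials_per_condition
    n_trials = n_cond_trials * len(CONDITIONS)
    n_total = n_gap + n_trials * (n_trial + n_gap)
    n_chan = len(montage)

    conditions = np.repeat(CONDITIONS, n_cond_trials)
    conditions = conditions[rng.permutation(n_trials)]

    # one frozen switching sequence per condition, shared by its trials
    cond_template_seq = {
        c: _template_sequence(templates, n_trial, fs, profile.switch_rate, rng)
        for c in CONDITIONS
    }

    signal = profile.noise_amp * _pink_noise((n_chan, n_total), fs, rng)
    events = []
    t_axis = np.arange(n_trial) / fs

    for trial_index, condition in enumerate(conditions):
        onset = n_gap + trial_index * (n_trial + n_gap)
        tmpl_seq = cond_template_seq[condition]
        offsets = templates.templates[tmpl_seq]  # (n_trial, n_chan)
        trial = np.zeros((n_chan, n_trial))
        for band in bands:
            envelope = amps[band.name] * _erd_envelope(paradigm, depths[band.name])
            drift = np.cumsum(rng.normal(0.0, 0.03, n_trial))
            base_phase = (
                2.0 * np.pi * band.center * t_axis
                + drift
                + rng.uniform(0.0, 2.0 * np.pi)
            )
            p = couplings[band.name]
            if p >= 1.0 - 1e-12:
                jitter = np.zeros(n_chan)
            else:
                jitter = rng.vonmises(0.0, _plv_to_kappa(p), n_chan)
            phase = base_phase[None, :] + offsets.T + jitter[:, None]
            trial += envelope[None, :] * np.cos(phase)
        signal[:, onset : onset + n_trial] += trial
        events.append(Event(onset, str(condition), trial_index))

    artifact_trials = set()
    if profile.artifact_fraction > 0:
        n_art = int(round(profile.artifact_fraction * n_trials))
        chosen = rng.choice(n_trials, size=n_art, replace=False)
        n_pulse = int(round(_ARTIFACT_DUR_S * fs))
        for trial_index in chosen:
            onset = n_gap + int(trial_index) * (n_trial + n_gap)
            ch = int(rng.integers(len(ANALYSIS_CHANNELS)))
            ch = montage.index(ANALYSIS_CHANNELS[ch])
            start = onset + int(rng.integers(0, n_trial - n_pulse))
            sign = 1.0 if rng.random() < 0.5 else -1.0
            signal[ch, start : start + n_pulse] += sign * _ARTIFACT_AMP_UV
            artifact_trials.add(int(trial_index))

    return EEGRecording(
        signal=signal,
        channel_labels=montage,
        sampling_rate=fs,
        events=events,
        participant={
            "participant_id": profile.participant_id,
            "group": profile.group,
            "age": profile.age,
            "gender": profile.gender,
            "n_trials": n_trials,
        },
        artifact_trials=frozenset(artifact_trials),
    )


@dataclass(frozen=True)
class GroupSpec:
    """One group's size and the profile its participants are drawn around."""

    n_participants: int
    profile: ParticipantProfile
    age_mean: float = 30.0
    age_sd: float = 6.0
    amp_jitter_sd: float = 0.05  # lognormal sd of between-subject amplitude scale

    def __post_init__(self):
        if self.n_participants < 2:
            raise ValueError("each group needs at least 2 participants")


@dataclass(frozen=True)
class CohortConfig:
    group_a: GroupSpec
    group_b: GroupSpec
    paradigm: ParadigmSpec = field(default_factory=ParadigmSpec)
    templates: PatternTemplateBank | None = None
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS


def generate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[list[EEGRecording], pd.DataFrame]:
    """Simulate a full two-group cohort.

    Per-participant seeds are spawned deterministically from the master
    seed, so the same master seed reproduces the cohort bit for bit.
    Returns the recordings and a participants table with one row each
    (participant_id, group, age, gender, n_trials).
    """
    master = np.random.SeedSequence(seed)
    n_total = config.group_a.n_participants + config.group_b.n_participants
    child_seeds = master.spawn(n_total + 1)
    meta_rng = np.random.default_rng(child_seeds[-1])

    recordings = []
    rows = []
    i = 0
    for group_label, spec in (("A", config.group_a), ("B", config.group_b)):
        for j in range(spec.n_participants):
            pid = f"{group_label}{j + 1:02d}"
            age = float(np.round(meta_rng.normal(spec.age_mean, spec.age_sd)))
            age = float(np.clip(age, 18.0, 70.0))
            gender = "F" if meta_rng.random() < 0.5 else "M"
            scale = float(np.exp(meta_rng.normal(0.0, spec.amp_jitter_sd)))
            amps = _per_band(spec.profile.baseline_amp, config.bands)
            profile = replace(
                spec.profile,
                participant_id=pid,
                group=group_label,
                age=age,
                gender=gender,
                baseline_amp={k: v * scale for k, v in amps.items()},
            )
            rec = generate_participant(
                profile,
                paradigm=config.paradigm,
                templates=config.templates,
                seed=child_seeds[i],
                bands=config.bands,
            )
            recordings.append(rec)
            rows.append(
                {
                    "participant_id": pid,
                    "group": group_label,
                    "age": age,
                    "gender": gender,
                    "n_trials": rec.participant["n_trials"],
                }
            )
            i += 1
    return recordings, pd.DataFrame(rows)
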