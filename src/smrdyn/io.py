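"""Text-based cohort I/O and simulation configs.

A cohort directory holds one delimited signal matrix per participant
(``<id>_signal.tsv``: header row of channel labels, one row per sample),
plus ``participants.tsv`` (participant_id, group, age, gender, n_trials,
sampling_rate) and ``events.tsv`` (participant_id, trial_index,
onset_sample, condition, group, age, gender).  EDF input is not supported
in this build; delimited matrices are the interchange format.
"""

from __future__ import annotations

import tomllib
from pathlib import Path

import numpy as np
import pandas as pd

from smrdyn.datatypes import EEGRecording, Event, ParadigmSpec
from smrdyn.simulate import CohortConfig, GroupSpec, ParticipantProfile


def write_cohort(
    recordings: list[EEGRecording], participants: pd.DataFrame, out_dir: str | Path
) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table = participants.copy()
    table["sampling_rate"] = [r.sampling_rate for r in recordings]
    table.to_csv(out / "participants.tsv", sep="\t", index=False)
    ev_rows = []
    for rec in recordings:
        pid = rec.participant["participant_id"]
        df = pd.DataFrame(rec.signal.T, columns=list(rec.channel_labels))
        df.to_csv(out / f"{pid}_signal.tsv", sep="\t", index=False, float_format="%.6f")
        for ev in rec.events:
            ev_rows.append(
                {
                    "participant_id": pid,
                    "trial_index": ev.trial_index,
                    "onset_sample": ev.onset_sample,
                    "condition": ev.condition,
                    "group": rec.participant.get("group", ""),
                    "age": rec.participant.get("age", ""),
                    "gender": rec.participant.get("gender", ""),
                }
            )
    pd.DataFrame(ev_rows).to_csv(out / "events.tsv", sep="\t", index=False)


def read_cohort(in_dir: str | Path) -> tuple[list[EEGRecording], pd.DataFrame]:
    src = Path(in_dir)
    participants = pd.read_csv(src / "participants.tsv", sep="\t")
    events = pd.read_csv(src / "events.tsv", sep="\t")
    recordings = []
    for row in participants.itertuples():
        pid = row.participant_id
        df = pd.read_csv(src / f"{pid}_signal.tsv", sep="\t")
        sub = events[events["participant_id"] == pid]
        evs = [
            Event(int(e.onset_sample), str(e.condition), int(e.trial_index))
            for e in sub.itertuples()
        ]
        recordings.append(
            EEGRecording(
                signal=df.to_numpy().T,
                channel_labels=tuple(df.columns),
                sampling_rate=float(row.sampling_rate),
                events=evs,
                participant={
                    "participant_id": pid,
                    "group": row.group,
                    "age": float(row.age),
                    "gender": row.gender,
                    "n_trials": int(row.n_trials),
                },
            )
        )
    return recordings, participants


def save_trials(trials, path: str | Path) -> None:
    """Persist a segmented trial set as a compressed archive (runtime cache)."""
    import json

    from smrdyn.datatypes import TrialSet  # noqa: F401  (shape contract)

    np.savez_compressed(
        path,
        data=trials.data,
        channel_labels=np.array(trials.channel_labels),
        sampling_rate=trials.sampling_rate,
        conditions=trials.conditions.astype(str),
        participant=json.dumps(trials.participant),
    )


def load_trials(path: str | Path):
    import json

    from smrdyn.datatypes import TrialSet

    with np.load(path, allow_pickle=False) as z:
        return TrialSet(
            data=z["data"],
            channel_labels=tuple(z["channel_labels"]),
            sampling_rate=float(z["sampling_rate"]),
            conditions=z["conditions"].astype(object),
            participant=json.loads(str(z["participant"])),
        )


_PROFILE_KEYS = (
    "baseline_amp",
    "erd_depth",
    "plv_target",
    "switch_rate",
    "noise_amp",
    "artifact_fraction",
    "n_trials_per_condition",
)


def _group_spec(section: dict, label: str) -> GroupSpec:
    profile_kwargs = {k: section[k] for k in _PROFILE_KEYS if k in section}
    profile = ParticipantProfile(
        participant_id=f"{label}00",
        group=label,
        age=30.0,
        gender="F",
        **profile_kwargs,
    )
    return GroupSpec(
        n_participants=int(section["n_participants"]),
        profile=profile,
        age_mean=float(section.get("age_mean", 30.0)),
        age_sd=float(section.get("age_sd", 6.0)),
    )


def load_cohort_config(path: str | Path) -> CohortConfig:
    """Parse a flat TOML config with [paradigm], [group_a], [group_b]."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    par = dict(raw.get("paradigm", {}))
    if "mi_window" in par:
        par["mi_window"] = tuple(par["mi_window"])
    paradigm = ParadigmSpec(**par)
    return CohortConfig(
        group_a=_group_spec(raw["group_a"], "A"),
        group_b=_group_spec(raw["group_b"], "B"),
        paradigm=paradigm,
    )
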