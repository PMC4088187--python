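import numpy as np
import pytest
from scipy.stats import spearmanr

from conftest import make_profile
from smrdyn import pipeline
from smrdyn.datatypes import BAND_BY_NAME, ParadigmSpec
from smrdyn.features import band_power
from smrdyn.plv import instantaneous_phase, plv_timecourse
from smrdyn.preprocess import bandpass
from smrdyn.simulate import (
    CohortConfig,
    GroupSpec,
    ParticipantProfile,
    default_template_bank,
    generate_cohort,
    generate_participant,
)

ALPHA = BAND_BY_NAME["alpha"]


def _trials(profile, paradigm, seed, condition="hand"):
    rec = generate_participant(profile, paradigm, seed=seed)
    trials, _ = pipeline.preprocess_recording(rec, paradigm, threshold=np.inf)
    return trials.select_condition(condition)


def _mean_power(profile, paradigm, seed, window):
    """Mean squared-RMS alpha power over a time window, all trials pooled."""
    trials = _trials(profile, paradigm, seed)
    series = band_power(bandpass(trials, ALPHA))
    sl = series.window_slice(*window)
    return float((series.values[..., sl] ** 2).mean())


class TestGenerateParticipant:
    def test_determinism(self, paradigm):
        profile = make_profile()
        a = generate_participant(profile, paradigm, seed=42)
        b = generate_participant(profile, paradigm, seed=42)
        assert np.array_equal(a.signal, b.signal)
        assert a.events == b.events

    def test_montage_and_events(self, small_recording):
        assert len(small_recording.channel_labels) == 10
        assert len(small_recording.events) == 10
        conds = {e.condition for e in small_recording.events}
        assert conds == {"hand", "feet"}

    def test_low_sampling_rate_rejected(self):
        from smrdyn.datatypes import BandDefinition

        with pytest.raises(ValueError, match="sampling rate"):
            ParadigmSpec(sampling_rate=50.0)
        par = ParadigmSpec(sampling_rate=80.0)
        gamma = (BandDefinition("gamma", 30.0, 45.0),)
        with pytest.raises(ValueError, match="too low for band"):
            generate_participant(make_profile(), par, seed=0, bands=gamma)

    def test_zero_erd_leaves_power_flat(self, paradigm):
        # erd_depth 0 in every band: MI-window power == baseline power
        profile = make_profile(
            erd_depth=0.0, n_trials_per_condition=30, noise_amp=0.5
        )
        mi = _mean_power(profile, paradigm, 3, (3.0, 7.5))
        base = _mean_power(profile, paradigm, 3, (0.25, 1.5))
        assert abs(mi - base) / base < 0.05

    def test_perfect_coupling_gives_unit_plv(self, paradigm):
        # alpha-only, single-template configuration: cross-band leakage and
        # template-switch transients would otherwise perturb the extracted
        # phase differently per trial
        amps = {"alpha": 5.0, "lower_beta": 0.0, "mid_beta": 0.0, "upper_beta": 0.0}
        profile = make_profile(plv_target=1.0, noise_amp=0.0, baseline_amp=amps)
        bank = default_template_bank(n_templates=1)
        rec = generate_participant(profile, paradigm, templates=bank, seed=5)
        trials, _ = pipeline.preprocess_recording(rec, paradigm, threshold=np.inf)
        trials = trials.select_condition("hand")
        phases = instantaneous_phase(bandpass(trials, ALPHA))
        series = plv_timecourse(phases, ("C3", "CP4"))
        sl = series.window_slice(*series.valid_window)
        assert series.values[..., sl].min() > 0.999

    def test_erd_depth_power_relation(self, paradigm):
        # amplitude drop by factor (1-d) => power drop by 1-(1-d)^2 of baseline
        d = 0.5
        profile = make_profile(
            erd_depth=d, n_trials_per_condition=50, noise_amp=0.3
        )
        base = _mean_power(profile, paradigm, 7, (0.25, 1.5))
        mi = _mean_power(profile, paradigm, 7, (3.0, 7.5))
        expected_drop = (1.0 - (1.0 - d) ** 2) * base
        assert abs((base - mi) - expected_drop) < 0.10 * expected_drop

    def test_erd_monotone_in_depth(self, paradigm):
        depths = [0.0, 0.2, 0.4, 0.6, 0.8]
        drops = []
        for d in depths:
            profile = make_profile(erd_depth=d, n_trials_per_condition=25)
            base = _mean_power(profile, paradigm, 9, (0.25, 1.5))
            mi = _mean_power(profile, paradigm, 9, (3.0, 7.5))
            drops.append(base - mi)
        rho, _ = spearmanr(depths, drops)
        assert rho == pytest.approx(1.0)

    def test_plv_monotone_in_target(self, paradigm):
        targets = [0.1, 0.3, 0.5, 0.7, 0.9]
        measured = []
        for p in targets:
            profile = make_profile(
                plv_target=p, n_trials_per_condition=25, noise_amp=0.5
            )
            trials = _trials(profile, paradigm, 13)
            phases = instantaneous_phase(bandpass(trials, ALPHA))
            series = plv_timecourse(phases, ("C3", "C4"))
            sl = series.window_slice(*series.valid_window)
            measured.append(float(series.values[..., sl].mean()))
        rho, _ = spearmanr(targets, measured)
        assert rho == pytest.approx(1.0)

    def test_amplitude_stays_below_threshold(self, small_recording):
        assert np.abs(small_recording.signal).max() < 80.0

    def test_artifact_injection_flags(self, paradigm):
        profile = make_profile(artifact_fraction=0.3, n_trials_per_condition=10)
        rec = generate_participant(profile, paradigm, seed=21)
        assert len(rec.artifact_trials) == 6
        assert np.abs(rec.signal).max() > 80.0


class TestTemplateBank:
    def test_rows_stochastic(self):
        bank = default_template_bank()
        assert np.allclose(bank.transition_matrix.sum(axis=1), 1.0, atol=1e-12)

    def test_offsets_wrapped(self):
        bank = default_template_bank()
        assert bank.templates.max() <= np.pi
        assert bank.templates.min() > -np.pi

    def test_bad_transition_matrix_rejected(self):
        bank = default_template_bank()
        with pytest.raises(ValueError, match="sum to 1"):
            type(bank)(bank.templates, bank.transition_matrix * 2)


class TestGenerateCohort:
    @staticmethod
    def _config(n_a=3, n_b=3, switch_a=4.0, switch_b=4.0, n_trials=4):
        def spec(group, switch, n):
            profile = make_profile(
                group=group,
                participant_id=f"{group}00",
                switch_rate=switch,
                n_trials_per_condition=n_trials,
            )
            return GroupSpec(n, profile, age_mean=30.0, age_sd=5.0)

        return CohortConfig(group_a=spec("A", switch_a, n_a), group_b=spec("B", switch_b, n_b))

    def test_cohort_sizes_and_table(self):
        # emulated cohort sizes: 12 healthy + 14 with CP = 26
        config = self._config(n_a=12, n_b=14, n_trials=1)
        recordings, table = generate_cohort(config, seed=0)
        assert len(recordings) == 26
        assert len(table) == 26
        assert table["group"].value_counts().to_dict() == {"A": 12, "B": 14}

    def test_determinism(self):
        config = self._config()
        recs1, t1 = generate_cohort(config, seed=77)
        recs2, t2 = generate_cohort(config, seed=77)
        assert t1.equals(t2)
        for a, b in zip(recs1, recs2):
            assert np.array_equal(a.signal, b.signal)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            GroupSpec(1, make_profile())

    def test_switch_rate_raises_iii_variance(self, paradigm):
        # faster template switching => larger temporal variance of the
        # instability index, averaged over repeated cohorts
        from smrdyn.pipeline import gps_sequences

        fast_wins = 0
        for seed in range(10):
            config = self._config(switch_a=8.0, switch_b=2.0, n_trials=3)
            recordings, table = generate_cohort(config, seed=seed)
            tsets = [
                pipeline.preprocess_recording(r, paradigm)[0] for r in recordings
            ]
            gps = gps_sequences(tsets, ALPHA, seed=0, conditions=("hand",))
            var_a = np.mean(
                [gps.iii[(p, "hand")].var() for p in table[table.group == "A"].participant_id]
            )
            var_b = np.mean(
                [gps.iii[(p, "hand")].var() for p in table[table.group == "B"].participant_id]
            )
            fast_wins += var_a > var_b
        assert fast_wins >= 9
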