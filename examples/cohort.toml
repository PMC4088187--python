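# Two-group synthetic cohort: group A emulates the healthy contrast
# (deeper ERD, stronger coupling, faster phase-pattern switching),
# group B the reduced-activation contrast (shallower ERD, higher baseline
# amplitude, slower switching).

[paradigm]
trial_length = 8.0
cue_onset = 1.5
cue_offset = 3.5
sampling_rate = 250.0

[group_a]
n_participants = 12
n_trials_per_condition = 10
baseline_amp = 5.0
erd_depth = 0.6
plv_target = 0.7
switch_rate = 8.0
noise_amp = 2.0
age_mean = 26.0
age_sd = 3.0

[group_b]
n_participants = 14
n_trials_per_condition = 10
baseline_amp = 7.5
erd_depth = 0.25
plv_target = 0.4
switch_rate = 2.0
noise_amp = 2.0
age_mean = 36.0
age_sd = 8.0
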