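# Frozen benchmark regime: two separable classes whose differences follow
# the reported obstructive-HCM pulse morphology (steeper systolic rise,
# longer systolic ejection, multiple peaks of variable intensity, larger
# beat-to-beat and respiratory variability, higher heart rate).
# Calibrated once against the cohort heart-rate table and then frozen.
seed: 1729
healthy:
  n_subjects: 64
  hr_mean: 59.0
  hr_sd: 9.0
  recordings_per_subject: [1, 5]
  recording_duration: 300.0
  sampling_rate: 64.0
  beat_shape:
    crest_time: 0.21
    notch_time: 0.32
    pulse_amplitude: 1.0
    notch_ratio: 0.52
    diastolic_peak_ratio: 0.30
    mid_systolic_bump_amplitude: 0.03
    component_widths: [0.075, 0.022]
  beat_to_beat_cv: 0.04
  between_subject_cv: 0.05
  ibi_cv: 0.03
  resp_rate: 0.25
  resp_amplitude_mod: 0.10
  resp_baseline_mod: 0.05
  irregular_beat_prob: 0.01
  noise_sd: 0.01
  label: healthy
ohcm:
  n_subjects: 19
  hr_mean: 72.0
  hr_sd: 11.0
  recordings_per_subject: [1, 5]
  recording_duration: 300.0
  sampling_rate: 64.0
  beat_shape:
    crest_time: 0.10
    notch_time: 0.37
    pulse_amplitude: 0.88
    notch_ratio: 0.33
    diastolic_peak_ratio: 0.62
    mid_systolic_bump_amplitude: 0.32
    component_widths: [0.13, 0.022]
  beat_to_beat_cv: 0.14
  between_subject_cv: 0.05
  ibi_cv: 0.08
  resp_rate: 0.25
  resp_amplitude_mod: 0.18
  resp_baseline_mod: 0.05
  irregular_beat_prob: 0.08
  noise_sd: 0.01
  label: oHCM
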