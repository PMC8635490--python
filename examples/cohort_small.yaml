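# Scaled-down study for quick runs: 6 participants, artificial agents only.
cohort:
  n_participants: 6
  group_sizes: [2, 2, 2]
response:
  p_mimic_rfr: 0.25
  p_mimic_cfr: 0.35
questionnaire:
  noise_sd: 0.5
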