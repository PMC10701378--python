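# Default phenotype parameters for the three study groups.
#
# Calibrated by simulation so that cohorts of 100 trajectories per group
# reproduce the published group means of total duration, mean speed and
# stay-point counts (and the published orderings of all mined features).
# Units: speeds m/s, noise sd rad, detour length m, pause rate 1/s of
# walking time, pause mean s; accuracies are per-answer probabilities.

NC:
  base_speed_mps: 0.60
  heading_noise_sd_rad: 0.40
  detour_prob: 0.30
  detour_length_m: 0.9497
  pause_rate_per_s: 0.2817
  pause_duration_mean_s: 12.3609
  wrong_target_prob: 0.15
  subtest_accuracies:
    prospective: 0.33
    item_recall: 0.67
    place_recall: 0.78
    recognition: 0.97
    matching: 0.44

aMCI:
  base_speed_mps: 0.62
  heading_noise_sd_rad: 0.50
  detour_prob: 0.85
  detour_length_m: 1.3839
  pause_rate_per_s: 0.3424
  pause_duration_mean_s: 9.1782
  wrong_target_prob: 0.50
  subtest_accuracies:
    prospective: 0.15
    item_recall: 0.44
    place_recall: 0.56
    recognition: 0.78
    matching: 0.11

AD:
  base_speed_mps: 0.55
  heading_noise_sd_rad: 0.65
  detour_prob: 0.75
  detour_length_m: 0.1464
  pause_rate_per_s: 0.356
  pause_duration_mean_s: 10.3313
  wrong_target_prob: 0.35
  subtest_accuracies:
    prospective: 0.08
    item_recall: 0.22
    place_recall: 0.33
    recognition: 0.56
    matching: 0.11
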