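# Default generator settings: three hyperkinetic movement-disorder sway
# phenotypes and the reference cohort design.
#
# Phenotype parameters were calibrated by simulation so that the group
# orderings of the extracted features reproduce the qualitative contrasts
# the analysis is meant to detect:
#   chorea < dystonia on MD_AP, RMS_AP, VEL_AP
#   chorea > dystonia on FREQ_COP, FREQ_ML
#   chorea_dystonia > dystonia on VEL_AP, FREQ_ML
# Dystonia: slow, wide postural drift (low mean-reversion, high diffusion);
# chorea: rapid, small, irregular sway (fast reversion, fast oscillation,
# frequent jerks); chorea_dystonia: intermediate amplitude driven at high
# velocity.
phenotypes:
  dystonia:
    ou_theta: 0.3        # 1/s, mean-reversion rate of the postural drift
    ou_sigma_ap: 12.0    # mm/sqrt(s), AP diffusion scale
    ou_sigma_ml: 9.0
    osc_amp: 6.0         # mm, deterministic oscillation amplitude
    osc_freq_band: [0.2, 0.6]   # Hz, per-trial oscillation frequency range
    jerk_rate: 0.2       # events/s, Poisson rate of brief excursions
    jerk_amp: 8.0        # mm, jerk pulse height
  chorea:
    ou_theta: 1.5
    ou_sigma_ap: 6.0
    ou_sigma_ml: 5.0
    osc_amp: 2.5
    osc_freq_band: [1.0, 2.5]
    jerk_rate: 1.5
    jerk_amp: 4.0
  chorea_dystonia:
    ou_theta: 2.5
    ou_sigma_ap: 16.0
    ou_sigma_ml: 13.0
    osc_amp: 4.0
    osc_freq_band: [0.8, 2.0]
    jerk_rate: 1.0
    jerk_amp: 6.0

design:
  n_per_group:           # study cohort composition
    dystonia: 6
    chorea: 5
    chorea_dystonia: 5
  n_trials: 6            # repetitions of the 60-s quiet-standing trial
  duration_s: 60.0
  fs: 50.0               # Hz, platform sampling rate assumed for fixtures
  age_mean: 10.68        # years
  age_sd: 3.62
  age_range: [4.29, 18.22]
  therapy_probability:   # fraction of each group on pharmacological therapy
    dystonia: 0.3333333333333333    # 2 of 6
    chorea: 0.8                     # 4 of 5
    chorea_dystonia: 0.4            # 2 of 5
  subject_sd: 0.2        # sd of the per-subject log-amplitude intercept
  age_slope: -0.02       # per year, log-amplitude slope (sway shrinks with age)
  therapy_effect: -0.15  # log-amplitude shift while on therapy
  seed: 0
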