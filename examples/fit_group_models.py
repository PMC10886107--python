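"""Fit the per-outcome linear mixed models on a synthetic cohort.

Simulates a 60-subject cohort (the 6/5/5 composition scaled up for
power), extracts features, screens outliers and fits
``y ~ group * (age + therapy) + age:therapy + (1 | subject)`` per
outcome, then prints the main-effects report for the contrasts the
generator plants.
"""

import pandas as pd

from copsway import SimulationDesign, analyze_all, simulate_cohort
from copsway.io import features_from_trials, join_features_metadata

design = SimulationDesign(
    n_per_group={"dystonia": 22, "chorea": 19, "chorea_dystonia": 19},
    seed=1)
trials, truth = simulate_cohort(design)
features = features_from_trials(trials)
metadata = pd.DataFrame([
    {"subject_id": t.subject_id, "group": t.group,
     "age_years": t.age_years, "therapy": t.therapy,
     "trial_id": t.trial_id} for t in trials])
table = join_features_metadata(features, metadata)

outcomes = ["MD_AP", "RMS_AP", "VEL_AP", "FREQ_COP", "FREQ_ML"]
results = analyze_all(table, outcomes=outcomes)

main = results.main_effects()
contrasts = main[main["term"].str.contains("_vs_")]
print(f"{design.n_subjects} subjects, {len(table)} trials; "
      "group contrasts vs the dystonia reference:\n")
print(contrasts.round(4).to_string(index=False))

print("\nNegative chorea-vs-dystonia estimates on MD_AP/RMS_AP/VEL_AP "
      "(chorea sways less in AP) and positive ones on FREQ_COP/FREQ_ML "
      "(chorea rotates faster), with the mixed group faster and "
      "higher-velocity than dystonia, reproduce the planted phenotype "
      "directions; 'significant' marks p < 0.05 (Wald z).")
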