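"""Run the whole study pipeline with one call.

simulate → extract → screen → model, writing every artifact (trial CSVs,
features table, main-effects/interactions/outlier reports, provenance)
into one directory. Re-running with the same seed reproduces every file
byte-for-byte.
"""

import json
import tempfile
from pathlib import Path

from copsway import RunConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "study"
    config = RunConfig(out_dir=str(out), seed=0)
    report = run_pipeline(config)

    print(f"pipeline ok: {report.ok}")
    print(f"trials generated:  {report.n_trials} "
          f"({report.n_subjects} subjects)")
    print(f"outcomes modelled: {report.n_outcomes_modelled} "
          f"({report.n_converged} converged)")
    print(f"config digest:     {report.config_digest}")
    print("\noutliers excluded per outcome:")
    print(json.dumps(report.outliers_per_outcome, indent=2))
    print("\nartifacts written:")
    for f in sorted(out.iterdir()):
        print(f"  {f.name}")

print("\nThe report's counts tie the stages together: 16 subjects x 6 "
      "trials = 96 trials in, 16 outcome models out, each preceded by "
      "its own outlier screen.")
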