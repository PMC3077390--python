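#!/usr/bin/env python
"""Generate the synthetic study cohort.

Writes per-subject 4D DWI volumes (16 volumes: 1 baseline + 15 directions
at b = 800 s/mm^2), FSL-style gradient files, the subject covariate table
and the ground-truth JSON under results/study/cohort/.
"""

import pandas as pd

from _common import study_config
from limbictract.pipeline import run_simulate


def main() -> None:
    cfg = study_config()
    cohort_dir = run_simulate(cfg)
    subjects = pd.read_csv(cohort_dir / "subjects.csv")
    counts = subjects["group"].value_counts()
    print(f"cohort written to {cohort_dir}")
    print(f"subjects: {counts['control']} controls, {counts['patient']} patients")
    print(subjects.groupby("group")[["age", "education", "duration"]]
          .mean().round(1).to_string())


if __name__ == "__main__":
    main()
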