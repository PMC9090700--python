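"""Apply the trial exclusion cascade to the simulated study.

Removes, in order: trials with an error in either sub-task, trials whose
RT1 or RT2 lies beyond 3 SD of the participant x SOA cell, and trials with
an inter-response interval under 100 ms.  Participant screening flags are
reported but nobody is dropped.

Input:  results/study_trials.csv   (from 01_simulate_study.py)
Output: results/clean_trials.csv, results/exclusions.json
"""

import json
import sys
from pathlib import Path

from prp_introspect.io import read_trials
from prp_introspect.preprocess import run_cascade


def main() -> None:
    res = Path(__file__).resolve().parents[1] / "results"
    trials = read_trials(res / "study_trials.csv")
    clean, report = run_cascade(trials)
    clean.to_csv(res / "clean_trials.csv", index=False)
    with open(res / "exclusions.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    print(f"errors:      {report.pct_errors:.2f}% of all trials")
    print(f"RT outliers: {report.pct_rt_outliers:.2f}% of correct trials")
    print(f"grouped:     {report.pct_grouped:.2f}% of remaining trials")
    print(f"unmoved/degenerate reports still present: {report.n_degenerate_markers}")
    print(f"participants flagged: {report.participants_flagged or 'none'}")
    print(f"kept {report.n_output}/{report.n_input} trials")


if __name__ == "__main__":
    sys.exit(main())
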