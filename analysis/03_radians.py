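"""Compute the single-trial radian statistics.

For every clean trial: the objective radian (slope of the line through the
encoded true event times), the introspective radian (same line through the
placed markers), their absolute difference ∆rad — the per-trial measure of
introspective inaccuracy — and the central gap |t_S2 - t_R1|.

Input:  results/clean_trials.csv
Output: results/radians.csv
"""

import sys
from pathlib import Path

from prp_introspect.io import read_trials
from prp_introspect.radians import add_radian_columns


def main() -> None:
    res = Path(__file__).resolve().parents[1] / "results"
    trials = read_trials(res / "clean_trials.csv")
    rad = add_radian_columns(trials)
    rad.to_csv(res / "radians.csv", index=False)
    print(f"{int(rad['degenerate'].sum())} degenerate reports (all markers coincide)")
    for order, sub in rad.groupby("modality_order"):
        print(
            f"{order}: mean ∆rad {sub['delta_rad'].mean():.3f} "
            f"(short SOA {sub.loc[sub.soa == 50, 'delta_rad'].mean():.3f}, "
            f"long SOA {sub.loc[sub.soa == 1250, 'delta_rad'].mean():.3f})"
        )


if __name__ == "__main__":
    sys.exit(main())
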