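#!/usr/bin/env python
"""Molecular progression definitions versus imaging.

Matches plasma timepoints to restaging scans (±30 days, one-to-one), applies
the pseudoprogression and baseline-undetected exclusions, and scores the
full rule grid (any rise, rise >0.01, eVAF_75/50/25/10%, combined) against
the radiologist's adjudication in the measurable and complete populations.
Also reports the best-response ΔeVAF/Δdiameter Spearman correlation.
Writes results/progression_performance.csv.
"""

from pathlib import Path

from ctdnamon import (best_response_correlation, classify_cohort,
                      matched_pairs_with_exclusions, performance_table,
                      read_cohort)

ROOT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    trajs = classify_cohort(cohort)
    pairs = matched_pairs_with_exclusions(cohort, trajs)
    n_excl = sum(p.excluded for p in pairs)
    print(f"{len(pairs)} matched plasma/scan pairs "
          f"({n_excl} excluded: pseudoprogression or baseline-undetected)")

    table = performance_table(pairs)
    out = ROOT / "progression_performance.csv"
    table.to_csv(out, index=False)
    show = table[table.population == "all"][
        ["rule", "sensitivity", "specificity", "ppv", "npv", "accuracy",
         "c_index", "flagged_fraction"]]
    print(show.to_string(index=False,
                         float_format=lambda v: f"{v:.2f}"))

    corr = best_response_correlation(cohort, trajs)
    print(f"best-response correlation: rho {corr.rho:.2f} "
          f"(n={corr.n}, p={corr.p_value:.2g})")
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
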