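#!/usr/bin/env python
"""Generate the working synthetic cohort.

Emits a 50-patient study-conditions cohort (serial plasma eVAF, restaging
scans, outcomes) plus its latent truth table under results/cohort/.  All
downstream analysis scripts read these tables, so the whole analysis is
reproducible from this single seed.
"""

from pathlib import Path

from ctdnamon import validate_cohort, write_cohort
from ctdnamon.simulate import generate, scenario

SEED = 7
N_PATIENTS = 50
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main() -> None:
    cohort, truth = generate(scenario("study_like", n_patients=N_PATIENTS,
                                      seed=SEED))
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, OUT)
    truth.to_csv(OUT / "truth.csv", index=False)

    issues = validate_cohort(cohort)
    errors = [i for i in issues if i.level == "error"]
    print(f"cohort: {len(cohort.patients)} patients, "
          f"{len(cohort.samples)} plasma samples, {len(cohort.scans)} scans")
    print(f"validation: {len(errors)} errors, "
          f"{len(issues) - len(errors)} warnings")
    for i in issues:
        print(f"  {i.level}: {i.message}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
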