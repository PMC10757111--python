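#!/usr/bin/env python
"""Generate the working synthetic cohort.

Writes a 49-patient newly-diagnosed-myeloma-like cohort (variants, clinical
covariates, ground truth) plus a 200-patient cohort used for the
coupling-recovery checks, under scratch/cohort/ (regenerated on demand;
only the small summary tables under results/ are kept).
"""

from pathlib import Path

import pandas as pd

from mmith.io_variants import write_variant_table
from mmith.synthetic_cohort import CohortSpec, simulate_cohort

OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def write_cohort(n: int, seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    profiles, truth = simulate_cohort(CohortSpec(n_patients=n, seed=seed))
    write_variant_table([v for p in profiles for v in p.variants], out / "variants.tsv")
    pd.DataFrame(
        [
            {"patient_id": p.patient_id, "disease_stage": p.disease_stage.value,
             "iss": p.iss_stage, "age": p.age, "gender": p.gender.value,
             "ecog": p.ecog, "fish_high_risk": int(p.fish_high_risk),
             "hyperdiploid": int(p.hyperdiploid), "light_chain": p.light_chain.value,
             "pfs_months": p.pfs_months, "pfs_event": int(p.pfs_event),
             "best_response": p.best_response,
             "hla_alleles": ";".join(p.hla_alleles),
             **p.lymphocyte_fractions}
            for p in profiles
        ]
    ).to_csv(out / "clinical.csv", index=False)
    truth.to_csv(out / "ground_truth.csv", index=False)
    n_var = sum(len(p.variants) for p in profiles)
    print(f"{out.name}: {n} patients, {n_var} somatic variants, "
          f"median true MATH {truth['true_math'].median():.1f}, "
          f"median NAL {truth['nal'].median():.0f}, "
          f"event rate {truth['pfs_event'].mean():.2f}")


if __name__ == "__main__":
    write_cohort(49, seed=1, out=OUT / "n49")
    write_cohort(200, seed=1, out=OUT / "n200")
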