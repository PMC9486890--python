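#!/usr/bin/env python
"""Generate the synthetic study data every later step consumes.

Writes a serology cohort (patients + controls) and a paired tumour/blood
B-cell repertoire with embeddings and label-transfer scores under
results/data/.
"""

from pathlib import Path

from seroclone import (CohortConfig, RepertoireConfig, io,
                       simulate_repertoire, simulate_serology_cohort)

SEED = 2026
DATA = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    samples, controls = simulate_serology_cohort(CohortConfig(seed=SEED))
    io.write_serology(samples, DATA / "serology_samples.csv", seed=SEED)
    io.write_serology(controls, DATA / "serology_controls.csv", seed=SEED)

    rep = simulate_repertoire(RepertoireConfig(seed=SEED + 1))
    io.write_repertoire(rep.cells, DATA / "repertoire_cells.tsv", seed=SEED + 1)
    rep.scores.to_csv(DATA / "label_transfer_scores.csv", index=False)

    n_ot = samples.groupby("patient_id")["ot_status"].first().eq("OT").sum()
    print(f"cohort: {samples['patient_id'].nunique()} patients "
          f"({n_ot} with ovarian teratoma), {len(samples)} samples, "
          f"{len(controls)} control sera")
    print(f"repertoire: {len(rep.cells)} cells "
          f"({(rep.cells.tissue == 'tumour').sum()} tumour, "
          f"{(rep.cells.tissue == 'blood').sum()} blood)")


if __name__ == "__main__":
    main()
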