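#!/usr/bin/env python
"""Simulate the default study cohort.

Generates a synthetic adenosine first-pass perfusion cohort — 38 post-CABG
patients (native + graft territories, LGE flags) and 20 no-CAD patients
(three native territories each) — and writes the raw exchange files
(curves CSV, territory JSON, ground truth) under ``scratch/cohort``.
The raw curves are bulky and regenerable, hence scratch; the downstream
scripts read them from there.
"""

from pathlib import Path

from perfcmr.io import FLOAT_FMT, write_cohort
from perfcmr.simulate import CohortSpec, simulate_cohort

SEED = 1234
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main() -> None:
    spec = CohortSpec()
    sim = simulate_cohort(spec, SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    paths = write_cohort(sim.patients, OUT)
    sim.truth.to_csv(OUT / "ground_truth.csv", index=False, float_format=FLOAT_FMT)
    sim.patient_truth.to_csv(OUT / "ground_truth_patients.csv", index=False,
                             float_format=FLOAT_FMT)
    n_cabg = sum(p.group == "cabg" for p in sim.patients)
    n_terr = sum(len(p.territories) for p in sim.patients)
    n_grafts = int((sim.truth.supply_kind != "native").sum())
    print(f"seed {SEED}: {len(sim.patients)} patients ({n_cabg} CABG), "
          f"{n_terr} territories ({n_grafts} graft territories)")
    print(f"wrote {paths['curves']} and {paths['territories']}")


if __name__ == "__main__":
    main()
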