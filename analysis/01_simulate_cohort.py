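"""Simulate the study cohort: 9 control / 15 treated centroid LC-MS runs,
200 metabolites (10 discriminating at 8-fold, balanced up/down), chemical
noise and sodium adducts.  Writes the runs (run-csv + manifest) and the
ground-truth catalog under scratch/cohort/ and prints a design summary.

Usage: python analysis/01_simulate_cohort.py [seed]
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from metabosense import build_design, generate_cohort, write_runs

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "cohort"


def main():
    design = build_design(seed=SEED)
    runs, truth = generate_cohort(design)
    manifest = write_runs(runs, OUT, fmt="run-csv")
    truth.to_json(OUT / "ground_truth.json")
    n_adducts = sum(1 for e in truth.catalog if e.adduct_of is not None)
    print(f"cohort: {design.n_control} control + {design.n_treated} treated runs")
    print(f"catalog: {len(truth.catalog)} ion species "
          f"({design.n_discriminating_metabolites} discriminating metabolites, "
          f"{n_adducts} Na adducts)")
    print(f"ions per run: {runs[0].n_ions()} "
          f"({len(runs[0].scans)} scans, {design.scan_interval} min interval)")
    print(f"wrote {manifest}")


if __name__ == "__main__":
    main()
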