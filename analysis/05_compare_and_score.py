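"""Compare the discriminating-variable sets across processing parameter sets
and pre-treatments (Venn regions, Jaccard), and score every cell's selection
against the planted ground truth.

Reads the selection evidence written by steps 03/04 and writes
results/comparison.json plus a short Markdown digest.  The qualitative
finding to reproduce: all cells share a common core of variables, several
cells contribute unique ones, and recovery of the planted discriminators
depends on the upstream choices.
"""

import json
import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from metabosense.pipeline import compare_methods, evaluate_against_truth
from metabosense.select import FeatureSelectionResult, SelectionCriteria
from metabosense.synthetic import GroundTruth

COHORT = ROOT / "scratch" / "cohort"
TABLES = ROOT / "scratch" / "tables"
RESULTS = ROOT / "results"


def load_selection(path: Path, label: str):
    ev = pd.read_csv(path, comment="#", index_col="feature_id")
    res = FeatureSelectionResult(
        method_label=label,
        selected=list(ev.index[ev.selected]),
        candidates=list(ev.index[ev.candidate]),
        evidence=ev, criteria=SelectionCriteria())
    meta = ev[["rt", "mz"]]
    return res, meta


def main():
    truth = GroundTruth.from_json(COHORT / "ground_truth.json")
    selections, metas, labels = [], [], []
    for path in sorted(TABLES.glob("selection_*.csv")):
        label = path.stem.replace("selection_", "")
        res, meta = load_selection(path, label)
        selections.append(res)
        metas.append(meta)
        labels.append(label)
    comp = compare_methods(selections, metas)
    recovery = {lbl: vars(evaluate_against_truth(res, meta, truth))
                for lbl, res, meta in zip(labels, selections, metas)}
    payload = {
        "labels": labels,
        "jaccard": comp.jaccard.round(3).to_dict(),
        "core_size": comp.core_size(),
        "universe_size": comp.universe_size,
        "unique_counts": comp.unique_counts,
        "venn_regions": {"".join("1" if b else "0" for b in k): v
                         for k, v in comp.venn.items()},
        "recovery": recovery,
    }
    RESULTS.mkdir(exist_ok=True)
    with open(RESULTS / "comparison.json", "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
    lines = ["# Feature-set comparison", "",
             f"- {len(labels)} grid cells, matched universe of "
             f"{comp.universe_size} variables",
             f"- common core: {comp.core_size()} variables",
             f"- cells with unique variables: "
             f"{[l for l, c in comp.unique_counts.items() if c]}", "",
             "## Recovery vs planted truth", ""]
    for lbl in labels:
        r = recovery[lbl]
        lines.append(f"- {lbl}: sensitivity {r['sensitivity']:.1f} "
                     f"({r['n_recovered']}/{r['n_planted']}), "
                     f"false selections {r['n_false']}")
    (RESULTS / "comparison.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
    print("\n".join(lines))
    print(f"\nwrote {RESULTS / 'comparison.json'}")


if __name__ == "__main__":
    main()
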