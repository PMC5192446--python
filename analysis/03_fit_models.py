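"""Chemometric models of the four matrices under the study's standard
pre-treatment (Pareto scaling, no transformation).

For each matrix: missing-value filtering, Pareto scaling, cross-validated
NIPALS PCA, OPLS-DA with CV-chosen orthogonal components, and the validation
battery (Hotelling's T2, DModX, CV-ANOVA, 50-permutation response test).
Writes results/table_models.csv with one row per matrix.

What to look for: the models' goodness of fit (R2X) and predictive power
(Q2) shift with the processing parameters even though the underlying raw
data are identical.
"""

import sys
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from metabosense import read_runs
from metabosense.peaks import METHOD_PRESETS, FeatureTable, ProcessingParams
from metabosense.pipeline import run_method
from metabosense.pretreat import PretreatmentSpec
from metabosense.synthetic import GroundTruth

COHORT = ROOT / "scratch" / "cohort"
TABLES = ROOT / "scratch" / "tables"
RESULTS = ROOT / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main():
    runs = read_runs(COHORT / "manifest.csv")
    truth = GroundTruth.from_json(COHORT / "ground_truth.json")
    spec = PretreatmentSpec(scaling="pareto")
    rows = []
    for name, (tol, thr) in METHOD_PRESETS.items():
        table = FeatureTable.from_csv(TABLES / f"{name.replace(' ', '_').lower()}.csv")
        params = ProcessingParams(mass_tolerance=tol, intensity_threshold=thr)
        r = run_method(runs, params, spec, truth=truth, label=name, table=table,
                       n_permutations=50, permutation_seed=SEED)
        perm = r.validation.permutation
        rows.append({
            "method": name,
            "pca_components": r.pca_n_components,
            "pca_r2x_cum": round(r.pca_r2x_cum, 3),
            "pca_q2_cum": round(r.pca_q2_cum, 3),
            "oplsda_r2x_cum": round(r.oplsda_r2x_cum, 3),
            "oplsda_r2y_cum": round(r.oplsda_r2y, 3),
            "oplsda_q2_cum": round(r.oplsda_q2, 3),
            "cv_anova_p": f"{r.validation.cv_anova.p:.3g}",
            "perm_r2_intercept": round(perm.r2_intercept, 3),
            "perm_q2_intercept": round(perm.q2_intercept, 3),
            "model_trusted": r.selection.model_trusted,
            "selected_features": len(r.selection.selected),
        })
        print(f"{name}: R2Y={rows[-1]['oplsda_r2y_cum']} Q2={rows[-1]['oplsda_q2_cum']} "
              f"perm intercepts ({rows[-1]['perm_r2_intercept']}, "
              f"{rows[-1]['perm_q2_intercept']})")
        # persist the per-method selection evidence for step 05
        from metabosense.select import selection_to_csv
        selection_to_csv(r.selection, table,
                         TABLES / f"selection_{name.replace(' ', '_').lower()}.csv")
    pd.DataFrame(rows).to_csv(RESULTS / "table_models.csv", index=False)
    print(f"\nwrote {RESULTS / 'table_models.csv'}")


if __name__ == "__main__":
    main()
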