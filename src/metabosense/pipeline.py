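"""The sensitivity experiment: run the full pipeline over a grid of
pre-processing parameter sets ("Methods", varying mass tolerance and intensity
threshold) and pre-treatment combinations (scaling x transformation), compare
the selected feature sets, and score recovery against the planted truth."""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .synthetic import CentroidRun, GroundTruth, SyntheticDesign, build_design, generate_cohort
from .peaks import (METHOD_PRESETS, FeatureTable, ProcessingParams,
                    build_feature_table)
from .pretreat import PretreatmentSpec, pretreat
from .models import fit_oplsda, fit_pca_retained
from .validate import ValidationReport, cv_anova, dmodx, hotelling_t2, permutation_test
from .select import (FeatureSelectionResult, SelectionCriteria, select_features)

log = logging.getLogger(__name__)

# the pre-treatment grid of the scaling/transformation experiment
PRETREATMENT_GRID = [
    ("none", "none"), ("center", "none"), ("uv", "none"), ("pareto", "none"),
    ("uv", "log"), ("pareto", "log"), ("uv", "power"), ("pareto", "power"),
]


@dataclass
class MethodResult:
    label: str
    processing: ProcessingParams
    pretreatment: PretreatmentSpec
    n_features: int
    missing_fraction: float
    noise_fraction: Optional[float]
    pca_n_components: int
    pca_r2x_cum: float
    pca_q2_cum: float
    oplsda_n_ortho: int
    oplsda_r2x_cum: float
    oplsda_r2y: float
    oplsda_q2: float
    validation: ValidationReport
    selection: FeatureSelectionResult
    feature_meta: pd.DataFrame  # rt/mz of the modeled features

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "mass_tolerance": self.processing.mass_tolerance,
            "intensity_threshold": self.processing.intensity_threshold,
            "scaling": self.pretreatment.scaling,
            "transform": self.pretreatment.transform,
            "n_features": self.n_features,
            "missing_fraction": round(self.missing_fraction, 6),
            "noise_fraction": None if self.noise_fraction is None else round(self.noise_fraction, 6),
            "pca_n_components": self.pca_n_components,
            "pca_r2x_cum": round(self.pca_r2x_cum, 4),
            "pca_q2_cum": round(self.pca_q2_cum, 4),
            "oplsda_n_ortho": self.oplsda_n_ortho,
            "oplsda_r2x_cum": round(self.oplsda_r2x_cum, 4),
            "oplsda_r2y": round(self.oplsda_r2y, 4),
            "oplsda_q2": round(self.oplsda_q2, 4),
            "n_selected": len(self.selection.selected),
            **self.validation.to_dict(),
        }


def run_method(runs: Sequence[CentroidRun], processing: ProcessingParams,
               pretreatment: PretreatmentSpec,
               truth: Optional[GroundTruth] = None,
               label: str = "",
               table: Optional[FeatureTable] = None,
               criteria: SelectionCriteria = SelectionCriteria(),
               n_permutations: int = 50, permutation_seed: int = 0,
               max_pca_components: int = 10, max_ortho: int = 5) -> MethodResult:
    """Execute matrix creation -> pre-treatment -> PCA/OPLS-DA -> validation
    -> feature selection for one grid cell.  Deterministic for fixed inputs.

    A pre-built ``table`` may be supplied to share matrix creation between
    cells that differ only in pre-treatment.
    """
    stage = "matrix creation"
    try:
        if table is None:
            table = build_feature_table(runs, processing, truth=truth)
        raw_table = table
        stage = "pretreatment"
        pt = pretreat(table, pretreatment)
        stage = "PCA"
        pca, _cv = fit_pca_retained(pt, max_components=max_pca_components)
        stage = "OPLS-DA"
        opls = fit_oplsda(pt, max_ortho=max_ortho)
        stage = "validation"
        labels = [str(pt.groups.loc[s]) for s in opls.sample_ids]
        report = ValidationReport(
            hotelling=hotelling_t2(pca),
            dmodx=dmodx(pca),
            cv_anova=cv_anova(opls),
            permutation=permutation_test(pt, labels, n=n_permutations,
                                         seed=permutation_seed, max_ortho=max_ortho,
                                         model=opls))
        stage = "feature selection"
        selection = select_features(
            opls, pt, raw_table, criteria=criteria, method_label=label,
            cv_anova_valid=report.cv_anova.valid,
            permutation_valid=report.permutation.valid)
    except Exception as exc:
        raise RuntimeError(f"{label or 'method'}: failed at {stage}: {exc}") from exc
    return MethodResult(
        label=label, processing=processing, pretreatment=pretreatment,
        n_features=raw_table.n_features,
        missing_fraction=raw_table.missing_fraction(),
        noise_fraction=raw_table.noise_fraction(),
        pca_n_components=pca.n_components,
        pca_r2x_cum=pca.r2x_cum[-1],
        pca_q2_cum=pca.q2_cum[-1] if pca.q2_cum else float("nan"),
        oplsda_n_ortho=opls.n_ortho,
        oplsda_r2x_cum=opls.r2x_cum, oplsda_r2y=opls.r2y, oplsda_q2=opls.q2,
        validation=report, selection=selection,
        feature_meta=raw_table.feature_meta)


# --------------------------------------------------------- set comparison --

@dataclass
class MethodComparison:
    labels: list[str]
    jaccard: pd.DataFrame
    venn: dict[tuple[bool, ...], int]  # membership pattern -> universe count
    unique_counts: dict[str, int]
    universe_size: int

    def core_size(self) -> int:
        return self.venn.get(tuple([True] * len(self.labels)), 0)

    def n_unique_regions(self) -> int:
        return sum(1 for lbl, c in self.unique_counts.items() if c > 0)


def _match_features(selections: Sequence[tuple[str, list[tuple[str, float, float]]]],
                    mz_window: float, rt_window: float) -> list[set[int]]:
    """Cluster (rt, mz) features across methods into a shared universe.

    Greedy nearest-centroid clustering within the alignment windows; returns
    one membership set (universe ids) per method.
    """
    clusters: list[list[float]] = []  # [rt, mz, weight]
    memberships: list[set[int]] = []
    for _label, feats in selections:
        mem: set[int] = set()
        for (_fid, rt, mz) in sorted(feats, key=lambda f: (f[2], f[1])):
            best = None
            for ci, (crt, cmz, _w) in enumerate(clusters):
                if abs(crt - rt) <= rt_window and abs(cmz - mz) <= mz_window:
                    d = ((cmz - mz) / mz_window) ** 2 + ((crt - rt) / rt_window) ** 2
                    if best is None or d < best[0]:
                        best = (d, ci)
            if best is None:
                clusters.append([rt, mz, 1.0])
                mem.add(len(clusters) - 1)
            else:
                ci = best[1]
                crt, cmz, w = clusters[ci]
                clusters[ci] = [(crt * w + rt) / (w + 1), (cmz * w + mz) / (w + 1), w + 1]
                mem.add(ci)
        memberships.append(mem)
    return memberships


def compare_methods(results: Sequence[FeatureSelectionResult],
                    metas: Sequence[pd.DataFrame],
                    mz_window: float = 0.05, rt_window: float = 0.20,
                    use_candidates: bool = True) -> MethodComparison:
    """Cross-method overlap of selected feature sets.

    Feature identities are matched across methods by Rt/m/z proximity (methods
    differ in mass tolerance, so label equality is not sufficient), then the
    Jaccard matrix and the full Venn-region decomposition are computed.

    By default the comparison is over the S-plot + VIP candidate sets (the
    variables the per-model statistics put forward), before the per-variable
    dot-plot confirmation.
    """
    sel_feats = []
    for res, meta in zip(results, metas):
        ids = res.candidates if use_candidates else res.selected
        feats = [(fid, float(meta.rt.loc[fid]), float(meta.mz.loc[fid]))
                 for fid in ids]
        sel_feats.append((res.method_label, feats))
    memberships = _match_features(sel_feats, mz_window, rt_window)
    labels = [r.method_label for r in results]
    universe = set().union(*memberships) if memberships else set()
    venn: dict[tuple[bool, ...], int] = {}
    for u in universe:
        pattern = tuple(u in m for m in memberships)
        venn[pattern] = venn.get(pattern, 0) + 1
    n = len(labels)
    jac = np.eye(n)
    for i, j in itertools.combinations(range(n), 2):
        a, b = memberships[i], memberships[j]
        denom = len(a | b)
        jac[i, j] = jac[j, i] = (len(a & b) / denom) if denom else 1.0
    unique = {}
    for i, lbl in enumerate(labels):
        pattern = tuple(k == i for k in range(n))
        unique[lbl] = venn.get(pattern, 0)
    return MethodComparison(labels=labels,
                            jaccard=pd.DataFrame(jac, index=labels, columns=labels),
                            venn=venn, unique_counts=unique,
                            universe_size=len(universe))


@dataclass
class RecoveryMetrics:
    sensitivity: float
    false_discovery_fraction: Optional[float]
    n_recovered: int
    n_planted: int
    n_selected: int
    n_false: int


def evaluate_against_truth(selection: FeatureSelectionResult, meta: pd.DataFrame,
                           truth: GroundTruth,
                           mz_window: float = 0.05, rt_window: float = 0.20) -> RecoveryMetrics:
    """Recovery of planted discriminating metabolites by the selection.

    A selected feature matching a discriminating catalog entry (or its adduct)
    counts toward that parent metabolite; selected features matching no
    discriminating entry are false discoveries.
    """
    planted = truth.discriminating_ids()
    recovered: set[str] = set()
    n_false = 0
    dis_entries = [e for e in truth.catalog if e.is_discriminating]
    for fid in selection.selected:
        rt, mz = float(meta.rt.loc[fid]), float(meta.mz.loc[fid])
        hit = None
        for e in dis_entries:
            if abs(e.rt_center - rt) <= rt_window and abs(e.mz_center - mz) <= mz_window:
                hit = e
                break
        if hit is None:
            n_false += 1
        else:
            recovered.add(hit.adduct_of or hit.id)
    n_sel = len(selection.selected)
    return RecoveryMetrics(
        sensitivity=len(recovered) / len(planted) if planted else float("nan"),
        false_discovery_fraction=(n_false / n_sel) if n_sel else None,
        n_recovered=len(recovered), n_planted=len(planted),
        n_selected=n_sel, n_false=n_false)


# ----------------------------------------------------------- experiment --

DEFAULT_CONFIG = {
    "design": {},  # overrides for SyntheticDesign
    "methods": {name: {"mass_tolerance": mt, "intensity_threshold": it}
                for name, (mt, it) in METHOD_PRESETS.items()},
    "method_pretreatment": {"scaling": "pareto", "transform": "none"},
    "pretreatment_grid": [{"scaling": s, "transform": t} for s, t in PRETREATMENT_GRID],
    "pretreatment_method": "Method 1",
    "n_permutations": 50,
    "seed": 0,
}


@dataclass
class ExperimentReport:
    method_results: dict[str, MethodResult]
    pretreatment_results: dict[str, MethodResult]
    method_comparison: Optional[MethodComparison]
    pretreatment_comparison: Optional[MethodComparison]
    recovery: dict[str, RecoveryMetrics]
    failures: dict[str, str]
    truth: Optional[GroundTruth] = None


def run_experiment(config: Optional[dict | str | Path] = None,
                   runs: Optional[Sequence[CentroidRun]] = None,
                   truth: Optional[GroundTruth] = None,
                   out_dir: Optional[str | Path] = None) -> ExperimentReport:
    """Run the full sensitivity grid.

    Default grid: the four processing Methods under Pareto/no-transform, plus
    the eight scaling/transformation combinations under Method-1 processing
    (12 cells).  A failing cell is recorded, not fatal.  Deterministic under a
    fixed seed.
    """
    if isinstance(config, (str, Path)):
        with open(config, encoding="utf-8") as fh:
            config = yaml.safe_load(fh)
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    seed = int(cfg.get("seed", 0))
    if runs is None:
        design = build_design(**{"seed": seed, **cfg["design"]})
        runs, truth = generate_cohort(design)
    mp = cfg["method_pretreatment"]
    base_spec = PretreatmentSpec(scaling=mp["scaling"], transform=mp["transform"])
    n_perm = int(cfg["n_permutations"])

    tables: dict[str, FeatureTable] = {}
    method_results: dict[str, MethodResult] = {}
    failures: dict[str, str] = {}
    for name, p in cfg["methods"].items():
        params = ProcessingParams(mass_tolerance=p["mass_tolerance"],
                                  intensity_threshold=p["intensity_threshold"])
        try:
            tables[name] = build_feature_table(runs, params, truth=truth)
            method_results[name] = run_method(
                runs, params, base_spec, truth=truth, label=name,
                table=tables[name], n_permutations=n_perm, permutation_seed=seed)
        except Exception as exc:
            failures[name] = str(exc)
            log.error("grid cell %s failed: %s", name, exc)

    pre_method = cfg["pretreatment_method"]
    pre_results: dict[str, MethodResult] = {}
    if pre_method in tables:
        params = ProcessingParams(**cfg["methods"][pre_method] | {})
        for sp in cfg["pretreatment_grid"]:
            spec = PretreatmentSpec(scaling=sp["scaling"], transform=sp["transform"])
            label = f"{pre_method}:{spec.label}"
            try:
                pre_results[label] = run_method(
                    runs, params, spec, truth=truth, label=label,
                    table=tables[pre_method], n_permutations=n_perm,
                    permutation_seed=seed)
            except Exception as exc:
                failures[label] = str(exc)
                log.error("grid cell %s failed: %s", label, exc)

    def _compare(results: dict[str, MethodResult]) -> Optional[MethodComparison]:
        if len(results) < 2:
            return None
        return compare_methods([r.selection for r in results.values()],
                               [r.feature_meta for r in results.values()])

    recovery = {}
    if truth is not None:
        for label, r in {**method_results, **pre_results}.items():
            recovery[label] = evaluate_against_truth(r.selection, r.feature_meta, truth)

    report = ExperimentReport(
        method_results=method_results, pretreatment_results=pre_results,
        method_comparison=_compare(method_results),
        pretreatment_comparison=_compare(pre_results),
        recovery=recovery, failures=failures, truth=truth)
    if out_dir is not None:
        write_report(report, out_dir)
    return report


def write_report(report: ExperimentReport, out_dir: str | Path) -> None:
    """Write the report bundle: CSV tables, comparison JSON, Markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = [r.to_dict() for r in report.method_results.values()]
    if rows:
        pd.DataFrame(rows).to_csv(out / "methods.csv", index=False)
    rows = [r.to_dict() for r in report.pretreatment_results.values()]
    if rows:
        pd.DataFrame(rows).to_csv(out / "pretreatments.csv", index=False)
    comp = {}
    for key, c in (("methods", report.method_comparison),
                   ("pretreatments", report.pretreatment_comparison)):
        if c is None:
            continue
        comp[key] = {
            "labels": c.labels,
            "jaccard": c.jaccard.round(4).to_dict(),
            "venn_regions": {"".join("1" if b else "0" for b in k): v
                             for k, v in c.venn.items()},
            "unique_counts": c.unique_counts,
            "core_size": c.core_size(),
            "universe_size": c.universe_size,
        }
    if report.recovery:
        comp["recovery"] = {k: vars(v) for k, v in report.recovery.items()}
    if report.failures:
        comp["failures"] = report.failures
    with open(out / "comparison.json", "w", encoding="utf-8") as fh:
        json.dump(comp, fh, indent=1)
    lines = ["# Sensitivity experiment report", ""]
    if report.method_results:
        lines += ["## Processing methods (feature-count / noise sensitivity)", ""]
        for label, r in report.method_results.items():
            noise = "n/a" if r.noise_fraction is None else f"{100 * r.noise_fraction:.0f}%"
            lines.append(f"- {label}: {r.n_features} features, noise {noise}, "
                         f"PCA R2X(cum)={r.pca_r2x_cum:.3f} Q2={r.pca_q2_cum:.3f}; "
                         f"OPLS-DA R2Y={r.oplsda_r2y:.3f} Q2={r.oplsda_q2:.3f}, "
                         f"{len(r.selection.selected)} selected"
                         + ("" if r.selection.model_trusted else " [UNTRUSTED]"))
    if report.pretreatment_results:
        lines += ["", "## Pre-treatment grid", ""]
        for label, r in report.pretreatment_results.items():
            lines.append(f"- {label}: PCA R2X(cum)={r.pca_r2x_cum:.3f} Q2={r.pca_q2_cum:.3f}; "
                         f"OPLS-DA R2Y={r.oplsda_r2y:.3f} Q2={r.oplsda_q2:.3f}, "
                         f"CV-ANOVA p={r.validation.cv_anova.p:.2e}, "
                         f"{len(r.selection.selected)} selected"
                         + ("" if r.selection.model_trusted else " [UNTRUSTED]"))
    if report.failures:
        lines += ["", "## Failed cells", ""]
        lines += [f"- {k}: {v}" for k, v in report.failures.items()]
    (out / "report.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
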