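"""Discriminating-variable selection from a fitted OPLS-DA model.

The S-plot pairs each variable's covariance with the predictive score (p1,
model influence) with its correlation (p(corr)1, reliability); variables in
the far corners are candidates.  VIP summarizes importance across the
predictive and orthogonal components (mean VIP^2 = 1).  A dot-plot-style
range-overlap fraction on the normalized intensities provides the visual
"no overlap between groups" confirmation as a number.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .models import OPLSDAModel
from .peaks import FeatureTable
from .pretreat import PretreatedTable

log = logging.getLogger(__name__)


def splot(model: OPLSDAModel, table: PretreatedTable) -> pd.DataFrame:
    """S-plot coordinates on the pretreated matrix.

    p1_k = cov(t, x_k) over the cells observed in x_k (n-1 denominator);
    pcorr1_k = corr(t, x_k).  Zero-variance columns get missing pcorr1.
    """
    X = table.modeling_matrix().loc[model.sample_ids, model.feature_ids]
    t = model.t
    p1 = np.empty(X.shape[1])
    pcorr = np.empty(X.shape[1])
    Xv = X.to_numpy(float)
    for k in range(Xv.shape[1]):
        x = Xv[:, k]
        obs = ~np.isnan(x)
        n = obs.sum()
        if n < 2:
            p1[k], pcorr[k] = np.nan, np.nan
            continue
        ts, xs = t[obs], x[obs]
        tc, xc = ts - ts.mean(), xs - xs.mean()
        cov = float(tc @ xc) / (n - 1)
        sd_t = np.sqrt(float(tc @ tc) / (n - 1))
        sd_x = np.sqrt(float(xc @ xc) / (n - 1))
        p1[k] = cov
        pcorr[k] = cov / (sd_t * sd_x) if sd_t > 0 and sd_x > 0 else np.nan
    return pd.DataFrame({"p1": p1, "pcorr1": pcorr}, index=model.feature_ids)


def vip(model: OPLSDAModel) -> pd.Series:
    """Variable importance in projection over predictive + orthogonal
    components.  Component weights are the explained-Y share (predictive) and
    explained-X shares (orthogonal); sum of VIP^2 equals the number of
    variables."""
    K = len(model.w)
    # component weights are explained-variance *shares*: R2Y for the
    # predictive component, R2X share for each orthogonal one
    ssy_pred = model.r2y
    weights2 = (model.w / np.linalg.norm(model.w)) ** 2 * ssy_pred
    total = ssy_pred
    for j in range(model.n_ortho):
        w_o = model.W_o[:, j]
        share = model.r2x_ortho[j]
        weights2 = weights2 + (w_o / np.linalg.norm(w_o)) ** 2 * share
        total += share
    v = np.sqrt(K * weights2 / total)
    return pd.Series(v, index=model.feature_ids, name="vip")


def vip_predictive(model: OPLSDAModel) -> pd.Series:
    """Predictive-component-only VIP variant."""
    K = len(model.w)
    v = np.sqrt(K) * np.abs(model.w) / np.linalg.norm(model.w)
    return pd.Series(v, index=model.feature_ids, name="vip")


def group_overlap(table: FeatureTable, feature_id: str,
                  labels: Optional[Sequence[str]] = None) -> float:
    """Dot-plot surrogate: overlap of the two groups' observed [min, max]
    ranges as a fraction of their union range (0 = disjoint)."""
    col = table.values[feature_id]
    groups = table.groups if labels is None else pd.Series(list(labels), index=col.index)
    classes = sorted(groups.unique())
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(classes)}")
    ranges = []
    for c in classes:
        v = col[groups == c].dropna()
        if v.empty:
            raise ValueError(f"group {c} has no observed values for {feature_id}")
        ranges.append((float(v.min()), float(v.max())))
    (a0, a1), (b0, b1) = ranges
    inter = min(a1, b1) - max(a0, b0)
    union = max(a1, b1) - min(a0, b0)
    if union <= 0:  # both groups constant and equal
        return 1.0 if inter >= 0 else 0.0
    return max(inter, 0.0) / union


@dataclass(frozen=True)
class SelectionCriteria:
    """Defaults follow the full selection workflow: S-plot cutoffs, VIP above
    1, and the dot-plot confirmation that the groups' value ranges do not
    overlap."""

    p1_min: float = 0.05
    pcorr_min: float = 0.5
    vip_min: float = 1.0
    require_no_overlap: bool = True


@dataclass
class FeatureSelectionResult:
    method_label: str
    selected: list[str]  # after every criterion, incl. dot-plot confirmation
    candidates: list[str]  # S-plot + VIP stage only (pre dot-plot)
    evidence: pd.DataFrame  # p1, pcorr1, vip, overlap, selected per feature
    criteria: SelectionCriteria
    cv_anova_valid: Optional[bool] = None
    permutation_valid: Optional[bool] = None
    provenance: dict = field(default_factory=dict)

    @property
    def model_trusted(self) -> bool:
        flags = [f for f in (self.cv_anova_valid, self.permutation_valid) if f is not None]
        return all(flags) if flags else True


def select_features(model: OPLSDAModel, table: PretreatedTable,
                    raw_table: FeatureTable,
                    criteria: SelectionCriteria = SelectionCriteria(),
                    method_label: str = "",
                    cv_anova_valid: Optional[bool] = None,
                    permutation_valid: Optional[bool] = None) -> FeatureSelectionResult:
    """Conjunctive selection: |p1| >= p1_min and |pcorr1| >= pcorr_min and
    vip > vip_min (and, optionally, zero group overlap).  A warning is logged
    when the model failed its validity checks — such selections are untrusted.
    """
    sp = splot(model, table)
    v = vip(model)
    overlaps = {}
    for fid in model.feature_ids:
        try:
            overlaps[fid] = group_overlap(raw_table, fid)
        except (KeyError, ValueError):
            overlaps[fid] = np.nan
    ev = sp.copy()
    ev["vip"] = v
    ev["overlap"] = pd.Series(overlaps)
    cand = ((ev.p1.abs() >= criteria.p1_min)
            & (ev.pcorr1.abs() >= criteria.pcorr_min)
            & (ev.vip > criteria.vip_min)).fillna(False)
    sel = cand.copy()
    if criteria.require_no_overlap:
        sel &= ev.overlap == 0.0
    ev["candidate"] = cand
    ev["selected"] = sel.fillna(False)
    if cv_anova_valid is False or permutation_valid is False:
        log.warning("selection %s: model failed validity checks; "
                    "selected variables should not be trusted", method_label)
    return FeatureSelectionResult(
        method_label=method_label,
        selected=list(ev.index[ev.selected]),
        candidates=list(ev.index[ev.candidate]),
        evidence=ev, criteria=criteria,
        cv_anova_valid=cv_anova_valid, permutation_valid=permutation_valid)


def selection_to_csv(result: FeatureSelectionResult, raw_table: FeatureTable, path) -> None:
    """Selection CSV with '#'-prefixed provenance header lines."""
    meta = raw_table.feature_meta
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# method: {result.method_label}\n")
        fh.write(f"# criteria: |p1|>={result.criteria.p1_min} |pcorr1|>={result.criteria.pcorr_min} "
                 f"vip>{result.criteria.vip_min}\n")
        fh.write(f"# model_trusted: {result.model_trusted}\n")
        out = result.evidence.copy()
        out.insert(0, "mz", meta.mz.reindex(out.index))
        out.insert(0, "rt", meta.rt.reindex(out.index))
        out.index.name = "feature_id"
        out.to_csv(fh)
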