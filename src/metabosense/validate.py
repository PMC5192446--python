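"""Model diagnostics: Hotelling's T2 normality area, DModX moderate-outlier
detection, CV-ANOVA significance, and the response permutation test."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .models import (OPLSDAModel, PCAModel, PretreatedTable, encode_labels,
                     fit_oplsda)


@dataclass
class HotellingResult:
    t2: np.ndarray
    limit: float
    flagged: np.ndarray  # strong-outlier mask

    def flagged_fraction(self) -> float:
        return float(self.flagged.mean())


def _score_matrix(model: Union[PCAModel, OPLSDAModel]) -> np.ndarray:
    if isinstance(model, PCAModel):
        return model.scores
    return np.column_stack([model.t, model.T_o]) if model.n_ortho else model.t[:, None]


def hotelling_t2(model: Union[PCAModel, OPLSDAModel], alpha: float = 0.05) -> HotellingResult:
    """Per-observation T2 = sum_a t_ia^2 / s_a^2 with the F-based limit
    A(N-1)/(N-A) * F_{1-alpha}(A, N-A)."""
    T = _score_matrix(model)
    N, A = T.shape
    if N <= A:
        raise ValueError(f"need more observations ({N}) than components ({A})")
    s2 = T.var(axis=0, ddof=1)
    t2 = (T ** 2 / s2).sum(axis=1)
    limit = A * (N - 1) / (N - A) * stats.f.ppf(1 - alpha, A, N - A)
    return HotellingResult(t2=t2, limit=float(limit), flagged=t2 > limit)


@dataclass
class DModXResult:
    dmodx: np.ndarray  # normalized units of standard deviation
    dcrit: float
    flagged: np.ndarray  # moderate-outlier mask


def dmodx(model: Union[PCAModel, OPLSDAModel], alpha: float = 0.05) -> DModXResult:
    """Distance to the model in X-space, normalized by the pooled residual SD;
    Dcrit from the F distribution at the given significance level."""
    E = model.residuals
    N, K = E.shape
    if isinstance(model, PCAModel):
        A = model.n_components
    else:
        A = 1 + model.n_ortho
    if K <= A:
        raise ValueError(f"need more features ({K}) than components ({A})")
    ss_rows = np.nansum(E ** 2, axis=1)
    s_i = np.sqrt(ss_rows / (K - A))
    denom = (N - A - 1) * (K - A)
    s0 = np.sqrt(np.nansum(E ** 2) / denom)
    if s0 == 0:
        d = np.zeros(N)
        return DModXResult(dmodx=d, dcrit=1.0, flagged=np.zeros(N, bool))
    d = s_i / s0
    dcrit = float(np.sqrt(stats.f.ppf(1 - alpha, K - A, denom)))
    return DModXResult(dmodx=d, dcrit=dcrit, flagged=d > dcrit)


@dataclass
class CVANOVAResult:
    F: float
    df1: int
    df2: int
    p: float

    @property
    def valid(self) -> bool:
        return self.p < 0.05


def cv_anova(model: OPLSDAModel) -> CVANOVAResult:
    """F-test of the cross-validated predictive residuals (PRESS) against the
    total corrected response variation."""
    df1 = 1 + model.n_ortho + 1  # predictive + orthogonal components + 1
    df2 = len(model.y) - df1
    if df2 <= 0:
        raise ValueError("not enough observations for CV-ANOVA degrees of freedom")
    press = model.cv_press
    ss_y = model.ss_y
    F = max((ss_y - press) / df1, 0.0) / (press / df2) if press > 0 else np.inf
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return CVANOVAResult(F=float(F), df1=df1, df2=df2, p=p)


@dataclass
class PermutationResult:
    correlations: np.ndarray  # |corr(permuted y, true y)| per permutation
    r2y: np.ndarray
    q2: np.ndarray
    true_r2y: float
    true_q2: float
    r2_intercept: float
    q2_intercept: float

    @property
    def n(self) -> int:
        return len(self.correlations)

    @property
    def valid(self) -> bool:
        """True model beats every permuted model on both R2Y and Q2."""
        return bool(self.true_r2y > self.r2y.max(initial=-np.inf)
                    and self.true_q2 > self.q2.max(initial=-np.inf))


def _intercept(corr: np.ndarray, vals: np.ndarray) -> float:
    slope, intercept = np.polyfit(corr, vals, 1)
    return float(intercept)


def permutation_test(table: PretreatedTable, labels: Sequence[str],
                     n: int = 50, seed: int = 0, max_ortho: int = 5,
                     model: Optional[OPLSDAModel] = None,
                     include_true_point: bool = True) -> PermutationResult:
    """Response permutation test: refit the OPLS-DA under n random
    reassignments of the class labels (class sizes preserved) and compare the
    true model's R2Y/Q2 with the permuted distribution.

    Permuted refits keep the true model's dimensionality (same number of
    orthogonal components) rather than re-selecting it by CV, so the permuted
    R2Y/Q2 measure what a model of equal complexity extracts from chance
    labels.  Regression-line intercepts at label-correlation 0 are reported,
    with the true model included as the correlation-1 point (toggleable)."""
    labels = list(labels)
    if model is None:
        model = fit_oplsda(table, labels, max_ortho=max_ortho)
    y_true, _, _ = encode_labels(labels)
    rng = np.random.default_rng(seed)
    corrs, r2s, q2s = [], [], []
    for _ in range(n):
        perm = rng.permutation(len(labels))
        lab_p = [labels[i] for i in perm]
        y_p, _, _ = encode_labels(lab_p)
        c = abs(float(np.corrcoef(y_true, y_p)[0, 1]))
        try:
            m = fit_oplsda(table, lab_p, n_ortho=model.n_ortho)
            r2, q2 = m.r2y, m.q2
        except ValueError:
            r2, q2 = 0.0, -1.0
        corrs.append(c)
        r2s.append(r2)
        q2s.append(q2)
    corrs_a, r2_a, q2_a = map(np.asarray, (corrs, r2s, q2s))
    if include_true_point:
        cx = np.r_[corrs_a, 1.0]
        r2_fit = np.r_[r2_a, model.r2y]
        q2_fit = np.r_[q2_a, model.q2]
    else:
        cx, r2_fit, q2_fit = corrs_a, r2_a, q2_a
    return PermutationResult(
        correlations=corrs_a, r2y=r2_a, q2=q2_a,
        true_r2y=model.r2y, true_q2=model.q2,
        r2_intercept=_intercept(cx, r2_fit),
        q2_intercept=_intercept(cx, q2_fit))


@dataclass
class ValidationReport:
    hotelling: HotellingResult
    dmodx: DModXResult
    cv_anova: Optional[CVANOVAResult] = None
    permutation: Optional[PermutationResult] = None

    def to_dict(self) -> dict:
        out = {
            "hotelling_t2_limit": self.hotelling.limit,
            "n_strong_outliers": int(self.hotelling.flagged.sum()),
            "dmodx_dcrit": self.dmodx.dcrit,
            "n_moderate_outliers": int(self.dmodx.flagged.sum()),
        }
        if self.cv_anova is not None:
            out["cv_anova_p"] = self.cv_anova.p
            out["cv_anova_F"] = self.cv_anova.F
        if self.permutation is not None:
            out["permutation_n"] = self.permutation.n
            out["permutation_r2_intercept"] = self.permutation.r2_intercept
            out["permutation_q2_intercept"] = self.permutation.q2_intercept
            out["permutation_valid"] = self.permutation.valid
        return out
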