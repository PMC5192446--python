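"""Latent-variable models: missing-value-aware NIPALS PCA with seven-fold
cross-validated component retention, and OPLS-DA for two-class discrimination.

Missing cells are handled NIPALS-style: every score/loading update is a least
squares regression over the observed cells only.  The per-element denominator
is never allowed to shrink below 1/3 of its complete-data value (a "correction
factor" of 3.0), so rows or columns observed in less than a third of their
cells cannot acquire extrapolated leverage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .pretreat import PretreatedTable

log = logging.getLogger(__name__)

CORRECTION_FACTOR = 3.0
CONV_TOL = 1e-10
MAX_ITER = 500


class ConvergenceError(RuntimeError):
    pass


def _capped_regression(num: np.ndarray, den: np.ndarray, full_den: float,
                       correction: float) -> np.ndarray:
    """Observed-cells least squares with the denominator floored at
    full_den / correction (the missing-value correction factor)."""
    floor = full_den / correction if correction else 0.0
    den = np.maximum(den, max(floor, 1e-300))
    return num / den


def _nipals_component(X: np.ndarray, mask: np.ndarray, correction: float,
                      tol: float = CONV_TOL, max_iter: int = MAX_ITER,
                      ) -> tuple[np.ndarray, np.ndarray, int]:
    """One PCA component by NIPALS on X (NaN already zeroed, mask = observed)."""
    Xf = X
    col_var = (Xf ** 2).sum(axis=0)
    t = Xf[:, int(np.argmax(col_var))].copy()
    if not np.any(t):
        t = Xf.sum(axis=1)
    mask_f = mask.astype(float)
    for it in range(max_iter):
        den_p = mask_f.T @ (t * t)
        p = _capped_regression(Xf.T @ t, den_p, float(t @ t), correction)
        nrm = np.linalg.norm(p)
        if nrm == 0:
            raise ConvergenceError("loading vector collapsed to zero")
        p /= nrm
        den_t = mask_f @ (p * p)
        t_new = _capped_regression(Xf @ p, den_t, 1.0, correction)
        if np.linalg.norm(t_new - t) <= tol * max(np.linalg.norm(t_new), 1e-300):
            # sign convention: largest-|p| element positive
            j = int(np.argmax(np.abs(p)))
            if p[j] < 0:
                p, t_new = -p, -t_new
            return t_new, p, it + 1
        t = t_new
    raise ConvergenceError(f"NIPALS did not converge in {max_iter} iterations")


@dataclass
class PCAModel:
    scores: np.ndarray  # N x A
    loadings: np.ndarray  # K x A
    r2x: list[float]  # per component
    r2x_cum: list[float]
    residuals: np.ndarray  # N x K with NaN at missing cells
    sample_ids: list[str]
    feature_ids: list[str]
    pretreatment: dict
    q2: Optional[list[float]] = None
    q2_cum: Optional[list[float]] = None

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def summary(self) -> dict:
        return {"n_components": self.n_components,
                "R2X(cum)": self.r2x_cum[-1] if self.r2x_cum else 0.0,
                "Q2(cum)": (self.q2_cum[-1] if self.q2_cum else None)}


def _as_matrix(table: PretreatedTable) -> tuple[np.ndarray, list[str], list[str]]:
    M = table.modeling_matrix()
    return M.to_numpy(float), list(M.index), list(M.columns)


def fit_pca(table: PretreatedTable, max_components: int,
            correction: float = CORRECTION_FACTOR) -> PCAModel:
    """Sequential missing-aware NIPALS PCA.

    On complete data the result coincides with the truncated SVD up to
    column sign.
    """
    X, samples, feats = _as_matrix(table)
    N, K = X.shape
    if N < 2 or K < 2:
        raise ValueError("need at least 2 samples and 2 usable features")
    mask = ~np.isnan(X)
    row_missing = 1 - mask.mean(axis=1)
    col_missing = 1 - mask.mean(axis=0)
    if row_missing.max(initial=0) > 0.5 or col_missing.max(initial=0) > 0.5:
        log.warning("fit_pca: some rows/columns exceed 50%% missing")
    Xw = np.where(mask, X, 0.0)
    ss_total = float((Xw ** 2).sum())
    if ss_total == 0:
        raise ValueError("matrix has zero total variance")
    T = np.zeros((N, 0))
    P = np.zeros((K, 0))
    r2x, r2x_cum = [], []
    ss_prev = ss_total
    for a in range(max_components):
        try:
            t, p, _ = _nipals_component(Xw, mask, correction)
        except ConvergenceError as exc:
            raise ConvergenceError(f"component {a + 1}: {exc}") from exc
        Xw = Xw - np.where(mask, np.outer(t, p), 0.0)
        ss_after = float((Xw ** 2).sum())
        r2x.append((ss_prev - ss_after) / ss_total)
        r2x_cum.append(1.0 - ss_after / ss_total)
        ss_prev = ss_after
        T = np.column_stack([T, t])
        P = np.column_stack([P, p])
        if ss_after <= 1e-12 * ss_total:
            break
    E = np.where(mask, Xw, np.nan)
    return PCAModel(scores=T, loadings=P, r2x=r2x, r2x_cum=r2x_cum, residuals=E,
                    sample_ids=samples, feature_ids=feats,
                    pretreatment=table.provenance.get("pretreatment", {}))


@dataclass
class CVResult:
    folds: int
    press: list[float]
    ss: list[float]  # SS of the matrix each component was fitted on
    q2: list[float]  # per-component Q2
    q2_cum: list[float]
    n_retained: int


def crossvalidate_pca(table: PretreatedTable, max_components: int,
                      folds: int = 7, correction: float = CORRECTION_FACTOR) -> CVResult:
    """Element-wise deletion cross-validation of the PCA.

    Cells are assigned to fold groups by (row + col) mod folds; each group is
    deleted in turn and predicted by a model fitted without it.
    Q2_a = 1 - PRESS_a / SS_{a-1}; components are retained while each adds to
    the cumulative Q2 (the "R1" retention rule, i.e. while Q2_a > 0).
    """
    X, _, _ = _as_matrix(table)
    N, K = X.shape
    if N < folds:
        log.warning("crossvalidate_pca: %d samples < %d folds; using %d folds", N, folds, N)
        folds = N
    mask = ~np.isnan(X)
    Xw = np.where(mask, X, 0.0)
    rows = np.arange(N)[:, None]
    cols = np.arange(K)[None, :]
    fold_of = (rows + cols) % folds
    press_list, ss_list, q2_list, q2c_list = [], [], [], []
    n_retained = 0
    for a in range(max_components):
        ss = float((Xw ** 2).sum())
        if ss <= 0:
            raise ValueError("degenerate zero residual matrix during CV")
        press = 0.0
        for g in range(folds):
            del_mask = mask & (fold_of == g)
            train_mask = mask & ~del_mask
            Xtr = np.where(train_mask, Xw, 0.0)
            try:
                t, p, _ = _nipals_component(Xtr, train_mask, correction)
            except ConvergenceError:
                press += float((Xw[del_mask] ** 2).sum())
                continue
            pred = np.outer(t, p)
            press += float(((Xw - pred)[del_mask] ** 2).sum())
        q2 = 1.0 - press / ss
        press_list.append(press)
        ss_list.append(ss)
        q2_list.append(q2)
        ratio = np.prod([pr / s for pr, s in zip(press_list, ss_list)])
        q2c_list.append(1.0 - float(ratio))
        if q2 <= 0:
            break
        n_retained = a + 1
        t, p, _ = _nipals_component(Xw, mask, correction)
        Xw = Xw - np.where(mask, np.outer(t, p), 0.0)
    return CVResult(folds=folds, press=press_list, ss=ss_list, q2=q2_list,
                    q2_cum=q2c_list, n_retained=n_retained)


def fit_pca_retained(table: PretreatedTable, max_components: int = 10,
                     folds: int = 7) -> tuple[PCAModel, CVResult]:
    """Cross-validate, then fit the PCA with the retained number of components."""
    cv = crossvalidate_pca(table, max_components, folds=folds)
    a = max(cv.n_retained, 1)
    model = fit_pca(table, a)
    model.q2 = cv.q2[:a]
    model.q2_cum = cv.q2_cum[:a]
    return model, cv


# ----------------------------------------------------------------- OPLS-DA --

@dataclass
class OPLSDAModel:
    w: np.ndarray  # predictive weight (unit norm)
    t: np.ndarray  # predictive score
    p: np.ndarray  # predictive X loading
    q: float  # y loading
    W_o: np.ndarray  # K x n_ortho
    T_o: np.ndarray  # N x n_ortho
    P_o: np.ndarray  # K x n_ortho
    y: np.ndarray  # centered encoded response
    y_mean: float
    classes: list[str]  # [class0, class1]
    class_score_means: tuple[float, float]  # fitted y-hat mean per class
    r2y: float
    r2x_pred: float
    r2x_ortho: list[float]
    q2: float
    cv_press: float
    ss_y: float
    ss_x: float
    residuals: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    pretreatment: dict
    correction: float = CORRECTION_FACTOR

    @property
    def n_ortho(self) -> int:
        return self.W_o.shape[1]

    @property
    def r2x_cum(self) -> float:
        return self.r2x_pred + float(sum(self.r2x_ortho))

    def summary(self) -> dict:
        return {"n_ortho": self.n_ortho, "R2X(cum)": self.r2x_cum,
                "R2Y(cum)": self.r2y, "Q2(cum)": self.q2}


def encode_labels(labels: Sequence[str]) -> tuple[np.ndarray, float, list[str]]:
    """Two-class 0/1 encoding (classes in sorted order), centered."""
    classes = sorted(set(labels))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    raw = np.array([1.0 if l == classes[1] else 0.0 for l in labels])
    for c in classes:
        if (raw == (1.0 if c == classes[1] else 0.0)).sum() < 2:
            raise ValueError(f"class {c} has fewer than 2 samples")
    mean = float(raw.mean())
    return raw - mean, mean, classes


def _opls_core(Xw: np.ndarray, mask: np.ndarray, y: np.ndarray, n_ortho: int,
               correction: float) -> dict:
    """Predictive + orthogonal decomposition on pre-masked data."""
    mask_f = mask.astype(float)
    Xd = Xw.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_ortho):
        w = Xd.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = _capped_regression(Xd @ w, mask_f @ (w * w), 1.0, correction)
        p = _capped_regression(Xd.T @ t, mask_f.T @ (t * t), float(t @ t), correction)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o <= 1e-12 * np.linalg.norm(p):
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = _capped_regression(Xd @ w_o, mask_f @ (w_o * w_o), 1.0, correction)
        p_o = _capped_regression(Xd.T @ t_o, mask_f.T @ (t_o * t_o), float(t_o @ t_o), correction)
        Xd = Xd - np.where(mask, np.outer(t_o, p_o), 0.0)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = Xd.T @ y
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("response carries no covariance with the matrix")
    w /= nw
    t = _capped_regression(Xd @ w, mask_f @ (w * w), 1.0, correction)
    p = _capped_regression(Xd.T @ t, mask_f.T @ (t * t), float(t @ t), correction)
    q = float((y @ t) / (t @ t))
    K = Xw.shape[1]
    return {"w": w, "t": t, "p": p, "q": q,
            "W_o": np.array(W_o).T if W_o else np.zeros((K, 0)),
            "T_o": np.array(T_o).T if T_o else np.zeros((len(y), 0)),
            "P_o": np.array(P_o).T if P_o else np.zeros((K, 0)),
            "Xd": Xd}


def _project(core: dict, Xnew: np.ndarray, mask_new: np.ndarray,
             correction: float) -> np.ndarray:
    """Predictive scores of new rows after removing orthogonal variation."""
    mask_f = mask_new.astype(float)
    Xd = np.where(mask_new, Xnew, 0.0).copy()
    for j in range(core["W_o"].shape[1]):
        w_o, p_o = core["W_o"][:, j], core["P_o"][:, j]
        t_o = _capped_regression(Xd @ w_o, mask_f @ (w_o * w_o), 1.0, correction)
        Xd = Xd - np.where(mask_new, np.outer(t_o, p_o), 0.0)
    w = core["w"]
    return _capped_regression(Xd @ w, mask_f @ (w * w), 1.0, correction)


def stratified_folds(labels: Sequence[str], folds: int = 7) -> np.ndarray:
    """Deterministic class-stratified round-robin fold assignment.

    Samples are sorted by id within class and dealt out in turn; the returned
    array maps each position (original order) to a fold index.
    """
    labels = list(labels)
    idx_sorted = sorted(range(len(labels)), key=lambda i: (labels[i], i))
    fold = np.empty(len(labels), int)
    counter = 0
    for i in idx_sorted:
        fold[i] = counter % folds
        counter += 1
    return fold


def _cv_q2(Xw, mask, y, n_ortho, labels, folds, correction) -> tuple[float, float]:
    """Observation-wise seven-fold CV: returns (Q2, PRESS).

    Column centering is recomputed on each training fold (no leakage from the
    held-out observations into the centering the submodel sees).
    """
    fold = stratified_folds(labels, folds)
    press = 0.0
    ss_y = float(y @ y)
    for g in range(folds):
        test = fold == g
        if not test.any() or test.all():
            continue
        train = ~test
        m_tr = mask[train]
        n_obs = np.maximum(m_tr.sum(axis=0), 1)
        col_mean = Xw[train].sum(axis=0) / n_obs
        Xtr = np.where(m_tr, Xw[train] - col_mean, 0.0)
        Xte = np.where(mask[test], Xw[test] - col_mean, 0.0)
        ytr = y[train] - y[train].mean()
        try:
            core = _opls_core(Xtr, m_tr, ytr, n_ortho, correction)
        except ValueError:
            press += float((y[test] ** 2).sum())
            continue
        t_pred = _project(core, Xte, mask[test], correction)
        yhat = t_pred * core["q"] + y[train].mean()
        press += float(((y[test] - yhat) ** 2).sum())
    return 1.0 - press / ss_y, press


def fit_oplsda(table: PretreatedTable, labels: Optional[Sequence[str]] = None,
               max_ortho: int = 5, folds: int = 7,
               correction: float = CORRECTION_FACTOR,
               n_ortho: Optional[int] = None) -> OPLSDAModel:
    """OPLS-DA: one predictive component plus as many orthogonal components
    as seven-fold cross-validation supports (added while Q2 increases).

    ``n_ortho`` fixes the number of orthogonal components instead (used e.g.
    to refit permuted models at the true model's dimensionality).
    """
    X, samples, feats = _as_matrix(table)
    if labels is None:
        labels = [str(table.groups.loc[s]) for s in samples]
    y, y_mean, classes = encode_labels(labels)
    mask = ~np.isnan(X)
    Xw = np.where(mask, X, 0.0)
    n = min(folds, len(y))
    if n_ortho is not None:
        q2_prev, press_prev = _cv_q2(Xw, mask, y, n_ortho, labels, n, correction)
    else:
        q2_prev, press_prev = _cv_q2(Xw, mask, y, 0, labels, n, correction)
        n_ortho = 0
        while n_ortho < max_ortho:
            q2_next, press_next = _cv_q2(Xw, mask, y, n_ortho + 1, labels, n, correction)
            if q2_next <= q2_prev:
                break
            q2_prev, press_prev = q2_next, press_next
            n_ortho += 1
    core = _opls_core(Xw, mask, y, n_ortho, correction)
    t, q = core["t"], core["q"]
    yhat = t * q
    ss_y = float(y @ y)
    r2y = 1.0 - float(((y - yhat) ** 2).sum()) / ss_y
    ss_x = float((Xw ** 2).sum())
    r2x_pred = float((np.where(mask, np.outer(t, core["p"]), 0.0) ** 2).sum()) / ss_x
    r2x_ortho = [float((np.where(mask, np.outer(core["T_o"][:, j], core["P_o"][:, j]), 0.0) ** 2).sum()) / ss_x
                 for j in range(core["T_o"].shape[1])]
    E = np.where(mask, core["Xd"] - np.outer(t, core["p"]), np.nan)
    cls0 = [l == classes[0] for l in labels]
    cls1 = [l == classes[1] for l in labels]
    return OPLSDAModel(
        w=core["w"], t=t, p=core["p"], q=q,
        W_o=core["W_o"], T_o=core["T_o"], P_o=core["P_o"],
        y=y, y_mean=y_mean, classes=classes,
        class_score_means=(float(yhat[cls0].mean()), float(yhat[cls1].mean())),
        r2y=r2y, r2x_pred=r2x_pred, r2x_ortho=r2x_ortho,
        q2=q2_prev, cv_press=press_prev, ss_y=ss_y, ss_x=ss_x,
        residuals=E, sample_ids=samples, feature_ids=feats,
        pretreatment=table.provenance.get("pretreatment", {}),
        correction=correction)


def predict_oplsda(model: OPLSDAModel, new_X: pd.DataFrame) -> pd.DataFrame:
    """Predict scores and classes for pretreated new observations.

    Orthogonal variation is removed, the predictive score computed
    (missing-aware), and the class assigned by the nearer of the two fitted
    class means on the predicted response.
    """
    missing_cols = [f for f in model.feature_ids if f not in new_X.columns]
    if missing_cols:
        raise ValueError(f"observations lack model features: {missing_cols[:5]}"
                         f"{'...' if len(missing_cols) > 5 else ''}")
    Xn = new_X[model.feature_ids].to_numpy(float)
    mask = ~np.isnan(Xn)
    core = {"w": model.w, "W_o": model.W_o, "P_o": model.P_o}
    t_pred = _project(core, Xn, mask, model.correction)
    y_pred = t_pred * model.q
    m0, m1 = model.class_score_means
    cls = [model.classes[1] if abs(v - m1) < abs(v - m0) else model.classes[0]
           for v in y_pred]
    return pd.DataFrame({"t_pred": t_pred, "y_pred": y_pred, "class": cls},
                        index=new_X.index)
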