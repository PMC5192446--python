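"""Pre-treatment of the feature matrix: missing-value filtering, log/power
transformation, and column-wise center / unit-variance / Pareto scaling.

The pipeline order is transform-then-scale; scaling statistics are computed on
the transformed values.  Per-column means and scaling weights are stored so
the pretreated matrix can be reproduced exactly, back-projected, and applied
to new observations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .peaks import FeatureTable

log = logging.getLogger(__name__)

TRANSFORMS = ("none", "log", "power")
SCALINGS = ("none", "center", "uv", "pareto")


@dataclass(frozen=True)
class PretreatmentSpec:
    transform: str = "none"
    c1: float = 1.0
    c2: float = 0.0
    c3: float = 2.0
    scaling: str = "none"
    missing_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if self.scaling not in SCALINGS:
            raise ValueError(f"scaling must be one of {SCALINGS}")
        if not (0.0 < self.missing_threshold <= 1.0):
            raise ValueError("missing_threshold must be in (0, 1]")

    @property
    def label(self) -> str:
        scale = {"none": "None", "center": "Center", "uv": "UV", "pareto": "Pareto"}[self.scaling]
        trans = {"none": "None", "log": "Log", "power": "Power"}[self.transform]
        return f"{scale}/{trans}"

    def to_dict(self) -> dict:
        return asdict(self)


def filter_missing(table: FeatureTable, spec: PretreatmentSpec) -> FeatureTable:
    """Drop features, then samples, whose missing fraction exceeds the
    threshold (50% by default)."""
    thr = spec.missing_threshold
    vals = table.values
    feat_missing = vals.isna().mean(axis=0)
    keep_feats = feat_missing[feat_missing <= thr].index
    dropped_f = vals.shape[1] - len(keep_feats)
    if len(keep_feats) == 0:
        raise ValueError("all features exceed the missing-value threshold")
    vals = vals[keep_feats]
    samp_missing = vals.isna().mean(axis=1)
    keep_samps = samp_missing[samp_missing <= thr].index
    dropped_s = vals.shape[0] - len(keep_samps)
    if dropped_f or dropped_s:
        log.info("missing-value filter: dropped %d features then %d samples", dropped_f, dropped_s)
    return FeatureTable(values=vals.loc[keep_samps],
                        groups=table.groups.loc[keep_samps],
                        feature_meta=table.feature_meta.loc[keep_feats],
                        provenance={**table.provenance, "missing_threshold": thr},
                        noise_flags=None if table.noise_flags is None
                        else table.noise_flags.loc[keep_feats])


def transform(table: FeatureTable, spec: PretreatmentSpec) -> FeatureTable:
    """Cell-wise transformation: log10(C1*x + C2), (C1*x + C2)^C3 or identity.

    A log of a non-positive argument yields a missing cell (counted in the
    log); no pseudo-count is added.
    """
    vals = table.values
    if spec.transform == "none":
        out = vals.copy()
    else:
        arg = spec.c1 * vals + spec.c2
        if spec.transform == "log":
            bad = (arg <= 0) & vals.notna()
            n_bad = int(bad.to_numpy().sum())
            if n_bad:
                log.info("log transform: %d non-positive cells became missing", n_bad)
            out = np.log10(arg.where(~bad))
        else:  # power
            out = arg ** spec.c3
    return FeatureTable(values=out, groups=table.groups, feature_meta=table.feature_meta,
                        provenance={**table.provenance, "transform": spec.transform,
                                    "c": [spec.c1, spec.c2, spec.c3]},
                        noise_flags=table.noise_flags)


@dataclass
class PretreatedTable:
    """Transformed + scaled matrix with the column statistics needed to scale
    new observations and to back-project."""

    X: pd.DataFrame  # scaled values, NaN = missing
    groups: pd.Series
    feature_meta: pd.DataFrame
    col_means: pd.Series
    col_weights: pd.Series  # multiplicative; 0 marks an excluded column
    spec: PretreatmentSpec
    provenance: dict = field(default_factory=dict)
    noise_flags: Optional[pd.Series] = None

    @property
    def usable_columns(self) -> pd.Index:
        return self.col_weights[self.col_weights > 0].index

    def modeling_matrix(self) -> pd.DataFrame:
        return self.X[self.usable_columns]

    def back_project(self) -> pd.DataFrame:
        """Undo scaling (not the transformation) using the stored parameters."""
        usable = self.usable_columns
        return self.X[usable] / self.col_weights[usable] + self.col_means[usable]

    def apply_to(self, new_values: pd.DataFrame) -> pd.DataFrame:
        """Transform + scale new observations with the stored parameters."""
        s = self.spec
        if s.transform == "log":
            arg = s.c1 * new_values + s.c2
            vals = np.log10(arg.where(arg > 0))
        elif s.transform == "power":
            vals = (s.c1 * new_values + s.c2) ** s.c3
        else:
            vals = new_values
        usable = self.usable_columns
        missing = usable.difference(vals.columns)
        if len(missing):
            raise ValueError(f"new observations lack model features: {list(missing)[:5]}...")
        return (vals[usable] - self.col_means[usable]) * self.col_weights[usable]


def scale(table: FeatureTable, spec: PretreatmentSpec) -> PretreatedTable:
    """Column-wise scaling over non-missing cells.

    center: x - mean; uv: (x - mean)/sd; pareto: (x - mean)/sqrt(sd); sd is the
    sample standard deviation (n-1).  Zero-variance columns get weight 0 and
    are excluded from modeling.
    """
    vals = table.values
    n_obs = vals.notna().sum(axis=0)
    too_few = n_obs[n_obs < 2]
    if len(too_few):
        raise ValueError(f"features with fewer than 2 non-missing values: {list(too_few.index)[:5]}")
    means = vals.mean(axis=0)
    sds = vals.std(axis=0, ddof=1)
    if spec.scaling == "none":
        weights = pd.Series(1.0, index=vals.columns)
        means = pd.Series(0.0, index=vals.columns)
    elif spec.scaling == "center":
        weights = pd.Series(1.0, index=vals.columns)
    elif spec.scaling == "uv":
        weights = 1.0 / sds
    else:  # pareto
        weights = 1.0 / np.sqrt(sds)
    zero_var = sds <= 0
    if spec.scaling in ("uv", "pareto") and zero_var.any():
        log.info("scaling: %d zero-variance columns excluded (weight 0)", int(zero_var.sum()))
        weights[zero_var] = 0.0
    weights = weights.replace([np.inf, -np.inf], 0.0).fillna(0.0)
    X = (vals - means) * weights
    return PretreatedTable(X=X, groups=table.groups, feature_meta=table.feature_meta,
                           col_means=means, col_weights=weights, spec=spec,
                           provenance={**table.provenance, "pretreatment": spec.to_dict()},
                           noise_flags=table.noise_flags)


def pretreat(table: FeatureTable, spec: PretreatmentSpec) -> PretreatedTable:
    """filter_missing -> transform -> scale, the standard pre-treatment chain."""
    return scale(transform(filter_missing(table, spec), spec), spec)
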