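"""Shared fixtures: synthetic cohorts and constructed statistical datasets.

Everything is generated at test time; session scope amortizes the expensive
cohorts (the full-size default cohort and the sensitivity grid) across tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from metabosense import (build_design, generate_cohort, pretreat,
                         PretreatmentSpec, fit_oplsda)
from metabosense.peaks import ProcessingParams, FeatureTable, build_feature_table

TINY = dict(n_control=4, n_treated=5, rt_range=(1.0, 3.0),
            n_background_metabolites=30, n_discriminating_metabolites=5,
            seed=1)
TINY_PARAMS = ProcessingParams(rt_range=(1.0, 3.0))


@pytest.fixture(scope="session")
def tiny_cohort():
    """Small 9-sample cohort (2 min Rt window, 35 metabolites) for module tests."""
    design = build_design(**TINY)
    runs, truth = generate_cohort(design)
    return design, runs, truth


@pytest.fixture(scope="session")
def tiny_table(tiny_cohort):
    _, runs, truth = tiny_cohort
    return build_feature_table(runs, TINY_PARAMS, truth=truth)


@pytest.fixture(scope="session")
def default_cohort():
    """The full study-sized cohort: 9 control / 15 treated, 200 metabolites,
    10 discriminating at 8-fold."""
    design = build_design(seed=1)
    runs, truth = generate_cohort(design)
    return design, runs, truth


@pytest.fixture(scope="session")
def experiment_report(default_cohort):
    """The full 12-cell sensitivity grid on the default cohort."""
    from metabosense.pipeline import run_experiment
    _, runs, truth = default_cohort
    return run_experiment({"seed": 1}, runs=runs, truth=truth)


@pytest.fixture(scope="session")
def weak_experiment():
    """Pre-treatment grid on a weak-signal cohort (1.3-fold discriminators):
    the setting where permutation validation is expected to reject models."""
    from metabosense.pipeline import run_experiment
    cfg = {"design": {"fold_changes": (1.3, 1 / 1.3)},
           "methods": {"Method 1": {"mass_tolerance": 0.005,
                                    "intensity_threshold": 10.0}},
           "n_permutations": 50, "seed": 2}
    return run_experiment(cfg)


def make_feature_table(values: np.ndarray, groups=None, rt=None, mz=None) -> FeatureTable:
    """Wrap a plain matrix as a FeatureTable for model-level tests."""
    n, k = values.shape
    idx = [f"s{i:02d}" for i in range(n)]
    cols = [f"f{j:03d}" for j in range(k)]
    if groups is None:
        groups = ["C"] * (n // 2) + ["T"] * (n - n // 2)
    vals = pd.DataFrame(values, index=idx, columns=cols)
    meta = pd.DataFrame({"rt": rt if rt is not None else np.zeros(k),
                         "mz": mz if mz is not None else np.arange(k, dtype=float)},
                        index=cols)
    return FeatureTable(values=vals, groups=pd.Series(list(groups), index=idx),
                        feature_meta=meta, provenance={})


def geometry_dataset(n: int = 96, n_first: int = 36, k: int = 40,
                     separation: float = 4.0, ortho_sd: float = 2.0,
                     noise_sd: float = 0.2, seed: int = 0,
                     with_signal: bool = True):
    """Two-class data whose class difference lies along one direction v with
    one additional orthogonal variance direction u: the construction used for
    the statistical-calibration checks."""
    rng = np.random.default_rng(seed)
    labels = ["C"] * n_first + ["T"] * (n - n_first)
    y01 = np.array([0.0] * n_first + [1.0] * (n - n_first))
    v = rng.normal(size=k)
    v /= np.linalg.norm(v)
    u = rng.normal(size=k)
    u -= (u @ v) * v
    u /= np.linalg.norm(u)
    X = np.outer(rng.normal(0, ortho_sd, n), u) + rng.normal(0, noise_sd, (n, k))
    if with_signal:
        X += np.outer(y01 * separation, v)
    table = make_feature_table(X, groups=labels)
    pt = pretreat(table, PretreatmentSpec(scaling="center"))
    return pt, labels, v, u
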