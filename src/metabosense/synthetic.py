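"""Synthetic centroid-mode LC-MS cohorts with planted ground truth.

The generator emulates a two-group plant-metabolomics acquisition: a small
control group and a larger treated group, positive-mode centroid spectra on a
regular retention-time grid, metabolites appearing as Gaussian chromatographic
peaks whose per-scan centroid m/z carries instrument jitter, plus uniform
chemical-noise ions and optional sodium-adduct companion ions.  Every
above-noise peak traces back to a catalog entry, so downstream peak picking,
alignment, modeling and feature selection can be scored against known truth.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

# Na+ replaces H+ on the same neutral: m/z shift of the [M+Na]+ companion ion.
NA_H_SHIFT = 21.9819


class DesignError(ValueError):
    """Invalid synthetic-cohort configuration."""


@dataclass(frozen=True)
class SyntheticDesign:
    """Study design for one synthetic cohort.

    Defaults mirror the emulated acquisition: 9 control / 15 treated samples,
    retention time 1-15 min, m/z 100-1000 Da, 200 metabolites of which 10
    discriminate between groups at fold change 8.
    """

    n_control: int = 9
    n_treated: int = 15
    rt_range: tuple[float, float] = (1.0, 15.0)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    scan_interval: float = 0.005  # min; a ~0.06 min FWHM peak spans >10 scans
    n_background_metabolites: int = 190
    n_discriminating_metabolites: int = 10
    # treated/control ratio per discriminating metabolite (cyclic); the default
    # plants balanced 8-fold up- and down-regulation so the treated total ion
    # current stays within biological variation of the control's, as in real
    # cohorts where discriminators are a negligible share of the TIC
    fold_changes: tuple[float, ...] = (8.0, 0.125)
    # diffuse biological response of the non-discriminating metabolome:
    # per-metabolite treated/control ratio is lognormal, median 1, with this
    # log-sd (0.1 -> ratios mostly within 0.8-1.25)
    background_log_fc_sd: float = 0.1
    peak_sigma_rt: float = 0.025  # min
    mz_jitter_sd: float = 0.0015  # Da
    intensity_cv: float = 0.2  # between-sample biological CV
    base_intensity_range: tuple[float, float] = (200.0, 20000.0)  # counts
    # discriminators are mid-to-low-abundance compounds (geometric-mean level);
    # keeps the group contrast out of the total-ion-current denominator
    disc_intensity_range: tuple[float, float] = (200.0, 2000.0)  # counts
    noise_ion_density: float = 0.2  # expected noise ions per scan
    noise_intensity_range: tuple[float, float] = (10.0, 250.0)  # counts
    adduct_probability: float = 0.3
    adduct_ratio_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 3:
            raise DesignError("n_control must be >= 3 (CV folds must be constructible)")
        if self.n_treated < 3:
            raise DesignError("n_treated must be >= 3 (CV folds must be constructible)")
        for name in ("rt_range", "mz_range", "noise_intensity_range",
                     "base_intensity_range", "disc_intensity_range",
                     "adduct_ratio_range"):
            lo, hi = getattr(self, name)
            if not (lo < hi):
                raise DesignError(f"{name} must be an increasing (low, high) pair")
        if self.scan_interval <= 0:
            raise DesignError("scan_interval must be positive")
        for name in ("n_background_metabolites", "n_discriminating_metabolites"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be non-negative")
        if any(f <= 0 for f in self.fold_changes):
            raise DesignError("fold_changes must be positive")
        if self.intensity_cv < 0:
            raise DesignError("intensity_cv must be non-negative")
        if self.peak_sigma_rt <= 0:
            raise DesignError("peak_sigma_rt must be positive")
        if self.mz_jitter_sd < 0:
            raise DesignError("mz_jitter_sd must be non-negative")
        if self.noise_ion_density < 0:
            raise DesignError("noise_ion_density must be non-negative")
        if self.background_log_fc_sd < 0:
            raise DesignError("background_log_fc_sd must be non-negative")
        if not (0.0 <= self.adduct_probability <= 1.0):
            raise DesignError("adduct_probability must be in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.n_control + self.n_treated

    def fold_change_for(self, i: int) -> float:
        """Fold change of discriminating metabolite ``i`` (cyclic broadcast)."""
        return float(self.fold_changes[i % len(self.fold_changes)])

    def scan_grid(self) -> np.ndarray:
        lo, hi = self.rt_range
        n = int(math.floor((hi - lo) / self.scan_interval)) + 1
        return lo + self.scan_interval * np.arange(n)


def build_design(**config) -> SyntheticDesign:
    """Build a validated :class:`SyntheticDesign`, filling defaults.

    Raises :class:`DesignError` naming the offending field on invalid input.
    """
    try:
        return SyntheticDesign(**config)
    except TypeError as exc:  # unknown field
        raise DesignError(str(exc)) from exc


@dataclass
class CatalogEntry:
    id: str
    rt_center: float
    mz_center: float
    base_intensity: float
    is_discriminating: bool
    fold_change: float
    adduct_of: Optional[str] = None


@dataclass
class GroundTruth:
    """Planted-metabolite catalog plus the intensity realized in each sample."""

    catalog: list[CatalogEntry]
    # sample_id -> {metabolite id -> realized peak height (counts)}
    sample_intensities: dict[str, dict[str, float]]

    def entry(self, metabolite_id: str) -> CatalogEntry:
        for e in self.catalog:
            if e.id == metabolite_id:
                return e
        raise KeyError(metabolite_id)

    def discriminating_ids(self) -> list[str]:
        return [e.id for e in self.catalog if e.is_discriminating and e.adduct_of is None]

    def to_json(self, path) -> None:
        payload = {
            "catalog": [asdict(e) for e in self.catalog],
            "sample_intensities": self.sample_intensities,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        catalog = [CatalogEntry(**e) for e in payload["catalog"]]
        return cls(catalog=catalog, sample_intensities=payload["sample_intensities"])


@dataclass
class Scan:
    rt: float
    mz: np.ndarray
    intensity: np.ndarray


@dataclass
class CentroidRun:
    """One sample's centroid acquisition: (m/z, intensity) sticks per scan."""

    sample_id: str
    group: str  # "C" or "T"
    scans: list[Scan]

    def __post_init__(self) -> None:
        rts = [s.rt for s in self.scans]
        if any(b <= a for a, b in zip(rts, rts[1:])):
            raise ValueError(f"scan retention times must be strictly increasing in {self.sample_id}")

    @property
    def rt_grid(self) -> np.ndarray:
        return np.array([s.rt for s in self.scans])

    def n_ions(self) -> int:
        return int(sum(len(s.mz) for s in self.scans))


def _lognormal_factor(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-1 multiplicative lognormal noise with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    s2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-s2 / 2.0, sigma=math.sqrt(s2), size=size)


def _build_catalog(design: SyntheticDesign, rng: np.random.Generator) -> list[CatalogEntry]:
    rt_lo, rt_hi = design.rt_range
    mz_lo, mz_hi = design.mz_range
    # keep centers away from the edges so whole peaks fit inside the windows
    rt_pad = min(4 * design.peak_sigma_rt, 0.25 * (rt_hi - rt_lo))
    mz_pad_hi = NA_H_SHIFT + 0.5 if (mz_hi - mz_lo) > 2 * (NA_H_SHIFT + 1.0) else 0.5 * (mz_hi - mz_lo)
    n_bg = design.n_background_metabolites
    n_dis = design.n_discriminating_metabolites
    n = n_bg + n_dis
    rts = rng.uniform(rt_lo + rt_pad, rt_hi - rt_pad, n)
    mzs = rng.uniform(mz_lo + 0.5, mz_hi - mz_pad_hi, n)
    lo, hi = design.base_intensity_range
    bases = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    is_dis = np.zeros(n, bool)
    if n_dis:
        is_dis[rng.choice(n, size=n_dis, replace=False)] = True
        dlo, dhi = design.disc_intensity_range
        bases[is_dis] = np.exp(rng.uniform(math.log(dlo), math.log(dhi), n_dis))
    catalog: list[CatalogEntry] = []
    d_idx = 0
    bg_fc = np.exp(rng.normal(0.0, design.background_log_fc_sd, n)) \
        if design.background_log_fc_sd > 0 else np.ones(n)
    for i in range(n):
        if is_dis[i]:
            fc = design.fold_change_for(d_idx)
            d_idx += 1
        else:
            fc = float(bg_fc[i])
        catalog.append(CatalogEntry(
            id=f"M{i:04d}", rt_center=float(rts[i]), mz_center=float(mzs[i]),
            base_intensity=float(bases[i]), is_discriminating=bool(is_dis[i]),
            fold_change=fc))
    # sodium-adduct companions: perfectly correlated with the parent pre-noise
    for i in range(n):
        if rng.uniform() < design.adduct_probability:
            parent = catalog[i]
            ratio = rng.uniform(*design.adduct_ratio_range)
            if parent.mz_center + NA_H_SHIFT > mz_hi:
                continue
            catalog.append(CatalogEntry(
                id=f"{parent.id}.Na", rt_center=parent.rt_center,
                mz_center=parent.mz_center + NA_H_SHIFT,
                base_intensity=parent.base_intensity * ratio,
                is_discriminating=parent.is_discriminating,
                fold_change=parent.fold_change, adduct_of=parent.id))
    return catalog


def generate_cohort(design: SyntheticDesign) -> tuple[list[CentroidRun], GroundTruth]:
    """Generate the cohort of centroid runs and its ground truth.

    Deterministic given the design (including its seed).  Each catalog
    metabolite appears in every sample as a Gaussian chromatographic profile
    (sd ``peak_sigma_rt``) with per-scan centroid m/z jitter; discriminating
    metabolites have expected treated/control intensity ratio equal to their
    fold change; between-sample variation is mean-preserving lognormal with
    the design's CV; chemical-noise ions are uniform in m/z and intensity at
    ``noise_ion_density`` per scan.
    """
    rng = np.random.default_rng(design.seed)
    catalog = _build_catalog(design, rng)
    grid = design.scan_grid()
    n_scans = len(grid)
    sample_ids = ([f"C{i + 1:02d}" for i in range(design.n_control)]
                  + [f"T{i + 1:02d}" for i in range(design.n_treated)])
    groups = ["C"] * design.n_control + ["T"] * design.n_treated

    # realized per-sample heights: parents get biological noise; adducts track
    # their parent exactly (ratio applied to the parent's realized height)
    parents = [e for e in catalog if e.adduct_of is None]
    realized: dict[str, dict[str, float]] = {sid: {} for sid in sample_ids}
    for e in parents:
        noise = _lognormal_factor(rng, design.intensity_cv, len(sample_ids))
        # base_intensity is the between-group geometric mean: the expected
        # treated/control ratio is fold_change, split symmetrically
        r = math.sqrt(e.fold_change)
        for j, (sid, grp) in enumerate(zip(sample_ids, groups)):
            amp = e.base_intensity * (r if grp == "T" else 1.0 / r)
            realized[sid][e.id] = float(amp * noise[j])
    parent_base = {p.id: p.base_intensity for p in parents}
    for e in catalog:
        if e.adduct_of is not None:
            ratio = e.base_intensity / parent_base[e.adduct_of]
            for sid in sample_ids:
                realized[sid][e.id] = realized[sid][e.adduct_of] * ratio

    runs: list[CentroidRun] = []
    for sid, grp in zip(sample_ids, groups):
        mz_per_scan: list[list[float]] = [[] for _ in range(n_scans)]
        int_per_scan: list[list[float]] = [[] for _ in range(n_scans)]
        for e in catalog:
            height = realized[sid][e.id]
            lo_idx = int(np.searchsorted(grid, e.rt_center - 4 * design.peak_sigma_rt))
            hi_idx = int(np.searchsorted(grid, e.rt_center + 4 * design.peak_sigma_rt, "right"))
            idx = np.arange(lo_idx, hi_idx)
            if idx.size == 0:
                continue
            prof = height * np.exp(-0.5 * ((grid[idx] - e.rt_center) / design.peak_sigma_rt) ** 2)
            jitter = rng.normal(0.0, design.mz_jitter_sd, idx.size) if design.mz_jitter_sd else np.zeros(idx.size)
            for k, s in enumerate(idx):
                mz_per_scan[s].append(e.mz_center + jitter[k])
                int_per_scan[s].append(prof[k])
        if design.noise_ion_density > 0:
            counts = rng.poisson(design.noise_ion_density, n_scans)
            for s in range(n_scans):
                for _ in range(counts[s]):
                    mz_per_scan[s].append(rng.uniform(*design.mz_range))
                    int_per_scan[s].append(rng.uniform(*design.noise_intensity_range))
        scans = []
        for s in range(n_scans):
            order = np.argsort(mz_per_scan[s], kind="stable")
            scans.append(Scan(rt=float(grid[s]),
                              mz=np.asarray(mz_per_scan[s], float)[order],
                              intensity=np.asarray(int_per_scan[s], float)[order]))
        runs.append(CentroidRun(sample_id=sid, group=grp, scans=scans))
    truth = GroundTruth(catalog=catalog, sample_intensities=realized)
    return runs, truth
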