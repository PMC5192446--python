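"""Matrix creation from centroid runs.

Stages, in the order a vendor-style matrix-creation tool applies them:

1. ROI construction — centroid ions are grouped in the m/z domain by mass
   tolerance (greedy running intensity-weighted centers), each ROI yielding an
   extracted ion chromatogram (EIC) on the run's scan grid.
2. Peak detection — Savitzky-Golay smoothing; candidate peaks are maximal runs
   of negative second derivative; apex, inflection points, local-minimum
   integration bounds, linear baseline, height/area, width at 5% height; a
   signal-to-baseline-noise gate based on the slope noise outside peaks.
3. Alignment — peaks pooled over samples and clustered greedily in descending
   height order within +/- m/z and Rt windows.
4. Intensity-threshold peak removal — a feature is kept if any sample reaches
   the intensity threshold; within a kept feature the threshold is lowered per
   sample down to the noise elimination level, below which values are missing.
5. Normalization — each sample's non-missing intensities are rescaled to a
   common total.
"""

from __future__ import annotations

import bisect
import json
import logging
import math
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .synthetic import CentroidRun, GroundTruth

log = logging.getLogger(__name__)

METHOD_PRESETS = {
    # mass tolerance (Da), intensity threshold (counts)
    "Method 1": (0.005, 10.0),
    "Method 2": (0.005, 100.0),
    "Method 3": (0.01, 10.0),
    "Method 4": (0.01, 100.0),
}


@dataclass(frozen=True)
class ProcessingParams:
    mass_tolerance: float = 0.005  # Da
    intensity_threshold: float = 10.0  # counts
    noise_elimination_level: Optional[float] = None  # default threshold/10
    align_mz_window: float = 0.05  # Da
    align_rt_window: float = 0.20  # min
    rt_range: tuple[float, float] = (1.0, 15.0)
    mz_range: tuple[float, float] = (100.0, 1000.0)
    sg_window: int | str = "auto"  # scans, odd
    sg_polyorder: int = 3
    peak_width_5pct: float | str = "auto"  # min
    baseline_threshold: float | str = "auto"  # signal / slope-noise ratio
    normalization_target: float = 10000.0

    def __post_init__(self) -> None:
        if self.mass_tolerance <= 0:
            raise ValueError("mass_tolerance must be positive")
        if self.intensity_threshold < 0:
            raise ValueError("intensity_threshold must be non-negative")
        nel = self.noise_level
        if not (0 <= nel <= self.intensity_threshold):
            raise ValueError("need intensity_threshold >= noise_elimination_level >= 0")
        if self.align_mz_window <= 0 or self.align_rt_window <= 0:
            raise ValueError("alignment windows must be positive")
        if isinstance(self.sg_window, int):
            if self.sg_window % 2 == 0 or self.sg_window <= self.sg_polyorder:
                raise ValueError("sg_window must be odd and greater than sg_polyorder")

    @property
    def noise_level(self) -> float:
        if self.noise_elimination_level is not None:
            return self.noise_elimination_level
        return self.intensity_threshold / 10.0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ROI:
    """A narrow m/z band traced across scans."""

    mz_center: float
    scan_idx: list[int] = field(default_factory=list)
    mz: list[float] = field(default_factory=list)
    intensity: list[float] = field(default_factory=list)
    _weight: float = 0.0

    def add(self, scan: int, mz: float, intensity: float) -> None:
        self.scan_idx.append(scan)
        self.mz.append(mz)
        self.intensity.append(intensity)
        w = self._weight + intensity
        if w > 0:
            self.mz_center = (self.mz_center * self._weight + mz * intensity) / w
            self._weight = w

    def __len__(self) -> int:
        return len(self.scan_idx)

    def eic(self, n_scans: int) -> np.ndarray:
        out = np.zeros(n_scans)
        np.add.at(out, np.asarray(self.scan_idx, int), np.asarray(self.intensity))
        return out


@dataclass
class Peak:
    sample_id: str
    mz: float  # intensity-weighted mean over the peak's scans
    rt_apex: float
    height: float
    area: float  # counts * min
    width_5pct: float
    rt_left_inflection: float
    rt_right_inflection: float


def build_rois(run: CentroidRun, params: ProcessingParams) -> list[ROI]:
    """Partition a run's in-range ions into ROIs by mass tolerance.

    Greedy streaming clustering: each ion joins the ROI whose running
    intensity-weighted center is nearest and within the mass tolerance, else
    it seeds a new ROI.  Every in-range ion with positive intensity lands in
    exactly one ROI.
    """
    rt_lo, rt_hi = params.rt_range
    mz_lo, mz_hi = params.mz_range
    tol = params.mass_tolerance
    centers: list[float] = []  # sorted, parallel to rois_sorted
    rois_sorted: list[ROI] = []
    for s, scan in enumerate(run.scans):
        if not (rt_lo <= scan.rt <= rt_hi):
            continue
        for mz, inten in zip(scan.mz, scan.intensity):
            if inten <= 0 or not (mz_lo <= mz <= mz_hi):
                continue
            pos = bisect.bisect_left(centers, mz)
            best = None
            for j in (pos - 1, pos):
                if 0 <= j < len(centers) and abs(centers[j] - mz) <= tol:
                    d = abs(centers[j] - mz)
                    if best is None or d < best[0]:
                        best = (d, j)
            if best is None:
                roi = ROI(mz_center=mz)
                roi.add(s, mz, inten)
                centers.insert(pos, mz)
                rois_sorted.insert(pos, roi)
            else:
                j = best[1]
                roi = rois_sorted[j]
                roi.add(s, mz, inten)
                centers[j] = roi.mz_center
                # weighted-center drift can break local order; bubble to fix
                while j > 0 and centers[j - 1] > centers[j]:
                    centers[j - 1], centers[j] = centers[j], centers[j - 1]
                    rois_sorted[j - 1], rois_sorted[j] = rois_sorted[j], rois_sorted[j - 1]
                    j -= 1
                while j + 1 < len(centers) and centers[j] > centers[j + 1]:
                    centers[j], centers[j + 1] = centers[j + 1], centers[j]
                    rois_sorted[j], rois_sorted[j + 1] = rois_sorted[j + 1], rois_sorted[j]
                    j += 1
    return _merge_converged_rois(rois_sorted, tol)


def _merge_converged_rois(rois: list[ROI], tol: float) -> list[ROI]:
    """Merge adjacent ROIs whose running centers ended within the tolerance.

    Centroid jitter comparable to the tolerance can split one ion species
    into two greedy clusters; such ROIs would have formed a single cluster
    under any ion ordering, so they are folded back together.
    """
    merged: list[ROI] = []
    for roi in rois:
        if merged and abs(roi.mz_center - merged[-1].mz_center) <= tol:
            prev = merged[-1]
            for s, m, i in zip(roi.scan_idx, roi.mz, roi.intensity):
                prev.add(s, m, i)
        else:
            merged.append(roi)
    return merged


def estimate_peak_width(run: CentroidRun, params: ProcessingParams, n_peaks: int = 20) -> float:
    """Median 5%-height width (min) of the tallest total-ion-chromatogram maxima.

    Stands in for the vendor's automatic peak-width setting when
    ``peak_width_5pct`` is ``"auto"``.
    """
    grid = run.rt_grid
    tic = np.zeros(len(grid))
    for s, scan in enumerate(run.scans):
        tic[s] = scan.intensity.sum()
    is_max = np.r_[False, (tic[1:-1] > tic[:-2]) & (tic[1:-1] >= tic[2:]), False]
    order = np.argsort(tic[is_max])[::-1][:n_peaks]
    apex_idx = np.flatnonzero(is_max)[order]
    widths = []
    for a in apex_idx:
        thr = 0.05 * tic[a]
        l = a
        while l > 0 and tic[l - 1] > thr and tic[l - 1] <= tic[l]:
            l -= 1
        r = a
        while r < len(tic) - 1 and tic[r + 1] > thr and tic[r + 1] <= tic[r]:
            r += 1
        if r > l:
            widths.append(grid[r] - grid[l])
    return float(np.median(widths)) if widths else 0.1


def resolve_params(params: ProcessingParams, run: CentroidRun) -> ProcessingParams:
    """Fill the "auto" peak-detection settings from the data."""
    width = params.peak_width_5pct
    if width == "auto":
        width = estimate_peak_width(run, params)
    sg = params.sg_window
    if sg == "auto":
        dt = float(np.median(np.diff(run.rt_grid)))
        # window ~ FWHM (half the 5%-height width): wide enough to suppress
        # noise, narrow enough not to flatten the peak or ring at its flanks
        sg = int(round(0.5 * width / dt)) | 1  # odd
        sg = min(max(sg, params.sg_polyorder + 2 + (params.sg_polyorder % 2)), 31)
        if sg % 2 == 0:
            sg += 1
    thr = params.baseline_threshold
    if thr == "auto":
        thr = 3.0
    return replace(params, sg_window=sg, peak_width_5pct=width, baseline_threshold=thr)


def _interp_crossing(rt, y, i0, i1, level):
    """Rt where y crosses `level` between samples i0 and i1 (linear)."""
    y0, y1 = y[i0], y[i1]
    if y1 == y0:
        return rt[i1]
    f = (level - y0) / (y1 - y0)
    return rt[i0] + f * (rt[i1] - rt[i0])


def _detect_on_eic(sample_id, roi, grid, smooth, d1, d2, params) -> list[Peak]:
    n = len(grid)
    neg = d2 < 0
    # maximal runs of negative second derivative
    edges = np.flatnonzero(np.diff(np.r_[0, neg.view(np.int8), 0]))
    runs = list(zip(edges[::2], edges[1::2] - 1))  # inclusive bounds
    if not runs:
        return []
    in_run = np.zeros(n, bool)
    for a, b in runs:
        in_run[a:b + 1] = True
    outside = ~in_run
    if outside.any():
        slope_noise = 1.4826 * float(np.median(np.abs(d1[outside])))
    else:
        slope_noise = 0.0

    mem_scan = np.asarray(roi.scan_idx, int)
    mem_mz = np.asarray(roi.mz, float)
    mem_int = np.asarray(roi.intensity, float)

    peaks = []
    for a, b in runs:
        apex = a + int(np.argmax(smooth[a:b + 1]))
        if smooth[apex] <= 0:
            continue
        # integration bounds: walk outward to the nearest local minimum
        l = a
        while l > 0 and smooth[l - 1] < smooth[l]:
            l -= 1
        r = b
        while r < n - 1 and smooth[r + 1] < smooth[r]:
            r += 1
        base_l, base_r = smooth[l], smooth[r]
        if r == l:
            continue
        baseline = base_l + (base_r - base_l) * (grid[l:r + 1] - grid[l]) / (grid[r] - grid[l])
        signal = smooth[l:r + 1] - baseline
        height = float(signal[apex - l])
        if height <= 0:
            continue
        area = float(np.trapezoid(np.clip(signal, 0, None), grid[l:r + 1]))
        if area <= 0:
            continue
        # width at 5% of height above baseline
        thr5 = 0.05 * height
        li = apex - l
        while li > 0 and signal[li - 1] > thr5:
            li -= 1
        ri = apex - l
        while ri < len(signal) - 1 and signal[ri + 1] > thr5:
            ri += 1
        rt_l5 = _interp_crossing(grid[l:r + 1], signal, max(li - 1, 0), li, thr5) if li > 0 else grid[l]
        rt_r5 = _interp_crossing(grid[l:r + 1], signal, ri, min(ri + 1, len(signal) - 1), thr5) if ri < len(signal) - 1 else grid[r]
        width5 = float(rt_r5 - rt_l5)
        # baseline-noise gate: noise-equivalent height from the slope scale
        # outside peaks and this peak's inflection half-width (h ~ e^1/2 s sigma)
        half_width = 0.5 * (grid[b] - grid[a])
        noise_height = math.e ** 0.5 * slope_noise * half_width
        if noise_height > 0 and height < params.baseline_threshold * noise_height:
            continue
        if height < params.noise_level:
            continue
        sel = (mem_scan >= l) & (mem_scan <= r)
        wsum = mem_int[sel].sum()
        mz = float((mem_mz[sel] * mem_int[sel]).sum() / wsum) if wsum > 0 else roi.mz_center
        peaks.append(Peak(
            sample_id=sample_id, mz=mz, rt_apex=float(grid[apex]),
            height=height, area=area, width_5pct=width5,
            rt_left_inflection=float(grid[a]), rt_right_inflection=float(grid[b])))
    return peaks


def detect_peaks_run(run: CentroidRun, rois: Sequence[ROI], params: ProcessingParams) -> list[Peak]:
    """Detect peaks in every ROI of a run (batched Savitzky-Golay smoothing)."""
    params = resolve_params(params, run)
    grid = run.rt_grid
    n = len(grid)
    w = int(params.sg_window)
    if n < w:
        log.warning("run %s: %d scans < SG window %d; no peaks", run.sample_id, n, w)
        return []
    usable = [roi for roi in rois if len(roi) > 0]
    if not usable:
        return []
    mat = np.zeros((len(usable), n))
    for i, roi in enumerate(usable):
        np.add.at(mat[i], np.asarray(roi.scan_idx, int), np.asarray(roi.intensity))
    dt = float(np.median(np.diff(grid)))
    smooth = savgol_filter(mat, w, params.sg_polyorder, axis=1)
    d1 = savgol_filter(mat, w, params.sg_polyorder, deriv=1, delta=dt, axis=1)
    d2 = savgol_filter(mat, w, params.sg_polyorder, deriv=2, delta=dt, axis=1)
    peaks: list[Peak] = []
    for i, roi in enumerate(usable):
        peaks.extend(_detect_on_eic(run.sample_id, roi, grid, smooth[i], d1[i], d2[i], params))
    return peaks


def detect_peaks(roi: ROI, run: CentroidRun, params: ProcessingParams) -> list[Peak]:
    """Detect chromatographic peaks in a single ROI's EIC."""
    return detect_peaks_run(run, [roi], params)


@dataclass
class Feature:
    rt: float  # consensus, intensity-weighted
    mz: float
    values: dict[str, float] = field(default_factory=dict)  # sample -> height
    _weight: float = 0.0

    def add(self, peak: Peak) -> None:
        w = self._weight + peak.height
        self.rt = (self.rt * self._weight + peak.rt_apex * peak.height) / w
        self.mz = (self.mz * self._weight + peak.mz * peak.height) / w
        self._weight = w
        self.values[peak.sample_id] = peak.height

    @property
    def feature_id(self) -> str:
        return f"{self.rt:.2f}_{self.mz:.4f}"


@dataclass
class AlignedFeatureSet:
    sample_ids: list[str]
    groups: dict[str, str]
    features: list[Feature]
    params: ProcessingParams

    def __len__(self) -> int:
        return len(self.features)


def align_peaks(peaks: Sequence[Peak], sample_ids: Sequence[str],
                groups: dict[str, str], params: ProcessingParams) -> AlignedFeatureSet:
    """Cluster peaks across samples into features within the alignment windows.

    Peaks are processed in descending height order; a peak joins the nearest
    existing feature (scaled squared distance) whose sample slot is still
    empty, else seeds a new feature.  Consensus Rt/m/z are incremental
    intensity-weighted means.
    """
    mzw, rtw = params.align_mz_window, params.align_rt_window
    order = sorted(range(len(peaks)), key=lambda i: -peaks[i].height)
    features: list[Feature] = []
    binw = 2.0 * mzw
    bins: dict[int, list[int]] = {}
    for i in order:
        pk = peaks[i]
        key = int(pk.mz / binw)
        best = None
        for k in (key - 1, key, key + 1):
            for fi in bins.get(k, ()):
                f = features[fi]
                if pk.sample_id in f.values:
                    continue
                dmz, drt = abs(f.mz - pk.mz), abs(f.rt - pk.rt_apex)
                if dmz <= mzw and drt <= rtw:
                    d = (dmz / mzw) ** 2 + (drt / rtw) ** 2
                    if best is None or d < best[0]:
                        best = (d, fi)
        if best is None:
            f = Feature(rt=pk.rt_apex, mz=pk.mz)
            f.add(pk)
            features.append(f)
            bins.setdefault(int(f.mz / binw), []).append(len(features) - 1)
        else:
            features[best[1]].add(pk)
    return AlignedFeatureSet(sample_ids=list(sample_ids), groups=dict(groups),
                             features=features, params=params)


def apply_intensity_threshold(aligned: AlignedFeatureSet,
                              params: Optional[ProcessingParams] = None) -> AlignedFeatureSet:
    """Peak-removal step: keep a feature iff some sample reaches the intensity
    threshold; within a kept feature the per-sample threshold is lowered to the
    noise elimination level (values below it become missing)."""
    p = params or aligned.params
    thr, nel = p.intensity_threshold, p.noise_level
    kept: list[Feature] = []
    for f in aligned.features:
        if not f.values:
            continue
        if max(f.values.values()) < thr:
            continue
        g = Feature(rt=f.rt, mz=f.mz, _weight=f._weight)
        g.values = {s: v for s, v in f.values.items() if v >= nel}
        kept.append(g)
    return AlignedFeatureSet(sample_ids=aligned.sample_ids, groups=aligned.groups,
                             features=kept, params=p)


@dataclass
class FeatureTable:
    """Samples x features intensity matrix with provenance."""

    values: pd.DataFrame  # index sample_id, columns feature_id, NaN = missing
    groups: pd.Series  # sample_id -> group label
    feature_meta: pd.DataFrame  # index feature_id, columns rt, mz
    provenance: dict
    noise_flags: Optional[pd.Series] = None  # feature_id -> bool

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Row subset (e.g. a training split) sharing features and provenance."""
        ids = list(sample_ids)
        return FeatureTable(values=self.values.loc[ids], groups=self.groups.loc[ids],
                           feature_meta=self.feature_meta, provenance=self.provenance,
                           noise_flags=self.noise_flags)

    def missing_fraction(self) -> float:
        return float(self.values.isna().to_numpy().mean()) if self.values.size else 0.0

    def noise_fraction(self) -> Optional[float]:
        if self.noise_flags is None or self.n_features == 0:
            return None
        return float(self.noise_flags.mean())

    def to_csv(self, path) -> None:
        path = Path(path)
        out = self.values.copy()
        out.insert(0, "group", self.groups.reindex(out.index))
        out.index.name = "sample_id"
        out.to_csv(path, na_rep="")
        sidecar = {"provenance": self.provenance,
                   "feature_meta": {fid: {"rt": float(r.rt), "mz": float(r.mz)}
                                    for fid, r in self.feature_meta.iterrows()}}
        if self.noise_flags is not None:
            sidecar["noise_flags"] = {k: bool(v) for k, v in self.noise_flags.items()}
        with open(path.with_suffix(path.suffix + ".json"), "w", encoding="utf-8") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def from_csv(cls, path) -> "FeatureTable":
        path = Path(path)
        df = pd.read_csv(path, index_col="sample_id")
        df.index.name = None
        groups = df.pop("group")
        with open(path.with_suffix(path.suffix + ".json"), encoding="utf-8") as fh:
            sidecar = json.load(fh)
        meta = pd.DataFrame.from_dict(sidecar["feature_meta"], orient="index")
        flags = sidecar.get("noise_flags")
        return cls(values=df.astype(float), groups=groups,
                   feature_meta=meta.loc[df.columns],
                   provenance=sidecar.get("provenance", {}),
                   noise_flags=None if flags is None else pd.Series(flags).reindex(df.columns))


def normalize_total_intensity(aligned: AlignedFeatureSet) -> FeatureTable:
    """Total-intensity normalization: each sample's non-missing feature
    intensities are rescaled to sum to the normalization target."""
    if not aligned.features:
        raise ValueError("no features to normalize")
    target = aligned.params.normalization_target
    fids, rts, mzs = [], [], []
    data = np.full((len(aligned.sample_ids), len(aligned.features)), np.nan)
    sample_pos = {s: i for i, s in enumerate(aligned.sample_ids)}
    seen = {}
    for j, f in enumerate(aligned.features):
        fid = f.feature_id
        if fid in seen:  # distinct features may round to the same label
            seen[fid] += 1
            fid = f"{fid}#{seen[fid]}"
        else:
            seen[fid] = 0
        fids.append(fid)
        rts.append(f.rt)
        mzs.append(f.mz)
        for s, v in f.values.items():
            data[sample_pos[s], j] = v
    sums = np.nansum(data, axis=1)
    for i, s in enumerate(aligned.sample_ids):
        if sums[i] <= 0:
            raise ValueError(f"sample {s}: total intensity is zero; cannot normalize")
    data = data * (target / sums)[:, None]
    values = pd.DataFrame(data, index=list(aligned.sample_ids), columns=fids)
    meta = pd.DataFrame({"rt": rts, "mz": mzs}, index=fids)
    prov = {"processing": aligned.params.to_dict()}
    return FeatureTable(values=values, groups=pd.Series(aligned.groups),
                        feature_meta=meta, provenance=prov)


def flag_noise_features(table: FeatureTable, truth: GroundTruth) -> FeatureTable:
    """Mark features that match no ground-truth catalog entry within the
    alignment windows (the synthetic harness's noise metric)."""
    p = table.provenance.get("processing", {})
    mzw = p.get("align_mz_window", 0.05)
    rtw = p.get("align_rt_window", 0.20)
    cat_rt = np.array([e.rt_center for e in truth.catalog])
    cat_mz = np.array([e.mz_center for e in truth.catalog])
    flags = {}
    for fid, row in table.feature_meta.iterrows():
        match = (np.abs(cat_rt - row.rt) <= rtw) & (np.abs(cat_mz - row.mz) <= mzw)
        flags[fid] = not bool(match.any())
    table.noise_flags = pd.Series(flags).reindex(table.values.columns)
    return table


def build_feature_table(runs: Sequence[CentroidRun], params: ProcessingParams,
                        truth: Optional[GroundTruth] = None) -> FeatureTable:
    """Full matrix creation for a cohort: ROIs, peaks, alignment, threshold
    removal and total-intensity normalization."""
    all_peaks: list[Peak] = []
    for run in runs:
        rois = build_rois(run, params)
        all_peaks.extend(detect_peaks_run(run, rois, params))
    groups = {r.sample_id: r.group for r in runs}
    aligned = align_peaks(all_peaks, [r.sample_id for r in runs], groups, params)
    aligned = apply_intensity_threshold(aligned)
    table = normalize_total_intensity(aligned)
    if truth is not None:
        table = flag_noise_features(table, truth)
    return table
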