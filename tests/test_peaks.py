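"""Matrix creation: ROI partitioning, peak-shape recovery, alignment,
threshold-based peak removal and normalization."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabosense.synthetic import CentroidRun, Scan, build_design, generate_cohort
from metabosense.peaks import (AlignedFeatureSet, Feature, Peak, ProcessingParams,
                               ROI, align_peaks, apply_intensity_threshold,
                               build_feature_table, build_rois, detect_peaks,
                               normalize_total_intensity)

P_TINY = ProcessingParams(rt_range=(1.0, 3.0))


def run_from_profile(grid, intensities, mz=300.0):
    scans = [Scan(rt=float(r), mz=np.array([mz]), intensity=np.array([float(i)]))
             for r, i in zip(grid, intensities)]
    return CentroidRun("s", "C", scans)


def roi_from_profile(intensities, mz=300.0):
    roi = ROI(mz_center=mz)
    for s, i in enumerate(intensities):
        roi.add(s, mz, float(i))
    return roi


class TestROIs:
    def two_ion_run(self, mz2):
        scans = [Scan(rt=1.0 + 0.005 * i, mz=np.array([]), intensity=np.array([]))
                 for i in range(5)]
        scans[1] = Scan(rt=scans[1].rt, mz=np.array([300.0]), intensity=np.array([50.0]))
        scans[2] = Scan(rt=scans[2].rt, mz=np.array([mz2]), intensity=np.array([60.0]))
        return CentroidRun("s", "C", scans)

    def test_ions_within_tolerance_share_a_roi(self):
        rois = build_rois(self.two_ion_run(300.0030), P_TINY)
        assert len(rois) == 1
        assert len(rois[0]) == 2

    def test_ions_beyond_tolerance_split(self):
        rois = build_rois(self.two_ion_run(300.020), P_TINY)
        assert len(rois) == 2

    def test_partition_covers_all_in_range_ions(self, tiny_cohort):
        _, runs, _ = tiny_cohort
        run = runs[0]
        rois = build_rois(run, P_TINY)
        n_in_range = sum(
            int(np.sum((s.mz >= 100) & (s.mz <= 1000) & (s.intensity > 0)))
            for s in run.scans if 1.0 <= s.rt <= 3.0)
        assert sum(len(r) for r in rois) == n_in_range
        # running centers drift and converged ROIs are merged, so members sit
        # within twice the tolerance of the final center
        for roi in rois:
            assert np.all(np.abs(np.asarray(roi.mz) - roi.mz_center)
                          <= 2 * P_TINY.mass_tolerance + 1e-9)

    def test_empty_run_gives_empty_list(self):
        run = CentroidRun("s", "C", [Scan(rt=1.0, mz=np.array([]), intensity=np.array([]))])
        assert build_rois(run, P_TINY) == []


class TestDetect:
    def test_gaussian_closed_form(self):
        # noiseless Gaussian, height 1000, sigma 0.05 min, zero baseline:
        # area must match h * sigma * sqrt(2*pi) within 2%
        dt = 0.005
        grid = np.arange(1.0, 3.0 + dt / 2, dt)
        h, mu, sig = 1000.0, 2.0, 0.05
        prof = h * np.exp(-0.5 * ((grid - mu) / sig) ** 2)
        peaks = detect_peaks(roi_from_profile(prof), run_from_profile(grid, prof), P_TINY)
        assert len(peaks) == 1
        pk = peaks[0]
        assert abs(pk.rt_apex - mu) <= dt + 1e-12
        assert pk.area == pytest.approx(h * sig * math.sqrt(2 * math.pi), rel=0.02)
        assert pk.rt_left_inflection < pk.rt_apex < pk.rt_right_inflection

    def test_flat_eic_has_no_peaks(self):
        grid = np.arange(1.0, 3.0, 0.005)
        prof = np.full(len(grid), 5.0)
        assert detect_peaks(roi_from_profile(prof), run_from_profile(grid, prof), P_TINY) == []

    def test_two_gaussians_ordered_apexes(self):
        dt = 0.005
        grid = np.arange(1.0, 3.0 + dt / 2, dt)
        prof = (1000 * np.exp(-0.5 * ((grid - 1.8) / 0.05) ** 2)
                + 600 * np.exp(-0.5 * ((grid - 2.3) / 0.05) ** 2))
        peaks = detect_peaks(roi_from_profile(prof), run_from_profile(grid, prof), P_TINY)
        assert len(peaks) == 2
        peaks.sort(key=lambda p: p.rt_apex)
        assert peaks[0].rt_apex == pytest.approx(1.8, abs=dt)
        assert peaks[1].rt_apex == pytest.approx(2.3, abs=dt)
        assert peaks[0].height > peaks[1].height


def _peak(sample, mz, rt, height):
    return Peak(sample_id=sample, mz=mz, rt_apex=rt, height=height, area=height,
                width_5pct=0.1, rt_left_inflection=rt - 0.02, rt_right_inflection=rt + 0.02)


class TestAlign:
    def test_same_metabolite_three_samples_one_feature(self):
        peaks = [_peak(f"s{i}", 300.0 + 0.01 * i, 5.0 + 0.05 * i, 100) for i in range(3)]
        out = align_peaks(peaks, [f"s{i}" for i in range(3)],
                          {f"s{i}": "C" for i in range(3)}, P_TINY)
        assert len(out) == 1
        assert len(out.features[0].values) == 3

    def test_peaks_beyond_rt_window_split(self):
        peaks = [_peak("a", 300.0, 5.0, 100), _peak("b", 300.0, 5.5, 100)]
        out = align_peaks(peaks, ["a", "b"], {"a": "C", "b": "T"}, P_TINY)
        assert len(out) == 2

    def test_one_slot_per_sample(self):
        # two close peaks of the same sample cannot share a feature
        peaks = [_peak("a", 300.0, 5.0, 100), _peak("a", 300.01, 5.01, 90)]
        out = align_peaks(peaks, ["a"], {"a": "C"}, P_TINY)
        assert len(out) == 2


def aligned_from_values(values_by_feature, params=P_TINY):
    samples = sorted({s for vals in values_by_feature for s in vals})
    feats = []
    for j, vals in enumerate(values_by_feature):
        f = Feature(rt=2.0 + 0.5 * j, mz=200.0 + 10.0 * j)
        f.values = dict(vals)
        f._weight = sum(vals.values())
        feats.append(f)
    return AlignedFeatureSet(sample_ids=samples, groups={s: "C" for s in samples},
                             features=feats, params=params)


class TestThreshold:
    def test_lowered_per_sample_threshold_rule(self):
        # above threshold in one sample lowers the others' threshold down to
        # the noise elimination level
        aligned = aligned_from_values([{"a": 120.0, "b": 40.0, "c": 8.0}],
                                      ProcessingParams(rt_range=(1.0, 3.0),
                                                       intensity_threshold=100.0,
                                                       noise_elimination_level=10.0))
        out = apply_intensity_threshold(aligned)
        assert len(out) == 1
        assert out.features[0].values == {"a": 120.0, "b": 40.0}

    def test_feature_below_threshold_everywhere_removed(self):
        aligned = aligned_from_values([{"a": 90.0, "b": 80.0}],
                                      ProcessingParams(rt_range=(1.0, 3.0),
                                                       intensity_threshold=100.0))
        assert len(apply_intensity_threshold(aligned)) == 0

    def test_monotone_in_threshold_on_cohort(self, tiny_cohort):
        _, runs, truth = tiny_cohort
        stats = {}
        for thr in (10.0, 100.0):
            p = ProcessingParams(rt_range=(1.0, 3.0), intensity_threshold=thr)
            t = build_feature_table(runs, p, truth=truth)
            stats[thr] = (t.n_features, t.noise_fraction())
        assert stats[100.0][0] < stats[10.0][0]
        assert stats[100.0][1] < stats[10.0][1]


@given(st.lists(st.dictionaries(st.sampled_from("abcdef"),
                                st.floats(0.1, 1000.0), min_size=1),
                min_size=1, max_size=8),
       st.floats(1.0, 500.0), st.floats(1.0, 500.0))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_threshold_monotone_for_any_feature_set(values_by_feature, t1, t2):
    """A higher intensity threshold never keeps a feature (or a value) that a
    lower one removed."""
    lo, hi = sorted((t1, t2))
    kept = {}
    for thr in (lo, hi):
        p = ProcessingParams(rt_range=(1.0, 3.0), intensity_threshold=thr,
                             noise_elimination_level=min(thr / 10, thr))
        out = apply_intensity_threshold(aligned_from_values(values_by_feature, p))
        kept[thr] = {(f.rt, f.mz): set(f.values) for f in out.features}
    assert set(kept[hi]) <= set(kept[lo])
    for key, samples in kept[hi].items():
        assert samples <= kept[lo][key]


class TestNormalize:
    def test_proportional_rescale(self):
        aligned = aligned_from_values([{"a": 2.0}, {"a": 3.0}, {"a": 5.0}])
        table = normalize_total_intensity(aligned)
        np.testing.assert_allclose(table.values.loc["a"].to_numpy(), [2000, 3000, 5000])

    def test_row_sums_conserved_and_scale_invariant(self, tiny_table):
        sums = tiny_table.values.sum(axis=1, skipna=True)
        np.testing.assert_allclose(sums.to_numpy(), 10000.0, rtol=1e-9)
        # doubling one sample's raw intensities leaves its normalized row alone
        aligned = aligned_from_values([{"a": 2.0, "b": 4.0}, {"a": 3.0, "b": 6.0}])
        base = normalize_total_intensity(aligned)
        doubled = aligned_from_values([{"a": 4.0, "b": 4.0}, {"a": 6.0, "b": 6.0}])
        table2 = normalize_total_intensity(doubled)
        np.testing.assert_allclose(table2.values.loc["a"].to_numpy(),
                                   base.values.loc["a"].to_numpy())

    def test_zero_sum_sample_is_an_error(self):
        aligned = aligned_from_values([{"a": 0.0, "b": 5.0}])
        with pytest.raises(ValueError, match="a"):
            normalize_total_intensity(aligned)


class TestRecovery:
    def test_no_noise_cohort_fully_recovered(self):
        # with no noise and well-separated metabolites the aligned matrix has
        # one feature per catalog entry, zero missing cells, and feature
        # coordinates match the planted truth
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 3.0),
                         n_background_metabolites=15, n_discriminating_metabolites=5,
                         noise_ion_density=0.0, adduct_probability=0.0,
                         mz_jitter_sd=0.001, intensity_cv=0.1, seed=21)
        runs, truth = generate_cohort(d)
        p = ProcessingParams(rt_range=(1.0, 3.0), intensity_threshold=10.0)
        table = build_feature_table(runs, p, truth=truth)
        assert table.n_features == len(truth.catalog)
        assert table.missing_fraction() == 0.0
        cat = sorted(truth.catalog, key=lambda e: e.mz_center)
        feats = table.feature_meta.sort_values("mz")
        for e, (_, row) in zip(cat, feats.iterrows()):
            assert abs(row.rt - e.rt_center) <= d.scan_interval + 1e-9
            assert abs(row.mz - e.mz_center) <= 2 * d.mz_jitter_sd + 1e-9

    def test_roundtrip_feature_table_csv(self, tiny_table, tmp_path):
        path = tmp_path / "table.csv"
        tiny_table.to_csv(path)
        from metabosense.peaks import FeatureTable
        back = FeatureTable.from_csv(path)
        pd.testing.assert_frame_equal(back.values, tiny_table.values)
        assert list(back.groups) == list(tiny_table.groups)
        assert back.noise_flags.equals(tiny_table.noise_flags)
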