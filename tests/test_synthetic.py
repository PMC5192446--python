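"""Synthetic cohort generator: design validation, determinism, ground-truth
calibration, and run file round trips."""

import math

import numpy as np
import pytest

from metabosense.synthetic import (DesignError, build_design, generate_cohort,
                                   NA_H_SHIFT)
from metabosense.io import (RunParseError, read_run_csv, read_run_mzml,
                            read_runs, write_run_csv, write_run_mzml, write_runs)


class TestDesign:
    def test_defaults_match_study_layout(self):
        d = build_design()
        assert d.n_control == 9
        assert d.n_treated == 15
        assert d.rt_range == (1.0, 15.0)
        assert d.mz_range == (100.0, 1000.0)
        assert d.n_background_metabolites + d.n_discriminating_metabolites == 200

    @pytest.mark.parametrize("bad", [
        {"n_control": 2},
        {"n_treated": 2},
        {"mz_range": (1000.0, 100.0)},
        {"intensity_cv": -0.1},
        {"fold_changes": (0.0,)},
        {"scan_interval": 0.0},
        {"no_such_field": 1},
    ])
    def test_invalid_config_raises_naming_error(self, bad):
        with pytest.raises(DesignError):
            build_design(**bad)

    def test_override_is_respected(self):
        d = build_design(mz_range=(100.0, 1000.0), n_control=5)
        assert d.mz_range == (100.0, 1000.0)
        assert d.n_control == 5


class TestGenerate:
    def test_determinism_bitwise(self):
        d = build_design(**{**_small(), "seed": 7})
        runs_a, truth_a = generate_cohort(d)
        runs_b, truth_b = generate_cohort(d)
        assert truth_a.sample_intensities == truth_b.sample_intensities
        for ra, rb in zip(runs_a, runs_b):
            for sa, sb in zip(ra.scans, rb.scans):
                assert sa.rt == sb.rt
                assert np.array_equal(sa.mz, sb.mz)
                assert np.array_equal(sa.intensity, sb.intensity)

    def test_no_noise_ions_lie_in_metabolite_envelopes(self):
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 2.0),
                         n_background_metabolites=1, n_discriminating_metabolites=0,
                         noise_ion_density=0.0, adduct_probability=0.0, seed=3)
        runs, truth = generate_cohort(d)
        entry = truth.catalog[0]
        for run in runs:
            for scan in run.scans:
                for mz, inten in zip(scan.mz, scan.intensity):
                    if inten > 0:
                        assert abs(scan.rt - entry.rt_center) <= 4 * d.peak_sigma_rt + 1e-9
                        assert abs(mz - entry.mz_center) <= 4 * d.mz_jitter_sd + 1e-9

    def test_every_catalog_entry_appears_in_every_run(self):
        # conservation: planted peaks per run equal catalog size without noise
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 3.0),
                         n_background_metabolites=10, n_discriminating_metabolites=2,
                         noise_ion_density=0.0, seed=4)
        runs, truth = generate_cohort(d)
        for run in runs:
            for e in truth.catalog:
                hits = sum(
                    1 for scan in run.scans
                    if abs(scan.rt - e.rt_center) <= d.scan_interval / 2
                    and np.any(np.abs(scan.mz - e.mz_center) <= 5 * d.mz_jitter_sd + 1e-9))
                assert hits == 1, f"{e.id} missing from {run.sample_id}"

    def test_fold_change_calibration(self):
        # lognormal noise is mean-preserving: E[treated]/E[control] = 8;
        # +/- 2 SE band computed from the lognormal mean ratio at cv = 0.1
        d = build_design(n_control=9, n_treated=15, rt_range=(1.0, 2.0),
                         n_background_metabolites=0, n_discriminating_metabolites=10,
                         fold_changes=(8.0,), intensity_cv=0.1,
                         noise_ion_density=0.0, adduct_probability=0.0, seed=5)
        runs, truth = generate_cohort(d)
        ratios = []
        for e in truth.catalog:
            tre = np.mean([truth.sample_intensities[f"T{i:02d}"][e.id] for i in range(1, 16)])
            ctl = np.mean([truth.sample_intensities[f"C{i:02d}"][e.id] for i in range(1, 10)])
            ratios.append(tre / ctl)
        assert 6.0 <= np.mean(ratios) <= 10.7

    def test_fold_change_exact_at_zero_cv(self):
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 2.0),
                         n_background_metabolites=0, n_discriminating_metabolites=2,
                         fold_changes=(4.0,), intensity_cv=0.0,
                         noise_ion_density=0.0, adduct_probability=0.0, seed=6)
        _, truth = generate_cohort(d)
        for e in truth.catalog:
            t = truth.sample_intensities["T01"][e.id]
            c = truth.sample_intensities["C01"][e.id]
            assert t / c == pytest.approx(4.0, rel=1e-12)

    def test_adducts_are_correlated_companions(self):
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 2.0),
                         n_background_metabolites=20, n_discriminating_metabolites=0,
                         adduct_probability=1.0, noise_ion_density=0.0, seed=8)
        _, truth = generate_cohort(d)
        adducts = [e for e in truth.catalog if e.adduct_of is not None]
        assert adducts
        for a in adducts:
            assert a.mz_center == pytest.approx(
                truth.entry(a.adduct_of).mz_center + NA_H_SHIFT)
            # realized intensities perfectly track the parent (r = 1 pre-noise)
            for sid, vals in truth.sample_intensities.items():
                ratio = vals[a.id] / vals[a.adduct_of]
                assert ratio == pytest.approx(a.base_intensity
                                              / truth.entry(a.adduct_of).base_intensity)


@pytest.fixture(scope="module")
def one_run():
    d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 1.2),
                     n_background_metabolites=5, n_discriminating_metabolites=0,
                     noise_ion_density=0.5, seed=9)
    runs, _ = generate_cohort(d)
    return runs[0]


class TestRoundTrip:
    @staticmethod
    def assert_runs_equal(a, b):
        assert len(a.scans) == len(b.scans)
        for sa, sb in zip(a.scans, b.scans):
            assert sa.rt == pytest.approx(sb.rt, abs=1e-12)
            np.testing.assert_allclose(sa.mz, sb.mz, rtol=1e-12)
            np.testing.assert_allclose(sa.intensity, sb.intensity, rtol=1e-12)

    def test_run_csv_round_trip(self, one_run, tmp_path):
        path = tmp_path / "r.csv"
        write_run_csv(one_run, path)
        back = read_run_csv(path)
        self.assert_runs_equal(one_run, back)

    def test_mzml_round_trip_via_pyteomics(self, one_run, tmp_path):
        path = tmp_path / "r.mzML"
        write_run_mzml(one_run, path)
        back = read_run_mzml(path)
        self.assert_runs_equal(one_run, back)

    def test_cohort_manifest_round_trip(self, tmp_path):
        d = build_design(n_control=3, n_treated=3, rt_range=(1.0, 1.1),
                         n_background_metabolites=3, n_discriminating_metabolites=0,
                         seed=10)
        runs, _ = generate_cohort(d)
        manifest = write_runs(runs, tmp_path / "cohort", fmt="run-csv")
        back = read_runs(manifest)
        assert [r.sample_id for r in back] == [r.sample_id for r in runs]
        assert [r.group for r in back] == [r.group for r in runs]
        for a, b in zip(runs, back):
            self.assert_runs_equal(a, b)

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            write_runs([], tmp_path / "x", fmt="netCDF")

    def test_decreasing_rt_is_a_parse_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("rt_min,mz,intensity\n2.0,100.0,5.0\n1.0,100.0,5.0\n")
        with pytest.raises(RunParseError):
            read_run_csv(path)


def _small():
    return dict(n_control=3, n_treated=3, rt_range=(1.0, 2.0),
                n_background_metabolites=5, n_discriminating_metabolites=2)
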