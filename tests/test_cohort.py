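"""Cohort I/O, mask volumetry and scan-interval summaries."""

import numpy as np
import pandas as pd
import pytest

from hgsoc_kinetics import (
    Cohort,
    LesionSeries,
    MaskSpec,
    Site,
    mask_volume,
    read_cohort,
    scan_interval_summary,
    write_cohort,
)
from hgsoc_kinetics.cohort import cohort_from_frame, nifti_mask_volume


def _series(pid, site, days, vols):
    return LesionSeries(patient_id=pid, site=Site.parse(site), scan_days=tuple(days), volumes=tuple(vols))


class TestMaskVolume:
    def test_ten_voxels(self):
        mask = np.zeros((5, 5, 5), dtype=int)
        mask.flat[:10] = 1
        assert mask_volume(MaskSpec(mask=mask, voxel_volume=0.001)) == pytest.approx(0.01)

    def test_empty_lesion(self):
        assert mask_volume(MaskSpec(mask=np.zeros((4, 4, 4)), voxel_volume=0.7)) == 0.0

    def test_matches_elementwise_loop_oracle(self):
        rng = np.random.default_rng(42)
        mask = (rng.random((20, 20, 20)) < 0.3).astype(int)
        dv = 0.0025
        count = 0
        for z in mask.ravel():  # independent brute-force voxel count
            if z == 1:
                count += 1
        assert mask_volume(MaskSpec(mask=mask, voxel_volume=dv)) == pytest.approx(count * dv)

    def test_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(0)
        a = (rng.random((10, 10, 10)) < 0.4).astype(int)
        b = ((rng.random((10, 10, 10)) < 0.4) & (a == 0)).astype(int)
        dv = 0.01
        va = mask_volume(MaskSpec(a, dv))
        vb = mask_volume(MaskSpec(b, dv))
        assert mask_volume(MaskSpec(a | b, dv)) == pytest.approx(va + vb)

    def test_non_binary_mask_rejected(self):
        with pytest.raises(ValueError, match="0/1"):
            mask_volume(MaskSpec(mask=np.array([[0, 2]]), voxel_volume=0.1))

    def test_non_positive_voxel_volume_rejected(self):
        with pytest.raises(ValueError, match="voxel_volume"):
            mask_volume(MaskSpec(mask=np.array([[0, 1]]), voxel_volume=0.0))

    def test_nifti_mask(self, tmp_path):
        nib = pytest.importorskip("nibabel")
        mask = np.zeros((6, 6, 6), dtype=np.uint8)
        mask[1:3, 1:4, 2] = 1  # 6 voxels
        affine = np.diag([2.0, 2.0, 5.0, 1.0])  # mm spacing -> dv = 20 mm^3
        path = tmp_path / "mask.nii.gz"
        nib.Nifti1Image(mask, affine).to_filename(str(path))
        assert nifti_mask_volume(path) == pytest.approx(6 * 20.0 / 1000.0)


class TestReadWrite:
    def test_two_row_file_single_series(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,site,scan_day,volume_cm3\nA,omentum,0,1.5\nA,omentum,30,2.5\n")
        cohort = read_cohort(p)
        assert len(cohort) == 1
        s = cohort.series[0]
        assert s.volumes == (1.5, 2.5) and s.scan_days == (0.0, 30.0)

    def test_rows_sorted_by_scan_day(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,site,scan_day,volume_cm3\nA,ovary,30,2.5\nA,ovary,0,1.5\n")
        s = read_cohort(p).series[0]
        assert s.scan_days == (0.0, 30.0) and s.volumes == (1.5, 2.5)

    def test_duplicate_measurement_named_in_error(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(
            "patient_id,site,scan_day,volume_cm3\nA,omentum,0,1.0\nA,omentum,0,1.2\n"
        )
        with pytest.raises(ValueError, match="duplicate.*'A'"):
            read_cohort(p)

    def test_missing_column(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,site,scan_day\nA,omentum,0\n")
        with pytest.raises(ValueError, match="volume_cm3"):
            read_cohort(p)

    def test_unparseable_number_named(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("patient_id,site,scan_day,volume_cm3\nA,omentum,0,abc\n")
        with pytest.raises(ValueError, match="abc"):
            read_cohort(p)

    def test_round_trip_preserves_measurements(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        path = tmp_path / "cohort.csv"
        write_cohort(cohort, path)
        back = read_cohort(path)
        assert len(back) == len(cohort)
        for s in cohort:
            r = back.get(s.patient_id, s.site)
            assert r is not None
            np.testing.assert_allclose(r.volumes, s.volumes, rtol=1e-9)
            np.testing.assert_allclose(r.scan_days, s.scan_days, rtol=1e-9)


class TestDomainTypes:
    def test_site_synonyms_normalised(self):
        for label in ["Ovary", "PELVIS", "ovaries/pelvis", "ovary_pelvis", "Ovarian"]:
            assert Site.parse(label) is Site.OVARY_PELVIS
        for label in ["Omentum", "omental"]:
            assert Site.parse(label) is Site.OMENTUM
        with pytest.raises(ValueError, match="unrecognised"):
            Site.parse("liver")

    def test_series_requires_increasing_days(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _series("A", "omentum", [0, 0], [1.0, 2.0])

    def test_series_rejects_negative_volume(self):
        with pytest.raises(ValueError, match="finite"):
            _series("A", "omentum", [0, 10], [1.0, -2.0])

    def test_cohort_unique_patient_site(self):
        s = _series("A", "omentum", [0, 10], [1.0, 2.0])
        with pytest.raises(ValueError, match="duplicate"):
            Cohort(series=(s, s))


class TestScanIntervalSummary:
    def test_median_of_three_patients(self):
        cohort = Cohort(
            series=(
                _series("A", "omentum", [0, 10], [1, 2]),
                _series("B", "omentum", [0, 31], [1, 2]),
                _series("C", "omentum", [0, 50], [1, 2]),
            )
        )
        out = scan_interval_summary(cohort)
        assert out["median_days"] == pytest.approx(31.0)

    def test_single_patient_zero_iqr_width(self):
        cohort = Cohort(series=(_series("A", "ovary", [0, 31], [1, 2]),))
        out = scan_interval_summary(cohort)
        assert out["median_days"] == 31.0
        q1, q3 = out["iqr_days"]
        assert q3 - q1 == 0.0

    def test_invariant_under_row_permutation(self, tmp_path, default_cohort):
        cohort, _ = default_cohort
        df = cohort.to_frame()
        shuffled = df.sample(frac=1.0, random_state=5)
        out_a = scan_interval_summary(cohort)
        out_b = scan_interval_summary(cohort_from_frame(shuffled))
        assert out_a == out_b

    def test_error_when_no_repeat_scans(self):
        cohort = Cohort(series=(_series("A", "ovary", [0], [1.0]),))
        with pytest.raises(ValueError, match="two or more"):
            scan_interval_summary(cohort)
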