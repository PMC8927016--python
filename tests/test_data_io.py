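"""Format round-trips, validation rules, and split stratification."""

import nibabel as nib
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ignet import data_io
from ignet.data_io import (GenotypeMatrix, VolumeRecord, assemble_cohort,
                           build_sequences, impute_missing, normalize_volume,
                           read_genotypes, read_volume, stratified_split,
                           write_genotypes_tsv, write_volume)


# ---------------- volumes ----------------

class TestVolumes:
    def test_roundtrip_is_voxel_identical(self, tmp_path, rng):
        voxels = rng.integers(0, 256, (32, 32, 32)).astype(np.int16)
        rec = VolumeRecord(subject_id="S1", voxels=voxels)
        path = tmp_path / "S1.nii.gz"
        write_volume(rec, path)
        back = read_volume(path)
        np.testing.assert_array_equal(back.voxels, voxels)
        assert back.dims == (32, 32, 32)
        assert back.voxels.min() >= 0 and back.voxels.max() <= 255

    def test_4d_image_rejected(self, tmp_path):
        img = nib.Nifti1Image(np.zeros((4, 4, 4, 2), dtype=np.float32), np.eye(4))
        path = tmp_path / "ts.nii"
        nib.save(img, path)
        with pytest.raises(ValueError, match="3D"):
            read_volume(path)

    def test_unreadable_file_rejected(self, tmp_path):
        path = tmp_path / "junk.nii"
        path.write_text("not a nifti")
        with pytest.raises(ValueError, match="cannot read"):
            read_volume(path)

    @pytest.mark.parametrize("value,expected", [
        (0, 0.0), (255, 1.0), (128, 128 / 255)])
    def test_normalization_closed_forms(self, value, expected):
        rec = VolumeRecord("S1", np.full((2, 2, 2), value, dtype=float))
        out = normalize_volume(rec)
        np.testing.assert_allclose(out.voxels, expected)

    def test_out_of_range_intensity_rejected(self):
        rec = VolumeRecord("S1", np.full((2, 2, 2), 300.0))
        with pytest.raises(ValueError, match="outside"):
            normalize_volume(rec)

    def test_two_axis_volume_rejected(self):
        with pytest.raises(ValueError, match="axes"):
            VolumeRecord("S1", np.zeros((4, 4)))


# ---------------- genotypes ----------------

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID=19>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)


class TestGenotypes:
    def test_vcf_gt_coding(self, tmp_path):
        path = tmp_path / "g.vcf"
        write_vcf(path, "19\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\t0/1\t1/1\n"
                        "19\t200\trs2\tC\tT\t.\t.\t.\tGT\t1/0\t./.\t0|0\n")
        g = read_genotypes(path, format="vcf")
        assert g.subject_ids == ["S1", "S2", "S3"]
        np.testing.assert_array_equal(g.dosages["rs1"], [0, 1, 2])
        assert g.dosages.loc["S1", "rs2"] == 1
        assert np.isnan(g.dosages.loc["S2", "rs2"])
        assert g.dosages.loc["S3", "rs2"] == 0

    def test_multiallelic_site_rejected_by_name(self, tmp_path):
        path = tmp_path / "m.vcf"
        write_vcf(path, "19\t300\trsX\tA\tG,T\t.\t.\t.\tGT\t0/1\t0/2\t1/1\n")
        with pytest.raises(ValueError, match="19:300"):
            read_genotypes(path, format="vcf")

    def test_tsv_roundtrip_cell_for_cell(self, tmp_path, rng):
        ids = pd.Index([f"S{i}" for i in range(5)], name="subject_id")
        df = pd.DataFrame(rng.integers(0, 3, (5, 4)).astype(float),
                          index=ids, columns=list("abcd"))
        df.iloc[0, 0] = np.nan
        g = GenotypeMatrix(dosages=df)
        path = tmp_path / "g.tsv"
        write_genotypes_tsv(g, path)
        back = read_genotypes(path, format="tsv")
        pd.testing.assert_frame_equal(back.dosages, g.dosages,
                                      check_names=False)

    def test_tsv_dosage_outside_coding_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("subject_id\trs1\nS1\t3\n")
        with pytest.raises(ValueError, match="outside"):
            read_genotypes(path, format="tsv")

    def test_impute_uses_training_mode_only(self):
        ids = pd.Index([f"S{i}" for i in range(6)], name="subject_id")
        df = pd.DataFrame({"rs1": [2.0, 2.0, 0.0, np.nan, 0.0, 0.0]}, index=ids)
        g = GenotypeMatrix(dosages=df)
        # training subjects have mode 2; cohort-wide mode would be 0
        out = impute_missing(g, training_ids=ids[:2])
        assert out.dosages.loc["S3", "rs1"] == 2.0
        assert out.n_missing == 0


# ---------------- splitting ----------------

def _labels(n_ad, n_cn):
    ids = [f"A{i}" for i in range(n_ad)] + [f"C{i}" for i in range(n_cn)]
    return pd.Series([1] * n_ad + [0] * n_cn,
                     index=pd.Index(ids, name="subject_id"))


class TestStratifiedSplit:
    def test_study_sized_cohort_ratios(self):
        labels = _labels(174, 205)
        split = stratified_split(labels, seed=0)
        test = labels[split == "test"]
        assert len(test) in (37, 38)
        ratio = (test == 1).sum() / (test == 0).sum()
        assert ratio == pytest.approx(174 / 205, abs=0.15)

    def test_ten_subject_partition_sizes(self):
        labels = _labels(5, 5)
        split = stratified_split(labels, seed=1)
        counts = split.value_counts()
        assert counts["train"] == 8 and counts["val"] == 1 and counts["test"] == 1
        assert set(split.index) == set(labels.index)

    def test_deterministic_per_seed(self):
        labels = _labels(20, 30)
        a = stratified_split(labels, seed=5)
        b = stratified_split(labels, seed=5)
        pd.testing.assert_series_equal(a, b)
        assert not stratified_split(labels, seed=6).equals(a)

    @given(st.integers(10, 60), st.integers(10, 60), st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_every_subject_assigned_exactly_once(self, n_ad, n_cn, seed):
        labels = _labels(n_ad, n_cn)
        split = stratified_split(labels, seed=seed)
        assert len(split) == n_ad + n_cn
        assert set(split.unique()) <= {"train", "val", "test"}

    def test_stratification_within_five_points_large_classes(self):
        labels = _labels(120, 150)
        split = stratified_split(labels, seed=3)
        overall = labels.mean()
        for part in ("train", "val", "test"):
            frac = labels[split == part].mean()
            assert frac == pytest.approx(overall, abs=0.05)

    def test_cohort_too_small_for_all_partitions_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            stratified_split(_labels(2, 1), seed=0)

    def test_split_file_roundtrip(self, tmp_path):
        labels = _labels(10, 10)
        split = stratified_split(labels, seed=0)
        path = tmp_path / "split.tsv"
        data_io.write_split(split, path)
        back = data_io.read_split(path)
        pd.testing.assert_series_equal(split, back)


# ---------------- cohort assembly ----------------

def _sources(n=3):
    ids = [f"S{i}" for i in range(n)]
    vols = {sid: np.zeros((2, 2, 2), dtype=np.float32) for sid in ids}
    geno = GenotypeMatrix(dosages=pd.DataFrame(
        np.ones((n, 2)), index=pd.Index(ids, name="subject_id"),
        columns=["rs1", "rs2"]))
    apoe = pd.Series([0] * n, index=pd.Index(ids, name="subject_id"))
    labels = pd.Series([1, 0, 1][:n], index=pd.Index(ids, name="subject_id"))
    return vols, geno, apoe, labels


class TestAssembleCohort:
    def test_inner_join_sorted(self):
        vols, geno, apoe, labels = _sources()
        cohort = assemble_cohort(vols, geno, apoe, labels)
        assert cohort.subject_ids == sorted(vols)
        assert len(cohort) == 3 and cohort.n_dropped == 0

    def test_subject_missing_a_modality_dropped_and_counted(self):
        vols, geno, apoe, labels = _sources()
        labels.loc["S9"] = 1
        cohort = assemble_cohort(vols, geno, apoe, labels)
        assert "S9" not in cohort.subject_ids
        assert cohort.n_dropped == 1

    def test_duplicate_subject_rejected(self):
        vols, geno, apoe, labels = _sources()
        labels = pd.concat([labels, labels.iloc[:1]])
        with pytest.raises(ValueError, match="duplicat"):
            assemble_cohort(vols, geno, apoe, labels)

    def test_empty_intersection_rejected(self):
        vols, geno, apoe, labels = _sources()
        labels.index = pd.Index(["X1", "X2", "X3"], name="subject_id")
        with pytest.raises(ValueError, match="no subject"):
            assemble_cohort(vols, geno, apoe, labels)

    def test_sequences_place_apoe_token(self, small_cohort):
        from ignet.snp_selection import SelectedPanel, append_apoe
        snps = small_cohort.genotypes.snp_ids[:3]
        panel = append_apoe(SelectedPanel(snp_ids=snps,
                                          p_values=[1e-4] * 3))
        tokens = build_sequences(small_cohort, panel)
        assert tokens.shape == (len(small_cohort.subject_ids), 4)
        np.testing.assert_array_equal(tokens[:, 3],
                                      small_cohort.apoe.to_numpy())
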