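"""Parsing, feature extraction, truth labeling and class balancing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tlsub.errors import ConfigurationError, FeatureExtractionError, VCFFormatError
from tlsub.vcf_features import (
    FEATURE_NAMES,
    LabeledDataset,
    VariantRecord,
    balance_classes,
    extract_features,
    label_by_truth,
    parse_vcf,
)

FIDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def make_record(info=None, fmt=None, qual=None, **kw):
    defaults = dict(chrom="chr1", pos=100, ref="N", alt="<DEL>", filter=".", id="r1")
    defaults.update(kw)
    return VariantRecord(info=info or {}, sample_format=fmt or {}, qual=qual, **defaults)


class TestParseVcf:
    def test_record_count_and_order(self, toy_vcf_path):
        records = parse_vcf(toy_vcf_path)
        assert [r.id for r in records] == ["v1", "v2", "v3"]
        assert [r.pos for r in records] == [1000, 5000, 9000]

    def test_info_flag_convention(self, toy_vcf_path):
        rec = parse_vcf(toy_vcf_path)[0]
        assert rec.info["IMPRECISE"] == "1"
        assert rec.info["CIPOS"] == "-10,10"

    def test_first_sample_format_map(self, toy_vcf_path):
        rec = parse_vcf(toy_vcf_path)[0]
        assert rec.sample_format["GT"] == "0/1"
        assert float(rec.sample_format["QR"]) == 70.0

    def test_missing_qual(self, toy_vcf_path):
        assert parse_vcf(toy_vcf_path)[1].qual is None

    def test_headerless_file_is_a_format_error(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("chr1\t100\t.\tA\tT\t50\t.\tDP=3\n")
        with pytest.raises(VCFFormatError):
            parse_vcf(bad)

    def test_missing_file(self, tmp_path):
        with pytest.raises(VCFFormatError):
            parse_vcf(tmp_path / "nope.vcf")

    def test_empty_body_is_not_an_error(self, tmp_path):
        path = tmp_path / "empty.vcf"
        path.write_text(
            "##fileformat=VCFv4.1\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        assert parse_vcf(path) == []


class TestExtractFeatures:
    def test_always_26_features(self):
        assert extract_features(make_record()).shape == (26,)
        full = make_record(
            info={"IMPRECISE": "1", "CIPOS": "-10,10", "PE": "3", "SR": "2", "DP": "100"},
            fmt={"GT": "0/1", "SU": "5", "GQ": "40", "GL": "-10,0,-20",
                 "QR": "70", "QA": "30", "CN": "2.5"},
            qual=55.0,
        )
        assert extract_features(full).shape == (26,)

    def test_allele_balance_formula(self):
        rec = make_record(fmt={"QA": "30", "QR": "70"})
        assert extract_features(rec)[FIDX["AB"]] == pytest.approx(0.30)

    def test_allele_balance_zero_denominator(self):
        rec = make_record(fmt={"QA": "0", "QR": "0"})
        assert extract_features(rec)[FIDX["AB"]] == 0.0

    def test_interval_width_encoding(self):
        rec = make_record(info={"CIPOS": "-10,10", "CIEND": "0,4"})
        vec = extract_features(rec)
        assert vec[FIDX["CIPOS"]] == 20.0
        assert vec[FIDX["CIEND"]] == 4.0

    @pytest.mark.parametrize(
        "gt,expected",
        [("0/0", 0), ("0/1", 1), ("1/0", 1), ("1/1", 2), ("1|0", 1), ("./.", -1)],
    )
    def test_genotype_encoding(self, gt, expected):
        rec = make_record(fmt={"GT": gt})
        assert extract_features(rec)[FIDX["GT"]] == expected

    def test_missing_fields_imputed(self):
        vec = extract_features(make_record())
        assert vec[FIDX["IMPRECISE"]] == 0.0
        assert vec[FIDX["DP"]] == 0.0
        assert vec[FIDX["GT"]] == -1.0  # missing genotype sentinel

    def test_qual_is_sq(self):
        assert extract_features(make_record(qual=42.0))[FIDX["SQ"]] == 42.0

    def test_gl_first_three(self):
        rec = make_record(fmt={"GL": "-1.5,0,-30.25"})
        vec = extract_features(rec)
        assert (vec[FIDX["GL1"]], vec[FIDX["GL2"]], vec[FIDX["GL3"]]) == (-1.5, 0.0, -30.25)

    def test_qr_qa_fall_back_to_format_ro_ao(self):
        rec = make_record(fmt={"RO": "80", "AO": "20"})
        vec = extract_features(rec)
        assert vec[FIDX["QR"]] == 80.0 and vec[FIDX["QA"]] == 20.0
        # explicit QR/QA tags win over the fallback
        rec2 = make_record(fmt={"RO": "80", "AO": "20", "QR": "700", "QA": "300"})
        assert extract_features(rec2)[FIDX["QA"]] == 300.0

    def test_multiallelic_takes_first_value(self):
        rec = make_record(info={"AO": "5,3"})
        assert extract_features(rec)[FIDX["AO"]] == 5.0

    def test_non_numeric_field_raises_naming_record_and_field(self):
        rec = make_record(info={"DP": "lots"}, id="oddball")
        with pytest.raises(FeatureExtractionError, match="oddball.*DP"):
            extract_features(rec)

    @given(qa=st.integers(0, 10_000), qr=st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_ab_always_in_unit_interval(self, qa, qr):
        rec = make_record(fmt={"QA": str(qa), "QR": str(qr)})
        assert 0.0 <= extract_features(rec)[FIDX["AB"]] <= 1.0


class TestLabelByTruth:
    def test_exact_match(self):
        recs = [make_record(pos=1000)]
        assert label_by_truth(recs, [("chr1", 1000, 2000, "DEL")], window=0).tolist() == [1]

    def test_outside_window(self):
        recs = [make_record(pos=1000)]
        assert label_by_truth(recs, [("chr1", 1300, 2300, "DEL")], window=200).tolist() == [0]

    def test_within_window(self):
        recs = [make_record(pos=1000)]
        assert label_by_truth(recs, [("chr1", 1150, 2000, "DEL")], window=200).tolist() == [1]

    def test_end_breakpoint_also_matches(self):
        recs = [make_record(pos=2050)]
        assert label_by_truth(recs, [("chr1", 500, 2000, "DEL")], window=100).tolist() == [1]

    def test_empty_truth_and_missing_chrom(self):
        recs = [make_record(pos=1000), make_record(chrom="chr9", pos=1000)]
        assert label_by_truth(recs, [], window=200).tolist() == [0, 0]
        assert label_by_truth(recs, [("chr1", 1000, 2000, "DEL")]).tolist() == [1, 0]


class TestBalanceClasses:
    @staticmethod
    def unbalanced(n_pos=30, n_neg=10, seed=3):
        rng = np.random.default_rng(seed)
        n = n_pos + n_neg
        return LabeledDataset(
            features=rng.normal(size=(n, 26)),
            labels=np.array([1] * n_pos + [0] * n_neg),
            proportion=0.1,
            ids=[f"c{i}" for i in range(n)],
        )

    def test_undersample_counts(self):
        out = balance_classes(self.unbalanced(), "undersample", seed=0)
        assert np.bincount(out.labels).tolist() == [10, 10]

    def test_oversample_counts(self):
        out = balance_classes(self.unbalanced(), "oversample", seed=0)
        assert np.bincount(out.labels).tolist() == [30, 30]

    def test_determinism(self):
        a = balance_classes(self.unbalanced(), "undersample", seed=5)
        b = balance_classes(self.unbalanced(), "undersample", seed=5)
        assert np.array_equal(a.features, b.features)
        c = balance_classes(self.unbalanced(), "oversample", seed=5)
        d = balance_classes(self.unbalanced(), "oversample", seed=5)
        assert np.array_equal(c.features, d.features)

    def test_undersample_rows_exist_in_input(self):
        data = self.unbalanced()
        out = balance_classes(data, "undersample", seed=1)
        in_rows = {tuple(row) for row in data.features}
        assert all(tuple(row) in in_rows for row in out.features)

    def test_oversample_preserves_all_minority_rows(self):
        data = self.unbalanced()
        out = balance_classes(data, "oversample", seed=1)
        minority = data.features[data.labels == 0]
        out_rows = {tuple(row) for row in out.features}
        assert all(tuple(row) in out_rows for row in minority)

    def test_oversample_rows_are_convex_combinations(self):
        data = self.unbalanced()
        out = balance_classes(data, "oversample", seed=2)
        minority = data.features[data.labels == 0]
        lo, hi = minority.min(axis=0), minority.max(axis=0)
        synth = out.features[len(data.features):]
        assert np.all(synth >= lo - 1e-12) and np.all(synth <= hi + 1e-12)

    def test_single_class_rejected(self):
        data = self.unbalanced()
        data.labels[:] = 1
        with pytest.raises(ConfigurationError):
            balance_classes(data, "undersample", seed=0)

    def test_tiny_minority_cannot_oversample(self):
        data = self.unbalanced(n_pos=10, n_neg=1)
        with pytest.raises(ConfigurationError):
            balance_classes(data, "oversample", seed=0)

    def test_already_balanced_input_keeps_both_classes(self):
        data = self.unbalanced(n_pos=10, n_neg=10)
        out = balance_classes(data, "undersample", seed=0)
        assert np.bincount(out.labels).tolist() == [10, 10]


def test_feature_table_round_trip(tmp_path, small_dataset):
    path = tmp_path / "features.tsv"
    small_dataset.write_tsv(path)
    back = LabeledDataset.read_tsv(path)
    np.testing.assert_allclose(back.features, small_dataset.features, rtol=0, atol=1e-12)
    assert np.array_equal(back.labels, small_dataset.labels)
    assert back.proportion == small_dataset.proportion
    assert back.ids == small_dataset.ids
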