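import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fedgi.encoding import (
    DEFAULT_VARIANT_CLASSES,
    AnnotatedVariant,
    CohortDataset,
    EncodingReport,
    GenePanel,
    VariantClassVocabulary,
    build_gene_histogram,
    concat_cohorts,
    encode_cohort,
    encode_sample,
    read_annovar_table,
    read_vcf_with_mapping,
)


class TestVocabulary:
    def test_default_has_nine_classes(self, vocab):
        assert len(vocab) == 9
        assert vocab.classes == DEFAULT_VARIANT_CLASSES

    def test_order_defines_index(self, vocab):
        assert vocab.index("exonic") == 0
        assert vocab.index("splicing") == 8

    def test_duplicate_names_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            VariantClassVocabulary(("exonic", "exonic"))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            VariantClassVocabulary(())


class TestAnnotatedVariant:
    def test_position_must_be_one_based(self):
        with pytest.raises(ValueError, match="pos"):
            AnnotatedVariant("1", 0, "A", "T", "NOD2", "exonic")


class TestGenePanel:
    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            GenePanel(("A", "A"), np.zeros(2), np.zeros(2))

    def test_missing_scores_imputed_with_warning(self):
        with pytest.warns(UserWarning, match="imputed"):
            panel = GenePanel(("A", "B"), np.array([np.nan, 1.0]), np.array([2.0, np.nan]))
        assert panel.intolerance[0] == 0.0
        assert panel.publication_weight[1] == 0.0

    def test_tsv_round_trip(self, small_panel, tmp_path):
        path = tmp_path / "panel.tsv"
        small_panel.to_tsv(path)
        loaded = GenePanel.from_tsv(path)
        assert loaded.genes == small_panel.genes
        np.testing.assert_array_equal(loaded.intolerance, small_panel.intolerance)
        np.testing.assert_array_equal(
            loaded.publication_weight, small_panel.publication_weight
        )


class TestReadAnnovarTable:
    def test_single_line(self, tmp_path, vocab):
        path = tmp_path / "t.tsv"
        path.write_text("exonic\tNOD2\t16\t50745926\t50745926\tC\tT\n")
        variants = read_annovar_table(path, vocab)
        assert len(variants) == 1
        v = variants[0]
        assert (v.variant_class, v.gene, v.chrom, v.pos) == ("exonic", "NOD2", "16", 50745926)
        assert (v.ref, v.alt) == ("C", "T")

    def test_multi_gene_fans_out(self, tmp_path, vocab):
        path = tmp_path / "t.tsv"
        path.write_text("intronic\tGENE1;GENE2\t1\t100\t100\tA\tG\n")
        variants = read_annovar_table(path, vocab)
        assert [v.gene for v in variants] == ["GENE1", "GENE2"]
        assert all(v.variant_class == "intronic" for v in variants)

    def test_unknown_class_counted_not_dropped_silently(self, tmp_path, vocab):
        # 3-line fixture: 2 in-vocabulary records, 1 'intergenic'
        path = tmp_path / "t.tsv"
        path.write_text(
            "exonic\tA\t1\t10\t10\tC\tT\n"
            "intergenic\tB\t1\t20\t20\tC\tT\n"
            "splicing\tC\t1\t30\t30\tC\tT\n"
        )
        report = EncodingReport()
        variants = read_annovar_table(path, vocab, report=report)
        assert len(variants) == 2
        assert report.unknown_class_counts == {"intergenic": 1}
        assert report.n_records == 3

    def test_malformed_line_reports_line_number(self, tmp_path, vocab):
        path = tmp_path / "t.tsv"
        path.write_text("exonic\tA\t1\t10\t10\tC\tT\nbadline\n")
        with pytest.raises(ValueError, match=":2"):
            read_annovar_table(path, vocab)

    def test_empty_file_warns(self, tmp_path, vocab):
        path = tmp_path / "t.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            assert read_annovar_table(path, vocab) == []


def test_read_vcf_with_mapping(tmp_path):
    path = tmp_path / "s.vcf"
    path.write_text(
        "##fileformat=VCFv4.2\n"
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        "16\t50745926\t.\tC\tT\t.\tPASS\t.\n"
        "1\t999\t.\tA\tG\t.\tPASS\t.\n"
    )
    mapping = {("16", 50745926, "C", "T"): ("NOD2", "exonic")}
    report = EncodingReport()
    variants = read_vcf_with_mapping(path, mapping, report=report)
    assert len(variants) == 1
    assert variants[0].gene == "NOD2"
    assert report.unknown_class_counts["<unmapped>"] == 1


class TestGeneHistogram:
    def test_direct_count(self, vocab):
        variants = [
            AnnotatedVariant("1", 1, "A", "T", "GENE1", "exonic"),
            AnnotatedVariant("1", 2, "A", "T", "GENE1", "exonic"),
            AnnotatedVariant("1", 3, "A", "T", "GENE1", "splicing"),
        ]
        np.testing.assert_array_equal(
            build_gene_histogram(variants, "GENE1", vocab),
            [2, 0, 0, 0, 0, 0, 0, 0, 1],
        )

    def test_no_variants_all_zero(self, vocab):
        np.testing.assert_array_equal(
            build_gene_histogram([], "GENE2", vocab), np.zeros(9)
        )

    def test_intronic_and_utr3_counts(self, vocab):
        variants = [
            AnnotatedVariant("1", i, "A", "T", "G", "intronic") for i in range(1, 4)
        ] + [AnnotatedVariant("1", 9, "A", "T", "G", "UTR3")]
        # cross-check against a naive per-class loop
        expected = [
            sum(1 for v in variants if v.variant_class == c) for c in vocab.classes
        ]
        assert expected == [0, 1, 0, 0, 0, 0, 0, 3, 0]
        np.testing.assert_array_equal(build_gene_histogram(variants, "G", vocab), expected)


class TestEncodeSample:
    def test_zero_variants_gives_score_rows_only(self, small_panel, vocab):
        mat = encode_sample([], small_panel, vocab)
        assert mat.shape == (11, 3)
        assert np.all(mat[:9] == 0)
        np.testing.assert_array_equal(mat[9], small_panel.intolerance)
        np.testing.assert_array_equal(mat[10], small_panel.publication_weight)

    def test_per_gene_vector_length_is_eleven(self, small_panel, toy_variants, vocab):
        mat = encode_sample(toy_variants, small_panel, vocab)
        assert mat[:, 0].shape == (len(vocab) + 2,) == (11,)

    def test_fixture_matches_hand_histograms(self, small_panel, toy_variants, vocab):
        report = EncodingReport()
        mat = encode_sample(toy_variants, small_panel, vocab, report=report)
        expected = np.zeros((11, 3))
        expected[0, 0] = 2  # exonic on NOD2
        expected[8, 0] = 1  # splicing on NOD2
        expected[7, 1] = 1  # intronic on IL23R
        expected[9] = small_panel.intolerance
        expected[10] = small_panel.publication_weight
        np.testing.assert_array_equal(mat, expected)
        assert report.off_panel_count == 1

    def test_empty_panel_rejected(self, vocab):
        with pytest.raises(ValueError):
            encode_sample([], GenePanel((), np.zeros(0), np.zeros(0)), vocab)


class TestEncodeCohort:
    def test_paper_scale_tensor_shape(self):
        rng = np.random.default_rng(0)
        panel = GenePanel(
            tuple(f"G{i}" for i in range(691)),
            rng.normal(size=691),
            rng.gamma(1.0, 1.0, size=691),
        )
        cohort = encode_cohort([[], [], [], []], [0, 1, 0, 1], panel)
        assert cohort.tensor.shape == (4, 11, 691)

    def test_save_load_round_trip(self, small_panel, toy_variants, tmp_path):
        cohort = encode_cohort(
            [toy_variants, []], [1, 0], small_panel, center_id="c1"
        )
        path = tmp_path / "cohort.npz"
        cohort.save(path)
        loaded = CohortDataset.load(path)
        np.testing.assert_array_equal(loaded.tensor, cohort.tensor)
        np.testing.assert_array_equal(loaded.labels, cohort.labels)
        assert loaded.panel.genes == small_panel.genes
        assert loaded.sample_ids == cohort.sample_ids
        assert loaded.center_id == "c1"
        assert loaded.vocabulary.classes == cohort.vocabulary.classes

    def test_panel_permutation_permutes_columns(self, small_panel, toy_variants, vocab):
        mat = encode_sample(toy_variants, small_panel, vocab)
        perm = [2, 0, 1]
        permuted_panel = GenePanel(
            tuple(small_panel.genes[i] for i in perm),
            small_panel.intolerance[perm],
            small_panel.publication_weight[perm],
        )
        mat_perm = encode_sample(toy_variants, permuted_panel, vocab)
        np.testing.assert_array_equal(mat_perm, mat[:, perm])

    def test_bad_label_rejected(self, small_panel):
        with pytest.raises(ValueError, match="binary"):
            encode_cohort([[]], [2], small_panel)

    def test_length_mismatch_rejected(self, small_panel):
        with pytest.raises(ValueError):
            encode_cohort([[], []], [1], small_panel)


class TestInvariants:
    def test_count_conservation(self, small_panel, toy_variants, vocab):
        mat = encode_sample(toy_variants, small_panel, vocab)
        on_panel = sum(1 for v in toy_variants if v.gene in small_panel)
        assert mat[:9].sum() == on_panel == 4

    @settings(max_examples=25, deadline=None)
    @given(st.permutations(range(5)))
    def test_variant_order_irrelevant(self, perm):
        panel = GenePanel(("A", "B"), np.array([0.1, -0.2]), np.array([1.0, 2.0]))
        variants = [
            AnnotatedVariant("1", 1, "A", "T", "A", "exonic"),
            AnnotatedVariant("1", 2, "A", "T", "A", "UTR3"),
            AnnotatedVariant("1", 3, "A", "T", "B", "splicing"),
            AnnotatedVariant("1", 4, "A", "T", "B", "exonic"),
            AnnotatedVariant("1", 5, "A", "T", "A", "exonic"),
        ]
        shuffled = [variants[i] for i in perm]
        np.testing.assert_array_equal(
            encode_sample(shuffled, panel), encode_sample(variants, panel)
        )

    def test_score_rows_constant_across_samples(self, small_panel, toy_variants):
        cohort = encode_cohort([toy_variants, [], toy_variants], [1, 0, 0], small_panel)
        for i in range(cohort.n_samples):
            np.testing.assert_array_equal(cohort.tensor[i, 9], small_panel.intolerance)
            np.testing.assert_array_equal(
                cohort.tensor[i, 10], small_panel.publication_weight
            )


def test_concat_cohorts_requires_same_panel(small_panel):
    other_panel = GenePanel(("X",), np.zeros(1), np.zeros(1))
    c1 = encode_cohort([[]], [0], small_panel)
    c2 = encode_cohort([[]], [1], other_panel)
    with pytest.raises(ValueError, match="panel"):
        concat_cohorts([c1, c2])
    merged = concat_cohorts([c1, encode_cohort([[]], [1], small_panel)])
    assert merged.n_samples == 2
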