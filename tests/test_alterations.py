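"""Mutation frequency tables, one-vs-rest contrasts, and gene-level
copy-number reduction with threshold calling."""

import numpy as np
import pandas as pd
import pytest

import cpgpairs as cp
from cpgpairs.io import MAF_COLUMNS, SEG_COLUMNS


def _maf(records):
    """records: (gene, sample, variant_class)."""
    return pd.DataFrame(
        [(g, "chr1", 100, 100, vc, s) for g, s, vc in records],
        columns=MAF_COLUMNS,
    )


def _labels(mapping):
    return pd.Series(mapping, name="cluster")


class TestMutationFrequency:
    def test_toy_counts_by_hand(self):
        maf = _maf(
            [
                ("VHL", "s1", "Missense_Mutation"),
                ("VHL", "s2", "Missense_Mutation"),
                ("VHL", "s2", "Nonsense_Mutation"),  # same sample, counted once
                ("BAP1", "s3", "Missense_Mutation"),
                ("SETD2", "s4", "Silent"),  # silent: excluded
            ]
        )
        labels = _labels({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        freq, top, union = cp.mutation_frequency(maf, labels, top_n=30)
        assert freq.loc["VHL", 1] == pytest.approx(1.0)
        assert freq.loc["VHL", 2] == pytest.approx(0.0)
        assert freq.loc["BAP1", 2] == pytest.approx(0.5)
        assert "SETD2" not in freq.index
        assert ((freq >= 0) & (freq <= 1)).all().all()

    def test_identical_lists_union_equals_top_n(self):
        records = []
        for s in ["s1", "s2", "s3", "s4"]:
            for g in ["G1", "G2", "G3"]:
                records.append((g, s, "Missense_Mutation"))
        labels = _labels({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        _, top, union = cp.mutation_frequency(_maf(records), labels, top_n=3)
        assert union == 3

    def test_disjoint_lists_union_is_sum(self):
        records = [
            ("A1", "s1", "Missense_Mutation"),
            ("A2", "s1", "Missense_Mutation"),
            ("B1", "s3", "Missense_Mutation"),
            ("B2", "s3", "Missense_Mutation"),
        ]
        labels = _labels({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        _, top, union = cp.mutation_frequency(_maf(records), labels, top_n=2)
        assert union == 4

    def test_tie_break_alphabetical(self):
        records = [
            ("ZZZ", "s1", "Missense_Mutation"),
            ("AAA", "s1", "Missense_Mutation"),
            ("MMM", "s1", "Missense_Mutation"),
        ]
        labels = _labels({"s1": 1, "s2": 1, "s3": 2, "s4": 2})
        _, top, _ = cp.mutation_frequency(_maf(records), labels, top_n=2)
        assert top[1] == ["AAA", "MMM"]

    def test_unlabeled_sample_raises(self):
        maf = _maf([("VHL", "mystery", "Missense_Mutation")])
        with pytest.raises(ValueError, match="mystery"):
            cp.mutation_frequency(maf, _labels({"s1": 1, "s2": 2}))


class TestCompareMutation:
    def test_extreme_enrichment_significant(self):
        records = [(f"G", f"c{i}", "Missense_Mutation") for i in range(10)]
        labels = _labels(
            {**{f"c{i}": 1 for i in range(10)}, **{f"r{i}": 2 for i in range(20)}}
        )
        res = cp.compare_mutation(_maf(records), labels, "G")
        assert res.loc[1, "p"] < 0.001

    def test_equal_frequencies_not_significant(self):
        records = [("G", "c0", "Missense_Mutation"), ("G", "r0", "Missense_Mutation")]
        labels = _labels(
            {**{f"c{i}": 1 for i in range(10)}, **{f"r{i}": 2 for i in range(10)}}
        )
        res = cp.compare_mutation(_maf(records), labels, "G")
        assert (res["p"] > 0.5).all()

    def test_fisher_fallback_flagged_on_small_counts(self):
        records = [("G", "c0", "Missense_Mutation")]
        labels = _labels({**{f"c{i}": 1 for i in range(4)}, **{f"r{i}": 2 for i in range(4)}})
        res = cp.compare_mutation(_maf(records), labels, "G")
        assert res["fisher"].all()

    def test_absent_gene_raises(self):
        maf = _maf([("G", "s1", "Missense_Mutation")])
        with pytest.raises(ValueError, match="NOPE"):
            cp.compare_mutation(maf, _labels({"s1": 1, "s2": 2}), "NOPE")

    def test_planted_driver_detected_in_cohort(self, alterations, pipeline):
        maf, _, _ = alterations
        labels = pipeline.truth.sample_subtype
        res = cp.compare_mutation(maf, labels, "VHL")
        assert res.loc[1, "freq_in"] > res.loc[1, "freq_rest"]
        assert res.loc[1, "p"] < 0.01


def _seg(records):
    """records: (sample, chrom, start, end, mean)."""
    return pd.DataFrame(
        [(s, c, a, b, (b - a) // 1000, m) for s, c, a, b, m in records],
        columns=SEG_COLUMNS,
    )


def _model(records):
    return pd.DataFrame(records, columns=["gene", "chromosome", "start", "end"])


class TestGeneLevelCnv:
    def test_fully_covered_gene_takes_segment_mean(self):
        seg = _seg([("s1", "chr1", 1, 10000, 0.3)])
        model = _model([("G", "chr1", 1000, 2000)])
        cnv = cp.gene_level_cnv(seg, model)
        assert cnv.loc["G", "s1"] == pytest.approx(0.3)

    def test_half_half_overlap_weighted_mean(self):
        # gene [1000, 2000): two segments covering 500 bp each
        seg = _seg(
            [("s1", "chr1", 1, 1500, 0.2), ("s1", "chr1", 1501, 9000, 0.4)]
        )
        model = _model([("G", "chr1", 1000, 2000)])
        cnv = cp.gene_level_cnv(seg, model)
        assert cnv.loc["G", "s1"] == pytest.approx(0.3)

    def test_uncovered_gene_is_missing(self):
        seg = _seg([("s1", "chr1", 1, 10000, 0.3)])
        model = _model([("G", "chr1", 1000, 2000), ("H", "chr2", 1000, 2000)])
        cnv = cp.gene_level_cnv(seg, model)
        assert np.isnan(cnv.loc["H", "s1"])

    def test_segment_record_order_invariance(self):
        recs = [
            ("s1", "chr1", 1, 1500, 0.2),
            ("s1", "chr1", 1501, 9000, 0.4),
            ("s1", "chr2", 1, 9000, -0.5),
        ]
        model = _model([("G", "chr1", 1000, 2000), ("H", "chr2", 0, 100)])
        fwd = cp.gene_level_cnv(_seg(recs), model)
        rev = cp.gene_level_cnv(_seg(recs[::-1]), model)
        pd.testing.assert_frame_equal(fwd, rev)

    def test_overlapping_segments_warn_keep_first(self):
        seg = _seg(
            [("s1", "chr1", 1, 5000, 0.9), ("s1", "chr1", 4000, 9000, -0.9)]
        )
        model = _model([("G", "chr1", 1000, 2000)])
        with pytest.warns(UserWarning, match="overlapping"):
            cnv = cp.gene_level_cnv(seg, model)
        assert cnv.loc["G", "s1"] == pytest.approx(0.9)


class TestCallGainLoss:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (0.2, "neutral"),
            (0.2000001, "gain"),
            (-0.2, "neutral"),
            (-0.3, "loss"),
            (0.0, "neutral"),
        ],
    )
    def test_threshold_calls(self, value, expected):
        call, flagged = cp.call_gain_loss(value)
        assert call == expected
        assert not flagged

    def test_missing_is_neutral_and_flagged(self):
        call, flagged = cp.call_gain_loss(float("nan"))
        assert call == "neutral" and flagged


class TestCompareCnv:
    def test_no_cnv_no_significant_genes(self):
        calls = pd.DataFrame(
            "neutral", index=["G1", "G2"], columns=[f"s{i}" for i in range(12)]
        )
        labels = _labels({f"s{i}": 1 + i % 3 for i in range(12)})
        out = cp.compare_cnv(calls, labels)
        assert not out["significant"].any()

    def test_planted_gain_detected_in_correct_cluster(self, alterations, pipeline):
        _, seg, model = alterations
        labels = pipeline.truth.sample_subtype
        cnv = cp.gene_level_cnv(seg, model)
        calls = cp.call_gain_loss_matrix(cnv)
        out = cp.compare_cnv(calls, labels)
        gain_gene = cp.synthetic.gene_universe(
            cp.SimConfig(n_genes=2000)
        )["immune_genes"][0]
        hits = out[(out.gene == gain_gene) & (out.direction == "gain") & out.significant]
        assert set(hits["cluster"]) == {1}

    def test_label_permutation_near_nominal_rate(self, alterations, pipeline):
        _, seg, model = alterations
        labels = pipeline.truth.sample_subtype
        cnv = cp.gene_level_cnv(seg, model)
        calls = cp.call_gain_loss_matrix(cnv)
        rng = np.random.default_rng(3)
        perm = pd.Series(rng.permutation(labels.to_numpy()), index=labels.index)
        out = cp.compare_cnv(calls, perm)
        assert out["significant"].mean() < 0.12
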