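"""Peak reading, replicate intersection, assignment, and motif utilities."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from granuleseq import annotation as ann
from granuleseq import peaks as pk


def make_peaks(rows, protein="G3BP1", condition="Ctrl", replicate=1):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "score"])
    df["protein"] = protein
    df["condition"] = condition
    df["replicate"] = replicate
    return df


class TestReadPeaks:
    def test_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text(
            "chr1\t10\t50\tp1\t3.5\t+\n"
            "chr1\t100\t140\tp2\t2.0\t-\n"
            "chr2\t5\t25\tp3\t1.0\t+\n"
        )
        df = pk.read_peaks(p, "G3BP1", "Ctrl", 1)
        assert len(df) == 3
        assert df.loc[0, "score"] == 3.5
        assert df.loc[1, "strand"] == "-"

    def test_narrowpeak_uses_signal_value(self, tmp_path):
        p = tmp_path / "a.narrowPeak"
        p.write_text("chr1\t10\t50\tp1\t800\t+\t6.25\t10.0\t8.0\t20\n")
        df = pk.read_peaks(p)
        assert df.loc[0, "score"] == 6.25

    def test_dot_strand_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t10\t50\tp1\t3.5\t.\n")
        with pytest.raises(ValueError, match="strand"):
            pk.read_peaks(p)

    def test_reversed_interval_rejected(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("chr1\t50\t10\tp1\t3.5\t+\n")
        with pytest.raises(ValueError, match="end <= start"):
            pk.read_peaks(p)


class TestIntersectReplicates:
    def test_identical_lists_idempotent(self):
        a = make_peaks([("chr1", 100, 200, "+", 2.0)])
        out = pk.intersect_replicates(a, a.assign(replicate=2))
        assert out[["chrom", "start", "end", "strand"]].values.tolist() == [
            ["chr1", 100, 200, "+"]
        ]

    def test_disjoint_lists_empty(self):
        a = make_peaks([("chr1", 100, 200, "+", 2.0)])
        b = make_peaks([("chr1", 300, 400, "+", 2.0)], replicate=2)
        assert pk.intersect_replicates(a, b).empty

    def test_partial_overlap_intersected_with_mean_score(self):
        a = make_peaks([("chr1", 100, 200, "+", 2.0)])
        b = make_peaks([("chr1", 150, 250, "+", 4.0)], replicate=2)
        out = pk.intersect_replicates(a, b)
        assert out[["start", "end"]].values.tolist() == [[150, 200]]
        assert out.loc[0, "score"] == 3.0

    def test_opposite_strands_do_not_intersect(self):
        a = make_peaks([("chr1", 100, 200, "+", 2.0)])
        b = make_peaks([("chr1", 100, 200, "-", 2.0)], replicate=2)
        assert pk.intersect_replicates(a, b).empty

    def test_label_mismatch_rejected(self):
        a = make_peaks([("chr1", 100, 200, "+", 2.0)], protein="G3BP1")
        b = make_peaks([("chr1", 100, 200, "+", 2.0)], protein="G3BP2")
        with pytest.raises(ValueError, match="protein"):
            pk.intersect_replicates(a, b)


@settings(max_examples=40, derandomize=True, deadline=None)
@given(
    hst.lists(
        hst.tuples(hst.integers(0, 400), hst.integers(1, 60), hst.floats(0.5, 8)),
        min_size=1,
        max_size=12,
    ),
    hst.lists(
        hst.tuples(hst.integers(0, 400), hst.integers(1, 60), hst.floats(0.5, 8)),
        min_size=1,
        max_size=12,
    ),
)
def test_intersection_commutative_and_contained(raw_a, raw_b):
    """Common-peak intervals are order-independent and contained in a source
    peak of each replicate."""
    a = make_peaks([("chr1", s, s + w, "+", sc) for s, w, sc in raw_a])
    b = make_peaks([("chr1", s, s + w, "+", sc) for s, w, sc in raw_b], replicate=2)
    ab = pk.intersect_replicates(a, b)
    ba = pk.intersect_replicates(b, a)
    key = ["chrom", "start", "end", "strand"]
    assert ab[key].values.tolist() == ba[key].values.tolist()
    for rec in ab.itertuples(index=False):
        assert any(s <= rec.start and rec.end <= s + w for s, w, _ in raw_a)
        assert any(s <= rec.start and rec.end <= s + w for s, w, _ in raw_b)


class TestPeakSetOverlap:
    def test_identical_singleton_sets_merge(self):
        a = make_peaks([("chr1", 10, 50, "+", 1.0)])
        out = pk.peak_set_overlap({"A": a, "B": a.copy()})
        counts = dict(zip(out["members"], out["count"]))
        assert counts == {"A": 0, "B": 0, "A&B": 1}

    def test_disjoint_singletons_exclusive(self):
        a = make_peaks([("chr1", 10, 50, "+", 1.0)])
        b = make_peaks([("chr1", 100, 150, "+", 1.0)])
        out = pk.peak_set_overlap({"A": a, "B": b})
        counts = dict(zip(out["members"], out["count"]))
        assert counts == {"A": 1, "B": 1, "A&B": 0}

    def test_three_sets_only_ab_overlap(self):
        a = make_peaks([("chr1", 10, 50, "+", 1.0)])
        b = make_peaks([("chr1", 40, 90, "+", 1.0)])
        c = make_peaks([("chr2", 10, 50, "+", 1.0)])
        out = pk.peak_set_overlap({"A": a, "B": b, "C": c})
        counts = dict(zip(out["members"], out["count"]))
        assert counts["A&B"] == 1 and counts["C"] == 1
        assert counts["A"] == counts["B"] == counts["A&B&C"] == 0

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            pk.peak_set_overlap({"A": make_peaks([("chr1", 1, 5, "+", 1.0)])})


@pytest.fixture()
def tiny_models(tiny_gtf):
    return ann.load_annotation(tiny_gtf)


class TestAssignPeaks:
    def test_peak_inside_3utr(self, tiny_models):
        peaks = make_peaks([("chr1", 165, 195, "+", 2.0)])
        out = pk.assign_peaks(peaks, tiny_models)
        assert out.loc[0, ["gene_id", "region"]].tolist() == ["GA", "3UTR"]

    def test_max_overlap_wins_over_precedence(self, tiny_models):
        # overlaps CDS (150..160: 10 nt) and 3UTR (160..200 truncated: 35 nt)
        peaks = make_peaks([("chr1", 150, 195, "+", 2.0)])
        out = pk.assign_peaks(peaks, tiny_models)
        assert out.loc[0, "region"] == "3UTR"
        assert out.loc[0, "overlap_nt"] == 35

    def test_antisense_peak_unassigned(self, tiny_models):
        peaks = make_peaks([("chr1", 165, 195, "-", 2.0)])
        out = pk.assign_peaks(peaks, tiny_models)
        assert out.loc[0, "region"] == "unassigned"
        assert out.loc[0, "overlap_nt"] == 0

    def test_lncrna_peak_is_noncoding_exon(self, tiny_models):
        peaks = make_peaks([("chr1", 610, 640, "+", 2.0)])
        out = pk.assign_peaks(peaks, tiny_models)
        assert out.loc[0, ["gene_id", "region"]].tolist() == ["GC", "noncoding_exon"]

    def test_counts_conserved(self, tiny_models):
        peaks = make_peaks(
            [("chr1", 165, 195, "+", 2.0), ("chr1", 5000, 5040, "+", 1.0)]
        )
        out = pk.assign_peaks(peaks, tiny_models)
        assigned = (out["region"] != "unassigned").sum()
        assert assigned + (out["region"] == "unassigned").sum() == len(peaks)


class TestRegionDistribution:
    def test_fractions_match_hand_tally_and_sum_to_one(self, tiny_models):
        peaks = make_peaks(
            [
                ("chr1", 165, 195, "+", 2.0),
                ("chr1", 170, 199, "+", 2.0),
                ("chr1", 175, 198, "+", 2.0),
                ("chr1", 35, 55, "+", 2.0),
            ]
        )
        out = pk.region_distribution(pk.assign_peaks(peaks, tiny_models))
        frac = dict(zip(out["region"], out["fraction"]))
        assert frac == {"3UTR": 0.75, "CDS": 0.25}
        assert out["fraction"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_all_unassigned_errors(self, tiny_models):
        peaks = make_peaks([("chr1", 5000, 5040, "+", 1.0)])
        with pytest.raises(ValueError, match="no assigned"):
            pk.region_distribution(pk.assign_peaks(peaks, tiny_models))


class TestGeneBindingProfiles:
    def test_count_and_mean_score(self, tiny_models):
        peaks = make_peaks(
            [("chr1", 165, 195, "+", 2.0), ("chr1", 170, 199, "+", 4.0)]
        )
        out = pk.gene_binding_profiles(pk.assign_peaks(peaks, tiny_models))
        row = out.set_index("gene_id").loc["GA"]
        assert row["peak_count"] == 2
        assert row["binding_level"] == 3.0

    def test_unbound_gene_absent(self, tiny_models):
        peaks = make_peaks([("chr1", 165, 195, "+", 2.0)])
        out = pk.gene_binding_profiles(pk.assign_peaks(peaks, tiny_models))
        assert set(out["gene_id"]) == {"GA"}


class TestIupacMotifs:
    @pytest.mark.parametrize(
        "motif, expected",
        [("CCAGSCUGG", True), ("AAA", False), ("GC", True), ("AU", True), ("ACG", False)],
    )
    def test_palindrome_examples(self, motif, expected):
        assert pk.is_palindrome(motif) is expected

    def test_revcomp_examples(self):
        assert pk.iupac_reverse_complement("AAA") == "UUU"
        assert pk.iupac_reverse_complement("CCAGSCUGG") == "CCAGSCUGG"
        assert pk.iupac_reverse_complement("RYKM") == "KMRY"

    def test_non_iupac_character_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            pk.iupac_reverse_complement("ACGX")

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(hst.text(alphabet="ACGURYSWKMBDHVN", min_size=1, max_size=30))
    def test_palindromy_invariant_under_revcomp(self, motif):
        rc = pk.iupac_reverse_complement(motif)
        assert pk.iupac_reverse_complement(rc) == motif
        assert pk.is_palindrome(motif) == pk.is_palindrome(rc)
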