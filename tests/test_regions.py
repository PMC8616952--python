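"""Gene-set loading, interval merging and SNP-to-region assignment."""

import numpy as np
import pandas as pd
import pytest

from pathpgs import GeneSet, assign_snps, build_regions, load_gene_set
from pathpgs.regions import GenomicInterval, normalize_chrom


def _annot(rows):
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


@pytest.fixture
def gmt_file(tmp_path):
    path = tmp_path / "sets.gmt"
    path.write_text(
        "OXT_PATH\tdesc\tOXTR\tCD38\tOXT\n"
        "DUP_SET\tdesc\tOXTR\tOXTR\tCD38\n"
        "EMPTY_SET\tdesc\n"
    )
    return path


class TestLoadGeneSet:
    def test_parses_symbols_in_file_order(self, gmt_file):
        gs = load_gene_set(gmt_file, "OXT_PATH")
        assert gs.genes == ("OXTR", "CD38", "OXT")

    def test_deduplicates_symbols(self, gmt_file):
        assert len(load_gene_set(gmt_file, "DUP_SET")) == 2

    def test_missing_set_name_raises(self, gmt_file):
        with pytest.raises(KeyError, match="gene set not found"):
            load_gene_set(gmt_file, "MISSING")

    def test_empty_set_raises(self, gmt_file):
        with pytest.raises(ValueError, match="empty"):
            load_gene_set(gmt_file, "EMPTY_SET")

    def test_symbols_uppercased(self):
        gs = GeneSet("x", ("oxtr", "cd38"))
        assert gs.genes == ("OXTR", "CD38")


class TestBuildRegions:
    def test_single_gene_identity(self):
        gs = GeneSet("g", ("OXT",))
        rs = build_regions(gs, _annot([("OXT", "3", 8_750_000, 8_770_000)]))
        assert len(rs) == 1
        iv = rs.intervals[0]
        assert (iv.chrom, iv.start, iv.end) == ("3", 8_750_000, 8_770_000)

    def test_transcript_and_regulatory_merge(self):
        gs = GeneSet("g", ("OXT",))
        rs = build_regions(
            gs,
            _annot([("OXT", "1", 100, 200)]),
            _annot([("OXT", "1", 150, 300)]),
        )
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(100, 300)]

    def test_disjoint_intervals_stay_separate(self):
        gs = GeneSet("g", ("OXT",))
        rs = build_regions(
            gs,
            _annot([("OXT", "1", 100, 200)]),
            _annot([("OXT", "1", 500, 600)]),
        )
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(100, 200), (500, 600)]

    def test_book_ended_intervals_coalesce(self):
        gs = GeneSet("g", ("A", "B"))
        rs = build_regions(
            gs, _annot([("A", "1", 100, 200), ("B", "1", 201, 250)])
        )
        assert [(iv.start, iv.end) for iv in rs.intervals] == [(100, 250)]
        assert set(rs.intervals[0].genes) == {"A", "B"}

    def test_random_instances_match_bruteforce_merge(self):
        # brute-force oracle: position-set union per chromosome
        rng = np.random.default_rng(5)
        for _ in range(20):
            genes = [f"G{i}" for i in range(4)]
            rows = []
            for g in genes:
                for _k in range(rng.integers(1, 4)):
                    s = int(rng.integers(1, 300))
                    rows.append((g, "1", s, s + int(rng.integers(0, 80))))
            rs = build_regions(GeneSet("x", tuple(genes)), _annot(rows))
            covered = set()
            for _, _, s, e in rows:
                covered.update(range(s, e + 1))
            merged = set()
            for iv in rs.intervals:
                span = set(range(iv.start, iv.end + 1))
                assert not (span & merged), "intervals overlap"
                merged |= span
            # book-ended merging never changes the covered positions
            assert merged == covered

    def test_merge_is_idempotent(self):
        gs = GeneSet("g", ("A", "B"))
        annot = _annot([("A", "1", 10, 50), ("B", "1", 40, 90), ("A", "2", 5, 9)])
        rs1 = build_regions(gs, annot)
        again = _annot(
            [(iv.gene.split(";")[0], iv.chrom, iv.start, iv.end) for iv in rs1.intervals]
        )
        rs2 = build_regions(gs, again)
        assert [(iv.chrom, iv.start, iv.end) for iv in rs1.intervals] == [
            (iv.chrom, iv.start, iv.end) for iv in rs2.intervals
        ]

    def test_missing_gene_recorded(self, caplog):
        gs = GeneSet("g", ("A", "NOPE"))
        rs = build_regions(gs, _annot([("A", "1", 1, 10)]))
        assert rs.genes_missing == ("NOPE",)
        assert rs.genes_covered == ("A",)

    def test_no_gene_found_raises(self):
        with pytest.raises(ValueError, match="no gene"):
            build_regions(GeneSet("g", ("ZZZ",)), _annot([("A", "1", 1, 10)]))

    def test_malformed_interval_raises(self):
        with pytest.raises(ValueError, match="start > end"):
            build_regions(GeneSet("g", ("A",)), _annot([("A", "1", 100, 50)]))

    def test_chr_prefix_normalized(self):
        rs = build_regions(GeneSet("g", ("A",)), _annot([("A", "chr2", 1, 10)]))
        assert rs.intervals[0].chrom == "2"
        assert normalize_chrom("chrX") == "X"


class TestAssignSnps:
    def _regions(self, intervals):
        gs = GeneSet("g", ("A",))
        return build_regions(gs, _annot([("A", c, s, e) for c, s, e in intervals]))

    def test_boundaries_inclusive(self):
        rs = self._regions([("1", 100, 300)])
        variants = pd.DataFrame(
            {"id": ["a", "b", "c"], "chrom": "1", "bp": [100, 300, 301]}
        )
        assert assign_snps(rs, variants).snp_ids == ["a", "b"]

    def test_no_overlap_gives_empty(self):
        rs = self._regions([("1", 100, 300)])
        variants = pd.DataFrame({"id": ["a"], "chrom": "2", "bp": [100]})
        assert len(assign_snps(rs, variants)) == 0

    def test_empty_variant_table(self):
        rs = self._regions([("1", 100, 300)])
        assert len(assign_snps(rs, pd.DataFrame(columns=["id", "chrom", "bp"]))) == 0

    def test_matches_bruteforce_point_in_interval(self):
        rng = np.random.default_rng(3)
        intervals = []
        for _ in range(10):
            c = str(rng.integers(1, 4))
            s = int(rng.integers(1, 10_000))
            intervals.append((c, s, s + int(rng.integers(10, 1500))))
        rs = self._regions(intervals)
        variants = pd.DataFrame(
            {
                "id": [f"v{i}" for i in range(1000)],
                "chrom": rng.integers(1, 4, 1000).astype(str),
                "bp": rng.integers(1, 12_000, 1000),
            }
        )
        got = set(assign_snps(rs, variants).snp_ids)
        expected = set()
        for row in variants.itertuples(index=False):
            for c, s, e in intervals:
                if row.chrom == c and s <= row.bp <= e:
                    expected.add(row.id)
                    break
        assert got == expected

    def test_invariant_under_interval_permutation(self):
        gs = GeneSet("g", ("A", "B", "C"))
        rows = [("A", "1", 10, 50), ("B", "1", 200, 260), ("C", "2", 5, 25)]
        rng = np.random.default_rng(0)
        variants = pd.DataFrame(
            {"id": [f"v{i}" for i in range(200)],
             "chrom": rng.integers(1, 3, 200).astype(str),
             "bp": rng.integers(1, 300, 200)}
        )
        base = assign_snps(build_regions(gs, _annot(rows)), variants).snp_ids
        perm = assign_snps(build_regions(gs, _annot(rows[::-1])), variants).snp_ids
        assert base == perm

    def test_monotone_in_added_intervals(self):
        rng = np.random.default_rng(1)
        variants = pd.DataFrame(
            {"id": [f"v{i}" for i in range(300)], "chrom": "1",
             "bp": rng.integers(1, 1000, 300)}
        )
        sizes = []
        for k in (1, 2, 3):
            ivs = [("1", 100, 200), ("1", 400, 500), ("1", 700, 800)][:k]
            sizes.append(len(assign_snps(self._regions(ivs), variants)))
        assert sizes == sorted(sizes)


def test_interval_invariants():
    with pytest.raises(ValueError):
        GenomicInterval(chrom="1", start=10, end=5, gene="A")
    with pytest.raises(ValueError):
        GenomicInterval(chrom="", start=1, end=5, gene="A")
    with pytest.raises(ValueError, match="empty"):
        GeneSet("x", ())


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(st.integers(1, 500), st.integers(0, 60)),
        min_size=1, max_size=12,
    )
)
def test_merged_intervals_cover_exactly_the_input_positions(raw):
    """Property: merging preserves covered positions and yields disjoint,
    sorted intervals."""
    rows = [("G0", "1", s, s + w) for s, w in raw]
    rs = build_regions(GeneSet("x", ("G0",)), _annot(rows))
    covered = set()
    for _, _, s, e in rows:
        covered.update(range(s, e + 1))
    merged = []
    for iv in rs.intervals:
        merged.append((iv.start, iv.end))
        assert iv.start <= iv.end
    # disjoint, sorted, non-book-ended
    for (s1, e1), (s2, e2) in zip(merged, merged[1:]):
        assert e1 + 1 < s2
    got = set()
    for s, e in merged:
        got.update(range(s, e + 1))
    assert got == covered
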