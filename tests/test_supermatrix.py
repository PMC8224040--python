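"""Supermatrix accounting: completeness, concatenation, partitions, export."""

import numpy as np
import pytest

from anchorkit import supermatrix as sm
from anchorkit.locus_qc import LocusAlignment, SplitLocus
from anchorkit.simdata import _CODONS_FOR_AA


def make_locus(locus_id, taxa, n_codons, rng, flank_len=0):
    codons = [c for cods in _CODONS_FOR_AA.values() for c in cods]
    rows = {
        t: "".join(rng.choice(codons) for _ in range(n_codons)) for t in taxa
    }
    flanks = {
        t: "".join(rng.choice(list("ACGT"), size=flank_len)) for t in taxa
    }
    empty = {t: "" for t in taxa}
    return SplitLocus(
        locus_id,
        LocusAlignment(locus_id, rows),
        LocusAlignment(locus_id + ".flank_L", flanks if flank_len else empty),
        LocusAlignment(locus_id + ".flank_R", empty),
        0,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


@pytest.fixture()
def locus_set(rng):
    universe = [f"x{i:02d}" for i in range(10)]
    sizes = [10, 8, 7, 5, 4, 3]
    return universe, [
        make_locus(f"loc{i}", universe[:k], 20 + 5 * i, rng)
        for i, k in enumerate(sizes)
    ]


class TestCompleteness:
    def test_at_least_half_kept(self, locus_set):
        universe, loci = locus_set
        kept = sm.filter_by_completeness(loci, universe, sm.MatrixParams(0.5))
        assert [l.locus_id for l in kept] == ["loc0", "loc1", "loc2", "loc3"]

    def test_below_half_dropped(self, locus_set):
        universe, loci = locus_set
        kept = sm.filter_by_completeness(loci, universe, sm.MatrixParams(0.5))
        assert "loc4" not in [l.locus_id for l in kept]  # 4/10 taxa

    def test_ceil_rule_at_fractional_threshold(self, locus_set):
        universe, loci = locus_set
        # 0.75 x 10 = 7.5 -> need >= 8, so the 7-taxon locus is dropped
        kept = sm.filter_by_completeness(loci, universe, sm.MatrixParams(0.75))
        assert [l.locus_id for l in kept] == ["loc0", "loc1"]
        assert sm.n_taxa_required(0.75, 10) == 8

    def test_nesting_of_completeness_sets(self, locus_set):
        universe, loci = locus_set
        k50 = {l.locus_id for l in sm.filter_by_completeness(loci, universe, sm.MatrixParams(0.5))}
        k75 = {l.locus_id for l in sm.filter_by_completeness(loci, universe, sm.MatrixParams(0.75))}
        assert k75 <= k50

    def test_empty_universe_rejected(self, locus_set):
        _, loci = locus_set
        with pytest.raises(ValueError):
            sm.filter_by_completeness(loci, [], sm.MatrixParams(0.5))


class TestConcatenate:
    def test_width_is_sum_of_parts(self, rng):
        universe = ["a", "b", "c"]
        loci = [
            make_locus("l1", universe, 100, rng),
            make_locus("l2", universe, 50, rng),
        ]
        bundle = sm.concatenate(loci, universe)
        assert bundle.width == 450

    def test_missing_taxon_filled(self, rng):
        universe = ["a", "b", "c"]
        loci = [
            make_locus("l1", universe, 100, rng),
            make_locus("l2", ["a", "b"], 50, rng),
        ]
        bundle = sm.concatenate(loci, universe)
        s, e, _ = bundle.coordinates["l2"]
        assert bundle.rows["c"][s:e] == "?" * 150

    def test_lexicographic_locus_order(self, rng):
        universe = ["a", "b"]
        loci = [make_locus(n, universe, 10, rng) for n in ["zz", "aa", "mm"]]
        bundle = sm.concatenate(loci, universe)
        starts = {n: bundle.coordinates[n][0] for n in ["aa", "mm", "zz"]}
        assert starts["aa"] < starts["mm"] < starts["zz"]

    def test_ungapped_content_conserved(self, rng):
        universe = [f"x{i}" for i in range(6)]
        loci = [make_locus(f"l{i}", universe[: 3 + i % 4], 30, rng) for i in range(5)]
        bundle = sm.concatenate(loci, universe)
        for t in universe:
            expected = "".join(
                loc.probe_region.rows[t].replace("-", "")
                for loc in sorted(loci, key=lambda l: l.locus_id)
                if t in loc.probe_region.rows
            )
            got = bundle.rows[t].replace("?", "").replace("-", "")
            assert got == expected

    def test_flanks_appended_after_probe_blocks(self, rng):
        universe = ["a", "b", "c"]
        loci = [make_locus("l1", universe, 30, rng, flank_len=20)]
        bundle = sm.concatenate(loci, universe, sm.MatrixParams(include_flanks=True))
        assert bundle.coordinates["l1"] == (0, 90, "probe")
        assert bundle.coordinates["l1.flank_L"] == (90, 110, "flank")
        assert bundle.width == 110


class TestPartitions:
    def _bundle(self, rng, flanks=False):
        universe = ["a", "b", "c", "d"]
        loci = [
            make_locus("l1", universe, 100, rng, flank_len=25 if flanks else 0),
            make_locus("l2", universe, 40, rng, flank_len=25 if flanks else 0),
        ]
        return sm.concatenate(
            loci, universe, sm.MatrixParams(include_flanks=flanks)
        )

    def test_stride_arithmetic(self, rng):
        bundle = self._bundle(rng)
        parts = sm.define_partitions(bundle)
        by_name = {p.name: p for p in parts}
        assert by_name["l1_pos1"].pieces == ((1, 300, 3),)
        assert by_name["l1_pos2"].pieces == ((2, 300, 3),)
        assert by_name["l1_pos3"].pieces == ((3, 300, 3),)
        assert by_name["l2_pos1"].pieces == ((301, 420, 3),)

    def test_positions_disjoint_and_tile_locus(self, rng):
        bundle = self._bundle(rng)
        parts = sm.define_partitions(bundle)
        l1 = [set(p.columns()) for p in parts if p.name.startswith("l1_")]
        assert not (l1[0] & l1[1] or l1[0] & l1[2] or l1[1] & l1[2])
        assert l1[0] | l1[1] | l1[2] == set(range(1, 301))

    def test_single_flank_partition_covers_all_flank_blocks(self, rng):
        bundle = self._bundle(rng, flanks=True)
        parts = sm.define_partitions(bundle)
        flank_parts = [p for p in parts if p.name == "flanks"]
        assert len(flank_parts) == 1
        assert len(flank_parts[0]) == 50  # two 25-column left flanks

    def test_partition_columns_sum_to_width(self, rng):
        bundle = self._bundle(rng, flanks=True)
        parts = sm.define_partitions(bundle)
        assert sum(len(p) for p in parts) == bundle.width

    def test_non_codon_block_rejected(self):
        bundle = sm.SupermatrixBundle(["a"], {"a": "ACGTA"}, {"l1": (0, 5, "probe")})
        with pytest.raises(ValueError, match="l1"):
            sm.define_partitions(bundle)


class TestSmallPartitions:
    @pytest.mark.parametrize("n_cols,kept", [(79, False), (80, True)])
    def test_80bp_boundary(self, n_cols, kept):
        p = sm.Partition("p", ((1, n_cols, 1),))
        result, removed = sm.drop_small_partitions([p])
        assert (p in result) == kept

    def test_removed_column_accounting(self, rng):
        parts = [
            sm.Partition(f"p{i}", ((1 + 100 * i, 100 * i + w, 1),))
            for i, w in enumerate([79, 80, 10, 200])
        ]
        kept, removed = sm.drop_small_partitions(parts)
        assert sum(len(p) for p in removed) == 89
        assert {p.name for p in kept} == {"p1", "p3"}


class TestStripAndTranslate:
    def _bundle(self, rng):
        universe = ["a", "b", "c"]
        loci = [make_locus("l1", universe, 100, rng, flank_len=50)]
        return sm.concatenate(loci, universe, sm.MatrixParams(include_flanks=True))

    def test_strip_third_positions_yields_two_thirds(self, rng):
        bundle = self._bundle(rng)
        stripped = sm.strip_third_positions(bundle)
        s, e, _ = stripped.coordinates["l1"]
        assert e - s == 200
        fs, fe, _ = stripped.coordinates["l1.flank_L"]
        assert fe - fs == 50  # flanks untouched
        assert stripped.width == 250

    def test_strip_preserves_first_two_positions(self, rng):
        bundle = self._bundle(rng)
        stripped = sm.strip_third_positions(bundle)
        row, srow = bundle.rows["a"], stripped.rows["a"]
        expected = "".join(row[c] for c in range(300) if c % 3 != 2) + row[300:]
        assert srow == expected

    def test_translate_after_strip_is_an_error(self, rng):
        stripped = sm.strip_third_positions(self._bundle(rng))
        with pytest.raises(ValueError, match="strip"):
            sm.translate_matrix(stripped)

    def test_translate_simple_codons(self):
        bundle = sm.SupermatrixBundle(
            ["a", "b"], {"a": "ATGAAA", "b": "ATGNAA"}, {"l1": (0, 6, "probe")}
        )
        aa = sm.translate_matrix(bundle)
        assert aa.rows["a"] == "MK"
        assert aa.rows["b"] == "MX"
        assert aa.datatype == "AA"

    def test_translate_excludes_flanks_and_is_compositional(self, rng):
        bundle = self._bundle(rng)
        aa = sm.translate_matrix(bundle)
        assert aa.width == 100
        # per-locus translation concatenated == matrix translation
        from anchorkit.locus_qc import translate_codon

        s, e, _ = bundle.coordinates["l1"]
        row = bundle.rows["a"][s:e]
        expected = "".join(translate_codon(row[k : k + 3]) for k in range(0, 300, 3))
        assert aa.rows["a"] == expected

    def test_gap_and_missing_codons(self):
        bundle = sm.SupermatrixBundle(
            ["a"], {"a": "AT-???"}, {"l1": (0, 6, "probe")}
        )
        aa = sm.translate_matrix(bundle)
        assert aa.rows["a"] == "-?"


class TestRoundTrip:
    def test_phylip_and_partition_files(self, rng, tmp_path):
        universe = [f"x{i}" for i in range(6)]
        loci = [make_locus(f"l{i}", universe, 40, rng, flank_len=10) for i in range(3)]
        bundle = sm.concatenate(loci, universe, sm.MatrixParams(include_flanks=True))
        parts = sm.define_partitions(bundle)
        mat, pf = tmp_path / "m.phy", tmp_path / "p.txt"
        sm.write_phylip(bundle, str(mat))
        sm.write_partition_file(parts, str(pf))
        taxa, rows = sm.read_phylip(str(mat))
        assert taxa == bundle.taxa
        assert rows == bundle.rows
        parts2 = sm.read_partition_file(str(pf))
        assert [(p.name, p.pieces) for p in parts2] == [(p.name, p.pieces) for p in parts]

    def test_raxml_line_format(self):
        p = sm.Partition("locus1_pos1", ((1, 300, 3),))
        assert p.to_raxml() == "DNA, locus1_pos1 = 1-300\\3"
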