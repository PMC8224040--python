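"""Target design: codon threading, conservation windows, excision, tiling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from anchorkit import orthotargets as ot
from anchorkit.simdata import _CODONS_FOR_AA, AA_ALPHABET


def brute_force_window_scores(aa_rows, window, max_gap_fraction):
    """Independent re-derivation of per-window conservation scores."""
    rows = list(aa_rows.values())
    n, L = len(rows), len(rows[0])
    out = []
    for s in range(L - window + 1):
        total, ok = 0.0, True
        for j in range(s, s + window):
            col = [r[j] for r in rows]
            residues = [c for c in col if c != "-"]
            if (n - len(residues)) / n > max_gap_fraction:
                ok = False
            if residues:
                freq = max(residues.count(c) for c in set(residues)) / len(residues)
            else:
                freq = 0.0
            total += freq
        out.append((s, total / window, ok))
    return out


class TestThreading:
    def test_gap_becomes_codon_gap(self):
        assert ot.thread_nucleotides("M-K", "ATGAAA") == "ATG---AAA"

    def test_identity_case(self):
        assert ot.thread_nucleotides("MK", "ATGAAA") == "ATGAAA"

    def test_terminal_stop_stripped(self):
        assert ot.thread_nucleotides("MK", "ATGAAATAA") == "ATGAAA"

    def test_length_mismatch_raises(self):
        with pytest.raises(ot.ThreadingError, match="length"):
            ot.thread_nucleotides("M-K", "ATGAAAAAA")

    def test_translation_mismatch_names_position(self):
        with pytest.raises(ot.ThreadingError, match="residue 1"):
            ot.thread_nucleotides("MM", "ATGAAA", ortholog_id="og1", taxon="t1")

    def test_internal_stop_rejected(self):
        with pytest.raises(ot.ThreadingError, match="stop"):
            ot.thread_nucleotides("M*K", "ATGTAAAAA")

    @settings(max_examples=50, deadline=None)
    @given(st.data())
    def test_roundtrip_ungap_recovers_cds(self, data):
        protein = data.draw(
            st.text(alphabet=AA_ALPHABET, min_size=1, max_size=40)
        )
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        cds = "".join(
            _CODONS_FOR_AA[aa][rng.integers(len(_CODONS_FOR_AA[aa]))] for aa in protein
        )
        gapped = list(protein)
        for _ in range(data.draw(st.integers(0, 10))):
            gapped.insert(rng.integers(len(gapped) + 1), "-")
        threaded = ot.thread_nucleotides("".join(gapped), cds)
        assert threaded.replace("-", "") == cds
        assert len(threaded) == 3 * len(gapped)


class TestConservationScores:
    def test_identical_rows_score_one(self):
        og = ot.OrthogroupAlignment(
            "og", [f"t{i}" for i in range(8)],
            {f"t{i}": "MKLV" * 10 for i in range(8)},
            {f"t{i}": "ATGAAACTGGTT" * 10 for i in range(8)},
        )
        scores = ot.score_conservation(og, ot.DesignParams(window_len_aa=10))
        assert all(s == 1.0 for _, s, _ in scores)
        assert all(ok for _, _, ok in scores)

    def test_half_split_column_scores_half(self):
        rows = {f"t{i}": ("A" if i < 4 else "G") * 10 for i in range(8)}
        og = ot.OrthogroupAlignment(
            "og", list(rows), rows,
            {t: ("GCA" if i < 4 else "GGA") * 10 for i, t in enumerate(rows)},
        )
        scores = ot.score_conservation(og, ot.DesignParams(window_len_aa=10))
        assert scores == [(0, 0.5, True)]

    def test_matches_brute_force_on_simulated_panel(self, orthogroup_panel):
        ogs, _ = orthogroup_panel
        params = ot.DesignParams()
        for og in ogs[:5]:
            got = ot.score_conservation(og, params)
            expected = brute_force_window_scores(
                og.aa_rows, params.window_len_aa, params.max_gap_fraction
            )
            for (s1, sc1, ok1), (s2, sc2, ok2) in zip(got, expected):
                assert s1 == s2 and ok1 == ok2
                assert sc1 == pytest.approx(sc2, abs=1e-12)

    def test_row_order_invariance(self, orthogroup_panel):
        ogs, _ = orthogroup_panel
        og = ogs[0]
        shuffled = ot.OrthogroupAlignment(
            og.ortholog_id, list(reversed(og.taxa)), og.aa_rows, og.nt_rows
        )
        assert ot.score_conservation(og) == ot.score_conservation(shuffled)

    def test_window_longer_than_alignment_warns_empty(self):
        rows = {"a": "MK", "b": "MK"}
        og = ot.OrthogroupAlignment("og", ["a", "b"], rows, {"a": "ATGAAA", "b": "ATGAAA"})
        with pytest.warns(UserWarning):
            assert ot.score_conservation(og, ot.DesignParams(window_len_aa=20)) == []

    def test_highest_windows_inside_planted_block(self, orthogroup_panel):
        ogs, truths = orthogroup_panel
        params = ot.DesignParams()
        for og, truth in zip(ogs[:5], truths[:5]):
            scores = ot.score_conservation(og, params)
            (bs, be) = truth.blocks[0]
            top = sorted(scores, key=lambda x: -x[1])[:5]
            for s, _, _ in top:
                assert bs - params.window_len_aa <= s <= be


def _identical_og(n_taxa, n_codons):
    aa = "MKLVIE" * (n_codons // 6 + 1)
    aa = aa[:n_codons]
    nt = "".join(_CODONS_FOR_AA[a][0] for a in aa)
    rows = {f"t{i}": aa for i in range(n_taxa)}
    return ot.OrthogroupAlignment("og", list(rows), rows, {t: nt for t in rows})


class TestExciseAndSelect:
    def test_overlapping_windows_merge_to_one_region(self):
        og = _identical_og(8, 60)
        params = ot.DesignParams()
        regions = ot.excise_targets(og, ot.score_conservation(og, params), params)
        assert len(regions) == 1
        assert regions[0].aa_span == (0, 60)
        assert regions[0].nt_span == (0, 180)

    def test_short_region_dropped(self):
        og = _identical_og(8, 30)  # 90 nt < 120
        params = ot.DesignParams()
        regions = ot.excise_targets(og, ot.score_conservation(og, params), params)
        assert regions == []

    def test_planted_block_recovered_within_window_len(self, orthogroup_panel):
        ogs, truths = orthogroup_panel
        params = ot.DesignParams()
        for og, truth in zip(ogs, truths):
            regions = ot.excise_targets(og, ot.score_conservation(og, params), params)
            assert len(regions) == 1
            (a, b) = regions[0].aa_span
            (bs, be) = truth.blocks[0]
            assert abs(a - bs) <= params.window_len_aa
            assert abs(b - be) <= params.window_len_aa
            # regions sorted, non-overlapping, codon-aligned
            assert regions[0].nt_span == (3 * a, 3 * b)

    def test_representation_rule_five_of_eight(self, orthogroup_panel):
        ogs, truths = orthogroup_panel
        params = ot.DesignParams()
        for og, truth in zip(ogs, truths):
            regions = ot.excise_targets(og, ot.score_conservation(og, params), params)
            kept = ot.select_targets(regions, params)
            assert (len(kept) == 1) == truth.expected_kept[0]
            if kept:
                expected = sorted(set(og.taxa) - set(truth.absent_taxa[0]))
                assert kept[0].represented_taxa == expected

    def test_half_gapped_taxon_not_represented(self):
        seqs = {f"t{i}": "A" * 150 for i in range(5)}
        seqs["gappy"] = "A" * 75  # ungapped content = 50% of span
        region = ot.TargetRegion("og", (0, 50), (0, 150), seqs)
        kept = ot.select_targets([region], ot.DesignParams(min_ref_taxa=5))
        assert kept and "gappy" not in kept[0].represented_taxa

    def test_select_monotone_in_min_ref_taxa(self, orthogroup_panel):
        ogs, _ = orthogroup_panel
        params = ot.DesignParams()
        for og in ogs[:8]:
            regions = ot.excise_targets(og, ot.score_conservation(og, params), params)
            strict = {
                r.region_id
                for r in ot.select_targets(regions, ot.DesignParams(min_ref_taxa=6))
            }
            loose = {
                r.region_id
                for r in ot.select_targets(regions, ot.DesignParams(min_ref_taxa=5))
            }
            assert strict <= loose


def _region_of_length(L, rng):
    seq = "".join(rng.choice(list("ACGT"), size=L))
    return ot.TargetRegion("og", (0, L // 3), (0, L), {"t1": seq}, ["t1"])


class TestTiling:
    def test_default_step_is_87(self):
        assert round(100 / 1.15) == 87

    @pytest.mark.parametrize(
        "L,expected_starts",
        [
            (100, [0]),
            (274, [0, 87, 174]),
            (275, [0, 87, 174, 175]),
        ],
    )
    def test_hand_enumerated_cases(self, L, expected_starts):
        rng = np.random.default_rng(L)
        bs = ot.tile_baits(_region_of_length(L, rng))
        assert [b[1] for b in bs.baits] == expected_starts
        assert all(len(b[2]) == 100 for b in bs.baits)
        assert bs.step_nt == 87

    def test_coverage_and_density_over_random_lengths(self):
        rng = np.random.default_rng(7)
        params = ot.DesignParams()
        for L in rng.integers(100, 2001, size=300):
            bs = ot.tile_baits(_region_of_length(int(L), rng), params)
            covered = np.zeros(int(L), dtype=bool)
            for _, s, seq in bs.baits:
                assert len(seq) == params.bait_len
                covered[s : s + params.bait_len] = True
            assert covered.all()
            density = len(bs.baits) * params.bait_len / int(L)
            assert density <= params.tiling_factor + params.bait_len / int(L)

    def test_short_sequence_skipped_with_warning(self):
        region = ot.TargetRegion("og", (0, 50), (0, 150), {"t1": "A" * 50}, ["t1"])
        with pytest.warns(UserWarning, match="shorter"):
            bs = ot.tile_baits(region)
        assert bs.baits == []

    def test_duplicate_sequences_removed_across_taxa(self):
        seq = "ACGT" * 30  # 120 nt
        region = ot.TargetRegion("og", (0, 40), (0, 120), {"t1": seq, "t2": seq}, ["t1", "t2"])
        bs = ot.tile_baits(region)
        assert len({b[2] for b in bs.baits}) == len(bs.baits)
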