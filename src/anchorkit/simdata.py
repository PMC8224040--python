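"""Synthetic fixtures with recorded ground truth.

Every generator here emulates one input class of the capture workflow and
returns, alongside the sequences, a machine-readable truth record that the
test suite checks the pipeline against:

* :func:`simulate_orthogroups` — reference orthogroups evolved from a
  common ancestor on a star tree, with planted high-conservation blocks
  (low per-site replacement rate) between fast-evolving spacers, and
  optional taxa made "absent" from a block via contiguous gap runs;
* :func:`simulate_contigs` — per-target mutated contigs at a requested
  identity, plus planted chimeras (one contig spanning two targets),
  paralogs (two contigs for one target) and sequence-free decoys;
* :func:`simulate_locus_with_flanks` — a coding core flanked by random
  non-coding runs with stop codons / out-of-frame gap runs planted at the
  core edges, and optionally one row carrying a 1-nt frameshift;
* :func:`simulate_quartet_alignment` — exact Jukes-Cantor simulation on a
  5-branch quartet tree (and :func:`simulate_cluster_alignment` for
  multi-taxon clusters around the same internal branch).

The amino-acid replacement process for orthogroups is deliberately simple
(per-site uniform replacement at a given rate); it controls identity
levels, which is all the design stage responds to.  Quartet data use the
exact JC69 transition probabilities.  All generators take an explicit
``numpy.random.Generator`` or integer seed; the same seed yields identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .orthotargets import OrthogroupAlignment

__all__ = [
    "OrthogroupTruth",
    "ContigTruth",
    "LocusTruth",
    "simulate_orthogroups",
    "simulate_contigs",
    "simulate_locus_with_flanks",
    "simulate_quartet_alignment",
    "simulate_cluster_alignment",
    "jc69_expected_distance",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT = "ACGT"

# Sense codons per amino acid (standard code), for codon re-randomisation.
from Bio.Data.CodonTable import standard_dna_table as _tab

_CODONS_FOR_AA: dict[str, list[str]] = {}
for codon, aa in _tab.forward_table.items():
    _CODONS_FOR_AA.setdefault(aa, []).append(codon)
for aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[aa].sort()


def _rng(seed: int | np.random.Generator) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _random_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA_ALPHABET), size=n))


def _codon_for(aa: str, rng: np.random.Generator) -> str:
    return str(rng.choice(_CODONS_FOR_AA[aa]))


# ---------------------------------------------------------------------------
# Orthogroups with planted conserved blocks


@dataclass
class OrthogroupTruth:
    ortholog_id: str
    # planted conserved blocks as (aa_start, aa_end) alignment intervals
    blocks: list[tuple[int, int]]
    # per block: taxa given gap runs there (non-gap fraction < 0.9)
    absent_taxa: list[list[str]]
    # per block: whether the >= min_ref_taxa representation rule should keep it
    expected_kept: list[bool]


def simulate_orthogroups(
    n_orthogroups: int = 20,
    n_taxa: int = 8,
    seed: int | np.random.Generator = 0,
    *,
    n_blocks: int = 1,
    block_len_aa: int = 60,
    spacer_len_aa: int = 40,
    conserved_rate: float = 0.02,
    spacer_rate: float = 1.0,
    absent_counts: list[int] | None = None,
    min_ref_taxa: int = 5,
) -> tuple[list[OrthogroupAlignment], list[OrthogroupTruth]]:
    """Simulate orthogroups on a star tree with planted conserved blocks.

    Layout per orthogroup: ``spacer (block spacer) x n_blocks``.  Each site
    of each taxon is replaced by a uniform random amino acid with the
    block's rate (0.02 in conserved blocks keeps AA identity ~0.96; 1.0 in
    spacers scrambles them).  For each block, ``absent_counts`` taxa (cycled
    across orthogroups when given, else 0) receive disjoint contiguous gap
    runs covering 15% of the block, pushing their non-gap fraction below
    the representation floor without ever putting two gaps in one column.
    """
    rng = _rng(seed)
    taxa = [f"t{i + 1:02d}" for i in range(n_taxa)]
    ogs: list[OrthogroupAlignment] = []
    truths: list[OrthogroupTruth] = []
    run_len = max(1, int(round(0.15 * block_len_aa)))
    for g in range(n_orthogroups):
        blocks: list[tuple[int, int]] = []
        rates: list[float] = [spacer_rate] * spacer_len_aa
        for _ in range(n_blocks):
            start = len(rates)
            rates.extend([conserved_rate] * block_len_aa)
            blocks.append((start, start + block_len_aa))
            rates.extend([spacer_rate] * spacer_len_aa)
        L = len(rates)
        ancestor = _random_aa(rng, L)
        aa_rows: dict[str, str] = {}
        for t in taxa:
            chars = list(ancestor)
            hits = rng.random(L) < np.asarray(rates).clip(max=1.0)
            for i in np.flatnonzero(hits):
                chars[i] = AA_ALPHABET[rng.integers(20)]
            aa_rows[t] = "".join(chars)
        absent_per_block: list[list[str]] = []
        kept: list[bool] = []
        for b, (bs, be) in enumerate(blocks):
            k = absent_counts[(g * n_blocks + b) % len(absent_counts)] if absent_counts else 0
            chosen = [str(t) for t in rng.choice(taxa, size=k, replace=False)] if k else []
            for slot, t in enumerate(chosen):
                gs = bs + slot * run_len
                row = list(aa_rows[t])
                for i in range(gs, min(gs + run_len, be)):
                    row[i] = "-"
                aa_rows[t] = "".join(row)
            absent_per_block.append(sorted(chosen))
            kept.append(n_taxa - k >= min_ref_taxa)
        cds = {
            t: "".join(_codon_for(aa, rng) for aa in aa_rows[t] if aa != "-")
            for t in taxa
        }
        og = OrthogroupAlignment.from_cds(f"og{g + 1:03d}", aa_rows, cds)
        ogs.append(og)
        truths.append(OrthogroupTruth(og.ortholog_id, blocks, absent_per_block, kept))
    return ogs, truths


# ---------------------------------------------------------------------------
# Contig sets for capture evaluation


@dataclass
class ContigTruth:
    expected_accepted: dict[str, str]  # target -> contig id
    expected_rejected_contigs: list[str]
    expected_rejected_targets: list[str]
    expected_unmatched: list[str]
    decoys: list[str] = field(default_factory=list)


def _mutate_to_identity(
    seq: str, identity: float, rng: np.random.Generator, protect: int = 20
) -> str:
    """Substitute exactly round((1-identity)*L) positions.

    The first *protect* positions are left untouched (when possible) so a
    seed-length exact match to the source always survives."""
    L = len(seq)
    n_mut = int(round((1.0 - identity) * L))
    lo = protect if L - protect >= n_mut else 0
    pos = lo + rng.choice(L - lo, size=n_mut, replace=False)
    chars = list(seq)
    for p in pos:
        chars[p] = rng.choice([b for b in NT if b != chars[p]])
    return "".join(chars)


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(NT), size=n))


def _shares_kmer(seq: str, kmer_set: set[str], k: int) -> bool:
    return any(seq[i : i + k] in kmer_set for i in range(len(seq) - k + 1))


def simulate_contigs(
    targets: dict[str, str],
    seed: int | np.random.Generator = 0,
    *,
    identity: float = 0.85,
    n_decoys: int = 0,
    chimera_pair: tuple[str, str] | None = None,
    paralog_target: str | None = None,
    seed_len: int = 15,
) -> tuple[dict[str, str], ContigTruth]:
    """One mutated full-length contig per target, plus planted ambiguities.

    *chimera_pair* plants one contig spanning two targets (it should be
    discarded as multi-target while both its targets remain recoverable
    from their own contigs); *paralog_target* plants a second independent
    copy of one target (that target should be discarded as multi-contig).
    Decoys are random sequences rejection-sampled to share no
    ``seed_len``-mer with any target.
    """
    rng = _rng(seed)
    contigs: dict[str, str] = {}
    for tid in sorted(targets):
        contigs[f"contig_{tid}"] = _mutate_to_identity(targets[tid], identity, rng)
    truth = ContigTruth(
        expected_accepted={tid: f"contig_{tid}" for tid in sorted(targets)},
        expected_rejected_contigs=[],
        expected_rejected_targets=[],
        expected_unmatched=[],
    )
    if chimera_pair is not None:
        t1, t2 = chimera_pair
        cid = f"chimera_{t1}_{t2}"
        contigs[cid] = (
            _mutate_to_identity(targets[t1], identity, rng)
            + _mutate_to_identity(targets[t2], identity, rng)
        )
        truth.expected_rejected_contigs.append(cid)
    if paralog_target is not None:
        cid = f"paralog_{paralog_target}"
        contigs[cid] = _mutate_to_identity(targets[paralog_target], identity, rng)
        truth.expected_rejected_targets.append(paralog_target)
        del truth.expected_accepted[paralog_target]
    kmers = {
        seq[i : i + seed_len]
        for seq in targets.values()
        for i in range(len(seq) - seed_len + 1)
    }
    mean_len = int(np.mean([len(s) for s in targets.values()]))
    for d in range(n_decoys):
        while True:
            cand = _random_nt(rng, mean_len)
            if not _shares_kmer(cand, kmers, seed_len):
                break
        cid = f"decoy_{d + 1:02d}"
        contigs[cid] = cand
        truth.decoys.append(cid)
    return contigs, truth


# ---------------------------------------------------------------------------
# Loci with planted flanks / frameshifts


@dataclass
class LocusTruth:
    core: tuple[int, int]  # expected probe-region boundaries (columns)
    frame: int
    left_demarcation: str | None  # "stop" | "gap" | None
    right_demarcation: str | None
    frameshift_taxon: str | None = None
    # expected N-mask interval in probe-region coordinates
    frameshift_mask: tuple[int, int] | None = None


def simulate_locus_with_flanks(
    seed: int | np.random.Generator = 0,
    *,
    n_taxa: int = 8,
    core_codons: int = 40,
    flank_len: int = 30,
    aa_rate: float = 0.05,
    left_demarcation: str | None = "stop",
    right_demarcation: str | None = "stop",
    frameshift: bool = False,
    locus_id: str = "locus1",
) -> tuple["LocusAlignment", LocusTruth]:
    """A coding core between random non-coding flanks.

    The demarcating feature (an in-frame TAA, or a 4-nt gap run) is planted
    in one row immediately outside the core on each requested side, so the
    expected flank boundaries are exactly the core edges.  With
    *frameshift*, one row gets a single-base gap mid-core whose mask is
    expected to run to the core end.
    """
    from .locus_qc import LocusAlignment

    rng = _rng(seed)
    taxa = [f"s{i + 1:02d}" for i in range(n_taxa)]
    ancestor_aa = _random_aa(rng, core_codons)
    core_rows: dict[str, str] = {}
    for t in taxa:
        aa = [
            AA_ALPHABET[rng.integers(20)] if rng.random() < aa_rate else c
            for c in ancestor_aa
        ]
        core_rows[t] = "".join(_codon_for(c, rng) for c in aa)
    left = {t: _random_nt(rng, flank_len) for t in taxa} if flank_len else {t: "" for t in taxa}
    right = {t: _random_nt(rng, flank_len) for t in taxa} if flank_len else {t: "" for t in taxa}

    def plant(flank_rows: dict[str, str], side: str, kind: str | None) -> None:
        if kind is None or flank_len == 0:
            return
        victim = taxa[int(rng.integers(n_taxa))]
        row = list(flank_rows[victim])
        if kind == "stop":
            if side == "left":  # in-frame codon ending at the core edge
                row[flank_len - 3 : flank_len] = "TAA"
            else:
                row[0:3] = "TAA"
        elif kind == "gap":
            if side == "left":
                row[flank_len - 4 : flank_len] = "----"
            else:
                row[0:4] = "----"
        else:
            raise ValueError(f"unknown demarcation kind {kind!r}")
        flank_rows[victim] = "".join(row)

    plant(left, "left", left_demarcation)
    plant(right, "right", right_demarcation)

    core_start = flank_len
    core_end = flank_len + 3 * core_codons
    shift_taxon = None
    mask = None
    if frameshift:
        shift_taxon = taxa[int(rng.integers(n_taxa))]
        col = core_start + 3 * (core_codons // 2)  # codon boundary mid-core
        row = list(core_rows[shift_taxon])
        row[col - core_start] = "-"
        core_rows[shift_taxon] = "".join(row)
        mask = (col - core_start, 3 * core_codons)

    rows = {t: left[t] + core_rows[t] + right[t] for t in taxa}
    locus = LocusAlignment(locus_id, rows, core=(core_start, core_end))
    truth = LocusTruth(
        (core_start, core_end), 0, left_demarcation, right_demarcation, shift_taxon, mask
    )
    return locus, truth


# ---------------------------------------------------------------------------
# Quartet alignments under JC69


def _simulate_jc_on_tree(
    tree: dendropy.Tree, n_sites: int, rng: np.random.Generator
) -> dict[str, str]:
    states: dict[int, np.ndarray] = {}
    root = tree.seed_node
    states[id(root)] = rng.integers(0, 4, size=n_sites)
    out: dict[str, str] = {}
    for node in tree.preorder_node_iter():
        if node is root:
            parent_states = states[id(root)]
        else:
            parent_states = states[id(node.parent_node)]
            t = node.edge.length or 0.0
            p_same = 0.25 + 0.75 * np.exp(-4.0 * t / 3.0)
            change = rng.random(n_sites) >= p_same
            shift = rng.integers(1, 4, size=n_sites)  # uniform among the 3 others
            child = np.where(change, (parent_states + shift) % 4, parent_states)
            states[id(node)] = child
            parent_states = child
        if node.is_leaf():
            out[node.taxon.label] = "".join("ACGT"[s] for s in parent_states)
    return out


_TOPOLOGY_PAIRS = {"T1": ("a", "b", "c", "d"), "T2": ("a", "c", "b", "d"), "T3": ("a", "d", "b", "c")}


def simulate_quartet_alignment(
    topology: str = "T1",
    branch_lengths: tuple[float, float, float, float, float] = (0.05, 0.05, 0.05, 0.05, 0.2),
    n_sites: int = 1000,
    seed: int | np.random.Generator = 0,
    taxa: tuple[str, str, str, str] = ("a", "b", "c", "d"),
) -> dict[str, str]:
    """Exact JC69 simulation on the unrooted quartet tree of *topology*.

    ``branch_lengths`` are (t_a, t_b, t_c, t_d, t_internal) in expected
    substitutions per site, matching the taxon order of the topology's
    sister pairs.  Returns taxon -> sequence.
    """
    rng = _rng(seed)
    x, y, z, w = _TOPOLOGY_PAIRS[topology]
    names = dict(zip(("a", "b", "c", "d"), taxa))
    ta, tb, tc, td, t5 = branch_lengths
    newick = (
        f"(({names[x]}:{ta},{names[y]}:{tb}):0.0,"
        f"({names[z]}:{tc},{names[w]}:{td}):{t5});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    return _simulate_jc_on_tree(tree, n_sites, rng)


def simulate_cluster_alignment(
    n_per_cluster: int = 2,
    topology: str = "T1",
    branch_lengths: tuple[float, float, float, float, float] = (0.05, 0.05, 0.05, 0.05, 0.2),
    within_cluster: float = 0.02,
    n_sites: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, str], dict[str, str]]:
    """JC69 data for four monophyletic clusters around one internal branch.

    Each cluster (C1..C4, taxa ``c<k>_<i>``) radiates from its quartet tip
    with short within-cluster branches.  Returns (rows, taxon -> cluster
    label) ready for :class:`~anchorkit.fclm.ClusterAssignment`.
    """
    rng = _rng(seed)
    x, y, z, w = _TOPOLOGY_PAIRS[topology]
    order = {"a": "c1", "b": "c2", "c": "c3", "d": "c4"}

    def clade(tag: str) -> str:
        tips = ",".join(
            f"{order[tag]}_{i + 1}:{within_cluster}" for i in range(n_per_cluster)
        )
        return f"({tips})"

    ta, tb, tc, td, t5 = branch_lengths
    newick = (
        f"(({clade(x)}:{ta},{clade(y)}:{tb}):0.0,"
        f"({clade(z)}:{tc},{clade(w)}:{td}):{t5});"
    )
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    rows = _simulate_jc_on_tree(tree, n_sites, rng)
    labels = {t: t.split("_")[0].upper() for t in rows}
    return rows, labels


def jc69_expected_distance(t: float) -> float:
    """Expected proportion of differing sites after total branch length t."""
    return 0.75 * (1.0 - np.exp(-4.0 * t / 3.0))
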