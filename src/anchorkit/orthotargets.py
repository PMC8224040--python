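"""Bait target design from paired amino-acid / nucleotide orthogroup alignments.

The workflow mirrors how anchored-hybrid-enrichment probe kits are designed
from a panel of reference transcriptomes:

1. each orthogroup's coding sequences are threaded codon-by-codon onto the
   amino-acid alignment (Tranalign semantics), giving a nucleotide alignment
   in which every gap is a whole codon;
2. a sliding window over the AA alignment scores conservation as the mean
   modal-residue frequency, windows above a threshold are merged and the
   corresponding nucleotide regions excised;
3. regions are kept only when enough reference taxa actually have sequence
   there (representation rule, e.g. at least 5 of 8 taxa);
4. each kept region is tiled with fixed-length baits at a given tiling
   density (e.g. 100-nt baits at 1.15X), per taxon, with duplicate bait
   sequences removed.

Coordinates are 0-based half-open throughout; amino-acid column *i* maps to
nucleotide columns ``[3i, 3i+3)``.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "OrthogroupAlignment",
    "DesignParams",
    "TargetRegion",
    "BaitSet",
    "ThreadingError",
    "thread_nucleotides",
    "score_conservation",
    "excise_targets",
    "select_targets",
    "tile_baits",
    "design_targets",
]

_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOP_CODONS = set(standard_dna_table.stop_codons)

GAP = "-"


class ThreadingError(ValueError):
    """Raised when a CDS cannot be threaded onto its amino-acid row."""


def _translate_codon(codon: str) -> str | None:
    codon = codon.upper()
    if codon in _STOP_CODONS:
        return "*"
    return _CODON_TO_AA.get(codon)


def thread_nucleotides(
    aa_row: str,
    cds: str,
    *,
    ortholog_id: str = "?",
    taxon: str = "?",
) -> str:
    """Thread an ungapped CDS onto a gapped amino-acid alignment row.

    Each residue is replaced by its codon and each gap by ``---``.  A single
    terminal stop codon on the CDS is stripped before threading; internal
    stops or residue/codon disagreements raise :class:`ThreadingError`.
    """
    cds = cds.upper().replace("U", "T")
    if len(cds) % 3 == 0 and len(cds) >= 3 and cds[-3:] in _STOP_CODONS:
        cds = cds[:-3]
    ungapped = aa_row.replace(GAP, "")
    if len(ungapped) * 3 != len(cds):
        raise ThreadingError(
            f"{ortholog_id}/{taxon}: CDS length {len(cds)} does not match "
            f"3 x {len(ungapped)} amino acids"
        )
    out: list[str] = []
    k = 0
    for i, aa in enumerate(aa_row):
        if aa == GAP:
            out.append(GAP * 3)
            continue
        codon = cds[3 * k : 3 * k + 3]
        trans = _translate_codon(codon)
        if trans == "*":
            raise ThreadingError(
                f"{ortholog_id}/{taxon}: internal stop codon {codon} at "
                f"residue {k} (alignment column {i})"
            )
        # 'X' in the AA row accepts any codon (ambiguity placeholder).
        if trans != aa.upper() and aa.upper() != "X":
            raise ThreadingError(
                f"{ortholog_id}/{taxon}: codon {codon} translates to "
                f"{trans}, expected {aa.upper()} at residue {k} "
                f"(alignment column {i})"
            )
        out.append(codon)
        k += 1
    return "".join(out)


@dataclass
class OrthogroupAlignment:
    """Paired AA / codon-threaded NT alignment for one ortholog."""

    ortholog_id: str
    taxa: list[str]
    aa_rows: dict[str, str]
    nt_rows: dict[str, str]

    @classmethod
    def from_cds(
        cls, ortholog_id: str, aa_rows: dict[str, str], cds: dict[str, str]
    ) -> "OrthogroupAlignment":
        """Build the NT alignment by threading each taxon's CDS."""
        taxa = list(aa_rows)
        nt_rows = {
            t: thread_nucleotides(aa_rows[t], cds[t], ortholog_id=ortholog_id, taxon=t)
            for t in taxa
        }
        og = cls(ortholog_id, taxa, dict(aa_rows), nt_rows)
        og.validate()
        return og

    @property
    def aa_length(self) -> int:
        return len(next(iter(self.aa_rows.values())))

    def validate(self) -> None:
        if set(self.aa_rows) != set(self.nt_rows) or set(self.taxa) != set(self.aa_rows):
            raise ValueError(f"{self.ortholog_id}: taxa mismatch between AA and NT rows")
        length = self.aa_length
        for t in self.taxa:
            if len(self.aa_rows[t]) != length:
                raise ValueError(f"{self.ortholog_id}/{t}: ragged AA alignment")
            if len(self.nt_rows[t]) != 3 * length:
                raise ValueError(f"{self.ortholog_id}/{t}: NT row is not 3x AA row")


@dataclass
class DesignParams:
    """Tunable knobs of the target-design stage (defaults are the kit's)."""

    window_len_aa: int = 20
    conservation_threshold: float = 0.7
    max_gap_fraction: float = 0.2
    min_target_len_nt: int = 120
    min_ref_taxa: int = 5
    representation_min_nongap: float = 0.9
    bait_len: int = 100
    tiling_factor: float = 1.15

    def __post_init__(self) -> None:
        if not 0 < self.conservation_threshold <= 1:
            raise ValueError("conservation_threshold must be in (0, 1]")
        if self.min_target_len_nt < self.bait_len:
            raise ValueError("min_target_len_nt must be >= bait_len")
        if self.min_target_len_nt % 3:
            raise ValueError("min_target_len_nt must be a multiple of 3")


@dataclass
class TargetRegion:
    """A conserved coding region excised from one orthogroup."""

    ortholog_id: str
    aa_span: tuple[int, int]  # 0-based half-open AA columns
    nt_span: tuple[int, int]  # = 3x aa_span
    sequences: dict[str, str]  # taxon -> UNGAPPED NT sequence within the span
    represented_taxa: list[str] = field(default_factory=list)

    @property
    def region_id(self) -> str:
        return f"{self.ortholog_id}|{self.nt_span[0]}-{self.nt_span[1]}"

    @property
    def length_nt(self) -> int:
        return self.nt_span[1] - self.nt_span[0]


@dataclass
class BaitSet:
    """Tiled baits covering one target region."""

    target: TargetRegion
    baits: list[tuple[str, int, str]]  # (taxon, start within ungapped seq, sequence)
    step_nt: int


def score_conservation(
    og: OrthogroupAlignment, params: DesignParams | None = None
) -> list[tuple[int, float, bool]]:
    """Sliding-window conservation scores over the AA alignment.

    Returns ``(start, score, eligible)`` for every window start.  The score
    is the mean, over window columns, of the modal-residue frequency among
    non-gap rows; a window is ineligible when any of its columns has a gap
    fraction above ``max_gap_fraction``.
    """
    params = params or DesignParams()
    w = params.window_len_aa
    rows = [og.aa_rows[t] for t in og.taxa]
    n = len(rows)
    if n < 2:
        raise ValueError(f"{og.ortholog_id}: need at least 2 taxa to score conservation")
    length = og.aa_length
    if w > length:
        warnings.warn(
            f"{og.ortholog_id}: window ({w} aa) longer than alignment ({length} aa)"
        )
        return []

    col_score: list[float] = []
    col_ok: list[bool] = []
    for j in range(length):
        col = [r[j] for r in rows]
        residues = [c for c in col if c != GAP]
        gap_frac = 1.0 - len(residues) / n
        col_ok.append(gap_frac <= params.max_gap_fraction)
        if residues:
            modal = Counter(residues).most_common(1)[0][1]
            col_score.append(modal / len(residues))
        else:
            col_score.append(0.0)

    out = []
    for s in range(length - w + 1):
        score = sum(col_score[s : s + w]) / w
        eligible = all(col_ok[s : s + w])
        out.append((s, score, eligible))
    return out


def excise_targets(
    og: OrthogroupAlignment,
    scores: list[tuple[int, float, bool]],
    params: DesignParams | None = None,
) -> list[TargetRegion]:
    """Merge passing windows and excise the matching nucleotide regions.

    Windows with score >= ``conservation_threshold`` and an eligible gap
    profile are merged when they overlap or touch; merged AA intervals are
    converted to NT intervals (x3) and regions shorter than
    ``min_target_len_nt`` are dropped.
    """
    params = params or DesignParams()
    w = params.window_len_aa
    passing = [
        (s, s + w) for s, score, ok in scores if ok and score >= params.conservation_threshold
    ]
    merged: list[list[int]] = []
    for start, end in sorted(passing):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])

    regions: list[TargetRegion] = []
    for a, b in merged:
        nt_span = (3 * a, 3 * b)
        if nt_span[1] - nt_span[0] < params.min_target_len_nt:
            continue
        seqs = {
            t: og.nt_rows[t][nt_span[0] : nt_span[1]].replace(GAP, "")
            for t in og.taxa
        }
        regions.append(
            TargetRegion(og.ortholog_id, (a, b), nt_span, seqs)
        )
    return regions


def select_targets(
    regions: list[TargetRegion], params: DesignParams | None = None
) -> list[TargetRegion]:
    """Keep regions represented in at least ``min_ref_taxa`` reference taxa.

    A taxon represents a region when its non-gap fraction within the region
    is at least ``representation_min_nongap``.
    """
    params = params or DesignParams()
    kept = []
    for region in regions:
        span_len = region.length_nt
        represented = [
            t
            for t, seq in region.sequences.items()
            if span_len > 0 and len(seq) / span_len >= params.representation_min_nongap
        ]
        if len(represented) >= params.min_ref_taxa:
            region.represented_taxa = sorted(represented)
            kept.append(region)
    return kept


def tile_baits(region: TargetRegion, params: DesignParams | None = None) -> BaitSet:
    """Tile fixed-length baits across each represented taxon's sequence.

    Baits of ``bait_len`` are placed at starts 0, step, 2*step, ... with
    step = round(bait_len / tiling_factor); if the last regular bait does
    not reach the sequence end, one extra right-aligned bait is added.
    Duplicate bait sequences across taxa are emitted once.
    """
    params = params or DesignParams()
    blen = params.bait_len
    step = round(blen / params.tiling_factor)
    baits: list[tuple[str, int, str]] = []
    seen: set[str] = set()
    taxa = region.represented_taxa or sorted(region.sequences)
    for taxon in taxa:
        seq = region.sequences[taxon]
        L = len(seq)
        if L < blen:
            warnings.warn(
                f"{region.region_id}/{taxon}: sequence ({L} nt) shorter than "
                f"bait length ({blen} nt); skipped"
            )
            continue
        starts = list(range(0, L - blen + 1, step))
        if starts[-1] + blen < L:
            starts.append(L - blen)
        for s in starts:
            bait = seq[s : s + blen]
            if bait not in seen:
                seen.add(bait)
                baits.append((taxon, s, bait))
    return BaitSet(region, baits, step)


def design_targets(
    og: OrthogroupAlignment, params: DesignParams | None = None
) -> tuple[list[TargetRegion], list[BaitSet]]:
    """Full design pipeline for one orthogroup: score, excise, select, tile."""
    params = params or DesignParams()
    scores = score_conservation(og, params)
    regions = select_targets(excise_targets(og, scores, params), params)
    return regions, [tile_baits(r, params) for r in regions]
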