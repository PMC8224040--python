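"""Completeness-filtered supermatrix construction with exact bookkeeping.

Per-locus alignments that survived QC are filtered by taxon completeness
(a locus is kept when at least ``ceil(fraction x n_taxa)`` taxa are
present), concatenated in lexicographic locus order — probe blocks first,
then all flank blocks — and partitioned by codon position per gene, with
all flank columns pooled into one ``flanks`` partition.  Utilities prune
tiny partitions (which break partitioned tree searches), strip third codon
positions from probe blocks, and translate probe blocks to amino acids.

Internally columns are 0-based half-open; exported partition files use the
conventional 1-based inclusive ranges with ``\\3`` codon strides.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

from .locus_qc import GAP, SplitLocus, translate_codon

__all__ = [
    "MatrixParams",
    "Partition",
    "SupermatrixBundle",
    "filter_by_completeness",
    "concatenate",
    "define_partitions",
    "drop_small_partitions",
    "strip_third_positions",
    "translate_matrix",
    "write_phylip",
    "write_fasta_matrix",
    "write_partition_file",
    "read_phylip",
    "read_partition_file",
]

MISSING = "?"


@dataclass
class MatrixParams:
    completeness_fraction: float = 0.50
    include_flanks: bool = False
    min_partition_len: int = 80
    missing_symbol: str = MISSING

    def __post_init__(self) -> None:
        if not 0 < self.completeness_fraction <= 1:
            raise ValueError("completeness_fraction must be in (0, 1]")


@dataclass(frozen=True)
class Partition:
    """A named set of matrix columns, stored as 1-based inclusive
    (start, end, stride) pieces (stride 3 = every third column)."""

    name: str
    pieces: tuple[tuple[int, int, int], ...]

    def columns(self) -> list[int]:
        cols: list[int] = []
        for start, end, stride in self.pieces:
            cols.extend(range(start, end + 1, stride))
        return cols

    def __len__(self) -> int:
        return len(self.columns())

    def to_raxml(self, datatype: str = "DNA") -> str:
        parts = []
        for start, end, stride in self.pieces:
            parts.append(f"{start}-{end}\\{stride}" if stride != 1 else f"{start}-{end}")
        return f"{datatype}, {self.name} = {', '.join(parts)}"


@dataclass
class SupermatrixBundle:
    taxa: list[str]
    rows: dict[str, str]
    # locus id -> (start, end, kind) with kind in {probe, flank}; 0-based half-open
    coordinates: dict[str, tuple[int, int, str]] = field(default_factory=dict)
    partitions: list[Partition] = field(default_factory=list)
    third_stripped: bool = False
    datatype: str = "DNA"

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def validate(self) -> None:
        w = self.width
        for t in self.taxa:
            if len(self.rows[t]) != w:
                raise ValueError(f"ragged supermatrix row {t}")
        spans = sorted((s, e) for s, e, _ in self.coordinates.values())
        pos = 0
        for s, e in spans:
            if s != pos:
                raise ValueError("coordinate map does not tile the matrix")
            pos = e
        if spans and pos != w:
            raise ValueError("coordinate map does not tile the matrix")


def n_taxa_required(fraction: float, universe_size: int) -> int:
    """'At least *fraction* of taxa present', rounded up at fractions."""
    return math.ceil(fraction * universe_size)


def filter_by_completeness(
    loci: list[SplitLocus], taxa_universe: list[str], params: MatrixParams | None = None
) -> list[SplitLocus]:
    params = params or MatrixParams()
    if not taxa_universe:
        raise ValueError("taxa universe is empty")
    need = n_taxa_required(params.completeness_fraction, len(taxa_universe))
    return [loc for loc in loci if len(set(loc.taxa) & set(taxa_universe)) >= need]


def concatenate(
    loci: list[SplitLocus], taxa_universe: list[str], params: MatrixParams | None = None
) -> SupermatrixBundle:
    """Concatenate loci (lexicographic id order), probe blocks first and —
    when ``include_flanks`` — all flank blocks after them; absent taxa are
    filled with the missing symbol."""
    params = params or MatrixParams()
    taxa = sorted(taxa_universe)
    loci = sorted(loci, key=lambda loc: loc.locus_id)
    pieces: dict[str, list[str]] = {t: [] for t in taxa}
    coords: dict[str, tuple[int, int, str]] = {}
    pos = 0

    def add_block(block_id: str, rows: dict[str, str], width: int, kind: str) -> None:
        nonlocal pos
        if width == 0:
            return
        for t in taxa:
            pieces[t].append(rows.get(t, params.missing_symbol * width))
        coords[block_id] = (pos, pos + width, kind)
        pos += width

    for loc in loci:
        add_block(loc.locus_id, loc.probe_region.rows, loc.probe_region.length, "probe")
    if params.include_flanks:
        for loc in loci:
            add_block(
                loc.locus_id + ".flank_L",
                loc.left_flank.rows,
                loc.left_flank.length,
                "flank",
            )
            add_block(
                loc.locus_id + ".flank_R",
                loc.right_flank.rows,
                loc.right_flank.length,
                "flank",
            )
    rows = {t: "".join(pieces[t]) for t in taxa}
    bundle = SupermatrixBundle(taxa, rows, coords)
    bundle.validate()
    return bundle


def define_partitions(bundle: SupermatrixBundle) -> list[Partition]:
    """Three codon-position partitions per probe locus plus one ``flanks``
    partition pooling every flank column."""
    parts: list[Partition] = []
    flank_pieces: list[tuple[int, int, int]] = []
    for block_id in sorted(bundle.coordinates):
        start, end, kind = bundle.coordinates[block_id]
        if kind == "probe":
            if (end - start) % 3:
                raise ValueError(f"probe block {block_id} length not divisible by 3")
            for k in range(3):
                parts.append(
                    Partition(f"{block_id}_pos{k + 1}", ((start + k + 1, end, 3),))
                )
        else:
            flank_pieces.append((start + 1, end, 1))
    if flank_pieces:
        parts.append(Partition("flanks", tuple(sorted(flank_pieces))))
    bundle.partitions = parts
    return parts


def drop_small_partitions(
    partitions: list[Partition], params: MatrixParams | None = None
) -> tuple[list[Partition], list[Partition]]:
    """Remove partitions spanning fewer than ``min_partition_len`` columns;
    returns (kept, removed)."""
    params = params or MatrixParams()
    kept = [p for p in partitions if len(p) >= params.min_partition_len]
    removed = [p for p in partitions if len(p) < params.min_partition_len]
    return kept, removed


def strip_third_positions(bundle: SupermatrixBundle) -> SupermatrixBundle:
    """Delete every third codon position of probe blocks; flanks untouched.

    Partitions are invalidated (codon structure no longer holds) and the
    coordinate map is rebuilt."""
    if bundle.third_stripped:
        return bundle
    keep_cols: list[int] = []
    new_coords: dict[str, tuple[int, int, str]] = {}
    pos = 0
    for block_id in sorted(bundle.coordinates, key=lambda b: bundle.coordinates[b][0]):
        start, end, kind = bundle.coordinates[block_id]
        if kind == "probe":
            cols = [c for c in range(start, end) if (c - start) % 3 != 2]
        else:
            cols = list(range(start, end))
        keep_cols.extend(cols)
        new_coords[block_id] = (pos, pos + len(cols), kind)
        pos += len(cols)
    rows = {t: "".join(r[c] for c in keep_cols) for t, r in bundle.rows.items()}
    out = replace(
        bundle, rows=rows, coordinates=new_coords, partitions=[], third_stripped=True
    )
    out.validate()
    return out


def translate_matrix(bundle: SupermatrixBundle) -> SupermatrixBundle:
    """Translate probe blocks to amino acids; flanks are excluded.

    Codons containing ``N`` translate to ``X``; codons containing an
    alignment gap become ``-``; codons containing the missing symbol
    become ``?``."""
    if bundle.third_stripped:
        raise ValueError("cannot translate after third positions were stripped")
    new_coords: dict[str, tuple[int, int, str]] = {}
    pieces: dict[str, list[str]] = {t: [] for t in bundle.taxa}
    pos = 0
    for block_id in sorted(bundle.coordinates, key=lambda b: bundle.coordinates[b][0]):
        start, end, kind = bundle.coordinates[block_id]
        if kind != "probe":
            continue
        if (end - start) % 3:
            raise ValueError(f"probe block {block_id} width not divisible by 3")
        w_aa = (end - start) // 3
        for t in bundle.taxa:
            seq = bundle.rows[t][start:end]
            aa = []
            for c in range(0, len(seq), 3):
                codon = seq[c : c + 3]
                if MISSING in codon:
                    aa.append(MISSING)
                elif GAP in codon:
                    aa.append(GAP)
                else:
                    aa.append(translate_codon(codon))
            pieces[t].append("".join(aa))
        new_coords[block_id] = (pos, pos + w_aa, "probe")
        pos += w_aa
    rows = {t: "".join(pieces[t]) for t in bundle.taxa}
    out = SupermatrixBundle(list(bundle.taxa), rows, new_coords, datatype="AA")
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Export / import


def write_phylip(bundle: SupermatrixBundle, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(bundle.taxa)} {bundle.width}\n")
        for t in bundle.taxa:
            fh.write(f"{t}  {bundle.rows[t]}\n")


def write_fasta_matrix(bundle: SupermatrixBundle, path: str) -> None:
    with open(path, "w") as fh:
        for t in bundle.taxa:
            fh.write(f">{t}\n{bundle.rows[t]}\n")


def write_partition_file(partitions: list[Partition], path: str, datatype: str = "DNA") -> None:
    with open(path, "w") as fh:
        for p in partitions:
            fh.write(p.to_raxml(datatype) + "\n")


def write_coordinate_map(bundle: SupermatrixBundle, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("block\tstart\tend\tkind\n")
        for block_id in sorted(bundle.coordinates, key=lambda b: bundle.coordinates[b][0]):
            s, e, k = bundle.coordinates[block_id]
            fh.write(f"{block_id}\t{s}\t{e}\t{k}\n")


def read_phylip(path: str) -> tuple[list[str], dict[str, str]]:
    with open(path) as fh:
        header = fh.readline().split()
        n, w = int(header[0]), int(header[1])
        taxa, rows = [], {}
        for line in fh:
            if not line.strip():
                continue
            name, seq = line.split(None, 1)
            seq = seq.strip()
            if len(seq) != w:
                raise ValueError(f"row {name} width {len(seq)} != {w}")
            taxa.append(name)
            rows[name] = seq
    if len(taxa) != n:
        raise ValueError("taxon count mismatch in phylip file")
    return taxa, rows


_PART_RE = re.compile(r"^(\w+),\s*(\S+)\s*=\s*(.+)$")


def read_partition_file(path: str) -> list[Partition]:
    parts: list[Partition] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            m = _PART_RE.match(line)
            if not m:
                raise ValueError(f"malformed partition line: {line!r}")
            pieces = []
            for chunk in m.group(3).split(","):
                chunk = chunk.strip()
                if "\\" in chunk:
                    rng, stride = chunk.split("\\")
                    stride = int(stride)
                else:
                    rng, stride = chunk, 1
                start, end = (int(x) for x in rng.split("-"))
                pieces.append((start, end, stride))
            parts.append(Partition(m.group(2), tuple(pieces)))
    return parts
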