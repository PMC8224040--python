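"""Codon-aware quality control of captured locus alignments.

Captured loci consist of a coding core (the region matched by baits) plus
co-captured, often non-coding, flanking sequence.  This module turns the
usual manual curation of such alignments into deterministic operations:

* :func:`infer_reading_frame` — pick the frame minimising in-frame stop
  codons over the probe-matching core;
* :func:`detect_flanks` — walk outward from the core and cut the probe
  region at the innermost stop codon, out-of-frame gap run, or window of
  poor amino-acid consensus agreement;
* :func:`split_locus` — trim the probe region to start on codon position
  one and carve off the flanks;
* :func:`mask_frameshifts` — convert out-of-frame gap runs and the
  downstream bases they corrupt to ``N``;
* :func:`drop_short_and_outliers` — remove near-empty rows and rows in
  broad disagreement with the amino-acid consensus.

All coordinates are alignment columns, 0-based half-open.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace

from Bio.Data.CodonTable import standard_dna_table

__all__ = [
    "LocusAlignment",
    "QcParams",
    "SplitLocus",
    "UnresolvableFrameError",
    "infer_reading_frame",
    "detect_flanks",
    "split_locus",
    "mask_frameshifts",
    "drop_short_and_outliers",
    "run_qc",
]

GAP = "-"
_CODON_TO_AA = dict(standard_dna_table.forward_table)
_STOPS = set(standard_dna_table.stop_codons)


class UnresolvableFrameError(ValueError):
    """All three frames contain stop codons in every row."""


def translate_codon(codon: str) -> str:
    codon = codon.upper()
    if codon in _STOPS:
        return "*"
    if GAP in codon or "?" in codon:
        return GAP
    if codon in _CODON_TO_AA:
        return _CODON_TO_AA[codon]
    return "X"  # any N / ambiguity


@dataclass
class LocusAlignment:
    locus_id: str
    rows: dict[str, str]
    core: tuple[int, int] | None = None  # probe-matching columns, if known
    reference_aa: str | None = None  # AA profile of the design target

    @property
    def length(self) -> int:
        return len(next(iter(self.rows.values())))

    def validate(self) -> None:
        L = self.length
        for t, r in self.rows.items():
            if len(r) != L:
                raise ValueError(f"{self.locus_id}/{t}: ragged alignment")
        if self.core is not None:
            a, b = self.core
            if not (0 <= a <= b <= L):
                raise ValueError(f"{self.locus_id}: core {self.core} out of bounds")

    def core_span(self) -> tuple[int, int]:
        return self.core if self.core is not None else (0, self.length)


@dataclass
class QcParams:
    min_seq_len: int = 9  # unambiguous bases
    outlier_max_divergence: float = 0.5  # min AA identity to consensus
    flank_consensus_window: int = 10  # amino acids
    flank_consensus_floor: float = 0.5

    def __post_init__(self) -> None:
        if self.min_seq_len < 1:
            raise ValueError("min_seq_len must be >= 1")


@dataclass
class SplitLocus:
    locus_id: str
    probe_region: LocusAlignment
    left_flank: LocusAlignment
    right_flank: LocusAlignment
    frame_offset: int
    masks: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.probe_region.rows)

    def reconstruct_row(self, taxon: str) -> str:
        return (
            self.left_flank.rows.get(taxon, "")
            + self.probe_region.rows[taxon]
            + self.right_flank.rows.get(taxon, "")
        )


def _row_stop_count(row: str, start: int, end: int, offset: int) -> int | None:
    """In-frame stop codons in ungapped row content of columns [start, end).

    Returns None when the row has < 30 unambiguous bases in the span.
    """
    seq = row[start:end].replace(GAP, "").replace("?", "")
    if sum(c in "ACGT" for c in seq) < 30:
        return None
    stops = 0
    for k in range(offset, len(seq) - 2, 3):
        if seq[k : k + 3] in _STOPS:
            stops += 1
    return stops


def infer_reading_frame(locus: LocusAlignment) -> int:
    """Frame offset (0/1/2) minimising in-frame stops over the core.

    The frame is the offset into each row's *ungapped* core sequence where
    codons begin.  Ties prefer agreement with the reference AA profile,
    then the smallest offset.  Raises :class:`UnresolvableFrameError` when
    every usable row has stops in all three frames.
    """
    a, b = locus.core_span()
    totals = [0, 0, 0]
    per_row_clean = [0, 0, 0]  # rows with zero stops in this frame
    usable_rows = 0
    for row in locus.rows.values():
        counts = [_row_stop_count(row, a, b, f) for f in range(3)]
        if all(c is None for c in counts):
            continue
        usable_rows += 1
        for f in range(3):
            if counts[f] is not None:
                totals[f] += counts[f]
                if counts[f] == 0:
                    per_row_clean[f] += 1
    if usable_rows == 0:
        raise ValueError(f"{locus.locus_id}: no row with >= 30 unambiguous bases")
    if all(per_row_clean[f] == 0 for f in range(3)):
        raise UnresolvableFrameError(
            f"{locus.locus_id}: stop codons in every row under all three frames"
        )
    best = min(totals)
    candidates = [f for f in range(3) if totals[f] == best]
    if len(candidates) > 1 and locus.reference_aa:
        agree = [
            _frame_reference_agreement(locus, f) if f in candidates else -1.0
            for f in range(3)
        ]
        top = max(agree[f] for f in candidates)
        candidates = [f for f in candidates if agree[f] == top]
    return candidates[0]


def _frame_reference_agreement(locus: LocusAlignment, frame: int) -> float:
    """Mean identity between row translations and the reference AA profile."""
    ref = locus.reference_aa or ""
    a, b = locus.core_span()
    scores = []
    for row in locus.rows.values():
        seq = row[a:b].replace(GAP, "")
        aa = "".join(
            translate_codon(seq[k : k + 3]) for k in range(frame, len(seq) - 2, 3)
        )
        n = min(len(aa), len(ref))
        if n:
            scores.append(sum(aa[i] == ref[i] for i in range(n)) / n)
    return sum(scores) / len(scores) if scores else 0.0


def _column_consensus_aa(locus: LocusAlignment, col_codons: list[tuple[int, int, int]]):
    """Per-codon-column consensus AA (modal over non-gap rows, ties alphabetical)."""
    cons = []
    for c0, c1, c2 in col_codons:
        aas = []
        for row in locus.rows.values():
            codon = row[c0] + row[c1] + row[c2]
            aa = translate_codon(codon)
            if aa != GAP:
                aas.append(aa)
        if aas:
            counts = Counter(aas)
            top = max(counts.values())
            cons.append(min(a for a, c in counts.items() if c == top))
        else:
            cons.append(GAP)
    return cons


def _gap_runs(row: str, start: int, end: int) -> list[tuple[int, int]]:
    runs = []
    i = start
    while i < end:
        if row[i] == GAP:
            j = i
            while j < end and row[j] == GAP:
                j += 1
            runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


def detect_flanks(
    locus: LocusAlignment, frame: int, params: QcParams | None = None
) -> tuple[int, int]:
    """Boundary columns (left, right) of the coding probe region.

    Scanning codon-by-codon outward from the probe-matching core, a
    boundary is set at the innermost position where any row shows an
    in-frame stop codon, where a gap run of length not divisible by 3
    occurs, or where a ``flank_consensus_window`` of codon columns falls
    below ``flank_consensus_floor`` mean agreement with the column
    consensus.  The triggering feature is left in the flank.
    """
    params = params or QcParams()
    locus.validate()
    L = locus.length
    a, b = locus.core_span()
    rows = list(locus.rows.values())

    # Codon columns are laid out from the core start, in the given frame.
    first_codon_col = a + frame
    # Columns [first_codon_col, ...) group into codons of 3 alignment columns.
    # (QC operates on near-gap-free cores; codon == 3 adjacent columns here,
    # with per-row gap runs handled by the mod-3 rule and downstream masking.)

    def codon_cols(idx: int) -> tuple[int, int, int]:
        c = first_codon_col + 3 * idx
        return (c, c + 1, c + 2)

    n_right = (L - first_codon_col) // 3  # codons available to the right
    n_left = first_codon_col // 3  # codons available to the left (idx -1, -2, ...)

    def codon_triggers(idx: int) -> bool:
        c0, c1, c2 = codon_cols(idx)
        for row in rows:
            codon = row[c0] + row[c1] + row[c2]
            if codon in _STOPS:
                return True
        return False

    bad_runs = [
        (s, e)
        for row in rows
        for s, e in _gap_runs(row, 0, L)
        if (e - s) % 3 != 0
    ]

    def bad_gap_run_in(idx: int) -> bool:
        c0, _, c2 = codon_cols(idx)
        return any(s <= c2 and e > c0 for s, e in bad_runs)

    core_start_idx = 0
    core_end_idx = (b - first_codon_col) // 3  # codons fully inside core

    # Precompute per-codon consensus agreement for the window criterion.
    all_idx = range(-n_left, n_right)
    cols = [codon_cols(i) for i in all_idx]
    cons = _column_consensus_aa(locus, cols)
    agree = []
    for (c0, c1, c2), cons_aa in zip(cols, cons):
        vals = []
        for row in rows:
            aa = translate_codon(row[c0] + row[c1] + row[c2])
            if aa != GAP:
                vals.append(1.0 if aa == cons_aa else 0.0)
        agree.append(sum(vals) / len(vals) if vals else 0.0)

    def window_bad(idx: int, direction: int) -> bool:
        """Mean consensus agreement of the window of codons starting at idx
        going outward; bad when < floor."""
        w = params.flank_consensus_window
        pos = idx + n_left  # into `agree`
        if direction > 0:
            chunk = agree[pos : pos + w]
        else:
            chunk = agree[max(0, pos - w + 1) : pos + 1]
        if len(chunk) < w:
            return False
        return sum(chunk) / len(chunk) < params.flank_consensus_floor

    # Scan right from the core end.
    right_boundary = L
    idx = core_end_idx
    while idx < n_right:
        if codon_triggers(idx) or bad_gap_run_in(idx) or window_bad(idx, +1):
            right_boundary = codon_cols(idx)[0]
            break
        idx += 1
    else:
        right_boundary = first_codon_col + 3 * n_right if n_right else first_codon_col
        if L - right_boundary < 3:
            right_boundary = L  # trailing partial codon stays in the probe span

    # Scan left from the core start.
    left_boundary = 0
    idx = core_start_idx - 1
    while idx >= -n_left:
        if codon_triggers(idx) or bad_gap_run_in(idx) or window_bad(idx, -1):
            left_boundary = codon_cols(idx)[2] + 1
            break
        idx -= 1
    else:
        left_boundary = first_codon_col - 3 * n_left
        if left_boundary < 3:
            left_boundary = 0

    return left_boundary, right_boundary


def split_locus(
    locus: LocusAlignment, frame: int, boundaries: tuple[int, int]
) -> SplitLocus:
    """Cut the alignment into left flank / codon-aligned probe region /
    right flank.  The probe region starts on codon position one; 1-2
    leading columns are reassigned to the left flank when the frame
    requires it, and a trailing partial codon moves to the right flank."""
    left, right = boundaries
    a, _ = locus.core_span()
    first_codon_col = a + frame
    # Advance left edge to the first codon start at or after `left`.
    shift = (left - first_codon_col) % 3
    probe_start = left + (3 - shift) % 3
    probe_len = ((right - probe_start) // 3) * 3
    probe_end = probe_start + probe_len
    if probe_len < 3:
        warnings.warn(f"{locus.locus_id}: probe region shorter than one codon; dropped")
        raise ValueError(f"{locus.locus_id}: empty probe region after trimming")

    def sub(a0: int, b0: int) -> dict[str, str]:
        return {t: r[a0:b0] for t, r in locus.rows.items()}

    return SplitLocus(
        locus_id=locus.locus_id,
        probe_region=LocusAlignment(
            locus.locus_id, sub(probe_start, probe_end), reference_aa=locus.reference_aa
        ),
        left_flank=LocusAlignment(locus.locus_id + ".flank_L", sub(0, probe_start)),
        right_flank=LocusAlignment(locus.locus_id + ".flank_R", sub(probe_end, locus.length)),
        frame_offset=frame,
    )


def mask_frameshifts(split: SplitLocus) -> SplitLocus:
    """Mask out-of-frame gap runs and the bases they throw out of frame.

    Within each probe-region row, scanning left to right while tracking the
    cumulative gap-length modulo 3: when a gap run leaves the row out of
    frame, everything from that run to the next compensating run (which
    restores frame, inclusive) — or to the region end — becomes ``N``.
    """
    probe = split.probe_region
    L = probe.length
    new_rows = {}
    masks: dict[str, list[tuple[int, int]]] = {}
    for taxon, row in probe.rows.items():
        runs = _gap_runs(row, 0, L)
        shift = 0
        mask_start: int | None = None
        intervals: list[tuple[int, int]] = []
        for s, e in runs:
            prev_shift = shift
            shift = (shift + (e - s)) % 3
            if prev_shift == 0 and shift != 0:
                mask_start = s
            elif prev_shift != 0 and shift == 0 and mask_start is not None:
                intervals.append((mask_start, e))
                mask_start = None
        if mask_start is not None:
            intervals.append((mask_start, L))
        if intervals:
            chars = list(row)
            for s, e in intervals:
                for k in range(s, e):
                    chars[k] = "N"
            new_rows[taxon] = "".join(chars)
            masks[taxon] = intervals
        else:
            new_rows[taxon] = row
    new_probe = LocusAlignment(probe.locus_id, new_rows, reference_aa=probe.reference_aa)
    return replace(split, probe_region=new_probe, masks=masks)


def _consensus_identity(probe: LocusAlignment, taxon: str) -> float | None:
    """AA identity of one row's translation to the column-wise consensus of
    the *other* rows; None when nothing comparable."""
    L = probe.length
    others = {t: r for t, r in probe.rows.items() if t != taxon}
    if not others:
        return None
    row = probe.rows[taxon]
    same = total = 0
    for c in range(0, L - 2, 3):
        aa = translate_codon(row[c : c + 3])
        if aa in (GAP, "X"):
            continue
        aas = [translate_codon(r[c : c + 3]) for r in others.values()]
        aas = [a for a in aas if a not in (GAP, "X")]
        if not aas:
            continue
        counts = Counter(aas)
        top = max(counts.values())
        cons = min(a for a, n in counts.items() if n == top)
        total += 1
        if aa == cons:
            same += 1
    if total == 0:
        return None
    return same / total


def drop_short_and_outliers(
    split: SplitLocus, params: QcParams | None = None
) -> tuple[SplitLocus, list[tuple[str, str]]]:
    """Remove rows with < ``min_seq_len`` unambiguous bases and rows whose
    probe-region translation disagrees broadly with the AA consensus.

    Returns the filtered locus and a removal report of (taxon, reason).
    """
    params = params or QcParams()
    report: list[tuple[str, str]] = []
    drop: set[str] = set()
    for taxon in split.probe_region.rows:
        full = split.reconstruct_row(taxon)
        n_unamb = sum(c in "ACGT" for c in full.upper())
        if n_unamb < params.min_seq_len:
            drop.add(taxon)
            report.append((taxon, "short"))
    for taxon in split.probe_region.rows:
        if taxon in drop:
            continue
        ident = _consensus_identity(split.probe_region, taxon)
        if ident is not None and ident < params.outlier_max_divergence:
            drop.add(taxon)
            report.append((taxon, "outlier"))

    def strip(al: LocusAlignment) -> LocusAlignment:
        return LocusAlignment(
            al.locus_id,
            {t: r for t, r in al.rows.items() if t not in drop},
            core=al.core,
            reference_aa=al.reference_aa,
        )

    out = SplitLocus(
        split.locus_id,
        strip(split.probe_region),
        strip(split.left_flank),
        strip(split.right_flank),
        split.frame_offset,
        {t: m for t, m in split.masks.items() if t not in drop},
    )
    return out, report


def estimate_core(locus: LocusAlignment, frame: int) -> tuple[int, int]:
    """Estimate the probe-matching core as the longest run of clean codons.

    A codon column (in the given frame over the whole alignment) is clean
    when no row shows a stop codon there and no out-of-frame gap run
    overlaps it.  Used when capture provenance (the true core) is absent;
    the returned span is codon-aligned, so the frame relative to it is 0.
    """
    L = locus.length
    rows = list(locus.rows.values())
    n_codons = (L - frame) // 3
    if n_codons == 0:
        raise ValueError(f"{locus.locus_id}: alignment shorter than one codon")
    bad_runs = [
        (s, e)
        for row in rows
        for s, e in _gap_runs(row, 0, L)
        if (e - s) % 3 != 0
    ]
    good = []
    for i in range(n_codons):
        c0 = frame + 3 * i
        ok = all(row[c0 : c0 + 3] not in _STOPS for row in rows)
        ok = ok and not any(s < c0 + 3 and e > c0 for s, e in bad_runs)
        good.append(ok)
    # longest run of clean codons
    best_len = best_start = cur_len = cur_start = 0
    for i, ok in enumerate(good + [False]):
        if ok:
            if cur_len == 0:
                cur_start = i
            cur_len += 1
            if cur_len > best_len:
                best_len, best_start = cur_len, cur_start
        else:
            cur_len = 0
    if best_len == 0:
        raise UnresolvableFrameError(f"{locus.locus_id}: no clean codon run")
    return (frame + 3 * best_start, frame + 3 * (best_start + best_len))


def run_qc(
    locus: LocusAlignment, params: QcParams | None = None
) -> tuple[SplitLocus, list[tuple[str, str]]]:
    """Full QC pipeline: frame -> flanks -> split -> mask -> drop.

    When the locus has no capture-derived core span, one is estimated as
    the longest clean codon run in the inferred frame.
    """
    params = params or QcParams()
    frame = infer_reading_frame(locus)
    if locus.core is None:
        core = estimate_core(locus, frame)
        locus = LocusAlignment(
            locus.locus_id, locus.rows, core=core, reference_aa=locus.reference_aa
        )
        frame = 0  # core is codon-aligned by construction
    boundaries = detect_flanks(locus, frame, params)
    split = split_locus(locus, frame, boundaries)
    split = mask_frameshifts(split)
    return drop_short_and_outliers(split, params)
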