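"""Match assembled contigs to bait targets and apply ambiguity filters.

Contigs from each assembler are matched to target loci with a self-contained
seed–chain–extend local aligner (shared k-mer seeds, collinear chaining,
banded affine Smith–Waterman around the chain).  Hits must clear minimum
identity and target-coverage thresholds (defaults 80% / 82%).  Two filters
then remove ambiguous matches, in this order:

1. contigs with passing hits to two or more distinct targets are discarded
   (possible chimeras / repetitive sequence);
2. targets hit by two or more distinct surviving contigs are discarded
   (possible paralogs).

The survivors form a one-to-one contig/target table.  When several
assemblers were run on the same sample, :func:`reconcile_assemblies` keeps
the longest accepted contig per target (ties broken by assembler name).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CaptureParams",
    "Hit",
    "MatchTable",
    "align_local",
    "match_contigs",
    "reconcile_assemblies",
    "recovery_summary",
]


@dataclass
class CaptureParams:
    min_identity: float = 0.80
    min_coverage: float = 0.82
    seed_len: int = 15
    match_score: int = 1
    mismatch_score: int = -1
    gap_open: int = -2  # score of the first gapped column
    gap_extend: int = -1
    band_pad: int = 24

    def __post_init__(self) -> None:
        if not (0 < self.min_identity <= 1 and 0 < self.min_coverage <= 1):
            raise ValueError("identity/coverage thresholds must be in (0, 1]")


@dataclass
class Hit:
    contig_id: str
    target_id: str
    identity: float
    coverage: float
    contig_span: tuple[int, int]
    target_span: tuple[int, int]
    score: int
    contig_len: int = 0


@dataclass
class MatchTable:
    accepted: dict[str, Hit] = field(default_factory=dict)  # target -> Hit
    rejected_contigs: list[tuple[str, str]] = field(default_factory=list)
    rejected_targets: list[tuple[str, str]] = field(default_factory=list)
    unmatched_targets: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for tid, hit in sorted(self.accepted.items()):
            rows.append(
                dict(target=tid, status="accepted", contig=hit.contig_id,
                     identity=round(hit.identity, 4), coverage=round(hit.coverage, 4))
            )
        for tid, reason in self.rejected_targets:
            rows.append(dict(target=tid, status=reason, contig="", identity="", coverage=""))
        for tid in self.unmatched_targets:
            rows.append(dict(target=tid, status="unmatched", contig="", identity="", coverage=""))
        return pd.DataFrame(rows, columns=["target", "status", "contig", "identity", "coverage"])


def _seed_positions(query: str, subject: str, k: int) -> list[tuple[int, int]]:
    index: dict[str, list[int]] = {}
    for j in range(len(subject) - k + 1):
        index.setdefault(subject[j : j + k], []).append(j)
    seeds = []
    for i in range(len(query) - k + 1):
        for j in index.get(query[i : i + k], ()):
            seeds.append((i, j))
    return seeds


def _chain_seeds(seeds: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Greedy collinear chain: longest run of seeds increasing in both axes."""
    seeds = sorted(seeds)
    best_chain: list[tuple[int, int]] = []
    # Patience-style LIS on the subject coordinate.
    import bisect

    tails: list[int] = []
    links: list[int] = []
    prev: list[int] = []
    for idx, (_, j) in enumerate(seeds):
        pos = bisect.bisect_left(tails, j)
        if pos == len(tails):
            tails.append(j)
            links.append(idx)
        else:
            tails[pos] = j
            links[pos] = idx
        prev.append(links[pos - 1] if pos > 0 else -1)
    if not seeds:
        return []
    idx = links[len(tails) - 1]
    while idx != -1:
        best_chain.append(seeds[idx])
        idx = prev[idx]
    best_chain.reverse()
    return best_chain


def align_local(query: str, subject: str, params: CaptureParams | None = None) -> Hit | None:
    """Seed–chain–extend local alignment of *query* against *subject*.

    Returns ``None`` when the sequences share no ``seed_len``-mer.  Identity
    is matches over aligned columns (gap columns included); coverage is the
    aligned fraction of the subject.
    """
    params = params or CaptureParams()
    if not query or not subject:
        raise ValueError("empty sequence")
    query = query.upper()
    subject = subject.upper()
    seeds = _seed_positions(query, subject, params.seed_len)
    if not seeds:
        return None
    chain = _chain_seeds(seeds)
    diags = [j - i for i, j in chain]
    dlo = min(diags) - params.band_pad
    dhi = max(diags) + params.band_pad

    m, n = len(query), len(subject)
    NEG = -(10**9)
    S = np.full((m + 1, n + 1), 0, dtype=np.int64)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int64)
    ptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 0 stop, 1 diag, 2 from E, 3 from F
    eptr = np.zeros((m + 1, n + 1), dtype=np.int8)  # 1 open, 0 extend
    fptr = np.zeros((m + 1, n + 1), dtype=np.int8)

    go, ge = params.gap_open, params.gap_extend
    best, bi, bj = 0, 0, 0
    for i in range(1, m + 1):
        jlo = max(1, i + dlo)
        jhi = min(n, i + dhi)
        qi = query[i - 1]
        for j in range(jlo, jhi + 1):
            e_open = S[i, j - 1] + go
            e_ext = E[i, j - 1] + ge
            if e_open >= e_ext:
                E[i, j], eptr[i, j] = e_open, 1
            else:
                E[i, j], eptr[i, j] = e_ext, 0
            f_open = S[i - 1, j] + go
            f_ext = F[i - 1, j] + ge
            if f_open >= f_ext:
                F[i, j], fptr[i, j] = f_open, 1
            else:
                F[i, j], fptr[i, j] = f_ext, 0
            sub = params.match_score if qi == subject[j - 1] else params.mismatch_score
            diag = S[i - 1, j - 1] + sub
            val, p = 0, 0
            if diag > val:
                val, p = diag, 1
            if E[i, j] > val:
                val, p = E[i, j], 2
            if F[i, j] > val:
                val, p = F[i, j], 3
            S[i, j], ptr[i, j] = val, p
            if val > best:
                best, bi, bj = val, i, j
    if best <= 0:
        return None

    # Traceback.
    i, j = bi, bj
    matches = columns = 0
    state = "S"
    while True:
        if state == "S":
            p = ptr[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if query[i - 1] == subject[j - 1]:
                    matches += 1
                i, j = i - 1, j - 1
            elif p == 2:
                state = "E"
            else:
                state = "F"
        elif state == "E":
            columns += 1
            opened = eptr[i, j]
            j -= 1
            if opened:
                state = "S"
        else:
            columns += 1
            opened = fptr[i, j]
            i -= 1
            if opened:
                state = "S"
    qspan = (i, bi)
    sspan = (j, bj)
    identity = matches / columns if columns else 0.0
    coverage = (sspan[1] - sspan[0]) / n
    return Hit("", "", identity, coverage, qspan, sspan, int(best), contig_len=m)


def match_contigs(
    contigs: dict[str, str],
    targets: dict[str, str],
    params: CaptureParams | None = None,
) -> MatchTable:
    """All-vs-all matching with identity/coverage thresholds and both
    ambiguity filters (multi-target contigs first, then multi-contig
    targets)."""
    params = params or CaptureParams()
    # duplicate ids within a FASTA are rejected at parse time (see _io)

    passing: list[Hit] = []
    for cid, cseq in contigs.items():
        for tid, tseq in targets.items():
            hit = align_local(cseq, tseq, params)
            if hit is None:
                continue
            if hit.identity >= params.min_identity and hit.coverage >= params.min_coverage:
                hit.contig_id, hit.target_id = cid, tid
                passing.append(hit)

    table = MatchTable()
    by_contig: dict[str, set[str]] = {}
    for h in passing:
        by_contig.setdefault(h.contig_id, set()).add(h.target_id)
    multi_target = {c for c, ts in by_contig.items() if len(ts) >= 2}
    table.rejected_contigs = sorted((c, "multi_target") for c in multi_target)

    surviving = [h for h in passing if h.contig_id not in multi_target]
    by_target: dict[str, set[str]] = {}
    for h in surviving:
        by_target.setdefault(h.target_id, set()).add(h.contig_id)
    multi_contig = {t for t, cs in by_target.items() if len(cs) >= 2}
    table.rejected_targets = sorted((t, "multi_contig") for t in multi_contig)

    for h in surviving:
        if h.target_id in multi_contig:
            continue
        prev = table.accepted.get(h.target_id)
        if prev is None or h.score > prev.score:
            table.accepted[h.target_id] = h

    covered = set(table.accepted) | multi_contig
    table.unmatched_targets = sorted(t for t in targets if t not in covered)
    return table


def reconcile_assemblies(
    per_assembler: dict[str, MatchTable],
) -> dict[str, tuple[str, str, int]]:
    """Retain the longest accepted contig per target across assemblers.

    Ties are broken by the lexicographically smallest assembler name.
    Returns target id -> (assembler, contig id, contig length).
    """
    if not per_assembler:
        raise ValueError("need at least one assembler")
    out: dict[str, tuple[str, str, int]] = {}
    for assembler in sorted(per_assembler):
        for tid, hit in per_assembler[assembler].accepted.items():
            cur = out.get(tid)
            if cur is None or hit.contig_len > cur[2]:
                out[tid] = (assembler, hit.contig_id, hit.contig_len)
    return out


def recovery_summary(
    reconciled: dict[str, dict[str, tuple[str, str, int]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample recovery table and per-locus taxon counts.

    *reconciled* maps sample id -> (target id -> (assembler, contig, length)).
    """
    sample_rows = []
    locus_counts: dict[str, int] = {}
    for sample in sorted(reconciled):
        loci = reconciled[sample]
        lengths = [v[2] for v in loci.values()]
        sample_rows.append(
            dict(
                sample=sample,
                n_loci=len(loci),
                mean_length=float(np.mean(lengths)) if lengths else 0.0,
            )
        )
        for tid in loci:
            locus_counts[tid] = locus_counts.get(tid, 0) + 1
    per_sample = pd.DataFrame(sample_rows, columns=["sample", "n_loci", "mean_length"])
    per_locus = pd.DataFrame(
        sorted(locus_counts.items()), columns=["target", "n_samples"]
    )
    return per_sample, per_locus
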