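# Methods notes

This note records the models and procedures anchorkit implements, the
parameter choices that matter, what the synthetic-data generators do and
do not emulate, and the places where the design was genuinely open.

## Bait target design

Orthogroup inputs are a paired amino-acid alignment and the unaligned
coding sequences of the same taxa. Threading (Tranalign semantics) maps
each residue to its codon and each alignment gap to `---`; a single
terminal stop codon is stripped, while internal stops or residue/codon
disagreements are hard errors — a disagreement means the CDS and the AA
row are out of sync and no downstream coordinate can be trusted.

Conservation is scored on the amino-acid alignment with a sliding window
(default 20 AA): the score of a window is the mean, over its columns, of
the frequency of the modal residue among non-gap rows. This statistic is
order-invariant, insensitive to residue identity (any bijective relabeling
gives the same score) and cheap to recompute exhaustively, which makes it
easy to verify against a brute-force oracle. Windows containing any column
with more than 20% gaps are ineligible, because a bait needs contiguous
sequence in most taxa. Windows scoring at least 0.7 are merged when they
overlap or touch; merged spans are multiplied by three, spans shorter than
120 nt (= longer than a bait with margin) are dropped. A taxon "represents"
a region when its non-gap fraction there is ≥ 0.9, and a region is kept
when at least 5 reference taxa represent it. All of window length,
threshold, gap tolerance and the representation floor are configurable;
the defaults are the package's own operating point, chosen so that a
60-AA block at ~96% within-block identity passes comfortably while
fast-evolving spacers at ~5–30% identity never do.

Tiling uses step = round(bait_len / tiling_factor) (87 nt for 100-nt baits
at 1.15X). Baits are placed per represented taxon at 0, 87, 174, … while
they fit; if the last regular bait does not reach the sequence end, one
extra right-aligned bait is added, so every position of every tiled
sequence is covered. Duplicate bait sequences across taxa are emitted
once. Whether a vendor would tile per-taxon or on a consensus is not
observable from the outside; per-taxon tiling plus deduplication was
chosen because it never loses taxon-specific variants and reduces to
consensus tiling when taxa agree.

## Capture evaluation

The matcher is a self-contained seed–chain–extend local aligner: shared
15-mers are chained (longest collinear subset via patience LIS), and a
banded affine Smith–Waterman (band = chain diagonals ± 24) is run around
the chain. Scoring is +1 match, −1 mismatch, −2 first gap column, −1 each
further gap column. Identity is matches over aligned columns (gap columns
included); coverage is the aligned fraction of the *target* — the target
is the known quantity, so "how much of the target did we recover" is the
meaningful ratio. A pair sharing no 15-mer is reported as no hit without
running the DP. The test suite holds this aligner against an independent
full Smith–Waterman (Biopython's PairwiseAligner with identical scoring):
scores must agree exactly; identity/coverage are compared with a small
tolerance because co-optimal local alignments can differ in traceback.

Filter semantics: a hit passes at identity ≥ 0.80 and coverage ≥ 0.82.
"Matching multiple targets" means passing hits to ≥ 2 *distinct* target
ids (secondary hits to the same target never trigger a filter). The
chimera filter (contigs) runs before the paralog filter (targets), so a
target hit by one good contig and one chimera survives. Reconciliation
across assemblers keeps the longest accepted contig per target, ties
broken by lexicographically smallest assembler name for determinism.

## Locus QC

The reading frame (offset 0/1/2 of the first codon start) minimises
in-frame stop codons summed over rows within the probe-matched core; rows
with fewer than 30 unambiguous bases are ignored as uninformative. Ties
prefer agreement with the design target's AA profile, then the smallest
offset. When every usable row has stops in all three frames the locus is
flagged unresolvable and routed to a manual list rather than guessed at.

Flank boundaries are found by scanning codon-wise outward from the core;
the boundary is placed so that the innermost triggering feature — a stop
codon in any row, a gap run of length mod 3 ≠ 0, or a 10-codon window with
mean consensus agreement below 0.5 — falls in the flank. Placing the
trigger inside the flank (not the probe) is what guarantees the post-QC
invariant that every unmasked probe-region row translates stop-free.
When capture provenance (the true probe-matched span) is unavailable, a
core is estimated as the longest run of codons that is stop-free and
unbroken by out-of-frame gap runs across all rows; this is the one place
where a mid-probe frameshift is indistinguishable from a flank boundary,
a documented limitation of provenance-free input.

Frameshift masking tracks the cumulative gap length mod 3 along each
probe-region row: from the gap run that breaks frame, through the next
compensating run (inclusive) or to the region end, all symbols become `N`.
Dimensions never change; the non-N symbol count never increases. Row
removal applies the < 9 unambiguous-bases rule (counted as bases, not
alignment columns) and drops rows whose translated probe region agrees
with the column-consensus AA (modal residue, ties alphabetical) at less
than 0.5 identity.

## Supermatrix

Completeness uses ceil: "at least 75% of 30 taxa" means ≥ 23. Loci are
concatenated in lexicographic id order, probe blocks first, then all
flank blocks; missing taxa are filled with `?` (`-` is reserved for
alignment gaps). Partitions are per-gene codon positions as 1-based
stride-3 ranges, with every flank column pooled into a single `flanks`
partition. Partitions under 80 bp are pruned (tiny partitions break
partitioned tree searches). Third-position stripping removes every third
probe column and rebuilds the coordinate map; translation must be taken
*before* stripping and raises afterwards, since stripped blocks no longer
carry codons. In translation, a codon containing `?` gives `?`, containing
a gap gives `-`, containing `N` gives `X`.

## Four-cluster likelihood mapping

Models are JC69 (4 states) and Poisson (20 states): equal frequencies and
equal exchange rates, so the transition probability depends only on
whether two states agree — P(same) = 1/k + (1−1/k)·exp(−kt/(k−1)). This
keeps the per-quartet likelihood analytic and bit-reproducible; richer
models change the absolute likelihoods but rarely the region a quartet
falls in, and the model interface (`SubstitutionModel`) is the extension
point if they are ever needed. Columns with a gap or ambiguity in any of
the four taxa are skipped (complete-case deletion per quartet); usable
columns are compressed to site patterns before pruning.

Each topology's five branch lengths are optimised by cyclic bounded 1-D
search (scipy bounded Brent; init 0.1, bounds [1e-8, 10], up to 100
sweeps, stopping when a sweep improves the log-likelihood by less than
1e-6 relative). Initialisation is deterministic, so results are exactly
reproducible. The test suite bounds the optimum from below with a coarse
5-dimensional grid search.

Weights are the softmax of the three log-likelihoods via logsumexp (shift
invariant, exact at double precision). The seven simplex regions are
operationalised as nearest attractor among the three corners, three edge
midpoints and the centre (Euclidean distance; ties resolve
corner > edge > centre, then lowest index). The original likelihood-mapping
geometry draws slightly different region boundaries; nearest-attractor was
chosen because it is simple, symmetric under topology relabeling, and
identical for the decisive points (corners, midpoints, centre) — region
proportions on well-resolved data are unaffected.

## Tree support

Percent is the canonical internal scale for UFB and SHT; LPP stays a
fraction. The classification (strong: UFB ≥ 95 and SHT ≥ 95, or
LPP ≥ 0.95; moderate: UFB ≥ 95 and SHT ≥ 80, or LPP ≥ 0.85; weak: exactly
one criterion; none otherwise) is monotone in every field. A
`three_class` mapping folds moderate into weak for figure-style
reporting. Note that published support tables sometimes bold values such
as 100/93 as strong even though SHT < 95; the stated rule is implemented
as stated and such rows classify as moderate. Collapse contracts internal
edges with UFB below the threshold (default 10) into polytomies; leaf
edges and the root are never touched, and unannotated internal edges are
an error unless explicitly assumed supported.

## What the generators emulate — and what they do not

* `simulate_orthogroups` evolves an ancestor protein on a star tree with
  per-site uniform replacement (rate 0.02 in 60-AA conserved blocks, 1.0
  in 40-AA spacers, 8 taxa). This controls identity levels — the only
  property the design stage responds to — but is not a continuous-time
  substitution model: no rate heterogeneity, no indels beyond the planted
  gap runs, no codon usage bias. Taxa made "absent" from a block receive
  disjoint contiguous gap runs of 15% of the block, so their non-gap
  fraction drops below the 0.9 representation floor while no column
  exceeds one gap in eight (keeping every window gap-eligible).
* `simulate_contigs` plants full-length mutated copies at an exact
  substitution identity (a 20-nt prefix is left unmutated so a seed always
  exists), chimeras (two targets concatenated), paralogs (a second
  independent copy) and decoys rejection-sampled to share no 15-mer with
  any target. Real assemblies additionally contain fragmented,
  low-coverage and indel-rich contigs that these fixtures do not model.
* `simulate_locus_with_flanks` plants the demarcating feature directly at
  the core edge, so the expected boundary is exactly the core edge; real
  flanks have their innermost stop/gap at some distance, where the
  boundary lands on the innermost trigger instead.
* `simulate_quartet_alignment` is an exact JC69 simulation (uniform root,
  exact transition probabilities) on the 5-branch quartet tree, and
  `simulate_cluster_alignment` extends it with short within-cluster
  branches (0.02) under the assumption — shared with FcLM itself — that
  the four clusters are monophyletic.

Passing tests therefore demonstrate that the implemented rules are applied
exactly and that the likelihood machinery recovers planted topology
signal; they do not demonstrate robustness to alignment error, model
misspecification, contamination beyond the planted kinds, or the
read-level artefacts of real capture data.

## Problem sizes

The standard verification conditions are: 20 orthogroups × 8 taxa for
design; 10 targets with one chimera, one paralog and 20 decoys for
capture; 4 assemblers × 100 loci for reconciliation; 50 loci for QC;
200 loci × 30 taxa for the supermatrix; 2/2/2/2 clusters (16 quartets) at
1000 sites (internal branch 0.2, terminals 0.05) and a 100-site star tree
for FcLM; 20 random 12-leaf trees for collapse. The full suite and the
acceptance script each complete in well under a minute on one CPU.
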