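# anchorkit

Toolkit for anchored-hybrid-enrichment (AHE) phylogenomics: design an
ortholog-targeting bait set from reference orthogroups, evaluate target
capture from assembled contigs, run codon-aware quality control on the
recovered loci, build completeness-filtered supermatrices with codon
partitions, diagnose conflicting phylogenetic signal with four-cluster
likelihood mapping (FcLM), and classify or collapse branch support on the
resulting trees.

It is aimed at systematists running target-capture projects (the driving
case is beetle phylogenomics — Elateroidea and the placement of the
bioluminescent "lampyroid" lineages inside the click beetles), but every
stage is generic: the inputs are plain FASTA/newick/TSV files and every
stage can also be driven as a Python library. All stages are testable
without any sequencing data: the `simdata` module generates inputs with
planted, machine-readable ground truth.

## The pipeline and its core rules

1. **Bait design** (`orthotargets`). Coding sequences are threaded codon by
   codon onto amino-acid orthogroup alignments (each residue becomes its
   codon, each gap `---`). A sliding window (default 20 AA) scores
   conservation as the mean modal-residue frequency per column; windows
   scoring ≥ 0.7 are merged, the matching nucleotide regions are excised
   (≥ 120 nt), and only regions represented in at least 5 of the 8
   reference taxa are kept. Each region is tiled with 100-nt baits at
   1.15X density: step = round(100/1.15) = 87 nt, plus one right-aligned
   terminal bait, with duplicate bait sequences emitted once.
2. **Capture evaluation** (`capture_eval`). Contigs are matched to targets
   with a seed–chain–extend local aligner (15-mer seeds, banded affine
   Smith–Waterman; scores +1/−1, gap −2 open/−1 extend). Hits need ≥ 80%
   identity and ≥ 82% target coverage. Contigs hitting ≥ 2 targets are
   discarded (chimera filter), then targets hit by ≥ 2 surviving contigs
   are discarded (paralog filter); across assemblers, the longest accepted
   contig per locus wins, ties broken by assembler name.
3. **Locus QC** (`locus_qc`). The reading frame minimises in-frame stop
   codons; flank boundaries are set at the innermost stop codon,
   out-of-frame gap run (length mod 3 ≠ 0), or window of poor amino-acid
   consensus agreement outside the probe-matched core; probe regions are
   trimmed to start on codon position one; frameshifted stretches are
   masked to `N`; rows with < 9 unambiguous bases or in broad disagreement
   with the AA consensus are removed.
4. **Supermatrix** (`supermatrix`). Loci with at least 50% (or 75%) of taxa
   are concatenated (missing taxa filled with `?`), partitioned per gene by
   codon position (`DNA, locus_pos1 = 1-300\3` …) with all flank columns
   as one partition; partitions under 80 bp are pruned; third codon
   positions can be stripped and probe blocks translated to amino acids.
5. **FcLM** (`fclm`). For four user-defined taxon clusters, every quartet
   (one taxon per cluster) gets maximum log-likelihoods `(ℓ1, ℓ2, ℓ3)` of
   the three unrooted topologies T1 = (a,b|c,d), T2 = (a,c|b,d),
   T3 = (a,d|b,c) under JC69 (or Poisson for AA), by Felsenstein pruning
   with the five branch lengths optimised cyclically. Posterior weights
   `p_i = exp(ℓ_i − logsumexp(ℓ))` place each quartet on the 2-simplex,
   binned into seven regions: three corners (resolved), three edges
   (inconclusive between two topologies), centre (star-like).
6. **Tree support** (`treesupport`). Branches are strong when UFB ≥ 95 and
   SHT ≥ 95 (or LPP ≥ 0.95), moderate when UFB ≥ 95 and SHT ≥ 80 (or
   LPP ≥ 0.85), weak when only one criterion holds; branches with UFB < 10
   are contracted into polytomies before coalescent species-tree analysis.

## Worked example

Simulate 20 reference orthogroups with planted conserved blocks, design a
bait set, then run FcLM on data simulated under a known quartet topology:

```sh
$ anchorkit simulate orthogroups --seed 11 --out sim
20 orthogroups written to sim
$ anchorkit design --aa-dir sim/aa --cds-dir sim/cds --out design
160 target sequences, 480 baits
$ anchorkit simulate quartets --per-cluster 2 --sites 1000 --seed 11 --out qsim
alignment (8 taxa x 1000 sites) written to qsim
$ anchorkit fclm --alignment qsim/alignment.fasta --clusters qsim/clusters.tsv --out fclm_out
16 quartets: resolved 1.000, partly 0.000, unresolved 0.000
```

The design step found one conserved region per orthogroup
(`design/targets.tsv` starts):

```
ortholog  aa_start  aa_end  nt_start  nt_end  n_represented
og001     33        107     99        321     8
og002     33        107     99        321     8
```

Each planted 60-AA block (alignment columns 40–100) is recovered with a
few columns of slack at each edge — the sliding window cannot resolve the
boundary more finely than its own length — and is represented in all 8
reference taxa, so 20 regions × 8 taxa = 160 target sequences, tiled into
480 unique baits. The FcLM run simulates the four clusters around an
internal branch of length 0.2 substitutions/site; all 16 quartets land in
region R1, i.e. 100% of the quartet signal supports the true topology
(`fclm_out/summary.tsv` has the per-region counts, `quartets.tsv` the
per-quartet likelihoods and simplex weights).

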