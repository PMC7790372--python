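# Methods

This note documents the models, parameter choices and limitations behind
each stage of the pipeline, and what the synthetic validation does and
does not demonstrate.

## Synthetic superfamilies

The generator emulates the structure of a curated superfamily retrieval:
families of internally similar, mutually dissimilar protein sequences,
each carrying short conserved motifs at fixed scaffold offsets (stand-ins
for fold elements such as the α1-α2 loop or the β4 strand), with a
minority of curated, functionally labelled records and a fungi-heavy
taxon mixture.

* **Scaffolds.** One ancestor per family, drawn i.i.d. from the BLOSUM62
  marginal amino-acid frequencies (more realistic under BLOSUM62 scoring
  than a uniform background). Independent ancestors make expected
  between-family identity random background (~5–10%), matching the high
  sequence diversity of a real superfamily. Default length 150 residues,
  roughly one GNAT domain.
* **Identity calibration.** `mutate_sequence(parent, t)` substitutes
  exactly `round((1−t)·L_unprotected)` unprotected positions with a
  different background residue. Members are mutated from the ancestor at
  *half* the family's target divergence: two members' mutations are
  independent, so their pairwise divergence is approximately twice the
  per-member rate and pairwise identity lands on the target (collisions
  and protected positions push the realized value slightly above it;
  measured values for a 0.75 target sit near 0.78).
* **Motif conservation.** Protected (motif) positions mutate at a
  10×-reduced per-site rate, leaving planted consensus residues modal in
  every column while allowing the minor within-family variation seen in
  real cluster logos.
* **Z-score fixtures.** Structure comparison consumes a symmetric matrix
  with within-family entries ~ Normal(μ_within, σ) truncated at 0 and
  between-family entries ~ Normal(μ_between, σ); defaults 20/5/1 mimic
  the separation of a fold family against the superfamily background.
* **Not modelled:** indels, tree-structured (phylogenetic) evolution,
  codon-level effects, domain architecture. Passing tests therefore show
  the pipeline recovers block-structured identity signal with conserved
  motifs; they do not certify behaviour under length variation or deep
  phylogenetic correlation.

## Alignment statistics

All pairs are aligned with exact Smith–Waterman (biopython's
`PairwiseAligner`, local mode) under BLOSUM62 with BLAST-convention
affine gaps: a gap of length g costs 11 + g (open_gap_score −12,
extend_gap_score −1 in biopython's convention). No heuristics (seeding,
two-hit, composition-based statistics) are used — affordable at desk
scale and exactly reproducible. E-values use the Karlin–Altschul formula
with published gapped BLOSUM62/11/1 constants λ = 0.267, K = 0.041 and
the plain m·n search space (no finite-size edge correction; at these
lengths the correction is a second-order effect). `X` scores 0 against
everything. Tie-breaking among co-optimal tracebacks follows the
aligner's deterministic internal order; scores are unaffected and
identity differences between co-optimal paths are below the tolerances
used anywhere downstream.

Two identity conventions coexist deliberately: redundancy filtering
divides identities by the shorter sequence length (cd-hit convention,
robust to short spurious local alignments), while SSN edge weights
divide by aligned columns (BLAST convention — "percent identity" of the
edge). Sequences shorter than 34 residues are dropped with a warning
before network construction.

The SSN edge score is −log10(E) with E floored at 1e−180 to avoid
infinities; an edge requires both `E ≤ E_max` and `score ≥ s_min`. The
convergence ratio |E|/(n(n−1)/2) summarises global divergence.

## Cohesiveness clustering

Cluster growth maximises `f(V) = w_in/(w_in + w_bound + p·|V|)` by the
single best add-or-remove step until a local maximum, with candidate
moves evaluated in deterministic order (additions by node id, then
removals) so ties resolve reproducibly. Defaults: penalty p = 2, overlap
merge threshold ω = 0.8 (ω(A,B) = |A∩B|²/(|A||B|), merged by union to a
fixpoint), minimum size 10, minimum density "auto" = 0.3 with identity
weights normalised to [0,1]. Seeds are taken in decreasing
weighted-degree order over uncovered nodes; surviving clusters are
numbered 1..k by decreasing size (cluster numbers are a repo convention,
not comparable across datasets).

An exhaustive oracle (`brute_force_best_cluster`, ≤ 15 nodes) searches
every connected subset; the greedy grower is validated to never exceed
it and to match it on most random instances. Note the global optimum of
f at small p is the whole connected component (any pendant node helps:
its edge moves from w_bound to w_in), so meaningful clusters rely on the
*local* search from dense seeds plus the size penalty — the same
behaviour the original cohesiveness-based methods exhibit.

## Pivot network and topology

Contraction puts one node per cluster and an edge wherever any
inter-cluster SSN edge exists; clusters sharing a member (overlap) are
also joined, shared membership being at least as strong evidence of
relatedness as a single cross edge. Unassigned SSN nodes are ignored.
Betweenness is Brandes', normalised by (n−1)(n−2)/2, disconnected pairs
contributing nothing; the pivot graph is unweighted and undirected.

## Small-world selection

σ = (C/C_rand)/(L/L_rand) against n_ref = 10 degree-preserving rewired
references (10·|E| attempted double-edge swaps each; on swap-saturated
graphs such as complete graphs all attempts fail and the reference
equals the graph, which is correct). A component is called small-world
iff σ > 1, the conventional criterion. Degree-preserving references are
preferred over Erdős–Rényi because SSN degree distributions are far from
Poisson. Representatives per cluster: curated members first
(lexicographically smallest ids when more than k), remaining slots by
seeded uniform sampling of unreviewed members; k = 3.

## Motif discovery and scanning

Discovery fits a ZOOPS mixture per width (5–10): each sequence contains
one motif site (prior γ, initialised 0.8) at a uniform position, or is
pure background (letter frequencies of the supplied set). EM runs from
five substring-derived starts (the three w-mers occurring in the most
distinct sequences, plus two random windows) to convergence
(log-likelihood change < 1e−4, cap 200 iterations); PPMs carry a 0.01
pseudocount per residue. Per round the best motif is reported and its
confident sites (posterior ≥ 0.5) are masked before the next round.

**Significance.** The discovery objective (total information content ×
expected site count) is recomputed on 20 residue-shuffled copies of the
dataset with the identical search; a Gumbel distribution — the natural
family for best-over-restarts maxima, with a tail heavier than normal —
is moment-fitted to the per-width null values, and the E-value is the
Gumbel tail probability times the number of candidate starting points
across all widths, i.e. the expected number of motifs this good from
background alone. Only motifs with E < 1 are reported. This calibration
makes planted motifs astronomically significant while pure-random
datasets essentially never pass, mirroring how analytic motif-discovery
E-values behave on random protein data. Within a round, widths passing
the filter are compared by objective (E-values of overwhelmingly
significant motifs are not finely comparable across widths).

**Regex fingerprints.** Columns are rendered in the field's table
convention: residues with probability ≥ 0.2 become a bare letter (one),
a bracketed set ordered by descending frequency (two or three), or `X`
(otherwise). The reverse mapping gives listed residues 95% of a column's
mass (earlier entries slightly favoured) over a background floor.
Discovered motifs are 5–10 columns wide; fingerprints imported from
published regex tables may be wider.

**Scanning.** Integer log-odds `round(100·log2(ppm/bg))`; the position
p-value is exact, from convolving per-column score distributions under
the background; the sequence p-value is `1 − (1−p)^(L−w+1)`; several
motifs' sequence p-values combine by the QFAST product rule
`P = p·Σ_{i<k} (−ln p)^i/i!`. Residues absent from the background get a
hard penalty instead of an infinite ratio.

## Annotation transfer and candidate prediction

Clusters whose labelled curated members agree on one label donate it to
unlabelled members (provenance "transferred"); conflicts flag the
cluster "mixed" with no transfer; curated labels are never overwritten.
Candidates are uncharacterized clusters adjacent in the pivot network to
a known-labelled cluster (plus explicitly requested isolated clusters).
Each candidate is scored against every group fingerprint; its own motifs
are discovered, matched to the best group's elements by maximal
column-correlation ungapped alignment (matches below correlation 0.5 are
dropped rather than forced), and diffed position by position. "Key"
positions have modal frequency ≥ 0.7 in the known group's motif — a
proxy for mutation-sensitive residues. Verdicts: *consistent* when at
least half the members match at α = 0.01 and no key position differs;
*divergent* when some members match or a key substitution is found;
*no-match* otherwise. The 0.5 member fraction and α = 0.01 are repo
conventions for what the field argues qualitatively.

## Structure stage

Distances are `Z_max − Z` (Z_max the largest off-diagonal entry) — a
fixed affine transform, chosen over 1/Z to avoid division by zero —
clustered by average linkage; the dendrogram is emitted as an
ultrametric newick string (node height = merge distance / 2). Threshold
networks use strict inequality `Z > z`; the separation threshold is the
smallest integer z at which at least two components of size ≥ 3 appear
(peeling singletons off a hairball does not count as separation). The
linkage choice is a repo convention; structural-alignment servers do not
publish theirs.

## Pipeline and determinism

Stage seeds derive from the master seed by SHA-256, so stages are
independently reproducible; manifests record parameters and SHA-256
content hashes of every output and contain no timestamps — two runs with
the same configuration are byte-identical. Configuration is a flat TOML
file with one section per stage.

## Problem sizes used in validation

Validation runs use 8 families × 15 sequences (150 residues) for
end-to-end recovery, 20 sequences for motif recovery, 50 random graphs
(≤ 10 nodes) for the clustering oracle, 100 short pairs for the
alignment oracle, 10⁴ draws for p-value calibration, and 200-node graphs
for small-world diagnostics — sizes at which the exhaustive oracles are
exact and the full suite runs in minutes on one core.

## Known limitations

* No indel evolution in the generator, hence no test coverage of
  alignment behaviour under length variation within families.
* Motif element labels (α1-α2, β4, β5, β6-β7) come from planted truth or
  correlation matching, not from structural mapping.
* The empirical motif E-value is calibrated for the E < 1 filter, not
  for comparing fine significance between motifs across datasets.
* Real-data cluster counts and convergence ratios depend on retrieval
  and external-tool versions and are not reproduced here; validation is
  property-based on synthetic ground truth.
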