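# Methods

## The prediction problem

HLA-DR molecules present extracellular peptides to helper T cells. A
peptide binds through a 9-residue core seated in a groove of nine pockets
(P1–P9), one core residue per pocket. Binding preferences differ between
alleles because the pocket-lining residues of the DRB β1 domain are
polymorphic, but experimentally characterized position-specific scoring
matrices (PSSMs) exist for only a handful of alleles, while hundreds of
DRB alleles have known sequences. `pocketpan` extrapolates: it predicts a
20×9 PSSM for *any* sequenced DRB allele from a small library of
characterized matrices, on the assumption that alleles with similar
pocket-lining residues have similar pocket preferences.

## Pocket definitions and pseudosequences

Each pocket is defined by the DRB positions whose residues contact the
corresponding core residue in solved HLA-DR/peptide complex structures.
The bundled default table is the union, over 32 complexes (shipped as
`data/dr_complexes.tsv`), of residues within 4.0 Å (heavy-atom minimum
distance, boundary inclusive) of the pocket's core residue:

| pocket | positions |
|---|---|
| P1 | 82 85 86 89 |
| P2 | 77 78 81 82 |
| P3 | 78 |
| P4 | 11 13 26 28 70 71 74 78 |
| P5 | 11 13 28 70 71 74 |
| P6 | 11 13 28 30 61 71 |
| P7 | 11 28 30 47 61 67 70 71 |
| P8 | 60 61 |
| P9 | 9 30 37 57 60 61 |

Positions are 1-based mature-protein numbering; input FASTA sequences are
assumed pre-aligned to it (character *k−1* is position *k*). Aligning raw
database entries — including leader-peptide offset handling — is out of
scope; the `contact_derivation` module can regenerate a table from
structures, with a per-structure numbering offset because PDB residue
numbers need not match the alignment. Whether hydrogens join the distance
test is a flag (`heavy_only`, default true): hydrogens are rarely resolved
and would make the cutoff resolution-dependent. An allele's *pocket
pseudosequence* is simply its residues at the pocket's positions; an
unknown residue (`X`) at a required position is an error, since no
similarity can be computed from it.

## Similarity and weighting

For query pseudosequence *q* and library pseudosequence *l* at a pocket
with |p| positions:

* raw similarity: `B(q,l) = Σ_i blosum62(q_i, l_i)`;
* normalized similarity:
  `S(q,l) = (1/|p|) Σ_i (blosum62(q_i,l_i) − m_i) / (M_i − m_i)`,
  with `M_i = blosum62(q_i,q_i)` and `m_i = min_b blosum62(q_i,b)`;
* library weights: `w(q,l) = S(q,l)^α / Σ_l' S(q,l')^α`, per pocket.

The min–max normalization is chosen because it provably yields S = 1
exactly for identical pseudosequences and S = 0 exactly for a partner
attaining the row minimum at every position, and is monotone in the raw
per-position score. It is deliberately asymmetric — the query supplies
the per-position scale — and this is the package's fixed convention.
Likewise `w ∝ S^α` is the simplest form that is normalized, defined for
all α > 0, sharpens monotonically with α, and converges to the 1-KNN rule
(copy the most similar library pocket; ties averaged) as α → ∞. Other
normalizations/weightings satisfying the same qualitative constraints
exist; exact numeric parity with other implementations of this idea is
not guaranteed for non-identical pseudosequences.

**α (default 9).** Dimensionless sharpening exponent. Small α pools the
whole library (robust but biased toward the library mean); large α
degenerates to nearest-neighbour copying (unbiased but noisy). The
default follows the published selection of this weighting scheme, where
benchmark AUC plateaued for α between roughly 5 and 30 with the best
average at α ≈ 9–10; the package's own synthetic sweep (below) reproduces
that shape. If every library allele has S = 0 at some pocket, weights are
undefined and the synthesis errors out rather than dividing by zero.

## PSSM synthesis and scanning

The query's pocket-p specificity vector is the weighted average
`β_q(p) = Σ_l w_p(q,l) β_l(p)`; the nine vectors form the PSSM. Pockets
in the library's *unused mask* (default P5 and P8, which carry no
specificity in the classical virtual-matrix libraries) stay all-zero.
Because weights are convex coefficients, every synthesized entry lies in
the library's per-entry range, and scaling the library scales the output.

A peptide of length L ≥ 9 is scored by summing, for each of its L−8
9-mer windows, the pocket entries of the window's residues; the maximal
window is the predicted binding core, ties broken at the leftmost offset
(deterministic, the usual scanner convention). Unknown residues
contribute 0, so peptides transcribed from structures with unresolved
termini scan verbatim. Binding motifs are estimated by sampling random
peptides (default 100,000 9-mers, uniform background; empirical
amino-acid frequencies injectable), keeping the top fraction (default 1%)
by best-window score, aligning each at its predicted core, and tallying
per-pocket frequencies. With the default length 9 the core is the whole
peptide; longer peptides realign on their predicted cores.

## Evaluation statistics

* **AUC** is the Mann–Whitney statistic (ties ½), computed via
  scikit-learn; the unit tests verify it against brute-force pair
  counting.
* **Affinity thresholds** binarize IC50 values inclusively
  (binder iff ≤ threshold), per-allele configurable (100 nM vs 1000 nM in
  common benchmark practice). The boundary rule is a package convention.
* **Paired method comparison** uses the one-tailed exact binomial test on
  per-allele win/loss counts, ties excluded; all ties is an explicit
  error, not p = 1.
* **Core identification** is scored by exact offset: a one-residue shift
  is an error.

## Synthetic data: what it emulates and what it does not

The generators make the package testable without external downloads.
Alleles are mutants of one random base sequence; `similarity_level` is
the per-pocket-position probability of keeping the base residue. Residues
are drawn on the full 95-residue sequence so pockets that share positions
(position 11 sits in P4–P7) stay mutually consistent. An allele's
ground-truth specificity vector at a pocket is the mean BLOSUM62 row of
its pocket residues, halved, plus N(0, 0.5) noise per entry — so
sequence similarity implies specificity similarity *by construction*,
with a realistic unexplained component (the noise sd is about a quarter
of the deterministic signal's range). Benchmarks draw binder cores
position-wise with probability ∝ exp(specificity) inside uniform flanks
of 15-mers; decoys are uniform. All generators are deterministic given a
seed.

What this does **not** emulate: real pocket chemistry (the BLOSUM-row map
is a smoothness device, not a binding model), linkage between natural
allele groups, peptide-flanking-residue effects, experimental affinity
noise, or the composition of real proteomes. Green tests therefore
demonstrate the machinery's correctness and the qualitative
bias–variance behaviour of α, not real-world predictive accuracy.

The α-sweep harness runs at desk scale: an 11-matrix library in which
each of 4 query alleles has two relatives (pocket positions kept with
probability 0.85) plus three unrelated alleles, 80 binders + 80 decoys
per query. These sizes mirror the characterized-library scale of the
field (11 alleles) while keeping the whole suite in seconds.

## Numerical and degenerate-input choices

* Amino-acid order is fixed alphabetically by one-letter code
  (`ACDEFGHIKLMNPQRSTVWY`) in every matrix and file.
* Per-pocket weights sum to 1 to ~1e-12 (floating normalization only).
* 1-KNN ties (several alleles at maximal S, atol 1e-12) average the tied
  vectors.
* Library files must list every non-masked pocket per allele; pockets
  absent for *all* alleles define the mask and load as zeros.
* Peptides shorter than 9 cannot be scanned (error in the API; logged and
  skipped with a count in the CLI).
* The bundled BLOSUM62 is a plain-text NCBI-layout file; any symmetric
  20×20 matrix in that layout can be substituted.

## Known limitations

* Requires pre-aligned DRB sequences; no built-in alignment of raw
  database entries, and no DP/DQ or non-human loci.
* The similarity normalization and weight form are one principled choice
  within the constraints stated above, not a unique solution.
* The real characterized 11-allele matrix library is not bundled (it is
  an external redistribution); the library TSV format is a documented
  drop-in for it, and `count_unique_vectors` reports the sharing
  structure so a dropped-in library can be checked (the classical one
  collapses to 35 distinct non-masked vectors).
* Motif sampling with a uniform background overstates enrichment of rare
  residues relative to a proteome background; supply empirical
  frequencies for logo-quality motifs.
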