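# pocketpan

Pan-specific peptide-binding prediction for HLA-DR molecules by
pocket-similarity extrapolation of position-specific scoring matrices
(PSSMs).

MHC class II (HLA-DR) molecules bind peptides through a 9-residue core,
one residue per groove pocket P1–P9. Experimentally characterized 20×9
scoring matrices exist for only a few DRB alleles, yet hundreds of
alleles are sequenced. `pocketpan` predicts a PSSM for *any* sequenced
allele: each pocket is represented by its *pseudosequence* (the allele's
residues at the pocket's contact positions), pockets of the query and of
each library allele are compared with a BLOSUM62 similarity normalized to
[0, 1],

    S_p(q, l) = (1/|p|) Σ_i (blosum62(q_i, l_i) − m_i) / (M_i − m_i),

and the query's pocket-p specificity vector is the weighted average of
the library's pocket-p vectors,

    β_q(p) = Σ_l w_p(q, l) β_l(p),   w_p(q, l) ∝ S_p(q, l)^α,

with sharpening exponent α = 9 by default (α → ∞ recovers 1-KNN
nearest-pocket copying). Peptides are scored by sliding a 9-mer window
over the sequence and summing pocket entries; the maximal window is the
predicted binding core. The package also derives pocket contact positions
from complex structures (4 Å heavy-atom rule), samples binding motifs for
sequence logos, and ships an evaluation harness (per-allele AUC, exact
binomial sign test, exact-core error counts) plus synthetic-fixture
generators, so the whole pipeline is testable offline. It is aimed at
immunoinformaticians doing epitope discovery or benchmarking pan-specific
class II predictors.

## Worked example

Synthesize a matrix for a new allele from a 5-allele library, then locate
a binding core (full scripts in `examples/`):

```python
import numpy as np
from pocketpan import (AlleleRecord, SimilarityConfig, extract_pseudosequences,
                       generate_fixture_library, scan_peptide, synthesize_pssm)

library, records = generate_fixture_library(n_alleles=5, similarity_level=0.5, rng=42)
lib_pseqs = {r.name: extract_pseudosequences(r) for r in records}

seq = list(records[2].sequence)
seq[86 - 1] = "W"                       # mutate a P1 contact residue
query = AlleleRecord("DRB1*99:01", "".join(seq))

pssm, profile = synthesize_pssm(query, library, lib_pseqs, SimilarityConfig(alpha=9))
print(profile.weight.loc["P1"].round(3).to_dict())
print(scan_peptide(pssm, "ENPVVHFFKNIVTPR").core_start)
```

prints

```
{'DRB1*90:01': 0.052, 'DRB1*90:02': 0.024, 'DRB1*90:03': 0.855, 'DRB1*90:04': 0.068, 'DRB1*90:05': 0.0}
5
```

— the template allele `DRB1*90:03` (whose sequence the query copies, bar
the mutated position 86) receives 0.855 of the P1 weight, the mutation
having let the other alleles in slightly, and the scanner reports the
best-scoring 9-mer window of the peptide at offset 5. Running
`python examples/alpha_sweep.py` reproduces the characteristic weighting
curve on synthetic benchmarks: mean AUC 0.766 at α = 1, 0.817 at α = 9,
0.798 for 1-KNN — moderate sharpening pools informative relatives while
down-weighting unrelated alleles.

A thin CLI mirrors the library (`pocketpan build-pssm | scan |
sample-motif | evaluate | derive-pockets | make-fixtures`); run
`pocketpan --help`.

Real characterized matrix libraries can be dropped in as a TSV (header
`allele pocket A … Y`, one row per allele and pocket, masked pockets
omitted); aligned DRB sequences load from FASTA. See `docs/methods.md`
for conventions, parameters and limitations.

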