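"""Choose the similarity-weighting exponent alpha on synthetic benchmarks.

Each of four query alleles has two moderately similar relatives in an
11-matrix library; benchmarks are generated from each query's ground-truth
specificity.  The sweep reports per-query and mean AUC at each alpha and
for the 1-KNN (single most similar pocket) rule.
"""

import numpy as np

from pocketpan import (
    alpha_sweep,
    generate_alleles,
    generate_fixture_benchmark,
    specificity_from_sequence,
)
from pocketpan.similarity import SubstitutionMatrix
from pocketpan.synthetic import library_from_records, mutate_allele

blosum62 = SubstitutionMatrix.blosum62()
rng = np.random.default_rng(5)

query_records = generate_alleles(4, 0.6, rng=rng, name_prefix="DRB1*93")
lib_records = [
    mutate_allele(q, 0.85, rng, name=f"DRB1*90:{2 * i + j + 1:02d}")
    for i, q in enumerate(query_records)
    for j in range(2)
]
lib_records += generate_alleles(3, 0.0, rng=rng, name_prefix="DRB1*91")
library = library_from_records(lib_records, blosum62, rng=rng)

queries = []
for query in query_records:
    truth = specificity_from_sequence(query, blosum62, noise_sd=0.5, rng=rng)
    queries.append((query, generate_fixture_benchmark(truth, 80, 80, rng=rng)))

table = alpha_sweep(library, lib_records, queries, alphas=(1, 2, 3, 5, 9, 10, 20, 50))
print(table.round(3).to_string())
print()
mean = table.loc["mean"]
print(
    f"mean AUC rises from {mean['1']:.3f} at alpha=1 to {mean['9']:.3f} at "
    f"alpha=9 and beats the 1-KNN rule ({mean['1-KNN']:.3f}): moderate "
    "sharpening pools the informative relatives while down-weighting "
    "unrelated alleles."
)
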