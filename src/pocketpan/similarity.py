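"""Pocket similarity between HLA-DR alleles and library weighting.

Two alleles' pockets are compared through their pseudosequences.  The raw
similarity of a query pseudosequence ``q`` and a library pseudosequence
``l`` is the summed BLOSUM62 score over positions,

    B_p(q, l) = sum_i blosum62(q_i, l_i).

The normalized similarity rescales each position between the best and the
worst partner the query residue could have,

    S_p(q, l) = (1/|p|) * sum_i (blosum62(q_i, l_i) - m_i) / (M_i - m_i),

with ``M_i = blosum62(q_i, q_i)`` (the diagonal, the row maximum for
BLOSUM62) and ``m_i = min_b blosum62(q_i, b)``.  S is 1 for two identical
pseudosequences and 0 for a totally distinctive partner that attains the
minimum at every position.  Note S is asymmetric: the first argument
always plays the query role, supplying the per-position scale.

Library weights sharpen S with a positive exponent ``alpha``:

    w_p(q, l) = S_p(q, l)^alpha / sum_l' S_p(q, l')^alpha.

A larger alpha suppresses dissimilar library alleles; alpha -> infinity
recovers 1-KNN, i.e. copying the most similar library pocket (ties
averaged).  The default alpha is 9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Align import substitution_matrices

from .alphabet import AMINO_ACIDS
from .pockets import POCKET_IDS, Pseudosequence

DEFAULT_ALPHA: float = 9.0


class SubstitutionMatrix:
    """A 20x20 amino-acid substitution matrix (BLOSUM62 by default)."""

    def __init__(self, scores: np.ndarray, name: str = "custom"):
        scores = np.asarray(scores, dtype=float)
        if scores.shape != (20, 20):
            raise ValueError(f"expected a 20x20 matrix, got {scores.shape}")
        if not np.allclose(scores, scores.T):
            raise ValueError("substitution matrix must be symmetric")
        self.name = name
        self._scores = scores
        self._index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
        self._row_min = scores.min(axis=1)

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[self._index[a], self._index[b]]
        except KeyError as exc:
            raise ValueError(f"non-standard amino acid {exc.args[0]!r}") from None

    def self_score(self, a: str) -> float:
        """Diagonal entry: the score of *a* against itself."""
        i = self._index[a]
        return self._scores[i, i]

    def min_score(self, a: str) -> float:
        """Worst score of *a* against any of the 20 amino acids."""
        return self._row_min[self._index[a]]

    @classmethod
    def from_ncbi_file(cls, path: str | Path, name: str | None = None):
        """Load a matrix in the standard NCBI text layout, restricted to the
        20 standard amino acids."""
        with open(path) as fh:
            mat = substitution_matrices.read(fh)
        idx = [mat.alphabet.index(aa) for aa in AMINO_ACIDS]
        scores = np.asarray(mat)[np.ix_(idx, idx)]
        return cls(scores, name=name or Path(path).stem)

    @classmethod
    def blosum62(cls) -> "SubstitutionMatrix":
        """The bundled BLOSUM62 matrix."""
        ref = resources.files("pocketpan.data") / "BLOSUM62.txt"
        with resources.as_file(ref) as path:
            return cls.from_ncbi_file(path, name="BLOSUM62")


@dataclass(frozen=True)
class SimilarityConfig:
    """Parameters of the similarity weighting.

    alpha
        Positive exponent sharpening the similarity weights (default 9).
    matrix
        Substitution matrix; BLOSUM62 unless overridden.
    """

    alpha: float = DEFAULT_ALPHA
    matrix: SubstitutionMatrix = field(default_factory=SubstitutionMatrix.blosum62)

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")


def _check_pair(query: Pseudosequence, lib: Pseudosequence) -> None:
    if query.pocket != lib.pocket:
        raise ValueError(
            f"pocket mismatch: query {query.pocket} vs library {lib.pocket}"
        )
    if len(query) != len(lib):
        raise ValueError(
            f"pseudosequence length mismatch at pocket {query.pocket}: "
            f"{len(query)} vs {len(lib)}"
        )


def raw_similarity(
    query: Pseudosequence, lib: Pseudosequence, matrix: SubstitutionMatrix
) -> float:
    """Summed substitution score over aligned pseudosequence positions."""
    _check_pair(query, lib)
    return float(sum(matrix.score(a, b) for a, b in zip(query.residues, lib.residues)))


def normalized_similarity(
    query: Pseudosequence, lib: Pseudosequence, matrix: SubstitutionMatrix
) -> float:
    """Per-position min-max normalized similarity in [0, 1].

    1 iff the library residue attains the query residue's self-score at
    every position; 0 iff it attains the row minimum at every position.
    """
    _check_pair(query, lib)
    total = 0.0
    for a, b in zip(query.residues, lib.residues):
        hi = matrix.self_score(a)
        lo = matrix.min_score(a)
        total += (matrix.score(a, b) - lo) / (hi - lo)
    return total / len(query)


@dataclass(frozen=True)
class SimilarityProfile:
    """Per-pocket, per-library-allele similarity breakdown.

    Each attribute is a DataFrame indexed by pocket id (rows P1..P9) with
    one column per library allele: ``raw`` holds the summed BLOSUM scores,
    ``similarity`` the normalized S values, ``weight`` the alpha-weights
    (each row sums to 1).
    """

    raw: pd.DataFrame
    similarity: pd.DataFrame
    weight: pd.DataFrame

    def to_tsv(self, path: str | Path) -> None:
        frames = {"raw": self.raw, "similarity": self.similarity, "weight": self.weight}
        combined = pd.concat(frames, names=["quantity", "pocket"])
        combined.to_csv(path, sep="\t", float_format="%.6g")


def pocket_weights(
    query_pseqs: dict[str, Pseudosequence],
    library_pseqs: dict[str, dict[str, Pseudosequence]],
    config: SimilarityConfig | None = None,
) -> SimilarityProfile:
    """Compute raw/normalized similarity and alpha-weights per pocket.

    Parameters
    ----------
    query_pseqs
        Pocket id -> query pseudosequence.
    library_pseqs
        Library allele name -> (pocket id -> pseudosequence).
    config
        Similarity configuration (alpha, matrix).

    Raises
    ------
    ValueError
        If the library is empty, or if at some pocket every library allele
        has similarity 0 to the query (the weight is then undefined).
    """
    config = config or SimilarityConfig()
    if not library_pseqs:
        raise ValueError("library is empty")
    alleles = list(library_pseqs.keys())
    raw = pd.DataFrame(index=list(POCKET_IDS), columns=alleles, dtype=float)
    sim = pd.DataFrame(index=list(POCKET_IDS), columns=alleles, dtype=float)
    for pocket in POCKET_IDS:
        q = query_pseqs[pocket]
        for allele in alleles:
            l = library_pseqs[allele][pocket]
            raw.loc[pocket, allele] = raw_similarity(q, l, config.matrix)
            sim.loc[pocket, allele] = normalized_similarity(q, l, config.matrix)
    powered = sim.to_numpy() ** config.alpha
    row_sums = powered.sum(axis=1)
    if np.any(row_sums == 0):
        bad = [p for p, s in zip(POCKET_IDS, row_sums) if s == 0]
        raise ValueError(
            f"all library similarities are zero at pocket(s) {bad}; "
            "weights are undefined for this query"
        )
    weight = pd.DataFrame(
        powered / row_sums[:, None], index=list(POCKET_IDS), columns=alleles
    )
    return SimilarityProfile(raw=raw, similarity=sim, weight=weight)


def knn_weights(
    query_pseqs: dict[str, Pseudosequence],
    library_pseqs: dict[str, dict[str, Pseudosequence]],
    matrix: SubstitutionMatrix | None = None,
) -> SimilarityProfile:
    """1-KNN weighting: all weight on the most similar library pocket.

    The alpha -> infinity limit of :func:`pocket_weights`; alleles tied at
    the maximal similarity share the weight equally.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    base = pocket_weights(
        query_pseqs, library_pseqs, SimilarityConfig(alpha=1.0, matrix=matrix)
    )
    sim = base.similarity.to_numpy()
    weight = np.zeros_like(sim)
    for i in range(sim.shape[0]):
        top = np.isclose(sim[i], sim[i].max(), rtol=0, atol=1e-12)
        weight[i, top] = 1.0 / top.sum()
    return SimilarityProfile(
        raw=base.raw,
        similarity=base.similarity,
        weight=pd.DataFrame(weight, index=base.weight.index, columns=base.weight.columns),
    )
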