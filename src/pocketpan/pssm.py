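"""Position-specific scoring matrices (PSSMs) and matrix libraries.

A PSSM here is a 20x9 matrix: one 20-valued binding-specificity vector per
groove pocket P1..P9.  A matrix library holds the PSSMs of experimentally
characterized alleles; the engine extrapolates a PSSM for any query allele
as the per-pocket weighted average of library vectors, with weights from
pocket-pseudosequence similarity.  Pockets flagged "unused" (by default P5
and P8, which carry no specificity in the classical virtual-matrix
libraries) hold all-zero vectors and are excluded from averaging.

Library file format (TSV)::

    # comment lines allowed
    allele  pocket  A   C   D   ... Y        <- header, fixed AA order
    DRB1*01:01  P1  0.0 ...                  <- one row per (allele, pocket)

Masked pockets may be omitted from the file; they are filled with zeros.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .alphabet import AMINO_ACIDS
from .pockets import (
    POCKET_IDS,
    AlleleRecord,
    PocketTable,
    Pseudosequence,
    extract_pseudosequences,
    normalize_allele_name,
)
from .similarity import SimilarityConfig, SimilarityProfile, knn_weights, pocket_weights

#: Pockets carrying no specificity in the classical 11-allele library.
DEFAULT_UNUSED_POCKETS: frozenset[str] = frozenset({"P5", "P8"})


@dataclass(frozen=True)
class PocketVector:
    """One PSSM column: the 20 preference values of one pocket."""

    pocket: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (20,):
            raise ValueError(
                f"pocket vector must have exactly 20 values, got {values.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError(f"non-finite value in pocket {self.pocket} vector")
        object.__setattr__(self, "values", values)

    def value(self, aa: str) -> float:
        return float(self.values[AMINO_ACIDS.index(aa)])


@dataclass(frozen=True)
class PSSM:
    """A 20x9 scoring matrix for one allele, stored pocket-major (9x20)."""

    allele: str
    matrix: np.ndarray
    unused_pockets: frozenset[str] = field(default=DEFAULT_UNUSED_POCKETS)

    def __post_init__(self) -> None:
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (9, 20):
            raise ValueError(f"PSSM matrix must be 9x20, got {matrix.shape}")
        for pocket in self.unused_pockets:
            row = matrix[POCKET_IDS.index(pocket)]
            if np.any(row != 0.0):
                raise ValueError(
                    f"unused pocket {pocket} of {self.allele} must be all-zero"
                )
        object.__setattr__(self, "matrix", matrix)
        object.__setattr__(self, "unused_pockets", frozenset(self.unused_pockets))

    def vector(self, pocket: str) -> PocketVector:
        return PocketVector(pocket, self.matrix[POCKET_IDS.index(pocket)])

    @classmethod
    def from_vectors(
        cls,
        allele: str,
        vectors: Mapping[str, np.ndarray],
        unused_pockets: Iterable[str] = DEFAULT_UNUSED_POCKETS,
    ) -> "PSSM":
        unused = frozenset(unused_pockets)
        matrix = np.zeros((9, 20))
        for i, pocket in enumerate(POCKET_IDS):
            if pocket in unused:
                continue
            matrix[i] = np.asarray(vectors[pocket], dtype=float)
        return cls(allele, matrix, unused)


_HEADER = "allele\tpocket\t" + "\t".join(AMINO_ACIDS)


@dataclass(frozen=True)
class MatrixLibrary:
    """An ordered collection of per-allele PSSMs sharing one unused-pocket mask."""

    pssms: tuple[PSSM, ...]
    unused_pockets: frozenset[str] = field(default=DEFAULT_UNUSED_POCKETS)

    def __post_init__(self) -> None:
        names = [p.allele for p in self.pssms]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate allele(s) in library: {dupes}")
        for pssm in self.pssms:
            if pssm.unused_pockets != frozenset(self.unused_pockets):
                raise ValueError(
                    f"PSSM {pssm.allele} mask {sorted(pssm.unused_pockets)} "
                    f"differs from library mask {sorted(self.unused_pockets)}"
                )
        object.__setattr__(self, "pssms", tuple(self.pssms))
        object.__setattr__(self, "unused_pockets", frozenset(self.unused_pockets))

    def __len__(self) -> int:
        return len(self.pssms)

    @property
    def alleles(self) -> tuple[str, ...]:
        return tuple(p.allele for p in self.pssms)

    def get(self, allele: str) -> PSSM:
        allele = normalize_allele_name(allele)
        for pssm in self.pssms:
            if pssm.allele == allele:
                return pssm
        raise KeyError(f"allele {allele} not in library")


def load_library(path: str | Path) -> MatrixLibrary:
    """Load a matrix library from the TSV format described in the module docs."""
    path = Path(path)
    rows: dict[str, dict[str, np.ndarray]] = {}
    order: list[str] = []
    header_seen = False
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        if not header_seen:
            if line != _HEADER:
                raise ValueError(
                    f"{path}:{lineno}: bad header; expected amino-acid columns "
                    f"in order {AMINO_ACIDS}"
                )
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != 22:
            raise ValueError(
                f"{path}:{lineno}: expected 22 tab-separated fields, "
                f"got {len(fields)}"
            )
        allele = normalize_allele_name(fields[0])
        pocket = fields[1]
        if pocket not in POCKET_IDS:
            raise ValueError(f"{path}:{lineno}: unknown pocket {pocket!r}")
        try:
            values = np.array([float(v) for v in fields[2:]])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed number: {exc}") from None
        pockets = rows.setdefault(allele, {})
        if allele not in order:
            order.append(allele)
        if pocket in pockets:
            raise ValueError(
                f"{path}:{lineno}: duplicate pocket {pocket} for allele {allele}"
            )
        pockets[pocket] = values
    if not header_seen:
        raise ValueError(f"{path}: empty library file")
    if not rows:
        raise ValueError(f"{path}: no matrix rows")
    # Pockets absent from the file for every allele form the unused mask.
    present = {p for pockets in rows.values() for p in pockets}
    unused = frozenset(set(POCKET_IDS) - present)
    pssms = []
    for allele in order:
        missing = set(POCKET_IDS) - set(rows[allele]) - unused
        if missing:
            raise ValueError(
                f"{path}: allele {allele} missing pocket(s) {sorted(missing)}"
            )
        pssms.append(PSSM.from_vectors(allele, rows[allele], unused))
    return MatrixLibrary(tuple(pssms), unused)


def save_library(library: MatrixLibrary, path: str | Path) -> None:
    lines = [_HEADER]
    for pssm in library.pssms:
        for i, pocket in enumerate(POCKET_IDS):
            if pocket in library.unused_pockets:
                continue
            values = "\t".join(repr(float(v)) for v in pssm.matrix[i])
            lines.append(f"{pssm.allele}\t{pocket}\t{values}")
    Path(path).write_text("\n".join(lines) + "\n")


def save_pssm_tsv(pssm: PSSM, path: str | Path) -> None:
    """Export one PSSM as a 9x20 TSV (pocket rows, amino-acid columns)."""
    lines = ["pocket\t" + "\t".join(AMINO_ACIDS)]
    for i, pocket in enumerate(POCKET_IDS):
        lines.append(pocket + "\t" + "\t".join(f"{v:.6g}" for v in pssm.matrix[i]))
    Path(path).write_text("\n".join(lines) + "\n")


def synthesize_pssm(
    query: AlleleRecord,
    library: MatrixLibrary,
    library_pseqs: Mapping[str, Mapping[str, Pseudosequence]],
    config: SimilarityConfig | None = None,
    *,
    pocket_table: PocketTable | None = None,
    mode: str = "weighted",
) -> tuple[PSSM, SimilarityProfile]:
    """Extrapolate the query allele's PSSM from the library.

    For each non-masked pocket p the query's specificity vector is the
    weighted average ``beta_q(p) = sum_l w_p(q, l) * beta_l(p)`` over
    library alleles l, with weights from pocket-pseudosequence similarity
    (``mode="weighted"``) or from the most-similar-pocket rule
    (``mode="1-knn"``).  Masked pockets are set to zero.

    Returns the PSSM together with the similarity profile used to build it.
    """
    config = config or SimilarityConfig()
    if len(library) == 0:
        raise ValueError("library is empty")
    query_pseqs = extract_pseudosequences(query, pocket_table)
    lib_pseqs = {a: dict(library_pseqs[a]) for a in library.alleles}
    if mode == "weighted":
        profile = pocket_weights(query_pseqs, lib_pseqs, config)
    elif mode == "1-knn":
        profile = knn_weights(query_pseqs, lib_pseqs, config.matrix)
    else:
        raise ValueError(f"unknown mode {mode!r}; use 'weighted' or '1-knn'")
    stack = np.stack([p.matrix for p in library.pssms])  # (n_alleles, 9, 20)
    weights = profile.weight.loc[list(POCKET_IDS), list(library.alleles)].to_numpy()
    matrix = np.einsum("pl,lpa->pa", weights, stack)
    for pocket in library.unused_pockets:
        matrix[POCKET_IDS.index(pocket)] = 0.0
    return PSSM(query.name, matrix, library.unused_pockets), profile


def count_unique_vectors(
    library: MatrixLibrary,
) -> tuple[int, dict[tuple[str, ...], list[tuple[str, str]]]]:
    """Count distinct non-masked pocket vectors across the library.

    Alleles often share identical experimentally derived pocket vectors, so
    the number of distinct vectors can be far below 9 x n_alleles.  Returns
    the count and a sharing map: vector (as a value tuple) -> list of
    (allele, pocket) pairs carrying it.
    """
    sharing: dict[tuple[str, ...], list[tuple[str, str]]] = {}
    for pssm in library.pssms:
        for i, pocket in enumerate(POCKET_IDS):
            if pocket in library.unused_pockets:
                continue
            key = tuple(repr(v) for v in pssm.matrix[i])
            sharing.setdefault(key, []).append((pssm.allele, pocket))
    return len(sharing), sharing
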