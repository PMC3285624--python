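"""Synthetic alleles, matrix libraries and benchmarks for desk-scale testing.

Real pocket-specificity libraries are experimentally derived and small;
real benchmarks are external downloads.  These generators build study-size
stand-ins whose key property — alleles with similar pocket pseudosequences
have similar pocket specificities — holds by construction:

* Allele sequences are mutants of one base sequence; ``similarity_level``
  is the probability that a polymorphic (pocket) position keeps the base
  residue.  Because pockets share positions (e.g. position 11 sits in
  P4-P7), residues are drawn on the full-length sequence, keeping
  overlapping pockets mutually consistent.
* An allele's "true" specificity vector at pocket p is a smooth function
  of its pseudosequence — the mean BLOSUM62 row of the pocket residues,
  halved — plus idiosyncratic Gaussian noise.  Similar pseudosequences
  therefore imply correlated matrices, with a realistic unexplained
  component.
* Benchmark binders carry a 9-mer core sampled position-wise with
  probability proportional to exp(specificity); decoys are uniform.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import numpy as np

from .alphabet import AMINO_ACIDS
from .evaluate import BenchmarkRecord
from .pockets import (
    POCKET_IDS,
    AlleleRecord,
    PocketTable,
    Pseudosequence,
    extract_pseudosequences,
)
from .pssm import PSSM, MatrixLibrary
from .similarity import SubstitutionMatrix

#: Length of generated aligned DRB sequences; covers every default pocket
#: position (max 89) with margin.
SEQUENCE_LENGTH = 95

DEFAULT_NOISE_SD = 0.5


def _blosum_rows(matrix: SubstitutionMatrix) -> np.ndarray:
    return np.array(
        [[matrix.score(a, b) for b in AMINO_ACIDS] for a in AMINO_ACIDS]
    )


def specificity_from_sequence(
    allele: AlleleRecord,
    matrix: SubstitutionMatrix,
    *,
    table: PocketTable | None = None,
    noise_sd: float = 0.0,
    rng: np.random.Generator | int | None = None,
    unused_pockets: frozenset[str] = frozenset(),
) -> PSSM:
    """The generator's ground-truth PSSM for one synthetic allele.

    Pocket p's vector is the mean BLOSUM62 row over the pocket's residues,
    divided by 2, plus optional N(0, noise_sd) noise per entry.
    """
    table = table or PocketTable()
    rng = np.random.default_rng(rng)
    rows = _blosum_rows(matrix)
    pseqs = extract_pseudosequences(allele, table)
    out = np.zeros((9, 20))
    for i, pocket in enumerate(POCKET_IDS):
        if pocket in unused_pockets:
            continue
        idx = [AMINO_ACIDS.index(aa) for aa in pseqs[pocket].residues]
        vec = rows[idx].mean(axis=0) / 2.0
        if noise_sd > 0:
            vec = vec + rng.normal(0.0, noise_sd, size=20)
        out[i] = vec
    return PSSM(allele.name, out, unused_pockets)


def generate_alleles(
    n_alleles: int,
    similarity_level: float,
    rng: np.random.Generator | int | None = None,
    *,
    table: PocketTable | None = None,
    name_prefix: str = "DRB1*90",
) -> list[AlleleRecord]:
    """Generate aligned synthetic DRB allele sequences.

    Each allele keeps the shared base residue at every pocket position
    with probability *similarity_level*, otherwise mutates it uniformly.
    Names are drawn from an unassigned-looking series (``DRB1*90:01``...).
    """
    if n_alleles < 1:
        raise ValueError("n_alleles must be >= 1")
    if not 0 <= similarity_level <= 1:
        raise ValueError("similarity_level must be in [0, 1]")
    table = table or PocketTable()
    rng = np.random.default_rng(rng)
    aa = np.array(list(AMINO_ACIDS))
    base = rng.choice(20, size=SEQUENCE_LENGTH)
    polymorphic = [p - 1 for p in table.all_positions()]
    records = []
    for k in range(n_alleles):
        seq = base.copy()
        for pos in polymorphic:
            if rng.random() >= similarity_level:
                seq[pos] = rng.integers(20)
        records.append(
            AlleleRecord(
                name=f"{name_prefix}:{k + 1:02d}", sequence="".join(aa[seq])
            )
        )
    return records


def mutate_allele(
    record: AlleleRecord,
    keep_prob: float,
    rng: np.random.Generator | int | None = None,
    *,
    name: str,
    table: PocketTable | None = None,
) -> AlleleRecord:
    """A relative of *record*: each pocket position keeps its residue with
    probability *keep_prob*, else mutates uniformly.  Used to plant
    clusters of moderately similar alleles in a library."""
    if not 0 <= keep_prob <= 1:
        raise ValueError("keep_prob must be in [0, 1]")
    table = table or PocketTable()
    rng = np.random.default_rng(rng)
    seq = list(record.sequence)
    for pos in table.all_positions():
        if rng.random() >= keep_prob:
            seq[pos - 1] = AMINO_ACIDS[rng.integers(20)]
    return AlleleRecord(name=name, sequence="".join(seq))


def library_from_records(
    records: list[AlleleRecord],
    matrix: SubstitutionMatrix | None = None,
    *,
    table: PocketTable | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    rng: np.random.Generator | int | None = None,
    unused_pockets: frozenset[str] = frozenset(),
) -> MatrixLibrary:
    """Build a matrix library from allele records via their ground-truth
    specificities (see :func:`specificity_from_sequence`)."""
    rng = np.random.default_rng(rng)
    matrix = matrix or SubstitutionMatrix.blosum62()
    pssms = tuple(
        specificity_from_sequence(
            rec,
            matrix,
            table=table,
            noise_sd=noise_sd,
            rng=rng,
            unused_pockets=unused_pockets,
        )
        for rec in records
    )
    return MatrixLibrary(pssms, unused_pockets)


def generate_fixture_library(
    n_alleles: int,
    similarity_level: float,
    rng: np.random.Generator | int | None = None,
    *,
    table: PocketTable | None = None,
    matrix: SubstitutionMatrix | None = None,
    noise_sd: float = DEFAULT_NOISE_SD,
    unused_pockets: frozenset[str] = frozenset(),
) -> tuple[MatrixLibrary, list[AlleleRecord]]:
    """Generate a matrix library plus the matching allele sequences.

    Inter-allele pseudosequence similarity is controlled by
    *similarity_level* (1.0: all alleles identical at pocket positions;
    0.0: independent draws), and each allele's matrix follows its
    pseudosequence via :func:`specificity_from_sequence`, so library
    matrices are correlated exactly as strongly as the sequences are.
    """
    rng = np.random.default_rng(rng)
    records = generate_alleles(n_alleles, similarity_level, rng, table=table)
    library = library_from_records(
        records,
        matrix,
        table=table,
        noise_sd=noise_sd,
        rng=rng,
        unused_pockets=unused_pockets,
    )
    return library, records


def generate_fixture_benchmark(
    pssm: PSSM,
    n_binders: int,
    n_decoys: int,
    noise: float = 0.0,
    rng: np.random.Generator | int | None = None,
    *,
    peptide_length: int = 15,
) -> list[BenchmarkRecord]:
    """Generate a labeled benchmark from a generating PSSM.

    Binder cores are sampled residue-wise with probability proportional to
    ``exp(specificity)`` at each pocket and embedded at a random offset in
    uniform flanks; *noise* is the per-core-residue probability of
    replacement by a uniform residue.  Decoys are fully uniform peptides.
    """
    if n_binders < 1 or n_decoys < 1:
        raise ValueError("n_binders and n_decoys must be >= 1")
    if not 0 <= noise <= 1:
        raise ValueError("noise must be in [0, 1]")
    if peptide_length < 9:
        raise ValueError("peptide_length must be >= 9")
    rng = np.random.default_rng(rng)
    aa = np.array(list(AMINO_ACIDS))
    probs = np.exp(pssm.matrix)
    probs /= probs.sum(axis=1, keepdims=True)

    records = []
    for _ in range(n_binders):
        seq = rng.integers(20, size=peptide_length)
        offset = int(rng.integers(0, peptide_length - 9 + 1))
        for p in range(9):
            if rng.random() < noise:
                seq[offset + p] = rng.integers(20)
            else:
                seq[offset + p] = rng.choice(20, p=probs[p])
        records.append(
            BenchmarkRecord(
                allele=pssm.allele, peptide="".join(aa[seq]), label=1,
                source="synthetic-binder",
            )
        )
    for _ in range(n_decoys):
        seq = rng.integers(20, size=peptide_length)
        records.append(
            BenchmarkRecord(
                allele=pssm.allele, peptide="".join(aa[seq]), label=0,
                source="synthetic-decoy",
            )
        )
    return records


def planted_core_peptides(
    pssm: PSSM,
    n_peptides: int,
    rng: np.random.Generator | int | None = None,
    *,
    peptide_length: int = 15,
) -> list[tuple[str, int]]:
    """Peptides with strongly rewarded cores planted at known offsets.

    Each peptide carries, at a random offset, the 9-mer of per-pocket
    argmax residues of *pssm* (a core the scanner should find exactly),
    in uniform random flanks.  Returns (peptide, true_offset) pairs.
    """
    rng = np.random.default_rng(rng)
    aa = np.array(list(AMINO_ACIDS))
    best_core = pssm.matrix.argmax(axis=1)
    out = []
    for _ in range(n_peptides):
        seq = rng.integers(20, size=peptide_length)
        offset = int(rng.integers(0, peptide_length - 9 + 1))
        seq[offset : offset + 9] = best_core
        out.append(("".join(aa[seq]), offset))
    return out
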