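import numpy as np
import pytest

from pocketpan import (
    AMINO_ACIDS,
    AlleleRecord,
    MatrixLibrary,
    PSSM,
    PocketTable,
    SubstitutionMatrix,
    extract_pseudosequences,
)
from pocketpan.synthetic import SEQUENCE_LENGTH


@pytest.fixture(scope="session")
def blosum62() -> SubstitutionMatrix:
    return SubstitutionMatrix.blosum62()


@pytest.fixture(scope="session")
def pocket_table() -> PocketTable:
    return PocketTable()


def make_allele(name: str, residue: str = "A", length: int = SEQUENCE_LENGTH) -> AlleleRecord:
    return AlleleRecord(name, residue * length)


@pytest.fixture()
def distinct_library(pocket_table, blosum62):
    """A tie-free library: allele k carries AA k at every pocket position.

    No two alleles share any pocket pseudosequence, so the most-similar
    library allele is always unique.  Matrices are deterministic random
    values (seeded), with no masked pockets.
    """
    rng = np.random.default_rng(7)
    records, pssms = [], []
    for k in range(5):
        seq = list("G" * SEQUENCE_LENGTH)
        for pos in pocket_table.all_positions():
            seq[pos - 1] = AMINO_ACIDS[k]
        rec = AlleleRecord(f"DRB1*91:{k + 1:02d}", "".join(seq))
        records.append(rec)
        pssms.append(PSSM(rec.name, rng.normal(size=(9, 20)), frozenset()))
    library = MatrixLibrary(tuple(pssms), frozenset())
    pseqs = {r.name: extract_pseudosequences(r, pocket_table) for r in records}
    return library, records, pseqs
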