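"""Deriving pocket contact positions from MHC-II complex structures.

The pocket definitions used for pseudosequence extraction come from solved
HLA-DR/peptide complexes: an MHC residue belongs to pocket ``Pj`` if any
of its atoms lies within a distance cutoff (default 4.0 A, inclusive) of
any atom of the j-th binding-core residue.  Contacts are unioned over a
collection of complexes to give a robust pocket table.  By default only
heavy atoms participate in the distance test (hydrogens are rarely
resolved in crystal structures and would make the cutoff
resolution-dependent); set ``heavy_only=False`` to include all atoms.

Residue numbering in coordinate files does not always match mature-protein
numbering; a per-structure ``mhc_offset`` shifts structure numbering onto
the alignment (alignment position = structure number + offset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import cdist

from .pockets import POCKET_IDS, PocketTable, normalize_allele_name

DEFAULT_CUTOFF = 4.0
CORE_LENGTH = 9


@dataclass(frozen=True)
class ComplexRecord:
    """One solved HLA-DR/peptide complex with a known binding core."""

    pdb_id: str
    allele: str
    peptide: str
    core_start: int

    def __post_init__(self) -> None:
        if self.core_start < 0 or self.core_start + CORE_LENGTH > len(self.peptide):
            raise ValueError(
                f"{self.pdb_id}: core at {self.core_start} does not fit in "
                f"peptide of length {len(self.peptide)}"
            )

    @property
    def core(self) -> str:
        return self.peptide[self.core_start : self.core_start + CORE_LENGTH]


def load_complex_records(path: str | Path | None = None) -> list[ComplexRecord]:
    """Load complex records (bundled reference set of 32 DR complexes by default).

    TSV columns: pdb_id, allele, peptide, core_start.
    """
    if path is None:
        ref = resources.files("pocketpan.data") / "dr_complexes.tsv"
        text = ref.read_text()
        source = "bundled dr_complexes.tsv"
    else:
        text = Path(path).read_text()
        source = str(path)
    records = []
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("pdb_id\t"):
            continue
        fields = line.split("\t")
        if len(fields) != 4:
            raise ValueError(f"{source}:{lineno}: expected 4 columns, got {len(fields)}")
        records.append(
            ComplexRecord(
                pdb_id=fields[0],
                allele=normalize_allele_name(fields[1]),
                peptide=fields[2].upper(),
                core_start=int(fields[3]),
            )
        )
    if not records:
        raise ValueError(f"{source}: no complex records")
    return records


@dataclass(frozen=True)
class ContactRecord:
    """DRB positions contacting one core residue (pocket) in one structure."""

    pdb_id: str
    pocket: str
    positions: frozenset[int]


def read_structure(path: str | Path, structure_id: str = "complex"):
    """Parse a PDB-format coordinate file (first model is used downstream)."""
    parser = PDBParser(QUIET=True)
    return parser.get_structure(structure_id, str(path))


def _residue_coords(residue, heavy_only: bool) -> np.ndarray:
    coords = [
        atom.coord
        for atom in residue.get_atoms()
        if not (heavy_only and atom.element == "H")
    ]
    if not coords:
        raise ValueError(f"residue {residue.get_id()} has no usable atoms")
    return np.asarray(coords)


def find_contact_positions(
    structure,
    mhc_chain: str,
    peptide_chain: str,
    core_residue_ids: list[int],
    cutoff: float = DEFAULT_CUTOFF,
    *,
    heavy_only: bool = True,
    mhc_offset: int = 0,
    pdb_id: str = "complex",
) -> list[ContactRecord]:
    """Find, per pocket, the MHC residues contacting each binding-core residue.

    Parameters
    ----------
    core_residue_ids
        The 9 residue numbers (in *peptide_chain*'s own numbering) of the
        binding core, N- to C-terminal, mapping onto pockets P1..P9.
    cutoff
        Maximum inter-atomic distance in Angstrom; the boundary is
        inclusive (a pair at exactly the cutoff is a contact).
    mhc_offset
        Added to MHC residue numbers to convert structure numbering to
        mature-protein alignment numbering.
    """
    if cutoff <= 0:
        raise ValueError(f"cutoff must be positive, got {cutoff}")
    if len(core_residue_ids) != CORE_LENGTH:
        raise ValueError(
            f"need exactly {CORE_LENGTH} core residue ids, got {len(core_residue_ids)}"
        )
    model = next(structure.get_models())
    chains = {c.id: c for c in model.get_chains()}
    for cid in (mhc_chain, peptide_chain):
        if cid not in chains:
            raise ValueError(
                f"{pdb_id}: chain {cid!r} not present (has {sorted(chains)})"
            )
    # Water and other heteroatom records carry a non-blank hetero flag.
    mhc_residues = [r for r in chains[mhc_chain] if r.id[0] == " "]
    pep_residues = {r.id[1]: r for r in chains[peptide_chain] if r.id[0] == " "}

    mhc_coords = {}
    for res in mhc_residues:
        mhc_coords[res.id[1] + mhc_offset] = _residue_coords(res, heavy_only)

    records = []
    for pocket, res_id in zip(POCKET_IDS, core_residue_ids):
        if res_id not in pep_residues:
            raise ValueError(
                f"{pdb_id}: core residue {res_id} not resolved in chain "
                f"{peptide_chain!r}"
            )
        core_xyz = _residue_coords(pep_residues[res_id], heavy_only)
        positions = frozenset(
            pos
            for pos, xyz in mhc_coords.items()
            if cdist(xyz, core_xyz).min() <= cutoff
        )
        records.append(ContactRecord(pdb_id, pocket, positions))
    return records


def union_positions(records: list[ContactRecord]) -> PocketTable:
    """Union per-pocket contact positions over complexes into a PocketTable."""
    if not records:
        raise ValueError("no contact records to union")
    union: dict[str, set[int]] = {p: set() for p in POCKET_IDS}
    for rec in records:
        union[rec.pocket].update(rec.positions)
    empty = [p for p in POCKET_IDS if not union[p]]
    if empty:
        raise ValueError(
            f"no contacts observed for pocket(s) {empty}; cannot build a table"
        )
    return PocketTable({p: tuple(sorted(union[p])) for p in POCKET_IDS})


def contact_records_to_tsv(
    records: list[ContactRecord], path: str | Path, *, with_union: bool = True
) -> None:
    """Write per-complex contact rows (per-pocket columns) plus a union row."""
    by_pdb: dict[str, dict[str, frozenset[int]]] = {}
    for rec in records:
        by_pdb.setdefault(rec.pdb_id, {})[rec.pocket] = rec.positions
    lines = ["pdb_id\t" + "\t".join(POCKET_IDS)]
    for pdb_id, pockets in by_pdb.items():
        row = [pdb_id]
        for pocket in POCKET_IDS:
            positions = sorted(pockets.get(pocket, frozenset()))
            row.append(",".join(str(p) for p in positions))
        lines.append("\t".join(row))
    if with_union:
        try:
            table = union_positions(records)
        except ValueError as exc:
            warnings.warn(f"union row omitted: {exc}")
        else:
            row = ["union"] + [
                ",".join(str(p) for p in table.positions(pk)) for pk in POCKET_IDS
            ]
            lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")
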