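"""Binding-groove pocket definitions and pocket pseudosequences.

The HLA-DR peptide-binding groove has nine pockets, P1..P9, each formed by
a handful of polymorphic residues of the DRB beta-1 domain.  A pocket's
*pseudosequence* is the string of amino acids an allele carries at those
contact positions; it is the pocket's sequence fingerprint, used downstream
to measure how similar two alleles' pockets are.

Positions are 1-based mature-DRB-protein numbering.  Allele sequences are
expected pre-aligned to that numbering (sequence character ``k-1`` is
position ``k``); multiple sequence alignment of raw database entries is
out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from .alphabet import AA_INDEX

POCKET_IDS: tuple[str, ...] = (
    "P1", "P2", "P3", "P4", "P5", "P6", "P7", "P8", "P9",
)

#: Default pocket -> DRB contact positions, derived as the union of
#: peptide-contact residues (heavy-atom distance <= 4 A) over 32 solved
#: HLA-DR/peptide complex structures.
DEFAULT_POCKET_POSITIONS: dict[str, tuple[int, ...]] = {
    "P1": (82, 85, 86, 89),
    "P2": (77, 78, 81, 82),
    "P3": (78,),
    "P4": (11, 13, 26, 28, 70, 71, 74, 78),
    "P5": (11, 13, 28, 70, 71, 74),
    "P6": (11, 13, 28, 30, 61, 71),
    "P7": (11, 28, 30, 47, 61, 67, 70, 71),
    "P8": (60, 61),
    "P9": (9, 30, 37, 57, 60, 61),
}

_MAX_POSITION = 120


@dataclass(frozen=True)
class PocketTable:
    """Mapping from pocket id to the ordered DRB positions that form it."""

    entries: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(DEFAULT_POCKET_POSITIONS)
    )

    def __post_init__(self) -> None:
        if tuple(self.entries.keys()) != POCKET_IDS:
            raise ValueError(
                f"pocket table must define exactly {POCKET_IDS}, "
                f"got {tuple(self.entries.keys())}"
            )
        for pocket, positions in self.entries.items():
            if not positions:
                raise ValueError(f"pocket {pocket} has no positions")
            if list(positions) != sorted(set(positions)):
                raise ValueError(
                    f"pocket {pocket} positions must be strictly increasing: "
                    f"{positions}"
                )
            if positions[0] < 1 or positions[-1] > _MAX_POSITION:
                raise ValueError(
                    f"pocket {pocket} positions out of range 1..{_MAX_POSITION}: "
                    f"{positions}"
                )

    def positions(self, pocket: str) -> tuple[int, ...]:
        return tuple(self.entries[pocket])

    def all_positions(self) -> tuple[int, ...]:
        """Sorted union of positions over all nine pockets."""
        return tuple(sorted({p for ps in self.entries.values() for p in ps}))

    def max_position(self) -> int:
        return max(ps[-1] for ps in self.entries.values())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PocketTable":
        """Read a table: one row per pocket, ``pocket<TAB>pos,pos,...``."""
        entries: dict[str, tuple[int, ...]] = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                pocket, pos_field = line.split("\t")
                positions = tuple(int(p) for p in pos_field.split(","))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row: {line!r}") from exc
            if pocket in entries:
                raise ValueError(f"{path}:{lineno}: duplicate pocket {pocket}")
            entries[pocket] = positions
        ordered = {p: entries[p] for p in POCKET_IDS if p in entries}
        if len(ordered) != len(entries):
            unknown = set(entries) - set(POCKET_IDS)
            raise ValueError(f"{path}: unknown pocket ids {sorted(unknown)}")
        return cls(ordered)

    def to_tsv(self, path: str | Path) -> None:
        lines = [
            f"{pocket}\t{','.join(str(p) for p in self.entries[pocket])}"
            for pocket in POCKET_IDS
        ]
        Path(path).write_text("\n".join(lines) + "\n")


_ALLELE_RE = re.compile(
    r"^(?:HLA-)?(DRB\d)\*?(\d{2,}(?::\d{2,})*[NLSCAQ]?)$", re.IGNORECASE
)


def normalize_allele_name(raw: str) -> str:
    """Normalize an HLA-DRB allele name to current colon-delimited nomenclature.

    Accepts current names (``DRB1*01:01``), legacy digit-run names
    (``DRB1*0101`` -> ``DRB1*01:01``) and an optional ``HLA-`` prefix.

    Raises
    ------
    ValueError
        If *raw* cannot be parsed as a DRB allele name.
    """
    if not raw or not raw.strip():
        raise ValueError("empty allele name")
    token = raw.strip()
    match = _ALLELE_RE.match(token)
    if match is None:
        raise ValueError(f"unparseable HLA-DRB allele name: {token!r}")
    gene = match.group(1).upper()
    fields_part = match.group(2).upper()
    suffix = ""
    if fields_part[-1].isalpha():
        suffix, fields_part = fields_part[-1], fields_part[:-1]
    if ":" in fields_part:
        fields = fields_part.split(":")
    else:
        # Legacy digit run: split into two-digit fields (4-digit "0101",
        # 6-digit "010101", ...); odd lengths are not valid legacy names.
        if len(fields_part) % 2 != 0 or len(fields_part) < 4:
            raise ValueError(
                f"cannot split legacy allele designation {fields_part!r} "
                f"in {token!r} into two-digit fields"
            )
        fields = [fields_part[i : i + 2] for i in range(0, len(fields_part), 2)]
    if any(len(f) < 2 for f in fields):
        raise ValueError(f"allele field too short in {token!r}")
    return f"{gene}*{':'.join(fields)}{suffix}"


@dataclass(frozen=True)
class AlleleRecord:
    """A DRB allele: normalized name plus aligned beta-1-domain sequence."""

    name: str
    sequence: str

    def residue_at(self, position: int) -> str:
        """Amino acid at 1-based mature-protein *position*."""
        if position < 1 or position > len(self.sequence):
            raise ValueError(
                f"allele {self.name}: position {position} outside sequence "
                f"of length {len(self.sequence)}"
            )
        return self.sequence[position - 1]


@dataclass(frozen=True)
class Pseudosequence:
    """Amino acids of one allele at one pocket's contact positions."""

    pocket: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


def extract_pseudosequences(
    allele: AlleleRecord, table: PocketTable | None = None
) -> dict[str, Pseudosequence]:
    """Extract the nine pocket pseudosequences of *allele*.

    Residue ``i`` of pocket ``p``'s pseudosequence is the allele's amino
    acid at the ``i``-th contact position of ``p``.  A gap or unknown
    character at a required position is an error: no pseudosequence, and
    hence no pocket similarity, can be formed from it.
    """
    table = table or PocketTable()
    out: dict[str, Pseudosequence] = {}
    for pocket in POCKET_IDS:
        chars = []
        for pos in table.positions(pocket):
            aa = allele.residue_at(pos)
            if aa not in AA_INDEX:
                raise ValueError(
                    f"allele {allele.name}: non-standard residue {aa!r} at "
                    f"position {pos} required by pocket {pocket}"
                )
            chars.append(aa)
        out[pocket] = Pseudosequence(pocket, "".join(chars))
    return out


def read_allele_fasta(
    path: str | Path, *, normalize: bool = True
) -> list[AlleleRecord]:
    """Read aligned DRB sequences from FASTA; header word one is the allele name."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id.split()[0]
        if normalize:
            name = normalize_allele_name(name)
        records.append(AlleleRecord(name=name, sequence=str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_allele_fasta(records: Iterable[AlleleRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.name}\n{rec.sequence}\n")
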