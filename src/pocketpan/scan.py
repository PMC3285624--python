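"""Peptide scoring, binding-core location and motif sampling.

A class II binding peptide is typically 11-20 residues long but binds
through a 9-residue core seated in the groove, one residue per pocket.
The scanner scores every 9-mer window of a peptide against a PSSM (sum of
the pocket entries for the window's residues) and reports the maximal
window as the predicted binding core; ties go to the leftmost offset.
Unknown residues ('X') contribute zero, so peptides transcribed from
structures with unresolved termini scan verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .alphabet import AA_INDEX, AMINO_ACIDS
from .pockets import POCKET_IDS
from .pssm import PSSM

CORE_LENGTH = 9


def score_window(pssm: PSSM, nonamer: str) -> float:
    """Score one 9-mer: sum over pockets of the entry for its residue there."""
    if len(nonamer) != CORE_LENGTH:
        raise ValueError(f"window must be length {CORE_LENGTH}, got {len(nonamer)!r}")
    total = 0.0
    for p, aa in enumerate(nonamer):
        idx = AA_INDEX.get(aa)
        if idx is not None:
            total += pssm.matrix[p, idx]
    return total


@dataclass(frozen=True)
class ScanResult:
    """All 9-mer window scores of one peptide plus the best (core) window."""

    peptide: str
    window_scores: tuple[float, ...]
    core_start: int
    name: str | None = None

    @property
    def best_score(self) -> float:
        return self.window_scores[self.core_start]

    @property
    def core(self) -> str:
        return self.peptide[self.core_start : self.core_start + CORE_LENGTH]


def scan_peptide(pssm: PSSM, peptide: str, *, name: str | None = None) -> ScanResult:
    """Score all 9-mer windows of *peptide*; the best one is the predicted core."""
    if len(peptide) < CORE_LENGTH:
        raise ValueError(
            f"peptide must be at least {CORE_LENGTH} residues, "
            f"got {len(peptide)}: {peptide!r}"
        )
    scores = tuple(
        score_window(pssm, peptide[i : i + CORE_LENGTH])
        for i in range(len(peptide) - CORE_LENGTH + 1)
    )
    core_start = int(np.argmax(scores))  # argmax takes the first maximum
    return ScanResult(peptide, scores, core_start, name=name)


def scan_peptides(
    pssm: PSSM, peptides: Iterable[tuple[str | None, str]]
) -> list[ScanResult]:
    """Scan (name, peptide) pairs, preserving input order."""
    return [scan_peptide(pssm, pep, name=name) for name, pep in peptides]


def read_peptides(path: str | Path) -> list[tuple[str | None, str]]:
    """Read peptides from FASTA or one-peptide-per-line text."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    return [
        (None, line.strip().upper())
        for line in text.splitlines()
        if line.strip() and not line.startswith("#")
    ]


def results_to_frame(results: Sequence[ScanResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [r.name or f"peptide_{i + 1}" for i, r in enumerate(results)],
            "peptide": [r.peptide for r in results],
            "score": [r.best_score for r in results],
            "core_start": [r.core_start for r in results],
            "core": [r.core for r in results],
        }
    )


@dataclass(frozen=True)
class MotifMatrix:
    """Position frequency matrix of sampled high-scoring cores.

    ``frequencies`` is 9 x 20 (pocket x amino acid); each row sums to 1.
    ``n_generated`` / ``n_selected`` record the sampling depth.
    """

    frequencies: np.ndarray
    n_generated: int
    n_selected: int

    def __post_init__(self) -> None:
        freq = np.asarray(self.frequencies, dtype=float)
        if freq.shape != (CORE_LENGTH, 20):
            raise ValueError(f"motif matrix must be 9x20, got {freq.shape}")
        if not np.allclose(freq.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("motif rows must each sum to 1")
        object.__setattr__(self, "frequencies", freq)

    def frequency(self, position: int, aa: str) -> float:
        """Frequency of *aa* at 1-based core position (pocket) *position*."""
        return float(self.frequencies[position - 1, AA_INDEX[aa]])

    def to_tsv(self, path: str | Path) -> None:
        lines = ["pocket\t" + "\t".join(AMINO_ACIDS)]
        for i, pocket in enumerate(POCKET_IDS):
            row = "\t".join(f"{v:.6g}" for v in self.frequencies[i])
            lines.append(f"{pocket}\t{row}")
        Path(path).write_text("\n".join(lines) + "\n")


def sample_motif(
    pssm: PSSM,
    n_peptides: int = 100_000,
    top_fraction: float = 0.01,
    length: int = CORE_LENGTH,
    rng: np.random.Generator | int | None = None,
    background: np.ndarray | None = None,
) -> MotifMatrix:
    """Estimate the binding motif by scoring random peptides.

    Draws *n_peptides* random peptides of *length* residues from the
    background amino-acid distribution (uniform unless given), scores each
    against *pssm*, keeps the top *top_fraction* by best-window score, and
    tallies per-pocket residue frequencies of the predicted cores.  With
    the default length of 9 the core is the whole peptide.  The resulting
    frequency matrix is the input expected by sequence-logo renderers.
    """
    if n_peptides < 100:
        raise ValueError("n_peptides must be at least 100")
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    if length < CORE_LENGTH:
        raise ValueError(f"peptide length must be >= {CORE_LENGTH}")
    rng = np.random.default_rng(rng)
    if background is None:
        background = np.full(20, 1 / 20)
    else:
        background = np.asarray(background, dtype=float)
        if background.shape != (20,):
            raise ValueError("background must have 20 frequencies")
        if np.count_nonzero(background) < 2:
            raise ValueError("degenerate background: needs at least 2 residues")
        background = background / background.sum()

    codes = rng.choice(20, size=(n_peptides, length), p=background)
    # Vectorized sliding-window scoring over the integer-coded peptides.
    n_windows = length - CORE_LENGTH + 1
    scores = np.full((n_peptides, n_windows), 0.0)
    for w in range(n_windows):
        window = codes[:, w : w + CORE_LENGTH]
        scores[:, w] = pssm.matrix[np.arange(CORE_LENGTH), window].sum(axis=1)
    best = scores.max(axis=1)
    core_start = scores.argmax(axis=1)

    n_selected = int(np.ceil(top_fraction * n_peptides))
    top = np.argsort(-best, kind="stable")[:n_selected]
    counts = np.zeros((CORE_LENGTH, 20))
    for i in top:
        core = codes[i, core_start[i] : core_start[i] + CORE_LENGTH]
        counts[np.arange(CORE_LENGTH), core] += 1
    return MotifMatrix(counts / counts.sum(axis=1, keepdims=True), n_peptides, n_selected)
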