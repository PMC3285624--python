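"""Benchmark evaluation: AUC, paired binomial tests, core-location errors.

The conventions follow standard immunoinformatics benchmarking practice:

* AUC is the Mann-Whitney statistic — the probability that a random binder
  outscores a random non-binder, ties counted one half.
* Quantitative affinities (IC50, nM) are binarized with an inclusive
  threshold: binder iff affinity <= threshold.  Common thresholds are
  100 nM for tight-binding alleles and 1000 nM otherwise.
* Two methods are compared per allele with a one-tailed exact binomial
  (sign) test on win/loss counts, ties excluded.
* Binding-core predictions are judged by exact position: any shift,
  however small, counts as an error.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.metrics import roc_auc_score

from .pockets import AlleleRecord, extract_pseudosequences, normalize_allele_name
from .pssm import MatrixLibrary, synthesize_pssm
from .scan import ScanResult, scan_peptide
from .similarity import SimilarityConfig, SubstitutionMatrix


@dataclass(frozen=True)
class BenchmarkRecord:
    """One measured peptide: allele, sequence, label and/or affinity."""

    allele: str
    peptide: str
    label: int | None = None
    affinity_nM: float | None = None
    source: str | None = None

    def __post_init__(self) -> None:
        if self.affinity_nM is not None and self.affinity_nM <= 0:
            raise ValueError(
                f"affinity must be positive, got {self.affinity_nM} for "
                f"{self.peptide}"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


def read_benchmark_tsv(path: str | Path) -> list[BenchmarkRecord]:
    """Read a benchmark table: columns allele, peptide, then label and/or
    affinity_nM (header required)."""
    df = pd.read_csv(path, sep="\t")
    required = {"allele", "peptide"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: benchmark needs columns {sorted(required)}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            BenchmarkRecord(
                allele=normalize_allele_name(str(row.allele)),
                peptide=str(row.peptide).upper(),
                label=int(row.label) if "label" in df.columns and pd.notna(row.label) else None,
                affinity_nM=float(row.affinity_nM)
                if "affinity_nM" in df.columns and pd.notna(row.affinity_nM)
                else None,
            )
        )
    return records


def write_benchmark_tsv(records: Sequence[BenchmarkRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "allele": [r.allele for r in records],
            "peptide": [r.peptide for r in records],
            "label": [r.label for r in records],
            "affinity_nM": [r.affinity_nM for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def threshold_labels(
    records: Sequence[BenchmarkRecord],
    threshold_nM: float | Mapping[str, float],
) -> list[BenchmarkRecord]:
    """Binarize affinities: binder iff affinity <= threshold (inclusive).

    *threshold_nM* may be one value or a per-allele mapping, so mixed
    100 nM / 1000 nM benchmarks are supported.
    """
    out = []
    for rec in records:
        if rec.affinity_nM is None:
            raise ValueError(f"record {rec.peptide} ({rec.allele}) has no affinity")
        thr = (
            threshold_nM[rec.allele]
            if isinstance(threshold_nM, Mapping)
            else threshold_nM
        )
        out.append(
            BenchmarkRecord(
                allele=rec.allele,
                peptide=rec.peptide,
                label=int(rec.affinity_nM <= thr),
                affinity_nM=rec.affinity_nM,
                source=rec.source,
            )
        )
    return out


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve (Mann-Whitney statistic, ties one half)."""
    labels = np.asarray(labels)
    if len(labels) != len(scores):
        raise ValueError("scores and labels differ in length")
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def per_allele_binomial(wins: int, losses: int) -> float:
    """One-tailed exact binomial test on win/loss counts (ties pre-excluded).

    Returns P(X >= wins) for X ~ Binomial(wins + losses, 1/2): the
    probability, under no real difference, of the first method winning at
    least this often.
    """
    if wins < 0 or losses < 0:
        raise ValueError("wins and losses must be non-negative")
    n = wins + losses
    if n == 0:
        raise ValueError("binomial test undefined: all comparisons were ties")
    return float(binom.sf(wins - 1, n, 0.5))


@dataclass(frozen=True)
class CoreTruthRecord:
    """Experimentally determined binding core of one peptide."""

    record_id: str
    allele: str
    peptide: str
    core_start: int

    def __post_init__(self) -> None:
        if not 0 <= self.core_start <= len(self.peptide) - 9:
            raise ValueError(
                f"{self.record_id}: core offset {self.core_start} does not "
                f"fit peptide of length {len(self.peptide)}"
            )

    @property
    def core(self) -> str:
        return self.peptide[self.core_start : self.core_start + 9]


def core_error_count(
    results: Sequence[ScanResult], truth: Sequence[CoreTruthRecord]
) -> tuple[int, pd.DataFrame]:
    """Count exact-position binding-core errors.

    A prediction is an error iff its core offset differs from the true
    offset — a one-residue shift is as wrong as any other.  Returns the
    total and a per-record report.
    """
    if len(results) != len(truth):
        raise ValueError("one scan result per truth record required")
    rows = []
    for res, tru in zip(results, truth):
        if res.peptide != tru.peptide:
            raise ValueError(
                f"{tru.record_id}: scanned peptide {res.peptide!r} does not "
                f"match truth peptide {tru.peptide!r}"
            )
        rows.append(
            {
                "record_id": tru.record_id,
                "allele": tru.allele,
                "peptide": tru.peptide,
                "true_start": tru.core_start,
                "predicted_start": res.core_start,
                "error": res.core_start != tru.core_start,
            }
        )
    report = pd.DataFrame(rows)
    return int(report["error"].sum()), report


def evaluate_per_allele(
    records: Sequence[BenchmarkRecord],
    scores: Sequence[float],
) -> pd.DataFrame:
    """Per-allele AUC report: columns allele, count, binder, auc.

    Alleles where only one class is present get auc = NaN rather than an
    error, so heterogeneous benchmarks evaluate end to end.
    """
    if len(records) != len(scores):
        raise ValueError("one score per benchmark record required")
    df = pd.DataFrame(
        {
            "allele": [r.allele for r in records],
            "label": [r.label for r in records],
            "score": list(scores),
        }
    )
    if df["label"].isna().any():
        raise ValueError("all records must be labeled (use threshold_labels)")
    rows = []
    for allele, grp in df.groupby("allele", sort=True):
        try:
            value = auc(grp["score"].to_numpy(), grp["label"].to_numpy())
        except ValueError:
            value = float("nan")
        rows.append(
            {
                "allele": allele,
                "count": len(grp),
                "binder": int(grp["label"].sum()),
                "auc": value,
            }
        )
    return pd.DataFrame(rows)


def score_benchmark(
    pssm_by_allele: Mapping[str, "object"],
    records: Sequence[BenchmarkRecord],
) -> list[float]:
    """Best-window score of each benchmark peptide under its allele's PSSM."""
    scores = []
    for rec in records:
        pssm = pssm_by_allele[rec.allele]
        scores.append(scan_peptide(pssm, rec.peptide).best_score)
    return scores


def alpha_sweep(
    library: MatrixLibrary,
    library_records: Sequence[AlleleRecord],
    queries: Sequence[tuple[AlleleRecord, Sequence[BenchmarkRecord]]],
    alphas: Sequence[float] = (1, 2, 3, 5, 9, 10, 20, 50),
    matrix: SubstitutionMatrix | None = None,
) -> pd.DataFrame:
    """AUC of synthesized PSSMs over a grid of alpha values plus 1-KNN.

    For each (query allele, labeled benchmark) pair, a PSSM is synthesized
    at every alpha (and with the most-similar-pocket rule, column
    ``1-KNN``) and the benchmark AUC recorded.  A final ``mean`` row
    averages over query alleles — the form in which the weighting exponent
    is usually chosen.
    """
    matrix = matrix or SubstitutionMatrix.blosum62()
    lib_pseqs = {rec.name: extract_pseudosequences(rec) for rec in library_records}
    columns = [str(a) for a in alphas] + ["1-KNN"]
    rows = {}
    for query, bench in queries:
        labels = [r.label for r in bench]
        row = {}
        for alpha in alphas:
            pssm, _ = synthesize_pssm(
                query, library, lib_pseqs, SimilarityConfig(alpha=alpha, matrix=matrix)
            )
            row[str(alpha)] = auc(
                [scan_peptide(pssm, r.peptide).best_score for r in bench], labels
            )
        pssm, _ = synthesize_pssm(
            query, library, lib_pseqs, SimilarityConfig(matrix=matrix), mode="1-knn"
        )
        row["1-KNN"] = auc(
            [scan_peptide(pssm, r.peptide).best_score for r in bench], labels
        )
        rows[query.name] = row
    table = pd.DataFrame(rows).T[columns]
    table.loc["mean"] = table.mean(axis=0)
    return table
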