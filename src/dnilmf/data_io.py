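"""Reading, writing and construction of drug-target interaction data.

The canonical on-disk layout is the tab-delimited matrix format of the
Yamanishi benchmark files: the first row holds target identifiers, the
first column drug identifiers, and each cell of the interaction matrix
is 0 or 1.  Similarity matrices use the same layout with matching row
and column identifiers.

Besides plain file I/O this module builds the two similarity matrices
the pipeline can construct on its own: Tanimoto similarity from binary
fingerprints and a k-mer spectrum kernel from protein sequences.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


class FormatError(ValueError):
    """Raised when an input file does not follow the expected layout."""


@dataclass
class DTIDataset:
    """A drug-target interaction dataset.

    Attributes
    ----------
    drug_ids, target_ids
        Ordered, duplicate-free identifier lists.
    Y
        Binary interaction matrix, drugs on rows, targets on columns.
    S_cs
        Drug-drug chemical-structure similarity, values in [0, 1].
    S_ts
        Target-target sequence similarity, values in [0, 1].
    """

    drug_ids: list[str]
    target_ids: list[str]
    Y: np.ndarray
    S_cs: np.ndarray | None = None
    S_ts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.Y = np.asarray(self.Y, dtype=float)
        if self.Y.shape != (len(self.drug_ids), len(self.target_ids)):
            raise ValueError(
                f"Y shape {self.Y.shape} does not match "
                f"{len(self.drug_ids)} drugs x {len(self.target_ids)} targets"
            )
        if not np.isin(self.Y, (0.0, 1.0)).all():
            raise ValueError("interaction matrix entries must be 0 or 1")
        for ids, label in ((self.drug_ids, "drug"), (self.target_ids, "target")):
            if len(ids) != len(set(ids)):
                raise ValueError(f"duplicate {label} identifiers")
        for S, n, label in (
            (self.S_cs, len(self.drug_ids), "S_cs"),
            (self.S_ts, len(self.target_ids), "S_ts"),
        ):
            if S is not None:
                _validate_similarity(np.asarray(S, dtype=float), n, label)

    @property
    def n_drugs(self) -> int:
        return len(self.drug_ids)

    @property
    def n_targets(self) -> int:
        return len(self.target_ids)


@dataclass
class PredictionTable:
    """Scored drug-target pairs ranked by descending score.

    Ties are broken by drug identifier then target identifier so a
    listing is reproducible run to run.
    """

    records: list[dict] = field(default_factory=list)

    @classmethod
    def from_scores(
        cls,
        drug_ids: Sequence[str],
        target_ids: Sequence[str],
        scores: Sequence[float],
        known: Sequence[bool],
    ) -> "PredictionTable":
        rows = [
            {"drug_id": d, "target_id": t, "score": float(s), "known": bool(k)}
            for d, t, s, k in zip(drug_ids, target_ids, scores, known, strict=True)
        ]
        rows.sort(key=lambda r: (-r["score"], r["drug_id"], r["target_id"]))
        for rank, row in enumerate(rows, start=1):
            row["rank"] = rank
        table = cls(records=rows)
        table.validate()
        return table

    def validate(self) -> None:
        scores = [r["score"] for r in self.records]
        if any(not (0.0 <= s <= 1.0) for s in scores):
            raise ValueError("scores must lie in [0, 1]")
        ranks = [r["rank"] for r in self.records]
        if ranks != list(range(1, len(self.records) + 1)):
            raise ValueError("ranks must be 1..N in order")
        if scores != sorted(scores, reverse=True):
            raise ValueError("records must be in descending score order")

    def __len__(self) -> int:
        return len(self.records)


def _validate_similarity(S: np.ndarray, n: int, label: str, tol: float = 1e-6) -> None:
    if S.shape != (n, n):
        raise ValueError(f"{label} must be {n}x{n}, got {S.shape}")
    if np.abs(S - S.T).max(initial=0.0) > 1e-8:
        raise ValueError(f"{label} not symmetric within 1e-8")
    if S.size and (S.min() < -tol or S.max() > 1 + tol):
        raise ValueError(f"{label} entries outside [0, 1]")
    if S.size and np.abs(np.diag(S) - 1.0).max() > tol:
        raise ValueError(f"{label} diagonal must be 1")


def _read_matrix(path: str | Path, header: bool = True) -> tuple[pd.DataFrame, list[str], list[str]]:
    path = Path(path)
    if header:
        df = pd.read_csv(path, sep="\t", index_col=0)
        row_ids = [str(i) for i in df.index]
        col_ids = [str(c) for c in df.columns]
    else:
        df = pd.read_csv(path, sep="\t", header=None)
        row_ids = [f"r{i}" for i in range(df.shape[0])]
        col_ids = [f"c{j}" for j in range(df.shape[1])]
    if df.isna().any().any():
        raise FormatError(f"{path}: ragged rows or missing cells")
    return df, row_ids, col_ids


def read_interaction_matrix(path: str | Path, header: bool = True) -> DTIDataset:
    """Read a binary drug x target adjacency matrix.

    Rows are drugs, columns are targets.  Every cell must parse as 0 or
    1; the offending row/column is named otherwise.
    """
    df, drug_ids, target_ids = _read_matrix(path, header=header)
    values = df.to_numpy()
    try:
        Y = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric cell ({exc})") from exc
    bad = ~np.isin(Y, (0.0, 1.0))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise FormatError(
            f"{path}: non-binary value {Y[i, j]!r} at drug {drug_ids[i]!r}, "
            f"target {target_ids[j]!r}"
        )
    return DTIDataset(drug_ids=drug_ids, target_ids=target_ids, Y=Y)


def read_similarity_matrix(
    path: str | Path, header: bool = True
) -> tuple[np.ndarray, list[str]]:
    """Read a square similarity matrix; returns ``(S, ids)``.

    The matrix is symmetrized as ``(S + S.T) / 2``; the maximum
    asymmetry found before symmetrization is reported via logging.
    """
    df, row_ids, col_ids = _read_matrix(path, header=header)
    if row_ids != col_ids:
        raise FormatError(f"{path}: row/column identifiers differ")
    S = df.to_numpy(dtype=float)
    asym = np.abs(S - S.T).max(initial=0.0)
    if asym > 0:
        logger.info("%s: max asymmetry %.3g before symmetrization", path, asym)
    S = (S + S.T) / 2.0
    if S.size and (S.min() < -1e-6 or S.max() > 1 + 1e-6):
        raise ValueError(f"{path}: similarity values outside [0, 1]")
    return np.clip(S, 0.0, 1.0), row_ids


def write_interaction_matrix(path: str | Path, ds: DTIDataset) -> None:
    df = pd.DataFrame(ds.Y.astype(int), index=ds.drug_ids, columns=ds.target_ids)
    df.to_csv(path, sep="\t")


def write_similarity_matrix(path: str | Path, S: np.ndarray, ids: Sequence[str]) -> None:
    pd.DataFrame(S, index=list(ids), columns=list(ids)).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def distance_to_similarity(D: np.ndarray) -> np.ndarray:
    """Convert a distance matrix in [0, 1] to a similarity matrix as 1 - D."""
    D = np.asarray(D, dtype=float)
    if D.size and (D.min() < 0 or D.max() > 1):
        raise ValueError("distance entries must lie in [0, 1]")
    return 1.0 - D


def tanimoto_similarity(F: np.ndarray) -> np.ndarray:
    """Tanimoto (Jaccard) similarity between binary fingerprint rows.

    ``S[i, j] = c / (a + b - c)`` with ``a``, ``b`` the bit counts of
    molecules i and j and ``c`` the shared-bit count.  An all-zero
    fingerprint gets similarity 0 to everything and 1 to itself.
    """
    F = np.asarray(F, dtype=float)
    if not np.isin(F, (0.0, 1.0)).all():
        raise ValueError("fingerprint matrix must be binary")
    counts = F.sum(axis=1)
    if (counts == 0).any():
        warnings.warn("all-zero fingerprint(s); similarity defined as 0", stacklevel=2)
    common = F @ F.T
    denom = counts[:, None] + counts[None, :] - common
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, common / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(S, 1.0)
    return S


def _kmer_counts(seq: str, k: int) -> dict[str, int]:
    valid = set(AMINO_ACIDS)
    counts: dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        # k-mers containing ambiguous residues (B, Z, X, U, O, ...) are
        # skipped to keep the feature space at 20^k
        if set(kmer) <= valid:
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


def spectrum_kernel(sequences: Sequence[str], k: int = 3) -> np.ndarray:
    """Cosine-normalized k-mer spectrum kernel between protein sequences.

    The raw kernel is the dot product of k-mer count vectors; it is
    normalized so the diagonal equals 1.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences given")
    for i, s in enumerate(seqs):
        if len(s) < k:
            raise ValueError(f"sequence {i} shorter than k={k}: {s!r}")
    counts = [_kmer_counts(s, k) for s in seqs]
    n = len(seqs)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            dot = sum(c * counts[j].get(m, 0) for m, c in counts[i].items())
            K[i, j] = K[j, i] = dot
    norms = np.sqrt(np.diag(K))
    if (norms == 0).any():
        bad = int(np.argmax(norms == 0))
        raise ValueError(f"sequence {bad} has no valid {k}-mers")
    K = K / np.outer(norms, norms)
    np.fill_diagonal(K, 1.0)
    return K


def read_fasta_sequences(path: str | Path) -> tuple[list[str], list[str]]:
    """Read a protein FASTA file; returns ``(ids, sequences)``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    return [r.id for r in records], [str(r.seq) for r in records]


def dataset_summary(ds: DTIDataset) -> dict:
    """Counts and sparsity (known interactions / all possible pairs)."""
    n_int = int(ds.Y.sum())
    sparsity = n_int / (ds.n_drugs * ds.n_targets) if ds.Y.size else 0.0
    return {
        "n_drugs": ds.n_drugs,
        "n_targets": ds.n_targets,
        "n_interactions": n_int,
        "sparsity": sparsity,
        "sparsity_3dp": round(sparsity, 3),
    }


def write_dataset_summary(path: str | Path, ds: DTIDataset) -> None:
    with open(path, "w") as fh:
        json.dump(dataset_summary(ds), fh, indent=2)
        fh.write("\n")


def write_predictions(table: PredictionTable, path: str | Path) -> None:
    """Write a prediction table as CSV with a fixed header."""
    table.validate()
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["drug_id", "target_id", "score", "rank", "known"])
        for r in table.records:
            writer.writerow(
                [r["drug_id"], r["target_id"], f"{r['score']:.6f}", r["rank"],
                 int(r["known"])]
            )


def read_predictions(path: str | Path) -> PredictionTable:
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                {
                    "drug_id": rec["drug_id"],
                    "target_id": rec["target_id"],
                    "score": float(rec["score"]),
                    "rank": int(rec["rank"]),
                    "known": bool(int(rec["known"])),
                }
            )
    return PredictionTable(records=rows)


def read_fingerprint_matrix(path: str | Path, header: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a binary fingerprint matrix (molecules x bits)."""
    df, row_ids, _ = _read_matrix(path, header=header)
    F = df.to_numpy(dtype=float)
    if not np.isin(F, (0.0, 1.0)).all():
        raise FormatError(f"{path}: fingerprint cells must be 0/1")
    return F, row_ids


def pairs_product(drug_ids: Sequence[str], target_ids: Sequence[str]):
    """All (drug, target) pairs in row-major order."""
    return list(product(drug_ids, target_ids))
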