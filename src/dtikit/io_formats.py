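"""Readers and writers for the standard DTI inputs and the feature-matrix artifact.

Input formats: FASTA protein sequences, PSI-BLAST ASCII PSSM profiles,
delimited 881-bit fingerprint tables, and two-column drug/protein
interaction lists.  The feature-matrix artifact is a plain CSV with a
``pair_id,label,<feature names...>`` header that round-trips losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The 20 standard amino acids in alphabetical one-letter order.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

#: Dummy residue used to right-pad short sequences to a fixed length.
DUMMY_AA = "O"

#: Full alphabet accepted on input: 20 standard residues plus the dummy 'O'.
ALPHABET = STANDARD_AA + DUMMY_AA

#: Number of substructure bits in a PubChem-style fingerprint.
FINGERPRINT_LENGTH = 881


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein with an amino-acid sequence over the 21-letter alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: sequence must be non-empty")
        for pos, letter in enumerate(self.sequence):
            if letter not in ALPHABET:
                raise ParseError(
                    f"protein {self.id!r}: disallowed letter {letter!r} "
                    f"at position {pos + 1}"
                )


@dataclass(frozen=True)
class DrugRecord:
    """A drug identified by an 881-bit binary substructure fingerprint."""

    id: str
    fingerprint: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("drug id must be non-empty")
        if len(self.fingerprint) != FINGERPRINT_LENGTH:
            raise ParseError(
                f"drug {self.id!r}: fingerprint has {len(self.fingerprint)} bits, "
                f"expected {FINGERPRINT_LENGTH}"
            )
        if any(b not in (0, 1) for b in self.fingerprint):
            raise ParseError(f"drug {self.id!r}: fingerprint entries must be 0 or 1")


@dataclass
class PSSMMatrix:
    """Position-specific scoring matrix: L rows x 20 integer substitution scores."""

    protein_id: str
    scores: np.ndarray
    row_residues: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"PSSM for {self.protein_id!r}: expected L x 20 matrix, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] < 1:
            raise ValueError(f"PSSM for {self.protein_id!r}: needs at least one row")
        if not np.issubdtype(self.scores.dtype, np.integer):
            if not np.all(self.scores == np.round(self.scores)):
                raise ValueError(f"PSSM for {self.protein_id!r}: scores must be integers")
            self.scores = self.scores.astype(np.int64)

    @property
    def length(self) -> int:
        return self.scores.shape[0]


@dataclass
class InteractionList:
    """Unique (drug_id, protein_id) pairs known to interact."""

    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[tuple[str, str]] = []
        for drug_id, protein_id in self.pairs:
            if not drug_id or not protein_id:
                raise ValueError("interaction ids must be non-empty")
            key = (drug_id, protein_id)
            if key not in seen:
                seen.add(key)
                unique.append(key)
        self.pairs = unique

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in set(self.pairs)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into protein records.

    Wrapped sequence lines are concatenated and uppercased; any letter
    outside the 21-letter alphabet raises :class:`ParseError` naming the
    record and 1-based position.  An empty file yields an empty list.
    """
    records: list[ProteinRecord] = []
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"protein {current_id!r}: empty sequence")
        records.append(ProteinRecord(current_id, seq))

    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                current_id = line[1:].split()[0] if line[1:].strip() else ""
                if not current_id:
                    raise ParseError("FASTA header with empty id")
                chunks = []
            else:
                if current_id is None:
                    raise ParseError("sequence data before first FASTA header")
                chunks.append(line.upper())
    flush()
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write protein records as FASTA, wrapping sequences at ``width`` columns."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for start in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[start : start + width] + "\n")


def read_pssm(path: str | Path, protein_id: str | None = None) -> PSSMMatrix:
    """Read a PSI-BLAST ASCII PSSM profile.

    Header and trailer lines are skipped; each data row carries a 1-based
    position index, the residue letter, and at least 20 integer scores
    (PSI-BLAST files often carry 40 columns; only the first 20 are kept).
    """
    path = Path(path)
    rows: list[list[int]] = []
    residues: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        fields = line.split()
        # data rows start with an integer position index then a residue letter
        if len(fields) < 2 or not fields[0].isdigit() or len(fields[1]) != 1 or not fields[1].isalpha():
            continue
        numeric = fields[2:]
        if len(numeric) < 20:
            raise ParseError(f"{path.name}:{lineno}: PSSM row has fewer than 20 score columns")
        try:
            scores = [int(tok) for tok in numeric[:20]]
        except ValueError as exc:
            raise ParseError(f"{path.name}:{lineno}: non-integer PSSM score") from exc
        rows.append(scores)
        residues.append(fields[1].upper())
    if not rows:
        raise ParseError(f"{path.name}: no PSSM data rows found")
    return PSSMMatrix(
        protein_id=protein_id or path.stem,
        scores=np.array(rows, dtype=np.int64),
        row_residues="".join(residues),
    )


def write_pssm(pssm: PSSMMatrix, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII dialect (header + indexed rows)."""
    with open(path, "w") as handle:
        handle.write("\n")
        handle.write("Last position-specific scoring matrix computed\n")
        handle.write("            " + "   ".join(STANDARD_AA) + "\n")
        residues = pssm.row_residues or "A" * pssm.length
        for i, row in enumerate(pssm.scores):
            vals = " ".join(f"{int(v):4d}" for v in row)
            handle.write(f"{i + 1:5d} {residues[i]} {vals}\n")


def read_fingerprints(path: str | Path, delimiter: str | None = None) -> list[DrugRecord]:
    """Read a delimited fingerprint table: drug id then 881 binary columns.

    The delimiter is sniffed (comma vs tab/whitespace) unless given.  A
    header row is auto-detected: if the second field of the first line is
    not 0/1 the line is treated as a header and skipped.
    """
    path = Path(path)
    records: list[DrugRecord] = []
    lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
    if not lines:
        return records

    def split(line: str) -> list[str]:
        if delimiter is not None:
            return [f.strip() for f in line.split(delimiter)]
        if "," in line:
            return [f.strip() for f in line.split(",")]
        return line.split()

    start = 0
    first = split(lines[0])
    if len(first) >= 2 and first[1] not in ("0", "1"):
        start = 1  # header row
    for lineno, line in enumerate(lines[start:], start=start + 1):
        fields = split(line)
        drug_id, bits = fields[0], fields[1:]
        if len(bits) != FINGERPRINT_LENGTH:
            raise ParseError(
                f"{path.name}:{lineno}: drug {drug_id!r} has {len(bits)} fingerprint "
                f"columns, expected {FINGERPRINT_LENGTH}"
            )
        values = []
        for b in bits:
            if b not in ("0", "1"):
                raise ParseError(
                    f"{path.name}:{lineno}: drug {drug_id!r} has non-binary entry {b!r}"
                )
            values.append(int(b))
        records.append(DrugRecord(drug_id, tuple(values)))
    return records


def write_fingerprints(drugs: Iterable[DrugRecord], path: str | Path) -> None:
    """Write drug fingerprints as a headerless CSV table (id + 881 bits)."""
    with open(path, "w") as handle:
        for drug in drugs:
            handle.write(drug.id + "," + ",".join(str(b) for b in drug.fingerprint) + "\n")


def read_interactions(path: str | Path) -> InteractionList:
    """Read a two-column (drug_id, protein_id) interaction list.

    Blank lines are ignored, duplicates collapsed; the unique pair count
    is reported via the module logger.
    """
    path = Path(path)
    pairs: list[tuple[str, str]] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ParseError(
                f"{path.name}:{lineno}: expected 2 fields (drug_id protein_id), "
                f"got {len(fields)}"
            )
        pairs.append((fields[0], fields[1]))
    interactions = InteractionList(pairs)
    logger.info("read %d unique interaction pairs from %s", len(interactions), path)
    return interactions


def write_interactions(interactions: InteractionList, path: str | Path) -> None:
    with open(path, "w") as handle:
        for drug_id, protein_id in interactions:
            handle.write(f"{drug_id}\t{protein_id}\n")


def write_feature_matrix(
    X: np.ndarray,
    feature_names: Sequence[str],
    pair_ids: Sequence[str],
    labels: Sequence[int],
    path: str | Path,
) -> None:
    """Write a labeled feature matrix as CSV with header ``pair_id,label,...``."""
    names = list(feature_names)
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate feature column names: {dupes[:5]}")
    df = pd.DataFrame(np.asarray(X), columns=names)
    df.insert(0, "label", list(labels))
    df.insert(0, "pair_id", list(pair_ids))
    # repr of a Python float is its shortest exact decimal form, so the
    # round trip with read_feature_matrix is lossless
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def _exact(path: str | Path) -> pd.DataFrame:
    # the default fast float parser can be one ULP off; round_trip parses
    # exactly, keeping the matrix artifact lossless
    return pd.read_csv(path, float_precision="round_trip")


def read_feature_matrix(path: str | Path) -> tuple[np.ndarray, list[str], list[str], np.ndarray]:
    """Read the CSV feature-matrix artifact back.

    Returns ``(X, feature_names, pair_ids, labels)``; the round trip with
    :func:`write_feature_matrix` is lossless to full float precision.
    """
    df = _exact(path)
    if list(df.columns[:2]) != ["pair_id", "label"]:
        raise ParseError(f"{path}: expected 'pair_id,label,...' header")
    pair_ids = df["pair_id"].astype(str).tolist()
    labels = df["label"].to_numpy(dtype=int)
    feature_names = list(df.columns[2:])
    X = df[feature_names].to_numpy(dtype=float)
    return X, feature_names, pair_ids, labels
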