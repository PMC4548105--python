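"""File formats for the pair-prediction pipeline.

Protein sequences travel as FASTA, conserved-domain annotations as a
6-column TSV modelled on NCBI Batch CD-Search hit tables, interaction
pairs as 2-column TSV, and predictions as 4-column TSV.  All readers
validate invariants eagerly so downstream code can assume clean data.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("rtkpair")

#: Default E-value retention bound for domain hits.
DEFAULT_E_CUTOFF = 1.0e-8

DOMAIN_HIT_COLUMNS = ["protein_id", "domain_acc", "superfamily_acc", "e_value", "start", "end"]
PAIR_COLUMNS = ["receptor_id", "ligand_id"]
PREDICTION_COLUMNS = ["receptor_id", "ligand_id", "decision_value", "predicted_label"]


class SeqIOError(ValueError):
    """Malformed or inconsistent input file."""


class Role(str, enum.Enum):
    """Which half of a pair a protein plays."""

    RECEPTOR = "receptor"
    LIGAND = "ligand"


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with its pairing role.

    Sequences are stored uppercased; the canonical 20 letters plus the
    ambiguity codes X, B, Z, U, O, J are accepted on input (non-canonical
    letters are handled at featurization time).
    """

    id: str
    role: Role
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("protein id must be nonempty")
        if not self.sequence:
            raise SeqIOError(f"protein {self.id!r}: sequence must be nonempty")


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain match on one protein.

    Coordinates are 1-based inclusive, following CD-Search convention.
    They are carried for provenance but featurization uses presence/absence
    only.
    """

    protein_id: str
    domain_acc: str
    superfamily_acc: str
    e_value: float
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.e_value < 0 or not math.isfinite(self.e_value):
            raise SeqIOError(
                f"hit {self.domain_acc} on {self.protein_id}: e_value must be finite and >= 0"
            )
        if not (1 <= self.start <= self.end):
            raise SeqIOError(
                f"hit {self.domain_acc} on {self.protein_id}: "
                f"need 1 <= start <= end, got start={self.start}, end={self.end}"
            )


@dataclass(frozen=True)
class PairExample:
    """A (receptor, ligand) instance with a binary interaction label."""

    receptor_id: str
    ligand_id: str
    label: int

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise SeqIOError(f"pair ({self.receptor_id}, {self.ligand_id}): label must be 0 or 1")

    @property
    def key(self) -> tuple[str, str]:
        return (self.receptor_id, self.ligand_id)


def read_fasta(path: str | Path, role: Role) -> list[ProteinRecord]:
    """Read a FASTA file, applying ``role`` to every record.

    Ids are the first whitespace-delimited token of each header; sequences
    are uppercased.  Duplicate ids and empty sequences are errors.
    """
    role = Role(role)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    with open(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if rec.id in seen:
                raise SeqIOError(f"{path}: duplicate protein id {rec.id!r}")
            seq = str(rec.seq).upper()
            if not seq:
                raise SeqIOError(f"{path}: empty sequence for id {rec.id!r}")
            seen.add(rec.id)
            records.append(ProteinRecord(id=rec.id, role=role, sequence=seq))
    return records


def write_fasta(path: str | Path, records: Iterable[ProteinRecord], width: int = 60) -> None:
    """Write records as wrapped FASTA (deterministic layout)."""
    with open(path, "w") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                handle.write(rec.sequence[i : i + width] + "\n")


def _read_tsv(path: str | Path, columns: Sequence[str]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise SeqIOError(f"{path}: file is empty (expected a header row)") from None
    if list(df.columns) != list(columns):
        raise SeqIOError(
            f"{path}: expected columns {list(columns)}, found {list(df.columns)}"
        )
    return df


def read_domain_hits(path: str | Path, e_cutoff: float = DEFAULT_E_CUTOFF) -> list[DomainHit]:
    """Read a 6-column domain-hit TSV, keeping hits with e_value <= e_cutoff.

    The cutoff is a retention bound (search-tool convention); row order is
    preserved.  Malformed rows raise with their 1-based data line number.
    """
    if e_cutoff < 0:
        raise SeqIOError("e_cutoff must be nonnegative")
    df = _read_tsv(path, DOMAIN_HIT_COLUMNS)
    hits: list[DomainHit] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        try:
            hit = DomainHit(
                protein_id=row.protein_id,
                domain_acc=row.domain_acc,
                superfamily_acc=row.superfamily_acc,
                e_value=float(row.e_value),
                start=int(row.start),
                end=int(row.end),
            )
        except (ValueError, SeqIOError) as exc:
            raise SeqIOError(f"{path}: line {i}: {exc}") from None
        if hit.e_value <= e_cutoff:
            hits.append(hit)
    return hits


def write_domain_hits(path: str | Path, hits: Iterable[DomainHit]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(DOMAIN_HIT_COLUMNS) + "\n")
        for h in hits:
            handle.write(
                f"{h.protein_id}\t{h.domain_acc}\t{h.superfamily_acc}\t"
                f"{h.e_value:.6g}\t{h.start}\t{h.end}\n"
            )


def read_pairs(path: str | Path) -> list[PairExample]:
    """Read a 2-column (receptor_id, ligand_id) TSV as positive pairs."""
    df = _read_tsv(path, PAIR_COLUMNS)
    pairs: list[PairExample] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        key = (row.receptor_id, row.ligand_id)
        if key in seen:
            raise SeqIOError(f"{path}: line {i}: duplicate pair {key}")
        seen.add(key)
        pairs.append(PairExample(receptor_id=key[0], ligand_id=key[1], label=1))
    return pairs


def write_pairs(path: str | Path, pairs: Iterable[PairExample]) -> None:
    with open(path, "w") as handle:
        handle.write("\t".join(PAIR_COLUMNS) + "\n")
        for p in pairs:
            handle.write(f"{p.receptor_id}\t{p.ligand_id}\n")


def write_predictions(
    path: str | Path,
    pairs: Sequence[PairExample],
    scores: Sequence[float],
    labels: Sequence[int],
) -> None:
    """Write (receptor_id, ligand_id, decision_value, predicted_label) rows.

    Row order is input order; decision values are printed to 6 decimal
    places so a read/write round trip recovers them at that precision.
    """
    if not (len(pairs) == len(scores) == len(labels)):
        raise SeqIOError(
            f"length mismatch: {len(pairs)} pairs, {len(scores)} scores, {len(labels)} labels"
        )
    with open(path, "w") as handle:
        handle.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for p, s, y in zip(pairs, scores, labels):
            handle.write(f"{p.receptor_id}\t{p.ligand_id}\t{s:.6f}\t{int(y)}\n")


def read_predictions(path: str | Path) -> tuple[list[PairExample], list[float], list[int]]:
    """Inverse of :func:`write_predictions` (pairs carry the predicted label)."""
    df = _read_tsv(path, PREDICTION_COLUMNS)
    pairs, scores, labels = [], [], []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            score = float(row.decision_value)
            label = int(row.predicted_label)
        except ValueError as exc:
            raise SeqIOError(f"{path}: line {i}: {exc}") from None
        pairs.append(PairExample(receptor_id=row.receptor_id, ligand_id=row.ligand_id, label=label))
        scores.append(score)
        labels.append(label)
    return pairs, scores, labels


def check_cross_references(
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit] = (),
    pairs: Sequence[PairExample] = (),
) -> None:
    """Validate that hits and pairs refer to known proteins with the right roles."""
    by_id = {p.id: p for p in proteins}
    if len(by_id) != len(proteins):
        raise SeqIOError("duplicate protein ids across the dataset")
    for h in hits:
        if h.protein_id not in by_id:
            raise SeqIOError(f"domain hit references unknown protein {h.protein_id!r}")
    for pair in pairs:
        rec = by_id.get(pair.receptor_id)
        lig = by_id.get(pair.ligand_id)
        if rec is None or rec.role is not Role.RECEPTOR:
            raise SeqIOError(f"pair {pair.key}: {pair.receptor_id!r} is not a known receptor")
        if lig is None or lig.role is not Role.LIGAND:
            raise SeqIOError(f"pair {pair.key}: {pair.ligand_id!r} is not a known ligand")
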