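"""Labelled pair datasets: redundancy reduction, negatives, weights, splits.

Negative pairs are enumerated exhaustively as the receptor x ligand cross
product minus the known positives, so the class imbalance (e.g. 95
positives against 2183 negatives on a 34 x 67 dataset) is a property of
the data, not of a sampling step.  Redundancy reduction uses a greedy
representative-based clustering under a full-length global-alignment
identity criterion (identity >= 80% over the whole alignment by default)
— a deterministic stand-in for BLASTclust-style clustering, not a
bit-exact clone of it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import Align
from sklearn.model_selection import StratifiedKFold

from . import seqio
from .seqio import DomainHit, PairExample, ProteinRecord, Role


class DatasetError(ValueError):
    pass


@dataclass(frozen=True)
class ClusteringCriteria:
    """Identity threshold over the full-length alignment (coverage fixed at 1)."""

    identity_threshold: float = 0.80
    coverage: float = 1.0

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "coverage"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise DatasetError(f"{name} must be in (0, 1], got {v}")


@dataclass(frozen=True)
class ClassWeights:
    """Per-class misclassification weights compensating imbalance."""

    w_pos: float
    w_neg: float

    def __post_init__(self) -> None:
        if self.w_pos <= 0 or self.w_neg <= 0:
            raise DatasetError("class weights must be positive")


def _make_aligner() -> Align.PairwiseAligner:
    # match=1 / mismatch=0 with a linear gap penalty of -1: gaps are only
    # opened when they buy at least one extra identical column.
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -1.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of identical columns in an end-to-end global alignment.

    Identity = identical columns / total alignment columns (gap columns
    included), which realises a 100%-coverage criterion.  Symmetric by
    construction: arguments are ordered canonically before aligning.
    """
    if not seq_a or not seq_b:
        raise DatasetError("cannot align an empty sequence")
    if seq_b < seq_a:
        seq_a, seq_b = seq_b, seq_a
    alignment = _ALIGNER.align(seq_a, seq_b)[0]
    top, bottom = str(alignment[0]), str(alignment[1])
    identical = sum(1 for x, y in zip(top, bottom) if x == y and x != "-")
    return identical / len(top)


def cluster_redundant(
    proteins: Sequence[ProteinRecord],
    criteria: ClusteringCriteria = ClusteringCriteria(),
) -> tuple[list[list[str]], list[str]]:
    """Greedy representative-based redundancy clustering within one role.

    Proteins are visited longest-first (ties broken by id); each joins the
    first existing cluster whose representative is at least
    ``identity_threshold`` identical to it, otherwise founds a new cluster
    with itself as representative.  Returns (clusters, representatives),
    parallel lists in founding order.
    """
    roles = {p.role for p in proteins}
    if len(roles) > 1:
        raise DatasetError("cluster_redundant expects proteins of a single role")
    order = sorted(proteins, key=lambda p: (-len(p.sequence), p.id))
    clusters: list[list[str]] = []
    representatives: list[ProteinRecord] = []
    for p in order:
        for cluster, rep in zip(clusters, representatives):
            if pairwise_identity(p.sequence, rep.sequence) >= criteria.identity_threshold:
                cluster.append(p.id)
                break
        else:
            clusters.append([p.id])
            representatives.append(p)
    return clusters, [r.id for r in representatives]


def generate_negatives(
    receptors: Sequence[str],
    ligands: Sequence[str],
    positives: Sequence[PairExample],
) -> list[PairExample]:
    """All (receptor, ligand) combinations minus positives, labelled 0.

    Enumeration is lexicographic in (receptor_id, ligand_id), so the
    result is deterministic and has size |R|*|L| - |positives|.
    """
    rset, lset = set(receptors), set(ligands)
    pos_keys = set()
    for p in positives:
        if p.receptor_id not in rset or p.ligand_id not in lset:
            raise DatasetError(f"positive pair {p.key} references an unknown id")
        pos_keys.add(p.key)
    if len(pos_keys) != len(positives):
        raise DatasetError("duplicate positive pairs")
    return [
        PairExample(receptor_id=r, ligand_id=l, label=0)
        for r in sorted(rset)
        for l in sorted(lset)
        if (r, l) not in pos_keys
    ]


def class_weights(n_pos: int, n_neg: int) -> ClassWeights:
    """Weights proportional to the opposite class's size: w_pos = n_neg/n_pos."""
    if n_pos < 1 or n_neg < 1:
        raise DatasetError(f"both classes must be nonempty, got {n_pos} / {n_neg}")
    return ClassWeights(w_pos=n_neg / n_pos, w_neg=1.0)


def stratified_kfold(
    pairs: Sequence[PairExample], n_folds: int = 5, seed: int = 0
) -> np.ndarray:
    """Per-pair fold index (0..n_folds-1); per-class counts balanced to +-1."""
    labels = np.array([p.label for p in pairs])
    for cls in (0, 1):
        if int((labels == cls).sum()) < n_folds:
            raise DatasetError(
                f"class {cls} has fewer than n_folds={n_folds} examples"
            )
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignment = np.empty(len(pairs), dtype=int)
    for fold, (_, test_idx) in enumerate(splitter.split(np.zeros(len(pairs)), labels)):
        assignment[test_idx] = fold
    return assignment


def holdout_split(
    pairs: Sequence[PairExample], fraction: float = 0.2, seed: int = 0
) -> tuple[list[PairExample], list[PairExample]]:
    """Stratified holdout with floor(fraction * class size) per class held out.

    The floor matches the convention of holding out 436 of 2183 negatives
    at fraction 0.2.  Returns (train, test); both preserve input order.
    """
    if not (0 < fraction < 1):
        raise DatasetError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    test_idx: set[int] = set()
    for cls in (0, 1):
        idx = [i for i, p in enumerate(pairs) if p.label == cls]
        n_test = math.floor(fraction * len(idx))
        if n_test == 0 or n_test == len(idx):
            raise DatasetError(
                f"degenerate split for class {cls}: {n_test} of {len(idx)} held out"
            )
        chosen = rng.permutation(len(idx))[:n_test]
        test_idx.update(idx[i] for i in chosen)
    train = [p for i, p in enumerate(pairs) if i not in test_idx]
    test = [p for i, p in enumerate(pairs) if i in test_idx]
    return train, test


@dataclass
class PairDataset:
    """Proteins, retained domain hits and the fully labelled pair list."""

    proteins: list[ProteinRecord]
    hits: list[DomainHit]
    pairs: list[PairExample]

    def __post_init__(self) -> None:
        seqio.check_cross_references(self.proteins, self.hits, self.pairs)

    @property
    def labels(self) -> np.ndarray:
        return np.array([p.label for p in self.pairs])

    @property
    def receptors(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.role is Role.RECEPTOR]

    @property
    def ligands(self) -> list[ProteinRecord]:
        return [p for p in self.proteins if p.role is Role.LIGAND]

    @classmethod
    def from_files(
        cls,
        receptor_fasta: str | Path,
        ligand_fasta: str | Path,
        hits_tsv: str | Path,
        positives_tsv: str | Path,
        e_cutoff: float = seqio.DEFAULT_E_CUTOFF,
        cluster: bool = False,
        criteria: ClusteringCriteria = ClusteringCriteria(),
    ) -> "PairDataset":
        """Assemble a dataset: read, optionally cluster per role, enumerate negatives.

        With ``cluster=True`` each role is redundancy-reduced independently
        and only representative proteins (and positives between them) are
        kept.
        """
        receptors = seqio.read_fasta(receptor_fasta, Role.RECEPTOR)
        ligands = seqio.read_fasta(ligand_fasta, Role.LIGAND)
        hits = seqio.read_domain_hits(hits_tsv, e_cutoff=e_cutoff)
        positives = seqio.read_pairs(positives_tsv)
        if cluster:
            _, rep_r = cluster_redundant(receptors, criteria)
            _, rep_l = cluster_redundant(ligands, criteria)
            receptors = [p for p in receptors if p.id in set(rep_r)]
            ligands = [p for p in ligands if p.id in set(rep_l)]
            keep = {p.id for p in receptors} | {p.id for p in ligands}
            positives = [p for p in positives if p.receptor_id in keep and p.ligand_id in keep]
            hits = [h for h in hits if h.protein_id in keep]
        negatives = generate_negatives(
            [p.id for p in receptors], [p.id for p in ligands], positives
        )
        return cls(proteins=receptors + ligands, hits=hits, pairs=list(positives) + negatives)

    def write_manifest(self, path: str | Path, folds: np.ndarray | None = None) -> None:
        """TSV manifest (receptor_id, ligand_id, label, fold); fold -1 if absent."""
        fold_col = folds if folds is not None else np.full(len(self.pairs), -1)
        df = pd.DataFrame(
            {
                "receptor_id": [p.receptor_id for p in self.pairs],
                "ligand_id": [p.ligand_id for p in self.pairs],
                "label": [p.label for p in self.pairs],
                "fold": fold_col,
            }
        )
        df.to_csv(path, sep="\t", index=False)
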