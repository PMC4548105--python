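"""Numeric representations of proteins and protein pairs.

Four per-protein recipes are supported: amino-acid k-mer relative
frequencies (k = 1 and 2 by default), and binary presence/absence vectors
over conserved-domain types or their superfamilies.  Pair vectors
concatenate the receptor block before the ligand block; a composite
vector concatenates two pair vectors built from different recipes.

k-mer vectors use relative frequencies: each coordinate is the count of
that k-mer among windows made solely of canonical letters, divided by the
number of such windows.  Windows containing an ambiguity code (X, B, Z,
U, O, J, ...) are excluded from both numerator and denominator, so the
20-letter basis never has to represent a letter outside it.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .seqio import DomainHit, ProteinRecord, Role

logger = logging.getLogger("rtkpair")

#: Canonical amino-acid alphabet in fixed lexicographic order.
CANONICAL_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

Recipe = Literal["kmer1", "kmer2", "domain", "superfamily", "composite"]

#: Recipe identifiers in presentation order.
RECIPES: tuple[str, ...] = ("kmer1", "kmer2", "domain", "superfamily", "composite")


class FeaturizeError(ValueError):
    pass


@dataclass(frozen=True)
class KmerConfig:
    """Window length and alphabet for k-mer featurization (dimension 20**k)."""

    k: int = 1
    alphabet: str = CANONICAL_ALPHABET

    def __post_init__(self) -> None:
        if self.k < 1:
            raise FeaturizeError(f"k must be >= 1, got {self.k}")
        if len(set(self.alphabet)) != len(self.alphabet):
            raise FeaturizeError("alphabet letters must be unique")

    @property
    def dimension(self) -> int:
        return len(self.alphabet) ** self.k

    def names(self) -> list[str]:
        return ["".join(t) for t in itertools.product(self.alphabet, repeat=self.k)]


@dataclass(frozen=True)
class FeatureVector:
    """A dense named vector tagged with the recipe that produced it."""

    values: np.ndarray
    names: tuple[str, ...]
    recipe: str

    def __post_init__(self) -> None:
        if len(self.values) != len(self.names):
            raise FeaturizeError(
                f"values/names length mismatch: {len(self.values)} vs {len(self.names)}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class DomainVocabulary:
    """Ordered domain/superfamily type lists defining binary-vector layouts.

    Receptor and ligand blocks use separate vocabularies, so an accession
    annotated on both roles occupies one coordinate in each block.  Lists
    are sorted lexicographically for a deterministic dimension order.
    """

    receptor_domains: tuple[str, ...]
    ligand_domains: tuple[str, ...]
    receptor_superfamilies: tuple[str, ...]
    ligand_superfamilies: tuple[str, ...]
    domain_to_superfamily: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("receptor_domains", "ligand_domains",
                     "receptor_superfamilies", "ligand_superfamilies"):
            entries = getattr(self, name)
            if list(entries) != sorted(set(entries)):
                raise FeaturizeError(f"{name} must be unique and lexicographically sorted")
        sfs = set(self.receptor_superfamilies) | set(self.ligand_superfamilies)
        for dom, sf in self.domain_to_superfamily.items():
            if sf not in sfs:
                raise FeaturizeError(
                    f"domain {dom!r} maps to superfamily {sf!r} absent from both superfamily lists"
                )

    def domains(self, role: Role) -> tuple[str, ...]:
        return self.receptor_domains if role is Role.RECEPTOR else self.ligand_domains

    def superfamilies(self, role: Role) -> tuple[str, ...]:
        return self.receptor_superfamilies if role is Role.RECEPTOR else self.ligand_superfamilies


def kmer_vector(sequence: str, config: KmerConfig) -> FeatureVector:
    """Relative k-mer frequencies of ``sequence`` over canonical-only windows.

    If no window is free of non-canonical letters the vector is all-zero
    and a warning is logged.
    """
    if not sequence:
        raise FeaturizeError("cannot featurize an empty sequence")
    k = config.k
    index = {c: i for i, c in enumerate(config.alphabet)}
    base = len(config.alphabet)
    counts = np.zeros(base**k)
    valid = 0
    for i in range(len(sequence) - k + 1):
        window = sequence[i : i + k]
        code = 0
        for c in window:
            j = index.get(c)
            if j is None:
                break
            code = code * base + j
        else:
            counts[code] += 1
            valid += 1
    if valid:
        counts /= valid
    else:
        logger.warning(
            "sequence of length %d has no valid %d-mer window; emitting all-zero vector",
            len(sequence), k,
        )
    return FeatureVector(values=counts, names=tuple(config.names()), recipe=f"kmer{k}")


def build_vocabulary(
    hits: Sequence[DomainHit], proteins: Sequence[ProteinRecord]
) -> DomainVocabulary:
    """Collect per-role domain and superfamily type lists from retained hits.

    Receptor lists come from hits on receptor-role proteins only, ligand
    lists from ligand-role hits; a domain accession annotated with two
    different superfamilies is an inconsistency error.
    """
    role_by_id = {p.id: p.role for p in proteins}
    domains: dict[Role, set[str]] = {Role.RECEPTOR: set(), Role.LIGAND: set()}
    superfamilies: dict[Role, set[str]] = {Role.RECEPTOR: set(), Role.LIGAND: set()}
    mapping: dict[str, str] = {}
    for h in hits:
        role = role_by_id.get(h.protein_id)
        if role is None:
            raise FeaturizeError(f"hit references unknown protein {h.protein_id!r}")
        prev = mapping.setdefault(h.domain_acc, h.superfamily_acc)
        if prev != h.superfamily_acc:
            raise FeaturizeError(
                f"domain {h.domain_acc!r} mapped to both superfamilies "
                f"{prev!r} and {h.superfamily_acc!r}"
            )
        domains[role].add(h.domain_acc)
        superfamilies[role].add(h.superfamily_acc)
    return DomainVocabulary(
        receptor_domains=tuple(sorted(domains[Role.RECEPTOR])),
        ligand_domains=tuple(sorted(domains[Role.LIGAND])),
        receptor_superfamilies=tuple(sorted(superfamilies[Role.RECEPTOR])),
        ligand_superfamilies=tuple(sorted(superfamilies[Role.LIGAND])),
        domain_to_superfamily=mapping,
    )


def domain_vector(
    protein_id: str,
    hits: Sequence[DomainHit],
    vocab: DomainVocabulary,
    level: Literal["domain", "superfamily"],
    role: Role,
) -> FeatureVector:
    """Binary presence/absence vector for one protein at the requested level.

    A coordinate is 1 iff the protein has at least one retained hit of
    that type; several domains of one superfamily still light a single
    superfamily coordinate.  Types seen on the protein but absent from
    the vocabulary (routine with fold-restricted vocabularies) are
    dropped with a logged warning.
    """
    role = Role(role)
    if level == "domain":
        universe = vocab.domains(role)
    elif level == "superfamily":
        universe = vocab.superfamilies(role)
    else:
        raise FeaturizeError(f"unknown level {level!r}")
    position = {acc: i for i, acc in enumerate(universe)}
    values = np.zeros(len(universe))
    for h in hits:
        if h.protein_id != protein_id:
            continue
        acc = h.domain_acc if level == "domain" else h.superfamily_acc
        i = position.get(acc)
        if i is None:
            logger.warning(
                "protein %s: %s type %r absent from vocabulary; ignored",
                protein_id, level, acc,
            )
            continue
        values[i] = 1.0
    return FeatureVector(values=values, names=tuple(universe), recipe=level)


def pair_vector(receptor_vec: FeatureVector, ligand_vec: FeatureVector) -> FeatureVector:
    """Concatenate receptor block then ligand block (recipes must match)."""
    if receptor_vec.recipe != ligand_vec.recipe:
        raise FeaturizeError(
            f"recipe mismatch: {receptor_vec.recipe!r} vs {ligand_vec.recipe!r}"
        )
    return FeatureVector(
        values=np.concatenate([receptor_vec.values, ligand_vec.values]),
        names=tuple(f"R:{n}" for n in receptor_vec.names)
        + tuple(f"L:{n}" for n in ligand_vec.names),
        recipe=receptor_vec.recipe,
    )


def composite_vector(vec_a: FeatureVector, vec_b: FeatureVector) -> FeatureVector:
    """Concatenate two pair-level vectors into a composite (a-block first)."""
    return FeatureVector(
        values=np.concatenate([vec_a.values, vec_b.values]),
        names=tuple(f"A:{n}" for n in vec_a.names) + tuple(f"B:{n}" for n in vec_b.names),
        recipe="composite",
    )


def protein_vector(
    protein: ProteinRecord,
    hits: Sequence[DomainHit],
    vocab: DomainVocabulary | None,
    recipe: str,
) -> FeatureVector:
    """Per-protein vector under any non-composite recipe."""
    if recipe == "kmer1":
        return kmer_vector(protein.sequence, KmerConfig(k=1))
    if recipe == "kmer2":
        return kmer_vector(protein.sequence, KmerConfig(k=2))
    if recipe in ("domain", "superfamily"):
        if vocab is None:
            raise FeaturizeError(f"recipe {recipe!r} requires a DomainVocabulary")
        return domain_vector(protein.id, hits, vocab, recipe, protein.role)
    raise FeaturizeError(f"unknown per-protein recipe {recipe!r}")


def pair_feature_matrix(
    pairs: Sequence,
    proteins: Sequence[ProteinRecord],
    hits: Sequence[DomainHit],
    vocab: DomainVocabulary | None,
    recipe: str,
) -> tuple[np.ndarray, tuple[str, ...]]:
    """Feature matrix (rows = pairs) for any recipe, composite included.

    The composite recipe is the 2-mer pair block followed by the
    superfamily pair block, matching the best-performing combination.
    Per-protein vectors are computed once and reused across pairs.
    """
    if recipe == "composite":
        xa, na = pair_feature_matrix(pairs, proteins, hits, vocab, "kmer2")
        xb, nb = pair_feature_matrix(pairs, proteins, hits, vocab, "superfamily")
        names = tuple(f"A:{n}" for n in na) + tuple(f"B:{n}" for n in nb)
        return np.hstack([xa, xb]), names
    if recipe not in ("kmer1", "kmer2", "domain", "superfamily"):
        raise FeaturizeError(f"unknown recipe {recipe!r}")
    by_id = {p.id: p for p in proteins}
    cache: dict[str, FeatureVector] = {}

    def vec(pid: str) -> FeatureVector:
        if pid not in cache:
            if pid not in by_id:
                raise FeaturizeError(f"pair references unknown protein {pid!r}")
            cache[pid] = protein_vector(by_id[pid], hits, vocab, recipe)
        return cache[pid]

    rows, names = [], None
    for p in pairs:
        pv = pair_vector(vec(p.receptor_id), vec(p.ligand_id))
        if names is None:
            names = pv.names
        rows.append(pv.values)
    if names is None:
        return np.zeros((0, 0)), ()
    return np.vstack(rows), names


def write_feature_matrix(
    path, pairs: Sequence, matrix: np.ndarray, names: Sequence[str]
) -> None:
    """Export a feature matrix as TSV (rows = pairs, named feature columns)."""
    df = pd.DataFrame(matrix, columns=list(names))
    df.insert(0, "receptor_id", [p.receptor_id for p in pairs])
    df.insert(1, "ligand_id", [p.ligand_id for p in pairs])
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")
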