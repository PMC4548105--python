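import numpy as np
import pytest

from rtkpair.dataset import PairDataset, generate_negatives
from rtkpair.seqio import DomainHit, PairExample, ProteinRecord, Role
from rtkpair.synthdata import GeneratorConfig, SyntheticBundle, generate


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """A 12x16 generator config small enough for fast end-to-end protocols."""
    return GeneratorConfig(
        n_receptors=12,
        n_ligands=16,
        n_receptor_domains=18,
        n_ligand_domains=22,
        n_receptor_superfamilies=7,
        n_ligand_superfamilies=9,
        domains_per_protein=(1, 3),
        positive_rate_target=0.15,
        sequence_length=(60, 200),
        seed=11,
    )


@pytest.fixture(scope="session")
def small_bundle(small_config) -> SyntheticBundle:
    return generate(small_config)


def bundle_to_dataset(bundle: SyntheticBundle) -> PairDataset:
    receptors = [p.id for p in bundle.proteins if p.role is Role.RECEPTOR]
    ligands = [p.id for p in bundle.proteins if p.role is Role.LIGAND]
    negatives = generate_negatives(receptors, ligands, bundle.positives)
    return PairDataset(
        proteins=bundle.proteins,
        hits=bundle.hits,
        pairs=list(bundle.positives) + negatives,
    )


@pytest.fixture(scope="session")
def small_dataset(small_bundle) -> PairDataset:
    return bundle_to_dataset(small_bundle)


@pytest.fixture
def toy_proteins() -> list[ProteinRecord]:
    return [
        ProteinRecord(id="R1", role=Role.RECEPTOR, sequence="ACDEFGHIKL"),
        ProteinRecord(id="R2", role=Role.RECEPTOR, sequence="MKVLWAALLV"),
        ProteinRecord(id="L1", role=Role.LIGAND, sequence="GGSSAATTNN"),
        ProteinRecord(id="L2", role=Role.LIGAND, sequence="PPQQRRSSVV"),
    ]


@pytest.fixture
def toy_hits() -> list[DomainHit]:
    return [
        DomainHit("R1", "d1", "SF1", 1e-20, 1, 5),
        DomainHit("R1", "d2", "SF1", 1e-15, 3, 8),
        DomainHit("R2", "d3", "SF2", 1e-12, 2, 6),
        DomainHit("L1", "d4", "SF3", 1e-30, 1, 4),
        DomainHit("L2", "d5", "SF4", 1e-9, 2, 9),
    ]


@pytest.fixture
def toy_pairs() -> list[PairExample]:
    return [
        PairExample("R1", "L1", 1),
        PairExample("R2", "L2", 1),
    ]
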