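import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from rtkpair import seqio
from rtkpair.dataset import generate_negatives
from rtkpair.model import SvmConfig
from rtkpair.seqio import Role
from rtkpair.synthdata import (
    GeneratorConfig,
    SynthError,
    generate,
    read_config_file,
    write_bundle,
)
from conftest import bundle_to_dataset


class TestConfig:
    def test_superfamily_counts_bounded_by_domain_counts(self):
        with pytest.raises(SynthError):
            GeneratorConfig(n_receptor_domains=5, n_receptor_superfamilies=6)

    def test_label_noise_range(self):
        with pytest.raises(SynthError):
            GeneratorConfig(label_noise=0.5)

    def test_explicit_empty_compatibility_with_positive_target_errors(self):
        with pytest.raises(SynthError):
            GeneratorConfig(compatibility=frozenset(), positive_rate_target=0.1)


class TestGenerate:
    def test_default_shape_reproduces_curated_dataset_counts(self):
        bundle = generate(GeneratorConfig(seed=3))
        receptors = [p for p in bundle.proteins if p.role is Role.RECEPTOR]
        ligands = [p for p in bundle.proteins if p.role is Role.LIGAND]
        assert (len(receptors), len(ligands)) == (34, 67)
        negatives = generate_negatives(
            [p.id for p in receptors], [p.id for p in ligands], bundle.positives
        )
        # 95 positives targeted -> 34*67 - 95 = 2183 negatives
        assert len(bundle.positives) == 95
        assert len(negatives) == 2183

    def test_labels_match_compatibility_rule_exactly_without_noise(self, small_bundle):
        sf_sets = {Role.RECEPTOR: {}, Role.LIGAND: {}}
        for h in small_bundle.hits:
            if h.e_value > 1e-8:
                continue  # decoys don't define ground truth
            role = Role.RECEPTOR if h.protein_id.startswith("R") else Role.LIGAND
            sf_sets[role].setdefault(h.protein_id, set()).add(
                int(h.superfamily_acc[3:]) - 1
            )
        for (rid, lid), true in small_bundle.true_labels.items():
            rset = sf_sets[Role.RECEPTOR].get(rid, set())
            lset = sf_sets[Role.LIGAND].get(lid, set())
            expected = int(
                any((a, b) in small_bundle.compatibility for a in rset for b in lset)
            )
            assert true == expected

    def test_observed_equals_true_when_noise_free(self, small_bundle):
        assert small_bundle.config.label_noise == 0.0
        assert small_bundle.observed_labels == small_bundle.true_labels

    def test_label_noise_flips_a_bounded_fraction(self, small_config):
        from dataclasses import replace

        noisy = generate(replace(small_config, label_noise=0.1))
        n = len(noisy.true_labels)
        flips = sum(
            noisy.true_labels[k] != noisy.observed_labels[k] for k in noisy.true_labels
        )
        assert 0 < flips < 0.25 * n

    def test_achieved_rate_near_target(self):
        for seed in (0, 1, 2):
            bundle = generate(GeneratorConfig(seed=seed))
            target = bundle.config.positive_rate_target
            assert abs(bundle.achieved_positive_rate - target) / target <= 0.2

    def test_zero_bias_sequences_are_composition_uniform(self):
        from dataclasses import replace

        bundle = generate(GeneratorConfig(seed=5, composition_bias=0.0, n_receptors=10,
                                          n_ligands=10, sequence_length=(500, 500)))
        counts = np.zeros(20)
        from rtkpair.featurize import CANONICAL_ALPHABET
        for p in bundle.proteins:
            for c in p.sequence:
                counts[CANONICAL_ALPHABET.index(c)] += 1
        freqs = counts / counts.sum()
        assert abs(freqs - 0.05).max() < 0.01  # near-uniform residue usage

    def test_same_seed_gives_identical_bundles(self, small_config, tmp_path):
        a = write_bundle(generate(small_config), tmp_path / "a")
        b = write_bundle(generate(small_config), tmp_path / "b")
        for key in a:
            assert a[key].read_bytes() == b[key].read_bytes()


class TestWriteBundle:
    def test_round_trip_through_standard_readers(self, small_bundle, tmp_path):
        paths = write_bundle(small_bundle, tmp_path)
        receptors = seqio.read_fasta(paths["receptors"], Role.RECEPTOR)
        ligands = seqio.read_fasta(paths["ligands"], Role.LIGAND)
        all_hits = seqio.read_domain_hits(paths["hits"], e_cutoff=math.inf)
        positives = seqio.read_pairs(paths["positives"])
        assert len(receptors) == small_bundle.config.n_receptors
        assert len(ligands) == small_bundle.config.n_ligands
        assert len(all_hits) == len(small_bundle.hits)  # infinite cutoff keeps all rows
        assert {p.key for p in positives} == {p.key for p in small_bundle.positives}
        seqio.check_cross_references(receptors + ligands, all_hits, positives)

    def test_no_compatibility_and_zero_target_give_header_only_positives(self, tmp_path):
        config = GeneratorConfig(
            n_receptors=5, n_ligands=5, n_receptor_domains=6, n_ligand_domains=6,
            n_receptor_superfamilies=3, n_ligand_superfamilies=3,
            positive_rate_target=0.0, sequence_length=(50, 80), seed=0,
        )
        paths = write_bundle(generate(config), tmp_path)
        assert paths["positives"].read_text() == "receptor_id\tligand_id\n"


class TestConfigFile:
    def test_flat_key_value_round_trip(self, tmp_path):
        path = tmp_path / "gen.cfg"
        path.write_text(
            "n_receptors = 8\nn_ligands = 9\n"
            "domains_per_protein = 1,3\nsequence_length = 50,100\n"
            "label_noise = 0.05\nseed = 4\n"
        )
        config = read_config_file(path)
        assert (config.n_receptors, config.n_ligands) == (8, 9)
        assert config.domains_per_protein == (1, 3)
        assert config.label_noise == 0.05

    def test_unknown_key_errors(self, tmp_path):
        path = tmp_path / "gen.cfg"
        path.write_text("nonsense = 1\n")
        with pytest.raises(SynthError, match="unknown key"):
            read_config_file(path)


def _protein_disjoint_kmer_auc(bias: float, seed: int) -> float:
    """2-mer AUC on pairs of proteins never seen in training.

    Pair-level CV lets an RBF SVM memorize each protein's unique k-mer
    fingerprint, which hides the composition-bias effect; holding out
    whole proteins isolates how much transferable sequence signal the
    generator actually planted.
    """
    from rtkpair.featurize import pair_feature_matrix
    from rtkpair.model import decision_values, train
    from rtkpair.evaluate import roc_auc

    config = GeneratorConfig(
        n_receptors=20, n_ligands=20, n_receptor_domains=6, n_ligand_domains=6,
        n_receptor_superfamilies=3, n_ligand_superfamilies=3,
        domains_per_protein=(1, 2), positive_rate_target=0.25,
        sequence_length=(200, 300), composition_bias=bias, seed=seed,
    )
    bundle = generate(config)
    ds = bundle_to_dataset(bundle)
    receptors = [p.id for p in bundle.proteins if p.role is Role.RECEPTOR]
    ligands = [p.id for p in bundle.proteins if p.role is Role.LIGAND]
    train_ids = set(receptors[:10]) | set(ligands[:10])
    test_ids = set(receptors[10:]) | set(ligands[10:])
    train_pairs = [p for p in ds.pairs
                   if p.receptor_id in train_ids and p.ligand_id in train_ids]
    test_pairs = [p for p in ds.pairs
                  if p.receptor_id in test_ids and p.ligand_id in test_ids]
    X_train, _ = pair_feature_matrix(train_pairs, ds.proteins, ds.hits, None, "kmer2")
    X_test, _ = pair_feature_matrix(test_pairs, ds.proteins, ds.hits, None, "kmer2")
    m = train(X_train, [p.label for p in train_pairs], SvmConfig(C=10.0, gamma=1.0))
    _, auc = roc_auc([p.label for p in test_pairs], decision_values(m, X_test))
    return auc


class TestSignalStrength:
    def test_kmer_auc_increases_with_composition_bias(self):
        """Stronger sequence-domain coupling raises transferable 2-mer AUC."""
        biases = [0.0, 0.45, 0.9]
        seeds = (21, 22, 23, 24, 25)
        mean_aucs = [
            np.mean([_protein_disjoint_kmer_auc(bias, s) for s in seeds])
            for bias in biases
        ]
        rho, _ = spearmanr(biases, mean_aucs)
        assert rho > 0
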