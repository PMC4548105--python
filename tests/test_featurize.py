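import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rtkpair.featurize import (
    CANONICAL_ALPHABET,
    DomainVocabulary,
    FeaturizeError,
    KmerConfig,
    build_vocabulary,
    composite_vector,
    domain_vector,
    kmer_vector,
    pair_feature_matrix,
    pair_vector,
)
from rtkpair.seqio import DomainHit, PairExample, ProteinRecord, Role

canonical_seq = st.text(alphabet=CANONICAL_ALPHABET, min_size=2, max_size=60)


class TestKmerVector:
    def test_single_letter_composition(self):
        v = kmer_vector("AAAA", KmerConfig(k=1))
        assert len(v) == 20
        assert dict(zip(v.names, v.values))["A"] == 1.0
        assert v.values.sum() == 1.0

    def test_two_mer_window_frequencies(self):
        # "ACDC" has 3 windows: AC, CD, DC -> 1/3 each over 400 dims
        v = kmer_vector("ACDC", KmerConfig(k=2))
        nz = {n: x for n, x in zip(v.names, v.values) if x}
        assert len(v) == 400
        assert nz == pytest.approx({"AC": 1 / 3, "CD": 1 / 3, "DC": 1 / 3})

    def test_ambiguity_codes_invalidate_windows(self):
        # both windows of "AXA" contain X -> all-zero 400-dim vector
        v = kmer_vector("AXA", KmerConfig(k=2))
        assert len(v) == 400
        assert not v.values.any()

    def test_ambiguous_letters_excluded_from_denominator(self):
        # "AXAA": windows AX, XA invalid; AA the only valid one
        v = kmer_vector("AXAA", KmerConfig(k=2))
        assert dict(zip(v.names, v.values))["AA"] == 1.0

    def test_empty_sequence_and_bad_k_error(self):
        with pytest.raises(FeaturizeError):
            kmer_vector("", KmerConfig(k=1))
        with pytest.raises(FeaturizeError):
            KmerConfig(k=0)

    @given(seq=canonical_seq, k=st.integers(1, 2))
    @settings(deadline=None)
    def test_frequencies_sum_to_one_on_canonical_sequences(self, seq, k):
        v = kmer_vector(seq, KmerConfig(k=k))
        if len(seq) >= k:
            assert v.values.sum() == pytest.approx(1.0, abs=1e-12)


class TestVocabulary:
    def test_built_per_role_and_sorted(self, toy_proteins):
        hits = [
            DomainHit("R1", "d2", "SF1", 1e-10, 1, 5),
            DomainHit("R1", "d1", "SF1", 1e-10, 1, 5),
            DomainHit("L1", "d3", "SF2", 1e-10, 1, 5),
        ]
        vocab = build_vocabulary(hits, toy_proteins)
        assert vocab.receptor_domains == ("d1", "d2")
        assert vocab.receptor_superfamilies == ("SF1",)
        assert vocab.ligand_domains == ("d3",)
        assert vocab.ligand_superfamilies == ("SF2",)

    def test_no_hits_give_empty_lists(self, toy_proteins):
        vocab = build_vocabulary([], toy_proteins)
        assert vocab.receptor_domains == ()
        assert vocab.ligand_superfamilies == ()

    def test_shared_accession_occupies_both_role_lists(self, toy_proteins):
        # the same domain type may sit on a receptor and on a ligand
        hits = [
            DomainHit("R1", "d1", "SF1", 1e-10, 1, 5),
            DomainHit("L1", "d1", "SF1", 1e-10, 1, 5),
        ]
        vocab = build_vocabulary(hits, toy_proteins)
        assert vocab.receptor_domains == ("d1",)
        assert vocab.ligand_domains == ("d1",)

    def test_inconsistent_superfamily_mapping_errors(self, toy_proteins):
        hits = [
            DomainHit("R1", "d1", "SF1", 1e-10, 1, 5),
            DomainHit("R2", "d1", "SF2", 1e-10, 1, 5),
        ]
        with pytest.raises(FeaturizeError, match="both superfamilies"):
            build_vocabulary(hits, toy_proteins)


def make_vocab(rd=(), ld=(), rs=(), ls=(), mapping=None):
    return DomainVocabulary(
        receptor_domains=tuple(sorted(rd)),
        ligand_domains=tuple(sorted(ld)),
        receptor_superfamilies=tuple(sorted(rs)),
        ligand_superfamilies=tuple(sorted(ls)),
        domain_to_superfamily=mapping or {},
    )


class TestDomainVector:
    def test_presence_absence_layout(self):
        vocab = make_vocab(rd=["d1", "d2", "d3", "d4"], rs=["SF1"])
        hits = [
            DomainHit("R1", "d1", "SF1", 1e-10, 1, 5),
            DomainHit("R1", "d3", "SF1", 1e-10, 1, 5),
        ]
        v = domain_vector("R1", hits, vocab, "domain", Role.RECEPTOR)
        assert v.values.tolist() == [1, 0, 1, 0]

    def test_two_domains_of_one_superfamily_give_single_one(self):
        # d1, d3 in SF2 and d4 in SF3; the protein carries d1 and d3 only
        vocab = make_vocab(
            rd=["d1", "d3", "d4"],
            rs=["SF1", "SF2", "SF3"],
            mapping={"d1": "SF2", "d3": "SF2", "d4": "SF3"},
        )
        hits = [
            DomainHit("R1", "d1", "SF2", 1e-10, 1, 5),
            DomainHit("R1", "d3", "SF2", 1e-10, 1, 5),
        ]
        v = domain_vector("R1", hits, vocab, "superfamily", Role.RECEPTOR)
        assert v.values.tolist() == [0, 1, 0]

    def test_zero_hits_give_zero_vector(self):
        vocab = make_vocab(rd=["d1"], rs=["SF1"])
        v = domain_vector("R9", [], vocab, "domain", Role.RECEPTOR)
        assert not v.values.any()

    def test_unknown_vocabulary_type_is_ignored(self, caplog):
        vocab = make_vocab(rd=["d1"], rs=["SF1"])
        hits = [DomainHit("R1", "dX", "SFX", 1e-10, 1, 5)]
        v = domain_vector("R1", hits, vocab, "domain", Role.RECEPTOR)
        assert not v.values.any()

    @given(data=st.data())
    @settings(deadline=None, max_examples=60)
    def test_superfamily_vector_is_or_projection_of_domain_vector(self, data):
        n_dom = data.draw(st.integers(1, 12))
        n_sf = data.draw(st.integers(1, n_dom))
        domains = [f"d{i:02d}" for i in range(n_dom)]
        sfs = [f"S{i:02d}" for i in range(n_sf)]
        mapping = {
            d: sfs[data.draw(st.integers(0, n_sf - 1), label=d)] for d in domains
        }
        present = data.draw(st.sets(st.sampled_from(domains)))
        hits = [DomainHit("R1", d, mapping[d], 1e-10, 1, 5) for d in sorted(present)]
        vocab = make_vocab(rd=domains, rs=set(mapping.values()), mapping=mapping)
        dv = domain_vector("R1", hits, vocab, "domain", Role.RECEPTOR)
        sv = domain_vector("R1", hits, vocab, "superfamily", Role.RECEPTOR)
        projected = {mapping[d] for d, x in zip(dv.names, dv.values) if x}
        assert {n for n, x in zip(sv.names, sv.values) if x} == projected


class TestPairAndComposite:
    def test_pair_dimensions_for_each_recipe(self):
        k1 = KmerConfig(k=1)
        assert len(pair_vector(kmer_vector("ACD", k1), kmer_vector("MKV", k1))) == 40
        k2 = KmerConfig(k=2)
        assert len(pair_vector(kmer_vector("ACD", k2), kmer_vector("MKV", k2))) == 800

    def test_domain_level_pair_dimension_is_sum_of_role_blocks(self):
        rd = [f"rd{i:03d}" for i in range(80)]
        ld = [f"ld{i:03d}" for i in range(98)]
        vocab = make_vocab(rd=rd, ld=ld, rs=["SF1"], ls=["SF2"])
        rv = domain_vector("R1", [], vocab, "domain", Role.RECEPTOR)
        lv = domain_vector("L1", [], vocab, "domain", Role.LIGAND)
        assert len(pair_vector(rv, lv)) == 178

    def test_recipe_mismatch_errors(self):
        a = kmer_vector("ACD", KmerConfig(k=1))
        b = kmer_vector("ACD", KmerConfig(k=2))
        with pytest.raises(FeaturizeError, match="recipe mismatch"):
            pair_vector(a, b)

    def test_composite_concatenates_a_then_b(self):
        k2 = KmerConfig(k=2)
        pair_k2 = pair_vector(kmer_vector("ACDE", k2), kmer_vector("MKVL", k2))
        rs = [f"S{i}" for i in range(26)]
        ls = [f"T{i}" for i in range(68)]
        vocab = make_vocab(rs=rs, ls=ls)
        pair_sf = pair_vector(
            domain_vector("R1", [], vocab, "superfamily", Role.RECEPTOR),
            domain_vector("L1", [], vocab, "superfamily", Role.LIGAND),
        )
        comp = composite_vector(pair_k2, pair_sf)
        assert len(comp) == 894
        assert comp.recipe == "composite"
        np.testing.assert_array_equal(comp.values[:800], pair_k2.values)

    def test_composite_with_empty_block_keeps_values(self):
        a = kmer_vector("ACDE", KmerConfig(k=1))
        empty = domain_vector("R1", [], make_vocab(), "domain", Role.RECEPTOR)
        comp = composite_vector(a, empty)
        np.testing.assert_array_equal(comp.values, a.values)

    def test_matrix_layout_is_deterministic(self, toy_proteins, toy_hits, toy_pairs):
        vocab = build_vocabulary(toy_hits, toy_proteins)
        X1, names1 = pair_feature_matrix(toy_pairs, toy_proteins, toy_hits, vocab, "composite")
        X2, names2 = pair_feature_matrix(toy_pairs, toy_proteins, toy_hits, vocab, "composite")
        assert names1 == names2
        np.testing.assert_array_equal(X1, X2)
        assert X1.shape == (2, 800 + len(vocab.receptor_superfamilies) + len(vocab.ligand_superfamilies))
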