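"""The seven base feature sets and the S1-S6 combinations."""

import numpy as np
import pytest

from genetriage.corpus import (
    ABSTRACT,
    TITLE,
    ConceptMention,
    Corpus,
    EntityMention,
    MeshDescriptor,
    Predication,
)
from genetriage.features import (
    BASE_SETS,
    COMBINATION_SETS,
    GENE_COUNT_KEYS,
    FeatureConfigError,
    SignificanceConfig,
    bag_of_words,
    build_feature_set,
    gene_counts,
    gene_significance,
    gene_subject_predicate,
    mesh_features,
    read_matrix,
    semtype_count,
    species_check,
    write_matrix,
)
from genetriage.synth import SyntheticConfig, generate_corpus

from conftest import make_article


class TestBagOfWords:
    def test_zone_suffixes_and_stoplist(self):
        art = make_article(title="TNF and preeclampsia", abstract="")
        counts = bag_of_words(art, stoplist=frozenset({"and"}))
        assert counts == {"tnfTITLE": 1, "preeclampsiaTITLE": 1}

    def test_same_word_in_both_zones_gives_two_keys(self):
        art = make_article(title="Preeclampsia genes", abstract="Preeclampsia was studied.")
        counts = bag_of_words(art, stoplist=frozenset({"was"}))
        assert counts["preeclampsiaTITLE"] == 1
        assert counts["preeclampsiaABSTRACT"] == 1

    def test_short_tokens_and_numbers_dropped(self):
        art = make_article(title="A 120 p53 study", abstract="")
        counts = bag_of_words(art, stoplist=frozenset())
        assert set(counts) == {"p53TITLE", "studyTITLE"}


class TestMesh:
    def test_worked_example_heading_and_qualifier_keys(self):
        art = make_article()
        art.mesh = [
            MeshDescriptor("Premature Birth", False, (("Genetics", True),)),
        ]
        assert mesh_features(art) == {
            "Premature Birth-No": 1,
            "Premature Birth-Genetics-Yes": 1,
        }

    def test_no_mesh_empty(self):
        assert mesh_features(make_article()) == {}

    def test_repeated_heading_indicator_idempotent(self):
        art = make_article()
        art.mesh = [MeshDescriptor("Risk", False), MeshDescriptor("Risk", False)]
        assert mesh_features(art) == {"Risk-No": 1}


class TestGeneSubjectPredicate:
    def _pred(self, s, p, o):
        return Predication("C1", s, p, "C2", o, 1)

    def test_gene_diso_pair_counted(self):
        art = make_article()
        art.predications = [self._pred("GENE", "ASSOCIATED_WITH", "DISO")]
        assert gene_subject_predicate(art) == {"GENE-ASSOCIATED_WITH-DISO": 1}

    def test_other_group_pairs_filtered(self):
        art = make_article()
        art.predications = [self._pred("DISO", "AFFECTS", "LIVB")]
        assert gene_subject_predicate(art) == {}

    def test_identical_predications_accumulate(self):
        art = make_article()
        art.predications = [
            Predication("C1", "GENE", "CAUSES", "C2", "DISO", 1),
            Predication("C1", "GENE", "CAUSES", "C2", "DISO", 2),
        ]
        assert gene_subject_predicate(art)["GENE-CAUSES-DISO"] == 2


class TestGeneSignificance:
    def test_gene_and_negation_indicators(self, concept_article, sig_cfg):
        counts = gene_significance(concept_article, sig_cfg)
        # sentence 1: significance CUI with gene, no negation
        assert counts["C0237881-G1-N0"] == 1
        # sentence 2: significance CUI with negation, no gene
        assert counts["C0237881-G0-N1"] == 1
        # the significance concept is itself quantitative: qnco keys too
        assert counts["C0237881-G1"] == 1 and counts["C0237881-G0"] == 1

    def test_no_concepts_empty(self, sig_cfg):
        assert gene_significance(make_article(), sig_cfg) == {}


class TestGeneCounts:
    def test_abstract_counts(self):
        art = make_article()
        art.entities = [
            EntityMention("GENE", "7124", "TNF", 1, ABSTRACT),
            EntityMention("GENE", "7124", "TNF", 1, ABSTRACT),
            EntityMention("GENE", "7124", "TNF", 2, ABSTRACT),
            EntityMention("GENE", "7157", "TP53", 2, ABSTRACT),
        ]
        counts = gene_counts(art)
        assert counts["unique_genes_abstract"] == 2
        assert counts["max_single_gene_abstract"] == 3
        assert counts["total_gene_mentions_abstract"] == 4
        assert counts["unique_genes_title"] == 0
        assert counts["max_single_gene_title"] == 0

    def test_all_zero_without_genes(self):
        counts = gene_counts(make_article())
        assert set(counts) == set(GENE_COUNT_KEYS)
        assert all(v == 0 for v in counts.values())

    def test_single_title_gene(self):
        art = make_article()
        art.entities = [EntityMention("GENE", "348", "APOE", 0, TITLE)]
        counts = gene_counts(art)
        assert (
            counts["unique_genes_title"],
            counts["max_single_gene_title"],
            counts["total_gene_mentions_title"],
        ) == (1, 1, 1)


class TestSpeciesAndSemtype:
    def _livb_article(self, with_gene):
        art = make_article()
        art.concepts = [
            ConceptMention("C0086418", "Humans", frozenset({"humn"}),
                           frozenset({"LIVB"}), 1)
        ]
        if with_gene:
            art.concepts.append(
                ConceptMention("C3100001", "TNF gene", frozenset({"gngm"}),
                               frozenset({"GENE"}), 1)
            )
        return art

    def test_species_gene_cooccurrence(self):
        assert species_check(self._livb_article(True)) == {"C0086418-G1": 1}
        assert species_check(self._livb_article(False)) == {"C0086418-G0": 1}
        assert species_check(make_article()) == {}

    def test_semtype_presence_per_sentence(self):
        art = self._livb_article(True)
        counts = semtype_count(art)
        assert counts == {"humn-G1": 1, "gngm-G1": 1}

    def test_semtype_accumulates_over_sentences(self):
        art = make_article(abstract="One. Two. Three.")
        art.concepts = [
            ConceptMention("C0000001", "X", frozenset({"dsyn"}), frozenset({"DISO"}), i)
            for i in (1, 2, 3)
        ]
        assert semtype_count(art) == {"dsyn-G0": 3}


class TestBuildFeatureSet:
    def test_combination_is_exact_concatenation(self, small_corpus, sig_cfg):
        for name, members in COMBINATION_SETS.items():
            combo = build_feature_set(small_corpus, name, cfg=sig_cfg)
            blocks = [build_feature_set(small_corpus, m, cfg=sig_cfg) for m in members]
            assert len(combo.vocabulary) == sum(len(b.vocabulary) for b in blocks)
            from scipy.sparse import hstack

            stacked = hstack([b.values for b in blocks], format="csr")
            assert (combo.values != stacked).nnz == 0

    def test_s6_membership(self):
        assert COMBINATION_SETS["S6"] == (
            "MeSH", "GeneSignificance", "SemtypeCount", "SpeciesCheck"
        )
        assert set(COMBINATION_SETS["S2"]) == set(COMBINATION_SETS["S1"]) - {"MeSH"}
        assert set(COMBINATION_SETS["S3"]) == set(COMBINATION_SETS["S2"]) - {"GeneCount"}
        assert set(COMBINATION_SETS["S4"]) == set(COMBINATION_SETS["S1"]) - {"GeneSubjectPredicate"}
        assert set(COMBINATION_SETS["S5"]) == set(COMBINATION_SETS["S1"]) - {"GeneCount"}
        assert set(COMBINATION_SETS["S6"]) == (
            set(COMBINATION_SETS["S1"]) - {"GeneSubjectPredicate", "GeneCount"}
        )

    def test_gene_count_vocabulary_is_six_on_any_corpus(self, small_corpus):
        fm = build_feature_set(small_corpus, "GeneCount")
        assert len(fm.vocabulary) == 6
        tiny = Corpus([make_article()])
        assert len(build_feature_set(tiny, "GeneCount").vocabulary) == 6

    def test_frozen_vocabulary_drops_unseen_keys(self, small_corpus, sig_cfg):
        fm = build_feature_set(small_corpus, "MeSH", cfg=sig_cfg)
        novel = make_article(pmid="new")
        novel.mesh = [MeshDescriptor("Entirely Novel Heading", True)]
        out = build_feature_set(
            Corpus([novel]), "MeSH", cfg=sig_cfg, fit=False, vocabulary=fm.vocabulary
        )
        assert out.values.nnz == 0
        assert out.shape == (1, len(fm.vocabulary))

    def test_determinism_and_monotone_vocabulary(self, sig_cfg):
        c1 = generate_corpus(SyntheticConfig(n_articles=30, seed=5))
        c2 = generate_corpus(SyntheticConfig(n_articles=30, seed=5))
        a = build_feature_set(c1, "S2", cfg=sig_cfg)
        b = build_feature_set(c2, "S2", cfg=sig_cfg)
        assert a.vocabulary.keys == b.vocabulary.keys
        assert (a.values != b.values).nnz == 0
        donor = generate_corpus(SyntheticConfig(n_articles=5, seed=99)).articles[0]
        donor.pmid = "extra"
        augmented = Corpus(c1.articles + [donor])
        bigger = build_feature_set(augmented, "S2", cfg=sig_cfg)
        assert set(a.vocabulary.keys) <= set(bigger.vocabulary.keys)

    def test_values_nonnegative(self, small_corpus, sig_cfg):
        fm = build_feature_set(small_corpus, "S1", cfg=sig_cfg)
        assert fm.values.min() >= 0

    def test_unknown_set_name_rejected(self, small_corpus):
        with pytest.raises(FeatureConfigError):
            build_feature_set(small_corpus, "S99")

    def test_matrix_market_round_trip(self, small_corpus, sig_cfg, tmp_path):
        fm = build_feature_set(small_corpus, "SemtypeCount", cfg=sig_cfg)
        write_matrix(fm, tmp_path / "m")
        back = read_matrix(tmp_path / "m")
        assert back.vocabulary.keys == fm.vocabulary.keys
        assert back.pmids == fm.pmids
        assert (back.values != fm.values).nnz == 0


def test_significance_cui_sets_must_be_disjoint():
    with pytest.raises(FeatureConfigError):
        SignificanceConfig(frozenset({"C1"}), frozenset({"C1"}))
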