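import numpy as np
import pytest

from genetriage.corpus import (
    AnnotatedArticle,
    ConceptMention,
    Corpus,
    EntityMention,
    MeshDescriptor,
    Predication,
    segment_sentences,
)
from genetriage.features import SignificanceConfig
from genetriage.synth import SyntheticConfig, generate_corpus


@pytest.fixture(scope="session")
def sig_cfg() -> SignificanceConfig:
    return SignificanceConfig(
        significant_cuis=frozenset({"C0237881"}),
        negation_cuis=frozenset({"C0205160"}),
    )


def make_article(
    pmid="1",
    title="Gene study of TNF.",
    abstract="We tested TNF in humans. It was significant.",
    **kw,
):
    art = AnnotatedArticle(
        pmid=pmid,
        title=title,
        abstract=abstract,
        sentences=segment_sentences(title, abstract),
        **kw,
    )
    return art


@pytest.fixture
def concept_article(sig_cfg):
    """Three sentences (title + 2 abstract) with curated concept layout.

    Sentence 1 holds a significance CUI and a gene concept; sentence 2
    holds the significance CUI with a negation concept and no gene.
    """
    art = make_article(pmid="42")
    art.concepts = [
        ConceptMention("C0237881", "Statistical Significance", frozenset({"qnco"}),
                       frozenset({"CONC"}), 1),
        ConceptMention("C3100001", "TNF gene", frozenset({"gngm"}),
                       frozenset({"GENE"}), 1),
        ConceptMention("C0237881", "Statistical Significance", frozenset({"qnco"}),
                       frozenset({"CONC"}), 2),
        ConceptMention("C0205160", "Negative", frozenset({"qlco"}),
                       frozenset({"CONC"}), 2),
    ]
    art.validate()
    return art


@pytest.fixture(scope="session")
def small_corpus() -> Corpus:
    return generate_corpus(SyntheticConfig(n_articles=80, seed=17))


@pytest.fixture(scope="session")
def strong_split():
    """Train/test corpora from a 600-article strong-signal corpus."""
    from genetriage.experiment import SplitSpec, stratified_split

    corpus = generate_corpus(SyntheticConfig(n_articles=600, seed=23))
    train_pmids, test_pmids = stratified_split(corpus, SplitSpec(seed=23))
    return corpus.subset(train_pmids), corpus.subset(test_pmids)


def random_scored(rng, n_min=5, n_max=40, with_genes=True, tie_prob=0.3):
    """A random small ScoredTestSet for oracle comparisons."""
    from genetriage.evaluate import ScoredTestSet

    n = int(rng.integers(n_min, n_max + 1))
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[int(rng.integers(n))] = 1
    if labels.sum() == n:
        labels[int(rng.integers(n))] = 0
    probs = rng.random(n)
    if rng.random() < tie_prob:
        probs = np.round(probs, 1)
    pmids = [f"p{i}" for i in range(n)]
    gene_sets = {}
    if with_genes:
        pool = [f"G{k}" for k in range(8)]
        for i in range(n):
            if labels[i] == 1:
                k = int(rng.integers(1, 4))
                gene_sets[pmids[i]] = set(rng.choice(pool, size=k, replace=False))
    return ScoredTestSet(pmids=pmids, labels=labels, probabilities=probs, gene_sets=gene_sets)
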