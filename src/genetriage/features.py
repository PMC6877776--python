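"""Feature generation for annotation-based article triage.

Seven base feature sets are computed per article, six of them derived
from entity/concept/predication annotations rather than raw text:

* **BOW** — zone-suffixed unigram counts (the baseline).
* **MeSH** — heading / heading-subheading indicators carrying the
  major-topic flag ("Premature Birth-No", "Premature Birth-Genetics-Yes").
* **GeneSubjectPredicate** — counts of GENE--predicate--DISO (and
  DISO--predicate--GENE) predication triples.
* **GeneSignificance** — per-sentence Quantitative-Concept and
  significance-CUI keys with gene co-occurrence (G1/G0) and, for
  significance CUIs, negation (N1/N0) indicators — so "not statistically
  significant" sentences are kept distinct.
* **GeneCount** — six numeric summaries of gene mentions per zone.
* **SpeciesCheck** — LIVB-group concept keys with gene co-occurrence.
* **SemtypeCount** — per-sentence semantic-type presence with gene
  co-occurrence.

Combination sets S1–S6 are column-wise concatenations of base sets.
Vocabularies are learned on the training articles only and frozen;
unseen keys at test time are dropped.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import scipy.sparse as sp

from .corpus import ABSTRACT, TITLE, AnnotatedArticle, Corpus

__all__ = [
    "FeatureVocabulary",
    "FeatureMatrix",
    "SignificanceConfig",
    "FeatureConfigError",
    "BASE_SETS",
    "COMBINATION_SETS",
    "GENE_COUNT_KEYS",
    "default_stoplist",
    "bag_of_words",
    "mesh_features",
    "gene_subject_predicate",
    "gene_significance",
    "gene_counts",
    "species_check",
    "semtype_count",
    "build_feature_set",
    "write_matrix",
    "read_matrix",
]


class FeatureConfigError(ValueError):
    """Unknown feature-set name or invalid significance configuration."""


@dataclass(frozen=True)
class FeatureVocabulary:
    """Ordered, frozen mapping from feature-key strings to columns."""

    name: str
    keys: tuple[str, ...]
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.keys)) != len(self.keys):
            raise FeatureConfigError(f"duplicate keys in vocabulary {self.name!r}")
        object.__setattr__(self, "index", {k: i for i, k in enumerate(self.keys)})

    def __len__(self) -> int:
        return len(self.keys)


@dataclass
class FeatureMatrix:
    """Articles × features sparse count matrix over a vocabulary."""

    vocabulary: FeatureVocabulary
    pmids: list[str]
    values: sp.csr_matrix

    def __post_init__(self) -> None:
        assert self.values.shape == (len(self.pmids), len(self.vocabulary))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _read_cui_list(path_or_lines) -> frozenset[str]:
    if isinstance(path_or_lines, (str, Path)):
        lines = Path(path_or_lines).read_text().splitlines()
    else:
        lines = list(path_or_lines)
    cuis = set()
    for raw in lines:
        line = raw.split("#", 1)[0].strip()
        if line:
            cuis.add(line)
    return frozenset(cuis)


@dataclass(frozen=True)
class SignificanceConfig:
    """CUI lists driving the gene/significance co-occurrence features.

    ``significant_cuis`` denote statistical significance, P value or
    z-score concepts; ``negation_cuis`` denote "Negative" / "Negation" /
    "Unchanged".  The packaged defaults are a starting point a curation
    team is expected to edit for its domain.
    """

    significant_cuis: frozenset[str]
    negation_cuis: frozenset[str]

    def __post_init__(self) -> None:
        if self.significant_cuis & self.negation_cuis:
            raise FeatureConfigError("significant and negation CUI sets must be disjoint")

    @classmethod
    def from_files(cls, significant: str | Path, negation: str | Path) -> "SignificanceConfig":
        return cls(_read_cui_list(significant), _read_cui_list(negation))

    @classmethod
    def default(cls) -> "SignificanceConfig":
        pkg = resources.files("genetriage.data")
        return cls(
            _read_cui_list(pkg.joinpath("significant_cuis.txt").read_text().splitlines()),
            _read_cui_list(pkg.joinpath("negation_cuis.txt").read_text().splitlines()),
        )


def default_stoplist() -> frozenset[str]:
    """Standard English stopwords (articles, prepositions, pronouns included)."""
    from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

    return frozenset(ENGLISH_STOP_WORDS)


_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def _tokens(text: str, stoplist: frozenset[str]) -> list[str]:
    out = []
    for tok in _TOKEN_RE.split(text.lower()):
        if len(tok) <= 1 or tok.isdigit() or tok in stoplist:
            continue
        out.append(tok)
    return out


def bag_of_words(article: AnnotatedArticle, stoplist: frozenset[str] | None = None) -> Counter:
    """Zone-suffixed unigram frequencies (tokenTITLE / tokenABSTRACT)."""
    stoplist = stoplist if stoplist is not None else default_stoplist()
    counts: Counter = Counter()
    for tok in _tokens(article.title, stoplist):
        counts[tok + "TITLE"] += 1
    for tok in _tokens(article.abstract, stoplist):
        counts[tok + "ABSTRACT"] += 1
    return counts


def mesh_features(article: AnnotatedArticle) -> Counter:
    """Heading and heading-subheading indicators with Yes/No major flags."""
    counts: Counter = Counter()
    for d in article.mesh:
        counts[f"{d.heading}-{'Yes' if d.heading_major else 'No'}"] = 1
        for qname, qmajor in d.qualifiers:
            counts[f"{d.heading}-{qname}-{'Yes' if qmajor else 'No'}"] = 1
    return counts


def gene_subject_predicate(article: AnnotatedArticle) -> Counter:
    """Counts of predications linking the GENE and DISO semantic groups."""
    counts: Counter = Counter()
    for p in article.predications:
        pair = (p.subject_group, p.object_group)
        if pair in (("GENE", "DISO"), ("DISO", "GENE")):
            counts[f"{p.subject_group}-{p.predicate}-{p.object_group}"] += 1
    return counts


def _gene_sentences(article: AnnotatedArticle, include_pubtator: bool = False) -> set[int]:
    """Sentence indices containing a GENE-group concept mention.

    With ``include_pubtator`` the union with PubTator gene-entity
    sentences is used instead.
    """
    idx = {c.sentence_index for c in article.concepts if "GENE" in c.semgroups}
    if include_pubtator:
        idx |= {e.sentence_index for e in article.entities if e.kind == "GENE"}
    return idx


def gene_significance(
    article: AnnotatedArticle,
    cfg: SignificanceConfig,
    include_pubtator_genes: bool = False,
) -> Counter:
    """Quantitative-concept and significance-CUI keys with G/N indicators.

    Two key families, accumulated over sentences: ``cui-G{0,1}`` for each
    Quantitative Concept (semtype ``qnco``), and ``cui-G{0,1}-N{0,1}``
    for each configured significance CUI, where N1 marks a negation CUI
    in the same sentence.
    """
    counts: Counter = Counter()
    gene_sents = _gene_sentences(article, include_pubtator_genes)
    neg_sents = {
        c.sentence_index for c in article.concepts if c.cui in cfg.negation_cuis
    }
    for c in article.concepts:
        g = "G1" if c.sentence_index in gene_sents else "G0"
        if "qnco" in c.semtypes:
            counts[f"{c.cui}-{g}"] += 1
        if c.cui in cfg.significant_cuis:
            n = "N1" if c.sentence_index in neg_sents else "N0"
            counts[f"{c.cui}-{g}-{n}"] += 1
    return counts


GENE_COUNT_KEYS = (
    "unique_genes_title",
    "unique_genes_abstract",
    "max_single_gene_title",
    "max_single_gene_abstract",
    "total_gene_mentions_title",
    "total_gene_mentions_abstract",
)


def gene_counts(article: AnnotatedArticle) -> Counter:
    """Six numeric gene-mention summaries from PubTator GENE entities."""
    counts: Counter = Counter({k: 0 for k in GENE_COUNT_KEYS})
    for zone, suffix in ((TITLE, "title"), (ABSTRACT, "abstract")):
        per_gene: Counter = Counter(
            e.identifier for e in article.entities if e.kind == "GENE" and e.zone == zone
        )
        counts[f"unique_genes_{suffix}"] = len(per_gene)
        counts[f"max_single_gene_{suffix}"] = max(per_gene.values(), default=0)
        counts[f"total_gene_mentions_{suffix}"] = sum(per_gene.values())
    return counts


def species_check(article: AnnotatedArticle, include_pubtator_genes: bool = False) -> Counter:
    """LIVB-group concept keys with per-sentence gene co-occurrence."""
    counts: Counter = Counter()
    gene_sents = _gene_sentences(article, include_pubtator_genes)
    for c in article.concepts:
        if "LIVB" in c.semgroups:
            g = "G1" if c.sentence_index in gene_sents else "G0"
            counts[f"{c.cui}-{g}"] += 1
    return counts


def semtype_count(article: AnnotatedArticle, include_pubtator_genes: bool = False) -> Counter:
    """Per-sentence semantic-type presence with gene co-occurrence."""
    counts: Counter = Counter()
    gene_sents = _gene_sentences(article, include_pubtator_genes)
    per_sentence: dict[int, set[str]] = {}
    for c in article.concepts:
        per_sentence.setdefault(c.sentence_index, set()).update(c.semtypes)
    for idx, semtypes in sorted(per_sentence.items()):
        g = "G1" if idx in gene_sents else "G0"
        for st in sorted(semtypes):
            counts[f"{st}-{g}"] += 1
    return counts


BASE_SETS = (
    "BOW",
    "MeSH",
    "GeneSignificance",
    "GeneSubjectPredicate",
    "SemtypeCount",
    "SpeciesCheck",
    "GeneCount",
)

# Combination sets: S1 is every annotation-derived set; the others drop
# the most expensive (MeSH) or weakest (GeneCount, GeneSubjectPredicate)
# members.  Order fixes the column layout.
COMBINATION_SETS: dict[str, tuple[str, ...]] = {
    "S1": ("MeSH", "GeneSignificance", "SemtypeCount", "GeneSubjectPredicate",
           "SpeciesCheck", "GeneCount"),
    "S2": ("GeneSignificance", "SemtypeCount", "GeneSubjectPredicate",
           "SpeciesCheck", "GeneCount"),
    "S3": ("GeneSignificance", "SemtypeCount", "GeneSubjectPredicate", "SpeciesCheck"),
    "S4": ("MeSH", "GeneSignificance", "SemtypeCount", "SpeciesCheck", "GeneCount"),
    "S5": ("MeSH", "GeneSignificance", "SemtypeCount", "GeneSubjectPredicate",
           "SpeciesCheck"),
    "S6": ("MeSH", "GeneSignificance", "SemtypeCount", "SpeciesCheck"),
}


def _article_counts(
    article: AnnotatedArticle,
    set_name: str,
    cfg: SignificanceConfig,
    stoplist: frozenset[str],
    include_pubtator_genes: bool,
) -> Counter:
    if set_name == "BOW":
        return bag_of_words(article, stoplist)
    if set_name == "MeSH":
        return mesh_features(article)
    if set_name == "GeneSignificance":
        return gene_significance(article, cfg, include_pubtator_genes)
    if set_name == "GeneSubjectPredicate":
        return gene_subject_predicate(article)
    if set_name == "SemtypeCount":
        return semtype_count(article, include_pubtator_genes)
    if set_name == "SpeciesCheck":
        return species_check(article, include_pubtator_genes)
    if set_name == "GeneCount":
        return gene_counts(article)
    raise FeatureConfigError(f"unknown feature set {set_name!r}")


def _build_base(
    corpus: Corpus,
    set_name: str,
    cfg: SignificanceConfig,
    fit: bool,
    vocabulary: FeatureVocabulary | None,
    stoplist: frozenset[str],
    include_pubtator_genes: bool,
) -> FeatureMatrix:
    per_article = [
        _article_counts(a, set_name, cfg, stoplist, include_pubtator_genes)
        for a in corpus.articles
    ]
    if fit:
        if set_name == "GeneCount":
            keys = GENE_COUNT_KEYS
        else:
            seen: dict[str, None] = {}
            for counts in per_article:  # first-seen order: deterministic, monotone
                for k in counts:
                    seen.setdefault(k)
            keys = tuple(seen)
        vocabulary = FeatureVocabulary(name=set_name, keys=keys)
    elif vocabulary is None:
        raise FeatureConfigError("a learned vocabulary is required when fit=False")
    index = vocabulary.index
    rows, cols, data = [], [], []
    for i, counts in enumerate(per_article):
        for k, v in counts.items():
            j = index.get(k)
            if j is not None and v != 0:  # unseen-at-test keys dropped
                rows.append(i)
                cols.append(j)
                data.append(v)
    values = sp.csr_matrix(
        (np.asarray(data, dtype=np.float64), (rows, cols)),
        shape=(len(corpus.articles), len(vocabulary)),
    )
    return FeatureMatrix(vocabulary=vocabulary, pmids=corpus.pmids, values=values)


def build_feature_set(
    corpus: Corpus,
    set_name: str,
    cfg: SignificanceConfig | None = None,
    fit: bool = True,
    vocabulary: FeatureVocabulary | None = None,
    stoplist: frozenset[str] | None = None,
    include_pubtator_genes: bool = False,
) -> FeatureMatrix:
    """Build one base or combination feature matrix over a corpus.

    With ``fit=True`` the vocabulary is learned from ``corpus`` (training
    articles); with ``fit=False`` the supplied ``vocabulary`` is frozen
    and unseen keys are dropped.  A combination set is the exact
    column-wise concatenation of its members with member-prefixed keys.
    """
    cfg = cfg if cfg is not None else SignificanceConfig.default()
    stoplist = stoplist if stoplist is not None else default_stoplist()
    if set_name in BASE_SETS:
        return _build_base(
            corpus, set_name, cfg, fit, vocabulary, stoplist, include_pubtator_genes
        )
    if set_name not in COMBINATION_SETS:
        raise FeatureConfigError(f"unknown feature set {set_name!r}")
    members = COMBINATION_SETS[set_name]
    if fit:
        member_vocabs: list[FeatureVocabulary | None] = [None] * len(members)
    else:
        if vocabulary is None:
            raise FeatureConfigError("a learned vocabulary is required when fit=False")
        member_vocabs = []
        for m in members:
            prefix = m + "|"
            keys = tuple(
                k[len(prefix):] for k in vocabulary.keys if k.startswith(prefix)
            )
            member_vocabs.append(FeatureVocabulary(name=m, keys=keys))
    blocks = [
        _build_base(corpus, m, cfg, fit, mv, stoplist, include_pubtator_genes)
        for m, mv in zip(members, member_vocabs)
    ]
    keys = tuple(
        f"{m}|{k}" for m, b in zip(members, blocks) for k in b.vocabulary.keys
    )
    vocab = FeatureVocabulary(name=set_name, keys=keys)
    if len(keys) == 0:
        values = sp.csr_matrix((len(corpus.articles), 0))
    else:
        values = sp.hstack([b.values for b in blocks], format="csr")
    return FeatureMatrix(vocabulary=vocab, pmids=corpus.pmids, values=values)


def write_matrix(fm: FeatureMatrix, basename: str | Path) -> None:
    """Export as MatrixMarket plus sidecar key and pmid files."""
    from scipy.io import mmwrite

    base = Path(basename)
    mmwrite(str(base.with_suffix(".mtx")), fm.values)
    base.with_suffix(".keys.txt").write_text("\n".join(fm.vocabulary.keys) + "\n")
    base.with_suffix(".pmids.txt").write_text("\n".join(fm.pmids) + "\n")


def read_matrix(basename: str | Path, name: str = "features") -> FeatureMatrix:
    from scipy.io import mmread

    base = Path(basename)
    values = sp.csr_matrix(mmread(str(base.with_suffix(".mtx"))))
    keys = tuple(base.with_suffix(".keys.txt").read_text().splitlines())
    pmids = base.with_suffix(".pmids.txt").read_text().splitlines()
    return FeatureMatrix(
        vocabulary=FeatureVocabulary(name=name, keys=keys), pmids=pmids, values=values
    )
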