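"""Domain model for annotated articles.

An :class:`AnnotatedArticle` bundles everything the triage pipeline knows
about one PubMed record: the zoned text (title + abstract, segmented into
sentences), MeSH descriptors, entity mentions (genes, diseases, species,
mutations), UMLS concept mentions, semantic predications, the curation
label (1 = "considered" for the database, 0 = "not considered") and — for
considered articles — the set of curator-accepted gene symbols.

Sentence scoping matters because every co-occurrence feature is computed
per sentence; the segmentation rule here is deterministic so that feature
matrices are stable across runs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

__all__ = [
    "TITLE",
    "ABSTRACT",
    "ENTITY_KINDS",
    "Sentence",
    "MeshDescriptor",
    "EntityMention",
    "ConceptMention",
    "Predication",
    "AnnotatedArticle",
    "Corpus",
    "CorpusError",
    "segment_sentences",
    "sentence_spans",
]

TITLE = "TITLE"
ABSTRACT = "ABSTRACT"

ENTITY_KINDS = frozenset({"GENE", "DISEASE", "SPECIES", "MUTATION"})

_CUI_RE = re.compile(r"^C\d+$")

# Sentence boundary: sentence-final punctuation, whitespace, then an
# uppercase letter or digit.  "e.g. value" therefore does not split.
_BOUNDARY_RE = re.compile(r"(?<=[.!?])\s+(?=[A-Z0-9])")


class CorpusError(ValueError):
    """Raised when an article or corpus violates a structural invariant."""


@dataclass(frozen=True)
class Sentence:
    index: int
    zone: str  # TITLE | ABSTRACT
    text: str


@dataclass(frozen=True)
class MeshDescriptor:
    """One MeSH heading with its qualifier (subheading) list.

    ``heading_major`` / per-qualifier major flags mirror MajorTopicYN in
    MEDLINE XML: whether the descriptor or subheading is a central focus
    of the article.
    """

    heading: str
    heading_major: bool = False
    qualifiers: tuple[tuple[str, bool], ...] = ()

    def __post_init__(self) -> None:
        if not self.heading:
            raise CorpusError("MeSH heading must be nonempty")
        names = [q[0] for q in self.qualifiers]
        if len(names) != len(set(names)):
            raise CorpusError(f"duplicate qualifier names for heading {self.heading!r}")


@dataclass(frozen=True)
class EntityMention:
    """A PubTator-style entity annotation mapped onto a sentence."""

    kind: str  # GENE | DISEASE | SPECIES | MUTATION
    identifier: str
    surface: str
    sentence_index: int
    zone: str

    def __post_init__(self) -> None:
        if self.kind not in ENTITY_KINDS:
            raise CorpusError(f"unknown entity kind {self.kind!r}")


@dataclass(frozen=True)
class ConceptMention:
    """A MetaMap UMLS concept mapping scoped to one sentence."""

    cui: str
    preferred_name: str
    semtypes: frozenset[str]
    semgroups: frozenset[str]
    sentence_index: int

    def __post_init__(self) -> None:
        if not _CUI_RE.match(self.cui):
            raise CorpusError(f"malformed CUI {self.cui!r}")


@dataclass(frozen=True)
class Predication:
    """A SemRep subject-predicate-object triple scoped to one sentence."""

    subject_cui: str
    subject_group: str
    predicate: str
    object_cui: str
    object_group: str
    sentence_index: int

    def __post_init__(self) -> None:
        if not self.predicate:
            raise CorpusError("predicate must be nonempty")


@dataclass
class AnnotatedArticle:
    pmid: str
    title: str = ""
    abstract: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    mesh: list[MeshDescriptor] = field(default_factory=list)
    entities: list[EntityMention] = field(default_factory=list)
    concepts: list[ConceptMention] = field(default_factory=list)
    predications: list[Predication] = field(default_factory=list)
    label: int | None = None
    curated_genes: set[str] = field(default_factory=set)
    year: int | None = None

    def validate(self) -> None:
        """Check structural invariants; raise :class:`CorpusError` on failure."""
        if not self.pmid:
            raise CorpusError("pmid must be nonempty")
        n = len(self.sentences)
        for i, s in enumerate(self.sentences):
            if s.index != i:
                raise CorpusError(f"pmid {self.pmid}: sentence indices not contiguous")
        # TITLE sentences precede ABSTRACT sentences
        zones = [s.zone for s in self.sentences]
        if zones != sorted(zones, key=lambda z: 0 if z == TITLE else 1):
            raise CorpusError(f"pmid {self.pmid}: TITLE sentences must precede ABSTRACT")
        for m in self.entities:
            if not (0 <= m.sentence_index < n):
                raise CorpusError(
                    f"pmid {self.pmid}: entity sentence_index {m.sentence_index} out of range"
                )
            if self.sentences[m.sentence_index].zone != m.zone:
                raise CorpusError(f"pmid {self.pmid}: entity zone inconsistent with sentence")
        for c in self.concepts:
            if not (0 <= c.sentence_index < n):
                raise CorpusError(
                    f"pmid {self.pmid}: concept sentence_index {c.sentence_index} out of range"
                )
        for p in self.predications:
            if not (0 <= p.sentence_index < n):
                raise CorpusError(
                    f"pmid {self.pmid}: predication sentence_index {p.sentence_index} out of range"
                )
        if self.label == 0 and self.curated_genes:
            raise CorpusError(f"pmid {self.pmid}: curated_genes must be empty when label=0")

    @property
    def title_sentences(self) -> list[Sentence]:
        return [s for s in self.sentences if s.zone == TITLE]

    @property
    def abstract_sentences(self) -> list[Sentence]:
        return [s for s in self.sentences if s.zone == ABSTRACT]


@dataclass
class Corpus:
    articles: list[AnnotatedArticle] = field(default_factory=list)
    name: str = "corpus"

    def validate(self, require_labels: bool = False) -> None:
        seen: set[str] = set()
        for a in self.articles:
            if a.pmid in seen:
                raise CorpusError(f"duplicate pmid {a.pmid}")
            seen.add(a.pmid)
            a.validate()
            if require_labels and a.label is None:
                raise CorpusError(f"pmid {a.pmid}: label required")

    def __len__(self) -> int:
        return len(self.articles)

    def __iter__(self):
        return iter(self.articles)

    def by_pmid(self, pmid: str) -> AnnotatedArticle:
        for a in self.articles:
            if a.pmid == pmid:
                return a
        raise KeyError(pmid)

    def subset(self, pmids) -> "Corpus":
        """Articles restricted to ``pmids``, keeping corpus order."""
        wanted = set(pmids)
        return Corpus(
            articles=[a for a in self.articles if a.pmid in wanted],
            name=self.name,
        )

    @property
    def pmids(self) -> list[str]:
        return [a.pmid for a in self.articles]


def segment_sentences(title: str, abstract: str) -> list[Sentence]:
    """Split title + abstract into zoned sentences.

    The title is kept as a single TITLE sentence.  The abstract is split
    at sentence-final punctuation (``.!?``) followed by whitespace and an
    uppercase letter or digit; this keeps abbreviations like "e.g. value"
    intact.  Deterministic: identical input yields identical output.
    """
    sentences: list[Sentence] = []
    if title.strip():
        sentences.append(Sentence(index=0, zone=TITLE, text=title))
    if abstract.strip():
        base = len(sentences)
        for i, chunk in enumerate(_BOUNDARY_RE.split(abstract)):
            sentences.append(Sentence(index=base + i, zone=ABSTRACT, text=chunk))
    return sentences


def sentence_spans(title: str, abstract: str) -> list[tuple[int, int]]:
    """Character span (start, end-exclusive) of each sentence.

    Coordinates are over the concatenation ``title + " " + abstract``, the
    dialect PubTator offsets use.  Aligned 1:1 with
    :func:`segment_sentences` output.
    """
    spans: list[tuple[int, int]] = []
    if title.strip():
        spans.append((0, len(title)))
    if abstract.strip():
        offset = len(title) + 1 if title else 0
        pos = 0
        boundaries = [m.span() for m in _BOUNDARY_RE.finditer(abstract)]
        for sep_start, sep_end in boundaries:
            spans.append((offset + pos, offset + sep_start))
            pos = sep_end
        spans.append((offset + pos, offset + len(abstract)))
    return spans
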