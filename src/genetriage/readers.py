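"""File-format readers for the four annotation sources.

All ingestion is file-based: PubMed/MEDLINE XML for text and MeSH,
PubTator tab-delimited for entity mentions, MetaMap MMI-style fielded
output for UMLS concept mappings and SemRep fielded output for
predications.  Character offsets (PubTator, MetaMap) are interpreted as
0-based, end-exclusive positions over the concatenation
``title + " " + abstract`` and are mapped onto the article's sentence
segmentation at ingest; a span crossing a sentence boundary is assigned
to the sentence containing its start.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .corpus import (
    ABSTRACT,
    TITLE,
    AnnotatedArticle,
    ConceptMention,
    Corpus,
    EntityMention,
    MeshDescriptor,
    Predication,
    segment_sentences,
    sentence_spans,
)
from .semgroups import default_semgroup_table, groups_for

__all__ = [
    "ReaderWarnings",
    "PubMedParseError",
    "read_pubmed_xml",
    "read_pubtator",
    "read_metamap",
    "read_semrep",
    "read_labels",
    "read_gene_sets",
    "assemble_corpus",
]

_PUBTATOR_KIND = {
    "GENE": "GENE",
    "DISEASE": "DISEASE",
    "SPECIES": "SPECIES",
    "MUTATION": "MUTATION",
    "PROTEINMUTATION": "MUTATION",
    "DNAMUTATION": "MUTATION",
    "SNP": "MUTATION",
}


class PubMedParseError(ValueError):
    """Malformed XML; message names the byte offset reported by the parser."""


@dataclass
class ReaderWarnings:
    """Non-fatal issues collected during ingestion."""

    messages: list[str] = field(default_factory=list)

    def add(self, msg: str) -> None:
        self.messages.append(msg)

    def __len__(self) -> int:
        return len(self.messages)


def _text(node) -> str:
    return "".join(node.itertext()) if node is not None else ""


def read_pubmed_xml(
    path: str | Path, warnings: ReaderWarnings | None = None
) -> list[AnnotatedArticle]:
    """Parse a PubmedArticleSet file into partial articles.

    Returns one record per ``PubmedArticle`` carrying pmid, title,
    abstract, MeSH descriptors (MajorTopicYN flags mapped to booleans)
    and publication year; sentences are pre-segmented.  Records without
    an abstract are returned with an empty abstract and flagged in
    ``warnings``; a record missing its PMID is skipped with a warning
    while other records are still returned.
    """
    warnings = warnings if warnings is not None else ReaderWarnings()
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:  # byte offset per the parser
        raise PubMedParseError(
            f"malformed XML in {path}: {exc.msg} (line {exc.lineno}, column {exc.position[1]})"
        ) from exc
    articles: list[AnnotatedArticle] = []
    for rec in tree.iter("PubmedArticle"):
        pmid_node = rec.find(".//MedlineCitation/PMID")
        pmid = (_text(pmid_node) or "").strip()
        if not pmid:
            warnings.add("record without PMID skipped")
            continue
        art = rec.find(".//MedlineCitation/Article")
        title = _text(art.find("ArticleTitle")).strip() if art is not None else ""
        abstract = ""
        if art is not None:
            parts = [_text(t).strip() for t in art.findall("Abstract/AbstractText")]
            abstract = " ".join(p for p in parts if p)
        if not abstract:
            warnings.add(f"pmid {pmid}: no abstract")
        year = None
        if art is not None:
            ynode = art.find("Journal/JournalIssue/PubDate/Year")
            if ynode is None:
                ynode = art.find("ArticleDate/Year")
            if ynode is not None and _text(ynode).strip().isdigit():
                year = int(_text(ynode).strip())
        mesh: list[MeshDescriptor] = []
        for mh in rec.findall(".//MedlineCitation/MeshHeadingList/MeshHeading"):
            dn = mh.find("DescriptorName")
            if dn is None or not _text(dn).strip():
                continue
            quals = tuple(
                (_text(q).strip(), q.get("MajorTopicYN", "N") == "Y")
                for q in mh.findall("QualifierName")
                if _text(q).strip()
            )
            mesh.append(
                MeshDescriptor(
                    heading=_text(dn).strip(),
                    heading_major=dn.get("MajorTopicYN", "N") == "Y",
                    qualifiers=quals,
                )
            )
        articles.append(
            AnnotatedArticle(
                pmid=pmid,
                title=title,
                abstract=abstract,
                sentences=segment_sentences(title, abstract),
                mesh=mesh,
                year=year,
            )
        )
    return articles


def _locate(offset: int, spans: list[tuple[int, int]]) -> int | None:
    """Sentence index containing a character offset, else None."""
    for i, (s, e) in enumerate(spans):
        if s <= offset < e:
            return i
    # offsets falling in inter-sentence whitespace attach to the next sentence
    for i, (s, _) in enumerate(spans):
        if offset < s:
            return i
    return None


def read_pubtator(
    path: str | Path, warnings: ReaderWarnings | None = None
) -> dict[str, list[EntityMention]]:
    """Parse PubTator tab-delimited annotations.

    Expects per-document ``pmid|t|...`` and ``pmid|a|...`` text lines
    followed by tab-delimited mention lines
    ``pmid  start  end  surface  type  identifier``.  Offsets beyond the
    text length are record-level errors collected in ``warnings``.
    """
    warnings = warnings if warnings is not None else ReaderWarnings()
    titles: dict[str, str] = {}
    abstracts: dict[str, str] = {}
    mentions: dict[str, list[EntityMention]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if "|t|" in line or "|a|" in line:
            pmid, tag, text = line.split("|", 2)
            if tag == "t":
                titles[pmid] = text
            else:
                abstracts[pmid] = text
            mentions.setdefault(pmid, [])
            continue
        parts = line.split("\t")
        if len(parts) < 5:
            warnings.add(f"unparseable PubTator line: {line!r}")
            continue
        pmid, start_s, end_s, surface, kind_s = parts[:5]
        identifier = parts[5] if len(parts) > 5 else ""
        kind = _PUBTATOR_KIND.get(kind_s.upper())
        if kind is None:
            continue  # annotation classes outside the four are ignored
        title = titles.get(pmid, "")
        abstract = abstracts.get(pmid, "")
        spans = sentence_spans(title, abstract)
        total = len(title) + (1 + len(abstract) if abstract else 0)
        start = int(start_s)
        if start >= total or int(end_s) > total:
            warnings.add(f"pmid {pmid}: offset {start_s}-{end_s} beyond text length {total}")
            continue
        idx = _locate(start, spans)
        if idx is None:
            warnings.add(f"pmid {pmid}: offset {start_s} not inside any sentence")
            continue
        zone = TITLE if start < len(title) else ABSTRACT
        mentions.setdefault(pmid, []).append(
            EntityMention(
                kind=kind,
                identifier=identifier,
                surface=surface,
                sentence_index=idx,
                zone=zone,
            )
        )
    return mentions


_MMI_POS_RE = re.compile(r"(\d+)/(\d+)")


def read_metamap(
    path: str | Path,
    semgroup_table: dict[str, str] | None = None,
    texts: dict[str, tuple[str, str]] | None = None,
    warnings: ReaderWarnings | None = None,
) -> dict[str, list[ConceptMention]]:
    """Parse MetaMap MMI-style fielded output into concept mentions.

    Accepted line dialect (pipe-delimited)::

        pmid|MMI|score|preferred name|CUI|[st1,st2]|trigger|location|start/len[;start/len]

    ``texts`` maps pmid -> (title, abstract) and is required to convert
    the positional field into a sentence index; lines for pmids absent
    from ``texts`` are flagged.  Semantic groups are derived from the
    semantic types via the configured table.
    """
    warnings = warnings if warnings is not None else ReaderWarnings()
    table = semgroup_table if semgroup_table is not None else default_semgroup_table()
    texts = texts or {}
    out: dict[str, list[ConceptMention]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        parts = raw.split("|")
        if len(parts) < 9 or parts[1] != "MMI":
            warnings.add(f"unparseable MMI line: {raw!r}")
            continue
        pmid, _, _score, name, cui, st_field = parts[:6]
        pos_field = parts[8]
        semtypes = frozenset(
            s.strip() for s in st_field.strip("[]").split(",") if s.strip()
        )
        if pmid not in texts:
            warnings.add(f"pmid {pmid}: no text available for MMI positional mapping")
            continue
        m = _MMI_POS_RE.search(pos_field)
        if not m:
            warnings.add(f"pmid {pmid}: bad MMI positional field {pos_field!r}")
            continue
        start = int(m.group(1))
        title, abstract = texts[pmid]
        idx = _locate(start, sentence_spans(title, abstract))
        if idx is None:
            warnings.add(f"pmid {pmid}: MMI offset {start} outside text")
            continue
        out.setdefault(pmid, []).append(
            ConceptMention(
                cui=cui,
                preferred_name=name,
                semtypes=semtypes,
                semgroups=groups_for(semtypes, table),
                sentence_index=idx,
            )
        )
    return out


_UTT_RE = re.compile(r"^(ti|ab)\.(\d+)$")


def read_semrep(
    path: str | Path,
    semgroup_table: dict[str, str] | None = None,
    warnings: ReaderWarnings | None = None,
) -> dict[str, list[Predication]]:
    """Parse SemRep fielded predication output.

    Accepted line dialect (pipe-delimited)::

        pmid|utterance|subj CUI|subj name|subj semtype|PREDICATE|obj CUI|obj name|obj semtype

    where ``utterance`` is ``ti.k`` or ``ab.k`` (1-based within zone);
    with the one-sentence title convention ``ti.1`` maps to sentence 0
    and ``ab.k`` to sentence ``k``.  Subject/object groups are derived
    from the semantic types via the configured table (first group wins;
    ungrouped types map to "OTHER").
    """
    warnings = warnings if warnings is not None else ReaderWarnings()
    table = semgroup_table if semgroup_table is not None else default_semgroup_table()

    def group_of(semtype: str) -> str:
        return table.get(semtype, "OTHER")

    out: dict[str, list[Predication]] = {}
    for raw in Path(path).read_text().splitlines():
        if not raw.strip():
            continue
        parts = raw.split("|")
        if len(parts) < 9:
            warnings.add(f"unparseable SemRep line: {raw!r}")
            continue
        pmid, utt, s_cui, _s_name, s_st, pred, o_cui, _o_name, o_st = parts[:9]
        m = _UTT_RE.match(utt)
        if not m:
            warnings.add(f"pmid {pmid}: bad utterance id {utt!r}")
            continue
        k = int(m.group(2))
        idx = k - 1 if m.group(1) == "ti" else k
        out.setdefault(pmid, []).append(
            Predication(
                subject_cui=s_cui,
                subject_group=group_of(s_st),
                predicate=pred,
                object_cui=o_cui,
                object_group=group_of(o_st),
                sentence_index=idx,
            )
        )
    return out


def read_labels(path: str | Path) -> dict[str, int]:
    """Two-column delimited (pmid, label) file; label in {0, 1}."""
    labels: dict[str, int] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        pmid, value = re.split(r"[\t,;]+|\s+", line)[:2]
        labels[pmid] = int(value)
    return labels


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Two-column delimited (pmid, gene symbol) file, one gene per line."""
    genes: dict[str, set[str]] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        pmid, symbol = re.split(r"[\t,;]+|\s+", line)[:2]
        genes.setdefault(pmid, set()).add(symbol)
    return genes


def assemble_corpus(
    articles: list[AnnotatedArticle],
    entities: dict[str, list[EntityMention]] | None = None,
    concepts: dict[str, list[ConceptMention]] | None = None,
    predications: dict[str, list[Predication]] | None = None,
    labels: dict[str, int] | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    name: str = "corpus",
) -> Corpus:
    """Join the per-source readers' outputs into a validated Corpus."""
    for a in articles:
        if entities and a.pmid in entities:
            a.entities = list(entities[a.pmid])
        if concepts and a.pmid in concepts:
            a.concepts = list(concepts[a.pmid])
        if predications and a.pmid in predications:
            a.predications = list(predications[a.pmid])
        if labels and a.pmid in labels:
            a.label = labels[a.pmid]
        if gene_sets and a.pmid in gene_sets and a.label == 1:
            a.curated_genes = set(gene_sets[a.pmid])
    corpus = Corpus(articles=articles, name=name)
    corpus.validate()
    return corpus
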