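"""Synthetic annotated corpora with controllable label signal.

The generator emulates the statistical structure of the four annotation
sources (PubMed text + MeSH, PubTator entities, MetaMap concepts, SemRep
predications) for a disease-gene curation task.  Each signal channel
plants, with probability equal to its strength, the characteristic
evidence its feature set keys on:

* ``mesh`` — a disease heading with a major "Genetics" qualifier;
* ``predication`` — a GENE-ASSOCIATED_WITH-DISO predication;
* ``significance`` — a significance CUI co-occurring with a gene concept
  (negatives instead receive negated-significance sentences);
* ``species`` — a human LIVB concept co-occurring with a gene concept
  (negatives: human concept in a gene-free sentence);
* ``semtype`` — a Genetic Function concept co-occurring with a gene
  (negatives: the same semtype without a gene);
* ``gene_count`` — elevated PubTator gene-mention counts.

With all strengths at 0 the annotation distributions are identical in
both classes, so feature matrices carry no label information.  Curated
gene sets for positive articles are drawn Zipf-weighted so they overlap
across articles: gene recall and article recall then genuinely differ.

Generated text is template-based English-like filler with planted entity
surface forms; realism is not a goal — deterministic parser round-trip
fidelity is.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from lxml import etree

from .corpus import (
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
from .readers import (
    assemble_corpus,
    read_gene_sets,
    read_labels,
    read_metamap,
    read_pubmed_xml,
    read_pubtator,
    read_semrep,
)

__all__ = [
    "CHANNELS",
    "SyntheticConfig",
    "generate_corpus",
    "write_fixture_files",
    "read_fixture_files",
    "corpora_equivalent",
]

CHANNELS = ("mesh", "predication", "significance", "species", "semtype", "gene_count")

_DISEASE_CUI = "C0032914"  # Pre-Eclampsia
_HUMAN_CUI = "C0086418"  # Humans
_SIG_CUI = "C0237881"  # Statistical Significance (packaged default list)
_NEG_CUI = "C0205160"  # Negative (packaged default list)
_GENF_CUI = "C0017343"  # Genetic Function

_BG_SEMTYPES = ("fndg", "tmco", "topp", "bpoc", "qlco", "diap", "popg", "celf")

_SEMGROUPS = default_semgroup_table()

_FILLERS = (
    "The cohort comprised {n} participants recruited from two clinical centers.",
    "Baseline characteristics were recorded at enrollment and at delivery.",
    "Statistical analyses were adjusted for maternal age and parity.",
    "Samples were processed according to a standardized laboratory protocol.",
    "Outcomes were assessed by investigators blinded to exposure status.",
    "The study protocol was approved by the institutional review board.",
    "Follow-up visits were scheduled at regular intervals during gestation.",
    "Data were collected prospectively using structured case report forms.",
)


@dataclass(frozen=True)
class SyntheticConfig:
    n_articles: int = 500
    prevalence: float = 0.337
    seed: int = 0
    signal: dict[str, float] = field(
        default_factory=lambda: {ch: 0.9 for ch in CHANNELS}
    )
    genes_per_positive: tuple[int, int] = (1, 4)
    n_genes: int = 120
    n_cuis: int = 300
    n_semtypes: int = 8
    n_mesh_headings: int = 40
    sentence_count: tuple[int, int] = (3, 7)

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        for ch, s in self.signal.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown signal channel {ch!r}")
            if not 0 <= s <= 1:
                raise ValueError(f"signal strength for {ch} must be in [0, 1]")


@dataclass
class _Gene:
    symbol: str
    entrez: str
    cui: str


def _zipf_weights(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


class _ArticleBuilder:
    """Accumulates sentences and annotations; title occupies index 0."""

    def __init__(self, pmid: str, title: str):
        self.pmid = pmid
        self.title = title
        self.abstract_sentences: list[str] = []
        self.concepts: list[ConceptMention] = []
        self.predications: list[Predication] = []
        self.entities: list[tuple[str, str, str, int]] = []  # surface, kind, id, sent idx

    def add_sentence(self, text: str) -> int:
        self.abstract_sentences.append(text)
        return len(self.abstract_sentences)  # title is sentence 0

    def gene_concept(self, gene: _Gene, idx: int) -> None:
        self.concept(gene.cui, f"{gene.symbol} gene", {"gngm"}, idx)

    def concept(self, cui, name, semtypes, idx) -> None:
        # groups derived via the same table the readers use, so the
        # fixture-file round-trip is exact
        self.concepts.append(
            ConceptMention(
                cui=cui,
                preferred_name=name,
                semtypes=frozenset(semtypes),
                semgroups=groups_for(semtypes, _SEMGROUPS),
                sentence_index=idx,
            )
        )


def generate_corpus(cfg: SyntheticConfig) -> Corpus:
    """Generate a fully annotated, labeled corpus; reproducible from seed."""
    n = cfg.n_articles
    n_pos = int(round(cfg.prevalence * n))
    if n_pos < 1 or n - n_pos < 1:
        raise ValueError(
            f"impossible config: {n} articles at prevalence {cfg.prevalence} "
            "leaves an empty class"
        )
    rng = np.random.default_rng(cfg.seed)
    genes = [
        _Gene(symbol=f"TRG{i + 1}", entrez=str(7001 + i), cui=f"C31{i:05d}")
        for i in range(cfg.n_genes)
    ]
    gene_w = _zipf_weights(cfg.n_genes)
    bg_semtypes = _BG_SEMTYPES[: max(1, min(cfg.n_semtypes, len(_BG_SEMTYPES)))]
    headings = [f"Research Topic {j + 1}" for j in range(cfg.n_mesh_headings)]
    labels = np.zeros(n, dtype=int)
    labels[rng.permutation(n)[:n_pos]] = 1
    sig = {ch: float(cfg.signal.get(ch, 0.0)) for ch in CHANNELS}

    def draw_gene() -> _Gene:
        return genes[int(rng.choice(cfg.n_genes, p=gene_w))]

    articles: list[AnnotatedArticle] = []
    for i in range(n):
        label = int(labels[i])
        pmid = str(9100000 + i)
        fired = {ch: label == 1 and rng.random() < sig[ch] for ch in CHANNELS}
        neg_fired = {ch: label == 0 and rng.random() < sig[ch] for ch in CHANNELS}
        planted: list[_Gene] = []

        count_genes: list[_Gene] = []
        if fired["gene_count"]:
            count_genes = [draw_gene(), draw_gene()]
        title_sym = count_genes[0].symbol if count_genes else None
        title = (
            f"{title_sym} and preeclampsia risk in a genetic cohort study"
            if title_sym
            else f"Clinical and genetic correlates of preeclampsia in cohort {i + 1}"
        )
        b = _ArticleBuilder(pmid, title)
        if count_genes:
            b.entities.append((count_genes[0].symbol, "GENE", count_genes[0].entrez, 0))
            planted.append(count_genes[0])

        n_fill = int(rng.integers(cfg.sentence_count[0], cfg.sentence_count[1] + 1))
        for _ in range(n_fill):
            tpl = _FILLERS[int(rng.integers(len(_FILLERS)))]
            idx = b.add_sentence(tpl.format(n=int(rng.integers(40, 900))))
            if rng.random() < 0.5:  # label-independent background concept
                j = int(rng.integers(cfg.n_cuis))
                st = bg_semtypes[int(rng.integers(len(bg_semtypes)))]
                b.concept(f"C20{j:05d}", f"Background concept {j}", {st}, idx)
            if rng.random() < 0.4:  # label-independent quantitative concept
                j = int(rng.integers(50))
                b.concept(f"C12{j:05d}", f"Quantitative value {j}", {"qnco"}, idx)

        if rng.random() < 0.3:  # background gene mention, both classes
            g = draw_gene()
            idx = b.add_sentence(f"Expression of {g.symbol} was recorded during routine assays.")
            b.entities.append((g.symbol, "GENE", g.entrez, idx))

        if fired["predication"]:
            g = draw_gene()
            planted.append(g)
            idx = b.add_sentence(
                f"The gene {g.symbol} was associated with preeclampsia in affected pregnancies."
            )
            b.gene_concept(g, idx)
            b.concept(_DISEASE_CUI, "Pre-Eclampsia", {"dsyn"}, idx)
            b.predications.append(
                Predication(
                    subject_cui=g.cui,
                    subject_group="GENE",
                    predicate="ASSOCIATED_WITH",
                    object_cui=_DISEASE_CUI,
                    object_group="DISO",
                    sentence_index=idx,
                )
            )
        elif neg_fired["predication"]:
            idx = b.add_sentence("Standard care was compared with expectant management for preeclampsia.")
            b.concept(_DISEASE_CUI, "Pre-Eclampsia", {"dsyn"}, idx)
            b.predications.append(
                Predication(
                    subject_cui="C0087111",
                    subject_group="PROC",
                    predicate="TREATS",
                    object_cui=_DISEASE_CUI,
                    object_group="DISO",
                    sentence_index=idx,
                )
            )

        if fired["significance"]:
            g = draw_gene()
            planted.append(g)
            idx = b.add_sentence(
                f"The association with {g.symbol} reached statistical significance in the adjusted model."
            )
            b.concept(_SIG_CUI, "Statistical Significance", {"qnco"}, idx)
            b.gene_concept(g, idx)
        elif neg_fired["significance"]:
            idx = b.add_sentence("No comparison reached statistical significance in the cohort.")
            b.concept(_SIG_CUI, "Statistical Significance", {"qnco"}, idx)
            b.concept(_NEG_CUI, "Negative", {"qlco"}, idx)

        if fired["species"]:
            g = draw_gene()
            planted.append(g)
            idx = b.add_sentence(
                f"Gene expression of {g.symbol} was profiled in human placental tissue."
            )
            b.concept(_HUMAN_CUI, "Humans", {"humn"}, idx)
            b.gene_concept(g, idx)
        elif neg_fired["species"]:
            idx = b.add_sentence("Clinical records of human participants were reviewed retrospectively.")
            b.concept(_HUMAN_CUI, "Humans", {"humn"}, idx)

        if fired["semtype"]:
            g = draw_gene()
            planted.append(g)
            idx = b.add_sentence(
                f"Genetic function of {g.symbol} was characterized in trophoblast cells."
            )
            b.concept(_GENF_CUI, "Genetic Function", {"genf"}, idx)
            b.gene_concept(g, idx)
        elif neg_fired["semtype"]:
            idx = b.add_sentence("Genetic function was discussed in relation to placental physiology.")
            b.concept(_GENF_CUI, "Genetic Function", {"genf"}, idx)

        if count_genes:
            ga, gb = count_genes
            idx = b.add_sentence(
                f"Levels of {ga.symbol} and {gb.symbol} were measured and {ga.symbol} "
                "was elevated in cases."
            )
            reps = int(rng.integers(2, 5))
            for _ in range(reps):
                b.entities.append((ga.symbol, "GENE", ga.entrez, idx))
            b.entities.append((gb.symbol, "GENE", gb.entrez, idx))
            planted.append(gb)

        mesh: list[MeshDescriptor] = []
        if fired["mesh"]:
            mesh.append(
                MeshDescriptor(
                    heading="Pre-Eclampsia",
                    heading_major=False,
                    qualifiers=(("genetics", True),),
                )
            )
        for _ in range(int(rng.integers(1, 4))):  # background headings, both classes
            h = headings[int(rng.integers(len(headings)))]
            if any(d.heading == h for d in mesh):
                continue
            mesh.append(MeshDescriptor(heading=h, heading_major=bool(rng.random() < 0.3)))

        curated: set[str] = set()
        if label == 1:
            k = int(rng.integers(cfg.genes_per_positive[0], cfg.genes_per_positive[1] + 1))
            curated = {draw_gene().symbol for _ in range(k)} | {g.symbol for g in planted}

        abstract = " ".join(b.abstract_sentences)
        sentences = segment_sentences(title, abstract)
        assert len(sentences) == 1 + len(b.abstract_sentences), pmid
        article = AnnotatedArticle(
            pmid=pmid,
            title=title,
            abstract=abstract,
            sentences=sentences,
            mesh=mesh,
            entities=[
                EntityMention(
                    kind=kind,
                    identifier=ident,
                    surface=surface,
                    sentence_index=si,
                    zone=sentences[si].zone,
                )
                for surface, kind, ident, si in b.entities
            ],
            concepts=b.concepts,
            predications=b.predications,
            label=label,
            curated_genes=curated,
            year=2000 + int(rng.integers(0, 20)),
        )
        article.validate()
        articles.append(article)
    corpus = Corpus(articles=articles, name=f"synthetic-seed{cfg.seed}")
    corpus.validate(require_labels=True)
    return corpus


def write_fixture_files(corpus: Corpus, directory: str | Path) -> dict[str, Path]:
    """Emit the four ingestion formats plus label and gene files.

    The files are valid inputs for the corresponding readers, and
    re-reading them reconstructs the corpus exactly (see
    :func:`read_fixture_files` / :func:`corpora_equivalent`).
    """
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise IOError(f"cannot create fixture directory {directory}: {exc}") from exc
    paths = {
        "pubmed": directory / "pubmed.xml",
        "pubtator": directory / "annotations.pubtator",
        "metamap": directory / "concepts.mmi",
        "semrep": directory / "predications.semrep",
        "labels": directory / "labels.tsv",
        "genes": directory / "genes.tsv",
    }

    root = etree.Element("PubmedArticleSet")
    for a in corpus.articles:
        rec = etree.SubElement(root, "PubmedArticle")
        cit = etree.SubElement(rec, "MedlineCitation")
        etree.SubElement(cit, "PMID").text = a.pmid
        art = etree.SubElement(cit, "Article")
        etree.SubElement(art, "ArticleTitle").text = a.title
        if a.abstract:
            abst = etree.SubElement(art, "Abstract")
            etree.SubElement(abst, "AbstractText").text = a.abstract
        if a.year is not None:
            journal = etree.SubElement(art, "Journal")
            issue = etree.SubElement(journal, "JournalIssue")
            pubdate = etree.SubElement(issue, "PubDate")
            etree.SubElement(pubdate, "Year").text = str(a.year)
        if a.mesh:
            mhl = etree.SubElement(cit, "MeshHeadingList")
            for d in a.mesh:
                mh = etree.SubElement(mhl, "MeshHeading")
                dn = etree.SubElement(mh, "DescriptorName")
                dn.text = d.heading
                dn.set("MajorTopicYN", "Y" if d.heading_major else "N")
                for qname, qmajor in d.qualifiers:
                    qn = etree.SubElement(mh, "QualifierName")
                    qn.text = qname
                    qn.set("MajorTopicYN", "Y" if qmajor else "N")
    paths["pubmed"].write_bytes(
        etree.tostring(root, pretty_print=True, xml_declaration=True, encoding="UTF-8")
    )

    pub_lines: list[str] = []
    mmi_lines: list[str] = []
    sem_lines: list[str] = []
    for a in corpus.articles:
        spans = sentence_spans(a.title, a.abstract)
        text = a.title + (" " + a.abstract if a.abstract else "")
        total = len(text)
        pub_lines.append(f"{a.pmid}|t|{a.title}")
        pub_lines.append(f"{a.pmid}|a|{a.abstract}")
        cursors: dict[tuple[int, str], int] = {}
        for e in a.entities:
            s_start, s_end = spans[e.sentence_index]
            key = (e.sentence_index, e.surface)
            start = text.find(e.surface, cursors.get(key, s_start), s_end)
            if start < 0:
                start = s_start  # surface absent from text: anchor at the sentence
            cursors[key] = start + 1
            end = min(start + len(e.surface), total)
            kind = e.kind.capitalize()
            pub_lines.append(
                f"{a.pmid}\t{start}\t{end}\t{e.surface}\t{kind}\t{e.identifier}"
            )
        pub_lines.append("")
        for c in a.concepts:
            start = spans[c.sentence_index][0]
            st = ",".join(sorted(c.semtypes))
            mmi_lines.append(
                f"{a.pmid}|MMI|5.00|{c.preferred_name}|{c.cui}|[{st}]|"
                f'|TI;AB|{start}/5|'
            )
        for p in a.predications:
            st_s = _semtype_for_group(p.subject_group)
            st_o = _semtype_for_group(p.object_group)
            utt = (
                "ti.1"
                if p.sentence_index == 0
                else f"ab.{p.sentence_index}"
            )
            sem_lines.append(
                f"{a.pmid}|{utt}|{p.subject_cui}|subject|{st_s}|{p.predicate}|"
                f"{p.object_cui}|object|{st_o}"
            )
    paths["pubtator"].write_text("\n".join(pub_lines) + "\n")
    paths["metamap"].write_text("\n".join(mmi_lines) + ("\n" if mmi_lines else ""))
    paths["semrep"].write_text("\n".join(sem_lines) + ("\n" if sem_lines else ""))
    paths["labels"].write_text(
        "".join(f"{a.pmid}\t{a.label}\n" for a in corpus.articles if a.label is not None)
    )
    paths["genes"].write_text(
        "".join(
            f"{a.pmid}\t{g}\n" for a in corpus.articles for g in sorted(a.curated_genes)
        )
    )
    return paths


_GROUP_SEMTYPE = {
    "GENE": "gngm",
    "DISO": "dsyn",
    "LIVB": "humn",
    "CHEM": "aapp",
    "CONC": "qnco",
    "PROC": "topp",
    "PHYS": "genf",
    "ANAT": "tisu",
}


def _semtype_for_group(group: str) -> str:
    return _GROUP_SEMTYPE.get(group, "fndg")


def read_fixture_files(directory: str | Path, name: str = "corpus") -> Corpus:
    """Reconstruct a corpus from files written by :func:`write_fixture_files`."""
    directory = Path(directory)
    articles = read_pubmed_xml(directory / "pubmed.xml")
    texts = {a.pmid: (a.title, a.abstract) for a in articles}
    return assemble_corpus(
        articles,
        entities=read_pubtator(directory / "annotations.pubtator"),
        concepts=read_metamap(directory / "concepts.mmi", texts=texts),
        predications=read_semrep(directory / "predications.semrep"),
        labels=read_labels(directory / "labels.tsv"),
        gene_sets=(
            read_gene_sets(directory / "genes.tsv")
            if (directory / "genes.tsv").read_text().strip()
            else None
        ),
        name=name,
    )


def corpora_equivalent(a: Corpus, b: Corpus) -> bool:
    """Field-level equality, order-insensitive for annotation lists."""
    if len(a) != len(b):
        return False
    for x, y in zip(a.articles, b.articles):
        if (
            x.pmid != y.pmid
            or x.title != y.title
            or x.abstract != y.abstract
            or x.sentences != y.sentences
            or x.mesh != y.mesh
            or x.label != y.label
            or x.year != y.year
            or x.curated_genes != y.curated_genes
        ):
            return False
        if sorted(map(repr, x.entities)) != sorted(map(repr, y.entities)):
            return False
        if sorted(map(repr, x.concepts)) != sorted(map(repr, y.concepts)):
            return False
        if sorted(map(repr, x.predications)) != sorted(map(repr, y.predications)):
            return False
    return True
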