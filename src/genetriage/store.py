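"""Embedded relational annotation store.

All articles, sentences, MeSH rows, entity/concept mentions and
predications are persisted in a single SQLite file with the same logical
schema a server-backed deployment would use (tables: articles,
sentences, mesh, mesh_qualifiers, entities, concepts, predications,
curated_genes).  The point is queryability — e.g. "all unique gene
identifiers mentioned in titles" is one SQL statement — plus an exact
round-trip: ``load_corpus(store_corpus(c)) == c`` field for field.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

from .corpus import (
    AnnotatedArticle,
    ConceptMention,
    Corpus,
    EntityMention,
    MeshDescriptor,
    Predication,
    Sentence,
)

__all__ = ["AnnotationStore", "store_corpus", "load_corpus"]

_SCHEMA = """
CREATE TABLE meta (key TEXT PRIMARY KEY, value TEXT);
CREATE TABLE articles (
    pmid TEXT PRIMARY KEY, title TEXT, abstract TEXT,
    label INTEGER, year INTEGER, ord INTEGER
);
CREATE TABLE sentences (
    pmid TEXT, idx INTEGER, zone TEXT, text TEXT,
    PRIMARY KEY (pmid, idx)
);
CREATE TABLE mesh (
    pmid TEXT, ord INTEGER, heading TEXT, heading_major INTEGER,
    PRIMARY KEY (pmid, ord)
);
CREATE TABLE mesh_qualifiers (
    pmid TEXT, ord INTEGER, qord INTEGER, name TEXT, major INTEGER,
    PRIMARY KEY (pmid, ord, qord)
);
CREATE TABLE entities (
    pmid TEXT, ord INTEGER, kind TEXT, identifier TEXT, surface TEXT,
    sentence_index INTEGER, zone TEXT, PRIMARY KEY (pmid, ord)
);
CREATE TABLE concepts (
    pmid TEXT, ord INTEGER, cui TEXT, preferred_name TEXT,
    semtypes TEXT, semgroups TEXT, sentence_index INTEGER,
    PRIMARY KEY (pmid, ord)
);
CREATE TABLE predications (
    pmid TEXT, ord INTEGER, subject_cui TEXT, subject_group TEXT,
    predicate TEXT, object_cui TEXT, object_group TEXT,
    sentence_index INTEGER, PRIMARY KEY (pmid, ord)
);
CREATE TABLE curated_genes (
    pmid TEXT, gene TEXT, PRIMARY KEY (pmid, gene)
);
"""


def _join(items) -> str:
    return "\x1f".join(sorted(items))


def _split(text: str) -> frozenset[str]:
    return frozenset(text.split("\x1f")) if text else frozenset()


class AnnotationStore:
    """Handle over the SQLite annotation database."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self.connection = sqlite3.connect(str(self.path))

    def query(self, sql: str, params=()) -> list[tuple]:
        return self.connection.execute(sql, params).fetchall()

    def close(self) -> None:
        self.connection.close()

    def __enter__(self) -> "AnnotationStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()


def store_corpus(corpus: Corpus, path: str | Path) -> AnnotationStore:
    """Persist a corpus; overwrites any existing file at ``path``."""
    path = Path(path)
    if path.exists():
        path.unlink()
    try:
        store = AnnotationStore(path)
    except sqlite3.OperationalError as exc:
        raise IOError(f"cannot open annotation store at {path}: {exc}") from exc
    con = store.connection
    con.executescript(_SCHEMA)
    con.execute("INSERT INTO meta VALUES ('name', ?)", (corpus.name,))
    for ord_, a in enumerate(corpus.articles):
        con.execute(
            "INSERT INTO articles VALUES (?,?,?,?,?,?)",
            (a.pmid, a.title, a.abstract, a.label, a.year, ord_),
        )
        con.executemany(
            "INSERT INTO sentences VALUES (?,?,?,?)",
            [(a.pmid, s.index, s.zone, s.text) for s in a.sentences],
        )
        for i, d in enumerate(a.mesh):
            con.execute(
                "INSERT INTO mesh VALUES (?,?,?,?)",
                (a.pmid, i, d.heading, int(d.heading_major)),
            )
            con.executemany(
                "INSERT INTO mesh_qualifiers VALUES (?,?,?,?,?)",
                [(a.pmid, i, j, q, int(m)) for j, (q, m) in enumerate(d.qualifiers)],
            )
        con.executemany(
            "INSERT INTO entities VALUES (?,?,?,?,?,?,?)",
            [
                (a.pmid, i, e.kind, e.identifier, e.surface, e.sentence_index, e.zone)
                for i, e in enumerate(a.entities)
            ],
        )
        con.executemany(
            "INSERT INTO concepts VALUES (?,?,?,?,?,?,?)",
            [
                (a.pmid, i, c.cui, c.preferred_name, _join(c.semtypes),
                 _join(c.semgroups), c.sentence_index)
                for i, c in enumerate(a.concepts)
            ],
        )
        con.executemany(
            "INSERT INTO predications VALUES (?,?,?,?,?,?,?,?)",
            [
                (a.pmid, i, p.subject_cui, p.subject_group, p.predicate,
                 p.object_cui, p.object_group, p.sentence_index)
                for i, p in enumerate(a.predications)
            ],
        )
        con.executemany(
            "INSERT INTO curated_genes VALUES (?,?)",
            [(a.pmid, g) for g in sorted(a.curated_genes)],
        )
    con.commit()
    return store


def load_corpus(path: str | Path | AnnotationStore) -> Corpus:
    store = path if isinstance(path, AnnotationStore) else AnnotationStore(path)
    con = store.connection
    (name,) = con.execute("SELECT value FROM meta WHERE key='name'").fetchone()
    articles: list[AnnotatedArticle] = []
    rows = con.execute(
        "SELECT pmid, title, abstract, label, year FROM articles ORDER BY ord"
    ).fetchall()
    for pmid, title, abstract, label, year in rows:
        sentences = [
            Sentence(index=i, zone=z, text=t)
            for i, z, t in con.execute(
                "SELECT idx, zone, text FROM sentences WHERE pmid=? ORDER BY idx", (pmid,)
            )
        ]
        mesh = []
        for ord_, heading, major in con.execute(
            "SELECT ord, heading, heading_major FROM mesh WHERE pmid=? ORDER BY ord", (pmid,)
        ):
            quals = tuple(
                (q, bool(m))
                for q, m in con.execute(
                    "SELECT name, major FROM mesh_qualifiers WHERE pmid=? AND ord=? ORDER BY qord",
                    (pmid, ord_),
                )
            )
            mesh.append(MeshDescriptor(heading=heading, heading_major=bool(major), qualifiers=quals))
        entities = [
            EntityMention(kind=k, identifier=i_, surface=s, sentence_index=si, zone=z)
            for k, i_, s, si, z in con.execute(
                "SELECT kind, identifier, surface, sentence_index, zone "
                "FROM entities WHERE pmid=? ORDER BY ord",
                (pmid,),
            )
        ]
        concepts = [
            ConceptMention(
                cui=c, preferred_name=n, semtypes=_split(st),
                semgroups=_split(sg), sentence_index=si,
            )
            for c, n, st, sg, si in con.execute(
                "SELECT cui, preferred_name, semtypes, semgroups, sentence_index "
                "FROM concepts WHERE pmid=? ORDER BY ord",
                (pmid,),
            )
        ]
        predications = [
            Predication(
                subject_cui=sc, subject_group=sg, predicate=p,
                object_cui=oc, object_group=og, sentence_index=si,
            )
            for sc, sg, p, oc, og, si in con.execute(
                "SELECT subject_cui, subject_group, predicate, object_cui, object_group, "
                "sentence_index FROM predications WHERE pmid=? ORDER BY ord",
                (pmid,),
            )
        ]
        genes = {
            g for (g,) in con.execute("SELECT gene FROM curated_genes WHERE pmid=?", (pmid,))
        }
        articles.append(
            AnnotatedArticle(
                pmid=pmid, title=title, abstract=abstract, sentences=sentences,
                mesh=mesh, entities=entities, concepts=concepts,
                predications=predications, label=label,
                curated_genes=genes, year=year,
            )
        )
    if not isinstance(path, AnnotationStore):
        store.close()
    return Corpus(articles=articles, name=name)
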