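"""Readers for the four annotation-source file formats."""

import pytest

from genetriage.corpus import ABSTRACT, TITLE
from genetriage.readers import (
    PubMedParseError,
    ReaderWarnings,
    read_gene_sets,
    read_labels,
    read_metamap,
    read_pubmed_xml,
    read_pubtator,
    read_semrep,
)

_XML_HEAD = '<?xml version="1.0"?>\n<PubmedArticleSet>'
_XML_TAIL = "</PubmedArticleSet>"


def _record(pmid, title, abstract=None, mesh="", year="2015"):
    abstract_xml = (
        f"<Abstract><AbstractText>{abstract}</AbstractText></Abstract>" if abstract else ""
    )
    return f"""
<PubmedArticle><MedlineCitation>
  <PMID>{pmid}</PMID>
  <Article>
    <Journal><JournalIssue><PubDate><Year>{year}</Year></PubDate></JournalIssue></Journal>
    <ArticleTitle>{title}</ArticleTitle>
    {abstract_xml}
  </Article>
  {mesh}
</MedlineCitation></PubmedArticle>"""


class TestPubMedXML:
    def test_mesh_major_flags(self, tmp_path):
        mesh = """<MeshHeadingList><MeshHeading>
          <DescriptorName MajorTopicYN="N">Premature Birth</DescriptorName>
          <QualifierName MajorTopicYN="Y">genetics</QualifierName>
        </MeshHeading></MeshHeadingList>"""
        path = tmp_path / "a.xml"
        path.write_text(_XML_HEAD + _record("1", "T", "A.", mesh=mesh) + _XML_TAIL)
        (art,) = read_pubmed_xml(path)
        (d,) = art.mesh
        assert d.heading == "Premature Birth"
        assert d.heading_major is False
        assert d.qualifiers == (("genetics", True),)
        assert art.year == 2015

    def test_empty_set_and_missing_abstract_warning(self, tmp_path):
        empty = tmp_path / "empty.xml"
        empty.write_text(_XML_HEAD + _XML_TAIL)
        assert read_pubmed_xml(empty) == []

        three = tmp_path / "three.xml"
        three.write_text(
            _XML_HEAD
            + _record("1", "T1", "Has abstract.")
            + _record("2", "T2", None)
            + _record("3", "T3", "Also has one.")
            + _XML_TAIL
        )
        warnings = ReaderWarnings()
        records = read_pubmed_xml(three, warnings)
        assert len(records) == 3
        assert records[1].abstract == ""
        assert sum("no abstract" in m for m in warnings.messages) == 1

    def test_missing_pmid_skips_record_only(self, tmp_path):
        bad = "<PubmedArticle><MedlineCitation><Article><ArticleTitle>X</ArticleTitle></Article></MedlineCitation></PubmedArticle>"
        path = tmp_path / "m.xml"
        path.write_text(_XML_HEAD + bad + _record("2", "T2", "A.") + _XML_TAIL)
        warnings = ReaderWarnings()
        records = read_pubmed_xml(path, warnings)
        assert [a.pmid for a in records] == ["2"]
        assert any("PMID" in m for m in warnings.messages)

    def test_malformed_xml_names_position(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<PubmedArticleSet><PubmedArticle>")
        with pytest.raises(PubMedParseError, match="line"):
            read_pubmed_xml(path)


class TestPubTator:
    def test_zone_and_kind_mapping(self, tmp_path):
        title = "TNF in preeclampsia"
        abstract = "We measured TNF. Mice and humans were studied."
        lines = [
            f"9|t|{title}",
            f"9|a|{abstract}",
            "9\t0\t3\tTNF\tGene\t7124",
            f"9\t{len(title) + 1 + 12}\t{len(title) + 1 + 15}\tTNF\tGene\t7124",
            f"9\t{len(title) + 1 + 17}\t{len(title) + 1 + 21}\tMice\tSpecies\t10090",
        ]
        path = tmp_path / "p.txt"
        path.write_text("\n".join(lines) + "\n")
        mentions = read_pubtator(path)["9"]
        assert len(mentions) == 3
        assert mentions[0].zone == TITLE and mentions[0].sentence_index == 0
        assert mentions[1].zone == ABSTRACT and mentions[1].sentence_index == 1
        assert {m.kind for m in mentions} == {"GENE", "SPECIES"}

    def test_offset_beyond_text_is_record_level_error(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("9|t|Short\n9|a|Tiny.\n9\t900\t905\tXXX\tGene\t1\n")
        warnings = ReaderWarnings()
        mentions = read_pubtator(path, warnings)
        assert mentions["9"] == []
        assert any("beyond text length" in m for m in warnings.messages)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "e.txt"
        path.write_text("")
        assert read_pubtator(path) == {}


class TestMetaMapSemRep:
    def test_mmi_line_maps_to_sentence_and_groups(self, tmp_path):
        texts = {"9": ("TNF study", "We found an effect. It was big.")}
        start = len("TNF study") + 1 + len("We found an effect. ")
        path = tmp_path / "c.mmi"
        path.write_text(f"9|MMI|5.00|Disease|C0012634|[dsyn,fndg]||TI;AB|{start}/5|\n")
        (m,) = read_metamap(path, texts=texts)["9"]
        assert m.cui == "C0012634"
        assert m.sentence_index == 2
        assert m.semtypes == {"dsyn", "fndg"}
        assert m.semgroups == {"DISO"}

    def test_semrep_utterance_mapping(self, tmp_path):
        path = tmp_path / "s.sem"
        path.write_text(
            "9|ti.1|C3100001|TNF|gngm|ASSOCIATED_WITH|C0032914|Pre-Eclampsia|dsyn\n"
            "9|ab.2|C0032914|Pre-Eclampsia|dsyn|AFFECTS|C0086418|Humans|humn\n"
        )
        preds = read_semrep(path)["9"]
        assert preds[0].sentence_index == 0
        assert (preds[0].subject_group, preds[0].object_group) == ("GENE", "DISO")
        assert preds[1].sentence_index == 2
        assert preds[1].object_group == "LIVB"


def test_labels_and_gene_files(tmp_path):
    (tmp_path / "labels.tsv").write_text("1\t1\n2\t0\n# comment\n3\t1\n")
    assert read_labels(tmp_path / "labels.tsv") == {"1": 1, "2": 0, "3": 1}
    (tmp_path / "genes.tsv").write_text("1\tTNF\n1\tTP53\n3\tAPOE\n")
    assert read_gene_sets(tmp_path / "genes.tsv") == {"1": {"TNF", "TP53"}, "3": {"APOE"}}
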