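from __future__ import annotations

import random

import pandas as pd
import pytest

from nuoscan.formats_io import (
    AssemblyLevel,
    GeneCall,
    GenomeMetadata,
    ParseError,
    RepliconType,
    curate_genomes,
    dedupe_hits,
    read_gene_calls,
    read_hmm_hits,
    read_metadata,
    read_table,
    write_metadata,
    write_table,
)

TBLOUT = """\
# comment line
#                                  --- full sequence ----
# target name        accession  query name accession   E-value  score  bias ...
geneA                -          NuoB       -            3.2e-50  170.1   0.1   1e-49  169.0  0.1  1.0  1  0  0  1  1  1  1 -
geneB                -          NuoCD      -            1.5e-80  260.0   0.0   2e-80  259.0  0.0  1.0  1  0  0  1  1  1  1 -
# trailing comment
"""

# one protein with two domain rows: a fused gene seen by two profiles
DOMTBLOUT = """\
# target name  accession tlen query name accession qlen  E-value score bias # of c-Evalue i-Evalue score bias hmm_from hmm_to ali_from ali_to env_from env_to acc description
geneF - 620 NuoC - 200 2.0e-60 201.0 0.1 1 2 1e-60 2e-60 100.0 0.1 1 200 1 198 1 200 0.98 -
geneF - 620 NuoD - 410 4.0e-70 230.0 0.2 2 2 2e-70 4e-70 120.0 0.2 1 410 205 616 203 618 0.97 -
"""


class TestReadHmmHits:
    def test_tblout_skips_comments(self, tmp_path):
        p = tmp_path / "hits.tblout"
        p.write_text(TBLOUT)
        hits = read_hmm_hits(p, dialect="tblout")
        assert len(hits) == 2
        assert hits[0].gene_id == "geneA"
        assert hits[0].profile == "NuoB"
        assert hits[0].evalue == 3.2e-50
        assert hits[0].bitscore == 170.1
        assert hits[0].env_from is None

    def test_domtblout_two_domains_one_protein(self, tmp_path):
        p = tmp_path / "hits.domtblout"
        p.write_text(DOMTBLOUT)
        hits = read_hmm_hits(p, dialect="domtblout")
        assert len(hits) == 2
        assert {h.gene_id for h in hits} == {"geneF"}
        by_profile = {h.profile: h for h in hits}
        assert by_profile["NuoC"].evalue == 2.0e-60
        assert (by_profile["NuoC"].env_from, by_profile["NuoC"].env_to) == (1, 200)
        assert (by_profile["NuoD"].env_from, by_profile["NuoD"].env_to) == (203, 618)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.tblout"
        p.write_text("geneA - NuoB - not_a_number 10 0.1 1 1 1 1 1 1 1 1 1 1 1\n")
        with pytest.raises(ParseError, match="bad.tblout:1"):
            read_hmm_hits(p, dialect="tblout")

    def test_empty_file_gives_empty_list(self, tmp_path, caplog):
        p = tmp_path / "empty.tblout"
        p.write_text("# nothing here\n")
        assert read_hmm_hits(p, dialect="tblout") == []

    def test_order_independence(self, tmp_path):
        lines = [l for l in TBLOUT.splitlines() if not l.startswith("#")]
        p1, p2 = tmp_path / "a.tblout", tmp_path / "b.tblout"
        p1.write_text("\n".join(lines) + "\n")
        p2.write_text("\n".join(reversed(lines)) + "\n")
        assert set(read_hmm_hits(p1, "tblout")) == set(read_hmm_hits(p2, "tblout"))

    def test_duplicate_rows_keep_smallest_evalue(self):
        from conftest import make_hit

        hits = [make_hit("g1", "NuoB", 1e-10), make_hit("g1", "NuoB", 1e-40)]
        kept = dedupe_hits(hits)
        assert len(kept) == 1
        assert kept[0].evalue == 1e-40


GFF3 = """\
##gff-version 3
chr1\tprodigal\tCDS\t100\t400\t.\t+\t0\tID=gene1
chr1\tprodigal\tCDS\t600\t1200\t.\t-\t0\tID=gene2
p1_plasmid\tprodigal\tCDS\t10\t310\t.\t+\t0\tID=gene3
"""


class TestReadGeneCalls:
    def test_gff3_fields(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF3)
        genes = read_gene_calls(p, dialect="gff3", genome_id="G1")
        by_id = {g.gene_id: g for g in genes}
        g1 = by_id["gene1"]
        assert (g1.start, g1.end, g1.strand) == (100, 400, "+")
        assert g1.protein_length == (400 - 100 + 1) // 3 - 1
        assert by_id["gene2"].strand == "-"

    def test_plasmid_keyword_typing(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF3)
        genes = read_gene_calls(p, dialect="gff3", genome_id="G1")
        by_id = {g.gene_id: g for g in genes}
        assert by_id["gene3"].replicon_type is RepliconType.PLASMID
        assert by_id["gene1"].replicon_type is RepliconType.UNKNOWN

    def test_explicit_replicon_map_beats_keyword(self, tmp_path):
        p = tmp_path / "genes.gff3"
        p.write_text(GFF3)
        genes = read_gene_calls(
            p, dialect="gff3", genome_id="G1",
            replicon_types={"p1_plasmid": "chromosome"},
        )
        by_id = {g.gene_id: g for g in genes}
        assert by_id["gene3"].replicon_type is RepliconType.CHROMOSOME

    def test_prodigal_defline(self, tmp_path):
        p = tmp_path / "prot.faa"
        p.write_text(">ctg1_1 # 2 # 308 # 1 # ID=1_1;partial=00\nMKT\n")
        genes = read_gene_calls(p, dialect="prodigal_headers", genome_id="G1")
        (g,) = genes
        assert (g.start, g.end, g.strand) == (2, 308, "+")
        # (308 - 2 + 1) / 3 - 1 = 101, computed by hand
        assert g.protein_length == 101
        assert g.replicon_id == "ctg1"

    def test_prodigal_unknown_strand_errors(self, tmp_path):
        p = tmp_path / "prot.faa"
        p.write_text(">ctg1_1 # 2 # 308 # 5 # ID=1_1\nMKT\n")
        with pytest.raises(ParseError, match="strand"):
            read_gene_calls(p, dialect="prodigal_headers")


def _meta(**kw) -> GenomeMetadata:
    base = dict(
        genome_id="G1",
        assembly_level=AssemblyLevel.COMPLETE,
        phylum="Pseudomonadota",
        genus="Escherichia",
        species="Escherichia coli",
    )
    base.update(kw)
    return GenomeMetadata(**base)


class TestCurateGenomes:
    @pytest.mark.parametrize(
        "record, rule",
        [
            (_meta(candidatus_flag=True), "candidatus"),
            (_meta(phylum=""), "phylum"),
            (_meta(genus=""), "genus"),
            (_meta(assembly_level=AssemblyLevel.OTHER), "assembly_level"),
        ],
    )
    def test_exclusion_rules(self, record, rule):
        retained, excluded = curate_genomes([record])
        assert retained == []
        assert excluded[rule] == 1

    def test_fully_annotated_retained(self):
        retained, excluded = curate_genomes([_meta()])
        assert len(retained) == 1
        assert all(v == 0 for v in excluded.values())

    def test_idempotent_and_subset(self):
        records = [_meta(), _meta(genome_id="G2", phylum=""), _meta(genome_id="G3")]
        once, _ = curate_genomes(records)
        twice, _ = curate_genomes(once)
        assert twice == once
        assert all(r in records for r in once)


class TestTables:
    def test_write_table_round_trip(self, tmp_path):
        df = pd.DataFrame(
            {"genome_id": ["G2", "G1"], "variant": ["Absent", "Complete14"], "n": [0, 1]}
        )
        p = tmp_path / "t.tsv"
        write_table(df, p, sort_by=["genome_id"])
        back = read_table(p)
        assert list(back.columns) == ["genome_id", "variant", "n"]
        assert list(back["genome_id"]) == ["G1", "G2"]  # deterministic sort

    def test_metadata_round_trip(self, tmp_path):
        records = [
            _meta(contig_lengths=[400, 100], lifestyle="aerobe"),
            _meta(genome_id="G0", candidatus_flag=True),
        ]
        p = tmp_path / "meta.tsv"
        write_metadata(records, p)
        back = read_metadata(p)
        assert [r.genome_id for r in back] == ["G0", "G1"]
        g1 = next(r for r in back if r.genome_id == "G1")
        assert g1.contig_lengths == [400, 100]
        assert g1.lifestyle == "aerobe"
        g0 = next(r for r in back if r.genome_id == "G0")
        assert g0.candidatus_flag is True
        assert g0.lifestyle is None

    def test_metadata_rejects_nonpositive_contig(self, tmp_path):
        p = tmp_path / "meta.tsv"
        write_metadata([_meta(contig_lengths=[100])], p)
        text = (p.read_text()).replace("100", "0")
        p.write_text(text)
        with pytest.raises(ParseError):
            read_metadata(p)


def test_gene_call_invariants():
    with pytest.raises(ValueError):
        GeneCall("g", "G", "chr", 10, 5, "+", 10)
    with pytest.raises(ValueError):
        GeneCall("g", "G", "chr", 1, 30, "x", 9)
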