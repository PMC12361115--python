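from __future__ import annotations

import numpy as np
import pytest

from _oracles import max_disjoint_covers
from conftest import make_gene, make_hit
from nuoscan.formats_io import RepliconType
from nuoscan.hit_clustering import cluster_hits
from nuoscan.variant_classification import (
    Arrangement,
    PlasmidStatus,
    SubunitScheme,
    Variant,
    _count_complete_sets,
    aggregate_species,
    classify_genome,
    nuo_scheme,
    resolve_gene_subunits,
    summarize_by_rank,
)
from nuoscan.variant_classification import GenomeVariantCall, SpeciesSummary


class TestScheme:
    def test_default_nuo_scheme(self, scheme):
        assert len(scheme.subunits) == 14
        assert scheme.modules["N"] == {"NuoE", "NuoF", "NuoG"}
        assert scheme.fused_profiles["NuoCD"] == ("NuoC", "NuoD")
        assert frozenset({"NuoE", "NuoF"}) in scheme.complex_like_missing_sets

    def test_yaml_round_trip(self, scheme, tmp_path):
        import yaml

        p = tmp_path / "scheme.yaml"
        p.write_text(yaml.safe_dump(scheme.to_dict()))
        back = SubunitScheme.from_yaml(p)
        assert back.subunits == scheme.subunits
        assert back.required_for_complete == scheme.required_for_complete

    def test_fused_profile_outside_scheme_rejected(self):
        with pytest.raises(ValueError):
            SubunitScheme(
                name="bad",
                subunits=("A", "B"),
                modules={},
                fused_profiles={"AB": ("A", "Z")},
                required_for_complete=frozenset({"A", "B"}),
                complex_like_missing_sets=(),
            )


class TestResolveGeneSubunits:
    def test_fused_profile_expands(self, scheme):
        hits = [make_hit("g1", "NuoCD", 1e-80)]
        assert resolve_gene_subunits(hits, scheme) == {"NuoC", "NuoD"}

    def test_disjoint_envelopes_fuse(self, scheme):
        hits = [
            make_hit("g1", "NuoB", 1e-60, env=(1, 180)),
            make_hit("g1", "NuoC", 1e-55, env=(200, 380)),
        ]
        assert resolve_gene_subunits(hits, scheme) == {"NuoB", "NuoC"}

    def test_full_overlap_collapses_to_best(self, scheme):
        hits = [
            make_hit("g1", "NuoL", 1e-90, env=(1, 500)),
            make_hit("g1", "NuoM", 1e-60, env=(1, 500)),
        ]
        assert resolve_gene_subunits(hits, scheme) == {"NuoL"}

    def test_missing_envelopes_collapse_to_best(self, scheme):
        hits = [make_hit("g1", "NuoL", 1e-90), make_hit("g1", "NuoM", 1e-60)]
        assert resolve_gene_subunits(hits, scheme) == {"NuoL"}

    def test_hits_must_share_gene(self, scheme):
        with pytest.raises(ValueError):
            resolve_gene_subunits(
                [make_hit("g1", "NuoB"), make_hit("g2", "NuoC")], scheme
            )


def _operon(labels, genome="G1", replicon="chr", start=1, strand="+",
            rtype=RepliconType.UNKNOWN, evalue=1e-60):
    """Lay an operon of single-profile genes with 100 bp gaps."""
    genes, hits, pos = [], [], start
    for i, profile in enumerate(labels):
        g = make_gene(
            f"{genome}_{replicon}_{start}_{i}", pos, pos + 899, strand,
            genome=genome, replicon=replicon, plen=299, rtype=rtype,
        )
        genes.append(g)
        hits.append(make_hit(g.gene_id, profile, evalue))
        pos += 1000
    return genes, hits


ALL14 = [f"Nuo{c}" for c in "ABCDEFGHIJKLMN"]


def _classify(genes, hits, scheme, genome="G1"):
    clusters = cluster_hits(genes, hits, max_gap=250, scheme=scheme)
    gidx = {g.gene_id: g for g in genes}
    return classify_genome(clusters, hits, scheme, genes=gidx, genome_id=genome)


class TestClassifyGenome:
    def test_single_complete_cluster(self, scheme):
        genes, hits = _operon(ALL14)
        call = _classify(genes, hits, scheme)
        assert call.variant is Variant.COMPLETE14
        assert call.arrangement is Arrangement.SINGLE_CLUSTER
        assert call.n_complete_sets == 1
        assert call.on_plasmid is PlasmidStatus.NONE

    def test_fused_cd_variant(self, scheme):
        labels = ["NuoA", "NuoB", "NuoCD"] + [f"Nuo{c}" for c in "EFGHIJKLMN"]
        genes, hits = _operon(labels)
        call = _classify(genes, hits, scheme)
        assert call.variant is Variant.COMPLETE13_FUSED_CD
        assert call.fused_cd and not call.fused_bcd

    def test_fused_bcd_variant(self, scheme):
        labels = ["NuoA", "NuoBCD"] + [f"Nuo{c}" for c in "EFGHIJKLMN"]
        genes, hits = _operon(labels)
        call = _classify(genes, hits, scheme)
        assert call.variant is Variant.COMPLETE_FUSED_BCD

    @pytest.mark.parametrize("missing", [("NuoE", "NuoF"), ("NuoE", "NuoF", "NuoG")])
    def test_ci_like(self, scheme, missing):
        labels = [s for s in ALL14 if s not in missing]
        genes, hits = _operon(labels)
        assert _classify(genes, hits, scheme).variant is Variant.CI_LIKE

    def test_other_missing_sets_are_incomplete(self, scheme):
        labels = [s for s in ALL14 if s not in ("NuoL", "NuoM")]
        genes, hits = _operon(labels)
        assert _classify(genes, hits, scheme).variant is Variant.INCOMPLETE

    def test_absent(self, scheme):
        call = classify_genome([], [], scheme, genes={}, genome_id="G1")
        assert call.variant is Variant.ABSENT
        assert call.subunits_found == frozenset()
        assert call.arrangement is Arrangement.NONE

    def test_dual_copy(self, scheme):
        g1, h1 = _operon(ALL14, start=1)
        g2, h2 = _operon(ALL14, start=100000)
        # second copy needs distinct gene ids
        g2 = [
            make_gene(g.gene_id + "b", g.start, g.end, g.strand, genome=g.genome_id,
                      replicon=g.replicon_id, plen=g.protein_length)
            for g in g2
        ]
        h2 = [make_hit(h.gene_id + "b", h.profile, h.evalue) for h in h2]
        call = _classify(g1 + g2, h1 + h2, scheme)
        assert call.variant is Variant.COMPLETE14
        assert call.n_complete_sets == 2

    def test_split_arrangement(self, scheme):
        g1, h1 = _operon(ALL14[:7], start=1)
        g2, h2 = _operon(ALL14[7:], start=100000)
        call = _classify(g1 + g2, h1 + h2, scheme)
        assert call.variant is Variant.COMPLETE14
        assert call.arrangement is Arrangement.SPLIT

    def test_plasmid_exclusive(self, scheme):
        genes, hits = _operon(ALL14, replicon="plasmid_1", rtype=RepliconType.PLASMID)
        call = _classify(genes, hits, scheme)
        assert call.variant is Variant.COMPLETE14
        assert call.on_plasmid is PlasmidStatus.EXCLUSIVE

    def test_plasmid_partial(self, scheme):
        g1, h1 = _operon(ALL14[:13], replicon="chr")
        g2, h2 = _operon(ALL14[13:], replicon="plasmid_1", rtype=RepliconType.PLASMID)
        call = _classify(g1 + g2, h1 + h2, scheme)
        assert call.on_plasmid is PlasmidStatus.PARTIAL

    def test_deterministic_and_order_invariant(self, scheme):
        genes, hits = _operon(ALL14)
        call1 = _classify(genes, hits, scheme)
        call2 = _classify(list(reversed(genes)), list(reversed(hits)), scheme)
        assert call1 == call2


class TestGreedyCompleteSets:
    @pytest.mark.parametrize("seed", range(20))
    def test_matches_exhaustive_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        required = frozenset({"A", "B", "C", "D"})
        n_genes = int(rng.integers(1, 8))
        gene_sets = {
            f"g{i}": set(
                rng.choice(sorted(required), size=int(rng.integers(1, 5)),
                           replace=False)
            )
            for i in range(n_genes)
        }
        evalues = {g: float(10.0 ** -rng.uniform(5, 60)) for g in gene_sets}
        got = _count_complete_sets(gene_sets, evalues, required)
        oracle = max_disjoint_covers(gene_sets, required)
        assert got == oracle


class TestAggregateSpecies:
    def _call(self, gid, variant):
        return GenomeVariantCall(
            genome_id=gid, variant=variant, n_complete_sets=0,
            arrangement=Arrangement.NONE, on_plasmid=PlasmidStatus.NONE,
            subunits_found=frozenset(),
        )

    def test_consistent_species(self):
        calls = [self._call(f"G{i}", Variant.COMPLETE14) for i in range(3)]
        (summ,) = aggregate_species(calls, {f"G{i}": "sp1" for i in range(3)})
        assert summ.consistent and summ.n_strains == 3
        assert summ.representative_variant is Variant.COMPLETE14

    def test_inconsistent_species_lists_all_variants(self):
        calls = [
            self._call("G0", Variant.COMPLETE14),
            self._call("G1", Variant.COMPLETE13_FUSED_CD),
        ]
        (summ,) = aggregate_species(calls, {"G0": "sp1", "G1": "sp1"})
        assert not summ.consistent
        assert summ.variants_observed == {
            Variant.COMPLETE14, Variant.COMPLETE13_FUSED_CD,
        }
        # modal tie breaks toward the more complete variant
        assert summ.representative_variant is Variant.COMPLETE14

    def test_single_strain_consistent_and_unmapped_dropped(self):
        calls = [self._call("G0", Variant.ABSENT), self._call("G9", Variant.ABSENT)]
        summaries = aggregate_species(calls, {"G0": "sp1"})
        assert len(summaries) == 1
        assert summaries[0].consistent


class TestSummarizeByRank:
    def _summary(self, species, variant):
        return SpeciesSummary(
            species=species, n_strains=1, variants_observed=frozenset({variant}),
            consistent=True, representative_variant=variant,
        )

    def test_small_taxa_excluded_and_rows_sum_100(self):
        summaries = [
            self._summary(f"spA{i}", Variant.COMPLETE14) for i in range(4)
        ] + [self._summary(f"spA{i+4}", Variant.ABSENT) for i in range(6)]
        summaries += [self._summary(f"spB{i}", Variant.ABSENT) for i in range(9)]
        taxonomy = {s.species: s.species[2] for s in summaries}  # A or B
        table = summarize_by_rank(summaries, taxonomy, rank="phylum", min_species=10)
        assert list(table["phylum"]) == ["A"]  # B has 9 species, excluded
        row = table.iloc[0]
        assert row["Complete14"] == pytest.approx(40.0)
        assert row["Absent"] == pytest.approx(60.0)
        variant_cols = [v.value for v in Variant]
        assert row[variant_cols].sum() == pytest.approx(100.0, abs=0.01)
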