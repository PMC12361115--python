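"""Synthetic fixture generator with planted ground truth.

Emits gene coordinates, HMMER-style hits and genome metadata for a population
of simulated prokaryotic genomes in which every feature the pipeline must
recover is planted explicitly: same-strand subunit operons with bounded
intergenic gaps, split operons, dual operon copies, fused genes (emitted
either as fused-profile hits or as two tandem domain hits on one gene),
plasmid-borne operons, decoy homolog hits drawn from a separate, higher
e-value mixture component (mimicking HycG-like cross-hits on the NuoB
profile), multi-strain species and a handful of genomes that fail curation.
No sequence content is generated — only coordinates, lengths and scores.

Everything is drawn from one seeded generator stream, so a config (including
its seed) fully determines the dataset, byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from nuoscan.formats_io import (
    AssemblyLevel,
    GeneCall,
    GenomeMetadata,
    HmmHit,
    RepliconType,
    write_metadata,
    write_table,
)
from nuoscan.variant_classification import SubunitScheme, Variant, nuo_scheme

# Approximate subunit protein lengths (aa) of the E. coli enzyme.
DEFAULT_LENGTH_MODEL: dict[str, tuple[float, float]] = {
    "NuoA": (147, 12),
    "NuoB": (220, 18),
    "NuoC": (200, 16),
    "NuoD": (417, 33),
    "NuoE": (166, 13),
    "NuoF": (445, 36),
    "NuoG": (908, 73),
    "NuoH": (325, 26),
    "NuoI": (180, 14),
    "NuoJ": (184, 15),
    "NuoK": (100, 8),
    "NuoL": (613, 49),
    "NuoM": (509, 41),
    "NuoN": (485, 39),
}

# Lifestyle propensities per variant; they make the planted variant-lifestyle
# association detectable by the chi-square stage.
_LIFESTYLE_PROBS: dict[Variant, dict[str, float]] = {
    Variant.COMPLETE14: {"aerobe": 0.55, "facultative_anaerobe": 0.30,
                         "microaerobe": 0.05, "anaerobe": 0.10},
    Variant.COMPLETE13_FUSED_CD: {"aerobe": 0.50, "facultative_anaerobe": 0.35,
                                  "microaerobe": 0.05, "anaerobe": 0.10},
    Variant.COMPLETE_FUSED_BCD: {"aerobe": 0.05, "facultative_anaerobe": 0.15,
                                 "microaerobe": 0.10, "anaerobe": 0.70},
    Variant.CI_LIKE: {"aerobe": 0.05, "facultative_anaerobe": 0.15,
                      "microaerobe": 0.60, "anaerobe": 0.20},
    Variant.INCOMPLETE: {"aerobe": 0.20, "facultative_anaerobe": 0.40,
                         "microaerobe": 0.10, "anaerobe": 0.30},
    Variant.ABSENT: {"aerobe": 0.10, "facultative_anaerobe": 0.25,
                     "microaerobe": 0.05, "anaerobe": 0.60},
}


@dataclass
class SimulationConfig:
    """Stated world of the generator; defaults mirror the modelled biology.

    Intra-operon gaps are uniform on [0, gap_max] with gap_max = 100 bp (the
    regime in which real operon recovery levels off), distinct gene
    neighbourhoods sit at least ``inter_cluster_gap_min`` apart, genuine hits
    draw log10 e-values from the ``true_evalue_component`` normal and decoy
    homolog hits from the well-separated ``decoy_evalue_component``.
    """

    n_species: int = 40
    # probability of a species having 1, 2 or 3 strain genomes
    strains_per_species: tuple[float, ...] = (0.80, 0.15, 0.05)
    variant_mix: dict[Variant, float] = field(
        default_factory=lambda: {
            Variant.COMPLETE14: 0.30,
            Variant.COMPLETE13_FUSED_CD: 0.15,
            Variant.COMPLETE_FUSED_BCD: 0.10,
            Variant.CI_LIKE: 0.10,
            Variant.INCOMPLETE: 0.15,
            Variant.ABSENT: 0.20,
        }
    )
    gap_max: int = 100  # intra-operon intergenic gaps ~ U[0, gap_max]
    inter_cluster_gap_min: int = 2000
    true_evalue_component: tuple[float, float] = (-50.0, 2.0)  # log10 (mean, sd)
    decoy_evalue_component: tuple[float, float] = (-6.0, 2.0)
    decoy_rate: float = 3.0  # expected decoy hits per genome (Poisson)
    decoy_profile_bias: float = 0.6  # fraction of decoys hitting the NuoB profile
    fused_fraction: float = 0.7  # fused gene emitted as fused-profile hit
    plasmid_fraction: float = 0.06  # operon placed on a plasmid replicon
    split_fraction: float = 0.20  # complete operons split into two clusters
    dual_copy_fraction: float = 0.05  # complete genomes with two operon copies
    length_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_MODEL)
    )
    n_uncurated: int = 2  # extra genomes that fail metadata curation
    ensure_coverage: bool = True  # first species cover every planted category
    n_phyla: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.variant_mix.values())
        if not np.isclose(total, 1.0):
            raise ValueError("variant_mix probabilities must sum to 1")
        if self.decoy_evalue_component[0] <= self.true_evalue_component[0]:
            raise ValueError("decoy component mean must exceed true component mean")
        if self.inter_cluster_gap_min <= self.gap_max:
            raise ValueError("inter_cluster_gap_min must exceed gap_max")


@dataclass
class SimulatedDataset:
    genes: list[GeneCall]
    hits: list[HmmHit]
    metadata: list[GenomeMetadata]
    truth: pd.DataFrame  # one row per genome: planted labels for scoring
    hit_truth: pd.DataFrame  # one row per hit: genuine vs decoy
    scheme: SubunitScheme


# per-species planted features covering every category the classifier knows
_COVERAGE_PLAN: list[dict] = [
    {"variant": Variant.COMPLETE14},
    {"variant": Variant.COMPLETE13_FUSED_CD},
    {"variant": Variant.COMPLETE_FUSED_BCD},
    {"variant": Variant.CI_LIKE, "missing": ("NuoE", "NuoF")},
    {"variant": Variant.CI_LIKE, "missing": ("NuoE", "NuoF", "NuoG")},
    {"variant": Variant.INCOMPLETE},
    {"variant": Variant.ABSENT},
    {"variant": Variant.COMPLETE14, "dual": True},
    {"variant": Variant.COMPLETE14, "plasmid": True},
    {"variant": Variant.COMPLETE14, "split": True},
]


def _draw_lengths(
    rng: np.random.Generator, subunit: str, model: Mapping[str, tuple[float, float]]
) -> int:
    mean, sd = model[subunit]
    return max(50, int(round(rng.normal(mean, sd))))


def _sample_missing_set(rng: np.random.Generator, scheme: SubunitScheme) -> set[str]:
    """A missing set that classifies as Incomplete (not C-I-like, not Absent)."""
    subunits = list(scheme.subunits)
    while True:
        k = int(rng.integers(1, len(subunits) - 1))
        missing = set(rng.choice(subunits, size=k, replace=False))
        if frozenset(missing) not in scheme.complex_like_missing_sets:
            return missing


class _GenomeBuilder:
    """Lays genes onto replicons left to right with controlled gaps."""

    def __init__(self, genome_id: str, rng: np.random.Generator) -> None:
        self.genome_id = genome_id
        self.rng = rng
        self.genes: list[GeneCall] = []
        self.cursor: dict[str, int] = {}
        self.counter = 0

    def _advance(self, replicon: str, gap: int) -> int:
        start = self.cursor.get(replicon, 1) + gap
        return start

    def add_gene(
        self,
        replicon: str,
        replicon_type: RepliconType,
        gap: int,
        protein_length: int,
        strand: str,
    ) -> GeneCall:
        start = self._advance(replicon, gap)
        nt_len = (protein_length + 1) * 3  # CDS includes the stop codon
        end = start + nt_len - 1
        self.counter += 1
        gene = GeneCall(
            gene_id=f"{self.genome_id}_g{self.counter:03d}",
            genome_id=self.genome_id,
            replicon_id=replicon,
            start=start,
            end=end,
            strand=strand,
            protein_length=protein_length,
            replicon_type=replicon_type,
        )
        self.genes.append(gene)
        self.cursor[replicon] = end + 1
        return gene


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a dataset with planted ground truth; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    scheme = nuo_scheme()
    variants = list(config.variant_mix)
    probs = np.array([config.variant_mix[v] for v in variants])

    genes: list[GeneCall] = []
    hits: list[HmmHit] = []
    metadata: list[GenomeMetadata] = []
    truth_rows: list[dict] = []
    hit_truth_rows: list[dict] = []
    genome_counter = 0

    for s in range(config.n_species):
        species = f"Species_{s:03d}"
        plan: dict = {}
        if config.ensure_coverage and s < len(_COVERAGE_PLAN):
            plan = dict(_COVERAGE_PLAN[s])
        else:
            plan = {"variant": variants[rng.choice(len(variants), p=probs)]}
        variant: Variant = plan["variant"]
        is_complete = variant in (
            Variant.COMPLETE14,
            Variant.COMPLETE13_FUSED_CD,
            Variant.COMPLETE_FUSED_BCD,
        )
        if "dual" not in plan and variant is Variant.COMPLETE14:
            plan["dual"] = rng.random() < config.dual_copy_fraction
        if "plasmid" not in plan and is_complete:
            plan["plasmid"] = rng.random() < config.plasmid_fraction
        if "split" not in plan and is_complete and not plan.get("dual"):
            plan["split"] = rng.random() < config.split_fraction
        if variant is Variant.CI_LIKE and "missing" not in plan:
            plan["missing"] = (
                ("NuoE", "NuoF") if rng.random() < 0.5 else ("NuoE", "NuoF", "NuoG")
            )
        if variant is Variant.INCOMPLETE and "missing" not in plan:
            plan["missing"] = tuple(sorted(_sample_missing_set(rng, scheme)))

        lp = _LIFESTYLE_PROBS[variant]
        lifestyle = str(
            rng.choice(list(lp), p=np.array(list(lp.values())) / sum(lp.values()))
        )

        n_strains = 1 + int(
            rng.choice(len(config.strains_per_species), p=config.strains_per_species)
        )
        for _ in range(n_strains):
            genome_counter += 1
            genome_id = f"G{genome_counter:04d}"
            g_genes, g_hits, g_hit_truth, layout = _build_genome(
                genome_id, plan, scheme, config, rng
            )
            genes.extend(g_genes)
            hits.extend(g_hits)
            hit_truth_rows.extend(g_hit_truth)
            replicon_lengths = layout["replicon_lengths"]
            metadata.append(
                GenomeMetadata(
                    genome_id=genome_id,
                    assembly_level=AssemblyLevel.COMPLETE,
                    contig_lengths=replicon_lengths,
                    taxid=f"tax{s:05d}",
                    species=species,
                    genus=f"Genus_{s:03d}",
                    phylum=f"Phylum_{s % config.n_phyla}",
                    class_=f"Class_{s % config.n_phyla}",
                    candidatus_flag=False,
                    lifestyle=lifestyle,
                )
            )
            truth_rows.append(
                {
                    "genome_id": genome_id,
                    "species": species,
                    "variant": variant.value,
                    "missing_subunits": ",".join(plan.get("missing", ())),
                    "n_complete_sets": layout["n_complete_sets"],
                    "arrangement": layout["arrangement"],
                    "on_plasmid": layout["on_plasmid"],
                    "lifestyle": lifestyle,
                    "curated": True,
                }
            )

    # genomes that must fall to metadata curation (Candidatus / missing ranks)
    for u in range(config.n_uncurated):
        genome_counter += 1
        genome_id = f"G{genome_counter:04d}"
        builder = _GenomeBuilder(genome_id, rng)
        builder.add_gene(
            f"{genome_id}.chr", RepliconType.UNKNOWN, 500,
            _draw_lengths(rng, "NuoA", config.length_model), "+",
        )
        genes.extend(builder.genes)
        metadata.append(
            GenomeMetadata(
                genome_id=genome_id,
                assembly_level=AssemblyLevel.COMPLETE,
                contig_lengths=[50000],
                taxid=f"taxu{u:04d}",
                species=f"Uncurated_{u:02d}",
                genus="" if u % 2 else f"Genus_u{u:02d}",
                phylum=f"Phylum_u" if u % 2 else "",
                class_="",
                candidatus_flag=(u % 2 == 0),
                lifestyle=None,
            )
        )
        truth_rows.append(
            {
                "genome_id": genome_id,
                "species": f"Uncurated_{u:02d}",
                "variant": Variant.ABSENT.value,
                "missing_subunits": "",
                "n_complete_sets": 0,
                "arrangement": "none",
                "on_plasmid": "none",
                "lifestyle": "",
                "curated": False,
            }
        )

    truth = pd.DataFrame(truth_rows)
    hit_truth = pd.DataFrame(
        hit_truth_rows, columns=["gene_id", "profile", "genuine"]
    )
    return SimulatedDataset(
        genes=genes,
        hits=hits,
        metadata=metadata,
        truth=truth,
        hit_truth=hit_truth,
        scheme=scheme,
    )


def _true_evalue(rng: np.random.Generator, config: SimulationConfig) -> float:
    mean, sd = config.true_evalue_component
    return float(10.0 ** rng.normal(mean, sd))


def _decoy_evalue(rng: np.random.Generator, config: SimulationConfig) -> float:
    mean, sd = config.decoy_evalue_component
    return float(min(1.0, 10.0 ** rng.normal(mean, sd)))


def _bitscore(evalue: float) -> float:
    return float(round(max(5.0, -3.2 * float(np.log10(max(evalue, 1e-300))) + 10.0), 1))


def _build_genome(
    genome_id: str,
    plan: dict,
    scheme: SubunitScheme,
    config: SimulationConfig,
    rng: np.random.Generator,
):
    builder = _GenomeBuilder(genome_id, rng)
    hits: list[HmmHit] = []
    hit_truth: list[dict] = []
    variant: Variant = plan["variant"]
    on_plasmid = "none"

    chrom = f"{genome_id}.chr"
    present = [s for s in scheme.subunits if s not in set(plan.get("missing", ()))]
    if variant is Variant.ABSENT:
        present = []

    operon_replicon, operon_rt = chrom, RepliconType.UNKNOWN
    if plan.get("plasmid"):
        operon_replicon, operon_rt = f"{genome_id}.plasmid_1", RepliconType.PLASMID
        on_plasmid = "exclusive"

    n_copies = 2 if plan.get("dual") else 1
    split = bool(plan.get("split"))
    arrangement = "none"
    if present and set(present) >= scheme.required_for_complete:
        arrangement = "split" if split else "single_cluster"

    def emit_operon(sub_list: list[str], replicon: str, rtype: RepliconType,
                    lead_gap: int, strand: str) -> None:
        first = True
        i = 0
        while i < len(sub_list):
            gap = lead_gap if first else int(rng.integers(0, config.gap_max + 1))
            first = False
            sub = sub_list[i]
            fused: tuple[str, ...] | None = None
            if variant is Variant.COMPLETE_FUSED_BCD and sub == "NuoB":
                fused = ("NuoB", "NuoC", "NuoD")
                i += 3
            elif variant is Variant.COMPLETE13_FUSED_CD and sub == "NuoC":
                fused = ("NuoC", "NuoD")
                i += 2
            else:
                i += 1
            if fused:
                part_lens = [
                    _draw_lengths(rng, p, config.length_model) for p in fused
                ]
                plen = sum(part_lens)
                gene = builder.add_gene(replicon, rtype, gap, plen, strand)
                if rng.random() < config.fused_fraction:
                    profile = "".join(["Nuo"] + [p[3:] for p in fused])
                    ev = _true_evalue(rng, config)
                    hits.append(
                        HmmHit(gene.gene_id, profile, ev, _bitscore(ev), 1, plen)
                    )
                    hit_truth.append(
                        {"gene_id": gene.gene_id, "profile": profile, "genuine": True}
                    )
                else:
                    # tandem single-subunit domain hits with disjoint envelopes
                    pos = 1
                    for p, ln in zip(fused, part_lens):
                        ev = _true_evalue(rng, config)
                        hits.append(
                            HmmHit(gene.gene_id, p, ev, _bitscore(ev),
                                   pos, pos + ln - 1)
                        )
                        hit_truth.append(
                            {"gene_id": gene.gene_id, "profile": p, "genuine": True}
                        )
                        pos += ln
            else:
                plen = _draw_lengths(rng, sub, config.length_model)
                gene = builder.add_gene(replicon, rtype, gap, plen, strand)
                ev = _true_evalue(rng, config)
                hits.append(HmmHit(gene.gene_id, sub, ev, _bitscore(ev), 1, plen))
                hit_truth.append(
                    {"gene_id": gene.gene_id, "profile": sub, "genuine": True}
                )

    for copy in range(n_copies):
        if not present:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        lead = 500 if copy == 0 else config.inter_cluster_gap_min + int(
            rng.integers(0, 500)
        )
        if split:
            cut = len(present) // 2
            emit_operon(list(present[:cut]), operon_replicon, operon_rt, lead, strand)
            emit_operon(
                list(present[cut:]),
                operon_replicon,
                operon_rt,
                config.inter_cluster_gap_min + int(rng.integers(0, 500)),
                strand,
            )
        else:
            emit_operon(list(present), operon_replicon, operon_rt, lead, strand)

    # background genes without hits, well away from the operon
    for _ in range(int(rng.integers(2, 6))):
        builder.add_gene(
            chrom,
            RepliconType.UNKNOWN,
            config.inter_cluster_gap_min + int(rng.integers(0, 2000)),
            int(rng.integers(100, 600)),
            "+" if rng.random() < 0.5 else "-",
        )

    # decoy homolog hits: wrong-profile matches on non-operon genes, mostly on
    # the NuoB profile (HycG mimicry), always far from planted operons
    n_decoys = int(rng.poisson(config.decoy_rate))
    for _ in range(n_decoys):
        plen = int(rng.integers(120, 500))
        gene = builder.add_gene(
            chrom,
            RepliconType.UNKNOWN,
            config.inter_cluster_gap_min + int(rng.integers(0, 2000)),
            plen,
            "+" if rng.random() < 0.5 else "-",
        )
        if rng.random() < config.decoy_profile_bias:
            profile = "NuoB"
        else:
            profile = str(rng.choice([s for s in scheme.subunits if s != "NuoB"]))
        ev = _decoy_evalue(rng, config)
        hits.append(HmmHit(gene.gene_id, profile, ev, _bitscore(ev), 1, plen))
        hit_truth.append({"gene_id": gene.gene_id, "profile": profile, "genuine": False})

    replicon_lengths = [
        builder.cursor.get(chrom, 1) + 499,
    ]
    if plan.get("plasmid"):
        replicon_lengths.append(builder.cursor[operon_replicon] + 499)

    layout = {
        "replicon_lengths": replicon_lengths,
        "n_complete_sets": n_copies
        if present and set(present) >= scheme.required_for_complete
        else 0,
        "arrangement": arrangement,
        "on_plasmid": on_plasmid,
    }
    return builder.genes, hits, hit_truth, layout


def write_fixture(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset in the exact dialects the readers consume.

    Emits ``genes.gff3``, ``hits.tblout``, ``hits.domtblout``,
    ``metadata.tsv``, ``truth.tsv`` and ``hit_truth.tsv``; parsing them back
    reproduces the in-memory dataset.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "genes": out / "genes.gff3",
        "tblout": out / "hits.tblout",
        "domtblout": out / "hits.domtblout",
        "metadata": out / "metadata.tsv",
        "truth": out / "truth.tsv",
        "hit_truth": out / "hit_truth.tsv",
    }

    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for g in dataset.genes:
            attrs = f"ID={g.gene_id};genome_id={g.genome_id}"
            fh.write(
                f"{g.replicon_id}\tsim\tCDS\t{g.start}\t{g.end}\t.\t{g.strand}\t0\t{attrs}\n"
            )

    gene_len = {g.gene_id: g.protein_length for g in dataset.genes}
    with open(paths["tblout"], "w") as fh:
        fh.write("#                                 --- full sequence ---\n")
        fh.write("# target name  accession  query name  accession  E-value  score  bias\n")
        for h in dataset.hits:
            fh.write(
                f"{h.gene_id} - {h.profile} - {h.evalue!r} {h.bitscore!r} 0.1 "
                f"{h.evalue!r} {h.bitscore!r} 0.1 1.0 1 0 0 1 1 1 1 -\n"
            )
    with open(paths["domtblout"], "w") as fh:
        fh.write("# target name  accession  tlen  query name  accession  qlen ...\n")
        for h in dataset.hits:
            tlen = gene_len[h.gene_id]
            ef = h.env_from if h.env_from is not None else 1
            et = h.env_to if h.env_to is not None else tlen
            fh.write(
                f"{h.gene_id} - {tlen} {h.profile} - {tlen} {h.evalue!r} "
                f"{h.bitscore!r} 0.1 1 1 {h.evalue!r} {h.evalue!r} {h.bitscore!r} 0.1 "
                f"1 {tlen} {ef} {et} {ef} {et} 0.95 -\n"
            )

    write_metadata(dataset.metadata, paths["metadata"])
    write_table(dataset.truth, paths["truth"], sort_by=["genome_id"])
    write_table(dataset.hit_truth, paths["hit_truth"], sort_by=["gene_id", "profile"])
    return paths
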