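"""End-to-end workflow: curate -> cluster -> threshold -> filter -> re-cluster
-> classify -> aggregate -> summarize -> associate.

Every stage writes a deterministic TSV; the run manifest records the package
version, the config and its hash, and the seed, so a run is a pure function
of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

import nuoscan
from nuoscan.association_stats import build_contingency, chi_square_independence
from nuoscan.evalue_filtering import (
    SubunitThreshold,
    ThresholdSource,
    derive_length_range,
    derive_threshold,
    estimate_kde,
    filter_hits,
    log10_evalues,
)
from nuoscan.formats_io import (
    GeneCall,
    GenomeMetadata,
    HmmHit,
    curate_genomes,
    gene_index,
    read_gene_calls,
    read_hmm_hits,
    read_metadata,
    write_table,
)
from nuoscan.hit_clustering import (
    ClusterType,
    HitCluster,
    cluster_hits,
    detect_plateau,
    scan_gap_thresholds,
)
from nuoscan.variant_classification import (
    GenomeVariantCall,
    SubunitScheme,
    aggregate_species,
    classify_genome,
    nuo_scheme,
    summarize_by_rank,
)

logger = logging.getLogger(__name__)

DEFAULT_GLOBAL_CUTOFF = 1e-7  # generic homology-search default


@dataclass
class RunConfig:
    hits_path: str
    genes_path: str
    metadata_path: str
    out_dir: str
    hits_dialect: str = "domtblout"
    genes_dialect: str = "gff3"
    scheme_path: str | None = None
    max_gap: int = 250
    scan_grid: tuple[int, int, int] = (0, 500, 25)  # start, stop, step
    bandwidth_rule: str = "silverman"
    fixed_bandwidth: float | None = None
    lo_pct: float = 1.0
    hi_pct: float = 99.0
    min_species: int = 10
    rank: str = "phylum"
    count_unit: str = "species"  # or "genome"
    default_cutoff: float = DEFAULT_GLOBAL_CUTOFF
    iterate: bool = False
    seed: int = 0


def derive_all_thresholds(
    hits: Sequence[HmmHit],
    clusters: Sequence[HitCluster],
    genes: Mapping[str, GeneCall],
    scheme: SubunitScheme,
    bandwidth_rule: str = "silverman",
    fixed_bandwidth: float | None = None,
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
    default_cutoff: float = DEFAULT_GLOBAL_CUTOFF,
) -> dict[str, SubunitThreshold]:
    """Per-profile e-value/length thresholds from cluster-segregated scores.

    Cluster membership = the hit's gene sits in a Complete cluster (complete
    sets with fused subunits included).  Profiles without enough member or
    total e-values for a KDE fall back to the global default cutoff.
    Reference length ranges from the scheme override percentile-derived ones.
    """
    member_gene_ids = {
        g
        for c in clusters
        if c.cluster_type is ClusterType.COMPLETE
        for g in c.member_genes
    }
    by_profile: dict[str, list[HmmHit]] = {}
    for hit in hits:
        by_profile.setdefault(hit.profile, []).append(hit)

    thresholds: dict[str, SubunitThreshold] = {}
    for profile in sorted(by_profile):
        phits = by_profile[profile]
        members = [h for h in phits if h.gene_id in member_gene_ids]
        member_lengths = [genes[h.gene_id].protein_length for h in members]
        if profile in scheme.length_ranges:
            length_range = tuple(scheme.length_ranges[profile])
        elif len(member_lengths) >= 5:
            length_range = derive_length_range(member_lengths, lo_pct, hi_pct)
        else:
            length_range = (1, 10**9)
        try:
            kde = estimate_kde(
                [h.evalue for h in phits],
                bandwidth_rule=bandwidth_rule,
                fixed_bandwidth=fixed_bandwidth,
            )
            thr = derive_threshold(
                kde,
                log10_evalues([h.evalue for h in members]),
                log10_evalues([h.evalue for h in phits]),
                subunit=profile,
                length_range=length_range,
            )
        except ValueError as exc:
            logger.warning(
                "profile %s: %s; using global default cutoff %.1e",
                profile,
                exc,
                default_cutoff,
            )
            thr = SubunitThreshold(
                subunit=profile,
                evalue_cutoff=default_cutoff,
                source=ThresholdSource.DEFAULT,
                length_range=length_range,
            )
        thresholds[profile] = thr
    return thresholds


def classify_all(
    clusters: Sequence[HitCluster],
    filtered_hits: Sequence[HmmHit],
    genes: Mapping[str, GeneCall],
    scheme: SubunitScheme,
    genome_ids: Sequence[str],
) -> list[GenomeVariantCall]:
    """One variant call per genome, Absent when a genome has no retained hits."""
    clusters_by_genome: dict[str, list[HitCluster]] = {}
    for c in clusters:
        clusters_by_genome.setdefault(c.genome_id, []).append(c)
    hits_by_genome: dict[str, list[HmmHit]] = {}
    for h in filtered_hits:
        hits_by_genome.setdefault(genes[h.gene_id].genome_id, []).append(h)
    calls = []
    for gid in sorted(genome_ids):
        calls.append(
            classify_genome(
                clusters_by_genome.get(gid, []),
                hits_by_genome.get(gid, []),
                scheme,
                genes=genes,
                genome_id=gid,
            )
        )
    return calls


def _clusters_frame(clusters: Sequence[HitCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "genome_id": c.genome_id,
                "replicon_id": c.replicon_id,
                "strand": c.strand,
                "start": c.span[0],
                "end": c.span[1],
                "n_members": len(c.member_genes),
                "cluster_type": c.cluster_type.value,
                "member_genes": ",".join(c.member_genes),
                "subunits": ",".join(c.subunits_present),
            }
            for c in clusters
        ],
        columns=[
            "cluster_id", "genome_id", "replicon_id", "strand", "start", "end",
            "n_members", "cluster_type", "member_genes", "subunits",
        ],
    )


def _thresholds_frame(thresholds: Mapping[str, SubunitThreshold]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subunit": t.subunit,
                "evalue_cutoff": t.evalue_cutoff,
                "source": t.source.value,
                "length_min": t.length_range[0],
                "length_max": t.length_range[1],
            }
            for _, t in sorted(thresholds.items())
        ]
    )


def _variants_frame(calls: Sequence[GenomeVariantCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "genome_id": c.genome_id,
                "variant": c.variant.value,
                "n_complete_sets": c.n_complete_sets,
                "arrangement": c.arrangement.value,
                "on_plasmid": c.on_plasmid.value,
                "fused_cd": c.fused_cd,
                "fused_bcd": c.fused_bcd,
                "subunits_found": ",".join(sorted(c.subunits_found)),
            }
            for c in calls
        ],
        columns=[
            "genome_id", "variant", "n_complete_sets", "arrangement",
            "on_plasmid", "fused_cd", "fused_bcd", "subunits_found",
        ],
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full post-search workflow; returns the written file paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        scheme = (
            SubunitScheme.from_yaml(config.scheme_path)
            if config.scheme_path
            else nuo_scheme()
        )

        stage = "curate"
        metadata = read_metadata(config.metadata_path)
        curated, exclusions = curate_genomes(metadata)
        curated_ids = {m.genome_id for m in curated}
        species_of = {m.genome_id: m.species for m in curated if m.species}
        logger.info("curation kept %d/%d genomes", len(curated), len(metadata))

        stage = "parse"
        genes_all = read_gene_calls(config.genes_path, dialect=config.genes_dialect)
        genes = [g for g in genes_all if g.genome_id in curated_ids]
        gidx = gene_index(genes)
        hits_all = read_hmm_hits(config.hits_path, dialect=config.hits_dialect)
        hits = [h for h in hits_all if h.gene_id in gidx]

        stage = "gap_scan"
        start, stop, step = config.scan_grid
        grid = list(range(start, stop + 1, step))
        scan = scan_gap_thresholds(
            genes, hits, grid, scheme,
            species_of=species_of if config.count_unit == "species" else None,
        )
        plateau = detect_plateau(scan, step=step)
        write_table(
            pd.DataFrame(
                [
                    {"max_gap": r.max_gap, "n_complete": r.n_complete,
                     "n_partial": r.n_partial}
                    for r in scan
                ]
            ),
            out / "gap_scan.tsv",
            sort_by=["max_gap"],
        )

        stage = "threshold"
        provisional = cluster_hits(genes, hits, max_gap=config.max_gap, scheme=scheme)
        thresholds = derive_all_thresholds(
            hits, provisional, gidx, scheme,
            bandwidth_rule=config.bandwidth_rule,
            fixed_bandwidth=config.fixed_bandwidth,
            lo_pct=config.lo_pct,
            hi_pct=config.hi_pct,
            default_cutoff=config.default_cutoff,
        )
        write_table(_thresholds_frame(thresholds), out / "thresholds.tsv",
                    sort_by=["subunit"])

        stage = "filter"
        default_thr = SubunitThreshold(
            subunit="__default__",
            evalue_cutoff=config.default_cutoff,
            source=ThresholdSource.DEFAULT,
            length_range=(1, 10**9),
        )
        filtered, rejected = filter_hits(hits, thresholds, gidx, default=default_thr)
        write_table(
            pd.DataFrame(
                [
                    {"gene_id": r.hit.gene_id, "profile": r.hit.profile,
                     "evalue": r.hit.evalue, "reason": r.reason}
                    for r in rejected
                ],
                columns=["gene_id", "profile", "evalue", "reason"],
            ),
            out / "rejected_hits.tsv",
            sort_by=["gene_id", "profile"],
        )

        stage = "recluster"
        clusters = cluster_hits(genes, filtered, max_gap=config.max_gap, scheme=scheme)
        if config.iterate:
            # iterate threshold -> filter -> re-cluster to a fixpoint
            for _ in range(10):
                thresholds = derive_all_thresholds(
                    filtered, clusters, gidx, scheme,
                    bandwidth_rule=config.bandwidth_rule,
                    fixed_bandwidth=config.fixed_bandwidth,
                    lo_pct=config.lo_pct,
                    hi_pct=config.hi_pct,
                    default_cutoff=config.default_cutoff,
                )
                new_filtered, _ = filter_hits(
                    filtered, thresholds, gidx, default=default_thr
                )
                if len(new_filtered) == len(filtered):
                    break
                filtered = new_filtered
                clusters = cluster_hits(
                    genes, filtered, max_gap=config.max_gap, scheme=scheme
                )
        write_table(_clusters_frame(clusters), out / "clusters.tsv",
                    sort_by=["cluster_id"])

        stage = "classify"
        calls = classify_all(clusters, filtered, gidx, scheme, sorted(curated_ids))
        write_table(_variants_frame(calls), out / "variants.tsv",
                    sort_by=["genome_id"])

        stage = "aggregate"
        summaries = aggregate_species(calls, species_of)
        write_table(
            pd.DataFrame(
                [
                    {
                        "species": s.species,
                        "n_strains": s.n_strains,
                        "variants_observed": ",".join(
                            sorted(v.value for v in s.variants_observed)
                        ),
                        "consistent": s.consistent,
                        "representative_variant": s.representative_variant.value,
                    }
                    for s in summaries
                ],
                columns=["species", "n_strains", "variants_observed", "consistent",
                         "representative_variant"],
            ),
            out / "species_summary.tsv",
            sort_by=["species"],
        )

        stage = "summarize"
        rank_of = {}
        for m in curated:
            taxon = getattr(m, "class_" if config.rank == "class" else config.rank, "")
            if m.species and taxon:
                rank_of[m.species] = taxon
        rank_table = summarize_by_rank(
            summaries, rank_of, rank=config.rank, min_species=config.min_species
        )
        write_table(rank_table, out / "rank_distribution.tsv",
                    sort_by=[config.rank] if config.rank in rank_table.columns else None)

        stage = "associate"
        lifestyles = {
            m.species: m.lifestyle for m in curated if m.species and m.lifestyle
        }
        association = None
        if lifestyles:
            observed, n_excluded = build_contingency(summaries, lifestyles)
            result = chi_square_independence(observed)
            obs_out = result.observed.copy()
            obs_out.insert(0, "lifestyle", obs_out.index)
            write_table(obs_out.reset_index(drop=True), out / "contingency.tsv",
                        sort_by=["lifestyle"])
            res_out = result.residuals.copy()
            res_out.insert(0, "lifestyle", res_out.index)
            write_table(res_out.reset_index(drop=True), out / "residuals.tsv",
                        sort_by=["lifestyle"])
            association = {
                "chi2": result.chi2,
                "dof": result.dof,
                "p_value": result.p_value,
                "species_without_lifestyle": n_excluded,
            }
        else:
            logger.info("no lifestyle annotations; association stage skipped")

        stage = "manifest"
        cfg_dict = dataclasses.asdict(config)
        cfg_dict.pop("out_dir")  # output location is not an analysis parameter
        cfg_json = json.dumps(cfg_dict, sort_keys=True)
        manifest = {
            "package": "nuoscan",
            "version": nuoscan.__version__,
            "config": cfg_dict,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config.seed,
            "curation_exclusions": exclusions,
            "n_genomes_curated": len(curated),
            "n_hits": len(hits),
            "n_hits_retained": len(filtered),
            "gap_plateau": plateau,
            "association": association,
            "timestamp": datetime.now(timezone.utc).isoformat(),
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    except Exception:
        failed_marker.write_text(f"stage: {stage}\n")
        logger.exception("pipeline failed at stage %s", stage)
        raise
    return {p.name: p for p in sorted(out.iterdir())}
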