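"""Genomic-context clustering of HMM hits.

Hit-bearing genes on the same replicon and strand are grouped into maximal
runs in which consecutive hit-bearing genes are separated by at most
``max_gap`` intergenic base pairs (default 250 bp).  A cluster carrying the
scheme's full required subunit set (fusions resolved) is Complete, otherwise
Partial.  Intervening non-hit genes never join a cluster but their span counts
toward the gap, so a long foreign insertion naturally breaks a cluster.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

from nuoscan.formats_io import GeneCall, HmmHit, gene_index
from nuoscan.variant_classification import SubunitScheme, resolve_gene_subunits

logger = logging.getLogger(__name__)


class ClusterType(str, Enum):
    COMPLETE = "Complete"
    PARTIAL = "Partial"


@dataclass(frozen=True)
class HitCluster:
    """A maximal run of same-strand, gap-bounded hit-bearing genes."""

    cluster_id: str
    genome_id: str
    replicon_id: str
    strand: str
    member_genes: tuple[str, ...]  # gene ids ordered by start
    subunits_present: tuple[str, ...]  # fusion-resolved labels, with multiplicity
    cluster_type: ClusterType
    span: tuple[int, int]  # first gene start .. last gene end

    @property
    def subunit_counts(self) -> Counter:
        return Counter(self.subunits_present)


def intergenic_gap(a: GeneCall, b: GeneCall) -> int:
    """Intergenic distance in bp between two genes, ``a`` starting first.

    Overlapping or book-ended genes return 0.
    """
    if a.replicon_id != b.replicon_id:
        raise ValueError(
            f"genes {a.gene_id} and {b.gene_id} lie on different replicons"
        )
    if a.start > b.start:
        raise ValueError("first argument must start at or before the second")
    return max(0, b.start - a.end - 1)


def _hits_by_gene(hits: Iterable[HmmHit]) -> dict[str, list[HmmHit]]:
    by_gene: dict[str, list[HmmHit]] = {}
    for hit in hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    return by_gene


def cluster_hits(
    genes: Sequence[GeneCall],
    hits: Sequence[HmmHit],
    max_gap: int = 250,
    scheme: SubunitScheme | None = None,
) -> list[HitCluster]:
    """Partition hit-bearing genes into intergenic-distance clusters.

    Every hit-bearing gene belongs to exactly one cluster; singletons are
    allowed.  Clusters never span replicons or strands.  When a ``scheme`` is
    given, per-gene subunit labels are fusion-resolved and clusters are typed
    Complete/Partial against the scheme's required set; without a scheme the
    raw profile names are used and every cluster is Partial.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    index = gene_index(genes)
    by_gene = _hits_by_gene(hits)
    missing = sorted(g for g in by_gene if g not in index)
    if missing:
        raise ValueError(
            "hits reference unknown gene ids: " + ", ".join(missing[:10])
        )

    groups: dict[tuple[str, str, str], list[GeneCall]] = {}
    for gid in by_gene:
        gene = index[gid]
        groups.setdefault((gene.genome_id, gene.replicon_id, gene.strand), []).append(
            gene
        )

    clusters: list[HitCluster] = []
    for (genome_id, replicon_id, strand) in sorted(groups):
        members = sorted(
            groups[(genome_id, replicon_id, strand)],
            key=lambda g: (g.start, g.end, g.gene_id),
        )
        # Sweep by start, tracking the rightmost end of the current run: a gene
        # joins iff its gap to the closest member (the one with the max end) is
        # within max_gap.  This equals the transitive closure of the pairwise
        # gap relation even when genes are nested or overlapping.
        runs: list[list[GeneCall]] = [[members[0]]]
        run_max_end = members[0].end
        for cur in members[1:]:
            if max(0, cur.start - run_max_end - 1) <= max_gap:
                runs[-1].append(cur)
            else:
                runs.append([cur])
            run_max_end = max(run_max_end, cur.end) if runs[-1][0] is not cur else cur.end
        for i, run in enumerate(runs):
            labels: list[str] = []
            for gene in run:
                if scheme is not None:
                    labels.extend(
                        sorted(resolve_gene_subunits(by_gene[gene.gene_id], scheme))
                    )
                else:
                    labels.extend(sorted({h.profile for h in by_gene[gene.gene_id]}))
            ctype = ClusterType.PARTIAL
            if scheme is not None and set(labels) >= scheme.required_for_complete:
                ctype = ClusterType.COMPLETE
            clusters.append(
                HitCluster(
                    cluster_id=f"{genome_id}|{replicon_id}|{strand}|{i}",
                    genome_id=genome_id,
                    replicon_id=replicon_id,
                    strand=strand,
                    member_genes=tuple(g.gene_id for g in run),
                    subunits_present=tuple(labels),
                    cluster_type=ctype,
                    span=(run[0].start, max(g.end for g in run)),
                )
            )
    return clusters


@dataclass(frozen=True)
class GapScanRow:
    """One point of the intergenic-distance threshold scan."""

    max_gap: int
    n_complete: int  # units (genomes or species) holding >= 1 Complete cluster
    n_partial: int  # units with hits but only Partial clusters


def scan_gap_thresholds(
    genes: Sequence[GeneCall],
    hits: Sequence[HmmHit],
    thresholds: Sequence[int],
    scheme: SubunitScheme,
    species_of: Mapping[str, str] | None = None,
) -> list[GapScanRow]:
    """Re-cluster at each threshold and count Complete vs Partial-only units.

    The counting unit is the species when ``species_of`` (genome id ->
    species) is given, else the genome.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")

    def unit(genome_id: str) -> str:
        if species_of is not None:
            return species_of.get(genome_id, genome_id)
        return genome_id

    rows: list[GapScanRow] = []
    for t in thresholds:
        clusters = cluster_hits(genes, hits, max_gap=t, scheme=scheme)
        complete_units = {
            unit(c.genome_id) for c in clusters if c.cluster_type is ClusterType.COMPLETE
        }
        any_units = {unit(c.genome_id) for c in clusters}
        rows.append(
            GapScanRow(
                max_gap=int(t),
                n_complete=len(complete_units),
                n_partial=len(any_units - complete_units),
            )
        )
    return rows


def detect_plateau(
    scan: Sequence[GapScanRow], step: int, rel_epsilon: float = 0.01
) -> int:
    """Smallest threshold where the Complete-unit count has stopped growing.

    Returns the first threshold ``t`` whose relative increase to ``t + step``
    falls below ``rel_epsilon``; if growth never levels off, returns the
    largest scanned threshold with a warning.
    """
    if len(scan) < 2:
        raise ValueError("scan must cover at least two thresholds")
    for cur, nxt in zip(scan, scan[1:]):
        if nxt.max_gap - cur.max_gap != step:
            raise ValueError("scan thresholds must be uniformly spaced by step")
        rel = (nxt.n_complete - cur.n_complete) / max(1, cur.n_complete)
        if rel < rel_epsilon:
            return cur.max_gap
    logger.warning(
        "Complete-cluster count grows across the whole scan; returning the "
        "largest threshold %d",
        scan[-1].max_gap,
    )
    return scan[-1].max_gap
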