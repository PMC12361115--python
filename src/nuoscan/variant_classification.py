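"""Fusion resolution and complex-variant classification.

The shipped default scheme describes the canonical prokaryotic NADH-quinone
oxidoreductase (Complex I): 14 core subunits NuoA-NuoN organised in the
N-module (NADH oxidation: E, F, G), Q-module (quinone reduction: B, C, D, H,
I) and P-module (proton translocation: A, J, K, L, M, N), with the common
fused genes NuoCD and NuoBCD.  A genome whose subunit complement misses
exactly the N-module pair {E, F} or triple {E, F, G} is called C-I-like; any
other missing set is Incomplete.  The scheme is a plain config object so
other multi-subunit complexes can reuse the machinery.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import pandas as pd

from nuoscan.formats_io import GeneCall, HmmHit, RepliconType

if TYPE_CHECKING:  # pragma: no cover - type hints only, avoids an import cycle
    from nuoscan.hit_clustering import HitCluster


class Variant(str, Enum):
    """Complex variant of a genome, ordered from most to least complete."""

    COMPLETE14 = "Complete14"
    COMPLETE13_FUSED_CD = "Complete13_fusedCD"
    COMPLETE_FUSED_BCD = "Complete_fusedBCD"
    CI_LIKE = "CI_like"
    INCOMPLETE = "Incomplete"
    ABSENT = "Absent"


_COMPLETENESS_ORDER = {v: i for i, v in enumerate(Variant)}


class Arrangement(str, Enum):
    SINGLE_CLUSTER = "single_cluster"
    SPLIT = "split"
    NONE = "none"


class PlasmidStatus(str, Enum):
    NONE = "none"
    PARTIAL = "partial"
    COMPLETE = "complete"
    EXCLUSIVE = "exclusive"


@dataclass(frozen=True)
class SubunitScheme:
    """Configurable definition of a multi-subunit complex."""

    name: str
    subunits: tuple[str, ...]
    modules: Mapping[str, frozenset[str]]
    fused_profiles: Mapping[str, tuple[str, ...]]
    required_for_complete: frozenset[str]
    complex_like_missing_sets: tuple[frozenset[str], ...]
    # Optional reference protein-length ranges per profile (aa), e.g. curated
    # from reviewed database entries; they override percentile-derived ranges.
    length_ranges: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(self.subunits)
        for profile, parts in self.fused_profiles.items():
            if not set(parts) <= known:
                raise ValueError(f"fused profile {profile} maps outside the scheme")
        covered: set[str] = set()
        for mod, members in self.modules.items():
            if covered & set(members):
                raise ValueError(f"module {mod} overlaps another module")
            covered |= set(members)

    @property
    def profiles(self) -> tuple[str, ...]:
        return tuple(self.subunits) + tuple(self.fused_profiles)

    def expand_profile(self, profile: str) -> tuple[str, ...]:
        """Subunit labels a profile stands for (fused profiles expand)."""
        if profile in self.fused_profiles:
            return tuple(self.fused_profiles[profile])
        return (profile,)

    @classmethod
    def from_dict(cls, data: Mapping) -> "SubunitScheme":
        return cls(
            name=data["name"],
            subunits=tuple(data["subunits"]),
            modules={k: frozenset(v) for k, v in data.get("modules", {}).items()},
            fused_profiles={
                k: tuple(v) for k, v in data.get("fused_profiles", {}).items()
            },
            required_for_complete=frozenset(
                data.get("required_for_complete", data["subunits"])
            ),
            complex_like_missing_sets=tuple(
                frozenset(s) for s in data.get("complex_like_missing_sets", [])
            ),
            length_ranges={
                k: (int(v[0]), int(v[1]))
                for k, v in data.get("length_ranges", {}).items()
            },
        )

    @classmethod
    def from_yaml(cls, path) -> "SubunitScheme":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "subunits": list(self.subunits),
            "modules": {k: sorted(v) for k, v in self.modules.items()},
            "fused_profiles": {k: list(v) for k, v in self.fused_profiles.items()},
            "required_for_complete": sorted(self.required_for_complete),
            "complex_like_missing_sets": [
                sorted(s) for s in self.complex_like_missing_sets
            ],
            "length_ranges": {k: list(v) for k, v in self.length_ranges.items()},
        }


# Reference subunit lengths (aa) from the E. coli enzyme, widened generously;
# used as default length-filter ranges.
_NUO_LENGTH_RANGES = {
    "NuoA": (80, 250),
    "NuoB": (120, 400),
    "NuoC": (120, 400),
    "NuoD": (250, 700),
    "NuoE": (100, 300),
    "NuoF": (280, 700),
    "NuoG": (500, 1200),
    "NuoH": (200, 500),
    "NuoI": (100, 350),
    "NuoJ": (120, 320),
    "NuoK": (60, 200),
    "NuoL": (400, 900),
    "NuoM": (350, 750),
    "NuoN": (320, 700),
    "NuoCD": (400, 900),
    "NuoBCD": (550, 1200),
}


def nuo_scheme() -> SubunitScheme:
    """The default 14-subunit Complex I (Nuo) scheme."""
    subunits = tuple(f"Nuo{c}" for c in "ABCDEFGHIJKLMN")
    return SubunitScheme(
        name="nuo14",
        subunits=subunits,
        modules={
            "N": frozenset({"NuoE", "NuoF", "NuoG"}),
            "Q": frozenset({"NuoB", "NuoC", "NuoD", "NuoH", "NuoI"}),
            "P": frozenset({"NuoA", "NuoJ", "NuoK", "NuoL", "NuoM", "NuoN"}),
        },
        fused_profiles={
            "NuoCD": ("NuoC", "NuoD"),
            "NuoBCD": ("NuoB", "NuoC", "NuoD"),
        },
        required_for_complete=frozenset(subunits),
        complex_like_missing_sets=(
            frozenset({"NuoE", "NuoF"}),
            frozenset({"NuoE", "NuoF", "NuoG"}),
        ),
        length_ranges=dict(_NUO_LENGTH_RANGES),
    )


def _merged_envelopes(hits: Sequence[HmmHit]) -> tuple[int, int] | None:
    envs = [(h.env_from, h.env_to) for h in hits if h.env_from is not None]
    if not envs:
        return None
    return (min(e[0] for e in envs), max(e[1] for e in envs))


def _overlap_frac(a: tuple[int, int], b: tuple[int, int]) -> float:
    overlap = min(a[1], b[1]) - max(a[0], b[0]) + 1
    shorter = min(a[1] - a[0] + 1, b[1] - b[0] + 1)
    return max(0, overlap) / shorter


def resolve_gene_subunits(
    hits_on_gene: Sequence[HmmHit],
    scheme: SubunitScheme,
    max_overlap_frac: float = 0.2,
) -> set[str]:
    """Subunit labels contributed by one gene, resolving fusions.

    Fused-profile hits expand to their mapped subunit lists.  A gene hit by
    two or more distinct single-subunit profiles contributes all of them only
    when their domain envelopes are essentially disjoint (pairwise overlap at
    most ``max_overlap_frac`` of the shorter envelope) — the tandem-domain
    signature of a gene fusion.  Overlapping profiles are paralog ambiguity
    and collapse to the best-e-value profile's subunit.
    """
    if not hits_on_gene:
        return set()
    gene_ids = {h.gene_id for h in hits_on_gene}
    if len(gene_ids) != 1:
        raise ValueError(f"hits span several genes: {sorted(gene_ids)}")

    labels: set[str] = set()
    per_profile: dict[str, list[HmmHit]] = {}
    for hit in hits_on_gene:
        if hit.profile in scheme.fused_profiles:
            labels.update(scheme.fused_profiles[hit.profile])
        else:
            per_profile.setdefault(hit.profile, []).append(hit)

    if not per_profile:
        return labels
    # Best (lowest e-value) profile always contributes; further profiles only
    # if their envelope is disjoint from every accepted one.
    ranked = sorted(
        per_profile.items(), key=lambda kv: (min(h.evalue for h in kv[1]), kv[0])
    )
    accepted: list[tuple[str, tuple[int, int] | None]] = []
    for profile, hits in ranked:
        env = _merged_envelopes(hits)
        if not accepted:
            accepted.append((profile, env))
            continue
        if env is None or any(a_env is None for _, a_env in accepted):
            continue  # cannot establish disjoint domains without envelopes
        if all(_overlap_frac(env, a_env) <= max_overlap_frac for _, a_env in accepted):
            accepted.append((profile, env))
    for profile, _ in accepted:
        labels.update(scheme.expand_profile(profile))
    return labels


@dataclass(frozen=True)
class GenomeVariantCall:
    genome_id: str
    variant: Variant
    n_complete_sets: int
    arrangement: Arrangement
    on_plasmid: PlasmidStatus
    subunits_found: frozenset[str]
    fused_cd: bool = False
    fused_bcd: bool = False


def _count_complete_sets(
    gene_subunits: Mapping[str, set[str]],
    gene_evalue: Mapping[str, float],
    required: frozenset[str],
) -> int:
    """Maximum number of disjoint gene-sets each covering the required subunits.

    Genes are collapsed to their (required-restricted) subunit-set type and
    the maximum is found by a memoized depth-first search over type counts —
    exact at the scale of one genome (tens of genes, 14 subunits).  Unusually
    large inputs fall back to a greedy count, which can only undercount.
    """
    relevant = {
        g: frozenset(s & required) for g, s in gene_subunits.items() if s & required
    }
    if len(relevant) > 60:  # pathological; never reached by real genomes
        return _greedy_complete_sets(gene_subunits, gene_evalue, required)
    type_counts: dict[frozenset[str], int] = {}
    for t in relevant.values():
        type_counts[t] = type_counts.get(t, 0) + 1
    types = sorted(type_counts, key=sorted)
    counts0 = tuple(type_counts[t] for t in types)
    order = sorted(required)

    from functools import lru_cache

    @lru_cache(maxsize=None)
    def search(counts: tuple[int, ...], needed: frozenset[str]) -> int:
        if not needed:
            return 1 + search(counts, required)
        # pick the first still-needed subunit and try every provider type
        target = next(s for s in order if s in needed)
        best = 0
        for i, t in enumerate(types):
            if counts[i] > 0 and target in t:
                nxt = counts[:i] + (counts[i] - 1,) + counts[i + 1 :]
                best = max(best, search(nxt, needed - t))
        if not best and needed == required:
            return 0  # cannot even start another cover
        return best

    result = search(counts0, required)
    search.cache_clear()
    return result


def _greedy_complete_sets(
    gene_subunits: Mapping[str, set[str]],
    gene_evalue: Mapping[str, float],
    required: frozenset[str],
) -> int:
    """Greedy lower bound on the number of disjoint covering gene-sets."""
    unused = set(gene_subunits)
    count = 0
    while True:
        need = set(required)
        chosen: list[str] = []
        while need:
            best_gene, best_cover = None, 0
            for g in sorted(unused - set(chosen)):
                cover = len(gene_subunits[g] & need)
                if cover > best_cover or (
                    cover == best_cover
                    and cover > 0
                    and best_gene is not None
                    and gene_evalue[g] < gene_evalue[best_gene]
                ):
                    best_gene, best_cover = g, cover
            if best_gene is None or best_cover == 0:
                break
            chosen.append(best_gene)
            need -= gene_subunits[best_gene]
        if need:
            return count
        count += 1
        unused -= set(chosen)


def classify_genome(
    clusters: Sequence["HitCluster"],
    filtered_hits: Sequence[HmmHit],
    scheme: SubunitScheme,
    genes: Mapping[str, GeneCall] | None = None,
    genome_id: str | None = None,
    max_overlap_frac: float = 0.2,
) -> GenomeVariantCall:
    """Classify one genome into a complex variant.

    ``clusters`` and ``filtered_hits`` must belong to a single genome and to
    each other (clusters built from the filtered hits).  ``genes`` (gene id ->
    GeneCall) supplies replicon types for plasmid attribution; without it the
    plasmid status is reported as none.
    """
    gids = {c.genome_id for c in clusters} | (
        {genes[h.gene_id].genome_id for h in filtered_hits} if genes else set()
    )
    if genome_id is None:
        if len(gids) > 1:
            raise ValueError(f"hits/clusters span several genomes: {sorted(gids)}")
        genome_id = next(iter(gids)) if gids else "unknown"

    by_gene: dict[str, list[HmmHit]] = {}
    for hit in filtered_hits:
        by_gene.setdefault(hit.gene_id, []).append(hit)
    gene_subunits = {
        g: resolve_gene_subunits(hs, scheme, max_overlap_frac)
        for g, hs in by_gene.items()
    }
    gene_evalue = {g: min(h.evalue for h in hs) for g, hs in by_gene.items()}

    found: set[str] = set()
    for labels in gene_subunits.values():
        found |= labels

    fused_cd = any(
        {"NuoC", "NuoD"} <= labels and "NuoB" not in labels
        for labels in gene_subunits.values()
    )
    fused_bcd = any(
        {"NuoB", "NuoC", "NuoD"} <= labels for labels in gene_subunits.values()
    )

    required = scheme.required_for_complete
    if not found:
        variant = Variant.ABSENT
    elif found >= required:
        if fused_bcd:
            variant = Variant.COMPLETE_FUSED_BCD
        elif fused_cd:
            variant = Variant.COMPLETE13_FUSED_CD
        else:
            variant = Variant.COMPLETE14
    elif (required - found) in scheme.complex_like_missing_sets:
        variant = Variant.CI_LIKE
    else:
        variant = Variant.INCOMPLETE

    n_sets = (
        _count_complete_sets(gene_subunits, gene_evalue, required)
        if found >= required
        else 0
    )

    if found >= required:
        single = any(set(c.subunits_present) >= required for c in clusters)
        arrangement = Arrangement.SINGLE_CLUSTER if single else Arrangement.SPLIT
    else:
        arrangement = Arrangement.NONE

    on_plasmid = PlasmidStatus.NONE
    if genes is not None and by_gene:
        plasmid_genes = {
            g
            for g in by_gene
            if genes[g].replicon_type is RepliconType.PLASMID
        }
        if plasmid_genes == set(by_gene) and plasmid_genes:
            on_plasmid = PlasmidStatus.EXCLUSIVE
        elif plasmid_genes:
            plasmid_subunits: set[str] = set()
            for g in plasmid_genes:
                plasmid_subunits |= gene_subunits[g]
            on_plasmid = (
                PlasmidStatus.COMPLETE
                if plasmid_subunits >= required
                else PlasmidStatus.PARTIAL
            )

    return GenomeVariantCall(
        genome_id=genome_id,
        variant=variant,
        n_complete_sets=n_sets,
        arrangement=arrangement,
        on_plasmid=on_plasmid,
        subunits_found=frozenset(found),
        fused_cd=fused_cd,
        fused_bcd=fused_bcd,
    )


@dataclass(frozen=True)
class SpeciesSummary:
    species: str
    n_strains: int
    variants_observed: frozenset[Variant]
    consistent: bool
    representative_variant: Variant


def aggregate_species(
    calls: Sequence[GenomeVariantCall], species_of: Mapping[str, str]
) -> list[SpeciesSummary]:
    """Aggregate per-genome variant calls to species.

    The representative variant is the modal one, ties broken toward the more
    complete variant.  Genomes without a species mapping are dropped with a
    warning.
    """
    import logging

    by_species: dict[str, list[GenomeVariantCall]] = {}
    for call in calls:
        sp = species_of.get(call.genome_id)
        if sp is None:
            logging.getLogger(__name__).warning(
                "genome %s has no species mapping; excluded", call.genome_id
            )
            continue
        by_species.setdefault(sp, []).append(call)

    summaries = []
    for sp in sorted(by_species):
        variants = [c.variant for c in by_species[sp]]
        counts = Counter(variants)
        rep = min(
            counts,
            key=lambda v: (-counts[v], _COMPLETENESS_ORDER[v]),
        )
        observed = frozenset(variants)
        summaries.append(
            SpeciesSummary(
                species=sp,
                n_strains=len(variants),
                variants_observed=observed,
                consistent=len(observed) == 1,
                representative_variant=rep,
            )
        )
    return summaries


def summarize_by_rank(
    summaries: Sequence[SpeciesSummary],
    taxonomy: Mapping[str, str],
    rank: str = "phylum",
    min_species: int = 10,
) -> pd.DataFrame:
    """Percentage of species per variant within each taxon of a rank.

    ``taxonomy`` maps species to its taxon at the requested rank.  Taxa with
    fewer than ``min_species`` species are excluded.  Rows sum to 100%.
    """
    rows = []
    for summ in summaries:
        taxon = taxonomy.get(summ.species)
        if taxon:
            rows.append({rank: taxon, "variant": summ.representative_variant.value})
    if not rows:
        return pd.DataFrame(columns=[rank, "n_species"])
    df = pd.DataFrame(rows)
    counts = df.groupby([rank, "variant"]).size().unstack(fill_value=0)
    counts = counts.reindex(columns=[v.value for v in Variant], fill_value=0)
    totals = counts.sum(axis=1)
    counts = counts.loc[totals >= min_species]
    totals = totals.loc[counts.index]
    pct = counts.div(totals, axis=0) * 100.0
    pct.insert(0, "n_species", totals)
    return pct.reset_index().rename_axis(None, axis=1)
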