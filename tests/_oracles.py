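"""Independent brute-force oracles used by the test suite.

These deliberately re-derive results by the most naive correct method so they
stay independent of the implementation paths they check.
"""

from __future__ import annotations

from nuoscan.formats_io import GeneCall


def pairwise_gap(a: GeneCall, b: GeneCall) -> int:
    first, second = (a, b) if a.start <= b.start else (b, a)
    return max(0, second.start - first.end - 1)


def union_find_clusters(genes: list[GeneCall], max_gap: int) -> set[frozenset[str]]:
    """Transitive closure of "same replicon, same strand, gap <= max_gap"."""
    parent = {g.gene_id: g.gene_id for g in genes}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        parent[find(x)] = find(y)

    for i, a in enumerate(genes):
        for b in genes[i + 1 :]:
            if (
                a.replicon_id == b.replicon_id
                and a.strand == b.strand
                and a.genome_id == b.genome_id
                and pairwise_gap(a, b) <= max_gap
            ):
                union(a.gene_id, b.gene_id)
    components: dict[str, set[str]] = {}
    for g in genes:
        components.setdefault(find(g.gene_id), set()).add(g.gene_id)
    return {frozenset(v) for v in components.values()}


def n50_category_oracle(n50: int, total: int, contigs: int) -> str:
    """Literal transcription of the four-tier assembly-quality rules."""
    if n50 >= 0.9 * total and contigs <= 5:
        return "Excellent"
    if n50 >= 0.7 * total and contigs <= 10:
        return "Good"
    if n50 >= 0.5 * total and contigs <= 50:
        return "Moderate"
    return "Poor"


def max_disjoint_covers(gene_sets: dict[str, set[str]], required: frozenset[str]) -> int:
    """Exhaustive search for the max number of disjoint covering gene-sets."""
    genes = sorted(gene_sets)

    def best(available: frozenset[str]) -> int:
        # try every subset of available genes as one cover
        result = 0
        avail = sorted(available)
        n = len(avail)
        for mask in range(1, 2**n):
            chosen = [avail[i] for i in range(n) if mask >> i & 1]
            covered: set[str] = set()
            for g in chosen:
                covered |= gene_sets[g]
            if covered >= required:
                rest = frozenset(available - set(chosen))
                result = max(result, 1 + best(rest))
        return result

    return best(frozenset(genes))
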