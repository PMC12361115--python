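"""Assembly quality: N50 and the four-tier quality categories.

An assembly is Excellent when its N50 is at least 90% of the total length and
it has at most five contigs; Good at 70%/10; Moderate at 50%/50; otherwise
Poor.  Both conditions of a tier must hold; a genome meeting the N50 bound but
not the contig bound falls through to the next tier.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np


class AssemblyCategory(str, Enum):
    EXCELLENT = "Excellent"
    GOOD = "Good"
    MODERATE = "Moderate"
    POOR = "Poor"


@dataclass(frozen=True)
class AssemblyStats:
    n50: int
    total_length: int
    n_contigs: int
    category: AssemblyCategory


def compute_n50(contig_lengths: Sequence[int]) -> int:
    """N50: the length L such that contigs of length >= L cover half the assembly.

    Uses the common convention: sort descending, cumulate, and return the
    length of the first contig whose cumulative sum reaches total/2.
    """
    lengths = np.asarray(contig_lengths, dtype=np.int64)
    if lengths.size == 0:
        raise ValueError("contig_lengths must be non-empty")
    if np.any(lengths <= 0):
        raise ValueError("contig lengths must all be positive")
    lengths = np.sort(lengths)[::-1]
    cumsum = np.cumsum(lengths)
    half = cumsum[-1] / 2
    idx = int(np.searchsorted(cumsum, half, side="left"))
    return int(lengths[idx])


# (min n50 fraction of total, max contig count) per tier, most stringent first.
_TIERS = (
    (0.9, 5, AssemblyCategory.EXCELLENT),
    (0.7, 10, AssemblyCategory.GOOD),
    (0.5, 50, AssemblyCategory.MODERATE),
)


def classify_assembly(n50: int, total_length: int, n_contigs: int) -> AssemblyCategory:
    if not (0 < n50 <= total_length):
        raise ValueError("require 0 < n50 <= total_length")
    if n_contigs < 1:
        raise ValueError("n_contigs must be >= 1")
    for frac, max_contigs, cat in _TIERS:
        if n50 >= frac * total_length and n_contigs <= max_contigs:
            return cat
    return AssemblyCategory.POOR


def assembly_stats(contig_lengths: Sequence[int]) -> AssemblyStats:
    n50 = compute_n50(contig_lengths)
    total = int(sum(contig_lengths))
    n = len(contig_lengths)
    return AssemblyStats(n50, total, n, classify_assembly(n50, total, n))
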