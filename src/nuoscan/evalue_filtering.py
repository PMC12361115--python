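"""KDE-based e-value thresholds and protein-length filters.

HMMER e-values of genuine subunits and of distant homologs (e.g. HycG-like
hits on the NuoB profile) form well-separated modes in log10 space.  Hits
sitting inside Complete genomic-context clusters mark the high-confidence
mode; the antimode to its right is the natural per-subunit e-value cutoff.
All density work happens in log10(e-value); zeros are floored to 1e-300.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gaussian_kde

from nuoscan.formats_io import GeneCall, HmmHit

logger = logging.getLogger(__name__)

EVALUE_FLOOR = 1e-300
_GRID_POINTS = 512
# Local maxima below this fraction of the peak are floating-point-level
# wiggles in far tails, not modes.
_MIN_MODE_REL_DENSITY = 0.01


def log10_evalues(evalues: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(evalues), dtype=float)
    return np.log10(np.maximum(arr, EVALUE_FLOOR))


class ThresholdSource(str, Enum):
    ANTIMODE = "antimode"
    MEMBER_MAX_FALLBACK = "member_max_fallback"
    USER = "user"
    DEFAULT = "default"


@dataclass(frozen=True)
class KdeProfile:
    """A Gaussian KDE of log10 e-values with located modes and antimodes."""

    grid: np.ndarray  # ascending log10(e-value) points
    density: np.ndarray
    bandwidth: float  # log10 units
    modes: tuple[int, ...]  # grid indices of local maxima
    antimodes: tuple[int, ...]  # grid indices of local minima between modes

    @property
    def n_modes(self) -> int:
        return len(self.modes)


def _find_extrema(density: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    sign = np.sign(np.diff(density))
    # Ignore flat stretches by propagating the previous non-zero sign.
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.diff(sign)
    maxima = [int(i) + 1 for i in np.where(turns < 0)[0]]
    floor = _MIN_MODE_REL_DENSITY * float(density.max())
    maxima = [i for i in maxima if density[i] >= floor]
    # Antimodes: the minimum of the density between consecutive retained modes.
    antimodes = []
    for left, right in zip(maxima, maxima[1:]):
        antimodes.append(left + int(np.argmin(density[left : right + 1])))
    return tuple(maxima), tuple(antimodes)


def estimate_kde(
    evalues: Sequence[float],
    bandwidth_rule: str = "silverman",
    fixed_bandwidth: float | None = None,
) -> KdeProfile:
    """Gaussian KDE of log10 e-values on a 512-point grid.

    The grid spans [min - 4h, max + 4h] where h is the bandwidth (Silverman's
    rule by default; a fixed bandwidth in log10 units may be forced for
    reproducibility).  Modes and antimodes are found from sign changes of the
    discrete first differences.
    """
    if len(evalues) < 2:
        raise ValueError(
            "need at least 2 e-values for a KDE; supply a manual cutoff instead"
        )
    logs = log10_evalues(evalues)
    if bandwidth_rule == "silverman":
        kde = gaussian_kde(logs, bw_method="silverman")
    elif bandwidth_rule == "fixed":
        if fixed_bandwidth is None or fixed_bandwidth <= 0:
            raise ValueError("fixed bandwidth rule requires fixed_bandwidth > 0")
        std = logs.std(ddof=1)
        if std == 0:
            raise ValueError("degenerate (constant) sample; supply a manual cutoff")
        kde = gaussian_kde(logs, bw_method=fixed_bandwidth / std)
    else:
        raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")
    h = float(kde.factor * logs.std(ddof=1))
    if h == 0:
        raise ValueError("degenerate (constant) sample; supply a manual cutoff")
    grid = np.linspace(logs.min() - 4 * h, logs.max() + 4 * h, _GRID_POINTS)
    density = kde(grid)
    modes, antimodes = _find_extrema(density)
    return KdeProfile(
        grid=grid, density=density, bandwidth=h, modes=modes, antimodes=antimodes
    )


@dataclass(frozen=True)
class SubunitThreshold:
    subunit: str
    evalue_cutoff: float
    source: ThresholdSource
    length_range: tuple[int, int]

    def __post_init__(self) -> None:
        if not (0 < self.evalue_cutoff <= 1e100):
            raise ValueError("evalue_cutoff must be positive")
        if self.length_range[0] > self.length_range[1]:
            raise ValueError("length range min must be <= max")


def derive_threshold(
    kde: KdeProfile,
    member_log_evalues: Sequence[float],
    all_log_evalues: Sequence[float],
    subunit: str = "",
    length_range: tuple[int, int] = (1, 10**9),
) -> SubunitThreshold:
    """E-value cutoff from the cluster-segregated score distribution.

    The member-dominated mode is the mode of the full KDE with the highest
    density of cluster-member log e-values; the cutoff is placed at the first
    antimode to its right.  If no antimode lies to the right (unimodal
    distribution), the fallback cutoff is the members' maximum e-value with
    one decade of slack.  Either way the cutoff is raised, if necessary, so
    that at least 99% of members pass.
    """
    members = np.asarray(member_log_evalues, dtype=float)
    if members.size == 0:
        raise ValueError("no cluster-member e-values; supply a manual cutoff")
    if members.size >= 2 and members.std(ddof=1) > 0:
        member_kde = gaussian_kde(members, bw_method="silverman")
        member_density = member_kde(kde.grid[list(kde.modes)])
    else:
        v = members[0] if members.size else 0.0
        member_density = np.array(
            [1.0 / (1.0 + abs(kde.grid[m] - v)) for m in kde.modes]
        )
    dominant_pos = int(np.argmax(member_density))
    dominant_idx = kde.modes[dominant_pos]

    right_antimodes = [a for a in kde.antimodes if a > dominant_idx]
    if right_antimodes:
        cutoff_log = float(kde.grid[right_antimodes[0]])
        source = ThresholdSource.ANTIMODE
    else:
        # Unimodal: no decoy population is visible, so accept the whole
        # high-confidence mode — out to where its density falls below 1% of
        # the peak — with at least one decade of slack past the member max.
        # The mode edge matters when genuine hits sit outside Complete
        # clusters (split operons) and members under-sample the mode.
        peak = float(kde.density[dominant_idx])
        j = dominant_idx
        while j + 1 < len(kde.grid) and kde.density[j + 1] >= 0.01 * peak:
            j += 1
        cutoff_log = max(float(members.max() + 1.0), float(kde.grid[j]))
        source = ThresholdSource.MEMBER_MAX_FALLBACK

    # Never cut off more than 1% of the cluster members themselves.
    p99 = float(np.percentile(members, 99))
    cutoff_log = max(cutoff_log, p99)
    cutoff = float(10.0**cutoff_log)
    return SubunitThreshold(
        subunit=subunit,
        evalue_cutoff=min(cutoff, 1.0),
        source=source,
        length_range=length_range,
    )


def derive_length_range(
    member_lengths: Sequence[int],
    lo_pct: float = 1.0,
    hi_pct: float = 99.0,
    override: tuple[int, int] | None = None,
) -> tuple[int, int]:
    """Protein-length window from cluster-member lengths.

    Returns the [lo_pct, hi_pct] percentile range; a user-supplied reference
    range (e.g. curated from reviewed database entries) overrides it.
    """
    if override is not None:
        return (int(override[0]), int(override[1]))
    if len(member_lengths) < 5:
        raise ValueError("need >= 5 member lengths; supply a manual range")
    lo = float(np.percentile(member_lengths, lo_pct))
    hi = float(np.percentile(member_lengths, hi_pct))
    return (int(np.floor(lo)), int(np.ceil(hi)))


@dataclass(frozen=True)
class RejectedHit:
    hit: HmmHit
    reason: str  # "evalue" | "length" | "both"


def filter_hits(
    hits: Sequence[HmmHit],
    thresholds: Mapping[str, SubunitThreshold],
    genes: Mapping[str, GeneCall],
    default: SubunitThreshold | None = None,
) -> tuple[list[HmmHit], list[RejectedHit]]:
    """Apply per-profile e-value and length filters.

    A hit is retained iff its e-value is at most the profile's cutoff AND its
    length falls inside the profile's length range.  The length checked is the
    domain envelope span when the hit carries one (so a single-subunit domain
    inside a fused gene is judged by its own extent, not by the fused
    protein's length), else the whole protein length.  Rejected hits carry the
    failing criterion.  Idempotent by construction.
    """
    missing = sorted(
        {h.profile for h in hits if h.profile not in thresholds and default is None}
    )
    if missing:
        raise ValueError(
            "no threshold (and no default) for profiles: " + ", ".join(missing)
        )
    retained: list[HmmHit] = []
    rejected: list[RejectedHit] = []
    for hit in hits:
        thr = thresholds.get(hit.profile, default)
        assert thr is not None
        bad_e = hit.evalue > thr.evalue_cutoff
        if hit.env_from is not None:
            plen = hit.env_to - hit.env_from + 1
        else:
            plen = genes[hit.gene_id].protein_length
        bad_len = not (thr.length_range[0] <= plen <= thr.length_range[1])
        if bad_e and bad_len:
            rejected.append(RejectedHit(hit, "both"))
        elif bad_e:
            rejected.append(RejectedHit(hit, "evalue"))
        elif bad_len:
            rejected.append(RejectedHit(hit, "length"))
        else:
            retained.append(hit)
    return retained, rejected
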