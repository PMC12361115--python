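"""Variant-lifestyle association: chi-square test of independence.

Species are the counting unit.  Oxygen tolerance is categorised as aerobe,
anaerobe, facultative anaerobe or microaerobe; the contingency table crosses
lifestyle (rows) with the representative complex variant (columns).  Cellwise
deviations are reported as Pearson residuals (O - E) / sqrt(E): positive
values indicate association of a variant with a lifestyle, negative values
dissociation.  No continuity correction is applied (the table is 4 x k).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from nuoscan.formats_io import LIFESTYLES
from nuoscan.variant_classification import SpeciesSummary, Variant

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyResult:
    observed: pd.DataFrame  # rows = lifestyle, cols = variant
    expected: pd.DataFrame
    chi2: float
    dof: int
    p_value: float
    residuals: pd.DataFrame  # Pearson residuals (O - E) / sqrt(E)


def build_contingency(
    summaries: Sequence[SpeciesSummary],
    lifestyles: Mapping[str, str],
) -> tuple[pd.DataFrame, int]:
    """Count species per (lifestyle, representative variant).

    Species without a lifestyle annotation are excluded; the count of
    exclusions is returned alongside the table.
    """
    rows = []
    n_excluded = 0
    for summ in summaries:
        lifestyle = lifestyles.get(summ.species)
        if lifestyle is None or lifestyle == "":
            n_excluded += 1
            continue
        if lifestyle not in LIFESTYLES:
            raise ValueError(f"unknown lifestyle label {lifestyle!r}")
        rows.append(
            {"lifestyle": lifestyle, "variant": summ.representative_variant.value}
        )
    if not rows:
        raise ValueError("no species with lifestyle annotations")
    df = pd.DataFrame(rows)
    observed = pd.crosstab(df["lifestyle"], df["variant"])
    observed = observed.reindex(
        index=[l for l in LIFESTYLES if l in observed.index],
        columns=[v.value for v in Variant if v.value in observed.columns],
    )
    return observed, n_excluded


def chi_square_independence(
    observed: pd.DataFrame | np.ndarray,
    min_col_total: int = 0,
) -> ContingencyResult:
    """Pearson chi-square test of independence with cellwise residuals.

    Zero-marginal rows/columns (and columns below ``min_col_total``) are
    dropped with a warning before testing.  Expected counts are the usual
    product of marginals over the grand total; a warning is logged when any
    expected count falls below 5.
    """
    if not isinstance(observed, pd.DataFrame):
        observed = pd.DataFrame(np.asarray(observed))
    table = observed.astype(float)
    if (table.values < 0).any():
        raise ValueError("counts must be non-negative")

    col_totals = table.sum(axis=0)
    drop_cols = col_totals.index[(col_totals == 0) | (col_totals < min_col_total)]
    if len(drop_cols):
        logger.warning("dropping columns with low/zero totals: %s", list(drop_cols))
        table = table.drop(columns=drop_cols)
    row_totals = table.sum(axis=1)
    drop_rows = row_totals.index[row_totals == 0]
    if len(drop_rows):
        logger.warning("dropping zero-marginal rows: %s", list(drop_rows))
        table = table.drop(index=drop_rows)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table with positive marginals")

    obs = table.values
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    expected = row @ col / total
    if (expected < 5).any():
        logger.warning("some expected counts are below 5; chi-square may be unreliable")

    with np.errstate(divide="ignore", invalid="ignore"):
        contrib = np.where(expected > 0, (obs - expected) ** 2 / expected, 0.0)
        residuals = np.where(expected > 0, (obs - expected) / np.sqrt(expected), 0.0)
    chi2 = float(contrib.sum())
    dof = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p_value = float(chi2_dist.sf(chi2, dof))

    return ContingencyResult(
        observed=table,
        expected=pd.DataFrame(expected, index=table.index, columns=table.columns),
        chi2=chi2,
        dof=dof,
        p_value=p_value,
        residuals=pd.DataFrame(residuals, index=table.index, columns=table.columns),
    )
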