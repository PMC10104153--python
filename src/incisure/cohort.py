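"""Cohort-level aggregation and group comparison.

Morphometry rows (one per disc) are aggregated to one value per animal
before testing, so the animal -- not the disc -- is the statistical unit.
The group comparison is a two-sided unpaired t-test on per-animal means
(pooled-variance Student by default, Welch on request). Incisure presence
per genotype is summarized with a Clopper-Pearson exact binomial CI.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from incisure.errors import InvalidInputError

__all__ = [
    "CohortTable",
    "GroupComparison",
    "PresenceSummary",
    "make_cohort_table",
    "per_animal_means",
    "unpaired_t_test",
    "presence_frequency",
]

COHORT_COLUMNS = (
    "genotype",
    "animal_id",
    "disc_id",
    "diameter",
    "incisure_fraction",
    "has_incisure",
)

#: A cohort table is a plain DataFrame with the columns above.
CohortTable = pd.DataFrame


@dataclass(frozen=True)
class GroupComparison:
    """Unpaired two-sided t-test between two groups of per-animal means."""

    group_a: str
    group_b: str
    means_a: tuple[float, ...]
    means_b: tuple[float, ...]
    t_statistic: float
    df: float
    p_value: float
    welch: bool = False


@dataclass(frozen=True)
class PresenceSummary:
    """Incisure presence per genotype with an exact binomial CI."""

    genotype: str
    k: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95


def make_cohort_table(rows: Sequence[dict]) -> CohortTable:
    """Validate and assemble a cohort table from per-disc records."""
    table = pd.DataFrame(list(rows))
    missing = set(COHORT_COLUMNS) - set(table.columns)
    if missing:
        raise InvalidInputError(f"cohort table missing columns: {sorted(missing)}")
    key = ["genotype", "animal_id", "disc_id"]
    if table.duplicated(subset=key).any():
        raise InvalidInputError("duplicate (genotype, animal_id, disc_id) rows")
    if (table["diameter"] <= 0).any():
        raise InvalidInputError("diameters must be positive")
    return table


def per_animal_means(table: CohortTable, field: str) -> pd.DataFrame:
    """One row per (genotype, animal): the arithmetic mean of ``field``."""
    if len(table) == 0:
        raise InvalidInputError("empty cohort table")
    if field not in table.columns:
        raise InvalidInputError(
            f"unknown field {field!r}; available: {sorted(table.columns)}"
        )
    out = (
        table.groupby(["genotype", "animal_id"], sort=True)[field]
        .mean()
        .reset_index()
    )
    return out


def unpaired_t_test(
    means_a: Sequence[float],
    means_b: Sequence[float],
    group_a: str = "A",
    group_b: str = "B",
    welch: bool = False,
) -> GroupComparison:
    """Two-sided unpaired t-test on per-animal means.

    Pooled-variance Student's t by default; Welch with ``welch=True``.
    Degenerate zero-variance inputs are handled explicitly: identical
    groups give t = 0, p = 1; distinct means with zero pooled variance give
    an infinite t and the smallest representable p.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise InvalidInputError("each group needs at least 2 values")
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if welch and (va + vb) > 0:
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        df = float(na + nb - 2)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            t, p = 0.0, 1.0
        else:
            t = np.inf if a.mean() > b.mean() else -np.inf
            p = float(np.finfo(float).tiny)
    else:
        res = stats.ttest_ind(a, b, equal_var=not welch)
        t, p = float(res.statistic), float(res.pvalue)
    return GroupComparison(
        group_a=group_a,
        group_b=group_b,
        means_a=tuple(a),
        means_b=tuple(b),
        t_statistic=t,
        df=df,
        p_value=p,
        welch=welch,
    )


def presence_frequency(
    table: CohortTable, ci_level: float = 0.95
) -> list[PresenceSummary]:
    """Incisure presence counts per genotype with Clopper-Pearson CIs."""
    if len(table) == 0:
        raise InvalidInputError("empty cohort table")
    out = []
    for genotype, sub in table.groupby("genotype", sort=True):
        n = len(sub)
        k = int(sub["has_incisure"].sum())
        ci = stats.binomtest(k, n).proportion_ci(
            confidence_level=ci_level, method="exact"
        )
        out.append(
            PresenceSummary(
                genotype=str(genotype),
                k=k,
                n=n,
                proportion=k / n,
                ci_low=float(ci.low),
                ci_high=float(ci.high),
                ci_level=ci_level,
            )
        )
    return out
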