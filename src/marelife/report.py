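"""EBV post-processing: standardization, accuracy, rank correlations, trends.

Standardized EBVs are expressed in genetic-standard-deviation units from a
fixed base cohort (recorded mares born in the base year, default 2000).
Stallion accuracy uses the classical progeny-test approximation from
half-sib daughter records, ``r = sqrt(n / (n + (4 - h2) / h2))``; the
operational selection rule is a minimum number of recorded daughters
(default 9).  Genetic trends are mean standardized EBVs per birth-year
cohort over a 15-year window ending at the latest cohort that still meets
a minimum size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "standardize_ebv",
    "accuracy_from_progeny",
    "count_recorded_daughters",
    "select_stallions",
    "rank_correlation",
    "genetic_trend",
    "GeneticTrend",
]


@dataclass
class GeneticTrend:
    group: str                  # 'mares' or 'sires'
    reference_year: int
    table: pd.DataFrame         # columns: birth_year, mean_std_ebv, n


def standardize_ebv(
    ebv: pd.Series,
    birth_year: pd.Series,
    recorded: pd.Series,
    base_year: int,
    genetic_sd: float,
) -> pd.Series:
    """(EBV - mean EBV of recorded base-year cohort) / genetic SD."""
    if genetic_sd <= 0:
        raise ValueError("genetic_sd must be > 0")
    mask = recorded.reindex(ebv.index, fill_value=False) & (
        birth_year.reindex(ebv.index) == base_year
    )
    if not mask.any():
        years = sorted(birth_year.reindex(ebv.index)[recorded.reindex(ebv.index, fill_value=False)].dropna().unique())
        raise ValueError(
            f"no recorded animals born in base year {base_year}; "
            f"recorded cohorts available: {years}"
        )
    base_mean = float(ebv[mask].mean())
    return (ebv - base_mean) / genetic_sd


def accuracy_from_progeny(n_daughters: int, h2: float) -> float:
    """Progeny-test EBV accuracy from n half-sib daughter records."""
    if n_daughters < 0:
        raise ValueError("n_daughters must be >= 0")
    if h2 <= 0.0:
        return 0.0
    if h2 > 1.0:
        raise ValueError("h2 must be in (0, 1]")
    k = (4.0 - h2) / h2
    return float(np.sqrt(n_daughters / (n_daughters + k)))


def count_recorded_daughters(pedigree: pd.DataFrame, recorded_mares) -> pd.Series:
    """Number of recorded daughters per sire (index: sire animal_id)."""
    rec = set(int(m) for m in recorded_mares)
    daughters = pedigree[
        (pedigree["sex"] == "F")
        & (pedigree["sire_id"] != 0)
        & pedigree["animal_id"].isin(rec)
    ]
    return daughters.groupby("sire_id").size().rename("n_recorded_daughters")


def select_stallions(
    ebv_table: pd.DataFrame,
    min_daughters: int = 9,
    min_accuracy: float | None = None,
    h2: float | None = None,
) -> pd.DataFrame:
    """Stallions eligible for rank comparison.

    ``ebv_table`` needs columns ``n_recorded_daughters`` (and ``sex`` 'M'
    rows only, if mixed).  The operational rule is the daughter-count
    threshold; a ``min_accuracy`` with ``h2`` may be supplied instead, in
    which case the smallest daughter count whose accuracy reaches it is
    used.
    """
    if min_accuracy is not None:
        if h2 is None:
            raise ValueError("min_accuracy requires h2")
        n = 0
        while accuracy_from_progeny(n, h2) < min_accuracy and n < 10**6:
            n += 1
        min_daughters = n
    tab = ebv_table
    if "sex" in tab:
        tab = tab[tab["sex"] == "M"]
    return tab[tab["n_recorded_daughters"] >= min_daughters]


def rank_correlation(ebv_a, ebv_b) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    a = np.asarray(ebv_a, float)
    b = np.asarray(ebv_b, float)
    if a.size == 0 or a.shape != b.shape:
        raise ValueError("EBV vectors must be non-empty and aligned")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant vector")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)


def genetic_trend(
    std_ebv: pd.Series,
    birth_year: pd.Series,
    group: str,
    min_cohort_size: int,
    window: int = 15,
) -> GeneticTrend:
    """Mean standardized EBV per birth-year cohort over a trailing window.

    The reference year is the latest birth year whose cohort size exceeds
    ``min_cohort_size``; the series covers the ``window`` years ending
    there.  Raises with the observed cohort sizes if no year qualifies.
    """
    by = birth_year.reindex(std_ebv.index)
    sizes = by.value_counts().sort_index()
    qualifying = sizes[sizes > min_cohort_size]
    if qualifying.empty:
        raise ValueError(
            f"no birth year with more than {min_cohort_size} {group}; "
            f"cohort sizes: {sizes.to_dict()}"
        )
    ref = int(qualifying.index.max())
    years = list(range(ref - window + 1, ref + 1))
    rows = []
    for yr in years:
        sel = std_ebv[by == yr]
        rows.append(
            {
                "birth_year": yr,
                "mean_std_ebv": float(sel.mean()) if len(sel) else np.nan,
                "n": int(len(sel)),
            }
        )
    return GeneticTrend(group=group, reference_year=ref, table=pd.DataFrame(rows))
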