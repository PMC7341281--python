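"""Studbook I/O and the dataset editing rules.

Reads the studbook (per-season reproductive events) and pedigree CSVs and
applies the career-level filters that define the two analysis datasets:
complete careers (6 consecutive registered breeding seasons) for training
the projection, and careers with at least 3 seasons for the full genetic
analysis.

Filters, applied per mare and reported per rule:

* born strictly after ``min_birth_year``;
* both parents known (optional);
* registered seasons in consecutive calendar years, no gaps;
* first registered event at 36-59 months of age (the 3- and 4-year-old
  first-foaling classes);
* interval between two adjacent registered events that are both foalings
  within [11, 17] months (a data-completeness check: a longer gap between
  consecutive registered foalings implies an unregistered season);
* at least ``min_seasons`` seasons (only the first 6 count toward the
  lifetime endpoint);
* environmental-unit-by-birth-year (EU-BY) levels with fewer than
  ``min_eu_by_records`` mares removed, iterated to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EditingRules",
    "MareCareer",
    "read_studbook",
    "read_pedigree",
    "apply_editing",
    "build_eu_by",
]

EVENT_TYPES = {"F", "A", "O"}
STUDBOOK_COLS = ["mare_id", "event_year", "event_type", "age_months", "eu_id"]
PEDIGREE_COLS = ["animal_id", "sire_id", "dam_id", "birth_year", "sex"]


class StudbookFormatError(ValueError):
    pass


@dataclass
class EditingRules:
    min_birth_year: int = 1990          # strict: born after this year
    min_first_event_age: int = 36       # months; start of age-3 class
    max_first_event_age: int = 59       # months; end of age-4 class
    min_foaling_interval: int = 11      # months
    max_foaling_interval: int = 17      # months
    min_eu_by_records: int = 2
    require_both_parents: bool = True
    min_seasons: int = 6                # 6 = training dataset, 3 = full dataset

    def validate(self) -> None:
        if self.min_first_event_age >= self.max_first_event_age:
            raise ValueError("first-event age window must be increasing")
        if self.min_foaling_interval >= self.max_foaling_interval:
            raise ValueError("foaling-interval window must be increasing")
        if self.min_seasons not in (3, 4, 5, 6):
            raise ValueError("min_seasons must be in {3,...,6}")


@dataclass
class MareCareer:
    """A mare's edited career: consecutive seasons, capped at 6."""

    mare_id: int
    birth_year: int
    eu_id: int
    af_class: int                      # 3 or 4 (years at first foaling)
    events: list                       # [(event_year, event_type, age_months)]
    n_registered: int                  # seasons registered before capping at 6

    @property
    def eu_by(self) -> tuple:
        return (self.eu_id, self.birth_year)

    def foals_after(self, k: int) -> int:
        if not 1 <= k <= 6:
            raise ValueError("k must be in 1..6")
        return sum(1 for (_, t, _) in self.events[:k] if t == "F")

    @property
    def n_seasons(self) -> int:
        return len(self.events)


def read_studbook(path) -> pd.DataFrame:
    """Read and validate a studbook CSV written by the generator schema."""
    df = pd.read_csv(path)
    missing = set(STUDBOOK_COLS) - set(df.columns)
    if missing:
        raise StudbookFormatError(f"studbook missing columns: {sorted(missing)}")
    bad = ~df["event_type"].isin(EVENT_TYPES)
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header + 1-based
        raise StudbookFormatError(
            f"line {line}: invalid event_type {df.loc[bad, 'event_type'].iloc[0]!r}"
        )
    for col in ("mare_id", "event_year", "age_months", "eu_id"):
        if not np.issubdtype(df[col].dtype, np.number) or df[col].isna().any():
            raise StudbookFormatError(f"column {col} must be numeric and complete")
    dup = df.duplicated(subset=["mare_id", "event_year"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise StudbookFormatError(f"line {line}: duplicate (mare_id, event_year)")
    return df[STUDBOOK_COLS].copy()


def read_pedigree(path) -> pd.DataFrame:
    """Read and validate a pedigree CSV; missing parents normalized to 0."""
    df = pd.read_csv(path)
    missing = set(PEDIGREE_COLS) - set(df.columns)
    if missing:
        raise StudbookFormatError(f"pedigree missing columns: {sorted(missing)}")
    for col in ("sire_id", "dam_id"):
        df[col] = df[col].fillna(0).astype(int)
    df["animal_id"] = df["animal_id"].astype(int)
    self_parent = (df["animal_id"] == df["sire_id"]) | (df["animal_id"] == df["dam_id"])
    if self_parent.any():
        line = int(df.index[self_parent][0]) + 2
        raise StudbookFormatError(f"line {line}: animal listed as its own parent")
    dup = df.duplicated(subset=["animal_id"])
    if dup.any():
        line = int(df.index[dup][0]) + 2
        raise StudbookFormatError(f"line {line}: duplicate animal_id")
    return df[PEDIGREE_COLS].copy()


def _mare_passes(ev: pd.DataFrame, ped_row, rules: EditingRules):
    """Return (MareCareer, None) or (None, rejection-rule name)."""
    if ped_row is None:
        return None, "not_in_pedigree"
    if ped_row.birth_year <= rules.min_birth_year:
        return None, "birth_year"
    if rules.require_both_parents and (ped_row.sire_id == 0 or ped_row.dam_id == 0):
        return None, "unknown_parent"
    ev = ev.sort_values("event_year")
    years = ev["event_year"].to_numpy()
    if len(years) > 1 and np.any(np.diff(years) != 1):
        return None, "season_gap"
    ages = ev["age_months"].to_numpy()
    if not rules.min_first_event_age <= ages[0] <= rules.max_first_event_age:
        return None, "first_event_age"
    types = ev["event_type"].to_numpy()
    foal_adjacent = (types[:-1] == "F") & (types[1:] == "F") if len(types) > 1 else np.array([], bool)
    intervals = np.diff(ages)[foal_adjacent]
    if np.any(intervals < rules.min_foaling_interval) or np.any(
        intervals > rules.max_foaling_interval
    ):
        return None, "foaling_interval"
    if len(ev) < rules.min_seasons:
        return None, "too_few_seasons"

    capped = ev.iloc[:6]
    foal_ages = capped.loc[capped["event_type"] == "F", "age_months"]
    af_age = float(foal_ages.iloc[0]) if len(foal_ages) else float(ages[0])
    af_class = 3 if af_age < 48 else 4
    career = MareCareer(
        mare_id=int(ev["mare_id"].iloc[0]),
        birth_year=int(ped_row.birth_year),
        eu_id=int(ev["eu_id"].iloc[0]),
        af_class=af_class,
        events=list(
            zip(capped["event_year"], capped["event_type"], capped["age_months"])
        ),
        n_registered=len(ev),
    )
    return career, None


def apply_editing(
    events: pd.DataFrame, pedigree: pd.DataFrame, rules: EditingRules
) -> tuple[list[MareCareer], dict]:
    """Apply every editing rule; returns (careers, per-rule removal report)."""
    rules.validate()
    ped_idx = pedigree.set_index("animal_id")
    report: dict[str, int] = {}
    careers: list[MareCareer] = []
    for mare_id, ev in events.groupby("mare_id", sort=True):
        row = ped_idx.loc[mare_id] if mare_id in ped_idx.index else None
        career, reason = _mare_passes(ev, row, rules)
        if career is None:
            report[reason] = report.get(reason, 0) + 1
        else:
            careers.append(career)

    # EU-BY minimum-records filter, iterated to a fixed point
    removed_eu = 0
    while True:
        counts = build_eu_by(careers)
        keep = [c for c in careers if counts[c.eu_by] >= rules.min_eu_by_records]
        if len(keep) == len(careers):
            break
        removed_eu += len(careers) - len(keep)
        careers = keep
    if removed_eu:
        report["eu_by_min_records"] = removed_eu
    report["retained"] = len(careers)
    return careers, report


def build_eu_by(careers) -> dict:
    """(eu_id, birth_year) -> record count over the given careers."""
    counts: dict[tuple, int] = {}
    for c in careers:
        counts[c.eu_by] = counts.get(c.eu_by, 0) + 1
    return counts
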