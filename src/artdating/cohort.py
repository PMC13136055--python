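"""Cohort construction: inclusion/exclusion rules and onset classification.

The analysis population is singleton live births without registered
congenital malformation, born between 22 weeks (GA 154 days) and GA 310
days on the ultrasound scale, with complete ART dating information for
ART-conceived records.  Exclusions are tallied in a fixed order so each
record is counted once, at the first rule it trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import MAX_GA_DAYS, MIN_GA_DAYS, ONSET_TYPES, SPONTANEOUS

__all__ = [
    "ExclusionTally",
    "apply_exclusions",
    "classify_onset",
    "event_indicator",
    "nonspontaneous_proportions",
]

#: fixed exclusion order; first rule tripped wins
EXCLUSION_RULES = (
    "multiple_birth",
    "perinatal_death",
    "malformation",
    "ga_over_310",
    "art_missing_info",
)

_ART_REQUIRED = ("fertilization_date", "culture_days", "transfer_date")


@dataclass
class ExclusionTally:
    """Auditable record counts for each exclusion rule."""

    n_input: int = 0
    n_retained: int = 0
    counts: dict = field(default_factory=lambda: {r: 0 for r in EXCLUSION_RULES})

    def check(self) -> None:
        total = self.n_retained + sum(self.counts.values())
        if total != self.n_input:
            raise AssertionError(
                f"exclusion tally does not conserve records: {total} != {self.n_input}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"rule": r, "n_excluded": self.counts[r]} for r in EXCLUSION_RULES]
        rows.append({"rule": "retained", "n_excluded": self.n_retained})
        rows.append({"rule": "input", "n_excluded": self.n_input})
        return pd.DataFrame(rows)


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionTally]:
    """Filter a registry frame down to the analysis cohort.

    Rules, in order: multiple birth (plurality > 1); stillbirth or
    perinatal death; congenital malformation; ultrasound GA at birth
    outside [154, 310] days; ART record with missing or ambiguous dating
    information (missing dates, culture days, or inconsistent fresh-ET
    dates).  Returns the retained records and the tally.
    """
    tally = ExclusionTally(n_input=len(records))
    if len(records) == 0:
        return records.copy(), tally

    excluded = pd.Series(False, index=records.index)

    def trip(rule: str, mask: pd.Series) -> None:
        fresh_hits = np.asarray(mask, dtype=bool) & ~excluded
        tally.counts[rule] = int(fresh_hits.sum())
        excluded[fresh_hits] = True

    trip("multiple_birth", records["plurality"].fillna(1) > 1)
    trip("perinatal_death", records["perinatal_death"].fillna(False).astype(bool))
    trip("malformation", records["malformation"].fillna(False).astype(bool))
    ga = records["ga_us_birth_days"]
    trip("ga_over_310", ga.isna() | (ga > MAX_GA_DAYS) | (ga < MIN_GA_DAYS))
    trip("art_missing_info", _art_incomplete(records))

    retained = records.loc[~excluded].copy()
    tally.n_retained = len(retained)
    tally.check()
    return retained, tally


def _art_incomplete(records: pd.DataFrame) -> pd.Series:
    art = records["conception_mode"] != SPONTANEOUS
    missing = pd.Series(False, index=records.index)
    for col in _ART_REQUIRED:
        if col in records.columns:
            missing |= records[col].isna()
        else:
            missing |= True
    # fresh-ET internal consistency: transfer - fertilization = culture days
    if all(c in records.columns for c in _ART_REQUIRED):
        fresh = records["conception_mode"] == "fresh_et"
        gap = (records["transfer_date"] - records["fertilization_date"]).dt.days
        inconsistent = fresh & ~missing & (gap != records["culture_days"].astype("Float64"))
        missing |= inconsistent.fillna(True) & fresh
    return art & missing


def classify_onset(onset_type: str) -> str:
    """Map an onset-of-birth type to its time-to-event role.

    Spontaneous onsets are events; induced births, elective cesareans
    and pre-labor emergency cesareans pre-empt the spontaneous onset and
    are right-censored.
    """
    if onset_type not in ONSET_TYPES:
        raise ValueError(f"unknown onset_type: {onset_type!r}")
    return "event" if onset_type == "spontaneous" else "censored"


def event_indicator(records: pd.DataFrame) -> np.ndarray:
    """Vectorized event flags (True = spontaneous onset) for a frame."""
    bad = ~records["onset_type"].isin(ONSET_TYPES)
    if bad.any():
        raise ValueError(
            f"unknown onset_type values: {sorted(records.loc[bad, 'onset_type'].unique())}"
        )
    return (records["onset_type"] == "spontaneous").to_numpy()


def nonspontaneous_proportions(records: pd.DataFrame) -> pd.DataFrame:
    """Fraction of right-censored (nonspontaneous) births per group.

    Returns one row per conception mode with numerator, denominator and
    the percentage to one decimal.  Empty input gives an empty frame.
    """
    rows = []
    for group, sub in records.groupby("conception_mode", sort=True):
        n = len(sub)
        k = int((~event_indicator(sub)).sum())
        rows.append(
            {
                "conception_mode": group,
                "n_nonspontaneous": k,
                "n_total": n,
                "fraction": k / n,
                "percent": round(100.0 * k / n, 1),
            }
        )
    return pd.DataFrame(rows)
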