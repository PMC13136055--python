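"""Gestational-age scales and date arithmetic.

Day 0 of every scale is the first day of the last menstrual period
(LMP).  The ultrasound scale (GA_US) is anchored by the registry-recorded
GA at birth; the ART scale adds a follicular-phase constant ``k`` to the
embryo's known age.  GA arithmetic at the registry interface is in whole
days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

from .params import EDD_DAY

#: customary follicular-phase constant used by registries
K14 = 14
#: recalibrated constant aligning ART dating with the ultrasound scale
K15 = 15

__all__ = [
    "K14",
    "K15",
    "DatingEstimate",
    "ga_art_at_birth",
    "ga_at_date",
    "edd",
    "pairwise_ga_difference",
]


@dataclass(frozen=True)
class DatingEstimate:
    """A GA value tied to a calendar date and a dating method."""

    ga_days: float
    reference_date: dt.date
    method: str  # "us" or "art"
    k: int | None = None

    def at(self, query_date: dt.date) -> "DatingEstimate":
        """Propagate this estimate to another (earlier) calendar date."""
        ga = ga_at_date(self.ga_days, self.reference_date, query_date)
        return DatingEstimate(ga, query_date, self.method, self.k)

    @property
    def edd(self) -> dt.date:
        return edd(self.ga_days, self.reference_date)


def ga_art_at_birth(k: int, culture_days: int, transfer_to_birth: int) -> int:
    """ART-based GA at birth.

    ``k`` days of follicular phase, plus the days from oocyte
    fertilization to embryo transfer (fresh ET) or to cryopreservation
    (frozen ET), plus the days from transfer to birth.
    """
    if k <= 0:
        raise ValueError(f"follicular-phase constant k must be positive, got {k}")
    if culture_days < 0 or transfer_to_birth < 0:
        raise ValueError("culture_days and transfer_to_birth must be >= 0")
    return k + culture_days + transfer_to_birth


def ga_at_date(ga_at_ref: float, ref_date: dt.date, query_date: dt.date) -> float:
    """GA at any date at or before the reference date.

    GA advances one day per calendar day, so the registry-recorded GA at
    birth determines GA on every earlier date; the operation is the same
    for the ultrasound and ART scales.
    """
    lag = (ref_date - query_date).days
    if lag < 0:
        raise ValueError(f"query_date {query_date} is after reference date {ref_date}")
    return ga_at_ref - lag


def edd(ga_at_ref: float, ref_date: dt.date) -> dt.date:
    """Estimated date of delivery: the date at which GA reaches day 283."""
    return ref_date + dt.timedelta(days=round(EDD_DAY - ga_at_ref))


def pairwise_ga_difference(record, k: int) -> int:
    """GA_US minus GA_ART,k for one ART-conceived pregnancy.

    ``record`` is any object (dataclass, namedtuple, pandas row) with
    attributes ``conception_mode``, ``ga_us_birth_days``, ``culture_days``,
    ``transfer_date`` and ``birth_date``.  The difference is constant
    through pregnancy, so it is evaluated at birth.
    """
    mode = getattr(record, "conception_mode")
    if mode == "spontaneous":
        raise ValueError("pairwise GA difference is defined for ART records only")
    ga_us = getattr(record, "ga_us_birth_days")
    culture = getattr(record, "culture_days")
    transfer = _as_date(getattr(record, "transfer_date"))
    birth = _as_date(getattr(record, "birth_date"))
    if ga_us is None or culture is None or transfer is None or birth is None:
        raise ValueError("ART record is missing dating fields")
    t2b = (birth - transfer).days
    return int(ga_us) - ga_art_at_birth(k, int(culture), t2b)


def _as_date(x) -> dt.date | None:
    if x is None:
        return None
    if isinstance(x, dt.datetime):
        return x.date()
    if isinstance(x, dt.date):
        return x
    # pandas Timestamp
    if hasattr(x, "to_pydatetime"):
        return x.to_pydatetime().date()
    return None
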