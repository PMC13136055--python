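"""Statistical agreement between ultrasound and ART-based dating.

The unit of analysis is the per-pregnancy pairwise difference
GA_US - GA_ART,k, which is constant through pregnancy.  Agreement is
summarized by the median and quartile offsets of the differences, a
binned frequency table of absolute differences, and seeded percentile
bootstrap CIs for medians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dating import ga_art_at_birth

__all__ = [
    "AgreementSummary",
    "pairwise_differences",
    "summarize_agreement",
    "bootstrap_median_ci",
    "ga_on_transfer_day_by_culture",
]

#: frequency-table bins on the rounded absolute difference, in days
ABS_DIFF_BINS = ("<=1", "2", "3", "4", ">=5")


@dataclass(frozen=True)
class AgreementSummary:
    """Median/quartile summary and |difference| frequency table."""

    n: int
    median_diff: float
    q1_offset: float  # 1st quartile minus median (<= 0)
    q3_offset: float  # 3rd quartile minus median (>= 0)
    freq_table: dict  # bin label -> count
    percent_table: dict  # bin label -> percent, one decimal
    ci_median: tuple[float, float] | None = None
    ci_method: str = "none"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_abs_diff_days": list(self.freq_table),
                "count": list(self.freq_table.values()),
                "percent": [self.percent_table[b] for b in self.freq_table],
            }
        )


def pairwise_differences(records: pd.DataFrame, k: int) -> np.ndarray:
    """Vectorized GA_US - GA_ART,k over the ART records of a frame.

    GA_ART,k at birth is ``k`` plus culture days plus the days from
    (thaw-)transfer to birth; for frozen ET the culture days count
    fertilization to cryopreservation.
    """
    art = records[records["conception_mode"] != "spontaneous"]
    if art[["transfer_date", "birth_date", "culture_days"]].isna().any().any():
        raise ValueError("ART records with missing dating fields; apply exclusions first")
    t2b = (art["birth_date"] - art["transfer_date"]).dt.days.to_numpy()
    if np.any(t2b < 0):
        raise ValueError("birth before transfer")
    ga_art = ga_art_at_birth(k, 0, 0) + art["culture_days"].to_numpy(dtype=np.int64) + t2b
    return art["ga_us_birth_days"].to_numpy(dtype=np.int64) - ga_art


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def summarize_agreement(diffs, ci: tuple[float, float] | None = None, ci_method: str = "none") -> AgreementSummary:
    """Summarize a sample of pairwise GA differences.

    Median and quartiles use linear interpolation of order statistics
    (numpy's default); absolute differences are rounded half away from
    zero before binning into {<=1, 2, 3, 4, >=5} days.  Percentages are
    reported to one decimal.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size == 0:
        raise ValueError("cannot summarize an empty difference sample")
    q1, med, q3 = np.quantile(d, [0.25, 0.5, 0.75])
    a = np.abs(_round_half_away(d))
    counts = {
        "<=1": int((a <= 1).sum()),
        "2": int((a == 2).sum()),
        "3": int((a == 3).sum()),
        "4": int((a == 4).sum()),
        ">=5": int((a >= 5).sum()),
    }
    percents = {b: round(100.0 * c / d.size, 1) for b, c in counts.items()}
    return AgreementSummary(
        n=int(d.size),
        median_diff=float(med),
        q1_offset=float(q1 - med),
        q3_offset=float(q3 - med),
        freq_table=counts,
        percent_table=percents,
        ci_median=ci,
        ci_method=ci_method,
    )


def bootstrap_median_ci(
    diffs, B: int = 10_000, level: float = 0.95, seed: int = 0
) -> tuple[float, float]:
    """Seeded percentile bootstrap CI for the sample median.

    A degenerate all-equal sample yields a zero-width interval rather
    than an error.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("bootstrap CI needs at least two observations")
    if B < 1:
        raise ValueError("B must be >= 1")
    if np.all(d == d[0]):
        return (float(d[0]), float(d[0]))
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    # resample in blocks to bound memory at large n * B
    block = max(1, int(5e7) // d.size)
    meds = np.empty(B)
    for start in range(0, B, block):
        stop = min(B, start + block)
        idx = rng.integers(0, d.size, size=(stop - start, d.size))
        meds[start:stop] = np.median(d[idx], axis=1)
    lo, hi = np.quantile(meds, [alpha, 1.0 - alpha])
    point = float(np.median(d))
    return (float(min(lo, point)), float(max(hi, point)))


def ga_on_transfer_day_by_culture(
    records: pd.DataFrame, B: int = 10_000, level: float = 0.95, seed: int = 0
) -> pd.DataFrame:
    """Median ultrasound GA on the day of transfer, by culture day.

    Propagates the registry-recorded ultrasound GA at birth back to the
    (thaw-)transfer date.  If the gestational clock starts at oocyte
    fertilization, the median equals the median follicular phase plus
    the culture days — for a frozen ET the embryo's developmental age at
    thaw-transfer equals its age at cryopreservation, so the same
    propagation applies to both groups.  Empty strata are omitted.
    """
    art = records[records["conception_mode"] != "spontaneous"]
    rows = []
    for (mode, culture), sub in art.groupby(["conception_mode", "culture_days"], sort=True):
        if len(sub) == 0:
            continue
        lag = (sub["birth_date"] - sub["transfer_date"]).dt.days.to_numpy()
        ga_transfer = sub["ga_us_birth_days"].to_numpy(dtype=np.int64) - lag
        med = float(np.median(ga_transfer))
        if len(sub) >= 2:
            ci = bootstrap_median_ci(ga_transfer, B=B, level=level, seed=seed)
        else:
            ci = (med, med)
        rows.append(
            {
                "conception_mode": mode,
                "culture_days": int(culture),
                "n": len(sub),
                "median_ga_days": med,
                "ci_lo": ci[0],
                "ci_hi": ci[1],
            }
        )
    return pd.DataFrame(rows)
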