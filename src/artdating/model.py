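"""Model/Results interface over the dating-agreement and duration analyses.

Two model classes mirror the two halves of the analysis:

``DatingAgreement``
    within-pregnancy comparison of ultrasound and ART-based GA under one
    or more follicular-phase constants ``k``;

``PregnancyDuration``
    censoring-aware birth-distribution estimation per conception group,
    with Monte Carlo CIs for medians and group differences.

Each model is built from a registry-schema DataFrame and ``fit()``
returns a results object carrying estimates, intervals and a
``summary()`` table; plotting hangs off the results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import agreement as agr
from . import survival as surv
from .cohort import event_indicator
from .dating import K14, K15
from .io import read_registry
from .params import GROUPS

__all__ = ["DatingAgreement", "DatingAgreementResults", "PregnancyDuration", "PregnancyDurationResults"]


class DatingAgreement:
    """Agreement model for GA_US versus GA_ART,k on ART records.

    Parameters
    ----------
    data : DataFrame in the registry schema (ART rows are used).
    ks : follicular-phase constants to compare (default (14, 15)).
    group_col : grouping column, default conception mode.
    """

    def __init__(self, data: pd.DataFrame, ks=(K14, K15), group_col: str = "conception_mode"):
        self.data = data[data["conception_mode"] != "spontaneous"]
        if len(self.data) == 0:
            raise ValueError("no ART records to compare dating methods on")
        self.ks = tuple(int(k) for k in ks)
        self.group_col = group_col

    @classmethod
    def from_registry(cls, path, **kwargs) -> "DatingAgreement":
        return cls(read_registry(path), **kwargs)

    def fit(self, B: int = 10_000, level: float = 0.95, seed: int = 0) -> "DatingAgreementResults":
        summaries: dict[tuple[str, int], agr.AgreementSummary] = {}
        for group, sub in self.data.groupby(self.group_col, sort=True):
            for k in self.ks:
                diffs = agr.pairwise_differences(sub, k)
                ci = agr.bootstrap_median_ci(diffs, B=B, level=level, seed=seed)
                summaries[(group, k)] = agr.summarize_agreement(
                    diffs, ci=ci, ci_method="bootstrap_percentile"
                )
        transfer_day = agr.ga_on_transfer_day_by_culture(self.data, B=B, level=level, seed=seed)
        return DatingAgreementResults(
            model=self, summaries=summaries, transfer_day_ga=transfer_day,
            B=B, level=level, seed=seed,
        )


@dataclass
class DatingAgreementResults:
    model: DatingAgreement
    summaries: dict
    transfer_day_ga: pd.DataFrame
    B: int
    level: float
    seed: int

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for (group, k), s in sorted(self.summaries.items()):
            rows.append(
                {
                    "group": group,
                    "k": k,
                    "n": s.n,
                    "median_diff_days": s.median_diff,
                    "ci_lo": s.ci_median[0],
                    "ci_hi": s.ci_median[1],
                    "q1_offset": s.q1_offset,
                    "q3_offset": s.q3_offset,
                    **{f"pct_abs_{b}": s.percent_table[b] for b in agr.ABS_DIFF_BINS},
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        frame = self.summary_frame()
        lines = [
            "Dating agreement: GA_US - GA_ART,k (days)",
            "=" * 72,
            frame.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
            "-" * 72,
            f"median CI: percentile bootstrap, B={self.B}, level={self.level:.0%}, seed={self.seed}",
            "",
            "Ultrasound GA on day of transfer (fresh) / embryo age at thaw-transfer (frozen):",
            self.transfer_day_ga.to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        ]
        return "\n".join(lines)

    def plot(self, ax=None, k: int | None = None):
        """Histogram of pairwise differences per group at one k."""
        import matplotlib.pyplot as plt

        k = k if k is not None else self.model.ks[0]
        if ax is None:
            _, ax = plt.subplots()
        for group, sub in self.model.data.groupby(self.model.group_col, sort=True):
            diffs = agr.pairwise_differences(sub, k)
            lo, hi = diffs.min(), diffs.max()
            ax.hist(
                diffs, bins=np.arange(lo - 0.5, hi + 1.5), alpha=0.5,
                label=f"{group} (n={len(diffs)})",
            )
        ax.set_xlabel(f"GA_US - GA_ART,{k} (days)")
        ax.set_ylabel("pregnancies")
        ax.legend()
        return ax


class PregnancyDuration:
    """Censoring-aware model of GA at birth per conception group.

    Spontaneous onsets are events; induced and pre-labor cesarean births
    are right-censored (``strategy='censor'``, the primary analysis).
    """

    def __init__(
        self,
        data: pd.DataFrame,
        time_col: str = "ga_us_birth_days",
        group_col: str = "conception_mode",
        strategy: str = "censor",
    ):
        if strategy not in surv.STRATEGIES:
            raise ValueError(f"strategy must be one of {surv.STRATEGIES}")
        self.data = data
        self.time_col = time_col
        self.group_col = group_col
        self.strategy = strategy

    @classmethod
    def from_registry(cls, path, **kwargs) -> "PregnancyDuration":
        return cls(read_registry(path), **kwargs)

    def fit(
        self, n_sim: int = 10_000, level: float = 0.95, seed: int = 0, interpolate: bool = True
    ) -> "PregnancyDurationResults":
        curves: dict[str, surv.SurvivalCurve] = {}
        medians: dict[str, surv.MedianEstimate] = {}
        notes: dict[str, str] = {}
        for group, sub in self.data.groupby(self.group_col, sort=True):
            curve = surv.strategy_compare(sub, self.strategy, time_col=self.time_col)
            curves[group] = curve
            try:
                medians[group] = surv.mc_median_ci(curve, n_sim=n_sim, level=level, seed=seed)
            except ValueError as err:
                notes[group] = str(err)
        return PregnancyDurationResults(
            model=self, curves=curves, medians=medians, notes=notes,
            n_sim=n_sim, level=level, seed=seed, interpolate=interpolate,
        )


@dataclass
class PregnancyDurationResults:
    model: PregnancyDuration
    curves: dict
    medians: dict
    notes: dict
    n_sim: int
    level: float
    seed: int
    interpolate: bool = True
    _diff_cache: dict = field(default_factory=dict, repr=False)

    def median_difference(self, group_a: str, group_b: str) -> surv.MedianEstimate:
        """Monte Carlo CI for median(A) - median(B)."""
        key = (group_a, group_b)
        if key not in self._diff_cache:
            self._diff_cache[key] = surv.mc_median_difference_ci(
                self.curves[group_a], self.curves[group_b],
                n_sim=self.n_sim, level=self.level, seed=self.seed,
            )
        return self._diff_cache[key]

    def median_frame(self) -> pd.DataFrame:
        rows = []
        for group in sorted(self.curves):
            curve = self.curves[group]
            row = {
                "group": group,
                "n": curve.n_total,
                "n_events": int(curve.n_events.sum()),
                "n_censored": int(curve.n_censored.sum()),
                "strategy": self.model.strategy,
                "scale": self.model.time_col,
            }
            if group in self.medians:
                est = self.medians[group]
                row.update(median_days=est.median, ci_lo=est.ci[0], ci_hi=est.ci[1])
            else:
                row.update(median_days=np.nan, ci_lo=np.nan, ci_hi=np.nan)
            rows.append(row)
        return pd.DataFrame(rows)

    def difference_frame(self, pairs=None) -> pd.DataFrame:
        if pairs is None:
            groups = [g for g in GROUPS if g in self.medians]
            pairs = [(a, b) for i, a in enumerate(groups) for b in groups[:i]]
        rows = []
        for a, b in pairs:
            est = self.median_difference(a, b)
            rows.append(
                {"comparison": f"{a} - {b}", "difference_days": est.median,
                 "ci_lo": est.ci[0], "ci_hi": est.ci[1]}
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            f"Pregnancy duration (Kaplan-Meier, strategy={self.model.strategy!r}, "
            f"scale={self.model.time_col})",
            "=" * 72,
            self.median_frame().to_string(index=False, float_format=lambda v: f"{v:.1f}"),
        ]
        if len(self.medians) > 1:
            lines += ["-" * 72, self.difference_frame().to_string(
                index=False, float_format=lambda v: f"{v:.1f}")]
        for group, note in self.notes.items():
            lines.append(f"note [{group}]: {note}")
        lines.append(
            f"median CI: parametric Monte Carlo on log S, n_sim={self.n_sim}, "
            f"level={self.level:.0%}, seed={self.seed}"
        )
        return "\n".join(lines)

    def plot(self, ax=None):
        """Cumulative birth distributions F(t) = 1 - S(t) per group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for group in sorted(self.curves):
            curve = self.curves[group]
            ax.step(curve.times, 1.0 - curve.S, where="post", label=f"{group} (n={curve.n_total})")
        ax.set_xlabel(f"{self.model.time_col} (days)")
        ax.set_ylabel("proportion delivered")
        ax.axhline(0.5, color="grey", lw=0.5, ls="--")
        ax.legend()
        return ax

    def competing_risks(self) -> dict:
        """Aalen-Johansen CIFs per group (pre-eclampsia as competing event)."""
        out = {}
        for group, sub in self.model.data.groupby(self.model.group_col, sort=True):
            times = sub[self.model.time_col].to_numpy(dtype=float)
            causes = surv.causes_from_records(sub)
            try:
                out[group] = surv.aalen_johansen(times, causes)
            except ValueError:
                continue
        return out

    def event_table(self, group: str) -> pd.DataFrame:
        return self.curves[group].to_frame()

    @property
    def event_rate(self) -> pd.Series:
        grouped = self.model.data.groupby(self.model.group_col, sort=True)
        return grouped.apply(lambda s: float(event_indicator(s).mean()), include_groups=False)
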