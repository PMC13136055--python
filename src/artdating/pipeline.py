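"""End-to-end analysis: generate-or-read, exclude, date, agree, survive, report.

All randomness is seeded through the config, so a run is deterministic:
the same config produces byte-identical report tables.  Outputs are flat
CSV tables plus long-format step-function exports of every survival
curve and a JSON manifest enabling exact reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort import apply_exclusions, nonspontaneous_proportions
from .dating import K14, K15
from .io import read_registry, write_registry
from .model import DatingAgreement, PregnancyDuration
from .params import GeneratorParams, default_params
from .simulate import simulate_cohort
from .survival import STRATEGIES, remaining_duration_by_culture, survival_median

log = logging.getLogger("artdating")

__all__ = ["AnalysisConfig", "AnalysisReport", "run_analysis"]


@dataclass
class AnalysisConfig:
    """Configuration of one full analysis run."""

    input_csv: str | None = None
    generator: GeneratorParams | None = None
    ks: tuple[int, ...] = (K14, K15)
    strategies: tuple[str, ...] = ("censor",)
    bootstrap_B: int = 10_000
    n_sim: int = 10_000
    level: float = 0.95
    seed: int = 0
    out_dir: str = "artdating-report"

    def validate(self) -> None:
        if (self.input_csv is None) == (self.generator is None):
            raise ValueError("exactly one of input_csv or generator must be set")
        if len(set(self.ks)) != len(self.ks) or any(k <= 0 for k in self.ks):
            raise ValueError("k values must be distinct positive integers")
        for s in self.strategies:
            if s not in STRATEGIES:
                raise ValueError(f"unknown strategy {s!r}")
        if self.seed is None:
            raise ValueError("a seed is mandatory: all stochastic steps are seeded")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        gen = raw.pop("generator", None)
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        if gen is not None:
            cfg.generator = default_params(**gen)
        return cfg


@dataclass
class AnalysisReport:
    """Flat result tables of one run; every table round-trips via CSV."""

    exclusions: pd.DataFrame
    proportions: pd.DataFrame
    agreement: pd.DataFrame
    transfer_day_ga: pd.DataFrame
    medians: pd.DataFrame
    median_differences: pd.DataFrame
    strategy_medians: pd.DataFrame
    remaining_duration: pd.DataFrame
    cif_summary: pd.DataFrame
    tables: dict = field(default_factory=dict)

    def _named(self):
        for f in dataclasses.fields(self):
            if f.name == "tables":
                continue
            yield f.name, getattr(self, f.name)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, frame in self._named():
            frame.to_csv(out / f"{name}.csv", index=False)
        curves_dir = out / "curves"
        curves_dir.mkdir(exist_ok=True)
        for name, frame in self.tables.items():
            frame.to_csv(curves_dir / f"{name}.csv", index=False)


def run_analysis(config: AnalysisConfig) -> AnalysisReport:
    config.validate()
    if config.input_csv is not None:
        records = read_registry(config.input_csv)
        log.info("read %d records from %s", len(records), config.input_csv)
    else:
        records = simulate_cohort(config.generator)
        log.info("simulated %d records (seed=%d)", len(records), config.generator.seed)

    cohort, tally = apply_exclusions(records)
    log.info(
        "exclusions: %s; retained %d of %d", dict(tally.counts), tally.n_retained, tally.n_input
    )

    proportions = nonspontaneous_proportions(cohort)

    # dating agreement per k, ART groups only
    has_art = (cohort["conception_mode"] != "spontaneous").any()
    if has_art:
        agree_res = DatingAgreement(cohort, ks=config.ks).fit(
            B=config.bootstrap_B, level=config.level, seed=config.seed
        )
        agreement = agree_res.summary_frame()
        transfer_day = agree_res.transfer_day_ga
    else:
        agreement = pd.DataFrame()
        transfer_day = pd.DataFrame()

    # censoring-aware birth distributions on the ultrasound scale
    duration_res = PregnancyDuration(cohort, strategy="censor").fit(
        n_sim=config.n_sim, level=config.level, seed=config.seed
    )
    medians = duration_res.median_frame()
    median_differences = (
        duration_res.difference_frame() if len(duration_res.medians) > 1 else pd.DataFrame()
    )
    curve_tables = {}
    for group, curve in duration_res.curves.items():
        frame = curve.to_frame()
        frame.insert(0, "group", group)
        frame.insert(1, "scale", "ga_us_birth_days")
        curve_tables[f"km_censor_{group}"] = frame

    # censoring-strategy sensitivity
    strat_rows = []
    for strategy in config.strategies:
        res = PregnancyDuration(cohort, strategy=strategy).fit(
            n_sim=config.n_sim, level=config.level, seed=config.seed
        )
        for group, est in res.medians.items():
            strat_rows.append(
                {
                    "strategy": strategy,
                    "group": group,
                    "median_days": est.median,
                    "ci_lo": est.ci[0],
                    "ci_hi": est.ci[1],
                }
            )
    strategy_medians = pd.DataFrame(strat_rows)

    remaining = (
        remaining_duration_by_culture(
            cohort, n_sim=config.n_sim, level=config.level, seed=config.seed
        )
        if has_art
        else pd.DataFrame()
    )

    # competing risks: pre-eclamptic delivery vs spontaneous onset
    cif_rows = []
    for group, inc in duration_res.competing_risks().items():
        frame = inc.to_frame()
        frame.insert(0, "group", group)
        curve_tables[f"aalen_johansen_{group}"] = frame
        final = frame.iloc[-1]
        row = {"group": group, "n": inc.n_total, "S_overall_final": final["S_overall"]}
        for cause in inc.cif:
            row[f"cif_{cause}_final"] = final[f"cif_{cause}"]
        cif_rows.append(row)
    cif_summary = pd.DataFrame(cif_rows)

    report = AnalysisReport(
        exclusions=tally.to_frame(),
        proportions=proportions,
        agreement=agreement,
        transfer_day_ga=transfer_day,
        medians=medians,
        median_differences=median_differences,
        strategy_medians=strategy_medians,
        remaining_duration=remaining,
        cif_summary=cif_summary,
        tables=curve_tables,
    )
    report.write(config.out_dir)
    _write_manifest(config, report)
    return report


def _write_manifest(config: AnalysisConfig, report: AnalysisReport) -> None:
    cfg = dataclasses.asdict(config)
    if cfg.get("generator") is not None:
        gen = cfg["generator"]
        for key in ("onset_median_days", "onset_spread_days", "censor_target_fraction"):
            gen[key] = dict(gen[key])
        for key in ("culture_day_mix_fresh", "culture_day_mix_frozen"):
            gen[key] = {str(k): v for k, v in gen[key].items()}
    manifest = {
        "artdating_version": __version__,
        "config": cfg,
        "tables": [name for name, _ in report._named()] + sorted(report.tables),
    }
    path = Path(config.out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def simulate_to_csv(params: GeneratorParams, path, include_truth: bool = False) -> pd.DataFrame:
    """Generate a cohort and write it in the registry CSV schema."""
    records = simulate_cohort(params)
    write_registry(records, path, include_truth=include_truth)
    return records
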