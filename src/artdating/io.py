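"""Registry CSV schema: the package's interoperability surface.

One header line, ISO-8601 dates, ``NA`` as the explicit missing token,
one row per singleton live birth.  Generator-truth columns are dropped
on write unless explicitly requested.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import GROUPS, ONSET_TYPES

__all__ = ["REGISTRY_COLUMNS", "TRUTH_COLUMNS", "write_registry", "read_registry", "validate_registry", "RegistryError"]

NA_TOKEN = "NA"

REGISTRY_COLUMNS = (
    "id",
    "conception_mode",
    "lmp_date",
    "fertilization_date",
    "culture_days",
    "transfer_date",
    "birth_date",
    "ga_us_birth_days",
    "onset_type",
    "preeclampsia",
    "plurality",
    "perinatal_death",
    "malformation",
    "maternal_age_years",
    "parity",
    "fetal_sex",
)

#: generator-only columns, absent from analysis input
TRUTH_COLUMNS = ("latent_onset_ga_days", "latent_intervention_ga_days")

_DATE_COLUMNS = ("lmp_date", "fertilization_date", "transfer_date", "birth_date")
_BOOL_COLUMNS = ("preeclampsia", "perinatal_death", "malformation")


class RegistryError(ValueError):
    """Schema violation in a registry CSV, with per-row diagnostics."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        preview = "\n".join(diagnostics[:20])
        more = "" if len(diagnostics) <= 20 else f"\n... and {len(diagnostics) - 20} more"
        super().__init__(f"{len(diagnostics)} registry schema violation(s):\n{preview}{more}")


def write_registry(records: pd.DataFrame, path, include_truth: bool = False) -> None:
    """Write records in the registry CSV schema (ISO dates, NA token)."""
    cols = list(REGISTRY_COLUMNS)
    if include_truth:
        cols += [c for c in TRUTH_COLUMNS if c in records.columns]
    out = records[cols].copy()
    for c in _DATE_COLUMNS:
        out[c] = pd.to_datetime(out[c]).dt.strftime("%Y-%m-%d")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, index=False, na_rep=NA_TOKEN)


def read_registry(path, validate: bool = True) -> pd.DataFrame:
    """Read a registry CSV back into the typed in-memory frame."""
    df = pd.read_csv(
        path,
        na_values=[NA_TOKEN],
        keep_default_na=False,
        dtype={"id": str, "conception_mode": str, "onset_type": str, "fetal_sex": str},
    )
    missing = [c for c in REGISTRY_COLUMNS if c not in df.columns]
    if missing:
        raise RegistryError([f"missing column(s): {', '.join(missing)}"])
    for c in _DATE_COLUMNS:
        df[c] = pd.to_datetime(df[c], format="%Y-%m-%d", errors="coerce")
    for c in _BOOL_COLUMNS:
        df[c] = df[c].map({"True": True, "False": False, True: True, False: False})
    df["culture_days"] = pd.array(
        pd.to_numeric(df["culture_days"], errors="coerce"), dtype="Int64"
    )
    if validate:
        diagnostics = validate_registry(df)
        if diagnostics:
            raise RegistryError(diagnostics)
    return df


def validate_registry(df: pd.DataFrame) -> list[str]:
    """Check schema invariants row by row; returns diagnostics (empty = valid)."""
    diags: list[str] = []

    def flag(mask, message: str) -> None:
        for i in np.flatnonzero(np.asarray(mask, dtype=bool))[:50]:
            diags.append(f"row {i}: {message}")

    flag(~df["conception_mode"].isin(GROUPS), "unknown conception_mode")
    flag(~df["onset_type"].isin(ONSET_TYPES), "unknown onset_type")
    flag(df["birth_date"].isna(), "missing or unparseable birth_date")
    ga = pd.to_numeric(df["ga_us_birth_days"], errors="coerce")
    flag(ga.isna() | (ga < 0), "ga_us_birth_days missing or negative")
    flag(pd.to_numeric(df["plurality"], errors="coerce").fillna(0) < 1, "plurality < 1")
    for c in _BOOL_COLUMNS:
        flag(df[c].isna(), f"{c} is not True/False")

    art = df["conception_mode"].isin(("fresh_et", "frozen_et"))
    order_ok = (df["fertilization_date"] <= df["transfer_date"]) & (
        df["transfer_date"] < df["birth_date"]
    )
    complete = ~(
        df["fertilization_date"].isna() | df["transfer_date"].isna() | df["culture_days"].isna()
    )
    flag(art & complete & ~order_ok.fillna(False), "ART dates out of order")
    fresh = df["conception_mode"] == "fresh_et"
    gap = (df["transfer_date"] - df["fertilization_date"]).dt.days
    bad_gap = fresh & complete & (gap != df["culture_days"].astype("Float64"))
    flag(bad_gap.fillna(False), "fresh ET: transfer - fertilization != culture_days")
    spont = df["conception_mode"] == "spontaneous"
    flag(spont & ~df["culture_days"].isna(), "spontaneous record carries culture_days")
    return diags
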