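"""Well-level viability table I/O, validation, and normalization.

A plate table is a tidy long-format frame: one row per well, carrying the
drug identities, per-drug log10 molar doses (empty = drug absent), the
mixture ratio label, replicate/experiment indices and the raw luminescence
reading. Normalization divides each reading by the maximum luminescence
among untreated wells of the same plate x experiment group, so the
brightest untreated well maps to viability 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = [
    "plate_id",
    "well",
    "drug_a",
    "log_dose_a",
    "drug_b",
    "log_dose_b",
    "drug_c",
    "log_dose_c",
    "ratio_label",
    "technical_rep",
    "experiment",
    "luminescence",
]

DOSE_COLUMNS = ["log_dose_a", "log_dose_b", "log_dose_c"]

DEFAULT_SCOPE = ("plate_id", "experiment")


class SchemaError(ValueError):
    """Input table does not have the required columns."""


class PlateValidationError(ValueError):
    """Input table violates a well-level invariant."""


@dataclass
class PlateTable:
    """Tidy collection of well records, optionally normalized.

    ``df`` always carries :data:`REQUIRED_COLUMNS`; after normalization it
    additionally carries ``viability`` and ``normalization_reference`` maps
    each (plate_id, experiment) group to the untreated reference reading.
    """

    df: pd.DataFrame
    normalized: bool = False
    normalization_reference: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def copy(self) -> "PlateTable":
        return PlateTable(self.df.copy(), self.normalized, dict(self.normalization_reference))


def _validate(df: pd.DataFrame) -> pd.DataFrame:
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing required column: {col!r}")
    df = df.copy()
    for col in DOSE_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["luminescence"] = pd.to_numeric(df["luminescence"], errors="raise")
    df["technical_rep"] = df["technical_rep"].astype(int)
    df["experiment"] = df["experiment"].astype(int)

    neg = df.index[df["luminescence"] < 0]
    if len(neg):
        raise PlateValidationError(f"negative luminescence at row index {neg[0]}")
    dup = df.duplicated(subset=["plate_id", "well"])
    if dup.any():
        row = df.loc[dup, ["plate_id", "well"]].iloc[0]
        raise PlateValidationError(
            f"duplicate (plate_id, well): ({row['plate_id']!r}, {row['well']!r})"
        )
    untreated = df["ratio_label"] == "untreated"
    bad = untreated & df[DOSE_COLUMNS].notna().any(axis=1)
    if bad.any():
        raise PlateValidationError(
            f"untreated record carries a dose at row index {df.index[bad][0]}"
        )
    if (df["technical_rep"] < 1).any() or (df["experiment"] < 1).any():
        raise PlateValidationError("technical_rep and experiment must be >= 1")
    return df


def make_plate_table(df: pd.DataFrame) -> PlateTable:
    """Validate a DataFrame of well records and wrap it as a PlateTable."""
    return PlateTable(_validate(df))


def read_plate_table(path) -> PlateTable:
    """Read and validate a long-format plate CSV.

    Comma-separated UTF-8 with a header row; empty dose cells mean the drug
    is absent. Row order is preserved.
    """
    df = pd.read_csv(path, dtype={"plate_id": str, "well": str})
    for col in ("drug_a", "drug_b", "drug_c", "ratio_label"):
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object).where(df[col].notna(), None)
    return make_plate_table(df)


def write_plate_table(table: PlateTable, path) -> None:
    """Write a PlateTable back to CSV (doses at full float precision)."""
    table.df.to_csv(path, index=False)


def normalize_viability(table: PlateTable, scope=DEFAULT_SCOPE) -> PlateTable:
    """Normalize luminescence to the maximum untreated reading per group.

    Each record's viability is its reading divided by the maximum
    luminescence among untreated wells of its ``scope`` group (default:
    plate_id x experiment). Untreated wells may therefore have viability
    slightly below 1; the brightest one is exactly 1.0. Viability is not
    clipped here — wells brighter than the reference keep values above 1
    (effect conversion clips later where a [0, 1] scale is required).

    Idempotent: normalizing an already-normalized table re-normalizes the
    viability column, whose untreated maximum is 1.0, changing nothing.

    Raises
    ------
    PlateValidationError
        A group has no untreated wells.
    """
    df = table.df.copy()
    values = df["viability"] if table.normalized else df["luminescence"]
    values = values.astype(float)

    viability = np.full(len(df), np.nan)
    reference: dict = {}
    untreated = (df["ratio_label"] == "untreated").to_numpy()
    for key, idx in df.groupby(list(scope)).indices.items():
        mask_unt = untreated[idx]
        if not mask_unt.any():
            raise PlateValidationError(f"no untreated wells in group {key}")
        ref = float(values.iloc[idx[mask_unt]].max())
        if ref <= 0:
            raise PlateValidationError(f"untreated reference is zero in group {key}")
        reference[key] = ref
        viability[idx] = values.iloc[idx] / ref

    out = df
    out["viability"] = viability
    return PlateTable(out, normalized=True, normalization_reference=reference)
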