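"""Patient-record CSV handling.

The record format is a plain CSV whose header names symptoms by their
acronyms (SP, DP, MAP, MDP, BV, PR, Wt, SV, SI, VPE, CI, Y, Yr, AC, FEK,
BLK, ...) plus the reserved attribute columns ``label``, ``age``,
``gender``, ``height_cm``, ``weight_kg``.  Empty cells mean *unknown*
(the symptom is absent from the record, never zero).  Unrecognized
numeric columns are carried through as additional symptom dimensions, so
wider symptom spaces than the bundled table round-trip losslessly.
"""

from __future__ import annotations

import math

import pandas as pd

from .condition_table import PatientRecord
from .errors import ValidationError

__all__ = ["read_records", "write_records", "records_to_frame", "frame_to_records"]

ATTRIBUTE_COLUMNS = ("label", "age", "gender", "height_cm", "weight_kg")


def frame_to_records(df: pd.DataFrame) -> list[PatientRecord]:
    symptom_cols = [c for c in df.columns if c not in ATTRIBUTE_COLUMNS]
    records = []
    for idx, row in df.iterrows():
        values: dict[str, float] = {}
        for col in symptom_cols:
            cell = row[col]
            if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
                continue
            try:
                values[col] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"row {idx}: non-numeric value {cell!r} in symptom column {col!r}"
                ) from exc
        attributes = {}
        for col in ("age", "height_cm", "weight_kg"):
            if col in df.columns and pd.notna(row[col]):
                attributes[col] = float(row[col])
        if "gender" in df.columns and pd.notna(row["gender"]):
            attributes["gender"] = str(row["gender"])
        label = None
        if "label" in df.columns and pd.notna(row["label"]) and str(row["label"]) != "":
            label = str(row["label"])
        records.append(PatientRecord(values=values, attributes=attributes, label=label))
    return records


def records_to_frame(records: list[PatientRecord]) -> pd.DataFrame:
    symptoms = sorted({s for r in records for s in r.values})
    rows = []
    for r in records:
        row: dict = {"label": r.label}
        for col in ("age", "gender", "height_cm", "weight_kg"):
            row[col] = r.attributes.get(col)
        for s in symptoms:
            row[s] = r.values.get(s)
        rows.append(row)
    return pd.DataFrame(rows, columns=["label", "age", "gender", "height_cm", "weight_kg", *symptoms])


def read_records(path) -> list[PatientRecord]:
    """Read a record CSV (``#`` comment lines allowed)."""
    return frame_to_records(pd.read_csv(path, comment="#"))


def write_records(records: list[PatientRecord], path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        records_to_frame(records).to_csv(fh, index=False)
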