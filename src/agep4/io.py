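"""CSV interchange formats, schema validation and run manifests.

All pipeline files are RFC-4180 CSV with a header row. Schemas are
strict: the column set must match exactly and missing values are
errors, except that an empty sire/dam field in ``pedigree.csv`` means
"unknown founder" and founders have no ``true_agep4`` in ``truth.csv``.
Every writing stage can record a JSON run manifest (stage, seed, config
snapshot, SHA-256 of inputs and outputs) so outputs stay traceable.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd

__all__ = ["SCHEMAS", "SchemaError", "read_table", "write_table", "RunManifest"]


class SchemaError(ValueError):
    """A table violates its declared schema."""


#: column name -> (pandas dtype, missing allowed)
SCHEMAS: dict[str, dict[str, tuple[str, bool]]] = {
    "pedigree": {
        "animal_id": ("str", False),
        "sire_id": ("str", True),
        "dam_id": ("str", True),
    },
    "animals": {
        "animal_id": ("str", False),
        "herd_id": ("str", False),
        "jersey_fraction": ("float", False),
        "birth_offset_days": ("int", False),
    },
    "visits": {
        "animal_id": ("str", False),
        "visit_index": ("str", False),
        "age_at_visit": ("int", False),
        "bp4_elevated": ("int", False),
    },
    "truth": {
        "animal_id": ("str", False),
        "breeding_value_a": ("float", False),
        "true_agep4": ("float", True),
    },
    "phenotypes_cat": {
        "animal_id": ("str", False),
        "cat_score": ("int", False),
        "censor_class": ("str", False),
    },
    "phenotypes_agevisit": {
        "animal_id": ("str", False),
        "agevisit_days": ("int", False),
        "censor_class": ("str", False),
    },
    "phenotypes_aug": {
        "animal_id": ("str", False),
        "lower_bound_days": ("int", False),
        "upper_bound_days": ("int", False),
        "censor_class": ("str", False),
    },
    "summaries": {
        "parameter": ("str", False),
        "mean": ("float", False),
        "cri_lower": ("float", False),
        "cri_upper": ("float", False),
    },
    "ebvs": {
        "id": ("str", False),
        "ebv": ("float", False),
    },
}

_PANDAS_DTYPES = {"str": "string", "float": "float64", "int": "int64"}


def _validate(frame: pd.DataFrame, schema_name: str, where: str) -> pd.DataFrame:
    try:
        schema = SCHEMAS[schema_name]
    except KeyError:
        raise KeyError(f"unknown schema {schema_name!r}") from None
    expected = list(schema)
    got = list(frame.columns)
    if sorted(got) != sorted(expected):
        extra = set(got) - set(expected)
        missing = set(expected) - set(got)
        raise SchemaError(
            f"{where}: column mismatch for schema {schema_name!r}"
            + (f"; unexpected {sorted(extra)}" if extra else "")
            + (f"; missing {sorted(missing)}" if missing else "")
        )
    frame = frame[expected].copy()
    for col, (dtype, allow_missing) in schema.items():
        na = frame[col].isna()
        if dtype == "str":
            frame[col] = frame[col].astype("object")
            frame.loc[na, col] = ""
            frame[col] = frame[col].astype(str)
            na = frame[col] == ""
        if not allow_missing and na.any():
            row = int(np.flatnonzero(na.to_numpy())[0])
            raise SchemaError(f"{where}: missing value in column {col!r} at row {row}")
        if dtype in ("int", "float") and not na.all():
            try:
                frame[col] = frame[col].astype(_PANDAS_DTYPES[dtype] if dtype != "int" else "int64")
            except (TypeError, ValueError) as exc:
                raise SchemaError(f"{where}: column {col!r} is not {dtype}: {exc}") from None
    return frame


def read_table(path: str | Path, schema: str) -> pd.DataFrame:
    """Read and validate a pipeline CSV."""
    path = Path(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    frame = raw.replace("", np.nan)
    for col, (dtype, _) in SCHEMAS.get(schema, {}).items():
        if col in frame.columns and dtype in ("int", "float"):
            parsed = pd.to_numeric(frame[col], errors="coerce")
            bad = (raw[col] != "") & parsed.isna()
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise SchemaError(
                    f"{path}: column {col!r} row {row}: {raw[col].iloc[row]!r} is not {dtype}"
                )
            frame[col] = parsed
    return _validate(frame, schema, str(path))


def write_table(frame: pd.DataFrame, path: str | Path, schema: str) -> Path:
    """Validate and write a pipeline CSV (booleans become 0/1)."""
    frame = frame.copy()
    for col in frame.columns:
        if frame[col].dtype == bool:
            frame[col] = frame[col].astype(int)
    frame = _validate(frame, schema, f"write:{path}")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    return path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance record for one pipeline stage."""

    stage: str
    seed: int
    config: Mapping[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    version: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path: str | Path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(asdict(self), indent=2, default=str) + "\n")
        return path
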