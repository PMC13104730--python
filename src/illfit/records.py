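"""Schema and validation for per-individual life-history records.

A records table holds one row per experimental animal: the clone it belongs
to, the nominal food concentration it was reared at, its initial and (if it
survived to first reproduction) final dry mass, age at first reproduction,
and first-clutch size. Animals that died before reproducing carry only the
clone, concentration, initial mass and ``survived = False``; their remaining
fields are empty.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import InvalidInputError, SchemaError

#: Canonical column order of the records CSV.
RECORD_COLUMNS = [
    "clone_id",
    "concentration_mgC_per_L",
    "initial_mass_ug",
    "final_mass_ug",
    "age_first_repro_d",
    "clutch_size",
    "survived",
]

#: Columns that must be empty for non-survivors.
SURVIVOR_ONLY_COLUMNS = ["final_mass_ug", "age_first_repro_d", "clutch_size"]


def validate_records(records: pd.DataFrame) -> list[str]:
    """Check a records table against the schema invariants.

    Returns a list of human-readable violation messages, each prefixed with
    the offending row number (0-based position in the table). An empty list
    means the table is valid.
    """
    violations: list[str] = []
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        return [f"missing required column(s): {', '.join(missing)}"]

    conc = pd.to_numeric(records["concentration_mgC_per_L"], errors="coerce")
    m0 = pd.to_numeric(records["initial_mass_ug"], errors="coerce")
    mt = pd.to_numeric(records["final_mass_ug"], errors="coerce")
    age = pd.to_numeric(records["age_first_repro_d"], errors="coerce")
    clutch = pd.to_numeric(records["clutch_size"], errors="coerce")
    survived = records["survived"].astype(bool)

    for i in range(len(records)):
        row = f"row {i}"
        if not np.isfinite(conc.iloc[i]) or conc.iloc[i] <= 0:
            violations.append(f"{row}: concentration must be positive, got "
                              f"{records['concentration_mgC_per_L'].iloc[i]!r}")
        if not np.isfinite(m0.iloc[i]) or m0.iloc[i] <= 0:
            violations.append(f"{row}: initial mass must be positive, got "
                              f"{records['initial_mass_ug'].iloc[i]!r}")
        if survived.iloc[i]:
            if not np.isfinite(mt.iloc[i]) or mt.iloc[i] <= 0:
                violations.append(f"{row}: survivor must carry a positive final mass")
            if not np.isfinite(age.iloc[i]) or age.iloc[i] < 1:
                violations.append(f"{row}: survivor must carry age_first_repro_d >= 1")
            if not np.isfinite(clutch.iloc[i]) or clutch.iloc[i] < 0:
                violations.append(f"{row}: survivor must carry clutch_size >= 0")
        else:
            for col, val in (("final_mass_ug", mt), ("age_first_repro_d", age),
                             ("clutch_size", clutch)):
                if np.isfinite(val.iloc[i]):
                    violations.append(
                        f"{row}: non-survivor must have empty {col}, got "
                        f"{records[col].iloc[i]!r}")
    return violations


def check_records(records: pd.DataFrame) -> pd.DataFrame:
    """Validate ``records`` and return it with normalized dtypes.

    Raises
    ------
    SchemaError
        Listing every violation with its row number.
    """
    if records is None or len(records) == 0:
        raise InvalidInputError("records table is empty")
    violations = validate_records(records)
    if violations:
        raise SchemaError(violations)
    out = records.copy()
    out["clone_id"] = out["clone_id"].astype(str)
    for col in ["concentration_mgC_per_L", "initial_mass_ug",
                "final_mass_ug", "age_first_repro_d", "clutch_size"]:
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    out["survived"] = out["survived"].astype(bool)
    return out[RECORD_COLUMNS]
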