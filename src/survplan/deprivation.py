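"""European Deprivation Index (EDI) quintiles by departmental distribution.

Each small geographic unit (IRIS) carries an EDI score — higher means more
deprived.  Within every department, units are ranked by score and cut at the
20/40/60/80 percentiles: quintile 1 holds the most affluent units, quintile
5 the most deprived.  The tie rule is min-rank with ceiling cut
(quintile = ceil(5 * rank / n)), so tied scores share the lower quintile.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd

from .model import PatientRecord


@dataclass(frozen=True)
class EDIRecord:
    unit_code: str
    department_code: str
    edi_score: Optional[float]

    def __post_init__(self) -> None:
        if not self.department_code:
            raise ValueError("department_code must be non-empty")


def read_edi_csv(path: Union[str, Path]) -> list[EDIRecord]:
    """Read unit_code,department_code,edi_score rows (blank score = missing)."""
    df = pd.read_csv(path, dtype={"unit_code": str, "department_code": str})
    required = {"unit_code", "department_code", "edi_score"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"EDI file missing columns {sorted(missing)}")
    return [
        EDIRecord(
            unit_code=row.unit_code,
            department_code=row.department_code,
            edi_score=None if pd.isna(row.edi_score) else float(row.edi_score),
        )
        for row in df.itertuples(index=False)
    ]


def assign_quintiles(records: Iterable[EDIRecord]) -> dict[str, Union[int, str]]:
    """Map unit_code -> quintile 1..5 within each department.

    Units with a missing score are assigned ``"unknown"``.  One score per
    unit is required.  Within a department, quintile = ceil(5 * rank / n)
    with min-rank ties, so the mapping is monotone in the score.
    """
    records = list(records)
    seen: set[str] = set()
    for r in records:
        if r.unit_code in seen:
            raise ValueError(f"duplicate unit_code {r.unit_code!r}")
        seen.add(r.unit_code)

    out: dict[str, Union[int, str]] = {}
    by_department: dict[str, list[EDIRecord]] = {}
    for r in records:
        if r.edi_score is None:
            out[r.unit_code] = "unknown"
        else:
            by_department.setdefault(r.department_code, []).append(r)

    for dept_records in by_department.values():
        scores = sorted(r.edi_score for r in dept_records)
        n = len(scores)
        for r in dept_records:
            rank = scores.index(r.edi_score) + 1  # min-rank over ties
            out[r.unit_code] = math.ceil(5 * rank / n)
    return out


def attach_quintile(
    patients: Iterable[PatientRecord],
    quintile_map: dict[str, Union[int, str]],
) -> list[PatientRecord]:
    """Annotate patients with their residence unit's EDI quintile.

    Patients without a residence unit, or whose unit is absent from the map,
    get ``"unknown"``.  Idempotent: re-attachment with the same map yields
    the same records.
    """
    out = []
    for p in patients:
        quintile = quintile_map.get(p.residence_unit, "unknown") if p.residence_unit else "unknown"
        out.append(p.model_copy(update={"edi_quintile": quintile}))
    return out
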