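"""Patient-level records, delimited-text I/O and response summary tables.

Records carry the response endpoints (MPR: <=10% viable tumor in the
resected specimen; pCR: 0% viable tumor, a subset of MPR), the covariates
used in subgroup summaries, and event-free-survival fields.  Booleans may
be missing (None) when an endpoint was not evaluable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields as dc_fields
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .inference import clopper_pearson

__all__ = [
    "PatientRecord",
    "CohortValidationError",
    "read_cohort",
    "write_cohort",
    "response_summary",
    "format_percent",
]

ARMS = ("NivoCT", "IpiNivoCT")
STAGE_GROUPS = ("IB-II", "IIIA")
HISTOLOGIES = ("squamous", "non-squamous")
SMOKING = ("never", "former/current")

_COLUMNS = [
    "id", "arm", "mpr", "pcr", "viable_tumor_pct", "resected", "stage_group",
    "histology", "smoking", "egfr_alk_altered", "efs_months", "efs_event",
    "surgery_months",
]


class CohortValidationError(ValueError):
    """Raised when a record violates the cohort invariants."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject: arm, pathologic response, covariates and survival."""

    id: str
    arm: str
    mpr: bool | None
    pcr: bool | None
    viable_tumor_pct: float | None
    resected: bool
    stage_group: str
    histology: str
    smoking: str
    egfr_alk_altered: bool | None
    efs_months: float
    efs_event: bool
    surgery_months: float | None = None

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise CohortValidationError(f"{self.id}: unknown arm {self.arm!r}")
        if self.stage_group not in STAGE_GROUPS:
            raise CohortValidationError(f"{self.id}: unknown stage_group {self.stage_group!r}")
        if self.histology not in HISTOLOGIES:
            raise CohortValidationError(f"{self.id}: unknown histology {self.histology!r}")
        if self.smoking not in SMOKING:
            raise CohortValidationError(f"{self.id}: unknown smoking {self.smoking!r}")
        if self.efs_months <= 0:
            raise CohortValidationError(f"{self.id}: efs_months must be positive")
        v = self.viable_tumor_pct
        if v is not None and not 0 <= v <= 100:
            raise CohortValidationError(f"{self.id}: viable_tumor_pct outside [0, 100]")
        if self.pcr and not self.mpr:
            raise CohortValidationError(f"{self.id}: pCR implies MPR")
        if self.pcr and v is not None and v != 0:
            raise CohortValidationError(f"{self.id}: pCR implies 0% viable tumor")
        if self.mpr is not None and v is not None and self.mpr != (v <= 10):
            raise CohortValidationError(
                f"{self.id}: MPR flag inconsistent with viable_tumor_pct={v}"
            )


_BOOL_COLS = ("mpr", "pcr", "resected", "egfr_alk_altered", "efs_event")
_FLOAT_COLS = ("viable_tumor_pct", "efs_months", "surgery_months")


def _parse_cell(col: str, value):
    if pd.isna(value) or value == "":
        return None
    if col in _BOOL_COLS:
        if isinstance(value, (bool, np.bool_)):
            return bool(value)
        s = str(value).strip().lower()
        if s in ("true", "1", "yes"):
            return True
        if s in ("false", "0", "no"):
            return False
        raise CohortValidationError(f"cannot parse boolean {value!r} in column {col}")
    if col in _FLOAT_COLS:
        return float(value)
    return str(value)


def read_cohort(path) -> list[PatientRecord]:
    """Read a delimited cohort file (comma or tab, sniffed from the header).

    Missing values are empty cells or ``NA``.  Unknown columns produce a
    warning and are ignored; invariant violations raise with the offending
    row number.
    """
    df = pd.read_csv(path, sep=None, engine="python", na_values=["NA"], dtype=object)
    unknown = [c for c in df.columns if c not in _COLUMNS]
    if unknown:
        warnings.warn(f"ignoring unknown columns: {unknown}", stacklevel=2)
    missing = [c for c in _COLUMNS if c not in df.columns and c != "surgery_months"]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    records = []
    for i, row in df.iterrows():
        kwargs = {
            c: _parse_cell(c, row[c]) if c in df.columns else None for c in _COLUMNS
        }
        try:
            records.append(PatientRecord(**kwargs))
        except (CohortValidationError, TypeError) as exc:
            raise CohortValidationError(f"row {i + 2}: {exc}") from exc
    return records


def write_cohort(records: Iterable[PatientRecord], path, sep: str = ",") -> None:
    """Write records as delimited text; missing values become empty cells.
    ``write_cohort`` followed by ``read_cohort`` is the identity."""
    rows = [{f.name: getattr(r, f.name) for f in dc_fields(PatientRecord)} for r in records]
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, sep=sep, index=False)


def format_percent(fraction: float, decimals: int = 1) -> str:
    """Render a probability as a percent string, round-half-away-from-zero."""
    q = Decimal(1).scaleb(-decimals) if decimals else Decimal(1)
    return str(Decimal(fraction * 100).quantize(q, rounding=ROUND_HALF_UP))


def _rate_block(count: int, n: int, level: float) -> dict:
    if n == 0:
        return {"count": 0, "n": 0, "rate": None, "percent": "not evaluable", "ci": None}
    return {
        "count": count,
        "n": n,
        "rate": count / n,
        "percent": format_percent(count / n),
        "ci": clopper_pearson(count, n, level),
    }


def response_summary(
    records: Sequence[PatientRecord],
    exclude_egfr_alk: bool = False,
    level: float = 0.95,
) -> dict:
    """MPR/pCR rates with exact binomial CIs and the viable-tumor median.

    With ``exclude_egfr_alk`` the denominator drops patients with known
    EGFR mutations or ALK rearrangements (missing profiling keeps a
    patient in).  The viable-tumor median and range are computed over
    resected patients with a recorded percentage; when none is recorded
    the entry is marked not evaluable rather than NaN.
    """
    pop = [r for r in records if not (exclude_egfr_alk and r.egfr_alk_altered)]
    n = len(pop)
    mpr = sum(1 for r in pop if r.mpr)
    pcr = sum(1 for r in pop if r.pcr)
    viable = [
        r.viable_tumor_pct for r in pop if r.resected and r.viable_tumor_pct is not None
    ]
    if viable:
        vt = {
            "median": float(np.median(viable)),
            "range": (min(viable), max(viable)),
            "n": len(viable),
        }
    else:
        vt = "not evaluable"
    return {
        "n": n,
        "mpr": _rate_block(mpr, n, level),
        "pcr": _rate_block(pcr, n, level),
        "viable_tumor": vt,
    }
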