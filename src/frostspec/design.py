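"""Experimental design: cultivars, low-temperature treatments, sample records.

The study design crosses two tea cultivars with six temperature/duration
treatments (a control at 25 °C, chilling at 4 °C and freezing at −4 °C, each
held for 8 or 12 h) and samples a fixed number of plants per cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: Six measured physiological components, in canonical order.
COMPONENTS = ("SPAD", "SS", "MDA", "CAT", "POD", "SOD")

#: Alias X1..X6 used in index equations.
COMPONENT_ALIASES = {f"X{i + 1}": name for i, name in enumerate(COMPONENTS)}


@dataclass(frozen=True)
class Treatment:
    """One low-temperature treatment: a label plus (temperature, duration)."""

    label: str
    temperature_c: float
    duration_h: float


#: Canonical treatment table, in severity order within each temperature level.
TREATMENTS: tuple[Treatment, ...] = (
    Treatment("CK8", 25.0, 8.0),
    Treatment("CK12", 25.0, 12.0),
    Treatment("C8", 4.0, 8.0),
    Treatment("C12", 4.0, 12.0),
    Treatment("F8", -4.0, 8.0),
    Treatment("F12", -4.0, 12.0),
)

TREATMENT_BY_LABEL = {t.label: t for t in TREATMENTS}

#: Stress-severity ordering used by trend checks: longer exposure and lower
#: temperature are more severe.
SEVERITY_ORDER = ("CK8", "CK12", "C8", "C12", "F8", "F12")

CULTIVARS = ("ZC108", "LJ43")


class DesignError(ValueError):
    """Raised for invalid design specifications."""


@dataclass
class SampleRecord:
    """One leaf sample: identity, treatment and (once simulated) biochemistry."""

    sample_id: str
    cultivar: str
    treatment: Treatment
    biochem: np.ndarray | None = None  # 6-vector, order of COMPONENTS
    ltri: float | None = None

    def copy(self) -> "SampleRecord":
        biochem = None if self.biochem is None else self.biochem.copy()
        return replace(self, biochem=biochem)


def generate_design(
    n_plants_per_cell: int,
    cultivars: Sequence[str] = CULTIVARS,
    treatments: Sequence[Treatment] = TREATMENTS,
) -> list[SampleRecord]:
    """Enumerate sample stubs for a full cultivar × treatment × plant design.

    Ordering is deterministic: cultivar-major, then treatments in the given
    (canonical) order, then plant number.
    """
    if n_plants_per_cell < 1:
        raise DesignError("n_plants_per_cell must be >= 1")
    if not cultivars:
        raise DesignError("cultivar list is empty")
    if not treatments:
        raise DesignError("treatment list is empty")
    records = []
    for cultivar in cultivars:
        for trt in treatments:
            for plant in range(1, n_plants_per_cell + 1):
                records.append(
                    SampleRecord(
                        sample_id=f"{cultivar}-{trt.label}-{plant:02d}",
                        cultivar=cultivar,
                        treatment=trt,
                    )
                )
    return records


def records_to_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Tabulate records as a DataFrame (sample_id, cultivar, treatment, X1..X6[, LTRI])."""
    rows = []
    for rec in records:
        row: dict = {
            "sample_id": rec.sample_id,
            "cultivar": rec.cultivar,
            "treatment": rec.treatment.label,
        }
        if rec.biochem is not None:
            for name, value in zip(COMPONENTS, rec.biochem):
                row[name] = float(value)
        if rec.ltri is not None:
            row["LTRI"] = float(rec.ltri)
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[SampleRecord]:
    """Inverse of :func:`records_to_frame`."""
    records = []
    has_biochem = all(c in frame.columns for c in COMPONENTS)
    for _, row in frame.iterrows():
        label = str(row["treatment"])
        if label not in TREATMENT_BY_LABEL:
            raise DesignError(f"unknown treatment label: {label!r}")
        rec = SampleRecord(
            sample_id=str(row["sample_id"]),
            cultivar=str(row["cultivar"]),
            treatment=TREATMENT_BY_LABEL[label],
        )
        if has_biochem:
            rec.biochem = np.array([float(row[c]) for c in COMPONENTS])
        if "LTRI" in frame.columns and not pd.isna(row.get("LTRI", np.nan)):
            rec.ltri = float(row["LTRI"])
        records.append(rec)
    return records
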