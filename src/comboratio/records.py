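"""Shared observation containers.

A :class:`ConcentrationRecord` is one pharmacokinetic/pharmacodynamic
observation: the sampling time, the plasma concentration of each measured
component (mg/L), and the binary whole-animal response (1 = effective,
i.e. no convulsive reaction in the MES assay).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd


@dataclass(frozen=True)
class ConcentrationRecord:
    """One time-stamped multi-component observation with a binary response."""

    time: float
    concentrations: Mapping[str, float]
    effective: int
    group: str | None = None

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if self.effective not in (0, 1):
            raise ValueError(f"effective must be 0 or 1, got {self.effective}")
        for label, c in self.concentrations.items():
            if c < 0:
                raise ValueError(f"negative concentration for {label!r}: {c}")


def records_to_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    """Flatten records into the tabular schema time_h, conc_<label>, effective."""
    if not records:
        return pd.DataFrame(columns=["time_h", "effective"])
    labels = list(records[0].concentrations)
    rows = []
    for r in records:
        row = {"time_h": r.time}
        for lab in labels:
            row[f"conc_{lab}"] = r.concentrations[lab]
        row["effective"] = r.effective
        if r.group is not None:
            row["group"] = r.group
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_records(frame: pd.DataFrame) -> list[ConcentrationRecord]:
    """Inverse of :func:`records_to_frame`."""
    labels = [c[len("conc_"):] for c in frame.columns if c.startswith("conc_")]
    out = []
    for _, row in frame.iterrows():
        out.append(
            ConcentrationRecord(
                time=float(row["time_h"]),
                concentrations={lab: float(row[f"conc_{lab}"]) for lab in labels},
                effective=int(row["effective"]),
                group=str(row["group"]) if "group" in frame.columns else None,
            )
        )
    return out
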