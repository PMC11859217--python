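"""Chou-Talalay Combination Index and median-effect machinery.

The median-effect equation links dose D and fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m,

with Dm the dose producing 50% effect and m the sigmoidicity.  Its
linearization, logit(fa) = m log D - m log Dm, is fitted by least squares
to monotherapy data; inverting it yields the equipotent monotherapy dose
for any effect level.  The Combination Index for a combination producing
effect fa is then

    CI = sum_drug (D_drug)combo / (D_drug)alone(fa),

with CI < 1 synergy, CI = 1 additivity, CI > 1 antagonism.  The summation
generalizes to three or more drugs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MedianEffectFit",
    "CIRecord",
    "SynergyError",
    "fit_median_effect",
    "predicted_fraction",
    "equipotent_dose",
    "combination_index",
    "classify_interaction",
    "ci_time_series",
    "read_monotherapy_csv",
    "write_ci_table",
]

#: logit-transform clipping bounds for observed fractions
CLIP_BOUNDS = (0.01, 0.99)

#: half-width of the additive band around CI = 1
ADDITIVE_TOLERANCE = 1e-6


class SynergyError(ValueError):
    """Raised on invalid synergy-analysis input."""


@dataclass(frozen=True)
class MedianEffectFit:
    """Median-effect parameters (Dm, m) for one drug."""

    Dm: float
    m: float
    drug: str = ""

    def __post_init__(self) -> None:
        if self.Dm <= 0:
            raise ValueError(f"Dm must be positive, got {self.Dm}")
        if self.m <= 0:
            raise ValueError(f"m must be positive, got {self.m}")


@dataclass(frozen=True)
class CIRecord:
    """Combination Index at one time point with its interaction class."""

    time: float
    ci: float
    interaction: str
    component_doses: Mapping[str, float]


def _clip_fraction(fa: "float | np.ndarray") -> "np.ndarray":
    arr = np.asarray(fa, dtype=float)
    lo, hi = CLIP_BOUNDS
    if np.any((arr < lo) | (arr > hi)):
        warnings.warn(
            f"fractions outside [{lo}, {hi}] clipped before the logit transform",
            RuntimeWarning,
        )
    return np.clip(arr, lo, hi)


def fit_median_effect(
    doses: Sequence[float],
    fractions_affected: Sequence[float],
    drug: str = "",
) -> MedianEffectFit:
    """Least-squares fit of the median-effect linearization.

    Fractions are clipped into [0.01, 0.99] before the logit transform so
    that observed extremes (0 or 1) remain usable.
    """
    d = np.asarray(doses, dtype=float)
    if np.any(d <= 0):
        raise SynergyError("doses must be strictly positive")
    if len(np.unique(d)) < 2:
        raise SynergyError("at least 2 distinct doses required")
    fa = _clip_fraction(fractions_affected)
    if len(fa) != len(d):
        raise SynergyError("doses and fractions must have equal length")
    y = np.log(fa / (1.0 - fa))
    x = np.log(d)
    m, intercept = np.polyfit(x, y, 1)
    if m <= 0:
        raise SynergyError(
            f"median-effect slope is non-positive (m={m:.4g}); "
            "effect does not increase with dose"
        )
    dm = float(np.exp(-intercept / m))
    return MedianEffectFit(Dm=dm, m=float(m), drug=drug)


def predicted_fraction(fit: MedianEffectFit, dose: "float | np.ndarray") -> "float | np.ndarray":
    """Forward median-effect prediction fa(D) = (D/Dm)^m / (1 + (D/Dm)^m)."""
    ratio = (np.asarray(dose, dtype=float) / fit.Dm) ** fit.m
    out = ratio / (1.0 + ratio)
    return float(out) if np.ndim(dose) == 0 else out


def equipotent_dose(fit: MedianEffectFit, effect: float) -> float:
    """Monotherapy dose producing the given effect: Dm (fa/(1-fa))^(1/m)."""
    fa = float(_clip_fraction(effect))
    if not (0.0 < fa < 1.0):
        raise SynergyError(f"effect must be in (0, 1), got {effect}")
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    combo_doses: Mapping[str, float],
    alone_doses: Mapping[str, float],
) -> float:
    """CI = sum over drugs of combination dose / equipotent monotherapy dose."""
    if set(combo_doses) != set(alone_doses):
        raise SynergyError(
            f"drug sets differ: {sorted(combo_doses)} vs {sorted(alone_doses)}"
        )
    ci = 0.0
    for drug, combo in combo_doses.items():
        alone = alone_doses[drug]
        if alone <= 0:
            raise SynergyError(f"alone dose for {drug!r} must be positive")
        if combo < 0:
            raise SynergyError(f"combo dose for {drug!r} must be nonnegative")
        ci += combo / alone
    return ci


def classify_interaction(ci: float, tolerance: float = ADDITIVE_TOLERANCE) -> str:
    """Map a CI value to synergy / additive / antagonism."""
    if ci < 0:
        raise SynergyError(f"CI must be nonnegative, got {ci}")
    if ci < 1.0 - tolerance:
        return "synergy"
    if ci > 1.0 + tolerance:
        return "antagonism"
    return "additive"


def ci_time_series(
    combo_profile: pd.DataFrame,
    mono_fits: Mapping[str, MedianEffectFit],
) -> list[CIRecord]:
    """Per-time-point CI records for a combination profile.

    ``combo_profile`` columns: ``time_h``, one dose/concentration column per
    drug (named by the drug label), and ``effect`` (inhibition rate as a
    fraction).  At each time point the equipotent monotherapy dose is the
    median-effect inversion of each drug's fit at the observed combination
    effect.
    """
    drugs = [c for c in combo_profile.columns if c not in ("time_h", "effect")]
    for drug in drugs:
        if drug not in mono_fits:
            raise SynergyError(f"missing monotherapy fit for drug {drug!r}")
    out: list[CIRecord] = []
    for _, row in combo_profile.iterrows():
        effect = float(row["effect"])
        combo = {drug: float(row[drug]) for drug in drugs}
        alone = {drug: equipotent_dose(mono_fits[drug], effect) for drug in drugs}
        ci = combination_index(combo, alone)
        out.append(
            CIRecord(
                time=float(row["time_h"]),
                ci=ci,
                interaction=classify_interaction(ci),
                component_doses=combo,
            )
        )
    return out


def read_monotherapy_csv(path: "str | Path") -> pd.DataFrame:
    """Read monotherapy data: dose (or time_h + dose) and effect_fraction."""
    df = pd.read_csv(path)
    if "effect_fraction" not in df.columns:
        raise SynergyError("monotherapy CSV requires an effect_fraction column")
    return df


def write_ci_table(records: Sequence[CIRecord], path: "str | Path") -> pd.DataFrame:
    """Write a CI-vs-time table mirroring the published table layout."""
    rows = []
    for rec in records:
        row = {"time_h": rec.time}
        row.update({f"dose_{k}": v for k, v in rec.component_doses.items()})
        row["combination_index"] = rec.ci
        row["interaction"] = rec.interaction
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df
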