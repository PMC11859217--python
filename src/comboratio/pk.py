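"""Single-compartment extravascular pharmacokinetics.

The model: after an extravascular dose, the plasma concentration of a
component follows the biexponential

    C(t) = Kc * (exp(-ke * t) - exp(-ka * t)),

where ``ka`` (1/h) is the absorption rate constant, ``ke`` (1/h) the
elimination rate constant, and ``Kc`` (mg/L) the lumped scale
``ka * F * Y0 / (Vd * (ka - ke))`` absorbing dose ``Y0``, bioavailability
``F``, and distribution volume ``Vd``.  With ``ka > ke`` the curve is
nonnegative, zero at ``t = 0``, and peaks at ``t = ln(ka/ke)/(ka - ke)``.

For two components i and j, eliminating ``Kc`` for the dose gives the
in-vivo drug-quantity ratio

    Q_i : Q_j = Kc_i (ka_i - ke_i) ka_j / (Kc_j (ka_j - ke_j) ka_i)

(assuming common ``Vd`` and ``F``), which bridges fitted plasma profiles to
administered-dose ratios: if the quantity ratio moves from q_old to q_new,
the administered-dose ratio scales by the same factor.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PKFit",
    "ProfilePoint",
    "RatioResult",
    "FitOptions",
    "PKError",
    "DegenerateDataError",
    "ConvergenceError",
    "predict_concentration",
    "fit_profile",
    "quantity_ratio",
    "dose_ratio_update",
    "goodness_of_fit",
    "read_profile_csv",
    "write_fit_json",
]

#: relative |ka - ke| below which the biexponential is evaluated by its
#: analytic limiting form (numerical continuity at the degenerate point)
DEGENERACY_RTOL = 1e-8


class PKError(ValueError):
    """Base class for pharmacokinetic model errors."""


class DegenerateDataError(PKError):
    """Raised when the data cannot identify the model (e.g. all-zero)."""


class ConvergenceError(PKError):
    """Raised when the fitter fails to converge; carries the best candidate."""

    def __init__(self, message: str, best: "PKFit | None" = None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class PKFit:
    """Fitted single-compartment parameters for one component."""

    component: str
    Kc: float  # mg/L
    ka: float  # 1/h
    ke: float  # 1/h
    r_squared: float = float("nan")
    Vd: float = 1.0  # L
    FBA: float = 1.0  # bioavailability fraction
    Y0: float | None = None  # administered dose
    flip_flop_warning: bool = False

    def __post_init__(self) -> None:
        if self.Kc < 0:
            raise ValueError(f"Kc must be nonnegative, got {self.Kc}")
        if self.ka <= 0 or self.ke <= 0:
            raise ValueError(f"rate constants must be positive (ka={self.ka}, ke={self.ke})")
        if not (0 < self.FBA <= 1):
            raise ValueError(f"FBA must be in (0, 1], got {self.FBA}")
        if self.Vd <= 0:
            raise ValueError(f"Vd must be positive, got {self.Vd}")
        if not math.isnan(self.r_squared) and self.r_squared > 1:
            raise ValueError(f"r_squared cannot exceed 1, got {self.r_squared}")

    @property
    def t_max(self) -> float:
        """Time of peak concentration, ln(ka/ke)/(ka - ke)."""
        if abs(self.ka - self.ke) < DEGENERACY_RTOL * self.ka:
            return 1.0 / self.ka
        return math.log(self.ka / self.ke) / (self.ka - self.ke)


@dataclass(frozen=True)
class ProfilePoint:
    """One point of a mean concentration-time profile."""

    time: float  # h
    concentration: float  # mg/L
    sd: float | None = None  # mg/L
    n: int | None = None  # replicate count

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError(f"time must be nonnegative, got {self.time}")
        if self.concentration < 0:
            raise ValueError(f"concentration must be nonnegative, got {self.concentration}")
        if self.sd is not None and self.sd < 0:
            raise ValueError(f"sd must be nonnegative, got {self.sd}")


@dataclass(frozen=True)
class RatioResult:
    """An in-vivo quantity ratio and the matching administered-dose ratio."""

    quantity_ratio: float
    dose_ratio: float
    component_pair: tuple[str, str]

    def __post_init__(self) -> None:
        if self.quantity_ratio <= 0 or self.dose_ratio <= 0:
            raise ValueError("ratios must be positive")

    def rounded(self, ndigits: int = 2) -> "RatioResult":
        return replace(
            self,
            quantity_ratio=round(self.quantity_ratio, ndigits),
            dose_ratio=round(self.dose_ratio, ndigits),
        )


@dataclass(frozen=True)
class FitOptions:
    weight_by_n: bool = False
    max_restarts: int = 5
    seed: int = 0


def predict_concentration(fit: PKFit, t: "float | np.ndarray") -> "float | np.ndarray":
    """Evaluate C(t) = Kc (e^{-ke t} - e^{-ka t}) at nonnegative times."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise PKError("time must be nonnegative")
    if abs(fit.ka - fit.ke) < DEGENERACY_RTOL * fit.ka:
        # L'Hopital limit of the normalized biexponential at ka == ke
        out = fit.Kc * fit.ka * t_arr * np.exp(-fit.ka * t_arr)
    else:
        out = fit.Kc * (np.exp(-fit.ke * t_arr) - np.exp(-fit.ka * t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _biexp(t: np.ndarray, kc: float, ka: float, ke: float) -> np.ndarray:
    return kc * (np.exp(-ke * t) - np.exp(-ka * t))


def _initial_guess(t: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Curve-stripping start: terminal slope -> ke, ka = 10 ke, Kc from the peak."""
    pos = c > 0
    tt, cc = t[pos], c[pos]
    if len(tt) >= 3:
        slope = np.polyfit(tt[-3:], np.log(cc[-3:]), 1)[0]
        ke0 = max(-slope, 1e-3)
    else:
        ke0 = 0.1
    ka0 = 10.0 * ke0
    tpk = math.log(ka0 / ke0) / (ka0 - ke0)
    unit_peak = math.exp(-ke0 * tpk) - math.exp(-ka0 * tpk)
    kc0 = float(np.max(c)) / unit_peak
    return np.array([kc0, ka0, ke0])


def fit_profile(
    points: Sequence[ProfilePoint],
    options: FitOptions | None = None,
    component: str = "",
) -> PKFit:
    """Nonlinear least-squares fit of the biexponential to a profile.

    The fit minimizes the (optionally replicate-weighted) sum of squared
    residuals.  The biexponential is invariant under exchanging ka and ke
    with a sign flip of Kc; the result is normalized to the conventional
    branch Kc > 0, ka > ke, and ``flip_flop_warning`` is set when the
    optimizer's raw optimum was on the exchanged branch.
    """
    options = options or FitOptions()
    if len(points) < 4:
        raise PKError(f"at least 4 points required to fit 3 parameters, got {len(points)}")
    pts = sorted(points, key=lambda p: p.time)
    t = np.array([p.time for p in pts], dtype=float)
    c = np.array([p.concentration for p in pts], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise PKError("profile times must be strictly increasing (duplicates found)")
    if not np.any(c > 0):
        raise DegenerateDataError("all concentrations are zero; nothing to fit")

    w = np.ones_like(c)
    if options.weight_by_n:
        n = np.array([p.n if p.n is not None else 1 for p in pts], dtype=float)
        w = np.sqrt(n)

    def residuals(p: np.ndarray) -> np.ndarray:
        return w * (_biexp(t, *p) - c)

    x0 = _initial_guess(t, c)
    rng = np.random.default_rng(options.seed)
    lower = np.array([-np.inf, 1e-9, 1e-9])
    upper = np.array([np.inf, np.inf, np.inf])

    best = None
    start = x0
    for _ in range(1 + options.max_restarts):
        try:
            sol = least_squares(residuals, np.clip(start, lower, upper), bounds=(lower, upper))
        except Exception:
            sol = None
        if sol is not None and np.isfinite(sol.cost):
            if best is None or sol.cost < best.cost:
                best = sol
        start = x0 * rng.lognormal(0.0, 0.5, size=3)

    if best is None:
        raise ConvergenceError("all fit attempts failed", best=None)

    kc, ka, ke = best.x
    flip = False
    if kc < 0:
        # exchanged branch: Kc (e^{-ke t} - e^{-ka t}) == -Kc (e^{-ka t} - e^{-ke t})
        kc, ka, ke = -kc, ke, ka
        flip = True
    if ka < ke:
        # relabel fast/slow exponentials; curve for this branch is nonpositive
        ka, ke = ke, ka
        flip = True
        warnings.warn(
            f"fit for {component or 'profile'} landed on the flip-flop branch; "
            "reporting the observationally equivalent ka > ke parameterization",
            RuntimeWarning,
        )
    fit = PKFit(component=component, Kc=float(kc), ka=float(ka), ke=float(ke),
                flip_flop_warning=flip)
    pred = predict_concentration(fit, t)
    r2 = goodness_of_fit(c, np.asarray(pred))
    fit = replace(fit, r_squared=r2)
    if not best.success:
        raise ConvergenceError("fit did not converge within the retry schedule", best=fit)
    return fit


def quantity_ratio(fit_i: PKFit, fit_j: PKFit) -> float:
    """In-vivo drug quantity ratio Q_i : Q_j from two fitted profiles.

    Q_i/Q_j = Kc_i (ka_i - ke_i) ka_j / (Kc_j (ka_j - ke_j) ka_i), valid
    when Vd and bioavailability are common to the two components (or the
    fits carry per-component values, which are then retained).
    """
    for f in (fit_i, fit_j):
        if abs(f.ka - f.ke) < DEGENERACY_RTOL * f.ka:
            raise PKError(f"ka == ke for component {f.component!r}; quantity ratio undefined")
        if f.Kc <= 0:
            raise PKError(f"Kc must be positive for a quantity ratio, got {f.Kc}")
    num = fit_i.Kc * (fit_i.ka - fit_i.ke) * fit_j.ka
    den = fit_j.Kc * (fit_j.ka - fit_j.ke) * fit_i.ka
    # per-component Vd / bioavailability mode (defaults 1 cancel)
    num *= fit_i.Vd / fit_i.FBA
    den *= fit_j.Vd / fit_j.FBA
    return num / den


def dose_ratio_update(old_dose_ratio: float, q_old: float, q_new: float) -> float:
    """Scale an administered-dose ratio by the change in in-vivo quantity ratio."""
    for name, v in (("old_dose_ratio", old_dose_ratio), ("q_old", q_old), ("q_new", q_new)):
        if v <= 0:
            raise PKError(f"{name} must be positive, got {v}")
    return old_dose_ratio * q_new / q_old


def goodness_of_fit(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot about the observed mean."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise PKError("observed and predicted must have equal length >= 2")
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateDataError("observed values are constant; R^2 undefined")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def read_profile_csv(path: "str | Path") -> list[ProfilePoint]:
    """Read a profile CSV with columns time_h, conc_mg_per_L[, sd_mg_per_L, n]."""
    df = pd.read_csv(path)
    pts = []
    for _, row in df.iterrows():
        pts.append(
            ProfilePoint(
                time=float(row["time_h"]),
                concentration=float(row["conc_mg_per_L"]),
                sd=float(row["sd_mg_per_L"]) if "sd_mg_per_L" in df.columns else None,
                n=int(row["n"]) if "n" in df.columns else None,
            )
        )
    return pts


def write_fit_json(fit: PKFit, path: "str | Path") -> None:
    payload = {
        "component": fit.component,
        "Kc": fit.Kc,
        "ka": fit.ka,
        "ke": fit.ke,
        "r_squared": fit.r_squared,
        "flip_flop_warning": fit.flip_flop_warning,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
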