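"""Packaged study tables and a correlation-preserving record generator.

The published concentration/response tables for the two case studies — the
*Cynanchum otophyllum* saponins (M1, M2) with phenobarbital (PHB) in the
mouse maximal-electroshock assay, and the *Erigeron breviscapus*
breviscapine/scutellarin/hispidulin (Bre, Scu, His) stroke model — ship as
CSV fixtures holding, per time point, each component's plasma
concentration mean +/- SD, the effective/total animal counts, and the
printed inhibition rate.

The record generator stands in for the study's deep generative
augmentation: per time point it draws component concentrations from a
Gaussian copula with a configurable target correlation structure and
zero-truncated-normal marginals whose post-truncation moments match the
table's mean +/- SD, then attaches a binary effectiveness.  Three response
couplings are supported: independent Bernoulli at the printed inhibition
rate (default), a logistic link on a linear score of the concentrations
(for classifier learnability studies), and a deterministic threshold on
the same score.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, ndtr

from .records import ConcentrationRecord

__all__ = [
    "TableSpec",
    "GenConfig",
    "FIXTURES",
    "FITTED_PK",
    "REPORTED_QUANTITY_RATIOS",
    "REPORTED_CORRELATIONS",
    "ADMINISTERED_DOSES",
    "load_fixture",
    "load_fitted_params",
    "generate_records",
    "inhibition_rate",
    "format_inhibition_pct",
    "validate_correlations",
    "default_correlations",
]

# ---------------------------------------------------------------------------
# fixtures

#: registry: fixture name -> (csv file, component labels); "tableN" aliases
#: follow the source tables' numbering
FIXTURES: dict[str, tuple[str, tuple[str, ...]]] = {
    "phb_alone": ("phb_alone.csv", ("PHB",)),
    "cynanchum_raw": ("cynanchum_raw.csv", ("M1", "M2", "PHB")),
    "cynanchum_augmented": ("cynanchum_augmented.csv", ("M1", "M2", "PHB")),
    "cynanchum_ci_initial": ("cynanchum_ci_initial.csv", ("M1", "M2", "PHB")),
    "cynanchum_improved": ("cynanchum_improved.csv", ("M1", "M2", "PHB")),
    "cynanchum_ci_improved": ("cynanchum_ci_improved.csv", ("M1", "M2", "PHB")),
    "erigeron_raw": ("erigeron_raw.csv", ("Bre", "Scu", "His")),
    "erigeron_augmented": ("erigeron_augmented.csv", ("Bre", "Scu", "His")),
    "erigeron_ci_initial": ("erigeron_ci_initial.csv", ("Bre", "Scu", "His")),
    "erigeron_improved": ("erigeron_improved.csv", ("Bre", "Scu", "His")),
    "erigeron_ci_improved": ("erigeron_ci_improved.csv", ("Bre", "Scu", "His")),
}

_ALIASES = {
    "table1": "phb_alone",
    "table2": "cynanchum_raw",
    "table3": "cynanchum_augmented",
    "table4": "cynanchum_ci_initial",
    "table5": "cynanchum_improved",
    "table8": "cynanchum_ci_improved",
    "table9": "erigeron_raw",
    "table10": "erigeron_augmented",
    "table11": "erigeron_ci_initial",
    "table12": "erigeron_improved",
    "table13": "erigeron_ci_improved",
}

#: published single-compartment coefficients (Kc, ka, ke) per case study.
#: The post-improvement Scu triple is stored as printed even though its
#: ka < ke is internally inconsistent (negative curve); ratio computations
#: on it report the magnitude and flag the inconsistency.
FITTED_PK: dict[str, dict[str, tuple[float, float, float]]] = {
    "cynanchum_initial": {"M1": (5.186, 11.457, 0.072), "M2": (0.409, 11.398, 0.198)},
    "cynanchum_improved": {"M1": (4.431, 5.172, 0.351), "M2": (0.279, 5.744, 0.201)},
    "erigeron_initial": {"Bre": (116.443, 1.647, 0.221), "Scu": (197.8, 0.903, 0.065)},
    "erigeron_improved": {"Bre": (34.315, 3.064, 0.111), "Scu": (125.667, 0.052, 0.106)},
}

#: published in-vivo quantity ratios (initial, post-improvement)
REPORTED_QUANTITY_RATIOS: dict[str, tuple[float, float]] = {
    "cynanchum": (12.83, 15.39),
    "erigeron": (0.543, 0.334),
}

#: administered doses defining the initial dose ratios (mg/L resp. mg/kg)
ADMINISTERED_DOSES: dict[str, dict[str, float]] = {
    "cynanchum": {"M1": 12.0, "M2": 6.0, "PHB": 2.0},
    "erigeron": {"Bre": 40.0, "Scu": 24.8},
}

#: published Pearson correlations of PHB concentration against the other
#: variables, before and after augmentation (reference constants only; the
#: replicate-level raw data behind them are not published)
REPORTED_CORRELATIONS: dict[str, dict[str, float]] = {
    "original": {"M1": -0.570, "M2": -0.572, "time": 0.643, "response": -0.327},
    "augmented": {"M1": 0.576, "M2": 0.418, "time": -0.473, "response": 0.274},
}


@dataclass(frozen=True)
class TableSpec:
    """One concentration/response table: per-time marginals and counts."""

    name: str
    components: tuple[str, ...]
    rows: pd.DataFrame = field(compare=False)

    def __post_init__(self) -> None:
        r = self.rows
        if "n_total" in r.columns:
            if ((r["n_effective"] < 0) | (r["n_effective"] > r["n_total"])).any():
                raise ValueError("counts must satisfy 0 <= n_effective <= n_total")
        for comp in self.components:
            if (r[f"conc_{comp}_sd"] < 0).any():
                raise ValueError(f"negative SD for component {comp}")

    @property
    def times(self) -> np.ndarray:
        return self.rows["time_h"].to_numpy(dtype=float)

    def means(self, component: str) -> np.ndarray:
        return self.rows[f"conc_{component}_mean"].to_numpy(dtype=float)

    def sds(self, component: str) -> np.ndarray:
        return self.rows[f"conc_{component}_sd"].to_numpy(dtype=float)

    @property
    def inhibition_fractions(self) -> np.ndarray:
        return self.rows["inhibition_pct"].to_numpy(dtype=float) / 100.0

    @property
    def ci_values(self) -> np.ndarray:
        if "combination_index" not in self.rows.columns:
            raise KeyError(f"fixture {self.name!r} carries no CI column")
        return self.rows["combination_index"].to_numpy(dtype=float)


def load_fixture(name: str) -> TableSpec:
    """Load a packaged table by name (or its ``tableN`` alias)."""
    key = _ALIASES.get(name.lower().replace(" ", ""), name)
    if key not in FIXTURES:
        raise KeyError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES) + sorted(_ALIASES)}"
        )
    filename, components = FIXTURES[key]
    with resources.files("comboratio.fixtures").joinpath(filename).open() as fh:
        rows = pd.read_csv(fh)
    return TableSpec(name=key, components=components, rows=rows)


def load_fitted_params(case: str) -> dict[str, tuple[float, float, float]]:
    """Published (Kc, ka, ke) triples for a case study stage."""
    if case not in FITTED_PK:
        raise KeyError(f"unknown parameter set {case!r}; available: {sorted(FITTED_PK)}")
    return dict(FITTED_PK[case])


# ---------------------------------------------------------------------------
# generator

ResponseMode = Literal["independent", "logistic", "threshold"]


@dataclass(frozen=True)
class GenConfig:
    """Generator settings.

    ``records_per_timepoint`` defaults to 99 so that an 8-time-point table
    expands to 792 records, the augmented-study scale.  ``target_correlations``
    may be a component-correlation matrix (aligned with the table's component
    order) or None for the built-in defaults.  ``logistic_scale`` is the
    steepness (per pooled SD) of the linear score in the coupled response
    modes.
    """

    records_per_timepoint: int = 99
    seed: int = 0
    target_correlations: np.ndarray | None = None
    response_mode: ResponseMode = "independent"
    logistic_weights: tuple[float, ...] | None = None
    logistic_scale: float = 8.0

    def __post_init__(self) -> None:
        if self.records_per_timepoint <= 0:
            raise ValueError("records_per_timepoint must be positive")


#: default pairwise correlation magnitudes, following the reported
#: augmented-data values where a pair was published
_DEFAULT_PAIR_R = {
    frozenset(("PHB", "M1")): 0.576,
    frozenset(("PHB", "M2")): 0.418,
}
_DEFAULT_R = 0.5


def default_correlations(components: Sequence[str]) -> np.ndarray:
    """Build the default target component-correlation matrix."""
    k = len(components)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            val = _DEFAULT_PAIR_R.get(frozenset((components[i], components[j])), _DEFAULT_R)
            r[i, j] = r[j, i] = val
    return r


def _repair_psd(r: np.ndarray) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix to the nearest PSD correlation."""
    vals, vecs = np.linalg.eigh((r + r.T) / 2)
    if vals.min() >= 1e-10:
        return r
    vals = np.clip(vals, 1e-10, None)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


#: post-truncation SD/mean above this is treated as unattainable for a
#: zero-truncated normal (the supremum as mu -> -inf is 1); beyond it the
#: solver matches the mean exactly and takes the nearest attainable SD
_FEASIBLE_CV = 0.99


def _truncated_moments_std(a: float) -> tuple[float, float]:
    """Mean and SD of a standard normal truncated to Z > a."""
    from scipy.special import erfcx

    lam = math.sqrt(2.0 / math.pi) / erfcx(a / math.sqrt(2.0))  # phi(a)/(1-Phi(a))
    mean = lam - a  # of (Z - a), shifted so the truncation point sits at 0
    var = 1.0 + a * lam - lam * lam
    return mean, math.sqrt(max(var, 0.0))


def _truncnorm_underlying(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (mu, sigma) of a zero-truncated normal whose
    post-truncation mean and SD match the targets.

    The coefficient of variation of a zero-truncated normal depends only on
    the standardized truncation point a = -mu/sigma and is monotone in it,
    so a is found by bisection and (mu, sigma) follow in closed form; the
    mean is always matched exactly.
    """
    if sd == 0 or mean == 0:
        return mean, 0.0
    if mean / sd >= 6:  # truncation mass negligible
        return mean, sd
    cv = sd / mean
    if cv > _FEASIBLE_CV:
        warnings.warn(
            f"target SD/mean {cv:.2f} exceeds the zero-truncated-normal bound; "
            "matching the mean and the nearest attainable SD",
            RuntimeWarning,
        )
        cv = _FEASIBLE_CV

    def cv_at(a: float) -> float:
        m, s = _truncated_moments_std(a)
        return s / m  # post-truncation SD/mean of mu + sigma*Z_trunc

    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cv_at(mid) < cv:
            lo = mid
        else:
            hi = mid
    a = 0.5 * (lo + hi)
    m_std, s_std = _truncated_moments_std(a)
    sigma = mean / m_std
    mu = -a * sigma
    return mu, sigma


def _sample_timepoint(
    spec: TableSpec,
    row_idx: int,
    n: int,
    corr: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw n copula samples of the component concentrations at one time."""
    comps = spec.components
    k = len(comps)
    chol = np.linalg.cholesky(_repair_psd(corr) + 1e-12 * np.eye(k))
    # antithetic pairs (z, -z): same copula, sharply reduced moment error
    half = rng.standard_normal(size=((n + 1) // 2, k))
    z = np.vstack([half, -half])[:n] @ chol.T
    u = ndtr(z)
    out = np.empty((n, k))
    for j, comp in enumerate(comps):
        mean = float(spec.means(comp)[row_idx])
        sd = float(spec.sds(comp)[row_idx])
        if sd == 0 or mean == 0:
            out[:, j] = mean
            continue
        mu, sigma = _truncnorm_underlying(mean, sd)
        a = -mu / sigma
        # guard the extreme quantiles against ppf overflow
        uu = np.clip(u[:, j], 1e-12, 1 - 1e-12)
        out[:, j] = stats.truncnorm.ppf(uu, a, np.inf, loc=mu, scale=sigma)
    return out


def generate_records(spec: TableSpec, config: GenConfig | None = None) -> list[ConcentrationRecord]:
    """Generate synthetic records emulating a table's marginal structure.

    Concentrations: Gaussian copula with the target correlation matrix and
    zero-truncated-normal marginals moment-matched to each time point's
    mean +/- SD.  Effectiveness: Bernoulli at the printed inhibition rate
    (``independent``), or coupled to a linear score of the standardized
    concentrations through a logistic link or a hard threshold, with a
    single global intercept calibrated so the overall effective fraction
    matches the table's pooled inhibition rate.
    """
    config = config or GenConfig()
    rng = np.random.default_rng(config.seed)
    comps = spec.components
    corr = (np.asarray(config.target_correlations, dtype=float)
            if config.target_correlations is not None
            else default_correlations(comps))
    if corr.shape != (len(comps), len(comps)):
        raise ValueError(f"correlation matrix must be {len(comps)}x{len(comps)}")
    if not np.allclose(corr, corr.T) or not np.allclose(np.diag(corr), 1.0):
        raise ValueError("correlation matrix must be symmetric with unit diagonal")

    n = config.records_per_timepoint
    times = spec.times
    rates = spec.inhibition_fractions
    conc_blocks = [
        _sample_timepoint(spec, i, n, corr, rng) for i in range(len(times))
    ]

    if config.response_mode == "independent":
        eff_blocks = [rng.uniform(size=n) < rates[i] for i in range(len(times))]
    else:
        weights = (np.asarray(config.logistic_weights, dtype=float)
                   if config.logistic_weights is not None
                   else np.ones(len(comps)))
        all_conc = np.vstack(conc_blocks)
        mu = all_conc.mean(axis=0)
        sd = all_conc.std(axis=0)
        sd[sd == 0] = 1.0
        score = ((all_conc - mu) / sd) @ weights
        score *= config.logistic_scale / max(np.linalg.norm(weights), 1e-12)
        overall = float(np.average(rates))

        def mean_prob(b0: float) -> float:
            return float(np.mean(expit(score + b0)))

        lo_b, hi_b = -50.0, 50.0
        for _ in range(200):
            mid = 0.5 * (lo_b + hi_b)
            if mean_prob(mid) < overall:
                lo_b = mid
            else:
                hi_b = mid
        b0 = 0.5 * (lo_b + hi_b)
        if config.response_mode == "logistic":
            eff_all = rng.uniform(size=len(score)) < expit(score + b0)
        else:  # deterministic threshold at the calibrated quantile
            cut = np.quantile(score, 1.0 - overall)
            eff_all = score >= cut
        eff_blocks = np.split(eff_all, len(times))

    records: list[ConcentrationRecord] = []
    for i, t in enumerate(times):
        for row, eff in zip(conc_blocks[i], eff_blocks[i]):
            records.append(
                ConcentrationRecord(
                    time=float(t),
                    concentrations=dict(zip(comps, (float(v) for v in row))),
                    effective=int(eff),
                    group=spec.name,
                )
            )
    return records


# ---------------------------------------------------------------------------
# summaries and validation

def inhibition_rate(n_effective: int, n_total: int) -> float:
    """Inhibition rate in percent (full precision; round for table style)."""
    if n_total <= 0:
        raise ValueError(f"n_total must be positive, got {n_total}")
    if not (0 <= n_effective <= n_total):
        raise ValueError("require 0 <= n_effective <= n_total")
    return 100.0 * n_effective / n_total


def format_inhibition_pct(n_effective: int, n_total: int) -> int:
    """Table-style integer percent."""
    return round(inhibition_rate(n_effective, n_total))


def _records_frame(records: Sequence[ConcentrationRecord]) -> pd.DataFrame:
    labels = list(records[0].concentrations)
    data = {lab: [r.concentrations[lab] for r in records] for lab in labels}
    data["time"] = [r.time for r in records]
    data["response"] = [r.effective for r in records]
    return pd.DataFrame(data)


def validate_correlations(
    reference: "Sequence[ConcentrationRecord] | np.ndarray",
    generated: Sequence[ConcentrationRecord],
    flag_threshold: float = 0.1,
) -> pd.DataFrame:
    """Pairwise Pearson r (+ two-tailed p) of generated records vs a reference.

    ``reference`` is either a reference record set (its empirical pooled
    correlations are used) or a target component-correlation matrix.  When
    validating against a matrix, component-pair correlations are computed
    within each time point and averaged, matching the copula target's
    estimand (pooled correlations are additionally inflated by the shared
    time trend of the means).  The report flags pairs whose |delta r|
    exceeds ``flag_threshold`` and marks pairs involving a constant column
    as undefined.
    """
    if len(generated) < 3:
        raise ValueError("need at least 3 generated records")
    gen = _records_frame(generated)
    cols = list(gen.columns)

    ref_r: dict[tuple[str, str], float] = {}
    within_timepoint = isinstance(reference, np.ndarray)
    if within_timepoint:
        comp_cols = [c for c in cols if c not in ("time", "response")]
        if reference.shape != (len(comp_cols), len(comp_cols)):
            raise ValueError("reference matrix shape does not match component count")
        for i, a in enumerate(comp_cols):
            for j, b in enumerate(comp_cols):
                ref_r[(a, b)] = float(reference[i, j])
    else:
        if len(reference) < 3:
            raise ValueError("need at least 3 reference records")
        ref = _records_frame(list(reference))
        for a in cols:
            for b in cols:
                if a in ref.columns and b in ref.columns:
                    if ref[a].std() == 0 or ref[b].std() == 0:
                        continue
                    ref_r[(a, b)] = float(ref[a].corr(ref[b]))

    def pair_r(a: str, b: str) -> tuple[float, float]:
        if within_timepoint and (a, b) in ref_r:
            # within-time-point mean correlation, Fisher-z p approximation
            parts, weights = [], []
            for _, grp in gen.groupby("time"):
                if len(grp) >= 3 and grp[a].std() > 0 and grp[b].std() > 0:
                    parts.append(float(grp[a].corr(grp[b])))
                    weights.append(len(grp))
            if not parts:
                return float("nan"), float("nan")
            r = float(np.average(parts, weights=weights))
            n_eff = sum(weights)
            z = np.arctanh(np.clip(r, -0.999999, 0.999999)) * math.sqrt(max(n_eff - 3, 1))
            p = float(2 * stats.norm.sf(abs(z)))
            return r, p
        r, p = stats.pearsonr(gen[a], gen[b])
        return float(r), float(p)

    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            if gen[a].std() == 0 or gen[b].std() == 0:
                rows.append({"var_a": a, "var_b": b, "r_generated": np.nan,
                             "p_value": np.nan, "r_reference": ref_r.get((a, b), np.nan),
                             "delta_r": np.nan, "flag": "undefined"})
                continue
            r, p = pair_r(a, b)
            rr = ref_r.get((a, b), np.nan)
            delta = abs(r - rr) if np.isfinite(rr) else np.nan
            flag = "ok"
            if np.isfinite(delta) and delta > flag_threshold:
                flag = "deviates"
            rows.append({"var_a": a, "var_b": b, "r_generated": float(r),
                         "p_value": float(p), "r_reference": rr,
                         "delta_r": delta, "flag": flag})
    return pd.DataFrame(rows)
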