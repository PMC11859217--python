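"""End-to-end orchestration: PK ratios, CI series, classifier, adjustment.

The workflow mirrors the study design:

1. **Initial stage** — fit (or inject) the single-compartment profiles of
   the two ratio-pair components, derive the in-vivo quantity ratio and
   the initial administered-dose ratio, compute the Combination Index
   series over the time course, and train the dose-effect classifier on
   generated records.
2. **Improvement stage** — raise the DET-classified effective fraction by
   ``delta_effect`` via per-component concentration factors, refit the PK
   profiles on the adjusted per-time means, recompute the quantity ratio,
   map it to the updated dose ratio (new = old * q_new/q_old, an exact
   identity in the report), and recompute the CI series.
3. **Comparison** — per-time-point CI change with a decrease flag.

Reports are plain dataclasses serializable to JSON; file outputs
(fits.json, ci_before/after.csv, adjusted_records.csv, report.json and a
CI-vs-time plot) are written when an output directory is configured.
Reports deliberately contain no wall-clock information so that two runs
with the same seed produce byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import data as data_mod
from . import net as net_mod
from . import pk as pk_mod
from . import synergy
from .records import ConcentrationRecord, records_to_frame

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_initial",
    "run_improvement",
    "run_all",
    "compare_ci",
]

log = logging.getLogger("comboratio.pipeline")


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one end-to-end run (see docs for the YAML schema)."""

    components: tuple[str, ...]
    ratio_pair: tuple[str, str]
    doses: Mapping[str, float]
    table: str = "cynanchum_augmented"
    monotherapy_table: str | None = None
    records_per_timepoint: int = 99
    response_mode: str = "logistic"
    logistic_weights: tuple[float, ...] | None = None
    independent_components: bool = False  # identity copula instead of defaults
    delta_effect: float = 0.05
    det_value: float = 0.5
    det_step: float = 0.01
    seed: int = 0
    epochs: int = 150
    learning_rate: float = 0.01
    tune: bool = False
    tune_population: int = 6
    tune_iterations: int = 5
    inject_pk: Mapping[str, tuple[float, float, float]] | None = None
    inject_pk_post: Mapping[str, tuple[float, float, float]] | None = None
    outdir: str | None = None

    def __post_init__(self) -> None:
        if len(self.ratio_pair) != 2:
            raise ValueError("exactly two components must form the ratio pair")
        if not (0 < self.delta_effect <= 0.5):
            raise ValueError(f"delta_effect must be in (0, 0.5], got {self.delta_effect}")
        for comp in self.ratio_pair:
            if comp not in self.components:
                raise ValueError(f"ratio-pair component {comp!r} not among components")
            if comp not in self.doses:
                raise ValueError(f"no administered dose for {comp!r}")

    @classmethod
    def from_yaml(cls, path: "str | Path") -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("components", "ratio_pair", "logistic_weights"):
            if raw.get(key) is not None and key in raw:
                raw[key] = tuple(raw[key])
        for key in ("inject_pk", "inject_pk_post"):
            if raw.get(key):
                raw[key] = {k: tuple(v) for k, v in raw[key].items()}
        return cls(**raw)


@dataclass
class PipelineReport:
    config: dict[str, Any]
    pk_initial: dict[str, dict[str, float]] = field(default_factory=dict)
    quantity_ratio_initial: float = float("nan")
    dose_ratio_initial: float = float("nan")
    ci_before: pd.DataFrame | None = None
    metrics: dict[str, float] = field(default_factory=dict)
    det_value: float = 0.5
    contribution_weights: dict[str, float] = field(default_factory=dict)
    adjustment_factors: dict[str, float] = field(default_factory=dict)
    achieved_fraction: float = float("nan")
    pk_post: dict[str, dict[str, float]] = field(default_factory=dict)
    quantity_ratio_post: float = float("nan")
    dose_ratio_updated: float = float("nan")
    ci_after: pd.DataFrame | None = None
    ci_comparison: pd.DataFrame | None = None
    ci_decrease_fraction: float = float("nan")
    # carried between stages, not serialized
    _net: Any = field(default=None, repr=False)
    _records: list = field(default_factory=list, repr=False)
    _adjusted_records: list = field(default_factory=list, repr=False)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {}
        for f in dataclasses.fields(self):
            if f.name.startswith("_"):
                continue
            val = getattr(self, f.name)
            if isinstance(val, pd.DataFrame):
                val = val.to_dict(orient="records")
            out[f.name] = val
        return out

    def to_json(self, **kwargs: Any) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True,
                          default=_json_default, **kwargs)


def _json_default(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _fit_to_dict(fit: pk_mod.PKFit) -> dict[str, float]:
    return {"Kc": fit.Kc, "ka": fit.ka, "ke": fit.ke,
            "r_squared": fit.r_squared,
            "flip_flop_warning": fit.flip_flop_warning}


def _profile_from_spec(spec: data_mod.TableSpec, comp: str) -> list[pk_mod.ProfilePoint]:
    return [
        pk_mod.ProfilePoint(time=float(t), concentration=float(m), sd=float(s))
        for t, m, s in zip(spec.times, spec.means(comp), spec.sds(comp))
    ]


def _pk_fits(
    config: PipelineConfig,
    spec_or_profiles: "data_mod.TableSpec | Mapping[str, Sequence[pk_mod.ProfilePoint]]",
    injected: Mapping[str, tuple[float, float, float]] | None,
) -> dict[str, pk_mod.PKFit]:
    fits = {}
    for comp in config.ratio_pair:
        if injected and comp in injected:
            kc, ka, ke = injected[comp]
            if ka < ke:  # stored as printed; use the magnitude-equivalent branch
                log.warning("injected parameters for %s have ka < ke; "
                            "using the exchanged (flip-flop) branch", comp)
                ka, ke = ke, ka
                flip = True
            else:
                flip = False
            fits[comp] = pk_mod.PKFit(component=comp, Kc=kc, ka=ka, ke=ke,
                                      flip_flop_warning=flip)
        else:
            if isinstance(spec_or_profiles, data_mod.TableSpec):
                profile = _profile_from_spec(spec_or_profiles, comp)
            else:
                profile = list(spec_or_profiles[comp])
            fits[comp] = pk_mod.fit_profile(profile, component=comp)
    return fits


def _mono_fits(
    config: PipelineConfig, spec: data_mod.TableSpec
) -> dict[str, synergy.MedianEffectFit]:
    """Median-effect fits per drug for equipotent-dose inversion.

    A drug with its own monotherapy table uses it.  Otherwise its combo
    concentration-effect pairs serve as a surrogate; when those are
    confounded by the time course (non-positive slope), the Hill slope m
    is borrowed from a monotherapy-fitted reference drug (the standard
    similar-shape assumption) and the drug's median combo concentration
    serves as its Dm.
    """
    mono: dict[str, synergy.MedianEffectFit] = {}
    mono_spec = (data_mod.load_fixture(config.monotherapy_table)
                 if config.monotherapy_table else None)
    deferred: list[str] = []
    for comp in config.components:
        if mono_spec is not None and comp in mono_spec.components:
            doses = mono_spec.means(comp)
            fa = mono_spec.inhibition_fractions
            keep = doses > 0
            mono[comp] = synergy.fit_median_effect(doses[keep], fa[keep], drug=comp)
        else:
            deferred.append(comp)
    for comp in deferred:
        doses = spec.means(comp)
        fa = spec.inhibition_fractions
        keep = doses > 0
        try:
            mono[comp] = synergy.fit_median_effect(doses[keep], fa[keep], drug=comp)
        except synergy.SynergyError:
            m_ref = next((f.m for f in mono.values()), 1.0)
            dm = float(np.median(doses[keep]))
            log.warning(
                "combo-profile median-effect fit failed for %s; borrowing the "
                "reference Hill slope m=%.3f with Dm=%.3g", comp, m_ref, dm)
            mono[comp] = synergy.MedianEffectFit(Dm=dm, m=m_ref, drug=comp)
    return mono


def _ci_series(
    config: PipelineConfig,
    times: np.ndarray,
    conc: Mapping[str, np.ndarray],
    effects: np.ndarray,
    mono: Mapping[str, synergy.MedianEffectFit],
) -> pd.DataFrame:
    profile = pd.DataFrame({"time_h": times})
    for comp in config.components:
        profile[comp] = conc[comp]
    profile["effect"] = effects
    recs = synergy.ci_time_series(profile, mono)
    return pd.DataFrame(
        {
            "time_h": [r.time for r in recs],
            "combination_index": [r.ci for r in recs],
            "interaction": [r.interaction for r in recs],
        }
    )


def run_initial(config: PipelineConfig) -> PipelineReport:
    """Initial stage: PK ratio, dose ratio, CI series, trained classifier."""
    report = PipelineReport(config=dataclasses.asdict(config))
    spec = data_mod.load_fixture(config.table)
    log.info("stage=initial table=%s seed=%d", spec.name, config.seed)

    ci, cj = config.ratio_pair
    fits = _pk_fits(config, spec, config.inject_pk)
    report.pk_initial = {c: _fit_to_dict(f) for c, f in fits.items()}
    report.quantity_ratio_initial = pk_mod.quantity_ratio(fits[ci], fits[cj])
    report.dose_ratio_initial = config.doses[ci] / config.doses[cj]

    mono = _mono_fits(config, spec)
    report.ci_before = _ci_series(
        config, spec.times,
        {c: spec.means(c) for c in config.components},
        spec.inhibition_fractions, mono,
    )

    gen_config = data_mod.GenConfig(
        records_per_timepoint=config.records_per_timepoint,
        seed=config.seed,
        response_mode=config.response_mode,  # type: ignore[arg-type]
        logistic_weights=config.logistic_weights,
        target_correlations=(np.eye(len(config.components))
                             if config.independent_components else None),
    )
    records = data_mod.generate_records(spec, gen_config)
    report._records = records

    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(records))
    n_test = max(1, int(round(0.15 * len(records))))
    test = [records[i] for i in idx[:n_test]]
    train_recs = [records[i] for i in idx[n_test:]]

    net_config = net_mod.NetConfig(
        input_components=tuple(config.components),
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        seed=config.seed,
    )
    if config.tune:
        def score(lr: float, epochs: int) -> float:
            cfg = dataclasses.replace(net_config, learning_rate=lr, epochs=epochs)
            candidate = net_mod.build_net(cfg)
            net_mod.train(candidate, train_recs, cfg)
            x, y = net_mod.design_matrix(test, cfg)
            p = np.clip(candidate.predict_proba(x), 1e-12, 1 - 1e-12)
            return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

        from . import hippo  # local import keeps the stage dependency explicit
        lr, epochs, _ = hippo.tune_hyperparameters(
            score, population=config.tune_population,
            iterations=config.tune_iterations, seed=config.seed,
        )
        net_config = dataclasses.replace(net_config, learning_rate=lr, epochs=epochs)
        log.info("tuned learning_rate=%.2e epochs=%d", lr, epochs)

    net = net_mod.build_net(net_config)
    net_mod.train(net, train_recs, net_config)
    report._net = net

    det = net_mod.DETState(value=config.det_value, step=config.det_step)
    report.det_value = det.value
    report.metrics = dataclasses.asdict(net_mod.evaluate(net, test, det))
    report.contribution_weights = dict(
        net_mod.contribution_weights(net, records).weights
    )
    return report


def run_improvement(config: PipelineConfig, report: PipelineReport) -> PipelineReport:
    """Improvement stage: adjust, refit, update ratios, recompute CI."""
    if report._net is None:
        raise RuntimeError("run_initial must complete before run_improvement")
    spec = data_mod.load_fixture(config.table)
    det = net_mod.DETState(value=config.det_value, step=config.det_step)
    log.info("stage=improvement delta=%.3f", config.delta_effect)

    result = net_mod.adjust_concentrations(
        report._net, report._records, config.delta_effect, det
    )
    report._adjusted_records = result.records
    report.adjustment_factors = dict(result.factors)
    report.achieved_fraction = result.achieved_fraction
    report.contribution_weights = dict(result.weights.weights)

    adjusted = records_to_frame(result.records)
    by_time = adjusted.groupby("time_h").mean(numeric_only=True)
    profiles = {
        comp: [
            pk_mod.ProfilePoint(time=float(t), concentration=float(row[f"conc_{comp}"]))
            for t, row in by_time.iterrows()
        ]
        for comp in config.ratio_pair
    }
    ci, cj = config.ratio_pair
    fits = _pk_fits(config, profiles, config.inject_pk_post)
    report.pk_post = {c: _fit_to_dict(f) for c, f in fits.items()}
    report.quantity_ratio_post = pk_mod.quantity_ratio(fits[ci], fits[cj])
    report.dose_ratio_updated = pk_mod.dose_ratio_update(
        report.dose_ratio_initial,
        report.quantity_ratio_initial,
        report.quantity_ratio_post,
    )

    # post-improvement inhibition rates: initial rate + delta, capped
    effects = np.minimum(spec.inhibition_fractions + config.delta_effect, 0.99)
    mono = _mono_fits(config, spec)
    factor = report.adjustment_factors
    conc_after = {
        c: spec.means(c) * factor.get(c, 1.0) for c in config.components
    }
    report.ci_after = _ci_series(config, spec.times, conc_after, effects, mono)

    comparison, frac = compare_ci(report.ci_before, report.ci_after)
    report.ci_comparison = comparison
    report.ci_decrease_fraction = frac
    if config.outdir:
        _write_outputs(config, report)
    return report


def run_all(config: PipelineConfig) -> PipelineReport:
    return run_improvement(config, run_initial(config))


def compare_ci(
    before: pd.DataFrame, after: pd.DataFrame
) -> tuple[pd.DataFrame, float]:
    """Per-time CI change with a decrease flag; summary = decreased fraction."""
    if before is None or after is None:
        raise ValueError("both CI series are required")
    t_before = before["time_h"].to_numpy(dtype=float)
    t_after = after["time_h"].to_numpy(dtype=float)
    if len(t_before) != len(t_after) or not np.allclose(t_before, t_after):
        raise ValueError("CI series time grids do not match")
    delta = (after["combination_index"].to_numpy()
             - before["combination_index"].to_numpy())
    out = pd.DataFrame(
        {
            "time_h": t_before,
            "ci_before": before["combination_index"].to_numpy(),
            "ci_after": after["combination_index"].to_numpy(),
            "delta_ci": delta,
            "decreased": delta < 0,
        }
    )
    frac = float(out["decreased"].mean()) if len(out) else 0.0
    return out, frac


def _write_outputs(config: PipelineConfig, report: PipelineReport) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(report.to_json() + "\n")
    (outdir / "fits.json").write_text(
        json.dumps({"initial": report.pk_initial, "post": report.pk_post}, indent=2)
        + "\n"
    )
    if report.ci_before is not None:
        report.ci_before.to_csv(outdir / "ci_before.csv", index=False)
    if report.ci_after is not None:
        report.ci_after.to_csv(outdir / "ci_after.csv", index=False)
    if report._adjusted_records:
        records_to_frame(report._adjusted_records).to_csv(
            outdir / "adjusted_records.csv", index=False
        )
    _plot_ci(report, outdir / "ci_comparison.png")


def _plot_ci(report: PipelineReport, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for frame, label in ((report.ci_before, "before"), (report.ci_after, "after")):
        if frame is not None:
            ax.plot(frame["time_h"], frame["combination_index"], marker="o", label=label)
    ax.axhline(1.0, color="grey", linestyle="--", linewidth=1, label="additive (CI = 1)")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("Combination Index")
    ax.set_yscale("log")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
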