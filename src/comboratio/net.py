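"""Dose-effect classification with a small 1-D convolutional network.

The classifier maps the vector of per-record component plasma
concentrations (optionally with time as an extra feature) to the
probability that the concentration state is effective.  Architecture:
standardized inputs -> one or more 1-D valid convolutions (ReLU) with
max-pooling where the sequence length permits -> dense ReLU layers ->
single sigmoid output.  Training is mini-batch stochastic gradient descent
on binary cross-entropy, fully reproducible given the config seed.

On top of the raw probability sits the Desired Effect Threshold (DET): a
probability cutoff that labels a state effective, nudged up when validation
accuracy improves and down when it degrades.  Per-component contribution
weights are the dataset-mean absolute input gradients of the output,
normalized to sum to one; they drive the concentration adjustment that
raises the DET-classified effective fraction by a requested amount.

The network is implemented directly in numpy with explicit forward and
backward passes; gradients are exact, not finite differences.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.metrics import accuracy_score, precision_score, recall_score

from .records import ConcentrationRecord

__all__ = [
    "NetConfig",
    "DETState",
    "ContributionWeights",
    "Metrics",
    "AdjustmentResult",
    "ConfigurationError",
    "InfeasibleAdjustmentError",
    "DoseEffectNet",
    "build_net",
    "train",
    "apply_det",
    "update_det",
    "contribution_weights",
    "adjust_concentrations",
    "evaluate",
    "design_matrix",
]

#: bounds on per-component multiplicative adjustment factors
FACTOR_BOUNDS = (0.1, 10.0)

#: DET clamp range
DET_BOUNDS = (0.05, 0.95)


class ConfigurationError(ValueError):
    """Raised for inconsistent network configurations."""


class InfeasibleAdjustmentError(RuntimeError):
    """Raised when the requested efficacy gain is unreachable within bounds."""

    def __init__(self, message: str, best_fraction: float):
        super().__init__(message)
        self.best_fraction = best_fraction


@dataclass(frozen=True)
class NetConfig:
    input_components: tuple[str, ...]
    conv_layers: tuple[tuple[int, int], ...] = ((16, 2),)  # (filters, kernel)
    pool_width: int = 2
    dense_units: tuple[int, ...] = (16,)
    learning_rate: float = 0.01
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    include_time: bool = False

    def __post_init__(self) -> None:
        if not self.input_components:
            raise ConfigurationError("at least one input component required")
        if self.learning_rate <= 0:
            raise ConfigurationError("learning_rate must be positive")
        if self.epochs < 0 or self.batch_size <= 0:
            raise ConfigurationError("epochs must be >= 0 and batch_size positive")

    @property
    def input_length(self) -> int:
        return len(self.input_components) + (1 if self.include_time else 0)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.input_components + (("time",) if self.include_time else ())


@dataclass(frozen=True)
class DETState:
    """Desired Effect Threshold with its adjustment history."""

    value: float = 0.5
    step: float = 0.01
    history: tuple[tuple[int, float], ...] = ()

    def __post_init__(self) -> None:
        lo, hi = DET_BOUNDS
        if not (lo <= self.value <= hi):
            raise ValueError(f"DET value must stay within [{lo}, {hi}], got {self.value}")


@dataclass(frozen=True)
class ContributionWeights:
    """Normalized per-component input-importance weights (sum to 1)."""

    weights: Mapping[str, float]

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if any(v < 0 for v in self.weights.values()):
            raise ValueError("weights must be nonnegative")
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1, got {total}")

    def as_array(self, order: Sequence[str]) -> np.ndarray:
        return np.array([self.weights[k] for k in order])


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float


@dataclass(frozen=True)
class AdjustmentResult:
    records: list[ConcentrationRecord]
    weights: ContributionWeights
    factors: Mapping[str, float]
    achieved_fraction: float
    target_fraction: float


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class DoseEffectNet:
    """A small 1-D CNN binary classifier over component concentrations."""

    def __init__(self, config: NetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.params: dict[str, np.ndarray] = {}
        self._conv_shapes: list[tuple[int, int, bool]] = []  # (filters, kernel, pooled)

        length = config.input_length
        channels = 1
        for li, (filters, kernel) in enumerate(config.conv_layers):
            if kernel > length:
                raise ConfigurationError(
                    f"conv layer {li}: kernel {kernel} wider than input length {length}"
                )
            fan_in = channels * kernel
            self.params[f"convW{li}"] = rng.normal(0, np.sqrt(2.0 / fan_in),
                                                   size=(filters, channels, kernel))
            self.params[f"convb{li}"] = np.zeros(filters)
            length = length - kernel + 1
            pooled = config.pool_width > 1 and length >= config.pool_width
            if pooled:
                length = length // config.pool_width
            self._conv_shapes.append((filters, kernel, pooled))
            channels = filters

        dims = [channels * length] + list(config.dense_units) + [1]
        for li in range(len(dims) - 1):
            self.params[f"W{li}"] = rng.normal(0, np.sqrt(2.0 / dims[li]),
                                               size=(dims[li], dims[li + 1]))
            self.params[f"b{li}"] = np.zeros(dims[li + 1])
        self._n_dense = len(dims) - 1

        # feature standardization, fitted when training starts
        self.mu = np.zeros(config.input_length)
        self.sd = np.ones(config.input_length)

    # ---- forward / backward -------------------------------------------------

    def _forward(self, x_raw: np.ndarray) -> tuple[np.ndarray, dict]:
        xs = (x_raw - self.mu) / self.sd
        a = xs[:, None, :]  # (n, channels=1, length)
        cache: dict = {"conv": [], "xs_shape": xs.shape}
        pw = self.config.pool_width
        for li, (_f, kernel, pooled) in enumerate(self._conv_shapes):
            w = self.params[f"convW{li}"]
            b = self.params[f"convb{li}"]
            windows = sliding_window_view(a, kernel, axis=2)  # (n, c, L', k)
            z = np.einsum("nclk,fck->nfl", windows, w) + b[None, :, None]
            relu = z > 0
            h = z * relu
            if pooled:
                n, f, lp = h.shape
                lout = lp // pw
                trimmed = h[:, :, : lout * pw].reshape(n, f, lout, pw)
                arg = trimmed.argmax(axis=3)
                pooled_out = np.take_along_axis(trimmed, arg[..., None], axis=3)[..., 0]
                cache["conv"].append((a, windows, relu, h.shape, arg))
                a = pooled_out
            else:
                cache["conv"].append((a, windows, relu, h.shape, None))
                a = h
        n = a.shape[0]
        h = a.reshape(n, -1)
        cache["flat_shape"] = a.shape
        cache["dense"] = []
        for li in range(self._n_dense):
            z = h @ self.params[f"W{li}"] + self.params[f"b{li}"]
            if li < self._n_dense - 1:
                relu = z > 0
                cache["dense"].append((h, relu))
                h = z * relu
            else:
                cache["dense"].append((h, None))
                h = z
        logits = h[:, 0]
        probs = _sigmoid(logits)
        return probs, cache

    def _backward(
        self, dlogits: np.ndarray, cache: dict, want_input_grad: bool = False
    ) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
        grads: dict[str, np.ndarray] = {}
        dh = dlogits[:, None]
        for li in range(self._n_dense - 1, -1, -1):
            h_in, relu = cache["dense"][li]
            if relu is not None:
                dh = dh * relu
            grads[f"W{li}"] = h_in.T @ dh
            grads[f"b{li}"] = dh.sum(axis=0)
            dh = dh @ self.params[f"W{li}"].T
        da = dh.reshape(cache["flat_shape"])
        pw = self.config.pool_width
        for li in range(len(self._conv_shapes) - 1, -1, -1):
            a_in, windows, relu, h_shape, arg = cache["conv"][li]
            if arg is not None:
                n, f, lp = h_shape
                lout = lp // pw
                dpool = np.zeros((n, f, lout, pw))
                np.put_along_axis(dpool, arg[..., None], da[..., None], axis=3)
                dz = np.zeros(h_shape)
                dz[:, :, : lout * pw] = dpool.reshape(n, f, lout * pw)
            else:
                dz = da
            dz = dz * relu
            w = self.params[f"convW{li}"]
            grads[f"convW{li}"] = np.einsum("nfl,nclk->fck", dz, windows)
            grads[f"convb{li}"] = dz.sum(axis=(0, 2))
            if li > 0 or want_input_grad:
                n, c_in, lin = a_in.shape
                da_in = np.zeros((n, c_in, lin))
                kernel = w.shape[2]
                for k in range(kernel):
                    da_in[:, :, k : k + dz.shape[2]] += np.einsum("nfl,fc->ncl", dz, w[:, :, k])
                da = da_in
            else:
                da = None
        input_grad = None
        if want_input_grad and da is not None:
            input_grad = da[:, 0, :] / self.sd  # w.r.t. raw (unscaled) inputs
        return grads, input_grad

    # ---- public surface -----------------------------------------------------

    def predict_proba(self, x_raw: np.ndarray) -> np.ndarray:
        probs, _ = self._forward(np.atleast_2d(np.asarray(x_raw, dtype=float)))
        return probs

    def input_gradients(self, x_raw: np.ndarray) -> np.ndarray:
        """d(probability)/d(raw input feature), one row per record."""
        x = np.atleast_2d(np.asarray(x_raw, dtype=float))
        probs, cache = self._forward(x)
        dlogits = probs * (1.0 - probs)
        _, ig = self._backward(dlogits, cache, want_input_grad=True)
        assert ig is not None
        return ig

    def clone(self) -> "DoseEffectNet":
        return copy.deepcopy(self)


def build_net(config: NetConfig) -> DoseEffectNet:
    """Deterministically initialize an untrained network from a config."""
    return DoseEffectNet(config)


def design_matrix(
    records: Sequence[ConcentrationRecord], config: NetConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Stack records into (X, y) following the config's feature order."""
    x = np.array(
        [
            [r.concentrations[c] for c in config.input_components]
            + ([r.time] if config.include_time else [])
            for r in records
        ],
        dtype=float,
    )
    y = np.array([r.effective for r in records], dtype=float)
    return x, y


def train(
    net: DoseEffectNet,
    records: Sequence[ConcentrationRecord],
    config: NetConfig | None = None,
) -> tuple[DoseEffectNet, list[float]]:
    """Mini-batch SGD on binary cross-entropy; returns the net and loss history."""
    config = config or net.config
    if len(records) < 2:
        raise ValueError("at least 2 records required for training")
    x, y = design_matrix(records, config)
    if len(np.unique(y)) < 2:
        warnings.warn("training data contain a single class; proceeding anyway",
                      RuntimeWarning)
    # standardize features on the training set
    net.mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd[sd == 0] = 1.0
    net.sd = sd

    rng = np.random.default_rng(np.uint32(config.seed) + np.uint32(1))
    n = len(y)
    history: list[float] = []
    eps = 1e-12
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = x[idx], y[idx]
            probs, cache = net._forward(xb)
            p = np.clip(probs, eps, 1.0 - eps)
            loss = float(-np.mean(yb * np.log(p) + (1 - yb) * np.log(1 - p)))
            epoch_loss += loss * len(idx)
            dlogits = (probs - yb) / len(idx)
            grads, _ = net._backward(dlogits, cache)
            for key, g in grads.items():
                net.params[key] -= config.learning_rate * g
        history.append(epoch_loss / n)
    return net, history


def apply_det(probability: float, det: DETState) -> int:
    """Classify a probability against the DET; ties count as effective."""
    if not (0.0 <= probability <= 1.0):
        raise ValueError(f"probability must be in [0, 1], got {probability}")
    return int(probability >= det.value)


def update_det(det: DETState, current_val_accuracy: float,
               previous_val_accuracy: float) -> DETState:
    """Raise the DET on improving accuracy, lower it on degradation."""
    if current_val_accuracy > previous_val_accuracy:
        new = det.value + det.step
    elif current_val_accuracy < previous_val_accuracy:
        new = det.value - det.step
    else:
        new = det.value
    lo, hi = DET_BOUNDS
    new = min(max(new, lo), hi)
    return DETState(value=new, step=det.step,
                    history=det.history + ((len(det.history), new),))


def contribution_weights(
    net: DoseEffectNet, records: Sequence[ConcentrationRecord]
) -> ContributionWeights:
    """Mean absolute input-gradient saliency per component, normalized to 1.

    Gradients are taken with respect to the standardized inputs so that the
    importance ranking does not depend on the measurement scale of each
    component.
    """
    if not records:
        raise ValueError("at least one record required")
    x, _ = design_matrix(records, net.config)
    grads = net.input_gradients(x) * net.sd  # per standardized unit
    ncomp = len(net.config.input_components)
    sal = np.abs(grads[:, :ncomp]).mean(axis=0)
    total = sal.sum()
    if total == 0:
        warnings.warn("all input gradients are zero; falling back to uniform weights",
                      RuntimeWarning)
        sal = np.ones(ncomp)
        total = float(ncomp)
    w = sal / total
    return ContributionWeights(dict(zip(net.config.input_components, w)))


def _effective_fraction(net: DoseEffectNet, x: np.ndarray, det: DETState) -> float:
    return float(np.mean(net.predict_proba(x) >= det.value))


def adjust_concentrations(
    net: DoseEffectNet,
    records: Sequence[ConcentrationRecord],
    delta_effect: float,
    det: DETState,
    tolerance: float = 0.01,
) -> AdjustmentResult:
    """Scale component concentrations to raise the effective fraction.

    One multiplicative factor per component, shared across records,
    searched on a log scale along the saliency-weighted gradient direction
    (smallest deviation from unit factors that achieves the target), with
    factors bounded to [0.1, 10].  Labels are never modified.
    """
    components = net.config.input_components
    x, _ = design_matrix(records, net.config)
    current = _effective_fraction(net, x, det)
    weights0 = contribution_weights(net, records)
    if delta_effect == 0:
        return AdjustmentResult(
            records=list(records),
            weights=weights0,
            factors={c: 1.0 for c in components},
            achieved_fraction=current,
            target_fraction=current,
        )
    if not (0 < delta_effect <= 1 - current + 1e-12):
        raise ValueError(
            f"delta_effect must lie in (0, {1 - current:.3f}], got {delta_effect}"
        )
    target = current + delta_effect

    ncomp = len(components)
    mean_grad = net.input_gradients(x)[:, :ncomp].mean(axis=0)
    w = weights0.as_array(components)
    direction = np.sign(mean_grad) * w
    if not np.any(direction):
        direction = np.ones(ncomp) / ncomp

    lo_f, hi_f = FACTOR_BOUNDS

    def fraction_at(tval: float) -> tuple[float, np.ndarray]:
        factors = np.clip(np.exp(tval * direction), lo_f, hi_f)
        xs = x.copy()
        xs[:, :ncomp] = x[:, :ncomp] * factors
        return _effective_fraction(net, xs, det), factors

    t_max = np.log(hi_f) / np.max(np.abs(direction[direction != 0])) if np.any(direction) else 0.0
    best_frac, _ = fraction_at(t_max)
    if best_frac < target - tolerance:
        raise InfeasibleAdjustmentError(
            f"target effective fraction {target:.3f} unreachable within factor "
            f"bounds; best achieved {best_frac:.3f}",
            best_fraction=best_frac,
        )
    lo_t, hi_t = 0.0, t_max
    for _ in range(60):
        mid = 0.5 * (lo_t + hi_t)
        frac_mid, _ = fraction_at(mid)
        if frac_mid >= target:
            hi_t = mid
        else:
            lo_t = mid
    achieved, factors = fraction_at(hi_t)
    if abs(achieved - target) > tolerance:
        warnings.warn(
            f"achieved fraction {achieved:.3f} differs from target {target:.3f} "
            "by more than the tolerance (finite-sample granularity)",
            RuntimeWarning,
        )
    factor_map = dict(zip(components, factors))
    adjusted = [
        ConcentrationRecord(
            time=r.time,
            concentrations={
                c: r.concentrations[c] * factor_map.get(c, 1.0)
                for c in r.concentrations
            },
            effective=r.effective,
            group=r.group,
        )
        for r in records
    ]
    return AdjustmentResult(
        records=adjusted,
        weights=contribution_weights(net, adjusted),
        factors=factor_map,
        achieved_fraction=achieved,
        target_fraction=target,
    )


def evaluate(
    net: DoseEffectNet,
    records: Sequence[ConcentrationRecord],
    det: DETState,
) -> Metrics:
    """Precision, recall, F1, accuracy of DET-thresholded predictions."""
    if not records:
        raise ValueError("at least one labelled record required")
    x, y = design_matrix(records, net.config)
    pred = (net.predict_proba(x) >= det.value).astype(int)
    if pred.sum() == 0 and y.sum() > 0:
        warnings.warn("no predicted positives; precision reported as 0", RuntimeWarning)
    precision = float(precision_score(y, pred, zero_division=0))
    recall = float(recall_score(y, pred, zero_division=0))
    f1 = 2 * precision * recall / (precision + recall) if (precision + recall) else 0.0
    accuracy = float(accuracy_score(y, pred))
    return Metrics(precision=precision, recall=recall, f1=f1, accuracy=accuracy)
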