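"""Coupling the ACVO optimizer to the TSK fuzzy model.

The trainer min-max normalizes features and target with statistics fitted
on the training split only, encodes the model's antecedent and consequent
parameters as one flat vector, and lets ACVO minimize the training-split
RMSE of the decoded model.  Metrics are reported on the normalized [0, 1]
scale by default (``metrics_scale="original"`` re-expresses them in the
target's native units).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import acvo
from .anfis import SIGMA_MIN_DEFAULT, AnfisModel, ShapeError, scatter_model
from .metrics import MetricsReport, metrics_report


class SchemaError(KeyError):
    """The dataset is missing a column the run requires."""


class SplitError(ValueError):
    """The dataset is too small to split."""


# -- normalization -------------------------------------------------------


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-column min-max statistics, fitted on training data only.

    ``transform`` maps ``x`` to ``(x - min) / (max - min)``.  Values outside
    the fitted range extrapolate outside [0, 1] — they are deliberately not
    clipped, so test rows keep their geometry.  A degenerate column
    (``max == min``) maps to zeros.
    """

    columns: tuple[str, ...]
    x_min: tuple[float, ...]
    x_max: tuple[float, ...]

    @classmethod
    def fit(cls, df: pd.DataFrame, columns: Sequence[str]) -> "NormalizationSpec":
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise SchemaError(f"missing column(s): {', '.join(missing)}")
        mins = tuple(float(df[c].min()) for c in columns)
        maxs = tuple(float(df[c].max()) for c in columns)
        return cls(tuple(columns), mins, maxs)

    def transform(self, df: pd.DataFrame) -> pd.DataFrame:
        out = {}
        for c, lo, hi in zip(self.columns, self.x_min, self.x_max):
            if c not in df.columns:
                raise SchemaError(f"missing column(s): {c}")
            span = hi - lo
            out[c] = (df[c] - lo) / span if span > 0 else 0.0 * df[c]
        return pd.DataFrame(out, index=df.index)

    def inverse_target(self, y: np.ndarray, column: str) -> np.ndarray:
        i = self.columns.index(column)
        return np.asarray(y) * (self.x_max[i] - self.x_min[i]) + self.x_min[i]


def normalize(column, spec_min: float, spec_max: float) -> np.ndarray:
    """Min-max normalize one column given fitted bounds (degenerate bounds
    map everything to zero)."""
    x = np.asarray(column, dtype=float)
    span = spec_max - spec_min
    if span <= 0:
        return np.zeros_like(x)
    return (x - spec_min) / span


# -- splitting -----------------------------------------------------------


def split(
    dataset: pd.DataFrame, seed: int, train_fraction: float = 0.8
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniformly random partition into train/test of sizes
    ``ceil(f n)`` / remainder, deterministic given the seed."""
    n = len(dataset)
    if n < 2:
        raise SplitError("need at least 2 rows to split")
    n_train = math.ceil(train_fraction * n)
    order = np.random.default_rng(seed).permutation(n)
    return (
        dataset.iloc[order[:n_train]],
        dataset.iloc[order[n_train:]],
    )


# -- parameter-vector encoding ------------------------------------------


@dataclass(frozen=True)
class AnfisTemplate:
    """Fixed model structure that the flat parameter vector fills in.

    ``init_center`` / ``init_width`` seed every antecedent with a shared
    (c, sigma) pair; they are initial values only — the optimizer moves
    every membership function independently.
    """

    n_inputs: int
    n_rules: int = 4
    partition_scheme: str = "scatter"
    sigma_min: float = SIGMA_MIN_DEFAULT
    init_center: float = 0.5
    init_width: float = 0.25

    def n_parameters(self) -> int:
        R, D = self.n_rules, self.n_inputs
        return 3 * R * D + R  # centers, widths, coeffs, biases

    def initial_model(self) -> AnfisModel:
        return scatter_model(
            self.n_inputs,
            self.n_rules,
            center=self.init_center,
            width=self.init_width,
            sigma_min=self.sigma_min,
        )


def encode(model: AnfisModel) -> np.ndarray:
    """Flatten a model to ``[centers, widths, coeffs, biases]`` (row-major
    over rules then inputs).  Bijective with :func:`decode`."""
    return np.concatenate(
        [
            model.centers.ravel(),
            model.widths.ravel(),
            model.coeffs.ravel(),
            model.biases.ravel(),
        ]
    )


def decode(vector: np.ndarray, template: AnfisTemplate) -> AnfisModel:
    """Rebuild a model from a flat parameter vector and its template."""
    vector = np.asarray(vector, dtype=float).ravel()
    R, D = template.n_rules, template.n_inputs
    expected = 3 * R * D + R
    if vector.size != expected:
        raise ShapeError(
            f"parameter vector has length {vector.size}, template needs {expected}"
        )
    k = R * D
    centers = vector[:k].reshape(R, D)
    widths = vector[k : 2 * k].reshape(R, D)
    coeffs = vector[2 * k : 3 * k].reshape(R, D)
    biases = vector[3 * k :]
    return AnfisModel.from_arrays(
        centers,
        widths,
        coeffs,
        biases,
        partition_scheme=template.partition_scheme,
        sigma_min=template.sigma_min,
    )


def parameter_bounds(template: AnfisTemplate) -> tuple[tuple[float, float], ...]:
    """Search box per encoded block: centers in [0, 1], widths in
    [sigma_min, 1], consequent coefficients and biases in [-10, 10]."""
    R, D = template.n_rules, template.n_inputs
    k = R * D
    bounds: list[tuple[float, float]] = []
    bounds += [(0.0, 1.0)] * k
    bounds += [(template.sigma_min, 1.0)] * k
    bounds += [(-10.0, 10.0)] * k
    bounds += [(-10.0, 10.0)] * R
    return tuple(bounds)


def rmse_objective(
    X: np.ndarray, y: np.ndarray, template: AnfisTemplate
) -> Callable[[np.ndarray], float]:
    """Objective factory: RMSE of the decoded model on ``(X, y)``.

    ``X`` and ``y`` are taken as already being on the scale the model sees
    (the trainer passes normalized arrays)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    R, D = template.n_rules, template.n_inputs
    k = R * D
    sigma_min = template.sigma_min
    n_rules = R

    def objective(vector: np.ndarray) -> float:
        v = np.asarray(vector, dtype=float)
        centers = v[:k].reshape(R, D)
        widths = np.maximum(v[k : 2 * k].reshape(R, D), sigma_min)
        coeffs = v[2 * k : 3 * k].reshape(R, D)
        biases = v[3 * k :]
        d = X[:, None, :] - centers[None, :, :]
        mu = np.exp(-(d * d) / (2.0 * widths[None, :, :] ** 2))
        w = mu.prod(axis=2)
        total = w.sum(axis=1, keepdims=True)
        wbar = np.where(
            total > 0, w / np.where(total == 0, 1.0, total), 1.0 / n_rules
        )
        f = X @ coeffs.T + biases[None, :]
        pred = (wbar * f).sum(axis=1)
        return float(np.sqrt(np.mean((pred - y) ** 2)))

    return objective


# -- the training loop ---------------------------------------------------


@dataclass
class TrainingRun:
    """Everything one training produced: the fitted model, the split, the
    normalization statistics and both metric reports."""

    feature_columns: tuple[str, ...]
    target: str
    split_seed: int
    train_fraction: float
    anfis: AnfisModel
    acvo_config: acvo.AcvoConfig
    norm: NormalizationSpec
    metrics_train: MetricsReport
    metrics_test: MetricsReport
    trace: np.ndarray
    initial_best_rmse: float

    def report_text(self) -> str:
        lines = [
            f"target: {self.target}",
            f"features: {', '.join(self.feature_columns)}",
            f"split_seed: {self.split_seed}",
            f"train_fraction: {self.train_fraction}",
            f"acvo: N={self.acvo_config.population_size} "
            f"iters={self.acvo_config.max_iterations} "
            f"seed={self.acvo_config.rng_seed}",
        ]
        for name, m in (("train", self.metrics_train), ("test", self.metrics_test)):
            lines.append(
                f"{name}: rmse={m.rmse:.6f} delta_pct={m.delta_pct:.4f} "
                f"aicc={m.aicc:.4f} n={m.n} k={m.k}"
            )
        return "\n".join(lines) + "\n"


def train(
    dataset: pd.DataFrame,
    feature_columns: Sequence[str],
    acvo_config: acvo.AcvoConfig,
    template: AnfisTemplate | None = None,
    target: str = "yield",
    split_seed: int | None = None,
    train_fraction: float = 0.8,
    metrics_scale: str = "normalized",
) -> TrainingRun:
    """Fit a TSK model to ``target`` from ``feature_columns`` with ACVO.

    The dataset is split 80/20 (by default), normalization statistics are
    fitted on the training split, and ACVO minimizes the training RMSE of
    the decoded model.  ``split_seed`` defaults to the optimizer seed so a
    single seed governs the whole run.
    """
    feature_columns = tuple(feature_columns)
    missing = [c for c in (*feature_columns, target) if c not in dataset.columns]
    if missing:
        raise SchemaError(f"missing column(s): {', '.join(missing)}")
    if template is None:
        template = AnfisTemplate(n_inputs=len(feature_columns))
    if template.n_inputs != len(feature_columns):
        raise ShapeError(
            f"template expects {template.n_inputs} inputs, got "
            f"{len(feature_columns)} feature columns"
        )
    if split_seed is None:
        split_seed = acvo_config.rng_seed
    train_df, test_df = split(dataset, split_seed, train_fraction)
    norm = NormalizationSpec.fit(train_df, (*feature_columns, target))
    Xtr = norm.transform(train_df)[list(feature_columns)].to_numpy()
    ytr = norm.transform(train_df)[target].to_numpy()
    Xte = norm.transform(test_df)[list(feature_columns)].to_numpy()
    yte = norm.transform(test_df)[target].to_numpy()

    objective = rmse_objective(Xtr, ytr, template)
    config = replace(acvo_config, bounds=parameter_bounds(template))
    initial_pop = acvo.initialize_population(
        config, objective, np.random.default_rng(config.rng_seed)
    )
    initial_best_rmse = -max(p.fitness for p in initial_pop)
    result = acvo.optimize(objective, config)
    model = decode(result.position, template)

    k = template.n_parameters()
    pred_tr = model.predict(Xtr)
    pred_te = model.predict(Xte)
    if metrics_scale == "original":
        ytr_r = norm.inverse_target(ytr, target)
        yte_r = norm.inverse_target(yte, target)
        pred_tr = norm.inverse_target(pred_tr, target)
        pred_te = norm.inverse_target(pred_te, target)
        m_train = metrics_report(ytr_r, pred_tr, k)
        m_test = metrics_report(yte_r, pred_te, k)
    else:
        m_train = metrics_report(ytr, pred_tr, k)
        m_test = metrics_report(yte, pred_te, k)

    return TrainingRun(
        feature_columns=feature_columns,
        target=target,
        split_seed=split_seed,
        train_fraction=train_fraction,
        anfis=model,
        acvo_config=config,
        norm=norm,
        metrics_train=m_train,
        metrics_test=m_test,
        trace=result.trace,
        initial_best_rmse=initial_best_rmse,
    )
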