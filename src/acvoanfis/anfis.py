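"""First-order Takagi-Sugeno (TSK) fuzzy inference.

The model is the classic five-layer adaptive neuro-fuzzy network:

1. *Fuzzification* — each crisp input is mapped to membership degrees by
   Gaussian membership functions ``mu(x) = exp(-(x - c)^2 / (2 sigma^2))``
   with center ``c`` and width ``sigma``.
2. *Implication* — the firing strength of a rule is the product of the
   membership degrees of its antecedents.
3. *Normalization* — firing strengths are rescaled to sum to one.
4. *Defuzzification* — each rule's consequent is a linear (first-order)
   function of the inputs, ``f = sum_d p_d x_d + r``.
5. *Combination* — the output is the firing-weighted sum of the rule
   consequents, a convex combination of the ``f_i``.

Two rule-base layouts are supported.  ``scatter`` partitioning gives every
rule its own Gaussian per input (parameter count linear in rules x inputs),
which is the default because grid partitioning with many inputs explodes
combinatorially.  ``grid`` partitioning builds ``M^D`` rules from ``M``
shared membership functions per input and is available for low-dimensional
problems.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import product as _iterproduct
from pathlib import Path
from typing import Sequence

import numpy as np

#: Default lower bound on Gaussian widths.  The membership formula divides
#: by sigma^2, so an optimizer must never drive widths to zero.
SIGMA_MIN_DEFAULT = 1e-3


class InvalidParameterError(ValueError):
    """A membership-function or model parameter violates its invariant."""


class ShapeError(ValueError):
    """An input vector does not match the model's dimensionality."""


@dataclass(frozen=True)
class GaussianMF:
    """Gaussian fuzzy set with center ``center`` and width ``width`` (> 0)."""

    center: float
    width: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.center) or not np.isfinite(self.width):
            raise InvalidParameterError("membership parameters must be finite")
        if self.width <= 0:
            raise InvalidParameterError(f"width must be positive, got {self.width}")


@dataclass(frozen=True)
class FuzzyRule:
    """One TSK rule: a Gaussian antecedent per input and a linear consequent.

    ``antecedent`` holds one :class:`GaussianMF` per active input;
    ``consequent_coeffs`` the matching linear coefficients and
    ``consequent_bias`` the constant term of ``f = sum_d p_d x_d + r``.
    """

    antecedent: tuple[GaussianMF, ...]
    consequent_coeffs: tuple[float, ...]
    consequent_bias: float

    def __post_init__(self) -> None:
        if len(self.consequent_coeffs) != len(self.antecedent):
            raise ShapeError(
                "consequent_coeffs length must equal antecedent length "
                f"({len(self.consequent_coeffs)} != {len(self.antecedent)})"
            )


def membership(x, mf: GaussianMF, sigma_min: float = SIGMA_MIN_DEFAULT):
    """Gaussian membership degree of ``x`` in the fuzzy set ``mf``.

    Returns ``exp(-(x - c)^2 / (2 sigma^2))``, in ``(0, 1]``; equals 1 iff
    ``x == c`` and is symmetric about the center.  ``x`` may be a scalar or
    an ndarray (evaluated elementwise).
    """
    if mf.width < sigma_min:
        raise InvalidParameterError(
            f"width {mf.width} below minimum {sigma_min}"
        )
    d = np.asarray(x, dtype=float) - mf.center
    out = np.exp(-(d * d) / (2.0 * mf.width * mf.width))
    return float(out) if out.ndim == 0 else out


class AnfisModel:
    """A TSK fuzzy model: ``n_inputs`` crisp inputs, a nonempty rule base.

    Parameters are cached as arrays of shape ``(R, D)`` (centers, widths,
    coefficients) and ``(R,)`` (biases) for vectorized evaluation; the model
    is treated as immutable after construction.
    """

    def __init__(
        self,
        n_inputs: int,
        rules: Sequence[FuzzyRule],
        partition_scheme: str = "scatter",
        sigma_min: float = SIGMA_MIN_DEFAULT,
    ) -> None:
        if n_inputs < 1:
            raise InvalidParameterError("n_inputs must be a positive integer")
        if len(rules) == 0:
            raise InvalidParameterError("rule base must be nonempty")
        if partition_scheme not in ("scatter", "grid"):
            raise InvalidParameterError(
                f"unknown partition scheme {partition_scheme!r}"
            )
        for rule in rules:
            if len(rule.antecedent) != n_inputs:
                raise ShapeError(
                    f"rule has {len(rule.antecedent)} antecedents, "
                    f"model has {n_inputs} inputs"
                )
        for rule in rules:
            for mf in rule.antecedent:
                if mf.width < sigma_min:
                    raise InvalidParameterError(
                        f"width {mf.width} below minimum {sigma_min}"
                    )
        self.n_inputs = int(n_inputs)
        self.rules = tuple(rules)
        self.partition_scheme = partition_scheme
        self.sigma_min = float(sigma_min)
        R, D = len(rules), n_inputs
        self.centers = np.array(
            [[mf.center for mf in r.antecedent] for r in rules], dtype=float
        ).reshape(R, D)
        self.widths = np.array(
            [[mf.width for mf in r.antecedent] for r in rules], dtype=float
        ).reshape(R, D)
        self.coeffs = np.array(
            [r.consequent_coeffs for r in rules], dtype=float
        ).reshape(R, D)
        self.biases = np.array([r.consequent_bias for r in rules], dtype=float)

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    @classmethod
    def from_arrays(
        cls,
        centers: np.ndarray,
        widths: np.ndarray,
        coeffs: np.ndarray,
        biases: np.ndarray,
        partition_scheme: str = "scatter",
        sigma_min: float = SIGMA_MIN_DEFAULT,
    ) -> "AnfisModel":
        centers = np.asarray(centers, dtype=float)
        R, D = centers.shape
        rules = [
            FuzzyRule(
                antecedent=tuple(
                    GaussianMF(float(centers[i, d]), float(widths[i][d]))
                    for d in range(D)
                ),
                consequent_coeffs=tuple(float(c) for c in np.asarray(coeffs)[i]),
                consequent_bias=float(np.asarray(biases)[i]),
            )
            for i in range(R)
        ]
        return cls(D, rules, partition_scheme=partition_scheme, sigma_min=sigma_min)

    # -- batch evaluation ------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Model output for each row of ``X`` (shape ``(n, n_inputs)``)."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_inputs:
            raise ShapeError(
                f"expected {self.n_inputs} columns, got {X.shape[1]}"
            )
        d = X[:, None, :] - self.centers[None, :, :]
        mu = np.exp(-(d * d) / (2.0 * self.widths[None, :, :] ** 2))
        w = mu.prod(axis=2)  # (n, R)
        total = w.sum(axis=1, keepdims=True)
        wbar = np.where(total > 0, w / np.where(total == 0, 1.0, total),
                        1.0 / self.n_rules)
        f = X @ self.coeffs.T + self.biases[None, :]
        return (wbar * f).sum(axis=1)


def firing_weights(x: Sequence[float], model: AnfisModel) -> np.ndarray:
    """Rule firing strengths: per-rule product of antecedent memberships."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_inputs:
        raise ShapeError(
            f"input has {x.shape[0]} entries, model has {model.n_inputs} inputs"
        )
    d = x[None, :] - model.centers
    mu = np.exp(-(d * d) / (2.0 * model.widths**2))
    return mu.prod(axis=1)


def normalize_weights(w: Sequence[float]) -> np.ndarray:
    """Rescale nonnegative firing strengths to sum to one.

    A zero total firing strength returns the uniform vector ``1/R`` so that
    downstream objectives stay finite everywhere in the search box.
    """
    w = np.asarray(w, dtype=float).ravel()
    if np.any(w < 0):
        raise InvalidParameterError("firing weights must be nonnegative")
    total = w.sum()
    if total == 0:
        return np.full(w.shape, 1.0 / w.size)
    return w / total


def rule_output(x: Sequence[float], rule: FuzzyRule) -> float:
    """First-order consequent ``f = sum_d p_d x_d + r`` for one rule."""
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != len(rule.consequent_coeffs):
        raise ShapeError(
            f"input has {x.shape[0]} entries, rule expects "
            f"{len(rule.consequent_coeffs)}"
        )
    return float(np.dot(rule.consequent_coeffs, x) + rule.consequent_bias)


def evaluate(x: Sequence[float], model: AnfisModel) -> float:
    """Single-vector model output: the firing-weighted combination of the
    rule consequents (a convex combination, hence bounded by their span)."""
    w = firing_weights(x, model)
    wbar = normalize_weights(w)
    f = np.array([rule_output(x, r) for r in model.rules])
    return float(np.dot(wbar, f))


def evaluate_layers(x: Sequence[float], model: AnfisModel) -> dict:
    """Stepwise five-layer evaluation, returned layer by layer.

    Useful for inspection and as an independent check that the layered
    network and the closed-form weighted sum agree.  Keys: ``O1`` (per-rule,
    per-input membership degrees), ``O2`` (firing strengths), ``O3``
    (normalized strengths), ``O4`` (weighted rule outputs), ``O5`` (scalar
    model output).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != model.n_inputs:
        raise ShapeError("dimension mismatch")
    O1 = np.array(
        [[membership(x[d], mf, model.sigma_min)
          for d, mf in enumerate(r.antecedent)]
         for r in model.rules]
    )
    O2 = O1.prod(axis=1)
    O3 = normalize_weights(O2)
    f = np.array([rule_output(x, r) for r in model.rules])
    O4 = O3 * f
    O5 = float(O4.sum())
    return {"O1": O1, "O2": O2, "O3": O3, "O4": O4, "O5": O5}


# -- builders ------------------------------------------------------------


def scatter_model(
    n_inputs: int,
    n_rules: int = 4,
    center: float = 0.5,
    width: float = 0.25,
    sigma_min: float = SIGMA_MIN_DEFAULT,
) -> AnfisModel:
    """Scatter-partition model with every antecedent initialized at the
    shared ``(center, width)`` pair and zero consequents."""
    centers = np.full((n_rules, n_inputs), float(center))
    widths = np.full((n_rules, n_inputs), float(width))
    coeffs = np.zeros((n_rules, n_inputs))
    biases = np.zeros(n_rules)
    return AnfisModel.from_arrays(
        centers, widths, coeffs, biases, "scatter", sigma_min
    )


def grid_model(
    n_inputs: int,
    m_per_input: int = 2,
    sigma_min: float = SIGMA_MIN_DEFAULT,
) -> AnfisModel:
    """Grid-partition model: ``m_per_input`` evenly spaced Gaussians per
    input on [0, 1], one rule per point of the ``m^D`` product grid."""
    centers_1d = np.linspace(0.0, 1.0, m_per_input)
    width = max(1.0 / (2 * m_per_input), sigma_min)
    rules = []
    for combo in _iterproduct(range(m_per_input), repeat=n_inputs):
        ant = tuple(GaussianMF(float(centers_1d[j]), width) for j in combo)
        rules.append(
            FuzzyRule(ant, tuple(0.0 for _ in range(n_inputs)), 0.0)
        )
    return AnfisModel(n_inputs, rules, "grid", sigma_min)


# -- serialization -------------------------------------------------------


def model_to_dict(model: AnfisModel) -> dict:
    return {
        "n_inputs": model.n_inputs,
        "partition_scheme": model.partition_scheme,
        "sigma_min": model.sigma_min,
        "rules": [
            {
                "centers": [mf.center for mf in r.antecedent],
                "widths": [mf.width for mf in r.antecedent],
                "coeffs": list(r.consequent_coeffs),
                "bias": r.consequent_bias,
            }
            for r in model.rules
        ],
    }


def model_from_dict(payload: dict) -> AnfisModel:
    rules = [
        FuzzyRule(
            antecedent=tuple(
                GaussianMF(c, w) for c, w in zip(r["centers"], r["widths"])
            ),
            consequent_coeffs=tuple(r["coeffs"]),
            consequent_bias=r["bias"],
        )
        for r in payload["rules"]
    ]
    return AnfisModel(
        payload["n_inputs"],
        rules,
        partition_scheme=payload["partition_scheme"],
        sigma_min=payload.get("sigma_min", SIGMA_MIN_DEFAULT),
    )


def save_model(model: AnfisModel, path: str | Path) -> None:
    """Write the model to a JSON text file; round-trips all parameters
    exactly (JSON float repr preserves IEEE doubles)."""
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model(path: str | Path) -> AnfisModel:
    return model_from_dict(json.loads(Path(path).read_text()))
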