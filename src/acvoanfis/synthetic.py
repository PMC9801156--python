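"""Synthetic agro-data generator.

Emulates the feature table the estimator expects — irrigation level I,
mean temperature T, mean relative humidity RHavg, sunshine hours Rn,
minimum wind speed Umin, crop variety V and effective rainfall Pe — plus
``yield`` and ``WP`` targets driven by a known smooth response with
additive Gaussian noise.  Feature ranges are plausible for a hot semi-arid
date-growing climate but are synthetic config defaults, not measurements.

Two ground-truth responses are available:

* ``"analytic"`` — a smooth deficit-response curve over {I, V, Pe} that
  peaks at the deficit irrigation level I = 0.75, so mild deficit beats
  over-irrigation by construction;
* ``"planted"`` — a fixed scatter-partition TSK model over the
  range-normalized {I, V, Pe}, enabling parameter-recovery experiments in
  which the generating model is known exactly.

WP is yield over a seasonal applied-water proxy proportional to the
irrigation level (about 10,040 m^3/ha at I = 1, matching a full-requirement
drip season).  Everything is a pure function of the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anfis import AnfisModel

FEATURE_COLUMNS = ("I", "T", "RHavg", "Rn", "Umin", "V", "Pe")
TARGET_COLUMNS = ("yield", "WP")

#: Seasonal applied water (m^3/ha) at full requirement (I = 1); the water
#: proxy for WP is this volume scaled by the irrigation level.
FULL_REQUIREMENT_M3_PER_HA = 10040.0

_YIELD_BASE = 5500.0   # kg/ha at normalized response 0
_YIELD_SPAN = 3000.0   # kg/ha per unit of normalized response


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings.

    ``noise_sd`` is the standard deviation of the additive noise on the
    normalized (0-1) response scale.  ``response`` selects the ground
    truth; ``planted`` requires ``planted`` to hold the generating model.
    ``corr_t_rh`` in [-1, 0] couples temperature and relative humidity
    through a Gaussian copula (hot days drier); 0 leaves all features
    independent.
    """

    n_rows: int = 300
    rng_seed: int = 0
    noise_sd: float = 0.02
    response: str = "analytic"
    planted: AnfisModel | None = None
    corr_t_rh: float = 0.0
    t_range: tuple[float, float] = (10.0, 45.0)
    rh_range: tuple[float, float] = (15.0, 85.0)
    rn_range: tuple[float, float] = (6.0, 12.0)
    umin_range: tuple[float, float] = (0.0, 4.0)
    pe_range: tuple[float, float] = (0.0, 90.0)
    i_levels: tuple[float, ...] = (0.75, 1.0, 1.25)
    v_levels: tuple[float, ...] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.n_rows < 0:
            raise ValueError("n_rows must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        for name in ("t_range", "rh_range", "rn_range", "umin_range", "pe_range"):
            lo, hi = getattr(self, name)
            if lo >= hi:
                raise ValueError(f"{name} must be a nonempty interval")
        if not (-1.0 <= self.corr_t_rh <= 0.0):
            raise ValueError("corr_t_rh must lie in [-1, 0]")
        if self.response not in ("analytic", "planted"):
            raise ValueError(f"unknown response {self.response!r}")


def planted_model(seed: int = 0) -> AnfisModel:
    """A deterministic 2-rule, 3-input scatter TSK model over the
    range-normalized {I, V, Pe}.

    Parameters are drawn (reproducibly per seed) from narrow documented
    ranges — centers in [0.25, 0.75], widths in [0.35, 0.6], coefficients
    in [0.05, 0.25], biases in [0.05, 0.15] — so the encoded vector lies
    strictly inside the trainer's search box and the response surface is
    smooth, positive and bounded by 1.
    """
    rng = np.random.default_rng(int(seed))
    R, D = 2, 3
    centers = rng.uniform(0.25, 0.75, size=(R, D))
    widths = rng.uniform(0.35, 0.6, size=(R, D))
    coeffs = rng.uniform(0.05, 0.25, size=(R, D))
    biases = rng.uniform(0.05, 0.15, size=R)
    return AnfisModel.from_arrays(centers, widths, coeffs, biases, "scatter")


def range_normalize(df: pd.DataFrame, config: SyntheticConfig) -> pd.DataFrame:
    """Map {I, V, Pe} onto [0, 1] with the generator's fixed declared
    ranges (not empirical min/max): I levels to equally spaced points,
    V as is, Pe by its range."""
    i_lo, i_hi = min(config.i_levels), max(config.i_levels)
    pe_lo, pe_hi = config.pe_range
    return pd.DataFrame(
        {
            "I": (df["I"] - i_lo) / (i_hi - i_lo),
            "V": df["V"].astype(float),
            "Pe": (df["Pe"] - pe_lo) / (pe_hi - pe_lo),
        },
        index=df.index,
    )


def analytic_response(df: pd.DataFrame, config: SyntheticConfig) -> np.ndarray:
    """Smooth deficit-response surface on the normalized 0-1 scale.

    A concave quadratic in the irrigation level peaking at I = 0.75 (mild
    deficit maximizes yield), plus additive variety and effective-rainfall
    effects; depends on {I, V, Pe} only.
    """
    I = df["I"].to_numpy(dtype=float)
    V = df["V"].to_numpy(dtype=float)
    Pe = df["Pe"].to_numpy(dtype=float)
    pe_lo, pe_hi = config.pe_range
    g = 1.0 - 1.2 * (I - 0.75) ** 2
    return 0.15 + 0.35 * g + 0.12 * V + 0.25 * (Pe - pe_lo) / (pe_hi - pe_lo)


def planted_response(df: pd.DataFrame, model: AnfisModel,
                     config: SyntheticConfig) -> np.ndarray:
    """Noise-free planted-model response on range-normalized {I, V, Pe}."""
    return model.predict(range_normalize(df, config).to_numpy())


def generate(config: SyntheticConfig) -> pd.DataFrame:
    """Draw a feature table with ``yield`` and ``WP`` columns.

    Features are sampled independently within their ranges (optionally with
    a negative T-RHavg coupling); the response is evaluated on the relevant
    features, noise is added on the normalized scale, and yield/WP are
    expressed in kg/ha and kg/m^3.
    """
    rng = np.random.default_rng(config.rng_seed)
    n = config.n_rows
    I = rng.choice(config.i_levels, size=n)
    V = rng.choice(config.v_levels, size=n)
    if config.corr_t_rh < 0.0:
        # Gaussian copula: correlated standard normals mapped through their
        # own CDF back to uniforms before scaling to the feature ranges.
        from math import erf

        z1 = rng.standard_normal(n)
        z2 = config.corr_t_rh * z1 + np.sqrt(
            1 - config.corr_t_rh**2
        ) * rng.standard_normal(n)
        ndtr = np.vectorize(lambda z: 0.5 * (1 + erf(z / np.sqrt(2.0))))
        u_t, u_rh = ndtr(z1), ndtr(z2)
    else:
        u_t = rng.uniform(size=n)
        u_rh = rng.uniform(size=n)
    T = config.t_range[0] + u_t * (config.t_range[1] - config.t_range[0])
    RH = config.rh_range[0] + u_rh * (config.rh_range[1] - config.rh_range[0])
    Rn = rng.uniform(*config.rn_range, size=n)
    Umin = rng.uniform(*config.umin_range, size=n)
    Pe = rng.uniform(*config.pe_range, size=n)
    df = pd.DataFrame(
        {"I": I, "T": T, "RHavg": RH, "Rn": Rn, "Umin": Umin, "V": V, "Pe": Pe}
    )
    if n == 0:
        df["yield"] = pd.Series(dtype=float)
        df["WP"] = pd.Series(dtype=float)
        return df
    if config.response == "planted":
        model = config.planted if config.planted is not None else planted_model()
        y01 = planted_response(df, model, config)
    else:
        y01 = analytic_response(df, config)
    y01 = y01 + rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd else y01
    yield_kg = _YIELD_BASE + _YIELD_SPAN * y01
    water_m3 = FULL_REQUIREMENT_M3_PER_HA * df["I"].to_numpy(dtype=float)
    df["yield"] = yield_kg
    df["WP"] = yield_kg / water_m3
    return df
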