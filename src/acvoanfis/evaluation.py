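"""Feature-combination models and the model-scan harness.

Eight candidate predictor subsets are scanned: phi1 uses all seven factors
(irrigation level I, mean temperature T, mean relative humidity RHavg,
sunshine hours Rn, minimum wind speed Umin, crop variety V and effective
rainfall Pe); phi2..phi7 each drop exactly one of the six non-irrigation
factors; phi8 keeps only {I, V, Pe}.  Irrigation level is present in every
subset.  The scan trains one model per subset per seed and tabulates
train/test RMSE, delta% and AICc.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace
from typing import Iterable, Sequence

import pandas as pd

from . import acvo
from .metrics import MetricsReport, aicc, delta_pct, metrics_report, rmse  # noqa: F401
from .training import AnfisTemplate, SchemaError, TrainingRun, train

ALL_FACTORS = ("I", "T", "RHavg", "Rn", "Umin", "V", "Pe")


@dataclass(frozen=True)
class FeatureModel:
    """A named subset of the seven candidate predictors."""

    name: str
    columns: tuple[str, ...]

    def __post_init__(self) -> None:
        unknown = [c for c in self.columns if c not in ALL_FACTORS]
        if unknown:
            raise SchemaError(f"unknown factor(s): {', '.join(unknown)}")


def _drop(factor: str) -> tuple[str, ...]:
    return tuple(c for c in ALL_FACTORS if c != factor)


FEATURE_MODELS: dict[str, FeatureModel] = {
    "phi1": FeatureModel("phi1", ALL_FACTORS),
    "phi2": FeatureModel("phi2", _drop("T")),
    "phi3": FeatureModel("phi3", _drop("RHavg")),
    "phi4": FeatureModel("phi4", _drop("Rn")),
    "phi5": FeatureModel("phi5", _drop("Umin")),
    "phi6": FeatureModel("phi6", _drop("V")),
    "phi7": FeatureModel("phi7", _drop("Pe")),
    "phi8": FeatureModel("phi8", ("I", "V", "Pe")),
}


def resolve_feature_model(spec) -> FeatureModel:
    """Accept a FeatureModel, a registry name, or an explicit column list."""
    if isinstance(spec, FeatureModel):
        return spec
    if isinstance(spec, str):
        if spec not in FEATURE_MODELS:
            raise SchemaError(
                f"unknown feature model {spec!r}; "
                f"known: {', '.join(FEATURE_MODELS)}"
            )
        return FEATURE_MODELS[spec]
    return FeatureModel("custom", tuple(spec))


SCAN_COLUMNS = [
    "model", "split", "rmse", "delta_pct", "aicc", "c", "sigma", "seed"
]


def scan_models(
    dataset: pd.DataFrame,
    acvo_config: acvo.AcvoConfig,
    anfis_template: AnfisTemplate,
    seeds: Sequence[int],
    models: Iterable[str] | None = None,
    target: str = "yield",
) -> pd.DataFrame:
    """Train every feature model for every seed; return a tidy table.

    The template's rule count, partition scheme and shared initial (c,
    sigma) antecedent pair are reused for every subset, with the input
    dimension adjusted per model.  Output columns: model, split
    (train/test), rmse, delta_pct, aicc, c, sigma, seed — two rows per
    (model, seed).
    """
    names = list(models) if models is not None else list(FEATURE_MODELS)
    rows = []
    for seed in seeds:
        config = _dc_replace(acvo_config, rng_seed=int(seed))
        for name in names:
            fm = resolve_feature_model(name)
            template = _dc_replace(anfis_template, n_inputs=len(fm.columns))
            run = train(
                dataset,
                fm.columns,
                config,
                template=template,
                target=target,
                split_seed=int(seed),
            )
            for split_name, m in (
                ("train", run.metrics_train),
                ("test", run.metrics_test),
            ):
                rows.append(
                    {
                        "model": fm.name,
                        "split": split_name,
                        "rmse": m.rmse,
                        "delta_pct": m.delta_pct,
                        "aicc": m.aicc,
                        "c": template.init_center,
                        "sigma": template.init_width,
                        "seed": int(seed),
                    }
                )
    return pd.DataFrame(rows, columns=SCAN_COLUMNS)
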