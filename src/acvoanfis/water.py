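"""Crop water-productivity and applied-water accounting.

Water productivity is economical yield over water consumed, WP = Y / ET
(kg/m^3 when Y is kg/ha and ET is m^3/ha).  Evapotranspiration is bookkept
from irrigation, wetted-area/precipitation, deep percolation, runoff and
soil-moisture change; a simplified form keeps only irrigation and storage
change.  The module also ships, as plain fixtures, the monthly applied-water
ledger and per-treatment summaries of a three-year subsurface-drip date-palm
trial with irrigation at 125% (T1), 100% (T2) and 75% (T3) of crop water
requirement, and reproduces the treatment-comparison arithmetic those tables
support.

Fixture values are stored exactly as printed in the source tables, including
their internal rounding slack; consistency checks therefore use tolerances
and the report surfaces residuals instead of silently correcting them.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class WaterAccountingError(ValueError):
    """Invalid water-balance or ledger input."""


MONTHS = (
    "January", "February", "March", "April", "May", "June",
    "July", "August", "September", "October", "November", "December",
)

#: Months in which the drip system runs; other months are irrigation-free.
IRRIGATION_MONTHS = ("April", "May", "June", "July", "August", "September")

#: Date-palm crop coefficients over the irrigation season (documentation
#: fixture; no reference-ET computation is performed here).
CROP_COEFFICIENTS = {
    "April": 0.91, "May": 0.94, "June": 0.97,
    "July": 1.00, "August": 1.00, "September": 1.00,
}

# Monthly applied-water ledger, values as printed:
# month, Pe (mm), irrigation T1/T2/T3 (m3/ha), totals T1/T2/T3 (m3/ha).
_LEDGER_CSV = """\
month,Pe,T1,T2,T3,Total_T1,Total_T2,Total_T3
January,86.60,0,0,0,866.50,866.50,866.50
February,12.00,0,0,0,119.60,119.60,119.60
March,33.00,0,0,0,330.10,330.10,330.10
April,24.80,800.60,640.40,480.30,1048.80,888.70,728.60
May,0.20,1959.90,1567.90,1175.90,1961.60,1569.60,1177.60
June,0.00,2663.40,2130.70,1598.00,2663.40,2130.70,1598.00
July,1.00,2855.10,2284.10,1713.10,2865.10,2294.10,1723.00
August,0.70,2519.00,2015.20,1511.40,2526.30,2022.50,1518.70
September,4.30,1750.10,1400.10,1050.10,1793.20,1443.10,1093.10
October,5.00,0,0,0,49.60,49.60,49.60
November,55.10,0,0,0,551.30,551.30,551.30
December,85.00,0,0,0,850.20,850.20,850.20
"""

# Per-treatment means: fruit weight (g), flesh/kernel ratio, strings per
# cluster, fruits per cluster, yield (kg/ha), WP (kg/m3), as printed.
_SUMMARY_CSV = """\
treatment,Fw,RFF,NS,NF,yield,WP
T3,7.80,8.10,67.80,1757.80,7288.30,0.698
T2,7.70,7.60,69.70,1990.60,7192.70,0.555
T1,7.40,8.20,67.20,1824.90,7003.20,0.452
"""

TREATMENTS = ("T1", "T2", "T3")


@dataclass(frozen=True)
class WaterBalance:
    """Terms of the ET bookkeeping, each with fixed units.

    ``irrigation`` (mm), ``wetted_area_pct`` (%, carried as printed in the
    source ledger's balance equation), ``deep_percolation`` (mm),
    ``runoff`` (mm) and ``storage_change`` (mm, signed: positive means the
    soil gained moisture).
    """

    irrigation: float
    wetted_area_pct: float | None = None
    deep_percolation: float | None = None
    runoff: float | None = None
    storage_change: float = 0.0

    def __post_init__(self) -> None:
        for name in ("irrigation", "wetted_area_pct", "deep_percolation", "runoff"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise WaterAccountingError(f"{name} must be nonnegative, got {v}")


@dataclass(frozen=True)
class WaterLedger:
    """Twelve monthly rows of effective rainfall, irrigation volumes per
    treatment and printed applied-water totals."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"month", "Pe", "T1", "T2", "T3",
                    "Total_T1", "Total_T2", "Total_T3"}
        missing = required - set(self.data.columns)
        if missing:
            raise WaterAccountingError(
                f"ledger missing column(s): {', '.join(sorted(missing))}"
            )
        months = set(self.data["month"])
        absent = [m for m in MONTHS if m not in months]
        if absent:
            raise WaterAccountingError(
                f"ledger missing month(s): {', '.join(absent)}"
            )

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "WaterLedger":
        return cls(pd.read_csv(path))


@dataclass(frozen=True)
class TreatmentSummary:
    """Per-treatment trait means; the four quantitative traits are opaque
    fixture fields (fruit weight, flesh/kernel ratio, strings and fruits
    per cluster)."""

    treatment: str
    yield_kg: float
    wp: float
    fw: float
    rff: float
    ns: float
    nf: float

    def __post_init__(self) -> None:
        if self.yield_kg <= 0 or self.wp <= 0:
            raise WaterAccountingError("yield and WP must be positive")


def applied_water_ledger() -> WaterLedger:
    """The packaged three-year-average monthly applied-water ledger."""
    return WaterLedger(pd.read_csv(io.StringIO(_LEDGER_CSV)))


def treatment_summaries() -> list[TreatmentSummary]:
    """The packaged per-treatment yield/WP/trait summaries."""
    df = pd.read_csv(io.StringIO(_SUMMARY_CSV))
    return [
        TreatmentSummary(
            treatment=row["treatment"], yield_kg=row["yield"], wp=row["WP"],
            fw=row["Fw"], rff=row["RFF"], ns=row["NS"], nf=row["NF"],
        )
        for _, row in df.iterrows()
    ]


def summaries_from_csv(path: str | Path) -> list[TreatmentSummary]:
    df = pd.read_csv(path)
    return [
        TreatmentSummary(
            treatment=row["treatment"], yield_kg=row["yield"], wp=row["WP"],
            fw=row["Fw"], rff=row["RFF"], ns=row["NS"], nf=row["NF"],
        )
        for _, row in df.iterrows()
    ]


# -- the accounting operations ------------------------------------------


def water_productivity(yield_kg_per_ha: float, et_m3_per_ha: float) -> float:
    """WP = Y / ET (kg/m^3)."""
    if et_m3_per_ha <= 0:
        raise WaterAccountingError(
            f"ET must be positive, got {et_m3_per_ha}"
        )
    return yield_kg_per_ha / et_m3_per_ha


def evapotranspiration(balance: WaterBalance, simplified: bool = False) -> float:
    """ET (mm) from the water balance.

    The simplified form is ET = I - dS; the full form additionally adds the
    wetted-area/precipitation, deep-percolation and runoff terms and
    requires them to be present.  The storage-change sign convention is
    fixed: dS is a storage *gain*, so depletion (dS < 0) adds to ET.
    """
    et = balance.irrigation - balance.storage_change
    if simplified:
        return et
    parts = {
        "wetted_area_pct": balance.wetted_area_pct,
        "deep_percolation": balance.deep_percolation,
        "runoff": balance.runoff,
    }
    missing = [k for k, v in parts.items() if v is None]
    if missing:
        raise WaterAccountingError(
            f"full balance missing term(s): {', '.join(missing)}"
        )
    return et + sum(parts.values())


def seasonal_applied_water(
    ledger: WaterLedger, treatment: str, include_rainfall: bool = False
) -> float:
    """Seasonal water for one treatment (m^3/ha).

    Without rainfall: the April-September irrigation volumes.  With
    rainfall: the printed year-round Total column (irrigation + 10*Pe).
    """
    if treatment not in TREATMENTS:
        raise WaterAccountingError(f"unknown treatment {treatment!r}")
    df = ledger.data
    if include_rainfall:
        return float(df[f"Total_{treatment}"].sum())
    season = df[df["month"].isin(IRRIGATION_MONTHS)]
    return float(season[treatment].sum())


def depth_mm(volume_m3_per_ha: float) -> float:
    """Convert a per-hectare volume to a depth: 1 mm over 1 ha = 10 m^3."""
    if volume_m3_per_ha < 0:
        raise WaterAccountingError("volume must be nonnegative")
    return volume_m3_per_ha / 10.0


def ledger_consistency(ledger: WaterLedger) -> pd.DataFrame:
    """Residual Total - (irrigation + 10*Pe) per month and treatment.

    The packaged fixture keeps the printed values verbatim, so residuals up
    to about +-1 m^3/ha of rounding slack are expected and surfaced here
    rather than corrected.
    """
    df = ledger.data
    out = {"month": df["month"]}
    for t in TREATMENTS:
        out[t] = df[f"Total_{t}"] - (df[t] + 10.0 * df["Pe"])
    return pd.DataFrame(out)


@dataclass(frozen=True)
class TreatmentComparison:
    treatment: str
    reference: str
    yield_advantage_pct: float  # (Y_ref - Y_t) / Y_ref * 100, 2 decimals
    wp_difference: float        # WP_ref - WP_t
    wp_ratio: float             # WP_ref / WP_t


def treatment_comparison(
    summaries: Sequence[TreatmentSummary], reference: str
) -> list[TreatmentComparison]:
    """Relative yield advantage and WP difference/ratio of the reference
    treatment against every other treatment."""
    names = [s.treatment for s in summaries]
    if len(set(names)) != len(names):
        raise WaterAccountingError("duplicate treatments in summaries")
    by_name = {s.treatment: s for s in summaries}
    if reference not in by_name:
        raise WaterAccountingError(f"reference treatment {reference!r} absent")
    ref = by_name[reference]
    out = []
    for s in summaries:
        if s.treatment == reference:
            continue
        out.append(
            TreatmentComparison(
                treatment=s.treatment,
                reference=reference,
                yield_advantage_pct=round(
                    (ref.yield_kg - s.yield_kg) / ref.yield_kg * 100.0, 2
                ),
                wp_difference=round(ref.wp - s.wp, 3),
                wp_ratio=round(ref.wp / s.wp, 3),
            )
        )
    return out


def water_report(
    ledger: WaterLedger | None = None,
    summaries: Sequence[TreatmentSummary] | None = None,
    reference: str = "T3",
) -> str:
    """Structured-text report: seasonal applied water per treatment, unit
    conversions, treatment comparisons and ledger residuals."""
    ledger = ledger if ledger is not None else applied_water_ledger()
    summaries = summaries if summaries is not None else treatment_summaries()
    lines = ["# Applied water (April-September irrigation, m3/ha)"]
    seasonal = {t: seasonal_applied_water(ledger, t) for t in TREATMENTS}
    for t in TREATMENTS:
        lines.append(f"{t}: {seasonal[t]:.2f} m3/ha = {depth_mm(seasonal[t]):.2f} mm")
    lines.append("")
    lines.append(f"# Savings of {reference} (m3/ha)")
    for t in TREATMENTS:
        if t != reference:
            lines.append(f"vs {t}: {seasonal[t] - seasonal[reference]:.2f}")
    lines.append("")
    lines.append(f"# Yield and WP advantage of {reference}")
    for c in treatment_comparison(summaries, reference):
        lines.append(
            f"vs {c.treatment}: yield +{c.yield_advantage_pct:.2f}%, "
            f"WP +{c.wp_difference:.3f} kg/m3 (ratio {c.wp_ratio:.3f})"
        )
    lines.append("")
    lines.append("# Ledger residuals Total - (irrigation + 10*Pe), m3/ha")
    res = ledger_consistency(ledger)
    for _, row in res.iterrows():
        lines.append(
            f"{row['month']}: "
            + " ".join(f"{t}={row[t]:+.2f}" for t in TREATMENTS)
        )
    return "\n".join(lines) + "\n"
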