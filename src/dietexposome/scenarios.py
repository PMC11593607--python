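"""Exposure scenarios: daily contaminant burdens from diet x concentration.

A percentile scenario stacks the chosen concentration percentile of *every*
food x contaminant simultaneously — a comonotonic, deliberately
conservative co-exposure construction.  The burden of contaminant ``c`` is

    burden(c) = sum over foods of conc(food, c, percentile) [µg/kg]
                x mass(food) [g/day] / 1000

in µg/day.  Burdens are partitioned into chemical-class totals, a global
total and a per-kilogram-of-diet normalisation, plus the regulatory
indicator sums PAH4, PAH8 and beta-carbolines (harman + norharman).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .diets import DietModel, total_mass
from .estimation import ConcentrationEstimate
from .vocab import BETA_CARBOLINES, CHEM_CLASSES, PAH4, PAH8

PERCENTILES = ("p25", "p50", "p75")

SUMMARY_COLUMNS = [
    "diet",
    "percentile",
    "heavy_metals",
    "haas",
    "mycotoxins",
    "pesticides",
    "pahs",
    "global_ug",
    "global_ug_per_kg",
]

_CLASS_TO_SUMMARY = {
    "heavy_metal": "heavy_metals",
    "HAA": "haas",
    "mycotoxin": "mycotoxins",
    "pesticide": "pesticides",
    "PAH": "pahs",
}


@dataclass(frozen=True)
class ExposureScenario:
    diet_name: str
    percentile: str
    burdens: dict[str, float]  # contaminant -> µg/day
    class_totals: dict[str, float]  # chem_class -> µg/day
    global_ug: float
    global_ug_per_kg: float


@dataclass(frozen=True)
class IndicatorSet:
    pah4: float
    pah8: float
    beta_carbolines: float


def contaminant_burden(
    diet: DietModel,
    estimates: Sequence[ConcentrationEstimate],
    percentile: str,
) -> dict[str, float]:
    """Per-contaminant daily burden (µg/day) at one percentile."""
    if percentile not in PERCENTILES:
        raise ValueError(f"percentile must be one of {PERCENTILES}, got {percentile!r}")
    burdens: dict[str, float] = {}
    for est in estimates:
        mass_g = diet.mass_of(est.food)
        if mass_g == 0.0:
            continue
        contrib = est.percentile(percentile) * mass_g / 1000.0
        burdens[est.contaminant] = burdens.get(est.contaminant, 0.0) + contrib
    return burdens


def build_scenario(
    diet: DietModel,
    estimates: Sequence[ConcentrationEstimate],
    percentile: str,
) -> ExposureScenario:
    """Assemble burdens, class totals and global totals for one percentile.

    ``global_ug`` equals both the sum of burdens and the sum of class
    totals by construction; ``global_ug_per_kg`` divides by the diet's
    total mass (error on a zero-mass diet).
    """
    burdens = contaminant_burden(diet, estimates, percentile)
    classes = {e.contaminant: e.chem_class for e in estimates}
    class_totals: dict[str, float] = {}
    for cont, b in burdens.items():
        cls = classes[cont]
        class_totals[cls] = class_totals.get(cls, 0.0) + b
    global_ug = sum(burdens.values())
    mass_kg = total_mass(diet)
    if mass_kg <= 0:
        raise ValueError(f"diet {diet.name!r} has zero total mass; cannot normalise per kg")
    return ExposureScenario(
        diet_name=diet.name,
        percentile=percentile,
        burdens=burdens,
        class_totals=class_totals,
        global_ug=global_ug,
        global_ug_per_kg=global_ug / mass_kg,
    )


def indicator_sums(burdens: Mapping[str, float]) -> IndicatorSet:
    """PAH4, PAH8 and beta-carboline indicator sums (absent member = 0)."""
    return IndicatorSet(
        pah4=sum(burdens.get(m, 0.0) for m in PAH4),
        pah8=sum(burdens.get(m, 0.0) for m in PAH8),
        beta_carbolines=sum(burdens.get(m, 0.0) for m in BETA_CARBOLINES),
    )


def round_for_report(x: float) -> float:
    """Display rounding: 1 decimal >= 100 µg, 2 decimals 1-100, 3 below 1."""
    if abs(x) >= 100:
        return round(x, 1)
    if abs(x) >= 1:
        return round(x, 2)
    return round(x, 3)


def scenario_to_frame(scenario: ExposureScenario) -> pd.DataFrame:
    """Long-format per-contaminant burdens (full precision)."""
    classes_rows = []
    for cont, b in sorted(scenario.burdens.items()):
        classes_rows.append(
            {
                "diet": scenario.diet_name,
                "percentile": scenario.percentile,
                "contaminant": cont,
                "chem_class": _class_of(scenario, cont),
                "burden_ug_day": b,
            }
        )
    return pd.DataFrame(
        classes_rows,
        columns=["diet", "percentile", "contaminant", "chem_class", "burden_ug_day"],
    )


def _class_of(scenario: ExposureScenario, contaminant: str) -> str:
    # recover the class from the totals partition; scenario burdens are
    # built from estimates, so every contaminant has exactly one class
    from .vocab import contaminant_classes

    cls = contaminant_classes().get(contaminant)
    if cls is not None:
        return cls
    # aggregate labels (ENNs/EgTs/ATs) are mycotoxin sums
    return "mycotoxin" if contaminant in ("ENNs", "EgTs", "ATs") else "unknown"


def summary_frame(scenarios: Iterable[ExposureScenario], rounded: bool = False) -> pd.DataFrame:
    """One row per scenario mirroring the published per-class summary table."""
    rows = []
    for s in scenarios:
        row = {"diet": s.diet_name, "percentile": s.percentile}
        for cls in CHEM_CLASSES:
            val = s.class_totals.get(cls, 0.0)
            row[_CLASS_TO_SUMMARY[cls]] = round_for_report(val) if rounded else val
        row["global_ug"] = round_for_report(s.global_ug) if rounded else s.global_ug
        row["global_ug_per_kg"] = (
            round_for_report(s.global_ug_per_kg) if rounded else s.global_ug_per_kg
        )
        rows.append(row)
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
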