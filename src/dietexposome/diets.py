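"""Dietary models: daily food masses and energies, with reference ranges.

Two built-in models — omnivorous and vegetarian — follow the EAT-Lancet
reference diet: each lists representative foods with their daily mass
(g/day) and energy (kcal/day), constrained so that both deliver the same
total food mass (1580 g/day) and closely matched energy (~2.3 Mcal/day).
Food-group totals are validated against the reference-diet g/day ranges
with inclusive bounds (the models deliberately sit on some bounds, e.g.
600 g whole grains).

Printed-total caveat: in both packaged models the per-item kcal values sum
to one kcal above the published totals (2339 vs 2338 omnivorous, 2305 vs
2304 vegetarian) because the published subtotals were rounded; the fixtures
keep the per-item values and checks on total energy should allow ±1 kcal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable

import pandas as pd

#: EAT-Lancet reference ranges, g/day per food group.
REFERENCE_RANGES: dict[str, tuple[float, float]] = {
    "whole_grains": (200, 600),
    "tubers_starchy_vegetables": (0, 100),
    "vegetables": (200, 600),
    "fruits": (100, 300),
    "dairy_foods": (0, 500),
    "animal_protein_sources": (0, 211),
    "other_protein_sources": (25, 250),
    "added_fats": (20, 91.8),
    "added_sugars": (0, 31),
}


@dataclass(frozen=True)
class DietItem:
    food: str
    mass: float  # g/day
    energy: float  # kcal/day
    group: str | None = None

    def __post_init__(self):
        if self.mass < 0 or self.energy < 0:
            raise ValueError(f"{self.food}: mass and energy must be >= 0")


@dataclass(frozen=True)
class DietModel:
    name: str
    items: tuple[DietItem, ...]
    group_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_RANGES)
    )

    def __post_init__(self):
        foods = [i.food for i in self.items]
        if len(foods) != len(set(foods)):
            raise ValueError(f"diet {self.name!r}: duplicate foods")

    def mass_of(self, food: str) -> float:
        for i in self.items:
            if i.food == food:
                return i.mass
        return 0.0


def total_mass(diet: DietModel) -> float:
    """Total daily food mass in kg/day."""
    return sum(i.mass for i in diet.items) / 1000.0


def total_energy(diet: DietModel) -> float:
    """Total daily energy in kcal/day (sum of per-item values)."""
    return sum(i.energy for i in diet.items)


def validate_ranges(diet: DietModel) -> list[tuple[str, str]]:
    """Compare each food group's mass total to its reference range.

    Returns ``(group, status)`` pairs with status within/below/above;
    bounds are inclusive.  A food without a group assignment is an error.
    """
    totals: dict[str, float] = {}
    for item in diet.items:
        if item.group is None:
            raise ValueError(f"food {item.food!r} has no group assignment")
        totals[item.group] = totals.get(item.group, 0.0) + item.mass
    out = []
    for group, mass in totals.items():
        try:
            lo, hi = diet.group_ranges[group]
        except KeyError:
            raise ValueError(f"no reference range for group {group!r}") from None
        status = "below" if mass < lo else "above" if mass > hi else "within"
        out.append((group, status))
    return out


def load_diet(path, name: str) -> DietModel:
    """Read a diet CSV (``food,mass_g_day,energy_kcal_day,group``)."""
    df = pd.read_csv(path)
    items = tuple(
        DietItem(
            food=row.food,
            mass=float(row.mass_g_day),
            energy=float(row.energy_kcal_day),
            group=getattr(row, "group", None),
        )
        for row in df.itertuples(index=False)
    )
    return DietModel(name=name, items=items)


def _packaged(name: str) -> DietModel:
    with resources.files("dietexposome.data").joinpath(f"diet_{name}.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return load_diet(fh, name)


def omnivorous_diet() -> DietModel:
    """The built-in omnivorous model (1580 g/day, ~2338 kcal/day)."""
    return _packaged("omnivorous")


def vegetarian_diet() -> DietModel:
    """The built-in vegetarian model (1580 g/day, ~2304 kcal/day)."""
    return _packaged("vegetarian")


def concatenate(name: str, diets: Iterable[DietModel]) -> DietModel:
    """Merge diets by summing masses/energies of shared foods."""
    acc: dict[str, DietItem] = {}
    for diet in diets:
        for i in diet.items:
            if i.food in acc:
                prev = acc[i.food]
                acc[i.food] = DietItem(i.food, prev.mass + i.mass, prev.energy + i.energy, i.group)
            else:
                acc[i.food] = i
    return DietModel(name=name, items=tuple(acc.values()))
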