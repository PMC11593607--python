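"""Synthetic occurrence tables with the structure the pipeline assumes.

Study-level mean concentrations for each food x contaminant pair are drawn
from a lognormal — occurrence data are non-negative and right-skewed — with
a configurable geometric mean (GM) and geometric standard deviation (GSD).
Left-censoring is imposed by thresholding at quantiles of the generating
distribution, so the expected censored fraction is controlled exactly:
values below the LOQ-quantile threshold are censored, and within those,
values below the LOD-quantile threshold are reported as <LOD rather than
<LOQ.  Records are expressed in a mix of reporting units and a fraction of
cereal records is flagged dry-basis, exercising every harmonisation rule
downstream.  Generation is fully reproducible from the seed.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path
from statistics import NormalDist
from typing import Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .occurrence import (
    OccurrenceRecord,
    harmonised_value,
    parse_occurrence,
    write_occurrence,
)
from .vocab import CEREALS, contaminant_classes

_UNIT_TO_FACTOR = {
    "ug/kg": 1.0,
    "mg/kg": 1000.0,
    "ng/g": 1.0,
    "ug/g": 1000.0,
    "ng/kg": 0.001,
    "ug/100g": 10.0,
}

_DEFAULT_FOODS = ["rice", "wheat", "maize", "potato", "apple", "beef", "salmon"]
_DEFAULT_CONTAMINANTS = [
    "cadmium",
    "lead",
    "benzo[a]pyrene",
    "chrysene",
    "chlorpyrifos",
    "deoxynivalenol",
    "ochratoxin A",
    "harman",
]


class GeneratorConfig(BaseModel):
    """Knobs of the occurrence-table generator (validated)."""

    foods: list[str] = Field(default_factory=lambda: list(_DEFAULT_FOODS))
    contaminants: list[str] = Field(default_factory=lambda: list(_DEFAULT_CONTAMINANTS))
    gm_ug_kg: float = 10.0  # geometric mean of study-level means
    gsd: float = 2.0  # geometric standard deviation (>1)
    pair_params: dict[str, tuple[float, float]] = Field(default_factory=dict)
    studies_per_pair: tuple[int, int] = (3, 8)
    n_per_study: tuple[int, int] = (5, 50)
    censored_fraction_target: float = 0.2
    lod_quantile: Optional[float] = None  # default: half the target
    loq_quantile: Optional[float] = None  # default: the target
    unit_mix: dict[str, float] = Field(
        default_factory=lambda: {
            "ug/kg": 0.5,
            "mg/kg": 0.2,
            "ng/g": 0.15,
            "ug/g": 0.05,
            "ng/kg": 0.05,
            "ug/100g": 0.05,
        }
    )
    dry_fraction: float = 0.3  # fraction of cereal records on dry basis
    seed: int = 0

    @field_validator("gsd")
    @classmethod
    def _gsd_gt_one(cls, v: float) -> float:
        if v <= 1:
            raise ValueError("gsd: geometric SD must be > 1")
        return v

    @field_validator("gm_ug_kg")
    @classmethod
    def _gm_positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("gm_ug_kg: geometric mean must be > 0")
        return v

    @field_validator("censored_fraction_target", "dry_fraction")
    @classmethod
    def _fraction(cls, v: float, info) -> float:
        if not 0.0 <= v < 1.0:
            raise ValueError(f"{info.field_name}: fraction must be in [0, 1)")
        return v

    @field_validator("studies_per_pair", "n_per_study")
    @classmethod
    def _range_ok(cls, v: tuple[int, int], info) -> tuple[int, int]:
        lo, hi = v
        if lo < 1 or hi < lo:
            raise ValueError(f"{info.field_name}: need 1 <= lo <= hi, got {v}")
        return v

    @field_validator("unit_mix")
    @classmethod
    def _units_known(cls, v: dict[str, float]) -> dict[str, float]:
        unknown = set(v) - set(_UNIT_TO_FACTOR)
        if unknown:
            raise ValueError(f"unit_mix: unknown units {sorted(unknown)}")
        if any(w < 0 for w in v.values()) or sum(v.values()) <= 0:
            raise ValueError("unit_mix: weights must be non-negative with positive sum")
        return v

    @model_validator(mode="after")
    def _quantiles(self) -> "GeneratorConfig":
        lod_q = self.lod_quantile
        loq_q = self.loq_quantile
        if lod_q is not None and not 0 <= lod_q < 1:
            raise ValueError("lod_quantile: must be in [0, 1)")
        if loq_q is not None and not 0 <= loq_q < 1:
            raise ValueError("loq_quantile: must be in [0, 1)")
        if lod_q is not None and loq_q is not None and lod_q > loq_q:
            raise ValueError("lod_quantile: must be <= loq_quantile")
        return self

    def resolved_quantiles(self) -> tuple[float, float]:
        loq_q = self.loq_quantile if self.loq_quantile is not None else self.censored_fraction_target
        lod_q = self.lod_quantile if self.lod_quantile is not None else loq_q / 2.0
        return lod_q, loq_q

    def pair(self, food: str, contaminant: str) -> tuple[float, float]:
        return self.pair_params.get(f"{food}/{contaminant}", (self.gm_ug_kg, self.gsd))


def _lognormal_quantile(gm: float, gsd: float, q: float) -> float:
    if q <= 0.0:
        return 0.0
    return gm * gsd ** NormalDist().inv_cdf(q)


def generate_occurrence(config: GeneratorConfig) -> list[OccurrenceRecord]:
    """Draw a fully reproducible occurrence table from ``config``."""
    rng = np.random.default_rng(config.seed)
    classes = contaminant_classes()
    lod_q, loq_q = config.resolved_quantiles()
    units = sorted(config.unit_mix)
    unit_p = np.array([config.unit_mix[u] for u in units], dtype=float)
    unit_p /= unit_p.sum()

    records: list[OccurrenceRecord] = []
    rid = 0
    for food in config.foods:
        for contaminant in config.contaminants:
            gm, gsd = config.pair(food, contaminant)
            lod = _lognormal_quantile(gm, gsd, lod_q)
            loq = _lognormal_quantile(gm, gsd, loq_q)
            n_studies = int(rng.integers(config.studies_per_pair[0], config.studies_per_pair[1] + 1))
            for s in range(n_studies):
                rid += 1
                true_value = gm * gsd ** rng.standard_normal()
                n = int(rng.integers(config.n_per_study[0], config.n_per_study[1] + 1))
                unit = units[int(rng.choice(len(units), p=unit_p))]
                factor = _UNIT_TO_FACTOR[unit]
                dry = food in CEREALS and rng.random() < config.dry_fraction
                if true_value < lod:
                    censor, value = "below_LOD", 0.0
                elif true_value < loq:
                    censor, value = "below_LOQ", 0.0
                else:
                    censor, value = "quantified", true_value / factor
                records.append(
                    OccurrenceRecord(
                        record_id=f"R{rid:05d}",
                        study_id=f"S-{food}-{contaminant}-{s + 1}",
                        food=food,
                        cooking_state="unspecified",
                        contaminant=contaminant,
                        chem_class=classes[contaminant],
                        stat_type="mean",
                        value=value,
                        unit=unit,
                        basis="dry" if dry else "wet",
                        n=n,
                        censor=censor,
                        lod=lod / factor if loq_q > 0 else None,
                        loq=loq / factor if loq_q > 0 else None,
                        sample_flag="normal",
                    )
                )
    return records


def _oracle_estimates(records: list[OccurrenceRecord]) -> pd.DataFrame:
    """Reference estimates via explicit weight expansion (numpy Hazen).

    Independent of the estimation module's closed-form percentile path:
    each record is literally repeated ``n`` times and summarised with
    :func:`numpy.quantile`.  Small tables only.
    """
    rows = []
    groups: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for r in records:
        groups.setdefault((r.food, r.contaminant), []).append(r)
    for (food, contaminant), recs in sorted(groups.items()):
        values = np.array([harmonised_value(r) for r in recs])
        weights = np.array([r.n if r.n is not None else 1 for r in recs])
        expanded = np.repeat(values, weights)
        rows.append(
            {
                "food": food,
                "contaminant": contaminant,
                "chem_class": recs[0].chem_class,
                "w_mean": float(np.average(values, weights=weights)),
                "p25": float(np.quantile(expanded, 0.25, method="hazen")),
                "p50": float(np.quantile(expanded, 0.50, method="hazen")),
                "p75": float(np.quantile(expanded, 0.75, method="hazen")),
                "n_records": len(recs),
                "total_weight": float(weights.sum()),
                "provenance": "direct",
            }
        )
    return pd.DataFrame(rows)


def generate_fixture_suite(out_dir, seed: int = 12345) -> list[Path]:
    """Write a small deterministic fixture set into ``out_dir``.

    Produces an occurrence table (synthetic), the two packaged diet models,
    the guidance-value registry, and an expected-estimates table computed
    with the expansion-oracle reference implementation.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = GeneratorConfig(
        foods=["rice", "wheat", "beef"],
        contaminants=["cadmium", "deoxynivalenol", "benzo[a]pyrene"],
        studies_per_pair=(3, 5),
        seed=seed,
    )
    records = generate_occurrence(config)
    occ_path = out / "occurrence_synthetic.csv"
    write_occurrence(records, occ_path)
    # round-trip through the CSV dialect so expectations match parsed data
    records = parse_occurrence(occ_path)
    est_path = out / "expected_estimates_oracle.csv"
    _oracle_estimates(records).to_csv(est_path, index=False)
    written = [occ_path, est_path]
    for fname in ("diet_omnivorous.csv", "diet_vegetarian.csv", "hbgv_registry.csv"):
        dest = out / fname
        with resources.files("dietexposome.data").joinpath(fname).open("rb") as src, open(
            dest, "wb"
        ) as dst:
            shutil.copyfileobj(src, dst)
        written.append(dest)
    return written
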