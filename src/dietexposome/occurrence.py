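"""Occurrence records: data model, CSV I/O, exclusion filters, harmonisation.

One :class:`OccurrenceRecord` is one study-level measurement of one
contaminant in one food — a reported mean or median concentration together
with the sample size behind it, the reporting unit, the wet/dry basis and
the left-censoring status (quantified, <LOD or <LOQ).

The harmonisation pipeline mirrors standard occurrence-data practice:

1. drop records unfit for dietary estimation (artificially spiked samples,
   feed samples, animal-model studies, min/max-only statistics, dry-basis
   records outside the cereal group);
2. substitute left-censored values by LOD/sqrt(2) or LOQ/sqrt(2);
3. convert every concentration to micrograms per kilogram of food.
"""

from __future__ import annotations

import enum
import math
from typing import Iterable, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .vocab import (
    CEREALS,
    VocabularyError,
    contaminant_classes,
    contaminant_vocabulary,
    food_vocabulary,
)

OCCURRENCE_COLUMNS = [
    "record_id",
    "study_id",
    "food",
    "cooking_state",
    "contaminant",
    "chem_class",
    "stat_type",
    "value",
    "unit",
    "basis",
    "n",
    "censor",
    "lod",
    "loq",
    "sample_flag",
]

#: multiplicative factor to µg/kg
_UNIT_FACTORS = {
    "ug/kg": 1.0,
    "mg/kg": 1000.0,
    "ng/g": 1.0,
    "ug/g": 1000.0,
    "ng/kg": 0.001,
    "ug/100g": 10.0,
}

# accept the micro sign and mu in unit strings
_UNIT_ALIASES = {"µg/kg": "ug/kg", "μg/kg": "ug/kg", "µg/g": "ug/g", "μg/g": "ug/g",
                 "µg/100g": "ug/100g", "μg/100g": "ug/100g"}


class CookingState(str, enum.Enum):
    raw = "raw"
    grilled = "grilled"
    fried = "fried"
    barbecued = "barbecued"
    oven_broiled = "oven_broiled"
    unspecified = "unspecified"


class StatType(str, enum.Enum):
    mean = "mean"
    median = "median"
    min_only = "min_only"
    max_only = "max_only"


class Censor(str, enum.Enum):
    quantified = "quantified"
    below_LOD = "below_LOD"
    below_LOQ = "below_LOQ"


class SampleFlag(str, enum.Enum):
    normal = "normal"
    artificial_contamination = "artificial_contamination"
    animal_feed = "animal_feed"
    animal_model = "animal_model"


class OccurrenceRecord(BaseModel):
    """A single curated concentration measurement."""

    model_config = ConfigDict(frozen=True)

    record_id: str
    study_id: str
    food: str
    cooking_state: CookingState = CookingState.unspecified
    contaminant: str
    chem_class: str
    stat_type: StatType
    value: float
    unit: str
    basis: str  # wet | dry
    n: Optional[int] = None
    censor: Censor = Censor.quantified
    lod: Optional[float] = None
    loq: Optional[float] = None
    sample_flag: SampleFlag = SampleFlag.normal

    @field_validator("value")
    @classmethod
    def _value_nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("concentration must be >= 0")
        return v

    @field_validator("unit")
    @classmethod
    def _unit_known(cls, v: str) -> str:
        u = _UNIT_ALIASES.get(v, v)
        if u not in _UNIT_FACTORS:
            raise ValueError(f"unknown unit: {v!r}")
        return u

    @field_validator("basis")
    @classmethod
    def _basis_known(cls, v: str) -> str:
        if v not in ("wet", "dry"):
            raise ValueError(f"basis must be 'wet' or 'dry', got {v!r}")
        return v

    @field_validator("n")
    @classmethod
    def _n_positive(cls, v: Optional[int]) -> Optional[int]:
        if v is not None and v < 1:
            raise ValueError("sample size n must be >= 1")
        return v

    @model_validator(mode="after")
    def _censor_thresholds(self) -> "OccurrenceRecord":
        if self.censor == Censor.below_LOD and self.lod is None:
            raise ValueError(f"record {self.record_id}: censor=below_LOD requires lod")
        if self.censor == Censor.below_LOQ and self.loq is None:
            raise ValueError(f"record {self.record_id}: censor=below_LOQ requires loq")
        if self.lod is not None and self.loq is not None and self.lod > self.loq:
            raise ValueError(f"record {self.record_id}: lod > loq")
        return self


class ExclusionReason(str, enum.Enum):
    artificial = "artificial"
    feed = "feed"
    animal_model = "animal_model"
    minmax_only = "minmax_only"
    dry_basis_noncereal = "dry_basis_noncereal"


class ExclusionReport(BaseModel):
    kept: list[str]
    dropped: list[tuple[str, ExclusionReason]]

    def kept_records(self, records: Iterable[OccurrenceRecord]) -> list[OccurrenceRecord]:
        keep = set(self.kept)
        return [r for r in records if r.record_id in keep]


class ParseError(ValueError):
    """CSV row failed validation; message names the row and column."""


def _opt_float(raw: str) -> Optional[float]:
    return None if raw == "" else float(raw)


def parse_occurrence(path, strict: bool = False) -> list[OccurrenceRecord]:
    """Read an occurrence CSV into validated records.

    Food and contaminant names are resolved against the controlled
    vocabularies (alias- and case-insensitive unless ``strict``).  Empty
    strings denote absent optional fields.  Errors name the offending
    1-based data row.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"missing columns: {missing}")
    foods = food_vocabulary()
    contaminants = contaminant_vocabulary()
    classes = contaminant_classes()
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            food = foods.resolve(row.food, strict=strict)
            contaminant = contaminants.resolve(row.contaminant, strict=strict)
            expected_class = classes[contaminant]
            if row.chem_class and row.chem_class != expected_class:
                raise ValueError(
                    f"chem_class {row.chem_class!r} does not match vocabulary "
                    f"class {expected_class!r} for {contaminant}"
                )
            rec = OccurrenceRecord(
                record_id=row.record_id,
                study_id=row.study_id,
                food=food,
                cooking_state=row.cooking_state or "unspecified",
                contaminant=contaminant,
                chem_class=expected_class,
                stat_type=row.stat_type,
                value=float(row.value),
                unit=row.unit,
                basis=row.basis,
                n=None if row.n == "" else int(row.n),
                censor=row.censor or "quantified",
                lod=_opt_float(row.lod),
                loq=_opt_float(row.loq),
                sample_flag=row.sample_flag or "normal",
            )
        except (ValueError, VocabularyError) as exc:
            raise ParseError(f"row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_occurrence(records: Iterable[OccurrenceRecord], path) -> None:
    """Write records in the occurrence CSV dialect (empty string = absent)."""
    rows = []
    for r in records:
        d = {k: getattr(r, k) for k in OCCURRENCE_COLUMNS}
        for k in ("cooking_state", "stat_type", "censor", "sample_flag"):
            d[k] = d[k].value
        for k in ("n", "lod", "loq"):
            if d[k] is None:
                d[k] = ""
        rows.append(d)
    pd.DataFrame(rows, columns=OCCURRENCE_COLUMNS).to_csv(path, index=False)


_FLAG_REASONS = {
    SampleFlag.artificial_contamination: ExclusionReason.artificial,
    SampleFlag.animal_feed: ExclusionReason.feed,
    SampleFlag.animal_model: ExclusionReason.animal_model,
}


def apply_exclusions(
    records: Iterable[OccurrenceRecord],
    cereal_set: frozenset[str] | set[str] = CEREALS,
) -> ExclusionReport:
    """Partition records into kept/dropped with a reason per drop.

    Drops spiked/feed/animal-model samples, min- or max-only statistics, and
    dry-basis records for non-cereal foods.  Pure filter: idempotent,
    order-independent, and ``|kept| + |dropped| = |input|``.
    """
    kept: list[str] = []
    dropped: list[tuple[str, ExclusionReason]] = []
    for r in records:
        if r.sample_flag in _FLAG_REASONS:
            dropped.append((r.record_id, _FLAG_REASONS[r.sample_flag]))
        elif r.stat_type in (StatType.min_only, StatType.max_only):
            dropped.append((r.record_id, ExclusionReason.minmax_only))
        elif r.basis == "dry" and r.food not in cereal_set:
            dropped.append((r.record_id, ExclusionReason.dry_basis_noncereal))
        else:
            kept.append(r.record_id)
    return ExclusionReport(kept=kept, dropped=dropped)


def standardize_unit(value: float, unit: str) -> float:
    """Convert a concentration to µg per kg of food (exact scalar factors)."""
    u = _UNIT_ALIASES.get(unit, unit)
    try:
        return value * _UNIT_FACTORS[u]
    except KeyError:
        raise ValueError(f"unknown unit: {unit!r}") from None


def censor_substitute(record: OccurrenceRecord) -> float:
    """Concentration in the record's own unit after censoring substitution.

    Quantified values pass through; left-censored values are replaced by
    threshold/sqrt(2), the standard substitution for moderate censoring.
    """
    if record.censor == Censor.quantified:
        return record.value
    if record.censor == Censor.below_LOD:
        if record.lod is None:
            raise ValueError(f"record {record.record_id}: below_LOD without lod")
        return record.lod / math.sqrt(2)
    if record.loq is None:
        raise ValueError(f"record {record.record_id}: below_LOQ without loq")
    return record.loq / math.sqrt(2)


def harmonised_value(record: OccurrenceRecord) -> float:
    """Censor-substituted concentration expressed in µg/kg."""
    return standardize_unit(censor_substitute(record), record.unit)
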