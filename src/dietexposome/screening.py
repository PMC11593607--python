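"""Screening of exposure scenarios against health-based guidance values.

The registry holds per-kg-body-weight guidance values of two kinds:

* intake limits — TWI (per week), TDI and ADI (per day) — converted to a
  per-person daily amount at the reference body weight (default 70 kg) and
  compared directly with the scenario burden;
* benchmark doses (BMDL05/01/10) used either as a margin-of-exposure (MOE)
  reference when the entry carries an ``moe_threshold`` (MOE below the
  threshold flags concern; 200 is the conventional low-concern bound for
  non-neoplastic endpoints, 10,000 for neoplastic ones), or as a direct
  daily-amount reference when it does not.

Boundary convention: exposure exactly at the reference is "within"; an MOE
exactly at the threshold is low concern (concern requires MOE strictly
below the threshold).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import pandas as pd

from .scenarios import ExposureScenario

DEFAULT_BODY_WEIGHT_KG = 70.0

REGISTRY_COLUMNS = ["contaminant", "gtype", "value", "units", "period", "endpoint", "moe_threshold"]

_INTAKE_TYPES = ("TWI", "TDI", "ADI")
_BMDL_TYPES = ("BMDL05", "BMDL01", "BMDL10")


class Flag(str, enum.Enum):
    within = "within"
    exceeds = "exceeds"
    moe_concern = "moe_concern"
    moe_low_concern = "moe_low_concern"
    no_reference = "no_reference"


@dataclass(frozen=True)
class HBGVEntry:
    """One guidance value, expressed per kg body weight."""

    contaminant: str
    gtype: str  # TWI | TDI | ADI | BMDL05 | BMDL01 | BMDL10
    value: float  # amount per kg bw per period
    units: str  # ug | mg
    period: str  # day | week
    endpoint: str = ""
    moe_threshold: Optional[float] = None

    def __post_init__(self):
        if self.gtype not in _INTAKE_TYPES + _BMDL_TYPES:
            raise ValueError(f"unknown guidance type {self.gtype!r}")
        if self.value <= 0:
            raise ValueError("guidance value must be > 0")
        if self.units not in ("ug", "mg"):
            raise ValueError(f"units must be ug or mg, got {self.units!r}")
        if self.gtype == "TWI" and self.period != "week":
            raise ValueError("TWI entries are per week")
        if self.gtype != "TWI" and self.period != "day":
            raise ValueError(f"{self.gtype} entries are per day")


@dataclass(frozen=True)
class ScreeningResult:
    contaminant: str
    percentile: str
    exposure_ug_day: float
    reference_ug_day: Optional[float]
    moe: Optional[float]
    flag: Flag
    gtype: str = ""
    endpoint: str = ""


def to_daily_amount(entry: HBGVEntry, bw: float = DEFAULT_BODY_WEIGHT_KG) -> float:
    """Per-person daily amount in the entry's own units (µg or mg).

    Scales the per-kg value by body weight and divides weekly values by 7.
    """
    if bw <= 0:
        raise ValueError(f"body weight must be > 0, got {bw}")
    amount = entry.value * bw
    if entry.period == "week":
        amount /= 7.0
    return amount


def to_weekly_amount(entry: HBGVEntry, bw: float = DEFAULT_BODY_WEIGHT_KG) -> float:
    """Per-person weekly amount (only meaningful for TWI entries)."""
    return to_daily_amount(entry, bw) * 7.0


def compute_moe(bmdl_per_kg_day: float, exposure_ug_day: float, bw: float) -> Optional[float]:
    """Margin of exposure: BMDL divided by exposure per kg bw per day.

    Returns ``None`` when the exposure is zero (not computable).
    """
    if exposure_ug_day < 0:
        raise ValueError("exposure must be >= 0")
    if exposure_ug_day == 0:
        return None
    return bmdl_per_kg_day / (exposure_ug_day / bw)


def _reference_ug_day(entry: HBGVEntry, bw: float) -> float:
    amount = to_daily_amount(entry, bw)
    return amount * 1000.0 if entry.units == "mg" else amount


def screen_scenario(
    scenario: ExposureScenario,
    registry: Sequence[HBGVEntry],
    bw: float = DEFAULT_BODY_WEIGHT_KG,
) -> list[ScreeningResult]:
    """Flag every scenario contaminant against the guidance registry.

    A contaminant may yield several results (one per applicable entry, e.g.
    two lead benchmark doses with different endpoints); contaminants with
    no entry yield a single ``no_reference`` result.  Duplicate entries for
    the same contaminant, guidance type and endpoint are rejected.
    """
    seen: set[tuple[str, str, str]] = set()
    by_contaminant: dict[str, list[HBGVEntry]] = {}
    for entry in registry:
        key = (entry.contaminant, entry.gtype, entry.endpoint)
        if key in seen:
            raise ValueError(f"duplicate guidance entry for {key}")
        seen.add(key)
        by_contaminant.setdefault(entry.contaminant, []).append(entry)

    results: list[ScreeningResult] = []
    for contaminant, exposure in sorted(scenario.burdens.items()):
        entries = by_contaminant.get(contaminant)
        if not entries:
            results.append(
                ScreeningResult(
                    contaminant=contaminant,
                    percentile=scenario.percentile,
                    exposure_ug_day=exposure,
                    reference_ug_day=None,
                    moe=None,
                    flag=Flag.no_reference,
                )
            )
            continue
        for entry in entries:
            if entry.gtype in _BMDL_TYPES and entry.moe_threshold is not None:
                bmdl_ug = entry.value * (1000.0 if entry.units == "mg" else 1.0)
                moe = compute_moe(bmdl_ug, exposure, bw)
                if moe is None:
                    flag = Flag.moe_low_concern  # zero exposure: no concern
                else:
                    flag = Flag.moe_concern if moe < entry.moe_threshold else Flag.moe_low_concern
                results.append(
                    ScreeningResult(
                        contaminant=contaminant,
                        percentile=scenario.percentile,
                        exposure_ug_day=exposure,
                        reference_ug_day=None,
                        moe=moe,
                        flag=flag,
                        gtype=entry.gtype,
                        endpoint=entry.endpoint,
                    )
                )
            else:
                ref = _reference_ug_day(entry, bw)
                flag = Flag.exceeds if exposure > ref else Flag.within
                results.append(
                    ScreeningResult(
                        contaminant=contaminant,
                        percentile=scenario.percentile,
                        exposure_ug_day=exposure,
                        reference_ug_day=ref,
                        moe=None,
                        flag=flag,
                        gtype=entry.gtype,
                        endpoint=entry.endpoint,
                    )
                )
    return results


def read_registry(path) -> list[HBGVEntry]:
    """Read a guidance-value CSV (empty string = absent threshold)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    entries = []
    for row in df.itertuples(index=False):
        entries.append(
            HBGVEntry(
                contaminant=row.contaminant,
                gtype=row.gtype,
                value=float(row.value),
                units=row.units,
                period=row.period,
                endpoint=row.endpoint,
                moe_threshold=float(row.moe_threshold) if row.moe_threshold else None,
            )
        )
    return entries


def default_registry() -> list[HBGVEntry]:
    """The packaged EFSA guidance-value registry."""
    with resources.files("dietexposome.data").joinpath("hbgv_registry.csv").open(
        "r", encoding="utf-8"
    ) as fh:
        return read_registry(fh)


def results_to_frame(results: Iterable[ScreeningResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contaminant": r.contaminant,
                "percentile": r.percentile,
                "exposure_ug_day": r.exposure_ug_day,
                "reference_ug_day": r.reference_ug_day,
                "moe": r.moe,
                "flag": r.flag.value,
                "gtype": r.gtype,
                "endpoint": r.endpoint,
            }
            for r in results
        ]
    )
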