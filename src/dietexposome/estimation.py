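"""Sample-size-weighted concentration estimates per food x contaminant.

Each curated record contributes its (censor-substituted, unit-harmonised)
central concentration, weighted by the sample size behind it, so a study of
200 samples moves the estimate more than a study of 5.  Per food and
contaminant we report the weighted mean and the weighted 25th/50th/75th
percentiles; the percentile triple later drives the low/central/high
co-exposure scenarios.

Weighted percentile conventions
-------------------------------
Weights here are sample sizes, i.e. counts of observations, so the default
``"expansion"`` convention is defined to agree *exactly*, for integer
weights, with the ordinary Hazen (midpoint) percentile computed on the
multiset in which each record is repeated ``n`` times.  It is computed in
closed form from cumulative weights, never by materialising the expansion.
Two alternatives are selectable:

``"midpoint"``
    the textbook weighted-Hazen rule — linear interpolation through the
    cumulative-weight midpoints ``(c_{i-1}+c_i)/2``.  Invariant to uniform
    weight rescaling, but for heavy weights it interpolates across a
    record's plateau instead of sitting on it, so it does not reproduce the
    expansion exactly.
``"inverted_cdf"``
    the step-function weighted quantile (no interpolation), delegated to
    :func:`numpy.quantile`.

The three agree for equal unit weights up to their unweighted analogues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .occurrence import OccurrenceRecord, StatType, harmonised_value
from .vocab import CONGENER_MAPS, DEFAULT_PROXY_MAP, contaminant_classes

CONVENTIONS = ("expansion", "midpoint", "inverted_cdf")

ESTIMATE_COLUMNS = [
    "food",
    "contaminant",
    "chem_class",
    "w_mean",
    "p25",
    "p50",
    "p75",
    "n_records",
    "total_weight",
    "provenance",
]


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Weighted summary of one contaminant in one food (µg/kg)."""

    food: str
    contaminant: str
    chem_class: str
    w_mean: float
    p25: float
    p50: float
    p75: float
    n_records: int
    total_weight: float
    provenance: str = "direct"

    def percentile(self, which: str) -> float:
        if which not in ("p25", "p50", "p75"):
            raise ValueError(f"percentile must be p25/p50/p75, got {which!r}")
        return getattr(self, which)


@dataclass(frozen=True)
class CongenerMap:
    """Aggregate label (e.g. ENNs) and its member analytes."""

    label: str
    members: tuple[str, ...]

    def __post_init__(self):
        if not self.members:
            raise ValueError(f"congener map {self.label!r} has no members")


DEFAULT_CONGENER_MAPS = tuple(
    CongenerMap(label=k, members=v) for k, v in CONGENER_MAPS.items()
)


def weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Weight-averaged concentration, ``sum(w*v)/sum(w)``."""
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1:
        raise ValueError("values and weights must be 1-D of equal length")
    if np.any(w < 0):
        raise ValueError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("sum of weights must be positive")
    return float((v * w).sum() / total)


def weighted_percentile(
    values: Sequence[float],
    weights: Sequence[float],
    q: float,
    convention: str = "expansion",
) -> float:
    """Weighted percentile of ``values`` at fraction ``q`` in (0, 1).

    See the module docstring for the available conventions.  All clamp to
    the smallest/largest value in the extreme tails.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"q must be in (0, 1), got {q}")
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; choose from {CONVENTIONS}")
    v = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if v.shape != w.shape or v.ndim != 1 or v.size == 0:
        raise ValueError("values and weights must be non-empty 1-D of equal length")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    keep = w > 0
    v, w = v[keep], w[keep]
    order = np.argsort(v, kind="stable")
    v, w = v[order], w[order]

    if convention == "inverted_cdf":
        return float(np.quantile(v, q, weights=w, method="inverted_cdf"))

    if convention == "midpoint":
        c = np.cumsum(w) / w.sum()
        p = (np.concatenate(([0.0], c[:-1])) + c) / 2.0
        return float(np.interp(q, p, v))

    # expansion: piecewise-linear quantile function whose knots are the
    # first and last copy midpoints of each record on the weight line
    # (copy k of W sits at mass position k - 0.5, so the target is q*W);
    # exact match to Hazen on the n-expanded multiset for integer weights.
    total = w.sum()
    upper = np.cumsum(w)
    lower = upper - w
    xs: list[float] = []
    ys: list[float] = []
    for lo, hi, wi, vi in zip(lower, upper, w, v):
        if wi >= 1.0:
            xs.extend((lo + 0.5, hi - 0.5))
            ys.extend((vi, vi))
        else:  # fractional weight: a single knot at the mass midpoint
            xs.append((lo + hi) / 2.0)
            ys.append(vi)
    return float(np.interp(q * total, xs, ys))


def expansion_oracle(values: Sequence[float], weights: Sequence[int], q: float) -> float:
    """Reference: Hazen percentile of the weight-expanded multiset.

    Materialises the expansion, so only suitable for small integer-weight
    instances; used as the independent check of :func:`weighted_percentile`.
    """
    w = np.asarray(weights)
    if not np.all(w == w.astype(int)) or np.any(w < 0):
        raise ValueError("expansion oracle needs non-negative integer weights")
    expanded = np.repeat(np.asarray(values, dtype=float), w.astype(int))
    return float(np.quantile(expanded, q, method="hazen"))


def _select_central(records: Sequence[OccurrenceRecord]) -> list[OccurrenceRecord]:
    """Prefer a study's reported means; use its medians only as fallback."""
    chosen: list[OccurrenceRecord] = []
    by_study: dict[str, list[OccurrenceRecord]] = {}
    for r in records:
        by_study.setdefault(r.study_id, []).append(r)
    for recs in by_study.values():
        means = [r for r in recs if r.stat_type == StatType.mean]
        chosen.extend(means if means else [r for r in recs if r.stat_type == StatType.median])
    return chosen


def estimate_food_contaminant(
    records: Sequence[OccurrenceRecord],
    convention: str = "expansion",
) -> ConcentrationEstimate:
    """Weighted mean and quartiles for one food x contaminant.

    Records must already have passed the exclusion filters and share a
    single food and contaminant; unit conversion and censoring substitution
    are applied here.  Weight is the record's sample size (1 when absent).
    """
    records = list(records)
    if not records:
        raise ValueError("no records to estimate from")
    foods = {r.food for r in records}
    contaminants = {r.contaminant for r in records}
    if len(foods) != 1 or len(contaminants) != 1:
        raise ValueError(f"records mix foods {foods} or contaminants {contaminants}")
    used = _select_central(records)
    if not used:
        raise ValueError("no mean or median records available")
    values = [harmonised_value(r) for r in used]
    weights = [float(r.n) if r.n is not None else 1.0 for r in used]
    return ConcentrationEstimate(
        food=used[0].food,
        contaminant=used[0].contaminant,
        chem_class=used[0].chem_class,
        w_mean=weighted_mean(values, weights),
        p25=weighted_percentile(values, weights, 0.25, convention),
        p50=weighted_percentile(values, weights, 0.50, convention),
        p75=weighted_percentile(values, weights, 0.75, convention),
        n_records=len(used),
        total_weight=float(sum(weights)),
        provenance="direct",
    )


def estimate_all(
    records: Sequence[OccurrenceRecord],
    convention: str = "expansion",
) -> list[ConcentrationEstimate]:
    """Group records by food x contaminant and estimate each group."""
    groups: dict[tuple[str, str], list[OccurrenceRecord]] = {}
    for r in records:
        groups.setdefault((r.food, r.contaminant), []).append(r)
    return [
        estimate_food_contaminant(recs, convention) for recs in groups.values()
    ]


def aggregate_congeners(
    estimates: Iterable[ConcentrationEstimate],
    maps: Sequence[CongenerMap] = DEFAULT_CONGENER_MAPS,
) -> list[ConcentrationEstimate]:
    """Collapse congener families into a single cumulative estimate per food.

    Mean and each percentile of the aggregate are the member-wise sums
    (absent members contribute zero), which treats members as comonotonic;
    members are removed from the output.
    """
    member_of: dict[str, str] = {}
    for m in maps:
        for name in m.members:
            if name in member_of:
                raise ValueError(f"{name!r} appears in more than one congener map")
            member_of[name] = m.label
    passthrough: list[ConcentrationEstimate] = []
    sums: dict[tuple[str, str], list[ConcentrationEstimate]] = {}
    for est in estimates:
        label = member_of.get(est.contaminant)
        if label is None:
            passthrough.append(est)
        else:
            sums.setdefault((est.food, label), []).append(est)
    aggregated = []
    for (food, label), members in sorted(sums.items()):
        aggregated.append(
            ConcentrationEstimate(
                food=food,
                contaminant=label,
                chem_class=members[0].chem_class,
                w_mean=sum(e.w_mean for e in members),
                p25=sum(e.p25 for e in members),
                p50=sum(e.p50 for e in members),
                p75=sum(e.p75 for e in members),
                n_records=sum(e.n_records for e in members),
                total_weight=sum(e.total_weight for e in members),
                provenance="congener_sum",
            )
        )
    return passthrough + aggregated


def proxy_fill(
    estimates: Sequence[ConcentrationEstimate],
    proxy_map: Mapping[str, str] = DEFAULT_PROXY_MAP,
) -> list[ConcentrationEstimate]:
    """Fill foods without occurrence data from a proxy food's estimates.

    By default bread borrows from maize and pasta from wheat.  A target's
    own direct estimates are never overwritten; a missing proxy source
    raises a warning and leaves the target empty.
    """
    out = list(estimates)
    by_food: dict[str, set[str]] = {}
    for e in estimates:
        by_food.setdefault(e.food, set()).add(e.contaminant)
    for target, source in proxy_map.items():
        source_ests = [e for e in estimates if e.food == source]
        if not source_ests:
            warnings.warn(
                f"proxy source {source!r} has no estimates; {target!r} left empty",
                stacklevel=2,
            )
            continue
        have = by_food.get(target, set())
        for e in source_ests:
            if e.contaminant in have:
                continue
            out.append(replace(e, food=target, provenance=f"proxy_from_{source}"))
    return out


def estimates_to_frame(estimates: Iterable[ConcentrationEstimate]) -> pd.DataFrame:
    return pd.DataFrame(
        [{k: getattr(e, k) for k in ESTIMATE_COLUMNS} for e in estimates],
        columns=ESTIMATE_COLUMNS,
    )


def write_estimates(estimates: Iterable[ConcentrationEstimate], path) -> None:
    estimates_to_frame(estimates).to_csv(path, index=False)


def read_estimates(path) -> list[ConcentrationEstimate]:
    df = pd.read_csv(path)
    classes = contaminant_classes()
    out = []
    for row in df.itertuples(index=False):
        out.append(
            ConcentrationEstimate(
                food=row.food,
                contaminant=row.contaminant,
                chem_class=getattr(row, "chem_class", None)
                or classes.get(row.contaminant, "mycotoxin"),
                w_mean=float(row.w_mean),
                p25=float(row.p25),
                p50=float(row.p50),
                p75=float(row.p75),
                n_records=int(row.n_records),
                total_weight=float(row.total_weight),
                provenance=str(row.provenance),
            )
        )
    return out
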