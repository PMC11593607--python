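"""Controlled vocabularies for foods and contaminant analytes.

The occurrence table uses 16 widely consumed foods (4 animal-based, 12
plant-based) and 73 analytes in five chemical classes (heavy metals, PAHs,
pesticides, mycotoxins, heterocyclic aromatic amines).  Literature-mined
tables show naming drift ("B[a]P", "BaP", "benzo[a]pyrene"), so lookups are
case-insensitive and alias-aware by default; a strict mode accepts canonical
names only.  The packaged vocabulary fills the handful of analytes the
source material counts but never names with standard EFSA/IARC members; see
the data-file headers.
"""

from __future__ import annotations

import functools
import unicodedata
from importlib import resources

import pandas as pd

CHEM_CLASSES = ("heavy_metal", "PAH", "pesticide", "mycotoxin", "HAA")

#: Cereals keep dry-basis records; everything else drops them.
CEREALS = frozenset({"wheat", "maize", "rice"})

#: Aggregates reported as a single cumulative estimate.
CONGENER_MAPS: dict[str, tuple[str, ...]] = {
    "ENNs": ("enniatin A", "enniatin B", "enniatin A1", "enniatin B1"),
    "EgTs": (
        "ergotamine",
        "ergotaminine",
        "ergokryptine",
        "ergokryptinine",
        "ergonisine",
        "ergosine",
        "ergometrine",
        "ergocornine",
        "ergocristine",
    ),
    "ATs": ("alternariol", "alternariol methyl ether"),
}

#: Regulatory indicator sums.
PAH4 = ("benzo[a]pyrene", "benz[a]anthracene", "chrysene", "benzo[b]fluoranthene")
PAH8 = PAH4 + (
    "benzo[k]fluoranthene",
    "dibenz[ah]anthracene",
    "benzo[ghi]perylene",
    "indeno[123-cd]pyrene",
)
BETA_CARBOLINES = ("harman", "norharman")

#: Proxy foods for items without direct occurrence data.
DEFAULT_PROXY_MAP = {"bread": "maize", "pasta": "wheat"}


class VocabularyError(ValueError):
    """Raised when a name is not in the controlled vocabulary."""


def _norm(name: str) -> str:
    return unicodedata.normalize("NFKC", name).strip().casefold()


def _load_csv(filename: str) -> pd.DataFrame:
    with resources.files("dietexposome.data").joinpath(filename).open("r", encoding="utf-8") as fh:
        return pd.read_csv(fh, dtype=str).fillna("")


class Vocabulary:
    """Canonical-name resolver backed by a name/alias table."""

    def __init__(self, table: pd.DataFrame, kind: str):
        self.kind = kind
        self.table = table
        self.canonical: list[str] = list(table["name"])
        self._lookup: dict[str, str] = {}
        for _, row in table.iterrows():
            self._lookup[_norm(row["name"])] = row["name"]
            for alias in filter(None, row["aliases"].split(";")):
                self._lookup[_norm(alias)] = row["name"]

    def resolve(self, name: str, strict: bool = False) -> str:
        """Return the canonical name, or raise :class:`VocabularyError`.

        In strict mode only an exact canonical name is accepted.
        """
        if strict:
            if name in self.canonical:
                return name
            raise VocabularyError(f"unknown {self.kind} (strict): {name!r}")
        canon = self._lookup.get(_norm(name))
        if canon is None:
            raise VocabularyError(f"unknown {self.kind}: {name!r}")
        return canon

    def __contains__(self, name: str) -> bool:
        try:
            self.resolve(name)
            return True
        except VocabularyError:
            return False


@functools.lru_cache(maxsize=1)
def food_vocabulary() -> Vocabulary:
    return Vocabulary(_load_csv("foods.csv"), "food")


@functools.lru_cache(maxsize=1)
def contaminant_vocabulary() -> Vocabulary:
    return Vocabulary(_load_csv("contaminants.csv"), "contaminant")


@functools.lru_cache(maxsize=1)
def contaminant_classes() -> dict[str, str]:
    """Canonical contaminant name -> chemical class."""
    table = _load_csv("contaminants.csv")
    return dict(zip(table["name"], table["chem_class"]))
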