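"""CYP2D6 star-allele genotype to metabolizer-phenotype translation.

The activity-score (AS) system assigns each star allele a numeric functional
value: 0 for no-function alleles, 0.5 for decreased function, 1 for normal
function.  The diplotype score is the sum of its two allele values, and the
score maps onto the ordered metabolizer categories

    PM (AS = 0)  <  IM (0 < AS < 1)  <  NM (1 <= AS <= 2)  <  UM (AS > 2)

Copy-number duplications written with an ``xN`` suffix (``*1x2``) multiply the
base allele's activity by N, which is how ultrarapid metabolizers arise.
Alleles missing from the activity table yield an *unknown* score and the
UNKNOWN phenotype rather than silently scoring 0.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "Phenotype",
    "StarAllele",
    "Diplotype",
    "ActivityScore",
    "DiplotypeParseError",
    "PhenotypeOrderError",
    "DEFAULT_ALLELE_ACTIVITY",
    "load_allele_table",
    "parse_diplotype",
    "diplotype_activity_score",
    "phenotype_from_score",
    "gpt_from_diplotype",
]


class DiplotypeParseError(ValueError):
    """Raised for malformed star-allele or diplotype strings."""


class PhenotypeOrderError(TypeError):
    """Raised when an UNKNOWN phenotype is compared against the metabolizer order."""


_RANK = {"PM": 0, "IM": 1, "NM": 2, "UM": 3}


class Phenotype(enum.Enum):
    """Ordered CYP2D6 metabolizer category, plus an unordered UNKNOWN sentinel."""

    PM = "PM"
    IM = "IM"
    NM = "NM"
    UM = "UM"
    UNKNOWN = "UNKNOWN"

    @property
    def rank(self) -> int:
        if self is Phenotype.UNKNOWN:
            raise PhenotypeOrderError("UNKNOWN phenotype has no position in the PM<IM<NM<UM order")
        return _RANK[self.value]

    def _cmp_rank(self, other: "Phenotype") -> tuple[int, int]:
        if not isinstance(other, Phenotype):
            raise TypeError(f"cannot compare Phenotype with {type(other).__name__}")
        return self.rank, other.rank

    def __lt__(self, other: "Phenotype") -> bool:
        a, b = self._cmp_rank(other)
        return a < b

    def __le__(self, other: "Phenotype") -> bool:
        a, b = self._cmp_rank(other)
        return a <= b

    def __gt__(self, other: "Phenotype") -> bool:
        a, b = self._cmp_rank(other)
        return a > b

    def __ge__(self, other: "Phenotype") -> bool:
        a, b = self._cmp_rank(other)
        return a >= b

    @classmethod
    def from_string(cls, text: str) -> "Phenotype":
        try:
            return cls(str(text).strip().upper())
        except ValueError:
            raise ValueError(
                f"unrecognized phenotype label {text!r}; expected one of PM, IM, NM, UM, UNKNOWN"
            ) from None


#: Default star-allele activity values, cross-checked against public CYP2D6
#: genotype-phenotype translation tables (normal function 1.0, decreased 0.5,
#: no function 0.0).  Fully overrideable via ``load_allele_table``.
DEFAULT_ALLELE_ACTIVITY: dict[str, float] = {
    "*1": 1.0,
    "*2": 1.0,
    "*35": 1.0,
    "*9": 0.5,
    "*10": 0.5,
    "*17": 0.5,
    "*29": 0.5,
    "*41": 0.5,
    "*3": 0.0,
    "*4": 0.0,
    "*5": 0.0,
    "*6": 0.0,
}

_ALLELE_RE = re.compile(r"^\*(\d+[A-Z]*)(?:X(\d+))?$", re.IGNORECASE)


@dataclass(frozen=True, order=True)
class StarAllele:
    """A star-nomenclature CYP2D6 haplotype label, e.g. ``*4`` or ``*1x2``.

    ``base`` is the allele without any copy-number suffix; ``copies`` is the
    duplication multiplier (1 for a plain allele).
    """

    base: str
    copies: int = 1

    def __post_init__(self) -> None:
        if not self.base.startswith("*"):
            raise DiplotypeParseError(f"star allele must begin with '*': {self.base!r}")
        if self.copies < 1:
            raise DiplotypeParseError(f"copy number must be >= 1: {self.copies}")

    @property
    def name(self) -> str:
        return self.base if self.copies == 1 else f"{self.base}x{self.copies}"

    def activity(self, table: Mapping[str, float]) -> float | None:
        """Per-allele activity, or None when the allele is absent from *table*."""
        base = table.get(self.base)
        if base is None:
            return None
        return base * self.copies

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        return self.name


@dataclass(frozen=True)
class Diplotype:
    """Unordered pair of star alleles; ``*1/*4`` and ``*4/*1`` compare equal."""

    allele1: StarAllele
    allele2: StarAllele

    def __post_init__(self) -> None:
        # canonical order so that equality/hash is orientation-free
        a, b = sorted((self.allele1, self.allele2))
        object.__setattr__(self, "allele1", a)
        object.__setattr__(self, "allele2", b)

    def __str__(self) -> str:
        return f"{self.allele1.name}/{self.allele2.name}"


@dataclass(frozen=True)
class ActivityScore:
    """Summed diplotype activity; ``known`` is False when any allele is untabulated."""

    value: float
    known: bool = True


def _parse_allele(token: str) -> StarAllele:
    tok = token.strip().replace(" ", "")
    m = _ALLELE_RE.match(tok)
    if not m:
        raise DiplotypeParseError(
            f"malformed star-allele token {token!r}: expected '*<number>' with optional 'xN' suffix"
        )
    return StarAllele(base="*" + m.group(1).upper(), copies=int(m.group(2)) if m.group(2) else 1)


def parse_diplotype(text: str) -> Diplotype:
    """Parse a ``"*a/*b"`` diplotype string into a canonical :class:`Diplotype`.

    Whitespace and case are tolerated; anything other than exactly two
    slash-separated star-allele tokens is a :class:`DiplotypeParseError`.
    """
    parts = str(text).split("/")
    if len(parts) != 2:
        raise DiplotypeParseError(
            f"diplotype {text!r} must contain exactly two '/'-separated alleles"
        )
    return Diplotype(_parse_allele(parts[0]), _parse_allele(parts[1]))


def load_allele_table(path: str | Path) -> dict[str, float]:
    """Load a YAML/JSON star-allele -> activity map and validate it."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"allele table {path} must be a mapping of star allele to activity")
    table: dict[str, float] = {}
    for name, activity in raw.items():
        key = str(name).strip()
        if not key.startswith("*"):
            raise ValueError(f"allele table key {name!r} must begin with '*'")
        val = float(activity)
        if val < 0:
            raise ValueError(f"allele activity for {key} must be >= 0, got {val}")
        table[key.upper()] = val
    return table


def diplotype_activity_score(
    d: Diplotype, table: Mapping[str, float] | None = None
) -> ActivityScore:
    """Sum the two allele activities of *d* under *table* (default table if None).

    Unknown alleles are not fatal: the result carries ``known=False`` and a
    value summing only what could be resolved.
    """
    table = DEFAULT_ALLELE_ACTIVITY if table is None else table
    a1 = d.allele1.activity(table)
    a2 = d.allele2.activity(table)
    if a1 is None or a2 is None:
        return ActivityScore(value=(a1 or 0.0) + (a2 or 0.0), known=False)
    return ActivityScore(value=a1 + a2, known=True)


def phenotype_from_score(s: ActivityScore) -> Phenotype:
    """Map an activity score onto the metabolizer category.

    0 -> PM, (0, 1) -> IM, [1, 2] -> NM, > 2 -> UM; an unknown score maps to
    UNKNOWN.  Negative values are a domain error.
    """
    if not s.known:
        return Phenotype.UNKNOWN
    v = s.value
    if v < 0:
        raise ValueError(f"activity score must be non-negative, got {v}")
    if v == 0:
        return Phenotype.PM
    if v < 1:
        return Phenotype.IM
    if v <= 2:
        return Phenotype.NM
    return Phenotype.UM


def gpt_from_diplotype(text: str, table: Mapping[str, float] | None = None) -> Phenotype:
    """Convenience: diplotype string -> genotype-predicted phenotype."""
    return phenotype_from_score(diplotype_activity_score(parse_diplotype(text), table))
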