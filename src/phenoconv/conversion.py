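"""Phenoconversion: correcting the genotype-predicted CYP2D6 phenotype for
concomitant inhibitor use.

A concomitant drug that inhibits CYP2D6 lowers the patient's effective
metabolic capacity below what the genotype predicts.  The correction used
here is the inhibitor-strength rule set common in clinical phenoconversion
calculators:

* strong inhibitor  -> poor metabolizer (PM), whatever the genotype says;
* moderate inhibitor -> one-step reduction of NM to IM; IM and PM are not
  reduced further (UM is reduced to NM as a one-step extrapolation — the
  source rule set never saw a UM, so this case is flagged in output);
* weak inhibitor or no inhibitor -> phenotype unchanged.

When several inhibitors are taken together the highest strength drives the
correction.  There are no known CYP2D6 inducers, so no induction pathway
exists; inhibitor tables containing inducer entries are rejected outright.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from .alleles import Phenotype

__all__ = [
    "InhibitorStrength",
    "InhibitorTable",
    "MedicationRecord",
    "ConversionEvent",
    "PhenoconversionError",
    "normalize_drug_name",
    "parse_medications",
    "format_medications",
    "classify_inhibitors",
    "phenoconvert",
    "annotate_cohort",
]


class PhenoconversionError(ValueError):
    """Raised for invalid phenoconversion inputs (UNKNOWN phenotypes, bad tables)."""


class InhibitorStrength(enum.IntEnum):
    """CYP2D6 inhibitor potency class, totally ordered NONE < WEAK < MODERATE < STRONG."""

    NONE = 0
    WEAK = 1
    MODERATE = 2
    STRONG = 3

    @classmethod
    def from_string(cls, text: str) -> "InhibitorStrength":
        key = str(text).strip().upper()
        if key in ("INDUCER", "INDUCTION"):
            raise PhenoconversionError(
                "inducer entries are not supported: there are no known CYP2D6 inducers"
            )
        try:
            return cls[key]
        except KeyError:
            raise PhenoconversionError(
                f"unrecognized inhibitor strength {text!r}; expected none/weak/moderate/strong"
            ) from None


# salt / formulation suffixes stripped during drug-name normalization
_SALT_SUFFIXES = {
    "hcl",
    "hydrochloride",
    "hydrobromide",
    "maleate",
    "mesylate",
    "besylate",
    "succinate",
    "oxalate",
    "citrate",
    "tartrate",
    "retard",
}


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim, and strip salt-form suffixes from a drug name."""
    tokens = str(name).strip().lower().split()
    while len(tokens) > 1 and tokens[-1] in _SALT_SUFFIXES:
        tokens.pop()
    return " ".join(tokens)


class InhibitorTable:
    """Case-insensitive map from generic drug name to CYP2D6 inhibitor strength.

    Drugs absent from the table have strength NONE.
    """

    def __init__(self, entries: Mapping[str, InhibitorStrength | str]):
        self._entries: dict[str, InhibitorStrength] = {}
        for name, strength in entries.items():
            s = strength if isinstance(strength, InhibitorStrength) else InhibitorStrength.from_string(strength)
            self._entries[normalize_drug_name(name)] = s

    @classmethod
    def default(cls) -> "InhibitorTable":
        """Table of the inhibitors observed in psychosis cohorts plus bupropion."""
        return cls(
            {
                "paroxetine": InhibitorStrength.STRONG,
                "fluoxetine": InhibitorStrength.STRONG,
                "bupropion": InhibitorStrength.STRONG,
                "citalopram": InhibitorStrength.WEAK,
                "sertraline": InhibitorStrength.WEAK,
                "escitalopram": InhibitorStrength.WEAK,
                "clomipramine": InhibitorStrength.WEAK,
                "levomepromazine": InhibitorStrength.WEAK,
            }
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "InhibitorTable":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict):
            raise PhenoconversionError(f"inhibitor table {path} must map drug name to strength")
        return cls(raw)

    def strength(self, drug_name: str) -> InhibitorStrength:
        return self._entries.get(normalize_drug_name(drug_name), InhibitorStrength.NONE)

    def __contains__(self, drug_name: str) -> bool:
        return normalize_drug_name(drug_name) in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    def items(self):
        return self._entries.items()


@dataclass(frozen=True)
class MedicationRecord:
    """One drug exposure: generic name, optional daily dose, and its role."""

    name: str
    dose_mg_per_day: float | None = None
    role: str = "concomitant"  # or "main_treatment"

    def __post_init__(self) -> None:
        if self.role not in ("main_treatment", "concomitant"):
            raise ValueError(f"medication role must be main_treatment/concomitant, got {self.role!r}")
        if self.dose_mg_per_day is not None and self.dose_mg_per_day < 0:
            raise ValueError(f"dose must be non-negative, got {self.dose_mg_per_day}")


@dataclass(frozen=True)
class ConversionEvent:
    """A patient whose corrected phenotype differs from the genotype prediction."""

    patient_id: str
    gpt: Phenotype
    ppt: Phenotype
    driver: InhibitorStrength
    extrapolated: bool = False  # True for the UM-under-moderate rule, which the
    # source rule set never exercised


def parse_medications(cell: str | float | None) -> list[MedicationRecord]:
    """Parse the cohort table's ``name:dose:role`` semicolon-list medication cell."""
    if cell is None or (isinstance(cell, float) and pd.isna(cell)) or str(cell).strip() == "":
        return []
    records = []
    for chunk in str(cell).split(";"):
        chunk = chunk.strip()
        if not chunk:
            continue
        parts = chunk.split(":")
        if len(parts) != 3:
            raise ValueError(f"medication entry {chunk!r} must be 'name:dose:role'")
        name, dose, role = (p.strip() for p in parts)
        records.append(
            MedicationRecord(
                name=name,
                dose_mg_per_day=float(dose) if dose else None,
                role=role,
            )
        )
    return records


def format_medications(meds: Iterable[MedicationRecord]) -> str:
    """Inverse of :func:`parse_medications`."""
    chunks = []
    for m in meds:
        dose = "" if m.dose_mg_per_day is None else format(m.dose_mg_per_day, "g")
        chunks.append(f"{m.name}:{dose}:{m.role}")
    return ";".join(chunks)


def classify_inhibitors(
    meds: Iterable[MedicationRecord], table: InhibitorTable | None = None
) -> InhibitorStrength:
    """Highest CYP2D6 inhibitor strength among the concomitant medications.

    An empty list, or a list with no tabulated inhibitor, classifies as NONE.
    """
    table = table or InhibitorTable.default()
    strengths = [
        table.strength(m.name) for m in meds if m.role == "concomitant"
    ]
    return max(strengths, default=InhibitorStrength.NONE)


def phenoconvert(g: Phenotype, s: InhibitorStrength) -> Phenotype:
    """Apply the inhibitor-strength correction to a genotype-predicted phenotype.

    Raises :class:`PhenoconversionError` for UNKNOWN input — unknown phenotypes
    must be excluded upstream, never converted.
    """
    if g is Phenotype.UNKNOWN:
        raise PhenoconversionError("cannot phenoconvert an UNKNOWN phenotype; exclude upstream")
    if s is InhibitorStrength.STRONG:
        return Phenotype.PM
    if s is InhibitorStrength.MODERATE:
        if g is Phenotype.NM:
            return Phenotype.IM
        if g is Phenotype.UM:
            return Phenotype.NM
        return g  # IM and PM are not reduced by moderate inhibitors
    return g  # WEAK and NONE leave the phenotype unchanged


def annotate_cohort(
    cohort: pd.DataFrame,
    table: InhibitorTable | None = None,
    medications_column: str = "medications",
) -> tuple[pd.DataFrame, list[ConversionEvent]]:
    """Assign every patient a phenoconversion-corrected phenotype (pPT).

    Returns a copy of *cohort* with ``inhibitor_strength`` and ``pPT`` columns
    plus the list of :class:`ConversionEvent` for patients whose pPT differs
    from their gPT.  Every patient must carry a non-UNKNOWN ``gPT``.
    """
    table = table or InhibitorTable.default()
    if "gPT" not in cohort.columns:
        raise PhenoconversionError("cohort has no 'gPT' column; derive it before annotating")
    out = cohort.copy()
    strengths: list[str] = []
    ppts: list[str] = []
    events: list[ConversionEvent] = []
    for _, row in out.iterrows():
        pid = str(row.get("patient_id", "?"))
        try:
            g = Phenotype.from_string(row["gPT"])
            meds = parse_medications(row.get(medications_column))
            s = classify_inhibitors(meds, table)
            p = phenoconvert(g, s)
        except (ValueError, PhenoconversionError) as exc:
            raise PhenoconversionError(f"patient {pid}: {exc}") from exc
        strengths.append(s.name)
        ppts.append(p.value)
        if p != g:
            events.append(
                ConversionEvent(
                    patient_id=pid,
                    gpt=g,
                    ppt=p,
                    driver=s,
                    extrapolated=(g is Phenotype.UM and s is InhibitorStrength.MODERATE),
                )
            )
    out["inhibitor_strength"] = strengths
    out["pPT"] = ppts
    return out, events
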