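"""Synthetic psychosis-cohort generation.

Two entry points:

* :func:`generate_cohort` draws a virtual cohort with the marginal structure
  the analysis assumes — sex ratio, genotype-predicted phenotype frequencies,
  inhibitor exposure rates, drug mix, dose and covariate distributions — and
  generates outcome scales from a configurable linear predictor whose
  phenotype effects can be keyed to either the genotype-predicted (gPT) or
  the phenoconversion-corrected (pPT) phenotype, so dual-basis model
  comparisons have a known ground truth.

* :func:`reconstruct_marginal_cohort` builds a deterministic cohort that
  reproduces a set of printed marginal counts exactly (phenotype counts,
  strong-inhibitor assignments, optional per-sex splits), for desk-scale
  verification of frequency arithmetic.

Defaults mirror a 412-patient Dutch psychosis cohort: 79.6% male, gPT
frequencies 4.1% PM / 40.5% IM / 55.3% NM, roughly a quarter of patients on
a CYP2D6 inhibitor of which 68% on a strong one, and a four-drug treatment
mix (olanzapine, risperidone, clozapine, aripiprazole).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .alleles import Phenotype
from .conversion import (
    InhibitorStrength,
    InhibitorTable,
    MedicationRecord,
    format_medications,
    phenoconvert,
)
from .models import BARS_LEVELS

__all__ = [
    "OutcomeEffect",
    "SimConfig",
    "MarginalSpec",
    "paper_like_config",
    "generate_cohort",
    "reconstruct_marginal_cohort",
]

#: Deterministic phenotype -> diplotype realization (configurable).
DIPLOTYPE_FOR_PHENOTYPE = {
    "PM": "*4/*4",  # AS 0
    "IM": "*4/*41",  # AS 0.5, the definitional intermediate score
    "NM": "*1/*1",  # AS 2
    "UM": "*1x2/*1",  # AS 3 via duplication
}

_WEAK_INHIBITORS = ["citalopram", "sertraline", "escitalopram", "clomipramine", "levomepromazine"]
_WEAK_WEIGHTS = np.array([20, 10, 5, 2, 1], dtype=float)
_STRONG_INHIBITORS = ["paroxetine", "fluoxetine"]
_STRONG_WEIGHTS = np.array([49, 10], dtype=float)


@dataclass(frozen=True)
class OutcomeEffect:
    """Generating model for one outcome scale.

    Continuous scales: score = intercept + phenotype effect + covariate
    slopes + Gaussian(0, sd).  The ordinal BARS uses the same linear
    predictor as a latent scale with logistic noise cut at ``thresholds``
    into the six ordered levels.
    """

    intercept: float
    pm: float = 0.0
    im: float = 0.0
    um: float = 0.0
    sd: float = 1.0
    slopes: Mapping[str, float] = field(default_factory=dict)
    thresholds: tuple[float, ...] = ()

    def phenotype_shift(self, category: str) -> float:
        return {"PM": self.pm, "IM": self.im, "UM": self.um}.get(category, 0.0)


def _default_effects() -> dict[str, OutcomeEffect]:
    # magnitudes sized after reported poor-metabolizer effect estimates
    # (e.g. PM on PANSS negative ~ +9 points)
    return {
        "aims": OutcomeEffect(intercept=2.0, pm=0.5, im=0.2, sd=2.0),
        "updrs": OutcomeEffect(intercept=10.0, pm=2.0, im=0.8, sd=5.0),
        "swn20": OutcomeEffect(intercept=80.0, pm=-10.0, im=-4.0, sd=15.0),
        "panss_pos": OutcomeEffect(intercept=14.0, pm=3.0, im=1.2, sd=8.0),
        "panss_neg": OutcomeEffect(intercept=14.0, pm=9.0, im=3.0, sd=8.0),
        "bars": OutcomeEffect(
            intercept=0.0,
            pm=1.0,
            im=0.4,
            sd=1.0,
            thresholds=(0.5, 1.5, 2.5, 3.5, 4.5),
        ),
    }


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the virtual cohort, with study-like defaults."""

    n: int = 412
    p_male: float = 0.796
    gpt_probs: Mapping[str, float] = field(
        default_factory=lambda: {"PM": 0.041, "IM": 0.405, "NM": 0.553}
    )
    p_inhibitor_user: float = 102 / 412
    p_strong_given_user: float = 0.68
    drug_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "olanzapine": 122 / 342,
            "risperidone": 111 / 342,
            "clozapine": 60 / 342,
            "aripiprazole": 49 / 342,
        }
    )
    dose_range: tuple[float, float] = (50.0, 700.0)
    age_mean: float = 27.0
    age_sd: float = 7.1
    illness_mean: float = 4.3
    illness_sd: float = 3.5
    episodes_rate: float = 0.7  # episodes = 1 + Poisson(rate), mean ~ 1.7
    smoking_rate: float = 0.354
    smoking_unknown_rate: float = 0.017
    birth_control_rate: float = 0.367  # among women
    effect_basis: str = "gPT"  # phenotype effects keyed to gPT or pPT
    effects: Mapping[str, OutcomeEffect] = field(default_factory=_default_effects)
    seed: int | None = None

    def __post_init__(self) -> None:
        for label, probs in (("gpt_probs", self.gpt_probs), ("drug_mix", self.drug_mix)):
            vals = np.array(list(probs.values()), dtype=float)
            # printed frequency tables round to 0.1%, so allow a near-simplex
            # and renormalize at sampling time
            if (vals < 0).any() or (vals > 1).any() or not math.isclose(vals.sum(), 1.0, abs_tol=5e-3):
                raise ValueError(f"{label} must be a probability simplex, got {dict(probs)}")
        for label, p in (
            ("p_male", self.p_male),
            ("p_inhibitor_user", self.p_inhibitor_user),
            ("p_strong_given_user", self.p_strong_given_user),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{label} must be in [0, 1], got {p}")
        lo, hi = self.dose_range
        if not (25.0 <= lo <= hi <= 1000.0):
            raise ValueError(f"dose_range must lie within [25, 1000] mg/day, got {self.dose_range}")
        if self.effect_basis not in ("gPT", "pPT"):
            raise ValueError(f"effect_basis must be gPT/pPT, got {self.effect_basis!r}")


def paper_like_config(seed: int | None = None) -> SimConfig:
    """The documented study-like defaults (n=412, 79.6% male, gPT
    4.1/40.5/55.3%, ~102/412 inhibitor users with a 68% strong share)."""
    return SimConfig(seed=seed)


def generate_cohort(config: SimConfig | None = None, seed: int | None = None) -> pd.DataFrame:
    """Draw a reproducible virtual cohort under *config*.

    ``seed`` overrides ``config.seed``.  The output carries diplotypes
    consistent with the sampled gPT, a medication list realizing the
    inhibitor draws, covariates, the pPT implied by the inhibitor rules, and
    outcome scales generated from the configured effects.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n

    gpt_levels = list(config.gpt_probs.keys())
    gp = np.array(list(config.gpt_probs.values()), dtype=float)
    gpt = rng.choice(gpt_levels, size=n, p=gp / gp.sum())
    sex = np.where(rng.random(n) < config.p_male, "male", "female")
    dp = np.array(list(config.drug_mix.values()), dtype=float)
    drugs = rng.choice(list(config.drug_mix.keys()), size=n, p=dp / dp.sum())
    lo, hi = config.dose_range
    doses = np.round(rng.uniform(lo, hi, size=n) / 5.0) * 5.0
    doses = np.clip(doses, 25.0, 1000.0)

    uses_inhibitor = rng.random(n) < config.p_inhibitor_user
    is_strong = rng.random(n) < config.p_strong_given_user
    strong_pick = rng.choice(_STRONG_INHIBITORS, size=n, p=_STRONG_WEIGHTS / _STRONG_WEIGHTS.sum())
    weak_pick = rng.choice(_WEAK_INHIBITORS, size=n, p=_WEAK_WEIGHTS / _WEAK_WEIGHTS.sum())

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n), 16, 50).round(1)
    illness = np.clip(rng.normal(config.illness_mean, config.illness_sd, size=n), 0, None).round(1)
    episodes = 1 + rng.poisson(config.episodes_rate, size=n)
    u = rng.random(n)
    smoking = np.where(
        u < config.smoking_rate,
        "smoker",
        np.where(u < config.smoking_rate + config.smoking_unknown_rate, "unknown", "non-smoker"),
    )
    birth_control = ((sex == "female") & (rng.random(n) < config.birth_control_rate)).astype(int)
    ethnicity = rng.choice(
        ["white", "mixed", "turkish", "moroccan", "other"],
        size=n,
        p=[0.82, 0.10, 0.03, 0.02, 0.03],
    )

    table = InhibitorTable.default()
    meds_col, strengths, ppt = [], [], []
    n_treatment = 1 + rng.poisson(0.3, size=n)
    extra_meds = rng.poisson(1.2, size=n)
    for i in range(n):
        meds = [MedicationRecord(drugs[i], float(doses[i]), "main_treatment")]
        if uses_inhibitor[i]:
            name = strong_pick[i] if is_strong[i] else weak_pick[i]
            meds.append(MedicationRecord(name, None, "concomitant"))
        meds_col.append(format_medications(meds))
        s = (
            table.strength(strong_pick[i] if is_strong[i] else weak_pick[i])
            if uses_inhibitor[i]
            else InhibitorStrength.NONE
        )
        strengths.append(s)
        ppt.append(phenoconvert(Phenotype.from_string(gpt[i]), s).value)
    n_meds_total = n_treatment + uses_inhibitor.astype(int) + extra_meds

    df = pd.DataFrame(
        {
            "patient_id": [f"S{i + 1:05d}" for i in range(n)],
            "sex": sex,
            "age": age,
            "ethnicity": ethnicity,
            "illness_duration": illness,
            "n_psychotic_episodes": episodes,
            "main_drug": drugs,
            "cpz_equivalent_dose": doses,
            "n_treatment_drugs": n_treatment,
            "n_medications_total": n_meds_total,
            "smoking": smoking,
            "birth_control": birth_control,
            "diplotype": [DIPLOTYPE_FOR_PHENOTYPE[g] for g in gpt],
            "gPT": gpt,
            "pPT": ppt,
            "medications": meds_col,
        }
    )

    basis = df[config.effect_basis].to_numpy()
    for outcome, eff in config.effects.items():
        shift = np.array([eff.phenotype_shift(c) for c in basis])
        linpred = eff.intercept + shift
        for cov, slope in eff.slopes.items():
            linpred = linpred + slope * pd.to_numeric(df[cov]).to_numpy()
        if outcome == "bars":
            latent = linpred + rng.logistic(0.0, eff.sd, size=n)
            codes = np.searchsorted(np.asarray(eff.thresholds), latent, side="left")
            df[outcome] = [BARS_LEVELS[c] for c in codes]
        else:
            df[outcome] = np.round(linpred + rng.normal(0.0, eff.sd, size=n), 2)
    return df


@dataclass(frozen=True)
class MarginalSpec:
    """Printed marginal counts to reconstruct exactly.

    ``gpt_counts`` maps phenotype category to patient count; ``strong_counts``
    says how many patients of each category are put on the canonical strong
    inhibitor (paroxetine).  Optional per-sex splits: ``female_counts`` (per
    category) and ``female_strong_counts`` (how many of the strong
    assignments within a category go to women; women are assigned first).
    """

    gpt_counts: Mapping[str, int]
    strong_counts: Mapping[str, int] = field(default_factory=dict)
    female_counts: Mapping[str, int] | None = None
    female_strong_counts: Mapping[str, int] | None = None
    main_drug: str = "risperidone"
    cpz_equivalent_dose: float = 400.0

    def __post_init__(self) -> None:
        for cat, count in self.gpt_counts.items():
            if cat not in ("PM", "IM", "NM", "UM"):
                raise ValueError(f"unknown phenotype category {cat!r}")
            if count < 0:
                raise ValueError(f"negative count for {cat}")
        for cat, count in self.strong_counts.items():
            if count > self.gpt_counts.get(cat, 0):
                raise ValueError(
                    f"strong-inhibitor count for {cat} ({count}) exceeds its category size"
                )
        if self.female_counts is not None:
            for cat, count in self.female_counts.items():
                if count > self.gpt_counts.get(cat, 0):
                    raise ValueError(f"female count for {cat} exceeds its category size")
        if self.female_strong_counts is not None:
            if self.female_counts is None:
                raise ValueError("female_strong_counts requires female_counts")
            for cat, count in self.female_strong_counts.items():
                if count > self.strong_counts.get(cat, 0):
                    raise ValueError(f"female strong count for {cat} exceeds strong count")
                if count > self.female_counts.get(cat, 0):
                    raise ValueError(f"female strong count for {cat} exceeds female count")

    @property
    def total(self) -> int:
        return sum(self.gpt_counts.values())


def reconstruct_marginal_cohort(spec: MarginalSpec) -> pd.DataFrame:
    """Deterministic cohort matching *spec*'s marginals with equality.

    All placeholder fields (age, dose, covariates, outcomes) are valid and
    inside the inclusion bounds, so the cohort passes the inclusion filter
    unchanged and its annotation reproduces the requested conversion counts
    exactly.
    """
    rows = []
    i = 0
    for cat in ("PM", "IM", "NM", "UM"):
        count = spec.gpt_counts.get(cat, 0)
        n_strong = spec.strong_counts.get(cat, 0)
        n_female = (spec.female_counts or {}).get(cat, 0)
        n_female_strong = (spec.female_strong_counts or {}).get(cat, None)
        if n_female_strong is None:
            # without an explicit split, strong assignments go to women first
            n_female_strong = min(n_strong, n_female)
        strong_flags = []
        # females first, then males; strong assignment within each sex block
        for j in range(count):
            female = j < n_female
            if female:
                strong = j < n_female_strong
            else:
                strong = (j - n_female) < (n_strong - n_female_strong)
            strong_flags.append((female, strong))
        for female, strong in strong_flags:
            i += 1
            meds = [MedicationRecord(spec.main_drug, spec.cpz_equivalent_dose, "main_treatment")]
            if strong:
                meds.append(MedicationRecord("paroxetine", 20.0, "concomitant"))
            rows.append(
                {
                    "patient_id": f"R{i:05d}",
                    "sex": "female" if female else "male",
                    "age": 27.0,
                    "ethnicity": "white",
                    "illness_duration": 4.0,
                    "n_psychotic_episodes": 2,
                    "main_drug": spec.main_drug,
                    "cpz_equivalent_dose": spec.cpz_equivalent_dose,
                    "n_treatment_drugs": 1,
                    "n_medications_total": 1 + int(strong),
                    "smoking": "non-smoker",
                    "birth_control": 0,
                    "diplotype": DIPLOTYPE_FOR_PHENOTYPE[cat],
                    "gPT": cat,
                    "medications": format_medications(meds),
                    "aims": 0.0,
                    "bars": "none",
                    "updrs": 0.0,
                    "swn20": 80.0,
                    "panss_pos": 7.0,
                    "panss_neg": 7.0,
                }
            )
    return pd.DataFrame(rows)
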