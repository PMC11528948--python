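"""End-to-end analysis pipeline: filter -> annotate -> summarize -> compare.

Writes the frequency tables, conversion metrics, between-group test results
and dual-basis model-comparison tables to the configured output directory,
logging every exclusion and phenoconversion event.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .alleles import load_allele_table
from .conversion import InhibitorTable, annotate_cohort
from .formatting import pct1, pct_int, ratio1
from .io import RunConfig, ensure_gpt, read_cohort, write_cohort
from .models import ModelError, compare_phenotype_models
from .simulate import SimConfig, generate_cohort
from .summary import (
    apply_inclusion_filter,
    conversion_metrics,
    kruskal_wallis,
    phenotype_frequency_table,
    stratified_conversion,
)

__all__ = ["PipelineError", "run_pipeline"]

log = logging.getLogger("phenoconv")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and identifiers."""


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the result bundle.

    The bundle maps stage names to their in-memory results; everything is
    also written as CSV (plus a plain-text report) under
    ``config.output_dir``.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log.info("phenoconv %s | config hash %s", __version__, _config_hash(config))

    # --- load or simulate -------------------------------------------------
    if config.cohort_path is not None:
        cohort = read_cohort(config.cohort_path)
    else:
        sim = SimConfig(seed=config.seed) if config.simulate_n is None else SimConfig(
            n=config.simulate_n, seed=config.seed
        )
        cohort = generate_cohort(sim)
        write_cohort(cohort, outdir / "simulated_cohort.csv")
    allele_table = (
        load_allele_table(config.allele_table_path) if config.allele_table_path else None
    )
    try:
        cohort = ensure_gpt(cohort, allele_table)
    except Exception as exc:
        raise PipelineError(f"genotype translation stage failed: {exc}") from exc

    # --- inclusion filter --------------------------------------------------
    included, exclusions = apply_inclusion_filter(cohort)
    exclusions.to_csv(outdir / "exclusions.csv", index=False)
    for _, row in exclusions.iterrows():
        log.info("excluded %s: %s", row["patient_id"], row["reason"])
    if len(included) == 0:
        raise PipelineError("inclusion filter stage left an empty cohort; no outputs written")

    # --- phenoconversion ---------------------------------------------------
    inh_table = (
        InhibitorTable.from_yaml(config.inhibitor_table_path)
        if config.inhibitor_table_path
        else InhibitorTable.default()
    )
    try:
        annotated, events = annotate_cohort(included, inh_table)
    except Exception as exc:
        raise PipelineError(f"phenoconversion stage failed: {exc}") from exc
    write_cohort(annotated, outdir / "annotated_cohort.csv")
    events_df = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "gPT": e.gpt.value,
                "pPT": e.ppt.value,
                "driver": e.driver.name,
                "extrapolated": e.extrapolated,
            }
            for e in events
        ]
    )
    events_df.to_csv(outdir / "conversion_events.csv", index=False)
    for e in events:
        log.info("phenoconversion %s: %s -> %s (%s)", e.patient_id, e.gpt.value, e.ppt.value, e.driver.name)

    # --- summaries ---------------------------------------------------------
    freq = {
        basis: phenotype_frequency_table(annotated, basis=basis) for basis in ("gPT", "pPT")
    }
    for basis, table in freq.items():
        table.to_csv(outdir / f"frequencies_{basis}.csv", index=False)
    freq_by_drug = phenotype_frequency_table(annotated, basis="pPT", stratum="main_drug")
    freq_by_drug.to_csv(outdir / "frequencies_pPT_by_drug.csv", index=False)
    metrics = conversion_metrics(annotated)
    strat = None
    if config.stratify_by_sex and annotated["sex"].nunique() > 1:
        strat = stratified_conversion(annotated, "sex")
        strat["levels"].to_csv(outdir / "conversion_by_sex.csv", index=False)

    # --- between-group tests ----------------------------------------------
    tests = []
    for basis in ("gPT", "pPT"):
        for outcome in config.outcomes:
            if outcome == "bars" or outcome not in annotated.columns:
                continue
            groups = [
                sub[outcome].dropna().to_numpy()
                for _, sub in annotated.groupby(basis, observed=True)
            ]
            groups = [g for g in groups if len(g) > 0]
            if len(groups) < 2:
                continue
            family = config.bonferroni_family or len(config.outcomes)
            r = kruskal_wallis(groups, family_size=family)
            tests.append(
                {
                    "basis": basis,
                    "outcome": outcome,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "p_adjusted": r.p_adjusted,
                    "method": r.method,
                }
            )
    tests_df = pd.DataFrame(tests)
    tests_df.to_csv(outdir / "group_tests.csv", index=False)

    # --- dual-basis model comparisons ---------------------------------------
    drug_groups = config.drug_groups or sorted(annotated["main_drug"].dropna().unique())
    comparisons, coef_rows = [], []
    for drug in drug_groups:
        for outcome in config.outcomes:
            if outcome not in annotated.columns:
                continue
            try:
                cmp = compare_phenotype_models(annotated, outcome, drug=drug)
            except ModelError as exc:
                log.warning("model comparison skipped (%s / %s): %s", drug, outcome, exc)
                continue
            comparisons.append(
                {
                    "drug": drug,
                    "outcome": outcome,
                    "aic_gPT": cmp.fit_g.aic,
                    "aic_pPT": cmp.fit_p.aic,
                    "delta_aic": cmp.delta_aic,
                    "r2_gPT": cmp.fit_g.r_squared,
                    "r2_pPT": cmp.fit_p.r_squared,
                    "indistinguishable": cmp.indistinguishable,
                    "preferred": cmp.preferred,
                }
            )
            for basis, fit in (("gPT", cmp.fit_g), ("pPT", cmp.fit_p)):
                for term in fit.params.index:
                    coef_rows.append(
                        {
                            "drug": drug,
                            "outcome": outcome,
                            "basis": basis,
                            "term": term,
                            "estimate": fit.params[term],
                            "ci_low": fit.conf_int.loc[term, "low"],
                            "ci_high": fit.conf_int.loc[term, "high"],
                            "p_value": fit.pvalues[term],
                        }
                    )
    comparisons_df = pd.DataFrame(comparisons)
    comparisons_df.to_csv(outdir / "model_comparisons.csv", index=False)
    pd.DataFrame(coef_rows).to_csv(outdir / "model_coefficients.csv", index=False)

    # --- plain-text report --------------------------------------------------
    lines = [
        f"phenoconv {__version__} | config {_config_hash(config)}",
        f"included patients: {metrics.n} (excluded {len(exclusions)})",
        f"phenoconversion events: {metrics.n_converted} ({pct1(metrics.pct_of_sample)} of sample)",
        f"PM count: {metrics.gPM_before} (gPT) -> {metrics.pPM_after} (pPT)"
        + (
            f", a {pct_int(metrics.pct_increase_PM)} increase"
            if metrics.pct_increase_PM is not None
            else ""
        ),
    ]
    if strat is not None and strat["risk_ratio"] is not None:
        lines.append(
            f"conversion risk ratio ({strat['higher_level']} vs {strat['lower_level']}): "
            f"{ratio1(strat['risk_ratio'])}"
        )
    report = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(report)

    return {
        "cohort": annotated,
        "exclusions": exclusions,
        "events": events,
        "frequencies": freq,
        "frequencies_by_drug": freq_by_drug,
        "metrics": metrics,
        "sex_stratified": strat,
        "group_tests": tests_df,
        "model_comparisons": comparisons_df,
        "report": report,
    }
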