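"""Dual-basis outcome modelling.

For each drug group and outcome the protocol fits the same candidate model
twice — once with the genotype-predicted phenotype (gPT) as predictor and
once with the phenoconversion-corrected phenotype (pPT) — runs backward
stepwise AIC selection with the phenotype term forced to stay, and compares
the two final models by AIC.  A difference below two points is treated as
model indistinguishability.

Continuous scales (AIMS, UPDRS, SWN20, PANSS positive/negative) use ordinary
least squares; the six-level akathisia scale (BARS) uses a proportional-odds
cumulative logit model.  Phenotype enters as an unordered factor with NM as
the reference level.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.miscmodels.ordinal_model import OrderedModel

__all__ = [
    "ModelSpec",
    "ModelFit",
    "ModelComparison",
    "ModelError",
    "CONTINUOUS_OUTCOMES",
    "ORDINAL_OUTCOMES",
    "DEFAULT_COVARIATES",
    "BARS_LEVELS",
    "fit_linear_model",
    "fit_cumulative_logit",
    "fit_model",
    "backward_stepwise",
    "compare_phenotype_models",
]

CONTINUOUS_OUTCOMES = ("aims", "updrs", "swn20", "panss_pos", "panss_neg")
ORDINAL_OUTCOMES = ("bars",)
BARS_LEVELS = ["none", "minimal", "mild", "moderate", "severe", "extreme"]

#: Candidate covariate pool: the full covariate list is the starting model.
DEFAULT_COVARIATES = (
    "sex",
    "age",
    "ethnicity",
    "illness_duration",
    "n_psychotic_episodes",
    "cpz_equivalent_dose",
    "n_treatment_drugs",
    "n_medications_total",
    "smoking",
    "birth_control",
)

_NUMERIC_TERMS = {
    "age",
    "illness_duration",
    "n_psychotic_episodes",
    "cpz_equivalent_dose",
    "n_treatment_drugs",
    "n_medications_total",
}


class ModelError(RuntimeError):
    """Raised for rank deficiency, non-convergence, or invalid model inputs."""


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, family, phenotype basis, and the term list.

    ``forced_terms`` may never be removed by stepwise selection; the phenotype
    term is always forced.
    """

    outcome: str
    phenotype_basis: str  # "gPT" or "pPT"
    terms: tuple[str, ...]
    forced_terms: tuple[str, ...] = ("phenotype",)

    def __post_init__(self) -> None:
        if self.phenotype_basis not in ("gPT", "pPT"):
            raise ValueError(f"phenotype basis must be gPT/pPT, got {self.phenotype_basis!r}")
        if not set(self.forced_terms) <= set(self.terms):
            raise ValueError("forced terms must be a subset of the model terms")
        if "phenotype" in self.terms and "phenotype" not in self.forced_terms:
            raise ValueError("the phenotype term must be forced when present")

    @property
    def family(self) -> str:
        return "cumulative_logit" if self.outcome in ORDINAL_OUTCOMES else "linear"

    def without(self, term: str) -> "ModelSpec":
        return replace(self, terms=tuple(t for t in self.terms if t != term))


@dataclass(frozen=True)
class ModelFit:
    """A fitted model: coefficients with Wald CIs, likelihood, AIC, and R^2.

    ``aic`` always equals ``2 * k - 2 * log_likelihood``; for linear fits k
    counts the intercept, slopes and the residual variance, for cumulative
    logit fits the slopes and the J-1 thresholds.  ``r_squared`` is the OLS
    R^2 for linear models and McFadden's pseudo-R^2 for ordinal ones.
    ``thresholds`` holds the (strictly increasing) cutpoints of ordinal fits.
    """

    spec: ModelSpec
    params: pd.Series
    conf_int: pd.DataFrame
    pvalues: pd.Series
    log_likelihood: float
    k: int
    aic: float
    r_squared: float
    n_used: int
    thresholds: np.ndarray | None = None
    stepwise_path: tuple = ()


@dataclass(frozen=True)
class ModelComparison:
    """gPT-model vs pPT-model verdict under the delta-AIC < 2 rule."""

    fit_g: ModelFit
    fit_p: ModelFit
    delta_aic: float
    indistinguishable: bool
    preferred: str  # "gPT", "pPT", or "neither"


def _source_columns(term: str) -> list[str]:
    if term == "phenotype":
        return []  # basis column handled separately
    return [term]


def _term_design(df: pd.DataFrame, term: str, basis: str) -> pd.DataFrame:
    """Expand one model term into its design-matrix columns."""
    if term == "phenotype":
        cats = pd.Categorical(df[basis])
        levels = [l for l in ("PM", "IM", "UM") if l in cats.categories]
        cols = {}
        for level in levels:  # NM is the reference level
            cols[f"phenotype[{level}]"] = (np.asarray(cats) == level).astype(float)
        return pd.DataFrame(cols, index=df.index)
    if term == "sex":
        return pd.DataFrame(
            {"sex[female]": (df["sex"].astype(str) == "female").astype(float)}, index=df.index
        )
    if term == "smoking":
        s = df["smoking"].astype(str)
        cols = {"smoking[smoker]": (s == "smoker").astype(float)}
        if (s == "unknown").any():
            cols["smoking[unknown]"] = (s == "unknown").astype(float)
        return pd.DataFrame(cols, index=df.index)
    if term == "ethnicity":
        return pd.DataFrame(
            {"ethnicity[non-white]": (df["ethnicity"].astype(str) != "white").astype(float)},
            index=df.index,
        )
    if term == "birth_control":
        return pd.DataFrame({"birth_control": df["birth_control"].astype(float)}, index=df.index)
    if term in _NUMERIC_TERMS or term in df.columns:
        return pd.DataFrame({term: pd.to_numeric(df[term])}, index=df.index)
    raise ModelError(f"unknown model term {term!r}")


def _complete_cases(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Complete-case subset over the outcome, the basis column, and every term
    of the *initial* spec, so all stepwise submodels see identical rows."""
    needed = [spec.outcome, spec.phenotype_basis]
    for term in spec.terms:
        needed.extend(_source_columns(term))
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ModelError(f"cohort is missing model columns: {missing}")
    return df.dropna(subset=needed)


def _build_design(df: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    blocks = [_term_design(df, t, spec.phenotype_basis) for t in spec.terms]
    X = pd.concat(blocks, axis=1) if blocks else pd.DataFrame(index=df.index)
    # drop constant columns arising from empty factor levels
    X = X.loc[:, X.std(ddof=0) > 0]
    return X


def _check_rank(X: pd.DataFrame, with_const: bool) -> None:
    M = X.to_numpy(dtype=float)
    if with_const:
        M = np.column_stack([np.ones(len(M)), M])
        names = ["const", *X.columns]
    else:
        names = list(X.columns)
    if M.shape[0] < M.shape[1]:
        raise ModelError(f"too few complete cases ({M.shape[0]}) for {M.shape[1]} parameters")
    _, R = np.linalg.qr(M)
    diag = np.abs(np.diag(R))
    bad = diag < 1e-8 * max(diag.max(), 1.0)
    if bad.any():
        collinear = [names[i] for i in np.flatnonzero(bad)]
        raise ModelError(f"design matrix is rank deficient; collinear columns: {collinear}")


def fit_linear_model(spec: ModelSpec, cohort: pd.DataFrame) -> ModelFit:
    """Ordinary least squares with Gaussian log-likelihood bookkeeping.

    k counts the intercept, the slopes and the residual variance, so the AIC
    matches the textbook 2k - 2 ln L with the profile Gaussian likelihood.
    """
    if spec.family != "linear":
        raise ModelError(f"outcome {spec.outcome!r} is not continuous")
    data = _complete_cases(cohort, spec)
    y = pd.to_numeric(data[spec.outcome]).to_numpy(dtype=float)
    X = _build_design(data, spec)
    _check_rank(X, with_const=True)
    exog = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero-residual edge case
        res = sm.OLS(y, exog).fit()
        names = ["const", *X.columns]
        llf = float(res.llf)
        k = len(names) + 1  # + residual variance
        aic = 2 * k - 2 * llf
        tss = float(((y - y.mean()) ** 2).sum())
        r2 = 1.0 - float(res.ssr) / tss if tss > 0 else float("nan")
        ci = res.conf_int()
    return ModelFit(
        spec=spec,
        params=pd.Series(res.params, index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["low", "high"]),
        pvalues=pd.Series(res.pvalues, index=names),
        log_likelihood=llf,
        k=k,
        aic=aic,
        r_squared=r2,
        n_used=len(y),
    )


def _null_ordinal_llf(y_codes: np.ndarray, n_levels: int) -> float:
    counts = np.bincount(y_codes, minlength=n_levels).astype(float)
    nz = counts[counts > 0]
    return float((nz * np.log(nz / counts.sum())).sum())


def _ordinal_start(codes: np.ndarray, n_levels: int, n_slopes: int) -> np.ndarray:
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    cum = np.cumsum(counts)[:-1] / counts.sum()
    t = np.log(cum / (1 - cum))
    return np.concatenate([np.zeros(n_slopes), [t[0]], np.log(np.diff(t))])


def fit_cumulative_logit(
    spec: ModelSpec, cohort: pd.DataFrame, start_params: np.ndarray | None = None
) -> ModelFit:
    """Proportional-odds cumulative logit fit for the ordinal BARS outcome.

    Thresholds are estimated under the ordered-increment reparameterization,
    slopes are shared across all cumulative splits, and McFadden's pseudo-R^2
    is reported.  Complete separation surfaces as a convergence / diverging-
    coefficient error rather than a silent fit.
    """
    if spec.family != "cumulative_logit":
        raise ModelError(f"outcome {spec.outcome!r} is not ordinal")
    data = _complete_cases(cohort, spec)
    raw = data[spec.outcome]
    observed = [l for l in BARS_LEVELS if l in set(raw.astype(str))]
    if len(observed) < 2:
        raise ModelError(f"ordinal outcome {spec.outcome!r} needs >= 2 observed levels")
    y = pd.Categorical(raw.astype(str), categories=observed, ordered=True)
    codes = np.asarray(y.codes)
    X = _build_design(data, spec)
    _check_rank(X, with_const=False)
    n_thresh = len(observed) - 1
    if X.shape[1] == 0:
        # null model: closed-form MLE from the category frequencies
        counts = np.bincount(codes, minlength=len(observed)).astype(float)
        cum = np.cumsum(counts)[:-1] / counts.sum()
        llf = _null_ordinal_llf(codes, len(observed))
        thresholds = np.log(cum / (1 - cum))
        k = n_thresh
        return ModelFit(
            spec=spec,
            params=pd.Series(thresholds, index=[f"threshold[{i}]" for i in range(n_thresh)]),
            conf_int=pd.DataFrame(
                {"low": np.full(n_thresh, np.nan), "high": np.full(n_thresh, np.nan)},
                index=[f"threshold[{i}]" for i in range(n_thresh)],
            ),
            pvalues=pd.Series(np.full(n_thresh, np.nan), index=[f"threshold[{i}]" for i in range(n_thresh)]),
            log_likelihood=llf,
            k=k,
            aic=2 * k - 2 * llf,
            r_squared=0.0,
            n_used=len(codes),
            thresholds=thresholds,
        )
    model = OrderedModel(pd.Series(y, index=data.index), X, distr="logit")
    # start at the null-model thresholds with zero slopes (or a caller-supplied
    # warm start); converge on the gradient norm (1e-6) of the log-likelihood
    if start_params is None:
        start_params = _ordinal_start(codes, len(observed), X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(
            method="bfgs", maxiter=500, gtol=1e-6, disp=False, start_params=start_params
        )
        if not res.mle_retvals.get("converged", False):
            res = model.fit(method="nm", maxiter=5000, disp=False, start_params=res.params)
    slopes = res.params[: X.shape[1]]
    if np.max(np.abs(slopes)) > 30:
        raise ModelError(
            "cumulative logit fit diverged (coefficients exploding); "
            "likely complete separation in the design"
        )
    thresholds = model.transform_threshold_params(res.params)[1:-1]
    llf = float(res.llf)
    k = X.shape[1] + n_thresh
    llf_null = _null_ordinal_llf(codes, len(observed))
    mcfadden = 1.0 - llf / llf_null if llf_null != 0 else 0.0
    names = [*X.columns, *[f"threshold[{i}]" for i in range(n_thresh)]]
    ci = np.asarray(res.conf_int())
    return ModelFit(
        spec=spec,
        params=pd.Series(np.asarray(res.params), index=names),
        conf_int=pd.DataFrame(ci, index=names, columns=["low", "high"]),
        pvalues=pd.Series(np.asarray(res.pvalues), index=names),
        log_likelihood=llf,
        k=k,
        aic=2 * k - 2 * llf,
        r_squared=float(mcfadden),
        n_used=len(codes),
        thresholds=np.asarray(thresholds, dtype=float),
    )


def fit_model(
    spec: ModelSpec, cohort: pd.DataFrame, start_params: np.ndarray | None = None
) -> ModelFit:
    """Dispatch to the family-appropriate fitter."""
    if spec.family == "linear":
        return fit_linear_model(spec, cohort)
    return fit_cumulative_logit(spec, cohort, start_params=start_params)


def _light_fit(spec: ModelSpec, data: pd.DataFrame) -> tuple[float, np.ndarray | None]:
    """AIC (and warm-start parameters) without standard errors.

    Used for stepwise candidate scans, where only the likelihood matters;
    the maximum found agrees with the full fitter to optimizer tolerance.
    """
    if spec.family == "linear":
        y = pd.to_numeric(data[spec.outcome]).to_numpy(dtype=float)
        X = _build_design(data, spec)
        _check_rank(X, with_const=True)
        M = np.column_stack([np.ones(len(y)), X.to_numpy(dtype=float)])
        beta, *_ = np.linalg.lstsq(M, y, rcond=None)
        # floor the RSS so a perfectly interpolated outcome yields a huge
        # finite likelihood instead of log(0)
        rss = max(float(((y - M @ beta) ** 2).sum()), 1e-300)
        n = len(y)
        llf = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
        k = M.shape[1] + 1
        return 2 * k - 2 * llf, None
    raw = data[spec.outcome]
    observed = [l for l in BARS_LEVELS if l in set(raw.astype(str))]
    if len(observed) < 2:
        raise ModelError(f"ordinal outcome {spec.outcome!r} needs >= 2 observed levels")
    y = pd.Categorical(raw.astype(str), categories=observed, ordered=True)
    codes = np.asarray(y.codes)
    X = _build_design(data, spec)
    _check_rank(X, with_const=False)
    n_thresh = len(observed) - 1
    if X.shape[1] == 0:
        llf = _null_ordinal_llf(codes, len(observed))
        return 2 * n_thresh - 2 * llf, None
    model = OrderedModel(pd.Series(y, index=data.index), X, distr="logit")
    start = _ordinal_start(codes, len(observed), X.shape[1])
    opt = optimize.minimize(
        lambda p: -model.loglike(p), start, method="BFGS", options={"gtol": 1e-6, "maxiter": 500}
    )
    k = X.shape[1] + n_thresh
    return 2 * k + 2 * float(opt.fun), opt.x


def backward_stepwise(spec: ModelSpec, cohort: pd.DataFrame) -> ModelFit:
    """Backward stepwise AIC selection with forced terms.

    At each step the single non-forced term whose removal most reduces the
    AIC is dropped (exact ties broken toward the smaller model, candidate
    order alphabetical); selection stops when no removal reduces AIC.
    Candidate models are scored with a likelihood-only fit; the accepted
    model is refit in full.  The returned fit's ``stepwise_path`` records
    ``(dropped_term, aic)`` pairs, starting with ``(None, initial_aic)``;
    the AIC trajectory along it is non-increasing.
    """
    data = _complete_cases(cohort, spec)  # freeze rows across all submodels
    cur_spec = spec
    cur_aic, cur_start = _light_fit(spec, data)
    path = [(None, cur_aic)]
    while True:
        free = sorted(t for t in cur_spec.terms if t not in cur_spec.forced_terms)
        best_aic, best_term, best_start = None, None, None
        for term in free:
            try:
                aic, start = _light_fit(cur_spec.without(term), data)
            except ModelError:
                continue
            if best_aic is None or aic < best_aic - 1e-10:
                best_aic, best_term, best_start = aic, term, start
        if best_aic is None or best_aic > cur_aic + 1e-10:
            break
        cur_spec, cur_aic, cur_start = cur_spec.without(best_term), best_aic, best_start
        path.append((best_term, best_aic))
    final = fit_model(cur_spec, data, start_params=cur_start)
    return replace(final, stepwise_path=tuple(path))


def compare_phenotype_models(
    cohort: pd.DataFrame,
    outcome: str,
    covariates: Sequence[str] = DEFAULT_COVARIATES,
    drug: str | None = None,
) -> ModelComparison:
    """Run the full per-outcome protocol on both phenotype bases and compare.

    Optionally restricts to one drug group first.  Covariates without
    variation in the (complete-case) group are dropped from the candidate
    pool before fitting.  delta_aic = AIC(gPT model) - AIC(pPT model);
    |delta| < 2 means the bases are indistinguishable.
    """
    df = cohort if drug is None else cohort[cohort["main_drug"] == drug]
    if len(df) == 0:
        raise ModelError(f"no patients in drug group {drug!r}")
    fits: dict[str, ModelFit] = {}
    for basis in ("gPT", "pPT"):
        terms = ("phenotype", *_informative(df, covariates, outcome, basis))
        spec = ModelSpec(outcome=outcome, phenotype_basis=basis, terms=terms)
        try:
            fits[basis] = backward_stepwise(spec, df)
        except ModelError as exc:
            raise ModelError(f"model fit failed on basis {basis}: {exc}") from exc
    delta = fits["gPT"].aic - fits["pPT"].aic
    indist = abs(delta) < 2.0
    if indist:
        preferred = "neither"
    else:
        preferred = "pPT" if delta > 0 else "gPT"
    return ModelComparison(
        fit_g=fits["gPT"],
        fit_p=fits["pPT"],
        delta_aic=delta,
        indistinguishable=indist,
        preferred=preferred,
    )


def _informative(
    df: pd.DataFrame, covariates: Sequence[str], outcome: str, basis: str
) -> tuple[str, ...]:
    """Covariates whose design columns vary within the complete-case group."""
    probe = ModelSpec(outcome=outcome, phenotype_basis=basis, terms=("phenotype", *covariates))
    data = _complete_cases(df, probe)
    keep = []
    for term in covariates:
        cols = _term_design(data, term, basis)
        if (cols.std(ddof=0) > 0).any():
            keep.append(term)
    return tuple(keep)
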