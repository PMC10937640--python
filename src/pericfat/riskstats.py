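"""Survival analysis layer: Cox models, Kaplan-Meier, discrimination and
reclassification statistics.

Cox models are fitted by partial likelihood (Efron tie handling) through
lifelines; hazard ratios for the EAT terms are reported per 10-unit change
(10 cm^3/m^2 volume, 10 HU density).  Cardiovascular-mortality analyses
are cause-specific: non-CV deaths are censored at their death time.

Harrell's C and the continuous net reclassification improvement (cNRI)
are implemented here directly (the toy-example tests check them against
exhaustive pair enumeration).  cNRI uses end-of-follow-up event status,
well-defined under the simulator's administrative censoring:

    cNRI = [P(new>old | event) - P(new<old | event)]
         + [P(new<old | non-event) - P(new>old | non-event)]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .simcohort import EVENT_CENSORED, EVENT_CV

#: columns fitted per 10-unit change; values are the per-10 column names
EAT_PER10 = {"eat_vol": "eat_vol_per10", "eat_dens": "eat_dens_per10"}

#: covariate sets of the three nested prognostic models; each is a strict
#: superset of the previous one (nesting enforced structurally)
MODEL_COVARIATES = {
    "model1": ["eat_vol", "eat_dens"],
    "model2": [
        "eat_vol",
        "eat_dens",
        "age",
        "male",
        "race",
        "ethnicity",
        "current_smoker",
        "pack_years",
        "hx_heart_disease",
        "hx_stroke",
        "diabetes",
        "hypertension",
        "education",
        "bmi",
    ],
    "model3": [
        "eat_vol",
        "eat_dens",
        "age",
        "male",
        "race",
        "ethnicity",
        "current_smoker",
        "pack_years",
        "hx_heart_disease",
        "hx_stroke",
        "diabetes",
        "hypertension",
        "education",
        "bmi",
        "ln_cac",
    ],
}

#: categorical covariates are expanded to treatment-coded dummies with a
#: fixed reference level so designs are stable across cohorts
CATEGORICAL_LEVELS = {
    "race": ["caucasian", "black", "asian", "other"],
    "ethnicity": ["non_hispanic", "hispanic", "other"],
    "education": ["hs_or_below", "post_hs", "college", "graduate", "other"],
}


class CoxFitError(RuntimeError):
    pass


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald CIs, plus fit summaries."""

    table: pd.DataFrame  # index: covariate; columns: hr, ci_lo, ci_hi, p, coef, se
    log_likelihood: float
    n: int
    events: int
    endpoint: str
    covariates: tuple
    fitter: object = field(default=None, repr=False, compare=False)

    def hr(self, name: str) -> float:
        return float(self.table.loc[name, "hr"])

    def ci(self, name: str) -> tuple[float, float]:
        return (
            float(self.table.loc[name, "ci_lo"]),
            float(self.table.loc[name, "ci_hi"]),
        )


@dataclass
class ReclassResult:
    cnri_total: float
    cnri_events: float
    cnri_nonevents: float
    p: float | None = None

    def __post_init__(self):
        if not np.isclose(self.cnri_total, self.cnri_events + self.cnri_nonevents):
            raise ValueError("cNRI components must sum to the total")


@dataclass
class DiscriminationResult:
    harrells_c: float
    lr_chi2: float | None = None
    df: int | None = None
    p: float | None = None


# ---------------------------------------------------------------------------
# Cox regression


def _endpoint_columns(cohort: pd.DataFrame, endpoint: str) -> pd.Series:
    if endpoint == "allcause":
        return (cohort["event"] != EVENT_CENSORED).astype(int)
    if endpoint == "cv":
        # cause-specific hazard: non-CV deaths censored at their death time
        return (cohort["event"] == EVENT_CV).astype(int)
    raise ValueError(f"unknown endpoint {endpoint!r}")


def _design(cohort: pd.DataFrame, covariates) -> pd.DataFrame:
    d = pd.DataFrame(index=cohort.index)
    for c in covariates:
        if c in EAT_PER10:
            d[EAT_PER10[c]] = cohort[c] / 10.0
        elif c == "ln_cac":
            d["ln_cac"] = ln_cac(cohort["cac"])
        elif c in CATEGORICAL_LEVELS:
            levels = CATEGORICAL_LEVELS[c]
            for lv in levels[1:]:  # first level is the reference
                d[f"{c}_{lv}"] = (cohort[c] == lv).astype(float)
        else:
            d[c] = cohort[c]
    return d


def fit_cox(cohort: pd.DataFrame, covariates, endpoint: str = "allcause") -> CoxResult:
    """Multivariable Cox proportional-hazards fit (Efron ties).

    EAT volume and density are rescaled so hazard ratios are per 10 units.
    """
    ev = _endpoint_columns(cohort, endpoint)
    if ev.sum() == 0:
        raise CoxFitError(f"no events for endpoint {endpoint!r}")
    d = _design(cohort, covariates)
    d["time_years"] = cohort["time_years"].to_numpy()
    d["event"] = ev.to_numpy()
    cph = CoxPHFitter()
    try:
        cph.fit(d, duration_col="time_years", event_col="event")
    except Exception as e:  # noqa: BLE001
        raise CoxFitError(f"Cox fit failed: {e}") from e
    s = cph.summary
    table = pd.DataFrame(
        {
            "coef": s["coef"],
            "se": s["se(coef)"],
            "hr": s["exp(coef)"],
            "ci_lo": s["exp(coef) lower 95%"],
            "ci_hi": s["exp(coef) upper 95%"],
            "p": s["p"],
        }
    )
    return CoxResult(
        table=table,
        log_likelihood=float(cph.log_likelihood_),
        n=len(d),
        events=int(ev.sum()),
        endpoint=endpoint,
        covariates=tuple(covariates),
        fitter=cph,
    )


def univariable_cox(cohort: pd.DataFrame, covariate: str, endpoint: str = "allcause") -> CoxResult:
    return fit_cox(cohort, [covariate], endpoint)


def fit_model(cohort: pd.DataFrame, model: str, endpoint: str = "allcause") -> CoxResult:
    """Fit one of the named nested models ('model1'..'model3')."""
    return fit_cox(cohort, MODEL_COVARIATES[model], endpoint)


def lr_test(nested: CoxResult, full: CoxResult) -> tuple[float, int, float]:
    """Likelihood-ratio test for nested Cox models: chi2, df, p."""
    if not set(nested.covariates) <= set(full.covariates):
        raise ValueError("models are not nested")
    if nested.n != full.n or nested.endpoint != full.endpoint:
        raise ValueError("models must be fitted on the same data and endpoint")
    df = len(full.table) - len(nested.table)
    chi2 = 2.0 * (full.log_likelihood - nested.log_likelihood)
    chi2 = max(chi2, 0.0)
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, df, p


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank


@dataclass
class KMResult:
    curves: dict  # group -> (times, survival)
    chi2: float
    df: int
    p: float


def km_logrank(cohort: pd.DataFrame, group_labels, endpoint: str = "allcause") -> KMResult:
    """Kaplan-Meier curves per group plus a k-sample log-rank test."""
    groups = pd.Series(np.asarray(group_labels), index=cohort.index)
    uniq = groups.unique()
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    ev = _endpoint_columns(cohort, endpoint)
    for gname, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {gname!r}")
    curves = {}
    for gname in uniq:
        m = groups == gname
        km = KaplanMeierFitter()
        km.fit(cohort.loc[m, "time_years"], ev[m])
        sf = km.survival_function_
        curves[gname] = (sf.index.to_numpy(), sf.iloc[:, 0].to_numpy())
    res = multivariate_logrank_test(cohort["time_years"], groups, ev)
    return KMResult(
        curves=curves,
        chi2=float(res.test_statistic),
        df=len(uniq) - 1,
        p=float(res.p_value),
    )


# ---------------------------------------------------------------------------
# Categorization helpers


def quartile_categorize(values) -> tuple[np.ndarray, np.ndarray]:
    """Data-driven quartile labels (1..4) and the three boundaries.

    Boundaries are linear-interpolation (type-7) sample percentiles.
    """
    v = np.asarray(values, dtype=float)
    bounds = np.percentile(v, [25, 50, 75])
    labels = 1 + np.searchsorted(bounds, v, side="left")
    return labels, bounds


CAC_CATEGORIES = ("0", "1-100", "101-300", ">300")


def cac_categorize(cac) -> np.ndarray:
    """Clinical CAC categories 0 / 1-100 / 101-300 / >300.

    Implemented as half-open intervals (0], (0,100], (100,300], (300,inf),
    so fractional scores such as 100.5 fall into the next category up.
    """
    c = np.asarray(cac, dtype=float)
    if (c < 0).any():
        raise ValueError("CAC scores must be non-negative")
    out = np.empty(c.shape, dtype=object)
    out[c == 0] = CAC_CATEGORIES[0]
    out[(c > 0) & (c <= 100)] = CAC_CATEGORIES[1]
    out[(c > 100) & (c <= 300)] = CAC_CATEGORIES[2]
    out[c > 300] = CAC_CATEGORIES[3]
    return out


def ln_cac(cac) -> np.ndarray:
    """ln(CAC + 1); the +1 offset accommodates the CAC = 0 mass."""
    return np.log1p(np.asarray(cac, dtype=float))


# ---------------------------------------------------------------------------
# Discrimination and reclassification


def harrells_c(risk_scores, times, events) -> float:
    """Harrell's concordance: concordant / comparable pairs.

    A pair is comparable when the earlier time is an event; risk-score
    ties count 1/2.  Raises if no pair is comparable.
    """
    r = np.asarray(risk_scores, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(r) == len(t) == len(e)):
        raise ValueError("vectors must be aligned")
    conc = 0.0
    comp = 0
    # chunked O(n^2) pair sweep over event subjects only
    ev_idx = np.flatnonzero(e)
    for i in ev_idx:
        # comparable partners: anyone with a strictly later time
        later = t > t[i]
        m = int(later.sum())
        if m == 0:
            continue
        comp += m
        conc += (r[i] > r[later]).sum() + 0.5 * (r[i] == r[later]).sum()
    if comp == 0:
        raise ValueError("no comparable pairs (all times tied or censored first)")
    return float(conc / comp)


def continuous_nri(risk_old, risk_new, events) -> ReclassResult:
    """Continuous net reclassification improvement of new vs old scores.

    Events should move up (new > old), non-events down; ties contribute
    zero.  Requires at least one event and one non-event.
    """
    old = np.asarray(risk_old, dtype=float)
    new = np.asarray(risk_new, dtype=float)
    e = np.asarray(events).astype(bool)
    if not (len(old) == len(new) == len(e)):
        raise ValueError("vectors must be aligned")
    if not e.any() or e.all():
        raise ValueError("cNRI needs both events and non-events")
    up = new > old
    down = new < old
    ev = e.sum()
    ne = (~e).sum()
    cnri_events = float((up & e).sum() - (down & e).sum()) / ev
    cnri_nonevents = float((down & ~e).sum() - (up & ~e).sum()) / ne
    return ReclassResult(
        cnri_total=cnri_events + cnri_nonevents,
        cnri_events=cnri_events,
        cnri_nonevents=cnri_nonevents,
    )


def predicted_risk(cohort: pd.DataFrame, result: CoxResult, horizon_years: float) -> np.ndarray:
    """Absolute event probability by ``horizon_years`` under a fitted model.

    Uses the model's own baseline hazard (Breslow), so risks from two
    different models are each calibrated to the cohort and can be compared
    subject-by-subject, e.g. in :func:`continuous_nri`.  Raw linear
    predictors must not be compared across models: their arbitrary
    centering offsets would dominate the up/down classification.
    """
    if result.fitter is None:
        raise ValueError("CoxResult carries no fitter (reloaded from summary?)")
    d = _design(cohort, result.covariates)
    sf = result.fitter.predict_survival_function(d, times=[horizon_years])
    return 1.0 - sf.iloc[0].to_numpy()


def discrimination(
    cohort: pd.DataFrame, result: CoxResult, nested: CoxResult | None = None
) -> DiscriminationResult:
    """Harrell's C of a fitted model's linear predictor, optional LR test."""
    d = _design(cohort, result.covariates)
    lp = d.to_numpy() @ result.table["coef"].to_numpy()
    ev = _endpoint_columns(cohort, result.endpoint)
    c = harrells_c(lp, cohort["time_years"], ev)
    if nested is None:
        return DiscriminationResult(harrells_c=c)
    chi2, df, p = lr_test(nested, result)
    return DiscriminationResult(harrells_c=c, lr_chi2=chi2, df=df, p=p)
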