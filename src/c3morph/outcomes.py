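"""Clinical-association layer: Kaplan-Meier, Cox, logistic, and AIC/BIC
comparison of sarcopenia- versus BMI-based outcome models.

Cohort tables are pandas DataFrames with binary covariates mirroring the
standard head-and-neck prognostic factors (age >= 65, >= 10 pack-years,
high comorbidity score, non-oropharynx site, T3-4, N2-3, stage III-IV).
Cox models use Efron's tie handling via lifelines; logistic models use
statsmodels. For PEG-tube duration the event is tube *removal*, so hazard
ratios below 1 mean longer tube dependency.

Information criteria: AIC = -2 loglik + 2k; BIC = -2 loglik + k log(m) with
m = number of events for Cox partial likelihood and m = number of rows for
logistic fits. Model comparison requires both fits to share rows and outcome.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError as _LLConvergence
from scipy import stats

from .types import EffectEstimate

OUTCOME_COLUMNS = {
    "os": ("os_time", "os_event"),
    "peg_duration": ("peg_time", "peg_event"),
}

COHORT_COVARIATES = ("sarcopenia", "bmi_class", "age65", "smoking10py",
                     "ace27_high", "nonoropharynx", "t34", "n23", "stage34")


class FitError(RuntimeError):
    """The model cannot be fit on this data (e.g. no events, single class)."""


class ConvergenceError(RuntimeError):
    """The likelihood is monotone/separated; no finite estimate exists."""


@dataclass
class FitResult:
    """A fitted outcome model with everything the comparison layer needs."""

    estimates: list[EffectEstimate]
    loglik: float
    n_params: int
    n_obs: int
    n_events: int | None
    outcome: str
    row_ids: tuple
    kind: str  # "cox" or "logistic"

    @property
    def aic(self) -> float:
        return -2.0 * self.loglik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        m = self.n_events if self.kind == "cox" else self.n_obs
        return -2.0 * self.loglik + self.n_params * float(np.log(m))


@dataclass
class ModelComparison:
    aic_a: float
    aic_b: float
    bic_a: float
    bic_b: float

    @property
    def delta_aic(self) -> float:
        return abs(self.aic_a - self.aic_b)

    @property
    def delta_bic(self) -> float:
        return abs(self.bic_a - self.bic_b)


def validate_cohort(cohort: pd.DataFrame, require=("os_time", "os_event")) -> None:
    if cohort.empty:
        raise ValueError("empty cohort")
    missing = [c for c in require if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns {missing}")


class KMEstimate:
    """Product-limit survival estimate; right-continuous step function."""

    def __init__(self, times, events):
        times = np.asarray(times, dtype=float)
        events = np.asarray(events).astype(bool)
        if times.size == 0:
            raise ValueError("empty input")
        if np.any(times <= 0):
            raise ValueError("times must be positive")
        self._kmf = KaplanMeierFitter()
        self._kmf.fit(times, events)

    def survival_at(self, t) -> np.ndarray | float:
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        sf = self._kmf.survival_function_
        grid = sf.index.to_numpy(dtype=float)
        vals = sf.iloc[:, 0].to_numpy(dtype=float)
        idx = np.searchsorted(grid, t_arr, side="right") - 1
        s = np.where(idx < 0, 1.0, vals[np.clip(idx, 0, len(vals) - 1)])
        return float(s[0]) if np.isscalar(t) else s

    @property
    def timeline(self) -> np.ndarray:
        return self._kmf.survival_function_.index.to_numpy()

    @property
    def survival(self) -> np.ndarray:
        return self._kmf.survival_function_.iloc[:, 0].to_numpy()


def km_estimate(times, events) -> KMEstimate:
    return KMEstimate(times, events)


def fit_cox(cohort: pd.DataFrame, outcome: str, terms: list[str]) -> FitResult:
    """Cox proportional hazards with Efron ties and Wald 95% CIs."""
    if outcome not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {sorted(OUTCOME_COLUMNS)}")
    tcol, ecol = OUTCOME_COLUMNS[outcome]
    validate_cohort(cohort, require=(tcol, ecol, *terms))
    df = cohort[[tcol, ecol, *terms]].copy()
    n_events = int(df[ecol].sum())
    if n_events < 2:
        raise FitError(f"{n_events} event(s); need at least 2 for a Cox fit")
    if df[terms].drop_duplicates().shape[0] < 2:
        raise FitError("fewer than 2 distinct covariate patterns")

    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col=tcol, event_col=ecol)
    except _LLConvergence as exc:
        raise ConvergenceError(
            f"Cox fit failed to converge (possible separation or monotone "
            f"likelihood): {exc}") from exc
    if not np.all(np.isfinite(cph.params_)) or np.any(np.abs(cph.params_) > 20):
        raise ConvergenceError("Cox estimates diverged; check for separation")

    summary = cph.summary
    estimates = [
        EffectEstimate(term=term,
                       ratio=float(np.exp(summary.loc[term, "coef"])),
                       ci_low=float(np.exp(summary.loc[term, "coef lower 95%"])),
                       ci_high=float(np.exp(summary.loc[term, "coef upper 95%"])),
                       p=float(summary.loc[term, "p"]))
        for term in terms
    ]
    return FitResult(estimates=estimates, loglik=float(cph.log_likelihood_),
                     n_params=len(terms), n_obs=len(df), n_events=n_events,
                     outcome=outcome, row_ids=tuple(cohort.index), kind="cox")


def fit_logistic(cohort: pd.DataFrame, outcome: str, terms: list[str]) -> FitResult:
    """Maximum-likelihood logistic regression; odds ratios with Wald CIs."""
    validate_cohort(cohort, require=(outcome, *terms))
    y = cohort[outcome].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise FitError(f"outcome {outcome!r} has a single class")
    x = sm.add_constant(cohort[list(terms)].to_numpy(dtype=float))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, x).fit(disp=0)
    except Exception as exc:  # statsmodels raises PerfectSeparation subclasses
        raise ConvergenceError(f"logistic fit failed: {exc}") from exc
    if not np.all(np.isfinite(res.params)) or np.any(np.abs(res.params[1:]) > 20):
        raise ConvergenceError("logistic estimates diverged; check for separation")

    se = np.sqrt(np.diag(res.cov_params()))
    zcrit = stats.norm.ppf(0.975)
    estimates = []
    for i, term in enumerate(terms, start=1):
        beta = res.params[i]
        z = beta / se[i]
        p = 2 * stats.norm.sf(abs(z))
        estimates.append(EffectEstimate(
            term=term, ratio=float(np.exp(beta)),
            ci_low=float(np.exp(beta - zcrit * se[i])),
            ci_high=float(np.exp(beta + zcrit * se[i])), p=float(p)))
    return FitResult(estimates=estimates, loglik=float(res.llf),
                     n_params=int(res.params.size), n_obs=len(y), n_events=None,
                     outcome=outcome, row_ids=tuple(cohort.index), kind="logistic")


def compare_information_criteria(fit_a: FitResult, fit_b: FitResult) -> ModelComparison:
    """AIC/BIC for two fits of the same outcome on the same rows."""
    if fit_a.row_ids != fit_b.row_ids:
        raise ValueError("fits use different row sets; comparison undefined")
    if fit_a.outcome != fit_b.outcome:
        raise ValueError(f"fits model different outcomes "
                         f"({fit_a.outcome!r} vs {fit_b.outcome!r})")
    return ModelComparison(aic_a=fit_a.aic, aic_b=fit_b.aic,
                           bic_a=fit_a.bic, bic_b=fit_b.bic)


def tidy_estimates(fits: dict[str, FitResult]) -> pd.DataFrame:
    """Long-format (model, term, ratio, ci_low, ci_high, p) table."""
    rows = []
    for name, fit in fits.items():
        for est in fit.estimates:
            rows.append({"model": name, "term": est.term, "ratio": est.ratio,
                         "ci_low": est.ci_low, "ci_high": est.ci_high, "p": est.p})
    return pd.DataFrame(rows)
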