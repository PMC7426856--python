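"""Discrimination and reclassification comparison of two indices.

The c statistic is the area under the ROC curve of a risk prediction
against the binary death outcome — the probability that a randomly
chosen decedent is ranked above a randomly chosen survivor, counting
ties as one half. Its variance and the test for a difference between
two correlated c statistics use the DeLong pairwise-placement
covariance. Continuous net reclassification improvement (cNRI)
summarizes whether the new index moves decedents up and survivors down
relative to the old one. Kaplan-Meier curves per risk group visualize
the score's mortality stratification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import add_age_group
from .recalibration import ConvergenceError, SeparationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# DeLong machinery


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    z = x[order]
    n = len(x)
    t = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        t[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = t
    return out


def _delong(preds: np.ndarray, outcome: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """AUCs and their DeLong covariance for k predictors on one outcome.

    preds: (k, n) array; outcome: boolean (n,). Returns (aucs (k,),
    covariance (k, k)).
    """
    outcome = np.asarray(outcome, dtype=bool)
    if outcome.all() or not outcome.any():
        raise ValueError("both outcome classes must be present")
    pos = preds[:, outcome]
    neg = preds[:, ~outcome]
    m, n = pos.shape[1], neg.shape[1]
    k = preds.shape[0]
    v01 = np.empty((k, m))
    v10 = np.empty((k, n))
    aucs = np.empty(k)
    for r in range(k):
        tx = _midrank(pos[r])
        ty = _midrank(neg[r])
        tz = _midrank(np.concatenate([pos[r], neg[r]]))
        aucs[r] = tz[:m].sum() / (m * n) - (m + 1.0) / (2.0 * n)
        v01[r] = (tz[:m] - tx) / n
        v10[r] = 1.0 - (tz[m:] - ty) / m
    sx = np.atleast_2d(np.cov(v01)) if m > 1 else np.zeros((k, k))
    sy = np.atleast_2d(np.cov(v10)) if n > 1 else np.zeros((k, k))
    cov = sx / m + sy / n
    return aucs, cov


def c_statistic(
    pred: Sequence[float], outcome: Sequence[bool], alpha: float = 0.05
) -> tuple[float, float, float]:
    """ROC c statistic with a DeLong asymptotic confidence interval.

    Returns ``(c, ci_low, ci_high)``; the CI is clipped to [0, 1].
    """
    preds = np.asarray(pred, dtype=float)[None, :]
    aucs, cov = _delong(preds, np.asarray(outcome))
    se = float(np.sqrt(max(cov[0, 0], 0.0)))
    z = stats.norm.ppf(1 - alpha / 2)
    c = float(aucs[0])
    return c, max(0.0, c - z * se), min(1.0, c + z * se)


@dataclass(frozen=True)
class AucContrast:
    """Difference of two correlated c statistics with its DeLong test."""

    c_a: float
    c_b: float
    difference: float
    se: float
    p_value: float


def compare_c(
    pred_a: Sequence[float], pred_b: Sequence[float], outcome: Sequence[bool]
) -> AucContrast:
    """Two-sided DeLong contrast test for paired ROC AUCs."""
    preds = np.vstack([np.asarray(pred_a, float), np.asarray(pred_b, float)])
    aucs, cov = _delong(preds, np.asarray(outcome))
    d = float(aucs[0] - aucs[1])
    var = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    if var <= 0:
        p = 1.0 if d == 0 else 0.0
        se = 0.0
    else:
        se = float(np.sqrt(var))
        p = float(2 * stats.norm.sf(abs(d) / se))
    return AucContrast(
        c_a=float(aucs[0]), c_b=float(aucs[1]), difference=d, se=se, p_value=p
    )


# ---------------------------------------------------------------------------
# Continuous NRI


@dataclass(frozen=True)
class NriComponent:
    estimate: float  # percent
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(frozen=True)
class NriResult:
    """cNRI components in percent; total = event + nonevent exactly."""

    event: NriComponent
    nonevent: NriComponent
    total: NriComponent


def _nri_component(delta: np.ndarray) -> tuple[float, float]:
    up = float(np.mean(delta > 0))
    down = float(np.mean(delta < 0))
    est = up - down
    var = (up + down - est**2) / len(delta)
    return est, var


def continuous_nri(
    pred_old: Sequence[float],
    pred_new: Sequence[float],
    outcome: Sequence[bool],
    alpha: float = 0.05,
    bootstrap: int | None = None,
    seed: int = 0,
) -> NriResult:
    """Continuous net reclassification improvement, in percent.

    Event component: net proportion of decedents whose predicted risk
    rises under the new model; non-event component: net proportion of
    survivors whose risk falls; total is their sum. CIs are asymptotic
    normal by default (components treated independently); with
    ``bootstrap=B`` patient-level resampling percentile CIs are used
    instead (p-values stay asymptotic).
    """
    old = np.asarray(pred_old, float)
    new = np.asarray(pred_new, float)
    y = np.asarray(outcome, bool)
    if y.all() or not y.any():
        raise ValueError("both outcome classes must be present")
    z = stats.norm.ppf(1 - alpha / 2)

    d_ev = new[y] - old[y]
    d_ne = old[~y] - new[~y]  # falls count positively for survivors
    e_est, e_var = _nri_component(d_ev)
    n_est, n_var = _nri_component(d_ne)
    t_est = e_est + n_est
    t_var = e_var + n_var

    def comp(est, var):
        se = np.sqrt(var)
        p = float(2 * stats.norm.sf(abs(est) / se)) if se > 0 else (1.0 if est == 0 else 0.0)
        return est, se, p

    cis = {}
    if bootstrap:
        rng = np.random.default_rng(seed)
        idx_ev = np.flatnonzero(y)
        idx_ne = np.flatnonzero(~y)
        reps = np.empty((bootstrap, 3))
        for b in range(bootstrap):
            ev = rng.choice(idx_ev, size=len(idx_ev), replace=True)
            ne = rng.choice(idx_ne, size=len(idx_ne), replace=True)
            de = new[ev] - old[ev]
            dn = old[ne] - new[ne]
            eb = np.mean(de > 0) - np.mean(de < 0)
            nb = np.mean(dn > 0) - np.mean(dn < 0)
            reps[b] = (eb, nb, eb + nb)
        lo, hi = np.percentile(reps, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
        cis = {"event": (lo[0], hi[0]), "nonevent": (lo[1], hi[1]), "total": (lo[2], hi[2])}

    out = {}
    for name, (est, var) in (
        ("event", (e_est, e_var)),
        ("nonevent", (n_est, n_var)),
        ("total", (t_est, t_var)),
    ):
        est_, se, p = comp(est, var)
        if cis:
            lo, hi = cis[name]
        else:
            lo, hi = est_ - stats.norm.ppf(1 - alpha / 2) * se, est_ + stats.norm.ppf(1 - alpha / 2) * se
        out[name] = NriComponent(
            estimate=100 * est_, ci_low=100 * lo, ci_high=100 * hi, p_value=p
        )
    return NriResult(event=out["event"], nonevent=out["nonevent"], total=out["total"])


# ---------------------------------------------------------------------------
# Logistic risk models


@dataclass(frozen=True)
class RiskModelSpec:
    """model1_univariate: score only; model2_adjusted: score plus age
    group, sex, region and income group (indicator contrasts)."""

    model_id: str = "model1_univariate"
    age_scheme: str = "quartile"

    def __post_init__(self):
        if self.model_id not in ("model1_univariate", "model2_adjusted"):
            raise ValueError(f"unknown model_id {self.model_id!r}")


def _risk_design(
    cohort: pd.DataFrame, scores: pd.Series | np.ndarray, spec: RiskModelSpec
) -> pd.DataFrame:
    X = pd.DataFrame({"score": np.asarray(scores, float)}, index=cohort.index)
    if spec.model_id == "model2_adjusted":
        ag = add_age_group(cohort, spec.age_scheme)
        for level in sorted(ag.unique())[1:]:
            X[f"age_group[{level}]"] = (ag == level).astype(float)
        X["sex[male]"] = (cohort["sex"] == "male").astype(float)
        X["region[metropolitan]"] = (cohort["region"] == "metropolitan").astype(float)
        inc = cohort["income_group"].astype(int)
        for level in range(1, 11):
            X[f"income_group[{level}]"] = (inc == level).astype(float)
    # constant columns (including a degenerate score) are dropped so the
    # model gracefully reduces, e.g. to intercept-only
    X = X.loc[:, X.nunique() > 1]
    return sm.add_constant(X, has_constant="add")


def fit_risk_model(
    cohort: pd.DataFrame,
    scores: pd.Series | np.ndarray,
    spec: RiskModelSpec | str = "model1_univariate",
) -> np.ndarray:
    """Logistic regression of death on the index score (plus covariates
    for model 2); returns fitted death probabilities in (0, 1)."""
    if isinstance(spec, str):
        spec = RiskModelSpec(model_id=spec)
    X = _risk_design(cohort, scores, spec)
    y = cohort["death"].astype(int)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    try:
        with _warnings.catch_warnings():
            # statsmodels may warn-and-continue, then die on a singular
            # Hessian; treat both signatures as separation
            _warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc)) from exc
    if not res.mle_retvals.get("converged", False):
        params = res.params
        if np.abs(params).max() > 15:
            raise SeparationError(
                f"separation suspected: extreme coefficient for "
                f"{params.abs().idxmax()!r}"
            )
        raise ConvergenceError(
            "logistic risk model did not converge", trace=res.mle_retvals
        )
    if np.abs(res.params).max() > 15:
        raise SeparationError(
            f"separation suspected: extreme coefficient for "
            f"{res.params.abs().idxmax()!r}"
        )
    return np.asarray(res.predict(X))


# ---------------------------------------------------------------------------
# Kaplan-Meier


def km_curve(
    followup_months: Sequence[int],
    death: Sequence[bool],
    groups: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Product-limit survival per risk group.

    Returns, per group, a step function DataFrame with columns
    ``month``, ``at_risk`` and ``survival``; censored patients leave
    the risk set after their follow-up month. Empty groups are omitted
    with a warning.
    """
    t = np.asarray(followup_months, float)
    if (t < 1).any():
        raise ValueError("follow-up must be at least 1 month")
    d = np.asarray(death, bool)
    g = pd.Series(groups).reset_index(drop=True)
    out: dict[str, pd.DataFrame] = {}
    for label in pd.unique(g):
        mask = (g == label).to_numpy()
        if not mask.any():
            logger.warning("empty risk group %r omitted from KM output", label)
            continue
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], event_observed=d[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        out[str(label)] = pd.DataFrame(
            {
                "month": tab.index.astype(int),
                "at_risk": tab["at_risk"].astype(int).to_numpy(),
                "survival": surv.reindex(tab.index).to_numpy(),
            }
        ).reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# Report


@dataclass
class ValidationReport:
    """Per-model comparison of two indices on one cohort."""

    results: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return self.results


def compare_indices(
    cohort: pd.DataFrame,
    scores_old: pd.Series | np.ndarray,
    scores_new: pd.Series | np.ndarray,
    models: Sequence[str] = ("model1_univariate", "model2_adjusted"),
    labels: tuple[str, str] = ("CCI", "mCCI-A"),
    age_scheme: str = "quartile",
) -> ValidationReport:
    """Fit the risk models for both indices and assemble c statistics,
    the AUC contrast and cNRI into a report keyed by model then index."""
    y = cohort["death"].astype(bool).to_numpy()
    report: dict[str, dict] = {}
    for model_id in models:
        spec = RiskModelSpec(model_id=model_id, age_scheme=age_scheme)
        p_old = fit_risk_model(cohort, scores_old, spec)
        p_new = fit_risk_model(cohort, scores_new, spec)
        c_old = c_statistic(p_old, y)
        c_new = c_statistic(p_new, y)
        contrast = compare_c(p_new, p_old, y)
        nri = continuous_nri(p_old, p_new, y)
        report[model_id] = {
            labels[0]: {"c": c_old[0], "c_ci": [c_old[1], c_old[2]]},
            labels[1]: {"c": c_new[0], "c_ci": [c_new[1], c_new[2]]},
            "auc_contrast_p": contrast.p_value,
            "c_difference": contrast.difference,
            "cnri": {k: asdict(getattr(nri, k)) for k in ("event", "nonevent", "total")},
        }
    return ValidationReport(results=report)
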