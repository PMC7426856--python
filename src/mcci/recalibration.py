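"""Severity-weight recalibration from an adjusted Cox model.

The 17 comorbidity flags enter a single proportional-hazards model of
all-cause mortality together with demographic adjustment covariates
(age group, sex, region, family-income group). Each comorbidity's
adjusted hazard ratio is divided by the smallest HR across the 17
categories to give a relative weight (the minimum-HR category gets
exactly 1), and relative weights are rounded to the nearest integer
(half away from zero) to give the assigned integer weight.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator

from .categories import CATEGORY_IDS, ORIGINAL_CCI_WEIGHTS
from .cohort import add_age_group

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("age_group", "sex", "region", "income_group")

# Fixed level orders so indicator contrasts (first level = reference)
# are reproducible across runs and platforms.
_LEVEL_ORDER = {
    "sex": ["female", "male"],
    "region": ["city_or_rural", "metropolitan"],
}


class ConvergenceError(RuntimeError):
    """Cox fit failed to converge; carries the optimizer trace."""

    def __init__(self, message: str, trace: dict | None = None):
        super().__init__(message)
        self.trace = trace or {}


class SeparationError(RuntimeError):
    """A covariate (quasi-)completely separates the outcome."""


@dataclass(frozen=True)
class CoxModelSpec:
    """Specification of the adjusted Cox model.

    ``covariates`` are demographic adjustment variables; all 17
    comorbidity flags always enter simultaneously. ``age_scheme`` is
    the grouping applied to age before dummy-coding (``10-year``
    default, ``quartile`` and ``3-strata`` also supported).
    """

    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    age_scheme: str = "10-year"
    tie_method: str = "efron"

    def __post_init__(self):
        if self.tie_method not in ("efron", "breslow"):
            raise ValueError("tie_method must be 'efron' or 'breslow'")


@dataclass(frozen=True)
class HazardRatioEstimate:
    """Adjusted HR with Wald 95% CI and p-value for one comorbidity."""

    category: str
    hr: float
    ci_low: float
    ci_high: float
    p_value: float

    def __post_init__(self):
        if not (self.hr > 0 and self.ci_low <= self.hr <= self.ci_high):
            raise ValueError(f"inconsistent HR estimate for {self.category}")


def _round_half_away(x: float) -> int:
    return int(math.floor(abs(x) + 0.5)) * (1 if x >= 0 else -1)


class WeightTable:
    """Per-category severity weights (HR, relative weight, integer weight)."""

    def __init__(self, table: Mapping[str, Mapping[str, float | int | None]]):
        self._table = {
            c: {
                "hr": table[c].get("hr"),
                "relative_weight": table[c].get("relative_weight"),
                "integer_weight": int(table[c]["integer_weight"]),
            }
            for c in table
        }

    def __getitem__(self, category: str) -> dict:
        return dict(self._table[category])

    def __contains__(self, category: str) -> bool:
        return category in self._table

    @property
    def categories(self) -> list[str]:
        return list(self._table)

    def weight(self, category: str) -> int:
        return self._table[category]["integer_weight"]

    @property
    def integer_weights(self) -> dict[str, int]:
        return {c: v["integer_weight"] for c, v in self._table.items()}

    @property
    def relative_weights(self) -> dict[str, float | None]:
        return {c: v["relative_weight"] for c, v in self._table.items()}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self._table).T.rename_axis("category")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self._table, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, path: str | Path) -> "WeightTable":
        return cls(json.loads(Path(path).read_text()))

    @classmethod
    def builtin(cls, name: str) -> "WeightTable":
        """Bundled tables: ``original_cci`` (1987 weights) or ``mcci_a``."""
        if name not in ("original_cci", "mcci_a"):
            raise ValueError(f"unknown builtin weight table {name!r}")
        with resources.as_file(
            resources.files("mcci.data").joinpath(f"{name}.json")
        ) as p:
            return cls.from_json(p)


def derive_weights(
    estimates: Iterable[HazardRatioEstimate] | Mapping[str, float],
) -> WeightTable:
    """Relative and integer weights from adjusted hazard ratios.

    relative_weight(c) = hr(c) / min_c hr(c); integer weight is the
    relative weight rounded half away from zero. The minimum-HR
    category gets relative and integer weight exactly 1. Invariant to
    rescaling all HRs by a common factor.
    """
    if isinstance(estimates, Mapping):
        hrs = dict(estimates)
    else:
        hrs = {e.category: e.hr for e in estimates}
    if not hrs:
        raise ValueError("no hazard ratio estimates supplied")
    if any(h <= 0 for h in hrs.values()):
        raise ValueError("hazard ratios must be positive")
    hr_min = min(hrs.values())
    table = {}
    for cat, hr in hrs.items():
        rel = hr / hr_min
        table[cat] = {
            "hr": hr,
            "relative_weight": rel,
            "integer_weight": max(1, _round_half_away(rel)),
        }
    return WeightTable(table)


class CoxWeightRecalibrator(BaseEstimator):
    """Fit the adjusted Cox model on a development cohort and derive weights.

    Parameters
    ----------
    covariates:
        Demographic adjustment variables (subset of ``age_group``,
        ``sex``, ``region``, ``income_group``); the 17 comorbidity
        flags always enter.
    age_scheme:
        Age grouping for adjustment: ``10-year`` (default),
        ``quartile`` or ``3-strata``.
    tie_method:
        ``efron`` (default; month-granular data are heavily tied) or
        ``breslow``.

    Attributes
    ----------
    hazard_ratios_:
        DataFrame indexed by category with columns hr, ci_low,
        ci_high, p_value.
    estimates_:
        The same as a list of :class:`HazardRatioEstimate`.
    weight_table_:
        :class:`WeightTable` derived from ``hazard_ratios_``.
    dropped_:
        Constant columns dropped before fitting.
    """

    def __init__(
        self,
        covariates: Sequence[str] = DEFAULT_COVARIATES,
        age_scheme: str = "10-year",
        tie_method: str = "efron",
        on_separation: str = "error",
        min_exposed_events: int = 0,
    ):
        self.covariates = covariates
        self.age_scheme = age_scheme
        self.tie_method = tie_method
        self.on_separation = on_separation
        self.min_exposed_events = min_exposed_events

    def _design(self, cohort: pd.DataFrame) -> pd.DataFrame:
        cols = {}
        for cat in CATEGORY_IDS:
            cols[cat] = cohort[cat].astype(float)
        df = cohort
        for cov in self.covariates:
            if cov == "age_group":
                levels = add_age_group(df, self.age_scheme)
                series, order = levels, sorted(levels.unique())
            elif cov in _LEVEL_ORDER:
                series, order = df[cov], _LEVEL_ORDER[cov]
            elif cov == "income_group":
                series, order = df[cov].astype(int), list(range(11))
            else:
                series, order = df[cov], sorted(pd.unique(df[cov]))
            for level in order[1:]:  # first level is the reference
                cols[f"{cov}[{level}]"] = (series == level).astype(float)
        return pd.DataFrame(cols, index=cohort.index)

    def fit(self, X: pd.DataFrame, y=None) -> "CoxWeightRecalibrator":
        """X is a cohort table with the 17 flags, covariates,
        ``followup_months`` and ``death``."""
        if self.on_separation not in ("error", "drop"):
            raise ValueError("on_separation must be 'error' or 'drop'")
        cohort = X
        if cohort["death"].sum() < 1:
            raise ValueError("cohort has no deaths; Cox model is not estimable")
        design = self._design(cohort)

        self.dropped_: list[str] = [
            c for c in design.columns if design[c].nunique() <= 1
        ]
        for c in self.dropped_:
            logger.warning("dropping constant column %r from Cox design", c)

        # A comorbidity flag with zero deaths among the exposed (or among
        # the unexposed) has a monotone partial likelihood: its MLE sits
        # at +-infinity, the practical form of separation in these data.
        death = cohort["death"].astype(bool).to_numpy()
        monotone, sparse = [], []
        for cat in CATEGORY_IDS:
            if cat in self.dropped_:
                continue
            exposed = design[cat].to_numpy() > 0
            n_ev_exposed = int(death[exposed].sum())
            n_ev_unexposed = int(death[~exposed].sum())
            if n_ev_exposed == 0 or n_ev_unexposed == 0:
                monotone.append(cat)
            elif n_ev_exposed < self.min_exposed_events:
                sparse.append(cat)
        if monotone:
            if self.on_separation == "error":
                raise SeparationError(
                    f"complete or quasi-complete separation for covariate(s) "
                    f"{monotone} (no events on one side of the flag)"
                )
            for c in monotone:
                logger.warning(
                    "dropping flag %r: no events on one side (separation)", c
                )
            self.dropped_ += monotone
        for c in sparse:
            logger.warning(
                "dropping flag %r: fewer than %d events among the exposed",
                c,
                self.min_exposed_events,
            )
        self.dropped_ += sparse
        design = design.drop(columns=self.dropped_)

        import warnings as _warnings

        from statsmodels.tools.sm_exceptions import ConvergenceWarning

        while True:
            model = sm.PHReg(
                cohort["followup_months"].astype(float),
                design,
                status=cohort["death"].astype(int),
                ties=self.tie_method,
            )
            try:
                with np.errstate(all="ignore"), _warnings.catch_warnings(
                    record=True
                ) as caught:
                    _warnings.simplefilter("always", ConvergenceWarning)
                    # L-BFGS with tight tolerances: Newton's analytic
                    # Hessian goes singular on nearly unidentified sparse
                    # flags long before the likelihood is a problem
                    res = model.fit(
                        method="lbfgs",
                        disp=False,
                        maxiter=500,
                        pgtol=1e-9,
                        factr=100.0,
                    )
                break
            except np.linalg.LinAlgError as exc:
                # singular Hessian: the practical signature of a nearly
                # unidentified coefficient; in drop mode shed the sparsest
                # remaining flag and retry, otherwise surface the failure
                flag_cols = [c for c in design.columns if c in CATEGORY_IDS]
                if self.on_separation != "drop" or not flag_cols:
                    raise ConvergenceError(
                        f"Cox fit failed with a singular Hessian: {exc}"
                    ) from exc
                ev = {
                    c: int(death[design[c].to_numpy() > 0].sum()) for c in flag_cols
                }
                worst = min(ev, key=ev.get)
                logger.warning(
                    "dropping flag %r after singular Hessian (%d exposed events)",
                    worst,
                    ev[worst],
                )
                self.dropped_.append(worst)
                design = design.drop(columns=[worst])
        params = pd.Series(res.params, index=design.columns)
        bse = pd.Series(res.bse, index=design.columns)
        extreme = params.index[(params.abs() > 15) | ~np.isfinite(bse)]
        if len(extreme):
            raise SeparationError(
                f"complete or quasi-complete separation for covariate(s) "
                f"{list(extreme)}"
            )
        if any(issubclass(w.category, ConvergenceWarning) for w in caught):
            score_norm = float(np.linalg.norm(model.score(res.params)))
            # BFGS sometimes stops with a "failed to converge" flag at a
            # point that is numerically stationary; only a genuinely
            # non-stationary stop is an error.
            if score_norm > 1e-2 * max(1, len(cohort)) ** 0.5:
                raise ConvergenceError(
                    "Cox partial-likelihood maximization did not converge",
                    trace={
                        "params": params.to_dict(),
                        "score_norm": score_norm,
                        "warnings": [str(w.message) for w in caught],
                    },
                )

        z = stats.norm.ppf(0.975)
        rows = {}
        for cat in CATEGORY_IDS:
            if cat in self.dropped_ or cat not in params.index:
                continue
            b, se = params[cat], bse[cat]
            rows[cat] = {
                "hr": math.exp(b),
                "ci_low": math.exp(b - z * se),
                "ci_high": math.exp(b + z * se),
                "p_value": 2 * stats.norm.sf(abs(b / se)),
            }
        self.hazard_ratios_ = pd.DataFrame(rows).T.rename_axis("category")
        self.estimates_ = [
            HazardRatioEstimate(category=c, **self.hazard_ratios_.loc[c].to_dict())
            for c in self.hazard_ratios_.index
        ]
        self.covariate_effects_ = pd.DataFrame(
            {"coef": params, "se": bse}
        ).drop(index=[c for c in CATEGORY_IDS if c in params.index])
        self.weight_table_ = derive_weights(self.estimates_)
        self.n_events_ = int(cohort["death"].sum())
        return self


def fit_cox(
    cohort: pd.DataFrame, spec: CoxModelSpec | None = None
) -> list[HazardRatioEstimate]:
    """Adjusted per-comorbidity hazard ratios on a cohort table."""
    spec = spec or CoxModelSpec()
    rec = CoxWeightRecalibrator(
        covariates=spec.covariates,
        age_scheme=spec.age_scheme,
        tie_method=spec.tie_method,
    ).fit(cohort)
    return rec.estimates_


def original_cci_weights() -> WeightTable:
    """The classic 1987 Charlson weight table."""
    return WeightTable(
        {c: {"hr": None, "relative_weight": None, "integer_weight": w}
         for c, w in ORIGINAL_CCI_WEIGHTS.items()}
    )
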