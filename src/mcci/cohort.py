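"""Cohort assembly from claims, demographics and death tables.

Time is month-granular throughout: admission and death are known only
to the calendar month, follow-up is counted in whole months from the
index admission (a patient's first admission in the study window), and
patients who die in their index month are excluded because their
follow-up would be zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .categories import CATEGORY_IDS
from .icd import CharlsonEncoder, MappingTable

logger = logging.getLogger(__name__)

COHORT_COLUMNS = (
    ["patient_id", "age", "sex", "region", "income_group", "index_month"]
    + list(CATEGORY_IDS)
    + ["followup_months", "death"]
)


class DataIntegrityError(ValueError):
    """Raised when the input tables contradict each other."""


def month_index(month: str) -> int:
    """Integer month counter for a 'YYYY-MM' string (grid is absolute)."""
    p = pd.Period(month, freq="M")
    return p.year * 12 + (p.month - 1)


def months_between(start: str, end: str) -> int:
    return month_index(end) - month_index(start)


@dataclass
class AssemblyResult:
    """Assembled cohort plus the exclusion tally."""

    cohort: pd.DataFrame
    n_input_patients: int
    n_same_month_deaths: int
    n_zero_followup: int = 0
    notes: dict = field(default_factory=dict)


def assemble_cohort(
    claims: pd.DataFrame,
    demographics: pd.DataFrame,
    deaths: pd.DataFrame,
    mapping: MappingTable | None = None,
    window_end: str = "2013-12",
    hierarchy: bool = False,
    ascertainment_months: int = 0,
) -> AssemblyResult:
    """Build the per-patient analysis table.

    Parameters
    ----------
    claims:
        Columns ``patient_id, admission_month (YYYY-MM), icd10_codes``
        (semicolon-delimited); one row per admission. The index
        admission is each patient's earliest admission; comorbidity
        flags are built from the codes of all claims rows falling
        within ``ascertainment_months`` months after the index month
        (default 0: the index month only). The window is exposed
        because claims sources differ in how long the diagnosis record
        around an index hospitalization extends.
    demographics:
        Columns ``patient_id, birth_year`` (or ``age``), ``sex, region,
        income_group``.
    deaths:
        Columns ``patient_id, death_month``; patients absent from this
        table are censored at ``window_end``.

    Patients whose death month equals their index month are excluded
    and tallied, as are censored patients admitted in the final window
    month (their follow-up would be zero).
    """
    claims = claims.copy()
    claims["_m"] = claims["admission_month"].map(month_index)
    index_adm = claims.loc[claims.groupby("patient_id")["_m"].idxmin()]
    index_adm = index_adm.set_index("patient_id")

    demo = demographics.set_index("patient_id")
    missing = index_adm.index.difference(demo.index)
    if len(missing):
        raise DataIntegrityError(
            f"{len(missing)} claims patients missing from demographics, "
            f"e.g. {list(missing[:5])}"
        )

    death_m = deaths.set_index("patient_id")["death_month"].map(month_index)
    end_m = month_index(window_end)

    pid = index_adm.index
    idx_m = index_adm["_m"]
    dm = death_m.reindex(pid)

    before = dm < idx_m
    if before.any():
        bad = list(pid[before.fillna(False)][:20])
        raise DataIntegrityError(f"death precedes index admission for patients {bad}")

    died = dm.notna()
    followup = np.where(died, dm - idx_m, end_m - idx_m)
    same_month = died & (followup == 0)
    zero_fu = ~died & (followup == 0)
    keep = ~(same_month | zero_fu)

    idx_of = idx_m.reindex(claims["patient_id"]).to_numpy()
    in_window = (claims["_m"].to_numpy() >= idx_of) & (
        claims["_m"].to_numpy() <= idx_of + ascertainment_months
    )
    codes = (
        claims.loc[in_window]
        .assign(icd10_codes=lambda d: d["icd10_codes"].fillna(""))
        .groupby("patient_id")["icd10_codes"]
        .agg(";".join)
        .reindex(pid[keep])
        .fillna("")
    )
    encoder = CharlsonEncoder(mapping=mapping, hierarchy=hierarchy).fit(None)
    flags = encoder.transform(codes)

    demo_kept = demo.reindex(pid[keep])
    if "age" in demo_kept.columns:
        age = demo_kept["age"].astype(int)
    elif "birth_year" in demo_kept.columns:
        index_year = (idx_m[keep] // 12).astype(int)
        age = (index_year - demo_kept["birth_year"].astype(int)).clip(lower=0)
    else:
        raise DataIntegrityError("demographics needs an 'age' or 'birth_year' column")

    cohort = pd.DataFrame(
        {
            "patient_id": pid[keep],
            "age": age.to_numpy(),
            "sex": demo_kept["sex"].to_numpy(),
            "region": demo_kept["region"].to_numpy(),
            "income_group": demo_kept["income_group"].astype(int).to_numpy(),
            "index_month": index_adm.loc[keep, "admission_month"].to_numpy(),
        }
    )
    for c in CATEGORY_IDS:
        cohort[c] = flags[c].to_numpy()
    cohort["followup_months"] = followup[keep].astype(int)
    cohort["death"] = died[keep].to_numpy()
    cohort = cohort.reset_index(drop=True)

    bad_income = ~cohort["income_group"].between(0, 10)
    if bad_income.any():
        raise DataIntegrityError(
            f"income_group outside 0..10 for patients "
            f"{list(cohort.loc[bad_income, 'patient_id'][:5])}"
        )

    n_excl = int(same_month.sum())
    n_zero = int(zero_fu.sum())
    if n_excl:
        logger.info("excluded %d same-month deaths", n_excl)
    if n_zero:
        logger.info("excluded %d zero-follow-up censored patients", n_zero)
    return AssemblyResult(
        cohort=cohort,
        n_input_patients=len(pid),
        n_same_month_deaths=n_excl,
        n_zero_followup=n_zero,
    )


def add_age_group(cohort: pd.DataFrame, scheme: str = "10-year") -> pd.Series:
    """Ordinal age groups under one of the supported schemes.

    ``10-year``: decade bands 0-9, 10-19, ..., 90+ (codes 0..9);
    ``quartile``: empirical age quartiles (codes 0..3);
    ``3-strata``: <60, 60-79, >=80 (codes 0..2).
    """
    age = cohort["age"].astype(float)
    if scheme == "10-year":
        return (age // 10).clip(upper=9).astype(int)
    if scheme == "quartile":
        return pd.qcut(age, 4, labels=False, duplicates="drop").astype(int)
    if scheme == "3-strata":
        return pd.cut(
            age, [-np.inf, 59, 79, np.inf], labels=False
        ).astype(int)
    raise ValueError(f"unknown age grouping scheme {scheme!r}")


def split_cohort(
    cohort: pd.DataFrame, train_fraction: float = 0.7, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Death-stratified random partition into development and validation sets.

    Within each death stratum the rows are shuffled and the first
    ``round(train_fraction * stratum size)`` go to development, so the
    death rate is preserved in both parts up to rounding. Deterministic
    for a fixed seed; exact partition (disjoint, exhaustive).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    dev_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    for _, stratum in cohort.groupby("death", sort=True):
        idx = stratum.index.to_numpy()
        if len(idx) < 2:
            logger.warning(
                "death stratum with %d member(s); assigning to development", len(idx)
            )
            dev_idx.append(idx)
            continue
        perm = rng.permutation(idx)
        n_dev = int(math.floor(train_fraction * len(idx) + 0.5))
        dev_idx.append(perm[:n_dev])
        val_idx.append(perm[n_dev:])
    dev = cohort.loc[np.concatenate(dev_idx)].sort_index()
    val = cohort.loc[np.concatenate(val_idx) if val_idx else []].sort_index()
    return dev, val
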