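"""Synthetic claims cohort with planted comorbidity effects.

Emulates the structure of Korean national health-insurance sample
claims: month-granular admissions over a 12-year window, an 11-group
family-income variable (0 = medical aid), metropolitan vs city/rural
region, three broad age strata, 17 comorbidity flags at configurable
prevalences, and an exponential-baseline proportional-hazards death
process whose per-comorbidity hazard ratios are planted. Death times
are drawn in continuous time and floored to months, reproducing the
heavy tie structure of month-resolved data; deaths in the admission
month are possible so the downstream exclusion filter is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .categories import CATEGORY_IDS
from .cohort import month_index
from .icd import MappingTable

# Published prevalence proportions of the 17 comorbidities in the
# source cohort (entire-cohort column).
DEFAULT_PREVALENCES: dict[str, float] = {
    "UD": 0.3710,
    "PVD": 0.0888,
    "MLD": 0.2405,
    "MI": 0.0178,
    "CTD": 0.0722,
    "CHF": 0.0490,
    "CPD": 0.4756,
    "DM": 0.1221,
    "DMW": 0.0617,
    "HEMI": 0.0178,
    "CVD": 0.1121,
    "DEME": 0.0290,
    "MSRD": 0.0131,
    "TUM": 0.0693,
    "MSLD": 0.0093,
    "MST": 0.0217,
    "AIDS": 0.0003,
}

# Published adjusted hazard ratios used as the planted truth.
DEFAULT_HRS: dict[str, float] = {
    "PVD": 0.79,
    "UD": 0.80,
    "MLD": 0.88,
    "CTD": 0.89,
    "DM": 0.94,
    "CPD": 0.95,
    "MI": 1.26,
    "DMW": 1.31,
    "CVD": 1.35,
    "CHF": 1.54,
    "HEMI": 1.57,
    "DEME": 1.81,
    "MSRD": 1.86,
    "TUM": 2.88,
    "MSLD": 2.94,
    "AIDS": 3.64,
    "MST": 4.29,
}

# Demographic strata frequencies of the source cohort.
AGE_STRATA_P = (0.7381, 0.2088, 0.0531)  # <60, 60-79, >=80
MALE_P = 0.4627
METRO_P = 0.4394
INCOME_P = (
    0.0347, 0.0704, 0.0668, 0.0665, 0.0730, 0.0817,
    0.0937, 0.1056, 0.1235, 0.1390, 0.1451,
)


@dataclass(frozen=True)
class CovariateEffects:
    """Log hazard ratios for the demographic strata.

    Not printed in the source; defaults are field-realistic: mortality
    rises steeply with age, is moderately higher in men and in the
    medical-aid group, and declines slightly with income decile.
    """

    age_60_79: float = 1.386  # HR 4 vs <60
    age_80_plus: float = 2.485  # HR 12 vs <60
    male: float = 0.336  # HR 1.4
    metropolitan: float = -0.051  # HR 0.95
    medical_aid: float = 0.35
    income_slope: float = -0.02  # per income decile


@dataclass
class SimulationConfig:
    n_patients: int = 10_000
    seed: int = 0
    window_start: str = "2002-01"
    window_end: str = "2013-12"
    prevalences: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES)
    )
    hr_table: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_HRS))
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    target_mortality: float = 0.0383
    # optional {(cat_a, cat_b): odds multiplier} applied to cat_b among
    # patients with cat_a set
    comorbidity_correlation: Mapping[tuple[str, str], float] | None = None
    baseline_hazard_scale: float = 1.0  # multiplies the calibrated baseline

    def __post_init__(self):
        for c, p in self.prevalences.items():
            if not 0 <= p < 1:
                raise ValueError(f"prevalence for {c} outside [0, 1): {p}")
        if any(h <= 0 for h in self.hr_table.values()):
            raise ValueError("hazard ratios must be positive")
        if not 0 < self.target_mortality < 1:
            raise ValueError("target mortality must be in (0, 1)")


@dataclass
class SimulationResult:
    claims: pd.DataFrame
    demographics: pd.DataFrame
    deaths: pd.DataFrame
    truth: dict

    def write_csv(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("claims", self.claims),
            ("demographics", self.demographics),
            ("deaths", self.deaths),
        ):
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        p = out / "truth.json"
        serializable = {
            k: v for k, v in self.truth.items() if k not in ("flags", "linear_predictor")
        }
        p.write_text(json.dumps(serializable, indent=2, default=str) + "\n")
        paths["truth"] = p
        return paths


def _sample_flags(
    rng: np.random.Generator, config: SimulationConfig
) -> pd.DataFrame:
    n = config.n_patients
    flags = pd.DataFrame(
        {c: rng.random(n) < config.prevalences.get(c, 0.0) for c in CATEGORY_IDS}
    )
    if config.comorbidity_correlation:
        for (a, b), mult in config.comorbidity_correlation.items():
            p_b = config.prevalences.get(b, 0.0)
            odds = p_b / (1 - p_b) * mult
            p_adj = odds / (1 + odds)
            among_a = flags[a].to_numpy()
            flags.loc[among_a, b] = rng.random(int(among_a.sum())) < p_adj
    return flags


def simulate_cohort(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate claims, demographics and death tables plus a truth record.

    The per-month baseline hazard is calibrated by root-finding so the
    expected death proportion over each patient's own follow-up horizon
    matches ``target_mortality``, then multiplied by
    ``baseline_hazard_scale`` (a knob for scale-invariance checks).
    Fully deterministic for a fixed seed.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    eff = config.covariate_effects

    # demographics ---------------------------------------------------------
    stratum = rng.choice(3, size=n, p=AGE_STRATA_P)
    age = np.where(
        stratum == 0,
        rng.integers(0, 60, size=n),
        np.where(
            stratum == 1, rng.integers(60, 80, size=n), rng.integers(80, 95, size=n)
        ),
    )
    sex = np.where(rng.random(n) < MALE_P, "male", "female")
    region = np.where(rng.random(n) < METRO_P, "metropolitan", "city_or_rural")
    income = rng.choice(11, size=n, p=INCOME_P)

    # comorbidity flags ----------------------------------------------------
    flags = _sample_flags(rng, config)

    # admissions -----------------------------------------------------------
    start_m, end_m = month_index(config.window_start), month_index(config.window_end)
    # final window month excluded so censored follow-up is always >= 1 month
    idx_m = rng.integers(start_m, end_m, size=n)
    horizon = (end_m - idx_m).astype(float)

    # proportional-hazards death process ----------------------------------
    log_hr = np.array([np.log(config.hr_table.get(c, 1.0)) for c in CATEGORY_IDS])
    lp = flags.to_numpy(dtype=float) @ log_hr
    lp += np.where(stratum == 1, eff.age_60_79, 0.0)
    lp += np.where(stratum == 2, eff.age_80_plus, 0.0)
    lp += np.where(sex == "male", eff.male, 0.0)
    lp += np.where(region == "metropolitan", eff.metropolitan, 0.0)
    lp += np.where(income == 0, eff.medical_aid, eff.income_slope * income)

    rel = np.exp(lp)

    def mean_death(lam0: float) -> float:
        return float(np.mean(1.0 - np.exp(-lam0 * rel * horizon)))

    lo, hi = 1e-12, 1.0
    if mean_death(hi) < config.target_mortality:
        raise ValueError("target mortality unreachable even at unit baseline hazard")
    lam0 = brentq(lambda l: mean_death(l) - config.target_mortality, lo, hi, xtol=1e-15)
    lam0 *= config.baseline_hazard_scale
    if (lam0 * rel).max() > 1.0:
        raise ValueError(
            "infeasible configuration: per-month hazard exceeds 1 for some patients"
        )

    t_death = rng.exponential(1.0, size=n) / (lam0 * rel)
    died = t_death < horizon
    death_m = idx_m + np.floor(t_death).astype(int)

    # tables ---------------------------------------------------------------
    pid = np.array([f"P{i:07d}" for i in range(n)])

    def fmt(m: np.ndarray) -> np.ndarray:
        years, mons = m // 12, m % 12 + 1
        return np.array([f"{y}-{mo:02d}" for y, mo in zip(years, mons)])

    mapping = MappingTable.bundled()
    noise_pool = ("Z999", "R51", "A09", "S720", "J06")
    codes_col = []
    for i in range(n):
        codes: list[str] = []
        row = flags.iloc[i]
        for c in CATEGORY_IDS:
            if row[c]:
                prefixes = mapping.entries[c]
                k = int(rng.integers(1, 4))
                picks = rng.choice(len(prefixes), size=min(k, len(prefixes)), replace=False)
                codes.extend(prefixes[j] for j in sorted(picks))
        n_noise = int(rng.integers(0, 3))
        codes.extend(noise_pool[j] for j in rng.integers(0, len(noise_pool), size=n_noise))
        codes_col.append(";".join(codes))

    claims = pd.DataFrame(
        {"patient_id": pid, "admission_month": fmt(idx_m), "icd10_codes": codes_col}
    )
    demographics = pd.DataFrame(
        {
            "patient_id": pid,
            "birth_year": (idx_m // 12) - age,
            "sex": sex,
            "region": region,
            "income_group": income,
        }
    )
    deaths = pd.DataFrame(
        {"patient_id": pid[died], "death_month": fmt(death_m[died])}
    )

    truth = {
        "config": _config_dict(config),
        "baseline_hazard": lam0,
        "n_deaths": int(died.sum()),
        "n_same_month_deaths": int((died & (np.floor(t_death) == 0)).sum()),
        "flags": flags.assign(patient_id=pid).set_index("patient_id"),
        "linear_predictor": pd.Series(lp, index=pid),
    }
    return SimulationResult(
        claims=claims, demographics=demographics, deaths=deaths, truth=truth
    )


def _config_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    if d.get("comorbidity_correlation"):
        d["comorbidity_correlation"] = {
            f"{a}|{b}": v for (a, b), v in d["comorbidity_correlation"].items()
        }
    return d


def recovery_experiment(
    config: SimulationConfig | None = None,
    train_fraction: float = 0.7,
    split_seed: int | None = None,
) -> dict:
    """Plant known hazard ratios, run the full recalibration pipeline and
    compare the recovered integer weights with those implied by the truth.

    Returns a report with per-category true/estimated HRs and weights,
    the number of matching integer weights, and cohort bookkeeping.
    """
    from .cohort import assemble_cohort, split_cohort
    from .recalibration import CoxWeightRecalibrator, derive_weights

    config = config or SimulationConfig(n_patients=50_000)
    sim = simulate_cohort(config)
    assembled = assemble_cohort(
        sim.claims, sim.demographics, sim.deaths, window_end=config.window_end
    )
    dev, val = split_cohort(
        assembled.cohort,
        train_fraction,
        seed=config.seed if split_seed is None else split_seed,
    )
    rec = CoxWeightRecalibrator(on_separation="drop").fit(dev)
    true_wt = derive_weights(dict(config.hr_table))

    rows = []
    n_match = 0
    for c in CATEGORY_IDS:
        true_hr = config.hr_table.get(c, 1.0)
        est = rec.hazard_ratios_.loc[c] if c in rec.hazard_ratios_.index else None
        est_w = rec.weight_table_.weight(c) if c in rec.weight_table_ else None
        match = est_w == true_wt.weight(c)
        n_match += bool(match)
        rows.append(
            {
                "category": c,
                "true_hr": true_hr,
                "estimated_hr": None if est is None else est["hr"],
                "ci_low": None if est is None else est["ci_low"],
                "ci_high": None if est is None else est["ci_high"],
                "true_weight": true_wt.weight(c),
                "estimated_weight": est_w,
                "match": match,
            }
        )
    return {
        "table": pd.DataFrame(rows).set_index("category"),
        "n_match": n_match,
        "n_categories": len(CATEGORY_IDS),
        "n_development": len(dev),
        "n_validation": len(val),
        "n_excluded_same_month": assembled.n_same_month_deaths,
        "weight_table": rec.weight_table_,
        "estimates": rec.estimates_,
    }
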