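"""Index scores and percentile-based risk groups.

A patient's score is the sum of integer weights over their flagged
comorbidities (after severity-pair resolution by default). Risk groups
follow the percentile scheme used for inpatient mortality
stratification: <=50th, 50-80th, 80-90th and >90th percentile of the
score distribution, with cut-offs read off the empirical CDF.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .categories import CATEGORY_IDS
from .icd import apply_hierarchy
from .recalibration import WeightTable

GROUP_LABELS = ("G1", "G2", "G3", "G4")


def score(
    profile: Mapping[str, bool], weights: WeightTable, hierarchy: bool = True
) -> int:
    """Sum of integer weights over a patient's flagged categories."""
    prof = apply_hierarchy(profile, hierarchy)
    missing = [c for c, on in prof.items() if on and c not in weights]
    if missing:
        raise KeyError(f"flagged categories missing from weight table: {missing}")
    return sum(weights.weight(c) for c, on in prof.items() if on)


class ComorbidityScorer(BaseEstimator, TransformerMixin):
    """Transformer from comorbidity-flag tables to integer index scores.

    Parameters
    ----------
    weights:
        A :class:`WeightTable` or the name of a bundled table
        (``original_cci`` or ``mcci_a``).
    hierarchy:
        Resolve severity pairs before summing (on by default: only the
        severer member of each pair is counted).
    """

    def __init__(self, weights: WeightTable | str = "mcci_a", hierarchy: bool = True):
        self.weights = weights
        self.hierarchy = hierarchy

    def _weights(self) -> WeightTable:
        if isinstance(self.weights, WeightTable):
            return self.weights
        return WeightTable.builtin(self.weights)

    def fit(self, X=None, y=None):
        self.weight_table_ = self._weights()
        return self

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        """X: DataFrame with the 17 boolean category columns. Returns an
        integer score per row."""
        if not hasattr(self, "weight_table_"):
            self.fit(X)
        wt = self.weight_table_
        flags = X[list(CATEGORY_IDS)].astype(bool).copy()
        if self.hierarchy:
            from .categories import SEVERITY_PAIRS

            for severe, mild in SEVERITY_PAIRS.items():
                flags.loc[flags[severe], mild] = False
        missing = [c for c in CATEGORY_IDS if c not in wt]
        if missing and flags[missing].to_numpy().any():
            raise KeyError(f"flagged categories missing from weight table: {missing}")
        w = np.array([wt.weight(c) if c in wt else 0 for c in CATEGORY_IDS])
        return flags.to_numpy() @ w


def score_cohort(
    cohort: pd.DataFrame, weights: WeightTable, hierarchy: bool = True
) -> pd.Series:
    """Scores for every row of a cohort table (17 flag columns required)."""
    scorer = ComorbidityScorer(weights=weights, hierarchy=hierarchy).fit()
    return pd.Series(scorer.transform(cohort), index=cohort.index, name="score")


@dataclass(frozen=True)
class RiskGrouping:
    """Percentile cut-offs and the resulting group label per patient."""

    cutoffs: tuple[int, ...]
    groups: pd.Series


def compute_cutoffs(
    scores: Iterable[int], percentiles: Sequence[float] = (50, 80, 90)
) -> tuple[int, ...]:
    """Inverse empirical CDF on the integer score distribution.

    The cut-off for percentile p is the smallest observed score s such
    that the fraction of scores <= s is at least p/100.
    """
    arr = np.sort(np.asarray(list(scores)))
    if arr.size == 0:
        raise ValueError("empty score list")
    if not all(0 < p < 100 for p in percentiles) or list(percentiles) != sorted(
        set(percentiles)
    ):
        raise ValueError("percentiles must be strictly increasing within (0, 100)")
    values, counts = np.unique(arr, return_counts=True)
    # compare counts on a common integer-ish scale to dodge float CDF ties
    scaled = np.cumsum(counts) * 100.0
    cutoffs = []
    for p in percentiles:
        i = int(np.searchsorted(scaled, p * arr.size))
        cutoffs.append(int(values[min(i, len(values) - 1)]))
    return tuple(cutoffs)


def assign_groups(scores: Iterable[int], cutoffs: Sequence[int]) -> RiskGrouping:
    """Four risk groups from three cut-offs (boundaries inclusive below):
    G1 if score <= c50; G2 if c50 < score <= c80; G3 if c80 < score <= c90;
    G4 otherwise."""
    c50, c80, c90 = cutoffs
    if not c50 <= c80 <= c90:
        raise ValueError("cutoffs must be non-decreasing")
    s = pd.Series(scores)
    labels = np.select(
        [s <= c50, s <= c80, s <= c90],
        ["G1", "G2", "G3"],
        default="G4",
    )
    return RiskGrouping(cutoffs=(c50, c80, c90), groups=pd.Series(labels, index=s.index, name="risk_group"))


class PercentileRiskGrouper(BaseEstimator, TransformerMixin):
    """Learn percentile cut-offs on a score distribution, then label scores.

    ``fit`` computes ``cutoffs_`` from the supplied scores (development
    cohort); ``transform`` assigns the G1-G4 labels to any scores.
    """

    def __init__(self, percentiles: Sequence[float] = (50, 80, 90)):
        self.percentiles = percentiles

    def fit(self, X, y=None):
        self.cutoffs_ = compute_cutoffs(np.ravel(np.asarray(X)), self.percentiles)
        return self

    def transform(self, X) -> np.ndarray:
        return assign_groups(np.ravel(np.asarray(X)), self.cutoffs_).groups.to_numpy()
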