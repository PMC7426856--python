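"""ICD-10 code normalization and Charlson comorbidity mapping.

Claims diagnosis codes arrive in assorted shapes ("C78.7", " i21 ");
they are normalized to uppercase dot-free form and matched against a
prefix table mapping codes to the 17 Charlson categories. The bundled
table follows the published ICD-10 Charlson coding algorithm of
Quan et al. (2005); users may substitute any CSV with columns
``category_id,icd10_prefix``.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .categories import CATEGORY_IDS, SEVERITY_PAIRS

logger = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z][0-9]{2}[A-Z0-9]{0,2}$")


class MalformedCodeError(ValueError):
    """Raised for diagnosis codes that cannot be normalized."""


@dataclass(frozen=True)
class DiagnosisCode:
    """An ICD-10 diagnosis code as found in claims plus its normalized form."""

    raw: str
    normalized: str


def normalize_code(raw: str) -> DiagnosisCode:
    """Normalize a raw ICD-10 code: strip whitespace, uppercase, drop the dot.

    Raises :class:`MalformedCodeError` for empty input or codes that do
    not start with a letter. Codes with trailing junk beyond the valid
    ``letter + 2 digits + up to 2 alphanumerics`` pattern are truncated
    to the valid prefix with a warning rather than rejected.
    """
    if not isinstance(raw, str):
        raise MalformedCodeError(f"diagnosis code must be a string, got {raw!r}")
    stripped = raw.strip()
    if not stripped:
        raise MalformedCodeError(f"empty diagnosis code: {raw!r}")
    if not stripped[0].isalpha():
        raise MalformedCodeError(f"malformed diagnosis code (no leading letter): {raw!r}")
    norm = stripped.upper().replace(".", "")
    if not _CODE_RE.match(norm):
        m = re.match(r"^[A-Z][0-9]{2}[A-Z0-9]{0,2}", norm)
        if m is None:
            raise MalformedCodeError(f"malformed diagnosis code: {raw!r}")
        logger.warning("truncating malformed diagnosis code %r to %r", raw, m.group(0))
        norm = m.group(0)
    return DiagnosisCode(raw=raw, normalized=norm)


class MappingTable:
    """Prefix table from ICD-10 codes to Charlson categories.

    Parameters
    ----------
    entries:
        Mapping of category id to a list of normalized ICD-10 prefixes.
    """

    def __init__(self, entries: Mapping[str, Sequence[str]]):
        unknown = set(entries) - set(CATEGORY_IDS)
        if unknown:
            raise ValueError(f"unknown category ids: {sorted(unknown)}")
        missing = [c for c in CATEGORY_IDS if not entries.get(c)]
        if missing:
            raise ValueError(f"categories with no ICD-10 prefixes: {missing}")
        self.entries: dict[str, tuple[str, ...]] = {
            c: tuple(entries[c]) for c in CATEGORY_IDS
        }

    @classmethod
    def from_csv(cls, path: str | Path) -> "MappingTable":
        df = pd.read_csv(path, dtype=str)
        required = {"category_id", "icd10_prefix"}
        if not required.issubset(df.columns):
            raise ValueError(f"mapping CSV must have columns {sorted(required)}")
        entries: dict[str, list[str]] = {}
        for cat, prefix in zip(df["category_id"], df["icd10_prefix"]):
            entries.setdefault(cat, []).append(prefix.strip().upper())
        return cls(entries)

    @classmethod
    def bundled(cls) -> "MappingTable":
        """The packaged Quan et al. ICD-10 Charlson coding table."""
        with resources.as_file(
            resources.files("mcci.data").joinpath("charlson_icd10.csv")
        ) as p:
            return cls.from_csv(p)

    def categories_for(self, normalized: str) -> set[str]:
        return {
            cat
            for cat, prefixes in self.entries.items()
            if any(normalized.startswith(p) for p in prefixes)
        }


def map_code(code: DiagnosisCode | str, table: MappingTable) -> set[str]:
    """Return the set of category ids whose prefix list matches the code.

    Unmapped codes are legal and yield the empty set.
    """
    norm = code.normalized if isinstance(code, DiagnosisCode) else normalize_code(code).normalized
    return table.categories_for(norm)


def build_profile(
    codes: Iterable[DiagnosisCode | str], table: MappingTable
) -> dict[str, bool]:
    """Collapse a patient's diagnosis codes into 17 comorbidity flags."""
    flags = {c: False for c in CATEGORY_IDS}
    for code in codes:
        for cat in map_code(code, table):
            flags[cat] = True
    return flags


def apply_hierarchy(profile: Mapping[str, bool], enabled: bool = True) -> dict[str, bool]:
    """Resolve severity pairs: the severe member suppresses the mild one.

    Moderate/severe liver disease clears mild liver disease; diabetes
    with end-organ damage clears uncomplicated diabetes; metastatic
    solid tumor clears any (non-metastatic) tumor. With ``enabled``
    false this is the identity.
    """
    out = {c: bool(profile[c]) for c in CATEGORY_IDS}
    if enabled:
        for severe, mild in SEVERITY_PAIRS.items():
            if out[severe]:
                out[mild] = False
    return out


class CharlsonEncoder(BaseEstimator, TransformerMixin):
    """Transformer from per-patient ICD-10 code lists to comorbidity flags.

    Parameters
    ----------
    mapping:
        A :class:`MappingTable`, a path to a mapping CSV, or None for
        the bundled table.
    hierarchy:
        Whether to resolve severity pairs in the output profiles.
        Off by default, matching how prevalences are reported;
        scoring turns it on separately.
    """

    def __init__(self, mapping: MappingTable | str | None = None, hierarchy: bool = False):
        self.mapping = mapping
        self.hierarchy = hierarchy

    def _table(self) -> MappingTable:
        if isinstance(self.mapping, MappingTable):
            return self.mapping
        if self.mapping is None:
            return MappingTable.bundled()
        return MappingTable.from_csv(self.mapping)

    def fit(self, X, y=None):
        self.mapping_table_ = self._table()
        self.categories_ = list(CATEGORY_IDS)
        return self

    def transform(self, X) -> pd.DataFrame:
        """X: iterable of code lists, or a Series/DataFrame with a
        semicolon-delimited ``icd10_codes`` column. Returns a boolean
        DataFrame with one column per category."""
        if not hasattr(self, "mapping_table_"):
            self.fit(X)
        if isinstance(X, pd.DataFrame):
            codes_iter = X["icd10_codes"]
        else:
            codes_iter = X
        rows = []
        for item in codes_iter:
            if item is None or (isinstance(item, float) and pd.isna(item)):
                codes = []  # missing cell in a claims CSV
            elif isinstance(item, str):
                codes = [c for c in item.split(";") if c.strip()]
            else:
                codes = list(item)
            prof = build_profile(codes, self.mapping_table_)
            rows.append(apply_hierarchy(prof, self.hierarchy))
        index = X.index if isinstance(X, (pd.DataFrame, pd.Series)) else None
        return pd.DataFrame(rows, columns=list(CATEGORY_IDS), index=index)
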