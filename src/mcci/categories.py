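"""The 17 Charlson comorbidity categories and their classic weights.

Category ids are short mnemonics used as column names throughout the
package; labels are the display names used in reports.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ComorbidityCategory:
    """One of the 17 Charlson comorbidity categories."""

    id: str
    label: str


CATEGORIES: tuple[ComorbidityCategory, ...] = (
    ComorbidityCategory("MI", "Myocardial infarct"),
    ComorbidityCategory("CHF", "Congestive heart failure"),
    ComorbidityCategory("PVD", "Peripheral vascular disease"),
    ComorbidityCategory("CVD", "Cerebrovascular disease"),
    ComorbidityCategory("DEME", "Dementia"),
    ComorbidityCategory("CPD", "Chronic pulmonary disease"),
    ComorbidityCategory("CTD", "Connective tissue disease"),
    ComorbidityCategory("UD", "Ulcer disease"),
    ComorbidityCategory("MLD", "Mild liver disease"),
    ComorbidityCategory("DM", "Diabetes mellitus"),
    ComorbidityCategory("HEMI", "Hemiplegia"),
    ComorbidityCategory("DMW", "Diabetes mellitus with end organ damage"),
    ComorbidityCategory("MSRD", "Moderate or severe renal disease"),
    ComorbidityCategory("TUM", "Any tumor, leukemia, lymphoma"),
    ComorbidityCategory("MSLD", "Moderate or severe liver disease"),
    ComorbidityCategory("MST", "Metastatic solid tumor"),
    ComorbidityCategory("AIDS", "AIDS"),
)

CATEGORY_IDS: tuple[str, ...] = tuple(c.id for c in CATEGORIES)

LABELS: dict[str, str] = {c.id: c.label for c in CATEGORIES}

# Severity pairs: when the severe member is present the mild one is not
# counted (classic Charlson scoring convention). Keys are severe -> mild.
SEVERITY_PAIRS: dict[str, str] = {
    "MSLD": "MLD",
    "DMW": "DM",
    "MST": "TUM",
}

# The 1987 Charlson weights.
ORIGINAL_CCI_WEIGHTS: dict[str, int] = {
    "MI": 1,
    "CHF": 1,
    "PVD": 1,
    "CVD": 1,
    "DEME": 1,
    "CPD": 1,
    "CTD": 1,
    "UD": 1,
    "MLD": 1,
    "DM": 1,
    "HEMI": 2,
    "DMW": 2,
    "MSRD": 2,
    "TUM": 2,
    "MSLD": 3,
    "MST": 6,
    "AIDS": 6,
}
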