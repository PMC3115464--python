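"""Disease definitions: ICD-9 pattern lists for the twelve studied conditions.

The shipped table covers twelve aging-related cancer and chronic non-cancer
diseases identified from administrative claims: acute coronary heart disease,
stroke, ulcer, breast / prostate / lung / colon cancer, melanoma, diabetes,
asthma, Parkinson's disease and Alzheimer's disease.  Breast cancer is
restricted to women and prostate cancer to men.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import pandas as pd

from .icd9 import match_icd9

__all__ = ["DiseaseDefinition", "load_definitions", "DISEASE_ORDER"]

#: canonical ordering (decreasing onset cost, as conventionally presented)
DISEASE_ORDER = [
    "achd",
    "stroke",
    "ulcer",
    "breast_cancer",
    "prostate_cancer",
    "melanoma",
    "lung_cancer",
    "colon_cancer",
    "diabetes",
    "asthma",
    "parkinsons",
    "alzheimers",
]


@dataclass(frozen=True)
class DiseaseDefinition:
    """A disease identified by a list of ICD-9 patterns.

    Parameters
    ----------
    key : short machine label, e.g. ``"achd"``.
    name : display name.
    icd9_patterns : patterns in the forms ``NNN.xx`` / ``NNN.x1`` / ``NNN.D``.
    sex_restriction : ``"female"``, ``"male"`` or None.
    """

    key: str
    name: str
    icd9_patterns: tuple[str, ...] = field(default_factory=tuple)
    sex_restriction: str | None = None

    def matches(self, code: str) -> bool:
        """True if *code* matches any of this disease's patterns."""
        return any(match_icd9(code, p) for p in self.icd9_patterns)


def load_definitions(path=None) -> dict[str, DiseaseDefinition]:
    """Load disease definitions from a CSV (disease,name,pattern,sex_restriction).

    With no *path*, the packaged definitions for the twelve studied diseases
    are returned, keyed by the short label.
    """
    if path is None:
        ref = importlib.resources.files("costtraj.data") / "disease_definitions.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, dtype=str)
    else:
        table = pd.read_csv(path, dtype=str)
    out: dict[str, DiseaseDefinition] = {}
    for key, grp in table.groupby("disease", sort=False):
        sex = grp["sex_restriction"].dropna().unique()
        out[key] = DiseaseDefinition(
            key=key,
            name=grp["name"].iloc[0],
            icd9_patterns=tuple(grp["pattern"]),
            sex_restriction=sex[0] if len(sex) else None,
        )
    return out
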