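"""Charlson comorbidity index from ICD-9 administrative claims.

Seventeen chronic-condition groups are identified from ICD-9-CM codes using
the Quan et al. enhanced coding algorithm; the index is the weighted sum of
the groups present in a person's claims over a lookback window (default
12 months), each group counted at most once.  Weights are the original
Charlson weights, which reflect relative mortality risk.

Hierarchy rules: complicated diabetes supersedes uncomplicated diabetes;
metastatic solid tumor supersedes any malignancy; moderate/severe liver
disease supersedes mild liver disease.
"""

from __future__ import annotations

from datetime import date, timedelta

import pandas as pd

from .icd9 import canonicalize

__all__ = ["CHARLSON_WEIGHTS", "code_to_groups", "charlson_index", "charlson_category"]

# dot-free ICD-9-CM prefixes per condition group (Quan ICD-9 enhanced)
_GROUP_PREFIXES: dict[str, tuple[str, ...]] = {
    "mi": ("410", "412"),
    "chf": (
        "39891", "40201", "40211", "40291", "40401", "40403", "40411",
        "40413", "40491", "40493", "4254", "4255", "4256", "4257", "4258",
        "4259", "428",
    ),
    "pvd": ("0930", "4373", "440", "441", "4431", "4432", "4433", "4434",
            "4435", "4436", "4437", "4438", "4439", "4471", "5571", "5579",
            "V434"),
    "cevd": ("36234", "430", "431", "432", "433", "434", "435", "436",
             "437", "438"),
    "dementia": ("290", "2941", "3312"),
    "copd": ("4168", "4169", "490", "491", "492", "493", "494", "495",
             "496", "497", "498", "499", "500", "501", "502", "503", "504",
             "505", "5064", "5081", "5088"),
    "rheumatic": ("4465", "7100", "7101", "7102", "7103", "7104", "7140",
                  "7141", "7142", "7148", "725"),
    "pud": ("531", "532", "533", "534"),
    "mild_liver": ("07022", "07023", "07032", "07033", "07044", "07054",
                   "0706", "0709", "570", "571", "5733", "5734", "5738",
                   "5739", "V427"),
    "diabetes": ("2500", "2501", "2502", "2503", "2508", "2509"),
    "diabetes_complicated": ("2504", "2505", "2506", "2507"),
    "paralysis": ("3341", "342", "343", "3440", "3441", "3442", "3443",
                  "3444", "3445", "3446", "3449"),
    "renal": ("40301", "40311", "40391", "40402", "40403", "40412", "40413",
              "40492", "40493", "582", "5830", "5831", "5832", "5833",
              "5834", "5835", "5836", "5837", "585", "586", "5880", "V420",
              "V451", "V56"),
    "cancer": tuple(str(r) for r in range(140, 173))
    + tuple(str(r) for r in range(174, 196))
    + tuple(str(r) for r in range(200, 209))
    + ("2386",),
    "severe_liver": ("4560", "4561", "4562", "5722", "5723", "5724", "5728"),
    "mets": ("196", "197", "198", "199"),
    "hiv": ("042", "043", "044"),
}

#: original Charlson weights per condition group
CHARLSON_WEIGHTS: dict[str, int] = {
    "mi": 1, "chf": 1, "pvd": 1, "cevd": 1, "dementia": 1, "copd": 1,
    "rheumatic": 1, "pud": 1, "mild_liver": 1, "diabetes": 1,
    "diabetes_complicated": 2, "paralysis": 2, "renal": 2, "cancer": 2,
    "severe_liver": 3, "mets": 6, "hiv": 6,
}

# (superseding group, superseded group)
_HIERARCHY = [
    ("diabetes_complicated", "diabetes"),
    ("mets", "cancer"),
    ("severe_liver", "mild_liver"),
]


def code_to_groups(code: str) -> set[str]:
    """Charlson condition groups matched by a single ICD-9 code."""
    c = canonicalize(code)
    return {
        g for g, prefixes in _GROUP_PREFIXES.items()
        if any(c.startswith(p) for p in prefixes)
    }


def _apply_hierarchy(groups: set[str]) -> set[str]:
    out = set(groups)
    for winner, loser in _HIERARCHY:
        if winner in out:
            out.discard(loser)
    return out


def charlson_index(
    claims: pd.DataFrame,
    person_id,
    index_date: date,
    lookback: int = 365,
) -> int:
    """Charlson index for one person from claims in ``[index_date - lookback, index_date)``.

    *claims* needs columns ``person_id``, ``service_date`` (datetime-like),
    ``icd9_primary`` and optionally ``icd9_secondary`` (pipe-delimited).
    All diagnosis positions and all claim sources contribute.  An empty
    window yields 0.
    """
    sub = claims[claims["person_id"] == person_id]
    if sub.empty:
        return 0
    dates = pd.to_datetime(sub["service_date"])
    lo = pd.Timestamp(index_date) - pd.Timedelta(days=lookback)
    sub = sub[(dates >= lo) & (dates < pd.Timestamp(index_date))]
    groups: set[str] = set()
    for _, row in sub.iterrows():
        groups |= code_to_groups(row["icd9_primary"])
        sec = row.get("icd9_secondary")
        if isinstance(sec, str) and sec:
            for code in sec.split("|"):
                groups |= code_to_groups(code)
    groups = _apply_hierarchy(groups)
    return sum(CHARLSON_WEIGHTS[g] for g in groups)


def charlson_indices(
    claims: pd.DataFrame,
    index_date: date,
    person_ids=None,
    lookback: int = 365,
) -> pd.Series:
    """Charlson index for many persons sharing one index date (vectorised).

    Returns a Series indexed by person_id covering *person_ids* (default:
    everyone appearing in the window), with 0 for persons without
    qualifying codes.
    """
    dates = pd.to_datetime(claims["service_date"])
    lo = pd.Timestamp(index_date) - pd.Timedelta(days=lookback)
    sub = claims[(dates >= lo) & (dates < pd.Timestamp(index_date))]
    if person_ids is not None:
        sub = sub[sub["person_id"].isin(set(person_ids))]

    group_map = {c: frozenset(code_to_groups(c)) for c in sub["icd9_primary"].unique()}
    person_groups: dict = {}
    for pid, code, sec in zip(
        sub["person_id"], sub["icd9_primary"], sub.get("icd9_secondary", [""] * len(sub))
    ):
        gs = group_map[code]
        if gs:
            person_groups.setdefault(pid, set()).update(gs)
        if isinstance(sec, str) and sec:
            for s in sec.split("|"):
                person_groups.setdefault(pid, set()).update(code_to_groups(s))
    index = person_ids if person_ids is not None else sorted(person_groups)
    out = {}
    for pid in index:
        groups = _apply_hierarchy(person_groups.get(pid, set()))
        out[pid] = sum(CHARLSON_WEIGHTS[g] for g in groups)
    return pd.Series(out, dtype=int)


def charlson_category(index: int) -> str:
    """Stratification level for a Charlson index: ``0``, ``1``, ``2`` or ``>2``."""
    if index < 0:
        raise ValueError("Charlson index cannot be negative")
    return str(index) if index <= 2 else ">2"
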