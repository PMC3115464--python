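"""Claims-based disease-onset ascertainment.

The onset date of a chronic disease is reconstructed from administrative
claims by a two-record rule:

(i)  the *onset record* is the earliest claim carrying a matching ICD-9
     code as the primary diagnosis in one of four qualifying sources
     (inpatient care, outpatient care, physician services, skilled
     nursing facilities);
(ii) a second such claim must exist on a strictly later, different date,
     no more than 0.3 years (109.575 days, so integer day gaps up to 109)
     after the onset record.

Persons with any matching claim — any diagnosis position, any source —
before the reference interview date are *prevalent* cases and are excluded
before incidence ascertainment.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .diseases import DiseaseDefinition
from .icd9 import match_icd9

__all__ = [
    "CONFIRM_WINDOW_DAYS",
    "QUALIFYING_SOURCES",
    "OnsetRecord",
    "find_onset",
    "find_onsets",
    "exclude_prevalent",
    "select_incident_cohort",
]

#: 0.3 years expressed in days; integer-day gaps <= 109 qualify
CONFIRM_WINDOW_DAYS = 0.3 * 365.25

QUALIFYING_SOURCES = frozenset({"inpatient", "outpatient", "physician", "snf"})


@dataclass(frozen=True)
class OnsetRecord:
    """A detected disease onset for one person."""

    person_id: str
    disease: str
    onset_date: date
    first_record_id: int
    confirming_record_id: int
    confirm_gap_days: int


def _codes_match_any(codes: pd.Series, disease: DiseaseDefinition) -> np.ndarray:
    """Vectorised: does each primary code match any of the disease patterns?"""
    uniq = codes.astype(str).unique()
    ok = {u for u in uniq if disease.matches(u)}
    return codes.astype(str).isin(ok).to_numpy()


def _secondary_matches(sec: pd.Series, disease: DiseaseDefinition) -> np.ndarray:
    out = np.zeros(len(sec), dtype=bool)
    cache: dict[str, bool] = {}
    for i, v in enumerate(sec.fillna("")):
        if not v:
            continue
        hit = False
        for code in str(v).split("|"):
            if code not in cache:
                cache[code] = disease.matches(code)
            if cache[code]:
                hit = True
                break
        out[i] = hit
    return out


def find_onset(
    records: pd.DataFrame, disease: DiseaseDefinition
) -> OnsetRecord | None:
    """Apply the two-record onset rule to one person's claims.

    *records* needs columns ``service_date``, ``source``, ``icd9_primary``
    (and optionally ``person_id``).  Returns the earliest qualifying
    primary-diagnosis record's date if a second qualifying record confirms
    it on a strictly later date within 0.3 years; otherwise None.  Ties on
    the earliest date are resolved by record id (the DataFrame index).
    """
    if records.empty:
        return None
    qual = records[
        records["source"].isin(QUALIFYING_SOURCES)
        & _codes_match_any(records["icd9_primary"], disease)
    ]
    if len(qual) < 2:
        return None
    dates = pd.to_datetime(qual["service_date"])
    first_date = dates.min()
    # earliest record; tie on date broken by record id
    firsts = qual[dates == first_date]
    first_id = int(firsts.index.min())
    gaps = (dates - first_date).dt.days
    confirm = qual[(gaps >= 1) & (gaps <= CONFIRM_WINDOW_DAYS)]
    if confirm.empty:
        return None
    confirm_dates = pd.to_datetime(confirm["service_date"])
    cfirst = confirm[confirm_dates == confirm_dates.min()]
    confirm_id = int(cfirst.index.min())
    gap = int((confirm_dates.min() - first_date).days)
    pid = records["person_id"].iloc[0] if "person_id" in records.columns else ""
    return OnsetRecord(
        person_id=pid,
        disease=disease.key,
        onset_date=first_date.date(),
        first_record_id=first_id,
        confirming_record_id=confirm_id,
        confirm_gap_days=gap,
    )


def find_onsets(
    claims: pd.DataFrame, disease: DiseaseDefinition, person_ids=None
) -> list[OnsetRecord]:
    """Two-record rule applied per person over a claims table.

    Restricting first to claims matching the disease keeps this linear in
    the number of matching claims, not the full table.
    """
    mask = claims["source"].isin(QUALIFYING_SOURCES) & _codes_match_any(
        claims["icd9_primary"], disease
    )
    matched = claims[mask]
    if person_ids is not None:
        matched = matched[matched["person_id"].isin(set(person_ids))]
    out = []
    for pid, grp in matched.groupby("person_id", sort=True):
        rec = find_onset(grp, disease)
        if rec is not None:
            out.append(rec)
    return out


def exclude_prevalent(
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    disease: DiseaseDefinition,
    interview_date: date | None = None,
    any_position: bool = True,
) -> pd.DataFrame:
    """Drop persons with a disease history before the interview date.

    A single matching record — by default in any diagnosis position and
    from any claim source — dated before *interview_date* marks the person
    prevalent.  *interview_date* defaults to the per-person interview date
    column; pass it explicitly to override.  ``any_position=False``
    restricts the history scan to primary diagnoses.
    """
    if interview_date is None:
        if "interview_date" not in persons.columns:
            raise ValueError("interview_date required (no column in persons)")
        cutoff = pd.to_datetime(persons.set_index("person_id")["interview_date"])
    else:
        cutoff = pd.Series(
            pd.Timestamp(interview_date), index=persons["person_id"].to_numpy()
        )
    hit = _codes_match_any(claims["icd9_primary"], disease)
    if any_position and "icd9_secondary" in claims.columns:
        hit = hit | _secondary_matches(claims["icd9_secondary"], disease)
    matched = claims[hit]
    dates = pd.to_datetime(matched["service_date"])
    person_cutoff = matched["person_id"].map(cutoff)
    prevalent = set(matched.loc[dates < person_cutoff, "person_id"])
    return persons[~persons["person_id"].isin(prevalent)].reset_index(drop=True)


def select_incident_cohort(
    persons: pd.DataFrame,
    onsets: list[OnsetRecord],
    interview_date: date,
    horizon_years: float = 5.0,
    sex_restriction: str | None = None,
) -> list[OnsetRecord]:
    """Keep onsets falling in ``(interview, interview + horizon]``.

    Applies the sex restriction, and keeps only persons present in
    *persons* (i.e. survivors of prevalence exclusion).
    """
    lo = pd.Timestamp(interview_date)
    hi = lo + pd.Timedelta(days=horizon_years * 365.25)
    keep_ids = set(persons["person_id"])
    if sex_restriction is not None:
        sex = persons.set_index("person_id")["sex"]
        keep_ids = {p for p in keep_ids if sex.get(p) == sex_restriction}
    out = []
    for rec in onsets:
        d = pd.Timestamp(rec.onset_date)
        if rec.person_id in keep_ids and lo < d <= hi:
            out.append(rec)
    return out
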