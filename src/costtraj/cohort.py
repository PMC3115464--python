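"""Cohort construction: onset-aligned person-month costs, stratification,
and 41-point trajectory profiles.

For each incident case, claims are CPI-adjusted to year-2000 dollars and
summed into calendar-month bins offset from the onset month (onset month =
offset 0), 20 months on each side.  Right censoring: the death month itself
stays at risk (partial-month outlays are real), months strictly after it do
not.  Profiles are per-month means with standard errors of the mean over
the at-risk persons.

Stratification variables: total population; a three-level ADL/IADL
disability index; Charlson comorbidity category (0 / 1 / 2 / >2) at the
interview date; age at diagnosis (<=80 vs >80); and survival status 2.5
years after onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date

import numpy as np
import pandas as pd

from .charlson import charlson_category, charlson_indices
from .cpi import CPISeries
from .profile import TrajectoryProfile

__all__ = [
    "Stratum",
    "DISABILITY_LEVELS",
    "disability_category",
    "person_month_costs",
    "build_profile",
    "stratify",
]

DISABILITY_LEVELS = ("nondisabled", "IADL only or/and 1-2 ADLs", "3-6 ADLs")

#: death within 2.5 years of onset, in days (2.5 * 365.25)
SURVIVAL_CUTOFF_DAYS = 913


@dataclass(frozen=True)
class Stratum:
    """One stratification cell, e.g. ``Stratum("charlson", ">2")``."""

    variable: str  # total | disability | charlson | age | survival
    level: str

    @property
    def label(self) -> str:
        return self.variable if self.variable == "total" else f"{self.variable}:{self.level}"


def disability_category(n_adl: int, has_iadl: bool) -> str:
    """Three-level disability index from ADL count and IADL indicator.

    3-6 ADLs takes precedence; IADL-only or 1-2 ADLs is the middle level;
    no ADL and no IADL is nondisabled.
    """
    if not 0 <= n_adl <= 6:
        raise ValueError(f"n_adl must be in 0..6, got {n_adl}")
    if n_adl >= 3:
        return DISABILITY_LEVELS[2]
    if has_iadl or n_adl >= 1:
        return DISABILITY_LEVELS[1]
    return DISABILITY_LEVELS[0]


def _month_index(ts) -> int:
    ts = pd.Timestamp(ts)
    return ts.year * 12 + ts.month - 1


def person_month_costs(
    claims: pd.DataFrame,
    person: pd.Series | dict,
    onset_date: date,
    cpi: CPISeries,
    window: int = 20,
) -> pd.DataFrame:
    """Monthly CPI-adjusted cost around onset for one person.

    Returns 2*window+1 rows (m, cost, at_risk).  Months after the death
    month, or outside enrollment, are not at risk and carry no cost;
    at-risk months with no claims cost 0 (zero-cost months are real
    person-months).
    """
    pid = person["person_id"]
    onset_m = _month_index(onset_date)
    m = np.arange(-window, window + 1)

    at_risk = np.ones(m.shape, dtype=bool)
    death = person.get("death_date")
    if death is not None and not pd.isna(death):
        death_m = _month_index(death)
        at_risk &= (onset_m + m) <= death_m
    for col, side in (("enrollment_start", "lo"), ("enrollment_end", "hi")):
        v = person.get(col)
        if v is not None and not pd.isna(v):
            if side == "lo":
                at_risk &= (onset_m + m) >= _month_index(v)
            else:
                at_risk &= (onset_m + m) <= _month_index(v)

    sub = claims[claims["person_id"] == pid]
    cost = np.zeros(m.shape)
    if len(sub):
        dates = pd.to_datetime(sub["service_date"])
        offsets = dates.dt.year * 12 + dates.dt.month - 1 - onset_m
        inwin = (offsets >= -window) & (offsets <= window)
        sub = sub[inwin]
        offsets = offsets[inwin]
        if len(sub):
            years = (
                sub["claim_year"].to_numpy()
                if "claim_year" in sub.columns
                else pd.to_datetime(sub["service_date"]).dt.year.to_numpy()
            )
            base = cpi.values[cpi.base_year]
            adj = sub["paid_amount"].to_numpy() * base / np.array(
                [cpi.values[y] for y in years]
            )
            totals = pd.Series(adj).groupby(offsets.to_numpy()).sum()
            for off, tot in totals.items():
                cost[off + window] = tot
    cost[~at_risk] = np.nan
    return pd.DataFrame(
        {"person_id": pid, "m": m, "cost": cost, "at_risk": at_risk}
    )


def build_profile(
    person_months: pd.DataFrame,
    disease: str = "",
    stratum: str = "total",
    window: int = 20,
    weights: pd.Series | None = None,
) -> TrajectoryProfile:
    """Aggregate person-month costs into a 41-point mean/SE profile.

    Per month: mean over at-risk persons and SE = sample SD / sqrt(n)
    (unbiased variance).  Months with fewer than two at-risk persons get
    SE 0, flagging them out of weighted fits.  Optional per-person
    *weights* (e.g. survey weights, indexed by person_id) give weighted
    means with an effective-sample-size SE.
    """
    if person_months.empty or not person_months["at_risk"].any():
        raise ValueError("empty stratum: no at-risk person-months to aggregate")
    rows = []
    at_risk = person_months[person_months["at_risk"]]
    grouped = dict(list(at_risk.groupby("m")))
    for m in range(-window, window + 1):
        grp = grouped.get(m)
        if grp is None or len(grp) == 0:
            rows.append((m, np.nan, 0.0, 0))
            continue
        x = grp["cost"].to_numpy(dtype=float)
        n = len(x)
        if weights is None:
            mean = x.mean()
            se = float(x.std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0
        else:
            w = grp["person_id"].map(weights).fillna(1.0).to_numpy(dtype=float)
            mean = float(np.average(x, weights=w))
            n_eff = w.sum() ** 2 / (w**2).sum()
            var = float(np.average((x - mean) ** 2, weights=w))
            se = float(np.sqrt(var / (n_eff - 1))) if n_eff > 1 else 0.0
        rows.append((m, float(mean), se, n))
    arr = np.array(rows, dtype=float)
    return TrajectoryProfile(
        m=arr[:, 0].astype(int),
        mean=arr[:, 1],
        se=arr[:, 2],
        n_at_risk=arr[:, 3].astype(int),
        disease=disease,
        stratum=stratum,
    )


def stratify(
    onsets,
    persons: pd.DataFrame,
    claims: pd.DataFrame,
    interview_date: date,
    charlson_lookback: int = 365,
) -> dict[Stratum, set]:
    """Partition an incident cohort into the stratification cells.

    *onsets* is a list of detected OnsetRecord for one disease.  Within
    each stratification variable the cells are disjoint and exhaustive
    over the cohort.  Charlson uses claims in the year before the
    interview; age is age at diagnosis with the boundary at 80.0 years
    inclusive; survival is death within 913 days of onset.
    """
    ids = [rec.person_id for rec in onsets]
    onset_dates = {rec.person_id: pd.Timestamp(rec.onset_date) for rec in onsets}
    p = persons.set_index("person_id").loc[ids]

    out: dict[Stratum, set] = {Stratum("total", "total"): set(ids)}

    for level in DISABILITY_LEVELS:
        out[Stratum("disability", level)] = set()
    for pid in ids:
        level = disability_category(int(p.loc[pid, "n_adl"]), bool(p.loc[pid, "has_iadl"]))
        out[Stratum("disability", level)].add(pid)

    cci = charlson_indices(claims, interview_date, person_ids=ids,
                           lookback=charlson_lookback)
    for level in ("0", "1", "2", ">2"):
        out[Stratum("charlson", level)] = set()
    for pid in ids:
        out[Stratum("charlson", charlson_category(int(cci[pid])))].add(pid)

    out[Stratum("age", "<=80")] = set()
    out[Stratum("age", ">80")] = set()
    births = pd.to_datetime(p["birth_date"])
    for pid in ids:
        age = (onset_dates[pid] - births[pid]).days / 365.25
        out[Stratum("age", "<=80" if age <= 80.0 else ">80")].add(pid)

    out[Stratum("survival", "died")] = set()
    out[Stratum("survival", "survived")] = set()
    deaths = pd.to_datetime(p["death_date"]) if "death_date" in p else None
    for pid in ids:
        died = False
        if deaths is not None and not pd.isna(deaths[pid]):
            died = (deaths[pid] - onset_dates[pid]).days <= SURVIVAL_CUTOFF_DAYS
        out[Stratum("survival", "died" if died else "survived")].add(pid)

    return out
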