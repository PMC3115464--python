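"""Synthetic Medicare-like person/claims generator with exported ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so that every stage (onset detection, profile construction, model
fitting, forecasting) can be exercised against known truth:

* per-person monthly medical costs follow the four-parameter trajectory
  model around a true onset month (pre-onset plateau, onset-month spike,
  exponential decline to a new plateau), plus zero-truncated Gaussian noise;
* incident cases carry a qualifying pair of primary-diagnosis claims (the
  two-record onset rule's signal); configurable fractions of cases are
  instead *prevalent* (qualifying records before the interview date) or
  *single-record* (unconfirmed, hence undetectable) contamination;
* post-onset mortality is a per-month Bernoulli hazard, and no claim is
  dated after death;
* chronic comorbid conditions are planted as zero-cost ICD-9 marker claims
  in the year before the interview so the Charlson index is nontrivial;
* claims are emitted in nominal dollars through a medical-care CPI series
  so the inflation-adjustment step is exercised.

The twelve shipped disease presets use the published total-population
parameter quadruples as generating truth.
"""

from __future__ import annotations

import calendar
import json
from dataclasses import dataclass, field, replace
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .cpi import CPISeries, load_medical_cpi
from .diseases import DISEASE_ORDER, load_definitions
from .icd9 import example_code
from .model import CostModelParams, evaluate_cost

__all__ = [
    "ConfigurationError",
    "DiseaseTruth",
    "SimulationConfig",
    "GroundTruth",
    "TOTAL_POPULATION_PARAMS",
    "preset_params",
    "default_disease_truths",
    "simulate_cost_series",
    "emit_claims",
    "simulate_population",
    "write_population",
]

QUALIFYING_SOURCES = ("inpatient", "outpatient", "physician", "snf")

#: published total-population parameter quadruples (c, P, r, delta) used as
#: generating truth for the twelve disease presets
TOTAL_POPULATION_PARAMS: dict[str, tuple[float, float, float, float]] = {
    "achd": (815, 29842, 1.15, 1005),
    "stroke": (1176, 22542, 0.80, 949),
    "ulcer": (1071, 17849, 1.15, 630),
    "breast_cancer": (795, 10477, 0.42, 613),
    "prostate_cancer": (618, 6466, 0.20, 399),
    "melanoma": (744, 3482, 0.22, 201),
    "lung_cancer": (876, 20524, 0.42, 2818),
    "colon_cancer": (1132, 27959, 1.03, 1288),
    "diabetes": (800, 3045, 0.68, 637),
    "asthma": (1198, 5530, 1.63, 985),
    "parkinsons": (1130, 3667, 0.52, 864),
    "alzheimers": (926, 5323, 1.14, 1244),
}

#: representative planted ICD-9 code per Charlson condition group; chosen,
#: where possible, to avoid the twelve studied diseases' pattern sets
BACKGROUND_CONDITION_CODES: dict[str, str] = {
    "mi": "412",
    "chf": "4280",
    "pvd": "4439",
    "cevd": "4380",
    "dementia": "2900",
    "copd": "496",
    "rheumatic": "7140",
    "pud": "5310",          # collides with the ulcer definition by nature
    "mild_liver": "5712",
    "diabetes": "25000",    # collides with the diabetes definition by nature
    "diabetes_complicated": "25040",
    "paralysis": "3420",
    "renal": "585",
    "cancer": "1930",
    "severe_liver": "5722",
    "mets": "1990",
    "hiv": "042",
}

#: default annual probabilities of carrying each planted condition group
#: (groups overlapping the twelve disease definitions are left out so the
#: planted comorbidity never creates accidental prevalent cases)
DEFAULT_BACKGROUND_RATES: dict[str, float] = {
    "chf": 0.06,
    "pvd": 0.04,
    "copd": 0.08,
    "renal": 0.02,
    "rheumatic": 0.03,
    "mild_liver": 0.015,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration; the message names the field."""


def preset_params(disease: str) -> CostModelParams:
    """Generating-truth parameter quadruple for a shipped disease preset."""
    c, P, r, d = TOTAL_POPULATION_PARAMS[disease]
    return CostModelParams(c=float(c), P=float(P), r=float(r), delta=float(d))


@dataclass
class DiseaseTruth:
    """Generating truth for one disease: parameters, onset hazard, sex rule."""

    name: str
    params: CostModelParams
    onset_hazard: float = 0.002  # per month
    sex_restriction: str | None = None
    icd9_patterns: tuple[str, ...] = ()

    def __post_init__(self):
        if not 0.0 <= self.onset_hazard <= 1.0:
            raise ConfigurationError(
                f"onset_hazard for {self.name!r} must be in [0, 1]"
            )
        if self.sex_restriction not in (None, "female", "male"):
            raise ConfigurationError(
                f"sex_restriction for {self.name!r} must be 'female', 'male' or None"
            )


def default_disease_truths(onset_hazard: float = 0.002) -> list[DiseaseTruth]:
    """The twelve shipped presets with a common onset hazard.

    Sex restrictions follow the disease definitions (breast cancer: women
    only; prostate cancer: men only).
    """
    defs = load_definitions()
    return [
        DiseaseTruth(
            name=key,
            params=preset_params(key),
            onset_hazard=onset_hazard,
            sex_restriction=defs[key].sex_restriction,
            icd9_patterns=defs[key].icd9_patterns,
        )
        for key in DISEASE_ORDER
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one simulated population."""

    n_persons: int = 1000
    seed: int = 0
    diseases: list[DiseaseTruth] = field(default_factory=default_disease_truths)
    interview_date: date = date(1994, 10, 1)
    followup_years: float = 5.0
    cpi_base_year: int = 2000
    prevalent_fraction: float = 0.07
    single_record_fraction: float = 0.05
    confirm_delay_days: tuple[int, int] = (7, 90)  # uniform over [low, high]
    noise_sd: float = 250.0  # USD/month on monthly totals, truncated at 0
    death_hazard_post_onset: float = 0.01  # per month
    background_condition_rates: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BACKGROUND_RATES)
    )
    background_monthly_cost: float = 800.0  # disease-free plateau, year-2000 USD
    cpi: CPISeries | None = None

    def __post_init__(self):
        if self.cpi is None:
            self.cpi = load_medical_cpi(self.cpi_base_year)

    def validate(self) -> "SimulationConfig":
        if self.n_persons <= 0:
            raise ConfigurationError("n_persons must be positive")
        for name in ("prevalent_fraction", "single_record_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.prevalent_fraction + self.single_record_fraction > 1.0:
            raise ConfigurationError(
                "prevalent_fraction + single_record_fraction must not exceed 1"
            )
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if not 0.0 <= self.death_hazard_post_onset <= 1.0:
            raise ConfigurationError("death_hazard_post_onset must be in [0, 1]")
        lo, hi = self.confirm_delay_days
        if lo < 1 or hi < lo:
            raise ConfigurationError(
                "confirm_delay_days must satisfy 1 <= low <= high"
            )
        for g, p in self.background_condition_rates.items():
            if g not in BACKGROUND_CONDITION_CODES:
                raise ConfigurationError(
                    f"background_condition_rates: unknown condition group {g!r}"
                )
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(
                    f"background_condition_rates[{g!r}] must be in [0, 1]"
                )
        return self

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        diseases = d.pop("diseases", None)
        if diseases is not None:
            defs = load_definitions()
            truths = []
            for entry in diseases:
                if isinstance(entry, str):
                    entry = {"name": entry}
                name = entry["name"]
                if all(k in entry for k in ("c", "P", "r", "delta")):
                    params = CostModelParams(
                        c=float(entry["c"]), P=float(entry["P"]),
                        r=float(entry["r"]), delta=float(entry["delta"]),
                    )
                else:
                    params = preset_params(name)
                dd = defs.get(name)
                truths.append(
                    DiseaseTruth(
                        name=name,
                        params=params,
                        onset_hazard=float(entry.get("onset_hazard", 0.002)),
                        sex_restriction=entry.get(
                            "sex_restriction",
                            dd.sex_restriction if dd else None,
                        ),
                        icd9_patterns=tuple(
                            entry.get(
                                "icd9_patterns", dd.icd9_patterns if dd else ()
                            )
                        ),
                    )
                )
            d["diseases"] = truths
        if "interview_date" in d and isinstance(d["interview_date"], str):
            d["interview_date"] = date.fromisoformat(d["interview_date"])
        if "confirm_delay_days" in d:
            lo, hi = d["confirm_delay_days"]
            d["confirm_delay_days"] = (int(lo), int(hi))
        return cls(**d).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class PersonTruth:
    """Ground truth for one simulated person."""

    person_id: str
    sex: str
    birth_date: date
    role: str  # "none", "incident", "prevalent", "single_record"
    disease: str | None = None
    onset_date: date | None = None
    onset_month: int | None = None  # absolute month index
    death_date: date | None = None
    charlson_groups: tuple[str, ...] = ()
    n_adl: int = 0
    has_iadl: bool = False


@dataclass
class GroundTruth:
    """Exported truth for a simulated population."""

    config: SimulationConfig
    persons: dict[str, PersonTruth]

    def cases(self, disease: str | None = None, role: str = "incident"):
        """Person truths with the given role (and disease, if named)."""
        return [
            p
            for p in self.persons.values()
            if p.role == role and (disease is None or p.disease == disease)
        ]

    def true_params(self, disease: str) -> CostModelParams:
        for t in self.config.diseases:
            if t.name == disease:
                return t.params
        raise KeyError(disease)

    def to_json(self) -> str:
        def enc(p: PersonTruth):
            return {
                "person_id": p.person_id,
                "sex": p.sex,
                "role": p.role,
                "disease": p.disease,
                "onset_date": p.onset_date.isoformat() if p.onset_date else None,
                "death_date": p.death_date.isoformat() if p.death_date else None,
                "charlson_groups": list(p.charlson_groups),
                "n_adl": p.n_adl,
                "has_iadl": p.has_iadl,
            }

        payload = {
            "true_params": {
                t.name: {
                    "c": t.params.c, "P": t.params.P,
                    "r": t.params.r, "delta": t.params.delta,
                    "onset_hazard": t.onset_hazard,
                }
                for t in self.config.diseases
            },
            "persons": [enc(p) for p in self.persons.values()],
        }
        return json.dumps(payload, indent=1)


# -- month arithmetic ------------------------------------------------------


def _month_index(d: date) -> int:
    return d.year * 12 + d.month - 1


def _month_first_day(idx: int) -> date:
    return date(idx // 12, idx % 12 + 1, 1)


def _month_last_day(idx: int) -> date:
    y, mo = idx // 12, idx % 12 + 1
    return date(y, mo, calendar.monthrange(y, mo)[1])


# -- operations ------------------------------------------------------------


def simulate_cost_series(
    truth: CostModelParams,
    onset_month: int | None,
    death_month: int | None,
    noise_sd: float,
    n_months: int,
    seed: int,
) -> pd.Series:
    """Monthly cost sequence (year-2000 USD) for one person.

    Months run 0..n_months-1; *onset_month* indexes the onset within that
    range (None: never diseased, the series stays at the plateau ``c``).
    Months after *death_month* are absent, not zero-filled; a death before
    month 0 yields an empty series.  Noise is Gaussian, truncated at zero.
    """
    if n_months < 1:
        raise ValueError("n_months must be >= 1")
    months = np.arange(n_months)
    if death_month is not None:
        months = months[months <= death_month]
    if onset_month is None:
        values = np.full(months.shape, truth.c, dtype=float)
    else:
        values = evaluate_cost(months - onset_month, truth)
        values = np.atleast_1d(np.asarray(values, dtype=float))
    if noise_sd > 0 and len(months):
        rng = np.random.default_rng(seed)
        values = np.clip(values + rng.normal(0.0, noise_sd, len(months)), 0.0, None)
    return pd.Series(values, index=months, name="cost")


def emit_claims(
    person_id: str,
    disease: DiseaseTruth,
    onset_date: date,
    confirm_delay_days: int,
    role: str = "incident",
) -> list[dict]:
    """Qualifying diagnosis-marker claims implementing an ascertainment role.

    ``incident`` (and ``prevalent``, whose onset_date the caller places
    before the interview) emits two primary-diagnosis records on distinct
    dates *confirm_delay_days* apart, both from qualifying sources;
    ``single_record`` emits exactly one.  Marker claims carry zero paid
    amount — monthly totals are carried by the cost claims.
    """
    if role not in ("incident", "prevalent", "single_record"):
        raise ValueError(f"unknown role {role!r}")
    code = example_code(disease.icd9_patterns[0]) if disease.icd9_patterns else "7999"
    first = {
        "person_id": person_id,
        "service_date": onset_date,
        "source": "inpatient",
        "icd9_primary": code,
        "icd9_secondary": "",
        "paid_amount": 0.0,
    }
    if role == "single_record":
        return [first]
    if confirm_delay_days < 1:
        raise ValueError(
            "confirm_delay_days must be >= 1: the confirming record needs a "
            "date different from the onset record's"
        )
    confirm = dict(
        first,
        service_date=onset_date + timedelta(days=int(confirm_delay_days)),
        source="outpatient",
    )
    return [first, confirm]


def simulate_population(config: SimulationConfig, seed: int | None = None):
    """Generate (persons, claims, ground_truth) for one population.

    Reproducible given (config, seed).  Claims lie within each person's
    enrollment and never after death; monthly claim totals follow the
    trajectory model around true onsets plus truncated-Gaussian noise.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    interview = config.interview_date
    interview_m = _month_index(interview)
    followup_months = int(round(config.followup_years * 12))
    start_m = interview_m - 21
    end_m = interview_m + followup_months + 21
    lo_delay, hi_delay = config.confirm_delay_days
    bg_groups = sorted(config.background_condition_rates)

    persons_rows = []
    claims_rows: list[dict] = []
    truths: dict[str, PersonTruth] = {}

    for i in range(config.n_persons):
        pid = f"P{i:06d}"
        sex = "female" if rng.random() < 0.58 else "male"
        age = float(np.clip(rng.normal(78.0, 7.0), 65.5, 97.0))
        birth = interview - timedelta(days=int(age * 365.25))

        # disability: ~78% nondisabled, 12% light (IADL / 1-2 ADL), 10% heavy
        u = rng.random()
        if u < 0.78:
            n_adl, has_iadl = 0, False
        elif u < 0.90:
            n_adl = int(rng.integers(0, 3))
            has_iadl = bool(rng.random() < 0.7) or n_adl == 0
        else:
            n_adl = int(rng.integers(3, 7))
            has_iadl = bool(rng.random() < 0.5)

        person_claims: list[dict] = []

        # planted chronic-condition markers in the pre-interview year
        groups = tuple(
            g for g in bg_groups
            if rng.random() < config.background_condition_rates[g]
        )
        for g in groups:
            offset = int(rng.integers(1, 366))
            person_claims.append(
                {
                    "person_id": pid,
                    "service_date": interview - timedelta(days=offset),
                    "source": "physician",
                    "icd9_primary": BACKGROUND_CONDITION_CODES[g],
                    "icd9_secondary": "",
                    "paid_amount": 0.0,
                }
            )

        # competing onset draw across diseases
        onset_t = None
        disease: DiseaseTruth | None = None
        for d in config.diseases:
            if d.sex_restriction is not None and d.sex_restriction != sex:
                continue
            if d.onset_hazard <= 0:
                continue
            t = int(rng.geometric(d.onset_hazard))
            if t < followup_months and (onset_t is None or t < onset_t):
                onset_t, disease = t, d

        role = "none"
        onset_m = None
        onset_date = None
        death_m: int | None = None
        death_date = None
        if disease is not None:
            v = rng.random()
            if v < config.prevalent_fraction:
                role = "prevalent"
                onset_m = interview_m - int(rng.integers(6, 37))
            elif v < config.prevalent_fraction + config.single_record_fraction:
                role = "single_record"
                onset_m = interview_m + onset_t
            else:
                role = "incident"
                onset_m = interview_m + onset_t
            onset_date = _month_first_day(onset_m) + timedelta(
                days=int(rng.integers(2, 15))
            )
            if config.death_hazard_post_onset > 0:
                k = int(rng.geometric(config.death_hazard_post_onset))
                if onset_m + k <= end_m:
                    death_m = onset_m + k
                    death_date = _month_last_day(death_m)

            delay = int(rng.integers(lo_delay, hi_delay + 1))
            markers = emit_claims(pid, disease, onset_date, delay, role)
            if death_date is not None:
                # a confirming record landing past death is moved to the death
                # date (still a distinct, later date than the onset record)
                for c in markers:
                    if c["service_date"] > death_date:
                        c["service_date"] = death_date
            person_claims.extend(markers)

        # monthly cost claims
        last_m = end_m if death_m is None else min(end_m, death_m)
        months = np.arange(start_m, last_m + 1)
        if onset_m is None:
            base = np.full(months.shape, config.background_monthly_cost)
        else:
            base = np.atleast_1d(
                np.asarray(evaluate_cost(months - onset_m, disease.params), float)
            )
        if config.noise_sd > 0:
            base = np.clip(
                base + rng.normal(0.0, config.noise_sd, len(months)), 0.0, None
            )
        for mo, amount in zip(months, base):
            if onset_m is not None and mo == onset_m:
                svc, source, code = (
                    onset_date,
                    "inpatient",
                    example_code(disease.icd9_patterns[0])
                    if disease.icd9_patterns
                    else "7999",
                )
            else:
                svc = _month_first_day(int(mo)) + timedelta(days=4)
                source, code = "carrier", "4019"
            nominal = config.cpi.deflate(float(amount), svc.year)
            person_claims.append(
                {
                    "person_id": pid,
                    "service_date": svc,
                    "source": source,
                    "icd9_primary": code,
                    "icd9_secondary": "",
                    "paid_amount": nominal,
                }
            )

        if death_date is not None:
            person_claims = [
                c for c in person_claims if c["service_date"] <= death_date
            ]
        claims_rows.extend(person_claims)

        persons_rows.append(
            {
                "person_id": pid,
                "sex": sex,
                "birth_date": birth,
                "interview_date": interview,
                "death_date": death_date,
                "enrollment_start": _month_first_day(start_m),
                "enrollment_end": death_date or _month_last_day(end_m),
                "n_adl": n_adl,
                "has_iadl": has_iadl,
                "weight": 1.0,
            }
        )
        truths[pid] = PersonTruth(
            person_id=pid,
            sex=sex,
            birth_date=birth,
            role=role,
            disease=disease.name if disease is not None and role != "none" else None,
            onset_date=onset_date,
            onset_month=onset_m,
            death_date=death_date,
            charlson_groups=groups,
            n_adl=n_adl,
            has_iadl=has_iadl,
        )

    persons = pd.DataFrame(persons_rows)
    claims = pd.DataFrame(claims_rows)
    claims["service_date"] = pd.to_datetime(claims["service_date"])
    claims = claims.sort_values(
        ["person_id", "service_date"], kind="stable"
    ).reset_index(drop=True)
    claims["claim_year"] = claims["service_date"].dt.year
    return persons, claims, GroundTruth(config=config, persons=truths)


def write_population(persons: pd.DataFrame, claims: pd.DataFrame,
                     truth: GroundTruth, outdir) -> None:
    """Write persons.csv, claims.csv and ground_truth.json to *outdir*."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons.to_csv(outdir / "persons.csv", index=False)
    out = claims.copy()
    out["service_date"] = out["service_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(outdir / "claims.csv", index=False)
    (outdir / "ground_truth.json").write_text(truth.to_json())
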