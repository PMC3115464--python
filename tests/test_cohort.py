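"""Cohort building: Charlson index, disability levels, CPI adjustment,
person-month aggregation, profiles and stratification."""

from datetime import date

import numpy as np
import pandas as pd
import pytest

from costtraj.charlson import (
    charlson_category,
    charlson_index,
    charlson_indices,
    code_to_groups,
)
from costtraj.cohort import (
    build_profile,
    disability_category,
    person_month_costs,
    stratify,
)
from costtraj.cpi import CPISeries, adjust_to_2000_dollars, load_medical_cpi
from costtraj.model import evaluate_cost


def _charlson_claims(codes, when=date(1994, 5, 1)):
    return pd.DataFrame(
        {
            "person_id": "p1",
            "service_date": [when] * len(codes),
            "source": "physician",
            "icd9_primary": codes,
            "icd9_secondary": "",
        }
    )


class TestCharlson:
    interview = date(1994, 10, 1)

    def test_no_qualifying_codes_is_zero(self):
        claims = _charlson_claims(["4019", "V700"])
        assert charlson_index(claims, "p1", self.interview) == 0

    def test_mi_plus_uncomplicated_diabetes_is_two(self):
        claims = _charlson_claims(["410", "25000"])
        assert charlson_index(claims, "p1", self.interview) == 2

    def test_metastatic_solid_tumor_is_six(self):
        claims = _charlson_claims(["1970"])
        assert charlson_index(claims, "p1", self.interview) == 6

    def test_hierarchy_complicated_diabetes_supersedes(self):
        claims = _charlson_claims(["25000", "25040"])
        assert charlson_index(claims, "p1", self.interview) == 2

    def test_hierarchy_mets_supersedes_malignancy(self):
        claims = _charlson_claims(["1740", "1970"])
        assert charlson_index(claims, "p1", self.interview) == 6

    def test_each_group_counted_once(self):
        claims = _charlson_claims(["4280", "42822", "4281"])
        assert charlson_index(claims, "p1", self.interview) == 1

    def test_lookback_window_is_half_open(self):
        # claim on the index date itself is outside [t-365, t)
        claims = _charlson_claims(["410"], when=self.interview)
        assert charlson_index(claims, "p1", self.interview) == 0
        old = _charlson_claims(["410"], when=date(1993, 9, 1))
        assert charlson_index(old, "p1", self.interview) == 0

    def test_secondary_position_counts(self):
        claims = _charlson_claims(["4019"])
        claims["icd9_secondary"] = "25000|4280"
        assert charlson_index(claims, "p1", self.interview) == 2

    def test_bulk_matches_single(self):
        claims = _charlson_claims(["410", "25040", "1970"])
        bulk = charlson_indices(claims, self.interview, person_ids=["p1"])
        assert bulk["p1"] == charlson_index(claims, "p1", self.interview)

    @pytest.mark.parametrize("idx,cat", [(0, "0"), (1, "1"), (2, "2"), (3, ">2"), (9, ">2")])
    def test_categories(self, idx, cat):
        assert charlson_category(idx) == cat


class TestDisability:
    @pytest.mark.parametrize(
        "n_adl,has_iadl,level",
        [
            (0, False, "nondisabled"),
            (0, True, "IADL only or/and 1-2 ADLs"),
            (2, False, "IADL only or/and 1-2 ADLs"),
            (1, True, "IADL only or/and 1-2 ADLs"),
            (3, False, "3-6 ADLs"),
            (4, True, "3-6 ADLs"),  # heavy-ADL level takes precedence
            (6, False, "3-6 ADLs"),
        ],
    )
    def test_levels(self, n_adl, has_iadl, level):
        assert disability_category(n_adl, has_iadl) == level

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            disability_category(7, False)


class TestCPI:
    def test_base_year_identity(self):
        cpi = load_medical_cpi()
        assert adjust_to_2000_dollars(100.0, 2000, cpi) == pytest.approx(100.0)

    def test_ratio_definition(self):
        cpi = CPISeries({2000: 100.0, 1995: 200.0})
        assert adjust_to_2000_dollars(100.0, 1995, cpi) == pytest.approx(50.0)

    def test_round_trip_inverse(self):
        cpi = load_medical_cpi()
        x = cpi.adjust(cpi.deflate(815.0, 1996), 1996)
        assert x == pytest.approx(815.0, abs=1e-9)

    def test_idempotent_on_base_year_amounts(self):
        cpi = load_medical_cpi()
        once = cpi.adjust(123.45, 2000)
        assert cpi.adjust(once, 2000) == once

    def test_missing_year_raises(self):
        cpi = load_medical_cpi()
        with pytest.raises(KeyError):
            cpi.adjust(1.0, 1975)


def _person(pid="p1", death=None):
    return pd.Series(
        {
            "person_id": pid,
            "death_date": death,
            "enrollment_start": date(1991, 1, 1),
            "enrollment_end": death or date(2001, 12, 31),
        }
    )


class TestPersonMonthCosts:
    onset = date(1996, 6, 15)
    cpi = load_medical_cpi()

    def test_no_claims_gives_41_zero_cost_at_risk_months(self):
        claims = pd.DataFrame(
            columns=["person_id", "service_date", "paid_amount", "claim_year"]
        )
        pm = person_month_costs(claims, _person(), self.onset, self.cpi)
        assert len(pm) == 41
        assert pm["at_risk"].all()
        assert (pm["cost"] == 0).all()

    def test_censored_after_death_month(self):
        pm = person_month_costs(
            pd.DataFrame(columns=["person_id", "service_date", "paid_amount",
                                  "claim_year"]),
            _person(death=date(1996, 9, 20)),  # 3 months after onset
            self.onset,
            self.cpi,
        )
        by_m = pm.set_index("m")["at_risk"]
        assert by_m.loc[3]  # death month itself stays at risk
        assert not by_m.loc[4:].any()

    def test_claims_summed_into_calendar_month_bins(self):
        claims = pd.DataFrame(
            {
                "person_id": "p1",
                "service_date": pd.to_datetime(
                    ["1996-06-02", "1996-06-28", "1996-07-01"]
                ),
                "paid_amount": [100.0, 50.0, 30.0],
                "claim_year": [1996, 1996, 1996],
            }
        )
        pm = person_month_costs(claims, _person(), self.onset, self.cpi).set_index("m")
        factor = self.cpi.values[2000] / self.cpi.values[1996]
        assert pm.loc[0, "cost"] == pytest.approx(150.0 * factor)
        assert pm.loc[1, "cost"] == pytest.approx(30.0 * factor)

    def test_earlier_death_never_increases_at_risk_months(self):
        claims = pd.DataFrame(
            columns=["person_id", "service_date", "paid_amount", "claim_year"]
        )
        late = person_month_costs(
            claims, _person(death=date(1997, 6, 1)), self.onset, self.cpi
        )["at_risk"].sum()
        early = person_month_costs(
            claims, _person(death=date(1996, 12, 1)), self.onset, self.cpi
        )["at_risk"].sum()
        assert early < late


class TestBuildProfile:
    def test_single_person_profile_reproduces_series(self, achd_params):
        m = np.arange(-20, 21)
        series = evaluate_cost(m, achd_params)
        pm = pd.DataFrame(
            {"person_id": "p1", "m": m, "cost": series, "at_risk": True}
        )
        prof = build_profile(pm)
        assert len(prof) == 41
        assert np.allclose(prof.mean, series)
        assert (prof.se == 0).all()  # single person: SE flagged
        assert not prof.usable.any()

    def test_identical_noiseless_persons_flag_zero_se(self, achd_params):
        m = np.arange(-20, 21)
        series = evaluate_cost(m, achd_params)
        pm = pd.concat(
            [
                pd.DataFrame({"person_id": p, "m": m, "cost": series, "at_risk": True})
                for p in ["a", "b", "c"]
            ]
        )
        prof = build_profile(pm)
        assert np.allclose(prof.mean, series)
        assert (prof.n_at_risk == 3).all()
        assert np.allclose(prof.se, 0.0, atol=1e-9)

    def test_se_is_sd_over_sqrt_n(self):
        rng = np.random.default_rng(0)
        m = np.arange(-20, 21)
        frames = []
        for i in range(50):
            frames.append(pd.DataFrame({
                "person_id": f"p{i}", "m": m,
                "cost": 800 + rng.normal(0, 100, len(m)), "at_risk": True,
            }))
        prof = build_profile(pd.concat(frames))
        sub = pd.concat(frames)
        x = sub[sub["m"] == 0]["cost"]
        assert prof.se[prof.m == 0][0] == pytest.approx(
            x.std(ddof=1) / np.sqrt(len(x))
        )

    def test_empty_stratum_raises(self):
        with pytest.raises(ValueError, match="empty stratum"):
            build_profile(
                pd.DataFrame(columns=["person_id", "m", "cost", "at_risk"])
            )


class TestStratify:
    def _fixture(self, definitions):
        from costtraj.onset import find_onsets, select_incident_cohort, exclude_prevalent
        from costtraj.simulate import SimulationConfig, simulate_population

        cfg = SimulationConfig(n_persons=250, seed=31)
        persons, claims, truth = simulate_population(cfg)
        dd = definitions["achd"]
        kept = exclude_prevalent(persons, claims, dd, cfg.interview_date)
        cohort = select_incident_cohort(
            kept,
            find_onsets(claims, dd, person_ids=kept["person_id"]),
            cfg.interview_date,
            sex_restriction=dd.sex_restriction,
        )
        return cfg, persons, claims, cohort

    def test_partitions_disjoint_and_exhaustive(self, definitions):
        cfg, persons, claims, cohort = self._fixture(definitions)
        assert cohort
        strata = stratify(cohort, persons, claims, cfg.interview_date)
        all_ids = {r.person_id for r in cohort}
        by_var = {}
        for st, ids in strata.items():
            by_var.setdefault(st.variable, []).append(ids)
        for var, sets in by_var.items():
            union = set().union(*sets)
            assert union == all_ids, var
            total = sum(len(s) for s in sets)
            assert total == len(all_ids), var  # pairwise disjoint

    def test_age_boundary_inclusive_at_80(self, definitions):
        cfg, persons, claims, cohort = self._fixture(definitions)
        strata = stratify(cohort, persons, claims, cfg.interview_date)
        births = persons.set_index("person_id")["birth_date"]
        onset_dates = {r.person_id: r.onset_date for r in cohort}
        from costtraj.cohort import Stratum

        for pid in strata[Stratum("age", "<=80")]:
            age = (pd.Timestamp(onset_dates[pid]) - pd.Timestamp(births[pid])).days / 365.25
            assert age <= 80.0
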