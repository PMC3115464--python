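"""Synthetic-population generator: degenerate cases, conservation,
censoring, determinism and ground-truth round trips."""

import math
from datetime import date

import numpy as np
import pandas as pd
import pytest

from costtraj.cpi import load_medical_cpi
from costtraj.model import evaluate_cost
from costtraj.onset import exclude_prevalent, find_onsets, select_incident_cohort
from costtraj.simulate import (
    ConfigurationError,
    DiseaseTruth,
    SimulationConfig,
    default_disease_truths,
    emit_claims,
    preset_params,
    simulate_cost_series,
    simulate_population,
)


def _adjusted_month_totals(claims, cpi):
    """Per-person, per-calendar-month claim totals in base-year dollars."""
    adj = claims["paid_amount"] * claims["claim_year"].map(
        lambda y: cpi.values[cpi.base_year] / cpi.values[y]
    )
    key = claims["service_date"].dt.year * 12 + claims["service_date"].dt.month - 1
    return adj.groupby([claims["person_id"], key]).sum()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs,fieldname",
        [
            ({"n_persons": 0}, "n_persons"),
            ({"prevalent_fraction": 1.2}, "prevalent_fraction"),
            ({"single_record_fraction": -0.1}, "single_record_fraction"),
            ({"noise_sd": -1.0}, "noise_sd"),
            ({"death_hazard_post_onset": 2.0}, "death_hazard_post_onset"),
            ({"confirm_delay_days": (0, 30)}, "confirm_delay_days"),
            ({"background_condition_rates": {"nope": 0.1}},
             "background_condition_rates"),
        ],
    )
    def test_invalid_field_named_in_error(self, kwargs, fieldname):
        kwargs.setdefault("n_persons", 10)
        with pytest.raises(ConfigurationError, match=fieldname):
            SimulationConfig(**kwargs).validate()

    def test_bad_onset_hazard(self):
        with pytest.raises(ConfigurationError, match="onset_hazard"):
            DiseaseTruth("x", preset_params("achd"), onset_hazard=1.5)


class TestCostSeries:
    def test_no_onset_noiseless_is_flat(self, achd_params):
        s = simulate_cost_series(achd_params, None, None, 0.0, 24, seed=0)
        assert len(s) == 24
        assert np.allclose(s.to_numpy(), achd_params.c)

    def test_onset_month_value_is_c_plus_P(self, achd_params):
        s = simulate_cost_series(achd_params, onset_month=10, death_month=None,
                                 noise_sd=0.0, n_months=40, seed=0)
        assert s[10] == pytest.approx(815 + 29842)

    def test_tail_approaches_new_plateau(self, achd_params):
        s = simulate_cost_series(achd_params, 0, None, 0.0, 41, seed=0)
        p = achd_params
        bound = math.exp(-p.r * 20) * (p.P - p.delta)
        assert abs(s[40] - (p.c + p.delta)) <= bound + 1e-9

    def test_months_after_death_absent(self, achd_params):
        s = simulate_cost_series(achd_params, 5, death_month=8, noise_sd=0.0,
                                 n_months=40, seed=0)
        assert list(s.index) == list(range(9))

    def test_death_before_start_empty(self, achd_params):
        s = simulate_cost_series(achd_params, 5, death_month=-1, noise_sd=0.0,
                                 n_months=40, seed=0)
        assert len(s) == 0

    def test_noise_is_truncated_at_zero(self):
        from costtraj.model import CostModelParams

        tiny = CostModelParams(c=10.0, P=100.0, r=1.0, delta=5.0)
        s = simulate_cost_series(tiny, None, None, 500.0, 200, seed=3)
        assert (s >= 0).all()


class TestEmitClaims:
    def _disease(self):
        return default_disease_truths()[0]  # achd

    def test_incident_emits_confirmable_pair(self, definitions):
        claims = pd.DataFrame(
            emit_claims("p1", self._disease(), date(1995, 3, 1), 60, "incident")
        )
        from costtraj.onset import find_onset

        rec = find_onset(claims, definitions["achd"])
        assert rec is not None and rec.onset_date == date(1995, 3, 1)

    def test_long_delay_defeats_detection(self, definitions):
        claims = pd.DataFrame(
            emit_claims("p1", self._disease(), date(1995, 3, 1), 150, "incident")
        )
        from costtraj.onset import find_onset

        assert find_onset(claims, definitions["achd"]) is None

    def test_single_record_not_detected(self, definitions):
        claims = pd.DataFrame(
            emit_claims("p1", self._disease(), date(1995, 3, 1), 60, "single_record")
        )
        from costtraj.onset import find_onset

        assert len(claims) == 1
        assert find_onset(claims, definitions["achd"]) is None

    def test_zero_delay_rejected(self):
        with pytest.raises(ValueError, match="different"):
            emit_claims("p1", self._disease(), date(1995, 3, 1), 0, "incident")


class TestPopulation:
    def test_deterministic_given_config_and_seed(self):
        cfg = SimulationConfig(n_persons=40, seed=9)
        a = simulate_population(cfg, seed=9)
        b = simulate_population(SimulationConfig(n_persons=40, seed=9), seed=9)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_no_onsets_flat_at_background_level(self):
        diseases = [
            DiseaseTruth("achd", preset_params("achd"), onset_hazard=0.0,
                         icd9_patterns=("410.xx",))
        ]
        cfg = SimulationConfig(
            n_persons=20, seed=5, diseases=diseases, noise_sd=0.0,
            background_condition_rates={},
        )
        persons, claims, truth = simulate_population(cfg)
        totals = _adjusted_month_totals(claims, cfg.cpi)
        assert np.allclose(totals.to_numpy(), cfg.background_monthly_cost)

    def test_preonset_plateau_equals_preset_c(self):
        """Noiseless ACHD cases sit exactly on the published 815 USD plateau."""
        diseases = [
            DiseaseTruth("achd", preset_params("achd"), onset_hazard=0.02,
                         icd9_patterns=("410.xx", "411.xx", "413.xx"))
        ]
        cfg = SimulationConfig(
            n_persons=60, seed=11, diseases=diseases, noise_sd=0.0,
            prevalent_fraction=0.0, single_record_fraction=0.0,
            background_condition_rates={},
        )
        persons, claims, truth = simulate_population(cfg)
        totals = _adjusted_month_totals(claims, cfg.cpi)
        cases = truth.cases("achd")
        assert cases
        for p in cases:
            pre = totals[p.person_id]
            pre = pre[pre.index < p.onset_month]
            assert np.allclose(pre.to_numpy(), 815.0)

    def test_conservation_against_cost_series(self):
        """Noiseless monthly claim totals reproduce the model series exactly."""
        cfg = SimulationConfig(n_persons=30, seed=13, noise_sd=0.0)
        persons, claims, truth = simulate_population(cfg)
        totals = _adjusted_month_totals(claims, cfg.cpi)
        for p in truth.persons.values():
            if p.role == "none" or p.onset_month is None:
                continue
            got = totals[p.person_id]
            params = truth.true_params(p.disease)
            expected = evaluate_cost(
                np.asarray(got.index) - p.onset_month, params
            )
            assert np.allclose(got.to_numpy(), expected)

    def test_no_claim_after_death(self):
        cfg = SimulationConfig(n_persons=120, seed=17,
                               death_hazard_post_onset=0.08)
        persons, claims, truth = simulate_population(cfg)
        merged = claims.merge(
            persons[["person_id", "death_date"]], on="person_id"
        )
        dead = merged[merged["death_date"].notna()]
        assert (dead["service_date"] <= pd.to_datetime(dead["death_date"])).all()
        assert any(p.death_date is not None for p in truth.persons.values())

    def test_monthly_mean_near_truth_with_noise(self):
        """Month -10 cross-person mean of ACHD cases within 3 sd/sqrt(n) of c."""
        diseases = [
            DiseaseTruth("achd", preset_params("achd"), onset_hazard=0.03,
                         icd9_patterns=("410.xx",))
        ]
        cfg = SimulationConfig(
            n_persons=500, seed=19, diseases=diseases, noise_sd=100.0,
            prevalent_fraction=0.0, single_record_fraction=0.0,
            background_condition_rates={}, death_hazard_post_onset=0.0,
        )
        persons, claims, truth = simulate_population(cfg)
        totals = _adjusted_month_totals(claims, cfg.cpi)
        vals = []
        for p in truth.cases("achd"):
            month = p.onset_month - 10
            if (p.person_id, month) in totals.index:
                vals.append(totals[(p.person_id, month)])
        vals = np.asarray(vals)
        assert len(vals) > 100
        assert abs(vals.mean() - 815.0) <= 3 * 100.0 / math.sqrt(len(vals))


def test_detection_round_trip_recovers_true_onsets(definitions):
    """With no contamination and short confirm delays, the two-record rule
    recovers at least 99% of true onset dates exactly (1,000 persons)."""
    cfg = SimulationConfig(
        n_persons=1000, seed=23, prevalent_fraction=0.0,
        single_record_fraction=0.0, confirm_delay_days=(7, 90),
    )
    persons, claims, truth = simulate_population(cfg)
    n_true = n_exact = 0
    for key, dd in definitions.items():
        true_cases = {
            p.person_id: p.onset_date for p in truth.cases(key)
        }
        if not true_cases:
            continue
        kept = exclude_prevalent(persons, claims, dd, cfg.interview_date)
        onsets = select_incident_cohort(
            kept,
            find_onsets(claims, dd, person_ids=kept["person_id"]),
            cfg.interview_date,
            sex_restriction=dd.sex_restriction,
        )
        detected = {r.person_id: r.onset_date for r in onsets}
        n_true += len(true_cases)
        n_exact += sum(
            1 for pid, d in true_cases.items() if detected.get(pid) == d
        )
    assert n_true > 500
    assert n_exact / n_true >= 0.99
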