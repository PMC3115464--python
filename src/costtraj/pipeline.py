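"""End-to-end orchestration: simulate -> detect -> build -> fit -> forecast.

Each stage writes a plain CSV so runs are inspectable and reproducible:
``onsets.csv``, ``profiles.csv``, ``estimates.csv``, ``forecast.csv`` and a
``run.log`` recording the analysis conventions (confirmation window, month
binning, weighting, model-selection threshold) and the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import Stratum, build_profile, person_month_costs, stratify
from .cpi import CPISeries, load_medical_cpi
from .diseases import DISEASE_ORDER, DiseaseDefinition, load_definitions
from .forecast import SurvivalInput, total_cost_constant_hazard
from .model import FitError, TrajectoryModel
from .onset import (
    CONFIRM_WINDOW_DAYS,
    exclude_prevalent,
    find_onsets,
    select_incident_cohort,
)
from .simulate import SimulationConfig, simulate_population, write_population

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]

log = logging.getLogger("costtraj")


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Configuration for one pipeline run.

    Exactly one of *simulation* (a :class:`SimulationConfig`) or
    *persons_path*/*claims_path* must be supplied.
    """

    simulation: SimulationConfig | None = None
    persons_path: str | None = None
    claims_path: str | None = None
    cpi_path: str | None = None
    interview_date: date | None = None  # required for file inputs
    diseases: list[str] = field(default_factory=lambda: list(DISEASE_ORDER))
    definitions_path: str | None = None
    stratify: bool = True
    weighting: str = "inverse_variance"
    rel_se_threshold: float = 10.0
    window: int = 20
    horizon_years: float = 5.0
    forecast_grid_months: int = 40
    min_stratum_size: int = 10
    out_dir: str = "costtraj_out"
    seed: int = 0
    make_plots: bool = False

    def validate(self) -> "PipelineConfig":
        has_sim = self.simulation is not None
        has_files = self.persons_path is not None or self.claims_path is not None
        if has_sim == has_files:
            raise ValueError(
                "exactly one of (simulation config, persons/claims paths) required"
            )
        if has_files and (self.persons_path is None or self.claims_path is None):
            raise ValueError("both persons_path and claims_path are required")
        if has_files and self.interview_date is None:
            raise ValueError("interview_date is required with file inputs")
        return self

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update(overrides)
        sim = raw.pop("simulation", None)
        if sim is not None:
            sim = SimulationConfig.from_dict(sim)
        if "interview_date" in raw and isinstance(raw["interview_date"], str):
            raw["interview_date"] = date.fromisoformat(raw["interview_date"])
        return cls(simulation=sim, **raw).validate()


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulation is not None:
        persons, claims, truth = simulate_population(cfg.simulation, seed=cfg.seed)
        write_population(persons, claims, truth, outdir)
        cpi = cfg.simulation.cpi
        interview = cfg.simulation.interview_date
    else:
        persons = pd.read_csv(cfg.persons_path)
        claims = pd.read_csv(cfg.claims_path)
        claims["service_date"] = pd.to_datetime(claims["service_date"])
        if "claim_year" not in claims.columns:
            claims["claim_year"] = claims["service_date"].dt.year
        cpi = (
            CPISeries.from_csv(cfg.cpi_path) if cfg.cpi_path else load_medical_cpi()
        )
        interview = cfg.interview_date
        truth = None
    return persons, claims, cpi, interview, truth


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns a report dict with outputs and counts."""
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info(
        "costtraj %s | seed=%d | confirm window=%.3f days | month binning="
        "calendar-month offsets | weighting=%s | model-selection rel SE "
        "threshold=%.1f | window=+/-%d months",
        __version__, config.seed, CONFIRM_WINDOW_DAYS, config.weighting,
        config.rel_se_threshold, config.window,
    )

    report: dict = {"out_dir": str(outdir)}
    try:
        stage = "simulate" if config.simulation is not None else "load"
        persons, claims, cpi, interview, truth = _load_inputs(config, outdir)
        report["n_persons"] = len(persons)
        report["n_claims"] = len(claims)
        log.info("%s: %d persons, %d claims", stage, len(persons), len(claims))

        stage = "detect"
        defs = load_definitions(config.definitions_path)
        onsets_by_disease = {}
        onset_rows = []
        for key in config.diseases:
            dd: DiseaseDefinition = defs[key]
            retained = exclude_prevalent(persons, claims, dd, interview)
            onsets = find_onsets(claims, dd, person_ids=retained["person_id"])
            cohort = select_incident_cohort(
                retained, onsets, interview, config.horizon_years,
                sex_restriction=dd.sex_restriction,
            )
            onsets_by_disease[key] = cohort
            for rec in cohort:
                onset_rows.append(
                    {
                        "person_id": rec.person_id,
                        "disease": key,
                        "onset_date": rec.onset_date.isoformat(),
                        "confirm_gap_days": rec.confirm_gap_days,
                    }
                )
            log.info("detect %s: %d incident onsets", key, len(cohort))
        pd.DataFrame(
            onset_rows,
            columns=["person_id", "disease", "onset_date", "confirm_gap_days"],
        ).to_csv(outdir / "onsets.csv", index=False)
        report["onsets"] = {k: len(v) for k, v in onsets_by_disease.items()}

        stage = "build"
        claims_by_person = dict(list(claims.groupby("person_id")))
        persons_ix = persons.set_index("person_id", drop=False)
        profile_frames = []
        profiles = {}
        for key, cohort in onsets_by_disease.items():
            if not cohort:
                log.warning("build %s: empty cohort, skipped", key)
                continue
            pm = {}
            for rec in cohort:
                pm[rec.person_id] = person_month_costs(
                    claims_by_person.get(rec.person_id, claims.iloc[0:0]),
                    persons_ix.loc[rec.person_id],
                    rec.onset_date,
                    cpi,
                    window=config.window,
                )
            all_pm = pd.concat(pm.values(), ignore_index=True)
            strata: dict[Stratum, set] = {Stratum("total", "total"): set(pm)}
            if config.stratify:
                strata = stratify(cohort, persons, claims, interview)
            for stratum, ids in strata.items():
                if not ids or (
                    stratum.variable != "total" and len(ids) < config.min_stratum_size
                ):
                    continue
                sub = all_pm[all_pm["person_id"].isin(ids)]
                prof = build_profile(
                    sub, disease=key, stratum=stratum.label, window=config.window
                )
                profiles[(key, stratum.label)] = (prof, len(ids))
                profile_frames.append(prof.to_frame())
        pd.concat(profile_frames, ignore_index=True).to_csv(
            outdir / "profiles.csv", index=False
        )

        stage = "fit"
        est_rows = []
        for (key, stratum_label), (prof, n_ids) in profiles.items():
            try:
                res = TrajectoryModel(prof, weighting=config.weighting).fit(
                    variant="auto", rel_se_threshold=config.rel_se_threshold
                )
            except FitError as exc:
                log.warning("fit %s/%s failed: %s", key, stratum_label, exc)
                continue
            p = res.cost_params
            est_rows.append(
                {
                    "disease": key,
                    "stratum": stratum_label,
                    "variant": p.variant,
                    "c": p.c, "se_c": p.se_c,
                    "P": p.P, "se_P": p.se_P,
                    "r": p.r, "se_r": p.se_r,
                    "delta": p.delta, "se_delta": p.se_delta,
                    "chi2_per_df": res.chi2_per_df,
                    "df": res.df_resid,
                    "n_persons": n_ids,
                }
            )
        estimates = pd.DataFrame(est_rows)
        estimates.to_csv(outdir / "estimates.csv", index=False)
        report["estimates"] = len(estimates)

        stage = "forecast"
        fc_rows = []
        followup_months = config.horizon_years * 12.0
        for key, cohort in onsets_by_disease.items():
            row = estimates[
                (estimates["disease"] == key)
                & (estimates["stratum"] == "total")
                & (estimates["variant"] == "full")
            ]
            if row.empty or not cohort:
                continue
            p = row.iloc[0]
            from .model import CostModelParams

            params = CostModelParams(
                c=p["c"], P=p["P"], r=p["r"], delta=p["delta"], variant="full"
            )
            # crude constant onset hazard from the cohort itself
            h = len(cohort) / (len(persons) * followup_months)
            for x in range(0, config.forecast_grid_months + 1):
                pt = total_cost_constant_hazard(float(x), params, h)
                fc_rows.append(
                    {
                        "disease": key,
                        "x": x,
                        "hazard": h,
                        "total": pt.total,
                        "healthy": pt.healthy,
                        "acquired": pt.acquired,
                        "treatment": pt.treatment,
                    }
                )
        pd.DataFrame(fc_rows).to_csv(outdir / "forecast.csv", index=False)

        if config.make_plots:
            stage = "plot"
            from .plotting import plot_profiles

            fig = plot_profiles(
                {k: v[0] for k, v in profiles.items() if k[1] == "total"},
                estimates,
            )
            fig.savefig(outdir / "profiles.png", dpi=120)

        if truth is not None:
            report["ground_truth"] = {
                "incident": sum(
                    1 for p in truth.persons.values() if p.role == "incident"
                ),
                "prevalent": sum(
                    1 for p in truth.persons.values() if p.role == "prevalent"
                ),
            }
    except Exception as exc:  # noqa: BLE001 - rewrapped with stage context
        log.error("stage %s failed: %s", stage, exc)
        raise PipelineError(stage, exc) from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return report
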