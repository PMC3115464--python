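"""Population-level per-capita cost forecast for a cohort exposed to one disease.

Given fitted trajectory parameters and the disease's onset-time distribution
(through a survival function S(x); x in months), the expected cost per
month per capita at time x is

    C_tot(x) = c S(x) + (c + delta) F(x)
               + (P - delta) * integral_0^x exp(-r (x - u)) f(u) du

where F = 1 - S and f is the onset-time density.  The first term is the
contribution of still-healthy individuals, the second the acquired
comorbidity of those with onset, and the third the decaying treatment cost
integrated over onset times.  Mortality and second health events are, by
assumption, outside this formula.

Three survival specifications are supported: a constant hazard (closed
form), a general constant-hazard density via adaptive quadrature (used as a
cross-check), and a tabulated step survival function, e.g. a Kaplan-Meier
estimate, whose point-mass density makes the integral an exact finite sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import integrate

from .model import CostModelParams

__all__ = [
    "SurvivalInput",
    "ForecastPoint",
    "total_cost",
    "total_cost_constant_hazard",
    "survival_from_km",
]

#: below this |r - h| the confluent (r = h) closed form is used
_CONFLUENT_TOL = 1e-12


@dataclass(frozen=True)
class SurvivalInput:
    """Onset-time survival specification.

    ``constant_hazard``: S(x) = exp(-h x) with per-month hazard ``h``.
    ``tabulated``: right-continuous step function through ``steps`` =
    ordered (time, S) pairs, S(0) = 1 before the first event time; the
    density is a sum of point masses at the event times.
    """

    kind: str
    h: float | None = None
    steps: tuple[tuple[float, float], ...] | None = None

    @classmethod
    def constant_hazard(cls, h: float) -> "SurvivalInput":
        if h < 0:
            raise ValueError("hazard must be non-negative")
        return cls(kind="constant_hazard", h=float(h))

    @classmethod
    def tabulated(cls, times, survival) -> "SurvivalInput":
        times = np.asarray(times, dtype=float)
        surv = np.asarray(survival, dtype=float)
        if len(times) != len(surv):
            raise ValueError("times and survival must have equal length")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(surv < 0) or np.any(surv > 1) or np.any(np.diff(surv) > 0):
            raise ValueError("survival must be non-increasing within [0, 1]")
        return cls(kind="tabulated", steps=tuple(zip(times, surv)))

    def S(self, x: float) -> float:
        """Survival (still-healthy fraction) at time x."""
        if self.kind == "constant_hazard":
            return math.exp(-self.h * x)
        s = 1.0
        for t, v in self.steps:
            if t <= x:
                s = v
            else:
                break
        return s

    def F(self, x: float) -> float:
        return 1.0 - self.S(x)

    def point_masses(self, x: float):
        """(time, mass) pairs of the onset density up to x (tabulated only)."""
        if self.kind != "tabulated":
            raise ValueError("point masses only defined for tabulated survival")
        prev = 1.0
        out = []
        for t, v in self.steps:
            if t > x:
                break
            mass = prev - v
            if mass > 0:
                out.append((t, mass))
            prev = v
        return out


@dataclass(frozen=True)
class ForecastPoint:
    """Per-capita cost forecast at horizon x, split into its three terms."""

    x: float
    healthy: float        # c * S(x)
    acquired: float       # (c + delta) * F(x)
    treatment: float      # (P - delta) * convolution integral

    @property
    def total(self) -> float:
        return self.healthy + self.acquired + self.treatment

    @property
    def components(self) -> tuple[float, float, float]:
        return (self.healthy, self.acquired, self.treatment)


def _require_full(params: CostModelParams):
    if params.variant != "full" or not np.isfinite(params.r):
        raise ValueError("forecast requires a full-variant parameter set")


def total_cost(x: float, params: CostModelParams, survival: SurvivalInput) -> ForecastPoint:
    """Expected per-capita cost at horizon *x* months.

    The convolution integral uses adaptive quadrature for a constant-hazard
    density (absolute tolerance 1e-10 * (c + P)) and an exact finite sum of
    point masses for tabulated survival.
    """
    if x < 0:
        raise ValueError("horizon x must be non-negative")
    _require_full(params)
    c, P, r, delta = params.c, params.P, params.r, params.delta
    S = survival.S(x)
    if survival.kind == "constant_hazard":
        h = survival.h
        if h == 0 or x == 0:
            integral = 0.0
        else:
            integral, _ = integrate.quad(
                lambda u: math.exp(-r * (x - u)) * h * math.exp(-h * u),
                0.0,
                x,
                epsabs=1e-10 * (abs(c) + abs(P)),
                epsrel=1e-12,
                limit=500,
            )
    else:
        integral = sum(
            mass * math.exp(-r * (x - t)) for t, mass in survival.point_masses(x)
        )
    return ForecastPoint(
        x=float(x),
        healthy=c * S,
        acquired=(c + delta) * (1.0 - S),
        treatment=(P - delta) * integral,
    )


def total_cost_constant_hazard(x: float, params: CostModelParams, h: float) -> ForecastPoint:
    """Closed form of the forecast under a constant onset hazard *h* (1/month).

    The convolution integral is h (e^{-hx} - e^{-rx}) / (r - h) for r != h
    and h x e^{-hx} in the confluent case r = h.
    """
    if x < 0:
        raise ValueError("horizon x must be non-negative")
    if h < 0:
        raise ValueError("hazard must be non-negative")
    _require_full(params)
    c, P, r, delta = params.c, params.P, params.r, params.delta
    S = math.exp(-h * x)
    if abs(r - h) < _CONFLUENT_TOL:
        integral = h * x * math.exp(-h * x)
    else:
        integral = h * (math.exp(-h * x) - math.exp(-r * x)) / (r - h)
    return ForecastPoint(
        x=float(x),
        healthy=c * S,
        acquired=(c + delta) * (1.0 - S),
        treatment=(P - delta) * integral,
    )


def survival_from_km(event_table) -> SurvivalInput:
    """Product-limit (Kaplan-Meier) survival from an aggregated event table.

    *event_table* is a DataFrame (or records) with columns ``time``,
    ``n_at_risk`` and ``n_events``, times strictly increasing.  Censoring
    is encoded implicitly by decreasing ``n_at_risk`` between event times.
    """
    table = pd.DataFrame(event_table)
    for col in ("time", "n_at_risk", "n_events"):
        if col not in table.columns:
            raise ValueError(f"event table missing column {col!r}")
    t = table["time"].to_numpy(dtype=float)
    n = table["n_at_risk"].to_numpy(dtype=float)
    d = table["n_events"].to_numpy(dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("event times must be strictly increasing")
    if np.any(d < 0) or np.any(n <= 0) or np.any(d > n):
        raise ValueError("need 0 <= n_events <= n_at_risk and n_at_risk > 0")
    s = np.cumprod(1.0 - d / n)
    return SurvivalInput.tabulated(t, s)
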