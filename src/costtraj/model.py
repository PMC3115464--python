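"""Four-parameter model of medical-cost trajectories around disease onset.

The mean cost per month per capita at month offset ``m`` (onset at ``m = 0``)
is modelled as

    C(m) = c + (delta + (P - delta) * exp(-r * m)) * I(m >= 0)

with four interpretable parameters:

* ``c``     — pre-diagnosis plateau (initial comorbidity), USD/month;
* ``P``     — cost of the disease onset (peak above ``c`` at month 0), USD;
* ``r``     — population recovery rate, 1/month: exponential slope of the
  post-onset decline of expenses;
* ``delta`` — acquired comorbidity: difference between the post-onset
  asymptotic plateau ``c + delta`` and the pre-onset plateau ``c``, USD/month.

The model is fitted to a 41-point monthly profile by (weighted) nonlinear
least squares with a multi-start grid over the recovery rate.  When the
recovery rate is unidentifiable (e.g. the post-onset curve is flat), a
two-parameter step model ``C(m) = c + P * I(m >= 0)`` is used instead.

The public surface follows the statsmodels convention: build a
:class:`TrajectoryModel` from profile data, call :meth:`TrajectoryModel.fit`,
and read estimates, standard errors and diagnostics off the returned
:class:`TrajectoryResults`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .profile import TrajectoryProfile

__all__ = [
    "CostModelParams",
    "FitDiagnostics",
    "FitError",
    "TrajectoryModel",
    "TrajectoryResults",
    "evaluate_cost",
    "fit_full_model",
    "fit_step_model",
    "select_model",
    "chi2_per_df",
]

#: multi-start grid of recovery-rate starting values (1/month)
R_STARTS = (0.05, 0.2, 0.5, 1.0, 2.0)

#: default relative-SE threshold above which the recovery rate is deemed
#: unidentifiable and the step model is selected
REL_SE_THRESHOLD = 10.0


class FitError(RuntimeError):
    """Nonlinear least squares failed from every starting point."""

    def __init__(self, message, best_residual=np.inf):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class CostModelParams:
    """Parameter quadruple (c, P, r, delta) with SEs and covariance.

    ``variant="step"`` denotes the degenerate two-parameter model in which
    the recovery rate and acquired comorbidity are not identified (stored
    as NaN).
    """

    c: float
    P: float
    r: float = math.nan
    delta: float = math.nan
    se_c: float = math.nan
    se_P: float = math.nan
    se_r: float = math.nan
    se_delta: float = math.nan
    covariance: np.ndarray | None = None
    variant: str = "full"

    @property
    def names(self) -> tuple[str, ...]:
        return ("c", "P") if self.variant == "step" else ("c", "P", "r", "delta")

    @property
    def values(self) -> np.ndarray:
        if self.variant == "step":
            return np.array([self.c, self.P])
        return np.array([self.c, self.P, self.r, self.delta])

    @property
    def bse(self) -> np.ndarray:
        if self.variant == "step":
            return np.array([self.se_c, self.se_P])
        return np.array([self.se_c, self.se_P, self.se_r, self.se_delta])

    @property
    def k_params(self) -> int:
        return 2 if self.variant == "step" else 4


@dataclass
class FitDiagnostics:
    chi2_per_df: float
    df: int
    converged: bool
    n_restarts_used: int = 1
    weighting: str = "inverse_variance"


def evaluate_cost(m, params: CostModelParams):
    """Model cost at month offset(s) *m* (scalar or array; float offsets allowed).

    Before onset (m < 0) the cost is the plateau ``c``; from the onset month
    onward it is ``c + delta + (P - delta) * exp(-r * m)``.
    """
    m_arr = np.asarray(m, dtype=float)
    onset = m_arr >= 0
    if params.variant == "step":
        out = params.c + params.P * onset
    else:
        post = params.delta + (params.P - params.delta) * np.exp(
            -params.r * np.where(onset, m_arr, 0.0)
        )
        out = params.c + post * onset
    if np.isscalar(m) or np.ndim(m) == 0:
        return float(out)
    return out


def _safe_chi2(profile, params):
    """chi2/df for diagnostics; NaN when SEs carry no information (all zero)."""
    try:
        return chi2_per_df(profile, params)
    except ValueError:
        return math.nan


def _curve(m, c, P, r, delta):
    onset = m >= 0
    return c + (delta + (P - delta) * np.exp(-r * np.where(onset, m, 0.0))) * onset


def _curve_jac(m, c, P, r, delta):
    onset = (m >= 0).astype(float)
    mp = np.where(m >= 0, m, 0.0)
    e = np.exp(-r * mp)
    return np.column_stack(
        [
            np.ones_like(m),
            e * onset,
            -(P - delta) * mp * e * onset,
            (1.0 - e) * onset,
        ]
    )


class TrajectoryModel:
    """Cost-trajectory model bound to one monthly profile.

    Parameters
    ----------
    profile : TrajectoryProfile
        Onset-aligned means/SEs, normally 41 monthly points.
    weighting : {"inverse_variance", "unweighted"}
        ``inverse_variance`` minimises sum((C_i - C(m_i))^2 / se_i^2) and
        reports unscaled (absolute-sigma) parameter covariance; months with
        se = 0 are excluded.  ``unweighted`` minimises the plain residual
        sum of squares and scales the covariance by the residual variance.
    """

    def __init__(self, profile: TrajectoryProfile, weighting: str = "inverse_variance"):
        if weighting not in ("inverse_variance", "unweighted"):
            raise ValueError(f"unknown weighting {weighting!r}")
        self.profile = profile
        self.weighting = weighting
        if weighting == "inverse_variance":
            mask = profile.usable
        else:
            mask = np.isfinite(profile.mean)
        self._mask = mask
        self.m = profile.m[mask].astype(float)
        self.y = profile.mean[mask]
        self.sigma = profile.se[mask] if weighting == "inverse_variance" else None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, **kwargs) -> "TrajectoryModel":
        """Build from a DataFrame with columns m, mean, se, n."""
        return cls(TrajectoryProfile.from_frame(frame), **kwargs)

    # -- helpers -----------------------------------------------------------

    def _check_points(self, k_params: int):
        n_pre = int(np.sum(self.m < 0))
        n_post = int(np.sum(self.m >= 0))
        # the step model's closed form only needs one point on each side
        min_post = 2 if k_params == 4 else 1
        min_total = max(5, k_params + 1) if k_params == 4 else k_params + 1
        if len(self.m) < min_total or n_pre < 1 or n_post < min_post:
            raise FitError(
                f"insufficient usable points (pre={n_pre}, post={n_post}) "
                f"for a {k_params}-parameter fit"
            )

    def _weights(self) -> np.ndarray:
        if self.sigma is None:
            return np.ones_like(self.y)
        return 1.0 / self.sigma**2

    def _start_values(self, r0: float) -> np.ndarray:
        w = self._weights()
        pre = self.m < 0
        post = self.m >= 0
        c0 = float(np.average(self.y[pre], weights=w[pre]))
        at0 = self.y[self.m == 0]
        P0 = float(at0[0] - c0) if at0.size else float(self.y[post].max() - c0)
        tail = self.y[post][-min(5, int(post.sum())):]
        d0 = float(tail.mean() - c0)
        return np.array([c0, P0, r0, d0])

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        variant: str = "auto",
        rel_se_threshold: float = REL_SE_THRESHOLD,
        r_starts=R_STARTS,
    ) -> "TrajectoryResults":
        """Fit the trajectory model.

        ``variant="full"`` forces the four-parameter model, ``"step"`` the
        two-parameter step model, and ``"auto"`` fits the full model and
        falls back to the step model when the fit fails or the recovery
        rate is unidentifiable (se_r / |r| above *rel_se_threshold*, or a
        non-positive rate with an unidentified acquired-comorbidity level).
        """
        if variant == "full":
            params, diag = self._fit_full(r_starts)
        elif variant == "step":
            params, diag = self._fit_step()
        elif variant == "auto":
            try:
                params, diag = self._fit_full(r_starts)
            except FitError:
                params, diag = self._fit_step()
            else:
                if select_model((params, diag), rel_se_threshold) == "step":
                    params, diag = self._fit_step()
        else:
            raise ValueError(f"unknown variant {variant!r}")
        return TrajectoryResults(self, params, diag)

    def _fit_full(self, r_starts=R_STARTS):
        self._check_points(4)
        best = None
        n_tried = 0
        best_residual = np.inf

        def _one_fit(p0):
            # an unestimable covariance (infinite SEs) is an expected outcome
            # on degenerate profiles and is handled by select_model
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", optimize.OptimizeWarning)
                return optimize.curve_fit(
                    _curve,
                    self.m,
                    self.y,
                    p0=p0,
                    sigma=self.sigma,
                    absolute_sigma=self.sigma is not None,
                    method="lm",
                    jac=_curve_jac,
                    maxfev=20000,
                    xtol=1e-14,
                    ftol=1e-14,
                )

        for r0 in r_starts:
            n_tried += 1
            try:
                popt, pcov = _one_fit(self._start_values(r0))
                # polish: restart from the optimum to squeeze out the last
                # digits in ill-conditioned (slow-rate) corners
                popt, pcov = _one_fit(popt)
            except (RuntimeError, optimize.OptimizeWarning, ValueError):
                continue
            resid = self.y - _curve(self.m, *popt)
            ssr = float(np.sum(self._weights() * resid**2))
            if ssr < best_residual:
                best_residual = ssr
                best = (popt, pcov)
        if best is None:
            raise FitError("full model failed to converge from all starts",
                           best_residual=best_residual)
        popt, pcov = best
        se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
        params = CostModelParams(
            c=popt[0], P=popt[1], r=popt[2], delta=popt[3],
            se_c=se[0], se_P=se[1], se_r=se[2], se_delta=se[3],
            covariance=pcov, variant="full",
        )
        diag = FitDiagnostics(
            chi2_per_df=_safe_chi2(self.profile, params),
            df=len(self.m) - 4,
            converged=True,
            n_restarts_used=n_tried,
            weighting=self.weighting,
        )
        return params, diag

    def _fit_step(self):
        self._check_points(2)
        w = self._weights()
        pre = self.m < 0
        post = ~pre
        c = float(np.average(self.y[pre], weights=w[pre]))
        level_post = float(np.average(self.y[post], weights=w[post]))
        P = level_post - c
        var_c = 1.0 / float(w[pre].sum())
        var_post = 1.0 / float(w[post].sum())
        if self.sigma is None:
            # scale by residual variance, as in unweighted NLS
            resid = self.y - (c + P * post)
            dof = max(len(self.y) - 2, 1)
            s2 = float(np.sum(resid**2)) / dof
            var_c *= s2
            var_post *= s2
        cov = np.array([[var_c, -var_c], [-var_c, var_c + var_post]])
        params = CostModelParams(
            c=c, P=P,
            se_c=math.sqrt(var_c), se_P=math.sqrt(var_c + var_post),
            covariance=cov, variant="step",
        )
        diag = FitDiagnostics(
            chi2_per_df=_safe_chi2(self.profile, params),
            df=len(self.m) - 2,
            converged=True,
            n_restarts_used=1,
            weighting=self.weighting,
        )
        return params, diag


class TrajectoryResults:
    """Estimates, uncertainties and diagnostics from a trajectory fit."""

    def __init__(self, model: TrajectoryModel, params: CostModelParams,
                 diagnostics: FitDiagnostics):
        self.model = model
        self._params = params
        self.diagnostics = diagnostics

    # -- statsmodels-flavoured accessors -----------------------------------

    @property
    def cost_params(self) -> CostModelParams:
        return self._params

    @property
    def variant(self) -> str:
        return self._params.variant

    @property
    def params(self) -> pd.Series:
        return pd.Series(self._params.values, index=list(self._params.names))

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self._params.bse, index=list(self._params.names))

    def cov_params(self) -> pd.DataFrame:
        names = list(self._params.names)
        return pd.DataFrame(self._params.covariance, index=names, columns=names)

    @property
    def df_resid(self) -> int:
        return self.diagnostics.df

    @property
    def chi2_per_df(self) -> float:
        return self.diagnostics.chi2_per_df

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Normal-approximation (delta-method) confidence intervals."""
        z = stats.norm.ppf(1 - alpha / 2)
        lo = self._params.values - z * self._params.bse
        hi = self._params.values + z * self._params.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=list(self._params.names))

    def predict(self, m=None):
        """Model cost at month offset(s) *m* (default: the profile's months)."""
        if m is None:
            m = self.model.profile.m
        return evaluate_cost(m, self._params)

    def forecast(self, survival, x):
        """Population per-capita cost forecast at horizon(s) *x* months.

        Delegates to :func:`costtraj.forecast.total_cost`; *survival* is a
        :class:`costtraj.forecast.SurvivalInput`.
        """
        from .forecast import total_cost

        if np.ndim(x) == 0:
            return total_cost(float(x), self._params, survival)
        return [total_cost(float(xi), self._params, survival) for xi in x]

    def plot(self, ax=None, group_months: int = 2):
        """Dots-with-errorbars of the profile and the fitted curve."""
        from .plotting import plot_fit

        return plot_fit(self.model.profile, self, ax=ax, group_months=group_months)

    def summary(self) -> str:
        p = self._params
        d = self.diagnostics
        lines = [
            "Cost Trajectory Model Results",
            "=" * 64,
            f"Disease:            {self.model.profile.disease or '-'}",
            f"Stratum:            {self.model.profile.stratum}",
            f"Variant:            {p.variant}",
            f"Weighting:          {d.weighting}",
            f"No. points used:    {len(self.model.m)}",
            f"Df residuals:       {d.df}",
            f"Chi2 / df:          {d.chi2_per_df:.3f}",
            f"Converged:          {d.converged} (starts tried: {d.n_restarts_used})",
            "-" * 64,
            f"{'':>8}{'coef':>12}{'std err':>12}{'[0.025':>12}{'0.975]':>12}",
        ]
        ci = self.conf_int()
        units = {"c": "USD/mo", "P": "USD", "r": "1/mo", "delta": "USD/mo"}
        for name, val, se in zip(p.names, p.values, p.bse):
            lines.append(
                f"{name:>8}{val:>12.4g}{se:>12.3g}"
                f"{ci.loc[name, 'lower']:>12.4g}{ci.loc[name, 'upper']:>12.4g}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def __repr__(self):
        vals = ", ".join(f"{n}={v:.4g}" for n, v in self.params.items())
        return f"<TrajectoryResults {self.variant}: {vals}>"


# -- module-level operation surface ---------------------------------------


def fit_full_model(profile: TrajectoryProfile, weighting: str = "inverse_variance"):
    """Fit the four-parameter model; returns (CostModelParams, FitDiagnostics)."""
    res = TrajectoryModel(profile, weighting=weighting).fit(variant="full")
    return res.cost_params, res.diagnostics


def fit_step_model(profile: TrajectoryProfile, weighting: str = "inverse_variance"):
    """Fit the degenerate step model ``C(m) = c + P I(m>=0)`` (closed form)."""
    res = TrajectoryModel(profile, weighting=weighting).fit(variant="step")
    return res.cost_params, res.diagnostics


def select_model(full_fit, rel_se_threshold: float = REL_SE_THRESHOLD) -> str:
    """Choose between the full and step variants after a full-model fit.

    *full_fit* is a (CostModelParams, FitDiagnostics) pair, or None when the
    full fit failed outright.  The step model is selected when the fit
    failed, when ``se_r / |r|`` exceeds the threshold, or when the rate is
    non-positive and the acquired-comorbidity level is itself unidentified.
    """
    if full_fit is None:
        return "step"
    params, diag = full_fit
    if not diag.converged:
        return "step"
    if params.r == 0 or not np.isfinite(params.r):
        return "step"
    if params.se_r / abs(params.r) > rel_se_threshold:
        return "step"
    if params.r <= 0 and (
        not np.isfinite(params.se_delta)
        or (params.delta != 0 and params.se_delta / abs(params.delta) > rel_se_threshold)
    ):
        return "step"
    return "full"


def chi2_per_df(profile: TrajectoryProfile, params: CostModelParams,
                group_months: int = 1) -> float:
    """Goodness of fit: sum of squared standardised residuals per residual df.

    ``sum_i (C_i - C(m_i))^2 / se_i^2 / df`` over the profile's usable
    points, with ``df = n_points - k_params`` counted on the monthly points
    (41 - 4 = 37 for a complete full-model profile).  ``group_months=2``
    aggregates adjacent months into two-month groups before computing the
    residuals (as done when plotting), leaving df unchanged.
    """
    mask = profile.usable
    if not mask.any():
        raise ValueError("no usable points: all standard errors are zero or missing")
    m = profile.m[mask].astype(float)
    y = profile.mean[mask]
    se = profile.se[mask]
    df = len(m) - params.k_params
    if df <= 0:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    if group_months > 1:
        groups = [
            slice(i, min(i + group_months, len(m)))
            for i in range(0, len(m), group_months)
        ]
        resid2 = 0.0
        for g in groups:
            k = g.stop - g.start
            cg = y[g].mean()
            pg = float(np.mean(evaluate_cost(m[g], params)))
            seg = math.sqrt(float(np.sum(se[g] ** 2))) / k
            resid2 += (cg - pg) ** 2 / seg**2
        return resid2 / df
    resid = (y - evaluate_cost(m, params)) / se
    return float(np.sum(resid**2)) / df
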