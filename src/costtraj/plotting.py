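"""Profile/fit figures: empirical dots with error bars, fitted curve overlay."""

from __future__ import annotations

import numpy as np

from .model import evaluate_cost

__all__ = ["plot_fit", "plot_profiles"]


def _aggregate(profile, group_months: int = 2):
    """Two-month (or k-month) display aggregation of a profile's points."""
    m, mean, se = profile.m, profile.mean, profile.se
    xs, ys, es = [], [], []
    for i in range(0, len(m), group_months):
        sl = slice(i, min(i + group_months, len(m)))
        k = sl.stop - sl.start
        xs.append(float(np.mean(m[sl])))
        ys.append(float(np.mean(mean[sl])))
        es.append(float(np.sqrt(np.sum(se[sl] ** 2)) / k))
    return np.array(xs), np.array(ys), np.array(es)


def plot_fit(profile, results=None, ax=None, group_months: int = 2):
    """One panel: profile dots (aggregated for display) and fitted curve."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    xs, ys, es = _aggregate(profile, group_months)
    ax.errorbar(xs, ys, yerr=es, fmt="o", ms=3, lw=1, capsize=2, color="k")
    if results is not None:
        grid = np.linspace(profile.m.min(), profile.m.max(), 400)
        # keep the pre-onset plateau flat across the discontinuity at 0
        pred = evaluate_cost(grid, results.cost_params)
        ax.plot(grid, pred, "-", color="tab:red", lw=1.2)
        ax.text(
            0.97, 0.95, f"$\\chi^2/df$ = {results.chi2_per_df:.2f}",
            transform=ax.transAxes, ha="right", va="top", fontsize=8,
        )
    ax.set_xlabel("months since onset")
    ax.set_ylabel("cost per month (2000 USD)")
    title = profile.disease or ""
    if profile.stratum != "total":
        title += f" [{profile.stratum}]"
    ax.set_title(title, fontsize=9)
    return ax


def plot_profiles(profiles: dict, estimates, group_months: int = 2):
    """Grid of panels, one per disease, dots + fitted curves + chi2/df.

    *profiles* maps (disease, stratum) or disease -> TrajectoryProfile;
    *estimates* is the estimates table (one row per disease/stratum) whose
    disease set must cover the profiles.
    """
    import matplotlib.pyplot as plt

    from .model import CostModelParams
    from .profile import TrajectoryProfile

    items = []
    for k, v in profiles.items():
        disease = k[0] if isinstance(k, tuple) else k
        items.append((disease, v))
    have = {d for d, _ in items}
    est_diseases = set(estimates["disease"].unique())
    if not have <= est_diseases:
        raise ValueError(
            f"profiles without matching estimates: {sorted(have - est_diseases)}"
        )
    n = len(items)
    ncols = min(4, max(1, n))
    nrows = int(np.ceil(n / ncols))
    fig, axes = plt.subplots(
        nrows, ncols, figsize=(3.2 * ncols, 2.6 * nrows), squeeze=False
    )
    for ax in axes.flat[n:]:
        ax.set_visible(False)
    for (disease, prof), ax in zip(items, axes.flat):
        row = estimates[
            (estimates["disease"] == disease) & (estimates["stratum"] == "total")
        ]
        results = None
        if not row.empty:
            r0 = row.iloc[0]
            params = CostModelParams(
                c=r0["c"], P=r0["P"], r=r0["r"], delta=r0["delta"],
                variant=r0.get("variant", "full"),
            )

            class _Shim:
                cost_params = params
                chi2_per_df = float(r0["chi2_per_df"])

            results = _Shim()
        if not isinstance(prof, TrajectoryProfile):
            prof = TrajectoryProfile.from_frame(prof, disease=disease)
        plot_fit(prof, results, ax=ax, group_months=group_months)
    fig.tight_layout()
    return fig
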