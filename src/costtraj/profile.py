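"""Onset-aligned monthly cost profiles.

A :class:`TrajectoryProfile` holds, for one disease and stratum, the mean
monthly medical cost per capita and its standard error at integer month
offsets around disease onset (month 0 = onset month), by default 20 months
on each side, i.e. 41 points.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TrajectoryProfile"]


@dataclass
class TrajectoryProfile:
    """Mean/SE cost profile on integer month offsets ``-window..window``.

    Attributes
    ----------
    m : month offsets (ints), onset month is 0.
    mean : mean cost per month per capita, year-2000 USD.
    se : standard error of the mean; 0 is allowed but flags the month as
        unusable for weighted fitting.
    n_at_risk : persons contributing to each month.
    """

    m: np.ndarray
    mean: np.ndarray
    se: np.ndarray
    n_at_risk: np.ndarray
    disease: str = ""
    stratum: str = "total"

    def __post_init__(self):
        self.m = np.asarray(self.m, dtype=int)
        self.mean = np.asarray(self.mean, dtype=float)
        self.se = np.asarray(self.se, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        n = len(self.m)
        if not (len(self.mean) == len(self.se) == len(self.n_at_risk) == n):
            raise ValueError("profile arrays must have equal length")
        order = np.argsort(self.m)
        for name in ("m", "mean", "se", "n_at_risk"):
            setattr(self, name, getattr(self, name)[order])
        if len(np.unique(self.m)) != n:
            raise ValueError("duplicate month offsets in profile")

    def __len__(self) -> int:
        return len(self.m)

    @property
    def usable(self) -> np.ndarray:
        """Months that can enter a weighted fit: finite mean, positive SE,
        at least one contributing person (SE > 0 implies n > 1 in practice)."""
        return np.isfinite(self.mean) & np.isfinite(self.se) & (self.se > 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "disease": self.disease,
                "stratum": self.stratum,
                "m": self.m,
                "mean": self.mean,
                "se": self.se,
                "n": self.n_at_risk,
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, disease: str = "", stratum: str = "total"):
        """Build from a DataFrame with columns m, mean, se and n (or n_at_risk)."""
        ncol = "n" if "n" in frame.columns else "n_at_risk"
        if "disease" in frame.columns and not disease:
            disease = str(frame["disease"].iloc[0])
        if "stratum" in frame.columns and stratum == "total":
            stratum = str(frame["stratum"].iloc[0])
        return cls(
            m=frame["m"].to_numpy(),
            mean=frame["mean"].to_numpy(),
            se=frame["se"].to_numpy(),
            n_at_risk=frame[ncol].to_numpy(),
            disease=disease,
            stratum=stratum,
        )

    @classmethod
    def from_params(cls, params, window: int = 20, se: float = 1.0,
                    disease: str = "", stratum: str = "total"):
        """Noiseless profile evaluated from a fitted/true parameter set.

        Nominal unit SEs keep the months usable by weighted fitting while
        carrying no information (all weights equal).
        """
        from .model import evaluate_cost

        m = np.arange(-window, window + 1)
        return cls(
            m=m,
            mean=evaluate_cost(m, params),
            se=np.full(m.shape, float(se)),
            n_at_risk=np.ones(m.shape, dtype=int),
            disease=disease,
            stratum=stratum,
        )
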