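"""Medical-care CPI series and inflation adjustment to base-year dollars."""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import pandas as pd

__all__ = ["CPISeries", "adjust_to_2000_dollars", "load_medical_cpi"]


@dataclass(frozen=True)
class CPISeries:
    """Annual price-index values with a base year.

    Amounts are converted to base-year dollars by multiplying with
    ``index[base_year] / index[year]``; the base year maps to the identity.
    """

    values: dict[int, float]
    base_year: int = 2000

    def __post_init__(self):
        if self.base_year not in self.values:
            raise ValueError(f"base year {self.base_year} missing from CPI series")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("CPI index values must be positive")

    def adjust(self, amount: float, year: int) -> float:
        """Nominal *amount* from *year* in base-year dollars."""
        if year not in self.values:
            raise KeyError(f"year {year} not in CPI series")
        return amount * self.values[self.base_year] / self.values[year]

    def deflate(self, amount: float, year: int) -> float:
        """Base-year *amount* expressed in nominal dollars of *year* (inverse of adjust)."""
        if year not in self.values:
            raise KeyError(f"year {year} not in CPI series")
        return amount * self.values[year] / self.values[self.base_year]

    @classmethod
    def from_csv(cls, path, base_year: int = 2000) -> "CPISeries":
        table = pd.read_csv(path)
        return cls(
            {int(y): float(v) for y, v in zip(table["year"], table["index"])}, base_year
        )


def load_medical_cpi(base_year: int = 2000) -> CPISeries:
    """Packaged BLS medical-care CPI annual averages, 1990-2005 (1982-84 = 100)."""
    ref = importlib.resources.files("costtraj.data") / "cpi_medical.csv"
    with importlib.resources.as_file(ref) as p:
        table = pd.read_csv(p)
    return CPISeries(
        {int(y): float(v) for y, v in zip(table["year"], table["index"])}, base_year
    )


def adjust_to_2000_dollars(amount: float, year: int, cpi: CPISeries) -> float:
    """Convert a nominal amount from *year* to year-2000 dollars via *cpi*."""
    return cpi.adjust(amount, year)
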