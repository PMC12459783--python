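"""Expected counts, SMRs, crude rates and annual descriptive summaries.

Indirect standardization here uses a single reference rate — by default the
panel-wide pooled rate ``sum(Y) / sum(P)`` — applied to each area-year
population, so expected counts conserve the observed total. A per-year
reference is available for users who prefer year effects absorbed into E
rather than modeled.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = ["CountPanel", "expected_counts", "smr", "crude_rates", "annual_summary"]

#: Table-style column order for annual summaries
SUMMARY_COLUMNS = [
    "overall_rate", "median", "sd", "iqr", "min", "max", "pct_zero",
]


@dataclass(frozen=True)
class CountPanel:
    """Rectangular area-by-year count panel.

    Attributes
    ----------
    areas : tuple of str
        Area identifiers (length n).
    years : tuple of int
        Ordered distinct years (length T).
    Y : (n, T) int array of observed counts.
    P : (n, T) float array of positive populations.
    E : (n, T) float array of expected counts, or None until computed.
    """

    areas: tuple
    years: tuple
    Y: np.ndarray
    P: np.ndarray
    E: np.ndarray | None = None

    def __post_init__(self):
        n, T = len(self.areas), len(self.years)
        Y = np.asarray(self.Y)
        P = np.asarray(self.P, dtype=float)
        if Y.shape != (n, T) or P.shape != (n, T):
            raise ValueError(f"Y and P must have shape ({n}, {T})")
        if np.any(Y < 0):
            raise ValueError("negative counts")
        if np.any(P <= 0):
            raise ValueError("populations must be strictly positive")
        if self.E is not None and np.asarray(self.E).shape != (n, T):
            raise ValueError("E shape mismatch")
        object.__setattr__(self, "Y", Y)
        object.__setattr__(self, "P", P)
        if self.E is not None:
            object.__setattr__(self, "E", np.asarray(self.E, dtype=float))
        if list(self.years) != sorted(set(self.years)):
            raise ValueError("years must be distinct and ascending")

    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def shape(self) -> tuple:
        return self.Y.shape


def expected_counts(panel: CountPanel, per_year: bool = False) -> CountPanel:
    """Fill E by indirect standardization.

    ``E_it = P_it * rate`` with the reference rate pooled over the whole
    panel (default) or per year (``per_year=True``). Either way the
    expected total matches the observed total.
    """
    if panel.Y.sum() == 0:
        raise ValueError("all counts are zero: reference rate undefined")
    if per_year:
        rate = panel.Y.sum(axis=0) / panel.P.sum(axis=0)  # (T,)
        E = panel.P * rate[None, :]
    else:
        rate = panel.Y.sum() / panel.P.sum()
        E = panel.P * rate
    return replace(panel, E=E)


def smr(panel: CountPanel) -> np.ndarray:
    """Standardized mortality ratios ``Y / E`` (zero counts give SMR 0)."""
    if panel.E is None:
        raise ValueError("expected counts not computed; call expected_counts first")
    return panel.Y / panel.E


def crude_rates(panel: CountPanel, scale: float = 10_000.0) -> np.ndarray:
    """Crude rates ``scale * Y / P`` per area-year."""
    if scale <= 0:
        raise ValueError("scale must be positive")
    return scale * panel.Y / panel.P


def annual_summary(panel: CountPanel, scale: float = 10_000.0) -> pd.DataFrame:
    """Per-year descriptive summary of district crude rates.

    Columns: overall rate (pooled numerator/denominator), median, SD
    (n-1 denominator), IQR (linear-interpolation quartiles), min, max of
    the per-area crude rates, and the percentage of areas with zero
    counts. Indexed by year.
    """
    rates = crude_rates(panel, scale=scale)
    q1, q3 = np.quantile(rates, [0.25, 0.75], axis=0)
    out = pd.DataFrame(
        {
            "overall_rate": scale * panel.Y.sum(axis=0) / panel.P.sum(axis=0),
            "median": np.median(rates, axis=0),
            "sd": np.std(rates, axis=0, ddof=1),
            "iqr": q3 - q1,
            "min": rates.min(axis=0),
            "max": rates.max(axis=0),
            "pct_zero": 100.0 * (panel.Y == 0).mean(axis=0),
        },
        index=pd.Index(panel.years, name="year"),
    )
    return out[SUMMARY_COLUMNS]
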