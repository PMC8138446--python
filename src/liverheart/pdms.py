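"""Correction of nominal drug doses for absorption into PDMS.

PDMS absorbs small hydrophobic molecules, so the concentration a tissue in
a PDMS chip actually sees is well below the nominal dose.  Two correction
modes are provided and never mixed silently: a fixed absorbed fraction
(default 0.64, the constant used for the cisapride work) and the measured
percent-remaining table from cell-free dose-escalation runs of the device,
interpolated on log-dose because the measurements span two decades.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import pandas as pd

__all__ = [
    "AbsorptionTable",
    "DEFAULT_ABSORBED_FRACTION",
    "percent_remaining",
    "effective_dose",
]

#: Fixed absorbed fraction used when no measured table is supplied.
DEFAULT_ABSORBED_FRACTION = 0.64

#: Measured cisapride percent remaining after passage through a cell-free
#: device, by nominal dose (nM).
DEFAULT_TABLE: Dict[float, float] = {
    10.0: 35.52,
    50.0: 30.54,
    100.0: 30.95,
    500.0: 34.55,
    1000.0: 39.79,
}


@dataclass(frozen=True)
class AbsorptionTable:
    """Nominal dose (nM) -> percent of drug remaining in the efflux."""

    values: Dict[float, float] = field(default_factory=lambda: dict(DEFAULT_TABLE))

    def __post_init__(self):
        if not self.values:
            raise ValueError("absorption table is empty")
        for dose, pct in self.values.items():
            if not dose > 0:
                raise ValueError("table doses must be positive")
            if not 0.0 < pct < 100.0:
                raise ValueError("percent remaining must lie in (0, 100)")

    @property
    def doses(self) -> np.ndarray:
        return np.array(sorted(self.values))

    @property
    def mean_remaining_fraction(self) -> float:
        return float(np.mean(list(self.values.values()))) / 100.0

    @classmethod
    def from_csv(cls, path, dose_col="dose_nm", pct_col="percent_remaining"):
        df = pd.read_csv(path)
        return cls(dict(zip(df[dose_col], df[pct_col])))


def percent_remaining(
    nominal: float, table: AbsorptionTable | None = None, mode: str = "log-linear"
) -> float:
    """Percent of a nominal dose remaining after device passage.

    ``mode='nearest'`` returns the table value at the closest measured dose
    (exact keys reproduce the measurements); ``'log-linear'`` interpolates
    the percentages linearly in log10(dose).  Queries outside the measured
    range are clamped to the edge value with a warning.
    """
    if not nominal > 0:
        raise ValueError("nominal dose must be positive")
    table = table or AbsorptionTable()
    doses = table.doses
    pcts = np.array([table.values[d] for d in doses])
    if mode == "nearest":
        return float(pcts[np.argmin(np.abs(np.log10(doses) - math.log10(nominal)))])
    if mode != "log-linear":
        raise ValueError(f"unknown mode {mode!r}")
    if nominal < doses[0] or nominal > doses[-1]:
        warnings.warn(
            f"dose {nominal} nM outside the measured range "
            f"[{doses[0]}, {doses[-1]}]; clamping", RuntimeWarning,
        )
        nominal = min(max(nominal, doses[0]), doses[-1])
    return float(np.interp(math.log10(nominal), np.log10(doses), pcts))


def effective_dose(
    nominal: float, absorbed_fraction: float = DEFAULT_ABSORBED_FRACTION
) -> float:
    """Dose the tissue sees: ``nominal * (1 - absorbed_fraction)``."""
    if nominal < 0:
        raise ValueError("nominal dose must be non-negative")
    if not 0.0 <= absorbed_fraction < 1.0:
        raise ValueError("absorbed_fraction must lie in [0, 1)")
    return nominal * (1.0 - absorbed_fraction)
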