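"""Well-mixed kinetics of hepatic drug metabolism with CYP3A4 inhibition.

The liver stage of the coupled system is represented by the fraction of
parent drug converted to its (inactive) metabolite after an exposure of
duration t:

    f(t) = A * (1 - exp(-t / tau)) / (1 + I / Ki)

a saturating-exponential time course (the measured 3/6/24-h series is
visibly sub-first-order: a single rate constant cannot pass through
2.66/6.19/9.33 %) scaled by the classical competitive-inhibition factor
``1/(1 + I/Ki)`` for an inhibitor at concentration I - ketoconazole is a
competitive CYP3A4 inhibitor.  ``A`` is the plateau percent metabolized,
``tau`` the formation time constant, ``Ki`` the inhibition constant.

:class:`MetabolismKinetics` fits (A, tau, Ki) to observed (t, f%, I)
triplets by bounded least squares with a deterministic multi-start, in the
construct -> ``fit()`` -> results pattern; :func:`calibrate` is the
functional wrapper.  :func:`liver_stage` turns a fitted parameter set into
the parent-drug/metabolite split of the device efflux.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import reported

__all__ = [
    "MetabolismParams",
    "EffluxRecord",
    "MetabolismKinetics",
    "MetabolismResults",
    "fraction_metabolized",
    "calibrate",
    "calibrate_printed_series",
    "liver_stage",
]


@dataclass(frozen=True)
class MetabolismParams:
    """Parameters of the saturating-exponential metabolism model."""

    a_max_pct: float  # plateau percent metabolized, (0, 100]
    tau_h: float  # formation time constant, h
    ki_um: float  # competitive inhibition constant, uM

    def __post_init__(self):
        if not 0.0 < self.a_max_pct <= 100.0:
            raise ValueError("a_max_pct must lie in (0, 100]")
        if not self.tau_h > 0:
            raise ValueError("tau_h must be positive")
        if not self.ki_um > 0:
            raise ValueError("ki_um must be positive")

    def inhibition_factor(self, inhibitor_um: float) -> float:
        """Competitive factor 1/(1 + I/Ki) in (0, 1]."""
        if inhibitor_um < 0:
            raise ValueError("inhibitor concentration must be non-negative")
        return 1.0 / (1.0 + inhibitor_um / self.ki_um)


def fraction_metabolized(
    t_h, params: MetabolismParams, inhibitor_um: float = 0.0
):
    """Percent of parent drug metabolized after ``t_h`` hours."""
    t = np.asarray(t_h, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (
        params.a_max_pct
        * (1.0 - np.exp(-t / params.tau_h))
        * params.inhibition_factor(inhibitor_um)
    )
    return out if out.ndim else float(out)


@dataclass
class EffluxRecord:
    """Composition of the liver-device efflux after one exposure."""

    time_h: float
    parent_nm: float
    metabolite_fraction_pct: float
    arm: str  # e.g. "cisapride" or "cisapride+inhibitor"

    @property
    def metabolized_nm(self) -> float:
        return self.parent_nm / (1.0 - self.metabolite_fraction_pct / 100.0) \
            - self.parent_nm if self.metabolite_fraction_pct < 100.0 else float("nan")


def liver_stage(
    dose_in_nm: float,
    duration_h: float,
    params: MetabolismParams,
    inhibitor_um: float = 0.0,
    drug: str = "drug",
) -> EffluxRecord:
    """Pass a dose through the liver stage for ``duration_h`` hours.

    Parent out is ``dose_in * (1 - f/100)``; parent plus metabolized amount
    equals the dose by construction (mass balance).
    """
    if dose_in_nm < 0:
        raise ValueError("dose must be non-negative")
    f = fraction_metabolized(duration_h, params, inhibitor_um)
    arm = drug if inhibitor_um == 0 else f"{drug}+inhibitor"
    return EffluxRecord(
        time_h=duration_h,
        parent_nm=dose_in_nm * (1.0 - f / 100.0),
        metabolite_fraction_pct=f if dose_in_nm > 0 else 0.0,
        arm=arm,
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

_BOUNDS = ([1e-2, 1e-2, 1e-3], [100.0, 1e3, 1e3])  # (A, tau, Ki)


class MetabolismKinetics:
    """Fit (A, tau, Ki) to metabolized-fraction observations.

    Parameters
    ----------
    time_h, fraction_pct, inhibitor_um : array-like
        Observation triplets; at least three time points are needed and at
        least one inhibited observation for Ki to be identifiable (without
        one, Ki is returned at its upper bound and flagged).
    """

    def __init__(self, time_h, fraction_pct, inhibitor_um):
        self.t = np.asarray(time_h, dtype=float)
        self.f = np.asarray(fraction_pct, dtype=float)
        self.i = np.asarray(inhibitor_um, dtype=float)
        if not (self.t.shape == self.f.shape == self.i.shape):
            raise ValueError("time, fraction and inhibitor arrays must align")
        if np.unique(self.t[self.i == 0]).size < 3 and np.unique(self.t).size < 3:
            raise ValueError("at least 3 time points are required")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, time_col="time_h",
                       fraction_col="fraction_pct", inhibitor_col="inhibitor_um"):
        return cls(df[time_col], df[fraction_col], df[inhibitor_col])

    def _model(self, theta):
        a, tau, ki = theta
        return a * (1.0 - np.exp(-self.t / tau)) / (1.0 + self.i / ki)

    def fit(self) -> "MetabolismResults":
        resid = lambda th: self._model(th) - self.f
        fmax = max(self.f.max(), 1.0)
        # deterministic multi-start over decades of tau and Ki
        starts = itertools.product(
            [0.5 * fmax, fmax, 2.0 * fmax],
            [1.0, 5.0, 20.0, 80.0],
            [0.5, 5.0, 50.0],
        )
        best = None
        for a0, tau0, ki0 in starts:
            x0 = np.clip([a0, tau0, ki0], _BOUNDS[0], _BOUNDS[1])
            sol = least_squares(resid, x0, bounds=_BOUNDS, xtol=1e-15, ftol=1e-15, gtol=1e-15)
            if best is None or sol.cost < best.cost:
                best = sol
        params = MetabolismParams(*best.x)
        return MetabolismResults(self, params, best)


class MetabolismResults:
    """Fitted metabolism kinetics with diagnostics."""

    def __init__(self, model: MetabolismKinetics, params: MetabolismParams, sol):
        self.model = model
        self.params = params
        self.converged = bool(sol.success)
        self.residuals = np.asarray(sol.fun)
        self.cost = float(sol.cost)

    def predict(self, time_h, inhibitor_um=0.0):
        return fraction_metabolized(time_h, self.params, inhibitor_um)

    def summary(self) -> str:
        p = self.params
        return "\n".join(
            [
                "Metabolism kinetics fit  f(t) = A (1 - e^(-t/tau)) / (1 + I/Ki)",
                "---------------------------------------------------------------",
                f"n obs              {self.model.t.size}",
                f"converged          {self.converged}",
                f"A (plateau, %)     {p.a_max_pct:.4g}",
                f"tau (h)            {p.tau_h:.4g}",
                f"Ki (uM)            {p.ki_um:.4g}",
                f"factor at 10 uM    {p.inhibition_factor(10.0):.3f}",
                f"rss                {2 * self.cost:.4g}",
            ]
        )


def calibrate(
    observations: pd.DataFrame | Sequence[Tuple[float, float]],
    inhibitor_um: Optional[float] = None,
) -> Tuple[MetabolismParams, np.ndarray]:
    """Least-squares calibration; returns (params, residuals).

    ``observations`` is either a long-format frame with columns
    ``time_h, fraction_pct, inhibitor_um`` or a sequence of (t, f%) pairs
    with the single inhibitor level given separately.
    """
    if isinstance(observations, pd.DataFrame):
        model = MetabolismKinetics.from_dataframe(observations)
    else:
        t, f = zip(*observations)
        i = np.full(len(t), inhibitor_um or 0.0)
        model = MetabolismKinetics(t, f, i)
    res = model.fit()
    return res.params, res.residuals


def calibrate_printed_series() -> MetabolismResults:
    """Calibrate against the published 3/6/24-h cisapride series."""
    return MetabolismKinetics.from_dataframe(
        reported.cisapride_metabolism_series()
    ).fit()
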