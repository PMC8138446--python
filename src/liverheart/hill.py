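"""Hill dose-response fitting and the margin of safety.

The concentration-response of a cardiac readout (e.g. the rate-corrected
action potential duration) to an arrhythmogenic drug is summarized by the
log-logistic (Hill) curve

    r(d) = floor + (ceiling - floor) / (1 + 10^(slope * (log10 EC50 - log10 d)))

fitted by nonlinear least squares.  The default is the three-parameter
form - EC50 plus the two asymptotes with the slope fixed at one - with a
four-parameter mode (slope free) selectable.  The ratio of the fitted EC50
to the estimated therapeutic plasma concentration (ETPC) is the margin of
safety.

The model object follows the construct -> ``fit()`` -> results pattern:
``HillDoseResponse(dose, response).fit()`` returns a :class:`HillResults`
with parameter estimates, standard errors, residuals and a ``summary()``
table; :func:`fit_hill` is the one-call functional wrapper.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "DoseResponseFit",
    "HillDoseResponse",
    "HillResults",
    "hill_response",
    "fit_hill",
    "margin_of_safety",
]


def hill_response(dose, ec50, floor, ceiling, slope=1.0):
    """Evaluate the Hill curve; ``dose=0`` returns the floor exactly."""
    arr = np.atleast_1d(np.asarray(dose, dtype=float))
    out = np.full(arr.shape, float(floor))
    pos = arr > 0
    x = np.log10(arr[pos]) - np.log10(ec50)
    out[pos] = floor + (ceiling - floor) / (1.0 + 10.0 ** (-slope * x))
    return out if np.ndim(dose) else float(out[0])


@dataclass
class DoseResponseFit:
    """Fitted Hill parameters with diagnostics."""

    ec50: float
    hill_slope: float
    floor: float
    ceiling: float
    residual_norm: float
    converged: bool
    n_obs: int
    stderr: Optional[dict] = None

    def predict(self, dose):
        return hill_response(dose, self.ec50, self.floor, self.ceiling, self.hill_slope)


class HillDoseResponse:
    """Hill dose-response model for one response variable.

    Parameters
    ----------
    dose, response : array-like
        Paired observations; doses in any consistent concentration unit
        (the EC50 comes back in the same unit).  Non-positive doses are
        dropped with a warning (a zero-dose vehicle point anchors the floor
        but cannot enter the log-dose regression).
    slope : float or None
        Fixed Hill slope (default 1.0); ``None`` frees it (4-parameter fit).
    """

    def __init__(self, dose, response, *, slope: Optional[float] = 1.0):
        dose = np.asarray(dose, dtype=float)
        response = np.asarray(response, dtype=float)
        if dose.shape != response.shape:
            raise ValueError("dose and response must have the same shape")
        if not np.all(np.isfinite(response)):
            raise ValueError("responses must be finite")
        if np.all(dose <= 0):
            raise ValueError("all doses are non-positive")
        keep = dose > 0
        if not keep.all():
            warnings.warn(
                f"dropping {np.sum(~keep)} non-positive dose(s) from the fit",
                RuntimeWarning,
            )
        self.dose = dose[keep]
        self.response = response[keep]
        if np.unique(self.dose).size < 4:
            raise ValueError("at least 4 distinct positive doses are required")
        self.slope = slope

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, dose_col: str, response_col: str, **kw):
        return cls(df[dose_col].to_numpy(), df[response_col].to_numpy(), **kw)

    def fit(self, n_starts: int = 7) -> "HillResults":
        d, r = self.dose, self.response
        span = float(r.max() - r.min())
        scale = max(abs(r).max(), 1.0)
        if span < 1e-12 * scale:
            return HillResults(
                self,
                DoseResponseFit(np.nan, self.slope or np.nan, float(r.mean()),
                                float(r.mean()), 0.0, False, d.size),
            )

        free_slope = self.slope is None
        logd = np.log10(d)

        def unpack(theta):
            if free_slope:
                le, fl, ce, sl = theta
            else:
                le, fl, ce = theta
                sl = self.slope
            return le, fl, ce, sl

        def resid(theta):
            le, fl, ce, sl = unpack(theta)
            return hill_response(d, 10.0 ** le, fl, ce, sl) - r

        lo_d, hi_d = logd.min(), logd.max()
        starts = np.linspace(lo_d - 0.5, hi_d + 0.5, n_starts)
        best = None
        for le0 in starts:
            theta0 = [le0, float(r.min()), float(r.max())]
            lb = [lo_d - 3.0, -np.inf, -np.inf]
            ub = [hi_d + 3.0, np.inf, np.inf]
            if free_slope:
                theta0.append(1.0)
                lb.append(0.05)
                ub.append(10.0)
            sol = least_squares(resid, theta0, bounds=(lb, ub), xtol=1e-14, ftol=1e-14)
            if best is None or sol.cost < best.cost:
                best = sol

        le, fl, ce, sl = unpack(best.x)
        stderr = None
        try:
            jac = best.jac
            dof = max(d.size - best.x.size, 1)
            s2 = 2.0 * best.cost / dof
            cov = s2 * np.linalg.inv(jac.T @ jac)
            names = ["log10_ec50", "floor", "ceiling"] + (["slope"] if free_slope else [])
            stderr = dict(zip(names, np.sqrt(np.diag(cov))))
            # delta method for the EC50 itself
            stderr["ec50"] = 10.0 ** le * np.log(10.0) * stderr["log10_ec50"]
        except np.linalg.LinAlgError:
            pass
        fitres = DoseResponseFit(
            ec50=10.0 ** le,
            hill_slope=sl,
            floor=fl,
            ceiling=ce,
            residual_norm=float(np.sqrt(2.0 * best.cost)),
            converged=bool(best.success),
            n_obs=d.size,
            stderr=stderr,
        )
        return HillResults(self, fitres)


class HillResults:
    """Results wrapper for a fitted :class:`HillDoseResponse`."""

    def __init__(self, model: HillDoseResponse, fit: DoseResponseFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> pd.Series:
        f = self.fit
        return pd.Series(
            {"ec50": f.ec50, "slope": f.hill_slope, "floor": f.floor, "ceiling": f.ceiling}
        )

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def predict(self, dose):
        return self.fit.predict(dose)

    @property
    def resid(self) -> np.ndarray:
        return self.predict(self.model.dose) - self.model.response

    def summary(self) -> str:
        f = self.fit
        lines = [
            "Hill dose-response fit",
            "----------------------",
            f"n obs            {f.n_obs}",
            f"converged        {f.converged}",
            f"EC50             {f.ec50:.6g}"
            + (f"  (se {f.stderr['ec50']:.3g})" if f.stderr and "ec50" in f.stderr else ""),
            f"slope            {f.hill_slope:.6g}"
            + ("  (fixed)" if self.model.slope is not None else ""),
            f"floor            {f.floor:.6g}",
            f"ceiling          {f.ceiling:.6g}",
            f"residual norm    {f.residual_norm:.3g}",
        ]
        return "\n".join(lines)


def fit_hill(doses: Sequence[float], responses: Sequence[float],
             *, slope: Optional[float] = 1.0) -> DoseResponseFit:
    """Least-squares Hill fit; see :class:`HillDoseResponse`.

    Returns the bare :class:`DoseResponseFit`; a flat (degenerate) response
    yields ``converged=False`` with NaN EC50 rather than an exception.
    """
    return HillDoseResponse(doses, responses, slope=slope).fit().fit


def margin_of_safety(ec50: float, etpc: float) -> float:
    """EC50 over the estimated therapeutic plasma concentration (fold)."""
    if not (ec50 > 0 and etpc > 0):
        raise ValueError("ec50 and etpc must be positive")
    return ec50 / etpc
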