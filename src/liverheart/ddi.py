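"""In-silico functional coupling of the liver and cardiac devices.

The drug-drug interaction experiment is orchestrated as three arms:

* **direct** - the PDMS-corrected nominal dose goes straight to the
  cardiac tissue;
* **liver** - the dose first passes the liver stage, which removes the
  metabolized fraction (the metabolite is pharmacologically inactive);
* **liver+inhibitor** - the liver stage runs with the CYP inhibitor
  present, so clearance is suppressed by the competitive factor.

Each arm's effective cardiac dose is mapped through a Hill curve for the
vehicle-normalized cAPD90 (vehicle = 1.0); an arm is flagged as QT-like
prolongation when the predicted increase exceeds a configurable threshold
(default 10 % over vehicle).  The model arms carry no biological
replicates, so "significance" there is this threshold; when real per-beat
metric sets are supplied, :func:`compare_to_vehicle` applies a standard
two-sample test instead.  The report records the provenance of every
parameter so measured constants, calibrated fits and user overrides are
never mixed silently.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .hill import hill_response, margin_of_safety
from .metabolism import MetabolismParams, liver_stage
from .pdms import effective_dose, DEFAULT_ABSORBED_FRACTION

__all__ = [
    "CardiacResponseCurve",
    "DDIConfig",
    "DDIReport",
    "ConfigurationError",
    "run_ddi",
    "compare_to_vehicle",
    "VehicleComparison",
]


class ConfigurationError(ValueError):
    """A required model parameter source is missing."""


@dataclass(frozen=True)
class CardiacResponseCurve:
    """Hill curve for the vehicle-normalized cAPD90 versus dose (nM)."""

    ec50_nm: float
    ceiling: float
    floor: float = 1.0
    slope: float = 1.0

    def __post_init__(self):
        if not self.ec50_nm > 0:
            raise ValueError("ec50_nm must be positive")
        if self.ceiling < self.floor:
            raise ValueError("ceiling must be >= floor for a prolongation curve")

    def predict(self, dose_nm: float) -> float:
        return float(hill_response(dose_nm, self.ec50_nm, self.floor, self.ceiling, self.slope))


@dataclass
class DDIConfig:
    """Configuration of one in-silico coupling experiment.

    The metabolism parameters and the cardiac response curve must be given
    explicitly (typically from :func:`liverheart.metabolism.calibrate` and a
    Hill fit); there are no silent kinetic defaults.
    """

    drug: str = "cisapride"
    nominal_dose_nm: float = 50.0
    absorbed_fraction: float = DEFAULT_ABSORBED_FRACTION
    liver_duration_h: float = 8.0
    inhibitor_um: float = 10.0
    metabolism: Optional[MetabolismParams] = None
    cardiac: Optional[CardiacResponseCurve] = None
    prolongation_threshold: float = 0.10  # fractional cAPD90 increase over vehicle
    triangulation_threshold: Optional[float] = None
    etpc_nm: Optional[float] = None
    provenance: Dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.nominal_dose_nm < 0:
            raise ValueError("nominal dose must be non-negative")
        if not self.prolongation_threshold > 0:
            raise ValueError("prolongation_threshold must be positive")


@dataclass
class DDIArm:
    name: str
    effective_dose_nm: float
    predicted_capd90_norm: float
    prolongation: bool


@dataclass
class DDIReport:
    """Per-arm predictions with full parameter provenance."""

    arms: Dict[str, DDIArm]
    margin_of_safety: Optional[float]
    provenance: Dict[str, str]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(a) for a in self.arms.values()]).set_index("name")

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(
            {
                "arms": {k: asdict(v) for k, v in self.arms.items()},
                "margin_of_safety": self.margin_of_safety,
                "provenance": self.provenance,
            },
            indent=indent,
        )

    def summary(self) -> str:
        lines = ["DDI coupling report", "-------------------"]
        for a in self.arms.values():
            flag = "PROLONGED" if a.prolongation else "no change"
            lines.append(
                f"{a.name:<16} dose {a.effective_dose_nm:8.3f} nM   "
                f"cAPD90/vehicle {a.predicted_capd90_norm:6.3f}   {flag}"
            )
        if self.margin_of_safety is not None:
            lines.append(f"margin of safety {self.margin_of_safety:.2f}-fold")
        return "\n".join(lines)


def run_ddi(config: DDIConfig) -> DDIReport:
    """Run the three-arm coupling experiment.

    Deterministic: identical configurations produce identical reports.
    """
    if config.metabolism is None:
        raise ConfigurationError(
            "metabolism parameters are required (calibrate first; kinetics "
            "have no silent default)"
        )
    if config.cardiac is None:
        raise ConfigurationError("a cardiac response curve is required")

    dose_eff = effective_dose(config.nominal_dose_nm, config.absorbed_fraction)
    arms: Dict[str, DDIArm] = {}

    def build(name, dose):
        pred = config.cardiac.predict(dose)
        flag = (pred - config.cardiac.floor) / config.cardiac.floor > config.prolongation_threshold
        return DDIArm(name, dose, pred, bool(flag))

    arms["direct"] = build("direct", dose_eff)
    efflux_b = liver_stage(dose_eff, config.liver_duration_h, config.metabolism,
                           inhibitor_um=0.0, drug=config.drug)
    arms["liver"] = build("liver", efflux_b.parent_nm)
    efflux_c = liver_stage(dose_eff, config.liver_duration_h, config.metabolism,
                           inhibitor_um=config.inhibitor_um, drug=config.drug)
    arms["liver+inhibitor"] = build("liver+inhibitor", efflux_c.parent_nm)

    mos = (
        margin_of_safety(config.cardiac.ec50_nm, config.etpc_nm)
        if config.etpc_nm
        else None
    )
    provenance = {
        "absorbed_fraction": "fixed constant (device absorption)",
        "metabolism": "user-supplied calibration",
        "cardiac_curve": "user-supplied Hill parameters",
        "prolongation_threshold": f"{config.prolongation_threshold:g} fractional increase",
    }
    provenance.update(config.provenance)
    return DDIReport(arms=arms, margin_of_safety=mos, provenance=provenance)


@dataclass
class VehicleComparison:
    ratio: float  # treated / vehicle median cAPD90
    p_value: float
    n_treated: int
    n_vehicle: int


def compare_to_vehicle(
    treated, vehicle, *, column: str = "capd90_ms", test: str = "t"
) -> VehicleComparison:
    """Normalize a treated metric set to its vehicle control.

    ``treated``/``vehicle`` are per-beat metric tables (or plain arrays of
    cAPD90 values), at least 3 beats each.  The ratio of medians measures
    the effect; significance comes from a standard two-sample test
    (Student's t by default, Mann-Whitney U with ``test='u'``).
    """
    def extract(x):
        if isinstance(x, pd.DataFrame):
            x = x[column]
        arr = np.asarray(x, dtype=float)
        return arr[np.isfinite(arr)]

    t_arr, v_arr = extract(treated), extract(vehicle)
    if t_arr.size < 3 or v_arr.size < 3:
        raise ValueError("at least 3 beats per condition are required")
    if test == "t":
        p = stats.ttest_ind(t_arr, v_arr, equal_var=True).pvalue
    elif test == "u":
        p = stats.mannwhitneyu(t_arr, v_arr, alternative="two-sided").pvalue
    else:
        raise ValueError(f"unknown test {test!r}")
    return VehicleComparison(
        ratio=float(np.median(t_arr) / np.median(v_arr)),
        p_value=float(p),
        n_treated=int(t_arr.size),
        n_vehicle=int(v_arr.size),
    )
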