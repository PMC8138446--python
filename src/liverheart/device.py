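"""Geometry, transport constants and analytic hydraulics of the liver chip.

The liver microphysiological system (MPS) is a two-chamber PDMS device: a
media channel perfused by a syringe pump, separated from a cell chamber
(seeded with hiPSC-derived hepatocytes) by a low-porosity track-etched PET
membrane, the whole assembly capped by a thick gas-permeable PDMS slab.
This module holds the device dimensions and every physical constant the
transport solver needs, plus the closed-form plane-Poiseuille hydraulics of
the media channel.  At the working flow rate the channel Reynolds number is
``~1e-2``, so the laminar velocity profile is analytic and no numerical flow
solve is required.

Units: the public dataclasses carry the mixed bench units the quantities are
usually quoted in (micrometres, uL/h, mmHg, mM/atm); properties convert to a
fixed internal SI system (m, s, mol/m3) at the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict, fields
from importlib import resources
from typing import Optional

import yaml

__all__ = [
    "DeviceGeometry",
    "TransportParams",
    "HydraulicSummary",
    "InvalidGeometryError",
    "channel_hydraulics",
    "chamber_volume",
    "km_in_concentration_units",
    "ocr_per_million_cells",
    "load_device_config",
]

#: mmHg per standard atmosphere, used to convert the Michaelis constant.
MMHG_PER_ATM = 760.0
#: dyn/cm2 per Pascal.
DYN_PER_CM2_PER_PA = 10.0
#: m3/s per uL/h.
M3S_PER_ULH = 1e-9 / 3600.0

#: Wall shear stress (dyn/cm2) above which hepatocyte albumin and urea
#: synthesis are known to be impaired; the design must stay below this.
SHEAR_DAMAGE_THRESHOLD_DYN_CM2 = 5.0


class InvalidGeometryError(ValueError):
    """A geometric or physical parameter violates its invariant."""


def _require_positive(obj, names):
    for name in names:
        value = getattr(obj, name)
        if not (value > 0 and math.isfinite(value)):
            raise InvalidGeometryError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class DeviceGeometry:
    """Printed dimensions of the liver MPS.

    Defaults are the as-fabricated values: a 5,560 x 560 x 100 um cell
    chamber, a media channel of the same footprint and 100 um height, a
    15-um PET membrane with 5.6 % porosity and 3-um pores, and a 3.5-mm
    PDMS slab above the channel.
    """

    chamber_length_um: float = 5560.0
    chamber_width_um: float = 560.0
    cell_chamber_height_um: float = 100.0
    media_channel_height_um: float = 100.0
    membrane_thickness_um: float = 15.0
    membrane_porosity: float = 0.056
    membrane_pore_diameter_um: float = 3.0
    pdms_slab_thickness_mm: float = 3.5

    def __post_init__(self):
        _require_positive(
            self,
            [
                "chamber_length_um",
                "chamber_width_um",
                "cell_chamber_height_um",
                "media_channel_height_um",
                "membrane_thickness_um",
                "membrane_pore_diameter_um",
                "pdms_slab_thickness_mm",
            ],
        )
        if not 0.0 < self.membrane_porosity < 1.0:
            raise InvalidGeometryError(
                f"membrane_porosity must lie in (0, 1), got {self.membrane_porosity}"
            )

    # --- SI conversions -------------------------------------------------
    @property
    def length_m(self) -> float:
        return self.chamber_length_um * 1e-6

    @property
    def width_m(self) -> float:
        return self.chamber_width_um * 1e-6

    @property
    def cell_chamber_height_m(self) -> float:
        return self.cell_chamber_height_um * 1e-6

    @property
    def media_channel_height_m(self) -> float:
        return self.media_channel_height_um * 1e-6

    @property
    def membrane_thickness_m(self) -> float:
        return self.membrane_thickness_um * 1e-6

    @property
    def pdms_slab_thickness_m(self) -> float:
        return self.pdms_slab_thickness_mm * 1e-3

    @property
    def footprint_m2(self) -> float:
        """Plan-view area shared by both chambers (m2)."""
        return self.length_m * self.width_m


@dataclass(frozen=True)
class TransportParams:
    """Fluid, diffusion and oxygen-uptake constants.

    ``vo2max`` (mol/s/cell) is the maximal per-cell oxygen consumption rate
    of the hiPSC-hepatocytes; ``km_mmhg`` and ``s_cell_mm_per_atm`` express
    the Michaelis constant as an oxygen partial pressure together with the
    oxygen solubility of cells, so the half-saturation concentration is
    ``Km * S_cell`` once both are put in mol/m3.
    """

    flow_rate_ul_per_h: float = 20.0
    fluid_density_kg_m3: float = 1000.0
    dynamic_viscosity_mpa_s: float = 0.78
    d_o2_media: float = 3.0e-9  # m2/s
    d_o2_pdms: float = 3.25e-9  # m2/s
    d_small_molecule: float = 1.0e-9  # m2/s
    c_inlet_o2: float = 0.173  # mol/m3, media saturated against incubator air
    c_sat_pdms_mm: float = 1.11  # mM, PDMS saturated against incubator air
    vo2max: float = 1.04e-16  # mol/s/cell
    km_mmhg: float = 5.6
    s_cell_mm_per_atm: float = 1.049
    rho_cell: float = 6.44e13  # cells/m3 in the cell chamber
    n_cells: float = 9812.0
    ambient_o2_fraction: float = 0.187

    def __post_init__(self):
        _require_positive(
            self,
            [f.name for f in fields(self) if f.name != "flow_rate_ul_per_h"],
        )
        if self.flow_rate_ul_per_h < 0 or not math.isfinite(self.flow_rate_ul_per_h):
            raise InvalidGeometryError("flow_rate_ul_per_h must be >= 0 and finite")

    # --- SI conversions -------------------------------------------------
    @property
    def q_m3_s(self) -> float:
        return self.flow_rate_ul_per_h * M3S_PER_ULH

    @property
    def viscosity_pa_s(self) -> float:
        return self.dynamic_viscosity_mpa_s * 1e-3

    @property
    def c_sat_pdms(self) -> float:
        """PDMS oxygen saturation in mol/m3 (1 mM == 1 mol/m3)."""
        return self.c_sat_pdms_mm

    @property
    def km_conc(self) -> float:
        """Half-saturation oxygen concentration Km*S_cell in mol/m3."""
        return km_in_concentration_units(self)

    @property
    def partition_coefficient(self) -> float:
        """Henry-law PDMS/media concentration ratio at equal partial pressure."""
        return self.c_sat_pdms / self.c_inlet_o2

    @property
    def vmax_volumetric(self) -> float:
        """Maximal volumetric uptake VO2max * rho_cell (mol/m3/s)."""
        return self.vo2max * self.rho_cell


@dataclass(frozen=True)
class HydraulicSummary:
    """Analytic plane-Poiseuille descriptors of the media channel."""

    mean_velocity: float  # m/s
    wall_shear_stress: float  # dyn/cm2
    channel_residence_time: float  # s (inf when there is no flow)
    peclet_number: float  # v*h/D_O2, dimensionless
    no_flow: bool = False


def channel_hydraulics(
    geometry: DeviceGeometry, params: TransportParams
) -> HydraulicSummary:
    """Mean velocity, wall shear, residence time and Peclet number.

    Plane-Poiseuille flow between parallel plates of gap ``h`` and width
    ``w`` gives mean velocity ``Q/(w*h)`` and wall shear ``6*mu*Q/(w*h^2)``.
    A zero flow rate is legal and flagged rather than an error.
    """
    q = params.q_m3_s
    w = geometry.width_m
    h = geometry.media_channel_height_m
    v = q / (w * h)
    shear_pa = 6.0 * params.viscosity_pa_s * q / (w * h * h)
    if q == 0.0:
        return HydraulicSummary(0.0, 0.0, math.inf, 0.0, no_flow=True)
    return HydraulicSummary(
        mean_velocity=v,
        wall_shear_stress=shear_pa * DYN_PER_CM2_PER_PA,
        channel_residence_time=geometry.length_m / v,
        peclet_number=v * h / params.d_o2_media,
    )


def chamber_volume(geometry: DeviceGeometry, which: str = "media") -> float:
    """Volume of the selected chamber in microlitres.

    ``which`` is ``"media"`` (media channel) or ``"cell"`` (cell chamber);
    both share the chip footprint and differ only in height.
    """
    heights = {
        "media": geometry.media_channel_height_m,
        "cell": geometry.cell_chamber_height_m,
    }
    try:
        h = heights[which]
    except KeyError:
        raise ValueError(f"unknown chamber selector {which!r}; use 'media' or 'cell'")
    return geometry.footprint_m2 * h * 1e9  # m3 -> uL


def km_in_concentration_units(params: TransportParams) -> float:
    """Convert Km (mmHg) x S_cell (mM/atm) to a concentration in mol/m3."""
    return params.km_mmhg * params.s_cell_mm_per_atm / MMHG_PER_ATM


def ocr_per_million_cells(params: TransportParams) -> float:
    """Maximal oxygen consumption rate in nmol/s per 1e6 cells."""
    return params.vo2max * 1e6 * 1e9


# ---------------------------------------------------------------------------
# Parameter files
# ---------------------------------------------------------------------------

def load_device_config(path: Optional[str] = None):
    """Load a (geometry, transport) parameter file.

    The file is flat YAML with units encoded in the key names (see the
    bundled ``data/device_default.yaml``, which reproduces every default).
    With ``path=None`` the bundled defaults are returned.
    """
    if path is None:
        text = resources.files("liverheart").joinpath("data/device_default.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    geo = DeviceGeometry(**raw.get("geometry", {}))
    par = TransportParams(**raw.get("transport", {}))
    return geo, par


def dump_device_config(geometry: DeviceGeometry, params: TransportParams) -> str:
    """Serialize a configuration back to the flat YAML dialect."""
    return yaml.safe_dump(
        {"geometry": asdict(geometry), "transport": asdict(params)},
        sort_keys=False,
    )
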