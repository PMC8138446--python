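"""Finite-volume oxygen and small-molecule transport in the liver chip.

The device is reduced to a 2-D longitudinal cross-section (flow direction x,
stacking direction z; the width direction is averaged out).  From bottom to
top the stack is: cell chamber (hepatocytes consuming oxygen by
Michaelis-Menten kinetics), porous membrane, media channel (the only layer
with flow, plane-Poiseuille profile), and - for oxygen - the thick
gas-permeable PDMS slab whose exterior is held at ambient saturation.

Oxygen partial pressure is continuous across the media/PDMS interface while
concentration jumps by the Henry partition coefficient
``k = c_sat_pdms / c_inlet``.  The solver therefore works in a
"media-equivalent" variable ``u`` (aqueous concentration at the same partial
pressure): in aqueous layers ``c = u``, inside the PDMS ``c = k*u``, so the
PDMS is simply a layer of permeability ``D_pdms*k`` and storage capacity
``k``, and ``u`` is continuous everywhere.  The membrane is an
effective-medium layer (straight cylindrical pores, tortuosity 1):
permeability and storage are both scaled by the porosity.

The width-averaged model cannot see the PDMS walls on either side of the
0.56-mm-wide channels, yet in 3-D those walls carry several times more
ambient oxygen than the 1-D through-roof path.  They are represented by a
linear exchange term in the aqueous stack whose conductance comes from the
classical conduction shape factor of a duct buried below a plane surface
(see :func:`sidewall_exchange_coefficient`); it is enabled whenever PDMS
permeation is on and can be switched off.

Numerics: conservative finite volumes on a tensor grid, first-order upwind
advection, central diffusion, implicit Euler in time (the scheme is an
M-matrix, hence unconditionally stable and positivity preserving at the
channel Peclet number of ~3), damped Newton for the Michaelis-Menten
nonlinearity with a sparse LU at each iteration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix, csc_matrix, diags, identity
from scipy.sparse.linalg import splu

from .device import DeviceGeometry, TransportParams, InvalidGeometryError

__all__ = [
    "Layer",
    "DiscretizedDevice",
    "ConcentrationField",
    "SimulationSummary",
    "TransientResult",
    "ConvergenceError",
    "discretize",
    "mm_uptake",
    "solve_steady",
    "solve_steady_oxygen",
    "solve_transient_oxygen",
    "solve_tracer_washin",
    "sidewall_exchange_coefficient",
]

DEFAULT_NZ = {"cell_chamber": 6, "membrane": 3, "media_channel": 6, "pdms": 12}


class ConvergenceError(RuntimeError):
    """Nonlinear solve failed; carries the residual history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = list(history or [])


@dataclass(frozen=True)
class Layer:
    """One horizontal slab of the discretized stack.

    ``perm`` is the permeability of the media-equivalent variable (D for
    aqueous layers, porosity*D for the membrane, D_pdms*k for PDMS) and
    ``capacity`` the storage coefficient relating stored concentration to u.
    """

    name: str
    height: float  # m
    nz: int
    perm: float  # m2/s
    capacity: float = 1.0
    flow: bool = False
    uptake: bool = False
    side_supply: bool = False


def sidewall_exchange_coefficient(
    geometry: DeviceGeometry, params: TransportParams
) -> float:
    """Volumetric ambient-exchange coefficient (1/s) for the aqueous stack.

    The channel stack (cell chamber + membrane + media channel) is treated
    as a duct of rectangular cross-section buried a slab-thickness below the
    ambient-facing PDMS surface.  Its total supply conductance per unit
    length is ``P * S`` with ``S = 2*pi / acosh(2*z_d/d_eq)`` (buried
    isothermal cylinder of equal perimeter, a standard conduction shape
    factor) and ``P = D_pdms*k`` the PDMS permeability.  The 1-D through-
    roof portion ``w/L`` is subtracted because the roof is meshed
    explicitly; the remainder is spread uniformly over the stack volume.
    """
    h_stack = (
        geometry.cell_chamber_height_m
        + geometry.membrane_thickness_m
        + geometry.media_channel_height_m
    )
    w = geometry.width_m
    slab = geometry.pdms_slab_thickness_m
    perm = params.d_o2_pdms * params.partition_coefficient
    d_eq = 2.0 * (w + h_stack) / math.pi
    z_axis = slab + 0.5 * h_stack
    shape = 2.0 * math.pi / math.acosh(2.0 * z_axis / d_eq)
    shape_side = max(shape - w / slab, 0.0)
    return perm * shape_side / (w * h_stack)


@dataclass
class DiscretizedDevice:
    """Grid, coefficients and boundary data for the 2-D solver."""

    geometry: DeviceGeometry
    params: TransportParams
    species: str
    nx: int
    layers: List[Layer]
    dx: float
    dz: np.ndarray  # (nz,)
    z_centers: np.ndarray  # (nz,)
    perm: np.ndarray  # (nz,)
    capacity: np.ndarray  # (nz,)
    conc_factor: np.ndarray  # (nz,) converts u -> physical concentration
    uptake_rows: np.ndarray  # (nz,) bool
    side_kappa: np.ndarray  # (nz,) 1/s
    velocity: np.ndarray  # (nz,) m/s
    layer_of_row: List[str]
    u_inlet: float
    u_ambient: float
    top_dirichlet: Optional[float]  # media-equivalent units; None = no flux
    bottom_dirichlet: Optional[float] = None

    @property
    def nz(self) -> int:
        return len(self.dz)

    @property
    def n(self) -> int:
        return self.nz * self.nx

    @property
    def chamber_rows(self) -> np.ndarray:
        return np.array([name == "cell_chamber" for name in self.layer_of_row])

    def row_volume(self) -> np.ndarray:
        """Control-volume size per row (m3 per node, full device width)."""
        return self.dz * self.dx * self.geometry.width_m


def _velocity_profile(zeta: np.ndarray, mean_velocity: float) -> np.ndarray:
    """Plane-Poiseuille profile sampled at cell centers, renormalized so the
    discrete mean equals the prescribed mean velocity (exact flow rate)."""
    prof = 6.0 * zeta * (1.0 - zeta)
    m = prof.mean()
    return mean_velocity * prof / m if m > 0 else np.zeros_like(prof)


def discretize(
    geometry: DeviceGeometry,
    params: TransportParams,
    species: str = "oxygen",
    *,
    nx: int = 120,
    nz_per_layer: Optional[dict] = None,
    pdms_flux: bool = True,
    side_walls: bool = True,
) -> DiscretizedDevice:
    """Build the layered 2-D grid for a species.

    ``species='oxygen'`` stacks cell chamber / membrane / media channel and,
    if ``pdms_flux``, the PDMS slab with an ambient-saturation Dirichlet top;
    ``side_walls`` additionally enables the width-averaged wall-supply term.
    ``species='tracer'`` is the inert small molecule in the empty device:
    impermeable walls, no PDMS layer, no uptake.
    """
    if nx < 10:
        raise InvalidGeometryError(f"nx must be >= 10, got {nx}")
    nz_cfg = dict(DEFAULT_NZ)
    nz_cfg.update(nz_per_layer or {})
    for name, n in nz_cfg.items():
        if n < 3:
            raise InvalidGeometryError(
                f"layer {name!r} requested with {n} nodes; at least 3 are "
                "required to resolve it"
            )

    d_aq = params.d_o2_media if species == "oxygen" else params.d_small_molecule
    k = params.partition_coefficient
    phi = geometry.membrane_porosity

    layers = [
        Layer(
            "cell_chamber",
            geometry.cell_chamber_height_m,
            nz_cfg["cell_chamber"],
            d_aq,
            uptake=(species == "oxygen"),
            side_supply=True,
        ),
        Layer("membrane", geometry.membrane_thickness_m, nz_cfg["membrane"], phi * d_aq, capacity=phi, side_supply=True),
        Layer("media_channel", geometry.media_channel_height_m, nz_cfg["media_channel"], d_aq, flow=True, side_supply=True),
    ]
    top_dirichlet = None
    if species == "oxygen" and pdms_flux:
        layers.append(
            Layer("pdms", geometry.pdms_slab_thickness_m, nz_cfg["pdms"], params.d_o2_pdms * k, capacity=k)
        )
        # Ambient saturation in the PDMS is c_sat = k * u, so in media-
        # equivalent units the exterior sits at c_sat/k == c_inlet exactly.
        top_dirichlet = params.c_sat_pdms / k
    elif species not in ("oxygen", "tracer"):
        raise ValueError(f"unknown species {species!r}")

    dz_list, perm_list, cap_list, upt_list, side_list, name_list, cf_list = (
        [], [], [], [], [], [], []
    )
    for layer in layers:
        dz_layer = layer.height / layer.nz
        for _ in range(layer.nz):
            dz_list.append(dz_layer)
            perm_list.append(layer.perm)
            cap_list.append(layer.capacity)
            upt_list.append(layer.uptake)
            side_list.append(layer.side_supply)
            name_list.append(layer.name)
            cf_list.append(k if layer.name == "pdms" else 1.0)

    dz = np.asarray(dz_list)
    z_edges = np.concatenate([[0.0], np.cumsum(dz)])
    z_centers = 0.5 * (z_edges[:-1] + z_edges[1:])

    # velocity in the media channel only
    vel = np.zeros(len(dz))
    flow_rows = np.array([n == "media_channel" for n in name_list])
    if flow_rows.any() and params.q_m3_s > 0:
        z0 = z_edges[np.argmax(flow_rows)]
        h = geometry.media_channel_height_m
        zeta = (z_centers[flow_rows] - z0) / h
        vbar = params.q_m3_s / (geometry.width_m * h)
        vel[flow_rows] = _velocity_profile(zeta, vbar)

    kappa = np.zeros(len(dz))
    if species == "oxygen" and pdms_flux and side_walls:
        kappa[np.asarray(side_list)] = sidewall_exchange_coefficient(geometry, params)

    u_inlet = params.c_inlet_o2 if species == "oxygen" else 0.0
    return DiscretizedDevice(
        geometry=geometry,
        params=params,
        species=species,
        nx=nx,
        layers=layers,
        dx=geometry.length_m / nx,
        dz=dz,
        z_centers=z_centers,
        perm=np.asarray(perm_list),
        capacity=np.asarray(cap_list),
        conc_factor=np.asarray(cf_list),
        uptake_rows=np.asarray(upt_list),
        side_kappa=kappa,
        velocity=vel,
        layer_of_row=name_list,
        u_inlet=u_inlet,
        u_ambient=params.c_inlet_o2,
        top_dirichlet=top_dirichlet,
    )


# ---------------------------------------------------------------------------
# Michaelis-Menten uptake
# ---------------------------------------------------------------------------

def mm_uptake(c, params: TransportParams):
    """Volumetric oxygen sink -VO2max*rho_cell*c/(Km*S_cell + c), mol/m3/s.

    Negative concentrations are a caller error, not something to clip.
    """
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("oxygen concentration must be non-negative")
    k = params.km_conc
    out = -params.vmax_volumetric * c / (k + c)
    return out if out.ndim else float(out)


def _uptake_and_derivative(u, vmax, km):
    """Sink magnitude s(u) = vmax*u/(km+u) and ds/du, linearized below zero
    so the Newton Jacobian stays an M-matrix even for transient negatives."""
    pos = u > 0
    s = np.where(pos, vmax * u / (km + u), vmax * u / km)
    ds = np.where(pos, vmax * km / (km + u) ** 2, vmax / km)
    return s, ds


# ---------------------------------------------------------------------------
# Operator assembly
# ---------------------------------------------------------------------------

def _assemble(
    device: DiscretizedDevice,
    *,
    inlet_u: Optional[float] = None,
    top: Optional[Tuple[str, float]] = None,
    bottom: Optional[Tuple[str, float]] = None,
    include_side: bool = True,
):
    """Assemble the linear transport operator in per-volume form.

    Returns sparse ``A`` and vector ``b`` such that the semi-discrete balance
    is ``capacity * du/dt = -(A u - b) - uptake``.  ``A`` contains diffusion,
    upwind advection (with the inlet Dirichlet folded into ``b``), the top /
    bottom boundary conditions and, optionally, the side-wall exchange.
    """
    nz, nx = device.nz, device.nx
    n = nz * nx
    dx = device.dx
    dz = device.dz
    perm = device.perm
    vel = device.velocity
    if inlet_u is None:
        inlet_u = device.u_inlet
    if top is None:
        top = ("dirichlet", device.top_dirichlet) if device.top_dirichlet is not None else ("noflux", None)
    if bottom is None:
        bottom = (
            ("dirichlet", device.bottom_dirichlet)
            if device.bottom_dirichlet is not None
            else ("noflux", None)
        )

    rows, cols, vals = [], [], []
    b = np.zeros(n)

    def idx(j, i):
        return j * nx + i

    def add(j, i, j2, i2, v):
        rows.append(idx(j, i))
        cols.append(idx(j2, i2))
        vals.append(v)

    # vertical diffusion between rows (interface conductance, harmonic)
    for j in range(nz - 1):
        g = 1.0 / (dz[j] / (2.0 * perm[j]) + dz[j + 1] / (2.0 * perm[j + 1]))
        for i in range(nx):
            add(j, i, j, i, g / dz[j])
            add(j, i, j + 1, i, -g / dz[j])
            add(j + 1, i, j + 1, i, g / dz[j + 1])
            add(j + 1, i, j, i, -g / dz[j + 1])

    # horizontal diffusion within rows
    for j in range(nz):
        g = perm[j] / dx
        for i in range(nx - 1):
            add(j, i, j, i, g / dx)
            add(j, i, j, i + 1, -g / dx)
            add(j, i + 1, j, i + 1, g / dx)
            add(j, i + 1, j, i, -g / dx)

    # upwind advection in flow rows (velocities are non-negative)
    for j in range(nz):
        v = vel[j]
        if v <= 0:
            continue
        for i in range(nx):
            add(j, i, j, i, v / dx)
            if i > 0:
                add(j, i, j, i - 1, -v / dx)
            else:
                b[idx(j, 0)] += v * inlet_u / dx
        # diffusive part of the inlet Dirichlet
        g_in = perm[j] / (0.5 * dx)
        add(j, 0, j, 0, g_in / dx)
        b[idx(j, 0)] += g_in * inlet_u / dx
        # outlet: advective outflow only (zero diffusive flux)

    # top / bottom boundaries
    kind, value = top
    if kind == "dirichlet":
        j = nz - 1
        g = perm[j] / (0.5 * dz[j])
        for i in range(nx):
            add(j, i, j, i, g / dz[j])
            b[idx(j, i)] += g * value / dz[j]
    kind, value = bottom
    if kind == "dirichlet":
        g = perm[0] / (0.5 * dz[0])
        for i in range(nx):
            add(0, i, 0, i, g / dz[0])
            b[idx(0, i)] += g * value / dz[0]

    # width-averaged side-wall exchange with ambient
    if include_side and device.side_kappa.any():
        for j in range(nz):
            kap = device.side_kappa[j]
            if kap <= 0:
                continue
            for i in range(nx):
                add(j, i, j, i, kap)
                b[idx(j, i)] += kap * device.u_ambient

    a = coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return a, b


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class ConcentrationField:
    """Discrete species field with its grid; ``values`` are physical
    concentrations (mol/m3) per node - inside the PDMS the partition factor
    is applied, everywhere else concentration equals the solved variable."""

    device: DiscretizedDevice
    u: np.ndarray  # (nz, nx), media-equivalent
    time: Optional[float]
    species: str

    @property
    def values(self) -> np.ndarray:
        return self.u * self.device.conc_factor[:, None]

    def chamber(self) -> np.ndarray:
        return self.u[self.device.chamber_rows, :]


@dataclass
class SimulationSummary:
    """Cell-chamber statistics and solver diagnostics."""

    cmin: float
    cmean: float
    cmax: float
    mass_balance_residual: float
    time: Optional[float] = None
    time_to_uniformity: Optional[float] = None
    time_to_depletion: Optional[float] = None


@dataclass
class TransientResult:
    """Time series of cell-chamber statistics from a transient solve."""

    times: np.ndarray
    cmin: np.ndarray
    cmean: np.ndarray
    cmax: np.ndarray
    time_to_depletion: Optional[float] = None
    time_to_uniformity: Optional[float] = None
    final_field: Optional[ConcentrationField] = None

    def summaries(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_s": self.times, "cmin": self.cmin, "cmean": self.cmean, "cmax": self.cmax}
        )


def _chamber_stats(device: DiscretizedDevice, u: np.ndarray):
    ch = u.reshape(device.nz, device.nx)[device.chamber_rows, :]
    return float(ch.min()), float(ch.mean()), float(ch.max())


def _first_crossing(times, series, threshold, direction):
    """Linearly interpolated first time ``series`` crosses ``threshold``."""
    s = np.asarray(series, dtype=float)
    if direction == "below":
        hit = s < threshold
    else:
        hit = s >= threshold
    if not hit.any():
        return None
    i = int(np.argmax(hit))
    if i == 0:
        return float(times[0])
    t0, t1 = times[i - 1], times[i]
    s0, s1 = s[i - 1], s[i]
    if s1 == s0:
        return float(t1)
    frac = (threshold - s0) / (s1 - s0)
    return float(t0 + frac * (t1 - t0))


# ---------------------------------------------------------------------------
# Solvers
# ---------------------------------------------------------------------------

def _newton(a, b, device, u0, *, uptake, theta_over_dt=None, u_prev=None,
            tol=1e-12, maxiter=60):
    """Damped Newton for A u - b + s(u) [+ theta/dt (u - u_prev)] = 0."""
    vmax = device.params.vmax_volumetric if uptake else 0.0
    km = device.params.km_conc
    mask = device.uptake_rows.repeat(device.nx) if uptake else None

    def residual(u):
        r = a @ u - b
        if uptake:
            s, _ = _uptake_and_derivative(u, vmax, km)
            r = r + np.where(mask, s, 0.0)
        if theta_over_dt is not None:
            r = r + theta_over_dt * (u - u_prev)
        return r

    ref = max(np.abs(b).max(), vmax, 1e-30)
    u = u0.copy()
    history = []
    for _ in range(maxiter):
        r = residual(u)
        rn = np.abs(r).max()
        history.append(rn)
        if rn < tol * ref:
            return u, history
        j = a
        if uptake:
            _, ds = _uptake_and_derivative(u, vmax, km)
            j = j + diags(np.where(mask, ds, 0.0))
        if theta_over_dt is not None:
            j = j + diags(theta_over_dt)
        du = splu(csc_matrix(j)).solve(-r)
        alpha = 1.0
        while alpha > 1e-6:
            rn_new = np.abs(residual(u + alpha * du)).max()
            if rn_new < rn:
                break
            alpha *= 0.5
        u = u + alpha * du
    raise ConvergenceError(
        f"Newton did not reach tol={tol:g} in {maxiter} iterations", history
    )


def solve_steady(
    device: DiscretizedDevice,
    *,
    uptake: bool = True,
    inlet_u: Optional[float] = None,
    top: Optional[Tuple[str, float]] = None,
    bottom: Optional[Tuple[str, float]] = None,
    initial: Optional[float] = None,
    tol: float = 1e-12,
) -> Tuple[ConcentrationField, SimulationSummary]:
    """Steady solution of the transport problem on ``device``.

    This is the general entry point; :func:`solve_steady_oxygen` wraps it
    with the oxygen boundary conditions.  ``top``/``bottom`` accept
    ``("dirichlet", value)`` or ``("noflux", None)`` overrides (values in
    media-equivalent units).
    """
    a, b = _assemble(device, inlet_u=inlet_u, top=top, bottom=bottom)
    u0 = np.full(device.n, device.u_inlet if initial is None else initial, dtype=float)
    u, history = _newton(a, b, device, u0, uptake=uptake, tol=tol)
    field = ConcentrationField(device, u.reshape(device.nz, device.nx), None, device.species)
    cmin, cmean, cmax = _chamber_stats(device, u)
    ref = max(np.abs(b).max(), 1e-30)
    summary = SimulationSummary(cmin, cmean, cmax, history[-1] / ref if history else 0.0)
    return field, summary


def solve_steady_oxygen(
    device: DiscretizedDevice, **kwargs
) -> Tuple[ConcentrationField, SimulationSummary]:
    """Steady oxygen field with cell uptake.

    Boundary conditions are carried by the device (built by
    :func:`discretize` with ``pdms_flux`` on or off): inlet Dirichlet at the
    media saturation, advective outflow, ambient-saturation Dirichlet above
    the PDMS slab when permeation is enabled, no-flux otherwise.
    """
    if device.species != "oxygen":
        raise ValueError("device was not discretized for oxygen")
    return solve_steady(device, uptake=True, **kwargs)


def solve_transient_oxygen(
    device: DiscretizedDevice,
    *,
    t_end: float,
    dt: float,
    hypoxia_threshold: Optional[float] = None,
    uptake: bool = True,
    initial: Optional[float] = None,
    keep_final_field: bool = False,
) -> TransientResult:
    """Implicit-Euler transient oxygen solve.

    Starts from media saturation in every layer (the stated initial
    condition for the media channel and cell chamber; the PDMS, when
    present, also starts equilibrated).  Reports the first time the
    cell-chamber minimum falls below the hypoxia threshold, which defaults
    to the Michaelis constant in concentration units (~7.7e-3 mol/m3).
    """
    if device.species != "oxygen":
        raise ValueError("device was not discretized for oxygen")
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError("dt must be positive and finite")
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    if hypoxia_threshold is None:
        hypoxia_threshold = device.params.km_conc

    a, b = _assemble(device)
    theta = device.capacity.repeat(device.nx)
    theta_over_dt = theta / dt
    u = np.full(device.n, device.params.c_inlet_o2 if initial is None else initial, dtype=float)

    nsteps = int(math.ceil(t_end / dt))
    times = [0.0]
    stats = [_chamber_stats(device, u)]
    for step in range(1, nsteps + 1):
        u, _ = _newton(
            a, b, device, u, uptake=uptake, theta_over_dt=theta_over_dt, u_prev=u
        )
        times.append(step * dt)
        stats.append(_chamber_stats(device, u))

    times = np.asarray(times)
    cmin, cmean, cmax = (np.asarray(x) for x in zip(*stats))
    t_dep = _first_crossing(times, cmin, hypoxia_threshold, "below")
    final = None
    if keep_final_field:
        final = ConcentrationField(
            device, u.reshape(device.nz, device.nx), float(times[-1]), "oxygen"
        )
    return TransientResult(times, cmin, cmean, cmax, time_to_depletion=t_dep, final_field=final)


def solve_tracer_washin(
    device: DiscretizedDevice,
    *,
    c_inlet: float = 1.0,
    uniformity_fraction: float = 0.95,
    t_end: float = 600.0,
    dt: float = 2.0,
    initial: float = 0.0,
) -> TransientResult:
    """Wash-in of an inert tracer into the empty device.

    The device must be discretized for the tracer species (impermeable
    walls, no uptake).  ``time_to_uniformity`` is the first time the
    cell-chamber minimum reaches ``uniformity_fraction * c_inlet``.
    The problem is linear, so one LU factorization serves every step.
    """
    if device.species != "tracer":
        raise ValueError("device was not discretized for the tracer species")
    if not 0.0 < uniformity_fraction <= 1.0:
        raise ValueError("uniformity_fraction must lie in (0, 1]")
    if dt <= 0 or not math.isfinite(dt):
        raise ValueError("dt must be positive and finite")

    a, b = _assemble(device, inlet_u=c_inlet)
    theta = device.capacity.repeat(device.nx)
    m = csc_matrix(a + diags(theta / dt))
    lu = splu(m)
    u = np.full(device.n, initial, dtype=float)

    target = uniformity_fraction * c_inlet
    nsteps = int(math.ceil(t_end / dt))
    times = [0.0]
    stats = [_chamber_stats(device, u)]
    for step in range(1, nsteps + 1):
        u = lu.solve(b + theta / dt * u)
        times.append(step * dt)
        stats.append(_chamber_stats(device, u))
        if stats[-1][0] >= target and len(times) > 3:
            break

    times = np.asarray(times)
    cmin, cmean, cmax = (np.asarray(x) for x in zip(*stats))
    t_unif = _first_crossing(times, cmin, target, "above")
    if t_unif is None:
        warnings.warn(
            "tracer did not reach the uniformity target within t_end; "
            "increase t_end", RuntimeWarning,
        )
    return TransientResult(times, cmin, cmean, cmax, time_to_uniformity=t_unif)
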