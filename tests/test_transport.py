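"""Finite-volume transport solver: discretization, physics and numerics."""

import numpy as np
import pytest

from liverheart.device import DeviceGeometry, TransportParams, InvalidGeometryError
from liverheart import transport as tr
from liverheart.transport import (
    discretize,
    mm_uptake,
    solve_steady,
    solve_steady_oxygen,
    solve_transient_oxygen,
    solve_tracer_washin,
)

COARSE_NZ = {"cell_chamber": 3, "membrane": 3, "media_channel": 3, "pdms": 3}


class TestDiscretize:
    def test_membrane_effective_diffusivity(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20)
        rows = [i for i, n in enumerate(dev.layer_of_row) if n == "membrane"]
        assert dev.perm[rows[0]] == pytest.approx(0.056 * 3.0e-9)

    def test_transparent_membrane_limit(self, params):
        geo = DeviceGeometry(membrane_porosity=0.999999)
        dev = discretize(geo, params, "oxygen", nx=20)
        rows = [i for i, n in enumerate(dev.layer_of_row) if n == "membrane"]
        assert dev.perm[rows[0]] == pytest.approx(params.d_o2_media, rel=1e-5)

    def test_partition_coefficient(self, params):
        # ratio of the two printed saturation levels
        assert params.partition_coefficient == pytest.approx(1.11 / 0.173, rel=1e-6)
        assert params.partition_coefficient == pytest.approx(6.42, abs=0.01)

    def test_refinement_error(self, geometry, params):
        with pytest.raises(InvalidGeometryError):
            discretize(geometry, params, "oxygen", nx=20, nz_per_layer={"membrane": 2})
        with pytest.raises(InvalidGeometryError):
            discretize(geometry, params, "oxygen", nx=5)

    def test_velocity_zero_outside_media_channel(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20)
        flow = np.array([n == "media_channel" for n in dev.layer_of_row])
        assert np.all(dev.velocity[~flow] == 0.0)
        assert np.all(dev.velocity[flow] > 0.0)
        # discrete mean reproduces Q/(w*h) exactly
        h = geometry.media_channel_height_m
        vbar = params.q_m3_s / (geometry.width_m * h)
        assert dev.velocity[flow].mean() == pytest.approx(vbar)

    def test_layer_heights_sum_to_stack(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20)
        total = (
            geometry.cell_chamber_height_m
            + geometry.membrane_thickness_m
            + geometry.media_channel_height_m
            + geometry.pdms_slab_thickness_m
        )
        assert dev.dz.sum() == pytest.approx(total)


class TestMMUptake:
    def test_zero_concentration(self, params):
        assert mm_uptake(0.0, params) == 0.0

    def test_half_saturation_identity(self, params):
        c = params.km_conc
        assert mm_uptake(c, params) == pytest.approx(-0.5 * params.vmax_volumetric)

    def test_saturating_limit(self, params):
        # far above Km the sink approaches -VO2max*rho_cell ~ -6.7e-3 mol/m3/s
        assert mm_uptake(0.173, params) == pytest.approx(-6.7e-3, rel=0.05)
        assert mm_uptake(100.0, params) == pytest.approx(-params.vmax_volumetric, rel=1e-4)

    def test_negative_concentration_rejected(self, params):
        with pytest.raises(ValueError):
            mm_uptake(-1e-6, params)


class TestSteadyOxygen:
    def test_no_uptake_equilibrium_is_uniform(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20, nz_per_layer=COARSE_NZ)
        field, _ = solve_steady(dev, uptake=False)
        assert np.allclose(field.u, params.c_inlet_o2, rtol=1e-9)

    def test_dense_direct_solve_oracle(self, geometry, params):
        """Coarse-grid steady solution matches a dense solve with an outer
        fixed-point iteration on the Michaelis-Menten term."""
        dev = discretize(geometry, params, "oxygen", nx=20, nz_per_layer=COARSE_NZ)
        field, _ = solve_steady_oxygen(dev)

        a, b = tr._assemble(dev)
        dense = a.toarray()
        vmax, km = params.vmax_volumetric, params.km_conc
        mask = dev.uptake_rows.repeat(dev.nx)
        u = np.full(dev.n, params.c_inlet_o2)
        for _ in range(400):
            sink = np.where(mask, vmax * u / (km + u), 0.0)
            u_new = np.linalg.solve(dense, b - sink)
            if np.abs(u_new - u).max() < 1e-15:
                break
            u = u_new
        assert np.abs(field.u.ravel() - u).max() / np.abs(u).max() < 1e-6

    def test_monotone_in_vo2max(self, geometry, params):
        means = []
        for scale in (1.0, 3.0):
            p = TransportParams(vo2max=params.vo2max * scale)
            dev = discretize(geometry, p, "oxygen", nx=30, nz_per_layer=COARSE_NZ)
            _, s = solve_steady_oxygen(dev)
            means.append(s.cmean)
        assert means[1] < means[0]

    def test_monotone_in_flow_rate(self, geometry, params):
        means = []
        for q in (10.0, 40.0):
            p = TransportParams(flow_rate_ul_per_h=q)
            dev = discretize(
                geometry, p, "oxygen", nx=30, nz_per_layer=COARSE_NZ, side_walls=False
            )
            _, s = solve_steady_oxygen(dev)
            means.append(s.cmean)
        assert means[1] > means[0]

    def test_grid_convergence(self, geometry, params):
        dev1 = discretize(geometry, params, "oxygen", nx=60)
        _, s1 = solve_steady_oxygen(dev1)
        dev2 = discretize(
            geometry, params, "oxygen", nx=120,
            nz_per_layer={k: 2 * v for k, v in tr.DEFAULT_NZ.items()},
        )
        _, s2 = solve_steady_oxygen(dev2)
        assert abs(s1.cmean - s2.cmean) / s2.cmean < 0.02

    def test_summary_ordering_and_residual(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=30, nz_per_layer=COARSE_NZ)
        field, s = solve_steady_oxygen(dev)
        assert s.cmin <= s.cmean <= s.cmax
        assert s.mass_balance_residual < 1e-6
        assert np.all(field.u >= 0)


class TestAnalyticLimits:
    def test_two_layer_slab_profile(self, geometry):
        """Flow off, uptake off, Dirichlet faces: piecewise-linear profile
        with flux continuity across the membrane (closed-form check)."""
        params = TransportParams(flow_rate_ul_per_h=0.0)
        dev = discretize(geometry, params, "tracer", nx=12,
                         nz_per_layer={"cell_chamber": 5, "membrane": 3, "media_channel": 5})
        u_bot, u_top = 1.0, 0.0
        field, _ = solve_steady(
            dev, uptake=False, bottom=("dirichlet", u_bot), top=("dirichlet", u_top)
        )
        # analytic: flux J = (u_bot - u_top) / sum(h_i / P_i)
        heights = [l.height for l in dev.layers]
        perms = [l.perm for l in dev.layers]
        resistance = sum(h / p for h, p in zip(heights, perms))
        flux = (u_bot - u_top) / resistance
        # cumulative resistance down to each node center
        expected = np.empty(dev.nz)
        z0 = 0.0
        r_acc = 0.0
        row = 0
        for l in dev.layers:
            dz = l.height / l.nz
            for i in range(l.nz):
                r_here = r_acc + (i + 0.5) * dz / l.perm
                expected[row] = u_bot - flux * r_here
                row += 1
            r_acc += l.height / l.perm
        assert np.allclose(field.u, expected[:, None], atol=1e-10)
        # no lateral variation
        assert np.abs(np.diff(field.u, axis=1)).max() < 1e-12


class TestTransient:
    def test_mass_conservation_single_step(self, geometry, params):
        """Accumulation equals boundary fluxes minus the uptake integral,
        with the fluxes recomputed independently from the field."""
        dt = 5.0
        dev = discretize(geometry, params, "oxygen", nx=30,
                         nz_per_layer=COARSE_NZ, pdms_flux=False)
        res = solve_transient_oxygen(dev, t_end=dt, dt=dt, keep_final_field=True)
        u1 = res.final_field.u
        u0 = np.full_like(u1, params.c_inlet_o2)
        w = geometry.width_m
        vol = dev.dz[:, None] * dev.dx * w
        accumulation = (dev.capacity[:, None] * (u1 - u0) * vol).sum() / dt

        flow = dev.velocity > 0
        area = dev.dz[flow] * w
        influx = (dev.velocity[flow] * params.c_inlet_o2 * area).sum()
        influx += (
            dev.perm[flow] / (0.5 * dev.dx)
            * (params.c_inlet_o2 - u1[flow, 0]) * area
        ).sum()
        outflux = (dev.velocity[flow] * u1[flow, -1] * area).sum()
        vmax, km = params.vmax_volumetric, params.km_conc
        uptake = (vmax * u1 / (km + u1) * vol)[dev.uptake_rows, :].sum()

        residual = accumulation - (influx - outflux - uptake)
        assert abs(residual) / max(uptake, influx) < 1e-8

    def test_no_uptake_no_pdms_stays_at_initial(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20,
                         nz_per_layer=COARSE_NZ, pdms_flux=False)
        res = solve_transient_oxygen(dev, t_end=20.0, dt=5.0, uptake=False)
        assert np.allclose(res.cmin, params.c_inlet_o2, rtol=1e-9)
        assert res.time_to_depletion is None

    def test_depletion_without_pdms_supply(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=40, pdms_flux=False)
        res = solve_transient_oxygen(dev, t_end=300.0, dt=2.0)
        assert res.time_to_depletion is not None
        assert res.time_to_depletion <= 300.0
        # the minimum trace is monotonically non-increasing
        assert np.all(np.diff(res.cmin) <= 1e-12)

    def test_bad_dt_rejected(self, geometry, params):
        dev = discretize(geometry, params, "oxygen", nx=20, nz_per_layer=COARSE_NZ)
        with pytest.raises(ValueError):
            solve_transient_oxygen(dev, t_end=10.0, dt=0.0)


class TestTracerWashin:
    def test_starts_uniform_means_instant(self, geometry, params):
        dev = discretize(geometry, params, "tracer", nx=20,
                         nz_per_layer={"cell_chamber": 3, "membrane": 3, "media_channel": 3})
        res = solve_tracer_washin(dev, c_inlet=1.0, initial=1.0, t_end=20.0, dt=5.0)
        assert res.time_to_uniformity == 0.0

    def test_slower_diffusion_is_slower(self, geometry, params):
        times = []
        for d in (1.0e-9, 0.5e-9):
            p = TransportParams(d_small_molecule=d)
            dev = discretize(geometry, p, "tracer", nx=40)
            res = solve_tracer_washin(dev, t_end=1200.0, dt=5.0)
            times.append(res.time_to_uniformity)
        assert times[1] > times[0]

    def test_bad_uniformity_fraction(self, geometry, params):
        dev = discretize(geometry, params, "tracer", nx=20,
                         nz_per_layer={"cell_chamber": 3, "membrane": 3, "media_channel": 3})
        with pytest.raises(ValueError):
            solve_tracer_washin(dev, uniformity_fraction=1.5)

    def test_positivity(self, geometry, params):
        dev = discretize(geometry, params, "tracer", nx=30)
        res = solve_tracer_washin(dev, t_end=100.0, dt=2.0)
        assert np.all(res.cmin >= -1e-12)
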