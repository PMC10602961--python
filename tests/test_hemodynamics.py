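import numpy as np
import pytest

from aneuflow import (
    FieldSeries,
    MetricsReport,
    RegionSet,
    kinetic_energy,
    ker,
    lsa,
    metrics_report,
    ntawss,
    ovi,
    tawss,
    vorticity,
    wss_from_velocity,
)
from aneuflow.hemodynamics import GradientOperator

from conftest import toy_surface_series


def grid_series(field_fn, times=(0.0, 1.0), n=6, rho=1055.0):
    """Cartesian cube of points with an analytic velocity field."""
    xs = np.linspace(-1, 1, n)
    pts = np.array(np.meshgrid(xs, xs, xs, indexing="ij")).reshape(3, -1).T
    from scipy.spatial import Delaunay

    tets = Delaunay(pts).simplices
    tris = np.array([[0, 1, 2]])
    normals = np.array([[0, 0, 1.0]])
    times = np.asarray(times, float)
    vel = np.stack([np.apply_along_axis(lambda p: field_fn(p, t), 1, pts) for t in times])
    return FieldSeries(points=pts, tets=tets, surface_tris=tris,
                       surface_normals=normals, times=times, velocity=vel, rho=rho)


class TestVorticity:
    def test_rigid_rotation_curl_is_twice_omega(self, rotation_phantom):
        series, _, presc = rotation_phantom
        curl = vorticity(series, 0)
        assert np.allclose(curl[:, 2], presc["vorticity"], rtol=0.02)
        assert np.abs(curl[:, :2]).max() < 1e-8 * abs(presc["vorticity"])

    def test_uniform_flow_is_irrotational(self):
        s = grid_series(lambda p, t: np.array([1.0, 0.0, 0.0]))
        assert np.abs(vorticity(s, 0)).max() < 1e-10

    def test_simple_shear(self):
        k = 3.0
        s = grid_series(lambda p, t: np.array([k * p[1], 0.0, 0.0]))
        curl = vorticity(s, 0)
        assert np.allclose(curl[:, 2], -k, rtol=0.02)


class TestKineticEnergy:
    def test_uniform_speed_arithmetic(self):
        s = grid_series(lambda p, t: np.array([0.1, 0.0, 0.0]), rho=1055.0)
        region = np.arange(len(s.tets))
        assert kinetic_energy(s, 0, region) == pytest.approx(5.275)

    def test_zero_field(self):
        s = grid_series(lambda p, t: np.zeros(3))
        assert kinetic_energy(s, 0, np.arange(len(s.tets))) == 0.0

    def test_poiseuille_four_thirds_factor(self, poiseuille_phantom):
        series, regions, presc = poiseuille_phantom
        ke = kinetic_energy(series, 0, regions.sac_cells)
        assert ke == pytest.approx(presc["ke"], rel=0.02)

    def test_empty_region_rejected(self):
        s = grid_series(lambda p, t: np.zeros(3))
        with pytest.raises(ValueError):
            kinetic_energy(s, 0, np.array([], dtype=int))


class TestKerOvi:
    def test_identical_regions_give_unity(self, poiseuille_phantom):
        series, regions, _ = poiseuille_phantom
        assert ker(series, regions) == pytest.approx(1.0, abs=1e-12)

    def test_speed_ratio_squared(self, sac_phantom):
        series, regions, presc = sac_phantom
        assert ker(series, regions) == pytest.approx(presc["ker"], rel=0.01)

    def test_steady_flow_ovi_zero(self, poiseuille_phantom):
        series, regions, _ = poiseuille_phantom
        assert ovi(series, regions.sac_cells) == 0.0

    def test_reversing_flow_ovi_half(self, reversing_phantom):
        series, regions, _ = reversing_phantom
        assert ovi(series, regions.sac_cells) == pytest.approx(0.5, abs=1e-12)

    def test_large_offset_suppresses_ovi(self):
        # u = (c + sin(2 pi t), 0, 0): OVI -> 0 as c grows; oracle = dense
        # 1D quadrature of the definition
        tq = np.linspace(0, 1, 20001)
        for c in (2.0, 10.0):
            s = grid_series(
                lambda p, t, c=c: np.array([c + np.sin(2 * np.pi * t), 0.0, 0.0]),
                times=np.linspace(0, 1, 65),
            )
            got = ovi(s, np.arange(len(s.tets)))
            sig = c + np.sin(2 * np.pi * tq)
            expected = 0.5 * (1 - abs(np.trapezoid(sig, tq)) / np.trapezoid(np.abs(sig), tq))
            assert got == pytest.approx(expected, abs=1e-4)
        assert expected < 0.01  # large offset: nearly steady

    def test_ovi_invariant_under_velocity_rescaling(self, reversing_phantom):
        series, regions, _ = reversing_phantom
        scaled = FieldSeries(
            points=series.points, tets=series.tets, surface_tris=series.surface_tris,
            surface_normals=series.surface_normals, times=series.times,
            velocity=3.7 * series.velocity,
        )
        assert ovi(scaled, regions.sac_cells) == pytest.approx(
            ovi(series, regions.sac_cells), abs=1e-12
        )


class TestShearMetrics:
    def test_constant_wss(self):
        s, parent, sac = toy_surface_series([2.0] * 4, [2.0] * 4)
        assert tawss(s, sac).mean == pytest.approx(2.0)

    def test_abs_sine_quadrature(self):
        # |WSS|(t) = |sin(2 pi t)| * pi/2 has cycle mean exactly 1
        times = np.linspace(0, 1, 101)
        mags = np.abs(np.sin(2 * np.pi * times)) * np.pi / 2
        s, parent, sac = toy_surface_series([1.0], [1.0], times=times)
        s.wss = np.zeros((101, 2, 3))
        s.wss[:, :, 0] = mags[:, None]
        assert tawss(s, np.array([0, 1])).mean == pytest.approx(1.0, rel=0.01)

    def test_lsa_hand_weighted_example(self):
        # parent cells 2,2,4,4 Pa -> mean 3, SD 1, boundary 2;
        # sac cells 1,1,5,5 Pa, equal areas -> half the area below 2
        s, parent, sac = toy_surface_series([2, 2, 4, 4], [1, 1, 5, 5])
        regions = RegionSet(sac_cells=[0], parent_cells=[], sac_surface=sac,
                            parent_surface=parent)
        assert lsa(s, regions) == pytest.approx(0.5)

    def test_lsa_extremes(self):
        s, parent, sac = toy_surface_series([3, 3, 3, 3], [10, 10, 10, 10])
        regions = RegionSet(sac_cells=[0], parent_cells=[], sac_surface=sac,
                            parent_surface=parent)
        assert lsa(s, regions) == 0.0  # sac everywhere above the boundary
        s2, parent2, sac2 = toy_surface_series([3, 3, 3, 3], [0.1] * 4)
        regions2 = RegionSet(sac_cells=[0], parent_cells=[], sac_surface=sac2,
                             parent_surface=parent2)
        assert lsa(s2, regions2) == 1.0

    def test_ntawss_ratio(self):
        s, parent, sac = toy_surface_series([4.0] * 3, [1.0] * 3)
        regions = RegionSet(sac_cells=[0], parent_cells=[], sac_surface=sac,
                            parent_surface=parent)
        assert ntawss(s, regions) == pytest.approx(0.25)

    def test_missing_wss_rejected(self):
        s, parent, sac = toy_surface_series([1.0], [1.0])
        s.wss = None
        with pytest.raises(ValueError, match="WSS"):
            tawss(s, sac)


class TestWssFromVelocity:
    def test_linear_shear_is_exact(self):
        # u_x = k z above a z=0 wall: |WSS| = mu k exactly
        k = 3.0
        xs = np.linspace(0, 1, 6)
        pts = np.array(np.meshgrid(xs, xs, xs, indexing="ij")).reshape(3, -1).T
        from scipy.spatial import Delaunay

        tets = Delaunay(pts).simplices
        wall = np.flatnonzero(pts[:, 2] == 0)
        grid = {tuple(np.round(p[:2], 6)): i for i, p in enumerate(pts[wall])}
        tris = []
        for i in range(5):
            for j in range(5):
                a = grid[(round(xs[i], 6), round(xs[j], 6))]
                b = grid[(round(xs[i + 1], 6), round(xs[j], 6))]
                c = grid[(round(xs[i], 6), round(xs[j + 1], 6))]
                tris.append([wall[a], wall[b], wall[c]])
        tris = np.array(tris)
        normals = np.tile([0, 0, -1.0], (len(tris), 1))  # outward = below wall
        vel = np.zeros((2, len(pts), 3))
        vel[:, :, 0] = k * pts[:, 2]
        s = FieldSeries(points=pts, tets=tets, surface_tris=tris, surface_normals=normals,
                        times=[0, 1], velocity=vel, mu=0.004)
        w = wss_from_velocity(s, np.arange(len(tris)))
        assert np.allclose(np.linalg.norm(w[0], axis=1), 0.004 * k, rtol=1e-8)

    def test_poiseuille_closed_form(self, poiseuille_phantom):
        series, regions, presc = poiseuille_phantom
        w = wss_from_velocity(series, np.arange(len(series.surface_tris)))
        mags = np.linalg.norm(w[0], axis=1)
        area_mean = np.average(mags, weights=series.surface_areas)
        assert area_mean == pytest.approx(presc["tawss"], rel=0.05)

    def test_uniform_flow_has_zero_wss(self, poiseuille_phantom):
        series, _, _ = poiseuille_phantom
        flat = FieldSeries(
            points=series.points, tets=series.tets, surface_tris=series.surface_tris,
            surface_normals=series.surface_normals, times=series.times,
            velocity=np.broadcast_to([0.1, 0, 0], series.velocity.shape).copy(),
        )
        w = wss_from_velocity(flat, np.arange(len(series.surface_tris)))
        assert np.abs(w).max() < 1e-10


class TestMetricsReport:
    def test_steady_phantom_composition(self, poiseuille_phantom):
        series, regions, presc = poiseuille_phantom
        rep = metrics_report(series, regions)
        assert rep.OVI == 0.0
        assert rep.KER == pytest.approx(1.0, abs=1e-12)
        assert rep.nTAWSS == pytest.approx(1.0, abs=1e-12)
        assert rep.LSA in (0.0, 1.0)
        assert rep.TAWSS == pytest.approx(presc["tawss"], rel=1e-9)

    def test_doubling_density_doubles_ke_not_ker(self, poiseuille_phantom):
        series, regions, _ = poiseuille_phantom
        rep1 = metrics_report(series, regions)
        dense = FieldSeries(
            points=series.points, tets=series.tets, surface_tris=series.surface_tris,
            surface_normals=series.surface_normals, times=series.times,
            velocity=series.velocity, wss=series.wss, rho=2 * series.rho, mu=series.mu,
        )
        rep2 = metrics_report(dense, regions)
        assert rep2.KE == pytest.approx(2 * rep1.KE, rel=1e-12)
        assert rep2.KER == pytest.approx(rep1.KER, rel=1e-12)

    def test_report_bounds_enforced(self):
        with pytest.raises(ValueError):
            MetricsReport(mean_V=0, mean_vorticity=0, KE=0, KER=0, OVI=0.7,
                          TAWSS=0, nTAWSS=0, LSA=0)
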