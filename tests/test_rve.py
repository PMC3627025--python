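"""RVE geometry, averaged pressure, porosity, clipped volumes, beta."""

import numpy as np
import pytest

from darcyparam.network import Vessel, VesselNode, VascularNetwork
from darcyparam.poiseuille import poiseuille_conductance, solve_network_flow
from darcyparam.rve import (
    RVEAverager,
    RVESpec,
    beta_field,
    nearest_fill,
    rve_volume_in_domain,
    vessels_in_rve,
)

from conftest import make_network, random_tree

BIG = np.array([[-100.0, 100.0]] * 3)


def straight_vessel_network(pa, pb, radius=0.001, extra=None):
    positions = [pa, pb] + (extra or [])
    radii = [radius] * len(positions)
    edges = [(0, 1)] + [(1, i + 2) for i in range(len(extra or []))]
    return make_network(positions, radii, edges)


class TestSegmentBallFractions:
    def test_fully_inside(self):
        net = straight_vessel_network((-0.1, 0, 0), (0.1, 0, 0))
        avg = RVEAverager(net)
        out = vessels_in_rve((0, 0, 0), RVESpec(1.0, BIG), None, avg)
        assert out == [(0, pytest.approx(1.0))]

    def test_fully_outside_excluded(self):
        net = straight_vessel_network((5.0, 0, 0), (6.0, 0, 0))
        avg = RVEAverager(net)
        assert vessels_in_rve((0, 0, 0), RVESpec(1.0, BIG), None, avg) == []

    def test_symmetric_chord_fraction(self):
        # vessel of length 4 through the centre of a ball of radius 1 -> 2R/l
        net = straight_vessel_network((-2.0, 0, 0), (2.0, 0, 0))
        avg = RVEAverager(net)
        out = vessels_in_rve((0, 0, 0), RVESpec(1.0, BIG), None, avg)
        assert out[0][1] == pytest.approx(2 * 1.0 / 4.0, rel=1e-12)

    def test_matches_brute_force_scan(self):
        net = random_tree(6, max_nodes=40)
        avg = RVEAverager(net)
        rng = np.random.default_rng(2)
        vids = net.sorted_vessel_ids()
        for _ in range(50):
            x = rng.normal(scale=0.5, size=3)
            R = rng.uniform(0.05, 0.6)
            got = dict(vessels_in_rve(x, RVESpec(R, BIG), None, avg))
            # O(n) reference: clip the parametric segment to the ball
            for vid in vids:
                v = net.vessels[vid]
                a = net.nodes[v.node_a].position
                b = net.nodes[v.node_b].position
                ts = np.linspace(0, 1, 2001)
                pts = a[None] + ts[:, None] * (b - a)[None]
                inside = np.linalg.norm(pts - x, axis=1) <= R
                frac = inside.mean()
                if frac == 0:
                    assert vid not in got
                else:
                    assert got.get(vid, 0.0) == pytest.approx(frac, abs=2e-3)


class TestAveragedPressure:
    def _two_vessel_case(self):
        # two disjoint-pressure vessels fully inside the ball; choose radii so
        # the volumes are in ratio 1:3
        l = 0.4
        r1 = 0.01
        r2 = r1 * np.sqrt(3.0)
        positions = [(-0.3, 0, 0), (-0.3 + l, 0, 0), (-0.3 + 2 * l, 0, 0)]
        nodes = [
            VesselNode(0, np.array(positions[0]), r1),
            VesselNode(1, np.array(positions[1]), r1),
            VesselNode(2, np.array(positions[2]), r2),
        ]
        # vessel radii are endpoint means; build radii per vessel directly
        net = VascularNetwork(nodes, [Vessel(0, 0, 1), Vessel(1, 1, 2)], root_id=0)
        net.vessels[0].radius = r1
        net.vessels[1].radius = r2
        return net

    def test_volume_weighted_hand_value(self):
        net = self._two_vessel_case()
        # impose vessel mean pressures 1000 and 2000 Pa directly
        avg = RVEAverager(net)
        avg.p_vessel = np.array([1000.0, 2000.0])
        avg.dp = np.zeros(2)
        avg.volume = np.array([1.0, 3.0])
        p = avg.averaged_pressure(np.array([0.0, 0.0, 0.0]), RVESpec(5.0, BIG), None)
        assert p == pytest.approx(1750.0, rel=1e-12)

    def test_constant_pressure_recovered(self):
        net = random_tree(4)
        dirichlet = {net.root_id: 9000.0}
        for t in net.terminal_node_ids():
            dirichlet[t] = 9000.0
        flow = solve_network_flow(net, dirichlet)
        avg = RVEAverager(net, flow=flow)
        p = avg.averaged_pressure(np.zeros(3), RVESpec(10.0, BIG), None)
        assert p == pytest.approx(9000.0, rel=1e-12)

    def test_empty_ball_flagged(self):
        net = straight_vessel_network((5.0, 0, 0), (6.0, 0, 0))
        flow = solve_network_flow(net, {0: 1.0, 1: 0.0})
        avg = RVEAverager(net, flow=flow)
        assert np.isnan(avg.averaged_pressure(np.zeros(3), RVESpec(0.5, BIG), None))

    def test_invariant_under_vessel_split(self):
        """Splitting a vessel into collinear halves leaves the average fixed."""
        whole = make_network(
            [(0, 0, 0), (0.4, 0, 0), (0.4, 0.3, 0)],
            [0.002, 0.002, 0.001],
            [(0, 1), (1, 2)],
        )
        split = make_network(
            [(0, 0, 0), (0.2, 0, 0), (0.4, 0, 0), (0.4, 0.3, 0)],
            [0.002, 0.002, 0.002, 0.001],
            [(0, 1), (1, 2), (2, 3)],
        )
        x = np.array([0.1, 0.05, 0.0])
        spec = RVESpec(0.8, BIG)
        vals = []
        for net in (whole, split):
            dirichlet = {0: 2000.0, net.n_nodes - 1: 1000.0}
            flow = solve_network_flow(net, dirichlet)
            avg = RVEAverager(net, flow=flow)
            vals.append(avg.averaged_pressure(x, spec, None))
        # pressure varies linearly along the collinear run, so the
        # volume-weighted mean over matching lumen volumes agrees
        assert vals[0] == pytest.approx(vals[1], rel=1e-12)


class TestPorosity:
    def test_hand_value_fully_inside(self):
        net = straight_vessel_network((-0.25, 0, 0), (0.25, 0, 0), radius=0.01)
        avg = RVEAverager(net)
        phi = avg.porosity(np.zeros(3), RVESpec(0.5, BIG), None)
        expected = (np.pi * 0.01**2 * 0.5) / (4.0 / 3.0 * np.pi * 0.5**3)
        assert phi == pytest.approx(expected, rel=1e-12)
        assert phi == pytest.approx(3.0e-4, rel=1e-2)

    def test_empty_ball_zero(self):
        net = straight_vessel_network((5.0, 0, 0), (6.0, 0, 0))
        avg = RVEAverager(net)
        assert avg.porosity(np.zeros(3), RVESpec(0.5, BIG), None) == 0.0

    def test_additivity_over_compartments(self):
        net = random_tree(5)
        for v in net.vessels.values():
            v.compartment = 1 + v.id % 3
        avg = RVEAverager(net)
        spec = RVESpec(0.4, BIG)
        x = np.array([0.1, 0.0, -0.1])
        total = avg.porosity(x, spec, None)
        parts = sum(avg.porosity(x, spec, c) for c in (1, 2, 3))
        assert parts == pytest.approx(total, rel=1e-12)


class TestClippedVolume:
    DOMAIN = np.array([[-1.0, 1.0]] * 3)

    def test_interior_analytic(self):
        spec = RVESpec(0.25, self.DOMAIN)
        vol = rve_volume_in_domain(np.zeros(3), spec)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 0.25**3, rel=1e-14)

    def test_face_centre_half_volume(self):
        spec = RVESpec(0.25, self.DOMAIN)
        full = 4.0 / 3.0 * np.pi * 0.25**3
        vol = rve_volume_in_domain(np.array([1.0, 0.0, 0.0]), spec)
        se = full / np.sqrt(100_000)  # generous bound on the MC error
        assert abs(vol - 0.5 * full) <= 3 * se

    def test_corner_eighth_volume(self):
        spec = RVESpec(0.25, self.DOMAIN)
        full = 4.0 / 3.0 * np.pi * 0.25**3
        vol = rve_volume_in_domain(np.array([1.0, 1.0, 1.0]), spec)
        se = full / np.sqrt(100_000)
        assert abs(vol - full / 8.0) <= 3 * se

    def test_cache_symmetry(self):
        net = straight_vessel_network((0, 0, 0), (0.1, 0, 0))
        avg = RVEAverager(net)
        spec = RVESpec(0.3, self.DOMAIN)
        v1 = avg.ball_volume_in_domain(np.array([0.9, 0.0, 0.0]), spec)
        v2 = avg.ball_volume_in_domain(np.array([0.0, -0.9, 0.0]), spec)
        assert v1 == v2  # same clipping signature -> shared cache entry


class TestIntercompartmentFluxAndBeta:
    def _coupled_network(self):
        """cpt-1 feeder joined to a cpt-2 chain; connector is the feeder."""
        positions = [(0, 0, 0), (0.3, 0, 0), (0.6, 0, 0), (0.9, 0, 0)]
        radii = [0.004, 0.004, 0.002, 0.002]
        net = make_network(positions, radii, [(0, 1), (1, 2), (2, 3)])
        net.vessels[0].compartment = 1
        net.vessels[1].compartment = 2
        net.vessels[2].compartment = 2
        return net

    def test_no_connectors_zero(self):
        net = self._coupled_network()
        flow = solve_network_flow(net, {0: 2000.0, 3: 1000.0})
        avg = RVEAverager(net, flow=flow)
        # ball far from the compartment-1 vessel
        q = avg.intercompartment_flux(np.array([0.9, 0, 0]), RVESpec(0.2, BIG), 2, 1)
        assert q == 0.0

    def test_single_connector_reduces_to_conductance_times_dp(self):
        net = self._coupled_network()
        flow = solve_network_flow(net, {0: 2000.0, 3: 1000.0})
        avg = RVEAverager(net, flow=flow)
        spec = RVESpec(5.0, BIG)
        q = avg.intercompartment_flux(np.zeros(3), spec, 2, 1)
        v = net.vessels[0]
        c = poiseuille_conductance(v.radius, v.length, flow.mu)
        dp = flow.pressure[0] - flow.pressure[1]
        assert q == pytest.approx(c * dp, rel=1e-12)

    def test_beta_hand_ratio(self):
        net = self._coupled_network()
        flow = solve_network_flow(net, {0: 2000.0, 3: 1000.0})
        avg = RVEAverager(net, flow=flow)
        spec = RVESpec(5.0, BIG)
        q = avg.intercompartment_flux(np.zeros(3), spec, 2, 1)
        p1 = avg.averaged_pressure(np.zeros(3), spec, 1)
        p2 = avg.averaged_pressure(np.zeros(3), spec, 2)
        assert avg.beta(np.zeros(3), spec, 2, 1) == pytest.approx(
            abs(q) / abs(p1 - p2), rel=1e-12
        )

    def test_beta_zero_when_pressures_equal(self):
        net = self._coupled_network()
        flow = solve_network_flow(net, {0: 1500.0, 3: 1500.0})
        avg = RVEAverager(net, flow=flow)
        assert avg.beta(np.zeros(3), RVESpec(5.0, BIG), 2, 1) == 0.0

    def test_beta_field_nonnegative_and_filled(self):
        net = random_tree(8)
        for v in net.vessels.values():
            v.compartment = 1 if v.radius > 0.005 else 2
        dirichlet = {net.root_id: 13300.0}
        for t in net.terminal_node_ids():
            dirichlet[t] = 8000.0
        flow = solve_network_flow(net, dirichlet)
        avg = RVEAverager(net, flow=flow)
        pts = np.array([[x, 0.0, 0.0] for x in np.linspace(-0.5, 0.5, 9)])
        b = beta_field(pts, RVESpec(0.6, BIG), 2, 1, avg)
        assert np.all(np.isfinite(b)) and np.all(b >= 0)


class TestNearestFill:
    def test_fills_from_nearest_valid(self):
        pts = np.array([[0.0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        vals = np.array([5.0, np.nan, 7.0])
        out = nearest_fill(pts, vals)
        assert out[1] in (5.0, 7.0)
        np.testing.assert_array_equal(out[[0, 2]], [5.0, 7.0])

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            nearest_fill(np.zeros((2, 3)), np.array([np.nan, np.nan]))
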