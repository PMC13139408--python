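"""Spring forces, edge-force weighting, and overdamped integration."""

import math

import numpy as np
import pytest

from epiboly import Config, SimulationState
from epiboly import forces as frc
from epiboly.geometry import polar_angles

from conftest import make_ring_state


class TestPairSpring:
    def test_zero_at_rest_all_modes(self):
        a, b = np.zeros(3), np.array([1.0, 0, 0])
        for mode in ("full", "repel_only", "attract_only"):
            f = frc.pair_spring_force(a, b, 0.5, 1.0, mode)
            assert np.allclose(f, 0)

    def test_attract_only_hooke(self):
        a, b = np.zeros(3), np.array([1.1, 0, 0])
        f = frc.pair_spring_force(a, b, 0.5, 1.0, "attract_only")
        assert np.allclose(f, [0.05, 0, 0])  # pulls a toward b

    def test_repel_only_zero_beyond_rest(self):
        f = frc.pair_spring_force(
            np.zeros(3), np.array([1.1, 0, 0]), 0.5, 1.0, "repel_only"
        )
        assert np.allclose(f, 0)

    def test_repel_only_pushes_apart(self):
        f = frc.pair_spring_force(
            np.zeros(3), np.array([0.8, 0, 0]), 0.5, 1.0, "repel_only"
        )
        assert np.allclose(f, [-0.1, 0, 0])

    def test_newtons_third_law(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        fa = frc.pair_spring_force(a, b, 0.7, 1.3, "full")
        fb = frc.pair_spring_force(b, a, 0.7, 1.3, "full")
        assert np.allclose(fa, -fb)

    def test_coincident_raises(self):
        with pytest.raises(ValueError):
            frc.pair_spring_force(np.zeros(3), np.zeros(3), 0.5, 1.0)


def _two_cell_state(d, bonded=True, radius=3.09, cell_radius=0.158):
    # place the pair at chord distance d, both on the containment surface
    ang = 2 * math.asin(d / (2 * radius))
    pos = np.array([[radius, 0, 0], [radius * math.cos(ang),
                                     radius * math.sin(ang), 0]])
    st = SimulationState(pos, np.full(2, cell_radius), np.ones(2),
                         np.zeros(2, bool), 0.09, 3.0)
    if bonded:
        st.add_bond(0, 1)
    return st


class TestGlobalForces:
    def test_unbonded_pair_beyond_rest_no_mutual_force(self, default_config):
        st = _two_cell_state(0.5, bonded=False)
        f = frc.global_pair_forces(st, default_config)
        # only the (radial) yolk containment acts; no tangential component
        tangential = f - (f * st.pos).sum(1, keepdims=True) * st.pos / (
            np.linalg.norm(st.pos, axis=1, keepdims=True) ** 2
        )
        assert np.allclose(tangential, 0, atol=1e-12)

    def test_equilibrium_configuration(self, default_config):
        # bonded pair at rest separation, both on the containment surface
        st = _two_cell_state(2 * 0.158, bonded=True)
        f = frc.global_pair_forces(st, default_config)
        assert np.allclose(f, 0, atol=1e-9)

    def test_radial_displacement_restored_by_yolk_spring(self, default_config):
        st = _two_cell_state(0.5, bonded=False)
        delta = 0.05
        st.pos[0] *= (3.09 + delta) / 3.09
        f = frc.global_pair_forces(st, default_config)
        rhat = st.pos[0] / np.linalg.norm(st.pos[0])
        assert f[0] @ rhat == pytest.approx(
            -default_config.harmonic_yolk_evl_spring_constant * delta, abs=1e-9
        )

    def test_newtons_third_law_summed(self, default_config, layered_state):
        # with no exogenous forces, internal pair forces cancel; what is left
        # is the yolk containment reaction (purely radial per cell)
        rng = np.random.default_rng(1)
        layered_state.pos += rng.normal(scale=0.02, size=layered_state.pos.shape)
        f = frc.global_pair_forces(layered_state, default_config)
        r = np.linalg.norm(layered_state.pos, axis=1)
        rest = layered_state.yolk_radius + layered_state.particle_radius
        yolk = -(default_config.harmonic_yolk_evl_spring_constant
                 * (r - rest) / r)[:, None] * layered_state.pos
        assert np.allclose(f.sum(0), yolk.sum(0), atol=1e-9)


class TestEdgeForces:
    def test_uniform_ring_equal_shares(self, default_config):
        st = make_ring_state(n=10)
        out = frc.edge_forces_model1(st, default_config)
        expected = default_config.force_per_unit_length * 2 * math.pi / 10
        assert np.allclose(np.linalg.norm(out.forces, axis=1), expected)

    def test_lengths_sum_to_two_pi(self, default_config, initialized_state):
        out = frc.edge_forces_model1(initialized_state, default_config)
        assert out.weights.sum() == pytest.approx(2 * math.pi, abs=1e-12)

    def test_three_cell_ring_hand_enumeration(self, default_config):
        # ring at theta = 0, 90, 180 degrees: midlines at 45, 135, 270
        st = make_ring_state(n=3)
        theta = np.array([0.0, math.pi / 2, math.pi])
        r, phi = 3.09, math.pi / 2
        st.pos[:] = r * np.stack(
            [np.cos(theta), np.sin(theta), np.zeros(3)], axis=1
        )
        out = frc.edge_forces_model1(st, default_config)
        by_id = dict(zip(out.ring, out.weights))
        assert by_id[0] == pytest.approx(math.pi / 4 + math.pi / 2)   # wraps via 270
        assert by_id[1] == pytest.approx(math.pi / 4 + math.pi / 4)
        assert by_id[2] == pytest.approx(math.pi / 4 + math.pi / 2)

    def test_model2_reduces_to_model1_at_equal_phi(self, default_config):
        st = make_ring_state(n=12)
        m1 = frc.edge_forces_model1(st, default_config)
        m2 = frc.edge_forces_model2(st, default_config)
        phi = polar_angles(st.pos[m2.ring])
        radius = st.yolk_radius + st.particle_radius
        scale = radius * math.sin(phi.mean())
        assert np.allclose(m2.weights, m1.weights * scale, atol=1e-9)

    def test_lagging_cells_pulled_harder(self, default_config):
        st = make_ring_state(n=12)
        # lift one cell toward the animal pole (smaller phi = lagging)
        lifted = 3
        p = st.pos[lifted]
        phi = math.acos(p[2] / np.linalg.norm(p)) - 0.2
        theta = math.atan2(p[1], p[0])
        st.pos[lifted] = 3.09 * np.array(
            [math.sin(phi) * math.cos(theta), math.sin(phi) * math.sin(theta), math.cos(phi)]
        )
        out = frc.edge_forces_model2(st, default_config)
        mags = dict(zip(out.ring, np.linalg.norm(out.forces, axis=1)))
        others = [m for i, m in mags.items() if i != lifted]
        assert mags[lifted] > max(others)

    def test_model2_weights_sum_to_circumference(self, default_config, initialized_state):
        out = frc.edge_forces_model2(initialized_state, default_config)
        phi = polar_angles(initialized_state.pos[out.ring])
        radius = initialized_state.yolk_radius + initialized_state.particle_radius
        assert out.weights.sum() == pytest.approx(
            2 * math.pi * radius * math.sin(phi.mean())
        )


class TestIntegration:
    def test_zero_force_no_motion(self, hex_ring_state):
        before = hex_ring_state.pos.copy()
        frc.integrate_step(hex_ring_state, np.zeros_like(before), 0.1)
        assert np.array_equal(hex_ring_state.pos, before)

    def test_overdamped_displacement_law(self):
        st = SimulationState(
            np.zeros((1, 3)), np.array([0.1]), np.array([2.0]),
            np.zeros(1, bool), 0.09, 3.0,
        )
        f = np.array([[1.0, 0, 0]])
        frc.integrate_step(st, f, 0.05)
        assert np.allclose(st.pos, [[0.025, 0, 0]])  # |F| dt / drag

    def test_pair_relaxation_matches_exponential(self, default_config):
        # isolated bonded pair stretched by delta0 relaxes with rate 2k/gamma
        k, gamma, rest, delta0, dt = 0.5, 1.0, 1.0, 0.2, 1e-3
        pos = np.array([[0.0, 0, 0], [rest + delta0, 0, 0]])
        st = SimulationState(pos, np.full(2, rest / 2), np.full(2, gamma),
                             np.zeros(2, bool), 0.09, 3.0)
        st.add_bond(0, 1)
        cfg = default_config.replace(harmonic_yolk_evl_spring_constant=0.0)
        for _ in range(1000):
            f = frc.global_pair_forces(st, cfg)
            frc.integrate_step(st, f, dt)
        t = 1000 * dt
        expected = delta0 * math.exp(-2 * k * t / gamma)
        observed = np.linalg.norm(st.pos[1] - st.pos[0]) - rest
        assert observed == pytest.approx(expected, rel=5e-3)

    def test_spring_energy_non_increasing(self, default_config):
        pos = np.array([[0.0, 0, 0], [1.3, 0, 0]])
        st = SimulationState(pos, np.full(2, 0.5), np.ones(2),
                             np.zeros(2, bool), 0.09, 3.0)
        st.add_bond(0, 1)
        cfg = default_config.replace(harmonic_yolk_evl_spring_constant=0.0)
        prev = math.inf
        for _ in range(200):
            f = frc.global_pair_forces(st, cfg)
            frc.integrate_step(st, f, 0.01)
            d = np.linalg.norm(st.pos[1] - st.pos[0])
            energy = 0.5 * 0.5 * (d - 1.0) ** 2
            assert energy <= prev + 1e-12
            prev = energy

    def test_nonfinite_force_raises(self, hex_ring_state):
        f = np.zeros_like(hex_ring_state.pos)
        f[0, 0] = math.nan
        with pytest.raises(frc.NumericalBlowupError):
            frc.integrate_step(hex_ring_state, f, 0.1)
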