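"""Bond-angle energetics, Metropolis acceptance, and sweep invariants."""

import math

import numpy as np
import pytest

from epiboly import Config
from epiboly import remodeling as rem

from conftest import make_ring_state


class TestTargetAngle:
    @pytest.mark.parametrize("n, expected", [(3, math.pi / 3), (4, math.pi / 2),
                                             (6, 2 * math.pi / 3), (360, math.pi * (1 - 1 / 180))])
    def test_edge_polygon_angles(self, n, expected):
        assert rem.target_angle(n, edge=True) == pytest.approx(expected)

    def test_edge_limit_approaches_pi(self):
        assert rem.target_angle(10**6, edge=True) == pytest.approx(math.pi, abs=1e-5)

    def test_internal_is_sixty_degrees(self):
        assert rem.target_angle(edge=False) == math.pi / 3

    def test_too_small_margin_raises(self):
        with pytest.raises(ValueError):
            rem.target_angle(2, edge=True)


class TestBondPairEnergy:
    def test_zero_at_target(self):
        assert rem.bond_pair_energy([math.pi / 3] * 4, math.pi / 3) == 0.0

    def test_bisected_wide_angles(self):
        # two 120-degree flanking angles vs a 60-degree target: unbonded
        # energy 2*(pi/3)^2; a bond bisecting both zeroes it
        e_unb = rem.bond_pair_energy([2 * math.pi / 3] * 2, math.pi / 3)
        assert e_unb == pytest.approx(2 * (math.pi / 3) ** 2)
        assert e_unb == pytest.approx(2.1932, abs=1e-4)
        e_b = rem.bond_pair_energy([math.pi / 3] * 4, math.pi / 3)
        assert e_b == 0.0


class TestAccept:
    def test_non_positive_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(rem.accept(de, rng) for de in (0.0, -0.5, -100.0) for _ in range(100))

    def test_ln2_accepted_half_the_time(self):
        rng = np.random.default_rng(1)
        n = 10**5
        hits = sum(rem.accept(math.log(2), rng) for _ in range(n))
        # 3 sigma binomial window around p = 1/2
        sigma = math.sqrt(n * 0.5 * 0.5)
        assert abs(hits - 0.5 * n) < 3 * sigma

    @pytest.mark.parametrize("de", [0.5, 1.0, 2.0, 4.0])
    def test_frequency_matches_boltzmann_factor(self, de):
        rng = np.random.default_rng(int(10 * de))
        n = 10**5
        p = math.exp(-de)
        hits = sum(rem.accept(de, rng) for _ in range(n))
        sigma = math.sqrt(n * p * (1 - p))
        assert abs(hits - p * n) < 3 * sigma

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            rem.accept(math.nan, np.random.default_rng(0))


class TestDeltaE:
    def test_formation_and_breaking_are_antisymmetric(self, layered_state, default_config):
        # pick an internal pair that is not bonded, at matching margin count
        n_margin = int(layered_state.is_margin.sum())
        ring = layered_state.margin_ring()
        i = len(ring)          # internal cell
        j = i + 2              # same tier, not bonded
        assert not layered_state.bonded(i, j)
        de_form = rem.bond_formation_delta_e(layered_state, i, j, default_config, n_margin)
        layered_state.add_bond(i, j)
        de_break = -rem.bond_formation_delta_e(
            layered_state, i, j, default_config, n_margin, bond_exists=True
        )
        assert de_form == pytest.approx(-de_break, abs=1e-12)

    def test_delta_e_finite_on_fixture(self, layered_state, default_config):
        n_margin = int(layered_state.is_margin.sum())
        de = rem.bond_formation_delta_e(layered_state, 0, 26, default_config, n_margin)
        assert math.isfinite(de)


def _sweep_state():
    return make_ring_state(n=24, interior_rows=4)


class TestSweep:
    def test_lambda_zero_accepts_every_valid_candidate(self, default_config):
        state = _sweep_state()
        cfg = default_config.replace(lambda_bond_angle=0.0, lambda_edge_bond_angle=0.0)
        rng = np.random.default_rng(7)
        events = rem.remodel_sweep(state, cfg, rng)
        assert events, "expected some valid candidates"
        assert all(ev.accepted for ev in events)
        assert all(ev.delta_e == 0.0 for ev in events)

    def test_sweep_preserves_topology(self, default_config):
        state = _sweep_state()
        rng = np.random.default_rng(11)
        for _ in range(30):
            rem.remodel_sweep(state, default_config, rng)
            assert state.validate_topology() == []

    def test_ring_changes_match_leave_join_counts(self, default_config):
        state = _sweep_state()
        rng = np.random.default_rng(13)
        for _ in range(20):
            before = int(state.is_margin.sum())
            events = rem.remodel_sweep(state, default_config, rng)
            leaves = sum(1 for e in events if e.type == "leave_margin" and e.accepted)
            joins = sum(1 for e in events if e.type == "join_margin" and e.accepted)
            after = int(state.is_margin.sum())
            assert after - before == joins - leaves

    def test_min_bond_floor_never_violated(self, default_config):
        state = _sweep_state()
        rng = np.random.default_rng(17)
        for _ in range(30):
            rem.remodel_sweep(state, default_config, rng)
            assert min(state.degree(i) for i in range(state.n_cells)) >= 3

    def test_high_lambda_suppresses_uphill_acceptance(self, default_config):
        # with lambda = 1000 on a near-regular fixture, accepted moves are
        # (almost) exclusively dE <= 0; rearrangement totals drop vs default
        rng_hi = np.random.default_rng(23)
        rng_lo = np.random.default_rng(23)
        hi = default_config.replace(lambda_bond_angle=1e3, lambda_edge_bond_angle=1e3)
        state_hi, state_lo = _sweep_state(), _sweep_state()
        n_hi = n_lo = 0
        for _ in range(15):
            n_hi += sum(e.accepted for e in rem.remodel_sweep(state_hi, hi, rng_hi))
            n_lo += sum(e.accepted for e in rem.remodel_sweep(state_lo, default_config, rng_lo))
        assert n_hi < n_lo

    def test_reproducible_under_fixed_seed(self, default_config):
        outs = []
        for _ in range(2):
            state = _sweep_state()
            rng = np.random.default_rng(29)
            evs = []
            for _ in range(10):
                evs.extend(rem.remodel_sweep(state, default_config, rng))
            outs.append([(e.type, e.focal, e.partner, e.accepted) for e in evs])
        assert outs[0] == outs[1]

    def test_convex_margin_cell_cannot_leave(self, default_config):
        # on a perfect latitude ring every cell has phi equal to its
        # neighbors: never "unambiguously concave", so no leave events
        state = make_ring_state(n=24, interior_rows=2)
        rng = np.random.default_rng(31)
        events = []
        for _ in range(10):
            events.extend(rem.remodel_sweep(state, default_config, rng))
        assert not any(e.type == "leave_margin" for e in events)
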