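"""Deposition kernel unit and property tests."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aerotree import (AIR_BODY, ModelValidityWarning, Particle, TubeSpec,
                      capture_minimizing_flow, cunningham_correction,
                      deposition_probabilities, diffusion_parameter,
                      diffusion_probability, escape_probability,
                      impaction_probability, reynolds_number,
                      sedimentation_probability, settling_velocity,
                      stokes_number)

from oracles import grid_argmin_flow, settling_monte_carlo


class TestCunningham:
    def test_continuum_limit(self):
        assert cunningham_correction(1.0) == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("d_p, expected", [
        (8e-6, 1.0220),       # micron particle: slight slip
        (0.035e-6, 7.2433),   # nanoparticle: large slip
    ])
    def test_hand_values(self, d_p, expected):
        assert cunningham_correction(d_p, 0.070e-6) == pytest.approx(
            expected, rel=1e-3)

    def test_nanoparticle_slip_exceeds_five(self):
        assert cunningham_correction(0.035e-6, 0.070e-6) > 5.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            cunningham_correction(0.0)
        with pytest.raises(ValueError):
            cunningham_correction(1e-6, -1.0)


class TestSettlingVelocity:
    def test_stokes_law_value(self, air):
        # rho_p g d_p^2 C_c / (18 mu) by independent arithmetic
        v = settling_velocity(Particle(8e-6, 1000.0), air)
        assert v == pytest.approx(1.876e-3, rel=1e-3)

    def test_quadratic_diameter_scaling(self, air):
        # with slip ~1, doubling d_p quadruples v_s
        v1 = settling_velocity(Particle(10e-6, 1000.0), air)
        v2 = settling_velocity(Particle(20e-6, 1000.0), air)
        c1 = cunningham_correction(10e-6)
        c2 = cunningham_correction(20e-6)
        assert v2 / v1 == pytest.approx(4.0 * c2 / c1, rel=1e-12)

    def test_vanishes_with_diameter(self, air):
        assert settling_velocity(Particle(1e-9, 1000.0), air) < 1e-6


class TestSedimentation:
    def test_vertical_tube_never_settles(self, air, micron_particle):
        tube = TubeSpec(0.063, 0.0135, angle=-math.pi / 2)
        p_s, kappa, _ = sedimentation_probability(1e-4, tube, micron_particle, air)
        assert p_s == 0.0
        assert kappa == 0.0

    def test_kappa_one_is_certain_capture(self):
        from aerotree.physics import _p_s_of_kappa
        assert _p_s_of_kappa(1.0) == pytest.approx(1.0, abs=1e-12)
        assert _p_s_of_kappa(5.0) == pytest.approx(1.0, abs=1e-12)

    def test_zero_flow_is_certain_capture(self, air, micron_particle,
                                          bronchus_tube):
        p_s, kappa, _ = sedimentation_probability(0.0, bronchus_tube,
                                                  micron_particle, air)
        assert p_s == 1.0

    def test_negative_flow_rejected(self, air, micron_particle, bronchus_tube):
        with pytest.raises(ValueError):
            sedimentation_probability(-1.0, bronchus_tube, micron_particle, air)

    @pytest.mark.parametrize("Q, seed", [
        (1e-4, 0), (3e-5, 1), (5e-4, 2), (2e-4, 3), (6e-5, 4),
    ])
    def test_monte_carlo_settling_oracle(self, air, micron_particle, Q, seed):
        """Closed form agrees with direct particle tracking within 3 SE."""
        tube = TubeSpec(0.063, 0.0135, 0.0)
        p_s, _, _ = sedimentation_probability(Q, tube, micron_particle, air)
        v_s = settling_velocity(micron_particle, air)
        mc, se = settling_monte_carlo(Q, tube.length, tube.diameter, v_s,
                                      n=100_000, seed=seed)
        assert abs(p_s - mc) < 3.0 * se + 1e-9

    def test_validity_warning_for_large_particles(self, air):
        # a 200 um particle is far outside d_p << d_s at low flow
        tube = TubeSpec(0.063, 0.0135, angle=math.pi / 6)
        with pytest.warns(ModelValidityWarning):
            sedimentation_probability(1e-6, tube, Particle(200e-6, 1000.0), air)


class TestStokesAndImpaction:
    def test_zero_flow_zero_stokes(self, air, micron_particle):
        assert stokes_number(0.0, 0.0135, micron_particle, air) == 0.0

    def test_hand_value_below_linear_bound(self, air, micron_particle):
        stk = stokes_number(1e-3, 0.0135, micron_particle, air)
        assert stk == pytest.approx(0.0990, rel=1e-3)
        assert stk < 0.15

    def test_nanoparticle_stokes_negligible(self, air, nanoparticle):
        assert stokes_number(1e-3, 0.0135, nanoparticle, air) < 0.01

    def test_intercept(self):
        assert impaction_probability(0.0) == 0.0023

    def test_linear_value(self):
        assert impaction_probability(0.1) == pytest.approx(0.1629, abs=1e-12)

    def test_clipped_above_one(self):
        with pytest.warns(ModelValidityWarning):
            assert impaction_probability(10.0) == 1.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            impaction_probability(-0.1)


class TestDiffusion:
    def test_parameter_hand_value(self, air, nanoparticle, bronchus_tube):
        delta = diffusion_parameter(bronchus_tube, 1e-4, nanoparticle, air)
        assert delta == pytest.approx(5.115e-8, rel=1e-3)

    def test_parameter_inverse_in_flow(self, air, nanoparticle, bronchus_tube):
        d1 = diffusion_parameter(bronchus_tube, 1e-4, nanoparticle, air)
        d2 = diffusion_parameter(bronchus_tube, 2e-4, nanoparticle, air)
        assert d1 / d2 == pytest.approx(2.0, rel=1e-12)

    def test_parameter_ignores_density_and_angle(self, air, bronchus_tube):
        d1 = diffusion_parameter(bronchus_tube, 1e-4, Particle(1e-6, 500.0), air)
        d2 = diffusion_parameter(bronchus_tube, 1e-4, Particle(1e-6, 2000.0), air)
        tilted = TubeSpec(bronchus_tube.length, bronchus_tube.diameter,
                          angle=math.pi / 4)
        d3 = diffusion_parameter(tilted, 1e-4, Particle(1e-6, 500.0), air)
        assert d1 == d2 == d3

    def test_certain_capture_at_cutoff(self):
        assert diffusion_probability(0.16853) == 1.0
        assert diffusion_probability(0.5) == 1.0

    def test_zero_delta(self):
        assert diffusion_probability(0.0) == pytest.approx(0.0009, abs=1e-12)

    def test_four_term_expansion_value(self):
        # independent evaluation of the four-exponential sum at Delta = 0.05
        assert diffusion_probability(0.05) == pytest.approx(0.60479079, rel=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            diffusion_probability(-1e-3)


class TestEscapeCombination:
    @pytest.mark.parametrize("ps, pi, pd, pe", [
        (0.0, 0.0, 0.0, 1.0),
        (1.0, 0.3, 0.7, 0.0),
        (0.1, 0.2, 0.3, 0.504),
    ])
    def test_product_rule(self, ps, pi, pd, pe):
        got, cap = escape_probability(ps, pi, pd)
        assert got == pytest.approx(pe, abs=1e-12)
        assert cap == pytest.approx(1.0 - pe, abs=1e-12)

    @given(st.tuples(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1)))
    @settings(max_examples=50, derandomize=True)
    def test_symmetric_in_mechanisms(self, probs):
        a, b, c = probs
        assert escape_probability(a, b, c)[0] == \
            pytest.approx(escape_probability(c, a, b)[0], rel=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            escape_probability(1.1, 0.0, 0.0)


class TestReynolds:
    def test_hand_value(self, air):
        assert reynolds_number(5e-4, 0.0135, air) == pytest.approx(2829.4, rel=1e-3)

    def test_linearity(self, air):
        assert reynolds_number(2e-4, 0.0135, air) == \
            pytest.approx(2 * reynolds_number(1e-4, 0.0135, air), rel=1e-12)

    def test_zero_flow(self, air):
        assert reynolds_number(0.0, 0.0135, air) == 0.0


class TestCombinedKernels:
    @given(st.floats(1e-7, 1e-3), st.floats(0.2e-6, 10e-6),
           st.floats(-math.pi / 2, math.pi / 2))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_probabilities_always_in_unit_interval(self, Q, d_p, angle):
        tube = TubeSpec(0.05, 0.01, angle=angle)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            probs = deposition_probabilities(Q, tube, Particle(d_p, 1000.0),
                                             AIR_BODY)
        for p in (probs.p_s, probs.p_i, probs.p_d, probs.p_e, probs.p_c):
            assert 0.0 <= p <= 1.0
        assert probs.p_e == pytest.approx(
            (1 - probs.p_s) * (1 - probs.p_i) * (1 - probs.p_d), rel=1e-12)

    def test_monotonicity_in_flow(self, air, micron_particle, bronchus_tube):
        """p_s and p_d fall with flow, p_i rises (log sweep)."""
        qs = np.logspace(-7, -3, 60)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            all_probs = [deposition_probabilities(q, bronchus_tube,
                                                  micron_particle, air)
                         for q in qs]
        ps = [p.p_s for p in all_probs]
        pi = [p.p_i for p in all_probs]
        pd = [p.p_d for p in all_probs]
        assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))
        assert all(a <= b + 1e-15 for a, b in zip(pi, pi[1:]))
        assert all(a >= b - 1e-15 for a, b in zip(pd, pd[1:]))


class TestOptimalFlow:
    def test_micron_interior_minimum(self, air, micron_particle, bronchus_tube):
        """The 8 um tradeoff has an interior argmin near 0.1-0.2 L/s."""
        q_star = capture_minimizing_flow(bronchus_tube, micron_particle, air)
        assert 0.5e-4 < q_star < 4e-4  # within a factor of 2 of 0.2 L/s

    def test_nanoparticle_high_flow_regime(self, air, nanoparticle,
                                           bronchus_tube):
        """Nanoparticle capture is minimized at high flow.

        The diffusion-dominated decline puts the optimum far above the
        slow-inhalation regime; the residual impaction slope makes the
        curve nearly flat there, so capture at the maximum admissible
        flow stays within ~10% of the minimum.
        """
        q_star = capture_minimizing_flow(bronchus_tube, nanoparticle, air)
        assert q_star > 1e-4  # above 0.1 L/s
        p_min = deposition_probabilities(q_star, bronchus_tube, nanoparticle,
                                         air).p_c
        p_max = deposition_probabilities(1e-3, bronchus_tube, nanoparticle,
                                         air).p_c
        p_low = deposition_probabilities(1e-6, bronchus_tube, nanoparticle,
                                         air).p_c
        assert p_max < 1.1 * p_min
        assert p_low > 2.0 * p_max

    def test_diffusion_sedimentation_part_monotone(self, air, nanoparticle,
                                                   bronchus_tube):
        """Without the impaction term the nanoparticle capture decreases
        monotonically over the whole admissible range."""
        qs = np.logspace(-7, -3, 80)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ModelValidityWarning)
            pc = [1 - (1 - deposition_probabilities(q, bronchus_tube,
                                                    nanoparticle, air).p_s)
                  * (1 - deposition_probabilities(q, bronchus_tube,
                                                  nanoparticle, air).p_d)
                  for q in qs]
        assert all(a >= b - 1e-15 for a, b in zip(pc, pc[1:]))

    def test_matches_grid_oracle(self, air, micron_particle, bronchus_tube):
        def p_c(q):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ModelValidityWarning)
                return deposition_probabilities(q, bronchus_tube,
                                                micron_particle, air).p_c
        brute = grid_argmin_flow(p_c, 1e-7, 1e-3, n=2000)
        q_star = capture_minimizing_flow(bronchus_tube, micron_particle, air)
        # agree within one step of the 2000-point log grid
        step = (1e-3 / 1e-7) ** (1 / 1999)
        assert brute / step <= q_star <= brute * step

    def test_invalid_range_rejected(self, air, micron_particle, bronchus_tube):
        with pytest.raises(ValueError):
            capture_minimizing_flow(bronchus_tube, micron_particle, air,
                                    q_range=(1e-3, 1e-7))
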