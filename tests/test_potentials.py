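import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kinkwlc.potentials import (
    BendPotential,
    ChainSpec,
    Family,
    bend_energy,
    calibrate_rigidity,
    joint_partition_function,
    kink_statistics,
    mean_cos_theta,
    persistence_length,
    theta_crossover,
    theta_cut_from_b,
)

from conftest import A_NM, L_NM


class TestBendEnergy:
    @pytest.mark.parametrize(
        "pot_kw, theta, expected, tol",
        [
            (dict(family="quadratic", g=141.2), 0.0, 0.0, 0.0),
            (dict(family="quadratic", g=141.2), 0.1, 0.706, 1e-3),
            # at theta = 1 rad the harmonic branch costs ~70 kT, so the
            # kinkable joint sits on its plateau
            (dict(family="kinkable", g=141.2, h=12.0, b=0.3), 1.0, 12.0, 0.0),
            (dict(family="linear", alpha=20.0), 0.5, 10.0, 0.0),
        ],
    )
    def test_pointwise_values(self, pot_kw, theta, expected, tol):
        pot = BendPotential(**pot_kw)
        assert bend_energy(pot, theta) == pytest.approx(expected, abs=tol)

    def test_domain_error_outside_0_pi(self, quad):
        with pytest.raises(ValueError):
            bend_energy(quad, -0.5)
        with pytest.raises(ValueError):
            bend_energy(quad, 3.5)

    @given(
        g=st.floats(0.0, 500.0),
        h=st.floats(0.0, 30.0),
        b=st.sampled_from([0.3, 0.5, 1.0]),
        theta=st.floats(0.0, math.pi),
    )
    @settings(max_examples=200, deadline=None)
    def test_energy_properties(self, g, h, b, theta):
        """E(0) = 0, energy finite, and the kink branch never exceeds the stack."""
        pot = BendPotential(family=Family.KINKABLE, g=g, h=h, b=b)
        e = bend_energy(pot, theta)
        assert np.isfinite(e)
        assert bend_energy(pot, 0.0) == 0.0
        assert e <= 0.5 * g * theta**2 + 1e-12

    def test_monotone_beyond_theta_cut(self, kink12):
        thetas = np.linspace(kink12.theta_cut, math.pi, 50)
        e = bend_energy(kink12, thetas)
        assert np.all(np.diff(e) >= -1e-12)

    def test_crossover_angle(self, kink12):
        t = theta_crossover(kink12)
        assert t == pytest.approx(math.sqrt(2 * 12.0 / kink12.g))
        eps = 1e-6
        assert bend_energy(kink12, t + eps) == pytest.approx(12.0)
        assert bend_energy(kink12, t - eps) < 12.0

    def test_theta_cut_anchors(self):
        assert theta_cut_from_b(0.3) == pytest.approx(math.pi / 2)
        assert theta_cut_from_b(1.0) == pytest.approx(math.pi)


class TestCalibration:
    def test_freely_jointed_limit(self):
        pot = calibrate_rigidity(Family.QUADRATIC, a=L_NM, l=L_NM)
        assert pot.g == 0.0

    def test_stiff_limit_matches_a_over_l(self, quad):
        # Eq-style proportionality g ~ a/l holds to ~1% at a/l ~ 140
        assert quad.g == pytest.approx(A_NM / L_NM, rel=0.02)

    def test_linear_family_regression(self, linear_pot):
        # value frozen from the quadrature + root-finding oracle
        assert linear_pot.alpha == pytest.approx(20.4824, abs=2e-3)

    def test_infeasible_below_segment_length(self):
        with pytest.raises(ValueError):
            calibrate_rigidity(Family.QUADRATIC, a=0.2, l=0.34)

    @pytest.mark.parametrize("a", [1.0, 5.0, 20.0, 48.0, 100.0])
    @pytest.mark.parametrize("family", [Family.QUADRATIC, Family.LINEAR])
    def test_roundtrip_identity(self, a, family):
        pot = calibrate_rigidity(family, a=a, l=L_NM)
        assert persistence_length(pot, L_NM) == pytest.approx(a, rel=1e-4)

    def test_persistence_length_freely_jointed(self):
        pot = BendPotential(family=Family.QUADRATIC, g=0.0)
        assert persistence_length(pot, L_NM) == pytest.approx(L_NM)

    def test_kink_branch_barely_shifts_persistence_length(self, quad, kink16):
        a_quad = persistence_length(quad, L_NM)
        a_kink = persistence_length(kink16, L_NM)
        assert abs(a_kink - a_quad) / a_quad < 0.01


class TestPartitionFunction:
    def test_freely_jointed_total(self):
        pot = BendPotential(family=Family.QUADRATIC, g=0.0)
        assert joint_partition_function(pot, "all") == pytest.approx(2.0, rel=1e-8)

    def test_stiff_gaussian_limit(self, quad):
        # Z ~ 1/g for a stiff harmonic joint
        z = joint_partition_function(quad, "all")
        assert z == pytest.approx(1.0 / quad.g, rel=0.01)

    def test_kink_branch_weight(self, kink12):
        # plateau from the crossover to pi/2 plus the thin wall tail carries
        # essentially the full e^-h (the idealised flat-plateau value)
        z = joint_partition_function(kink12, "kink")
        assert z == pytest.approx(math.exp(-12.0), rel=0.05)

    def test_branches_sum_to_total(self, kink16):
        z_all = joint_partition_function(kink16, "all")
        z_k = joint_partition_function(kink16, "kink")
        z_s = joint_partition_function(kink16, "stack")
        assert z_k + z_s == pytest.approx(z_all, rel=1e-8)

    def test_mean_cos_consistency(self, kink12):
        assert -1.0 < mean_cos_theta(kink12) < 1.0


class TestKinkThermodynamics:
    def test_free_energy_offset_h12(self, kink12):
        """The kink's angular breadth lowers its free energy ~5 kT below h."""
        s = kink_statistics(kink12)
        assert 12.0 - s["delta_f_kt"] == pytest.approx(5.0, abs=0.5)

    def test_opening_probability_h16(self, kink16):
        s = kink_statistics(kink16)
        assert 0.5e-5 <= s["p_kink"] <= 2.0e-5

    def test_free_energy_kcal_h16(self, kink16):
        s = kink_statistics(kink16)
        assert s["delta_f_kcal_mol"] == pytest.approx(7.0, rel=0.10)


class TestConfigRoundTrip:
    @given(
        family=st.sampled_from(list(Family)),
        g=st.floats(0.0, 300.0),
        h=st.floats(0.0, 20.0),
        b=st.floats(0.1, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_lossless(self, family, g, h, b):
        pot = BendPotential(family=family, g=g, alpha=min(g, 50.0), h=h, b=b)
        again = BendPotential.from_config(pot.to_config())
        assert again == pot


class TestChainSpec:
    def test_joint_counts(self, quad):
        lin = ChainSpec(n_bp=70, topology="linear", joint_potential=quad)
        circ = ChainSpec(n_bp=70, topology="circular", joint_potential=quad)
        assert lin.n_joints == 69
        assert circ.n_joints == 70
        assert lin.n_segments == circ.n_segments == 70

    def test_two_bp_has_single_joint(self, quad):
        assert ChainSpec(n_bp=2, topology="linear", joint_potential=quad).n_joints == 1

    def test_nick_assignment(self, quad, nick8):
        spec = ChainSpec(
            n_bp=100, topology="circular", joint_potential=quad,
            nick_potential=nick8, nick_index=0,
        )
        assert spec.potential_at(0) is nick8
        assert spec.potential_at(1) is quad

    def test_invalid_nick_index(self, quad, nick8):
        with pytest.raises(ValueError):
            ChainSpec(
                n_bp=10, topology="linear", joint_potential=quad,
                nick_potential=nick8, nick_index=40,
            )
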