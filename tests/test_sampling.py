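import math

import numpy as np
import pytest
from scipy import stats as sps

from kinkwlc.potentials import (
    BendPotential,
    Family,
    joint_partition_function,
    mean_cos_theta,
    theta_crossover,
)
from kinkwlc.sampling import (
    Conformation,
    EnsembleRun,
    JointAngleSampler,
    linear_end_states,
    regular_polygon,
    sample_circular_chain,
    sample_joint_angle,
    sample_linear_chain,
)

from conftest import A_NM, L_NM, circular_spec, linear_spec


class TestJointAngleSampler:
    def test_freely_jointed_cos_mean(self, rng):
        pot = BendPotential(family=Family.QUADRATIC, g=0.0)
        th = sample_joint_angle(pot, rng, 200_000)
        c = np.cos(th)
        assert abs(c.mean()) < 3 * c.std() / math.sqrt(len(c))

    def test_stiff_second_moment(self, quad, rng):
        # Gaussian limit: <theta^2> ~ 2/g
        th = sample_joint_angle(quad, rng, 200_000)
        assert (th**2).mean() == pytest.approx(2.0 / quad.g, rel=0.02)

    def test_kink_fraction_matches_partition_functions(self, kink12, rng):
        th = sample_joint_angle(kink12, rng, 2_000_000)
        frac = float((th > theta_crossover(kink12)).mean())
        expected = joint_partition_function(kink12, "kink") / joint_partition_function(
            kink12, "all"
        )
        se = math.sqrt(expected * (1 - expected) / len(th))
        assert abs(frac - expected) < 3 * se + 1e-7

    def test_histogram_matches_quadrature_density(self, kink12, rng):
        """Chi-square test of 1e6 draws against the tabulated density."""
        sampler = JointAngleSampler(kink12)
        th = sampler.sample(rng, 1_000_000)
        edges = np.linspace(0, math.pi, 40)
        counts, _ = np.histogram(th, bins=edges)
        # expected mass per bin from the sampler's own CDF table (quadrature)
        cdf_at = np.interp(edges, sampler.theta, sampler.cdf)
        expected = np.diff(cdf_at) * len(th)
        keep = expected > 10
        chi2 = ((counts[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = sps.chi2.sf(chi2, keep.sum() - 1)
        assert p > 0.001

    def test_mc_vs_quadrature_mean_cos(self, linear_pot, rng):
        th = sample_joint_angle(linear_pot, rng, 1_000_000)
        c = np.cos(th)
        se = c.std(ddof=1) / math.sqrt(len(c))
        assert abs(c.mean() - mean_cos_theta(linear_pot)) < 3 * se


class TestLinearChains:
    def test_two_bp_single_joint_density(self, quad, rng):
        """A 2-bp chain's end angle is exactly the one-joint density."""
        u = sample_linear_chain(linear_spec(2, quad), 100_000, rng_seed=7)
        theta = np.arccos(np.clip(np.einsum("ij,ij->i", u[:, 0], u[:, 1]), -1, 1))
        sampler = JointAngleSampler(quad)
        ks = sps.ks_1samp(theta, lambda t: np.interp(t, sampler.theta, sampler.cdf))
        assert ks.statistic < 0.01

    def test_tangent_correlation_decay(self, quad, rng):
        """<cos Theta(k joints)> = (1 - l/a)^k, the discrete-chain decay."""
        m = 141  # about one persistence length of joints
        n = 150_000
        for x, w in linear_end_states([quad] * m, n, rng):
            pass
        c = w[:, 2]
        se = c.std(ddof=1) / math.sqrt(n)
        assert c.mean() == pytest.approx((1 - L_NM / A_NM) ** m, abs=3 * se)

    def test_unit_norm_tangents(self, quad):
        u = sample_linear_chain(linear_spec(30, quad), 500, rng_seed=3)
        assert np.allclose(np.linalg.norm(u, axis=2), 1.0, atol=1e-9)

    def test_nick_joint_kink_fraction_unstressed(self, quad, nick8, rng):
        """In a linear chain the nick joint kinks at its one-joint rate."""
        spec = linear_spec(21, quad, nick_potential=nick8, nick_index=10)
        u = sample_linear_chain(spec, 150_000, rng_seed=5)
        cth = np.einsum("ij,ij->i", u[:, 10], u[:, 11])
        frac = float((np.arccos(np.clip(cth, -1, 1)) > theta_crossover(nick8)).mean())
        zk = joint_partition_function(nick8, "kink")
        za = joint_partition_function(nick8, "all")
        expected = zk / za
        se = math.sqrt(expected * (1 - expected) / len(cth))
        assert abs(frac - expected) < 3 * se


class TestCircularChains:
    def test_regular_polygon_geometry(self):
        c = Conformation(regular_polygon(70), topology="circular")
        assert np.allclose(c.joint_angles, 2 * math.pi / 70, atol=1e-12)
        assert c.closure_defect(L_NM) < 1e-12

    def test_rejects_tiny_circles(self, quad):
        with pytest.raises(ValueError):
            sample_circular_chain(circular_spec(10, quad), EnsembleRun(n_samples=10))

    def test_quadratic_ring_energy_equipartition(self, quad):
        """Mean ring energy = ground state + kT/2 per free bending mode.

        A 70-segment ring has 140 tangent degrees of freedom minus 3
        closure constraints and 3 global rotations: <E> ~ E_circle + 67 kT.
        """
        res = sample_circular_chain(
            circular_spec(70, quad),
            EnsembleRun(n_samples=20_000, burn_in=5_000, rng_seed=2),
        )
        ground = 0.5 * quad.g * 70 * (2 * math.pi / 70) ** 2
        assert res.energy.mean() == pytest.approx(ground + 67.0, abs=2.0)
        assert 0.2 < res.acceptance_rate < 0.8

    def test_closure_preserved(self, quad):
        res = sample_circular_chain(
            circular_spec(64, quad),
            EnsembleRun(n_samples=2_000, burn_in=1_000, rng_seed=9),
        )
        assert res.final.closure_defect(L_NM) < 1e-6 * L_NM
        assert np.allclose(np.linalg.norm(res.final.tangents, axis=1), 1.0, atol=1e-9)

    def test_seeded_runs_are_reproducible(self, quad):
        run = EnsembleRun(n_samples=500, burn_in=200, rng_seed=42)
        a = sample_circular_chain(circular_spec(40, quad), run)
        b = sample_circular_chain(circular_spec(40, quad), run)
        assert np.array_equal(a.energy, b.energy)
        assert np.array_equal(a.final.tangents, b.final.tangents)

    def test_detailed_balance_two_seed_agreement(self):
        """Single-joint angle distribution of a 12-ring agrees across seeds.

        Uses a moderately flexible ring (g = 10) whose joint-angle
        correlation time is short enough that two independent runs can
        resolve a Kolmogorov-Smirnov distance of 0.01; stiff-ring
        stationarity is checked separately through energy equipartition.
        """
        pot = BendPotential(family=Family.QUADRATIC, g=10.0)
        samples = []
        for seed in (101, 202):
            res = sample_circular_chain(
                circular_spec(12, pot),
                EnsembleRun(n_samples=120_000, burn_in=10_000, thinning=10, rng_seed=seed),
            )
            samples.append(res.monitor_theta)
        ks = sps.ks_2samp(samples[0], samples[1])
        assert ks.statistic < 0.01

    def test_replica_exchange_preserves_harmonic_marginals(self, quad, kink16):
        """With exchange on, non-kink observables match the plain-MC run."""
        spec = circular_spec(70, kink16)
        r1 = sample_circular_chain(
            spec, EnsembleRun(n_samples=8_000, burn_in=4_000, rng_seed=3, n_replicas=1)
        )
        r4 = sample_circular_chain(
            spec, EnsembleRun(n_samples=8_000, burn_in=4_000, rng_seed=4, n_replicas=4)
        )
        # total energy distributions should agree within a few kT
        assert r1.energy.mean() == pytest.approx(r4.energy.mean(), abs=4.0)
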