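import numpy as np
import pytest

from kinkwlc.ligation import (
    DIMER_FACTOR,
    KineticsSeries,
    LigaseTitration,
    LigationKinetics,
    generate_kinetics_fixture,
    jfactor_from_kinetics,
    permissive_range_check,
    read_kinetics_table,
    write_kinetics_table,
)


class TestEstimator:
    def test_constant_ratio_recovers_exact_j(self):
        """C/D = 0.05 at all times with M0 = 1e-9 M gives j = 1e-10 M."""
        t = np.linspace(1, 10, 10)
        M0 = 1e-9
        D = 2e-12 * t
        series = KineticsSeries(t=t, C=0.05 * D, D=D, M0=M0)
        res = jfactor_from_kinetics(series)
        assert res.j == pytest.approx(DIMER_FACTOR * M0 * 0.05, rel=1e-9)

    def test_no_circles_means_zero_j(self):
        t = np.linspace(1, 10, 10)
        series = KineticsSeries(t=t, C=np.zeros(10), D=2e-12 * t, M0=1e-9)
        assert jfactor_from_kinetics(series).j == 0.0

    def test_all_zero_dimers_is_an_error(self):
        t = np.linspace(1, 10, 5)
        series = KineticsSeries(t=t, C=1e-12 * t, D=np.zeros(5), M0=1e-9)
        with pytest.raises(ZeroDivisionError):
            jfactor_from_kinetics(series)

    def test_roundtrip_within_ten_percent(self):
        """Synthetic series with 5% multiplicative noise, 12 points."""
        j_true, M0 = 1e-10, 1e-9
        series = generate_kinetics_fixture(j_true, M0, n_points=12, noise_cv=0.05, rng_seed=2)
        res = jfactor_from_kinetics(series)
        assert res.j == pytest.approx(j_true, rel=0.10)

    @pytest.mark.parametrize("noise_cv, tol", [(0.0, 1e-9), (0.02, 0.01), (0.05, 0.02)])
    def test_consistency_bias_shrinks_with_noise(self, noise_cv, tol):
        """Mean estimate over replicates converges to j_true as noise -> 0."""
        j_true, M0 = 2e-10, 1e-9
        est = [
            jfactor_from_kinetics(
                generate_kinetics_fixture(j_true, M0, 12, noise_cv, rng_seed=s)
            ).j
            for s in range(60)
        ]
        assert np.mean(est) == pytest.approx(j_true, rel=tol + 3 * np.std(est) / (60**0.5) / j_true)

    def test_nonmonotone_data_warns(self):
        t = np.linspace(1, 10, 10)
        D = 2e-12 * t
        C = 0.05 * D
        C[4] = C[3] * 0.5
        series = KineticsSeries(t=t, C=C, D=D, M0=1e-9)
        with pytest.warns(UserWarning, match="non-monotone"):
            jfactor_from_kinetics(series)

    def test_summary_table(self):
        series = generate_kinetics_fixture(1e-10, 1e-9, rng_seed=1)
        res = LigationKinetics(series).fit()
        text = res.summary()
        assert "j =" in text and "mol/L" in text
        assert res.params["j_mol_per_L"] == res.j
        assert res.bse["j_mol_per_L"] > 0

    def test_from_dataframe_constructor(self):
        series = generate_kinetics_fixture(1e-10, 1e-9, rng_seed=3)
        model = LigationKinetics.from_dataframe(series.to_frame(), M0=series.M0)
        assert model.fit().j == pytest.approx(jfactor_from_kinetics(series).j)

    def test_invalid_series_rejected(self):
        with pytest.raises(ValueError):
            KineticsSeries(t=[2.0, 1.0], C=[0, 0], D=[0, 0], M0=1e-9)
        with pytest.raises(ValueError):
            KineticsSeries(t=[1.0, 2.0], C=[0, 2e-9], D=[0, 0], M0=1e-9)


class TestPermissiveRange:
    def test_flat_titration_is_permissive(self):
        rng = np.random.default_rng(5)
        tit = LigaseTitration(
            ligase=np.array([1, 3, 10, 30, 100.0]),
            j_app=1e-9 * (1 + 0.03 * rng.standard_normal(5)),
            stderr=np.full(5, 5e-11),
        )
        assert permissive_range_check(tit).verdict == "permissive"

    def test_threefold_rise_is_violated(self):
        tit = LigaseTitration(
            ligase=np.array([1, 3, 10, 30, 100.0]),
            j_app=np.array([1.0, 1.4, 1.9, 2.5, 3.0]) * 1e-9,
            stderr=np.full(5, 5e-11),
        )
        assert permissive_range_check(tit).verdict == "violated"

    def test_two_points_insufficient(self):
        tit = LigaseTitration(ligase=np.array([1.0, 10.0]), j_app=np.array([1e-9, 1e-9]))
        with pytest.raises(ValueError):
            permissive_range_check(tit)

    def test_type_one_error_at_nominal_level(self):
        """Flat synthetic titrations are rarely flagged (alpha = 0.05)."""
        rng = np.random.default_rng(7)
        alpha, reps = 0.05, 200
        rejections = 0
        for _ in range(reps):
            j = 1e-9 * (1 + 0.05 * rng.standard_normal(6))
            tit = LigaseTitration(
                ligase=np.array([1, 2, 5, 15, 40, 100.0]),
                j_app=j,
                stderr=np.full(6, 5e-11),
            )
            if permissive_range_check(tit, alpha=alpha).verdict == "violated":
                rejections += 1
        assert rejections / reps <= alpha + 3 * (alpha * (1 - alpha) / reps) ** 0.5


class TestFixtureAndIO:
    def test_noiseless_fixture_has_exact_ratio(self):
        s = generate_kinetics_fixture(1e-10, 1e-9, noise_cv=0.0, rng_seed=0)
        np.testing.assert_allclose(s.C / s.D, 1e-10 / (DIMER_FACTOR * 1e-9))

    def test_zero_j_gives_zero_circles(self):
        s = generate_kinetics_fixture(0.0, 1e-9, noise_cv=0.05, rng_seed=0)
        assert np.all(s.C == 0.0)

    def test_fixture_is_seeded(self):
        a = generate_kinetics_fixture(1e-10, 1e-9, rng_seed=9)
        b = generate_kinetics_fixture(1e-10, 1e-9, rng_seed=9)
        np.testing.assert_array_equal(a.C, b.C)

    def test_table_roundtrip(self, tmp_path):
        s = generate_kinetics_fixture(1e-10, 1e-9, rng_seed=4)
        path = tmp_path / "series.tsv"
        write_kinetics_table(s, path)
        back = read_kinetics_table(path)
        np.testing.assert_allclose(back.C, s.C)
        np.testing.assert_allclose(back.t, s.t)
        assert back.M0 == pytest.approx(s.M0)
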