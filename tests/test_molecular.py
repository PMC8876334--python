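"""Molecular dielectrics: cavity fields, Langevin, Kirkwood, protein dipoles."""

import math

import numpy as np
import pytest

from prodep import (
    DEBYE,
    EPS_0,
    DebyeMode,
    DipoleEnsemble,
    Environment,
    ProteinRecord,
    SolventRef,
    cm_law_eps,
    dipole_from_beta,
    eps_from_polarizability,
    frohlich_eps_embedded,
    frohlich_eps_self,
    frohlich_msq_from_eps,
    generate_correlated_dipole_configs,
    gkp_from_b,
    kirkwood_frohlich_product,
    kirkwood_frohlich_solve,
    kirkwood_g,
    kirkwood_g_central,
    kirkwood_tetrahedral,
    langevin,
    lorentz_cavity_chi,
    maxwell_cavity_chi,
    moment_fluctuation_error,
    oncley_delta_eps,
    onsager_interface_moment,
    orientation_parameter,
    south_grant_delta_eps,
    south_grant_mixture_eps,
    two_polar_mixture_spectrum,
)


class TestClausiusMossottiLaw:
    def test_dilute_limit(self):
        assert cm_law_eps(0.0) == 1.0

    def test_closed_form_value(self):
        assert cm_law_eps(0.5) == pytest.approx(4.0)

    def test_mossotti_catastrophe(self):
        assert cm_law_eps(0.999999) > 1e6
        with pytest.raises(ValueError, match="[Cc]atastrophe"):
            cm_law_eps(1.0)
        with pytest.raises(ValueError):
            eps_from_polarizability(1.0)


class TestCavityFields:
    def test_vacuum_is_unity(self):
        assert lorentz_cavity_chi(1.0) == 1.0
        assert maxwell_cavity_chi(1.0) == 1.0

    def test_water_values(self):
        assert lorentz_cavity_chi(78.0) == pytest.approx(80.0 / 3.0)
        assert maxwell_cavity_chi(78.0) == pytest.approx(234.0 / 157.0)

    def test_maxwell_bounded_below_three_halves(self):
        assert maxwell_cavity_chi(1e9) == pytest.approx(1.5, abs=1e-8)
        for eps in (1.0, 2.0, 78.0, 1e4):
            assert 1.0 <= maxwell_cavity_chi(eps) < 1.5

    def test_lorentz_always_dominates_maxwell(self):
        for eps in np.linspace(1.0, 200.0, 50):
            assert lorentz_cavity_chi(eps) >= maxwell_cavity_chi(eps)

    def test_near_field_correction_term(self):
        assert lorentz_cavity_chi(78.0, s=0.1) == pytest.approx((78 + 2 + 7.7) / 3)


class TestLangevin:
    def test_small_argument_series(self):
        assert langevin(1e-3) == pytest.approx(1e-3 / 3, rel=1e-6)

    def test_bsa_orientation_parameter(self):
        x = orientation_parameter(710.0, 1e6, Environment(295.0))
        assert x == pytest.approx(0.58, abs=0.01)

    def test_saturation_regime_value(self):
        assert langevin(5.8) == pytest.approx(1 / math.tanh(5.8) - 1 / 5.8, rel=1e-12)
        assert langevin(5.8) == pytest.approx(0.8276, abs=1e-4)

    def test_odd_and_bounded(self):
        x = np.linspace(-50, 50, 101)
        L = langevin(x)
        assert np.allclose(L, -langevin(-x))
        assert np.all(np.abs(L) < 1.0)
        assert np.all(np.diff(L) > 0)


class TestOnsager:
    def test_vacuum_no_reaction_field(self):
        assert onsager_interface_moment(1.0, 1.0) == 0.0

    def test_water_nearly_cancels(self):
        assert onsager_interface_moment(78.0, 1.0) == pytest.approx(-154 / 157)

    def test_high_permittivity_limit(self):
        assert onsager_interface_moment(1e9, 2.5) == pytest.approx(-2.5, abs=1e-6)


class TestKirkwood:
    def test_single_dipole_is_unity(self):
        ens = DipoleEnsemble(vectors=[[1.0, 0, 0]], unit="debye")
        assert kirkwood_g(ens, 1.0) == pytest.approx(1.0)

    def test_parallel_dipoles_give_n(self):
        n = 7
        ens = DipoleEnsemble(vectors=[[0, 0, 2.0]] * n, unit="debye")
        assert kirkwood_g(ens, 2.0) == pytest.approx(float(n))

    def test_isotropic_random_dipoles_near_unity(self):
        # T configurations of N random unit dipoles: mean over configs -> 1
        rng = np.random.default_rng(11)
        T, N = 4000, 16
        v = rng.standard_normal((T, N, 3))
        v /= np.linalg.norm(v, axis=2, keepdims=True)
        g = kirkwood_g(DipoleEnsemble(vectors=v, kind="trajectory", unit="debye"), 1.0)
        assert g == pytest.approx(1.0, abs=3.0 / math.sqrt(T))

    def test_central_estimator_recovers_prescribed_correlation(self):
        z, c = 4, 0.35
        ens = generate_correlated_dipole_configs(5000, z=z, cos_theta=c, seed=5)
        g = kirkwood_g_central(ens, 1.0)
        # exact construction: central projection is c for each neighbour
        assert g == pytest.approx(1.0 + z * c, abs=1e-9)

    def test_central_estimator_uncorrelated(self):
        ens = generate_correlated_dipole_configs(20000, z=3, cos_theta=0.0, seed=6)
        g = kirkwood_g_central(ens, 1.0)
        assert g == pytest.approx(1.0, abs=3.0 * math.sqrt(3) / math.sqrt(20000))

    def test_zero_moment_rejected(self):
        ens = DipoleEnsemble(vectors=[[1.0, 0, 0]])
        with pytest.raises(ValueError):
            kirkwood_g(ens, 0.0)

    def test_tetrahedral_formula(self):
        assert kirkwood_tetrahedral(0, 104.5) == 1.0
        assert kirkwood_tetrahedral(4, 104.5) == pytest.approx(2.50, abs=0.005)
        assert kirkwood_tetrahedral(4, 180.0) == pytest.approx(1.0)


class TestKirkwoodFrohlich:
    def test_zero_density_gives_vacuum(self):
        assert kirkwood_frohlich_solve(0.0) == pytest.approx(1.0)

    def test_water_back_solve(self):
        assert kirkwood_frohlich_product(78.2) == pytest.approx(17.26, abs=0.01)

    def test_round_trip_exact(self):
        for eps in (1.0, 2.5, 31.0, 78.2, 500.0):
            P = kirkwood_frohlich_product(eps)
            assert kirkwood_frohlich_solve(P) == pytest.approx(eps, rel=1e-12)

    def test_monotone_in_density(self):
        P = np.linspace(0, 100, 200)
        eps = np.array([kirkwood_frohlich_solve(p) for p in P])
        assert np.all(np.diff(eps) > 0)


class TestFrohlichFluctuation:
    def test_zero_fluctuation_is_vacuum(self):
        assert frohlich_eps_self(0.0, 1e-26) == pytest.approx(1.0)
        assert frohlich_eps_embedded(0.0, 1e-26, eps_m=78.0) == pytest.approx(1.0)

    def test_embedded_reduces_to_self_consistent(self):
        # with eps_p = eps_m the embedding relation collapses to the
        # self-consistent one (the cavity factor becomes Maxwell's)
        env = Environment(295.0)
        V = 4 / 3 * math.pi * (2.4e-9) ** 3
        msq = frohlich_msq_from_eps(25.0, V, eps_m=25.0, env=env)
        assert frohlich_eps_self(msq, V, env) == pytest.approx(25.0, rel=1e-12)

    def test_inverse_forward_round_trip(self):
        env = Environment(295.0)
        V = 4 / 3 * math.pi * (2.4e-9) ** 3
        msq = frohlich_msq_from_eps(25.0, V, eps_m=78.0, env=env)
        assert frohlich_eps_embedded(msq, V, eps_m=78.0, env=env) == pytest.approx(
            25.0, rel=1e-9
        )


class TestMomentFluctuation:
    def test_zero_width(self):
        assert moment_fluctuation_error(145.0, 0.0) == 0.0

    def test_lysozyme_and_ubiquitin_at_most_4_percent(self):
        lys = moment_fluctuation_error(145.0, 29.0)
        ubi = moment_fluctuation_error(218.0, 37.0)
        assert lys == pytest.approx(4.0, abs=0.01)
        assert ubi == pytest.approx(2.88, abs=0.01)
        assert max(lys, ubi) <= 4.0 + 1e-9


class TestProteinBetaDispersion:
    @pytest.fixture
    def bsa(self):
        return ProteinRecord(
            name="bsa", molecular_weight=66000.0, mass_density=1.41, dipole_moment=710.0
        )

    def test_zero_moment_no_dispersion(self):
        rec = ProteinRecord(name="x", molecular_weight=1e4, dipole_moment=1e-12)
        assert oncley_delta_eps(rec, 10.0) == pytest.approx(0.0, abs=1e-20)

    def test_oncley_inverse_bsa(self):
        m = dipole_from_beta(21.0, 12.0, 66000.0, b=4.5, env=Environment(298.0))
        # exceeds the structural 710 D: the relation lumps the protein-water
        # correlation factor into b
        assert m == pytest.approx(1.1e3, rel=0.03)

    def test_linearity_in_concentration(self, bsa):
        assert oncley_delta_eps(bsa, 24.0) == pytest.approx(
            2 * oncley_delta_eps(bsa, 12.0), rel=1e-12
        )

    def test_forward_inverse_consistency(self, bsa):
        d = oncley_delta_eps(bsa, 12.0)
        assert dipole_from_beta(d, 12.0, 66000.0) == pytest.approx(710.0, rel=1e-12)

    def test_gkp_bridge_values(self):
        assert gkp_from_b(4.5, 0.5) == pytest.approx(1.0)
        assert gkp_from_b(4.5, 0.75) == pytest.approx(0.67, abs=0.005)

    def test_south_grant_equals_oncley_when_bridged(self, bsa):
        # h * g_kp = b/9 makes the two beta-dispersion relations identical
        for h in (0.5, 0.75):
            sg = south_grant_delta_eps(bsa, 12.0, h=h, g_kp=gkp_from_b(4.5, h))
            on = oncley_delta_eps(bsa, 12.0, b=4.5)
            assert sg == pytest.approx(on, rel=1e-12)

    def test_nonstandard_h_warns(self, bsa):
        with pytest.warns(UserWarning):
            south_grant_delta_eps(bsa, 12.0, h=0.6)


class TestSouthGrantMixture:
    WATER = SolventRef(eps_static=78.4, eps_inf=5.2)

    def test_no_protein_gives_solvent(self):
        assert south_grant_mixture_eps(
            0.0, 1.0, 500.0, 1e-21, self.WATER
        ) == pytest.approx(78.4)

    def test_monotone_in_protein_count(self):
        vals = [
            south_grant_mixture_eps(n, 1.0, 500.0, 1e-21, self.WATER)
            for n in (0.0, 1e3, 1e4, 1e5)
        ]
        assert vals == sorted(vals)
        assert vals[-1] > 78.4

    def test_small_concentration_linearization(self):
        # first-order increment equals N_p g_kp m^2/(3 kT eps_0 V)
        env = Environment(298.0)
        V = 1e-21
        m_si = 500.0 * DEBYE
        for n_p in (1.0, 10.0):
            S = n_p * 1.0 * m_si**2 / (3 * env.kT * EPS_0 * V)
            got = south_grant_mixture_eps(n_p, 1.0, 500.0, V, self.WATER, env) - 78.4
            assert got == pytest.approx(S, rel=0.01)


class TestTwoPolarMixture:
    P_MODE = DebyeMode(delta_eps=1.0, tau=160e-9)
    W_MODE = DebyeMode(delta_eps=1.0, tau=16e-12)

    def test_pure_water_limit(self):
        val = two_polar_mixture_spectrum(
            0.0, self.P_MODE, 1.0, 500.0, self.W_MODE, 2.67, 1.8, 1e3
        )
        assert val == pytest.approx(2.67 * 1.8**2)

    def test_pure_protein_limit(self):
        val = two_polar_mixture_spectrum(
            1.0, self.P_MODE, 1.0, 500.0, self.W_MODE, 2.67, 1.8, 1.0
        )
        assert val == pytest.approx(1.0 * 500.0**2, rel=1e-9)

    def test_intermediate_band_separates_terms(self):
        # at 250 MHz the protein term is dispersed away (>1e3 attenuation)
        # while the water term still sits within 0.1% of its static value
        f = 250e6
        omega = 2 * math.pi * f
        assert 1 + (omega * self.P_MODE.tau) ** 2 > 1e3
        assert 1 + (omega * self.W_MODE.tau) ** 2 < 1.001
        vp = 0.01
        val = two_polar_mixture_spectrum(
            vp, self.P_MODE, 1.0, 500.0, self.W_MODE, 2.67, 1.8, f
        )
        water_static = (1 - vp) * 2.67 * 1.8**2
        # residual protein tail contributes <0.5% here
        assert val == pytest.approx(water_static, rel=0.006)
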