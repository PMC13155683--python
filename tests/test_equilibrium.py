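"""Analytic equilibrium solver: closed forms, root-finding, ODE oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import repeco as rp
from conftest import integrate_mass, random_community, random_environment

grid_kinetics = st.builds(
    rp.SpeciesKinetics,
    a=st.sampled_from(list(np.linspace(50, 100, 21))),
    b=st.sampled_from(list(np.linspace(5, 10, 21))),
    c=st.sampled_from(list(np.linspace(1, 5, 21))),
)


class TestInvertGrowthRate:
    def test_closed_form_example(self):
        # a=72.5, b=6, c=5, r=1, phi=2: (bcr - (b+cr)phi - phi^2)/(2 a phi) = 4/290
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        x_hat = rp.invert_growth_rate(kin, 1.0, 2.0)
        assert x_hat == pytest.approx(4.0 / 290.0, rel=1e-12)
        assert rp.growth_rate(kin, 1.0, x_hat) == pytest.approx(2.0, rel=1e-12)

    def test_at_intrinsic_rate_concentration_is_zero(self):
        kin = rp.SpeciesKinetics(a=72.5, b=7.0, c=3.6)
        lam = rp.intrinsic_growth_rate(kin, 1.0)
        assert rp.invert_growth_rate(kin, 1.0, lam) == 0.0

    @given(kin=grid_kinetics, u=st.floats(0.05, 0.95), r=st.floats(0.25, 4.0))
    @settings(max_examples=60, deadline=None)
    def test_round_trip_identity(self, kin, u, r):
        lam = rp.intrinsic_growth_rate(kin, r)
        phi = u * lam
        x_hat = rp.invert_growth_rate(kin, r, phi)
        assert x_hat > 0
        assert rp.growth_rate(kin, r, x_hat) == pytest.approx(phi, rel=1e-12)

    def test_rejects_invalid_production(self):
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        lam = rp.intrinsic_growth_rate(kin, 1.0)
        with pytest.raises(ValueError):
            rp.invert_growth_rate(kin, 1.0, lam * 1.01)
        with pytest.raises(ValueError):
            rp.invert_growth_rate(kin, 1.0, 0.0)
        with pytest.raises(ValueError):
            rp.invert_growth_rate(rp.SpeciesKinetics(a=0.0, b=6.0, c=5.0), 1.0, 1.0)


class TestSpeciesEquilibriumMass:
    def test_excluded_species_holds_zero_mass(self):
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        lam = rp.intrinsic_growth_rate(kin, 1.0)
        assert rp.species_equilibrium_mass(kin, 1.0, lam) == 0.0
        assert rp.species_equilibrium_mass(kin, 1.0, lam + 1.0) == 0.0

    def test_chained_closed_form_example(self):
        # mu_hat = r c x_hat / phi = 5 * (4/290) / 2
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        assert rp.species_equilibrium_mass(kin, 1.0, 2.0) == pytest.approx(
            5.0 * (4.0 / 290.0) / 2.0, rel=1e-12
        )

    def test_low_production_asymptote_and_monotonicity(self):
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        r = 1.0
        # mu_hat ~ r c * b c r / (2 a phi^2) as phi -> 0+
        phi = 1e-8
        expected = r * kin.c * kin.b * kin.c * r / (2 * kin.a * phi**2)
        assert rp.species_equilibrium_mass(kin, r, phi) == pytest.approx(expected, rel=1e-6)
        lam = rp.intrinsic_growth_rate(kin, r)
        grid = np.linspace(0.01 * lam, 0.99 * lam, 40)
        masses = [rp.species_equilibrium_mass(kin, r, p) for p in grid]
        assert all(u > v for u, v in zip(masses, masses[1:]))


class TestEquilibriumPhi:
    def test_single_e_species_pins_production(self):
        kin = rp.SpeciesKinetics(a=0.0, b=7.0, c=3.6, label="E")
        for m in (0.5, 2.0, 10.0):
            sol = rp.equilibrium_phi([kin], rp.MassEnvironment(m=m, r=1.0))
            assert round(sol.phi_hat, 3) == 2.000
            assert sol.mu_hat[0] == pytest.approx(m, rel=1e-12)
            assert sol.resident_E == "E"

    def test_e_variant_community_production_and_survivors(self, table1_e, env):
        sol = rp.equilibrium_phi(table1_e, env)
        assert sol.phi_hat == pytest.approx(2.000, abs=5e-4)
        assert sol.resident_E == "3"
        # S-survivors are exactly the species with lambda above lambda_0
        expected = {"3"} | {
            k.label
            for k in table1_e
            if k.a > 0 and rp.intrinsic_growth_rate(k, env.r) > sol.phi_hat
        }
        assert set(sol.survivors) == expected

    def test_pure_s_root_matches_ode_oracle(self, table1, env):
        sol = rp.equilibrium_phi(table1, env)
        traj = integrate_mass(table1, env)
        assert traj.converged
        phi_ode = rp.normalized_production(traj.x[-1], table1, env)
        assert sol.phi_hat == pytest.approx(phi_ode, rel=1e-6)
        assert np.allclose(traj.mu[-1], sol.mu_hat, rtol=1e-6)

    def test_mass_balance_and_ratio_identities(self, table1, env):
        sol = rp.equilibrium_state(table1, env)
        assert sol.mu_hat.sum() == pytest.approx(env.m, rel=1e-10)
        for i, kin in enumerate(table1):
            if sol.labels[i] not in sol.survivors:
                continue
            assert sol.x_hat[i] / sol.mu_hat[i] == pytest.approx(
                sol.phi_hat / (env.r * kin.c), rel=1e-10
            )
            assert sol.y_hat[i] / sol.x_hat[i] == pytest.approx(
                (kin.c * env.r - sol.phi_hat) / (2 * sol.phi_hat), rel=1e-10
            )

    def test_survivor_growth_rates_bracket_production(self, table1, env):
        sol = rp.equilibrium_phi(table1, env)
        for i in range(len(table1)):
            lam = sol.lambdas[i]
            if sol.labels[i] in sol.survivors:
                assert lam > sol.phi_hat
            else:
                assert lam <= sol.phi_hat

    def test_phi_monotone_in_m_and_r(self, table1):
        phis_m = [
            rp.equilibrium_phi(table1, rp.MassEnvironment(m=m, r=1.0)).phi_hat
            for m in np.logspace(-1, 1, 7)
        ]
        assert all(u > v for u, v in zip(phis_m, phis_m[1:]))
        phis_r = [
            rp.equilibrium_phi(table1, rp.MassEnvironment(m=2.0, r=r)).phi_hat
            for r in np.logspace(-0.5, 0.5, 7)
        ]
        assert all(u < v for u, v in zip(phis_r, phis_r[1:]))

    def test_total_mass_strictly_decreasing_in_phi(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            kins = random_community(rng)
            env = random_environment(rng)
            lam_max = max(rp.intrinsic_growth_rate(k, env.r) for k in kins)
            grid = np.linspace(0.01 * lam_max, 0.999 * lam_max, 25)
            totals = [
                sum(rp.species_equilibrium_mass(k, env.r, p) for k in kins)
                for p in grid
            ]
            assert all(u > v for u, v in zip(totals, totals[1:]))
            assert totals[-1] < 1e-2  # vanishes at the largest intrinsic rate

    def test_e_species_monopolizes_added_mass(self, table1_e):
        # d mu_E / dm = 1 and d mu_i / dm = 0 for the S-survivors
        r = 1.0
        lo = rp.equilibrium_state(table1_e, rp.MassEnvironment(m=2.0, r=r))
        hi = rp.equilibrium_state(table1_e, rp.MassEnvironment(m=2.5, r=r))
        i_e = lo.labels.index("3")
        assert hi.mu_hat[i_e] - lo.mu_hat[i_e] == pytest.approx(0.5, rel=1e-9)
        for i in range(len(table1_e)):
            if i != i_e:
                assert hi.mu_hat[i] == pytest.approx(lo.mu_hat[i], rel=1e-12, abs=1e-15)

    def test_e_species_with_insufficient_residual_is_excluded(self, table1):
        # a weak E-species cannot claim mass when the S-species already fill m
        weak_e = rp.SpeciesKinetics(a=0.0, b=5.0, c=1.0, label="weakE")  # lambda 0.742
        env = rp.MassEnvironment(m=2.0, r=1.0)
        sol = rp.equilibrium_phi(list(table1) + [weak_e], env)
        assert sol.resident_E is None
        assert "weakE" not in sol.survivors
        assert sol.phi_hat == pytest.approx(
            rp.equilibrium_phi(table1, env).phi_hat, rel=1e-12
        )

    def test_tied_e_species_rejected(self):
        e1 = rp.SpeciesKinetics(a=0.0, b=7.0, c=3.6, label="E1")
        e2 = rp.SpeciesKinetics(a=0.0, b=7.0, c=3.6, label="E2")
        with pytest.raises(rp.DegenerateCommunityError):
            rp.equilibrium_phi([e1, e2], rp.MassEnvironment(m=2.0, r=1.0))

    def test_empty_community_and_zero_resource_rejected(self):
        with pytest.raises(ValueError):
            rp.equilibrium_phi([], rp.MassEnvironment(m=2.0, r=1.0))
        kin = rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0)
        with pytest.raises(ValueError):
            rp.equilibrium_phi([kin], rp.MassEnvironment(m=2.0, r=0.0))


class TestCriticalTargetConcentration:
    def test_first_extinction_is_lowest_lambda_species(self, table1):
        m_star = rp.critical_target_concentration(table1, 1.0)
        above = rp.equilibrium_phi(table1, rp.MassEnvironment(m=m_star * 1.001, r=1.0))
        below = rp.equilibrium_phi(table1, rp.MassEnvironment(m=m_star * 0.999, r=1.0))
        assert above.n_survivors - below.n_survivors == 1
        dropped = set(above.survivors) - set(below.survivors)
        assert dropped == {"6"}  # smallest intrinsic growth rate (1.239)

    def test_production_at_threshold_equals_lambda_min(self, table1):
        m_star = rp.critical_target_concentration(table1, 1.0)
        sol = rp.equilibrium_phi(table1, rp.MassEnvironment(m=m_star, r=1.0))
        lam_min = min(rp.intrinsic_growth_rate(k, 1.0) for k in table1)
        assert sol.phi_hat == pytest.approx(lam_min, abs=1e-10)

    def test_degenerate_communities_flagged(self):
        twin = [
            rp.SpeciesKinetics(a=72.5, b=6.0, c=5.0, label="t1"),
            rp.SpeciesKinetics(a=80.0, b=6.0, c=5.0, label="t2"),  # same lambda
        ]
        with pytest.raises(rp.DegenerateCommunityError):
            rp.critical_target_concentration(twin, 1.0)
        with pytest.raises(ValueError):
            rp.critical_target_concentration(twin[:1], 1.0)
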