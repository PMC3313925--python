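"""Reaction-scheme model: topology, conservation, integration, closed forms."""

import numpy as np
import pytest
from scipy.linalg import expm

import pgbkin as pk
from pgbkin.scheme import (
    N_SPECIES,
    initial_state,
    rate_matrix,
    detailed_balance_ratio,
)

from conftest import random_rateset


class TestRateSet:
    @pytest.mark.parametrize("bad", [0.0, -1.0, np.nan, np.inf])
    def test_nonpositive_rates_rejected(self, solution_rates, bad):
        with pytest.raises(ValueError):
            solution_rates.replace(kg_r=bad)

    def test_from_dict_roundtrip_and_validation(self, solution_rates):
        d = solution_rates.as_dict()
        assert pk.RateSet.from_dict(d) == solution_rates
        with pytest.raises(ValueError, match="unknown"):
            pk.RateSet.from_dict({**d, "bogus": 1.0})
        d.pop("k1")
        with pytest.raises(ValueError, match="missing"):
            pk.RateSet.from_dict(d)

    def test_all_seventeen_rates_present(self, solution_rates):
        assert len(solution_rates.as_dict()) == 17
        assert set(pk.scheme.PAPER_SYMBOLS) == set(solution_rates.as_dict())


class TestOdeRhs:
    def test_liganded_equilibrium_is_stationary(self, solution_rates):
        # bound ensemble at the r/t equilibrium with negligible dissociation:
        # the only open channels cancel, so the derivative is ~zero
        r = solution_rates.replace(kdiss_r=1e-300, kdiss_t=1e-300)
        fBr = r.km1 / (r.k1 + r.km1)
        y = np.zeros(N_SPECIES + 1)
        y[0], y[1] = fBr, 1 - fBr
        dy = pk.ode_rhs(y, r)
        # tolerance relative to the ~1e5 s^-1 one-way exchange fluxes
        assert np.max(np.abs(dy)) < 1e-15 * r.km1

    def test_protein_conservation_by_construction(self, solution_rates):
        rng = np.random.default_rng(0)
        for _ in range(20):
            rates = random_rateset(rng)
            y = np.append(rng.uniform(0, 1, N_SPECIES), rng.uniform(0, 1e-3))
            for pfo in (True, False):
                dy = pk.ode_rhs(y, rates, pseudo_first_order=pfo)
                assert abs(dy[:N_SPECIES].sum()) < 1e-9 * np.abs(dy).max()

    def test_co_conservation_mass_action(self, solution_rates):
        rng = np.random.default_rng(1)
        y = np.append(rng.uniform(0, 1e-4, N_SPECIES), 2e-4)
        dy = pk.ode_rhs(y, solution_rates, pseudo_first_order=False)
        # d(B + P + S + C)/dt = 0
        total_co_rate = dy[[0, 1, 2, 3, 4, 5, 8]].sum()
        assert abs(total_co_rate) < 1e-9 * np.abs(dy).max()

    def test_negative_state_rejected(self, solution_rates):
        y = np.zeros(N_SPECIES + 1)
        y[0] = -1e-9
        with pytest.raises(ValueError, match="negative"):
            pk.ode_rhs(y, solution_rates)

    def test_unliganded_exchange_equilibrium_constant(self, solution_rates):
        # isolated U_r <-> U_t pair (no CO): stationary exactly at U_t/U_r = 3
        y = np.zeros(N_SPECIES + 1)
        y[6], y[7] = 0.25, 0.75
        dy = pk.ode_rhs(y, solution_rates)
        assert np.max(np.abs(dy)) < 1e-12
        assert solution_rates.k3 / solution_rates.km3 == pytest.approx(3.0)


class TestInitialState:
    def test_flash_full_photolysis_split(self, solution_rates):
        cond = pk.Conditions(co_atm=1.0, phi=1.0, protein_molar=1.0)
        y0 = initial_state(cond, solution_rates)
        assert y0[2] == pytest.approx(0.7712, abs=1e-4)  # P_r
        assert y0[3] == pytest.approx(0.2288, abs=1e-4)  # P_t
        assert y0[[0, 1, 4, 5, 6, 7]].sum() == 0

    def test_flash_partial_photolysis_preserves_identity(self, solution_rates):
        cond = pk.Conditions(co_atm=1.0, phi=0.4, protein_molar=1.0)
        y0 = initial_state(cond, solution_rates)
        fBr = solution_rates.km1 / (solution_rates.k1 + solution_rates.km1)
        assert y0[0] == pytest.approx(0.6 * fBr)
        assert y0[2] == pytest.approx(0.4 * fBr)

    def test_stopped_flow_unliganded_populations(self, solution_rates):
        cond = pk.Conditions(
            co_molar=25e-6, mode="stopped_flow_association",
            protein_molar=1.0, pseudo_first_order=False,
        )
        y0 = initial_state(cond, solution_rates)
        assert y0[6] == pytest.approx(0.25)
        assert y0[7] == pytest.approx(0.75)

    def test_dissociation_mode_zero_free_co(self, solution_rates):
        cond = pk.Conditions(co_molar=1e-3, mode="dissociation_NO_displacement")
        y0 = initial_state(cond, solution_rates)
        assert y0[N_SPECIES] == 0.0
        assert y0[0] + y0[1] == pytest.approx(cond.protein_molar)

    def test_conditions_validation(self):
        with pytest.raises(ValueError, match="mode"):
            pk.Conditions(co_atm=1.0, mode="nonsense")
        with pytest.raises(ValueError, match="photolysis"):
            pk.Conditions(co_atm=1.0, phi=1.5)
        with pytest.raises(ValueError, match="exactly one"):
            pk.Conditions(co_atm=1.0, co_molar=1e-3)
        with pytest.raises(ValueError, match="exactly one"):
            pk.Conditions()
        with pytest.raises(ValueError, match="temperature"):
            pk.Conditions(co_atm=1.0, temperature_K=260.0)


class TestIntegration:
    def test_matches_matrix_exponential_oracle(self, solution_rates):
        """Stiff solver vs brute-force eigen/expm solution of the linear system."""
        cond = pk.Conditions(co_atm=1.0, phi=1.0)
        times = np.logspace(-8, -3, 30)
        traj = pk.integrate_scheme(solution_rates, cond, times)
        y0 = initial_state(cond, solution_rates)
        M = rate_matrix(solution_rates, y0[N_SPECIES])
        for i, t in enumerate(times):
            x = expm(M * t) @ y0[:N_SPECIES]
            err = np.max(np.abs(x - traj[i, :N_SPECIES])) / cond.protein_molar
            assert err < 1e-6

    def test_matches_oracle_on_random_rates(self, flash_conditions):
        """Property: BDF equals the matrix exponential on random rate sets."""
        rng = np.random.default_rng(42)
        times = np.logspace(-9, -3, 12)
        y0 = None
        for _ in range(100):
            rates = random_rateset(rng)
            y0 = initial_state(flash_conditions, rates)
            M = rate_matrix(rates, y0[N_SPECIES])
            traj = pk.integrate_scheme(rates, flash_conditions, times)
            oracle = np.stack(
                [expm(M * t) @ y0[:N_SPECIES] for t in times]
            )
            err = np.max(np.abs(oracle - traj[:, :N_SPECIES]))
            assert err / flash_conditions.protein_molar < 1e-6

    def test_eig_propagator_equals_bdf(self, solution_rates, flash_conditions,
                                       flash_times):
        t1 = pk.integrate_scheme(solution_rates, flash_conditions, flash_times)
        t2 = pk.integrate_scheme(
            solution_rates, flash_conditions, flash_times, method="eig"
        )
        assert np.max(np.abs(t1 - t2)) / flash_conditions.protein_molar < 1e-8

    def test_protein_conserved_along_trajectory(self, solution_rates,
                                                flash_conditions, flash_times):
        traj = pk.integrate_scheme(solution_rates, flash_conditions, flash_times)
        total = traj[:, :N_SPECIES].sum(axis=1)
        assert np.max(np.abs(total / flash_conditions.protein_molar - 1)) < 1e-9

    def test_unphotolyzed_sample_stays_bound(self, solution_rates):
        # phi=0: only thermal dissociation operates; the deoxy level reaches
        # its small binding steady state (~7e-6 at 1 atm) and no more
        cond = pk.Conditions(co_atm=1.0, phi=0.0)
        times = np.logspace(-8, -3, 40)
        traj = pk.integrate_scheme(solution_rates, cond, times)
        deoxy = traj[:, 2:N_SPECIES].sum(axis=1) / cond.protein_molar
        assert deoxy.max() < 1e-5

    def test_long_time_rebinding_steady_state(self, solution_rates):
        # t -> infinity at 1 atm CO: association wins, U+P+S << 1% of protein
        cond = pk.Conditions(co_atm=1.0, phi=1.0)
        times = np.logspace(-8, 2, 60)
        traj = pk.integrate_scheme(solution_rates, cond, times, method="eig")
        unbound = traj[-1, 2:N_SPECIES].sum() / cond.protein_molar
        assert unbound < 0.01
        assert unbound == pytest.approx(7.38e-6, rel=0.05)

    def test_integrator_failure_carries_conditions(self, solution_rates):
        cond = pk.Conditions(co_atm=1.0, phi=1.0)
        with pytest.raises(ValueError):
            pk.integrate_scheme(solution_rates, cond, np.array([1e-3, 1e-4]))


class TestObservable:
    def test_flash_normalization_near_unity(self, solution_rates,
                                            flash_conditions):
        # first sample at 10 ns: ~18% of P_r has already rebound through the
        # geminate channel (branching kg_r against kout + migration), a value
        # pinned by the matrix-exponential oracle
        times = np.logspace(-8, -2, 50)
        trace = pk.simulate_trace(solution_rates, flash_conditions, times)
        assert trace.signal[0] == pytest.approx(0.819, abs=0.005)
        assert trace.signal[0] < 1.0

    def test_dissociation_starts_fully_bound(self, solution_rates):
        cond = pk.Conditions(co_molar=0.0, mode="dissociation_NO_displacement")
        times = np.linspace(1e-6, 10.0, 20)
        traj = pk.integrate_scheme(solution_rates, cond, times)
        sig = pk.observable(traj, cond)
        assert sig[0] == pytest.approx(1.0, abs=1e-6)
        assert np.all(np.diff(sig) <= 0)

    def test_lower_co_slows_bimolecular_rebinding(self, solution_rates):
        times = np.logspace(-8, -2, 80)
        c1 = pk.Conditions(co_atm=1.0, phi=1.0)
        c01 = pk.Conditions(co_atm=0.1, phi=1.0)
        n1 = pk.simulate_trace(solution_rates, c1, times).signal
        n01 = pk.simulate_trace(solution_rates, c01, times).signal
        window = times > 1e-6
        assert np.all(n01[window] >= n1[window] - 1e-9)

    def test_faster_exit_reduces_geminate_amplitude(self, solution_rates,
                                                    flash_conditions):
        # N at 100 ns grows monotonically with kout
        times = np.logspace(-8, -5, 30)
        levels = []
        for scale in (0.5, 1.0, 2.0, 4.0):
            r = solution_rates.replace(kout=solution_rates.kout * scale)
            tr = pk.simulate_trace(r, flash_conditions, times)
            levels.append(np.interp(1e-7, times, tr.signal))
        assert np.all(np.diff(levels) > 0)

    def test_reduces_to_independent_conformations(self, solution_rates,
                                                  flash_conditions):
        """With conformational exchange off, N(t) is the population-weighted
        sum of the two single-conformation solutions."""
        tiny = 1e-8
        r = solution_rates.replace(k1=tiny, km1=tiny, k2=tiny, km2=tiny,
                                   k3=tiny, km3=tiny)
        times = np.logspace(-8, -2, 60)
        P0 = flash_conditions.protein_molar
        full = pk.simulate_trace(r, flash_conditions, times,
                                 method="eig").signal
        parts = []
        for idx in (2, 3):  # start entirely in P_r or in P_t
            y0 = np.zeros(N_SPECIES + 1)
            y0[idx] = P0
            y0[N_SPECIES] = flash_conditions.resolved_co_molar()
            traj = pk.integrate_scheme(r, flash_conditions, times, y0=y0,
                                       method="eig")
            parts.append(traj[:, 2:N_SPECIES].sum(axis=1) / P0)
        fBr = 0.5  # k1 = km1 in the decoupled limit
        y0_real = initial_state(flash_conditions, r)
        w_r = y0_real[2] / (flash_conditions.phi * P0)
        combined = w_r * parts[0] + (1 - w_r) * parts[1]
        assert np.max(np.abs(full - combined)) < 1e-8

    def test_slow_branch_transient_occupancy(self, solution_rates):
        # after full photolysis at 1 atm the t branch transiently holds
        # 40-50% of the photodissociated molecules before rebinding wins
        cond = pk.Conditions(co_atm=1.0, phi=1.0)
        times = np.logspace(-8, -2, 200)
        traj = pk.integrate_scheme(solution_rates, cond, times)
        t_branch = (traj[:, 3] + traj[:, 5] + traj[:, 7]) / cond.protein_molar
        assert 0.35 <= t_branch.max() <= 0.55


class TestDerivedQuantities:
    def test_apparent_on_rates(self, solution_rates):
        kon_r, kon_t = pk.derived_kon(solution_rates)
        assert kon_r == pytest.approx(2.0927e7, rel=1e-4)
        assert kon_t == pytest.approx(1.1538e6, rel=1e-4)

    def test_apparent_off_rates(self, solution_rates):
        koff_r, koff_t = pk.derived_koff(solution_rates)
        assert koff_r == pytest.approx(0.0322, abs=5e-4)
        assert koff_t == pytest.approx(0.0808, abs=5e-4)

    def test_on_rate_limit_no_exit(self, solution_rates):
        # kout -> 0: every entry converts to binding, k_ON -> k_in
        r = solution_rates.replace(kout=1e-6)
        kon_r, kon_t = pk.derived_kon(r)
        assert kon_r == pytest.approx(r.kin_r, rel=1e-9)

    def test_off_rate_limit_no_geminate(self, solution_rates):
        # kg -> 0: every dissociation escapes, k_OFF -> kdiss
        r = solution_rates.replace(kg_r=1e-6, kg_t=1e-6)
        koff_r, koff_t = pk.derived_koff(r)
        assert koff_r == pytest.approx(r.kdiss_r, rel=1e-9)
        assert koff_t == pytest.approx(r.kdiss_t, rel=1e-9)

    def test_equilibrium_summary(self, solution_rates):
        eq = pk.equilibrium_summary(solution_rates)
        assert eq["K1"] == pytest.approx(0.2967, abs=1e-3)
        assert eq["K2"] == pytest.approx(2.4)
        assert eq["K3"] == pytest.approx(3.0)
        assert eq["f_t_unliganded"] == pytest.approx(0.75)
        assert eq["f_Br_liganded"] == pytest.approx(0.7712, abs=1e-4)

    def test_gel_preset_equilibria(self):
        assert pk.equilibrium_summary(pk.DEOXY_CO_GEL_RATES)["K3"] == (
            pytest.approx(4.4)
        )
        assert pk.equilibrium_summary(pk.CO_GEL_RATES)["K3"] == (
            pytest.approx(2.857, abs=0.01)
        )

    def test_thermodynamic_cycle_closure_diagnostic(self, solution_rates):
        # the published parameters do not close the liganded cycle; the
        # diagnostic quantifies by how much
        assert detailed_balance_ratio(solution_rates) == pytest.approx(
            0.462, abs=0.005
        )
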