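import numpy as np
import pytest

import grnsim.dynamics as dyn
from grnsim.dynamics import (
    KineticParameters,
    ModeError,
    RegulatoryParameters,
    SystemState,
    activator_factor,
    binding_probabilities,
    binding_probability,
    default_kinetic_params,
    default_regulatory_params,
    integrate_dde,
    integrate_em,
    masked_concentrations,
    regulatory_factor,
    repressor_factor,
    rhs,
    simulate_genotype,
    solve_dde,
)
from grnsim.network import RegulatoryNetwork

from conftest import scipy_reference


def simple_params(n, exponent_base=1, **kw):
    defaults = dict(Gp=0.0, H=1.0, GA=0.0, GR=0.0, Phi=2.0)
    defaults.update(kw)
    return default_regulatory_params(n, exponent_base=exponent_base, **defaults)


def empty_network(n):
    z = np.zeros((n, n), dtype=int)
    return RegulatoryNetwork(A=z, R=z.copy())


class TestMaskedConcentrations:
    def test_no_regulators_gives_zero(self):
        adj = np.zeros((4, 4), dtype=int)
        assert np.array_equal(masked_concentrations(np.arange(4.0), adj, 2), np.zeros(4))

    def test_single_regulator(self):
        adj = np.zeros((4, 4), dtype=int)
        adj[1, 3] = 1
        s = np.array([5.0, 7.0, 9.0, 11.0])
        out = masked_concentrations(s, adj, 3)
        assert np.array_equal(out, [0.0, 7.0, 0.0, 0.0])

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            masked_concentrations(np.ones(3), np.zeros((4, 4)), 0)


class TestFactors:
    def test_activator_at_zero_is_one(self):
        params = simple_params(3)
        assert np.allclose(activator_factor(np.zeros(3), params), 1.0)

    def test_activator_identity_when_phi_one(self):
        params = simple_params(3, Phi=1.0)
        s = np.array([0.0, 1.0, 10.0])
        assert np.allclose(activator_factor(s, params), 1.0)

    def test_activator_hand_value(self):
        # hA=1, s=1, GA=0, Phi=2, exponent 1 -> (1+2)/(1+1) = 1.5
        params = simple_params(1)
        assert activator_factor(np.array([1.0]), params)[0] == pytest.approx(1.5)

    def test_repressor_at_zero_is_one(self):
        params = simple_params(3)
        assert np.allclose(repressor_factor(np.zeros(3), params), 1.0)

    def test_repressor_hand_value(self):
        # hR=1, s=1, GR=0, exponent 1 -> 1/(1+1) = 0.5
        params = simple_params(1)
        assert repressor_factor(np.array([1.0]), params)[0] == pytest.approx(0.5)

    def test_repressor_strictly_decreasing(self):
        params = simple_params(1)
        grid = np.array([0.0, 1.0, 2.0, 4.0, 8.0])
        vals = [repressor_factor(np.array([g]), params)[0] for g in grid]
        assert all(b < a for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1 for v in vals)


class TestRegulatoryFactor:
    def test_all_ones(self):
        assert regulatory_factor(np.ones(5), np.ones(5)) == 1.0

    def test_simple_product(self):
        fA = np.array([1.5, 1.0, 1.0])
        fR = np.array([1.0, 0.5, 1.0])
        assert regulatory_factor(fA, fR) == pytest.approx(0.75)

    @pytest.mark.parametrize("n", [2, 5, 8])
    def test_matches_determinant_oracle(self, n):
        rng = np.random.default_rng(n)
        fA = rng.uniform(0.5, 2.0, n)
        fR = rng.uniform(0.1, 1.0, n)
        oracle = np.linalg.det(np.diag(fA) @ np.diag(fR))
        assert regulatory_factor(fA, fR) == pytest.approx(oracle)


class TestBindingProbability:
    def test_neutral_case_is_one(self):
        params = simple_params(1)
        assert binding_probability(np.array([1.0]), params)[0] == pytest.approx(1.0)

    def test_large_energy_drives_to_zero(self):
        params = simple_params(1, Gp=50.0)
        assert binding_probability(np.array([1.0]), params)[0] < 1e-15

    def test_algebraic_identity_no_clamping(self):
        params = simple_params(1, Gp=2.0)
        F = np.exp(np.array([2.0]))  # F = exp(Gp/H) -> raw value exactly 1
        assert binding_probability(F, params)[0] == pytest.approx(1.0)

    def test_bounded_for_random_inputs(self):
        rng = np.random.default_rng(0)
        params = simple_params(100, Gp=rng.normal(0, 3, 100))
        F = np.exp(rng.normal(0, 4, 100))
        p = binding_probability(F, params)
        assert np.all(p >= 0) and np.all(p <= 1)

    def test_literal_form_decreases_with_F(self):
        params = simple_params(1, Gp=0.5, binding_form="literal")
        p1 = binding_probability(np.array([1.0]), params)[0]
        p2 = binding_probability(np.array([4.0]), params)[0]
        assert p2 < p1

    def test_nonpositive_H_rejected(self):
        with pytest.raises(ValueError, match="H"):
            RegulatoryParameters(
                Gp=np.zeros(2), H=np.array([1.0, 0.0]), GA=np.zeros(2),
                GR=np.zeros(2), Phi=np.ones(2),
            )


class TestMonotoneRegulation:
    def test_activator_increases_p(self, motif3):
        params = simple_params(3, Gp=1.0, Phi=3.0, exponent_base=3)
        prev = -1.0
        for s0 in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            s = np.array([s0, 0.0, 1.0])
            p = binding_probabilities(s, params, motif3)[2]
            assert p >= prev - 1e-12
            prev = p

    def test_repressor_decreases_p(self, motif3):
        params = simple_params(3, Gp=1.0, exponent_base=3)
        prev = 2.0
        for s1 in [0.0, 0.5, 1.0, 2.0, 4.0, 8.0]:
            s = np.array([0.0, s1, 1.0])
            p = binding_probabilities(s, params, motif3)[2]
            assert p <= prev + 1e-12
            prev = p

    def test_unregulated_gene_has_baseline_p(self, motif3):
        params = simple_params(3, Gp=1.0, exponent_base=3)
        p = binding_probabilities(np.array([3.0, 5.0, 7.0]), params, motif3)
        baseline = 2.0 / (1.0 + np.exp(1.0))
        assert p[0] == pytest.approx(baseline)
        assert p[1] == pytest.approx(baseline)


class TestRhs:
    def test_fixed_point_vanishes(self):
        rng = np.random.default_rng(5)
        n = 6
        net = empty_network(n)
        params = simple_params(n, Gp=rng.uniform(-1, 1, n))
        kin = default_kinetic_params(
            n, Kx=rng.uniform(0.5, 2, n), Ks=rng.uniform(0.5, 2, n),
            Zx=rng.uniform(0.1, 1, n), Zs=rng.uniform(0.1, 1, n),
        )
        s0 = rng.uniform(0, 3, n)
        p_frozen = binding_probabilities(s0, params, net)
        x_star = kin.Kx * p_frozen / kin.Zx
        s_star = kin.Ks * x_star / kin.Zs
        dx, ds = rhs(SystemState(x_star, s_star), x_star, s0, kin, params, net)
        assert np.max(np.abs(dx)) < 1e-12
        assert np.max(np.abs(ds)) < 1e-12

    def test_zero_state_unregulated(self):
        n = 3
        net = empty_network(n)
        params = simple_params(n, Gp=0.0)
        kin = default_kinetic_params(n, Kx=2.0, Ks=1.0, Zx=0.5, Zs=0.5)
        zero = np.zeros(n)
        dx, ds = rhs(SystemState(zero, zero), zero, zero, kin, params, net)
        assert np.allclose(dx, 2.0)  # Kx * p with p = 2/(1+1) = 1
        assert np.allclose(ds, 0.0)

    def test_arithmetic_fixed_point(self):
        # Kx=2, p=0.5, Zx=1 -> x*=1; Ks=3, Zs=1.5 -> s*=2
        n = 1
        net = empty_network(n)
        params = simple_params(n, Gp=np.log(3.0))  # p = 2/(1+3) = 0.5
        kin = default_kinetic_params(n, Kx=2.0, Ks=3.0, Zx=1.0, Zs=1.5)
        x = np.array([1.0])
        s = np.array([2.0])
        dx, ds = rhs(SystemState(x, s), x, s, kin, params, net)
        assert np.allclose(dx, 0.0, atol=1e-14)
        assert np.allclose(ds, 0.0, atol=1e-14)


class TestEulerMaruyama:
    def test_step_count_is_2000(self, gentle_system):
        net, reg, kin = gentle_system
        traj = integrate_em(SystemState(np.ones(5), np.ones(5)), kin, reg, net, seed=0)
        assert traj.times.size == 2001
        assert traj.times[-1] == kin.Tmax

    def test_matches_ode_oracle_without_noise(self, gentle_system):
        net, reg, kin = gentle_system
        traj = integrate_em(SystemState(np.ones(5), np.ones(5)), kin, reg, net, seed=0)
        ref = scipy_reference(net, reg, kin, np.ones(10))
        err = max(
            np.max(np.abs(np.concatenate([traj.x[i], traj.s[i]]) - ref.sol(t)))
            for i, t in enumerate(traj.times)
        )
        assert err < 1e-3

    def test_seed_determinism(self, gentle_system):
        net, reg, kin = gentle_system
        kin = dyn.replace(kin, gamma=0.1, sigma_q=0.5)
        init = SystemState(np.ones(5), np.ones(5))
        t1 = integrate_em(init, kin, reg, net, seed=42)
        t2 = integrate_em(init, kin, reg, net, seed=42)
        t3 = integrate_em(init, kin, reg, net, seed=43)
        assert np.array_equal(t1.x, t2.x) and np.array_equal(t1.s, t2.s)
        assert not np.array_equal(t1.x, t3.x)

    def test_nonnegative_under_noise(self, gentle_system):
        net, reg, kin = gentle_system
        kin = dyn.replace(kin, gamma=0.5, sigma_q=1.0)
        traj = integrate_em(SystemState(np.ones(5), np.ones(5)), kin, reg, net, seed=3)
        assert np.all(traj.x >= 0) and np.all(traj.s >= 0)

    def test_tau_rejected(self, gentle_system):
        net, reg, kin = gentle_system
        with pytest.raises(ValueError):
            dyn.replace(kin, tau=1.0, gamma=0.1)
        kin_tau = dyn.replace(kin, tau=1.0)
        with pytest.raises(ModeError):
            integrate_em(SystemState(np.ones(5), np.ones(5)), kin_tau, reg, net, seed=0)


class TestDelaySolver:
    def test_scalar_method_of_steps_oracle(self):
        # y' = -y(t-1), constant history 1:
        #   on [0,1]: y = 1 - t            -> y(1) = 0
        #   on [1,2]: y = t^2/2 - 2t + 3/2 -> y(2) = -1/2
        sol = solve_dde(
            lambda t, y, yd: -yd, (0.0, 2.0), np.array([1.0]), tau=1.0,
            rtol=1e-8, atol=1e-10,
        )
        assert abs(sol.sol(1.0)[0] - 0.0) < 1e-4
        assert abs(sol.sol(2.0)[0] + 0.5) < 1e-4

    def test_tau_zero_matches_ode_oracle(self, gentle_system):
        net, reg, kin = gentle_system
        traj = integrate_dde(SystemState(np.ones(5), np.ones(5)), kin, reg, net,
                             rel_tol=1e-6, abs_tol=1e-9)
        ref = scipy_reference(net, reg, kin, np.ones(10))
        err = max(
            np.max(np.abs(np.concatenate([traj.x[i], traj.s[i]]) - ref.sol(t)))
            for i, t in enumerate(traj.times)
        )
        assert err < 1e-4

    def test_halving_tolerance_does_not_increase_error(self):
        def err_at(rtol):
            sol = solve_dde(
                lambda t, y, yd: -yd, (0.0, 2.0), np.array([1.0]), tau=1.0,
                rtol=rtol, atol=rtol * 1e-3,
            )
            return abs(sol.sol(2.0)[0] + 0.5)

        errors = [err_at(r) for r in (1e-3, 5e-4, 2.5e-4, 1.25e-4)]
        assert errors[-1] <= errors[0] + 1e-12

    def test_em_and_dde_agree(self, gentle_system):
        net, reg, kin = gentle_system
        em = integrate_em(SystemState(np.ones(5), np.ones(5)), kin, reg, net, seed=0)
        dde = integrate_dde(SystemState(np.ones(5), np.ones(5)), kin, reg, net,
                            rel_tol=1e-7, abs_tol=1e-10)
        from scipy.interpolate import interp1d
        for em_block, dde_block in ((em.x, dde.x), (em.s, dde.s)):
            f = interp1d(dde.times, dde_block, axis=0)
            assert np.max(np.abs(em_block - f(em.times))) < 1e-2

    def test_delay_changes_solution(self, gentle_system):
        net, reg, kin = gentle_system
        init = SystemState(np.ones(5), np.ones(5))
        no_delay = integrate_dde(init, kin, reg, net)
        kin_tau = dyn.replace(kin, tau=3.0)
        with_delay = integrate_dde(init, kin_tau, reg, net)
        assert with_delay.mode == "delay"
        from scipy.interpolate import interp1d
        f = interp1d(with_delay.times, with_delay.x, axis=0)
        assert np.max(np.abs(no_delay.x - f(no_delay.times))) > 1e-4

    def test_gamma_rejected(self, gentle_system):
        net, reg, kin = gentle_system
        kin_noisy = dyn.replace(kin, gamma=0.1, sigma_q=0.1)
        with pytest.raises(ModeError):
            integrate_dde(SystemState(np.ones(5), np.ones(5)), kin_noisy, reg, net)

    def test_unregulated_matches_closed_form(self):
        # x(t) = x0 e^-Zx t + (Kx p/Zx)(1 - e^-Zx t), p constant
        n = 2
        net = empty_network(n)
        params = simple_params(n, Gp=np.log(3.0))  # p = 0.5
        kin = default_kinetic_params(n, Kx=2.0, Ks=1.0, Zx=0.4, Zs=0.1, Tmax=30.0)
        traj = integrate_dde(SystemState(np.ones(n), np.ones(n)), kin, params, net,
                             rel_tol=1e-8, abs_tol=1e-11)
        t = traj.times
        expected = 1.0 * np.exp(-0.4 * t) + (2.0 * 0.5 / 0.4) * (1 - np.exp(-0.4 * t))
        assert np.max(np.abs(traj.x[:, 0] - expected)) < 1e-6


class TestSimulateGenotype:
    def test_deterministic_repeatable(self, gentle_system):
        net, reg, kin = gentle_system
        g1 = simulate_genotype(kin.Kx, kin, reg, net, mode="deterministic")
        g2 = simulate_genotype(kin.Kx, kin, reg, net, mode="deterministic")
        assert np.array_equal(g1.mean_protein, g2.mean_protein)

    def test_unregulated_average_near_steady_state(self):
        n = 1
        net = empty_network(n)
        params = simple_params(n, Gp=0.0)  # p = 1
        kin = default_kinetic_params(n, Kx=2.0, Ks=1.0, Zx=1.0, Zs=1.0, Tmax=400.0)
        gp = simulate_genotype(kin.Kx, kin, params, net, mode="deterministic",
                               rel_tol=1e-8, abs_tol=1e-11)
        assert gp.mean_mrna[0] == pytest.approx(2.0, rel=1e-3)

    def test_burn_in_window_starts_at_20_percent(self, gentle_system):
        net, reg, kin = gentle_system
        gp = simulate_genotype(kin.Kx, kin, reg, net, mode="deterministic")
        t = gp.trajectory.times
        # recompute average over [0.2 Tmax, Tmax] directly
        from grnsim.traits import time_average
        mean_x, _ = time_average(gp.trajectory, 0.2)
        assert np.allclose(gp.mean_mrna, mean_x)
        assert t[-1] == kin.Tmax

    def test_stochastic_mode_uses_em(self, gentle_system):
        net, reg, kin = gentle_system
        kin = dyn.replace(kin, gamma=0.1, sigma_q=0.5)
        gp = simulate_genotype(kin.Kx, kin, reg, net, mode="stochastic", seed=1)
        assert gp.trajectory.mode == "stochastic"
        assert gp.trajectory.times.size == 2001

    def test_failure_annotated_with_genotype(self, gentle_system):
        net, reg, kin = gentle_system
        kin_bad = dyn.replace(kin, tau=1.0)
        with pytest.raises(dyn.SimulationError, match="g-17"):
            simulate_genotype(kin.Kx, kin_bad, reg, net, mode="stochastic",
                              genotype_id="g-17")
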