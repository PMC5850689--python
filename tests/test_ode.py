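"""Vector field, Jacobian and integrator tests.

The right-hand side is checked against an independently written,
loop-based term-by-term oracle; the analytic Jacobian against batched
finite differences; and the integrated trajectories against the
structural invariants of the system (pi/pibar symmetry, monomer
conservation, the no-catalysis limit).
"""

import numpy as np
import pytest

from nucleoreplicator import (
    ModelParameters,
    PolymerState,
    SolverOptions,
    integrate_to_steady,
    observables,
    rhs,
)
from nucleoreplicator.ode import ModelVariants, ReplicatorODE

from .conftest import random_state
from .oracle import oracle_rhs

BASE = ModelParameters()


class TestVectorField:
    def test_empty_system_is_fixed_point(self):
        # the pool regularization leaves a residual far below any
        # physically meaningful rate, otherwise the empty system rests
        p = BASE.with_(rho_p=0.0, rho_r=0.0)
        system = ReplicatorODE(p)
        dy = system(0.0, system.initial_state())
        assert np.max(np.abs(dy)) < 1e-40

    def test_spontaneous_dimerization_from_monomers(self):
        # zero polymer state: only the dimerization term survives,
        # equally for all three sequence classes
        system = ReplicatorODE(BASE)
        dy = system(0.0, system.initial_state())
        m = system.m
        expected = BASE.K_R_plus * BASE.rho_r ** 2
        for block in range(3):
            assert dy[block * m] == pytest.approx(expected, rel=1e-12)
            assert np.all(dy[block * m + 1:(block + 1) * m] == 0.0)
        # peptide dimerization is K_P_plus-slow but present
        assert dy[3 * m] == pytest.approx(BASE.K_P_plus * BASE.rho_p ** 2,
                                          rel=1e-12)

    @pytest.mark.parametrize("scale", [1e-12, 1e-8, 1e-5])
    def test_matches_term_by_term_oracle(self, rng, scale):
        system = ReplicatorODE(BASE)
        for _ in range(10):
            y = random_state(system, rng, scale)
            got = system(0.0, y)
            want = oracle_rhs(y, BASE, system.variants)
            np.testing.assert_allclose(got, want, rtol=1e-6,
                                       atol=1e-300)

    def test_oracle_agreement_under_overrides(self, rng):
        system = ReplicatorODE(BASE, overrides={"K_R_plus": 4e-8})
        y = random_state(system, rng, 1e-7)
        np.testing.assert_allclose(
            system(0.0, y), oracle_rhs(y, system.params, system.variants),
            rtol=1e-6)

    def test_rejects_unknown_override(self):
        with pytest.raises(ValueError):
            ReplicatorODE(BASE, overrides={"Z": 0.0})

    def test_state_record_roundtrip(self, rng):
        state = PolymerState.zeros(BASE)
        state.R_alpha[:] = rng.uniform(0, 1e-7, BASE.n_lengths)
        d = rhs(state, BASE)
        assert isinstance(d, PolymerState)
        assert np.all(np.isfinite(d.to_vector()))


class TestJacobian:
    @pytest.mark.parametrize("variants", [
        ModelVariants(),
        ModelVariants(binding_lengths="all"),
        ModelVariants(binding_classes="all", alpha_catalysis=False),
        ModelVariants(conservation_weights="literal",
                      stabilization_inflow="fragment"),
    ])
    def test_analytic_matches_finite_difference(self, rng, variants):
        system = ReplicatorODE(BASE, variants=variants)
        for scale in (1e-10, 1e-6):
            y = random_state(system, rng, scale)
            J_analytic = system.jacobian(0.0, y)
            J_fd = system.jacobian_fd(0.0, y)
            ref = np.abs(J_analytic).max()
            np.testing.assert_allclose(J_analytic, J_fd, atol=1e-5 * ref)

    def test_conservation_rows_are_weighted_sums(self, rng):
        # the pool rows must be exact negatives of the weighted polymer
        # rows so that conservation is a linear invariant of the
        # linearized dynamics too
        system = ReplicatorODE(BASE)
        y = random_state(system, rng, 1e-8)
        J = system.jacobian(0.0, y)
        m = system.m
        w = system.class_weight
        lhs = J[system.i_R1, :]
        blocks = (J[:m, :].sum(axis=0) + J[m:2 * m, :].sum(axis=0)
                  + w @ J[2 * m:3 * m, :])
        np.testing.assert_allclose(lhs, -blocks, rtol=1e-12, atol=1e-30)


class TestIntegration:
    def test_pi_pibar_symmetry_along_trajectory(self):
        # the symmetric all-zero polymer start must keep the polymerase
        # strand and its complement numerically identical
        p = BASE.with_(rho_p=1e-3, rho_r=1e-3)
        traj = integrate_to_steady(p, SolverOptions(t_cap=1e11))
        m = p.n_lengths
        for k in range(len(traj.times)):
            r_pi = traj.states[k][:m]
            r_pb = traj.states[k][m:2 * m]
            assert np.linalg.norm(r_pi - r_pb) <= (
                1e-6 * np.linalg.norm(r_pi) + 1e-30)
            p_pi = traj.states[k][3 * m:4 * m]
            p_pb = traj.states[k][4 * m:5 * m]
            assert np.linalg.norm(p_pi - p_pb) <= (
                1e-6 * np.linalg.norm(p_pi) + 1e-30)

    def test_monomer_conservation_along_trajectory(self, steady_runs):
        for rho, traj in steady_runs.items():
            system = ReplicatorODE(traj.params)
            for k in range(len(traj.times)):
                res_p, res_r = system.conservation_residuals(traj.states[k])
                assert abs(res_p) <= 1e-9 * traj.params.rho_p
                assert abs(res_r) <= 1e-9 * traj.params.rho_r

    def test_no_catalysis_limit_gives_unit_ratio(self):
        # Z = 0 removes copying and binding: the polymerase sequence is
        # just one sequence among n^L, so Q1 -> 1 at any concentration
        p = BASE.with_(Z=0.0, rho_p=1e-2, rho_r=1e-2)
        traj = integrate_to_steady(p)
        obs = traj.final_observables()
        assert obs.Q1 == pytest.approx(1.0, abs=1e-3)

    def test_initial_condition_is_all_monomer(self, steady_runs):
        traj = steady_runs[1e-3]
        assert traj.times[0] == 0.0
        assert np.all(traj.states[0][:-2] == 0.0)
        assert traj.states[0][-2] == traj.params.rho_p
        assert traj.states[0][-1] == traj.params.rho_r

    def test_fixed_duration_run_stops_at_t_end(self):
        p = BASE.with_(rho_p=1e-3, rho_r=1e-3)
        traj = integrate_to_steady(p, t_end=1e8)
        assert traj.times[-1] == pytest.approx(1e8)

    def test_tolerance_refinement_stability(self, steady_runs):
        # halving rtol must not move the settled Q1 by more than 0.1%
        traj = steady_runs[1e-2]
        q_ref = traj.final_observables().Q1
        opts = SolverOptions(rtol=5e-9)
        traj2 = integrate_to_steady(traj.params, opts)
        assert traj2.final_observables().Q1 == pytest.approx(q_ref,
                                                             rel=1e-3)


class TestObservables:
    def test_unit_ratio_for_identical_classes(self):
        state = PolymerState.zeros(BASE)
        state.P_pi[:] = 1e-9
        state.P_alpha[:] = 1e-9
        obs = observables(state, BASE)
        assert obs.Q1 == 1.0

    def test_zero_denominator_flagged(self):
        state = PolymerState.zeros(BASE)
        state.P_pi[-1] = 1e-9
        obs = observables(state, BASE)
        assert np.isinf(obs.Q1)
        assert obs.degenerate

    def test_sums_start_at_minimum_polymerase_length(self):
        state = PolymerState.zeros(BASE)
        state.P_pi[:] = 1.0  # lengths 2..10
        obs = observables(state, BASE)
        # only lengths 7..10 count
        assert obs.rho_pi == pytest.approx(4.0)
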