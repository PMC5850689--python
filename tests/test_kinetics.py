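"""Unit and property tests for the rate laws."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nucleoreplicator import (
    ModelParameters,
    PolymerState,
    binding_probability,
    catalyzed_rate_K,
    composite_rate,
    derived_rates,
    effective_step_rate,
    monomer_pools,
    polymerase_depoly_rate,
    quality_factor,
    stabilization_factor,
)

BASE = ModelParameters()


class TestCompositeRate:
    @pytest.mark.parametrize("K,k,m,expected", [
        (3.7e-4, 1e-2, 0, 3.7e-4),      # no multi-step part: single event
        (0.0, 1e-2, 5, 0.0),            # no initiating event
        (1e-3, 1e-2, 10, 5e-4),         # 1/(1/1e-3 + 10/1e-2) = 5e-4
    ])
    def test_values(self, K, k, m, expected):
        assert composite_rate(K, k, m) == pytest.approx(expected, rel=1e-12)

    @given(K=st.floats(1e-12, 1e3), k=st.floats(1e-12, 1e3),
           m=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_harmonic_sum_identity(self, K, k, m):
        # mean completion times add: 1/K~ = 1/K + m/k
        Kt = composite_rate(K, k, m)
        assert 1.0 / Kt == pytest.approx(1.0 / K + m / k, rel=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            composite_rate(-1.0, 1.0, 1)


class TestEffectiveStepRate:
    def test_zero_pool(self):
        assert effective_step_rate(BASE, 0.0) == 0.0

    def test_saturates_at_k_step(self):
        # h_R * R1 >> k_step: translocation limits the step
        assert effective_step_rate(BASE, 10.0) == pytest.approx(
            BASE.k_step, rel=1e-9)

    def test_direct_value(self):
        # k_step=4e-5, h_R*R1=1e3: 4e-5*1e3/(4e-5+1e3)
        val = effective_step_rate(BASE, 1e-3)
        assert val == pytest.approx(3.9999984e-5, rel=1e-6)

    def test_linear_for_scarce_nucleotides(self):
        # h_R * R1 << k_step: attachment limits the step
        assert effective_step_rate(BASE, 1e-15) == pytest.approx(
            BASE.h_R * 1e-15, rel=1e-4)


class TestQualityFactor:
    @pytest.mark.parametrize("l,expected", [(7, 0.25), (8, 0.5), (9, 0.75),
                                            (10, 1.0)])
    def test_linear_ramp(self, l, expected):
        assert quality_factor(l, BASE) == pytest.approx(expected)

    def test_flat_above_full_efficiency(self):
        p = BASE.with_(L_max=15, l_pi_max=10)
        assert quality_factor(12, p) == 1.0

    def test_below_domain(self):
        with pytest.raises(ValueError):
            quality_factor(6, BASE)

    def test_nondecreasing(self):
        vals = [quality_factor(l, BASE) for l in range(7, 11)]
        assert vals == sorted(vals)


class TestStabilizationFactor:
    def test_zero_below_minimum_length(self):
        assert stabilization_factor(BASE.l_pi_min - 1, BASE) == 0.0

    def test_at_minimum_length(self):
        expected = 1.0 - math.exp(-1.0 / 0.15)
        assert stabilization_factor(7, BASE) == pytest.approx(expected,
                                                              rel=1e-12)
        assert expected == pytest.approx(0.99873, rel=1e-4)

    def test_saturates_to_one(self):
        p = BASE.with_(L_max=200, l_pi_max=200)
        assert stabilization_factor(200, p) == pytest.approx(1.0, abs=1e-12)

    def test_strictly_increasing_on_active_range(self):
        vals = [stabilization_factor(l, BASE) for l in range(7, 11)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestPolymeraseDepolyRate:
    def test_unbound_is_unstabilized(self):
        assert polymerase_depoly_rate(10, 0.0, BASE) == BASE.K_P_minus

    def test_short_chains_unstabilized(self):
        assert polymerase_depoly_rate(5, 1.0, BASE) == BASE.K_P_minus

    def test_full_stabilization_limit(self):
        rate = polymerase_depoly_rate(10, 1.0, BASE)
        assert rate < 1e-20  # 1 - F(10) ~ 2.6e-12 of K_P_minus

    @given(P_b=st.floats(0.0, 1.0), l=st.integers(2, 10))
    @settings(max_examples=50, deadline=None)
    def test_never_exceeds_bare_rate(self, P_b, l):
        assert 0.0 <= polymerase_depoly_rate(l, P_b, BASE) <= BASE.K_P_minus


class TestCatalyzedRate:
    def test_zero_below_template_minimum(self):
        state = PolymerState.zeros(BASE)
        state.P_pi[:] = 1e-7
        assert catalyzed_rate_K(BASE.l_pi_min - 1, state, BASE) == 0.0

    def test_zero_without_polymerases(self):
        state = PolymerState.zeros(BASE)
        assert catalyzed_rate_K(8, state, BASE) == 0.0

    def test_single_polymerase_term(self):
        # one active polymerase length: the sum collapses to one composite
        state = PolymerState.zeros(BASE)
        state.P_pi[7 - 2] = 1e-7
        _, R1 = state.pools(BASE)
        k_eff = effective_step_rate(BASE, R1)
        expected = composite_rate(BASE.Z * 1e-7, k_eff, 7) * quality_factor(
            7, BASE)
        assert catalyzed_rate_K(7, state, BASE) == pytest.approx(
            expected, rel=1e-12)


class TestBindingProbability:
    def test_no_polynucleotides(self):
        assert binding_probability(PolymerState.zeros(BASE), BASE) == 0.0

    def test_in_unit_interval_on_random_states(self, rng):
        for _ in range(50):
            state = PolymerState.zeros(BASE)
            state.R_alpha[:] = rng.uniform(0, 1e-6, BASE.n_lengths)
            assert 0.0 <= binding_probability(state, BASE) <= 1.0

    def test_monotone_in_template_abundance(self):
        # scaling all binding sites up can only increase P_b, toward 1
        state = PolymerState.zeros(BASE)
        state.R_alpha[5:] = 1e-12
        values = []
        for scale in np.geomspace(1e-3, 1e3, 13):
            s = PolymerState.zeros(BASE)
            s.R_alpha[:] = state.R_alpha * scale
            values.append(binding_probability(s, BASE))
        assert all(b >= a for a, b in zip(values, values[1:]))
        assert values[-1] > 0.99


class TestMonomerPools:
    def test_empty_state_returns_initial(self):
        P1, R1 = monomer_pools(PolymerState.zeros(BASE), BASE)
        assert (P1, R1) == (BASE.rho_p, BASE.rho_r)

    def test_class_count_weighting(self):
        # n=4, L=2: 16 - 2 = 14 generic classes drain the pool
        p = BASE.with_(L_max=2, l_pi_min=2, l_pi_max=2)
        state = PolymerState.zeros(p)
        state.P_alpha[0] = 1e-5
        P1, _ = monomer_pools(state, p)
        assert P1 == pytest.approx(1e-3 - 14e-5, rel=1e-12)

    def test_overdrawn_pool_clamps_to_zero(self):
        p = BASE.with_(L_max=2, l_pi_min=2, l_pi_max=2)
        state = PolymerState.zeros(p)
        state.P_alpha[0] = 1.0
        P1, _ = monomer_pools(state, p)
        assert P1 == 0.0
        P1_raw, _ = monomer_pools(state, p, clamp=False)
        assert P1_raw < 0.0


class TestDerivedRates:
    def test_invariants_on_random_state(self, rng):
        state = PolymerState.zeros(BASE)
        for block in ("R_pi", "R_pibar", "R_alpha", "P_pi", "P_pibar",
                      "P_alpha"):
            getattr(state, block)[:] = rng.uniform(0, 1e-7, BASE.n_lengths)
        d = derived_rates(state, BASE)
        assert 0.0 <= d.P_b <= 1.0
        assert np.all(d.K_of_L[:BASE.l_pi_min - 2] == 0.0)
        assert np.all(d.K_P_minus_pi <= BASE.K_P_minus + 1e-30)
        assert np.all((0.0 <= d.W) & (d.W <= 1.0))
        assert np.all((0.0 <= d.F_pi) & (d.F_pi < 1.0))


class TestParameterValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ModelParameters(K_R_plus=-1.0)

    def test_structural_ordering_enforced(self):
        with pytest.raises(ValueError):
            ModelParameters(l_pi_min=12)

    def test_kt_folds_into_templated_rate(self):
        p = BASE.with_(k_t=0.5)
        assert p.k_P_templated == pytest.approx(0.05)
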