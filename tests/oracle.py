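"""Independent, deliberately naive reference implementation of the
replicator vector field.

Every term of the six concentration equations is evaluated literally
with explicit Python loops, term by term, with no shared code with the
package's vectorized right-hand side.  Used by the test suite as the
oracle against which ``ReplicatorODE`` is checked on random states.
"""

from __future__ import annotations

import math

import numpy as np


def oracle_rhs(y, params, variants):
    """Time derivative of the full state vector (six blocks + pools)."""
    n = params.n
    Lmax = params.L_max
    lmin = params.l_pi_min
    lmax_pi = params.l_pi_max
    m = Lmax - 1

    def R_pi(L):
        return y[L - 2]

    def R_pb(L):
        return y[m + L - 2]

    def R_al(L):
        return y[2 * m + L - 2]

    def P_pi(L):
        return y[3 * m + L - 2]

    def P_pb(L):
        return y[4 * m + L - 2]

    def P_al(L):
        return y[5 * m + L - 2]

    P1 = y[6 * m]
    R1 = y[6 * m + 1]

    # effective single-step rate of a bound polymerase
    a = params.h_R * R1
    k_eff = params.k_step * a / (params.k_step + a) if a != 0.0 else 0.0

    def W(l):
        if l > lmax_pi:
            return 1.0
        return (l - lmin + 1) / (lmax_pi - lmin + 1)

    def F(l):
        if l < lmin:
            return 0.0
        return 1.0 - math.exp(-(l - lmin + 1) / params.lambda_)

    def K_tilde(K, k, mm):
        if K == 0.0:
            return 0.0
        return K * k / (mm * K + k)

    def K(L):
        if L < lmin:
            return 0.0
        total = 0.0
        for l in range(lmin, Lmax + 1):
            total += K_tilde(params.Z * P_pi(l), k_eff, L) * W(l)
        return total

    # binding probability from attachment rates and mean bound times
    lengths = (range(lmin, Lmax + 1) if variants.binding_lengths == "active"
               else range(2, Lmax + 1))
    kb = {}
    for M in lengths:
        if variants.binding_classes == "alpha":
            sites = R_al(M) * n ** M
        else:
            sites = (n ** M - 2) * R_al(M) + R_pi(M) + R_pb(M)
        kb[M] = params.Z * sites
    total_kb = sum(kb.values())
    mean_bound_times_total = sum(M * kb[M] for M in kb)
    den = mean_bound_times_total + k_eff
    P_b = mean_bound_times_total / den if den != 0.0 else 0.0

    KRp, KRm = params.K_R_plus, params.K_R_minus
    KPp, KPm = params.K_P_plus, params.K_P_minus

    def dep_pi(l):
        return KPm * (1.0 - P_b * F(l))

    def kP(L):
        return params.k_t * params.k_P1_plus / L

    dy = np.zeros_like(y)
    for L in range(2, Lmax + 1):
        i = L - 2
        rpi_prev = R1 if L == 2 else R_pi(L - 1)
        rpb_prev = R1 if L == 2 else R_pb(L - 1)
        ral_prev = R1 if L == 2 else R_al(L - 1)
        ppi_prev = P1 if L == 2 else P_pi(L - 1)
        ppb_prev = P1 if L == 2 else P_pb(L - 1)
        pal_prev = P1 if L == 2 else P_al(L - 1)

        d = KRp * R1 * rpi_prev - n * KRp * R1 * R_pi(L)
        for l in range(L + 1, Lmax + 1):
            d += KRm * R_pi(l) + (2 * n ** (l - L) - 1) * KRm * R_al(l)
        d += -(L - 1) * KRm * R_pi(L) + K(L) * R_pb(L)
        dy[i] = d

        d = KRp * R1 * rpb_prev - n * KRp * R1 * R_pb(L)
        for l in range(L + 1, Lmax + 1):
            d += KRm * R_pb(l) + (2 * n ** (l - L) - 1) * KRm * R_al(l)
        d += -(L - 1) * KRm * R_pb(L) + K(L) * R_pi(L)
        dy[m + i] = d

        d = KRp * R1 * ral_prev - n * KRp * R1 * R_al(L)
        for l in range(L + 1, Lmax + 1):
            d += 2 * n ** (l - L) * KRm * R_al(l)
        d += -(L - 1) * KRm * R_al(L)
        if variants.alpha_catalysis:
            d += K(L) * R_al(L)
        dy[2 * m + i] = d

        d = KPp * P1 * ppi_prev - n * KPp * P1 * P_pi(L)
        for l in range(L + 1, Lmax + 1):
            rate = dep_pi(l) if variants.stabilization_inflow == "by-length" \
                else dep_pi(L)
            d += rate * P_pi(l) + (2 * n ** (l - L) - 1) * KPm * P_al(l)
        d += -(L - 1) * dep_pi(L) * P_pi(L) + kP(L) * P1 * R_pi(L)
        dy[3 * m + i] = d

        d = KPp * P1 * ppb_prev - n * KPp * P1 * P_pb(L)
        for l in range(L + 1, Lmax + 1):
            d += KPm * P_pb(l) + (2 * n ** (l - L) - 1) * KPm * P_al(l)
        d += -(L - 1) * KPm * P_pb(L) + kP(L) * P1 * R_pb(L)
        dy[4 * m + i] = d

        d = KPp * P1 * pal_prev - n * KPp * P1 * P_al(L)
        for l in range(L + 1, Lmax + 1):
            d += 2 * n ** (l - L) * KPm * P_al(l)
        d += -(L - 1) * KPm * P_al(L) + kP(L) * P1 * R_al(L)
        dy[5 * m + i] = d

    # pool derivatives: negative weighted sums of the polymer derivatives
    if variants.conservation_weights == "class-count":
        def weight(L):
            return n ** L - 2
    else:
        def weight(L):
            return n * L - 2
    dP1 = 0.0
    dR1 = 0.0
    for L in range(2, Lmax + 1):
        i = L - 2
        dP1 -= weight(L) * dy[5 * m + i] + dy[3 * m + i] + dy[4 * m + i]
        dR1 -= weight(L) * dy[2 * m + i] + dy[i] + dy[m + i]
    dy[6 * m] = dP1
    dy[6 * m + 1] = dR1
    return dy
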