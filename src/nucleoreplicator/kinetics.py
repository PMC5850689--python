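"""Rate laws of the reciprocal-replicator kinetics.

Every function here is a pure function of a polymer state and the model
parameters.  The catalytic machinery is summarized by two derived
quantities recomputed from the instantaneous state at every evaluation:

* ``K(L)`` — the total rate at which polynucleotide chains of length L
  are copied by the available polymerases, combining the attachment
  event (rate ``Z * P_pi[l]``) with the L nucleotide-addition steps
  (rate ``k_R_eff`` each) through the composite-rate law, weighted by a
  length-dependent quality factor ``W_l``;
* ``P_b`` — the probability that a polymerase is bound to some
  polynucleotide, which stabilizes it against depolymerization by the
  factor ``F_pi(l)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters
from .state import PolymerState

__all__ = [
    "composite_rate",
    "effective_step_rate",
    "quality_factor",
    "stabilization_factor",
    "catalyzed_rate_K",
    "binding_probability",
    "polymerase_depoly_rate",
    "DerivedRates",
    "derived_rates",
]


def composite_rate(K: float, k: float, m: float) -> float:
    """Rate of a complex reaction: one event at rate K plus m events at rate k.

    The mean completion time is the sum of the mean event times, so the
    composite rate is the harmonic combination ``K*k / (m*K + k)``.
    Returns 0 when the initiating rate K is 0.
    """
    if K < 0 or m < 0 or not k > 0:
        raise ValueError(f"require K >= 0, k > 0, m >= 0; got K={K}, k={k}, m={m}")
    if K == 0.0:
        return 0.0
    return K * k / (m * K + k)


def effective_step_rate(params: ModelParameters, R1: float) -> float:
    """Effective rate of one nucleotide-addition step of a bound polymerase.

    Combines attachment of a free nucleotide (rate ``h_R * R1``) with
    the translocation step (rate ``k_step``):
    ``k_step * h_R * R1 / (k_step + h_R * R1)``.  Saturates at
    ``k_step`` for abundant nucleotides and vanishes with the pool.
    """
    if R1 < 0:
        raise ValueError(f"R1 must be >= 0, got {R1}")
    a = params.h_R * R1
    if a == 0.0:
        return 0.0
    return params.k_step * a / (params.k_step + a)


def quality_factor(l: int, params: ModelParameters) -> float:
    """Polymerizing efficiency W_l of a polymerase of length l.

    Ramps linearly from ``1 / (l_pi_max - l_pi_min + 1)`` at the minimum
    active length to 1 at ``l_pi_max``, and stays 1 beyond.  Lengths
    below ``l_pi_min`` have no polymerase activity and are outside the
    domain.
    """
    if l < params.l_pi_min:
        raise ValueError(f"quality factor undefined for l={l} < l_pi_min={params.l_pi_min}")
    if l > params.l_pi_max:
        return 1.0
    return (l - params.l_pi_min + 1) / (params.l_pi_max - params.l_pi_min + 1)


def stabilization_factor(l: int, params: ModelParameters) -> float:
    """Depolymerization reduction F_pi(l) for a bound polymerase of length l.

    ``1 - exp(-(l - l_pi_min + 1) / lambda)`` for active lengths, 0
    below ``l_pi_min``; the exponent is a Boltzmann factor counting the
    hydrogen bonds anchoring the polymerase to the polynucleotide.
    """
    if l < params.l_pi_min:
        return 0.0
    return 1.0 - np.exp(-(l - params.l_pi_min + 1) / params.lambda_)


def polymerase_depoly_rate(L: int, P_b: float, params: ModelParameters) -> float:
    """Depolymerization rate of a pi-class peptide of length L.

    ``K_P_minus * (1 - P_b * F_pi(L))``: binding (probability ``P_b``)
    shields the polymerase by the factor ``F_pi(L)``.  The alpha and
    pibar classes depolymerize at the bare ``K_P_minus``.
    """
    if not 0.0 <= P_b <= 1.0:
        raise ValueError(f"P_b must lie in [0, 1], got {P_b}")
    return params.K_P_minus * (1.0 - P_b * stabilization_factor(L, params))


def _quality_vector(params: ModelParameters) -> np.ndarray:
    """W_l for l = l_pi_min..L_max."""
    ls = np.arange(params.l_pi_min, params.L_max + 1)
    ramp = (ls - params.l_pi_min + 1) / (params.l_pi_max - params.l_pi_min + 1)
    return np.minimum(ramp, 1.0)


def catalyzed_rate_K(L: int, state: PolymerState, params: ModelParameters) -> float:
    """Total catalyzed copy rate K(L) for polynucleotides of length L.

    Sums the composite rate of attachment (``Z * P_pi[l]``) and the L
    addition steps (``k_R_eff`` each) over all active polymerase
    lengths, weighted by quality.  Zero below the minimum template
    length ``l_pi_min``.
    """
    if L < params.l_pi_min:
        return 0.0
    _, R1 = state.pools(params)
    k_eff = effective_step_rate(params, R1)
    if k_eff == 0.0:
        return 0.0
    total = 0.0
    for l in range(params.l_pi_min, params.L_max + 1):
        P_l = max(state.P_pi[l - 2], 0.0)
        total += composite_rate(params.Z * P_l, k_eff, L) * quality_factor(l, params)
    return total


def binding_probability(state: PolymerState, params: ModelParameters) -> float:
    """Probability P_b that a polymerase is bound to some polynucleotide.

    Attachment to the n^M polynucleotides of length M proceeds at
    ``k_b,M = Z * R_alpha[M] * n^M``; the length-M channel is chosen
    with probability ``k_b,M / sum_m k_b,m`` and holds the polymerase
    for a mean time ``M / k_R_eff``.  ``P_b`` is the mean bound time
    over the mean bound-plus-search time, which reduces to the rational
    form ``W / (W + k_R_eff)`` with ``W = sum_M M k_b,M``.  Only
    templates a polymerase can copy (``M >= l_pi_min``) hold it; with
    every length counted instead, the abundant short chains would pin
    P_b at 1 at any concentration and erase the production transition.
    Defined as 0 when no templates are present (the expression tends to
    0 in that limit), and 1 when the nucleotide pool is empty while
    binding sites exist (the bound time diverges).
    """
    M = np.arange(2, params.L_max + 1, dtype=float)
    R_alpha = np.maximum(state.R_alpha, 0.0)
    k_b = params.Z * R_alpha * params.n ** M
    k_b[M < params.l_pi_min] = 0.0
    total_kb = k_b.sum()
    if total_kb <= 0.0:
        return 0.0
    _, R1 = state.pools(params)
    k_eff = effective_step_rate(params, R1)
    W = float((M * k_b).sum())
    return W / (W + k_eff)


@dataclass(frozen=True)
class DerivedRates:
    """Per-evaluation cache of the state-dependent rate quantities.

    Arrays over lengths are indexed by ``L - 2`` like the state blocks;
    ``W`` and ``F_pi`` are full vectors over 2..L_max with zeros below
    ``l_pi_min`` (where the quantities are unused or defined as 0).
    """

    k_R_eff: float            # effective per-step nucleotide-addition rate, s^-1
    K_of_L: np.ndarray        # catalyzed copy rate K(L), s^-1
    W: np.ndarray             # quality factor W_l, dimensionless
    F_pi: np.ndarray          # stabilization factor F_pi(l), dimensionless
    P_b: float                # polymerase bound-state probability
    K_P_minus_pi: np.ndarray  # pi-peptide depolymerization rate, s^-1


def derived_rates(state: PolymerState, params: ModelParameters) -> DerivedRates:
    """Evaluate all state-dependent rate quantities at once."""
    _, R1 = state.pools(params)
    k_eff = effective_step_rate(params, R1)
    P_b = binding_probability(state, params)
    lengths = np.arange(2, params.L_max + 1)
    W = np.zeros(params.n_lengths)
    F = np.zeros(params.n_lengths)
    for i, l in enumerate(lengths):
        if l >= params.l_pi_min:
            W[i] = quality_factor(int(l), params)
        F[i] = stabilization_factor(int(l), params)
    K_of_L = np.array([catalyzed_rate_K(int(L), state, params) for L in lengths])
    K_P_minus_pi = params.K_P_minus * (1.0 - P_b * F)
    return DerivedRates(k_R_eff=k_eff, K_of_L=K_of_L, W=W, F_pi=F,
                        P_b=P_b, K_P_minus_pi=K_P_minus_pi)
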