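"""Polymer concentration state: six classes by length, plus monomer pools.

The flat state vector used by the integrator stacks six blocks of
``L_max - 1`` entries each (lengths ``2..L_max``), in the order
``R_pi, R_pibar, R_alpha, P_pi, P_pibar, P_alpha``.  The free monomer
pools ``P1`` and ``R1`` are not integrated: they are derived from the
polymer state through the conservation expressions

    P1 = rho_p - sum_L [ (n^L - 2) P_alpha[L] + P_pi[L] + P_pibar[L] ]
    R1 = rho_r - sum_L [ (n^L - 2) R_alpha[L] + R_pi[L] + R_pibar[L] ]

where ``(n^L - 2)`` counts the generic sequence classes of length L
(all ``n^L`` sequences minus pi and pibar).  The alpha entries are
per-sequence-class concentrations, which is why they carry that weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .params import ModelParameters

__all__ = ["PolymerState", "BLOCKS", "monomer_pools"]

BLOCKS = ("R_pi", "R_pibar", "R_alpha", "P_pi", "P_pibar", "P_alpha")


def _class_weights(params: ModelParameters) -> np.ndarray:
    """Generic-class multiplicities ``n^L - 2`` for L = 2..L_max."""
    L = np.arange(2, params.L_max + 1, dtype=float)
    return params.n ** L - 2.0


def monomer_pools(state: "PolymerState", params: ModelParameters,
                  clamp: bool = True) -> tuple[float, float]:
    """Free per-type amino-acid and nucleotide pools ``(P1, R1)``.

    Evaluates the conservation expressions exactly as stated (each
    length-L concentration enters unweighted by L; the strict-mass
    variant is available via :class:`~nucleoreplicator.config.SolverOptions`).
    Negative pools are clamped to 0 when ``clamp`` is true; callers that
    need to detect drained pools can pass ``clamp=False``.
    """
    w = _class_weights(params)
    P1 = params.rho_p - float(w @ state.P_alpha + state.P_pi.sum() + state.P_pibar.sum())
    R1 = params.rho_r - float(w @ state.R_alpha + state.R_pi.sum() + state.R_pibar.sum())
    if clamp:
        P1 = max(P1, 0.0)
        R1 = max(R1, 0.0)
    return P1, R1


@dataclass
class PolymerState:
    """Concentrations of the six polymer classes for lengths 2..L_max.

    Arrays are indexed by ``L - 2`` (element 0 is length 2).  Units are
    mol m^-3 throughout; entries are per sequence class (one pi, one
    pibar, one representative alpha per length).
    """

    R_pi: np.ndarray
    R_pibar: np.ndarray
    R_alpha: np.ndarray
    P_pi: np.ndarray
    P_pibar: np.ndarray
    P_alpha: np.ndarray

    @classmethod
    def zeros(cls, params: ModelParameters) -> "PolymerState":
        m = params.n_lengths
        return cls(*(np.zeros(m) for _ in BLOCKS))

    @classmethod
    def from_vector(cls, y: np.ndarray, params: ModelParameters) -> "PolymerState":
        m = params.n_lengths
        if y.shape != (6 * m,):
            raise ValueError(f"expected state vector of length {6 * m}, got {y.shape}")
        return cls(*(y[i * m:(i + 1) * m].copy() for i in range(6)))

    def to_vector(self) -> np.ndarray:
        return np.concatenate([getattr(self, b) for b in BLOCKS])

    def pools(self, params: ModelParameters, clamp: bool = True) -> tuple[float, float]:
        return monomer_pools(self, params, clamp=clamp)

    def C_ptRNA(self, params: ModelParameters) -> float:
        """Loaded p-tRNA concentration, proportional to free amino acids."""
        P1, _ = self.pools(params)
        return params.k_t * P1

    def concentration(self, block: str, L: int, params: ModelParameters) -> float:
        """Concentration of one class at one length (L in 2..L_max)."""
        if not 2 <= L <= params.L_max:
            raise ValueError(f"length {L} outside 2..{params.L_max}")
        return float(getattr(self, block)[L - 2])
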