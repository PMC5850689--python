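"""Model parameters for the nucleopeptide reciprocal-replicator kinetics.

The model tracks polynucleotide and polypeptide chains of lengths
``2..L_max`` in three sequence classes each: the polymerase-encoding
sequence ``pi``, its complement ``pibar``, and a generic class ``alpha``
standing for any one of the remaining sequences of that length.  All
concentrations are in mol m^-3; all lengths are dimensionless counts of
building blocks (codons or amino acids).
"""

from __future__ import annotations

from dataclasses import dataclass, replace, fields

__all__ = ["ModelParameters", "YEAR_SECONDS"]

#: Seconds per year used when reporting durations in years.
YEAR_SECONDS = 3.15e7


@dataclass(frozen=True)
class ModelParameters:
    """Rate constants, structural integers and initial monomer pools.

    Defaults are the baseline parameter set of the replicator model:
    spontaneous polynucleotide polymerization ``K_R_plus = 4.2e-7``
    mol^-1 m^3 s^-1, hydrolysis ``K_R_minus = 8e-9`` s^-1, spontaneous
    peptide polymerization ``K_P_plus = 2.8e-21`` mol^-1 m^3 s^-1,
    peptide depolymerization ``K_P_minus = 4e-11`` s^-1, templated
    peptide unit rate ``k_P1_plus = 0.1`` mol^-1 m^3 s^-1, attachment
    rates ``Z = h_R = 1e6`` mol^-1 m^3 s^-1, translocation rate
    ``k_step = 4e-5`` s^-1 and stabilization scale ``lambda_ = 0.15``,
    with ``n = 4`` building-block types, chains up to ``L_max = 10`` and
    polymerase activity from length ``l_pi_min = 7`` at full efficiency
    by ``l_pi_max = 10``.
    """

    n: int = 4                      # building-block types (codons = amino acids)
    L_max: int = 10                 # maximal polymer length
    l_pi_min: int = 7               # minimum polymerase / template length
    l_pi_max: int = 10              # full-efficiency polymerase length
    K_R_plus: float = 4.2e-7        # spontaneous polynucleotide polymerization, mol^-1 m^3 s^-1
    K_R_minus: float = 8e-9         # polynucleotide cleaving rate, s^-1
    K_P_plus: float = 2.8e-21       # spontaneous polypeptide polymerization, mol^-1 m^3 s^-1
    K_P_minus: float = 4e-11        # polypeptide depolymerization base rate, s^-1
    k_P1_plus: float = 0.1          # templated peptide polymerization unit rate, mol^-1 m^3 s^-1
    Z: float = 1e6                  # polymerase-polynucleotide attachment rate, mol^-1 m^3 s^-1
    h_R: float = 1e6                # nucleotide attachment rate to a bound chain, mol^-1 m^3 s^-1
    k_step: float = 4e-5            # polymerase single-step translocation rate, s^-1
    lambda_: float = 0.15           # stabilization scale (free energy in k_B T units)
    k_t: float = 1.0                # loaded p-tRNA proportionality C_ptRNA = k_t * P1
    rho_p: float = 1e-3             # initial free amino-acid concentration per type, mol m^-3
    rho_r: float = 1e-3             # initial free nucleotide concentration per type, mol m^-3

    def __post_init__(self) -> None:
        rate_fields = (
            "K_R_plus", "K_R_minus", "K_P_plus", "K_P_minus", "k_P1_plus",
            "Z", "h_R", "k_step", "k_t", "rho_p", "rho_r",
        )
        for name in rate_fields:
            value = getattr(self, name)
            if not (value >= 0.0):
                raise ValueError(f"{name} must be >= 0, got {value!r}")
        if not self.lambda_ > 0.0:
            raise ValueError(f"lambda_ must be > 0, got {self.lambda_!r}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n!r}")
        if not (2 <= self.l_pi_min <= self.l_pi_max <= self.L_max):
            raise ValueError(
                "structural lengths must satisfy 2 <= l_pi_min <= l_pi_max "
                f"<= L_max, got l_pi_min={self.l_pi_min}, "
                f"l_pi_max={self.l_pi_max}, L_max={self.L_max}"
            )

    @property
    def lengths(self) -> range:
        """Polymer lengths carried by the state, ``2..L_max`` inclusive."""
        return range(2, self.L_max + 1)

    @property
    def n_lengths(self) -> int:
        return self.L_max - 1

    @property
    def k_P_templated(self) -> float:
        """Templated peptide unit rate including the p-tRNA loading factor.

        Loading of p-tRNA enters the dynamics only through the templated
        peptide polymerization, so the proportionality ``k_t`` simply
        multiplies ``k_P1_plus``.
        """
        return self.k_t * self.k_P1_plus

    def with_(self, **overrides) -> "ModelParameters":
        """Return a copy with the given fields replaced (re-validated)."""
        return replace(self, **overrides)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
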