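"""Assembly and integration of the replicator concentration ODEs.

The dynamical system couples six families of length-indexed
concentrations (polynucleotides and polypeptides in classes pi, pibar,
alpha), ``6 * (L_max - 1)`` components in all.  Each family combines

* spontaneous growth ``K+ * X1 * C[L-1]`` and n-type extension outflow
  ``-n * K+ * X1 * C[L]`` (X1 the relevant monomer pool);
* depolymerization: inflow from every longer chain that contains the
  length-L sequence as a prefix or suffix, with sequence-class
  multiplicities ``n^(l-L)``, and ``(L-1)``-way cleaving outflow;
* the catalyzed copy terms ``K(L) * R[L]`` crossing pi and pibar; and
* templated peptide production ``(k_P1+ / L) * P1 * R[L]``.

``K(L)`` and the binding probability ``P_b`` are recomputed from the
instantaneous state at every evaluation; no quasi-static caching.

The free monomer pools P1 and R1 obey the conservation laws
``P1 + sum_L [(n^L - 2) P_alpha + P_pi + P_pibar] = rho_p`` (and the
R analogue).  Numerically the pools are carried as two extra state
components whose derivatives are the exact negative weighted sums of
the polymer derivatives: the invariant is linear, so the implicit
multistep integrator preserves it to Newton/roundoff precision, while
the pools — which drop many orders of magnitude below the initial
concentrations once catalysis takes off — remain error-controlled on
their own scale instead of being recovered by catastrophic
cancellation from the big polymer components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParameters
from .state import PolymerState, BLOCKS

__all__ = [
    "ReplicatorODE",
    "SolverOptions",
    "Observables",
    "Trajectory",
    "rhs",
    "observables",
    "integrate_to_steady",
]

_ALLOWED_OVERRIDES = {"K_R_plus", "K_R_minus"}

#: regularization scale (mol m^-3) for the smooth positive part of the
#: monomer pools as they enter the rate laws; far below the smallest
#: physically meaningful pool (~1e-13 after catalytic exhaustion)
_EPS_POOL = 1e-18


def _spos(x):
    """Smooth positive part, ~max(x, 0) with rounding scale _EPS_POOL."""
    return 0.5 * (x + np.sqrt(x * x + _EPS_POOL ** 2))


def _dspos(x):
    """Derivative of the smooth positive part."""
    return 0.5 * (1.0 + x / np.sqrt(x * x + _EPS_POOL ** 2))


@dataclass(frozen=True)
class ModelVariants:
    """Resolutions of readings the source equations leave ambiguous.

    The defaults are the internally consistent combination the package
    adopts (class-count conservation weights are the only choice
    compatible with the depolymerization multiplicities, and binding
    restricted to copyable templates is required for a production
    transition to exist); the alternatives are kept selectable for
    sensitivity analysis.

    conservation_weights:
        'class-count' weights the generic polymer classes by n^L - 2
        (all length-L sequences minus pi and pibar) in the monomer
        conservation laws; 'literal' uses n*L - 2.
    binding_lengths:
        'active' lets a polymerase be held only by templates it can
        copy (M >= l_pi_min); 'all' counts every length M >= 2.
    binding_classes:
        'alpha' builds the attachment rates from the generic classes
        alone (k_b,M = Z R_alpha n^M); 'all' adds the pi and pibar
        chains ((n^M - 2) R_alpha + R_pi + R_pibar).
    alpha_catalysis:
        whether the catalyzed copy term K(L) R_alpha feeds the generic
        polynucleotide classes as well as pi/pibar.
    stabilization_inflow:
        'by-length' evaluates the bound-polymerase stabilization of
        depolymerization inflow at the length of the chain being
        cleaved (F_pi(l)); 'fragment' uses the fragment length
        (F_pi(L)).
    """

    conservation_weights: str = "class-count"
    binding_lengths: str = "active"
    binding_classes: str = "alpha"
    alpha_catalysis: bool = True
    stabilization_inflow: str = "by-length"

    def __post_init__(self):
        checks = {
            "conservation_weights": ("class-count", "literal",
                                     "peptide-literal"),
            "binding_lengths": ("active", "all"),
            "binding_classes": ("alpha", "all"),
            "stabilization_inflow": ("by-length", "fragment"),
        }
        for name, allowed in checks.items():
            if getattr(self, name) not in allowed:
                raise ValueError(f"{name} must be one of {allowed}")


class ReplicatorODE:
    """Vectorized right-hand side of the replicator system.

    The state vector stacks the six polymer blocks (lengths 2..L_max
    each) followed by the two monomer pools ``[P1, R1]``, for
    ``6 * (L_max - 1) + 2`` components.  Precomputes the
    length-coupling matrices once per parameter set; ``overrides`` may
    replace ``K_R_plus`` (switch-off experiments) or ``K_R_minus``
    (stability sweeps) without touching the base record.
    """

    def __init__(self, params: ModelParameters,
                 overrides: Mapping[str, float] | None = None,
                 variants: ModelVariants | None = None):
        if overrides:
            unknown = set(overrides) - _ALLOWED_OVERRIDES
            if unknown:
                raise ValueError(f"unsupported rate overrides: {sorted(unknown)}")
            params = params.with_(**dict(overrides))
        self.params = params
        self.variants = variants or ModelVariants()
        p = params
        m = p.n_lengths
        self.m = m
        self.dim = 6 * m + 2
        self.i_P1 = 6 * m
        self.i_R1 = 6 * m + 1
        L = np.arange(2, p.L_max + 1, dtype=float)
        self.L = L
        # Sequence-class multiplicities for depolymerization inflow:
        # cleaving a longer chain of length l can yield the length-L
        # sequence from n^(l-L) prefix classes and n^(l-L) suffix classes.
        diff = L[None, :] - L[:, None]              # l - L
        upper = diff > 0
        n_pow = np.where(upper, float(p.n) ** np.where(upper, diff, 0.0), 0.0)
        self.U = upper.astype(float)                # 1 for l > L
        self.A = np.where(upper, 2.0 * n_pow - 1.0, 0.0)   # pi/pibar inflow from alpha
        self.B = 2.0 * n_pow                        # alpha inflow from alpha
        count_w = float(p.n) ** L - 2.0     # n^L - 2 generic classes
        literal_w = float(p.n) * L - 2.0
        cw = self.variants.conservation_weights
        if cw == "class-count":
            self.class_weight_P = count_w
            self.class_weight_R = count_w
        elif cw == "literal":
            self.class_weight_P = literal_w
            self.class_weight_R = literal_w
        else:  # peptide-literal
            self.class_weight_P = literal_w
            self.class_weight_R = count_w
        self.class_weight = self.class_weight_R  # compat alias
        self.Lm1 = L - 1.0                          # cleavage positions
        self.k_P_L = p.k_P_templated / L            # templated peptide rate per length
        # Quality factor over active polymerase lengths l_pi_min..L_max.
        act = np.arange(p.l_pi_min, p.L_max + 1, dtype=float)
        self.active_slice = slice(p.l_pi_min - 2, m)
        self.W_active = np.minimum(
            (act - p.l_pi_min + 1) / (p.l_pi_max - p.l_pi_min + 1), 1.0)
        # Stabilization factor for all lengths (0 below l_pi_min).
        F = 1.0 - np.exp(-(L - p.l_pi_min + 1) / p.lambda_)
        self.F = np.where(L >= p.l_pi_min, F, 0.0)
        self.n_pow_L = float(p.n) ** L              # binding-site multiplicities
        self.mask_active_L = (L >= p.l_pi_min)      # templates long enough to copy
        self.bind_mask = (self.mask_active_L.astype(float)
                          if self.variants.binding_lengths == "active"
                          else np.ones(m))

    # -- state helpers -----------------------------------------------------

    def initial_state(self) -> np.ndarray:
        """All-monomer initial condition: zero polymers, full pools."""
        y = np.zeros(self.dim)
        y[self.i_P1] = self.params.rho_p
        y[self.i_R1] = self.params.rho_r
        return y

    def full_vector(self, state: PolymerState) -> np.ndarray:
        """Augment a polymer state with its conservation-law pools."""
        P1, R1 = state.pools(self.params)
        return np.concatenate([state.to_vector(), [P1, R1]])

    def conservation_residuals(self, y: np.ndarray) -> tuple[float, float]:
        """Absolute drift of the two linear conservation invariants."""
        p = self.params
        m = self.m
        res_p = (y[self.i_P1] + self.class_weight_P @ y[5 * m:6 * m]
                 + y[3 * m:4 * m].sum() + y[4 * m:5 * m].sum() - p.rho_p)
        res_r = (y[self.i_R1] + self.class_weight_R @ y[2 * m:3 * m]
                 + y[:m].sum() + y[m:2 * m].sum() - p.rho_r)
        return float(res_p), float(res_r)

    # -- the vector field --------------------------------------------------

    def _batch(self, Y: np.ndarray) -> np.ndarray:
        """Vector field for a batch of states, shape (dim, k) -> (dim, k)."""
        # NOTE: the field is evaluated as a smooth rational function on a
        # neighbourhood of the positive orthant — no clipping here.  Stiff
        # solvers probe slightly negative trial states, and any kink at
        # zero defeats their error estimators; undershoot is clamped at
        # accepted chunk boundaries instead (integrate_to_steady).
        p = self.params
        m = self.m
        r_pi, r_pb, r_al = Y[:m], Y[m:2 * m], Y[2 * m:3 * m]
        p_pi, p_pb, p_al = Y[3 * m:4 * m], Y[4 * m:5 * m], Y[5 * m:6 * m]
        # The pools enter every rate law through their smooth positive
        # part: solver excursions below zero then shut consumption down
        # instead of feeding the quadratic growth terms (or reaching the
        # k_eff pole at R1 = -k_step/h_R), and depolymerization inflow
        # restores the pool — the field stays smooth and self-correcting.
        P1 = _spos(Y[self.i_P1])
        R1 = _spos(Y[self.i_R1])

        a = p.h_R * R1
        k_eff = p.k_step * a / (p.k_step + a)

        # catalyzed copy rate K(L): one attachment + L addition steps,
        # summed over active polymerase lengths with quality weights
        k_att = p.Z * p_pi[self.active_slice]                   # (a, k)
        den = self.L[:, None, None] * k_att[None, :, :] + k_eff[None, None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(den != 0.0,
                             k_att[None, :, :] * k_eff[None, None, :] / den, 0.0)
        K = np.einsum("lak,a->lk", terms, self.W_active)
        K[~self.mask_active_L] = 0.0

        # binding probability P_b = W / (W + k_eff) with W the length-
        # weighted total attachment rate (mean bound time over mean
        # bound-plus-search time, in singularity-free rational form);
        # by default only templates a polymerase can copy hold it
        if self.variants.binding_classes == "alpha":
            sites = r_al * self.n_pow_L[:, None]
        else:
            sites = (self.n_pow_L - 2.0)[:, None] * r_al + r_pi + r_pb
        k_b = p.Z * sites * self.bind_mask[:, None]             # (m, k)
        weighted = (self.L[:, None] * k_b).sum(axis=0)
        den_b = weighted + k_eff
        with np.errstate(divide="ignore", invalid="ignore"):
            P_b = np.where(den_b != 0.0, weighted / den_b, 0.0)

        def grow(K_plus: float, X1: np.ndarray, c: np.ndarray) -> np.ndarray:
            prev = np.empty_like(c)
            prev[0] = X1
            prev[1:] = c[:-1]
            return K_plus * X1 * prev - p.n * K_plus * X1 * c

        KRm, KPm = p.K_R_minus, p.K_P_minus
        dep_pi = KPm * (1.0 - P_b[None, :] * self.F[:, None])   # (m, k)
        Lm1 = self.Lm1[:, None]

        d_r_pi = (grow(p.K_R_plus, R1, r_pi)
                  + KRm * (self.U @ r_pi + self.A @ r_al)
                  - Lm1 * KRm * r_pi + K * r_pb)
        d_r_pb = (grow(p.K_R_plus, R1, r_pb)
                  + KRm * (self.U @ r_pb + self.A @ r_al)
                  - Lm1 * KRm * r_pb + K * r_pi)
        d_r_al = (grow(p.K_R_plus, R1, r_al)
                  + KRm * (self.B @ r_al)
                  - Lm1 * KRm * r_al)
        if self.variants.alpha_catalysis:
            d_r_al += K * r_al

        template = self.k_P_L[:, None] * P1[None, :]
        if self.variants.stabilization_inflow == "by-length":
            pi_inflow = self.U @ (dep_pi * p_pi)
        else:
            pi_inflow = dep_pi * (self.U @ p_pi)
        d_p_pi = (grow(p.K_P_plus, P1, p_pi)
                  + pi_inflow + KPm * (self.A @ p_al)
                  - Lm1 * dep_pi * p_pi + template * r_pi)
        d_p_pb = (grow(p.K_P_plus, P1, p_pb)
                  + KPm * (self.U @ p_pb + self.A @ p_al)
                  - Lm1 * KPm * p_pb + template * r_pb)
        d_p_al = (grow(p.K_P_plus, P1, p_al)
                  + KPm * (self.B @ p_al)
                  - Lm1 * KPm * p_al + template * r_al)

        # pool derivatives: exact negatives of the weighted polymer sums,
        # so conservation is a linear invariant of the integrated system
        d_P1 = -(self.class_weight_P @ d_p_al + d_p_pi.sum(axis=0)
                 + d_p_pb.sum(axis=0))
        d_R1 = -(self.class_weight_R @ d_r_al + d_r_pi.sum(axis=0)
                 + d_r_pb.sum(axis=0))

        return np.concatenate(
            [d_r_pi, d_r_pb, d_r_al, d_p_pi, d_p_pb, d_p_al,
             d_P1[None, :], d_R1[None, :]], axis=0)

    def __call__(self, t: float, y: np.ndarray) -> np.ndarray:
        out = self._batch(y[:, None])[:, 0]
        if not np.all(np.isfinite(out)):
            raise FloatingPointError("non-finite derivative encountered")
        return out

    def jacobian_fd(self, t: float, y: np.ndarray) -> np.ndarray:
        """Forward-difference Jacobian via one batched vector-field call.

        Kept as an independent cross-check for the analytic Jacobian;
        step sizes are floored at a small fraction of the initial pools
        so that components sitting at or near zero are still perturbed
        within the (locally linear) physical regime.
        """
        p = self.params
        n = y.size
        floor = 1e-9 * max(p.rho_p, p.rho_r, 1e-30)
        h = np.sqrt(np.finfo(float).eps) * np.maximum(np.abs(y), floor)
        Y = np.repeat(y[:, None], n + 1, axis=1)
        Y[np.arange(n), np.arange(n)] += h
        F = self._batch(Y)
        return (F[:, :n] - F[:, n:]) / h[None, :]

    def jacobian(self, t: float, y: np.ndarray) -> np.ndarray:
        """Exact Jacobian of the vector field.

        The field is linear in the polymer concentrations except for
        the products with the monomer pools and for three smooth scalar
        couplings: the effective step rate ``k_eff(R1)``, the catalyzed
        copy rates ``K(L)`` (through the active polymerase block and
        ``k_eff``) and the binding probability ``P_b`` (through the
        generic polynucleotides and ``k_eff``).  The monomer-pool rows
        are exact negative weighted sums of the polymer rows, keeping
        conservation a linear invariant of the linearized system too.
        An exact Jacobian matters here: after catalytic take-off the
        pools are slaved variables with stiff eigenvalues many orders
        of magnitude above the integration timescale, and Newton
        iterations on finite-difference approximations stall.
        """
        p = self.params
        m = self.m
        dim = self.dim
        r_pi, r_pb, r_al = y[:m], y[m:2 * m], y[2 * m:3 * m]
        p_pi, p_pb, p_al = y[3 * m:4 * m], y[4 * m:5 * m], y[5 * m:6 * m]
        P1_raw = y[self.i_P1]
        R1_raw = y[self.i_R1]
        P1 = float(_spos(P1_raw))
        R1 = float(_spos(R1_raw))
        # chain-rule factors for the pool columns (see _batch)
        dP1_col = float(_dspos(P1_raw))
        dR1_col = float(_dspos(R1_raw))

        a = p.h_R * R1
        k_eff = p.k_step * a / (p.k_step + a)
        dk_eff = p.k_step ** 2 * p.h_R / (p.k_step + a) ** 2
        L = self.L
        Lm1 = self.Lm1

        # K(L) and its partials w.r.t. the active polymerase block and R1
        kappa = p.Z * p_pi[self.active_slice]            # (na,)
        den = L[:, None] * kappa[None, :] + k_eff        # (m, na)
        with np.errstate(divide="ignore", invalid="ignore"):
            good = den != 0.0
            T = np.where(good, kappa[None, :] * k_eff / den, 0.0)
            dT_dkap = np.where(good, k_eff ** 2 / den ** 2, 0.0)
            dT_dkeff = np.where(good, L[:, None] * kappa[None, :] ** 2 / den ** 2, 0.0)
        K = T @ self.W_active
        dK_dppi = dT_dkap * (p.Z * self.W_active)[None, :]       # (m, na)
        dK_dR1 = (dT_dkeff @ self.W_active) * dk_eff             # (m,)
        K[~self.mask_active_L] = 0.0
        dK_dppi[~self.mask_active_L, :] = 0.0
        dK_dR1[~self.mask_active_L] = 0.0

        # P_b = W / (W + k_eff) and its partials
        if self.variants.binding_classes == "alpha":
            sites = r_al * self.n_pow_L
            dsites_dral = self.n_pow_L
            dsites_dpi = 0.0
        else:
            sites = (self.n_pow_L - 2.0) * r_al + r_pi + r_pb
            dsites_dral = self.n_pow_L - 2.0
            dsites_dpi = 1.0
        k_b = p.Z * sites * self.bind_mask
        weighted = float((L * k_b).sum())
        den_b = weighted + k_eff
        if den_b != 0.0:
            common = p.Z * self.bind_mask * L * k_eff / den_b ** 2
            P_b = weighted / den_b
            dPb_dral = common * dsites_dral
            dPb_drpi = common * dsites_dpi
            dPb_dR1 = -weighted * dk_eff / den_b ** 2
        else:
            P_b = 0.0
            dPb_dral = np.zeros(m)
            dPb_drpi = np.zeros(m)
            dPb_dR1 = 0.0

        S = np.eye(m, k=-1)                       # shift: row L takes col L-1
        I = np.eye(m)
        e0 = np.zeros(m)
        e0[0] = 1.0
        G_R = p.K_R_plus * R1 * (S - p.n * I)     # spontaneous growth, R side
        G_P = p.K_P_plus * P1 * (S - p.n * I)
        KRm, KPm = p.K_R_minus, p.K_P_minus
        dep_pi = KPm * (1.0 - P_b * self.F)
        tmpl = self.k_P_L * P1

        def prev(c):
            out = np.empty(m)
            out[0] = 0.0
            out[1:] = c[:-1]
            return out

        J = np.zeros((dim, dim))
        b = [slice(i * m, (i + 1) * m) for i in range(6)]
        act = slice(3 * m + (p.l_pi_min - 2), 4 * m)   # active p_pi columns

        # polynucleotide pi / pibar / alpha rows
        J[b[0], b[0]] = G_R + KRm * self.U - np.diag(Lm1 * KRm)
        J[b[0], b[2]] = KRm * self.A
        J[b[0], b[1]] = np.diag(K)
        J[b[0], act] += r_pb[:, None] * dK_dppi
        J[b[0], self.i_R1] = (p.K_R_plus * (prev(r_pi) + e0 * R1)
                              - p.n * p.K_R_plus * r_pi
                              + p.K_R_plus * R1 * e0 + r_pb * dK_dR1)

        J[b[1], b[1]] = G_R + KRm * self.U - np.diag(Lm1 * KRm)
        J[b[1], b[2]] = KRm * self.A
        J[b[1], b[0]] = np.diag(K)
        J[b[1], act] += r_pi[:, None] * dK_dppi
        J[b[1], self.i_R1] = (p.K_R_plus * (prev(r_pb) + e0 * R1)
                              - p.n * p.K_R_plus * r_pb
                              + p.K_R_plus * R1 * e0 + r_pi * dK_dR1)

        J[b[2], b[2]] = G_R + KRm * self.B - np.diag(Lm1 * KRm)
        J[b[2], self.i_R1] = (p.K_R_plus * (prev(r_al) + e0 * R1)
                              - p.n * p.K_R_plus * r_al
                              + p.K_R_plus * R1 * e0)
        if self.variants.alpha_catalysis:
            J[b[2], b[2]] += np.diag(K)
            J[b[2], act] += r_al[:, None] * dK_dppi
            J[b[2], self.i_R1] += r_al * dK_dR1

        # polypeptide pi rows (stabilized depolymerization, P_b coupling)
        if self.variants.stabilization_inflow == "by-length":
            J[b[3], b[3]] = (G_P + self.U @ np.diag(dep_pi)
                             - np.diag(Lm1 * dep_pi))
            g = -KPm * (self.U @ (self.F * p_pi) - Lm1 * self.F * p_pi)
        else:
            J[b[3], b[3]] = (G_P + np.diag(dep_pi) @ self.U
                             - np.diag(Lm1 * dep_pi))
            g = -KPm * self.F * (self.U @ p_pi - Lm1 * p_pi)
        J[b[3], b[5]] = KPm * self.A
        J[b[3], b[0]] = np.diag(tmpl)
        J[b[3], b[2]] += np.outer(g, dPb_dral)
        J[b[3], b[0]] += np.outer(g, dPb_drpi)
        J[b[3], b[1]] += np.outer(g, dPb_drpi)
        J[b[3], self.i_R1] += g * dPb_dR1
        J[b[3], self.i_P1] = (p.K_P_plus * (prev(p_pi) + e0 * P1)
                              - p.n * p.K_P_plus * p_pi
                              + p.K_P_plus * P1 * e0 + self.k_P_L * r_pi)

        J[b[4], b[4]] = G_P + KPm * self.U - np.diag(Lm1 * KPm)
        J[b[4], b[5]] = KPm * self.A
        J[b[4], b[1]] = np.diag(tmpl)
        J[b[4], self.i_P1] = (p.K_P_plus * (prev(p_pb) + e0 * P1)
                              - p.n * p.K_P_plus * p_pb
                              + p.K_P_plus * P1 * e0 + self.k_P_L * r_pb)

        J[b[5], b[5]] = G_P + KPm * self.B - np.diag(Lm1 * KPm)
        J[b[5], b[2]] = np.diag(tmpl)
        J[b[5], self.i_P1] = (p.K_P_plus * (prev(p_al) + e0 * P1)
                              - p.n * p.K_P_plus * p_al
                              + p.K_P_plus * P1 * e0 + self.k_P_L * r_al)

        # pool rows: exact negatives of the weighted polymer rows
        J[self.i_P1, :] = -(self.class_weight_P @ J[b[5], :]
                            + J[b[3], :].sum(axis=0)
                            + J[b[4], :].sum(axis=0))
        J[self.i_R1, :] = -(self.class_weight_R @ J[b[2], :]
                            + J[b[0], :].sum(axis=0)
                            + J[b[1], :].sum(axis=0))
        # the rate laws see the smooth positive part of the pools
        J[:, self.i_P1] *= dP1_col
        J[:, self.i_R1] *= dR1_col
        return J


def rhs(state: PolymerState, params: ModelParameters,
        overrides: Mapping[str, float] | None = None,
        variants: ModelVariants | None = None) -> PolymerState:
    """Time derivative of a polymer state, as a state-shaped record.

    The monomer pools entering the rate laws are evaluated from the
    conservation expressions for the given polymer state.
    """
    system = ReplicatorODE(params, overrides, variants)
    dy = system(0.0, system.full_vector(state))
    return PolymerState.from_vector(dy[:6 * system.m], system.params)


# -- observables -----------------------------------------------------------


@dataclass(frozen=True)
class Observables:
    """Steady-state (or instantaneous) polymerase selection measures.

    ``rho_pi`` and ``rho_alpha`` sum the pi- and alpha-peptide
    concentrations over the active lengths ``l_pi_min..L_max``;
    ``Q1 = rho_pi / rho_alpha`` measures overall selection of the
    polymerase, ``Q2[l]`` the per-length ratio (indexed from length 2).
    Ratios with a zero denominator are reported as ``inf`` and flagged
    through ``degenerate``.
    """

    rho_pi: float
    rho_alpha: float
    Q1: float
    Q2: np.ndarray
    lengths: np.ndarray
    degenerate: bool = False

    def Q2_at(self, l: int) -> float:
        return float(self.Q2[l - 2])


def observables(state: PolymerState, params: ModelParameters) -> Observables:
    sl = slice(params.l_pi_min - 2, params.n_lengths)
    rho_pi = float(state.P_pi[sl].sum())
    rho_alpha = float(state.P_alpha[sl].sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        Q2 = np.where(state.P_alpha > 0.0,
                      state.P_pi / np.where(state.P_alpha > 0.0, state.P_alpha, 1.0),
                      np.where(state.P_pi > 0.0, np.inf, np.nan))
    degenerate = rho_alpha <= 0.0
    Q1 = rho_pi / rho_alpha if rho_alpha > 0.0 else math.inf
    return Observables(rho_pi=rho_pi, rho_alpha=rho_alpha, Q1=Q1, Q2=Q2,
                       lengths=np.arange(2, params.L_max + 1),
                       degenerate=degenerate)


# -- integration to steady state -------------------------------------------


@dataclass
class SolverOptions:
    """Stiff-integration and steady-state detection settings.

    The system spans tens of orders of magnitude in concentration, so
    the absolute tolerance sits far below the smallest physically
    meaningful values.  Steadiness is declared when every component
    would change by less than a fraction ``delta`` of itself (floored
    at ``eps``) over a window of ``window`` seconds, judged from the
    instantaneous derivative.
    """

    method: str = "BDF"
    rtol: float = 1e-8
    atol: float = 1e-40          # mol m^-3, per component
    t_cap: float = 1e13          # s, hard cap on simulated time
    window: float = 1e9          # s, steadiness window tau_w
    delta: float = 1e-6          # relative-change threshold
    eps: float = 1e-30           # mol m^-3, concentration floor in the test
    t_first: float = 1e5         # s, end of the first integration chunk
    chunk_factor: float = 10.0   # geometric growth of chunk ends
    negative_reject: float = 1e-12  # clamp guard, relative to max(rho_p, rho_r)
    save_per_chunk: int = 0      # extra log-spaced saves per chunk (0 = ends only)
    scale_floor: float = 1e-40   # mol m^-3, floor of the per-chunk state scaling


@dataclass
class Trajectory:
    """Integrated time course with per-run diagnostics.

    ``states`` holds one full state vector (six polymer blocks plus the
    two monomer pools) per saved time; ``settled`` reports whether the
    steady-state criterion fired before the simulated-time cap, at time
    ``t_settled``.
    """

    times: np.ndarray
    states: np.ndarray
    params: ModelParameters
    settled: bool
    t_settled: float | None
    diagnostics: dict = field(default_factory=dict)

    @property
    def final_state(self) -> PolymerState:
        return self.state_at(len(self.times) - 1)

    def state_at(self, i: int) -> PolymerState:
        return PolymerState.from_vector(
            self.states[i, :6 * self.params.n_lengths], self.params)

    def pools_at(self, i: int) -> tuple[float, float]:
        return float(self.states[i, -2]), float(self.states[i, -1])

    def final_observables(self) -> Observables:
        return observables(self.final_state, self.params)

    def to_frame(self):
        """Tidy table: one row per saved time, one column per component."""
        import pandas as pd

        m = self.params.n_lengths
        cols = {}
        for bi, block in enumerate(BLOCKS):
            for i, L in enumerate(self.params.lengths):
                cols[f"{block}_{L}"] = self.states[:, bi * m + i]
        frame = pd.DataFrame({"time_s": self.times, **cols})
        frame["P1"] = self.states[:, -2]
        frame["R1"] = self.states[:, -1]
        frame["Q1"] = [observables(self.state_at(i), self.params).Q1
                       for i in range(len(self.times))]
        return frame


def _steady(system: ReplicatorODE, y: np.ndarray, opts: SolverOptions) -> bool:
    dy = system(0.0, y)
    scale = np.maximum(np.abs(y), opts.eps)
    return bool(np.max(np.abs(dy) * opts.window / scale) < opts.delta)


def integrate_to_steady(
    params: ModelParameters,
    options: SolverOptions | None = None,
    overrides: Mapping[str, float] | None = None,
    y0: np.ndarray | None = None,
    t0: float = 0.0,
    t_end: float | None = None,
    variants: ModelVariants | None = None,
) -> Trajectory:
    """Integrate from the all-monomer initial condition toward steady state.

    Integration proceeds in geometrically growing chunks; after each
    accepted chunk small solver undershoots below zero are clipped and
    the steadiness criterion is evaluated.  ``t_end`` stops the run at
    a fixed time instead (switch-off schedules); otherwise the run ends
    at steadiness or at the simulated-time cap, in which case the
    result is returned flagged as not settled.

    Within each chunk the system is integrated in diagonally rescaled
    variables ``z_i = y_i / s_i`` with ``s_i = max(|y_i|, scale_floor)``
    frozen at the chunk start.  The concentrations span some thirty
    orders of magnitude, and without this equilibration the roundoff
    floor of the solver's linear algebra sits far above the error
    tolerance of the smallest components, collapsing the step size;
    the substitution is exact (tolerances are mapped accordingly) and
    the chunk restarts keep the scales current as the cascade grows.
    """
    opts = options or SolverOptions()
    system = ReplicatorODE(params, overrides, variants)
    y = system.initial_state() if y0 is None else np.asarray(y0, dtype=float).copy()
    if y.size != system.dim:
        raise ValueError(f"state vector must have {system.dim} components")
    t = t0
    cap = opts.t_cap if t_end is None else min(t_end, opts.t_cap)
    times = [t]
    states = [y.copy()]
    clamp_events = 0
    max_undershoot = 0.0
    max_cons_residual = 0.0
    settled = False
    t_settled = None
    guard = opts.negative_reject * max(params.rho_p, params.rho_r)
    use_jac = opts.method in ("BDF", "Radau")
    rescale_events = 0

    t_next = max(opts.t_first, t0 * opts.chunk_factor if t0 > 0 else opts.t_first)
    while t < cap:
        t_next = min(t_next, cap)
        t_eval = None
        if opts.save_per_chunk > 0:
            lo = max(t, opts.t_first / opts.chunk_factor)
            t_eval = np.geomspace(max(lo, 1.0), t_next, opts.save_per_chunk + 1)
            t_eval = t_eval[t_eval > t]
            if t_eval.size == 0 or t_eval[-1] < t_next:
                t_eval = np.append(t_eval, t_next)
        S = np.maximum(np.abs(y), opts.scale_floor)

        def f_scaled(tt, z, _S=S):
            return system(tt, z * _S) / _S

        def jac_scaled(tt, z, _S=S):
            return system.jacobian(tt, z * _S) * (_S[None, :] / _S[:, None])

        # The system is autonomous: integrate each chunk in shifted time
        # u = t - t_chunk so that fast transients late in the run are not
        # limited by the floating-point spacing of the large absolute t.
        u_eval = None if t_eval is None else t_eval - t
        sol = solve_ivp(f_scaled, (0.0, t_next - t), y / S, method=opts.method,
                        rtol=opts.rtol, atol=opts.atol / S, t_eval=u_eval,
                        jac=jac_scaled if use_jac else None, dense_output=False)
        sol.t = sol.t + t
        # Accept computed states.  Undershoots below zero are clamped
        # with the clipped (class-multiplicity-weighted) mass returned
        # to the corresponding monomer pool, keeping the conservation
        # invariant intact; a step whose undershoot exceeds the guard
        # is rejected together with the rest of the chunk (the retry
        # below redoes it with fresh scales).
        m = system.m
        guard_breach = False
        for k in range(1, sol.y.shape[1]):
            yk = sol.y[:, k] * S
            neg = yk[:6 * m].min()
            if neg < 0.0:
                if -neg > guard:
                    guard_breach = True
                    break
                max_undershoot = max(max_undershoot, -neg)
                clamp_events += int((yk[:6 * m] < 0.0).sum())
                clipped = np.minimum(yk[:6 * m], 0.0)
                r_mass = (clipped[:m].sum() + clipped[m:2 * m].sum()
                          + system.class_weight_R @ clipped[2 * m:3 * m])
                p_mass = (clipped[3 * m:4 * m].sum() + clipped[4 * m:5 * m].sum()
                          + system.class_weight_P @ clipped[5 * m:6 * m])
                yk[:6 * m] = np.maximum(yk[:6 * m], 0.0)
                # conservation: clipped polymer mass returns to the pools,
                # which may sit (harmlessly) just below zero — the rate
                # laws consume their smooth positive part
                yk[system.i_P1] += p_mass
                yk[system.i_R1] += r_mass
            times.append(float(sol.t[k]))
            states.append(yk.copy())
        if not sol.success or guard_breach:
            # Fast transients (catalytic take-off) can outrun the frozen
            # scaling mid-chunk.  Keep the accepted prefix, refresh the
            # scales there and continue; give up only on zero progress.
            rescale_events += 1
            if rescale_events > 1000 or times[-1] <= t0:
                raise RuntimeError(
                    f"integration failed on [{t:g}, {t_next:g}]: "
                    f"{'clamp guard breach' if guard_breach else sol.message}")
        t = times[-1]
        y = states[-1].copy()
        res_p, res_r = system.conservation_residuals(y)
        max_cons_residual = max(max_cons_residual, abs(res_p), abs(res_r))
        if _steady(system, y, opts):
            settled = True
            t_settled = t
            break
        if sol.success:
            t_next *= opts.chunk_factor

    diagnostics = {
        "clamp_events": clamp_events,
        "max_undershoot": max_undershoot,
        "conservation_residual": max_cons_residual,
        "rescale_events": rescale_events,
        "overrides": dict(overrides) if overrides else {},
    }
    return Trajectory(times=np.asarray(times), states=np.asarray(states),
                      params=system.params, settled=settled,
                      t_settled=t_settled, diagnostics=diagnostics)
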