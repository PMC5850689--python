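"""Experiment drivers: steady-state tables, critical concentrations,
switch-off windows and stability sweeps.

These reproduce the model's characteristic numerical experiments:

* steady-state observables over a range of initial monomer
  concentrations (the production / no-production dichotomy);
* bisection for the critical initial concentration at which sustained
  polymerase production switches on;
* the tau_pol experiment: spontaneous polynucleotide polymerization
  runs only for a window tau_pol before being switched off, probing
  when the catalytic cycle has become self-sustaining;
* the post-equilibrium cleaving-rate sweep: how unstable the
  polynucleotides may become before an established replicator
  collapses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .params import ModelParameters, YEAR_SECONDS
from .ode import (
    ModelVariants,
    Observables,
    SolverOptions,
    Trajectory,
    integrate_to_steady,
    observables,
)

__all__ = [
    "PRODUCTION_THRESHOLD",
    "classify_production",
    "steady_state",
    "CriticalConcentrationResult",
    "find_critical_concentration",
    "TauPolResult",
    "tau_pol_experiment",
    "kr_minus_stability_sweep",
    "reproduce_table",
]

#: Q1 above this is classified as polymerase production.  The observed
#: steady states are bimodal: Q1 stays below ~30 without production and
#: jumps to several hundred with it, so any threshold inside the gap
#: gives the same classification; 100 sits near the log-midpoint.
PRODUCTION_THRESHOLD = 100.0


def classify_production(obs: Observables,
                        threshold: float = PRODUCTION_THRESHOLD,
                        settled: bool = True) -> str:
    """Classify a steady state as ``'production'`` or ``'insignificant'``.

    Refuses (raises ``ValueError``) when the trajectory did not settle,
    since a transient Q1 says nothing about the steady regime.  A
    degenerate state with no generic peptides at the polymerase lengths
    (which makes Q1 formally infinite) is a fully collapsed system, not
    a producing one.
    """
    if not settled:
        raise ValueError("cannot classify an unsettled trajectory")
    if obs.degenerate:
        return "insignificant"
    return "production" if obs.Q1 >= threshold else "insignificant"


def steady_state(params: ModelParameters,
                 options: SolverOptions | None = None,
                 variants: ModelVariants | None = None) -> Trajectory:
    """Integrate the all-monomer initial condition to steady state."""
    return integrate_to_steady(params, options, variants=variants)


@dataclass
class CriticalConcentrationResult:
    """Outcome of a critical-concentration bisection.

    ``mode`` is ``'joint'`` (rho_p = rho_r varied together) or
    ``'rho_r'`` (rho_p fixed, nucleotides varied).  The estimate is the
    bracket midpoint after bisection to ``tol``; the bracket endpoints
    carry the classification evidence (Q1 at the last probes).
    """

    mode: str
    lower: float
    upper: float
    estimate: float
    Q1_lower: float
    Q1_upper: float
    n_runs: int
    history: list = field(default_factory=list)

    def __post_init__(self):
        assert self.lower <= self.estimate <= self.upper


def find_critical_concentration(
    params: ModelParameters,
    mode: str = "joint",
    bracket: tuple[float, float] = (2e-4, 1e-2),
    tol: float = 5e-5,
    options: SolverOptions | None = None,
    variants: ModelVariants | None = None,
    threshold: float = PRODUCTION_THRESHOLD,
) -> CriticalConcentrationResult:
    """Bisect the initial concentration to the production transition.

    Each probe is a full integrate-to-steady run.  The bracket must
    classify differently at its two endpoints (insignificant below,
    production above); bisection proceeds on the geometric midpoint
    until the bracket width falls below ``tol`` (absolute, mol m^-3).
    """
    if mode not in ("joint", "rho_r"):
        raise ValueError("mode must be 'joint' or 'rho_r'")

    def probe(rho: float) -> float:
        if mode == "joint":
            p = params.with_(rho_p=rho, rho_r=rho)
        else:
            p = params.with_(rho_r=rho)
        traj = integrate_to_steady(p, options, variants=variants)
        return traj.final_observables().Q1

    lo, hi = bracket
    if not lo < hi:
        raise ValueError("bracket must satisfy lower < upper")
    Q_lo, Q_hi = probe(lo), probe(hi)
    n_runs = 2
    history = [(lo, Q_lo), (hi, Q_hi)]
    if (Q_lo >= threshold) == (Q_hi >= threshold):
        raise ValueError(
            f"bracket endpoints classify identically: Q1({lo:g})={Q_lo:.4g}, "
            f"Q1({hi:g})={Q_hi:.4g}")
    while hi - lo > tol:
        mid = math.sqrt(lo * hi)  # geometric: the transition is log-sharp
        Q_mid = probe(mid)
        n_runs += 1
        history.append((mid, Q_mid))
        if Q_mid >= threshold:
            hi, Q_hi = mid, Q_mid
        else:
            lo, Q_lo = mid, Q_mid
    return CriticalConcentrationResult(
        mode=mode, lower=lo, upper=hi, estimate=0.5 * (lo + hi),
        Q1_lower=Q_lo, Q1_upper=Q_hi, n_runs=n_runs, history=history)


@dataclass
class TauPolResult:
    """Outcome of the spontaneous-polymerization switch-off experiment.

    ``outcomes`` maps each probed window tau_pol (seconds) to True
    (catalysis became self-sustaining) or False (collapse); the minimum
    sustaining window is refined by bisection between the bracketing
    grid neighbours, reported in seconds and years.
    """

    rho: float
    outcomes: dict
    tau_min_s: float
    tau_min_years: float
    monotone: bool

    def __post_init__(self):
        assert self.tau_min_s > 0


def _switchoff_run(params: ModelParameters, tau_pol: float,
                   options: SolverOptions | None,
                   variants: ModelVariants | None) -> Trajectory:
    """KR+ active for tau_pol seconds, then zero; integrate to steady.

    The system is autonomous, so the continuation restarts its clock at
    zero: its times are seconds since switch-off.
    """
    opts = options or SolverOptions()
    phase1 = integrate_to_steady(params, opts, t_end=tau_pol,
                                 variants=variants)
    return integrate_to_steady(
        params, opts, overrides={"K_R_plus": 0.0},
        y0=phase1.states[-1], t0=0.0, variants=variants)


def tau_pol_experiment(
    params: ModelParameters,
    rho: float,
    tau_grid: Sequence[float] | None = None,
    rel_tol: float = 0.02,
    options: SolverOptions | None = None,
    variants: ModelVariants | None = None,
    threshold: float = PRODUCTION_THRESHOLD,
) -> TauPolResult:
    """Minimum duration of spontaneous polymerization that still seeds
    a self-sustaining replicator.

    The run uses the stated reduced spontaneous rate
    ``K_R_plus = 4e-8`` mol^-1 m^3 s^-1 before the switch-off unless
    ``params`` overrides it explicitly.  Outcomes are classified at
    steady state; the grid bracket around the sustain/collapse boundary
    is refined by geometric bisection to ``rel_tol`` relative.
    """
    p = params.with_(rho_p=rho, rho_r=rho)
    if tau_grid is None:
        tau_grid = np.geomspace(1e6, 1e12, 13)

    def sustained(tau: float) -> bool:
        traj = _switchoff_run(p, tau, options, variants)
        obs = traj.final_observables()
        return classify_production(obs, threshold) == "production"

    outcomes: dict[float, bool] = {}
    for tau in tau_grid:
        outcomes[float(tau)] = sustained(float(tau))
    taus = sorted(outcomes)
    flags = [outcomes[t] for t in taus]
    # monotone: collapse below, sustain above
    monotone = all(b or not a for a, b in zip(flags, flags[1:]))
    if not any(flags):
        raise ValueError("no grid point sustains production; extend the grid")
    first_true = next(i for i, f in enumerate(flags) if f)
    if first_true == 0:
        lo, hi = taus[0] / 10.0, taus[0]
        if sustained(lo):
            raise ValueError("grid starts above the minimum window")
        outcomes[lo] = False
    else:
        lo, hi = taus[first_true - 1], taus[first_true]
    while hi / lo > 1.0 + rel_tol:
        mid = math.sqrt(lo * hi)
        ok = sustained(mid)
        outcomes[mid] = ok
        if ok:
            hi = mid
        else:
            lo = mid
    tau_min = math.sqrt(lo * hi)
    return TauPolResult(rho=rho, outcomes=outcomes, tau_min_s=tau_min,
                        tau_min_years=tau_min / YEAR_SECONDS,
                        monotone=monotone)


def kr_minus_stability_sweep(
    params: ModelParameters,
    rho: float,
    kr_minus_grid: Sequence[float],
    options: SolverOptions | None = None,
    variants: ModelVariants | None = None,
    threshold: float = PRODUCTION_THRESHOLD,
) -> pd.DataFrame:
    """Raise the polynucleotide cleaving rate after the system settles.

    Returns one row per probed ``K_R_minus`` with the continued
    steady-state Q1 and its classification; the largest rate that keeps
    production marks the stability edge of the established replicator.
    """
    p = params.with_(rho_p=rho, rho_r=rho)
    base = integrate_to_steady(p, options, variants=variants)
    rows = []
    for kr in kr_minus_grid:
        cont = integrate_to_steady(
            p, options, overrides={"K_R_minus": float(kr)},
            y0=base.states[-1], t0=0.0, variants=variants)
        obs = cont.final_observables()
        rows.append({
            "K_R_minus": float(kr),
            "Q1": obs.Q1,
            "rho_pi": obs.rho_pi,
            "settled": cont.settled,
            "production": obs.Q1 >= threshold,
        })
    return pd.DataFrame(rows)


def reproduce_table(
    which: int,
    params: ModelParameters | None = None,
    options: SolverOptions | None = None,
    variants: ModelVariants | None = None,
    fast: bool = False,
) -> pd.DataFrame:
    """Re-run the published experiment batteries.

    ``which`` selects the battery: 1 — steady-state observables over
    initial concentrations; 2 — critical nucleotide concentration at
    fixed amino-acid concentrations; 3 — minimum switch-off window
    tau_pol over concentrations; 4 — critical concentration under
    single-parameter variations.  ``fast`` trims the longest rows (used
    by the command-line tool's smoke mode).
    """
    p = params or ModelParameters()
    if which == 1:
        rows = []
        for rho in (2e-4, 9e-4, 1e-3, 1e-1):
            traj = integrate_to_steady(p.with_(rho_p=rho, rho_r=rho),
                                       options, variants=variants)
            obs = traj.final_observables()
            rows.append({
                "rho_p": rho, "rho_r": rho, "rho_pi": obs.rho_pi,
                "Q1": obs.Q1,
                "production": classify_production(obs, settled=True),
            })
        return pd.DataFrame(rows)
    if which == 2:
        rows = []
        rho_ps = (1e-4, 1e-3) if fast else (1e-4, 1e-3, 1e-2, 1e-1)
        for rho_p in rho_ps:
            res = find_critical_concentration(
                p.with_(rho_p=rho_p), mode="rho_r",
                bracket=(2e-4, 1e-2), options=options, variants=variants)
            rows.append({"rho_p": rho_p, "rho_r_crit": res.estimate,
                         "n_runs": res.n_runs})
        return pd.DataFrame(rows)
    if which == 3:
        rows = []
        rhos = (5e-3, 1e-2) if fast else (1e-3, 2e-3, 5e-3, 1e-2)
        for rho in rhos:
            res = tau_pol_experiment(
                p.with_(K_R_plus=4e-8), rho, options=options,
                variants=variants)
            rows.append({"rho": rho, "tau_pol_min_s": res.tau_min_s,
                         "tau_pol_min_years": res.tau_min_years})
        return pd.DataFrame(rows)
    if which == 4:
        variations = [
            ("K_P_minus", 5.1e-6, (2e-4, 1e-2)),
            ("k_step", 2e-2, (2e-4, 1e-2)),
            ("Z", 1e8, (5e-5, 1e-2)),
            ("K_R_plus", 4e-8, (1e-3, 5e-2)),
        ]
        if fast:
            variations = variations[:1]
        rows = []
        for name, value, bracket in variations:
            res = find_critical_concentration(
                p.with_(**{name: value}), mode="joint", bracket=bracket,
                options=options, variants=variants)
            rows.append({"parameter": name, "value": value,
                         "rho_crit": res.estimate, "n_runs": res.n_runs})
        return pd.DataFrame(rows)
    raise ValueError("table index must be 1, 2, 3 or 4")
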