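# Methods

## The model

`nucleoreplicator` integrates a deterministic mass-action model of a
*nucleopeptide reciprocal replicator*: a closed pool of nucleotides and
amino acids in which polynucleotide chains template the synthesis of
peptides, and a family of short catalytic peptides ("primordial
polymerases") copies the polynucleotides in return.  The question the
model answers is whether — and under which monomer concentrations and
rate constants — this mutual catalysis can bootstrap itself from
nothing but spontaneous chemistry and then sustain a polymerase
population far above the background of random peptides.

### State

Chains are tracked per *length* `L = 2..L_max` and per *sequence
class*:

* `pi` — the polymerase-encoding sequence (one specific sequence per
  length, the length-`L` prefix of the full polymerase);
* `pibar` — its base-pairing complement;
* `alpha` — one representative of the remaining `n^L - 2` sequences of
  length `L`, all assumed equally concentrated.

Both polynucleotides (`R`) and polypeptides (`P`) carry these three
classes, giving `6 (L_max - 1)` concentrations (mol m⁻³).  Monomers
are per-type pools `R1` (nucleotides/codons) and `P1` (amino acids),
with `n` types of each; amino-acylated adapter molecules (p-tRNA) are
assumed proportional to the free amino acids, `C_ptRNA = k_t P1`, so
the loading factor `k_t` simply multiplies the templated peptide rate.

### Processes

1. **Spontaneous polymerization** — any chain extends by one monomer
   at rate `K+ · X1` per chain per type (hence an `n·K+·X1` outflow for
   a specific sequence class), and cleaves at each of its `L-1` bonds
   at rate `K−`.  Cleaving longer chains feeds shorter ones with
   sequence-class multiplicities: a length-`L` class is a prefix or a
   suffix of `n^(l-L)` classes of length `l`.
2. **Templated peptide synthesis** — a polynucleotide of length `L`
   and class `S` produces the matching peptide class at rate
   `(k_t k_P1+ / L) · P1 · R_L^S`; the `1/L` reflects the `L`
   sequential adapter-binding steps.
3. **Catalyzed copying** — a polymerase of length `l ≥ l_pi_min`
   attaches to a template (rate `Z · P_l^pi`) and performs `L`
   elongation steps whose effective rate combines nucleotide attachment
   and translocation: `k_R_eff = k_step·h_R·R1 / (k_step + h_R·R1)`.
   The composite rate of one attachment plus `L` steps is the harmonic
   combination `K̃(Z P_l^pi, k_R_eff, L)`; summing over active
   polymerase lengths with the linear quality ramp `W_l` gives the
   per-chain copy rate `K(L)`.  Copying maps `pi ↔ pibar` and `alpha`
   onto itself (the complement of a generic class is another generic
   class of equal concentration).
4. **Bound-state stabilization** — a polymerase bound to a template it
   can copy is protected against hydrolysis.  The bound probability is
   `P_b = W / (W + k_R_eff)` with `W = Z Σ_M M n^M R_M^alpha` summed
   over copyable lengths `M ≥ l_pi_min`; the pi-peptide
   depolymerization rate becomes `K_P− (1 − P_b F(L))` with the
   Boltzmann-motivated shielding factor
   `F(L) = 1 − exp(−(L − l_pi_min + 1)/λ)`.

   Two remarks on this term.  First, the textbook form of `P_b` (mean
   bound time over bound-plus-search time) algebraically reduces to the
   rational `W/(W+k_R_eff)`; we evaluate that form, which is smooth in
   the empty-pool and no-template limits.  Second, restricting the
   binding sum to copyable lengths is essential for the model to have a
   production transition at all: short chains are so abundant that
   counting them as binding sites pins `P_b ≈ 1` at every
   concentration, which would fix the polymerase excess at
   `1/(1−F(l_pi_min)) ≈ 750` even in the most dilute regime —
   contradicting the near-unity polymerase ratio the model exhibits
   below the critical concentration.

### Conservation

The free pools are conservation laws, not independent chemistry:

    P1 = rho_p − Σ_L [ (n^L − 2) P_L^alpha + P_L^pi + P_L^pibar ]
    R1 = rho_r − Σ_L [ (n^L − 2) R_L^alpha + R_L^pi + R_L^pibar ]

The `n^L − 2` weights are the generic-class counts; they are the only
weighting consistent with the `n^(l−L)` depolymerization multiplicities
(under the literal alternative `n·L − 2`, offered as a sensitivity
variant `conservation_weights="literal"`, the cleaving inflows create
weighted monomer mass out of nothing, the pools can be driven far
negative, and the system has no steady state — we verified this
numerically with the invariant preserved to 1e-17).  A strict
per-monomer mass accounting (weighting each chain by `L`) would be the
physically tighter choice; the chain-count form is retained as the
model's defining convention.

### Observables

`rho_pi = Σ_{l≥l_pi_min} P_l^pi` and `rho_alpha` likewise for the
generic class; `Q1 = rho_pi / rho_alpha` and `Q2,l = P_l^pi / P_l^alpha`
measure selection of the polymerase over an arbitrary peptide.  `Q1 ≈ 1`
means no selection; the model is bimodal, jumping from `Q1 ∈ [1, ~30]`
to `Q1 ≈ 750` across a sharp critical initial concentration `rho_c`.
A steady state is classified as *production* when `Q1 ≥ 100`, the
log-midpoint of the observed gap; any threshold inside the gap gives
identical classifications.

## Numerical integration

The system is stiff and spans ~30 orders of magnitude in
concentration.  Choices that matter (all verified against failure
modes observed during development):

* **Pools as state components.**  `P1`/`R1` are integrated alongside
  the polymers, with derivatives defined as the exact negative weighted
  sums of the polymer derivatives.  Conservation is then a *linear*
  invariant, which the implicit multistep integrator preserves to
  Newton/roundoff precision (residuals ~1e-16 observed).  Recovering
  the pools by subtraction instead is catastrophically cancelling once
  catalysis drives them ~9 orders below `rho` and collapses the step
  size.
* **BDF with an analytic Jacobian.**  The vector field is linear
  except for products with the pools and three smooth scalar couplings
  (`k_R_eff`, `K(L)`, `P_b`); the Jacobian is assembled exactly and
  cross-checked against batched finite differences in the test suite.
  Finite-difference Jacobians (including scipy's adaptive one) stall
  the Newton iteration at the catalytic take-off, where the pools are
  slaved variables with eigenvalues ~1e2 s⁻¹ against integration
  steps of ~1e10 s.
* **Per-chunk diagonal rescaling.**  Integration proceeds in
  geometrically growing time chunks; each chunk solves in variables
  `z = y / max(|y|, 1e-40)` frozen at the chunk start, with tolerances
  mapped exactly.  Without this equilibration the solver's error
  estimator senses linear-algebra roundoff across the dynamic range
  and pins the step size near one second.
* **Shifted chunk time.**  The system is autonomous, so each chunk
  integrates `u = t − t_chunk` from zero; late fast transients are then
  not limited by the float spacing of `t ~ 1e12 s` (~1e-3 s).
* **Smooth positive-part pools.**  The rate laws consume
  `spos(x) = (x + sqrt(x² + δ²))/2` of the pools, `δ = 1e-18` mol m⁻³.
  Solver excursions below zero then switch consumption off smoothly
  instead of feeding the quadratic dimerization terms or reaching the
  `k_R_eff` pole at `R1 = −k_step/h_R`.  The residual vector field of
  the completely empty system is ~1e-43 mol m⁻³ s⁻¹, far below any
  physical rate.
* **Clamping with mass return.**  Accepted states clip polymer
  undershoots below zero (guarded at 1e-12 of `max(rho_p, rho_r)`;
  larger undershoots reject the remainder of the chunk and retry with
  fresh scales) and return the class-weighted clipped mass to the
  corresponding pool, so clamping never violates conservation.
* **Steadiness criterion.**  Steady state is declared when every
  component would change by less than `delta = 1e-6` of itself (floored
  at `eps = 1e-30` mol m⁻³) over a window of 1e9 s, judged from the
  instantaneous derivative; hard cap 1e13 s of simulated time, with
  unsettled results returned flagged rather than discarded.  Tolerances
  `rtol = 1e-8`, `atol = 1e-40` per component; halving `rtol` moves the
  settled `Q1` by well under 0.1%.

Typical wall time is one to five seconds per steady-state run
(56 stiff equations at the default `L_max = 10`), which keeps the
bisection experiments (7–10 runs each) and the full test battery at
desk scale.

## Experiments

* **Critical concentration** — geometric bisection on the initial
  concentration (joint `rho_p = rho_r`, or `rho_r` alone at fixed
  `rho_p`) against the production classification, to an absolute
  bracket width of 5e-5 mol m⁻³ by default (tighter for the
  low-threshold structural variants).  Each probe is a full
  integrate-to-steady run from the all-monomer initial condition.
* **Switch-off window (tau_pol)** — spontaneous polynucleotide
  polymerization runs at the reduced rate `K_R+ = 4e-8` mol⁻¹ m³ s⁻¹
  for a window `tau_pol`, then is set to zero; the run continues to
  steady state and is classified.  A grid locates the sustain/collapse
  boundary and geometric bisection refines the minimum sustaining
  window (reported in seconds and years, 1 year = 3.15e7 s).
* **Post-equilibrium cleaving sweep** — the system settles at the
  baseline `K_R−`, then continues from the settled state under raised
  cleaving rates; the largest rate that retains production marks the
  stability edge of the established replicator.

## Calibration status

The implementation reproduces the model's qualitative and structural
behaviour in full: the sharp bimodal production transition, the
`Q1 ≈ 750` plateau independent of concentration above threshold
(`1/(1−F(7)) = 785.6` is the bound-polymerase lifetime ratio), the
near-unity ratios below threshold, and the scaling of the critical
concentration with the rate constants — `rho_c ∝ Z^(-1/7)`,
`rho_c ∝ K_R+^(-6/7)`, near-invariance to `K_P−` and `k_P1+` (the
amino-pool drain self-compensates in the take-off loop gain), and the
weak `rho_p^(-1/6)` dependence of the nucleotide threshold.  On the
absolute scale the take-off calibrates to a critical concentration of
1.57e-3 mol m⁻³ under the baseline parameters (the reference analysis
of this replicator reports ~1.0e-3), with the single-parameter
variants shifted correspondingly (Z = 1e8 → 5.8e-4 here vs 5e-4;
K_R+ = 4e-8 → 9.8e-3 vs 7e-3; the minimum-length-4 variant's critical,
2.05e-5 vs 2e-5, agrees within the bisection tolerance).  The
loop-gain offset behind the baseline shift could not be attributed to
any defensible reading of the model equations (the systematic variant
analysis is summarized above and the alternatives are exposed as
`ModelVariants`).  Quantities tied to the absolute threshold inherit
the offset — in particular, concentrations just above the reference
critical point sit just below this calibration's, and the switch-off
windows under reduced `K_R+` are far longer here because `rho = 0.01`
is then only marginally supercritical.  Ratio-type observables (the
`Q1` plateau, the below-critical `Q1`) do not inherit it.

## Limitations

* No explicit sequences: the three-classes-per-length reduction is the
  model, not an approximation the package controls.
* No copying-fidelity/mutation dynamics and no stochastic
  small-copy-number effects; concentrations are deterministic
  continuum variables even at ~1e-32 mol m⁻³, where a real pool would
  contain no molecules at all.
* The steady states below the critical concentration are reached by
  ~1e12 s of simulated time; results at the 1e13 s cap are flagged if
  the steadiness criterion has not fired.
* The full-length polymerase concentration `P_L_max^pi` equilibrates on
  the bound-stabilized timescale `1/(9 K_P− (1−P_b F(L_max)))`, which
  exceeds the simulated-time cap; its reported steady value is the
  frozen post-take-off level, and length-resolved ratios at `L_max`
  should be read with that in mind.
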