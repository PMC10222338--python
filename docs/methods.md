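# Methods

`neqswitch` computes free energy differences ΔA between two *levels of
theory* — two Hamiltonians U_low and U_high sharing one configuration space —
from non-equilibrium work (NEW) switching simulations, and provides the
diagnostics needed to judge whether such calculations have converged.  The
package ships toy dual-level model systems with exact oracles so that every
estimator and every diagnostic can be validated end to end on a desk.

## The switching framework

A switch drives the system from one level to the other over `Nswitch`
Langevin-dynamics steps while a coupling parameter λ mixes the Hamiltonians,

    U(λ) = (1 − λ)·U_low + λ·U_high .

λ follows a piecewise-linear schedule in time; the standard ramp (label
`L1`) is λ(i) = i/Nswitch.  After every dynamics step the accumulated work is
incremented with both energies evaluated at the *post-step* coordinates,

    W(t+δt) = W(t) + U(x_{t+δt}, λ_{t+δt}) − U(x_{t+δt}, λ_t),

which for the linear mixture reduces to (Δλ)·[U_high − U_low] at the new
coordinates.  λ₀ = 0 at the start configuration and the first increment
happens at step 1.  The thermostat stays active during switches by default
(same friction as equilibrium sampling — dissipative switching under the
simulation thermostat is the regime the estimators are built for);
`SwitchSettings.friction` overrides it, and `friction=0` turns the stochastic
force off entirely.  A backward switch runs the same schedule on the
level-swapped system, starting from a high-level equilibrium configuration.

Three multi-stage schedules are shipped (2000 fs total), in which λ rises
quickly at first and more slowly afterwards: `L2-1` (0→0.35 in 200 fs,
0.35→1 in 1800 fs), `L3-1` (0→0.35→0.8→1 over 200/900/900 fs) and `L3-2`
(200/400/1400 fs).  Breakpoints are defined in time, not steps; λ at an
integer step is the exact piecewise-linear interpolation, so stage
boundaries need not align with steps.

## Estimators

* **Jarzynski (JAR)** — ΔA = −kT·ln⟨e^(−βW)⟩ over forward works, evaluated
  with a log-sum-exp reduction (overflow-free by construction).  Its
  uncertainty is a seeded bootstrap (default 1000 resamples); the asymptotic
  variance of an exponential average is unreliable at practical sample
  sizes.  JAR is bounded above by ⟨W⟩ (Jensen) and biased high at finite n;
  the work standard deviation σ_W is the convergence indicator.

* **Two-sided (CRO)** — the Bennett maximum-likelihood estimator on forward
  and backward works, i.e. the statistically efficient estimator implied by
  the Crooks relation P_F(W) = P_R(−W)·e^{β(W−ΔA)}.  The self-consistency
  equation is solved by bracketed root finding to |update| < 1e−8 kcal/mol;
  the stderr is the Bennett asymptotic value (clamped at zero in degenerate
  cases), cross-checked by bootstrap.  Diagnostics: σ_W per direction, the
  histogram overlap ∫min(P̂_F(W), P̂_R(−W)) dW on shared Freedman–Diaconis
  bins, and the *Crooks slope* — the fitted slope of ln[P̂_F(W)/P̂_R(−W)]
  vs W, which must equal β.  The slope is fitted by default in its
  maximum-likelihood (logistic-regression) form on the unbinned works; the
  binned weighted regression (bins holding ≥ 5 samples from each direction,
  delta-method weights) is available as `method="histogram"`.  The binned
  form carries a sparse-bin Jensen noise of ±20 % at 500+500 works; the MLE
  form measures the same slope with a few-percent scatter.

* **Staged BAR** — pairwise Bennett estimates between neighbouring states of
  a λ ladder, summed, with stage variances propagated in quadrature.  The
  default charge-perturbation ladder is λ = (0, 0.25, 0.5, 0.75, 1).  The
  simulation drivers (`staged_ladder_delta_a`, `charge_ladder_delta_a`,
  `brute_force_delta_a`) repeat the whole ladder from independent seeds
  (default 6–8 repetitions) and report the repetition mean with the
  repetition stderr — an error estimate that stays honest when samples
  within a window are time-correlated.  Windows are chained (each λ window
  starts from the previous window's final configuration) so only the first
  window pays the full equilibration cost.

δΔA reporting follows the two-path convention: a direct protocol is judged
by δΔA = ΔA_estimate − ΔA_reference; a protocol running through a hybrid
charge intermediate adds the classical low↔intermediate correction,
δΔA = ΔA(low↔MULL) + ΔA(MULL→high) − ΔA_reference.  `mad_and_spread`
summarizes a set of δΔA values by the mean, minimum and maximum of their
absolute values.

## Hybrid charge intermediates

When the two levels differ mainly in the solute's charge distribution, the
one-sided low→high estimate converges slowly because the solvent must
reorient during the switch.  A *hybrid charge intermediate* ("MULL" state)
is a low-level Hamiltonian whose fixed charges are the ensemble average of
the fluctuating high-level charges, derived by `derive_average_charges`:
instantaneous high-level charges are evaluated on a deterministic
even-spaced selection of pool configurations (default 200), averaged per
atom (per-atom std with the n−1 denominator), and re-neutralized by uniform
subtraction of the excess.  The source label records the averaging ensemble:
`MULL(gas)` (solvent-free low-level pool), `MULL(solv)` (solvated low-level
pool) or `MULL(solv*)` (solvated high-level pool).  On the toy systems the
gas-phase electrostatic potential vanishes, so `MULL(gas)` coincides with
the base charges — the gas-phase variant is degenerate by construction here,
and the variant comparisons concern `MULL(solv)` and `MULL(solv*)`.

The low↔MULL leg is purely classical and is computed by staged BAR over the
interpolated ladder q(λ) = (1−λ)·q_low + λ·q_MULL.  On the dipole-bath toy
this leg also has an exact closed form (below), which serves as a sharp
oracle for the staged route.

## Toy model systems

### Harmonic pair

One particle (mass 12 amu) with U_low = ½k_low·x² and
U_high = ½k_high·(x−offset)².  ΔA = ½kT·ln(k_high/k_low) exactly, offset
notwithstanding — the offset only controls how dissipative finite-rate
switches are.  This is the oracle for all estimator validation; the
reference configuration is k 1 → 4 kcal/mol/Å² at kT = 0.6 kcal/mol
(ΔA = 0.3·ln 4 ≈ 0.416 kcal/mol).

### Dipole-bath system

A rigid multi-site solute with fixed partial charges sits in a bath of
point-dipole rotors at fixed lattice positions; each rotor's dipole
(magnitude m, in e·Å) is confined to the xy-plane and evolves by rotational
Langevin dynamics on its angle (inertia I, friction γ).  Electrostatics are
untruncated charge–dipole interactions (Coulomb constant 332.0637
kcal·Å/(mol·e²)); rotors do not interact with each other.  The low level
uses the base charges q⁰.  The high level is an *induced-charge* model: with
φ the vector of electrostatic potentials at the atoms and P = I − (1/n)𝟙𝟙ᵀ
the neutrality projection,

    U_high = q⁰·φ + ½·(Pφ)ᵀ K (Pφ),        K = diag(κ),

whose φ-gradient defines the effective ("Mulliken-like") charges

    q_high = q⁰ + P·(κ ⊙ Pφ) .

For uniform κ this is exactly the plain linear response q⁰ + κφ
re-neutralized by uniform subtraction.  The ½-induction form is the standard
linear-response polarization energy; it makes the charges and the forces the
bath feels one consistent object, and it is positive semidefinite for any
κ ≥ 0, so the charge response is thermodynamically stable at every bath
configuration.  (The naive form U = q_high·φ doubles the force-level damping
relative to the charge damping; in that model the low-level-ensemble charge
average overshoots the high-level mean and the intermediate-state orderings
invert.)

Because the rotors are independent at any *fixed* charge set, the
configurational partition function factorizes into one-rotor integrals
2π·I₀(βA_j), with A_j the in-plane field amplitude at rotor j.  ΔA between
two fixed charge sets is therefore exact
(`analytic_charge_leg_delta_a`) — the oracle for the classical legs.  The
full low↔high ΔA has no closed form (the quadratic term couples the rotors
through the solute); the reference there is densely windowed staged BAR
(`brute_force_delta_a`) and long two-sided switching.

### The shipped fixture (`polar_solute_64rotors`)

A symmetric collinear 3-site rod (charges −0.35, 0, +0.35 e at ±0.55 Å) in
64 rotors on a 4×4×4 lattice spanning ±6 Å.  Defaults: m = 3.2 e·Å,
γ = 50 ps⁻¹, I = 25 amu·Å², κ = 0.0016 e/(kcal/mol/e) uniform, T = 300 K.
The symmetric rod is deliberate: uniform response to the projected potential
can only *rescale* its polarity, never restructure it, so the intermediate
states always lie on the one-parameter polarity path between the levels.
The defaults were calibrated once against the statistical regime the
analyses probe and then frozen:

* per-atom high-level charges fluctuate with std < 0.03 e about means
  shifted by ≈ 0.2 e from the base charges (averages are meaningful);
* bath reorientation after a charge jump relaxes with a fast inertial
  component and a slow diffusive component of ≈ 1.4–1.6 ps, so 2 ps
  switches from the low level are *marginally* converged — the regime where
  hybrid charge intermediates matter;
* the 2 ps MM-start one-sided estimate carries a bias of ≈ 1 kcal/mol,
  about three times its sampling noise, while intermediate-start switches
  are unbiased within noise.

What the fixture does *not* emulate: molecular solvents with
translational degrees of freedom and hydrogen-bond structure, flexible
solutes and conformational substates, periodic boundary conditions, and
real electronic-structure charge fluctuations (which respond to geometry,
not only to the environment field).  Passing tests demonstrate that the
estimators, protocols and diagnostics behave correctly in the statistical
regime they were designed for — not that any particular molecular system
converges at a particular switching length.

## Dynamics and sampling plans

The integrator is BAOAB Langevin splitting; with a 1 fs timestep all toy
systems are far below their stability limits and the configurational
sampling error is negligible against the statistical errors at the shipped
problem sizes (verified against the exact rotor partition function and the
harmonic Boltzmann distribution).  Velocities are drawn from the
Maxwell–Boltzmann distribution per replicate; restart records carry
positions *and* velocities, and switches start from the recorded velocities
without resampling.  All randomness flows from a master seed through a
splittable counter scheme (`seeds.child_seed`), so every pool, switch,
bootstrap and benchmark is bit-reproducible.

Two sampling-plan facts dominate the statistics and are reflected in the
benchmark defaults:

* **Start decorrelation.**  Switch starts are taken from saved restarts
  spaced by at least one relaxation time (harmonic: position relaxation
  ≈ 0.4 ps, saves every 0.5–1 ps; dipole bath: weak-field rotors relax by
  free diffusion with τ = ζ/2kT ≈ 2.5 ps at γ = 50 ps⁻¹, saves every 2 ps,
  equilibration 30 ps).  Correlated starts distort the Bennett stderr and
  the Crooks-slope diagnostic.
* **Replicate count.**  The pool-level fluctuation of a few long replicates
  propagates coherently into every work value they seed; benchmarks use 16
  shorter replicates at equal total cost, which measurably removes a
  between-seed variance component.  (`SamplerSettings` defaults to the
  classic 8-replicate design; the benchmarks scale the plan to the toy
  systems' relaxation times.)

## Stokes-shift analysis

After an instantaneous low→high jump from an equilibrated start, the
ensemble-averaged energy gap ΔU(t)‾ = ⟨U_high − U_start-level⟩(t) relaxes to
a long-time baseline ΔU(∞)‾, estimated by time-averaging the final 20 % of
the series (for a 10 ps / 1 fs series: the last 2000 entries; configurable
window).  The shifted series ΔΔU(t)‾ = ΔU(t)‾ − ΔU(∞)‾ is an unnormalized
Stokes shift.  It is fitted to a single exponential ΔU0·e^(−t/τ) by
unweighted least squares on the averaged series, with the first 0.5 ps
discarded so the fit captures the slow reorientation process; initial
guesses come from a log-linear regression on the positive segment, and no
additive offset is fitted (the baseline is already subtracted).  A
non-positive or sign-alternating series over the fit window raises a
degenerate-fit error rather than returning a meaningless τ.

The relaxation time is a property of the bath — MM-start and
intermediate-start ensembles give comparable τ — while the amplitude ΔU0
tracks the charge mismatch between the start level and the target, which is
why `evaluate_fit_at(fit, 2000 fs)` predicts how far from equilibrium a
2 ps switch ends.

## Charge-distribution and solvation-shell metrics

Charge sets are compared by RMSD_q (root-mean-square per-atom difference),
the differential dipole Δμ→ = Σᵢ Δqᵢ·rᵢ (reported in Debye, 1 e·Å =
4.80320 D; origin-independent for neutral differences — all fixtures are
neutral), and the angle between full dipole vectors.  Dipoles use the rigid
solute's fixed reference geometry.  The first solvation shell counts solvent
sites within ≤ 3 Å (inclusive) of any heavy solute site; `delta_n_waters`
compares shell means between two trajectories.

## Numerical choices and edge cases

* Bennett root bracketed at min/max work ± 100 kT; tolerance 1e−8 kcal/mol.
* Zero histogram overlap: the two-sided estimate is still returned, flagged,
  with the stderr inflated to the spread of the two sample means.
* Degenerate (constant) work samples: JAR returns the constant exactly;
  Bennett solves the constant-sample equation exactly.
* The asymptotic Bennett variance is clamped at zero before the square
  root; the benchmark drivers additionally report a leave-one-replicate-out
  jackknife stderr when starts carry replicate provenance, and use the
  larger of the two.
* `stepwise_schedule` validates that stage durations sum to the total and
  that λ never decreases; `lambda_at` is exact at breakpoints.
* Charge-set files, restart pools, work tables and estimates are plain text
  and round-trip byte-identically (floats serialized via shortest-repr).

## Problem sizes

The benchmark workflows follow the classic study design — 200 switches of
2000 steps per transformation, forward/backward pairs for two-sided
references, 200-configuration charge averages, three-state default charge
ladders — scaled onto toy systems whose relaxation times are picoseconds
rather than nanoseconds: equilibrium pools of 16 replicates × 25–55 ps,
ladders of 11 windows × 12 ps × 8 repetitions on the fixture's steep
classical leg, and 150 relaxation trajectories of 6 ps for the Stokes fits.
`scripts/acceptance.py --seed N --out results.json` re-runs all of them from
scratch and writes every measured quantity.
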