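# Methods

## The model

`cbvsim` simulates a minimal, well-mixed, materially open ecosystem in which
*what competes is not species but recycling pathways*. A biologically
essential element J occurs in three interconvertible variants J1, J2, J3.
Each variant enters the system abiotically at a constant rate `Fin0` and is
removed in proportion to its level (`Fout0`). Four microbial species drive
Michaelis–Menten interconversion reactions:

| species | reaction |
|---|---|
| A | J1 → J2 |
| B | J2 → J1 |
| C | J1 → J3 |
| D | J3 → J2 |

Two overlapping recycling loops — *cycle-biota variants* (CBVs) — result:
**AB** (J1 ↔ J2) and **CDB** (J1 → J3 → J2 → J1). Reaction B closes both
loops, so the two variants share genes and substrates and cannot be
distinguished by genotype-level selection alone.

Each species comprises two genotypes: the reaction-performing genotype *p*
and a wild type *q* (p + q = 1). The performer's absolute fitness is
`W0·(1 + s·J_substrate)`; the wild type's is `W0`. Mutation happens at
reproduction: loss of function with probability `m0` per event, gain of
function with probability `m0²` (gain-of-function is the rarer event).
Reproductive events per genotype are `round(W · frequency)`, and each event
draws a uniform number against the mutation probability; the realized
mutation fractions enter the frequency derivative

    dp/dt = (W_p − W̄)/W̄ − m_p + m_q,

with W̄ the count-weighted mean fitness. Population sizes follow a
density-regulated growth law (see *Numerical and interpretive choices*).

Reactions A and B divert a fraction `eps_X` of their throughput into
byproduct pools XA and XB of a second, climate-like cycle. The byproducts
react together (flux `Xvar`, Michaelis–Menten in the product XA·XB) and
titrate an initially inert solid-state reservoir `Xres`. Titrated material
accumulates in a transition pool `Xres2` and is released into the main X
pool only once the reservoir is exhausted — a threshold event analogous to
the sudden release of a frozen volatile reservoir. The X pool carries an
inherent bistability: a sigmoidal feedback flux of amplitude `Xfeedback0`
switches on between `Xon` and `Xoff`, so the release pulse can latch X onto
a high stable branch (X* ≈ Xin0 + Xfeedback0). Above `Xsuppress` the
suppression function

    α(X) = α0 / (1 + e^(−k_alpha·(X − Xsuppress)))

imposes a per-capita kill term on species C only. Killing C removes the CDB
variant; the AB variant, whose byproducts caused the transition, persists.
The competition between the two pathways is therefore decided entirely by
their climatic side effects — *persistence selection* — and never by
differential genotype-level selection.

## Timescales and integration

The three subsystems run on nested clocks: biology fastest, the J-cycle
slower by `tau_J`, the X-cycle slower again by `tau_X`. To avoid the
instabilities of infrequent large steps, every subsystem is integrated at
every biological step with its deterministic and diffusion contributions
scaled to effective substeps `dt_J = dt_bio/tau_J` and
`dt_X = dt_bio/(tau_J·tau_X)`.

Integration is Euler–Maruyama: each state variable receives
`f·dt_sub + sigma_bar·g·sqrt(dt_sub)·N(0,1)`. The diffusion coefficients
derive from the binomial variance of the mutation process: per species,
`g_S = sqrt(Σ_genotypes m0_k(1−m0_k)/RE_k)`; per reaction,
`g_R = (∂R/∂n_p)·sd(n_p)` with `VAR(n_p) = p²·VAR(S) + M²·VAR(p)`; per
J-variant, the root-sum-square of the g_R of the reactions entering its
equation; the main X pool combines the byproduct terms directly and through
the exact partial derivatives of the byproduct-reaction flux. All partial
derivatives are exact analytic forms, validated against central finite
differences in the test suite.

Randomness is consumed in a fixed, documented order per step (mutation
uniforms species A→D, then ten standard normals: bio A→D, J1→J3, XA, XB,
X), so a run is a pure function of its seed.

**Deterministic mode.** `sigma_bar = 0` removes the diffusion terms *and*
replaces sampled mutation fractions with their expectations, making runs
bit-identical across seeds. This is the package's definition of the
deterministic limit; it is what the reproducibility contracts and the
deterministic timescale scans use.

## Numerical and interpretive choices

Several published forms admit more than one reading; the package fixes each
with a documented default and, where useful, a switch:

* **Growth law.** Default `g0·M·(1 − M/K)·|1 − M/K|`: the square-outside
  reading of the density regulation, implemented with a restoring sign
  above K (a literal square would make any noise-driven overshoot of K
  self-amplifying). This form keeps per-capita growth strictly below `g0`
  at low density, which is what allows a near-unit suppression rate to
  drive species C extinct. The alternative `g0·M·(1 − (M/K)²)` is available
  (`growth_square_outside=False`); under it the density term vanishes at
  small M, the kill term is neutralized at `M* = K·sqrt(1−α)` ≈ 5–30
  individuals, and suppression stalls without completing an extinction.
* **Reproductive events** are computed from fitness × *frequency* as
  printed (counts of 0 or 1 at default fitness); a population-scaled
  variant (`re_scale_by_population=True`) is provided. The frequency form
  makes realized mutation fractions 0 or 1, so genotype frequencies move in
  unit jumps — the dominant noise source in the model. The
  population-scaled variant concentrates the fractions at `m0`, under which
  default selection (`s·J ≈ 0.01`) cannot balance default mutation loss
  (`0.1`) and performer frequencies collapse; the frequency form is what
  sustains cycling at the default parameters.
* **Frequency dynamics are literal.** The selection excess
  `(W_p − W̄)/W̄` lacks the factor p of the standard replicator equation
  and is therefore positive even at p = 0: selection can re-seed an extinct
  genotype. Suppressing that (mutation-only regeneration) was evaluated and
  collapses the byproduct flux entirely, so the literal form is kept. A
  consequence: a *strictly abiotic* configuration requires `s = 0` as well
  as `m0 = 0` and p(0) = 0.
* **Demographic extinction is absorbing.** A population whose size reaches
  0 has no reproductive events, hence no mutation, no selection update and
  no reproduction noise; its genotype frequencies are set to 0. Without
  this rule the suppression of species C can never reach the CBV index
  (the frequency dynamics are otherwise decoupled from population size) and
  displacement cannot occur.
* **Reservoir depletion cutoff.** The titration law `dXres/dt = −Xvar·Xres`
  decays multiplicatively and never reaches zero exactly; `xres_eps` sets
  the level below which the reservoir counts as exhausted. The residual is
  transferred to the transition pool in bulk, conserving the titration mass
  balance so that the release pulse carries the full initial reservoir
  (≈ `Xres_init` units) — enough to cross the bistable region. `Xres_init`
  and `xres_eps` jointly calibrate the depletion time; the defaults (5 and
  3) place exhaustion at ≈ 1100–1300 biological steps for `tau_X = 10` and
  ≈ 2× that for `tau_X = 20`, so the default 2000-step horizon separates
  the two regimes.
* **Release-rate parse.** `Xrelease = Xrel0·(Xres2 + Xvar)` — all titrated
  material plus the incoming flux passes through (with the default
  `Xrel0 = 1` the alternative parse coincides).
* **Diffusion composition.** The two genotypes' binomial variance rates
  combine by root-sum (additivity of independent variances); the literal
  product is available (`gs_literal_product=True`). "Sum of squares" terms
  combine as root-sum-square, so every g is a standard-deviation-scale
  coefficient.
* **Rounding** is to the nearest integer, ties away from zero, for
  performer counts and reproductive-event counts; the wild-type count is
  the (continuous) remainder `M − n_p`.
* **Clamping.** Frequencies are clamped to [0, 1] and nutrient/X-cycle
  levels to ≥ 0 after every step. The X-cycle constants not fixed by the
  standard table default to `Xin0 = Xout0 = 1`, placing the abiotic X
  steady state (1) below both `Xon` (3) and `Xsuppress` (3.5): suppression
  is impossible without biological byproducts.
* **Initial conditions.** Species at carrying capacity with p = 0.5,
  nutrient and X pools at their abiotic equilibria, byproduct pools empty,
  reservoir full: the system starts at the abiotic equilibrium with both
  CBVs equally represented.

## What the experiments show — and what they do not

All experiments are self-generated simulations; there is no external data.
The synthetic runs emulate the *structure* of the hypothesized phenomenon —
threshold-gated, timescale-dependent coupling between microbial byproducts
and an environmental switch — not any real biogeochemical system. Passing
tests demonstrate internal consistency (conservation, closed-form limits,
oracle agreement) and the qualitative regime structure (displacement below
a timescale threshold, none above; covariance of suppression with
displacement). They say nothing about real elemental cycles, real mutation
processes, or the realism of the parameter magnitudes.

The single-event mutation sampling deserves emphasis: with reproductive
events of 0 or 1 per step, realized mutation fractions are Bernoulli and
genotype frequencies execute unit-magnitude jumps. Population-genetic
quantities (mean performer frequency ≈ 0.3–0.5 at defaults) are emergent
properties of this jagged process, and the instantaneous CBV share
fluctuates with a standard deviation of roughly 0.18 even at steady state.
Steady-state comparisons of the share are therefore meaningful only in
replicate or time averages; single-timepoint share values are noisy. This
is a property of the published sampling scheme implemented literally.

"Steady state" is operationalized as the final recorded step of a
fixed-length run (default 2000 biological steps). A convergence diagnostic
(relative change of the mean J-level over the last 10% of the record) is
reported per replicate but not enforced.

## Problem sizes

Default experiment scales, chosen to run comfortably on a single CPU:
runs of 2000 biological steps; the timescale contrast uses 20 seeded run
pairs; sweeps use 5 × 5 grids with 50 replicates per cell (the replicate
count is a flag, so larger ensembles remain available); correlations reuse
the sweep replicates. Grid ranges: s ∈ [0, 0.05] (linear), m0 ∈ [0.01, 0.3]
(log), byproduct efficiency and suppression magnitude ∈ [0, 1] (linear).
The grid ranges are package choices; published sweep axes are not
enumerated numerically anywhere we could transcribe them.

## Known limitations

* The frequency-based reproductive-event counts make the mutation process
  independent of population size except at extinction; there is no genuine
  drift scaling with 1/M.
* The biological diffusion coefficient has allele-frequency units but is
  applied to the population-size update, as printed; treat absolute
  magnitudes of M-fluctuations as qualitative.
* The depletion cutoff and reservoir size are calibration knobs for the
  regime threshold, not measured quantities.
* The topology is fixed at three variants and four reactions; the wiring
  table exists to make extension possible, but no other topology has been
  exercised.
* Only species C can be suppressed, and only one environmental switch
  exists.
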