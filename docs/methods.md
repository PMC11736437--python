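# Methods

## The deterministic circuit

A C-controlled Type II R–M system is reduced to one ordinary differential
equation for the total control-protein concentration C_t. Production is
proportional to plasmid copy number n and to the P.CR transcription
activity; loss is dilution by growth (rate λ) — C is stable, so no
explicit degradation term. The activity is a Shea–Ackers-style
statistical-weight model over the C-binding configurations of P.CR: a
C dimer at the distal site activates (weight Z₁), a dimer at the proximal
site represses (Z₃, retained for completeness although not observed), and
the cooperative DBS·PBS tetramer represses (Z₂). Because the measured C
dimerization constant is comparable to cellular C concentrations, the
monomer–dimer equilibrium is kept exactly: free monomer C solves
2C²/K_d1 + C = C_t, and all binding weights are functions of C, not C_t.

After rescaling concentrations by K_d = √(K_d1 K_d2) and time by
K_d/(n φ_m), the circuit depends on five dimensionless parameters:
internal (p, ω, α) fixed by the biophysics of one system, and external
(s, r) set by physiology. The model's assumptions: binding equilibrates
fast relative to expression; transcription and translation are lumped
into one production step; R is co-transcribed with C so R_t = K_RC·C_t
exactly; cell volume is constant within a division cycle.

### Steady states and the fold boundary

Steady states are zeros of `rhs(C̃_t) = s + f(C̃) − C̃_t/r`. Since the
activity is bounded by s + 1, all roots lie in [0, r(s+1)]; they are
bracketed by sign changes over 2 000 log-spaced points, refined by
Brent's method (xtol 1e-12), deduplicated at 1e-8 relative distance, and
classified by the analytic derivative
`f′(C̃)·dC̃/dC̃_t − 1/r` (negative ⇒ stable), with
f′(C̃) = 2C̃(1 − (ω/p)C̃⁴)/den² and dC̃/dC̃_t = 1/√(1+8C̃_t/α). A root
count outside {1, 3} is flagged as boundary-degenerate rather than
raised: it occurs only at fold points.

Saddle-node (fold) parameter combinations satisfy `rhs = 0` and
`∂rhs/∂C̃_t = 0` simultaneously. Solving the second for r and
substituting into the first gives the fold locus **in closed parametric
form** over the steady-state coordinate:

    r(C̃_t) = 1 / (f′(C̃) · dC̃/dC̃_t),     s(C̃_t) = C̃_t / r − f(C̃),

admissible where f′ > 0, i.e. C̃ < (p/ω)^¼. The C̃_t grid is log-spaced
from 1e-8 to the total corresponding to C̃ = 0.999999·(p/ω)^¼ (r diverges
at both ends; log spacing resolves the cusp). The cusp — the tip of the
bistable wedge in the (r, s) plane and the global maximum of s along the
curve — is read off the grid; at the default 2 000 points its s value is
converged to ≈1e-6. For Esp1396I this yields s_max = 0.0504: bistability
requires promoter leakage below about 5% of maximal activity.

Region classification (`is_bistable`, `fold_interval`) intersects a
horizontal line at s with the two branches on either side of the cusp;
the wedge area within a finite window integrates the clipped interval
width over s (the wedge is unbounded in r, so a window is required).
Bifurcation diagrams and the cusp surface re-solve the steady states per
grid point; monostable cells assign their single root to the low or high
sheet by comparison with the cusp C̃_t, which keeps the sheets continuous
across the wedge edge.

### P.M architectures and the M-to-R ratio

* Esp1396I: C-dimer repression, M̃_t = φr/(1 + γC̃²), γ = K_d2/K_dM = 5.1.
* AhdI: M autorepression with its own monomer–dimer equilibrium
  (α_M = 2√5): M̃_t(1 + M̃²) = φr, solved by Brent bracketing on
  [0, φr] — the residual is strictly increasing, so the root is unique;
  φ = 0.2 from the measured constants.
* EcoRV: divergent overlapping promoters; P.M fires whenever RNA
  polymerase is not engaged at P.CR, giving
  M̃_t = φr(1 + Z̃₂ + Z̃₃)/(1 + Z̃₁ + Z̃₂ + Z̃₃).

φ defaults to 1 for Esp1396I and EcoRV (only AhdI's value is pinned by
measurements; the ratio axes are in arbitrary units regardless). Ratios
are reported per stable branch, never averaged across branches.

**Trend window.** The claim "M/R falls with expression strength" is a
figure-scale statement. Globally it is false for some architectures: far
above the fold region leakage dominates R production while P.M repression
saturates, and the ratio turns back up (e.g. EcoRV at s = 0.2 has its
ratio minimum near r ≈ 3.8; AhdI at s = 0.0043 near r ≈ 9.7). The
package therefore defines `trend_window`: from 5% of the cusp r up to
1.2× the upper fold r (bistable leakage) or 1.5× the cusp r
(monostable). Within that window the ratio is non-increasing along every
stable branch for all three presets; the turnaround beyond it is a
genuine model feature, documented rather than asserted away.

## Leakage calibration

Three fitting routes, all unit-invariant (amplitude rescaling moves only
the amplitude estimate):

* **Activity curves**: activity = A·(s + f(C̃)) is linear in (A·s, A);
  solved by linear least squares with a bounded nonlinear refit if the
  unconstrained basal offset leaves s ∈ [0, 1].
* **Establishment time series**: R(t) = A·C̃_t(t/T) with C̃_t integrated
  from zero (LSODA, rtol 1e-8, atol 1e-10); (s, A, T) fitted by
  least squares restricted to the last 60% of time points (later points
  carry more molecules and less relative background), multi-started from
  8 log-spaced s values against the fold-induced nonconvexity.
* **Steady levels vs copy number**: log-grid search over s ∈ [0.001, 1]
  with a nested 1-D optimisation of the copy-number-to-r scale and
  closed-form profiling of the two amplitudes, then a local polish;
  the fit reports whether the best s sits in the bistable band and which
  stable branch was used.

**Identifiability governs the synthetic study design.** A Cramér–Rao
analysis of the time-series model shows s is structurally unidentifiable
at high expression strength (at r = 30, s = 0.21 the steady state is
leakage-dominated and s trades off exactly against the amplitude). The
synthetic time-series fixture therefore emulates an establishment
experiment at low copy number, r = 2 — where the trajectory traverses the
activation-sensitive regime — on a 40-point geometric time grid out to
four relaxation times (dense early sampling resolves the leakage-driven
onset). At 5% multiplicative noise the per-replicate relative SD of ŝ is
≈10–20%; the median over 50 replicates recovers s to well within 15%.
Single replicates should not be over-interpreted.

The fixture generator applies mean-one log-normal noise whose coefficient
of variation equals the requested noise level, deterministically per
seed. It emulates smooth, background-free measurements with independent
multiplicative errors; real activity and expression data carry
background, correlated errors and count noise at low copy, so recovery
here bounds what the fits can do under idealized conditions, not what
any particular instrument achieves.

## Stochastic single-cell model

Esp1396I architecture, absolute molecule counts, time in division units
(divisions deterministic, one per unit time — only time is rescaled, not
molecule numbers). Reaction channels between divisions: C production at
n·(φ_l + φ_m f(C_free/K_d)) with the free monomer from the count-unit
dimerization equilibrium; R production at K_RC times the C rate
(independent Poisson channel by default — the simplest reading of strict
co-transcription; a `cotranscribe` flag couples R production to C events
for sensitivity analysis); M production at n·φ_M/(1 + D/K_dM) with D the
C-dimer count. No degradation channels: dilution happens only at
division, where plasmids replicate to 2n and partition Binomial(2n, ½)
and each molecular species partitions Binomial(count, ½) independently;
one daughter is followed. Between divisions the simulation is exact:
rates change only at C events, so C waiting times are exponential and
the R/M totals per cycle are Poisson with the integrated intensity.

**Calibration of absolute rates.** The deterministic analogue of this
model is a division-cycle map (integrate production for one unit, halve);
its fixed point satisfies end-of-cycle level = 2 × per-cycle production.
Given target end-of-cycle medians, φ_m is found by a bracketed 1-D search
on the cycle map, K_RC and φ_M follow in closed form, and constitutive
per-plasmid rates are target/(2n). Default study conditions, chosen once
from the qualitative constraints the source system is known to satisfy
(molecule counts on the order of thousands, M/R below one, mid plasmid
number): n = 30, s = 0.2 (monostable), operating point r = 15, end-of-
cycle medians C = 800, R = 1600, M = 400, 2000 cells, 10 divisions
(7 post-segregational).

**What the modes show.** Constitutive and regulated modes share the same
equilibrium medians, so their spreads are comparable. In the constitutive
mode the M/R ratio is insensitive to plasmid fluctuations (both rates
scale with the same n), leaving only Poisson/partition noise
(robust CV ≈ 0.08 at the default counts). Under regulation, plasmid-number
fluctuations — a martingale under replicate-then-partition, CV ≈ 0.4
after 10 divisions — propagate nonlinearly: R tracks n while M is
repressed roughly as 1/(γC̃²) ∝ 1/n², so the ratio inherits an
elasticity near −2 and its robust CV is ≈6× the constitutive value. In
the post-segregational mode (plasmids removed, initial states drawn from
the regulated equilibrium ensemble) median R halves per division; the
robust CV of M/R stays within ~15% of its initial value through four
divisions — the broad initial distribution dominates — and then rises
steeply (>2.5× by division 7) as binomial-thinning noise
(2^d − 1)(1/M₀ + 1/R₀) overtakes it. Trajectories whose R reaches zero
are excluded from ratio statistics (and counted); quartiles use linear
interpolation of order statistics; robust CV = IQR/median (reported
alongside the plain sd/mean CV).

Sampling convention: growth modes record each cell just before every
division (where the stationary mean is twice the per-cycle production);
the post-segregational mode records after each halving, division 0 being
the initial equilibrium state.

## Numerical choices and edge cases

* Free monomer uses the cancellation-safe root form
  2C̃_t/(1 + √(1+8C̃_t/α)).
* s = 0 puts an exact steady state at the origin; it is inserted
  analytically (the log grid cannot bracket it).
* Fold-curve residuals satisfy |rhs| ≤ 1e-10 and |∂rhs/∂C̃_t| ≤ 1e-8 at
  every emitted point (asserted in tests).
* Roots closer than 1e-8 relative are merged; exactly at a fold the
  root set is flagged degenerate instead of raising.
* M/R is NaN where total R is zero (C steady state at the origin).
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give bit-identical ensembles and fixtures.

## Problem sizes

Default grids (2 000 boundary points, 2 000-point root brackets) resolve
every quantity reported here to far better than the tolerances asserted;
the test suite and acceptance checks run the stochastic ensembles at 500
cells and the recovery studies at 50 replicates, sizes at which every
qualitative claim is stable under seed changes.

## Known limitations

* The stochastic reaction set is reconstructed from the deterministic
  model; mRNA intermediates and transcriptional bursting are not
  modelled, so absolute noise floors are lower bounds.
* Plasmid copy number performs an unbiased random walk (replicate ×2,
  partition binomially); real replication control adds restoring force
  that would slow the CV growth of n.
* No cell-death decision, phage dynamics or population structure: the
  post-segregational statistics stop at the M/R fluctuation level.
* The PvuII-style convergent-promoter interference and any fitting of
  raw binding data are out of scope.
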