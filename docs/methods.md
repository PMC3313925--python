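# Methods

## Reaction scheme

The model is a mass-action network over eight protein species — for each
tertiary conformation x ∈ {r, t}: the CO-bound state B_x, the primary
docking site P_x (CO photo-dissociated but still in the distal pocket),
a secondary internal docking site S_x, and the unliganded protein U_x with
CO in the solvent — plus the free-CO concentration C. The elementary
steps are

| step | rates | notes |
|---|---|---|
| B_r ⇌ B_t | k₁ / k₋₁ | bound-state conversion |
| P_r ⇌ P_t | k₂ / k₋₂ | docked-state conversion |
| U_r ⇌ U_t | k₃ / k₋₃ | unliganded conversion |
| P_x → B_x | k_g,r, k_g,t | geminate rebinding |
| B_x → P_x | k_d,r, k_d,t | thermal Fe–CO dissociation |
| P_x ⇌ S_x | k_c/k₋_c (r), k_d/k₋_d (t) | migration to the internal cavity |
| P_x → U_x + CO | k_out (shared) | escape to the solvent |
| U_x + CO → P_x | k_in,r, k_in,t | bimolecular entry |

Direction convention: the plain symbol is always r → t (so K₃ = k₃/k₋₃ = 3
for the solution rate set, i.e. 75% of unliganded protein in the slow
conformation). The secondary sites do not exchange conformation and do not
connect to the solvent — the minimal topology consistent with the closed
forms for k_ON and k_OFF (entry via the primary site, dissociation into
the primary site). Quaternary (dimer-level) cooperativity is deliberately
absent: photolysis-level independence of the observed kinetics rules it
out at the resolution of these data.

Detailed balance is *not* enforced. The published parameter values leave
the liganded thermodynamic cycle B_r → P_r → P_t → B_t → B_r open by a
factor ≈ 0.46 (forward/reverse rate product). The package reproduces the
parameters as fitted and exposes `detailed_balance_ratio` as a diagnostic
rather than silently re-balancing them.

Three experiment modes set the initial condition:

- **flash photolysis** — the bound ensemble sits at the liganded
  equilibrium f(B_r) = k₋₁/(k₁+k₋₁) ≈ 0.77; a fraction φ is transferred,
  conformational identity preserved, to P_r/P_t. The observable is the
  deoxy fraction (P+S+U over both conformations) normalized by the
  photolysed amount. With the fitted rates the first sample at 10 ns is
  ≈ 0.82, because ~26% of P_r (the branching k_g,r against k_out and
  migration) has already rebound by then.
- **stopped-flow association** — all protein unliganded at f(U_t) =
  k₃/(k₃+k₋₃); CO at the post-mix concentration; observable is the unbound
  fraction. Mass-action CO depletion is the default here (25 µM CO vs 5 µM
  haem is not pseudo-first-order).
- **NO-displacement dissociation** — bound ensemble at the liganded
  equilibrium with free CO forced to zero: NO binds any haem that releases
  its CO far faster than the seconds-scale observation, which is
  equivalent to removing the rebinding channel. No explicit NO species is
  modeled. Note that with the fitted rates the bound-state exchange
  (≈10⁵ s⁻¹) pre-equilibrates on this timescale, so the simulated decay is
  nearly mono-exponential at the population-weighted mean of the two
  closed-form off rates; the biexponential character of measured
  dissociation is therefore analyzed through the closed-form k_OFF
  expressions, not through the full scheme.

## Integration

`integrate_scheme` solves the stiff system (rates span 10⁻² – 10⁸ s⁻¹)
with scipy's BDF and the analytic Jacobian, rtol 10⁻¹⁰ and atol 10⁻¹² of
total protein; protein conservation holds to better than 10⁻⁹ relative at
all output times. Under pseudo-first-order (fixed C) or NO-displacement
(C = 0) conditions the system is linear, and an exact eigendecomposition
propagator (`method="eig"`, with a conditioning guard and BDF fallback) is
available; it agrees with BDF to ~10⁻¹⁰ and is what the global fit uses
internally, since a fit needs thousands of forward solves. The BDF route
remains the default and is validated against an independent
matrix-exponential oracle in the tests.

## Global fitting

`GlobalSchemeFit` minimizes the summed squared residual between simulated
observables and all supplied traces simultaneously, with every free rate
shared across traces. Residuals are taken in linear signal space on each
trace's stored log-spaced grid, so each decade of time carries comparable
weight; optional per-point σ weighting is available. Free rates are
optimized as log₁₀ values (positivity by construction) with scipy's
trust-region reflective solver; standard errors come from the Gauss–Newton
covariance and are reported on the rate scale.

The search box defaults to ±1 decade around the initial estimate. This is
a deliberate design choice: the t-channel parameters are sloppy, and with
a wide-open box a compensation branch (k_in,t → 0 with k_g,t large, their
product nearly fixed, the slow phase re-routed through the conformational
back-conversion) fits two-concentration synthetic data to within a few
χ² units of the truth while dragging every other rate off. Rate constants
entering such fits are always known to order of magnitude from the raw
phase positions, so the box encodes real prior knowledge. A multi-start
option (log-uniform jitter up to ±0.5 decade, seeded) probes the
remaining landscape.

Identifiability: a single 1-atm trace leaves k_in,t essentially
unconstrained (relative standard error in the hundreds); adding a 0.1-atm
trace tightens it by roughly two orders of magnitude — the quantitative
rationale for simultaneous multi-concentration analysis. Even then k_in,t
retains a relative standard error well above 1; only the four
well-identified rates (k_in,r, k_g,r, k₃, k₋₃) are recovered within 20%
in the synthetic-recovery tests.

## Multi-exponential and stretched-exponential fits

`MultiExponentialModel` fits y(t) = y∞ + Σᵢ Aᵢ exp[−(t/τᵢ)^βᵢ] via lmfit
(trust-region least squares), with lifetimes in log₁₀ space, βᵢ fixed at 1
unless `stretched`, and β bounded to (0.2, 1] to exclude the degenerate
β → 0 plateau. Exchangeable components are reported sorted by lifetime.
Initial lifetimes spread across the observed decades; a few seeded
restarts with jittered initializations guard against local minima.
Non-convergence raises a warning and is flagged on the result, never
silent. The β–τ correlation of stretched fits makes single noisy refits
of the relaxation-course model scatter by several percent in the
intermediate lifetime even at 0.1% noise; pipeline summaries therefore
report the median over eight replicate noise realizations.

## Maximum-entropy lifetime distributions

`MemInversion` represents a trace as y(t) = c + Σⱼ aⱼ exp(−t/τⱼ) on a
uniform log₁₀ τ grid (default 25 points/decade over 10⁻⁹–10⁻¹ s, one
decade beyond the standard 10 ns – 10 ms observation window) with aⱼ ≥ 0
and a constant-offset element for non-decaying baseline. The amplitudes
maximize the Skilling entropy S = Σⱼ [aⱼ − mⱼ − aⱼ ln(aⱼ/mⱼ)] relative to
a flat prior under a χ² constraint; the reported density is g = a/Δlog τ,
so ∫ g dlog τ equals the fitted decay amplitude.

Numerics: at fixed regularization weight α the objective χ²/2 − αS is
smooth and strictly convex on a > 0 (Hessian AᵀA/σ² + α diag(1/a)), and is
minimized by damped Newton iterations with a positivity-preserving
backtracking line search — first-order and multiplicative-update schemes
stall or oscillate on this severely ill-conditioned exponential kernel.
α is selected by continuation: starting from the gradient-balance scale,
α is walked downward in half-decade steps (warm-started, which keeps the
small-α solves on the solution path) until the classic criterion χ² = N
is bracketed, then refined by bisection to 2%. The prior level defaults to
10⁻³ of the signal scale spread over the grid; basis elements the data do
not constrain relax to the prior, so a small prior keeps dead grid regions
from accumulating visible mass. The solver is deterministic. For some
noise realizations the non-negativity constraint puts the best achievable
χ² above N; the result is then returned with `converged=False` and the
χ² actually reached. Noise σ is taken from the trace metadata or estimated
from median second differences. Band reporting (`peak_report`) segments
the distribution at 2% of its maximum and returns mode, trapezoid area
and FWHM in decades per band.

## SVD of time-resolved spectra

`decompose` computes the full SVD of the wavelength × delay matrix, fixes
signs so the largest-magnitude element of each spectral column is
positive, and attaches the lag-1 autocorrelation cᵢ = Σₖ xₖᵢ xₖ₊₁,ᵢ of each
unit-norm column — the standard significance statistic (smooth ≈ 1, white
noise ≈ 0 with sd ≈ n^−½). `select_components` keeps components whose U
*and* V autocorrelations exceed 0.8 (configurable), the common practice
threshold. No rotation toward physically interpretable spectra is applied:
raw SVD components are what gets interpreted downstream. Note that for
correlated generating time courses, V₂ of a two-component matrix is the
second course orthogonalized against V₁, not the raw course; shape
comparisons with mechanistic time courses (e.g. the t-branch occupancy)
are therefore made up to that orthogonalization.

## Eyring analysis

ΔG‡ = RT ln(k_B T / h k) with transmission coefficient 1 and a 1 M
standard state for second-order rates; energies in kcal/mol. ΔH‡ and ΔS‡
come from ordinary least squares of ln(k h / k_B T) against 1/T
(≥3 temperatures spanning ≥10 K), with standard errors propagated to
ΔG‡(T). The reporting temperature defaults to 298.15 K, the temperature at
which the tabulated barriers are internally consistent with the tabulated
rates (e.g. k_g,r = 5.5×10⁷ s⁻¹ → 6.89 kcal/mol). For generating synthetic
temperature series the package carries a default enthalpy assignment
(near-athermal bound-state conversion, modestly activated conformational
and entry steps, strongly activated solvent exit, bond-breaking enthalpies
for dissociation) anchored so each Eyring rate reproduces its 20 °C value
exactly; these enthalpies are a modeling convention of the generator, not
fitted quantities.

## Synthetic data

The generator produces: flash-photolysis deoxy-fraction traces on a
log grid (default 10 ns – 10 ms, 150 points) at 1 or 0.1 atm CO and
10–40 °C; stopped-flow association (default 25 µM-scale CO against 5 µM
haem, mass action) and NO-displacement dissociation traces with samples
inside the 1 ms dead time discarded; and 70-delay difference-spectra
matrices built from two Gaussian-band components whose time courses are
the simulated deoxy fraction and the normalized P_t+U_t occupancy (the
r → t relaxation marker), with the second component scaled so a clean
decomposition gives a singular-value ratio near the ~3% seen in such
experiments. All noise is i.i.d. Gaussian with mandatory seeds; defaults
are σ = 2×10⁻³ of full amplitude for flash traces and 5×10⁻³ for stopped
flow (typical of displayed single-wavelength data), 10⁻³ per pixel for
spectra. CO pressures convert to molarity through a built-in,
config-overridable Henry table (1.03×10⁻³ M/atm at 293 K, interpolated
283–313 K); solubility values are a physical-chemistry convention, not a
fitted input.

What the generator does **not** emulate: instrument response beyond
dead-time truncation, photoselection/anisotropy, baseline drifts,
wavelength-dependent noise, and — most importantly — the time-extended
(stretched) character of the real conformational relaxation, which the
mass-action scheme by construction renders exponential. Passing tests
therefore demonstrate correctness of the analysis machinery on data obeying
the scheme, not that the scheme captures every feature of measured traces.

## Problem sizes and summary estimators

The test suite and the acceptance script run everything at the study's
native scales: 150-point log traces, 70-delay spectra, two CO
concentrations for recovery fits, 5–10 seeds for Monte-Carlo style checks.
Pipeline summaries of fit-based scalar quantities use the median over
8 replicate noise realizations (amplitude ratio: 300-point, 300 s
dissociation windows covering ~10 slow-phase lifetimes with the baseline
fixed at zero, σ = 2×10⁻³; relaxation-course refit: σ = 10⁻³, appropriate
for an SVD-denoised amplitude course), because the individual estimates
scatter by several percent — the two dissociation lifetimes are only a
factor ~2.5 apart, and stretched-exponential β and τ are strongly
correlated.

## Known limitations

- The t-channel microscopic rates (k_in,t, k_g,t) are identified only as
  combinations under realistic noise; reported single-rate uncertainties
  for them should be read as such.
- The MEM χ² = N criterion is occasionally unattainable under the
  non-negativity constraint (flagged, not forced); an L-curve criterion is
  a straightforward alternative but is not implemented.
- NO-displacement simulations of the full scheme are nearly
  mono-exponential (bound-state exchange pre-averages the pathways), so
  biexponential dissociation amplitudes must be interpreted through the
  closed-form off rates.
- Eyring standard errors treat slope and intercept as independent; for
  strongly correlated 1/T designs this overestimates the ΔG‡ error.
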