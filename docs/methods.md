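# Methods

## The model landscape and what the synthetic data emulate

The generator produces one-dimensional umbrella-sampling data along the
separation r of two associating head groups, under a parametric free-energy
curve

    W(r) = h·exp(−s·(r − r_wall)) − Σᵢ dᵢ·exp(−(r − cᵢ)²/(2σᵢ²)),

an exponential repulsive wall plus negative Gaussian wells. Every term
decays to zero at large r, so the bulk plateau W = 0 beyond 10 Å is built
in rather than imposed. The default acid–acid landscape places the
closed-dimer (two hydrogen bonds) minimum at 3.8 Å and the shallower
open-dimer (one hydrogen bond) minimum at 4.6 Å, with wall position 3.5 Å,
wall height 20 kJ/mol and steepness 20 Å⁻¹. The acid–water landscapes put
the bound minimum at 2.7 Å; the variant for water binding at the acid O–H
adds a shallow 2 kJ/mol secondary minimum at 5.0 Å (the long-range
carbonyl–water contact), and both are flat beyond 6 Å.

Only the minima positions and the qualitative shape of such profiles are
constrained by the physics; depths and widths are free parameters of this
package. Defaults: closed/open depths 25/20 kJ/mol — chosen so the
dissociation free energy of the well comes out in the 14–20 kJ/mol range
typical of fatty-acid dimerization in alkanes — and Gaussian width 0.28 Å.
The width was set so that the saddle between the closed and open sub-wells
sits ≈4.5 kJ/mol (≈1.8 kT at 300 K) above the open minimum: sub-states
joined by a hydrogen-bond rearrangement interconvert readily, and measured
profiles show a smooth, shallow saddle rather than a sharp barrier. A
practical corollary is that no region of the profile is starved of samples
at the default window spacing.

The sampler is Metropolis Monte Carlo on the scalar coordinate with target
density ∝ exp(−[W(r) + k/2 (r−c)²]/kT). Only the stationary distribution
matters for WHAM, and a Markov chain is exactly seedable, which a
thermostatted dynamics run is not. Ten Metropolis moves (Gaussian
proposals, step 0.3 Å) separate stored samples, emulating the sparse
storage stride of a molecular simulation, so the 20,000 stored samples per
window are effectively decorrelated — the assumption the multinomial
bootstrap rests on. The first 2,000 moves are discarded. The coordinate is
sampled with no r² weight: W(r) is by definition the potential of mean
force that WHAM reconstructs, and the 4πr² volume element belongs to the
bound-state integral only. Per-window seeds are `seed + window index`.

The default schedule pulls from 15.0 Å to 3.5 Å in 0.5 Å steps (24
windows) with a 6 kcal/(mol Å²) harmonic bias; spring constants are
accepted in kcal/(mol Å²), the unit umbrella-sampling tools conventionally
use, and converted internally with 1 kcal = 4.184 kJ.

What the synthetic data do **not** contain: solvent degrees of freedom,
force-field specifics, barostat/thermostat artifacts, slow orthogonal
relaxation, or autocorrelation beyond the residual correlation of a thinned
Markov chain. Passing the recovery tests therefore demonstrates the
correctness of the estimators under ideal sampling statistics — not that
any particular molecular system is converged at 2 ns per window.

## WHAM

Window samples are binned on one uniform grid (default 0.05 Å, twenty bins
per window spacing, fine enough to resolve minima 0.8 Å apart) and the
standard pair of self-consistent equations is iterated directly — no
acceleration, for auditability — until the largest change of any window
shift is below 10⁻⁷ kT (cap 10⁵ iterations; non-convergence raises with
the final residual). The profile is W = −kT ln p referenced so its mean
over the plateau bins (r ≥ 10 Å by default) is zero. Bins with no counts
carry +∞ and are never interpolated; empty bins inside the sampled range
additionally warn. Datasets mixing temperatures are rejected — kT enters
from the dataset's single temperature.

Bootstrap errors redraw each window's histogram counts from a multinomial
with its sample size and empirical bin probabilities, then re-solve WHAM
warm-started from the full-data shifts (200 replicates by default). This
resamples counting noise, which is the error model appropriate to stored
decorrelated samples; it does not model residual time correlation.

The convergence check re-solves on the leading fraction of every window
and reports the maximum drift against the full solution over bins with at
least 10 aggregate counts; near-empty edge bins fluctuate by O(kT) from
shot noise alone and would otherwise dominate a statistic that is meant to
measure profile convergence.

The test suite cross-checks the fixed-point solver against an independent
maximum-likelihood solver (scipy BFGS on the variational form of the same
estimating equations) to <0.1 kJ/mol per bin, and against the generating
landscape to <0.5 kJ/mol across the sampled range at default density.

## From the well to thermodynamics

The bound-state integral Q = ∫ 4πr² exp(−W/kT) dr is taken by composite
trapezoid on the native bin grid, with the exact limits appended as nodes
(W linearly interpolated there) so the integration range is honored; no
other interpolation or smoothing is applied, which keeps the result
checkable against adaptive quadrature (agreement ~10⁻³ kJ/mol on default
fixtures, and halving the bin width moves ΔG_d by <0.05 kJ/mol). Default
limits r₀ = 3.9 Å and r₁ = 5.3 Å bracket both acid–acid sub-wells.
Integration windows that touch unsampled (+∞) bins are an error.

Two normalizations are selectable. The default 1 M molar standard state,
V_ref = 1/(c°N_A) ≈ 1660.5 Å³, is the convention under which ΔG_d and K_d
round-trip exactly via K_d = c°·exp(−ΔG_d/RT) (R = 8.314 J/mol K); it is
the scale on which the published free-energy/constant pairs are mutually
consistent. The solvent mole-fraction convention V_ref = v_s is retained,
with v_s computed from bulk density and molar mass (cyclohexane at
814 g/L → 171.7 Å³).

The Van't Hoff fit regresses ln K_d on 1/T (enthalpy of dissociation
assumed temperature-independent) and takes Δ_dH = −R·slope. K_d0 at the
reference temperature T₀ = 298 K is obtained by carrying the data point
nearest T₀ along the fitted enthalpy — the only convention consistent with
the published reference-temperature constants, since three-point
regression intercepts differ slightly; the regression-intercept variant is
available as an option.

Minima are located by peak finding with a 0.5 kJ/mol prominence floor and
refined by a three-point parabola; on profiles carrying bootstrap errors
the floor is raised to 3× the local error so statistical dips in thin bins
are not reported as states. The open/closed decomposition splits Q at a
boundary inside the well (the inter-well saddle, ≈4.2 Å by default usage);
the secondary-minimum contribution reports the relative increase of ΔG_d
when a disjoint outer range is added to the integration domain.

One documented inconsistency in the published acid–water table: the
CO-water 300 K free energy (18.81 kJ/mol) and constant (0.912 mM) disagree
under any fixed standard state, while the constant is what makes the
enthalpy/K_d0 chain consistent. Printed constants are therefore treated as
authoritative inputs for Van't Hoff fitting, and that free-energy/constant
pair is excluded from conversion checks.

## Speciation

With K_d = M²/D and K_h = M·W_free/MW, the acid balance is taken as
C = M + D (+ MW) — the convention of the source analysis, which counts the
dimer once — with the physically standard monomer-unit balance
C = M + 2D (+ MW) selectable. The water-free case is the closed-form
positive root; the coupled acid–water system is solved by Newton iteration
on (M, W_free) from the water-free initial guess, halving any step that
would cross zero, to a residual of 10⁻¹² of the problem scale (cap 200
iterations). D and MW are computed from the equilibrium identities, so
those hold exactly in every returned state. All concentrations are mM.

## Problem sizes

Defaults reproduce the reference density: 24 windows × 20,000 stored
samples, 200 bootstrap replicates. The full bootstrap analysis runs in
about ten seconds on one CPU; the dual-route WHAM checks use 18-window,
2,500-sample datasets, and speciation oracles use grid-plus-bisection
brute force.

## Known limitations

- One-dimensional coordinate only; no MBAR-style generalization, no
  autocorrelation estimation, no 2-D umbrella grids.
- Bootstrap errors quantify counting noise given decorrelated samples, not
  sampling-path correlation or systematic force-field error.
- The speciation model stops at dimers and 1:1 hydrates: no higher
  oligomers, no water self-association, no activity coefficients.
- Open-dimer fractions are PMF-based (population split of the bound well);
  fitting spectroscopic open/closed band intensities is out of scope.
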