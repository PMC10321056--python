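# Methods

## Model and coordinate conventions

The package analyses the passage of a guest ion along the symmetry axis of a
macrocyclic host cavity. The reaction coordinate is the signed difference
between the z-coordinate of the ion and the z-coordinate of the cavity
centre, defined as the unweighted centroid (centre of geometry) of the
inward-pointing cavity atoms; for a ring of identical atoms this coincides
with the centre of mass, so the simpler definition is used throughout.
Lateral motion is restrained to a flat-bottom cylinder: zero potential for
r_perp ≤ R_cyl, half-harmonic wall ½k_fb(r_perp − R_cyl)² outside
(continuous and once-differentiable at the wall; no hard wall). Internal
units are kcal mol⁻¹, Å, ps and K, with R = 1.98720425×10⁻³ kcal mol⁻¹ K⁻¹
and a default temperature of 298.15 K. Force constants quoted in
kJ mol⁻¹ nm⁻² convert by the exact factor 418.4.

## Synthetic system

The generator produces the statistical structure the estimators assume, not
molecular realism. The energy surface is separable,
U(x,y,z) = U_z(z) + ½k_r(x²+y²), with U_z a sum of Gaussians
a·exp(−(z−c)²/2w²); the exact PMF of the cylinder-restrained system is then
U_z plus a z-independent constant, which is the oracle every estimator is
benchmarked against. The default landscape has a −6 kcal/mol central well at
z = 0 (width 1.2 Å), −4 kcal/mol flanking wells at |z| = 3.5 Å (width 1 Å)
and a flat bulk beyond ~12 Å — a central binding pose plus portal poses, the
qualitative shape of an anion PMF through a slightly hydrophobic cavity.

Dynamics are overdamped Langevin integrated with Euler–Maruyama:
Δr = −(D/RT)∇(U+U_bias)dt + √(2D dt)·ξ. There is no inertia, no periodic
box and no explicit solvent: only the equilibrium distribution matters for
PMF recovery, and the radial harmonic confines the particle without box
artifacts. Per-window seeds are master_seed + window_index; identical
configurations reproduce byte-identical datasets.

**Step-size and diffusion defaults (D = 1.0 Å² ps⁻¹, dt = 0.01 ps).** These
are chosen for estimator testing, not physical realism (an aqueous halide
diffuses ~5× slower). Two opposing errors set the choice at a fixed step
budget. (i) Euler–Maruyama carries a first-order configurational bias,
measurable as a ladder tilt of the WHAM profile on a flat landscape
(−0.0066 kcal/mol/Å at dt = 0.01; −0.00014 at dt = 0.002). (ii) The
statistical error scales with the effective sample count n_eff ≈
n_steps·D·k_z·dt/(2RT), which shrinks proportionally as dt decreases. At
2×10⁵ steps per window the statistical term dominates: halving dt measurably
worsened both the PMF RMSE and the binding-energy recovery, so dt = 0.01
(bias parameter D·k_z·dt/RT ≈ 0.02) is kept. Stability is monitored through
the deterministic drift dt·D·|∇U|/RT — the step-size-dependent quantity; the
Gaussian random displacement is unbounded by design and is not a stability
signal — and a window aborts if the drift exceeds 0.5 Å in any step.

The pseudo-solvent generator emulates two observables. First, hydration-
shell replacement: the number of waters within the shell cutoff of the ion
is Poisson with mean bulk_count_mean·s(d), s(d) = 1/(1+exp(−(d −
cavity_radius)/halfwidth)), so the shell empties sigmoidally as the ion
approaches the cavity; waters are placed uniformly within the shell. Second,
cavity wetting: an exact two-state continuous-time Markov chain (rates
k_wet, k_dry) sampled at the frame times decides whether one extra water
occupies the cavity. Defaults k_wet = 0.35, k_dry = 0.05 ps⁻¹ give a
stationary de-wetted fraction of 12.5% with picosecond dwell times, the
regime reported for weakly polar macrocycle cavities. The two processes are
independent; when the ion itself sits inside the cavity its shell waters can
additionally wet the cavity, so clean Markov-rate recovery is tested from
windows where the ion stays outside. What passing these tests shows is that
the counting, binning and dwell-time machinery is correct — not that the
generator reproduces real water structure (no orientation, hydrogen bonding
or excluded volume).

## PMF estimation

Binned self-consistent WHAM (Kumar-style), defaults bin_width = 0.1 Å,
tol = 10⁻⁷ kcal/mol on the window free energies, max 10⁵ iterations. Only
the z-umbrella enters the bias list: the xy flat-bottom cylinder is common
to every window, which is exactly the premise that makes the cylindrical
standard-state correction the right downstream treatment. Bias factors are
evaluated at bin centres; empty bins are masked, never interpolated, and
exports mark gaps. Windows whose occupied bins form disconnected clusters
are rejected with the cluster membership named. Profiles are not
symmetrised about z = 0 unless the user folds them explicitly.

**Bulk reference.** W is referenced so the occupied bins of a declared bulk
region average to zero. The default region is the outermost 2 Å of the
sampled range, *ending at the outermost umbrella centre*: the occupied range
extends a few Å past the last window into the thin tail of its histogram,
and referencing there would add a common-mode offset of ±0.1–0.2 kcal/mol
to the whole profile (this dominated the recovery error before the rule was
adopted).

**Block errors.** Each window's first equil_discard ps are dropped; the
remainder is split by simulation time (not sample count) into n_blocks = 3
contiguous equal-duration blocks. WHAM runs per block on a shared bin grid,
each block profile is referenced to the bulk region, and the per-bin SD
across blocks is the error bar (absent for a single block). The dominant
contribution is a window-ladder matching error that is common-mode across
bins, so a 3-block SD is a noisy (2 degrees of freedom) estimate of a small
number of underlying modes; the acceptance check of the expected 1/√L
scaling therefore uses a nested paired design (6 blocks versus their 3
pairwise merges from the same trajectory), which has ~99.9% power where
independent-run comparisons at 5 seeds have ~85%.

**Overlap.** For each adjacent window pair the overlap coefficient
Σ_b min(p₁, p₂) of the normalised histograms is reported; pairs below 0.03
(configurable) are flagged.

## Binding free energies

The headline estimator is the minimum of the block-mean bulk-referenced PMF
(ties broken toward smaller |z|), with the SD of the per-block minima as the
uncertainty, plus the cylinder correction ΔG_corr = −RT ln(πR_cyl²/A⁰).
A⁰ = πr₀² ≈ 170 Å² with r₀ the radius of a sphere of the standard volume
1661 Å³ (1 M); the correction is treated as exact, is zero when the cylinder
section equals A⁰ (R_cyl ≈ 7.36 Å), is positive for the 2.5 Å (+1.279
kcal/mol at 298.15 K) and 3.5 Å (+0.880) cylinders, and positive "binding"
energies are reported as-is. The secondary estimator integrates
K_b = πR_cyl²∫_site exp(−W/RT)dz by trapezoid over the bin grid and returns
−RT ln(C⁰K_b); the two differ by −RT ln(ℓA⁰/V⁰) with ℓ the Boltzmann-
weighted site width (≈1.3 kcal/mol for the default −6 kcal/mol well), an
identity the tests verify.

## Solvation analysis

All distance counts use a closed interval (d ≤ cutoff) so boundary cases are
deterministic. Default cutoffs — 3.4 Å for waters, 4.0 Å for host contacts,
3 Å around the cavity centre for the wetted/de-wetted classification — are
exposed in the configuration and logged in every output, since shell-count
cutoffs have no single agreed value. Hydration profiles bin per-frame counts
by signed z (optionally folded to |z|) and report the per-bin mean,
population SD and frame count; frames are conserved across bins. Wetting
traces report the de-wetted fraction, transition count and per-state dwell
times at the native frame interval; runs touching either end of the trace
are censored and excluded from the dwell means but counted in the fractions.

## Pair energies

Both van der Waals forms are parameterised by the minimum location r_min and
depth ε and give exactly −ε at r_min. The 12-6 Lennard-Jones uses
σ = r_min/2^(1/6) and Lorentz–Berthelot combination; the buffered 14-7 uses
the standard Halgren constants δ = 0.07, γ = 0.12 with cubic-mean r_min and
HHG ε combination, matching its native polarizable-force-field ecosystem.
With equal (r_min, ε) the buffered 14-7 lies below the 12-6 along the whole
repulsive approach — it is the softer-cored form. Electrostatics is a plain
vacuum Coulomb term (332.0637 q₁q₂/r kcal/mol); multipoles and induced
polarization are deliberately out of scope, so interaction profiles show
what a fixed-charge description yields. Cross-form fits minimise the
(optionally weighted) least-squares residual of the like-pair curves on a
user grid, starting from the target parameters (the fit range and weights of
published cross-form fits are generally unstated, so both are parameters
here). Interaction profiles are binned by z and each component is shifted to
zero in the bin containing the 15 Å bulk reference; vdW + Coulomb = total
holds exactly per bin. No cutoffs, switching or Ewald: the toy hosts are
small and non-periodic.

## Numerical and design notes

* WHAM convergence is plain fixed-point iteration; at the package's problem
  sizes (≲60 windows, ≲500 bins) it converges in well under the iteration cap.
* Window files store full-precision floats (%.17g) so write/read round trips
  are bit-exact; multi-frame XYZ carries a variable per-frame atom count
  (waters are Poisson-distributed), which is why the reader/writer is local
  rather than delegated to a fixed-topology trajectory library.
* Degenerate inputs fail loudly with context: non-finite coordinates and
  malformed lines are reported with file and line number, empty blocks name
  the window, disconnected window sets name the clusters, unreferenced
  profiles are rejected by the binding estimators.
* Desk-scale problem sizes used by the acceptance checks: 26 windows ×
  2×10⁵ steps (PMF and binding recovery), 2×10⁶ steps (sampler
  goodness-of-fit, samples strided 25 ps for effective independence),
  10⁵ frames (wetting statistics), 4.5×10⁴ frames (hydration recovery).

## Known limitations

* The sampler's Euler–Maruyama scheme has O(dt) configurational bias; the
  defaults keep it an order of magnitude below the statistical error at the
  documented problem sizes, but very long runs would expose it.
* The binding-site minimum estimator inherits minimum-statistics bias from
  profile noise (the deepest fluctuation is selected); across seeds the
  recovered ΔG scatters by ~0.1–0.2 kcal/mol at the acceptance sampling level.
* No autocorrelation-based effective-sample-size correction (block scatter
  is the only error model), no 2-D PMFs, no enthalpy/entropy decomposition.
* The pseudo-solvent has no excluded volume or water–water structure; its
  purpose is to give the solvation analyses known expectations.
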