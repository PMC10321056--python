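# cavibind

Umbrella-sampling potential-of-mean-force (PMF) and standard-state binding
free-energy analysis for host–guest cavity systems — macrocyclic anion
carriers such as biotin[6]uril and its sulfoxide variants — together with a
synthetic Brownian-dynamics test bed whose exact free-energy profile is known
in closed form.

It is written for molecular-simulation practitioners who run biased MD of an
ion passing through a host cavity and need the downstream analysis: WHAM
estimation with overlap diagnostics and block errors, the cylindrical-
restraint standard-state correction, hydration-shell profiles, and
wetting/de-wetting statistics of the cavity — each testable end to end
against analytic ground truth.

## The model

The reaction coordinate is the signed axial distance z between the ion and
the cavity centre (centroid of the inward-pointing cavity atoms). Windows are
biased by a harmonic umbrella ½k_z(z − z_i)² and a flat-bottom cylinder of
radius R_cyl in the xy-plane (free inside, half-harmonic wall outside), which
keeps lateral excursions bounded so that a 1-D PMF suffices.

* **WHAM.** Binned self-consistent estimation: p_b ∝ Σ_i n_ib / Σ_i N_i
  exp((f_i − u_i(z_b))/RT), iterated on the window shifts f_i until
  max|Δf_i| < 10⁻⁷ kcal/mol. W(z) = −RT ln p(z), referenced so a declared
  bulk region averages to zero. The xy cylinder is common to all windows and
  never enters the bias list. Uncertainties come from splitting each window
  into three contiguous equal-duration blocks and repeating the estimate.
* **Binding free energy.** ΔG = −RT ln(C⁰K_b) with C⁰ = 1/1661 Å⁻³. The
  headline estimator is the minimum of the bulk-referenced block-mean PMF
  plus the cylinder correction ΔG_corr = −RT ln(πR_cyl²/A⁰), A⁰ = πr₀² ≈
  170 Å² (r₀ the radius of a sphere of 1661 Å³); the block scatter of the
  minimum is the error. A K_b-integral estimator over a declared binding
  site serves as a cross-check.
* **Solvation.** Per frame, waters (and host atoms) within a cutoff of the
  ion are counted and binned along z; the cavity is classified wetted when
  any water lies within 3 Å of the cavity centre, and dwell-time statistics
  of the two-state series are reported.
* **Pair energies.** 12-6 Lennard-Jones and buffered 14-7 (Halgren) van der
  Waals forms parameterised by (r_min, ε), vacuum Coulomb term, cross-form
  least-squares fitting, and guest–host interaction profiles referenced to
  zero at z = 15 Å.

The synthetic system is an overdamped Langevin (Euler–Maruyama) particle on
a separable landscape U(x,y,z) = U_z(z) + ½k_r(x²+y²) with Gaussian wells
and barriers in U_z, for which the restrained PMF equals U_z up to a
constant — the analytic oracle behind the tests. Internal units are
kcal/mol, Å, ps, K (R = 1.98720425×10⁻³ kcal/mol/K); converters accept
kJ/mol/nm² force constants (factor 418.4).

## Worked example

Generate a small synthetic dataset (13 windows over 0–12 Å, 40 000 steps per
window) and run the full pipeline:

```sh
python - <<'PY'
from cavibind import RunConfig, save_config
cfg = RunConfig()
cfg.seed = 11
cfg.windows.z_stop = 12.0
cfg.sampling.n_steps = 40000
cfg.sampling.equil_discard = 20.0
save_config("config.yaml", cfg)
PY
cavibind pipeline -c config.yaml -o out
```

which prints

```
dG_total = -4.937 +/- 0.235 kcal/mol (min -6.216 at z = -0.05 A, corr +1.279); outputs in out
```

Reading: the deepest point of the block-averaged PMF is −6.216 kcal/mol at
z ≈ 0 (the central binding pose; the generator's true well is −6.0, and this
short run carries a ±0.24 kcal/mol three-block error), the 2.5 Å cylinder
contributes a +1.279 kcal/mol standard-state correction, and their sum is the
standard-state binding free energy. `out/` contains the PMF with per-bin
block SD (`pmf.tsv`), the window-overlap report (`overlap.tsv`), the binding
summary (`binding.tsv`), hydration and wetting tables, the exact reference
profile (`pmf_analytic.tsv`), and a provenance manifest; a rerun with the
same config is byte-identical. The library API (`wham`, `block_pmfs`,
`dg_from_minimum`, `cylinder_correction`, `classify_wetting`, ...) exposes
each stage separately, including for externally produced window files
(GROMACS-style pull output is read with declared units).

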