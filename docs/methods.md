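# Methods

This note documents the models, estimators, numerical choices and
limitations of `afmpipe`. It states no empirical result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Force-field model

The nonbonded interaction between atoms of types *s* and *t* is

    u_st(r) = A_st exp(-b_st r) - C6_st / r^6 [- C8_st / r^8]
              + k_e q_s q_t / r

with pair-specific parameters: there is no combining rule, and the pair
table is symmetric under swapping the two types. The Buckingham repulsion
replaces the Lennard-Jones r^-12 wall because force-matched models need the
softer, more physical exponential form (in MD engines it must then be
evaluated as a tabulated potential; `write_tabulated_potential` emits the
7-column user-table layout: `r, f, -f', g, -g', h, -h'` for the Coulomb,
dispersion and repulsion shapes with analytic derivative columns). C8 is
exposed but defaults to zero. Dispersion coefficients are treated as fixed
inputs to every fit — in an AFM workflow they come from a separate
perturbation-theory calculation and are deliberately decoupled from the
strongly-correlated repulsion/Coulomb fit.

Bonded terms: harmonic bonds and angles `E = (k/2)(x - x0)^2` and a cosine
series `E = Σ_n c_n cos(nφ)` for proper dihedrals (the n = 0 constant
carries no force and is excluded from fits). Intramolecular nonbonded pairs
separated by one or two bonds are excluded; 1-4 and beyond interact at full
strength by default (`scale_14` is configurable). Units are kcal/mol, Å and
e internally, with the Coulomb constant 332.0637 kcal·Å/(mol·e²); observable
modules use bar, nm, ps, K and convert at their boundaries. Periodic
evaluation uses the orthorhombic minimum-image convention with a cutoff of
at most half the smallest box length; there is no Ewald summation, because
the fitting targets are short-range force differences on cluster-scale
training configurations. Pairs closer than 0.1 Å raise an error rather than
returning astronomically large numbers.

Atom typing is structural: sp2 carbons (degree 3, or flagged explicitly)
versus sp3, with the *hydrated* scheme further splitting sp3 carbons into
allylic (bonded to an sp2 carbon) and homoallylic; hydrogens inherit their
carbon's class. The *neat* scheme gives 2 carbon + 2 hydrogen types and 5
distinct bond terms on the cyclohexene graph, the hydrated scheme 3 + 3
types and 7 bond terms. Because typing depends only on the graph, symmetric
atoms always receive identical labels. The extra types exist because
repulsion and partial charges are strongly coupled: a model with charges
needs a separate short-range term per distinct charge environment.

## Force matching

The objective is weighted least squares over three observable classes per
training record: masked atomic forces, molecular net forces, and molecular
torques about each molecule's center of mass (torques are divided by a 1 Å
lever arm so all residuals share force units; the lever is configurable).
For QM/MM-style hydrated records only the solute atoms are masked in, and
molecular observables are taken over molecules fully covered by the mask.

Internal (bonded and intramolecular nonbonded) forces sum to zero net force
and zero net torque for any molecule, exactly. Molecular observables
therefore isolate the intermolecular parameters, and the default staging
fits them first (weights 0/1/1), then the bonded parameters from atomic
forces (1/0/0) with the nonbonded block frozen. This decoupling is what
makes the staged fit recover a zero-noise generator exactly.

Parameters linear in the force (A, C6, C8 when free, bond and angle
stiffnesses, dihedral coefficients) are solved by exact linear least
squares against design columns assembled from precomputed pair lists and
bonded geometry. The remaining parameters — Buckingham decays b, equilibrium
lengths/angles, and partial charges — are refined by bounded
variable-projection least squares (`scipy.optimize.least_squares`, TRF,
with the linear solve nested inside the residual). Charges sit in the
nonlinear block because forces are quadratic in them through the q_i q_j
products (including intramolecular 1-4+ pairs); a coordinate-wise scalar
search was considered and rejected because the b/r0/θ0 sets are too strongly
coupled for it to reach the sub-0.1% recovery the validation demands.
Bounds: b ∈ [1, 10] Å⁻¹, r0 ∈ [0.6, 2.5] Å, θ0 ∈ [0.5, 3.1] rad,
q ∈ [-3, 3] e, all overridable per stage. Exactly-zero design columns name
their parameters in a singular-fit error; numerically rank-deficient designs
auto-enable a ridge of 1e-8 with a warning (the default ridge is 0).

The mixed-phase fit proceeds in three separable steps: (1) the hydrated-only
fit of solute–solvent nonbonded parameters (and charges, unless a fixed
charge set is supplied as policy) on the hydrated records; (2) solute–solute
nonbonded parameters from the neat records' molecular observables; (3) one
shared bonded set from the masked atomic forces of both phases. Step 1 is
literally the hydrated-only fit, so the solute–solvent parameters of the
joint and hydrated-only fits are identical by construction — which is also
the physically correct statement, since neat records contain no
solute–solvent pairs and cannot inform those parameters.

Fit quality is reported as RMSE, regression slope and R² of model against
reference, pooled over vector components, separately for molecular forces,
molecular torques and atomic forces. The regression is through the origin by
default (forces are signed and symmetric about zero; R² then uses the
uncentered total sum of squares); an intercept variant is available.

## Slab observables

Surface and interfacial tension use the pressure-tensor route,
γ = (L_Z/2)(⟨P_Z⟩ - (⟨P_X⟩+⟨P_Y⟩)/2), the factor two accounting for the
slab's two interfaces; 1 bar·nm = 0.1 mN/m. Uncertainties are 1-σ block
averages with 5 blocks by default — few enough blocks that each remains long
against the pressure autocorrelation time, at the cost of a noisy error
estimate (a block-count argument is exposed). No dispersion tail correction
is applied to γ.

Liquid densities from slab profiles use a two-step protocol: find the
longest contiguous run of bins above `min + 0.5 (max - min)` (threshold
fraction configurable), then average the central 50% of that run. The
profile is treated as periodic (it is rolled so the least-dense bin sits at
an edge before run detection), so slabs crossing the boundary are handled.
The naive alternative — taking the densest region — is biased upward by
selection under noise, and interfacial cavities that drift into the liquid
bias it further; the two-step core measurement is insensitive to cavities
outside the central core, which the tests verify by carving cavities out of
paired point sets. Vapor densities average the bins farther than a 1 nm
buffer from the liquid run's edges.

## Critical point, vapor pressure, boiling point

The Wegner expansion `ρ_l - ρ_g = Σ_{k=0..3} A_k |τ|^{0.325 + 0.5k}`
(3D-Ising order-parameter exponent, first confluent correction) is fitted
with amplitudes linear given T_C and T_C by bounded scalar search over
(max data T + 1 K, max data T + 300 K); a best T_C at a search bound is an
error, not a value. The critical density comes from the rectilinear-diameter
law `ρ_l + ρ_g = 2ρ_C + D_{1-α'}|τ|^{1-α'} + D_1|τ|` with α' = 0.11 and T_C
held fixed. A caveat the tests quantify: with 6 temperatures and 5 free
parameters the full fourth-order Wegner fit is statistically identifiable
only for density noise well below 0.1%; at 1% noise the profile objective in
T_C is flat above the true value and the fit runs to the search bound. The
estimator is therefore validated noiselessly (exact recovery) and at the
noise level where it is statistically sound.

Antoine fits minimize squared error of ln P with A, B linear given C and C
by bounded scalar search (C > -T_min). Two windows are used in the pipeline,
360–440 K for the boiling point and 380–460 K for the critical pressure,
because a single Antoine form is unreliable over wide temperature ranges;
evaluating the fit at T_C beyond its window warns about extrapolation. The
fit carries a pressure-unit tag (bar internally).

The free-energy boiling-point route reconstructs vapor pressures from
ΔG_vap = -RT ln(ρ_g/ρ_l) and the liquid density via the ideal-gas relation
ln(P_g/P⁰) = ln(RT ρ_l/(M P⁰)) - ΔG_vap/RT (molar mass M = 82.143 g/mol,
P⁰ = 1 atm), fits ln(P/P_threshold) linearly in 1/T (Gibbs–Helmholtz), and
solves for the zero crossing. The boiling threshold defaults to 1 atm with a
switch for 1 bar. Composing the two relations gives P = ρ_g RT/M exactly —
the property tests assert this identity to machine precision, which pins the
unit conversions.

Auxiliary estimators use the standard textbook forms: ΔH_vap = U_gas -
U_liq + RT; κ_T = ⟨δV²⟩/(k_B T ⟨V⟩) from NPT volume fluctuations;
r = k_B T/(6πηD) for hydrodynamic radii; ΔG_sol = ΔG_vap + ΔG_hyd with
uncertainties combined in quadrature (all reported uncertainties in the
property table are 1-σ).

## Transport

Diffusion uses the Einstein relation D = slope/6 of the mean-squared
displacement, computed over multiple time origins (stride 10 frames, a
cost/variance compromise) on an evenly-spaced lag subsample up to half the
trajectory. The fit window is 20–80% of the maximum lag; a log-log slope
far from 1 in that window (e.g. 2 for ballistic motion) raises a
diffusive-regime error, and a negative fitted slope returns NaN with a
warning. The standard error pools per-particle slope estimates. No
finite-size (hydrodynamic self-interaction) correction is applied.

Viscosity is the Green–Kubo integral η = V/(k_B T) ∫ ⟨P_ab(0)P_ab(t)⟩ dt,
averaged over the three off-diagonal pressure components, with FFT-based
autocorrelations, trapezoidal integration, and truncation at the first zero
crossing of the component-averaged autocorrelation (capped at the requested
maximum lag). Zero-crossing truncation discards the noise-dominated tail at
the price of a small systematic underestimate when the true correlation
decays slowly; the reported error is the scatter among the three components.

## Synthetic data and what passing tests mean

Every input the pipeline consumes has a seeded generator with recorded
ground truth: one global seed fans out to fixed per-scenario substreams, so
each scenario is independently reproducible and bit-identical under a
repeated call. Noise draws use substreams separate from geometry, so noisy
and noiseless training sets are paired configuration by configuration.

Training sets: clusters of cyclohexene-like molecules built from a puckered
ring template, placed by overlap-rejected random rigid-body packing and
perturbed by 0.05 Å Gaussian jitter to exercise the bonded terms; reference
forces are the ground-truth force field's analytic forces plus optional
i.i.d. Gaussian noise. The hydrated variant embeds one solute in a shell of
a rigid three-site bent solvent surrogate (fixed, invented parameters — it
exercises the QM/MM masking logic, not water physics) with a solute-only
mask. The ground-truth parameter tables are themselves built from per-type
base values with fixed per-pair perturbations of up to 8%, so no combining
rule can reconstruct them — matching the pair-specific structure of the
model being fitted.

Observable generators invert the estimators' own relations: pressure-tensor
series carry a built-in anisotropy 2γ/L_Z under AR(1) noise (defaults:
γ = 25.4 mN/m, L_Z = 12 nm); slab frames realize a tanh density profile by
Poisson point placement (800 vs 5 g/L, 0.5 nm interface width, 8 nm slab in
a 3×3×24 nm box), with optional spherical cavities carved out of the same
point set for paired comparisons; coexistence curves are built exactly from
the Wegner difference and rectilinear sum then split (T_C = 513 K,
ρ_C = 303.9 g/L, amplitudes 579.5/4637.6/-8973.0/5706.9 g/L at six
temperatures 360–460 K); Brownian walks have increment variance 2D dt
(D defaults 0.99e-5 cm²/s hydrated, 1.9e-5 cm²/s pure phase); volume series
are Gaussian with variance κ_T k_B T ⟨V⟩ (κ_T = 1.0366e-3 MPa⁻¹); stress
series are AR(1) processes calibrated so their exact autocorrelation
integral matches a target viscosity (0.66 mPa·s).

Two generator constants deserve their rationale. The rectilinear
coefficients default to D_1 = 1496.8 g/L with D_{1-α'} = -350 g/L: the
latter is chosen so that the implied vapor densities stay positive and of
ideal-gas magnitude (≈7–40 g/L) across the sampled window — a thermodynamic
consistency requirement the generator must satisfy to produce a valid
curve. The Antoine truth (A = 10.352, B = -3143 K, C = -40 K, bar) is
constructed to place the 1-atm boiling point at 344 K with a
Clausius–Clapeyron slope matching a vaporization enthalpy of ≈33.5 kJ/mol,
i.e. a cyclohexene-like vapor-pressure curve whose moderate curvature in
1/T lets the Antoine inversion and the three-point free-energy route be
compared meaningfully.

What the closed loop does and does not show: recovering a generator's truth
validates the estimators' algebra, units, statistical behavior and
implementation — it does not validate the physics of any real force field,
because the synthetic data lack real anharmonicity, many-body polarization,
long-range dispersion, hydrodynamic correlations and the slow collective
fluctuations of real interfaces. Slab density measurements in the validation
suite average enough frames (up to 400) that Poisson counting noise
(≈0.03% on the core mean) is negligible against the 0.1% insensitivity
bound being verified.

## Problem sizes

The validation suite uses training sets of up to 20 configurations × 8
molecules (the full staged fit on that set recovers all ~80 free parameters
to better than 1e-3, typically 1e-9, in about a minute), 50-replicate Monte
Carlo for the critical-point fits, pooled Brownian ensembles of 1000
particles × 10⁴ steps for the 3% diffusion check, and 10⁵ samples for the
compressibility check. The demonstration pipeline (`afmpipe report`) uses
smaller sizes (6 × 4 training configurations, 200 particles) chosen to keep
a full run under ten seconds while every recovery tolerance still holds.

## Known limitations

- No Ewald electrostatics or dispersion PME; cutoff-scale evaluation only.
- No tail corrections to the surface tension.
- The Wegner T_C fit is honest about its identifiability limit (see above)
  rather than regularized toward a preferred answer.
- ΔG_hyd and ΔG_vap enter the solubility cycle as numbers; free-energy
  perturbation from raw trajectories is out of scope.
- The solvent surrogate is not a water model; hydrated-phase results
  exercise bookkeeping and masking, not aqueous physics.
- Viscosity truncation at the ACF zero crossing mildly underestimates
  slowly-decaying stress correlations.
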