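# Methods

## Bivalent-analyte SPR model

The surface scheme lets one soluble analyte molecule A bridge two
immobilised ligand molecules L:

    A + L  ⇌ AL      ka1 [M⁻¹s⁻¹], kd1 [s⁻¹]
    AL + L ⇌ AL2     ka2 [RU⁻¹s⁻¹], kd2 [s⁻¹]

    dL/dt   = −(ka1·A·L − kd1·AL) − (ka2·AL·L − kd2·AL2)
    dAL/dt  =  (ka1·A·L − kd1·AL) − (ka2·AL·L − kd2·AL2)
    dAL2/dt =   ka2·AL·L − kd2·AL2
    L(0) = R_max,  AL(0) = AL2(0) = 0

Surface species are expressed in response units, which is why ka2 has
RU⁻¹s⁻¹ units while ka1 is molar. The algebra conserves L + AL + 2·AL2
exactly; the integrator is required to preserve it to 10⁻⁶·R_max.

**Observable.** The instrument response is taken as R(t) = AL + AL2:
each captured analyte contributes its mass to the surface once whether
or not it bridges a second ligand. The alternative R = AL + 2·AL2 would
double-count the analyte's mass and is inconsistent with the mixed
units of the published constants; this choice follows standard
bivalent-analyte practice.

**Integration.** LSODA (stiff-capable, adaptive) with rtol 1e-8 and
atol 1e-10 RU, solved in two segments: association with A = C constant,
dissociation continuing from the end state with A = 0. All
concentrations of a titration are stacked into one vectorised system so
a global-fit residual evaluation costs a single solve. With
ka2 = kd2 = 0 the simulator agrees with the closed-form 1:1 Langmuir
solution to < 10⁻⁶ relative, which the tests enforce.

**Global fitting.** ka1, ka2, kd1, kd2 and R_max are shared across all
curves of a titration (optional per-curve baseline offsets, default
off). Because the parameters span ~8 decades, optimisation runs in
log₁₀ space with `scipy.optimize.least_squares` (TRF). Two numerical
choices matter and are deliberate:

* finite-difference step 1e-4 in log space — the default √ε step probes
  parameter changes of ~3·10⁻⁸ relative, far below the ODE solution's
  own 1e-8 error, and yields garbage Jacobians;
* multi-start (default 5 starts: the documented initial guess ka1=1e4,
  kd1=0.1, ka2=1e-3, kd2=0.01, R_max = max observed response, plus four
  seeded log-uniform ±0.5-decade perturbations), keeping the best SSE.

Standard errors come from the Jacobian at the optimum (Gauss–Newton
covariance), propagated from log to linear scale. Non-convergence and
flat (all-zero) data are flagged on the result rather than raised, so a
batch of fits can be triaged afterwards. Model discrimination between
1:1 Langmuir (ka2 = kd2 frozen at 0) and the bivalent scheme is
reported as an SSE ratio and an AIC difference
(AIC = N·ln(SSE/N) + 2k).

**Steady-state (avidity) analysis** fits R_eq(C) = R_max·C/(C + K_D)
with bounded `curve_fit`. K_D^appTOT from this hyperbola folds both
binding steps into one constant; K_D^app1 = kd1/ka1 is computed from
the fitted constants and never stored separately (internal-consistency
invariant).

## Hydrodynamics

**Radius of gyration** Rg = √(Σwᵢ|rᵢ − r_cm|²/Σwᵢ), mass-weighted by
default (uniform weighting available), reported in nm. Invariant under
rigid motion to < 1e-9 relative.

**SASA** is Shrake–Rupley: each atom's van der Waals sphere is expanded
by the probe radius (default 1.4 Å) and sampled with a deterministic
golden-spiral lattice (default 960 points; doubling changes totals by
< 0.5% on test structures); a point is accessible when outside every
neighbouring expanded sphere (neighbours from a k-d tree). Radii are
Bondi values bundled with the package; hydrogens absent from typical
PDB files are simply not present (united-atom areas). The
hydrophobic/hydrophilic split is by element — C and S apolar, all else
polar — a standard partition; totals are sums of the same per-atom
vector, so the split is exact by construction. Exactly coincident
duplicate atoms contribute zero marginal area. The implementation is
validated against closed forms (isolated sphere, far-separated pair)
and a Monte-Carlo surface-sampling oracle for overlapping spheres.

**DLS.** Second-order cumulant reduction: ln(g₂−1) = ln B − 2Γτ + µ₂τ²,
fitted as a weighted quadratic (weights g₂−1, countering log-transform
noise amplification at the tail). D = Γ/q², diameter via
Stokes–Einstein d = k_B·T/(3πηD), PDI = µ₂/Γ². Defaults assume the
common backscatter configuration: 37 °C, water viscosity 6.913·10⁻⁴
Pa·s, λ = 633 nm, n = 1.330, θ = 173°. Non-decaying correlograms (Γ·Δτ
< 1e-6) raise a fit-failure error.

**SEC.** Calibration is a least-squares line in (elution volume,
log₁₀ MW) — the simplest standard form; partition-coefficient variants
are out of scope. Predictions outside the calibrated volume range emit
an extrapolation warning. Note the scientific caveat the toolkit
exists to illustrate: apparent MW^SEC tracks Stokes radius and surface
chemistry, not mass, so a solvated hydrophobic monomer can read as a
dimer.

## Mass spectrometry

Deconvolution tries every window of consecutive charges in
[z_min, z_max] (highest charge on the lowest-m/z peak), computes
per-peak neutral masses z·(m/z − 1.00728) and keeps the assignment with
the smallest standard deviation; the reported mass is the
intensity-weighted mean. A best dispersion above 0.2% of the mass means
no consistent series exists and is an error, not a result. On exact
synthetic series the inversion is exact; with m/z rounded to integers
(as printed peak lists are) recovery stays within 0.1%.

Average masses are used throughout — intact-protein measurements at the
20 kDa scale report isotope-envelope centroids. Peptide masses are sums
of bundled average residue masses plus water (18.0153), with +42.037
for N-acetylation and −0.985 for C-amidation; the table is cross-checked
against an independent proteomics library in the tests. The DSBU bridge
mass defaults to 196.1 u (configurable); a one-side-reacted linker adds
a further water.

One documented mismatch: the ~23,964 Da 1:1 complex mass is reproduced
with a free (not acetylated) peptide N-terminus, although such peptides
are typically synthesised N-acetylated; the acetylated variant would be
42 u heavier. The modification flags expose both conventions rather
than hiding the discrepancy.

## Flexibility

Kabsch superposition via SVD with determinant correction (always a
proper rotation), validated against a staged quaternion-grid brute-force
search. RMSF_i = √(mean_t |rᵢ(t) − rᵢ,ref|²) over Cα atoms, after
per-frame superposition on the Cα set (default on). The reference is
the supplied equilibrated structure when given, else frame 0; a "mean"
mode uses the trajectory average, which by variance decomposition lower-
bounds any fixed-reference RMSF. Input coordinates are Å; profiles are
reported in nm. Using a noisy snapshot as reference inflates RMSF by
√2 relative to the true fluctuation amplitude — the examples demonstrate
this deliberately.

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`), bit-reproducible,
and return ground-truth sidecars. Default study conditions:

* titration: two-fold dilutions from 30 µM, 8 steps (down to 0.234 µM),
  120 s association / 200 s dissociation / 1 s sampling, R_max 500 RU
  (R_max is not a published value; 500 RU is a typical peptide-capture
  level and is recorded in the sidecar), published Mg²⁺-only constants
  as generating truth, additive homoscedastic Gaussian noise σ = 1 RU,
  optional linear drift;
* equilibrium isotherms: 7 two-fold dilutions from 1 mM (bracketing a
  ~200 µM K_D — identifiability requires sampling near and above K_D),
  4 replicate series, 2% multiplicative noise;
* peak lists: exact charge-series positions, optional rounding to
  emulate printed tables;
* toy structures: two-point (Rg = d/2), uniformly filled bead sphere
  (Rg → √(3/5)·R), two-sphere dumbbell (additive SASA);
* trajectories: isotropic Gaussian displacement about a helical curve
  (RMSF = σ√3), optional per-frame random rigid contamination.

Not emulated: injection spikes and bulk refractive-index jumps,
mass-transport limitation, surface heterogeneity, correlated instrument
noise, MALDI matrix adducts, real protein geometry. Passing the
recovery tests therefore demonstrates the estimators are correct and
well-conditioned under the stated noise model — not that real
instrument exports will fit this cleanly.

## Problem sizes and other choices

The replicate recovery study in the test suite runs 50 independent
noisy titrations, each refit single-start from the documented initial
guess (multi-start is reserved for data of unknown provenance; a
single start from the standard guess is the harder test of the
optimiser and keeps the study compact). The bead-sphere Rg fixture
uses 2·10⁴ beads (1% tolerance on the √(3/5)·R limit); RMSF law checks
use 10⁴ frames (2% tolerance on σ√3).

## Known limitations

* No mass-transport or conformational-change SPR models; fits assume
  reaction-limited kinetics.
* SASA ignores hydrogens unless present in the input; areas for
  hydrogen-rich models will differ from united-atom values.
* Cumulant DLS is valid for modest polydispersity only; multimodal
  distributions are reported as a single mean decay rate with PDI > 0,
  never resolved into components.
* Charge-series deconvolution assumes a single species; overlapping
  series from mixtures are rejected as inconsistent rather than
  separated.
* Binary trajectory formats are out of scope; trajectories come from
  the generators or multi-model PDB.
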