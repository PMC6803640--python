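# biophyskit

Integrative biophysics toolkit for characterising a protein's oligomeric
state and target-recognition mechanism, built around the case of a small
(21.7 kDa) EF-hand Ca²⁺/Mg²⁺-binding protein (CIB2) interacting with the
membrane-proximal peptide of α7B integrin. The package implements the
quantitative core of that kind of study so it can be exercised on
synthetic data with known ground truth, or on your own measurements:

* **Bivalent-analyte SPR kinetics** (`biophyskit.spr_kinetics`) — the
  two-step surface scheme

  ```
  A + L  ⇌ AL    (ka1 [M⁻¹s⁻¹], kd1 [s⁻¹])
  AL + L ⇌ AL2   (ka2 [RU⁻¹s⁻¹], kd2 [s⁻¹])
  ```

  with dL/dt = −(ka1·A·L − kd1·AL) − (ka2·AL·L − kd2·AL2),
  dAL/dt = (ka1·A·L − kd1·AL) − (ka2·AL·L − kd2·AL2),
  dAL2/dt = ka2·AL·L − kd2·AL2, L(0)=R_max, observed response
  R(t) = AL + AL2. Includes global multi-concentration fitting of both
  this and the 1:1 Langmuir model, model discrimination (SSE ratio,
  ΔAIC), the first-step affinity K_D^app1 = kd1/ka1 and the steady-state
  (avidity) constant K_D^appTOT from the saturation hyperbola
  R_eq(C) = R_max·C/(C + K_D).

* **Hydrodynamics** (`biophyskit.hydrodynamics`) — mass-weighted radius
  of gyration, Shrake–Rupley solvent-accessible surface area split into
  hydrophobic (C, S) and hydrophilic contributions, the Stokes–Einstein
  relation d = k_B·T/(3πηD), second-order cumulant analysis of DLS
  correlograms (mean decay rate Γ, PDI = µ₂/Γ²), and SEC calibration
  log₁₀(MW) = a·V + b with apparent-MW prediction.

* **Native-MS and cross-linking masses** (`biophyskit.ms_utils`) — ESI
  charge-series deconvolution (consecutive-charge search minimising the
  dispersion of z·(m/z − m_H⁺)), average peptide masses from sequence,
  DSBU cross-linker adduct ladders (Δm = 196.1 u per bridge) and
  protein–peptide complex masses.

* **Flexibility** (`biophyskit.flexibility`) — Kabsch superposition and
  per-residue Cα RMSF about a reference structure.

* **Synthetic data** (`biophyskit.synthetic_data`) — seeded generators
  for all of the above (sensorgram titrations, equilibrium isotherms,
  charge-state peak lists, toy structures with closed-form Rg/SASA,
  fluctuation trajectories), each returning a ground-truth sidecar.

## Worked example

```sh
python examples/spr_global_fit.py
```

```
generating truth: ka1=3.1e4 /M/s, ka2=1.9e-3 /RU/s, kd1=0.36 /s, kd2=0.02 /s, Rmax=500 RU
fitted  ka1 = 3.09e+04 /M/s  (+/- 8e+01)
fitted  ka2 = 0.0019 /RU/s
fitted  kd1 = 0.357 /s
fitted  kd2 = 0.0201 /s
fitted  Rmax = 499.5 RU
first-step affinity KD_app1 = kd1/ka1 = 11.5 uM
model discrimination: SSE(1:1)/SSE(bivalent) = 184, delta-AIC = 13391
```

The script simulates an 8-point two-fold titration (30 µM → 0.234 µM,
120 s association / 200 s dissociation) with 1 RU Gaussian noise and
refits it globally: all four rate constants and R_max come back within a
few percent, the derived first-step affinity is ~12 µM, and the 1:1
Langmuir model is rejected by two orders of magnitude in SSE — the
signature of one analyte molecule bridging two surface ligands.

The other examples (`steady_state_avidity.py`, `native_ms_masses.py`,
`hydrodynamics_metrics.py`, `rmsf_profile.py`) follow the same pattern:
build or load a small input, run one analysis, print the numbers next to
their expected values.

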