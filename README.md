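# hepatoflow

Spatially resolved simulation of first-pass drug perfusion, distribution and
metabolization in the liver.

Compartmental (well-stirred) liver models describe hepatic clearance well
once blood and tissue have reached quasi-equilibrium, but they cannot say
anything about the first seconds to minutes after a bolus reaches the organ —
when the compound is still threading its way through the portal tree, the
sinusoidal bed and the hepatic vein, and tissue exposure is strongly
heterogeneous.  `hepatoflow` targets exactly that regime, for modelers who
want an isolated-perfused-liver *in silico*: pharmacokineticists probing
first-pass effects and hepatic heterogeneity (steatosis, pericentral
necrosis, zonation-like gradients), and imaging scientists who need
spatio-temporal concentration fields to compare against contrast-agent data.

## Model

The organ is a voxel mask; between a supplying vascular tree (SVS) and a
draining tree (DVS) lies the homogenized hepatic space (HHS), a porous medium
whose every voxel holds four subspaces — red blood cells, plasma,
interstitium, liver cells — with volume fractions f_i.  One simulation couples:

- **Vascular trees**: grown by constrained constructive optimization (CCO) —
  each added terminal site is connected through the bifurcation minimizing
  total intravascular volume Σ πr²L — with equal terminal flows Q_liv/N,
  Murray-law radii (r_p³ = Σ r_c³) and the Pries et al. in-vitro law for the
  Fåhræus–Lindqvist viscosity drop in small vessels.
- **1D advection** ∂c/∂t + v_e ∂c/∂x = 0 per edge (conservative upwind,
  Courant sub-stepping, exact mass ledger); concentrations pass junctions
  unchanged downstream, and mix flow-weighted upstream.
- **Darcy perfusion**: terminal edges act as line sources/sinks q driving
  −∇·(K_eff ∇p) = q with no-flux organ boundary (trilinear finite elements on
  voxel centers); v = −(K_eff/f_sin)∇p advects the blood phases in 3D.
- **PBPK kinetics** per voxel: passive gradient-driven exchange
  dc_a/dt −= (P_ab/f_a)(c_a − K_ab c_b) across the interface chain
  rbc↔pls↔int↔cell, plus a cellular metabolization sink (first-order k_met c
  or Michaelis–Menten V_max c/(K_m+c)), integrated with adaptive RKF45.
- **Pathology**: steatosis as a lipid-ratio field ρ(x) scaling the cellular
  partition coefficient, K_cell(ρ) = K_cell(0)(1−ρ) + k_lip ρ; CCl₄-style
  necrosis converting the cellular space to interstitium in the fraction γ of
  tissue nearest the draining terminals.
- **Observables**: outflow concentration at the draining root, per-subspace
  amounts, c_total = Σ f_i c_i (the imaging observable), mass-balance audit,
  and a well-stirred compartment reference for head-to-head comparison.

Everything needed is generated synthetically (ellipsoidal two-lobe masks,
CCO trees, a synthetic compound set) — no external data.  See
`docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
import numpy as np
from hepatoflow.fixtures import standard_config, steatosis_spec, DEFAULT_Q_LIV, \
    DEFAULT_FRACTIONS, default_compounds
from hepatoflow.simulator import run, mass_balance_report, summarize_outflow
from hepatoflow.kinetics import wellstirred_reference

cfg = standard_config("mm_drug")                     # 64-leaf trees, 804 mm^3 organ
res = run(cfg)                                       # 60 s bolus simulation
rep = mass_balance_report(res)
s = summarize_outflow(res.times, res.c_out)
print(f"metabolized {100*rep['metabolized_fraction']:.1f}% of the dose, "
      f"ledger closure {rep['closure_error']:.1e}")
print(f"outflow peak {s['peak_time']:.1f} s at {s['peak_height']:.1f} umol/L, "
      f"FWHM {s['fwhm']:.1f} s")

sick = run(standard_config("mm_drug", pathology=steatosis_spec("heterogeneous")))
print(f"steatotic liver metabolizes "
      f"{100*mass_balance_report(sick)['metabolized_fraction']:.1f}%")
```

prints (exact values are deterministic for the shipped fixture seeds):

```
metabolized 10.2% of the dose, ledger closure 6.1e-15
outflow peak 11.0 s at 33.7 umol/L, FWHM 10.2 s
steatotic liver metabolizes 11.9%
```

Read: ~10% of the injected Michaelis–Menten drug is cleared during a single
60 s pass through the healthy organ, with the books balancing to round-off;
the outflow peaks 1 s *after* the 10 s injection ends (vascular + tissue
transit) and is wider than the well-stirred prediction; lipid accumulation
raises single-pass extraction to ~12% because cellular retention lengthens the
time the drug spends next to the metabolizing enzymes.

A command-line interface mirrors the library:

```sh
hepatoflow generate-mask --half-axes 8,6,4 --spacing 0.5 --out mask.nii.gz
hepatoflow generate-tree --mask mask.nii.gz --leaves 64 --seed 11 --out svs.json
hepatoflow fixtures --name standard --out fixture/
hepatoflow run fixture/config.yaml --out results/
hepatoflow fit --observed outflow.csv --template small --out fit.json
```

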