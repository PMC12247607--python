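# mrcdi

Desk-scale **MR current density imaging (MRCDI)** in Python: simulate the
magnetic field produced by mA-scale currents injected through scalp
electrodes, simulate and reconstruct its MR phase measurement, and optimize
the ohmic tissue conductivities of a volume-conductor head model against the
measured field.

MRCDI measures the component B_z,c of the current-induced magnetic field
parallel to the scanner's main field through the phase it adds to MR images.
Comparing the measurement with a simulation from an individualized head
model allows *calibrating* the model's tissue conductivities — valuable for
dose control in transcranial electric stimulation and for source modelling
in EEG/MEG.  This package re-creates that analysis chain end to end on fully
synthetic head phantoms, so every stage is testable without any MR data.

## What's inside

* `mrcdi.phantom` — nested-ellipsoid head phantoms with the six-compartment
  topology (scalp, skull, cortical CSF, gray matter, white matter,
  ventricular CSF), electrode montages (right–left and anterior–posterior),
  wire loops/leads, and randomized cohorts of "subjects".
* `mrcdi.forward` — quasi-static current flow ∇·(σ∇φ)=0 on the voxel grid
  (7-point finite volume, harmonic-mean face conductivities, CG), current
  density **J** = −σ∇φ, and B_z from **J** via FFT-based Biot–Savart
  convolution (with a direct-sum oracle and exact finite-wire-segment
  fields for leads and loops).
* `mrcdi.recon` — alternating-polarity multi-echo phase/magnitude series
  with thermal and spatially correlated "physiological" noise;
  reconstruction B_z,c = (φ⁺−φ⁻)/(2γT_E) per echo, tSNR-derived variances,
  inverse-variance echo combination, lead stray-field subtraction, masking,
  slice extraction.
* `mrcdi.optimize` — constrained fit of per-tissue conductivities by
  minimizing

  δB_z(σ) = √( (1/N) Σᵢ ( B_z,c^s(σ,i) − B_z,c^m(i) )² )

  subject to σʲ_low ≤ σʲ ≤ σʲ_high and σ_WM ≤ σ_GM, with ventricular CSF
  fixed at 1.79 S/m as the anchor of the otherwise scale-degenerate
  conductivity set.  Jointly over multiple montages if desired.
* `mrcdi.experiments` — the error metric
  δJ = 100%·√(Σ|J^rec−J^true|² / Σ|J^true|²) and three drivers: wire-loop
  validation, conductivity recovery under added noise floors, and
  leave-one-out cross-validation over a synthetic cohort.
* `mrcdi.io` / `mrcdi.cli` — NIfTI/JSON/YAML/CSV I/O and a `mrcdi` command
  with `phantom`, `forward`, `recon`, `optimize`, and `experiment`
  subcommands.

## Worked example

```python
import numpy as np
from mrcdi import (
    BzField, ConductivityVector, apply_mask, build_phantom, default_spec,
    joint_objective_stack, make_dataset, montage_ap, montage_rl,
    optimize_conductivities, simulate_montage,
)

vol = build_phantom(default_spec((32, 32, 32), 6.0))
truth = ConductivityVector.ground_truth()      # sigma_WM=0.11, ..., S/m

datasets = []
for montage in (montage_rl(), montage_ap()):   # 1 mA injections
    _, _, bz = simulate_montage(vol, truth, montage)
    _, mask = apply_mask(bz, vol)              # brain-only mask
    meas = BzField(bz=bz.bz.copy(), grid=vol.grid, provenance="measured")
    datasets.append(make_dataset(vol, montage, meas, mask))

result = optimize_conductivities(
    joint_objective_stack(datasets), ConductivityVector.literature(),
    max_evaluations=400,
)
print({t: round(v, 4) for t, v in result.sigma_opt.sigma.items()})
print(f"delta_Bz: {result.delta_initial:.3e} -> {result.delta_final:.3e} T")
```

Output:

```
{'wm': 0.11, 'gm': 0.23, 'ccsf': 0.9, 'scalp': 0.3, 'skull': 0.012, 'vcsf': 1.79}
delta_Bz: 1.390e-10 -> 1.175e-15 T
```

Starting from literature conductivities (σ_WM=0.126, σ_GM=0.275,
σ_cCSF=0.8, σ_scalp=0.465, σ_skull=0.01 S/m), the fit recovers the
generating values exactly on this noiseless problem, and the RMS field
misfit drops from 0.14 nT (the model error of the literature values at
1 mA) to numerical zero.

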