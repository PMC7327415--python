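# slimspore

Single-molecule Slimfield microscopy analysis of the sporulation
phosphatase **SpoIIE** in live *Bacillus subtilis*.

During sporulation a *B. subtilis* cell divides asymmetrically into a
small forespore and a large mother cell; SpoIIE, an integral membrane
phosphatase, couples that morphological program to forespore-specific
gene expression (activation of the sigma factor σ^F). `slimspore`
provides the complete computational pipeline for quantifying
SpoIIE-mYPet in two-channel millisecond fluorescence image stacks
(channel 1: SpoIIE-mYPet, channel 2: FM4-64 membrane stain; 5 ms/frame,
80 nm/pixel), for researchers doing live-cell single-molecule
quantification:

* **simulate** — ground-truthed synthetic Slimfield data: stage-labelled
  two-channel cell images (hollow-cylinder membrane + stage-specific
  spore features through a ~250 nm PSF with depth-of-field defocus and
  Poisson noise), photobleaching stacks, Brownian foci movies, FRAP
  curves;
* **staging** — automated sporulation-stage categorization
  (I, II_i, II_ii, II_iii, III) from sausage-model segmentation,
  double-threshold Otsu spore-feature detection, ellipse shape classes
  and septum curvature, plus eigenimage (Hotelling-deflation PCA)
  validation;
* **tracking** — foci detection by iterative Gaussian masking (~40 nm
  localization), background-corrected intensities, SNR-gated
  nearest-neighbour track linking;
* **stoichiometry** — Chung–Kennedy filtering, single-fluorophore
  intensity from terminal photobleach steps, molecule counts from
  I₀ = I_single·S exponential fits (I = I₀·exp(−t/t_b), t_b ≈ 100 ms),
  compartment copy numbers and the ×4 depth-of-field extrapolation;
* **cluster** — the Poisson foci-overlap mixture model
  P(x) = Σₖ Pois(k; λ)·N(x; kS, σ²kS) over apparent stoichiometry, with
  χ² selection among oligomer hypotheses S ∈ {1, 2, 4, 6, 8};
* **mobility** — MSD(τ) = 4Dτ + 4σ² diffusion fitting, D ~ S^−α power
  laws, and the Saffman–Delbrück membrane drag model
  γ = 4π(η₁+η₂)a·C(ε), C ≈ 1/(ε ln(2/ε)), D = k_BT/γ, with D ↔ a
  inversion (Stokes radius of the diffusing complex);
* **frap** — exponential recovery-time fitting with a principled
  no-recovery decision rule.

## Worked example

```python
import numpy as np
from slimspore.simulate import CellGeometry, simulate_stage_image
from slimspore.staging import classify_cell
from slimspore.mobility import MembraneDragModel, invert_D

# render one stage-II_iii cell (engulfment) and classify it
geom = CellGeometry(length_um=2.4, stage="II_iii")
stacks, truth = simulate_stage_image(geom, seed=11, noise=None)
res = classify_cell(stacks["mYPet"], stacks["FM"])
print(res.stage, round(res.mypet_feature.curvature, 2))

# Stokes radius of a slow SpoIIE cluster in the forespore membrane
model = MembraneDragModel(eta_membrane_cP=1000.0)
print(round(invert_D(0.47, model), 1), "nm")
```

prints

```
II_iii 1.7
40.4 nm
```

The cell is assigned its generating stage because its engulfing septum is
curved (κ = 1.7 > 1 distinguishes the hemispherical engulfment dome of
stage II_iii from the flat septum of II_i, κ ≈ 0); and a focus diffusing
at the low-mobility consensus D = 0.47 µm²/s in a 1000 cP forespore
membrane behaves like a membrane-spanning cylinder of ~40 nm radius — an
order of magnitude larger than the ~4 nm bare tetramer
(`helix_packing_radius(40, 1.2)` → 3.79 nm), the signature of SpoIIE
diffusing in complex with partner machinery.

A command-line interface mirrors the library:

```bash
slimspore simulate --stage II_i --n-cells 20 --noise none --seed 1 --out data/
slimspore track --in stack.tif --out tracks.csv
slimspore run --n-cells 4 --out results/
```

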