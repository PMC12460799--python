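# volsmlm

Simulation and analysis toolkit for **volumetric astigmatism-based 3D
single-molecule localization microscopy (SMLM)** with light-sheet
illumination — the acquisition scheme in which an entire suspended cell
(≈ 10 µm thick) is imaged plane by plane with DNA-PAINT blinking,
photostable fiducial beads embedded around the sample well provide the
reference signal for sensorless adaptive optics, real-time three-axis
drift feedback and plane-to-plane registration, and the per-plane
localization tables are assembled into one super-resolved volume.

The package is aimed at microscopists and method developers who want to
prototype, stress-test or teach the computational side of such a system
without a microscope: every input can be produced by the built-in
forward model with known ground truth.

## What is implemented

* **`sim_core`** — scalar Fourier-optics PSF with Noll-normalized Zernike
  aberrations (nm RMS), induced astigmatism for axial encoding, a
  depth-proportional first-order spherical term (0.031 rad·µm⁻¹ of
  imaging depth), exact high-NA defocus; DNA-PAINT two-state blinking;
  Poisson-placed fiducials outside a sample well; rigid 3-axis drift; an
  sCMOS camera (baseline 100 ADU, 0.46 e⁻/ADU, QE 0.82, read noise).
* **`ao_3n`** — sensorless modal adaptive optics by the *3N algorithm*:
  each Zernike mode is probed at (+α, 0, −α) with α = 60 nm RMS, a
  parabola is fitted through the three merit values (merit = 1 / max
  intensity of a point source) and the correction jumps to its vertex;
  2–3 sweeps over seven modes (astigmatism V/O, coma V/H, spherical,
  trefoil V/H).
* **`localizer`** — à-trous B3-spline wavelet spot detection, anisotropic
  2D Gaussian fitting, σx/σy-vs-z astigmatism calibration from a bead
  z-stack (25 nm steps), least-squares z lookup, and quality filtering
  (χ² ∈ [0.6, 1], z ∈ [−0.5, 0.5] µm).
* **`smartrack`** — per-plane fiducial selection (130 ≤ σ ≤ 300 nm,
  χ² > 0.65, outside the well), the Euclidean drift metric
  dᵢ = √((xᵢ−x₀)² + (yᵢ−y₀)² + (zᵢ−z₀)²), a sliding-window (W = 10)
  feedback loop on a simulated XYZ stage, and automatic multi-plane
  sequencing with gap handling.
* **`volume_builder`** — offline residual drift correction from the bead
  track, plane registration by the mean lateral shift of 4–10 shared
  fiducials, volume assembly with the (i−1)·Δz axial offset, axial
  coefficient of variation, Gaussian volume rendering (10 nm pixels,
  200 nm plane spacing, 10/50 nm blur), and a Fourier filter that zeroes
  the camera-pixel-frequency bins to remove reconstruction grid
  artifacts.
* **`resolution_metrics`** — Fourier ring correlation on even/odd
  localization splits with the 1/7 criterion, and bead-cluster FWHM
  (2.35 × the std of the principal-axis projections).
* **`cluster_analysis`** — 3D Voronoi local density, density-threshold +
  single-linkage clustering (≥ 10 localizations, 50 nm cutting
  distance), per-cluster FWHM/volume descriptors, best-fit sphere,
  spherical Voronoi membrane maps, and cluster-property-vs-z regression.
* **`io` / `pipeline` / `cli`** — ThunderSTORM-compatible CSV tables,
  YAML configuration, TIFF stacks, and a `volsmlm` command-line tool
  (`simulate`, `ao3n`, `acquire`, `localize`, `reconstruct`, `resolve`,
  `cluster`, `pipeline`).

## Worked example

Correct an unknown 40 nm RMS horizontal coma with the 3N loop on a
simulated bead, then localize a molecule in 3D:

```python
import numpy as np
from volsmlm.sim_core import OpticalConfig, CameraModel, render_psf
from volsmlm.ao_3n import run_3n
from volsmlm.zernike import ZernikeCoeffs

cfg = OpticalConfig()
hidden = ZernikeCoeffs({"coma_horizontal": 40.0})
state = run_3n(lambda c: render_psf(hidden.add(c), 0.0, 0.0, cfg),
               iterations=2)
print(round(state.correction.get("coma_horizontal"), 1))   # -40.8
print(round(hidden.add(state.correction).total_rms_nm(), 2))  # 0.78
```

The loop recovers the injected aberration to better than 1 nm RMS — the
residual printed above is the total remaining wavefront error across the
seven corrected modes, far below the 5 nm acceptance threshold used in
the test suite.

Or run the whole synthetic pipeline (AO → calibration → two-plane
drift-corrected acquisition → localization → assembly → rendering):

```bash
volsmlm pipeline --seed 3 --out demo/
```

which prints a manifest like

```json
{"n_planes_acquired": 2, "skipped_planes": [], "n_localizations": 137,
 "axial_cv": 0.417, "ao_initial_merit": 13.339, "ao_final_merit": 10.683,
 "calibration_symmetry": 0.00014}
```

— two planes acquired under closed-loop drift correction, a calibration
whose σx/σy curves are symmetric to 0.01%, and an axial localization
distribution whose coefficient of variation (42%) sits in the range
multi-plane DNA-PAINT volumes show in practice.

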