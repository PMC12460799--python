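# Methods

This note documents the models, numerical choices and limitations behind
`volsmlm`. It is written for readers who want to know what the
simulations and estimators actually compute, and what a passing test
does and does not demonstrate about real microscope data.

## Optical forward model

The PSF is computed with a scalar Fourier-optics pupil model: the pupil
is a circular aperture of radius NA/λ in frequency space, carrying a
phase with three contributions,

* the modal aberrations, expressed in unit-RMS (Noll-normalized) Zernike
  polynomials with amplitudes in nm RMS of optical path (converted to
  phase by 2π/λ);
* a first-order spherical term growing linearly with imaging depth at
  0.031 rad RMS µm⁻¹, the signature of residual refractive-index
  mismatch in water-dipped objectives;
* exact (non-paraxial) defocus, 2πz·√((n/λ)² − f²), for the emitter's
  axial offset z from the focal plane.

The intensity PSF is |FFT(pupil)|², computed on a fine grid
(camera pixel / 3 by default) and box-integrated onto camera pixels.
Sub-pixel emitter positions are applied as a pupil tilt. The default
optics (NA 1.2 water immersion, λ = 580 nm, 108 nm camera pixels — a
6.5 µm sCMOS pixel behind a 60× objective) are configurable.

A Gaussian *system blur* (default σ = 85 nm) is convolved with the
intensity PSF. It models the finite size of the ~100 nm fiducial beads
together with residual incoherent blur of a real system; its default is
chosen so that the fitted astigmatic widths σ(z) span ≈ 130–330 nm over
z ∈ ±0.4 µm, the range in which bead-selection filters of
130–300 nm are meaningful. Without it, a diffraction-limited model
produces astigmatic waists near 90 nm that no real calibration curve
shows. The blur applies to all emitters, so the bead-derived
calibration remains valid for molecules.

Two deliberate simplifications: the model is scalar (no vectorial
high-NA effects, no supercritical-angle fluorescence), and the only
depth-dependent aberration is the linear spherical term. Both are
sufficient to exercise the downstream algorithms, which is the purpose
of the simulator; absolute PSF photometry at NA > 1.2 is not.

## Photophysics, sample and camera

DNA-PAINT blinking is a discrete-time two-state Markov chain per
molecule and frame: OFF→ON with probability k_on (default 2×10⁻³ per
frame, the regime of ~1 nM imager at 10 Hz), ON→OFF with probability
1/τ_on (τ_on = 3 frames). Partial-frame on-times are ignored, so
photon counts per event are not sub-frame accurate. The steady-state ON
fraction k_on/(k_on + 1/τ_on) is a tested invariant.

Fiducial beads are placed as a Poisson process of configurable density
(the characterized device value is 4.5×10⁻³ µm⁻³) in the polymer volume
minus the sample well. In the small demonstration fields of view (≈ 5 µm
wide, versus a full camera frame in a real system) an equivalent *number
of beads per plane* requires a higher volumetric density; the pipeline
demo uses 0.3 µm⁻³ for that reason.

The camera converts expected photons to counts as
ADU = Poisson(N·QE)/g + baseline with QE = 0.82, g = 0.46 e⁻/ADU and
baseline = 100 ADU, plus Gaussian read noise (default 1.4 e⁻ RMS, a
typical sCMOS figure) and 16-bit quantization. A molecule emitting
3500×0.46/QE photons per frame therefore integrates to ~3500 ADU, the
single-molecule signal level the pipeline is parameterized around;
background is flat (0–200 ADU range) with an optional linear gradient —
real DNA-PAINT backgrounds are more structured than this.

Drift is a rigid per-frame offset of the whole sample; the regime used in tests is ~0.1–1 nm/frame, i.e. tens of nm over one plane.

## Sensorless adaptive optics (3N)

Merit factor: the inverse of the maximum pixel intensity of a point
source image, after subtracting the camera baseline so that the merit
reflects signal rather than offset (whether the hardware implementation
uses raw maxima is not documented; the baseline is exposed as a
parameter). Each mode is probed at −α, 0, +α about the current
correction (α = 60 nm RMS) and the parabola through the three merits
gives the update α_opt = α(m₋ − m₊)/(2(m₋ − 2m₀ + m₊)), clamped to
[−α, α]. Non-convex triplets (possible with noisy merits) fall back to
the best sampled point and are flagged. The default mode list is the
seven first aberration modes (astigmatism V/O, coma V/H, first
spherical, trefoil V/H); the list and iteration count (2–3) are
configuration, and noisy systems can average k frames per merit
evaluation. On noiseless simulated PSFs the loop recovers single-mode
injections ≤ 60 nm to < 1 nm residual in two sweeps, validated against
a 1 nm-step exhaustive merit scan.

## Localization

Detection runs an à-trous (undecimated) B3-spline wavelet transform and
thresholds the second wavelet plane at 1.5 × a MAD-based noise scale;
connected components of ≥ 4 pixels become candidates. The exact
constants of the original wavelet detector are not published; these
values reproduce its qualitative behavior (robust to smooth background,
sensitive at ~2–4 px scales).

Fitting is bounded least squares of an elliptical Gaussian
A·exp(−(x−x₀)²/2σx² − (y−y₀)²/2σy²) + b on a 15×15 px ROI. The ROI
must accommodate the largest astigmatic PSFs (~330 nm σ ≈ 3 px); a
smaller ROI truncates them and biases σ — an effect that directly
biases z. The goodness of fit is reported as χ² = 1 − SS_res/SS_tot
(the coefficient of determination) clamped to [0, 1]: the upstream
convention puts "good" near 1, which a classical chi-square statistic
does not; this surrogate is declared, not claimed equivalent to any
specific implementation.

The astigmatism calibration fits every plane of a bead z-stack
(±0.6 µm, 25 nm steps), recenters z on the σx = σy crossing, requires
σx−σy to be strictly monotone on ±0.4 µm, and scores symmetry as the
normalized L2 distance between σx(z) and σy(−z) (zero for an
aberration-free astigmatic PSF; residual spherical aberration degrades
it, which is how calibration quality is checked). z assignment
minimizes (σx−σx_cal(z))² + (σy−σy_cal(z))² on a 1 nm spline grid
restricted to |z| ≤ 0.5 µm — a least-squares lookup in σ-space rather
than inverting σx−σy, which is more robust when both σ estimates err in
the same direction. Quality filters keep χ² ∈ [0.6, 1] and
z ∈ [−0.5, 0.5] µm, both bounds inclusive.

Measured performance at the 3500 ADU signal level (simulated, matched
to ground truth by proximity): lateral precision ∝ 1/√photons (log–log
slope −0.5), ~10 nm lateral RMS and ~22 nm z RMSE over |z| ≤ 0.4 µm;
detection yield decays beyond |z| ≈ 0.4 µm at high background.

## Drift feedback and plane sequencing

The reference bead for each plane is chosen from a pre-acquisition
fiducial image: candidates must satisfy 130 ≤ σx, σy ≤ 300 nm and
χ² > 0.65 and lie outside the well; among them the smallest |σx−σy|
(axially closest to the plane) wins, ties broken by χ². "Closest to
focus with best accuracy" is the documented intent; the min-anisotropy
ordering is this package's concrete rule. Beads whose tracking ROI
would not fit inside the frame are excluded.

The drift at frame i is the Euclidean distance between the temporally
averaged bead position and its reference. The position estimate is the
sliding mean of the last W = 10 localizations *after compensating each
by the corrections issued up to its frame*: averaging raw positions
from a mix of pre- and post-correction frames makes the loop integrate
stale errors and oscillate, whereas the compensated (drift-space)
average is provably stable and reaches the analytic floor
σ/√W + lag, with lag ≈ rate·(W+1)/2 for linear drift. Corrections are
issued whenever the estimated displacement exceeds the threshold
(default 0) and act with one frame of latency; the stage can add
Gaussian positioning noise. The reference stays absolute for the whole
plane (corrections accumulate); a bead lost for 50 consecutive frames
aborts the plane. Per-axis bookkeeping — compensated drift plus final
residual equals injected drift — holds to numerical precision and is
tested.

Plane sequencing advances both the focal plane and (implicitly) the
excitation plane by Δz after each plane; planes with no eligible bead
are skipped and logged, and the acquisition errors out only if every
plane is bead-less. A constant per-plane offset between the pre-image
reference and the in-loop tracking estimate (mostly in z) is absorbed
downstream by the offline bead-track correction and registration, so
the per-plane stability metric is RMS about the settled mean.

## Reconstruction

Offline residual-drift correction subtracts the moving-averaged
(window W) bead displacement, interpolated at each localization's
frame, after removing its mean — the mean is a static offset that
belongs to registration. Registration matches per-plane mean bead
positions between adjacent planes by nearest neighbor within 500 nm
(the upstream workflow selects them manually; automated matching needs
a radius) and translates plane i+1 by the mean lateral shift;
shifts accumulate across planes. Assembly adds (i−1)·Δz to plane i and
renumbers localizations sequentially. The axial coefficient of
variation histograms counts along z in bins of the plane spacing
(population std / mean); the bin width is a package choice.

Rendering deposits localizations on a 10 nm lateral / 200 nm axial
grid and applies a Gaussian filter of σ = 10 nm lateral, 50 nm axial —
equivalent to per-localization Gaussian splatting up to voxel
quantization and much faster. The grid-artifact filter zeroes the DFT
rows and columns at integer non-zero multiples of N/z_sr (spatial
frequency 1/Δ and harmonics, Δ = camera pixel, z_sr = Δ/render pixel),
preserving DC; it removes single frequency lines rather than notch
neighborhoods, so any broadband signal sharing those exact bins is
also removed — the price of an exact comb filter.

## Resolution estimation

FRC splits the volume by localization-id parity, renders both halves on
one common grid, and computes per-z-plane ring correlations (1-bin
rings) smoothed with a 3-bin moving average before the 1/7 threshold
crossing (the reference implementation is an external plugin with no
published smoothing rule). Planes whose curve starts below 1/7 are
reported unresolved and excluded; curves that never drop below the
criterion floor at 2 render pixels (Nyquist). FRC on localization data
depends on localization density as well as on the smoothing kernel: on
densely sampled filaments the estimate approaches
2.35·√(σ_loc² + blur²), and tests assert agreement within 30% at high
density only.

Bead-FWHM resolution takes each bead's localization cloud, projects it
on its principal axes, and reports 2.35 × the projection std; lateral
is the mean of the two short axes, axial the long axis — justified
because astigmatic z precision is always the worst direction; beads
whose long axis deviates > 30° from z are flagged rather than silently
accepted.

## Cluster analysis

Local density uses the first-rank Voronoi neighborhood:
δᵢ = (1 + |N₁(i)|) / (Vᵢ + Σ_{j∈N₁(i)} Vⱼ). Cells on the cloud hull —
either formally unbounded or with vertices escaping the data bounding
box by > 5% — have no meaningful volume and receive the mean density of
their valid neighbors instead (iterated until all points are
assigned). The segmentation threshold, "greater than the average
density", is the dataset count divided by the dataset volume (the sum
of the valid Voronoi cell volumes), the normalization customary in
tessellation-based SMLM cluster analysis; thresholding at the *mean of
the per-point densities* instead would discard 30–50% of each Gaussian
cluster's periphery and bias FWHM low by ~15–20%. Above-threshold
points are linked at ≤ 50 nm (single linkage via a KD-tree and sparse
connected components); components with ≥ 10 points become clusters.

Cluster descriptors: d_z = 2.35 × std of z (the axis along which the
localization error is largest), d_r = the mean of the two lateral
principal-axis FWHMs (whether the upstream analysis averages the short
ellipsoid axes or uses an in-plane projection is not documented; the
lateral-principal-axes mean is this package's rule), volume
V = (4/3)π(d_r/2)²(d_z/2). The best-fit sphere is an algebraic (Coope)
fit refined by geometric least squares; cluster centroids are projected
radially and a spherical Voronoi diagram (SciPy) maps per-cluster
surface density (1/cell area); cell areas partition 4πR² exactly.
Property-vs-z regressions are ordinary least squares; for a property
independent of z the expected R² is ~1/(n−1), and R² ≤ 0.03 is the
homogeneity screen used on membrane receptor maps.

The synthetic receptor map places cluster centers uniformly on a
sphere (R = 5 µm, a suspended T cell), each cluster an anisotropic
Gaussian (σ_lat = 20 nm, σ_ax = 50 nm along global z, the
localization-precision anisotropy) of ~40 localizations, plus uniform
nonspecific background in a ±300 nm shell at 2 background localizations
per clustered one — roughly the specific/nonspecific balance of
membrane DNA-PAINT data. On this map the pipeline recovers ≥ 93% of
500 clusters, FWHMs within 10% and the sphere radius to ~1 nm. Close
cluster pairs merged by the 50 nm linkage account for most of the
missing count. What this does not show: performance on non-Gaussian
cluster shapes, strongly varying background, or membranes that are far
from spherical.

## Problem sizes and determinism

Tests and the acceptance script run simulations sized for a single CPU:
tens of emitters per localization statistic, 1000-frame feedback loops,
two-plane pipeline demonstrations with ~50–200 frames per plane, and a
500-cluster receptor map (~60k localizations). These sizes were chosen
so each statistic's Monte-Carlo error is well inside the asserted
tolerance. All randomness flows through seeded `numpy` generators;
identical seeds reproduce frame stacks bit for bit.

## Known limitations

* Scalar PSF, flat background, rigid drift: adequate for algorithm
  validation, not for instrument photometry.
* The χ² surrogate and wavelet constants emulate, but are not asserted
  identical to, the proprietary localization software they stand in
  for.
* High-density (overlapping-PSF) localization is out of scope; the
  localizer assumes the sparse blinking regime, and the grid-artifact
  filter exists because reconstructions from pixel-wise deep-learning
  localizers show a camera-pixel-frequency comb.
* Field-dependent (isoplanatic-patch) aberrations are not modeled; one
  Zernike set applies to the whole field.
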