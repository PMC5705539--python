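# Methods

## Scope and model

`y90voxdose` models the post-therapy imaging-and-dosimetry chain for ⁹⁰Y
microsphere radioembolization at the voxel level. The physical model is
deliberately minimal and fully stated:

* ⁹⁰Y decays with T½ = 2.67 d; each decay emits one beta particle with mean
  energy Ē = 0.932 MeV (endpoint 2.28 MeV), and with probability
  3.186 × 10⁻⁵ an internal-pair-production positron that PET can detect.
  The 0.932 MeV value is the dosimetry convention used throughout; the
  spectroscopic mean of the β⁻ spectrum is a few tenths of a percent higher
  (933.7 keV) and can be supplied through `NuclideConstants` if preferred.
* Tissue is water-equivalent with density ρ = 1 g/mL everywhere, so voxel
  mass in grams equals voxel volume in mL. Heterogeneity (lung, bone,
  phantom walls) is out of scope; so is Monte Carlo radiation transport.
* Microspheres are a permanent implant: time-activity integrates over the
  full physical decay, N_decays = A₀/λ = (T½/ln2)·A₀.

## Image simulation

The simulator emulates an already-reconstructed, fully corrected PET image,
not a scanner. For an activity map C (Bq/mL):

1. expected detected positron counts per voxel
   μ = C · v_voxel · BR · t_scan · s, with sensitivity s the effective
   detected fraction of emitted positrons;
2. isotropic Gaussian PSF blur of μ (default FWHM 6 mm — the emulated
   scanner's reconstructed resolution scale; the blur is applied in the
   counts domain, before sampling, so noise is not smoothed);
3. a flat additive expected-count floor (default 0) standing in for residual
   scatter/randoms bias;
4. Poisson sampling with a single integer seed (replicates use fixed seed
   increments, making every study bit-reproducible);
5. inversion of step 1 (times an optional calibration factor) back to Bq/mL.

This reproduces the features that matter for quantification studies —
Poisson noise scaling, positive skew at low counts, spill-in/spill-out bias —
but not OSEM noise correlations, attenuation/scatter artefacts, dead time,
or motion. Tests passing on these images therefore validate the analysis
chain, not scanner-specific image quality.

Defaults are the validation-experiment conditions the package emulates:
reconstruction voxels 2.73 × 2.73 × 3.27 mm (0.024371 mL); uniform cylinder
5640 mL at 273 kBq/mL; IEC spheres 0.52–26.52 mL at 2.28 MBq/mL over an 8:1
background; anthropomorphic torso (~10,300 mL cold water) with a 1200 mL
liver at 0.89 MBq/mL, cold lungs/spine, and a 19.13 mL cylindrical insert
(d = 28.5 mm, h = 30 mm) at 5.5 MBq/mL (6:1 insert:liver). The scanner's
absolute sensitivity is not publicly documented; the default s = 1 makes a
15-min scan of the day-1 insert yield ~3 × 10⁶ detected events, the right
order of magnitude for visibly noisy but quantifiable images. Absolute noise
magnitudes (e.g. a specific HI value at a given activity) are therefore not
calibrated; noise *scaling* with counts is.

## Phantom voxelisation

Compartments (cylinder, sphere, box) are painted in order onto the grid;
later compartments overwrite earlier ones. Each voxel's occupancy is
estimated by 3×3×3 sub-voxel sampling; ground-truth activity is
occupancy-blended at edges, and masks threshold occupancy at ≥ 0.5. This
reproduces nominal compartment volumes within ~1% on the default grids
without a meshing engine. A compartment extending outside the grid raises a
`GeometryError` naming it.

## Quantification conventions

* Quartiles: linear interpolation between order statistics.
* Standard deviation: population (ddof = 0), consistent with the HI identity
  HI = sd/mean for equal voxel volumes and with the {0, 2} Gy → (1, 1)
  dose-summary convention.
* Skewness: adjusted Fisher–Pearson sample coefficient; reported as 0 for a
  constant VOI.
* dAVH: default bin width (max − min)/100 of the masked values; the density
  is the negative discrete derivative of the cumulative volume fraction and
  integrates to 1 (tested to 1e-9).
* Recovery coefficients: interpolated linearly in log(volume) and clamped to
  the table's end values outside its range — extrapolating a six-point
  curve would be less defensible than clamping. RC uncertainty, where
  needed, is conventionally 5% (radionuclide-calibrator accuracy) and
  propagates multiplicatively.
* Partial-volume correction divides the measured mean by RC(V). Objects
  whose smallest dimension exceeds ~3× the PSF FWHM need no correction; the
  choice of contoured versus nominal volume for the RC lookup is left to the
  caller (the volume is an explicit argument).

## Dosimetry

**Local deposition.** D_voxel = C_voxel · k with
k = (T½/ln2) · Ē · 1.602 × 10⁻¹³ J/MeV · 10³ mL/kg = 4.969 × 10⁻⁵ Gy·s·mL
for ⁹⁰Y. A `rounded_factor` flag substitutes the rounded 1.44 permanent-implant
factor for 1/ln2 = 1.4427, giving 4.960 × 10⁻⁵; both conventions circulate in
the literature and differ by 0.19%. Negative voxels (possible in iterative
reconstructions) are clamped to zero with a logged count.

**Kernel convolution.** D = S ⊗ Ã with Ã = C·v_voxel/λ cumulated decays and
S a voxel S-value kernel (Gy per decay at each offset). Boundaries are
zero-padded — phantom activity is zero outside the grid by construction.
Convolution uses FFT (with a clamp of FFT round-off negatives); a 1×1×1
kernel short-circuits to an exact multiply, making the delta-kernel ≡
local-deposition identity exact. Two kernels ship:

* the delta kernel, S(0) = Ē_J/m_voxel;
* a synthetic analytic beta point kernel with radial energy-deposition
  density Ē·μ³e^(−μr)/8π (default μ = 2 mm⁻¹, concentrating ~98% of the
  energy within 4 mm, in the few-mm range of ⁹⁰Y beta transport in water).
  It is voxelised by midpoint quadrature over 5³ sub-voxels and renormalised
  to the analytic enclosed-energy fraction, so its energy closure is exact
  by construction and the declared `leakage` is the analytic tail
  (≤ 0.5% at the default radius). This kernel is a *synthetic stand-in*
  with the correct integral properties, not a transport-derived ⁹⁰Y kernel;
  measured or published kernels can be supplied as `DoseKernel` inputs.

**MIRD average.** For a uniformly filled unit-density volume with absorbed
fraction 1, mass and volume cancel and the average dose is C·k — identical
to local deposition on uniform activity. On uniform maps the three
algorithms agree: interior kernel-convolution dose matches LD/MIRD within
the kernel leakage (radiation equilibrium), which the tests assert.

**dDVH.** Equal-width histogram of masked dose values; heights are
dv/dD = counts · v_voxel / ΔD, so the accumulated volume (Σ counts · v_voxel)
equals the mask volume exactly and the quadrature integral matches to
floating-point precision.

## Noise power law

`fit_power_law` is OLS on (ln x, ln y); the exponent's uncertainty is the
slope standard error and r² is computed on the log scale (the log base
cancels in the exponent). `hi_noise_study` simulates a uniform cylinder
(default d = h = 60 mm on a 3-mm grid) at each activity level, computes HI
on the cylinder mask eroded by 2 voxels — edge voxels are excluded because
PSF spill-out adds a count-independent inhomogeneity that would bias the
slope — and pools all (emitted positrons, HI) pairs into one fit. The
default design is 5 levels spanning two decades × 3 replicates, mirroring a
multi-day decay series with two VOIs per day; designs narrower than 1.5
decades or with < 4 levels are rejected as degenerate. In the
Poisson-dominated regime the fitted exponent is −0.5 within a few percent;
in the infinite-count limit HI approaches a floor and the fit is flagged
unstable.

## TLD chain

The measurement equation is strictly multiplicative, so permuting factors
changes nothing and relative uncertainties add in quadrature (factors are
assumed uncorrelated; correlation support is deferred). Chip sets aggregate
by inverse-variance weighting with standard uncertainty (Σwᵢ)^(−1/2); the
aggregate uncertainty can never exceed the best single chip's. Outlier
handling defaults to manual contamination flags; a two-sided iterative
Grubbs test (α = 0.05) can be opted into and always logs what it removed.
Correction factors k_fv, H, k_mat default to 1 with zero uncertainty and
must be supplied for real measurements — they come from radiation-transport
calculations outside this package's scope. Dose per emitted particle divides
by N = C·V·(1 − e^(−λt))/λ; the liquid volume V is a mandatory explicit
input because the normalisation is directly proportional to it.

## Problem sizes and determinism

Default study grids are chosen so every analysis runs in seconds on one
core: the IEC grid is ~81×81×25 voxels, the anthropomorphic grid
~114×114×57, the noise-study cylinder ~30³. Every stochastic path takes a
single integer seed; the pipeline runner (`run_pipeline`) writes a JSON
report with a provenance block recording the nuclide constants, acquisition
parameters and every numeric default applied, and identical config + seed
produces a byte-identical report.

## Known limitations

* No sinogram-domain physics: attenuation, scatter spatial structure, OSEM
  convergence/noise correlations and dead time are not modelled.
* The synthetic beta kernel has the right energy integral but an idealised
  radial shape; absolute voxel-scale dose gradients from it are indicative
  only.
* Absolute noise levels are tied to the free sensitivity parameter; only
  count-scaling behaviour is calibrated.
* Uniform unit density throughout; no lung/bone or phantom-wall
  perturbations, no respiratory motion, no radiobiological (BED/EQD2)
  modelling.
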