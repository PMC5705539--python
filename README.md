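# y90voxdose

Quantitative ⁹⁰Y PET/CT phantom simulation and voxel-level absorbed-dose
calculation for liver radioembolization (SIRT) dosimetry.

After radioembolization, ⁹⁰Y microspheres are a permanent implant: a single
post-therapy PET image can be converted into an absorbed-dose map. But ⁹⁰Y is
an almost pure β⁻ emitter — PET only sees it through a rare internal pair
production branch (branch ratio ≈ 3.186 × 10⁻⁵), so the images are
count-starved, noisy, and biased by partial-volume effects. This package is
for medical physicists who want to study that whole chain on controlled
synthetic phantoms: how counting statistics and the point-spread function
distort the recovered activity, how well recovery-coefficient corrections
restore it, and how much the choice of dose algorithm matters.

## What it computes

**Simulation** (`y90voxdose.phantom`): voxelised phantoms (uniform cylinder,
IEC body phantom with six spheres, anthropomorphic torso with a hot lesion
insert in the liver) and reconstructed-image emulation — expected positron
counts per voxel `C · v_voxel · BR · t · s`, Gaussian PSF blur, Poisson noise,
inversion back to Bq/mL.

**Quantification** (`y90voxdose.quantify`): surrogate-nuclide calibration
rescaling by the β⁺ branch ratio; VOI statistics; differential
activity-volume histograms (dAVH), normalised so ∫ dAVH dc = 1; the
homogeneity index

HI = (1/C̄) √( Σᵢ (vᵢ/V)(cᵢ − C̄)² ),

i.e. the volume-weighted coefficient of variation; recovery coefficients
RC(V) = C_meas/C_true and partial-volume correction C̄/RC(V).

**Dosimetry** (`y90voxdose.dosimetry`): three dose algorithms —

* local deposition: `D_voxel [Gy] = C_voxel [Bq/mL] · (T½/ln2) · Ē · 1.602e-13 · 10³
  ≈ 4.97e-5 Gy·s·mL` for ⁹⁰Y (T½ = 2.67 d, Ē = 0.932 MeV);
* kernel convolution `D = S ⊗ Ã` of the cumulated-decay map `Ã = C·v/λ` with a
  voxel S-value kernel (a delta kernel and a synthetic analytic beta point
  kernel are provided; kernels are ordinary inputs);
* the MIRD average for a uniformly filled unit-density volume,

plus differential DVHs whose integral is exactly the VOI volume.

**Noise analysis** (`y90voxdose.noise_fit`): the power law HI = a·N^b versus
emitted positrons, fitted by log-log OLS; for Poisson-limited images the
exponent is −1/2.

**TLD dosimetry** (`y90voxdose.tld`): the multiplicative measurement equation
`D_w = TL · N_Dw · k_fv · H · k_mat` with quadrature uncertainty propagation,
inverse-variance chip aggregation, and normalisation to Gy per emitted beta
particle.

## Worked example

Simulate a day-1 anthropomorphic acquisition (insert 5.5 MBq/mL, liver
0.89 MBq/mL, 15-min scan, 6-mm PSF), quantify the insert, correct for partial
volume with an RC table measured on a simulated IEC phantom, and compare dose
algorithms:

```python
import numpy as np
import y90voxdose as y
from y90voxdose.phantom import IEC_SPHERE_VOLUMES_ML

activity, masks = y.build_phantom(y.anthropomorphic_spec())
img = y.simulate_pet(activity, y.Y90,
                     y.PETAcqParams(scan_time_s=900.0, psf_fwhm_mm=6.0, seed=1))
insert = masks["insert"]
s = y.voi_stats(img, insert)

iact, imasks = y.build_phantom(y.iec_body_spec())
iimg = y.simulate_pet(iact, y.Y90,
                      y.PETAcqParams(scan_time_s=14400.0, psf_fwhm_mm=6.0, seed=2))
meas = [np.mean(iimg.values[imasks[f"sphere_{v:g}mL"].values])
        for v in IEC_SPHERE_VOLUMES_ML]
rc = y.recovery_coefficients(meas, 2.28e6, IEC_SPHERE_VOLUMES_ML)

ld = y.local_deposition_dose(img, y.Y90)
mean_d, sd_d = y.dose_summary(ld, insert)
```

Output of the full script (seed 1):

```
insert mean   4.60 MBq/mL  [q1-q3 4.02-5.37]
deviation     -16.3 %
HI            0.18
RC table       [0.51 0.61 0.68 0.75 0.8  0.85]
PVE-corrected 5.53 MBq/mL  (+0.6 %)
LD dose       229 +/- 41 Gy
MIRD dose     273 Gy
kernel dose   225 +/- 41 Gy
dDVH integral 18.86 mL
HI power law  b = -0.50 +/- 0.00 (r2 = 1.00)
```

Reading it: the raw insert mean underestimates the true 5.5 MBq/mL by 16%
(spill-out at 6:1 contrast); dividing by the recovery coefficient at the
insert volume restores it to within 1%. Local-deposition and
kernel-convolution doses agree within 2% on the noisy image, and both sit
below the MIRD value computed from the *true* concentration for the same
reason the activity is underestimated. The dDVH integrates to the mask
volume, and the homogeneity index of uniform regions falls off with emitted
positrons with exponent −0.50, the Poisson square-root law.

A command-line interface mirrors the library:
`y90voxdose {simulate-phantom, quantify, dose, hi-fit, hi-study, tld, run}`.

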