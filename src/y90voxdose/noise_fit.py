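"""Power-law analysis of image noise versus counting statistics.

For Poisson-limited PET images of a uniform object, the homogeneity index
(coefficient of variation) is expected to fall off as the inverse square root
of the number of emitted positrons. This module fits HI = a * N^b by ordinary
least squares on the log-log scale and runs the simulation study that
measures the exponent on synthetic uniform-cylinder acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, stats

from .grid import VOIMask
from .nuclide import NuclideConstants, Y90
from .phantom import (
    Compartment,
    PETAcqParams,
    PhantomSpec,
    build_phantom,
    simulate_pet,
)
from .quantify import emitted_positrons, homogeneity_index


@dataclass(frozen=True)
class PowerLawFit:
    """Fit of y = a * x^b with OLS on (log x, log y).

    ``u_b`` is the standard error of the slope; ``r2`` the coefficient of
    determination on the log-log scale; ``unstable`` flags degenerate fits
    (zero spread in y).
    """

    a: float
    b: float
    u_b: float
    r2: float
    n_points: int
    unstable: bool = False


def fit_power_law(x, y) -> PowerLawFit:
    """Fit a power law to strictly positive data by log-log least squares."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1D arrays")
    if len(x) < 3:
        raise ValueError("power-law fit needs at least 3 points")
    if np.any(x <= 0) or np.any(y <= 0):
        raise ValueError("power-law fit requires strictly positive x and y")
    if np.ptp(np.log(x)) == 0:
        raise ValueError("x values are all identical")
    if np.ptp(np.log(y)) == 0:
        # flat response: slope 0 with no spread to estimate an error from
        return PowerLawFit(
            a=float(y[0]), b=0.0, u_b=0.0, r2=0.0, n_points=len(x), unstable=True
        )
    res = stats.linregress(np.log(x), np.log(y))
    return PowerLawFit(
        a=float(math.exp(res.intercept)),
        b=float(res.slope),
        u_b=float(res.stderr),
        r2=float(res.rvalue**2),
        n_points=len(x),
    )


def _uniform_cylinder(
    concentration_bq_ml: float,
    voxel_size_mm: tuple[float, float, float],
    diameter_mm: float,
    height_mm: float,
) -> PhantomSpec:
    vs = np.asarray(voxel_size_mm)
    extent = np.array([diameter_mm + 8 * vs[0], diameter_mm + 8 * vs[1], height_mm + 8 * vs[2]])
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, vs))
    center = tuple(n * s / 2 for n, s in zip(shape, vs))
    comp = Compartment(
        "cylinder", "cylinder", center, (diameter_mm, height_mm), concentration_bq_ml
    )
    return PhantomSpec(shape, tuple(voxel_size_mm), [comp], background_bq_ml=0.0)


def hi_noise_study(
    levels,
    acq: PETAcqParams,
    replicates: int = 3,
    seed: int = 0,
    nuclide: NuclideConstants = Y90,
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0),
    diameter_mm: float = 60.0,
    height_mm: float = 60.0,
    erosion_voxels: int = 2,
) -> PowerLawFit:
    """Measure the HI-versus-emitted-positrons power law on uniform cylinders.

    For each activity-concentration level a uniform cylinder is simulated
    ``replicates`` times (child seeds derived from ``seed`` by fixed
    increments); the homogeneity index is computed on an interior VOI (the
    cylinder mask eroded by ``erosion_voxels`` to keep PSF edge spill-out
    from contaminating the uniform region) and paired with the number of
    positrons emitted from that VOI during the scan. All pairs are pooled
    into a single log-log OLS fit.

    Requires >= 4 levels spanning at least 1.5 decades of emitted positrons.
    """
    levels = np.asarray(list(levels), dtype=float)
    if len(levels) < 4:
        raise ValueError("need at least 4 activity levels")
    if np.any(levels <= 0):
        raise ValueError("activity levels must be positive")
    if len(np.unique(levels)) != len(levels):
        raise ValueError("degenerate level spacing: duplicate levels")
    span = levels.max() / levels.min()
    if span < 10**1.5:
        raise ValueError(
            f"degenerate level spacing: levels span {math.log10(span):.2f} decades, "
            "need >= 1.5"
        )
    if replicates < 1:
        raise ValueError("replicates must be >= 1")

    xs: list[float] = []
    ys: list[float] = []
    for i, level in enumerate(levels):
        spec = _uniform_cylinder(level, voxel_size_mm, diameter_mm, height_mm)
        activity, masks = build_phantom(spec)
        voi = masks["cylinder"].values
        if erosion_voxels > 0:
            voi = ndimage.binary_erosion(voi, iterations=erosion_voxels)
        mask = VOIMask(voi, voxel_size_mm)
        n_pos = emitted_positrons(level, mask.volume_mL, nuclide, acq.scan_time_s)
        for j in range(replicates):
            acq_ij = replace(acq, seed=int(seed + i * replicates + j))
            image = simulate_pet(activity, nuclide, acq_ij)
            xs.append(n_pos)
            ys.append(homogeneity_index(image, mask))
    return fit_power_law(xs, ys)
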