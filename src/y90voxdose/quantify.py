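"""Quantitative accuracy analysis of 90Y-PET activity images.

Covers absolute calibration via the beta-plus branch ratio, VOI statistics,
differential activity-volume histograms (dAVH), the homogeneity index (the
volume-weighted coefficient of variation of the concentration in a VOI),
recovery coefficients, and partial-volume correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .grid import VOIMask, VoxelGrid, masked_values
from .nuclide import NuclideConstants


@dataclass(frozen=True)
class VOIStats:
    """Summary statistics of an activity image over a VOI (all in Bq/mL).

    Quartiles use linear interpolation between order statistics; ``sd`` is the
    population standard deviation; ``skewness`` is the adjusted
    Fisher-Pearson sample coefficient (0 by convention for a constant VOI).
    """

    mean: float
    sd: float
    min: float
    max: float
    q1: float
    q3: float
    skewness: float
    n_voxels: int


@dataclass(frozen=True)
class AVH:
    """Differential activity-volume histogram.

    ``density[i]`` is the fraction of the VOI volume per unit concentration
    in bin i, i.e. the negative discrete derivative of the cumulative volume
    fraction v(c)/V; it integrates to 1 over the bins.
    """

    bin_edges: np.ndarray  # Bq/mL, ascending, len = nbins + 1
    density: np.ndarray  # per (Bq/mL)

    def integral(self) -> float:
        return float(np.sum(self.density * np.diff(self.bin_edges)))


@dataclass
class RCTable:
    """Recovery coefficients tabulated against object volume.

    RC(V) is interpolated linearly in log(volume) and clamped to the end
    values outside the tabulated range.
    """

    volumes_mL: np.ndarray
    rc: np.ndarray

    def __post_init__(self) -> None:
        self.volumes_mL = np.asarray(self.volumes_mL, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        if self.volumes_mL.shape != self.rc.shape or self.volumes_mL.ndim != 1:
            raise ValueError("volumes_mL and rc must be aligned 1D arrays")
        if len(self.volumes_mL) < 2:
            raise ValueError("RC table needs at least 2 rows for interpolation")
        if np.any(self.volumes_mL <= 0):
            raise ValueError("volumes must be positive")
        if np.any(self.rc <= 0) or np.any(self.rc > 1.2):
            raise ValueError("recovery coefficients must be in (0, 1.2]")
        order = np.argsort(self.volumes_mL)
        self.volumes_mL = self.volumes_mL[order]
        self.rc = self.rc[order]

    def rc_at(self, volume_mL: float) -> float:
        if volume_mL <= 0:
            raise ValueError("volume must be positive")
        return float(
            np.interp(math.log(volume_mL), np.log(self.volumes_mL), self.rc)
        )


def calibration_factor_y90(cf_surrogate: float, branch_ratio: float) -> float:
    """Rescale a surrogate-nuclide PET calibration factor to 90Y.

    A scanner calibrated with a conventional positron emitter reports
    positron-equivalent concentration; dividing the calibration factor by the
    90Y internal-pair-production branch ratio converts it to true 90Y Bq/mL.
    """
    if branch_ratio <= 0:
        raise ValueError(f"branch_ratio must be > 0, got {branch_ratio}")
    return cf_surrogate / branch_ratio


def voi_stats(image: VoxelGrid, mask: VOIMask) -> VOIStats:
    """Mean, spread, quartiles and skewness of ``image`` inside ``mask``."""
    vals = masked_values(image, mask)
    sd = float(np.std(vals))
    if sd == 0 or len(vals) < 3:
        skew = 0.0
    else:
        skew = float(stats.skew(vals, bias=False))
    q1, q3 = np.percentile(vals, [25.0, 75.0])
    return VOIStats(
        mean=float(np.mean(vals)),
        sd=sd,
        min=float(np.min(vals)),
        max=float(np.max(vals)),
        q1=float(q1),
        q3=float(q3),
        skewness=skew,
        n_voxels=len(vals),
    )


def davh(image: VoxelGrid, mask: VOIMask, bin_width: float | None = None) -> AVH:
    """Differential activity-volume histogram of ``image`` over ``mask``.

    ``bin_width`` is the concentration binning resolution; by default
    (max - min)/100 of the masked values. The returned density is normalised
    so that sum(density * bin_width) == 1.
    """
    vals = masked_values(image, mask)
    lo, hi = float(np.min(vals)), float(np.max(vals))
    if bin_width is None:
        bin_width = (hi - lo) / 100.0 if hi > lo else 1.0
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    n_bins = max(1, int(math.ceil((hi - lo) / bin_width))) if hi > lo else 1
    edges = lo + bin_width * np.arange(n_bins + 1)
    edges[-1] = max(edges[-1], hi)  # fp guard: keep the max value in range
    counts, edges = np.histogram(vals, bins=edges)
    density = counts / (len(vals) * bin_width)
    return AVH(bin_edges=edges, density=density)


def homogeneity_index(image: VoxelGrid, mask: VOIMask) -> float:
    """Volume-weighted coefficient of variation of concentration in a VOI.

    HI = sqrt(sum_i (v_i / V) (c_i - C_mean)^2) / C_mean. With equal voxel
    volumes this is the population sd over the mean. Requires C_mean > 0.
    """
    vals = masked_values(image, mask)
    mean = float(np.mean(vals))
    if mean <= 0:
        raise ValueError(f"homogeneity index needs mean concentration > 0, got {mean}")
    return float(np.sqrt(np.mean((vals - mean) ** 2)) / mean)


def recovery_coefficients(
    measured: np.ndarray | list[float],
    true_conc: float,
    volumes: np.ndarray | list[float],
) -> RCTable:
    """Recovery coefficients RC_i = measured_i / true for objects of known volume."""
    if true_conc <= 0:
        raise ValueError(f"true_conc must be > 0, got {true_conc}")
    measured = np.asarray(measured, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if measured.shape != volumes.shape:
        raise ValueError("measured and volumes must be aligned")
    return RCTable(volumes_mL=volumes, rc=measured / true_conc)


def pve_correct(mean_conc: float, volume_mL: float, table: RCTable) -> float:
    """Partial-volume-correct a measured mean concentration.

    Divides by the recovery coefficient interpolated at ``volume_mL``
    (log-volume linear interpolation, end-clamped).
    """
    return mean_conc / table.rc_at(volume_mL)


def percent_deviation(measured: float, true_value: float) -> float:
    """Signed percent deviation 100 * (measured - true) / true."""
    if true_value == 0:
        raise ValueError("true_value must be non-zero")
    return 100.0 * (measured - true_value) / true_value


def emitted_positrons(
    conc_bq_ml: float,
    volume_mL: float,
    nuclide: NuclideConstants,
    scan_time_s: float,
) -> float:
    """Number of positrons emitted from a VOI during a scan.

    N = C * V * branch_ratio * (1 - exp(-lambda t)) / lambda, reducing to
    C * V * branch_ratio * t when the scan is short relative to the
    half-life.
    """
    if conc_bq_ml < 0 or volume_mL < 0 or scan_time_s < 0:
        raise ValueError("inputs must be >= 0")
    return (
        conc_bq_ml
        * volume_mL
        * nuclide.branch_ratio_beta_plus
        * nuclide.cumulated_time_s(scan_time_s)
    )
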