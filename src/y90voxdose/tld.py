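"""Thermoluminescent-dosimeter (TLD) absorbed-dose evaluation.

A LiF chip read out after irradiation in a 90Y liquid bath yields absorbed
dose to water through a multiplicative measurement equation:

    D_w = TL * N_Dw * k_fv * H * k_mat

where ``TL`` is the reader signal, ``N_Dw`` the 60Co calibration coefficient
(Gy per reader unit), ``k_fv`` the finite-volume correction (radioactivity is
excluded from the volume the chip occupies), ``H`` the energy/geometry
correction between the 90Y measurement and the 60Co calibration conditions,
and ``k_mat`` the correction for non-TLD materials (holder, envelope).
Relative standard uncertainties combine in quadrature under the uncorrelated
assumption. Chip sets aggregate by inverse-variance weighting, and the dose
normalises to Gy per emitted beta particle through the decay-corrected
emission count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .nuclide import NuclideConstants


class ContaminatedChipError(ValueError):
    """A reading flagged as contaminated cannot enter the dose evaluation."""


@dataclass(frozen=True)
class TLDReading:
    """One chip's signal, calibration coefficient, and correction factors.

    Each ``u_*_rel`` is the relative standard uncertainty of the matching
    factor. Correction factors default to 1 with zero uncertainty and must be
    supplied explicitly for real measurements (they come from radiation
    transport calculations, not from this package).
    """

    tl_signal: float
    n_dw: float
    u_tl_rel: float = 0.0
    u_n_dw_rel: float = 0.0
    k_fv: float = 1.0
    u_k_fv_rel: float = 0.0
    h_exp_ref: float = 1.0
    u_h_rel: float = 0.0
    k_mat: float = 1.0
    u_k_mat_rel: float = 0.0
    contaminated: bool = False

    def __post_init__(self) -> None:
        if self.tl_signal < 0:
            raise ValueError("tl_signal must be >= 0")
        for name in ("n_dw", "k_fv", "h_exp_ref", "k_mat"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("u_tl_rel", "u_n_dw_rel", "u_k_fv_rel", "u_h_rel", "u_k_mat_rel"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class DosePerParticle:
    """Absorbed dose to water per emitted beta particle."""

    value: float  # Gy / particle
    rel_u: float


def tld_dose(reading: TLDReading) -> tuple[float, float]:
    """Absorbed dose to water (Gy) and relative uncertainty for one chip.

    The dose is the product of the five factors of the measurement equation;
    the relative uncertainty is their quadrature sum (uncorrelated factors).
    Contaminated readings are rejected.
    """
    if reading.contaminated:
        raise ContaminatedChipError(
            "reading is flagged as contaminated and must be excluded"
        )
    dose = (
        reading.tl_signal
        * reading.n_dw
        * reading.k_fv
        * reading.h_exp_ref
        * reading.k_mat
    )
    rel_u = math.sqrt(
        reading.u_tl_rel**2
        + reading.u_n_dw_rel**2
        + reading.u_k_fv_rel**2
        + reading.u_h_rel**2
        + reading.u_k_mat_rel**2
    )
    return dose, rel_u


def grubbs_outliers(values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Iterative two-sided Grubbs test; returns a boolean outlier mask."""
    values = np.asarray(values, dtype=float)
    out = np.zeros(len(values), dtype=bool)
    while True:
        keep = ~out
        n = int(keep.sum())
        if n < 3:
            break
        v = values[keep]
        sd = v.std(ddof=1)
        if sd == 0:
            break
        g = np.abs(v - v.mean()) / sd
        i_max = int(np.argmax(g))
        t = stats.t.ppf(1 - alpha / (2 * n), n - 2)
        g_crit = (n - 1) / math.sqrt(n) * math.sqrt(t**2 / (n - 2 + t**2))
        if g[i_max] > g_crit:
            out[np.flatnonzero(keep)[i_max]] = True
        else:
            break
    return out


def aggregate_chips(
    doses: list[tuple[float, float]],
    flags: list[bool] | None = None,
    auto_flag: bool = False,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Inverse-variance weighted mean of chip doses and its relative uncertainty.

    ``doses`` are (Gy, relative uncertainty) pairs; ``flags`` marks chips to
    exclude (e.g. contaminated ones). With ``auto_flag`` a two-sided Grubbs
    test at ``alpha`` additionally rejects statistical outliers; any
    auto-flagged chips are reported through the module logger, never silently.
    """
    values = np.array([d for d, _ in doses], dtype=float)
    rel_us = np.array([u for _, u in doses], dtype=float)
    if flags is None:
        flags = [False] * len(values)
    keep = ~np.asarray(flags, dtype=bool)
    if not np.any(keep):
        raise ValueError("all chips are flagged; nothing to aggregate")
    if auto_flag:
        auto = grubbs_outliers(values[keep], alpha=alpha)
        if auto.any():
            import logging

            logging.getLogger(__name__).warning(
                "Grubbs test (alpha=%g) auto-flagged %d chip(s): doses %s",
                alpha,
                int(auto.sum()),
                values[keep][auto],
            )
            idx = np.flatnonzero(keep)[auto]
            keep[idx] = False
    values = values[keep]
    sigmas = rel_us[keep] * values
    if np.any(sigmas <= 0):
        # equal (or missing) uncertainties degrade to the arithmetic mean
        mean = float(values.mean())
        u = float(values.std(ddof=1) / math.sqrt(len(values))) if len(values) > 1 else 0.0
        return mean, u / mean if mean != 0 else 0.0
    w = 1.0 / sigmas**2
    mean = float(np.sum(w * values) / np.sum(w))
    u = float(1.0 / math.sqrt(np.sum(w)))
    return mean, u / mean if mean != 0 else 0.0


def dose_per_emitted_particle(
    d_w: float,
    conc_bq_ml: float,
    volume_mL: float,
    nuclide: NuclideConstants,
    exposure_s: float,
    d_w_rel_u: float = 0.0,
) -> DosePerParticle:
    """Normalise an absorbed dose to Gy per emitted beta particle.

    The divisor is the number of decays in the exposure,
    N = C * V * (1 - exp(-lambda t)) / lambda (every decay emits one beta).
    """
    if conc_bq_ml <= 0 or volume_mL <= 0 or exposure_s <= 0:
        raise ValueError("conc, volume and exposure time must be > 0")
    n_emitted = conc_bq_ml * volume_mL * nuclide.cumulated_time_s(exposure_s)
    if n_emitted <= 0:
        raise ValueError("zero emitted particles")
    return DosePerParticle(value=d_w / n_emitted, rel_u=d_w_rel_u)
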