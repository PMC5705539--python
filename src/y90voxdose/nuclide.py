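"""Radionuclide decay constants.

The package is built around yttrium-90, a nearly pure beta-minus emitter used
in liver radioembolization. A rare internal pair production branch
(0+ -> 0+ transition of the 90Zr daughter, branch ratio ~3.186e-5) emits a
positron, which is what makes post-therapy PET imaging of 90Y possible at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

SECONDS_PER_DAY = 86400.0
MEV_TO_J = 1.602e-13  # J per MeV


@dataclass(frozen=True)
class NuclideConstants:
    """Physical constants of a beta-emitting radionuclide.

    Parameters
    ----------
    half_life_s : float
        Physical half-life in seconds.
    mean_beta_energy_MeV : float
        Mean energy of the emitted beta spectrum, in MeV. For 90Y dosimetry
        the conventional value 0.932 MeV is used.
    max_beta_energy_MeV : float
        Spectrum endpoint energy in MeV (2.28 MeV for 90Y).
    branch_ratio_beta_plus : float
        Probability of positron emission per decay (internal pair
        production); dimensionless, strictly between 0 and 1.
    """

    half_life_s: float
    mean_beta_energy_MeV: float
    max_beta_energy_MeV: float
    branch_ratio_beta_plus: float

    def __post_init__(self) -> None:
        for name in (
            "half_life_s",
            "mean_beta_energy_MeV",
            "max_beta_energy_MeV",
            "branch_ratio_beta_plus",
        ):
            value = getattr(self, name)
            if not (value > 0 and math.isfinite(value)):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.branch_ratio_beta_plus >= 1:
            raise ValueError("branch_ratio_beta_plus must be < 1")

    @property
    def decay_constant(self) -> float:
        """Decay constant lambda = ln2 / T_half, in 1/s (always derived)."""
        return math.log(2.0) / self.half_life_s

    def mean_beta_energy_J(self) -> float:
        return self.mean_beta_energy_MeV * MEV_TO_J

    def cumulated_time_s(self, duration_s: float) -> float:
        """Time integral of exp(-lambda t) from 0 to ``duration_s``.

        Multiplying an initial activity by this gives the number of decays in
        the interval; ``duration_s = inf`` gives the permanent-implant total
        1/lambda = T_half / ln2.
        """
        if duration_s < 0:
            raise ValueError("duration_s must be >= 0")
        lam = self.decay_constant
        if math.isinf(duration_s):
            return 1.0 / lam
        return -math.expm1(-lam * duration_s) / lam


#: 90Y constants: T_half = 2.67 d, mean/max beta energies 0.932 / 2.28 MeV,
#: internal-pair-production branch ratio 3.186e-5.
Y90 = NuclideConstants(
    half_life_s=2.67 * SECONDS_PER_DAY,
    mean_beta_energy_MeV=0.932,
    max_beta_energy_MeV=2.28,
    branch_ratio_beta_plus=3.186e-5,
)
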