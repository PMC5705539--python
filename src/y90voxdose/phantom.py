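"""Synthetic phantoms and a post-reconstruction 90Y-PET image simulator.

Three phantom families are provided, mirroring standard quantitative-PET
validation hardware:

* a large uniform cylinder (calibration validation),
* the NEMA IEC body phantom with six fillable spheres (recovery coefficients),
* an anthropomorphic torso with liver, cold lungs/spine, and a small
  cylindrical "lesion" insert fixed in the liver.

The simulator emulates an already-reconstructed, fully corrected PET image:
expected positron counts per voxel are formed from the activity map and the
tiny beta-plus branch ratio, blurred by an isotropic Gaussian PSF, given an
optional flat background floor, Poisson-sampled, and converted back to
activity concentration. Sinogram physics (attenuation, scatter, randoms,
OSEM) is deliberately not modelled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .grid import GeometryError, UnitError, VOIMask, VoxelGrid
from .nuclide import NuclideConstants, Y90

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

_PRIMITIVES = ("cylinder", "sphere", "box")


@dataclass(frozen=True)
class Compartment:
    """One phantom compartment: a geometric primitive filled uniformly.

    ``dimensions_mm`` depends on the primitive:
    cylinder (z-axis): (diameter, height); sphere: (diameter,);
    box: (lx, ly, lz).
    """

    name: str
    primitive: str
    center_mm: tuple[float, float, float]
    dimensions_mm: tuple[float, ...]
    concentration_bq_ml: float

    def __post_init__(self) -> None:
        if self.primitive not in _PRIMITIVES:
            raise ValueError(f"unknown primitive {self.primitive!r} in {self.name!r}")
        if self.concentration_bq_ml < 0:
            raise ValueError(f"concentration must be >= 0 in {self.name!r}")
        ndims = {"cylinder": 2, "sphere": 1, "box": 3}[self.primitive]
        if len(self.dimensions_mm) != ndims:
            raise ValueError(
                f"{self.primitive} needs {ndims} dimension(s), got {self.dimensions_mm}"
            )
        if any(d <= 0 for d in self.dimensions_mm):
            raise ValueError(f"dimensions must be positive in {self.name!r}")

    def half_extent_mm(self) -> np.ndarray:
        if self.primitive == "cylinder":
            d, h = self.dimensions_mm
            return np.array([d / 2, d / 2, h / 2])
        if self.primitive == "sphere":
            (d,) = self.dimensions_mm
            return np.array([d / 2, d / 2, d / 2])
        return np.asarray(self.dimensions_mm) / 2

    def analytic_volume_mL(self) -> float:
        if self.primitive == "cylinder":
            d, h = self.dimensions_mm
            return math.pi * (d / 2) ** 2 * h / 1000.0
        if self.primitive == "sphere":
            (d,) = self.dimensions_mm
            return math.pi * d**3 / 6.0 / 1000.0
        lx, ly, lz = self.dimensions_mm
        return lx * ly * lz / 1000.0

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center_mm
        if self.primitive == "cylinder":
            d, h = self.dimensions_mm
            return ((x - cx) ** 2 + (y - cy) ** 2 <= (d / 2) ** 2) & (
                np.abs(z - cz) <= h / 2
            )
        if self.primitive == "sphere":
            (d,) = self.dimensions_mm
            return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= (d / 2) ** 2
        lx, ly, lz = self.dimensions_mm
        return (
            (np.abs(x - cx) <= lx / 2)
            & (np.abs(y - cy) <= ly / 2)
            & (np.abs(z - cz) <= lz / 2)
        )


@dataclass
class PhantomSpec:
    """Grid geometry plus an ordered list of compartments.

    Compartments are painted in order: where they overlap, later ones
    overwrite earlier ones. ``background_bq_ml`` fills the rest of the grid.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    compartments: list[Compartment] = field(default_factory=list)
    background_bq_ml: float = 0.0

    def __post_init__(self) -> None:
        if self.background_bq_ml < 0:
            raise ValueError("background concentration must be >= 0")


@dataclass(frozen=True)
class PETAcqParams:
    """Acquisition / simulation knobs for :func:`simulate_pet`.

    ``sensitivity`` is the effective fraction of emitted positrons that end
    up as counts in the reconstructed image (0 < s <= 1);
    ``background_counts_per_voxel`` is a flat additive expected-count floor
    standing in for residual scatter/randoms bias.
    """

    scan_time_s: float
    psf_fwhm_mm: float = 6.0
    sensitivity: float = 1.0
    background_counts_per_voxel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scan_time_s <= 0:
            raise ValueError("scan_time_s must be > 0")
        if not (0 < self.sensitivity <= 1):
            raise ValueError("sensitivity must be in (0, 1]")
        if self.psf_fwhm_mm < 0:
            raise ValueError("psf_fwhm_mm must be >= 0")
        if self.background_counts_per_voxel < 0:
            raise ValueError("background_counts_per_voxel must be >= 0")


def _occupancy(
    comp: Compartment,
    shape: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float],
    n_sub: int = 3,
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Fractional sub-voxel occupancy of ``comp`` over its bounding box.

    Each voxel is split into ``n_sub``^3 sub-voxels; occupancy is the fraction
    of sub-voxel centres inside the primitive.
    """
    vs = np.asarray(voxel_size_mm)
    center = np.asarray(comp.center_mm)
    he = comp.half_extent_mm()
    if np.any(center - he < -1e-9) or np.any(center + he > np.asarray(shape) * vs + 1e-9):
        raise GeometryError(
            f"compartment {comp.name!r} extends outside the grid "
            f"(centre {comp.center_mm} mm, half-extent {tuple(he)} mm)"
        )
    lo = np.maximum(np.floor((center - he) / vs).astype(int), 0)
    hi = np.minimum(np.ceil((center + he) / vs).astype(int), shape)
    sub = (np.arange(n_sub) + 0.5) / n_sub
    coords = []
    for ax in range(3):
        idx = np.arange(lo[ax], hi[ax])
        c = (idx[:, None] + sub[None, :]).ravel() * vs[ax]
        coords.append(c)
    X, Y, Z = np.meshgrid(coords[0], coords[1], coords[2], indexing="ij")
    inside = comp.contains(X, Y, Z)
    n = hi - lo
    occ = inside.reshape(n[0], n_sub, n[1], n_sub, n[2], n_sub).mean(axis=(1, 3, 5))
    box = tuple(slice(int(lo[ax]), int(hi[ax])) for ax in range(3))
    return box, occ  # type: ignore[return-value]


def build_phantom(
    spec: PhantomSpec, n_sub: int = 3
) -> tuple[VoxelGrid, dict[str, VOIMask]]:
    """Voxelise a phantom spec into an activity map and per-compartment masks.

    Edge voxels get partial-volume-weighted ground-truth concentrations
    (occupancy-blended); masks include voxels with occupancy >= 0.5, which
    reproduces nominal compartment volumes to within ~1%.
    """
    activity = np.full(spec.shape, float(spec.background_bq_ml))
    masks: dict[str, VOIMask] = {}
    for comp in spec.compartments:
        box, occ = _occupancy(comp, spec.shape, spec.voxel_size_mm, n_sub=n_sub)
        region = activity[box]
        activity[box] = occ * comp.concentration_bq_ml + (1.0 - occ) * region
        mask = np.zeros(spec.shape, dtype=bool)
        mask[box] = occ >= 0.5
        masks[comp.name] = VOIMask(mask, spec.voxel_size_mm)
    return VoxelGrid(activity, spec.voxel_size_mm, unit="Bq/mL"), masks


def counts_conversion_factor(
    grid: VoxelGrid, nuclide: NuclideConstants, acq: PETAcqParams
) -> float:
    """Expected detected counts per (Bq/mL of 90Y) in one voxel."""
    return (
        grid.voxel_volume_mL
        * nuclide.branch_ratio_beta_plus
        * acq.scan_time_s
        * acq.sensitivity
    )


def simulate_pet(
    activity: VoxelGrid,
    nuclide: NuclideConstants = Y90,
    acq: PETAcqParams = PETAcqParams(scan_time_s=900.0),
    calibration: float = 1.0,
) -> VoxelGrid:
    """Simulate a reconstructed 90Y-PET image of ``activity``.

    Pipeline: (i) expected positron counts per voxel
    ``C * v_voxel * branch_ratio * scan_time * sensitivity``; (ii) isotropic
    Gaussian PSF blur of the expected-count field; (iii) flat additive
    background floor; (iv) Poisson sampling with ``acq.seed``; (v) inversion
    of (i) times ``calibration`` back to Bq/mL. Deterministic given the seed.
    """
    if activity.unit != "Bq/mL":
        raise UnitError(f"activity image must be in Bq/mL, got {activity.unit!r}")
    scale = counts_conversion_factor(activity, nuclide, acq)
    expected = activity.values * scale
    if acq.psf_fwhm_mm > 0:
        sigma_vox = [
            acq.psf_fwhm_mm * FWHM_TO_SIGMA / s for s in activity.voxel_size_mm
        ]
        expected = ndimage.gaussian_filter(expected, sigma=sigma_vox, mode="constant")
        np.maximum(expected, 0.0, out=expected)  # filter ringing guard
    expected = expected + acq.background_counts_per_voxel
    if np.any(expected < 0):
        raise RuntimeError("internal error: negative expected counts")
    rng = np.random.default_rng(acq.seed)
    counts = rng.poisson(expected).astype(float)
    recovered = counts / scale * calibration
    return activity.with_values(recovered, unit="Bq/mL")


def replicate_seeds(base_seed: int, n: int, stride: int = 1) -> list[int]:
    """Child seeds for replicate simulations: fixed increments from a base."""
    return [int(base_seed + stride * i) for i in range(n)]


# --------------------------------------------------------------------------
# Phantom library. Default concentrations are the day-1 fills used in the
# validation experiments this package emulates.
# --------------------------------------------------------------------------

#: Reconstruction-grid voxel pitch of the emulated scanner (mm).
DEFAULT_VOXEL_SIZE_MM = (2.73, 2.73, 3.27)

#: Volumes of the six IEC body-phantom spheres (mL).
IEC_SPHERE_VOLUMES_ML = (0.52, 1.15, 2.57, 5.57, 11.49, 26.52)


def _sphere_diameter_mm(volume_mL: float) -> float:
    return (6.0 * volume_mL * 1000.0 / math.pi) ** (1.0 / 3.0)


def uniform_cylinder_spec(
    concentration_bq_ml: float = 273e3,
    voxel_size_mm: tuple[float, float, float] = (4.0, 4.0, 4.0),
) -> PhantomSpec:
    """Uniform 5640 mL cylinder (d = 200 mm) for calibration validation."""
    diameter = 200.0
    height = 5640e3 / (math.pi * (diameter / 2) ** 2)
    vs = np.asarray(voxel_size_mm)
    extent = np.array([diameter + 24, diameter + 24, height + 24])
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, vs))
    center = tuple(n * s / 2 for n, s in zip(shape, vs))
    comp = Compartment(
        "cylinder", "cylinder", center, (diameter, height), concentration_bq_ml
    )
    return PhantomSpec(shape, tuple(voxel_size_mm), [comp], background_bq_ml=0.0)


def iec_body_spec(
    sphere_concentration_bq_ml: float = 2.28e6,
    background_ratio: float = 8.0,
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM,
) -> PhantomSpec:
    """IEC body phantom: six spheres (0.52-26.52 mL) on a 57.2 mm ring.

    Spheres are filled at ``sphere_concentration_bq_ml`` over a warm
    background at a ``background_ratio``:1 sphere:background ratio (8:1 per
    the NEMA NU 2 protocol).
    """
    vs = np.asarray(voxel_size_mm)
    extent = np.array([220.0, 220.0, 80.0])
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, vs))
    center = np.array([n * s / 2 for n, s in zip(shape, vs)])
    ring_r = 57.2
    comps = []
    for i, vol in enumerate(IEC_SPHERE_VOLUMES_ML):
        ang = math.radians(60.0 * i)
        c = (
            center[0] + ring_r * math.cos(ang),
            center[1] + ring_r * math.sin(ang),
            center[2],
        )
        comps.append(
            Compartment(
                f"sphere_{vol:g}mL",
                "sphere",
                c,
                (_sphere_diameter_mm(vol),),
                sphere_concentration_bq_ml,
            )
        )
    return PhantomSpec(
        shape,
        tuple(voxel_size_mm),
        comps,
        background_bq_ml=sphere_concentration_bq_ml / background_ratio,
    )


def anthropomorphic_spec(
    insert_concentration_bq_ml: float = 5.5e6,
    liver_concentration_bq_ml: float = 0.89e6,
    voxel_size_mm: tuple[float, float, float] = DEFAULT_VOXEL_SIZE_MM,
) -> PhantomSpec:
    """Anthropomorphic torso phantom with a hot cylindrical lesion insert.

    Compartments: ~10,300 mL cold water background (torso cylinder), 1200 mL
    liver sphere, two cold lung boxes (900/1100 mL), a 200 mL cold spine
    cylinder, and a 19.13 mL cylindrical insert (d = 28.5 mm, h = 30 mm)
    fixed inside the liver at a nominal 6:1 insert:liver concentration ratio.
    """
    vs = np.asarray(voxel_size_mm)
    extent = np.array([310.0, 310.0, 185.0])
    shape = tuple(int(math.ceil(e / s)) for e, s in zip(extent, vs))
    center = np.array([n * s / 2 for n, s in zip(shape, vs)])
    torso_d, torso_h = 280.0, 167.5  # ~10,310 mL
    liver_d = _sphere_diameter_mm(1200.0)
    liver_center = (center[0] - 55.0, center[1] + 25.0, center[2])
    comps = [
        Compartment("body", "cylinder", tuple(center), (torso_d, torso_h), 0.0),
        Compartment(
            "liver", "sphere", liver_center, (liver_d,), liver_concentration_bq_ml
        ),
        Compartment(
            "left_lung",
            "box",
            (center[0] + 60.0, center[1] - 70.0, center[2]),
            (60.0, 100.0, 150.0),
            0.0,
        ),
        Compartment(
            "right_lung",
            "box",
            (center[0] - 60.0, center[1] - 80.0, center[2]),
            (73.3, 100.0, 150.0),
            0.0,
        ),
        Compartment(
            "spine",
            "cylinder",
            (center[0], center[1] + 105.0, center[2]),
            (40.0, 159.2),
            0.0,
        ),
        Compartment(
            "insert",
            "cylinder",
            liver_center,
            (28.5, 30.0),
            insert_concentration_bq_ml,
        ),
    ]
    return PhantomSpec(shape, tuple(voxel_size_mm), comps, background_bq_ml=0.0)


# ---------------------------------------------------------------------------
# Dict/YAML plumbing for the CLI
# ---------------------------------------------------------------------------

def spec_from_dict(d: dict) -> PhantomSpec:
    """Build a :class:`PhantomSpec` from a plain dict (YAML-friendly)."""
    comps = [
        Compartment(
            name=c["name"],
            primitive=c["primitive"],
            center_mm=tuple(c["center_mm"]),
            dimensions_mm=tuple(c["dimensions_mm"]),
            concentration_bq_ml=float(c["concentration_bq_ml"]),
        )
        for c in d.get("compartments", [])
    ]
    return PhantomSpec(
        shape=tuple(int(n) for n in d["shape"]),
        voxel_size_mm=tuple(float(v) for v in d["voxel_size_mm"]),
        compartments=comps,
        background_bq_ml=float(d.get("background_bq_ml", 0.0)),
    )


def spec_to_dict(spec: PhantomSpec) -> dict:
    return {
        "shape": list(spec.shape),
        "voxel_size_mm": list(spec.voxel_size_mm),
        "background_bq_ml": spec.background_bq_ml,
        "compartments": [
            {
                "name": c.name,
                "primitive": c.primitive,
                "center_mm": list(c.center_mm),
                "dimensions_mm": list(c.dimensions_mm),
                "concentration_bq_ml": c.concentration_bq_ml,
            }
            for c in spec.compartments
        ],
    }
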