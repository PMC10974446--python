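"""Digital bone-density calibration phantoms and simulated projections.

Emulates a calcium-hydroxyapatite (HA) calibration phantom of the kind used
to characterise bench micro-CT systems: a homogeneous resin disk housing
five cylindrical inserts whose HA densities are 0, 100, 200, 400 and
800 mg HA/cm³. The density→attenuation map is linear with a documented
slope, so the insert attenuations keep the 0:1:2:4:8 density ratios.

Projections are simulated with the same Beer–Lambert forward model the
reconstruction assumes (monochromatic, no scatter, no detector blur), either
noiselessly or with Poisson counting noise. Rasterisation is by pixel
center — innermost shape wins — with no anti-aliasing, so geometric oracles
stay exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import ImageGrid, ScanGeometry
from .mltr_core import ProjectionSet, estimate_projection
from .projector import compute_view_matrix, forward_project

__all__ = [
    "Cylinder",
    "PhantomSpec",
    "NoiseModel",
    "rasterize_phantom",
    "simulate_projections",
    "default_qrm_phantom",
    "HA_DENSITIES_MG_CM3",
    "ATTENUATION_PER_DENSITY",
]

#: Insert HA densities, mg HA/cm³.
HA_DENSITIES_MG_CM3 = (0.0, 100.0, 200.0, 400.0, 800.0)

#: Linear density→attenuation slope, (1/mm) per (mg HA/cm³): the densest
#: insert (800 mg/cm³) maps to 0.05/mm, a plausible magnitude at ~70 kV.
ATTENUATION_PER_DENSITY = 0.05 / 800.0

#: Resin background attenuation, 1/mm (water-like).
BACKGROUND_MU = 0.02

#: Default flat-field (blank scan) count level per detector bin.
DEFAULT_BLANK_COUNTS = 1.0e4


@dataclass(frozen=True)
class Cylinder:
    """A cylindrical insert seen in cross-section: a disk (mm, 1/mm)."""

    cx: float
    cy: float
    radius: float
    mu: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.mu < 0:
            raise ValueError("attenuation must be >= 0")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        return (x - self.cx) ** 2 + (y - self.cy) ** 2 <= self.radius**2


@dataclass(frozen=True)
class PhantomSpec:
    """Background disk plus inserts; later shapes overwrite earlier ones."""

    background: Cylinder | None
    inserts: tuple[Cylinder, ...]
    grid: ImageGrid

    def __post_init__(self) -> None:
        if self.background is not None:
            bg = self.background
            for ins in self.inserts:
                dist = np.hypot(ins.cx - bg.cx, ins.cy - bg.cy)
                if dist + ins.radius > bg.radius + 1e-9:
                    raise ValueError(
                        f"insert at ({ins.cx}, {ins.cy}) extends outside the "
                        "background disk"
                    )


@dataclass(frozen=True)
class NoiseModel:
    """Counting-noise description for simulated sinograms.

    ``kind`` is ``"none"`` (expected counts, noiseless) or ``"poisson"``
    (Poisson draws with the noiseless sinogram as mean, seeded).
    """

    kind: str = "none"
    blank_counts: float = DEFAULT_BLANK_COUNTS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "poisson"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.blank_counts <= 0:
            raise ValueError("blank_counts must be > 0")


def rasterize_phantom(spec: PhantomSpec) -> np.ndarray:
    """Attenuation image of the phantom: pixel value = μ of the innermost
    (last-listed) shape containing the pixel center; 0 outside all shapes."""
    grid = spec.grid
    centers = grid.pixel_centers()
    x, y = np.meshgrid(centers, centers)  # row index increases in +y
    img = np.zeros((grid.n, grid.n))
    shapes = ([] if spec.background is None else [spec.background]) + list(
        spec.inserts
    )
    for shape in shapes:
        img[shape.contains(x, y)] = shape.mu
    return img


def simulate_projections(
    image: np.ndarray,
    geom: ScanGeometry,
    grid: ImageGrid,
    noise: NoiseModel = NoiseModel(),
) -> ProjectionSet:
    """Simulate a transmission scan of an attenuation image.

    The noiseless sinogram is ``b·exp(−A μ)`` per view (the generative use of
    the Beer–Lambert model); Poisson noise, when requested, draws counts with
    that sinogram as mean under ``noise.seed``. The flat blank scan is
    returned alongside.
    """
    image = np.asarray(image, dtype=float)
    if image.shape != (grid.n, grid.n):
        raise ValueError(
            f"image shape {image.shape} does not match grid ({grid.n}, {grid.n})"
        )
    b = np.full(geom.n_det, noise.blank_counts)
    y = np.empty((geom.n_views, geom.n_det))
    for v in range(geom.n_views):
        vm = compute_view_matrix(geom, grid, v)
        y[v] = estimate_projection(forward_project(vm, image), b)
    if noise.kind == "poisson":
        rng = np.random.default_rng(noise.seed)
        y = rng.poisson(y).astype(float)
    return ProjectionSet(y=y, b=b, angles_deg=np.asarray(geom.angles_deg))


def default_qrm_phantom(grid: ImageGrid) -> PhantomSpec:
    """Five-insert HA calibration phantom scaled to the grid.

    The background disk fills 88% of the grid half-extent; the five inserts
    (densities 0, 100, 200, 400, 800 mg HA/cm³) sit at even 72° spacing on a
    ring at 55% of the background radius, each with radius 18% of the
    background radius. Insert attenuation = density × 6.25e-5 (1/mm per
    mg/cm³), i.e. ratios 0:1:2:4:8.
    """
    bg_radius = 0.88 * grid.half_extent
    ring = 0.55 * bg_radius
    ins_radius = 0.18 * bg_radius
    background = Cylinder(0.0, 0.0, bg_radius, BACKGROUND_MU)
    inserts = []
    for k, density in enumerate(HA_DENSITIES_MG_CM3):
        theta = np.deg2rad(90.0 + 72.0 * k)  # first insert at the top
        inserts.append(
            Cylinder(
                cx=ring * np.cos(theta),
                cy=ring * np.sin(theta),
                radius=ins_radius,
                mu=density * ATTENUATION_PER_DENSITY,
            )
        )
    return PhantomSpec(background=background, inserts=tuple(inserts), grid=grid)


def insert_means(
    image: np.ndarray, spec: PhantomSpec, interior_fraction: float = 0.6
) -> np.ndarray:
    """Mean image value inside each insert, measured on a concentric disk of
    ``interior_fraction`` × the insert radius to exclude edge pixels."""
    grid = spec.grid
    centers = grid.pixel_centers()
    x, y = np.meshgrid(centers, centers)
    means = []
    for ins in spec.inserts:
        roi = Cylinder(ins.cx, ins.cy, ins.radius * interior_fraction, ins.mu)
        mask = roi.contains(x, y)
        if not mask.any():
            raise ValueError("insert ROI contains no pixel centers; grid too coarse")
        means.append(float(image[mask].mean()))
    return np.asarray(means)
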