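"""Fan-beam scan geometry, image-grid conventions and ordered-subset partitioning.

Conventions (fixed, documented):

* Coordinates are isocenter-centered, in mm. View angle 0 places the X-ray
  source on the −x axis; angles are degrees, counter-clockwise.
* The detector is flat and equidistant, centered on the central ray, with bin
  centers at ``(k − (n_det−1)/2) · det_pitch`` along the detector axis.
* The image grid is square, centered on the isocenter. Pixel ``(r, c)`` maps
  to physical coordinates with ``c`` increasing in +x and ``r`` increasing in
  +y; pixel boundaries are half-open.
* Only the central slice is modelled: the beam is a 2-D fan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ScanGeometry",
    "ImageGrid",
    "OrderedSubsets",
    "make_angle_list",
    "partition_subsets",
    "detector_ray",
]

#: Defaults of the bench micro-CT the package models (mm).
DEFAULT_SID_MM = 127.0
DEFAULT_SOD_MM = 78.5928
DEFAULT_DET_PITCH_MM = 0.075


@dataclass(frozen=True)
class ScanGeometry:
    """Fan-beam acquisition description.

    Parameters
    ----------
    sid : float
        Source-to-detector distance, mm.
    sod : float
        Source-to-isocenter distance, mm. Magnification is ``sid / sod``.
    n_det : int
        Number of detector bins.
    det_pitch : float
        Detector bin width, mm.
    angles_deg : tuple of float
        View angles in degrees, strictly increasing within [0, 360).
    """

    sid: float = DEFAULT_SID_MM
    sod: float = DEFAULT_SOD_MM
    n_det: int = 256
    det_pitch: float = DEFAULT_DET_PITCH_MM
    angles_deg: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.sid > self.sod > 0):
            raise ValueError(
                f"require sid > sod > 0, got sid={self.sid}, sod={self.sod}"
            )
        if self.n_det < 1:
            raise ValueError(f"n_det must be >= 1, got {self.n_det}")
        if self.det_pitch <= 0:
            raise ValueError(f"det_pitch must be > 0, got {self.det_pitch}")
        angles = tuple(float(a) for a in self.angles_deg)
        if len(angles) < 1:
            raise ValueError("at least one view angle is required")
        arr = np.asarray(angles)
        if np.any(arr < 0) or np.any(arr >= 360):
            raise ValueError("angles must lie in [0, 360)")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles_deg", angles)

    @property
    def n_views(self) -> int:
        return len(self.angles_deg)

    @property
    def magnification(self) -> float:
        return self.sid / self.sod

    def det_offset(self, det_bin: int) -> float:
        """Signed bin-center offset (mm) of ``det_bin`` on the flat detector."""
        return (det_bin - (self.n_det - 1) / 2.0) * self.det_pitch


@dataclass(frozen=True)
class ImageGrid:
    """Square reconstruction grid centered on the isocenter.

    ``n`` is the side length in pixels and ``pixel_size`` the pixel width in
    mm, so the physical extent is ``n * pixel_size`` mm on each side.
    """

    n: int
    pixel_size: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"grid side must be >= 1, got {self.n}")
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def extent(self) -> float:
        """Physical side length, mm."""
        return self.n * self.pixel_size

    @property
    def half_extent(self) -> float:
        return 0.5 * self.extent

    def pixel_centers(self) -> np.ndarray:
        """Center coordinates of pixels along one axis, ascending, mm."""
        return (np.arange(self.n) - (self.n - 1) / 2.0) * self.pixel_size


@dataclass(frozen=True)
class OrderedSubsets:
    """Interleaved partition of view indices into ordered subsets.

    Subset ``s`` holds the views congruent to ``s`` modulo ``n_subsets``, in
    increasing order, so consecutive subsets sample maximally different
    angular positions.
    """

    n_subsets: int
    views_per_subset: int
    subsets: tuple

    def __iter__(self):
        return iter(self.subsets)

    def __len__(self) -> int:
        return self.n_subsets


def make_angle_list(n_views: int, full_arc_deg: float = 360.0) -> np.ndarray:
    """Equally spaced view angles starting at 0, spanning ``full_arc_deg``.

    The spacing is ``full_arc_deg / n_views`` — the end of the arc is not
    repeated (a full scan samples 0 .. 360·(n−1)/n).
    """
    if n_views < 1:
        raise ValueError(f"n_views must be >= 1, got {n_views}")
    if full_arc_deg <= 0:
        raise ValueError(f"full_arc_deg must be > 0, got {full_arc_deg}")
    return np.arange(n_views) * (full_arc_deg / n_views)


def partition_subsets(n_views: int, n_subsets: int) -> OrderedSubsets:
    """Partition ``n_views`` view indices into ``n_subsets`` interleaved subsets.

    The v-th view of subset s is ``v * n_subsets + s`` — subsets stride
    through the angle list so each covers the full arc as evenly as possible.

    Raises
    ------
    ValueError
        If ``n_subsets`` does not divide ``n_views`` (only the divisible case
        is defined).
    """
    if n_views < 1 or n_subsets < 1:
        raise ValueError("n_views and n_subsets must be positive")
    if n_views % n_subsets != 0:
        raise ValueError(
            f"n_subsets={n_subsets} does not divide n_views={n_views}; "
            "choose a subset count that divides the number of views"
        )
    per = n_views // n_subsets
    subsets = tuple(
        tuple(range(s, n_views, n_subsets)) for s in range(n_subsets)
    )
    return OrderedSubsets(n_subsets=n_subsets, views_per_subset=per, subsets=subsets)


def _rot(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s], [s, c]])


def detector_ray(
    geom: ScanGeometry, grid: ImageGrid, view: int, det_bin: int
) -> tuple[np.ndarray, np.ndarray]:
    """Endpoints (source, detector-bin center) of one fan-beam ray, mm.

    At view angle 0 the source sits at ``(−sod, 0)`` and the detector line at
    ``x = sid − sod``; the whole assembly is rotated counter-clockwise by the
    view angle. ``grid`` is accepted for interface symmetry (the ray itself
    does not depend on it).
    """
    del grid  # rays live in physical coordinates; clipping happens in tracing
    if not 0 <= view < geom.n_views:
        raise IndexError(f"view {view} out of range [0, {geom.n_views})")
    if not 0 <= det_bin < geom.n_det:
        raise IndexError(f"det_bin {det_bin} out of range [0, {geom.n_det})")
    rot = _rot(geom.angles_deg[view])
    src = rot @ np.array([-geom.sod, 0.0])
    det = rot @ np.array([geom.sid - geom.sod, geom.det_offset(det_bin)])
    return src, det
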