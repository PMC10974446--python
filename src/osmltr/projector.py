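"""On-the-fly sparse system-matrix blocks by Siddon-style ray tracing.

Each view's block of the system matrix — intersection lengths ``l_ij`` of ray
``i`` with pixel ``j`` — is recomputed on demand (OTFSM) rather than stored
for the whole scan; for realistic micro-CT sizes the full matrix does not fit
in memory, and a single view block is cheap to rebuild.

The traversal is the classic parametric (Siddon) scheme: the ray is clipped
to the grid rectangle, the sorted parameter values of all pixel-boundary
crossings partition it into segments, and each segment's length in mm is the
weight of the pixel containing its midpoint. Pixel intervals are half-open;
measure-zero corner touches produce zero-length segments and are dropped, so
the weights of a ray always sum to its clipped chord length exactly (up to
float round-off).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ImageGrid, ScanGeometry, _rot

__all__ = [
    "SparseRow",
    "SparseViewMatrix",
    "RowSums",
    "trace_ray",
    "compute_view_matrix",
    "forward_project",
    "back_project",
    "compute_row_sums",
    "ENTRY_BYTES",
]

#: Simulated storage cost per stored weight: 8-byte float + 4-byte index.
ENTRY_BYTES = 12

# Segments shorter than this fraction of a pixel are treated as measure-zero.
_REL_TOL = 1e-12


@dataclass(frozen=True)
class SparseRow:
    """One ray's sparse system-matrix row: pixel indices and lengths (mm)."""

    pixel_indices: np.ndarray
    weights: np.ndarray

    @property
    def chord(self) -> float:
        """Total intersection length of the ray with the grid, mm."""
        return float(self.weights.sum())


class SparseViewMatrix:
    """One view's system-matrix block as a CSR matrix (n_det × n_pixels).

    ``matrix[i, j]`` is the intersection length in mm of detector bin ``i``'s
    ray with flattened pixel ``j`` (row-major over the image grid). Forward
    projection is a product with this matrix; backprojection with its
    transpose — one stored copy serves both.
    """

    def __init__(self, view: int, matrix: sp.csr_matrix, grid_n: int):
        self.view = view
        self.matrix = matrix
        self.grid_n = grid_n

    @property
    def n_det(self) -> int:
        return self.matrix.shape[0]

    @property
    def nnz(self) -> int:
        return int(self.matrix.nnz)

    @property
    def bytes_estimate(self) -> int:
        """Simulated memory footprint of this block."""
        return self.nnz * ENTRY_BYTES

    def row(self, det_bin: int) -> SparseRow:
        start, stop = self.matrix.indptr[det_bin], self.matrix.indptr[det_bin + 1]
        return SparseRow(
            pixel_indices=self.matrix.indices[start:stop].copy(),
            weights=self.matrix.data[start:stop].copy(),
        )

    @property
    def rows(self) -> list[SparseRow]:
        return [self.row(i) for i in range(self.n_det)]

    def row_sums(self) -> np.ndarray:
        """Chord length per detector-bin ray, mm."""
        return np.asarray(self.matrix.sum(axis=1)).ravel()


@dataclass(frozen=True)
class RowSums:
    """Per-ray row sums Σ_h l_ih for every (view, detector bin), mm.

    ``ts[v, i]`` is the chord length of ray ``i`` of view ``v`` through the
    image support; zero exactly for rays that miss the grid.
    """

    ts: np.ndarray


def _trace_ray_bundle(
    p0: np.ndarray, p1: np.ndarray, grid: ImageGrid
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Siddon traversal of a bundle of rays.

    Parameters are ``(R, 2)`` endpoint arrays in mm. Returns
    ``(ray_ids, pixel_indices, weights)`` in ray order.
    """
    p0 = np.atleast_2d(np.asarray(p0, dtype=float))
    p1 = np.atleast_2d(np.asarray(p1, dtype=float))
    d = p1 - p0
    length = np.hypot(d[:, 0], d[:, 1])
    if np.any(length == 0):
        raise ValueError("degenerate ray: coincident endpoints")

    h = grid.half_extent
    px = grid.pixel_size
    n = grid.n

    # Clip each ray to the grid rectangle (slab method) in ray parameter α.
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (-h - p0) / d
        t_hi = (h - p0) / d
    # Axis-parallel rays: the slab is all of α if inside, empty if outside.
    flat = d == 0
    inside = np.abs(p0) <= h
    t_lo = np.where(flat, np.where(inside, -np.inf, np.inf), t_lo)
    t_hi = np.where(flat, np.where(inside, np.inf, -np.inf), t_hi)
    tmin = np.minimum(t_lo, t_hi)
    tmax = np.maximum(t_lo, t_hi)
    a_in = np.maximum(tmin.max(axis=1), 0.0)
    a_out = np.minimum(tmax.min(axis=1), 1.0)
    miss = a_in >= a_out
    a_in = np.where(miss, 0.0, a_in)
    a_out = np.where(miss, 0.0, a_out)

    # α of every pixel-boundary crossing, clipped into [a_in, a_out].
    planes = -h + np.arange(n + 1) * px  # boundary coordinates, both axes
    with np.errstate(divide="ignore", invalid="ignore"):
        ax = (planes[None, :] - p0[:, 0:1]) / d[:, 0:1]
        ay = (planes[None, :] - p0[:, 1:2]) / d[:, 1:2]
    alpha = np.concatenate([ax, ay], axis=1)
    alpha = np.where(np.isnan(alpha), a_in[:, None], alpha)
    alpha = np.clip(alpha, a_in[:, None], a_out[:, None])
    alpha.sort(axis=1)

    seg = np.diff(alpha, axis=1) * length[:, None]  # segment lengths, mm
    mid = (alpha[:, :-1] + alpha[:, 1:]) * 0.5
    mx = p0[:, 0:1] + mid * d[:, 0:1]
    my = p0[:, 1:2] + mid * d[:, 1:2]
    col = np.floor((mx + h) / px).astype(np.int64)
    row = np.floor((my + h) / px).astype(np.int64)

    tol = _REL_TOL * max(px, 1.0)
    valid = (
        (seg > tol)
        & (col >= 0) & (col < n)
        & (row >= 0) & (row < n)
        & ~miss[:, None]
    )
    ray_ids, seg_ids = np.nonzero(valid)
    pix = row[ray_ids, seg_ids] * n + col[ray_ids, seg_ids]
    return ray_ids, pix, seg[ray_ids, seg_ids]


def trace_ray(ray: tuple[np.ndarray, np.ndarray], grid: ImageGrid) -> SparseRow:
    """Trace one ray (pair of endpoints, mm) through the grid.

    Returns every pixel the open segment crosses with its intersection
    length; pixels touched only at a corner are excluded.
    """
    p0, p1 = ray
    _, pix, w = _trace_ray_bundle(np.asarray(p0)[None], np.asarray(p1)[None], grid)
    return SparseRow(pixel_indices=pix, weights=w)


def _view_endpoints(
    geom: ScanGeometry, view: int
) -> tuple[np.ndarray, np.ndarray]:
    rot = _rot(geom.angles_deg[view])
    src = rot @ np.array([-geom.sod, 0.0])
    offsets = (np.arange(geom.n_det) - (geom.n_det - 1) / 2.0) * geom.det_pitch
    det_local = np.stack(
        [np.full(geom.n_det, geom.sid - geom.sod), offsets], axis=1
    )
    det = det_local @ rot.T
    return np.tile(src, (geom.n_det, 1)), det


def compute_view_matrix(
    geom: ScanGeometry, grid: ImageGrid, view: int
) -> SparseViewMatrix:
    """Ray-trace every detector bin of one view into a sparse block.

    Stateless and deterministic: recomputing the same view always yields
    identical rows (this is what makes on-the-fly recomputation safe).
    """
    if not 0 <= view < geom.n_views:
        raise IndexError(f"view {view} out of range [0, {geom.n_views})")
    p0, p1 = _view_endpoints(geom, view)
    ray_ids, pix, w = _trace_ray_bundle(p0, p1, grid)
    mat = sp.csr_matrix(
        (w, (ray_ids, pix)), shape=(geom.n_det, grid.n * grid.n)
    )
    return SparseViewMatrix(view=view, matrix=mat, grid_n=grid.n)


def forward_project(view_matrix: SparseViewMatrix, image: np.ndarray) -> np.ndarray:
    """Line integrals P_i = Σ_j l_ij μ_j for one view (unitless)."""
    image = np.asarray(image, dtype=float)
    n = view_matrix.grid_n
    if image.shape != (n, n):
        raise ValueError(f"image shape {image.shape} does not match grid ({n}, {n})")
    return view_matrix.matrix @ image.ravel()


def back_project(view_matrix: SparseViewMatrix, residual: np.ndarray) -> np.ndarray:
    """Adjoint of :func:`forward_project`: out_j = Σ_i l_ij r_i, image-shaped."""
    residual = np.asarray(residual, dtype=float)
    if residual.shape != (view_matrix.n_det,):
        raise ValueError(
            f"residual length {residual.shape} does not match n_det "
            f"{view_matrix.n_det}"
        )
    n = view_matrix.grid_n
    return (view_matrix.matrix.T @ residual).reshape(n, n)


def compute_row_sums(geom: ScanGeometry, grid: ImageGrid) -> RowSums:
    """Chord length of every ray of every view — the Σ_h l_ih term.

    Computed once, before iterations begin; the per-view blocks used here are
    discarded afterwards (on-the-fly policy).
    """
    ts = np.empty((geom.n_views, geom.n_det))
    for v in range(geom.n_views):
        ts[v] = compute_view_matrix(geom, grid, v).row_sums()
    return RowSums(ts=ts)
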