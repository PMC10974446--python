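"""Maximum-likelihood transmission reconstruction (MLTR) with ordered subsets.

Model
-----
Transmission counts follow the Beer–Lambert law: a detector bin with blank
(flat-field) counts ``b_i`` measures, for attenuation image μ (1/mm),

    ŷ_i = b_i · exp(−Σ_j l_ij μ_j)

where ``l_ij`` is the intersection length of ray i with pixel j. Under the
Poisson log-likelihood

    L = Σ_i (y_i ln ŷ_i − ŷ_i)

the additive MLTR update with a separable surrogate is

    μ_j ← μ_j + Σ_i l_ij (ŷ_i − y_i) / Σ_i l_ij [Σ_h l_ih] ŷ_i

with the bracket the full row sum (chord length) of ray i. Ordered subsets
apply this update after each interleaved subset of views instead of after a
full pass, trading guaranteed monotonicity for speed; with a single subset
the iteration is plain MLTR and increases L monotonically.

The update is additive, so negative pixel values are possible and are *not*
clamped; the iteration log counts them instead.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np

from .geometry import ImageGrid, OrderedSubsets, ScanGeometry
from .projector import (
    RowSums,
    SparseViewMatrix,
    back_project,
    compute_row_sums,
    compute_view_matrix,
    forward_project,
)

__all__ = [
    "ProjectionSet",
    "ReconState",
    "StoppingRule",
    "IterationRecord",
    "estimate_projection",
    "log_likelihood",
    "subset_accumulate",
    "refine_update",
    "check_stopping",
    "run_os_mltr",
]


@dataclass
class ProjectionSet:
    """Measured transmission data: counts ``y`` per (view, bin), blank ``b``.

    ``b`` may be a scalar, a per-bin vector, or a full (view, bin) array; it
    is broadcast against ``y``. ``angles_deg`` records the view angles the
    sinogram was acquired at.
    """

    y: np.ndarray
    b: np.ndarray
    angles_deg: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.y.ndim != 2:
            raise ValueError(f"y must be (n_views, n_det), got shape {self.y.shape}")
        if self.y.shape[0] != len(self.angles_deg):
            raise ValueError(
                f"{self.y.shape[0]} projection views but "
                f"{len(self.angles_deg)} angles"
            )
        if np.any(self.y < 0):
            # Flat-field-corrected detector data can dip below zero; the
            # additive MLTR residual tolerates it, so warn and keep values.
            warnings.warn(
                f"{int(np.sum(self.y < 0))} negative count value(s) in the "
                "sinogram; kept as-is",
                stacklevel=2,
            )
        if np.any(self.b <= 0):
            raise ValueError("blank-scan counts must be strictly positive")
        np.broadcast_shapes(self.y.shape, self.b.shape)

    @property
    def n_views(self) -> int:
        return self.y.shape[0]

    @property
    def n_det(self) -> int:
        return self.y.shape[1]

    def blank_for_view(self, view: int) -> np.ndarray:
        """Blank counts broadcast to one view's detector row."""
        b = np.broadcast_to(self.b, self.y.shape)
        return b[view]


@dataclass
class ReconState:
    """Mutable reconstruction state: image μ and the subset accumulators."""

    mu: np.ndarray
    u1: np.ndarray
    u2: np.ndarray
    iter_count: int = 0
    subset_cursor: int = 0

    @classmethod
    def zeros(cls, grid: ImageGrid) -> "ReconState":
        shape = (grid.n, grid.n)
        return cls(mu=np.zeros(shape), u1=np.zeros(shape), u2=np.zeros(shape))

    def reset_accumulators(self) -> None:
        self.u1.fill(0.0)
        self.u2.fill(0.0)


@dataclass(frozen=True)
class StoppingRule:
    """Stop when consecutive-iteration RMSE drops below the threshold
    (strictly) or the iteration cap is reached."""

    rmse_threshold: float = 0.015
    max_iterations: int = 10

    def __post_init__(self) -> None:
        if self.rmse_threshold <= 0:
            raise ValueError("rmse_threshold must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class IterationRecord:
    """One full iteration's log entry; ``subset`` is the index of the last
    subset refined before the record was taken."""

    iteration: int
    subset: int
    log_likelihood: float
    rmse_consecutive: float
    negatives_count: int


def estimate_projection(P: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Expected counts ŷ = b·exp(−P) for line integrals P.

    The exponent is clipped at ±700 so extreme line integrals saturate
    instead of overflowing; within that range ŷ is exact.
    """
    P = np.asarray(P, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.any(b <= 0):
        raise ValueError("blank counts must be strictly positive")
    return b * np.exp(-np.clip(P, -700.0, 700.0))


def log_likelihood(y: np.ndarray, yhat: np.ndarray) -> float:
    """Poisson transmission log-likelihood L = Σ (y ln ŷ − ŷ), constants dropped."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.any(yhat <= 0):
        raise ValueError("estimated counts must be strictly positive")
    return float(np.sum(y * np.log(yhat) - yhat))


def subset_accumulate(
    state: ReconState,
    view_matrix: SparseViewMatrix,
    ts_slice: np.ndarray,
    y_view: np.ndarray,
    b: np.ndarray,
) -> None:
    """Accumulate one view's contribution into the U1/U2 images.

    U1 gathers the backprojected count residual (ŷ − y); U2 the backprojected
    curvature term ts·ŷ. Contributions of the views of a subset commute up to
    floating-point reordering, which is what lets workers process them in any
    order.
    """
    P = forward_project(view_matrix, state.mu)
    yhat = estimate_projection(P, b)
    state.u1 += back_project(view_matrix, yhat - y_view)
    state.u2 += back_project(view_matrix, ts_slice * yhat)


def refine_update(state: ReconState) -> np.ndarray:
    """Apply the additive MLTR refinement μ += U1/U2 and reset accumulators.

    Pixels with U2 == 0 received no ray information this subset and are left
    unchanged. Returns the updated image (the state is modified in place).
    """
    mask = state.u2 > 0
    state.mu[mask] += state.u1[mask] / state.u2[mask]
    state.reset_accumulators()
    return state.mu


def check_stopping(
    prev_mu: np.ndarray, mu: np.ndarray, rule: StoppingRule, iter_count: int
) -> bool:
    """True when the consecutive-image RMSE falls strictly below the
    threshold, or ``iter_count`` has reached the iteration cap."""
    if prev_mu.shape != mu.shape:
        raise ValueError("image shapes differ")
    if iter_count >= rule.max_iterations:
        return True
    rmse = float(np.sqrt(np.mean((mu - prev_mu) ** 2)))
    return rmse < rule.rmse_threshold


def run_os_mltr(
    proj: ProjectionSet,
    geom: ScanGeometry,
    grid: ImageGrid,
    subsets: OrderedSubsets,
    rule: StoppingRule,
    row_sums: RowSums | None = None,
    compute_likelihood: bool = True,
) -> tuple[np.ndarray, list[IterationRecord]]:
    """Single-worker OS-MLTR reference loop.

    Per full iteration, for each subset in order: recompute each member
    view's system-matrix block on the fly, accumulate U1/U2 over the subset,
    then apply the refinement update. The log records, per full iteration,
    the total log-likelihood over all views, the consecutive-image RMSE, and
    the count of negative pixels.

    Deterministic for fixed inputs. Returns ``(image, log)``.
    """
    if proj.n_views != geom.n_views:
        raise ValueError(
            f"projection set has {proj.n_views} views, geometry {geom.n_views}"
        )
    if proj.n_det != geom.n_det:
        raise ValueError(
            f"projection set has {proj.n_det} bins, geometry {geom.n_det}"
        )
    if subsets.n_subsets * subsets.views_per_subset != geom.n_views:
        raise ValueError("subset structure does not cover the view list")

    if row_sums is None:
        row_sums = compute_row_sums(geom, grid)
    ts = row_sums.ts

    state = ReconState.zeros(grid)
    log: list[IterationRecord] = []

    while True:
        prev_mu = state.mu.copy()
        for s, views in enumerate(subsets):
            state.subset_cursor = s
            state.reset_accumulators()
            for v in views:
                vm = compute_view_matrix(geom, grid, v)
                subset_accumulate(
                    state, vm, ts[v], proj.y[v], proj.blank_for_view(v)
                )
            refine_update(state)
        state.iter_count += 1

        L = (
            _total_log_likelihood(proj, geom, grid, state.mu)
            if compute_likelihood
            else float("nan")
        )
        rmse = float(np.sqrt(np.mean((state.mu - prev_mu) ** 2)))
        log.append(
            IterationRecord(
                iteration=state.iter_count,
                subset=subsets.n_subsets - 1,
                log_likelihood=L,
                rmse_consecutive=rmse,
                negatives_count=int(np.sum(state.mu < 0)),
            )
        )
        if check_stopping(prev_mu, state.mu, rule, state.iter_count):
            break

    return state.mu, log


def _total_log_likelihood(
    proj: ProjectionSet, geom: ScanGeometry, grid: ImageGrid, mu: np.ndarray
) -> float:
    L = 0.0
    for v in range(geom.n_views):
        vm = compute_view_matrix(geom, grid, v)
        yhat = estimate_projection(forward_project(vm, mu), proj.blank_for_view(v))
        L += log_likelihood(proj.y[v], yhat)
    return L


def iteration_log_csv(log: list[IterationRecord]) -> str:
    """Render an iteration log as CSV text."""
    buf = io.StringIO()
    buf.write("iteration,subset,log_likelihood,rmse_consecutive,negatives_count\n")
    for rec in log:
        buf.write(
            f"{rec.iteration},{rec.subset},{rec.log_likelihood!r},"
            f"{rec.rmse_consecutive!r},{rec.negatives_count}\n"
        )
    return buf.getvalue()
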