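"""Functional network construction from voxel time series.

A subject's masked voxel time series are turned into an ``N x N`` Pearson
correlation matrix (every voxel pair), which is then thresholded into a
binary adjacency matrix: two voxels are joined by an edge when their
correlation is sufficiently high-positive, high-negative, or high in
absolute value.  The resulting graph is the "functional network" on which
all downstream node features are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "VoxelGrid",
    "SubjectScan",
    "CorrelationMatrix",
    "AdjacencyGraph",
    "normalize_unit_range",
    "pearson_correlation",
    "build_correlation_matrix",
    "threshold_graph",
]

MODES = ("positive", "negative", "absolute")


@dataclass(frozen=True)
class VoxelGrid:
    """A regular 3-D voxel grid with a fixed linearization rule.

    Voxels at integer coordinates ``(x, y, z)`` are linearized 0-based and
    row-major over ``(x, y, z)`` — i.e. ``index = (x * ny + y) * nz + z`` —
    and every downstream vector (feature maps, feature vectors, masks)
    inherits this ordering, which is what makes features comparable across
    subjects.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: float = 4.0

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValueError(f"grid dims must be three integers >= 1, got {self.dims!r}")
        if not (self.voxel_size_mm > 0):
            raise ValueError("voxel_size_mm must be positive")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def linear_index(self, coords: np.ndarray) -> np.ndarray:
        """Map integer ``(x, y, z)`` coordinates (shape ``(..., 3)``) to linear indices."""
        coords = np.asarray(coords, dtype=np.intp)
        nx, ny, nz = self.dims
        if np.any(coords < 0) or np.any(coords >= np.array(self.dims)):
            raise ValueError("coordinates outside grid")
        return (coords[..., 0] * ny + coords[..., 1]) * nz + coords[..., 2]

    def coordinates(self, linear: np.ndarray) -> np.ndarray:
        """Inverse of :meth:`linear_index`: linear indices -> ``(x, y, z)``."""
        linear = np.asarray(linear, dtype=np.intp)
        nx, ny, nz = self.dims
        if np.any(linear < 0) or np.any(linear >= self.n_voxels):
            raise ValueError("linear index outside grid")
        x, rem = np.divmod(linear, ny * nz)
        y, z = np.divmod(rem, nz)
        return np.stack([x, y, z], axis=-1)

    def mask_linear_indices(self, mask: np.ndarray) -> np.ndarray:
        """Linear indices (sorted, linearization order) of the true voxels of a 3-D mask."""
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != self.dims:
            raise ValueError(f"mask shape {mask.shape} != grid dims {self.dims}")
        # np.flatnonzero on a C-ordered (x, y, z) array matches the linearization rule
        return np.flatnonzero(mask)


@dataclass
class SubjectScan:
    """Masked voxel time series of one subject.

    ``X`` holds one column per in-mask voxel (ordered by grid linearization)
    and one row per time sample; any two columns are the series u, v whose
    Pearson correlation defines the functional edge weight.
    """

    subject_id: str
    grid: VoxelGrid
    anatomical_mask: np.ndarray  # boolean (nx, ny, nz)
    X: np.ndarray  # (T, N) float
    label: str = "unknown"
    site: str = ""

    def __post_init__(self) -> None:
        self.anatomical_mask = np.asarray(self.anatomical_mask, dtype=bool)
        self.X = np.asarray(self.X, dtype=float)
        if self.anatomical_mask.shape != self.grid.dims:
            raise ValueError(
                f"anatomical mask shape {self.anatomical_mask.shape} != grid dims {self.grid.dims}"
            )
        if self.X.ndim != 2:
            raise ValueError("X must be a T x N matrix")
        n_mask = int(self.anatomical_mask.sum())
        if self.X.shape[1] != n_mask:
            raise ValueError(
                f"X has {self.X.shape[1]} columns but the mask selects {n_mask} voxels"
            )
        if self.X.shape[0] < 3:
            raise ValueError(f"need at least 3 time samples, got {self.X.shape[0]}")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("scan contains non-finite values")
        if self.label not in ("ADHD", "control", "unknown"):
            raise ValueError(f"label must be ADHD/control/unknown, got {self.label!r}")

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.X.shape[1]

    @property
    def voxel_linear_indices(self) -> np.ndarray:
        return self.grid.mask_linear_indices(self.anatomical_mask)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations of all in-mask voxels of one subject."""

    C: np.ndarray  # (N, N) float, symmetric, unit diagonal
    grid: VoxelGrid
    voxel_linear_indices: np.ndarray
    degenerate_voxels: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    @property
    def n_voxels(self) -> int:
        return self.C.shape[0]


@dataclass
class AdjacencyGraph:
    """Binary functional network: the thresholded correlation matrix."""

    A: np.ndarray  # (N, N) bool, symmetric, zero diagonal
    mode: str
    tau: float
    grid: VoxelGrid | None = None
    voxel_linear_indices: np.ndarray | None = None

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.A.sum()) // 2


def normalize_unit_range(series: np.ndarray) -> np.ndarray:
    """Min-max rescale a time series onto [-1, 1].

    A constant series maps to all zeros (the midpoint).  The map is affine,
    so the Pearson correlation of any two non-constant series is unchanged.
    """
    series = np.asarray(series, dtype=float)
    if series.size < 1:
        raise ValueError("series must have length >= 1")
    if not np.all(np.isfinite(series)):
        raise ValueError("series contains non-finite values")
    lo = series.min()
    hi = series.max()
    if hi == lo:
        return np.zeros_like(series)
    return 2.0 * (series - lo) / (hi - lo) - 1.0


def pearson_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Pearson product-moment correlation of two equal-length series.

    Computed from the raw-moment form

        r = (T * sum(u v) - sum(u) sum(v)) /
            sqrt[(T sum(u^2) - sum(u)^2)(T sum(v^2) - sum(v)^2)]

    If either series has zero variance the denominator vanishes; such a
    pair is defined to have r = 0 (degenerate, never an error).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError(f"series must be 1-D with equal length, got {u.shape} and {v.shape}")
    T = u.size
    if T < 3:
        raise ValueError(f"need T >= 3 time samples, got {T}")
    su, sv = u.sum(), v.sum()
    du = T * (u @ u) - su * su
    dv = T * (v @ v) - sv * sv
    if du <= 0 or dv <= 0:
        return 0.0
    r = (T * (u @ v) - su * sv) / np.sqrt(du * dv)
    return float(np.clip(r, -1.0, 1.0))


def build_correlation_matrix(scan: SubjectScan, chunk_size: int = 1024) -> CorrelationMatrix:
    """Correlation matrix over all voxel pairs of a scan.

    Columns are standardized once, then the matrix is accumulated in row
    blocks of ``chunk_size`` voxels so peak memory stays bounded; the result
    is identical (to floating-point roundoff) to looping
    :func:`pearson_correlation` over all pairs.  Zero-variance voxels get
    zero off-diagonal rows/columns and are listed in ``degenerate_voxels``.
    """
    X = scan.X
    T, N = X.shape
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    mean = X.mean(axis=0)
    Xc = X - mean
    ss = np.einsum("ij,ij->j", Xc, Xc)
    degenerate = np.flatnonzero(ss <= 0)
    denom = np.sqrt(ss)
    denom[degenerate] = 1.0  # avoid 0/0; those rows are zeroed below
    Z = Xc / denom

    C = np.empty((N, N), dtype=float)
    for start in range(0, N, chunk_size):
        stop = min(start + chunk_size, N)
        C[start:stop] = Z[:, start:stop].T @ Z
    np.clip(C, -1.0, 1.0, out=C)
    if degenerate.size:
        C[degenerate, :] = 0.0
        C[:, degenerate] = 0.0
    np.fill_diagonal(C, 1.0)
    # enforce exact symmetry against accumulation-order roundoff
    C = 0.5 * (C + C.T)
    return CorrelationMatrix(
        C=C,
        grid=scan.grid,
        voxel_linear_indices=scan.voxel_linear_indices,
        degenerate_voxels=degenerate,
    )


def threshold_graph(corr: CorrelationMatrix, tau: float, mode: str = "positive") -> AdjacencyGraph:
    """Binarize a correlation matrix into a functional graph.

    An edge joins voxels i != j when (strict inequalities)

    * ``positive``:  C[i, j] >  tau
    * ``negative``:  C[i, j] < -tau
    * ``absolute``: |C[i, j]| > tau
    """
    if not (0.0 < tau < 1.0):
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    C = corr.C
    if mode == "positive":
        A = C > tau
    elif mode == "negative":
        A = C < -tau
    else:
        A = np.abs(C) > tau
    A = A.copy()
    np.fill_diagonal(A, False)
    return AdjacencyGraph(
        A=A,
        mode=mode,
        tau=float(tau),
        grid=corr.grid,
        voxel_linear_indices=corr.voxel_linear_indices,
    )
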