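"""Per-voxel network feature maps.

Every feature assigns one value (or a small vector) to each node of the
functional graph; the collection over all nodes is the *feature map*:

* degree — number of edges at the node;
* varying-distance degree — the same edges binned by physical edge length
  (Euclidean distance between voxel centers, in mm), one count per bin;
* L-cycle count — number of distinct simple cycles of length L through the
  node, each undirected cycle counted once;
* weight sum — per-node sums of positive, negative (as magnitude), or
  absolute correlation weights, optionally keeping only weights beyond a
  threshold.

Cycle maps use closed-form adjacency-power identities for L in {3, 4}; an
exhaustive path-traversal oracle (exponential, small graphs only) provides
the ground truth for any L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from fcmotif.connectivity import AdjacencyGraph, CorrelationMatrix, VoxelGrid

__all__ = [
    "DistanceBinning",
    "FeatureMap",
    "FEATURE_KINDS",
    "degree_map",
    "varying_distance_degree_map",
    "cycle_count_map",
    "enumerate_cycles_oracle",
    "weight_sum_map",
]

FEATURE_KINDS = (
    "degree",
    "vd_degree",
    "cycle3",
    "cycle4",
    "weight_pos",
    "weight_neg",
    "weight_abs",
)


@dataclass(frozen=True)
class DistanceBinning:
    """Edge-length thresholds l_1 < ... < l_n in mm, defining n + 1 bins.

    Bin i (0-based) counts edges with length in (l_{i-1}, l_i]; the last bin
    counts edges longer than l_n.  Defaults 20/40/80 mm span local to
    hemispheric connections on a typical adult brain volume.
    """

    thresholds_mm: tuple[float, ...] = (20.0, 40.0, 80.0)

    def __post_init__(self) -> None:
        t = tuple(float(x) for x in self.thresholds_mm)
        if len(t) < 1:
            raise ValueError("need at least one distance threshold")
        if any(x <= 0 for x in t) or any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError(f"thresholds must be strictly increasing positives, got {t}")
        object.__setattr__(self, "thresholds_mm", t)

    @property
    def n_bins(self) -> int:
        return len(self.thresholds_mm) + 1

    def bin_of(self, length_mm: np.ndarray) -> np.ndarray:
        """0-based bin index for each edge length (right-closed bins)."""
        edges = np.asarray(self.thresholds_mm)
        # searchsorted 'left' gives count of thresholds strictly below length,
        # which with right-closed bins means bin i for length in (l_{i-1}, l_i]
        return np.searchsorted(edges, np.asarray(length_mm), side="left")


@dataclass
class FeatureMap:
    """Values of one network feature at every node of a subject's graph."""

    kind: str
    values: np.ndarray  # (N, c)
    grid: VoxelGrid | None = None
    voxel_linear_indices: np.ndarray | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]

    @property
    def n_nodes(self) -> int:
        return self.values.shape[0]

    @property
    def n_components(self) -> int:
        return self.values.shape[1]


def _provenance(graph: AdjacencyGraph) -> dict:
    return {"mode": graph.mode, "tau": graph.tau}


def degree_map(graph: AdjacencyGraph) -> FeatureMap:
    """Number of edges attached to each node (row sums of the adjacency matrix)."""
    deg = graph.A.sum(axis=1).astype(float)
    return FeatureMap(
        kind="degree",
        values=deg,
        grid=graph.grid,
        voxel_linear_indices=graph.voxel_linear_indices,
        provenance=_provenance(graph),
    )


def varying_distance_degree_map(
    graph: AdjacencyGraph,
    grid: VoxelGrid | None = None,
    binning: DistanceBinning = DistanceBinning(),
) -> FeatureMap:
    """Per-node edge counts binned by physical edge length.

    Edge length is ``voxel_size_mm`` times the Euclidean distance between the
    two voxels' integer grid coordinates.  The bins partition the edge set,
    so each node's bin counts sum to its total degree.
    """
    grid = grid or graph.grid
    if grid is None or graph.voxel_linear_indices is None:
        raise ValueError("varying-distance degree needs grid coordinates for every node")
    coords = grid.coordinates(graph.voxel_linear_indices).astype(float)
    N = graph.n_nodes
    if coords.shape[0] != N:
        raise ValueError("coordinate count does not match node count")
    values = np.zeros((N, binning.n_bins), dtype=float)
    iu, ju = np.nonzero(np.triu(graph.A, k=1))
    if iu.size:
        lengths = grid.voxel_size_mm * np.linalg.norm(coords[iu] - coords[ju], axis=1)
        bins = binning.bin_of(lengths)
        np.add.at(values, (iu, bins), 1.0)
        np.add.at(values, (ju, bins), 1.0)
    return FeatureMap(
        kind="vd_degree",
        values=values,
        grid=grid,
        voxel_linear_indices=graph.voxel_linear_indices,
        provenance={**_provenance(graph), "thresholds_mm": binning.thresholds_mm},
    )


def cycle_count_map(graph: AdjacencyGraph, L: int) -> FeatureMap:
    """Distinct simple L-cycles through each node, for L in {3, 4}.

    Each undirected cycle is counted once per participating node (direction
    and rotation do not multiply the count).  Closed forms:

    * L = 3: diag(A^3) / 2 — closed 3-walks at v are exactly the triangles,
      traversed in two directions.
    * L = 4: [diag(A^4) - deg(v)^2 - sum_{a in N(v)} (deg(a) - 1)] / 2 —
      closed 4-walks minus the degenerate v-a-v-b-v and v-a-b-a-v walks,
      halved for direction.
    """
    if L not in (3, 4):
        raise ValueError(f"closed forms exist for L in {{3, 4}} only, got {L}; use the enumeration oracle")
    A = graph.A.astype(float)
    deg = A.sum(axis=1)
    A2 = A @ A
    if L == 3:
        counts = np.einsum("ij,ij->i", A2, A) / 2.0  # A symmetric: diag(A^3)
    else:
        diag_A4 = np.einsum("ij,ij->i", A2, A2)  # A symmetric: diag(A^4) = row norms of A^2
        counts = (diag_A4 - deg**2 - (A @ deg - deg)) / 2.0
    counts = np.rint(counts)
    return FeatureMap(
        kind=f"cycle{L}",
        values=counts,
        grid=graph.grid,
        voxel_linear_indices=graph.voxel_linear_indices,
        provenance=_provenance(graph),
    )


def enumerate_cycles_oracle(graph: AdjacencyGraph, L: int, node: int) -> int:
    """Exact L-cycle count at one node by exhaustive path traversal.

    Walks every simple path of length L starting at ``node`` and counts the
    ones that return to it, then halves the count because each undirected
    cycle is traversed in both directions.  Exponential in L; intended for
    small test graphs only.
    """
    if L < 3:
        raise ValueError(f"cycles need length >= 3, got {L}")
    A = graph.A
    N = A.shape[0]
    if not (0 <= node < N):
        raise ValueError(f"node {node} outside graph of {N} nodes")
    neighbors = [np.flatnonzero(A[i]) for i in range(N)]

    def walk(current: int, remaining: int, visited: set[int]) -> int:
        if remaining == 0:
            return 1 if bool(A[current, node]) else 0
        total = 0
        for nxt in neighbors[current]:
            if nxt not in visited and nxt != node:
                visited.add(int(nxt))
                total += walk(int(nxt), remaining - 1, visited)
                visited.remove(int(nxt))
        return total

    # paths of L-1 intermediate steps, then one closing edge back to node
    directed = walk(node, L - 1, {node})
    return directed // 2


def weight_sum_map(
    corr: CorrelationMatrix,
    mode: str,
    tau_min: float | None = None,
) -> FeatureMap:
    """Per-node sums of correlation edge weights.

    Every node pair is treated as connected by a weighted edge (the
    correlation value); per node the positive weights, the magnitudes of the
    negative weights, or all absolute weights are summed.  With ``tau_min``
    only weights beyond the threshold are kept (r > tau_min, r < -tau_min,
    or |r| > tau_min respectively).  Unthresholded, absolute equals
    positive + negative.
    """
    if mode not in ("positive", "negative", "absolute"):
        raise ValueError(f"mode must be positive/negative/absolute, got {mode!r}")
    if tau_min is not None and not (0.0 < tau_min < 1.0):
        raise ValueError(f"tau_min must be in (0, 1), got {tau_min}")
    C = corr.C.copy()
    np.fill_diagonal(C, 0.0)
    lo = 0.0 if tau_min is None else tau_min
    if mode == "positive":
        values = np.where(C > lo, C, 0.0).sum(axis=1)
        kind = "weight_pos"
    elif mode == "negative":
        values = np.where(C < -lo, -C, 0.0).sum(axis=1)
        kind = "weight_neg"
    else:
        absC = np.abs(C)
        values = np.where(absC > lo, absC, 0.0).sum(axis=1)
        kind = "weight_abs"
    return FeatureMap(
        kind=kind,
        values=values,
        grid=corr.grid,
        voxel_linear_indices=corr.voxel_linear_indices,
        provenance={"mode": mode, "tau_min": tau_min},
    )
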