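"""Synthetic resting-state cohorts with planted, class-dependent connectivity.

Each subject's voxel time series are driven by shared latent signals: the
grid is tiled into small latent blocks (3^3 voxels by default), each block
has its own smooth (band-limited Gaussian) latent process, and every
in-brain voxel of a block observes

    x_voxel(t) = alpha * s_block(t) + noise_sd * eps_voxel(t)

with alpha chosen so the expected pairwise correlation of two voxels in the
same block hits a target coupling rho (alpha = noise_sd * sqrt(rho/(1-rho))
when the latent and noise have unit variance).  The latent tiling is
deliberately finer than — and not nested in — the 5^3 cube regions the
mask search partitions the volume into: functional parcels do not align
with an arbitrary tiling, and the resulting large number of independent
latent dimensions (~125 on the default grid, against 80 subjects) is what
makes whole-brain feature vectors overfit relative to masked ones.

Latent blocks whose center lies inside a designated *informative* cube
region carry the class effect — controls couple at ``coupling_strong``,
ADHD subjects at ``coupling_weak``, emulating the reduced synchronization
of affected brains in localized regions — while everywhere else both
classes share a class-independent ``coupling_background`` halfway between
the two.  With the background sitting at typical synchrony, irrelevant
blocks are exactly as variable across subjects as informative ones, so a
variance-driven projection cannot tell them apart and whole-brain feature
vectors bury the discriminative dimensions — the situation the region
search exists to fix.
Per subject and per block the realized coupling is jittered around its
target (``coupling_jitter_sd``), emulating between-subject variability in
connectivity strength; without it every subject of a class would present an
identical network and any single informative block would already separate
the classes perfectly.

The anatomical mask is an ellipsoid inscribed in the grid, so boundary
blocks are only partially in-brain, as with a real brain volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from fcmotif.connectivity import SubjectScan, VoxelGrid
from fcmotif.pca_lda import ADHD, CONTROL
from fcmotif.region_mask import RegionPartition, UsefulRegionMask, partition_into_cubes

__all__ = ["SyntheticCohortConfig", "generate_cohort", "ground_truth_mask", "ellipsoid_mask"]

#: default planted regions: three face-neighbours of the central cube
#: (tile coordinates (0,1,1), (1,0,1), (2,1,1) on the 3x3x3 tiling of a
#: 15^3 grid with 5-voxel cubes).  Each of these cubes covers the centers
#: of exactly two 3^3 latent blocks, so the three planted regions carry
#: equally strong signal; the central cube is avoided because the latent
#: tiling gives it only one block center.
_DEFAULT_INFORMATIVE = (4, 10, 22)


@dataclass
class SyntheticCohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults: 40 subjects per class on a 15x15x15 grid of 4 mm voxels,
    T = 120 time points, one latent signal per 3^3 latent block, three
    informative central 5^3 cube regions, coupling 0.80 (strong) vs 0.60
    (weak) with 0.15 between-subject jitter — calibrated so leave-one-out
    detection rates land in the 65-85% band rather than saturating, the
    regime in which region selection is both meaningful and measurable.
    """

    n_per_class: int = 40
    dims: tuple[int, int, int] = (15, 15, 15)
    voxel_size_mm: float = 4.0
    T: int = 120
    cube_size: int = 5
    latent_cube_size: int = 3
    cluster_layout: np.ndarray | None = None  # latent block -> latent signal id; default identity
    informative_regions: tuple[int, ...] = _DEFAULT_INFORMATIVE
    coupling_strong: float = 0.80
    coupling_weak: float = 0.60
    coupling_background: float = 0.70
    coupling_jitter_sd: float = 0.15
    noise_sd: float = 1.0
    latent_band_fraction: float = 0.2  # fraction of rfft bins kept in the latent signals
    mask_semi_axis_fraction: float = 0.52  # ellipsoid semi-axes as fraction of grid dims
    site: str = "SYN"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.T < 3:
            raise ValueError("need T >= 3")
        # equality is allowed: strong == weak is the null cohort with no class effect
        if not (0.0 < self.coupling_weak <= self.coupling_strong < 1.0):
            raise ValueError(
                "couplings must satisfy 0 < coupling_weak <= coupling_strong < 1, "
                f"got weak={self.coupling_weak}, strong={self.coupling_strong}"
            )
        if not (0.0 < self.coupling_background < 1.0):
            raise ValueError("coupling_background must be in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        grid = self.grid
        partition = self.partition
        bad = [r for r in self.informative_regions if not (0 <= r < partition.n_regions)]
        if bad:
            raise ValueError(f"informative regions {bad} outside the {partition.n_regions}-region partition")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid(dims=self.dims, voxel_size_mm=self.voxel_size_mm)

    @property
    def partition(self) -> RegionPartition:
        """The 5^3 search-cube tiling the mask search will use."""
        return partition_into_cubes(self.grid, self.cube_size)

    @property
    def latent_partition(self) -> RegionPartition:
        """Tiling of the grid into latent signal blocks.

        Deliberately finer than (and not nested in) the search cubes: real
        functional parcels do not align with an arbitrary cube tiling, and
        the many resulting latent dimensions are what make whole-brain
        feature vectors overfit relative to masked ones.
        """
        return partition_into_cubes(self.grid, self.latent_cube_size)

    @property
    def n_latent(self) -> int:
        layout = self.cluster_layout
        if layout is None:
            return self.latent_partition.n_regions
        return int(np.max(layout)) + 1

    def informative_latent_blocks(self) -> np.ndarray:
        """Latent blocks whose center voxel lies inside an informative region."""
        latent = self.latent_partition
        region_of = self.partition.region_of_voxel()
        informative = np.asarray(sorted(self.informative_regions), dtype=int)
        out = []
        for b, block in enumerate(latent.regions):
            center = block[block.size // 2]  # median linear index = block center
            if region_of[center] in informative:
                out.append(b)
        return np.asarray(out, dtype=int)


def ellipsoid_mask(grid: VoxelGrid, semi_axis_fraction: float = 0.52) -> np.ndarray:
    """Ellipsoid anatomical mask inscribed in the grid (semi-axes = fraction x dims)."""
    nx, ny, nz = grid.dims
    center = (np.array(grid.dims) - 1) / 2.0
    semi = semi_axis_fraction * np.array(grid.dims)
    x, y, z = np.ogrid[:nx, :ny, :nz]
    d2 = (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    )
    return d2 <= 1.0


def _band_limited_signal(rng: np.random.Generator, T: int, band_fraction: float) -> np.ndarray:
    """Smooth unit-variance signal: white noise low-passed in the Fourier domain."""
    white = rng.standard_normal(T)
    W = np.fft.rfft(white)
    keep = max(2, int(band_fraction * W.size))
    W[keep:] = 0.0
    W[0] = 0.0  # zero mean
    s = np.fft.irfft(W, n=T)
    sd = s.std()
    if sd <= 0:  # vanishingly unlikely; fall back to white noise
        s = white - white.mean()
        sd = s.std()
    return s / sd


def _coupling_alpha(rho: float, noise_sd: float) -> float:
    """Latent loading giving expected within-block correlation rho."""
    return noise_sd * np.sqrt(rho / (1.0 - rho))


def generate_cohort(config: SyntheticCohortConfig) -> list[SubjectScan]:
    """Generate the labeled cohort (controls first, then ADHD subjects).

    Deterministic under ``config.seed``: the same config yields bit-identical
    scans.  Every subject shares the grid and the ellipsoid anatomical mask.
    """
    grid = config.grid
    latent_partition = config.latent_partition
    anatomical = ellipsoid_mask(grid, config.mask_semi_axis_fraction)
    mask_lin = grid.mask_linear_indices(anatomical)
    layout = (
        np.arange(latent_partition.n_regions)
        if config.cluster_layout is None
        else np.asarray(config.cluster_layout, dtype=int)
    )
    if layout.size != latent_partition.n_regions:
        raise ValueError("cluster_layout must assign a latent signal to every latent block")
    informative = frozenset(config.informative_latent_blocks().tolist())
    rng = np.random.default_rng(config.seed)
    T = config.T

    # position of each in-mask voxel within the masked column ordering
    col_of_lin = np.full(grid.n_voxels, -1, dtype=np.intp)
    col_of_lin[mask_lin] = np.arange(mask_lin.size)

    scans: list[SubjectScan] = []
    labels = [CONTROL] * config.n_per_class + [ADHD] * config.n_per_class
    for s, label in enumerate(labels):
        latents = np.stack(
            [_band_limited_signal(rng, T, config.latent_band_fraction) for _ in range(config.n_latent)]
        )
        X = np.empty((T, mask_lin.size), dtype=float)
        for r, region in enumerate(latent_partition.regions):
            cols = col_of_lin[region]
            cols = cols[cols >= 0]
            if cols.size == 0:
                continue
            if r in informative:
                target = config.coupling_strong if label == CONTROL else config.coupling_weak
            else:
                target = config.coupling_background
            rho = float(np.clip(rng.normal(target, config.coupling_jitter_sd), 0.02, 0.97))
            alpha = _coupling_alpha(rho, config.noise_sd)
            noise = rng.standard_normal((T, cols.size)) * config.noise_sd
            X[:, cols] = alpha * latents[layout[r]][:, None] + noise
        scans.append(
            SubjectScan(
                subject_id=f"syn-{s:03d}",
                grid=grid,
                anatomical_mask=anatomical,
                X=X,
                label=label,
                site=config.site,
            )
        )
    return scans


def ground_truth_mask(config: SyntheticCohortConfig) -> UsefulRegionMask:
    """Binary mask of the planted informative regions, for recovery scoring.

    Confined, like the searched mask, to the brain volume (the planted
    default regions lie fully inside the default ellipsoid, so there the
    intersection changes nothing).
    """
    grid = config.grid
    partition = config.partition
    anatomical = ellipsoid_mask(grid, config.mask_semi_axis_fraction)
    probability = np.zeros(partition.n_regions, dtype=float)
    mask = np.zeros(grid.dims, dtype=bool)
    flat = mask.reshape(-1)
    for r in config.informative_regions:
        probability[r] = 1.0
        flat[partition.regions[r]] = True
    mask &= anatomical
    return UsefulRegionMask(mask=mask, grid=grid, region_probability=probability, partition=partition)
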