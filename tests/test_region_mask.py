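"""Cube partition, random subset sampling, mask search mechanics, and clusters."""

import numpy as np
import pandas as pd
import pytest

from fcmotif import (
    ADHD,
    CONTROL,
    FeatureMap,
    MaskSearchConfig,
    UsefulRegionMask,
    VoxelGrid,
    apply_mask,
    partition_into_cubes,
    sample_region_subset,
    search_useful_mask,
    summarize_mask_clusters,
)


class TestPartition:
    def test_even_tiling(self):
        part = partition_into_cubes(VoxelGrid((10, 10, 10)), 5)
        assert part.n_regions == 8
        assert all(len(r) == 125 for r in part.regions)

    def test_brain_sized_grid_has_1200_regions(self):
        part = partition_into_cubes(VoxelGrid((49, 58, 47)), 5)
        assert part.n_regions == 10 * 12 * 10

    def test_every_voxel_in_exactly_one_region(self):
        grid = VoxelGrid((7, 9, 6))
        part = partition_into_cubes(grid, 4)
        all_idx = np.concatenate(part.regions)
        assert len(all_idx) == grid.n_voxels
        assert len(np.unique(all_idx)) == grid.n_voxels

    def test_rejects_bad_cube_size(self):
        with pytest.raises(ValueError):
            partition_into_cubes(VoxelGrid((5, 5, 5)), 0)


class TestSampling:
    def test_p_one_selects_everything(self, rng):
        part = partition_into_cubes(VoxelGrid((10, 10, 10)), 5)
        assert len(sample_region_subset(part, 1.0, rng)) == 8

    def test_p_zero_errors_after_bounded_retries(self, rng):
        part = partition_into_cubes(VoxelGrid((10, 10, 10)), 5)
        with pytest.raises(RuntimeError):
            sample_region_subset(part, 0.0, rng)

    def test_inclusion_fraction_concentrates(self):
        part = partition_into_cubes(VoxelGrid((49, 58, 47)), 5)  # 1200 regions
        r = np.random.default_rng(7)
        draws = r.random((10_000, part.n_regions)) < 0.4
        # the vectorized draw is the same Bernoulli scheme the sampler uses
        assert 0.39 <= draws.mean() <= 0.41
        fractions = [
            len(sample_region_subset(part, 0.4, r)) / part.n_regions for _ in range(200)
        ]
        assert 0.37 <= np.mean(fractions) <= 0.43


def _toy_maps_and_labels(n_subjects=12, dims=(6, 6, 6), seed=0):
    """Tiny cohort whose signal lives entirely in region 0."""
    r = np.random.default_rng(seed)
    grid = VoxelGrid(dims)
    part = partition_into_cubes(grid, 3)
    labels = [ADHD, CONTROL] * (n_subjects // 2)
    maps = []
    for lab in labels:
        values = r.normal(0, 0.5, size=grid.n_voxels)
        bump = 3.0 if lab == ADHD else 0.0
        values[part.regions[0]] += bump + r.normal(0, 0.5)
        maps.append(
            FeatureMap(
                kind="degree",
                values=values,
                grid=grid,
                voxel_linear_indices=np.arange(grid.n_voxels),
            )
        )
    return maps, labels, part


class TestSearch:
    def test_log_has_m_rows_and_selection_count(self):
        maps, labels, part = _toy_maps_and_labels()
        cfg = MaskSearchConfig(p=0.5, m=20, top_fraction=0.10, th=0.0, k=3, seed=1)
        mask = search_useful_mask(maps, labels, cfg, partition=part)
        assert len(mask.iteration_log) == 20
        assert len(mask.selected_iterations) == int(np.ceil(0.10 * 20))

    def test_m500_top10pct_selects_50(self):
        cfg = MaskSearchConfig(m=500, top_fraction=0.10)
        assert cfg.n_selected == 50

    def test_th_zero_keeps_every_selected_region(self):
        maps, labels, part = _toy_maps_and_labels()
        cfg = MaskSearchConfig(p=0.5, m=20, th=0.0, k=3, seed=1)
        mask = search_useful_mask(maps, labels, cfg, partition=part)
        occurred = mask.region_probability > 0
        flat = mask.mask.reshape(-1)
        for reg, occ in zip(part.regions, occurred):
            assert flat[reg].all() == occ

    def test_raising_th_only_removes_voxels(self):
        maps, labels, part = _toy_maps_and_labels()
        masks = {}
        for th in (0.2, 0.6, 0.9):
            cfg = MaskSearchConfig(p=0.5, m=20, th=th, k=3, seed=1)
            masks[th] = search_useful_mask(maps, labels, cfg, partition=part)
        assert not (masks[0.6].mask & ~masks[0.2].mask).any()
        assert not (masks[0.9].mask & ~masks[0.6].mask).any()

    def test_same_seed_reproduces_probabilities(self):
        maps, labels, part = _toy_maps_and_labels()
        cfg = MaskSearchConfig(p=0.5, m=15, k=3, seed=3)
        m1 = search_useful_mask(maps, labels, cfg, partition=part)
        m2 = search_useful_mask(maps, labels, cfg, partition=part)
        assert np.array_equal(m1.region_probability, m2.region_probability)
        assert np.array_equal(m1.mask, m2.mask)

    def test_signal_region_tops_the_probability_map(self):
        maps, labels, part = _toy_maps_and_labels(n_subjects=20)
        cfg = MaskSearchConfig(p=0.4, m=40, th=0.6, k=3, seed=5)
        mask = search_useful_mask(maps, labels, cfg, partition=part)
        assert np.argmax(mask.region_probability) == 0
        assert mask.mask.reshape(-1)[part.regions[0]].all()


class TestApplyMask:
    def _feature_map(self, grid, n_components=1):
        lin = np.arange(grid.n_voxels)
        values = np.arange(grid.n_voxels * n_components, dtype=float).reshape(
            grid.n_voxels, n_components
        )
        return FeatureMap(kind="degree" if n_components == 1 else "vd_degree",
                          values=values, grid=grid, voxel_linear_indices=lin)

    def test_full_grid_mask_flattens_the_map(self):
        grid = VoxelGrid((3, 3, 3))
        fm = self._feature_map(grid)
        fv = apply_mask(fm, np.ones(grid.dims, dtype=bool))
        assert np.array_equal(fv.values, fm.values.ravel())

    def test_masked_length_counts_voxels(self):
        grid = VoxelGrid((4, 4, 4))
        fm = self._feature_map(grid)
        mask = np.zeros(grid.dims, dtype=bool)
        mask.reshape(-1)[:7] = True
        assert apply_mask(fm, mask).values.size == 7

    def test_multicomponent_layout_arithmetic(self):
        grid = VoxelGrid((4, 4, 4))
        fm = self._feature_map(grid, n_components=4)
        mask = np.zeros(grid.dims, dtype=bool)
        mask.reshape(-1)[:10] = True
        fv = apply_mask(fm, mask)
        assert fv.values.size == 40
        # per-voxel components contiguous
        assert np.array_equal(fv.values[:4], fm.values[0])

    def test_out_of_anatomy_voxels_contribute_zero(self):
        grid = VoxelGrid((3, 3, 3))
        lin = np.arange(5)  # subject anatomy covers only the first 5 voxels
        fm = FeatureMap(kind="degree", values=np.ones(5), grid=grid, voxel_linear_indices=lin)
        fv = apply_mask(fm, np.ones(grid.dims, dtype=bool))
        assert fv.values[:5].sum() == 5 and fv.values[5:].sum() == 0

    def test_empty_mask_rejected(self):
        grid = VoxelGrid((3, 3, 3))
        with pytest.raises(ValueError):
            apply_mask(self._feature_map(grid), np.zeros(grid.dims, dtype=bool))


class TestClusterSummary:
    def test_single_block_cluster(self):
        grid = VoxelGrid((6, 6, 6), voxel_size_mm=4.0)
        mask = np.zeros(grid.dims, dtype=bool)
        mask[2:4, 2:4, 2:4] = True
        table = summarize_mask_clusters(mask, grid)
        assert len(table) == 1
        row = table.iloc[0]
        assert row.size_mm3 == 8 * 64.0
        assert (row.center_x_vox, row.center_y_vox, row.center_z_vox) == (2.5, 2.5, 2.5)
        assert row.center_x_mm == pytest.approx(10.0)

    def test_two_separated_blocks(self):
        grid = VoxelGrid((8, 8, 8))
        mask = np.zeros(grid.dims, dtype=bool)
        mask[0:2, 0:2, 0:2] = True
        mask[5:7, 5:7, 5:7] = True
        assert len(summarize_mask_clusters(mask, grid)) == 2

    def test_diagonal_touch_is_not_connected(self):
        grid = VoxelGrid((4, 4, 4))
        mask = np.zeros(grid.dims, dtype=bool)
        mask[0, 0, 0] = mask[1, 1, 1] = True  # corner contact only
        assert len(summarize_mask_clusters(mask, grid)) == 2

    def test_sizes_conserve_voxel_count(self, rng):
        grid = VoxelGrid((6, 6, 6))
        mask = rng.random(grid.dims) < 0.3
        if not mask.any():
            mask[0, 0, 0] = True
        table = summarize_mask_clusters(mask, grid)
        assert table.size_mm3.sum() == mask.sum() * 64.0

    def test_empty_mask_rejected(self):
        grid = VoxelGrid((3, 3, 3))
        with pytest.raises(ValueError):
            summarize_mask_clusters(np.zeros(grid.dims, dtype=bool), grid)
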