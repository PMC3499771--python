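"""File formats: NIfTI-1 volumes, phenotype tables, array containers.

Scans are 4-D NIfTI (X x Y x Z x T), anatomical masks 3-D NIfTI (nonzero =
in-brain), phenotype tables CSV with header ``subject_id,dx,site``.
Correlation matrices persist as ``.npy`` with a CSV sidecar listing the
voxel coordinate of every row/column; feature maps and masks write back as
NIfTI volumes plus flat tables; trained models serialize to a single
``.npz`` archive.
"""

from __future__ import annotations

import os
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from fcmotif.connectivity import CorrelationMatrix, SubjectScan, VoxelGrid
from fcmotif.graph_features import FeatureMap
from fcmotif.pca_lda import ADHD, CONTROL, LdaScatter, PcaLdaModel
from fcmotif.region_mask import UsefulRegionMask

__all__ = [
    "ACCEPTED_LABELS",
    "grid_affine",
    "save_scan",
    "load_scan",
    "write_cohort",
    "load_cohort",
    "save_correlation",
    "load_correlation",
    "write_feature_map",
    "feature_table",
    "write_mask",
    "save_model",
    "load_model",
]

#: accepted diagnosis strings in phenotype tables (case-insensitive)
ACCEPTED_LABELS = {"adhd": ADHD, "control": CONTROL, "unknown": "unknown"}


def grid_affine(grid: VoxelGrid) -> np.ndarray:
    """Scaled-identity affine mapping voxel indices to mm."""
    affine = np.eye(4)
    affine[0, 0] = affine[1, 1] = affine[2, 2] = grid.voxel_size_mm
    return affine


def _parse_label(raw: str) -> str:
    key = str(raw).strip().lower()
    if key not in ACCEPTED_LABELS:
        raise ValueError(
            f"unknown diagnosis label {raw!r}; accepted labels are "
            f"{sorted(set(ACCEPTED_LABELS.values()))}"
        )
    return ACCEPTED_LABELS[key]


def save_scan(scan: SubjectScan, scan_path, mask_path) -> None:
    """Write one subject as a 4-D scan NIfTI and a 3-D mask NIfTI."""
    grid = scan.grid
    affine = grid_affine(grid)
    # float64 so a round-trip through disk reproduces in-memory results exactly
    vol = np.zeros(grid.dims + (scan.n_timepoints,), dtype=np.float64)
    coords = grid.coordinates(scan.voxel_linear_indices)
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = scan.X.T
    nib.save(nib.Nifti1Image(vol, affine), str(scan_path))
    nib.save(nib.Nifti1Image(scan.anatomical_mask.astype(np.uint8), affine), str(mask_path))


def load_scan(scan_path, mask_path, phenotype_row, voxel_size_mm: float | None = None) -> SubjectScan:
    """Load one subject from a 4-D scan NIfTI, a 3-D mask NIfTI, and a phenotype row.

    ``phenotype_row`` is a mapping with keys ``subject_id``, ``dx`` and
    (optionally) ``site``.  The mask's nonzero voxels define the in-brain
    columns, ordered by grid linearization.
    """
    scan_img = nib.load(str(scan_path))
    mask_img = nib.load(str(mask_path))
    data = np.asanyarray(scan_img.dataobj)
    mask = np.asanyarray(mask_img.dataobj) != 0
    if data.ndim != 4:
        raise ValueError(f"scan {scan_path} is {data.ndim}-D, expected 4-D (X,Y,Z,T)")
    if data.shape[:3] != mask.shape:
        raise ValueError(
            f"scan grid {data.shape[:3]} does not match mask grid {mask.shape} "
            f"({scan_path} vs {mask_path})"
        )
    if voxel_size_mm is None:
        zooms = scan_img.header.get_zooms()[:3]
        voxel_size_mm = float(zooms[0]) if zooms[0] > 0 else 4.0
    grid = VoxelGrid(dims=data.shape[:3], voxel_size_mm=voxel_size_mm)
    coords = grid.coordinates(grid.mask_linear_indices(mask))
    X = data[coords[:, 0], coords[:, 1], coords[:, 2], :].T.astype(float)
    return SubjectScan(
        subject_id=str(phenotype_row["subject_id"]),
        grid=grid,
        anatomical_mask=mask,
        X=X,
        label=_parse_label(phenotype_row["dx"]),
        site=str(phenotype_row.get("site", "")),
    )


def write_cohort(cohort: list[SubjectScan], out_dir) -> Path:
    """Write scans/, masks/ and phenotype.csv for a whole cohort."""
    out = Path(out_dir)
    (out / "scans").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for scan in cohort:
        save_scan(
            scan,
            out / "scans" / f"{scan.subject_id}.nii.gz",
            out / "masks" / f"{scan.subject_id}.nii.gz",
        )
        rows.append({"subject_id": scan.subject_id, "dx": scan.label, "site": scan.site})
    pd.DataFrame(rows).to_csv(out / "phenotype.csv", index=False)
    return out


def load_cohort(cohort_dir, voxel_size_mm: float | None = None) -> list[SubjectScan]:
    """Load a cohort written by :func:`write_cohort` (or laid out the same way)."""
    root = Path(cohort_dir)
    pheno = pd.read_csv(root / "phenotype.csv", dtype=str)
    scans = []
    for _, row in pheno.iterrows():
        sid = row["subject_id"]
        scans.append(
            load_scan(
                root / "scans" / f"{sid}.nii.gz",
                root / "masks" / f"{sid}.nii.gz",
                row,
                voxel_size_mm=voxel_size_mm,
            )
        )
    return scans


def save_correlation(corr: CorrelationMatrix, path) -> None:
    """``.npy`` matrix plus ``<path>.coords.csv`` sidecar of voxel coordinates."""
    path = Path(path)
    np.save(path, corr.C)
    coords = corr.grid.coordinates(corr.voxel_linear_indices)
    df = pd.DataFrame(coords, columns=["x", "y", "z"])
    df["linear_index"] = corr.voxel_linear_indices
    df["degenerate"] = 0
    df.loc[df.index[np.isin(np.arange(len(df)), corr.degenerate_voxels)], "degenerate"] = 1
    df.to_csv(path.with_suffix(path.suffix + ".coords.csv"), index=False)


def load_correlation(path, grid: VoxelGrid) -> CorrelationMatrix:
    path = Path(path)
    C = np.load(path)
    sidecar = pd.read_csv(path.with_suffix(path.suffix + ".coords.csv"))
    return CorrelationMatrix(
        C=C,
        grid=grid,
        voxel_linear_indices=sidecar["linear_index"].to_numpy(),
        degenerate_voxels=np.flatnonzero(sidecar["degenerate"].to_numpy()),
    )


def write_feature_map(fm: FeatureMap, path) -> None:
    """Feature map as a NIfTI volume (4-D when multi-component)."""
    grid = fm.grid
    affine = grid_affine(grid)
    coords = grid.coordinates(fm.voxel_linear_indices)
    vol = np.zeros(grid.dims + (fm.n_components,), dtype=np.float32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = fm.values.astype(np.float32)
    if fm.n_components == 1:
        vol = vol[..., 0]
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def feature_table(fm: FeatureMap) -> pd.DataFrame:
    """Flat per-voxel table: x, y, z, value columns."""
    coords = fm.grid.coordinates(fm.voxel_linear_indices)
    df = pd.DataFrame(coords, columns=["x", "y", "z"])
    if fm.n_components == 1:
        df["value"] = fm.values[:, 0]
    else:
        for c in range(fm.n_components):
            df[f"value_{c}"] = fm.values[:, c]
    return df


def write_mask(mask: UsefulRegionMask, out_dir, prefix: str = "useful_region") -> None:
    """Binary mask NIfTI + region-probability NIfTI + iteration-accuracy CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = grid_affine(mask.grid)
    nib.save(nib.Nifti1Image(mask.mask.astype(np.uint8), affine), str(out / f"{prefix}_mask.nii.gz"))
    if mask.partition is not None:
        prob_vol = np.zeros(mask.grid.dims, dtype=np.float32)
        flat = prob_vol.reshape(-1)
        for r, region in enumerate(mask.partition.regions):
            flat[region] = mask.region_probability[r]
        nib.save(nib.Nifti1Image(prob_vol, affine), str(out / f"{prefix}_probability.nii.gz"))
    if mask.iteration_log is not None:
        mask.iteration_log.to_csv(out / f"{prefix}_iterations.csv", index=False)


def save_model(model: PcaLdaModel, path) -> None:
    """Single ``.npz`` archive: basis, Fisher direction, midpoint, layout."""
    np.savez_compressed(
        path,
        training_mean=model.training_mean,
        components=model.components,
        explained_variance_fractions=model.explained_variance_fractions,
        k=model.k,
        w=model.w,
        class_means_projected=np.array(model.class_means_projected),
        class_counts=np.array(model.class_counts),
        class_mean_vectors=model.class_mean_vectors,
        decision_midpoint=model.decision_midpoint,
        label_order=np.array(model.label_order),
        layout=np.array(str(model.layout)),
        S_W=model.scatter.S_W if model.scatter else np.zeros((0, 0)),
        S_B=model.scatter.S_B if model.scatter else np.zeros((0, 0)),
    )


def load_model(path) -> PcaLdaModel:
    with np.load(path, allow_pickle=False) as z:
        scatter = None
        if z["S_W"].size:
            scatter = LdaScatter(S_W=z["S_W"], S_B=z["S_B"])
        return PcaLdaModel(
            training_mean=z["training_mean"],
            components=z["components"],
            explained_variance_fractions=z["explained_variance_fractions"],
            k=int(z["k"]),
            w=z["w"],
            class_means_projected=tuple(z["class_means_projected"]),
            class_counts=tuple(int(c) for c in z["class_counts"]),
            class_mean_vectors=z["class_mean_vectors"],
            decision_midpoint=float(z["decision_midpoint"]),
            label_order=tuple(z["label_order"]),
            layout=str(z["layout"]),
            scatter=scatter,
        )
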