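"""File formats and run configuration.

NIfTI-1 for volumes and masks (nibabel), whitespace-delimited 6-column text
for motion traces, TSV for phenotype and result tables, YAML for the run
configuration, JSON for QC reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .grid import SymmetricGrid, make_symmetric_grid
from .image import FuncImage, MotionTrace
from .synth import AGE_RANGE, GROUPS, NETWORK_NAMES, PHENOTYPE_COLUMNS

__all__ = [
    "RunConfig",
    "read_func",
    "write_func",
    "read_mask",
    "write_mask",
    "read_atlas",
    "write_atlas",
    "read_motion",
    "write_motion",
    "read_phenotype",
    "write_phenotype",
]


def _affine(grid: SymmetricGrid) -> np.ndarray:
    aff = np.diag([*grid.voxel_size_mm, 1.0])
    return aff


def _grid_from_img(img: nib.Nifti1Image) -> SymmetricGrid:
    zooms = img.header.get_zooms()[:3]
    return make_symmetric_grid(tuple(img.shape[:3]), tuple(float(z) for z in zooms))


def write_func(img: FuncImage, path: str | Path) -> None:
    """Write a 4-D functional run as NIfTI-1 (float32)."""
    nii = nib.Nifti1Image(img.data.astype(np.float32), _affine(img.grid))
    nii.header.set_zooms((*img.grid.voxel_size_mm, img.tr_seconds))
    nii.header.set_xyzt_units("mm", "sec")
    nib.save(nii, str(path))


def read_func(path: str | Path, tr_seconds: float | None = None) -> FuncImage:
    """Read a 4-D NIfTI functional run (plain or gzipped)."""
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise ValueError(f"{path}: expected a 4-D functional image, got {data.ndim}-D")
    grid = _grid_from_img(nii)
    if tr_seconds is None:
        zooms = nii.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return FuncImage(data=data, grid=grid, tr_seconds=tr_seconds)


def write_mask(mask: np.ndarray, grid: SymmetricGrid, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(mask, dtype=np.uint8), _affine(grid))
    nib.save(nii, str(path))


def read_mask(path: str | Path, grid: SymmetricGrid | None = None) -> np.ndarray:
    nii = nib.load(str(path))
    data = np.asarray(nii.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D mask, got {data.ndim}-D")
    vals = np.unique(data)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{path}: mask values must be 0/1, found {vals[:10]}")
    if grid is not None and data.shape != grid.dims:
        raise ValueError(f"{path}: mask grid {data.shape} does not match expected {grid.dims}")
    return data.astype(bool)


def write_metric_map(values: np.ndarray, grid: SymmetricGrid, path: str | Path) -> None:
    nii = nib.Nifti1Image(np.asarray(values, dtype=np.float32), _affine(grid))
    nib.save(nii, str(path))


def write_atlas(atlas: dict[str, np.ndarray], grid: SymmetricGrid, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, mask in atlas.items():
        write_mask(mask, grid, directory / f"{name}.nii")


def read_atlas(directory: str | Path) -> tuple[SymmetricGrid, dict[str, np.ndarray]]:
    """Load the 15-network mask bundle; names must match the roster exactly."""
    directory = Path(directory)
    files = {p.name.removesuffix(".nii.gz").removesuffix(".nii"): p
             for p in sorted(directory.glob("*.nii*"))}
    missing = [n for n in NETWORK_NAMES if n not in files]
    extra = [n for n in files if n not in NETWORK_NAMES]
    if missing or extra:
        raise ValueError(
            f"atlas at {directory} must contain exactly the {len(NETWORK_NAMES)} network "
            f"masks; missing: {missing}; unexpected: {extra}"
        )
    grid: SymmetricGrid | None = None
    atlas: dict[str, np.ndarray] = {}
    for name in NETWORK_NAMES:
        nii = nib.load(str(files[name]))
        g = _grid_from_img(nii)
        if grid is None:
            grid = g
        elif g.dims != grid.dims:
            raise ValueError(f"atlas grids differ: {name} has {g.dims}, expected {grid.dims}")
        atlas[name] = read_mask(files[name], grid)
    assert grid is not None
    return grid, atlas


def write_motion(motion: MotionTrace, path: str | Path) -> None:
    np.savetxt(str(path), motion.params, fmt="%.6f")


def read_motion(path: str | Path) -> MotionTrace:
    params = np.loadtxt(str(path))
    if params.ndim == 1:
        params = params[None, :]
    if params.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have 6 columns (3 translations mm, "
            f"3 rotations deg), found {params.shape[1]}"
        )
    return MotionTrace(params)


def write_phenotype(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_phenotype(path: str | Path) -> pd.DataFrame:
    """Read and validate a phenotype TSV (group, age, sex, scores)."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENOTYPE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing phenotype columns {missing}")
    if table["subject_id"].duplicated().any():
        dup = table["subject_id"][table["subject_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dup}")
    bad_group = sorted(set(table["group"]) - set(GROUPS))
    if bad_group:
        raise ValueError(f"{path}: column 'group' has invalid categories {bad_group}")
    hand = table["handedness"].to_numpy(dtype=np.float64)
    if np.any((hand < 0) | (hand > 1)):
        raise ValueError(f"{path}: column 'handedness' must lie in [0, 1]")
    age = table["age_years"].to_numpy(dtype=np.float64)
    out_of_range = (age < AGE_RANGE[0]) | (age > AGE_RANGE[1])
    if out_of_range.any():
        import logging
        logging.getLogger(__name__).warning(
            "%s: %d subject(s) outside the %g-%g year design range",
            path, int(out_of_range.sum()), *AGE_RANGE,
        )
    return table


def write_qc_report(report, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report.to_dict(), indent=2) + "\n")


@dataclass
class RunConfig:
    """All pipeline thresholds; every default is the protocol's stated value."""

    drop_n: int = 4
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    scale_target: float = 100.0
    fd_threshold_mm: float = 0.5
    fd_rotation_radius_mm: float = 50.0
    qc_max_censored_fraction: float = 0.10
    qc_max_translation_mm: float = 2.0
    qc_max_rotation_deg: float = 2.0
    ec_tol: float = 1e-6
    ec_max_iter: int = 1000
    ec_shift: str = "add-one-half"
    fdr_q: float = 0.05
    min_cluster_voxels: int = 30
    nn_level: int = 3
    significance_p: float = 0.01
    trend_p: float = 0.05
    simultaneous_censor_regress: bool = False
    welch: bool = False
    seed: int = 0

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(payload) - known)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {unknown}")
        return cls(**payload)
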