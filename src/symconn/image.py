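"""In-memory containers for functional runs, motion traces and metric maps."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .grid import SymmetricGrid

__all__ = ["FuncImage", "MotionTrace", "MetricMap"]


@dataclass
class FuncImage:
    """A 4-D functional run ``(x, y, z, t)`` on a symmetric grid.

    ``frame_mask`` marks frames retained for temporal statistics; motion
    censoring clears entries rather than deleting data, so frame indices
    stay aligned with the motion trace throughout the pipeline.
    """

    data: np.ndarray
    grid: SymmetricGrid
    tr_seconds: float
    frame_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4:
            raise ValueError(f"functional data must be 4-D (x,y,z,t), got {self.data.ndim}-D")
        if self.data.shape[:3] != self.grid.dims:
            raise ValueError(
                f"data grid {self.data.shape[:3]} does not match grid {self.grid.dims}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError("functional data contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValueError(f"tr_seconds must be positive, got {self.tr_seconds}")
        if self.frame_mask is None:
            self.frame_mask = np.ones(self.n_frames, dtype=bool)
        else:
            self.frame_mask = np.asarray(self.frame_mask, dtype=bool)
            if self.frame_mask.shape != (self.n_frames,):
                raise ValueError("frame_mask length does not match number of frames")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def n_retained(self) -> int:
        return int(self.frame_mask.sum())

    def retained_data(self) -> np.ndarray:
        """Data restricted to retained frames, shape ``(x, y, z, t_kept)``."""
        return self.data[..., self.frame_mask]

    def copy_with(self, **changes) -> "FuncImage":
        out = replace(self, **changes)
        return out


@dataclass
class MotionTrace:
    """Per-frame rigid-body motion parameters.

    Columns are three translations in mm followed by three rotations in
    degrees (the common realignment-file dialect).  Framewise displacement
    is derived from backward differences, rotations converted to arc length
    on a 50 mm sphere.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=np.float64)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion parameters must be (t, 6): 3 translations mm + 3 rotations deg, "
                f"got shape {self.params.shape}"
            )

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def translations_mm(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def rotations_deg(self) -> np.ndarray:
        return self.params[:, 3:]

    def drop_initial(self, n: int) -> "MotionTrace":
        if n >= self.n_frames:
            raise ValueError(f"cannot drop {n} of {self.n_frames} motion frames")
        return MotionTrace(self.params[n:])


@dataclass
class MetricMap:
    """A subject-level 3-D scalar map (EC or Fisher-z VMHC) on a grid.

    Out-of-mask and undefined voxels (e.g. midplane voxels in VMHC) are NaN.
    """

    values: np.ndarray
    mask: np.ndarray
    grid: SymmetricGrid
    metric: str  # "EC" or "VMHC_Z"
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.dims:
            raise ValueError(f"map shape {self.values.shape} does not match grid {self.grid.dims}")
        if self.mask.shape != self.grid.dims:
            raise ValueError(f"mask shape {self.mask.shape} does not match grid {self.grid.dims}")
        if self.metric not in ("EC", "VMHC_Z"):
            raise ValueError(f"metric must be 'EC' or 'VMHC_Z', got {self.metric!r}")

    def in_mask_values(self) -> np.ndarray:
        """Finite in-mask values as a flat vector."""
        vals = self.values[self.mask]
        return vals[np.isfinite(vals)]
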