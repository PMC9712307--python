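"""Left-right symmetric voxel grids.

Homotopic (mirrored) analyses require a grid on which reflecting a voxel
across the midsagittal plane lands on another voxel of the same grid.  Here
the left-right axis is fixed to the first array axis and mirroring is pure
index arithmetic: ``i -> Nx - 1 - i``.  With an even first dimension every
voxel has a distinct mirror partner; with an odd first dimension the
midplane slice maps onto itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SymmetricGrid", "make_symmetric_grid"]

#: index of the left-right axis (fixed by convention)
LR_AXIS = 0


@dataclass(frozen=True)
class SymmetricGrid:
    """A 3-D voxel grid that is mirror-symmetric along its first axis.

    Parameters
    ----------
    dims:
        Grid shape ``(Nx, Ny, Nz)``; the first axis is left-right.
    voxel_size_mm:
        Physical voxel edge lengths in millimetres.
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0)
    lr_axis: int = field(default=LR_AXIS, init=False)

    def __post_init__(self) -> None:
        if len(self.dims) != 3:
            raise ValueError(f"dims must be a triple, got {self.dims!r}")
        if any(int(d) < 1 for d in self.dims):
            raise ValueError(f"all grid dimensions must be >= 1, got {self.dims}")
        if any(s <= 0 for s in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    def mirror(self, index: tuple[int, int, int]) -> tuple[int, int, int]:
        """Mirror a voxel index across the midsagittal plane."""
        i, j, k = index
        nx = self.dims[0]
        if not (0 <= i < nx and 0 <= j < self.dims[1] and 0 <= k < self.dims[2]):
            raise IndexError(f"index {index} outside grid {self.dims}")
        return (nx - 1 - i, j, k)

    def mirror_array(self, vol: np.ndarray) -> np.ndarray:
        """Return ``vol`` reflected along the left-right axis."""
        if vol.shape[:3] != self.dims:
            raise ValueError(f"volume shape {vol.shape[:3]} does not match grid {self.dims}")
        return np.flip(vol, axis=self.lr_axis)

    def is_midplane(self, index: tuple[int, int, int]) -> bool:
        """True when the voxel is its own mirror image (odd Nx midplane)."""
        return self.mirror(index)[0] == index[0]

    def midplane_mask(self) -> np.ndarray:
        """Boolean volume marking self-mirroring voxels (empty for even Nx)."""
        mask = np.zeros(self.dims, dtype=bool)
        nx = self.dims[0]
        if nx % 2 == 1:
            mask[nx // 2] = True
        return mask


def make_symmetric_grid(
    dims: tuple[int, int, int],
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 4.0),
) -> SymmetricGrid:
    """Build a :class:`SymmetricGrid`, validating dimensions."""
    return SymmetricGrid(tuple(dims), tuple(voxel_size_mm))
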