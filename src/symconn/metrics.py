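"""Subject-level connectivity maps: eigenvector centrality and VMHC.

Eigenvector centrality (EC) scores each voxel by its entry in the Perron
eigenvector of a similarity matrix derived from the voxel-by-voxel Pearson
correlation matrix R (the leading solution of R v = lambda v after a
nonnegativity shift).  The default similarity S = (R + J)/2 maps
correlations into [0, 1], so by Perron-Frobenius the leading eigenvector is
unique and positive.  S is never materialized: with M the standardized
frames-by-voxels data matrix, S v = M^T (M v) / (2 (T - 1)) + sum(v)/2,
so power iteration costs O(T N) per step ("fast ECM").

Voxel-mirrored homotopic connectivity (VMHC) is the Pearson correlation of
each voxel's series with its left-right mirrored counterpart, Fisher
z-transformed: z = 1/2 ln((1 + r) / (1 - r)).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .grid import SymmetricGrid
from .image import FuncImage, MetricMap

__all__ = [
    "fisher_z",
    "eigenvector_centrality",
    "vmhc",
    "network_average",
    "ECConvergence",
]

logger = logging.getLogger(__name__)

MIN_RETAINED_FRAMES = 10
#: correlations are clipped to +-(1 - CLIP_EPS) before the Fisher transform
CLIP_EPS = 1e-7


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = arctanh(r) = 1/2 ln((1+r)/(1-r))."""
    r = np.asarray(r, dtype=np.float64)
    if np.any(np.abs(r) >= 1):
        raise ValueError("fisher_z requires |r| < 1; clip correlations first")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


@dataclass
class ECConvergence:
    """Power-iteration diagnostics attached to an EC map."""

    iterations: int
    final_delta: float
    eigenvalue: float


def _standardized_matrix(img: FuncImage, mask: np.ndarray) -> np.ndarray:
    """Frames-by-voxels matrix, columns zero-mean and unit-variance (ddof=1)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != img.grid.dims:
        raise ValueError(f"mask shape {mask.shape} does not match grid {img.grid.dims}")
    X = img.retained_data()[mask]  # voxels x frames
    T = X.shape[1]
    if T < MIN_RETAINED_FRAMES:
        raise ValueError(f"need >= {MIN_RETAINED_FRAMES} retained frames, have {T}")
    M = X.T - X.mean(axis=1)
    sd = M.std(axis=0, ddof=1)
    zero = sd == 0
    if zero.any():
        idx = np.argwhere(mask)[zero]
        raise ValueError(
            f"{zero.sum()} in-mask voxel(s) with zero temporal variance, e.g. at "
            f"{[tuple(i) for i in idx[:5]]}"
        )
    return M / sd


def _dense_similarity(M: np.ndarray, shift: str) -> np.ndarray:
    T = M.shape[0]
    R = (M.T @ M) / (T - 1)
    if shift == "add-one-half":
        return (R + 1.0) / 2.0
    if shift == "abs":
        return np.abs(R)
    if shift == "pos-part":
        return np.clip(R, 0.0, None)
    raise ValueError(f"unknown shift {shift!r}; expected add-one-half, abs or pos-part")


def eigenvector_centrality(
    img: FuncImage,
    mask: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 1000,
    shift: str = "add-one-half",
    subject_id: str = "",
) -> MetricMap:
    """Voxel-wise eigenvector centrality over the analysis mask.

    Power iteration starts from the uniform positive vector and stops when
    successive normalized iterates differ by less than ``tol`` in Euclidean
    norm.  The returned in-mask vector has unit Euclidean norm.  The default
    ``add-one-half`` shift runs matrix-free; the ``abs`` and ``pos-part``
    variants materialize the dense correlation matrix.
    """
    mask = np.asarray(mask, dtype=bool)
    n = int(mask.sum())
    if n < 2:
        raise ValueError(f"need >= 2 in-mask voxels, have {n}")
    M = _standardized_matrix(img, mask)
    T = M.shape[0]

    if shift == "add-one-half":
        def matvec(v):
            return (M.T @ (M @ v)) / (2.0 * (T - 1)) + v.sum() / 2.0
    else:
        S = _dense_similarity(M, shift)
        def matvec(v):
            return S @ v

    v = np.full(n, 1.0 / np.sqrt(n))
    delta = np.inf
    lam = 0.0
    for it in range(1, max_iter + 1):
        w = matvec(v)
        lam = float(v @ w)  # Rayleigh quotient (v is unit norm)
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("similarity matrix annihilated the iterate; cannot normalize")
        w /= nw
        delta = float(np.linalg.norm(w - v))
        v = w
        if delta < tol:
            break
    else:
        raise RuntimeError(
            f"eigenvector centrality did not converge in {max_iter} iterations "
            f"(final delta {delta:.3e})"
        )
    logger.debug("EC converged in %d iterations (delta %.2e, lambda %.4f)", it, delta, lam)

    values = np.full(img.grid.dims, np.nan)
    values[mask] = v
    out = MetricMap(values=values, mask=mask, grid=img.grid, metric="EC", subject_id=subject_id)
    out.convergence = ECConvergence(iterations=it, final_delta=delta, eigenvalue=lam)
    return out


def vmhc(img: FuncImage, mask: np.ndarray, subject_id: str = "") -> MetricMap:
    """Voxel-mirrored homotopic connectivity, Fisher z-transformed.

    A voxel gets a value only when both it and its mirror are in-mask;
    midplane voxels (odd first dimension) and voxels whose mirror falls
    outside the mask are NaN.  The map is mirror-symmetric by construction.
    """
    grid: SymmetricGrid = img.grid
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.dims:
        raise ValueError(f"mask shape {mask.shape} does not match grid {grid.dims}")
    paired = mask & grid.mirror_array(mask) & ~grid.midplane_mask()
    if not paired.any():
        raise ValueError("no voxel has an in-mask mirrored counterpart")

    data = img.retained_data()
    T = data.shape[3]
    if T < MIN_RETAINED_FRAMES:
        raise ValueError(f"need >= {MIN_RETAINED_FRAMES} retained frames, have {T}")
    mirrored = grid.mirror_array(data)

    X = data[paired]
    Y = mirrored[paired]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.linalg.norm(Xc, axis=1) * np.linalg.norm(Yc, axis=1)
    if np.any(denom == 0):
        raise ValueError("zero-variance voxel in a homotopic pair")
    r = np.einsum("ij,ij->i", Xc, Yc) / denom
    r = np.clip(r, -1.0 + CLIP_EPS, 1.0 - CLIP_EPS)
    z = np.arctanh(r)

    values = np.full(grid.dims, np.nan)
    values[paired] = z
    return MetricMap(values=values, mask=mask, grid=grid, metric="VMHC_Z", subject_id=subject_id)


def network_average(metric_map: MetricMap, atlas: dict[str, np.ndarray]) -> dict[str, float]:
    """Mean in-mask, non-missing map value per named network.

    Returns NaN for a network with no finite overlapping voxel.  For EC
    maps a network mean of exactly 0 marks the subject for exclusion
    downstream (callers check :func:`flags_exclusion`).
    """
    out: dict[str, float] = {}
    for name, net_mask in atlas.items():
        net_mask = np.asarray(net_mask, dtype=bool)
        if net_mask.shape != metric_map.grid.dims:
            raise ValueError(
                f"network {name!r} mask shape {net_mask.shape} does not match grid "
                f"{metric_map.grid.dims}"
            )
        vals = metric_map.values[net_mask & metric_map.mask]
        vals = vals[np.isfinite(vals)]
        out[name] = float(vals.mean()) if vals.size else float("nan")
    return out


def flags_exclusion(ec_means: dict[str, float]) -> bool:
    """True when any network EC mean is 0 or undefined (subject excluded)."""
    return any((not np.isfinite(v)) or v == 0.0 for v in ec_means.values())
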