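"""Resting-state preprocessing chain.

Stages, in pipeline order: drop the initial non-steady-state frames, scale
every voxel series to a temporal mean of 100, zero-phase band-pass
(0.01-0.1 Hz), nuisance regression (6 rigid-body motion parameters, their
6 backward-difference derivatives, optional mean nuisance-compartment
series), framewise-displacement censoring at 0.5 mm, and motion quality
gates (censored fraction < 10 %, |translation| < 2 mm, |rotation| < 2 deg).

Scaling runs before the band-pass because the filter's stopband includes
DC: rescaling a zero-mean series to mean 100 would be ill-defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .image import FuncImage, MotionTrace

__all__ = [
    "QCReport",
    "drop_initial_frames",
    "bandpass",
    "scale_to_mean",
    "compute_fd",
    "censor_frames",
    "nuisance_regress",
    "motion_regressors",
    "erode_mask",
    "run_preprocess",
]

logger = logging.getLogger(__name__)

FD_ROTATION_RADIUS_MM = 50.0
FD_THRESHOLD_MM = 0.5
QC_MAX_CENSORED_FRACTION = 0.10
QC_MAX_TRANSLATION_MM = 2.0
QC_MAX_ROTATION_DEG = 2.0


@dataclass
class QCReport:
    """Motion quality-control summary for one run."""

    censored_fraction: float
    max_abs_translation_mm: float
    max_abs_rotation_deg: float
    passed: bool = field(init=False)
    reasons: list[str] = field(init=False)

    max_censored_fraction: float = QC_MAX_CENSORED_FRACTION
    max_translation_mm: float = QC_MAX_TRANSLATION_MM
    max_rotation_deg: float = QC_MAX_ROTATION_DEG

    def __post_init__(self) -> None:
        reasons = []
        if not self.censored_fraction < self.max_censored_fraction:
            reasons.append(
                f"censored timepoints >= {self.max_censored_fraction:.0%} "
                f"({self.censored_fraction:.1%})"
            )
        if not self.max_abs_translation_mm < self.max_translation_mm:
            reasons.append(
                f"translation >= {self.max_translation_mm} mm "
                f"({self.max_abs_translation_mm:.2f} mm)"
            )
        if not self.max_abs_rotation_deg < self.max_rotation_deg:
            reasons.append(
                f"rotation >= {self.max_rotation_deg} deg "
                f"({self.max_abs_rotation_deg:.2f} deg)"
            )
        self.reasons = reasons
        self.passed = not reasons

    def to_dict(self) -> dict:
        return {
            "censored_fraction": self.censored_fraction,
            "max_abs_translation_mm": self.max_abs_translation_mm,
            "max_abs_rotation_deg": self.max_abs_rotation_deg,
            "passed": self.passed,
            "reasons": self.reasons,
        }


def drop_initial_frames(img: FuncImage, n: int = 4) -> FuncImage:
    """Remove the first ``n`` frames (magnetization steady-state transient)."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    if img.n_frames <= n:
        raise ValueError(f"cannot drop {n} frames from a {img.n_frames}-frame run")
    return img.copy_with(data=img.data[..., n:], frame_mask=img.frame_mask[n:].copy())


def scale_to_mean(img: FuncImage, target: float = 100.0) -> FuncImage:
    """Scale every voxel series so its temporal mean equals ``target``.

    Voxels with exactly zero temporal mean cannot be rescaled; they are set
    to the constant ``target`` and a warning is logged.
    """
    means = img.data.mean(axis=3, keepdims=True)
    zero = means[..., 0] == 0
    out = np.empty_like(img.data)
    safe = np.where(zero[..., None], 1.0, means)
    np.divide(img.data, safe, out=out)
    out *= target
    if zero.any():
        logger.warning("scale_to_mean: %d zero-mean voxel(s) set to constant %g", zero.sum(), target)
        out[zero] = target
    return img.copy_with(data=out)


def _design_filter(low_hz: float, high_hz: float, tr_seconds: float):
    nyq = 1.0 / (2.0 * tr_seconds)
    if not (0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low < high, got low={low_hz}, high={high_hz}")
    if high_hz >= nyq:
        raise ValueError(f"high cutoff {high_hz} Hz >= Nyquist {nyq} Hz (TR {tr_seconds}s)")
    # order-2 sections -> order-4 band-pass overall; applied forward-backward
    return signal.butter(2, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")


def bandpass(img: FuncImage, low_hz: float = 0.01, high_hz: float = 0.1) -> FuncImage:
    """Zero-phase Butterworth band-pass of every voxel series."""
    sos = _design_filter(low_hz, high_hz, img.tr_seconds)
    filtered = signal.sosfiltfilt(sos, img.data, axis=3)
    return img.copy_with(data=np.ascontiguousarray(filtered))


def compute_fd(motion: MotionTrace, rotation_radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Framewise displacement: summed |backward differences|.

    Translations contribute in mm; rotations (stored in degrees) are
    converted to arc length at ``rotation_radius_mm``.  The first frame has
    FD 0 by convention.
    """
    if motion.n_frames < 2:
        raise ValueError("need at least 2 frames to compute framewise displacement")
    dtrans = np.abs(np.diff(motion.translations_mm, axis=0)).sum(axis=1)
    drot_rad = np.abs(np.diff(np.deg2rad(motion.rotations_deg), axis=0)).sum(axis=1)
    fd = np.concatenate([[0.0], dtrans + rotation_radius_mm * drot_rad])
    return fd


def censor_frames(img: FuncImage, fd: np.ndarray, threshold_mm: float = FD_THRESHOLD_MM) -> FuncImage:
    """Mark frames with FD strictly above ``threshold_mm`` as censored.

    Ties at the threshold are retained.  Already-censored frames stay
    censored (idempotent).
    """
    fd = np.asarray(fd, dtype=np.float64)
    if fd.shape != (img.n_frames,):
        raise ValueError(f"FD length {fd.shape} does not match {img.n_frames} frames")
    keep = img.frame_mask & ~(fd > threshold_mm)
    if not keep.any():
        raise ValueError("all frames censored: framewise displacement exceeds threshold everywhere")
    return img.copy_with(data=img.data.copy(), frame_mask=keep)


def motion_regressors(motion: MotionTrace) -> np.ndarray:
    """6 motion parameters + 6 backward-difference derivatives (first row 0)."""
    p = motion.params
    d = np.vstack([np.zeros((1, 6)), np.diff(p, axis=0)])
    return np.hstack([p, d])


def erode_mask(mask: np.ndarray) -> np.ndarray:
    """One-voxel 6-neighbour (face-connectivity) morphological erosion."""
    structure = ndimage.generate_binary_structure(3, 1)
    return ndimage.binary_erosion(np.asarray(mask, dtype=bool), structure=structure)


def nuisance_regress(img: FuncImage, regressors: np.ndarray) -> FuncImage:
    """Per-voxel OLS residualization against nuisance regressors.

    An intercept column is always included.  Rows of ``regressors`` must be
    aligned to the image's retained frames; censored frames pass through
    unchanged (they are excluded from all temporal statistics anyway).
    """
    keep = img.frame_mask
    reg = np.asarray(regressors, dtype=np.float64)
    if reg.ndim != 2:
        raise ValueError("regressors must be a 2-D (frames x k) matrix")
    if reg.shape[0] == img.n_frames:
        reg = reg[keep]
    elif reg.shape[0] != int(keep.sum()):
        raise ValueError(
            f"regressor rows ({reg.shape[0]}) match neither total frames "
            f"({img.n_frames}) nor retained frames ({int(keep.sum())})"
        )
    X = np.hstack([np.ones((reg.shape[0], 1)), reg])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = _collinear_columns(X)
        raise ValueError(
            f"rank-deficient nuisance design (rank {rank} < {X.shape[1]}); "
            f"collinear columns (0 = intercept): {bad}"
        )
    Y = img.data[..., keep].reshape(-1, X.shape[0]).T  # frames x voxels
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    out = img.data.copy()
    out[..., keep] = resid.T.reshape(*img.grid.dims, X.shape[0])
    return img.copy_with(data=out)


def _collinear_columns(X: np.ndarray) -> list[int]:
    """Greedy scan for columns linearly dependent on their predecessors."""
    bad = []
    cols: list[np.ndarray] = []
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(j)
        else:
            cols.append(X[:, j])
    return bad


@dataclass
class PreprocessConfig:
    """Knobs of the preprocessing chain; defaults follow the study protocol."""

    drop_n: int = 4
    band_low_hz: float = 0.01
    band_high_hz: float = 0.1
    scale_target: float = 100.0
    fd_threshold_mm: float = FD_THRESHOLD_MM
    fd_rotation_radius_mm: float = FD_ROTATION_RADIUS_MM
    qc_max_censored_fraction: float = QC_MAX_CENSORED_FRACTION
    qc_max_translation_mm: float = QC_MAX_TRANSLATION_MM
    qc_max_rotation_deg: float = QC_MAX_ROTATION_DEG
    simultaneous_censor_regress: bool = False
    nuisance_mask: np.ndarray | None = None
    erode_nuisance_mask: bool = True


def run_preprocess(
    img: FuncImage,
    motion: MotionTrace,
    config: PreprocessConfig | None = None,
) -> tuple[FuncImage, QCReport]:
    """Run the full chain and return the processed image plus its QC report.

    QC failure does not raise; the caller decides on exclusion.
    """
    cfg = config or PreprocessConfig()
    if motion.n_frames != img.n_frames:
        raise ValueError(
            f"motion trace ({motion.n_frames} frames) not aligned with image ({img.n_frames})"
        )
    out = drop_initial_frames(img, cfg.drop_n)
    mot = motion.drop_initial(cfg.drop_n)
    out = scale_to_mean(out, cfg.scale_target)
    out = bandpass(out, cfg.band_low_hz, cfg.band_high_hz)

    fd = compute_fd(mot, cfg.fd_rotation_radius_mm)
    reg = motion_regressors(mot)
    if cfg.nuisance_mask is not None:
        nmask = cfg.nuisance_mask
        if cfg.erode_nuisance_mask:
            eroded = erode_mask(nmask)
            nmask = eroded if eroded.any() else nmask
        comp = out.data[nmask].mean(axis=0)
        reg = np.hstack([reg, comp[:, None]])

    # constant regressors (e.g. a perfectly still axis) duplicate the intercept
    keep_cols = reg.std(axis=0) > 0
    reg = reg[:, keep_cols]

    if cfg.simultaneous_censor_regress:
        out = censor_frames(out, fd, cfg.fd_threshold_mm)
        out = nuisance_regress(out, reg[out.frame_mask])
    else:
        out = nuisance_regress(out, reg)
        out = censor_frames(out, fd, cfg.fd_threshold_mm)

    censored_fraction = 1.0 - out.frame_mask.mean()
    report = QCReport(
        censored_fraction=float(censored_fraction),
        max_abs_translation_mm=float(np.abs(mot.translations_mm).max()),
        max_abs_rotation_deg=float(np.abs(mot.rotations_deg).max()),
        max_censored_fraction=cfg.qc_max_censored_fraction,
        max_translation_mm=cfg.qc_max_translation_mm,
        max_rotation_deg=cfg.qc_max_rotation_deg,
    )
    if not report.passed:
        logger.info("QC failed: %s", "; ".join(report.reasons))
    return out, report
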