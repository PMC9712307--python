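"""Group-level statistics: voxel-wise covariate-adjusted t-maps with FDR and
cluster-extent thresholding, network-level Student t-tests with Hedges' g,
Spearman correlation screens, and the motion control comparison.

Sign convention throughout: group contrasts are TYP minus ADHD, so a
negative t (or g) means the quantity is higher in the ADHD group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from statsmodels.stats.multitest import multipletests

from .image import MetricMap

__all__ = [
    "GroupStatMap",
    "Cluster",
    "voxelwise_group_test",
    "fdr_correct",
    "extract_clusters",
    "hedges_g",
    "network_group_test",
    "spearman_screen",
    "motion_control",
]

GROUP_ORDER = ("TYP", "ADHD")
SIGNIFICANCE_P = 0.01
TREND_P = 0.05
FDR_Q = 0.05
MIN_CLUSTER_VOXELS = 30
DEFAULT_NN_LEVEL = 3


@dataclass(frozen=True)
class Cluster:
    label: int
    size_voxels: int
    peak_index: tuple[int, int, int]
    peak_t: float


@dataclass
class GroupStatMap:
    """Voxel-wise group-difference maps (t, p, BH-adjusted q) plus clusters."""

    t_map: np.ndarray
    p_map: np.ndarray
    q_map: np.ndarray
    mask: np.ndarray
    df: int
    clusters: list[Cluster] = field(default_factory=list)


def _stack_maps(maps: list[MetricMap]) -> tuple[np.ndarray, np.ndarray]:
    """Common finite-valued mask and (subjects x voxels) value matrix."""
    mask = maps[0].mask.copy()
    for m in maps:
        if m.mask.shape != mask.shape:
            raise ValueError("metric maps are not on a common grid")
        mask &= np.isfinite(m.values)
    data = np.stack([m.values[mask] for m in maps])
    return mask, data


def voxelwise_group_test(
    maps: list[MetricMap],
    groups: list[str],
    covariates: pd.DataFrame | None = None,
    fdr_q: float = FDR_Q,
    min_cluster: int = MIN_CLUSTER_VOXELS,
    nn_level: int = DEFAULT_NN_LEVEL,
) -> GroupStatMap:
    """Per-voxel OLS of metric ~ group + centered covariates.

    The group regressor is 1 for TYP, 0 for ADHD, so the group coefficient
    (and its t) is the TYP - ADHD difference.  Covariates are centered at
    the grand mean; the group t uses n - k - 2 degrees of freedom.  Voxels
    with q < ``fdr_q`` are clustered at ``nn_level`` adjacency and clusters
    below ``min_cluster`` voxels discarded.
    """
    groups = list(groups)
    if len(maps) != len(groups):
        raise ValueError("one group label per map required")
    for g in groups:
        if g not in GROUP_ORDER:
            raise ValueError(f"unknown group label {g!r}")
    n = len(maps)
    counts = {g: groups.count(g) for g in GROUP_ORDER}
    if min(counts.values()) < 3:
        raise ValueError(f"need >= 3 subjects per group, have {counts}")

    mask, Y = _stack_maps(maps)
    indicator = np.array([1.0 if g == "TYP" else 0.0 for g in groups])
    X_cols = [np.ones(n), indicator]
    names = ["intercept", "group"]
    if covariates is not None:
        if len(covariates) != n:
            raise ValueError("covariate table length does not match number of maps")
        if covariates.isna().any().any():
            missing = covariates.index[covariates.isna().any(axis=1)].tolist()
            raise ValueError(f"missing covariate values for subjects {missing}")
        for col in covariates.columns:
            v = covariates[col].to_numpy(dtype=np.float64)
            X_cols.append(v - v.mean())
            names.append(str(col))
    X = np.column_stack(X_cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = [names[j] for j in _dependent_columns(X)]
        raise ValueError(f"collinear design columns: {bad}")

    k = X.shape[1] - 2  # number of covariates
    df = n - k - 2
    if df < 1:
        raise ValueError(f"non-positive degrees of freedom ({df})")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.clip(sigma2 * XtX_inv[1, 1], 1e-300, None))
    t = beta[1] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    q = fdr_correct(p)

    t_map = np.full(mask.shape, np.nan)
    p_map = np.full(mask.shape, np.nan)
    q_map = np.full(mask.shape, np.nan)
    t_map[mask], p_map[mask], q_map[mask] = t, p, q

    sig = np.zeros(mask.shape, dtype=bool)
    sig[mask] = q < fdr_q
    clusters = extract_clusters(sig, nn_level=nn_level, min_size=min_cluster, stat_map=t_map)
    return GroupStatMap(t_map=t_map, p_map=p_map, q_map=q_map, mask=mask, df=df, clusters=clusters)


def _dependent_columns(X: np.ndarray) -> list[int]:
    bad, cols = [], []
    for j in range(X.shape[1]):
        trial = np.column_stack(cols + [X[:, j]]) if cols else X[:, [j]]
        if np.linalg.matrix_rank(trial) < trial.shape[1]:
            bad.append(j)
        else:
            cols.append(X[:, j])
    return bad


def fdr_correct(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone q-values)."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    return q.reshape(p.shape)


def extract_clusters(
    binary_map: np.ndarray,
    nn_level: int = DEFAULT_NN_LEVEL,
    min_size: int = MIN_CLUSTER_VOXELS,
    stat_map: np.ndarray | None = None,
) -> list[Cluster]:
    """Connected components of a 3-D boolean map.

    ``nn_level`` 1/2/3 uses face (6), face+edge (18) or face+edge+corner
    (26) adjacency.  Components smaller than ``min_size`` are discarded;
    the rest are labeled 1.. in order of descending size, ties broken by
    ascending peak linear index.  The peak is the in-cluster maximum of
    |stat| (or the lowest linear index when no ``stat_map`` is given).
    """
    binary_map = np.asarray(binary_map)
    if binary_map.ndim != 3 or binary_map.dtype != bool:
        raise ValueError("binary_map must be a 3-D boolean array")
    if nn_level not in (1, 2, 3):
        raise ValueError(f"nn_level must be 1, 2 or 3, got {nn_level}")
    structure = ndimage.generate_binary_structure(3, nn_level)
    labels, n_comp = ndimage.label(binary_map, structure=structure)

    raw: list[Cluster] = []
    for lab in range(1, n_comp + 1):
        idx = np.argwhere(labels == lab)
        size = len(idx)
        if size < min_size:
            continue
        lin = np.ravel_multi_index(idx.T, binary_map.shape)
        if stat_map is not None:
            vals = np.abs(stat_map[tuple(idx.T)])
            vals = np.where(np.isfinite(vals), vals, -np.inf)
            best = np.lexsort((lin, -vals))[0]  # max |t|, tie -> lowest linear index
        else:
            best = int(np.argmin(lin))
        peak = tuple(int(c) for c in idx[best])
        peak_t = float(stat_map[peak]) if stat_map is not None else float("nan")
        raw.append(Cluster(label=0, size_voxels=size, peak_index=peak, peak_t=peak_t))

    raw.sort(key=lambda c: (-c.size_voxels, np.ravel_multi_index(c.peak_index, binary_map.shape)))
    return [Cluster(i + 1, c.size_voxels, c.peak_index, c.peak_t) for i, c in enumerate(raw)]


def hedges_g(x: np.ndarray, y: np.ndarray) -> float:
    """Hedges' g (small-sample corrected standardized mean difference x - y)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise ValueError("need >= 2 observations per group")
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled variance: effect size undefined")
    J = 1.0 - 3.0 / (4.0 * (n1 + n2) - 9.0)
    return float(J * (x.mean() - y.mean()) / np.sqrt(sp2))


def _student_t_row(x: np.ndarray, y: np.ndarray, welch: bool = False) -> dict:
    g = hedges_g(x, y)  # raises first on zero pooled variance
    t, p = stats.ttest_ind(x, y, equal_var=not welch)
    return {"t_statistic": float(t), "p_value": float(p), "hedges_g": g}


def network_group_test(
    summary: pd.DataFrame,
    groups: pd.Series | list[str],
    welch: bool = False,
) -> pd.DataFrame:
    """Per-column Student t-test (TYP - ADHD) with Hedges' g.

    ``summary`` is subjects x measures (network-metric columns, optionally a
    mean-FD column); returns one row per column with t, p and g.
    """
    groups = pd.Series(list(groups), index=summary.index)
    typ = summary[groups == "TYP"]
    adhd = summary[groups == "ADHD"]
    if len(typ) < 2 or len(adhd) < 2:
        raise ValueError("need >= 2 subjects per group")
    rows = []
    for col in summary.columns:
        x = typ[col].to_numpy(dtype=np.float64)
        y = adhd[col].to_numpy(dtype=np.float64)
        row = {"measure": col, **_student_t_row(x, y, welch=welch)}
        rows.append(row)
    out = pd.DataFrame(rows).set_index("measure")
    out["significant"] = out["p_value"] < TREND_P
    return out


def _band(p: float) -> str:
    if p < SIGNIFICANCE_P:
        return "significant"
    if p < TREND_P:
        return "trend"
    return "ns"


def spearman_screen(
    summary: pd.DataFrame,
    covariates: pd.DataFrame,
    groups: pd.Series | list[str] | None = None,
) -> pd.DataFrame:
    """Spearman rho of every summary column against every covariate.

    Run on the full sample and, when ``groups`` is given, on the TYP and
    ADHD subsets separately.  p-values use the t-approximation with n - 2
    degrees of freedom (average ranks for ties); bands follow the
    0.01 (significant) / 0.05 (trend) rule.  Constant inputs give a missing
    rho with a reason.
    """
    cohorts: dict[str, pd.Index] = {"overall": summary.index}
    if groups is not None:
        groups = pd.Series(list(groups), index=summary.index)
        for g in GROUP_ORDER:
            cohorts[g] = summary.index[groups == g]
    rows = []
    for cohort, idx in cohorts.items():
        if len(idx) < 5:
            raise ValueError(f"cohort {cohort!r} has fewer than 5 subjects")
        for cov in covariates.columns:
            cv = covariates.loc[idx, cov].to_numpy(dtype=np.float64)
            for col in summary.columns:
                sv = summary.loc[idx, col].to_numpy(dtype=np.float64)
                if np.all(cv == cv[0]) or np.all(sv == sv[0]):
                    rows.append(
                        dict(cohort=cohort, covariate=cov, measure=col,
                             spearman_rho=np.nan, p_value=np.nan, band="missing",
                             reason="constant input")
                    )
                    continue
                rho, p = stats.spearmanr(cv, sv)
                rows.append(
                    dict(cohort=cohort, covariate=cov, measure=col,
                         spearman_rho=float(rho), p_value=float(p),
                         band=_band(float(p)), reason="")
                )
    return pd.DataFrame(rows)


def motion_control(fd_means: pd.Series | np.ndarray, groups) -> dict:
    """Group comparison of per-run mean framewise displacement."""
    fd = pd.Series(np.asarray(fd_means, dtype=np.float64))
    groups = pd.Series(list(groups))
    x = fd[groups.values == "TYP"].to_numpy()
    y = fd[groups.values == "ADHD"].to_numpy()
    return _student_t_row(x, y)
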