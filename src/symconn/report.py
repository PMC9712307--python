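"""End-to-end cohort analysis: preprocessing, subject maps, exclusions,
group statistics and report files.

Mirrors the study's reporting structure: voxel-wise t/q maps with cluster
tables for EC and VMHC, a network-level test table (15 networks x 2 metrics
plus mean FD), Spearman screens of network summaries against age, severity,
IQ and handedness for the overall sample and each group, and a motion
control comparison.  Subjects failing motion QC, or with a zero network EC
mean, are excluded and counted.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import groupstats as gs
from .image import FuncImage, MetricMap, MotionTrace
from .io import (
    RunConfig,
    read_atlas,
    read_mask,
    read_motion,
    read_phenotype,
    read_func,
    write_metric_map,
    write_qc_report,
)
from .metrics import eigenvector_centrality, flags_exclusion, network_average, vmhc
from .preprocess import PreprocessConfig, compute_fd, run_preprocess

__all__ = ["CohortResult", "analyze_cohort", "end_to_end_report"]

logger = logging.getLogger(__name__)

VOXELWISE_COVARIATES = ("age_years", "sex_male", "full_iq", "verbal_iq", "performance_iq", "handedness")
SCREEN_COVARIATES = (
    "age_years",
    "adhd_index",
    "inattentive",
    "hyper_impulsive",
    "full_iq",
    "verbal_iq",
    "performance_iq",
    "handedness",
)


@dataclass
class CohortResult:
    """Everything the cohort analysis computes, in memory."""

    network_summary: pd.DataFrame  # subjects x (network_METRIC columns + mean_fd)
    network_tests: pd.DataFrame
    correlations: pd.DataFrame
    voxelwise: dict[str, gs.GroupStatMap]
    motion: dict
    qc_reports: dict[str, object]
    excluded: pd.DataFrame
    included_groups: pd.Series = field(default=None)  # type: ignore[assignment]
    ec_maps: dict[str, MetricMap] = field(default_factory=dict)
    vmhc_maps: dict[str, MetricMap] = field(default_factory=dict)


def _preprocess_config(cfg: RunConfig) -> PreprocessConfig:
    return PreprocessConfig(
        drop_n=cfg.drop_n,
        band_low_hz=cfg.band_low_hz,
        band_high_hz=cfg.band_high_hz,
        scale_target=cfg.scale_target,
        fd_threshold_mm=cfg.fd_threshold_mm,
        fd_rotation_radius_mm=cfg.fd_rotation_radius_mm,
        qc_max_censored_fraction=cfg.qc_max_censored_fraction,
        qc_max_translation_mm=cfg.qc_max_translation_mm,
        qc_max_rotation_deg=cfg.qc_max_rotation_deg,
        simultaneous_censor_regress=cfg.simultaneous_censor_regress,
    )


def analyze_cohort(
    subjects,
    phenotype: pd.DataFrame,
    atlas: dict[str, np.ndarray],
    config: RunConfig | None = None,
    mask: np.ndarray | None = None,
) -> CohortResult:
    """Run the full analysis on an iterable of (subject_id, image, motion).

    ``mask`` is the whole-brain analysis mask the voxel-wise metrics run
    over; by default the whole grid (networks are subsets of it).
    Exclusion rules: motion QC failure (censored fraction, translation,
    rotation gates) and any network with a zero or undefined EC mean.
    """
    cfg = config or RunConfig()
    pcfg = _preprocess_config(cfg)
    pheno = phenotype.set_index("subject_id")

    if mask is None:
        mask = np.ones(next(iter(atlas.values())).shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)

    rows_summary: list[dict] = []
    excluded: list[dict] = []
    qc_reports: dict[str, object] = {}
    ec_maps: dict[str, MetricMap] = {}
    vmhc_maps: dict[str, MetricMap] = {}

    for subject_id, img, motion in subjects:
        processed, qc = run_preprocess(img, motion, pcfg)
        qc_reports[subject_id] = qc
        if not qc.passed:
            excluded.append({"subject_id": subject_id, "reason": "; ".join(qc.reasons)})
            logger.info("excluding %s: %s", subject_id, "; ".join(qc.reasons))
            continue
        ec_map = eigenvector_centrality(
            processed, mask, tol=cfg.ec_tol, max_iter=cfg.ec_max_iter,
            shift=cfg.ec_shift, subject_id=subject_id,
        )
        vmhc_map = vmhc(processed, mask, subject_id=subject_id)
        ec_means = network_average(ec_map, atlas)
        if flags_exclusion(ec_means):
            excluded.append({"subject_id": subject_id, "reason": "zero network EC"})
            logger.info("excluding %s: zero network EC", subject_id)
            continue
        vmhc_means = network_average(vmhc_map, atlas)
        mot = motion.drop_initial(cfg.drop_n)
        fd = compute_fd(mot, cfg.fd_rotation_radius_mm)
        row = {"subject_id": subject_id, "mean_fd": float(fd.mean())}
        row.update({f"{name}_EC": v for name, v in ec_means.items()})
        row.update({f"{name}_VMHC": v for name, v in vmhc_means.items()})
        rows_summary.append(row)
        ec_maps[subject_id] = ec_map
        vmhc_maps[subject_id] = vmhc_map

    if not rows_summary:
        raise ValueError("no subject survived QC and exclusion rules")
    summary = pd.DataFrame(rows_summary).set_index("subject_id")
    logger.info(
        "included %d subjects, excluded %d (QC: %d, zero EC: %d)",
        len(summary), len(excluded),
        sum(1 for e in excluded if e["reason"] != "zero network EC"),
        sum(1 for e in excluded if e["reason"] == "zero network EC"),
    )

    groups = pheno.loc[summary.index, "group"]

    # voxel-wise covariate-adjusted group tests, one per metric
    cov = pheno.loc[summary.index, ["age_years", "full_iq", "verbal_iq",
                                    "performance_iq", "handedness"]].copy()
    cov["sex_male"] = (pheno.loc[summary.index, "sex"] == "M").astype(float)
    cov = cov[list(VOXELWISE_COVARIATES)]
    voxelwise = {}
    for metric, maps in (("EC", ec_maps), ("VMHC", vmhc_maps)):
        voxelwise[metric] = gs.voxelwise_group_test(
            [maps[s] for s in summary.index], list(groups), covariates=cov,
            fdr_q=cfg.fdr_q, min_cluster=cfg.min_cluster_voxels, nn_level=cfg.nn_level,
        )

    metric_cols = [c for c in summary.columns if c != "mean_fd"]
    tests = gs.network_group_test(summary[metric_cols + ["mean_fd"]], groups, welch=cfg.welch)
    tests = tests.rename(index={"mean_fd": "Mean FD"})

    screens = gs.spearman_screen(
        summary[metric_cols],
        pheno.loc[summary.index, list(SCREEN_COVARIATES)],
        groups=groups,
    )
    motion_row = gs.motion_control(summary["mean_fd"], groups)

    return CohortResult(
        network_summary=summary,
        network_tests=tests,
        correlations=screens,
        voxelwise=voxelwise,
        motion=motion_row,
        qc_reports=qc_reports,
        excluded=pd.DataFrame(excluded, columns=["subject_id", "reason"]),
        included_groups=groups,
        ec_maps=ec_maps,
        vmhc_maps=vmhc_maps,
    )


def _write_cluster_table(clusters, path: Path) -> None:
    rows = [
        {
            "label": c.label,
            "size_voxels": c.size_voxels,
            "peak_i": c.peak_index[0],
            "peak_j": c.peak_index[1],
            "peak_k": c.peak_index[2],
            "peak_t": c.peak_t,
        }
        for c in clusters
    ]
    pd.DataFrame(rows, columns=["label", "size_voxels", "peak_i", "peak_j", "peak_k", "peak_t"]).to_csv(
        path, sep="\t", index=False, float_format="%.6f"
    )


def _heatmap(corr: pd.DataFrame, title: str, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(corr.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(corr.columns)), corr.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(len(corr.index)), corr.index, fontsize=6)
    ax.set_title(title)
    fig.colorbar(im, ax=ax, label="Spearman rho")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "symconn"})
    plt.close(fig)


def _violin_fd(summary: pd.DataFrame, groups: pd.Series, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    data = [summary.loc[groups == g, "mean_fd"].to_numpy() for g in gs.GROUP_ORDER]
    parts = ax.violinplot(data, showextrema=False, quantiles=[[0.25, 0.5, 0.75]] * 2)
    del parts
    rng = np.random.default_rng(0)  # jitter only; cosmetic
    for i, vals in enumerate(data, start=1):
        ax.scatter(i + rng.uniform(-0.06, 0.06, len(vals)), vals, s=4, color="k", alpha=0.5)
    ax.set_xticks([1, 2], list(gs.GROUP_ORDER))
    ax.set_ylabel("mean FD (mm)")
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": "symconn"})
    plt.close(fig)


def end_to_end_report(dataset_dir: str | Path, out_dir: str | Path,
                      config: RunConfig | None = None) -> CohortResult:
    """Analyze a simulated dataset directory and write the report bundle.

    Expects the layout written by the ``simulate`` command: ``phenotype.tsv``,
    ``atlas/``, and one ``<subject_id>/`` directory per subject containing
    ``func.nii`` and ``motion.txt``.
    """
    dataset_dir = Path(dataset_dir)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config or RunConfig()

    phenotype = read_phenotype(dataset_dir / "phenotype.tsv")
    grid, atlas = read_atlas(dataset_dir / "atlas")
    mask_path = dataset_dir / "mask.nii"
    mask = read_mask(mask_path, grid) if mask_path.exists() else None

    def subject_stream():
        for sid in phenotype["subject_id"]:
            img = read_func(dataset_dir / sid / "func.nii")
            motion = read_motion(dataset_dir / sid / "motion.txt")
            yield sid, img, motion

    result = analyze_cohort(subject_stream(), phenotype, atlas, cfg, mask=mask)

    (out_dir / "qc").mkdir(exist_ok=True)
    for sid, qc in result.qc_reports.items():
        write_qc_report(qc, out_dir / "qc" / f"{sid}.json")
    result.excluded.to_csv(out_dir / "exclusions.tsv", sep="\t", index=False)
    result.network_summary.to_csv(out_dir / "network_summary.tsv", sep="\t", float_format="%.8f")
    result.network_tests.to_csv(out_dir / "network_tests.tsv", sep="\t", float_format="%.6f")
    result.correlations.to_csv(out_dir / "correlations.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out_dir / "motion_control.json", "w") as fh:
        json.dump({k: round(v, 6) for k, v in result.motion.items()}, fh, indent=2)

    (out_dir / "maps").mkdir(exist_ok=True)
    for metric, stat in result.voxelwise.items():
        for kind in ("t", "p", "q"):
            write_metric_map(getattr(stat, f"{kind}_map"), grid,
                             out_dir / "maps" / f"group_{metric}_{kind}.nii")
        _write_cluster_table(stat.clusters, out_dir / f"clusters_{metric}.tsv")

    for metric in ("EC", "VMHC"):
        cols = [c for c in result.network_summary.columns if c.endswith(f"_{metric}")]
        sub = result.correlations[
            (result.correlations["cohort"] == "overall")
            & (result.correlations["measure"].isin(cols))
        ]
        corr = sub.pivot(index="measure", columns="covariate", values="spearman_rho")
        corr = corr.reindex(index=cols, columns=list(SCREEN_COVARIATES))
        _heatmap(corr, f"{metric} network correlations (overall)", out_dir / f"heatmap_{metric}.png")
    _violin_fd(result.network_summary, result.included_groups, out_dir / "violin_fd.png")

    counts = {
        "n_input": int(len(phenotype)),
        "n_included": int(len(result.network_summary)),
        "n_excluded_qc": int((result.excluded["reason"] != "zero network EC").sum()),
        "n_excluded_zero_ec": int((result.excluded["reason"] == "zero network EC").sum()),
    }
    (out_dir / "report.json").write_text(json.dumps(counts, indent=2) + "\n")
    return result
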