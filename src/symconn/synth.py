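"""Synthetic resting-state cohorts with planted connectivity structure.

The generator produces 4-D BOLD-like volumes on a left-right symmetric
grid, per-run rigid-body motion traces, and a phenotype table, so that
every downstream stage (preprocessing, EC, VMHC, group statistics) can be
exercised against known ground truth.

Generative model (latent factors; population correlations in closed form).
Each voxel series is a unit-variance AR(1) process (coefficient ``phi``)
built as a linear mix of independent AR(1) sources:

* a network factor shared by all voxels of a network (loading sqrt(a)),
* a homotopic pair factor shared by a voxel and its mirror (loading sqrt(b)),
* hub factors shared, at small loading, with every analysis voxel,
* independent voxel noise carrying the remaining variance.

With ``a = within_network_rho * m`` and ``a + b = homotopic_rho * m`` the
population correlation is ``homotopic_rho * m`` for mirrored in-network
pairs and ``within_network_rho * m`` for other same-network pairs, where
``m`` is a per-subject coupling multiplier.  Subject heterogeneity, group
effects and covariate effects all act through ``m`` and the within-network
loading:

* heterogeneity: ``m = 1 + gamma * latent`` with latent ~ N(0, 1);
* a group effect with target standardized difference g shifts the
  within-network loading by +-(g/2) * gamma * within_network_rho (TYP up,
  ADHD down), keeping the homotopic total fixed so VMHC is untouched;
* a covariate effect with target Spearman rho ties ``latent`` to the
  covariate's normal scores through a Gaussian copula
  (r = 2 sin(pi * rho / 6)), so both EC- and VMHC-type network summaries
  depend monotonically on the covariate.

Motion traces are smooth low-amplitude drift plus occasional one-frame
spikes; spike frames also receive a global intensity offset so censoring
has a real artifact to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .grid import SymmetricGrid, make_symmetric_grid
from .image import FuncImage, MotionTrace

__all__ = [
    "NetworkSpec",
    "HubSpec",
    "GroupEffect",
    "CovariateEffect",
    "SyntheticConfig",
    "SimulatedSubject",
    "NETWORK_NAMES",
    "default_atlas",
    "default_config",
    "compact_config",
    "sample_phenotypes",
    "simulate_subject",
    "simulate_cohort",
    "covariate_normal_scores",
]

#: the 15 network labels of the atlas (14 functional networks + cerebellum)
NETWORK_NAMES = (
    "anterior_Salience",
    "Auditory",
    "Basal_Ganglia",
    "dorsal_DMN",
    "high_Visual",
    "Language",
    "LECN",
    "post_Salience",
    "Precuneus",
    "prim_Visual",
    "RECN",
    "Sensorimotor",
    "ventral_DMN",
    "Visuospatial",
    "Cerebellum",
)

GROUPS = ("TYP", "ADHD")

#: phenotype marginal parameters per group: (mean, sd) or male fraction
PHENOTYPE_MODEL = {
    "handedness": {"TYP": (0.62, 0.24), "ADHD": (0.66, 0.26)},
    "adhd_index": {"TYP": (45.50, 6.34), "ADHD": (71.20, 8.53)},
    "inattentive": {"TYP": (45.55, 6.14), "ADHD": (70.44, 8.81)},
    "hyper_impulsive": {"TYP": (46.40, 5.42), "ADHD": (67.43, 12.20)},
    "full_iq": {"TYP": (110.57, 14.38), "ADHD": (107.41, 14.26)},
    "verbal_iq": {"TYP": (110.98, 13.56), "ADHD": (108.06, 14.79)},
    "performance_iq": {"TYP": (107.74, 14.89), "ADHD": (104.70, 13.82)},
}
MALE_FRACTION = {"TYP": 40 / 86, "ADHD": 66 / 89}
AGE_RANGE = (7.0, 18.0)

PHENOTYPE_COLUMNS = (
    "subject_id",
    "group",
    "age_years",
    "sex",
    "handedness",
    "adhd_index",
    "inattentive",
    "hyper_impulsive",
    "full_iq",
    "verbal_iq",
    "performance_iq",
)


@dataclass(frozen=True)
class NetworkSpec:
    """A named symmetric network mask with planted correlation levels."""

    name: str
    mask: np.ndarray
    homotopic_rho: float = 0.6
    within_network_rho: float = 0.3

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        if not (0 <= self.homotopic_rho < 1):
            raise ValueError(f"{self.name}: homotopic_rho must be in [0, 1)")
        if not (0 <= self.within_network_rho < 1):
            raise ValueError(f"{self.name}: within_network_rho must be in [0, 1)")


@dataclass(frozen=True)
class HubSpec:
    """A planted hub voxel: shares a latent source with every analysis voxel."""

    index: tuple[int, int, int]
    strength: float

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise ValueError("hub strength must be >= 0")


@dataclass(frozen=True)
class GroupEffect:
    """Planted standardized group difference on a network's connectivity."""

    network: str
    hedges_g: float


@dataclass(frozen=True)
class CovariateEffect:
    """Planted Spearman correlation between a covariate and a network summary.

    ``metric`` selects the summary the dependence targets: "EC" modulates
    the within-network coupling (homotopic total untouched), "VMHC"
    modulates the homotopic correlation itself.
    """

    covariate: str
    network: str
    target_spearman_rho: float
    metric: str = "EC"

    def __post_init__(self) -> None:
        if not (-1 < self.target_spearman_rho < 1):
            raise ValueError("target_spearman_rho must be in (-1, 1)")
        if self.metric not in ("EC", "VMHC"):
            raise ValueError(f"metric must be 'EC' or 'VMHC', got {self.metric!r}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of a synthetic cohort's generative conditions.

    Defaults follow the study protocol: 152 frames at TR 2 s (a 304 s run),
    AR(1) temporal coefficient 0.3, voxel size 3 x 3 x 4 mm.
    """

    grid: SymmetricGrid
    networks: tuple[NetworkSpec, ...]
    n_frames: int = 152
    tr_seconds: float = 2.0
    hubs: tuple[HubSpec, ...] = ()
    group_effects: tuple[GroupEffect, ...] = ()
    covariate_effects: tuple[CovariateEffect, ...] = ()
    noise_sigma: float = 1.0
    motion_spike_prob: float = 0.02
    motion_spike_mm: float = 1.0
    seed: int = 0
    ar_coef: float = 0.3
    subject_coupling_sd: float = 0.4  # gamma: between-subject SD of the coupling multiplier
    hub_spread: float = 0.05  # fraction of a hub's loading shared with other voxels
    baseline: float = 1000.0
    signal_amplitude: float = 10.0  # fluctuation SD in image units per noise_sigma
    spike_signal_coupling: float = 2.0  # global offset per mm of spike, in signal_amplitude units
    background_in_mask: bool = True  # analysis mask = whole grid (whole-brain style) vs network union
    transmission_gain: float = 1.2  # compensates metric-estimation attenuation of planted effects

    def __post_init__(self) -> None:
        if self.n_frames < 20:
            raise ValueError("n_frames must be >= 20")
        if self.noise_sigma <= 0:
            raise ValueError("noise_sigma must be positive")
        if not (0 <= self.motion_spike_prob <= 1):
            raise ValueError("motion_spike_prob must be in [0, 1]")
        if self.motion_spike_mm < 0:
            raise ValueError("motion_spike_mm must be >= 0")
        if not (0 <= self.ar_coef < 1):
            raise ValueError("ar_coef must be in [0, 1)")
        names = [n.name for n in self.networks]
        if len(set(names)) != len(names):
            raise ValueError("network names must be unique")
        union = np.zeros(self.grid.dims, dtype=bool)
        for net in self.networks:
            if net.mask.shape != self.grid.dims:
                raise ValueError(f"network {net.name!r} mask does not match grid {self.grid.dims}")
            if not net.mask.any():
                raise ValueError(f"network {net.name!r} mask is empty")
            if (union & net.mask).any():
                raise ValueError(f"network {net.name!r} overlaps another network")
            union |= net.mask
        net_names = set(names)
        for eff in self.group_effects:
            if eff.network not in net_names:
                raise ValueError(f"group effect targets unknown network {eff.network!r}")
        for eff in self.covariate_effects:
            if eff.network not in net_names:
                raise ValueError(f"covariate effect targets unknown network {eff.network!r}")
        if self.background_in_mask:
            union[:] = True
        for hub in self.hubs:
            if not union[hub.index]:
                raise ValueError(f"hub at {hub.index} lies outside the analysis mask")
        self._validate_budget()

    def _validate_budget(self) -> None:
        """Check that the requested correlation structure is representable."""
        hub_spread_var = sum(self.hub_spread * h.strength / (1 + h.strength) for h in self.hubs)
        for net in self.networks:
            if net.within_network_rho > net.homotopic_rho:
                raise ValueError(
                    f"network {net.name!r}: within_network_rho "
                    f"{net.within_network_rho} > homotopic_rho {net.homotopic_rho} "
                    f"is not a valid (positive semi-definite) factor structure"
                )
        if hub_spread_var > 0.5:
            raise ValueError(
                f"combined hub spread variance {hub_spread_var:.2f} > 0.5: too many "
                f"or too strong hubs for the unit variance budget"
            )

    @property
    def network_union(self) -> np.ndarray:
        mask = np.zeros(self.grid.dims, dtype=bool)
        for net in self.networks:
            mask |= net.mask
        return mask

    @property
    def analysis_mask(self) -> np.ndarray:
        if self.background_in_mask:
            return np.ones(self.grid.dims, dtype=bool)
        return self.network_union

    def atlas(self) -> dict[str, np.ndarray]:
        return {net.name: net.mask.copy() for net in self.networks}

    def with_changes(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)


@dataclass
class SimulatedSubject:
    """One simulated participant: functional run, motion trace, phenotype row."""

    subject_id: str
    image: FuncImage
    motion: MotionTrace
    phenotype: dict


def default_atlas(grid: SymmetricGrid | None = None) -> tuple[SymmetricGrid, dict[str, np.ndarray]]:
    """Fifteen disjoint mirror-symmetric box networks on a 14 x 12 x 10 grid.

    Each network is a 2 x 2 x 2 box per hemisphere (16 voxels).  Boxes are
    laid out on a lattice of slots separated by one voxel.
    """
    if grid is None:
        grid = make_symmetric_grid((14, 12, 10))
    nx = grid.dims[0]
    atlas: dict[str, np.ndarray] = {}
    for i, name in enumerate(NETWORK_NAMES):
        x0 = 1 + 3 * (i % 2)
        y0 = 1 + 3 * ((i // 2) % 3)
        z0 = 1 + 3 * (i // 6)
        mask = np.zeros(grid.dims, dtype=bool)
        mask[x0 : x0 + 2, y0 : y0 + 2, z0 : z0 + 2] = True
        mask |= np.flip(mask, axis=0)
        if mask.sum() != 16:
            raise ValueError(f"default atlas does not fit grid {grid.dims}")
        atlas[name] = mask
    # sanity: disjoint by construction of the slot lattice
    assert nx >= 14
    return grid, atlas


def default_config(**overrides) -> SyntheticConfig:
    """Study-condition defaults: 15-network atlas, rho_homotopic 0.6, rho_within 0.3."""
    grid, atlas = default_atlas()
    networks = tuple(NetworkSpec(name, mask) for name, mask in atlas.items())
    return SyntheticConfig(grid=grid, networks=networks, **overrides)


def compact_config(
    n_networks: int = 4,
    homotopic_rho: float = 0.6,
    within_network_rho: float = 0.3,
    **overrides,
) -> SyntheticConfig:
    """A small-grid configuration for Monte-Carlo studies.

    Four (or fewer) 16-voxel box networks on an 8 x 6 x 6 grid; planted
    correlation levels as in the full default.  Network names reuse the
    start of the atlas roster.
    """
    if not (1 <= n_networks <= 4):
        raise ValueError("compact_config supports 1-4 networks")
    grid = make_symmetric_grid((8, 6, 6))
    slots = [(0, 0), (3, 0), (0, 3), (3, 3)]
    networks = []
    for i in range(n_networks):
        y0, z0 = slots[i]
        mask = np.zeros(grid.dims, dtype=bool)
        mask[1:3, y0 : y0 + 2, z0 : z0 + 2] = True
        mask |= np.flip(mask, axis=0)
        networks.append(
            NetworkSpec(NETWORK_NAMES[i], mask,
                        homotopic_rho=homotopic_rho,
                        within_network_rho=within_network_rho)
        )
    return SyntheticConfig(grid=grid, networks=tuple(networks), **overrides)


# ---------------------------------------------------------------------------
# phenotype sampling

def sample_phenotypes(n_per_group: tuple[int, int], rng: np.random.Generator) -> pd.DataFrame:
    """Draw a phenotype table with the study's column roster and marginals."""
    rows = []
    counter = 0
    for group, n in zip(GROUPS, n_per_group):
        for _ in range(n):
            counter += 1
            row = {
                "subject_id": f"sub-{counter:04d}",
                "group": group,
                "age_years": float(rng.uniform(*AGE_RANGE)),
                "sex": "M" if rng.random() < MALE_FRACTION[group] else "F",
            }
            for col, pars in PHENOTYPE_MODEL.items():
                mu, sd = pars[group]
                val = float(rng.normal(mu, sd))
                if col == "handedness":
                    val = float(np.clip(val, 0.0, 1.0))
                row[col] = val
            rows.append(row)
    return pd.DataFrame(rows, columns=list(PHENOTYPE_COLUMNS))


def covariate_normal_scores(values: np.ndarray) -> np.ndarray:
    """Rank-based normal scores: Phi^-1(rank / (n + 1)), average ranks for ties."""
    values = np.asarray(values, dtype=np.float64)
    ranks = stats.rankdata(values, method="average")
    return stats.norm.ppf(ranks / (len(values) + 1))


def _marginal_score(covariate: str, phenotype: dict) -> float:
    """Normal score of a covariate from its marginal model (standalone subjects)."""
    val = float(phenotype[covariate])
    if covariate == "age_years":
        lo, hi = AGE_RANGE
        u = np.clip((val - lo) / (hi - lo), 1e-6, 1 - 1e-6)
        return float(stats.norm.ppf(u))
    if covariate in PHENOTYPE_MODEL:
        mu, sd = PHENOTYPE_MODEL[covariate][phenotype["group"]]
        return (val - mu) / sd
    raise ValueError(f"unknown covariate {covariate!r}")


# ---------------------------------------------------------------------------
# time-series machinery

def _ar1(rng: np.random.Generator, n_series: int, n_frames: int, phi: float) -> np.ndarray:
    """Independent unit-variance stationary AR(1) series, shape (n_series, T)."""
    if phi == 0:
        return rng.standard_normal((n_series, n_frames))
    innov_sd = np.sqrt(1.0 - phi**2)
    x = np.empty((n_series, n_frames))
    x[:, 0] = rng.standard_normal(n_series)
    eps = rng.standard_normal((n_series, n_frames - 1)) * innov_sd
    for t in range(1, n_frames):
        x[:, t] = phi * x[:, t - 1] + eps[:, t - 1]
    return x


def _mirror_pairs(grid: SymmetricGrid, mask: np.ndarray):
    """Split in-mask voxels into mirrored pairs and unpaired voxels.

    Returns (left_idx, right_idx, unpaired_idx) as arrays of ijk rows; only
    pairs with both members in-mask are paired.
    """
    nx = grid.dims[0]
    paired_mask = mask & grid.mirror_array(mask) & ~grid.midplane_mask()
    left = np.argwhere(paired_mask & (np.arange(nx)[:, None, None] < nx - 1 - np.arange(nx)[:, None, None]))
    right = left.copy()
    right[:, 0] = nx - 1 - left[:, 0]
    unpaired = np.argwhere(mask & ~paired_mask)
    return left, right, unpaired


def _copula_latent(
    effects: list[CovariateEffect],
    covariate_scores: dict[str, float],
    rng: np.random.Generator,
    net_name: str,
    gain: float = 1.0,
) -> float:
    """Standard-normal latent tied to covariate normal scores (Gaussian copula).

    ``gain`` scales the copula loadings above their bivariate-normal value
    2 sin(pi rho / 6) to offset the attenuation that downstream metric
    estimation noise applies to the planted dependence.
    """
    r = np.array([2.0 * np.sin(np.pi * e.target_spearman_rho / 6.0) for e in effects])
    r = np.clip(r * gain, -0.99, 0.99)
    r_sq = float((r**2).sum())
    if r_sq >= 1:
        raise ValueError(
            f"network {net_name!r}: combined covariate effects too strong "
            f"(sum of squared copula loadings {r_sq:.2f} >= 1)"
        )
    z = np.array([covariate_scores[e.covariate] for e in effects])
    return float(r @ z) + np.sqrt(1.0 - r_sq) * float(rng.standard_normal())


def _subject_coupling(
    config: SyntheticConfig,
    phenotype: dict,
    covariate_scores: dict[str, float],
    rng: np.random.Generator,
) -> dict[str, tuple[float, float]]:
    """Per-network (a, b) factor variances for one subject.

    a is the network-factor variance share, b the pair-factor share; pair
    correlation = a + b, within-network correlation = a.  Subject
    heterogeneity, group effects and EC covariate effects act on a only,
    so the homotopic total stays at the planted value unless a
    VMHC-directed covariate effect modulates it.
    """
    gamma = config.subject_coupling_sd
    group = phenotype["group"]
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    ec_effects: dict[str, list[CovariateEffect]] = {}
    vmhc_effects: dict[str, list[CovariateEffect]] = {}
    for eff in config.covariate_effects:
        target = ec_effects if eff.metric == "EC" else vmhc_effects
        target.setdefault(eff.network, []).append(eff)
    group_shift = {eff.network: eff.hedges_g for eff in config.group_effects}

    gain = config.transmission_gain
    out: dict[str, tuple[float, float]] = {}
    for net in config.networks:
        latent_ec = _copula_latent(ec_effects.get(net.name, []), covariate_scores, rng,
                                   net.name, gain)
        pair_total = net.homotopic_rho
        v_effs = vmhc_effects.get(net.name, [])
        if v_effs:
            latent_v = _copula_latent(v_effs, covariate_scores, rng, net.name, gain)
            pair_total = float(np.clip(net.homotopic_rho * (1.0 + gamma * latent_v), 0.0, 0.97))
        m = float(np.clip(1.0 + gamma * latent_ec, 0.2, 1.8))
        a = net.within_network_rho * m
        g = group_shift.get(net.name, 0.0)
        sign = 1.0 if group == "TYP" else -1.0
        a = a + sign * 0.5 * g * gain * gamma * net.within_network_rho
        a = float(np.clip(a, 0.0, pair_total))
        out[net.name] = (a, pair_total - a)
    return out


def _hub_loadings(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-hub (own loading^2, spread loading^2)."""
    if not config.hubs:
        return None
    own = np.array([h.strength / (1.0 + h.strength) for h in config.hubs])
    spread = config.hub_spread * own
    return own, spread


def simulate_subject(
    config: SyntheticConfig,
    phenotype: dict,
    subject_seed,
    covariate_scores: dict[str, float] | None = None,
) -> tuple[FuncImage, MotionTrace]:
    """Simulate one participant's functional run and motion trace.

    ``covariate_scores`` are the cohort-level rank-based normal scores of
    the covariates named in covariate effects; when absent they are derived
    from the phenotype's marginal model (standalone use).
    """
    rng = np.random.default_rng(subject_seed)
    grid, T = config.grid, config.n_frames
    phi = config.ar_coef

    if covariate_scores is None:
        covariate_scores = {
            eff.covariate: _marginal_score(eff.covariate, phenotype)
            for eff in config.covariate_effects
        }

    coupling = _subject_coupling(config, phenotype, covariate_scores, rng)

    nvox = grid.n_voxels
    data = _ar1(rng, nvox, T, phi).reshape(*grid.dims, T)

    union = config.analysis_mask

    for net in config.networks:
        a, b = coupling[net.name]
        g_series = _ar1(rng, 1, T, phi)[0]
        left, right, unpaired = _mirror_pairs(grid, net.mask)
        n_pairs = len(left)
        pair_series = _ar1(rng, n_pairs, T, phi) if n_pairs else np.empty((0, T))
        for side in (left, right):
            for p, ijk in enumerate(map(tuple, side)):
                e = 1.0 - a - b
                if e < 0:
                    raise ValueError(
                        f"network {net.name!r}: variance budget exceeded at voxel {ijk} "
                        f"(a={a:.3f}, b={b:.3f})"
                    )
                data[ijk] = (
                    np.sqrt(a) * g_series
                    + np.sqrt(b) * pair_series[p]
                    + np.sqrt(e) * data[ijk]
                )
        for ijk in map(tuple, unpaired):
            data[ijk] = np.sqrt(a) * g_series + np.sqrt(1.0 - a) * data[ijk]

    # hubs mix proportionally into each analysis voxel's existing signal:
    # voxel <- sqrt(1 - w) * voxel + sum_h sqrt(load_h) * u_h, with w the
    # total hub variance share at that voxel (own loading at the hub itself,
    # small spread loading elsewhere).
    hub_l = _hub_loadings(config)
    if hub_l is not None:
        own, spread = hub_l
        hub_series = _ar1(rng, len(config.hubs), T, phi)
        uidx = np.argwhere(union)
        w = np.zeros(len(uidx))
        hub_terms = np.zeros((len(uidx), T))
        for h, (hub, o, s) in enumerate(zip(config.hubs, own, spread)):
            load = np.full(len(uidx), s)
            load[np.all(uidx == np.asarray(hub.index), axis=1)] = o
            hub_terms += np.sqrt(load)[:, None] * hub_series[h]
            w += load
        if np.any(w > 0.98):
            raise ValueError("combined hub loadings exceed the unit variance budget")
        data[union] = np.sqrt(1.0 - w)[:, None] * data[union] + hub_terms

    # motion: smooth drift + one-frame spikes
    drift = rng.standard_normal((T, 6))
    drift = ndimage.gaussian_filter1d(drift, sigma=8.0, axis=0)
    drift /= max(drift.std(), 1e-12)
    drift = drift * np.array([0.15, 0.15, 0.15, 0.05, 0.05, 0.05])
    spikes = rng.random(T) < config.motion_spike_prob
    spikes[0] = False
    params = drift.copy()
    params[spikes, 0] += config.motion_spike_mm
    motion = MotionTrace(params)

    vol = config.baseline + config.signal_amplitude * config.noise_sigma * data
    if spikes.any():
        offset = config.spike_signal_coupling * config.signal_amplitude * config.motion_spike_mm
        vol[..., spikes] += offset

    img = FuncImage(data=vol, grid=grid, tr_seconds=config.tr_seconds)
    return img, motion


def simulate_cohort(
    config: SyntheticConfig,
    n_per_group: tuple[int, int] = (86, 89),
    cohort_seed: int | None = None,
) -> tuple[list[SimulatedSubject], pd.DataFrame]:
    """Simulate a full cohort: subjects in phenotype-table order.

    Identical ``(config, n_per_group, cohort_seed)`` give byte-identical
    outputs.  Covariate effects are planted against cohort-level rank
    scores, so the targeted Spearman correlations hold at the sample level.
    """
    if any(n < 2 for n in n_per_group):
        raise ValueError(f"need >= 2 subjects per group, got {n_per_group}")
    seed = config.seed if cohort_seed is None else cohort_seed
    ss = np.random.SeedSequence(seed)
    pheno_rng = np.random.default_rng(ss.spawn(1)[0])
    table = sample_phenotypes(tuple(n_per_group), pheno_rng)

    cov_names = sorted({eff.covariate for eff in config.covariate_effects})
    scores = {
        name: covariate_normal_scores(table[name].to_numpy()) for name in cov_names
    }

    subjects: list[SimulatedSubject] = []
    child_seeds = ss.spawn(len(table) + 1)[1:]
    for i, row in table.iterrows():
        pheno = row.to_dict()
        subj_scores = {name: float(scores[name][i]) for name in cov_names}
        img, motion = simulate_subject(config, pheno, child_seeds[i], subj_scores)
        subjects.append(SimulatedSubject(pheno["subject_id"], img, motion, pheno))
    return subjects, table
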