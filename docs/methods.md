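# Methods

`symconn` implements a resting-state fMRI connectivity analysis built
around two subject-level, voxel-wise maps — eigenvector centrality (EC)
and voxel-mirrored homotopic connectivity (VMHC) — together with the
preprocessing chain that feeds them, the group-statistics layer that
compares a clinical and a neurotypical group, and a synthetic-cohort
generator with planted, analytically known structure so every stage can be
validated without real data.

## Subject-level metrics

**Eigenvector centrality.** For voxel series collected in a standardized
frames-by-voxels matrix `M` (columns zero-mean, unit variance over the
retained frames), the voxel-by-voxel Pearson correlation matrix is
`R = MᵀM / (T − 1)`. EC is the leading eigenvector of `R v = λ v` after
the nonnegativity shift `S = (R + J)/2` (entries `(r + 1)/2 ∈ [0, 1]`, `J`
the all-ones matrix), which by Perron–Frobenius has a unique, strictly
positive leading eigenvector. `S` is never materialized: the product

    S v = Mᵀ(M v) / (2(T − 1)) + (Σᵢ vᵢ) / 2 · 1

costs O(TN) per step, so power iteration (uniform positive start,
convergence when successive normalized iterates differ by < 1e−6 in
Euclidean norm, λ reported as the Rayleigh quotient) scales to whole-brain
masks. The output is the unit-Euclidean-norm eigenvector; no rescaling to
[0, 1] is applied because all downstream statistics (t, Hedges' g,
Spearman ρ) are location/scale-free. Alternative shifts (`abs`,
`pos-part`) are available but materialize the dense matrix, since `|R|v`
has no matrix-free product through the data matrix.

Because the EC vector has unit norm over the whole analysis mask, network
means are *shares* of total centrality: raising one network's internal
coupling lowers, slightly, every other network's mean. This zero-sum
leakage is negligible when each network is a small fraction of the mask
(the whole-brain situation) but dominates if the mask contains only a few
networks — which is why the analysis mask defaults to the full grid.

**VMHC.** Each voxel is paired with its mirror image across the
midsagittal plane (index mirroring `i → Nx − 1 − i` on a grid that is
left-right symmetric by construction). VMHC is the Pearson correlation of
the pair over retained frames, clipped to |r| ≤ 1 − 1e−7, then Fisher
z-transformed, `z = ½ ln((1 + r)/(1 − r))`. Midplane voxels (odd first
dimension) and voxels whose mirror leaves the mask are missing (NaN), and
missing values are excluded — never zero-filled — from network averages.
The map is mirror-symmetric by construction.

## Preprocessing

Stages run in this order with these defaults (each overridable in
`RunConfig` / on the CLI):

| stage | default | unit / note |
|---|---|---|
| drop initial frames | 4 | steady-state transient; 152-frame run → 148 |
| scale to temporal mean | 100 | per voxel, exact to machine precision |
| band-pass | 0.01–0.1 | Hz; zero-phase order-4 Butterworth (two order-2 sections, forward–backward) |
| nuisance regression | 6 motion + 6 derivatives (+ compartment mean) | OLS residuals, intercept always included; derivatives are backward differences with first row 0 |
| FD censoring | 0.5 | mm; strictly-greater censors, ties retained |
| QC gates | <10 % censored, <2 mm, <2° | failure flags the subject, does not raise |

Scaling precedes the band-pass deliberately: the filter's stopband
includes DC, and rescaling a zero-mean series to mean 100 would be
ill-defined. Framewise displacement is the summed absolute backward
difference of the three translations plus the three rotation arcs at a
50 mm radius; rotations are stored in degrees (the common motion-file
dialect) and converted internally. FD is a frame-level quantity, so
censoring removes frames. A `simultaneous_censor_regress` switch performs
censoring before the regression for users who prefer the joint treatment;
the default follows the protocol order (regress, then censor). Constant
nuisance columns (a perfectly still axis) are dropped rather than
reported as collinear with the intercept. The nuisance-compartment mask
(the stand-in for an anatomical CSF mask, which synthetic data cannot
provide) is eroded by one voxel with 6-neighbour erosion before its mean
series is added to the design.

Zero-phase band-pass filtering preserves the population correlation
structure (all series receive the identical filter) but concentrates the
usable signal into ~36 % of the spectrum, reducing the effective temporal
degrees of freedom. Metric estimates after filtering are therefore
noisier, and planted between-subject effects measured through the *full*
chain appear attenuated by roughly 30 % relative to the same effects
measured on unfiltered series. This is expected filter behavior, not a
defect; the parameter-recovery studies below quantify planting fidelity at
the metric stage.

## Group statistics

All group contrasts are TYP minus ADHD, so negative t (or g) means higher
in the ADHD group.

* **Voxel-wise:** per-voxel OLS of metric ~ group indicator +
  grand-mean-centered covariates (age, sex, three IQ scores, handedness);
  two-sided t for the group coefficient with n − k − 2 degrees of freedom.
  Benjamini–Hochberg adjustment (via `statsmodels.multipletests`) over
  in-mask voxels, each metric corrected separately; voxels with q < 0.05
  are clustered.
* **Clusters:** connected components at NN level 1/2/3 (6/18/26-neighbour
  adjacency, `scipy.ndimage.label`), minimum extent 30 voxels, labels
  ordered by descending size (ties: ascending peak linear index), peak =
  maximum |t| within the cluster (tie: lowest linear index).
* **Network level:** pooled-variance Student t (a `welch` switch exists)
  per network-metric column plus a mean-FD row; effect size is Hedges'
  g = J·(mean₁ − mean₂)/s_pooled with J = 1 − 3/(4(n₁+n₂) − 9); at
  n₁+n₂ = 6, J = 0.8 exactly.
* **Correlation screens:** Spearman ρ (average ranks; p from the
  t-approximation with n − 2 df — exact permutation is infeasible at
  n ≈ 175) of every network summary against age, three severity T-scores,
  three IQ scores and handedness, for the full sample and each group
  separately. Bands: p < 0.01 significant, 0.01 ≤ p < 0.05 trend. No
  further multiplicity correction is applied at the network level, by
  design of the analysis this package reproduces.
* **Exclusions:** subjects failing motion QC, and subjects for whom any
  network's mean EC is exactly 0 or undefined, are excluded and counted in
  the report.

## Synthetic cohorts

The generator emulates the statistical structure the analyses assume, with
population correlations available in closed form via a latent-factor
construction. Every series (factors and noise) is a unit-variance
stationary AR(1) process with coefficient 0.3 — BOLD-like temporal
smoothness with no free parameters — and linear mixing of identically
distributed sources preserves the designed correlations. Monte-Carlo
tolerance bands account for the autocorrelation through the effective
sample size T_eff = T(1 − φ)/(1 + φ) (≈ 80 at T = 148, φ = 0.3); in
practice the recovery tests use the empirical replicate SE, which embeds
this inflation.

Per network with homotopic correlation ρ and within-network correlation w
(defaults 0.6 and 0.3, typical of homotopic and intra-network coupling in
resting-state data), each voxel loads √a on a network factor and, with its
mirror partner, √b on a pair factor, with `a = w·m` and `a + b = ρ`; the
remainder is independent noise. The per-subject multiplier
`m = 1 + γ·latent` carries all between-subject structure:

* **Heterogeneity:** latent ~ N(0, 1), γ = 0.4 (subject coupling SD).
  γ was fixed by a design-phase sensitivity study so that between-subject
  coupling variance dominates metric-estimation noise at T = 148 — planted
  standardized effects then survive to the summary scale — mirroring the
  empirical observation that between-subject variance in connectivity
  metrics exceeds within-subject test-retest noise.
* **Group effects:** a planted Hedges' g shifts the within-network loading
  by ±(g/2)·gain·γ·w (TYP up, ADHD down) while keeping `a + b = ρ` fixed,
  so EC responds and VMHC does not — matching the finding structure the
  pipeline is designed to detect (group differences in centrality, null
  homotopic differences).
* **Covariate effects:** a target Spearman ρ_s ties the latent to the
  covariate's cohort-level rank-based normal scores through a Gaussian
  copula with loading `2 sin(π ρ_s / 6) · gain`; EC-directed effects
  modulate the within-network loading, VMHC-directed effects modulate the
  homotopic total itself.
* **Transmission gain:** the fixed factor 1.2 compensates the attenuation
  that metric-estimation noise applies between the planted coupling and
  the measured network summary, so that the *delivered* effect matches the
  requested one (measured at the drop→EC chain: planted g = 0.6 realizes
  0.59 ± 0.05; planted ρ_s = 0.5 realizes 0.49). The calibration is
  accurate for moderate effects (|g| ≲ 0.8, |ρ_s| ≲ 0.6) under the default
  grid, frame count and γ; extreme targets or strongly non-default
  configurations will deliver somewhat more or less than requested.
* **Hubs:** each hub voxel mixes a hub source into its signal at variance
  share s/(1+s) for strength s, and every other analysis voxel receives a
  small spread loading (5 % of the hub's share), so hubs correlate weakly
  with everything — the profile eigenvector centrality rewards. The mixing
  is proportional (`voxel ← √(1−w)·voxel + √w·hub`), so it cannot overflow
  the variance budget; it does locally perturb a hub's homotopic and
  within-network correlations, and hub-free configurations remain exactly
  at the planted values.
* **Motion:** smooth drift (Gaussian-smoothed white noise, SD 0.15 mm /
  0.05°) plus one-frame spikes of 1 mm with probability 0.02 per frame;
  spike frames also receive a global intensity offset (2× the signal
  amplitude per mm) so censoring has a real artifact to remove. The spike
  rate and magnitude are free knobs, not calibrated values — the empirical
  FD distribution of the original cohort is not published.
* **Phenotypes:** age uniform on [7, 18]; sex with the study's per-group
  male fractions; handedness, Conners T-scores and IQ normal with the
  study's per-group means/SDs (handedness clipped to [0, 1]). Plausible
  marginals, no claim of joint-distribution fidelity.

Identical (config, seed) inputs give byte-identical cohorts; per-subject
streams are spawned from a single seed sequence.

### What the generator does not emulate

No anatomy, no spatial autocorrelation beyond the planted factors, no
hemodynamic response or task structure, no scanner physics or slow drifts
in the image (only in the motion trace), no non-Gaussian marginals in the
BOLD signal, and no realistic spatial layout of networks (boxes on a small
grid). Passing tests therefore demonstrate the *statistical* correctness
of the pipeline — estimator accuracy, error control, effect-size recovery,
determinism — not robustness to anatomical misregistration, physiological
noise, or spatially structured artifacts.

## Numerical choices

* Correlations are computed over the shared retained-frame set, so `R` is
  a true correlation matrix; pairs never mix frame sets.
* VMHC clips |r| at 1 − 1e−7 before `arctanh`; an identical pair maps to
  z ≈ 8.41, finite by construction.
* Power iteration starts from the uniform positive vector (deterministic,
  inside the Perron cone); non-convergence after 1000 iterations is an
  error that reports the final delta.
* Zero-variance in-mask voxels are an error naming example indices;
  zero-temporal-mean voxels in scaling are set to the constant target with
  a logged warning.
* Censoring at exactly the threshold retains the frame; censoring is
  idempotent.
* The BH adjustment enforces monotone q-values, so q ≥ p voxel-wise.
* NIfTI volumes are written uncompressed (float32) so repeated runs are
  byte-identical; gzipped inputs are accepted on read.

## Validation problem sizes

The Monte-Carlo validation studies run the generator → frame-drop →
metric chain on a compact 8×6×6 grid with up to four 16-voxel networks:
VMHC recovery (ρ ∈ {0, 0.3, 0.6}, 100 replicates, within 3 MC SE of
arctanh ρ), hub-rank recovery (100 replicates, ≥ 95 % top-rank), network
type-I error (60 null cohorts), and power / effect-size recovery for a
planted g = 0.6 at n = 40+40 (200 cohorts; measured power ≈ 0.74, mean
estimated g ≈ 0.61). Solver and procedure oracles run at larger sizes
(dense eigensolver up to 500 voxels; flood-fill clustering on 12³
volumes). The full preprocessing chain is validated by stage-level unit
tests, an end-to-end planted-cohort fixture, and a byte-determinism check
of the complete `simulate → all` command-line chain.

## Known limitations

* The spatial layout is synthetic; cluster-extent inference is validated
  as an algorithm (oracle equivalence), not against smoothness-matched
  random-field expectations.
* Effect-size planting is calibrated at the metric stage; through the full
  filtered chain, delivered effects are ~30 % smaller (see above).
* The Spearman p-values rely on the t-approximation, slightly liberal
  below n ≈ 10.
* Demographic (rank-sum) testing of the phenotype table is not part of the
  pipeline's report; the phenotype marginals are inputs, not findings.
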