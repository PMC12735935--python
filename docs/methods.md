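# Methods

This note documents the models implemented in `neurofuse`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Tri-exponential IVIM model

The diffusion-weighted signal of a voxel is modelled as

S(b)/S0 = F_p·exp(−b·D_p) + F_f·exp(−b·D_f) + F_s·exp(−b·D_s),

with non-negative fractions on the simplex (F_p + F_f + F_s = 1): a fast,
perfusion-related pseudo-diffusion pool (D_p), an intermediate free-water
pool (D_f) and a slow pool of restricted tissue diffusion (D_s).

Fitting is a two-step constrained procedure:

1. **High-b seed.** Because the fast pools have decayed to ≤ e⁻³ of their
   weight by b = 1000 s/mm², D_s is first estimated by ordinary least
   squares of ln S on b over the shells with b ≥ 1000 (a closed-form
   log-linear fit, exact on clean mono-exponential data). The slope estimate
   is clipped into the D_s bounds, with a diagnostic flag when clipping
   occurs.
2. **Full fit.** Bounded nonlinear least squares (trust-region reflective)
   over all shells, with D_f fixed at the free-water diffusivity
   3×10⁻³ mm²/s, D_s free but initialised at the step-1 value, D_p
   initialised at 10⁻² mm²/s, and fractions initialised at (0.1, 0.1, 0.8).
   Bounds: D_s ∈ [10⁻⁵, 3×10⁻³], D_p ∈ [3×10⁻³, 0.2] mm²/s. The simplex is
   enforced exactly by the reparameterisation F_s = 1 − F_p − F_f; if the
   optimum implies F_s < 0 the voxel is re-solved on the simplex face
   F_s = 0 (where D_s is unidentifiable and is reported at the step-1
   value, flagged).

Numerical choices:

- **Direction handling.** The decay is treated as isotropic: volumes are
  averaged within each b-value shell before fitting. Per-direction or
  tensor-valued modelling is out of scope.
- **Residual weighting.** Shell means of n volumes have noise variance
  σ²/n, so shell residuals are weighted by √n — the generalized
  least-squares weighting that gives each acquired volume equal influence.
- **S0 handling.** S0 is fixed to the b0 shell mean by default (refit
  selectable via `TriExpFitConfig.refit_s0`); the b0 residual is then
  exactly zero and carries no information.
- **Voxel exclusion.** Voxels whose b0 mean falls below 5× the estimated
  noise floor (the median across-b0-repeat standard deviation) are excluded
  as signal dropouts; the factor is configurable because no principled
  universal value exists. No R²-based rejection is applied; the residual-RMS
  volume is emitted for inspection instead. Non-converged voxels return NaN
  parameters with an explicit flag — never silently.

On noise-free forward data with well-separated compartments the fit recovers
all free parameters to well below 0.5 % relative error (machine precision in
practice). Identifiability of F_p degrades sharply as D_p approaches D_f;
with the 14-shell scheme and the default phantom truth the voxelwise median
relative error at SNR 100 is ≈1.5 % for D_s and ≈9 % for F_p.

## ASL CBF quantification

The control−label difference ΔM (grand mean of control volumes minus grand
mean of label volumes; equivalent in expectation to pairwise means) is
converted to cerebral blood flow with the single-compartment kinetic model:

CBF = 6000·λ·ΔM·exp(PLD/T1b) / (2·α·T1b·M0·(1 − exp(−τ/T1b)))  [mL/100 g/min]

Defaults: labeling duration τ = 1.8 s and post-labeling delay PLD = 2.0 s
(the acquisition protocol values); partition coefficient λ = 0.9 mL/g,
labeling efficiency α = 0.85 and blood T1 = 1.650 s follow the consensus
recommendations for pCASL at 3 T. All constants are config-overridable and
recorded in output metadata. M0 is a dedicated reference volume; voxels with
non-positive M0 are masked and counted. The quantification is linear in
ΔM/M0, and the simulator inverts it exactly, so the noiseless round trip is
an identity to machine precision.

## ROI features

Parameter maps are reduced to means of in-mask, finite voxels over a
90-region integer atlas, stacked into one subject × ROI matrix per modality
(CBF, F_p, F_f, F_s, D_s) and z-scored across subjects with the n−1 sample
standard deviation. Zero-variance columns are set to zero and flagged rather
than dropped, keeping the 90-column contract intact. Regions without valid
voxels yield missing values with a warning; per-ROI valid-voxel counts are
the intended diagnostic rather than a hard exclusion rule.

## Two-stage fusion: RGCCA + joint ICA

**Stage 1 — RGCCA.** With per-block shrinkage τ = 1 the criterion is
covariance-based (PLS-like): maximise Σ_{b≠c} c_bc·g(cov(X_b w_b, X_c w_c))
over unit-norm block weights, with full off-diagonal connectivity c by
default. The scheme function g defaults to factorial (g(x) = x²; horst and
centroid are selectable) — factorial makes the two-block solution exactly
the leading singular-vector pair of X₁ᵀX₂, which serves as an analytic test
oracle. The block-relaxation update (w_b ∝ X_bᵀ Σ_c c_bc g'(cov) y_c) is
monotone in the criterion; iteration stops when the criterion increment
falls below 10⁻¹⁰ (relative). Initialisation is deterministic: each block's
leading right singular vector, sign-fixed. Components beyond the first are
obtained by deflating each block against its own canonical variate, which
makes within-block variates mutually orthogonal. τ < 1 (partial shrinkage
toward the correlation criterion) is not implemented.

**Outer AVE.** The variance a component explains in a block is the mean over
the block's features of the squared Pearson correlation between feature and
canonical variate, reported in percent. Component-count selection is fixed
k = 3 per block by default, matching the diminishing-returns point of
typical AVE profiles; an automatic rule (smallest k before the cross-block
mean marginal AVE drops below 5 points) is available.

**Stage 2 — joint ICA.** The canonical variates of all blocks are each
standardised to unit variance and concatenated into one subject × (B·k)
joint matrix. Variates that are numerically zero (an exhausted block — e.g.
a single-column behavioural block can yield only one non-trivial variate)
are left at zero rather than rescaled, so they do not fabricate rank. The
joint matrix is column-centred, whitened by SVD, and decomposed by symmetric
fixed-point ICA with the logcosh (tanh) contrast from a seeded random
orthogonal start. Independence is estimated over the subject dimension:
`joint ≈ loadings · sources`, where the loading columns are the maximally
independent subject-mode components ("IC subject scores") and the source
rows are their patterns over the concatenated variates. The component count
defaults to the effective rank of the joint matrix, capped at
min(subjects − 1, columns) — this is why five imaging blocks × 3 components
yield 15 ICs, and adding a 1-column outcome block yields 16 rather than 18.
ICA order and sign are conventions: components are sorted by decreasing
loading variance and signed so each source row's largest-magnitude element
is positive.

## Statistics

- Per-IC group comparison: two-sample t-test (pooled variance by default,
  Welch selectable), with group means and the 95 % CI of the difference.
- Multiplicity: Benjamini–Hochberg step-up FDR. Families: across ICs for
  the per-IC tables; within each IC × modality set of 90 ROI correlations;
  within the ROI's voxels for voxelwise maps. The family choices are
  recorded in run metadata.
- IC ↔ ROI and GOS-E associations: Spearman rank correlation
  (tie-corrected), with the top-5 |ρ| region ranking per IC × modality (ties
  broken by ascending ROI label).
- Demographics: Pearson chi-squared on the sex × group table **without**
  continuity correction (the variant consistent with the reference value on
  the 12F/12M vs 10F/9M table, X² = 0.029); Shapiro–Wilk normality per
  group; Wilcoxon rank-sum for group differences in continuous variables.

## Test–retest ICC

From the two-way ANOVA mean squares of the n × 2 subject-by-visit table:
consistency ICC(3,1) = (MS_R − MS_E)/(MS_R + MS_E) and absolute-agreement
ICC(2,1) = (MS_R − MS_E)/(MS_R + MS_E + (2/n)(MS_C − MS_E)). The default is
the consistency form; both are implemented because the published label
("two-way mixed for absolute agreement, ICC(3,1)") mixes the two
conventions, and the choice is recorded in output metadata. `icc_map`
applies the estimator voxelwise and summarises the in-mask distribution as
mean ± SD; degenerate voxels (zero total variance) are flagged and excluded
from the summary. A single n = 500 ICC estimate has sampling sd ≈ 0.03 at
ρ = 0.7, so calibration checks average several replicates.

## Synthetic cohort generator

The generator emulates every input the pipeline needs:

- **Acquisition scheme.** The 14-shell protocol (b = 10…3000 s/mm², 81
  weighted directions, 2 b0). Direction vectors are placed by a
  deterministic golden-angle spiral restricted to a hemisphere (antipodal
  directions are redundant for diffusion); exact placement is non-critical
  because fitting uses shell means.
- **Phantom.** 90 contiguous equal-size parcels on a configurable grid
  (default 24×24×12 for single-subject recovery studies; the end-to-end
  demo uses 10×10×6 to keep a 43-subject run at desk scale). Ground truth
  is region-wise constant: fractions (0.1, 0.2, 0.7), D_p = 2×10⁻² mm²/s
  (mid-range microvascular pseudo-diffusion), D_s = 7×10⁻⁴ mm²/s,
  CBF = 50 mL/100 g/min, with 10 % relative regional spread (shared
  anatomy) and 5 % between-subject jitter. The injured group receives
  configurable relative shifts in designated subcortical-like regions —
  default −15 % CBF, −15 % F_p, +3 % F_s, the expected mild-TBI direction —
  after which fractions are re-normalised to the simplex. Within-group
  biological variance is a free parameter, not calibrated to any cohort.
- **Noise.** DWI noise is Rician by default (magnitude of a complex
  Gaussian perturbation, σ = S0/SNR), Gaussian selectable for linear-theory
  tests; ASL noise is Gaussian per volume. At SNR ≥ 50 the Rician bias on
  the b0 mean is below 0.1 %.
- **Cohort.** 24 HC (12 F) and 19 mTBI (10 F) by default, ages ~29 ± 7 y;
  GOS-E is a deterministic monotone map from a latent source to integers
  3–8 with a discretised-normal profile centred at 6.4 (sd 1.1).
- **Block matrices.** For fusion tests, X_b = A·S_b + E_b with shared
  subject-mode sources A (unit-variance Laplace), block-specific sparse
  patterns and Gaussian noise; one source column can be shifted between
  groups by a configurable number of SDs.
- **Retest data.** The classic variance-components model
  y_iv = μ + u_i + e_iv, whose theoretical ICC σ_u²/(σ_u²+σ_e²) is returned
  alongside, optionally with spatially varying components for map-level
  reliability tests.

What the generator does **not** emulate: head motion, EPI distortion,
partial-volume mixing, physiological noise structure, scanner drift or
multi-site effects. Passing tests therefore demonstrate correctness of the
estimators and the fusion/statistics chain under the stated noise models,
not robustness to real-world acquisition artifacts.

## Problem sizes used in the shipped checks

Single-subject IVIM recovery uses the full 24×24×12 phantom at SNR 100;
fusion recovery uses 100 replicates of 200-subject, 90-ROI cohorts with a
1-SD planted group effect; null calibration uses 134 pure-noise 43-subject
cohorts (2010 ICs); ICC calibration averages eight n = 500 replicates.
These sizes were chosen so the whole verification runs comfortably on a
laptop-class single core.

## Known limitations

- F_p precision is bounded by the acquisition design: with only three
  directions per low-b shell, the information on a small fast-pool fraction
  is limited, and no estimator can do much better than ~9 % median relative
  error at SNR 100 under the default truth.
- RGCCA is implemented only for τ = 1 (covariance criterion).
- ICA component identifiability degrades when the joint matrix holds many
  noise-dominated columns relative to the subject count; order/sign
  conventions make runs reproducible but components are only defined up to
  the usual ICA ambiguities.
- The voxelwise ICC estimator assumes complete two-visit data; missing
  cells are rejected rather than imputed.
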