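# Methods

This note documents the models implemented in `pathstrat`, the assumptions
behind them, the defaults and why they were chosen, and what the synthetic
validation does and does not establish.

## Data model and preprocessing

The unit of analysis is a wide subject × feature table whose columns are
ROI–modality–hemisphere measurements named `<roi>_<MOD>_<HEMI>` with
`MOD ∈ {VOL, FA, MD, SBR}` and `HEMI ∈ {L, R, B, ASYM}`, plus reserved
clinical columns (`NP3TOT`, `NPTOT`, `MCATOT`, `QUIP_SUM`) and an `ICV`
column. Ingestion drops non-numeric columns, columns ending in `-std`
(per-ROI dispersion summaries that are nuisance for this analysis) and
columns with unparseable names; it removes rows containing NaN/inf and rows
in which *every* value of some imaging modality is exactly zero (read as a
failed acquisition for that modality, not as legitimate zeros elsewhere).
Every drop is recorded in a QC ledger, so rows_in = rows_out + rows_dropped
holds by construction.

Two normalizations are deliberately distinct:

* the **global z-transform** (cohort mean/SD per column, sample SD with
  ddof = 1) is the scale on which MPIS and all statistics operate;
* the **row/column normalization** used *only inside co-cluster training*
  standardizes columns then rows with population SD (ddof = 0). The
  population convention makes a matrix that already satisfies both
  constraints an exact fixed point, which is the behavior the training
  pipeline relies on; with sample SD there is no fixed point.

Zero-variance columns are excluded (and logged) rather than kept as zeros so
downstream covariance computations stay well posed. The asymmetry index is
(R − L)/(R + L); R + L = 0 yields a missing value and is left to row QC.

Feature views are nested subsets of the table: V1 (4 clinical scores),
V2 = V1 + 27 volumes + 17 SBR columns, V3 = V2 + 64 diffusion columns,
V4 = V2 + 96 free-water-corrected diffusion columns. The canonical schema
is much wider than any view (as a real metrics export is); view membership
is curated in `pathstrat.schema`, with a modality-based default rule for
tables from other sources.

## MPIS

For pathway p, MPIS is the signed, weighted sum of the bin's z-scored
features — FA, volume and SBR positive, MD negative — re-standardized
across subjects (sample SD). Properties that follow directly and are
enforced by tests: each MPIS column has mean 0 and SD 1 to 1e−9; the score
is invariant to rescaling all of a bin's weights (the final standardization
absorbs scale); permuting subjects permutes scores identically.

The six pathway bins (nigrostriatal, frontostriatal–executive,
cerebello–thalamo–cortical, limbic, microvascular, sensory/visuospatial)
are defined as ROI × modality member groups with sizes
(88, 128, 20, 80, 4, 112). Bins are nearly disjoint; the thalamus
(VOL/FA/MD) and the dorsal striatal SBR columns belong to both the
nigrostriatal and frontostriatal circuits, reflecting their shared role.
Asymmetry-index columns never enter MPIS by default: under the
"higher = more intact" convention an asymmetry has no defined sign.
Clinical columns never enter MPIS: it is an imaging composite.

Variants: *icv_normalized* divides raw volumes by intracranial volume
before re-z-scoring (ICV must be a column; it is never estimated);
*pathway_weighted* doubles SBR weight in the nigrostriatal bin and halves
volume weight in the microvascular bin (a minimal reading of "emphasize
dopaminergic markers / de-emphasize volumes", configurable);
*nonsigned_md* flips only the MD sign and serves as a negative control.

## Co-clustering (SRVCC)

Two VAEs are trained: rows (subjects, input dimension D) and columns
(features as samples of dimension N). Architecture per side: fully
connected encoder D→64→32 with tanh, linear heads for μ and log σ²,
latent d = 10, mirrored decoder. This is the smallest capacity that passes
the planted-recovery suite; there is no GPU requirement and the networks
run on the package's own reverse-mode autodiff engine (validated against
central finite differences in the tests).

The side loss is Σ‖x − x̂‖² (summed over input dimensions, averaged over
the batch) + β·KL(q(z|x) ‖ p(z)) with a Gaussian-mixture prior. The KL has
no closed form under a mixture prior and is estimated by a single-sample
reparameterized Monte Carlo estimator log q(z|x) − log p(z).

Coupling: with soft assignments Γ_r (N×Kr) and Γ_c (D×Kc) from the prior
responsibilities of the encoder means, the cross-tabulation is
T_org = Γ_r^T W Γ_c normalized to sum 1, with W = |X̃| the absolute
standardized data. (A plain Γ_r^T Γ_c does not typecheck for N ≠ D; the
data-weighted form is the minimal coupling that reduces to it when N = D
and W = I.) T_red replaces both Γ with one-hot hard assignments. The
coupling loss λ·ln(1 + (1 − MI(T_red)/MI(T_org))) is exactly zero when
hardening loses no association; the ratio is clamped to [0, 2−1e−6] and a
vanishing MI(T_org) disables the term with a warning.

Training schedule: (1) reconstruction-only pretraining; (2) k-means
(10 restarts) on the encoder means to initialize mixture weights, means and
variances; (3) joint Adam optimization with a linear KL warm-up β: 0 → 1.
Defaults: pretraining 40 epochs, joint 100 epochs, warm-up 30 epochs,
learning rate 1e−3, batch 64, λ = 1, validation fraction 0.20 (rows only;
the column model always sees full-length feature vectors). Pretraining
depth matters: with a substantially shorter pretraining the mixture is
initialized on an undertrained encoder and the joint phase cannot repair
the partition.

Two numerical guards proved essential. Prior component variances are kept
in [1e−2, 1] by clamping after every optimizer step: a near-degenerate
component produces KL gradients of order 1/σ² that destroy a perfect
initialization, and an unbounded component can inflate to swallow a
neighboring cluster. Hard labels are the arg max of responsibilities with
ties broken to the lowest index, making runs bit-reproducible for a given
seed. Inverse-frequency minibatch sampling by a cohort label is available
(off unless labels are supplied); labels never enter the loss.

## Model selection and stability

The grid (Kr, Kc) ∈ {3,…,7}² is scanned with five seeds per cell,
recording the final objective ℒ, held-out per-entry reconstruction error,
and the MI ratio (reported in the MI(T_org)/MI(T_red) orientation; the
coupling loss uses the reciprocal internally). Selection takes the smallest
cell — ordered by Kr + Kc, then Kr — whose median ℒ is within 2% of the
grid minimum. The objective, not held-out reconstruction, carries the
cluster-count signal in this model class: an under-clustered prior pays a
KL penalty for merged latent clusters, while the decoder reconstructs from
the encoder posterior and is largely indifferent to K (measured gaps in
validation reconstruction stayed under 1.5% even at 8σ separation, versus
>2% gaps in ℒ below the true K).

Seed stability retrains the selected model 10 times and reports all 45
pairwise ARI/NMI values on hard subject labels. Bootstrap stability draws
0.8·N subjects *with replacement* (100 resamples), refits, and compares
with the full-sample solution on the unique subjects present, counting each
duplicated subject once (first occurrence); resamples with fewer than Kr
unique subjects are skipped and counted. Row/column normalization is
computed once on the full cohort; resamples inherit that scaling. NMI is
normalized by the arithmetic mean of the label entropies; two constant
labelings score 1, exactly one constant scores 0.

## Statistics

* Spearman ρ uses average ranks; its p-value is the large-sample normal
  approximation z = ρ√(n−1) (two-sided); 95% CIs are percentile bootstrap
  over subjects (1,000 resamples). Constant inputs yield a missing ρ with a
  warning rather than an error.
* BH-FDR is applied per analysis table (e.g. all 18 pathway × outcome
  tests form one family).
* Kruskal–Wallis H is tie-corrected with a χ²(k−1) p-value; the rank
  effect size is η² = (H − k + 1)/(n − k), with k an explicit input.
* Cliff's δ = (#{a>b} − #{a<b})/(|a||b|), bootstrap CI resampling both
  groups. Cramér's V uses the Pearson χ² without continuity correction;
  Fisher's exact test replaces χ² for 2×2 tables with any expected cell
  below 5.
* Adjusted regressions are OLS with intercept; categoricals are one-hot
  with the first level as reference; rank-deficient designs raise an error
  naming the collinear columns. For cluster-indicator blocks the partial
  R² is (SSE_reduced − SSE_full)/SSE_reduced with a global F-test.
* Partition concordance reports NMI and ARI with permutation p-values
  (shuffle one labeling, add-one rule p = (1 + #{perm ≥ obs})/(1 + B), so p
  is never zero), 1,000 permutations by default.
* Complete-case analysis throughout; no imputation.

## Synthetic cohort generator

The generator emulates a baseline multimodal PD cohort at the tabular
level. Subjects carry a diagnosis (defaults 185 PD / 72 HC / 37 SWEDD), a
row-cluster label (default 4 clusters, uniform mixing), and six latent
pathway integrity factors u^(p) (standard normal, standardized exactly).
Raw imaging values follow

x_ij = M[r_i, c_j] + s(mod_j)·a_j·u_i^(p(j)) + ε_ij,  ε ~ N(0, noise_sd²),

with s(MD) = −1 so higher latent integrity lowers mean diffusivity, feature
loadings a_j = 1 by default (configurable per modality), and column blocks
c_j assigned by modality family (volumes / DaT / diffusion). The default
block pattern has zero-mean, pairwise affinely distinct rows so planted
strata stay distinguishable after the per-row normalization inside
training; defaults are shift scale 1.0 and noise_sd 1.0, i.e. moderately
overlapping strata, which is why the analysis drivers report partial rather
than perfect recovery at defaults — the exact-recovery guarantees hold at
5σ separation, as the tests assert.

Clinical outcomes are planted through a Gaussian copula: an outcome's
latent Gaussian score is Σ_p c_p u^(p) + σ_e e with c_p = 2 sin(π ρ_s/6),
the Pearson correlation whose bivariate-normal Spearman correlation is the
target ρ_s, then pushed through a monotone marginal transform (affine to
the target mean/SD, integer rounding, range clipping). Monotone transforms
preserve Spearman correlations exactly up to rounding ties; on the 30-point
cognition scale the tie attenuation is ≈ 0.005 in ρ, well inside the
validation tolerance. Default targets are the reported pathway × outcome
effect matrix; default marginals are motor 21.7 ± 9.6 (≥0), cognition
27.0 ± 2.2 (clipped to [0, 30]), impulsivity 4.5 ± 1.7 (≥0). Joint
feasibility (Σ c_p² < 1 per outcome) is validated at configuration time.

Within a (cluster, latent) cell, features are conditionally independent —
the within-cluster covariance of real regional metrics is unknown, and
independence given cluster and pathway factor is the documented assumption.
Covariates (age, sex, education, scanner field strength, medication) are
generated independently of imaging, matching a covariate-free clustering
design; outcome marginals are cohort-level (diagnosis-specific outcome
shifts are not modeled). No longitudinal structure and no site/batch
effects are simulated.

What passing on synthetic data shows: the pipeline recovers what was
planted — block structure, rank effects at reported magnitudes, view and
bin ledgers. What it does not show: robustness to the correlation structure,
missingness patterns, and confounding of real cohorts, which the generator
deliberately simplifies.

## Problem sizes

The test suite and the acceptance script run complete analyses at reduced
but structure-preserving sizes chosen as the smallest instances that
exercise every code path with unambiguous planted truth: co-cluster
recovery on 120–160 subjects × 40–60 features with shortened schedules
(which recover planted partitions exactly at 5σ separation), selection on
reduced grids around the truth, stability with 4–10 seeds and ≤ 8
resamples, and effect-recovery on 25 cohorts of n = 270–283 (the reported
per-pathway complete-case sizes). The analysis drivers under `analysis/`
run the full 294-subject cohort with the complete protocol (10 seeds ×
45 pairs, 100 bootstrap resamples, 1,000-draw bootstraps and permutations).

## Known limitations

* The KL estimator is single-sample; loss curves are noisy at small batch
  sizes, which is why convergence checks use full-data epoch evaluations.
* The mutual-information coupling uses a data-weighted cross-tabulation as
  a repair of a dimensionally inconsistent printed form; other readings are
  possible and the chosen one is documented, not asserted as canonical.
* Model selection depends on a parsimony tolerance (2%); very flat
  objective landscapes (weakly separated data) select the smallest grid
  cell, which is the intended conservative behavior.
* MPIS weights are fixed a priori, never learned; nonlinear composites are
  out of scope.
* The generator plants rank effects through a single shared latent per
  pathway; pathway–pathway correlation of integrity is not modeled.
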