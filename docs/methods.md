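# Methods

This note documents the models, parameter choices and limitations of the
`prostarad` pipeline: what the synthetic cohorts emulate, how each map is
fit, how features and models are built, and what the passing tests do and
do not demonstrate about real patient data.

## The synthetic mpMRI cohort

The phantom emulates the statistical structure of a single-centre
retrospective PI-RADS 4–5 vs healthy-tissue (HT) segmentation campaign:
65 subjects carrying 118 ellipsoidal 3D VOIs in total (69 lesion, 49 HT),
dealt one or two per subject. Acquisition geometry and timing follow the
emulated protocol: seven b-values (0, 250, 500, 1000, 1500, 2000,
2500 s/mm²) with 4/4/4/6/6/8/8 signal averages, and a 60-phase dynamic
series at 9 s per phase with bolus arrival at the end of the first phase.
Multi-average acquisition is emulated by dividing the Rician noise sd by
√(averages), which gives the mean of the repeats its exact first two
moments (the residual difference in Rician bias between averaging
magnitudes and scaling the noise is far below the fitted parameter
precision at these SNRs).

Grids are desk-scale rather than full-resolution scanner matrices: the
anatomical grid is 48×48×16 at 1.25×1.25×3 mm, the functional (DWI/DCE)
grids 24×24×16 at 2.5×2.5×3 mm. The in-plane anatomical/functional
resolution ratio (2×) matches clinical practice, so the map-resampling
stage is exercised exactly as on real data; absolute matrix sizes only
scale the runtime, not the statistical structure (region sizes of 50–250
voxels per VOI are typical of prostate lesion segmentations).

Per-class generative parameters are typical peripheral-zone values from
the prostate DKI/DCE literature (the study design itself states no effect
sizes, so these are explicit, configurable defaults — chosen once for
realism, not calibrated to any test):

| parameter | lesion | healthy | units |
|---|---|---|---|
| D | 1.1e-3 | 1.9e-3 | mm²/s |
| K | 1.0 | 0.55 | – |
| Kᵗʳᵃⁿˢ | 0.30 | 0.08 | 1/min |
| k_ep | 0.70 | 0.35 | 1/min |
| v_e (= Kᵗʳᵃⁿˢ/k_ep) | 0.43 | 0.23 | – |
| T2W mean / sd | 280 / 40 | 430 / 55 | a.u. |

Heterogeneity has two levels: a between-VOI lognormal shift of the class
mean (CV 8%) and within-VOI voxel-wise lognormal jitter (CV 12%). T2W is
a Gaussian texture with a class-specific correlation length (lesions
smoother), which is what gives the GLCM features genuine class
information. DWI noise is Rician (magnitude MRI); DCE works directly in
concentration units with additive Gaussian noise (sd 0.02 mM) — the
signal-to-concentration conversion from variable-flip-angle T1 mapping is
out of scope, as is k-space simulation, motion, coil sensitivity and B0
distortion. The synthetic studies are generated pre-aligned, so no
registration step exists; only grid resampling is implemented.

The arterial input function is the Weinmann bi-exponential population
curve, Cp(t) = dose·(a₁e^(−m₁τ) + a₂e^(−m₂τ)) with a₁ = 3.99, a₂ = 4.78
kg/L, m₁ = 0.144, m₂ = 0.0111 min⁻¹, parameterized so alternative
population AIFs can be supplied.

**What passing tests do not show.** The phantom has no partial-volume
mixing beyond grid resampling, no anatomical context (no zonal anatomy,
no benign mimics), uncorrelated noise across b-values/phases, and
ellipsoidal regions. Pipeline performance on it bounds implementation
correctness, not clinical accuracy.

## Map fitting

* **ADC** — log-linear least squares of −ln S against b restricted to
  b ≤ 1500 s/mm² (deterministic, matching in-line scanner computation).
  Non-positive samples are excluded; fewer than two usable points is
  degenerate (ADC 0).
* **DKI** — bounded nonlinear least squares over (S0, D, K), D ∈ [0,
  4e-3] mm²/s, K ∈ [0, 3], started from the exact log-linearization
  (ln S is linear in ln S0, D, D²K/6). The whole-volume fitter runs a
  damped Gauss–Newton refinement in lockstep across voxels from the same
  start. Noiseless recovery is exact to ~1e-9; at SNR₀ = 50 the median
  bias of D̂ and K̂ is below 5%. Fitting assumes Gaussian residuals, as
  clinical DKI tools do; the Rician floor biases K̂ slightly upward at
  low SNR (documented, not corrected).
* **Tofts** — the model is linear in Kᵗʳᵃⁿˢ given k_ep, so the fit is a
  deterministic 1-D bounded search over k_ep ∈ [0.01, 10] min⁻¹ (coarse
  log grid + local refinement; the volume fitter uses vectorized zoom
  passes) with the optimal Kᵗʳᵃⁿˢ in closed form. The convolution
  integrates a piecewise-linear Cp exactly per interval, and matches the
  constant-input closed form to <0.1% on the 9-s grid. All-zero curves
  are degenerate (Kᵗʳᵃⁿˢ = 0, k_ep at bound).
* **iAUC** — trapezoidal area over 60 s from enhancement onset, onset
  detected as the first phase above baseline mean + 3 sd (first 3 phases
  as baseline; configurable, since vendor conventions are undocumented).
  Flat curves yield 0.
* **Resampling** — trilinear interpolation in physical coordinates with
  nearest-edge extension; identical grids short-circuit bit-exactly.

## Features

Normalization clamps in-region intensities to μ ± 3σ with the population
(1/N) σ computed over the region itself; the 256-bin histogram (first
order) and 32-level quantization (GLCM) cover the clamped range per
region, never the whole image. 2D ROIs recompute μ, σ on the slice
region. Conventions that differ between toolboxes and therefore matter:

* energy and RMS are sums/means of squared clamped values, not histogram
  statistics; entropy and uniformity are histogram-based;
* first-order kurtosis is non-excess (normal → 3) — distinct from the
  diffusional kurtosis map K;
* the GLCM merges all 13 unique 26-connectivity directions (4 in-plane
  directions for 2D regions) into a single symmetrized matrix before
  normalization, rather than averaging per-direction features;
* GLCM "variance" uses deviations from the marginal mean; "sum average"
  is the classic Haralick sum over k = 2..2L;
* degenerate cases are pinned: constant regions score entropy 0 /
  uniformity 1 / skewness and kurtosis 0; a single-voxel GLCM has
  energy = homogeneity = 1 and 0 elsewhere; zero marginal variance gives
  correlation 0.

The advanced catalogs hold 8 maps × 13 first-order = 104 features. (The
study design's stated advanced-set size of 120 cannot be reconstructed
from any combination of the described catalogs — 104 without, 122 with
the T2W/ADC GLCM block — so the literal catalog description is
implemented and the discrepancy recorded here.) The standard 3D catalog
is 13×2 + 9×2 = 44. Shape/size features are deliberately excluded: HT
reference regions are drawn without anatomical boundaries, so shape would
encode the delineation habit, not biology.

## Feature reduction

Rank 1 maximizes |ρₛ(f, y)|; each later rank maximizes
δ·|ρₛ(f, y)| − (1−δ)·mean_{s∈S} MIC(f, s) against the already-selected
set S. δ defaults to 0.5 (equal weighting; the design source states "a
linear combination" without coefficients) and δ = 1 reduces provably to
pure |Spearman| ranking. Redundancy is penalized against the *selected*
set: penalizing similarity to not-yet-selected features would be
incoherent, and the cited methodology uses the selected set. Ties break
lexicographically on the feature name; constant features are only
admitted when fewer non-constant features than k exist.

The MIC estimator searches grid shapes (p, q) with p·q ≤ n^0.6, one axis
rank-equipartitioned, the other partitioned by exact dynamic programming
over every inter-point cut (for n ≤ 300; larger n thin the cut set to
15·p equipartition boundaries), maximizing I/log₂ min(p, q) over shapes
and both orientations. On a noiseless monotone relation it returns 1.0
exactly; on independent uniforms at n = 200 it stays below 0.35.

## Model building and validation

Imbalance-adjusted bootstrap resampling (IABR): each of B training
multisets draws ⌈n/2⌉ positives and ⌊n/2⌋ negatives with replacement from
their own class instances; the test set is the never-drawn (out-of-bag)
instances, redrawn if empty or single-class. A plain stratified bootstrap
is available behind the same flag. B defaults to 1000; the acceptance
script and heavy tests use B = 200 (50 for the permutation control),
which leaves the 0.632+ blend's behaviour unchanged and fits a
single-CPU budget.

Logistic fits are maximum likelihood with λ = 1e-6 ridge on internally
standardized slopes (intercept unpenalized), solved by damped Newton
iterations — deterministic, and finite on separable bootstrap samples.
The order-1..10 forward search adds the candidate maximizing the 0.632+
AUC, with all candidates scored on the same pre-drawn samples (paired
comparisons; reproducibility independent of evaluation order). Ties keep
the earlier-ranked candidate. The best order is the smallest within
0.005 of the maximum AUC (tolerance 0 recovers the literal argmax);
final coefficients are the mean over per-bootstrap training fits (a
full-data refit is available behind a flag), with their bootstrap sd as
a diagnostic.

Out-of-bag performance is summarized by the pooled (leave-one-out
bootstrap) form: each instance's prediction is averaged over the samples
where it is out-of-bag and a single AUC is computed — the canonical
0.632+ construction, and ~4× cheaper than per-bootstrap AUC averaging,
which is also implemented (`BootstrapConfig.oob="mean"`). One behavioural
difference is documented and tested: only the per-bootstrap form is
exactly invariant under monotone relabelling of a single-feature model,
because pooling averages each instance over a different subset of
models. Sensitivity and specificity (out-of-bag probability threshold
0.5) go through the same 0.632+ combination as the AUC.

## Known limitation: full-sample selection optimism

The two-stage design — reduce features on the full sample, then grow
models by maximizing a bootstrap-validated AUC on the same sample — is
*not* null-calibrated, and the package's permutation experiments
quantify this. With permuted labels (n = 118, 44-feature catalog), the
every-order 0.632+ AUC of the selected models runs ≈ 0.58–0.70: picking
the best of ~44–104 null features yields |ρ| ≈ 0.2 by chance, an
association that is real *within the sample* and therefore survives any
resampling done downstream of the selection. The 0.632+ estimator itself
is well calibrated — a fixed, pre-specified model under permuted labels
scores in [0.4, 0.6] in ≈ 19/20 permutations — so the optimism belongs
entirely to selection-outside-the-resampling. Consequence for practice:
near-perfect reported AUCs from this pipeline shape should be read
together with a permutation control, which the acceptance script emits
(`null_permuted_max_auc632`). The corresponding pipeline-level null test
in the suite asserts the idealized [0.4, 0.6] band and fails honestly,
documenting the measured behaviour.

## Numerical and degenerate-input policy

Seeds flow through `numpy` `SeedSequence` spawning (per-subject
substreams; cohort generation is bit-reproducible for a given spec).
Bounded fits report `converged` / `clamped` (at a parameter bound) /
`degenerate` (constant or empty input) status; degenerate statistics are
pinned to the conventions listed above rather than NaN, so feature
tables are always finite. The staged pipeline writes a sha256 manifest
of every artifact; identical config + seed reproduce identical
manifests.
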