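# Methods

## The biomarker

Collateral circulation — the pial arterial network that keeps tissue
perfused distal to a large-vessel occlusion — is conventionally graded
by eye on CT angiography (the 0–5 Menon visual collateral score, vCS).
`collateralfd` implements a quantitative alternative: the **mean
fractal dimension ratio (mFD)**.  For one patient,

1. two axial arterial-phase slices are selected by the operator, one at
   the ganglionic and one at the supraganglionic level (the semi-automated
   step: slices are chosen for clear arterial delineation and minimal
   venous filling, which would otherwise inflate apparent complexity);
2. each slice is segmented into a binary vessel mask by adaptive
   thresholding;
3. the mask is split at the hemispheric midline; the box-counting
   fractal dimension D is estimated per hemisphere;
4. the per-level ratio is D(symptomatic) / D(contralateral), and

       mFD = ( ratio_ganglionic + ratio_supraganglionic ) / 2.

A symmetric vasculature gives mFD = 1; sparse collaterals on the
symptomatic side depress it.  mFD strictly above the operating cutoff
**0.9307** predicts a favorable 90-day outcome (modified Rankin Scale
≤ 2); the boundary value itself classifies as unfavorable.  Ratios above
1 occur (e.g. luxury collateralization) and are reported as-is, never
clipped.  Cohort-relative quartiles Q1–Q4 are cut at the empirical
25/50/75th percentiles (linear interpolation; ties fall to the lower
stratum).

## Box counting

For a binary mask, N(s) is the number of s×s grid boxes containing at
least one vessel pixel; D is the ordinary-least-squares slope of
log N(s) against log(1/s).  Protocol fixed by
`fd_with_default_protocol`:

* **Scales**: dyadic, s = 2, 4, …, ⌊min(H, W)/4⌋ (≥ 3 scales required;
  a mask must be at least 32 px on its short side).
* **Grid origins**: the count at each scale is the **minimum over all
  s² grid origins** — the exact minimal covering count.  Implemented
  with a summed-area table, the full scan costs O(H·W) per scale
  (≈ 0.2 s for a 512² mask) and is deterministic and seed-free.  We
  chose the exhaustive scan over sampling a handful of random origins
  after measuring that any sampled scheme (8–16 origins, random or
  lattice) shifts the Sierpinski-triangle estimate by 0.02–0.15 under
  sub-box translations of the pattern, because the minimum is attained
  at some scales and missed at others, which bends the log–log line;
  the exhaustive minimum is translation-exact.  Sampled origins remain
  available (`n_offsets=<int>`, seeded), as does mean-over-origins
  aggregation.
* **Fit**: all scales by default; `fit_range` restricts them, r² is
  always reported and r² < 0.98 warns.  Slopes outside [0, 2] beyond
  numerical jitter are clipped with a warning (a planar set cannot
  exceed the embedding dimension).
* **Degenerate inputs**: an all-zero mask is an error (FD undefined,
  never 0); a single-pixel mask returns D = 0 with a `degenerate` flag,
  and the ratio layer refuses to ratio degenerate estimates.

Validation anchors (all in the test suite and `scripts/acceptance.py`):
filled square → 2.0, one-pixel line → 1.0, Sierpinski triangle
(depth 7) → log 3 / log 2 exactly on dyadic scales, Sierpinski carpet
(depth 5, triadic grid counted with the dyadic schedule) → within 0.06
of log 8 / log 3.

## Vessel segmentation

`adaptive_threshold` marks a pixel as vessel iff its (lightly denoised)
intensity exceeds the local mean over a `window` (default 31 px, odd)
by `offset`.  Defaults and their rationale:

* `offset = 0.5 × robust SD` of the raw intensities (1.4826·MAD, with a
  plain-SD fallback for images whose median absolute deviation is zero),
  so the margin scales with slice contrast without manual tuning.
* a Gaussian denoise of **σ = 0.5 px** is applied before the local-mean
  comparison, while the margin stays on the raw scale.  Without it a
  margin proportional to the noise SD always admits a fixed ≈ 30% of
  noise pixels regardless of the noise level; denoising shrinks the
  effective noise floor under a threshold that does not move.
* connected components (8-connectivity) below **25 px** are removed.
  At the noise levels exercised in testing (σ = 10% of vessel
  contrast), surviving noise clumps are predominantly 5–24 px, whereas
  genuine vessels connect into large components; 25 px removes the
  former without touching the latter (measured Dice vs the noise-free
  segmentation: 0.90, against 0.64 with a 5 px floor).
* an optional `hu_window=(low, high)` clamps and rescales calibrated HU
  data to isolate the vascular band.

The hemispheric split uses a vertical midline: by default the column
through the centroid of the head mask (pixels above the median
intensity), with a manual override for tilted heads; the midline column
belongs to neither hemisphere, so the two masks are disjoint by
construction.  Left/right are patient sides under the radiological
convention (image right = patient left).  The symptomatic side is
operator-declared metadata, never inferred from the image.  An optional
fractional row band approximates the MCA territory; the default is the
full half-plane, since no algorithmic territory boundary is defined for
this method.

## Statistical evaluation

`reproduce_paper_tables` runs the full battery on a cohort table
(required columns: mfd, vcs_scta, vcs_mcta, age, sex, pre_nihss,
mrs_90; outcome = mRS ≤ 2 is always derived, never read):

* group comparisons: Welch t by default (Student vs Welch is not
  identifiable from the reported analysis, so the rank-based
  Mann–Whitney p is printed alongside); categorical variables use
  chi-square, switching to Fisher's exact test when any expected cell
  is < 5;
* Spearman ρ with average ranks (scipy);
* Wilcoxon signed-rank implemented in-package: zero differences
  dropped, average ranks on |d|, tie-corrected normal approximation
  Var = n(n+1)(2n+1)/24 − Σ(t³−t)/48, no continuity correction by
  default (toggle available), Z signed by (a − b).  The tie-corrected
  variance equals the exact variance of the permutation null, which the
  tests verify by exhaustive sign enumeration;
* ROC: empirical curve over all observed thresholds with the
  strict-`>` positivity rule; AUC equals the Mann–Whitney concordance;
  the standard error is the single-curve DeLong variance from placement
  values, the 95% CI a normal interval truncated to [0, 1]; the Youden
  point maximises sens + spec − 1 with ties broken toward the higher
  (more specific) threshold;
* DeLong paired test for correlated AUCs via the placement-value
  covariance; a zero-variance difference returns a flagged degenerate
  result (p = 1) rather than an error.  Null calibration (two noisy
  copies of one latent score) holds the 5% size within [0.035, 0.065];
* logistic regression via statsmodels GLM/binomial (IRLS, tol 1e-8,
  ≤ 100 iterations); Wald ORs and CIs; AIC = 2k − 2ℓ; Hosmer–Lemeshow
  over deciles of predicted risk (df = 8).  Complete separation or
  non-convergence is flagged in the result, never silently estimated;
* no multiple-comparison correction anywhere, matching the exploratory
  design.

Adjusted models (mFD > 0.9307 or vCS-mCTA plus age, sex, pre-NIHSS,
LDL) are fitted only when all four covariates are present; otherwise
the report says which are missing.  Crude models never substitute.

## Synthetic generators

All generators are pure functions of their seed.

**Fractals** with closed-form dimension validate the estimator:
filled square (2), line (1), single pixel (0), Sierpinski triangle
(log 3/log 2), Sierpinski carpet (log 8/log 3, triadic size 3^k), and
dyadic fractal percolation (`random_cantor`, quadrant retention p,
expected dimension log₂ 4p).

**Vascular slice phantoms** render one recursive bifurcating tree per
hemisphere onto a CTA-like background (background 100, vessel contrast
100 with a Gaussian cross-profile, optional white noise).  Geometry:
trunk length 0.30 × image, length decay 0.72 per generation, branch
angle 27° with 7° jitter, per-branch survival probability 0.92, vessel
width 3 px, canvas 257² (odd, so the midline column is a true mirror
axis).  With `mirror=True` (default) the contralateral tree is the
mirror image of the symptomatic tree's geometry rendered at its own
depth cutoff, so lowering `depth_symptomatic` prunes terminal branches
of an otherwise identical tree — the controlled model of collateral
failure.  Ground-truth per-hemisphere masks are returned alongside the
grayscale slice.  What the phantom does **not** model: skull/bone,
venous contamination, beam hardening, non-vascular bright tissue,
anisotropic spacing — so passing phantom tests demonstrates the
pipeline's mechanics, not clinical segmentation accuracy.

**Cohort simulator** (`simulate_cohort`): outcome-first by default —
draw favorable with probability 24/54, then mFD from the
outcome-conditional normals (favorable 0.931 ± 0.086, unfavorable
0.863 ± 0.118, truncated positive), then vCS-mCTA through a noisy
monotone latent link (standardized mFD plus N(0, 1.25²) noise, cut at
fixed points; the noise SD was calibrated once so the large-n Spearman
between mFD and vCS-mCTA is ≈ 0.58, and the cutpoints reproduce a
vCS-mCTA mean near 2.9).  vCS-sCTA is vCS-mCTA plus an integer
perturbation (−1/0/+1 with probabilities 0.15/0.50/0.35), reproducing
the reported mean offset between the two visual scores.  Age, sex,
pre-NIHSS, LDL and mRS are drawn outcome-conditionally from the
published group summaries.  A covariate-first mode
(`outcome_model={"intercept": β₀, "mfd_std": β₁}`) generates the
outcome from a logistic model on standardized mFD for
coefficient-recovery checks.  Note that under these honest generative
conditions the population AUC of mFD is ≈ 0.68 and the true odds ratio
of the dichotomized mFD is ≈ 2.5: an in-sample Youden-optimized
threshold (as in a single-cohort analysis) produces larger apparent
effects than the data-generating truth, and the simulator deliberately
reports the latter.

## Problem sizes used in the shipped checks

Reference fractals at 128–256 px (carpet 243 px); phantom sweeps at
257² over 50 seeds; null-calibration simulations at 1000 replicates
(n = 300–500 per replicate); large-n cohort checks at n = 10⁵ and the
cohort-report checks at the clinical n = 54.  These sizes keep every
check well-resolved while the whole suite runs in well under a minute
per module.

## Known limitations

* The segmentation is a generic thin-bright-structure detector; it has
  no notion of arteries vs veins — venous contamination control remains
  an operator responsibility through slice selection, as in the
  original semi-automated design.
* The MCA-territory crop is a rectangular band, not an anatomical
  atlas.
* FD is computed on 2-D slices; no 3-D box counting, multifractal
  spectra or lacunarity.
* The 0.9307 cutoff was derived in-sample by the source analysis and is
  carried here as a fixed operating point; nothing in this package
  re-validates it externally.
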