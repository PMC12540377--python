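# Methods

This note documents the models, conventions and numerical choices behind
`scvq`, what the synthetic generators do and do not emulate, and the known
limitations.

## MinIP reconstruction

An SWI magnitude volume is tiled along the axial slice axis into slabs of
`thickness_mm` (default 20 mm) separated by `gap_mm` (default 1 mm) of
unprojected tissue, i.e. the stride between slab starts is thickness + gap.
The alternative reading — slabs overlapping by the "gap" — was rejected
because thickness/gap pairs in clinical reformat dialogs denote exactly this
stride convention. Each slab pixel is the minimum intensity over the slab's
slices, which is what makes hypointense veins stand out. A trailing partial
slab is kept (and flagged) when it is at least half the nominal thickness,
otherwise dropped; a volume thinner than one slab yields a single flagged
slab with a warning rather than an error.

Window/level mapping to 8 bits is linear: intensities at or below
level − width/2 map to 0, at or above level + width/2 to 255, with
round-half-up after clamping. The clinically used ranges are width 40–65 and
level 30–45; the choice within those ranges is operator-dependent, so both
parameters are explicit arguments everywhere. Export defaults to PNG even
though clinical workstations commonly export JPEG: JPEG block artifacts
perturb downstream masks, so the lossy dialect is opt-in (quality 95).

## Vessel masks

Masks are binary rasters aligned to a slab, with provenance `annotation`
(rasterized polygons), `model` (an external segmentation model's output) or
`baseline`. Training a segmentation model is out of scope — the mask is the
interface. Polygon rasterization fills each polygon by the even-odd rule
over pixel centers, boundary inclusive (an axis-aligned square with corners
at 10 and 20 covers the 11 × 11 pixel centers), and unions polygons.

The baseline segmenter marks pixels *strictly* darker than a within-image
intensity percentile (default 10th), then removes 8-connected objects
smaller than `min_object_px`; strict inequality makes a uniform image yield
an empty mask. Evaluation reports pixel accuracy (TP+TN)/total — the
convention behind headline segmentation accuracies, inflated by background
on sparse vessel images — together with Dice 2TP/(2TP+FP+FN), defined as 1
for two empty masks. Foreground connectivity is 8 throughout the package.

## Morphometry

One 8-connected component = one vein. Branch points are not decomposed: the
curvature definition (arc over chord "between the two ends") presupposes a
single end-to-end curve, so the vein's centerline is the *geodesic diameter*
of its morphological skeleton — the longest shortest-path in the skeleton
graph (edge weights 1 axially, √2 diagonally), located by a double sweep
(farthest node from a fixed start, then farthest from that) with
lexicographic tie-breaks for determinism.

Metrics, with in-plane spacing default 0.8 mm:

* **Length** — the Euclidean step sum along the path after a small
  moving-average smoothing of the coordinates (window 7, endpoints
  anchored). Raw 8-connected step sums overestimate oblique digital curves
  by up to ~8% (staircase bias); coordinate smoothing restores the polyline
  to the underlying smooth curve while leaving axis-aligned and 45° paths
  exact. On the default phantom this brings length errors from ~5% to
  below 1%.
* **Chord** — endpoint-to-endpoint distance, anisotropic spacing applied
  per axis.
* **Curvature (tortuosity)** — length/chord ≥ 1. A component whose chord is
  shorter than one pixel (a closed loop) gets curvature 1.0 and a flag, to
  keep subject means finite.
* **Diameter** — mean ribbon width: component area divided by centerline
  length. For a digital strip this estimator is unbiased at every
  orientation; sampling the Euclidean distance transform along the path was
  measured to underestimate the half-width of oblique strips by up to
  ~0.5 px, because the transform measures to the nearest background pixel
  *center*. Blob-like components (path under one pixel) fall back to the
  distance-transform estimate. The mean (not maximum) width is used so that
  caliber taper does not dominate.

Hemisphere assignment sends each component wholly to one side by the
majority of its skeleton pixels relative to the midline column (default
width/2); under the radiological display convention the image-left half is
the subject's right hemisphere (configurable). Components with skeletons
shorter than `min_skeleton_px` (default 5 px ≈ 4 mm) are discarded as noise
specks. Subject summaries sum counts over slabs without cross-slab
deduplication — per-slice bookkeeping, which is what makes subject totals of
several hundred veins reachable — and average diameter/curvature/length over
segments (not slabs); a side with no segments has count 0 and missing means.

## Cognitive staging

Stages are ordered NC < SCD < SCD-plus < MCI. MCI is actuarial: a score is
impaired when it is worse than `z_cutoff` (default 1.0) standard deviations
from its normative mean in the disadvantaged direction — the cutoff is not
standardized across studies, so it is a parameter — and MCI holds with two
impaired indicators in one cognitive domain (memory: AVLT long-delay and
recognition; execution: STT-A/B, timed so higher is worse; language: AFT,
BNT), one impaired test in each of the three domains, or FAQ ≥ 9. SCD
requires an affirmed chief complaint of sustained decline that is affirmed
*not* acute in onset, without meeting MCI. SCD-plus additionally requires
concern about the decline (the mandatory condition) plus, by default, at
least one of the seven other risk conditions (memory-specific decline,
onset < 5 years, onset age ≥ 60, worse than peers, informant confirmation,
ApoE-ε4 carriage, AD-biomarker positivity); whether concern alone should
suffice is genuinely ambiguous in the published rule, so
`concern_alone_suffices` exposes the other reading. Tri-state (unknown)
condition values never satisfy a rule, the conservative choice. MCI
dominates everything; every decision carries a fired-rule trace.

## Statistical battery

* **Normality**: Shapiro–Wilk below n = 50, Kolmogorov–Smirnov with
  Lilliefors correction (parameters estimated; p-values by the
  Dallal–Wilkinson approximation, which simulation shows calibrated at
  large n) at or above 50 — the dispatch rule of the classical clinical
  workflow this package mirrors.
* **Group comparisons**: all groups normal → one-way ANOVA (k ≥ 3) with
  Bonferroni post hocs under Levene-homogeneous variance (α = 0.05) or
  Tamhane-T2 (Welch pairwise with Šidák adjustment) otherwise, or the
  independent t-test (k = 2); any group non-normal → Kruskal–Wallis with
  Bonferroni-multiplied pairwise rank-sum post hocs, or the two-sample
  rank-sum test reported in the Wilcoxon-W convention (rank sum of the
  smaller group). Dispatch decisions are logged in a trace.
* **Contingency tables**: Pearson χ² with expecteds from the margins;
  whenever any expected cell lies in [1, 5) the Yates continuity correction
  (|O−E| reduced by 0.5, floored at 0) is applied to all cells, *also* for
  r×c tables larger than 2×2 where this is nonstandard — the rule is applied
  verbatim as stated by the workflow being reproduced, and the uncorrected
  statistic is always reported alongside. Expecteds below 1 trigger a
  warning recommending an exact test. Column-proportion z-tests compare
  row-conditional proportions within each column with pooled variance and
  Bonferroni adjustment.
* **Correlation**: Pearson when both vectors pass the normality dispatch,
  Spearman (average ranks for ties) otherwise; two-sided p values.
* **Ordinal regression**: proportional-odds cumulative-logit model in the
  PLUM sign convention, logit P(Y ≤ j) = θ_j − x'β, so a positive β means
  higher odds of a worse stage. The likelihood is maximized by statsmodels'
  ordinal model; thresholds are mapped back to the natural scale with
  delta-method standard errors. Wald χ² = (estimate/SE)², 95% CI =
  estimate ± 1.96 SE. The model-fit LR test compares against the
  closed-form intercept-only likelihood; goodness of fit reports Pearson and
  deviance statistics over distinct covariate patterns. The parallel-lines
  test fits the generalized cumulative model (one slope vector per
  threshold) by direct maximum likelihood — cell probabilities are clipped
  at 1e−12 because the unconstrained alternative can wander through
  non-monotone configurations — and compares likelihoods on
  (K−2) × p degrees of freedom; simulation at n = 200 puts its type-I error
  at ~4.6%.

Two-sided p values and α = 0.05 throughout. Missing data are handled by
complete-case analysis only.

## Synthetic data

**Phantoms.** Dark tubes (vessel intensity 40) on a bright background (200),
optional Gaussian noise, quantized to 8 bits; the truth mask is the
noiseless tube support (pixel centers within one tube radius of the
centerline). Three centerline families with independent analytic truth:
straight lines (closed form), circular arcs (rθ), sinusoids (adaptive
quadrature at 1e−8 relative tolerance). The default spec has 12
non-overlapping tubes, six per hemisphere, radii 1.2 mm, lengths ≥ 150 px so
that skeleton end-retraction (about one tube radius per end) stays well
inside the 3% recovery tolerances. Phantoms emulate the *geometry* of MinIP
vein images — they have none of the background texture, vessel-caliber
variation, crossing vessels, partial-volume fading or susceptibility
artifacts of real SWI, so passing recovery bounds validates the measurement
chain, not segmentation difficulty on real data.

**Cohorts.** Subjects are drawn per stratum (default: the male/female strata
of the reference cohort, n = 184/180) with vein features normal around the
stratum mean and sd = SE·√n, since the reference summaries are reported as
mean ± SE. Hemisphere counts are generated as a total times a right-side
share (≈ 0.509), so number_total = number_right + number_left holds by
construction; curvatures are truncated at 1.0 to respect the metric's
definition. The cognition stage is drawn from the proportional-odds model at
the subject's own features (default effects: right-hemisphere curvature 8.0
per unit, right length −0.33 per mm, echoing the direction and scale of the
reference regression), with thresholds placed so the cohort-mean predictor
reproduces the reference stage proportions (104/104/79/77). Biomarkers
(Aβ1-42, T-tau, P-tau181) and the 3-level tea habit are tied to features
through a Gaussian copula: continuous-margin targets use the exact latent
conversion ρ = 2 sin(π r_s/6); the discretized tea margin attenuates rank
correlation, so its latent correlation is calibrated by root-finding on a
fixed common-random-number sample to hit the target Spearman (−0.227 with
T-tau) after discretization. Within-stratum features are otherwise
independent — the reference reports no within-subject correlation structure
— which is the main respect in which simulated cohorts are cleaner than real
ones. The default global seed is 20251008; every generator takes a seed.

## Problem sizes in tests and the acceptance script

Calibration checks use 500–1000 null simulations (omnibus tests and the
parallel-lines test at n = 200, K = 3) and 150 replicates at n = 2000 for
ordinal coefficient recovery, reported as the fraction of coefficient
estimates within 2 SE of truth (nominal coverage 95.4% per coefficient; a
both-coefficients-jointly criterion would have nominal coverage ~91% and is
not what a 93% bar can mean). These sizes keep a full run around a minute on
one CPU while leaving binomial noise well inside the stated tolerance bands.

## Known limitations

* 2D per-slab analysis: veins spanning adjacent slabs are counted in each,
  and no 3D tracking or deduplication is attempted (matching the per-slice
  bookkeeping the package reproduces).
* The geodesic-diameter centerline ignores side branches entirely; a
  branch-rich vein contributes only its longest limb to length/curvature.
* The skeleton of a mirrored mask is not the exact mirror (thinning is not
  reflection-equivariant), so metrics under horizontal flip agree only to
  ~1–2%, with hemisphere labels swapping exactly.
* The published sex and age cross-tabulations are internally inconsistent
  (their per-stage column totals disagree with each other, 105 vs 103 in the
  SCD column, and with the overall stage counts), and the χ² statistics
  printed for them (8.963, 38.483) do not recompute from the printed counts
  (recomputation gives 8.713, 38.633). The education and career tables do
  recompute exactly; only those anchor reproduction checks.
* Fitted regression coefficients of the reference analysis (e.g. 8.153 for
  right-hemisphere curvature) are not reproducible without the original
  subject-level data, which are not public; what is checkable — and checked —
  is the model structure (K−1 thresholds, reference levels, Wald and CI
  identities, the sign convention) and parameter recovery on simulated data.
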