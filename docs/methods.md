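# Methods

## Scope and model

The package quantifies 2-D microvessel morphology inside a nodule ROI and
classifies nodules from the resulting biomarkers. It deliberately separates
image formation (slow-time ensemble → power image) from quantification
(image → biomarkers → classifier), so analyses can start at whichever stage
data exist for. No acoustics are modelled: beamforming, IQ demodulation and
motion correction are out of scope, and the slow-time generator emulates only
the algebraic structure the clutter filter relies on (low-rank, slowly
varying, high-amplitude tissue + weak moving blood + white noise).

## Clutter filtering

The stack is reshaped to the Casorati matrix (pixels × frames) and the
leading `rank_cutoff` right singular vectors are projected out; an optional
high cutoff removes the noise tail. The filter is exposed both as a one-call
`svd_clutter_filter` and as a fitted `ClutterFilter` object, because an
orthogonal projection is idempotent only when the *fitted* subspace is
reapplied — re-estimating the SVD on filtered data would remove the next
components instead. The default cutoff is 2 (the synthetic fixtures' tissue
rank); `suggest_rank_cutoff` offers a knee-of-the-singular-value-curve
heuristic for data where the rank is unknown. Real and complex stacks are
accepted; power is mean squared magnitude over frames.

Validation constructs mixtures whose blood term is projected off the tissue
temporal subspace (`orthogonal_blood=True`), making the decomposition exact;
with realistic (non-orthogonal) blood the filter still strictly increases the
blood-to-tissue energy ratio, which is the property that matters in use.

## Vessel enhancement

Vesselness is the Frangi measure computed on Hessian eigenvalues scaled by
sigma² (gamma-normalized derivatives). The normalization matters: without it
the per-scale responses decay with sigma and the maximum over scales always
selects the smallest scale; with it, a Gaussian ridge of profile sigma_r is
maximally enhanced near sigma = √2·sigma_r, so the scale maximum adapts to
vessel width. Defaults: scales {1, 2, 3, 4} px (vessel radii ≈ 1.5–6 px at
the 40 µm pixels of the synthetic images), beta = 0.5, adaptive gamma (half
the maximum Hessian norm per scale).

Binarization defaults to Otsu-seeded hysteresis (low threshold = 0.65 × the
in-ROI Otsu value): plain Otsu under-segments vessel borders on dense masks
(round-trip Dice ≈ 0.88 on noise-free malignant-like images), while
hysteresis keeps the border pixels connected to confident ridge seeds
(Dice ≥ 0.92 for both phenotypes). Cleanup is closing with a 1-px disc
*before* removing 8-connected components under 30 px, so speckle-broken
vessels are reconnected before the size filter judges them.

## Skeleton graph

Thinning is `skimage.morphology.skeletonize` (topology preserving).
Connectivity is 8 throughout. Branch pixels (≥ 3 skeleton neighbours) are
clustered with 8-connectivity into one node each — thinning emits 2×2
junction clusters, and without merging, NB is inflated and an X-crossing
becomes several branch points instead of one node with four segments.
Degree-1 pixels are endpoints; remaining degree-2 pixels form chains;
isolated cycles are anchored at one pixel and kept as loop segments.

Spur pruning removes terminal segments shorter than `min_spur_px` (default
5 px ≈ the smallest fixture vessel radius) whose far end is a branch node,
re-thins, rebuilds, and iterates to a fixpoint — which is what makes the
operation idempotent and lets branch nodes reduced to degree 2 merge their
two segments. An accounting invariant (chains ∪ node clusters = skeleton
pixel set) is tested.

## Morphometrics

* **Diameter.** Local diameter at a chain pixel is 2 × (EDT − 0.5 px),
  where the EDT value is the 3×3-neighbourhood maximum of the Euclidean
  distance transform. The neighbourhood maximum compensates the ≤ 0.5 px
  off-axis wander of the thinned centerline; the half-pixel term corrects
  the center-to-center overshoot of the EDT relative to the true boundary.
  The residual lattice error is bounded by ±1 px across orientations (the
  bound is attained by axis-aligned integer-radius tubes). D_max summarizes
  segments by their *mean* local diameter (max-of-means), which is robust to
  single-pixel distance-transform spikes at junctions.
* **Tortuosity.** Chains are resampled every 4 px before arc-length
  measurement; raw 8-connected step sums overestimate smooth curves by up to
  ~7% (staircase bias), while the resampled polyline is within 2% of the
  closed-form arc length of the generator's sinusoids. Segments with chords
  under 2 px are excluded (degenerate geometry); DM is clipped at 1 from
  below.
* **Murray deviation.** At each junction the parent is the largest-mean-
  diameter incident segment (no flow direction exists in a static mask);
  MD = |d_p³ − Σd_c³| / max(d_p³, Σd_c³) ∈ [0, 1). The bounded form matches
  the magnitude of published per-nodule values.
* **Bifurcation angle.** Each child's direction is the unit vector from the
  node to its chain point at arc distance `k`; the angle is between the two
  largest-diameter children. Default k = 20 px: thinning displaces the
  junction node by roughly one vessel radius into the parent, which biases
  short-probe angles by >10° at k = 10 for 3–5 px radii; k of a few radii
  keeps recovery within 5° at 60/90/120°. k is configurable and validation
  uses k = 30 on its long-segment fixtures.
* **Fractal dimension.** Box counting on the vessel mask clipped to the ROI
  bounding box, grid anchored at the box corner, sizes = powers of 2 from
  2 px to min(shape)/4, dimension = least-squares slope of log N(s) vs
  log(1/s). Verified against a line (1), a filled square (2) and a depth-7
  Sierpinski raster (log3/log2).
* **VDR / SVP.** The ROI is eroded by a unit disc until its area is closest
  to half the ROI area; VDR = VD(center)/VD(periphery); SVP is intratumoral
  when VDR ≥ 1 (the natural balance point of a ratio), peritumoral
  otherwise; an avascular periphery yields VDR = ∞, intratumoral.
* Undefined markers (no segments, no junctions, empty mask) are NaN and
  listed in `BiomarkerSet.missing`, never silently zero.

## Statistics and classification

The Wilcoxon rank-sum test uses midranks; `auto` mode enumerates all rank
assignments when n_x + n_y ≤ 12 (exact, tie-safe) and otherwise applies the
normal approximation with tie-corrected variance and 0.5 continuity
correction. Screening keeps biomarkers with two-sided p < 0.05, in panel
order. By default screening sees the full cohort — mirroring a
screen-then-model analysis — with a leakage-safe `screen_on="train"` variant
recommended for new studies.

The split is stratified 70/30 (the minority class is small enough that an
unstratified split can starve a fold). The SVM uses an RBF kernel;
hyperparameters are chosen by 5-fold stratified CV AUC over C ∈ 10^{−2..3}
and kernel widths 2^{−4..4} × the median positive pairwise distance of the
standardized training points (zero distances are ignored so exact duplication
does not move the heuristic). Standardization is fit on the training split
only. The ROC uses all score thresholds; AUC is trapezoidal with a DeLong
95% CI (structural-components formulation); the operating cutoff minimizes
the Euclidean distance to (FPR 0, TPR 1), with ties broken toward higher
specificity. A single-class test set raises rather than reporting a
meaningless AUC.

## Synthetic data: what it emulates, and what it does not

Trees are binary: diameters follow Σd_c^γ = (1 − δ)·d_p^γ with equal
children and γ = 3, so the measured Murray deviation equals δ exactly and
children taper downstream (keeping the largest-diameter parent rule
truthful). Children leave at ± half the branch angle around the parent
chord; tortuosity is one sinusoid per segment (closed-form arc length for
oracles); rasterization paints pixels whose centers fall within the local
capsule radius, making painted area exactly checkable per pixel. Phenotype
defaults encode the malignant signature — 4 trees of depth 4 vs 2 of depth
3, 60° vs 120° bifurcations, δ = 0.55 vs 0.15, four-fold tortuosity
amplitude, thicker roots — with roots stratified around the ROI rim because
tree crossings create spurious junctions that dilute the angle and Murray
contrasts. Speckle is multiplicative Gaussian plus a Rayleigh-like floor.

Cohorts are drawn per label from truncated normals matching published
benign/malignant mean ± SD for each biomarker on its legal domain (counts
rounded to non-negative integers); no inter-biomarker correlation is imposed
by default because only marginal summaries are published — a Gaussian-copula
hook exists. Several published SDs are implausibly small (e.g. NV
49.00 ± 1.41 benign), which makes the synthetic classification task easier
than the clinical one; the cohort generator therefore validates pipeline
plumbing, not clinical performance, and published p-values are not expected
to be reproducible from these summaries.

None of the synthetic constructions include out-of-plane motion, depth-
dependent resolution, acoustic shadowing, vessel networks with anastomoses,
or segmentation errors of a human-drawn ROI; passing tests demonstrate
correctness of the measurement chain, not clinical accuracy.

## Problem sizes and numerical choices

Validation uses 25 trees per parameter setting on 512² canvases (768² at
25 µm/pixel for Murray recovery, where thin-child lattice errors would
otherwise dominate), 20+20 phenotype images at 256², 1,000 permutations for
the type-I error of the screen, and a 200-nodule cohort for the end-to-end
AUC; the whole validation suite reruns in about a minute. Determinism:
every generator is a pure function of its spec and an integer seed
(numpy `default_rng`); pipeline artifacts are byte-identical under a fixed
seed and config, and the run manifest records a SHA-256 of the canonical
config JSON.

## Known limitations

2-D only; single-sinusoid tortuosity cannot express coiling or kinking;
bifurcation angles of very short children saturate toward the junction
geometry; diameter accuracy is lattice-limited to ±1 px; the SVP threshold
(VDR = 1) and center construction (erosion to half area) are reasonable but
not uniquely determined by the literature the biomarker derives from; and
classification numbers on synthetic cohorts should not be compared against
clinical studies.
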