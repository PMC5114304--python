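# Methods

## Scope and model

`myelinmap` compares six myelin-sensitive MR parameters — R1, T1w, T2*,
T2*w, T1w/T2*w, R1/T2* — as per-vertex maps on a triangulated cortical
surface, using FWHM-normalized coefficients of variation, parcellability
variation, CNR per unit scan time, depth-resolved correlations, and two
areal-border methods. Because the statistics are defined on generic
per-vertex maps, they apply equally to real surface-mapped data (GIFTI
metrics or CSV vertex tables) and to the package's synthetic phantom; all
development-time and test-time numbers come from the phantom.

## The synthetic phantom

### Geometry and atlas

The cortex is an icosphere (default: subdivision 4, radius 15 mm, 2562
vertices, ~1 mm edges — edge lengths comparable to a high-resolution
cortical mesh) or a planar patch for analytic validation. The atlas grows 13
contiguous ROIs from farthest-point seeds — nine heavily myelinated analogs
(BA1/2/3/4, V1, V2, MT, transverse-temporal gyrus and sulcus), three
moderate (BA6/44/45), one light (retrosplenial analog) — and labels the
remainder lightly myelinated background. Because the background is the
complement of the grown patches, every ROI borders lightly myelinated
cortex, which serves as its CNR reference region.

Icospheres have constant geometric curvature, so a smooth seeded
pseudo-curvature field (`synthetic_curvature`, sd 0.1 mm⁻¹, 4 mm FWHM)
stands in for the gyral/sulcal folding pattern; a configurable coefficient
(default 0.1 s⁻¹ per mm⁻¹) injects a curvature-correlated component into R1
so curvature residualisation is exercised with a known ground truth.

### Ground truth

Mid-depth class means are R1 = 0.55/0.515/0.48 s⁻¹ and T2* =
0.026/0.030/0.034 s for heavy/moderate/light cortex — 7 T cortical gray
matter sits near R1 ≈ 0.5 s⁻¹ and T2* ≈ 0.03 s, with heavily myelinated
cortex faster-relaxing on both axes. A shared smooth "myelin anomaly" field
(sd 0.03 s⁻¹) modulates R1 identically in all subjects; the class gaps are
deliberately small relative to the within-class spread so the value
histogram is unimodal-skewed like a real cortical distribution rather than
a mixture of separated modes (separated modes make half-maximum widths
knife-edge unstable). The resulting depth-averaged R1 distribution has a
raw FWHM of order 0.1 s⁻¹ and T2* of order 0.006 s — the right orders of
magnitude for cortical relaxometry at 7 T.

Depth profiles are linear in depth fraction: R1 falls by 12 % and T2* rises
by 8 % from the white-matter boundary to the pia. T2* couples negatively to
the myelin anomaly with a coefficient that decays by 70 % toward the pial
surface, so the R1-vs-T2* anticorrelation is strongest in deep cortex and
weakens superficially — the depth structure the correlation analysis is
meant to resolve.

Inter-subject variation is multiplicative and log-normal at two scales:
per-ROI factors (sd 0.03 for R1, 0.05 for T2*) plus a per-subject smooth
field (sd 0.03 / 0.08). The transversal parameter is given the larger
inter-subject variability: T2* is susceptibility-weighted and in practice
much less stable across heads than R1. 1.5 % of vertices are flagged as
vein artifacts with ground-truth T2* drawn uniformly from 0.012–0.020 s at
all depths, below the 0.024 s exclusion threshold applied downstream.

### Acquisition model

Echo signals follow S(TE) = S0·exp(−TE/T2*) at TEs 2.53/7.03/12.55/20.35 ms
with additive zero-mean Gaussian noise (sd 0.015 on S0 ≈ 1). The
longitudinal measurement is R1 plus Gaussian noise (sd 0.005 s⁻¹, ~1 % of
the cortical mean — quantitative T1 mapping is precise). Gaussian rather
than Rician noise is a deliberate simplification: at cortical SNR the
magnitude-noise distribution is effectively Gaussian, and the choice keeps
the noiseless fit round trip exact and the variance analysis tractable.
Scan times are 8:02 min for the T1-domain source and 8:33 min for the GRE
source; ratio parameters charge the sum (16.58 min), since both
acquisitions are needed to form them.

T1w is a documented monotone compressive map of R1,
`offset + scale·tanh((R1 − center)/width)` with center 0.51 s⁻¹, width
0.12 s⁻¹, scale 600, offset 800 a.u. — not a Bloch simulation of the
underlying sequence. The width, about twice the cortical R1 spread, makes
the transform locally expansive around typical cortical values (a given
quantitative range maps to a broader relative range, so the weighted image's
rescaled FWHM exceeds R1's) while the modest offset keeps the relative noise
amplification near 2, reproducing the characteristic behaviour of weighted
images: more apparent dynamic range, less reproducibility. An optional
multiplicative bias field (default off) can emulate residual receive bias.

Default design: 10 subjects, the first 3 with one rescan. All subjects share
one mesh, so no inter-subject surface registration is modelled. Every
generator function is a pure function of its inputs and an integer seed;
shared anatomy is seeded separately (`anatomy_seed`) from subject effects,
so setting the inter-subject SDs to zero makes subjects identical.

### What the phantom does not emulate

Volumetric imaging and reconstruction, B1+/B0 field structure, gradient
distortions, motion, segmentation errors, surface registration error,
Rician noise floors, multi-compartment T2* decay, and B0-orientation
dependence of T2*. Passing tests therefore demonstrate the correctness and
the qualitative behaviour of the statistics under a controlled generative
model, not the performance of any acquisition protocol on real brains.

## Analysis pipeline choices

* **T2* fit**: ordinary least squares on log-signal (slope = −1/T2*),
  exact in the noiseless limit; a signal-weighted variant (the first-order
  equivalent of nonlinear least squares) is available via `weighted=True`.
  Vertices with non-positive signal carry an explicit unfittable marker
  (NaN value plus boolean mask) rather than a sentinel number; a
  non-decaying train yields +inf T2*.
* **Depth averaging**: unweighted mean over the 11-point depth grid with
  both window endpoints included (20–80 % default, 7 samples). No
  thickness weighting.
* **Curvature residualisation**: OLS of map on signed curvature with
  intercept, residuals shifted back to the map mean; applied by default to
  R1 and T1w only (the longitudinal maps are where gyral bias is
  strongest). Constant curvature is a documented no-op.
* **Geodesic smoothing**: iterated explicit heat diffusion with unit edge
  weights and per-vertex areas; the symmetric edge flux conserves the
  area-weighted mean to machine precision and the step size cap makes every
  update a convex combination (max principle). The iteration count matches
  the accumulated kernel variance to the requested Gaussian FWHM; at 1 mm
  FWHM on ~1 mm edges this is a small number of iterations, adequate for
  pre-smoothing and far cheaper than exact geodesic kernels. NaN-aware
  smoothing normalises by the smoothed finite-mask indicator.
* **FWHM estimation**: density via Freedman–Diaconis histogram (default) or
  Silverman-bandwidth Gaussian KDE; the width spans the *outermost*
  half-maximum crossings, so secondary modes inside the envelope widen the
  estimate instead of breaking it; an unbracketed crossing raises a
  diagnostic error. The normalization FWHM for COV and PV is computed from
  the across-subject average map's value distribution (not the average of
  per-subject FWHMs — the phrase is ambiguous; this reading is fixed here).
* **Rescaling**: the 3rd–97th percentile band maps linearly to [0, 1];
  values outside the band are not clamped, since clamping would pile mass at
  the endpoints and distort the half-max crossings.
* **COV conventions**: sample (n−1) standard deviations everywhere —
  unbiased variance at 2–3 units. Intra-subject COV is computed per subject
  and then averaged across rescanned subjects (default); pooling
  within-subject variances first is available behind `pooling="pooled"`.
* **CNR**: the reference value is a seeded random vertex from the designated
  lightly myelinated neighbor region (faithful to a randomly selected
  reference vertex); `region_median` gives a deterministic alternative.
  Minutes per parameter: source acquisition time, sum for ratios.
* **AUC thresholds**: the threshold at pct % is the pct-quantile of the
  distribution truncated to [p3, p97] — the histogram-area reading written
  out as a formula. Comparison is `>=`. Before thresholding, T2*(w) maps
  are reciprocal-transformed to R2*(w) so every parameter increases with
  myelination; metrics and correlations use the raw orientation.
* **Jaccard**: |A∩B| / |A∪B|; two empty masks are defined to overlap
  perfectly (1.0).
* **Surface gradients**: one-ring linear regression in the tangent plane,
  normal from area-weighted triangle normals (angle-weighted behind a
  flag). Exact for linear fields on planar meshes. Quadratic or
  distance-weighted regressions were not needed at the ~1 mm edge scale.
  Gradient borders are a bare threshold with no ridge linking — completing
  discontinuous borders is genuinely an observer decision.
* **Exclusion**: vertices with across-subject average T2* below 0.024 s or
  unfittable are excluded from every statistic; they never enter any
  reported n.

## Degenerate inputs and tie-breaks

Constant distributions raise `DegenerateDistributionError` (rescale, FWHM);
zero pooled SD raises `DegenerateContrastError` (CNR); empty ROIs raise
`EmptyRegionError`; constant maps yield NaN correlation markers; boundary or
collinear one-rings yield NaN gradients. Config schema violations raise
`ConfigError` before any computation starts.

## Problem sizes

Default runs use icosphere subdivision 4 (2562 vertices), 10 subjects and 13
sessions; the full experiment takes a few seconds on one CPU. The test
suite validates estimator accuracy at up to 10⁶ samples (FWHM) and 10⁴
replicate vertices (fit bias) and uses icosphere 3 (642 vertices) for
cohort-level checks.

## Known limitations

The ROI growth is graph-geodesic and produces roughly round patches, not
anatomically shaped areas. The weighted transform is a one-parameter-family
stand-in for a sequence simulation, so absolute T1w values are arbitrary
units by construction. The FWHM estimator's outermost-crossing convention
makes it sensitive to secondary modes near half maximum; distributions close
to bimodal can shift the estimate discontinuously between seeds. Monotone
orderings among parameters (which parameter has lowest COV, etc.) are
properties of the phantom's default calibration and are validated as such,
not as predictions for any particular scanner or protocol.
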