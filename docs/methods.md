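# Methods

This note documents the models, parameter choices and numerical decisions
behind `hdwm`, and what the synthetic-data tests do and do not demonstrate
about real data.

## Coordinate conventions

The world frame is RAS millimetres. Voxel indices are 0-based with centers
at integer continuous coordinates, so voxel `c` owns the half-open extent
`[c − 0.5, c + 0.5)` per axis. A single convention is used by tractometry
(trilinear weights from the fractional parts of the inverse-affine-mapped
vertex) and by TBCA (nearest-integer rounding during streamline traversal),
which prevents off-by-half disagreements between the two stages.

## Quantitative maps

**MTR.** `(S0 − S_MT)/S0 × 100`, in percent units. Voxels with `S0 ≤ 0` or
outside the mask are NaN, never ±∞. The map is invariant to a common
positive rescaling of the two inputs.

**Diffusion tensor.** Linearly weighted least squares on the log signal:
an ordinary LS pass, then one reweighting pass with weights equal to the
squared predicted signal (the standard first-order variance correction for
log-transformed Rician-free data). Only `b = 0` and `500 ≤ b ≤ 1200 s/mm²`
volumes enter the fit — the upper bound is *inclusive*, since the operative
description of the analysis is a fit "between" 500 and 1200 — which
suppresses CSF partial-volume bias and keeps the signal in the
Gaussian-diffusion regime. Eigenvalues are sorted descending and clipped at
zero before FA; voxels with any non-positive selected signal are excluded
and counted.

**CHARMED restricted fraction.** Two compartments,
`S = S0 [(1 − FR)·E_h + FR·E_r]`, with

- `E_h = exp(−b gᵀ D_h g)`, an axially symmetric hindered tensor about the
  cylinder axis;
- `E_r = exp(−b cos²θ · D∥) · exp(−(7/96) · (b sin²θ / (Δ − δ/3)) ·
  (a⁴/(D⊥Δ)) · (2 − (99/112) · a²/(D⊥Δ)))`, free axial diffusion along the
  cylinder times the Gaussian-phase small-radius perpendicular attenuation,
  with `4π²q² = b/(Δ − δ/3)` used to express the q-space magnitude through
  the b-value and the pulse timings (δ = 7 ms, Δ = 24 ms by default).

Simplifications: a single cylinder population of fixed radius `a = 3 µm`
(the resolvability floor for these gradients), restricted axial diffusivity
fixed at 1.7×10⁻³ mm²/s, and the intracylinder diffusivity tied to it. Only
FR is consumed downstream, so the fit's accuracy target is self-consistent
FR recovery, not radius estimation. Per voxel, `scipy.optimize.least_squares`
(trust-region reflective, box constraints `FR ∈ [0, 1]`) minimizes the
magnitude-domain squared misfit — a Gaussian approximation that is adequate
at SNR ≥ 20. The cylinder axis is fixed at the principal eigenvector of the
low-b tensor fit (exact for noise-free axially symmetric data). Two FR
starts (0.3 and 0.7) are tried and the lower misfit kept, avoiding the
boundary minima at 0 and 1. Noise-free self-inversion recovers FR to
≤ 10⁻³; at SNR 30 the median absolute FR error over 200 voxels is ≈ 0.02.

**Free-water fraction.** `S/S0 = FWF·exp(−b·D_free) + (1 − FWF)·
exp(−b gᵀD_t g)` on the `b ≤ 1200` shells with `D_free = 3.0×10⁻³ mm²/s`
fixed. FWF is found by bounded 1-D minimization with an exact inner
log-linear tensor fit at each candidate, so the procedure is deterministic
and has no multi-start sensitivity. The inner tissue tensor's mean
diffusivity is capped at 2.0×10⁻³ mm²/s: without the cap the two
compartments are unidentifiable whenever the tissue tensor can mimic free
water, and the pure-free-water limit would not be recoverable. This
estimator is a deliberately simple stand-in for more elaborate regularized
free-water elimination schemes, and its outputs are labeled accordingly.

## Tractometry

Per bundle: trilinear samples at every vertex, per-streamline median over
vertices, then the mean over streamlines. The aggregation order is
exposed (`pooled-median` pools all vertices before one median) because the
field's verbal convention — "medians were derived … then the overall mean" —
is ambiguous; median-within-streamline-then-mean matches tractometry
practice and is the default. Vertices outside the voxel-center hull are
missing values; fully-missing streamlines are dropped with a logged count.
The summary is invariant to streamline order and point reversal, and stable
under 2× vertex oversampling to well within 1% on smooth fields.

## Tract-based cluster analysis

- **GLM.** Per voxel, OLS of the metric on intercept + group indicator +
  age + sex; the contrast selects the group effect, `t = cᵀβ̂ / SE`,
  residual df = n − rank(X). Zero-residual-variance voxels yield t = 0 and
  are counted.
- **Permutation.** Freedman–Lane: the nuisance-only model is fitted once,
  its residual rows permuted, the nuisance fit added back, and the full
  model refitted per permutation. Voxel
  `p = (1 + #{t* ≥ t}) / (n_perm + 1)`, one-sided in the tested direction.
  Floating-point ties (permutations that happen to preserve the group
  labelling reproduce t to ~1e−16) are counted as ≥ via a relative
  tolerance — without this the test would be anti-conservative at the p
  floor. If the requested permutation count reaches the number of distinct
  orderings, the non-identity orderings are enumerated exhaustively.
- **Hypervoxels.** The template stores voxel ↔ streamline incidence built
  by segment traversal at half-voxel steps (vertex-only assignment misses
  voxels crossed between sparse vertices). Orientation-binned extra
  dimensions of the published hypervoxel construction are not modeled: the
  clustering rule used here needs only adjacency-or-shared-streamline
  incidence.
- **Clusters.** The permutation p-map is thresholded at p = .01 (a
  nonparametric threshold, not a parametric t cut); suprathreshold voxels
  are nodes, edges are 26-neighborhood adjacency ∪ shared-streamline pairs,
  clusters are union-find connected components, and the mass is the sum of
  member scores (signed t in the tested direction, hence positive).
  Patient-greater and patient-lower effects are run as two one-sided
  analyses, each with its own maximum-mass null.
- **FWE.** For every permutation the same thresholding and clustering is
  applied to that permutation's p-row (each row ranked against the full
  joint permutation distribution) and the maximum mass recorded;
  `p_fwe = (1 + #{max-mass* ≥ mass}) / (n_perm + 1)`. The cluster-level
  uncorrected p compares the mass against the pooled distribution of all
  permutation cluster masses, capped at `p_fwe` so corrected never
  undercuts uncorrected. With no streamline edges the whole procedure
  reduces exactly to classical 26-connectivity cluster-mass inference,
  which serves as an independent oracle in the tests.

Defaults: `n_perm = 1000` for library use (the demo pipeline uses 300,
calibration tests 500), 26-connectivity, threshold p = .01, α = .05, fixed
recorded seeds.

## Group statistics

- **PCA.** Correlation-matrix PCA on internally standardized columns;
  loadings are eigenvector × √eigenvalue; varimax (Kaiser-normalized) when
  ≥ 2 components are retained; per-subject scores by the regression method
  `Z R⁻¹ Λ` on the rotated loadings (rotated scores are the default; the
  unrotated route is available via `rotate=False`). Components are labeled
  by their dominant-|loading| variable and signed so the dominant loading
  is positive. Retention supports the Kaiser rule (λ > 1) and a fixed
  count. The pipeline's microstructure PCA retains two components — the
  axon-density block (FA/FR/AD positive, RD negative) and the
  magnetization-transfer dimension — by interpretability: when the planted
  patient MTR pattern anti-aligns with the axon-density segment gradient,
  the MT dimension's sample eigenvalue can dip below 1 even though varimax
  separates it cleanly. A strictly isolated single-variable factor has
  population eigenvalue exactly 1, so a bare λ > 1 rule can never retain it
  reliably; this is a property of the Kaiser criterion, not of the
  implementation.
- **Adequacy.** KMO from zero-order vs partial correlations
  (`P = −R⁻¹` scaled to unit diagonal); Bartlett
  `χ² = −(n − 1 − (2p + 5)/6)·ln det R`, `df = p(p − 1)/2`.
- **ANCOVA.** OLS with sum-to-zero factor coding and Type III F tests
  (via statsmodels `anova_lm`), matching the convention of mainstream
  point-and-click statistics packages for unbalanced groups. Group×segment
  is always included; group×age (and group×FWF in the free-water
  re-analysis) are added where the analysis design specifies them.
  Adjusted means are model predictions at covariate means. Covariates are
  screened in by Pearson |r| > 0.3 against the component scores.
- **Simple slopes.** The conditional patient-minus-control effect at each
  segment, evaluated as a linear contrast of the fitted moderation model
  with covariates at their means — β, SE, t and p per segment.
- **Correlation families.** Spearman per segment with Bonferroni
  `p_corr = min(1, 7p)`; the partial variant is the partial Pearson on
  rank-transformed data (the standard definition), which reduces exactly to
  plain Spearman with an empty covariate set.
- **Outliers.** |z| > 3 within each group separately; removals are logged
  with their z-scores.
- Segments repeat within subject but are modeled as a crossed fixed factor
  with no subject random effect — a deliberate fidelity-over-preference
  choice, flagged in the README.

## Synthetic cohort generator

The generator defines the study conditions for all pipeline-level tests.

- **Geometry.** 48³ voxels of 2 mm by default (tests and the demo use 24³);
  seven callosal bundles as half-ellipse arcs in parallel slabs ordered
  along x (anterior → posterior), one straight vertical CST-like tube,
  spatially disjoint from the arcs; 2000 streamlines per bundle by default
  (reducible; the demo uses 200). Geometry violating the grid raises,
  naming the bundle.
- **Maps.** Background + planted bundle values painted on bundle masks
  dilated by one voxel (dilation keeps every vertex's interpolation support
  inside painted voxels, so tractometry reproduces planted values exactly
  on noise-free maps; overlapping dilated regions are resolved to the
  nearest bundle). Baselines (bundle/background): MTR 45/25 pu,
  FA 0.65/0.15, AD 1.6/0.8 ×10⁻³ mm²/s, RD 0.45/0.7 ×10⁻³, FR 0.32/0.08,
  FWF 0.10/0.25.
- **Planted effects** (native map units; magnitudes are generator
  parameters, chosen once for conventional ~80%+ power at 12 + 12 subjects,
  since the reference analyses report component-score statistics rather
  than native-unit effect sizes): patient MTR segment offsets
  (+1.0, +0.6, +0.3, 0, −0.3, −0.6, −1.0) pu; CAG slope 0.15 pu per repeat
  about the mid-range repeat count; group×age −0.05 pu per year about the
  age mean; CST FR offset +0.05; axon-density gradient half-spans FA/FR
  0.06, AD/RD 1.2×10⁻⁴ (RD opposed).
- **Noise and variability.** Additive Gaussian noise per metric (MTR 0.5 pu,
  FA 0.02, AD/RD 6×10⁻⁵, FR 0.015, FWF 0.02), spatially smoothed at 4 mm
  FWHM and rescaled to the target SD — derived maps inherit spatial
  correlation from acquisition and fitting, and correlated noise makes the
  cluster-level null realistically wide. Between-subject biology is a
  global MTR offset (SD 0.5 pu) and a latent axon-density factor moving
  FA/FR/AD up and RD down together; without metric-specific
  between-subject variance all map columns would correlate through the
  shared segment profile and the PCA could not separate them.
- **Demographics.** Patient ages truncated-normal (mean 42, SD 12.7,
  range 21–71); controls age-matched by permuting patient ages ± U(−2, 2);
  CAG uniform on 37–45; `DBS = age × (CAG − 35.5)` for patients only.
- **Cognition.** 13 outcomes = loading × latent factor + noise; default
  loadings 0.7 on ten outcomes and 0.2 on digit span, visual patterns and
  phonetic fluency; noise SD 0.5.
- **Determinism.** Every draw flows from one root seed through named
  substreams (`maps/<subject>/<metric>`, `cohort-demographics`, …), so
  adding a generator never perturbs existing draws, and a fixed seed gives
  byte-identical outputs.
- **DWI simulation.** The composite-model forward signal with optional
  Rician noise (two Gaussian channels, SD = S0/SNR); deterministic
  Fibonacci-sphere gradient directions; the default shell table is b = 0
  (×14), 500 (×30), 1200 (×30), 2400 (×60), 4000 (×60), 6000 (×60) s/mm²
  with δ/Δ = 7/24 ms.

**What passing tests show — and do not.** The phantom has rectilinear,
disjoint bundles, stationary Gaussian map noise and effects that are exactly
bundle-shaped, so recovery results demonstrate the *statistical machinery*
(calibration of the permutation FWE, power of the cluster and moderation
analyses at the planted effect sizes, correctness of the estimators against
closed forms). They do not demonstrate robustness to registration error,
crossing fibers, physiological artifacts, or effect shapes that straddle
bundle boundaries — none of which the generator emulates.

## Problem sizes

The test suite and `scripts/acceptance.py` run the study at reduced scale,
chosen as the smallest sizes at which the planted effects are conventionally
powered: 24³ grids, 200 streamlines per bundle, 12 + 12 subjects, 300–500
permutations, 20-seed replicate tallies, and a 40–100-repeat Monte-Carlo
loop for the family-wise-error calibration. The full-scale defaults (48³,
2000 streamlines, 1000 permutations) are exercised through the same code
paths.

## Known limitations

- The FWF estimator is a fixed-`D_free` two-compartment fit, not a
  spatially regularized free-water elimination.
- CHARMED is single-population with fixed radius; no axon-diameter
  distribution, no multi-fiber voxels.
- The ANCOVA ignores within-subject correlation across segments (fixed
  crossed factors only).
- The cluster-level uncorrected p is a pooled-null convention, capped at
  the FWE value; only the FWE p carries the calibration guarantee.
- No spatial normalization is modeled: all subjects share the phantom grid
  by construction.
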