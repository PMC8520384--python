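# Methods

## Multi-scale edge-preserving filter

The filter operates on 2-D luminance grids in [0, 1]. Its primitive is
the point-wise remapping

    r(i) = i − m_f (i − g) exp(−(i − g)² / 2σ_r²),

a continuous, total perturbation of the identity with a fixed point at
the reference `g`. Its deviation from the identity peaks at
`m_f σ_r e^{−1/2}` when `|i − g| = σ_r` and decays with the Gaussian
envelope `|i − g| exp(−(i − g)²/2σ_r²)` beyond — at `|i − g| = 5σ_r`
the deviation is at most `5 e^{−12.5} m_f σ_r ≈ 1.9e−5 m_f σ_r`, which
is what "edges pass through" means quantitatively.

The multi-scale construction evaluates, for every output Laplacian
coefficient `(l, x, y)`, the level-`l` band coefficient of the pyramid
of the input remapped with `g = G_l[x, y]` (the input's own Gaussian
coefficient there). The coarsest Gaussian residual is copied unchanged
and the pyramid is collapsed. This is the exhaustive per-coefficient
algorithm; it is implemented as such (no discretised-reference
interpolation), vectorised over chunks of coefficients sized to keep
the working set near 8 M doubles. Desk-scale images are the intended
regime: a 128² input with 3 levels takes tens of seconds on one core,
which is why the bundled phantom experiments use 64²–128² frames.

Pyramids use the separable 5-tap binomial kernel `[1,4,6,4,1]/16` with
symmetric (mirror) boundaries; levels ceil-halve, so any size ≥ 1 is
valid. Expansion zero-inserts a one-pixel symmetric-padded copy of the
coarse grid, convolves with twice the kernel, and crops to the target
level's exact shape; the pre-pad is what makes expansion constant-
preserving at borders. Reduction and expansion share the kernel, so
`collapse(laplacian(I)) = I` holds to ~1 ulp by construction (the only
error is the rounding of `(G − E) + E`). Outputs are clipped to [0, 1]
after collapse because the remapping can overshoot the nominal range.

### Parameters

| knob | default | units | meaning |
|---|---|---|---|
| `n_levels` | 3 | — | pyramid depth; needs `2^(n_levels−1) ≤ min(H, W)` |
| `base_sigma` (σ₀) | 0.15 | luminance | contour threshold: fluctuations below it are detail, above it edges |
| `base_mf` (m₀) | 1.0 | — | attenuation amplitude; 0 = identity |
| `adaptive` | off | — | per-pixel σ/m fields from local variance |
| `k` | 2 | px | variance-window half-width (window side 2k+1) |

σ₀ = 0.15 sits between typical speckle amplitude (±0.05 on the
phantoms) and the tone separations of interest (≥ 0.5 across chamber
walls), so the defaults smooth the former and provably barely move the
latter.

### Adaptive fields

Local variance is the population variance over the mirror-padded
`(2k+1)²` window. The adaptive threshold uses the saturating inverse
relation `σ_ra = σ₀ V̄/(V̄ + V)` with `V̄` the image-mean variance
(+1e−12): antitone in V, equal to σ₀ at V = 0 and σ₀/2 at V = V̄, and
free of the blow-up a literal `1/V` would have in flat regions. The
amplitude matrix is tied to the same profile, `m_fa = m₀ σ_ra/σ₀`, so
one knob moves both; busy regions are both harder to classify as detail
*and* attenuated less. Fields are computed once at full resolution and
box-averaged (2×2, ceil semantics) down to each level.

### Structure/texture decomposition

`decompose` returns `S = multiscale_filter(I)` and `T = I − S`;
additivity is exact by construction (one subtraction). `T` is signed.

## Exemplar inpainting

Standard exemplar bookkeeping: confidence starts at 1 on known pixels
and 0 inside the hole Ω; the fill front is the set of Ω-pixels
4-adjacent to known ones. Priority is `P(p) = C(p)·D(p)` with

* `C(p)` = summed confidence of known pixels in the `(2k+1)²` patch
  divided by the in-image patch area, and
* `D(p) = |∇⊥S(p) · n(p)| + ε`, the isophote of the **structure**
  component `S` projected on the front normal (central differences on
  the known-indicator), ε = 1e−3 so structure-free front pixels remain
  fillable.

Evaluating `D` on `S` rather than on the raw image is the point of the
design: speckle gradients are removed before they can steer the fill,
so the front advances along chamber boundaries first. `S` is computed
once, from the image with Ω set to the known-pixel mean (a neutral
placeholder; only gradients near the front matter, and they are
dominated by the known side).

Matching minimises the SSD between the target patch and every
*originally*-known candidate patch, restricted to the target's
currently-known pixels via point-wise multiplication with the known
indicator; the whole image is the search region. Ties (including the
degenerate all-unknown target, whose masked SSD is 0 everywhere) break
in scan order. SSD is computed on the original intensities, not on S,
so the fill inherits realistic texture. Filled pixels get confidence
`C(p)` and are never re-copied from (the source region is frozen at the
original mask), and known pixels are never written, so each iteration
strictly shrinks Ω and the loop terminates in at most |Ω| iterations.

## Biomarker statistics

* **Rank sum**: mid-ranks, tie-corrected variance, `Z = (W − μ_W)/σ_W`
  with no continuity correction and a two-sided normal p; for pooled
  n ≤ 12 without ties the p-value is replaced by full enumeration of
  rank assignments. Identical samples give Z = 0 by symmetry.
* **2×2 tables**: Fisher's exact two-sided p (sum of hypergeometric
  probabilities ≤ the observed table's) and Pearson chi-square without
  continuity correction; `compare_counts_2x2` picks Fisher whenever an
  expected cell is below 5, chi-square otherwise.
* **ROC**: positives are scores ≥ threshold; thresholds are the
  distinct scores descending (prefixed by +∞); AUC by trapezoid, which
  equals pairwise concordance with ties counted ½. The best cut-off
  maximises Youden's J = sens + spec − 1, ties resolved toward the
  higher threshold (higher specificity). The curve, AUC and operating
  point are invariant under strictly increasing score transforms.

## Synthetic cohort generator

Targets follow the published two-group summary (aPDA n = 56:
10068 ± 1361 pg/mL day 3, 3116 ± 665 day 5; PDA n = 13: 48539 ± 8114
and 19713 ± 5730). The "±" is read as a standard error, so the margin
SD is `SEM·√n` — with these means that puts the coefficient of
variation near 1, which is why the margins are lognormal
(positive, right-skewed) with `σ² = ln(1 + (SD/mean)²)`,
`μ = ln(mean) − σ²/2` in closed form.

Within each group, (day-3 level, day-5 level, ductal diameter, LA/AO
ratio) are drawn through a Gaussian copula: latent 4-variate normals
with pairwise correlation `2 sin(π ρ_s/6)` are pushed through each
margin's monotone quantile map, which realises the target Spearman
correlations exactly in distribution. The calibrated rank-correlation
targets are 0.856 (day 3 ↔ duct), 0.528 (day 5 ↔ duct) and 0.721
(day 5 ↔ LA/AO); the unconstrained pairs are set to mild positive
values (0.5–0.6) checked for positive definiteness. Rank targets are
used deliberately: with CV ≈ 1 lognormal margins, the Pearson
attenuation factor `σ/√(e^{σ²}−1)` ≈ 0.83 makes a product-moment 0.856
unreachable inside a valid copula, whereas rank correlations survive
the monotone margins untouched.

Ultrasound-index margins are not published; the defaults (duct
diameter 1.2 ± 0.4 mm aPDA vs 2.2 ± 0.5 mm PDA; LA/AO 1.15 ± 0.12 vs
1.45 ± 0.15) are chosen so the symptomatic group straddles the
diagnostic thresholds (duct > 1.5 mm, LA/AO > 1.3) and the asymptomatic
group sits below them.

### What the phantoms and cohorts do and do not show

The image phantoms are piecewise-constant scenes under unit-mean gamma
speckle and additive Gaussian noise — they reproduce the *contrast and
noise structure* that makes echo filtering hard, not beam geometry,
attenuation shadows, motion, or anisotropic speckle; passing tests
demonstrate the algorithms' contracts (exact reconstruction, edge
retention, oracle-equal matching), not clinical image quality. The
synthetic cohorts match first/second moments and rank correlations but
cannot reproduce the original patients' joint distribution, so
cohort-level outputs (e.g. a synthetic AUC near 0.95–0.98) characterise
the generator's separation, not the published cohort; the published
patient-level results (AUC, cut-offs, Z values) are reproducible only
from the unpublished raw data. The original report is itself
inconsistent about the day-3 cut-off (27035 pg/mL with specificity
94.6 % in one place, 6411 pg/mL with 92.9 % in another), one more
reason no cut-off value is treated as ground truth here.

## Numerical notes

* Variance estimator: population (divide by n) — deterministic and
  oracle-checkable; cancellation in `E[x²] − E[x]²` is clipped at 0.
* Exact rank-sum enumeration bound: pooled n ≤ 12 (C(12,6) = 924
  assignments, microseconds); beyond that the tie-corrected normal
  approximation is used.
* Acceptance experiments use 64²–128² phantoms, 50 random
  block-matching instances, 200 random ROC cohorts and 10 000 subjects
  per group for generator calibration — sizes at which every check is
  stable across seeds while the whole script finishes in about a
  minute.
* Degenerate inputs: 1×1 images are valid pyramids; an all-unknown
  patch matches the first candidate in scan order; identical rank-sum
  samples return (0, 1); single-class ROC labels and all-masked images
  raise errors.
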