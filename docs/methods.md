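# Methods

This note records the models, conventions and numerical choices behind
`tangmorph`, and what the synthetic-data tests do and do not establish.

## Outline model and conventions

An outline is an ordered closed polygon; the first vertex is **not**
repeated at the end (implicit closure), which avoids double-counting a
segment in the Fourier integrals. All geometry uses y-up coordinates
("dorsal side up"); mask readers flip raster row order accordingly. The
analysis normal form is counterclockwise traversal (positive shoelace
area) with the tang at smaller x ("tang facing left").

Automatic tang-side detection compares the mean half-width of the outer
25% of the x-extent at each end and calls the narrower end the tang, with
a 1% tie band that raises an ambiguity error. This rule is reliable for
round-tipped tools but can misjudge sharply pointed ones, whose tip tapers
below the tang's width; `orient` therefore also accepts an explicit
current-side hint (`left`/`right`), and the file-input pipeline defaults
to trusting the documented tang-left convention rather than auto-detection.
A consequence of the same geometry is that the 180° axis ambiguity inside
the coefficient standardization (below) is broken toward the input's own
orientation rather than by re-detecting the tang on the reconstruction:
the alignment rotation never exceeds a quarter turn. This makes the
standardization a deterministic, shape-independent map — an earlier
lobe-width rule was found to flip even harmonics inconsistently across a
mixed assemblage, scrambling the asymmetry axis.

Resampling places `n_points` (default 512, comfortably supporting 11+
harmonics) vertices equally spaced by arc length. Resampling a resampled
outline shifts vertices only at the O(h²) chord-shortening of the previous
pass (~10⁻⁵ relative at 256 points); tests check stability at that bound,
not exact idempotence, which no polygonal scheme achieves.

## Elliptical Fourier transform

Coefficients are computed by the exact per-segment Kuhl–Giardina integrals
of the piecewise-linear, arc-length-parametrized contour — exact for
polygons and independent of sampling phase, unlike an FFT of sampled
points. Two consequences of arc-length parametrization are worth stating
because they are often assumed away:

* only a **circle** is exactly one harmonic. An eccentric ellipse is not
  traversed at constant speed, so odd harmonics ≥3 pick up a small tail;
  for a 2:1 ellipse the first harmonic holds 99.4% of the power and
  a₁/d₁ = 1.7040 (not the axis ratio 2). Tests freeze these values from a
  dense trapezoid-rule integration oracle.
* forward∘inverse is the identity only for constant-speed curves. For
  anything else the re-parametrization shifts coefficients at first order
  in the deviation from a circle, while the synthesized *geometry* is
  preserved; the tests assert shape preservation (nearest-neighbour
  distance) rather than coefficient identity.

## Standardization dialect

Order of operations, all performed in coefficient space (equivalent to
transforming coordinates, but computed once):

1. **Translation** — offsets A0, C0 set to 0 (centroid at origin).
2. **Size** — all coefficients divided by √area of the source outline, so
   the reconstructed shape has unit area (verified to 10⁻³, limited only
   by polygonal area of the inverse reconstruction).
3. **Rotation + start point** — the first-harmonic ellipse's major axis is
   rotated onto +x and the parametric start moved to its larger-x end.
   The semi-axes are **not** rescaled: elongation is retained, because the
   analysis is about shape change along the reduction axis. The residual
   half-turn ambiguity is resolved toward the input orientation (see
   above) by the joint spatial+start half-turn, which negates even
   harmonics only.

A first harmonic that is a circle to 1e-9 leaves rotation undefined; it is
skipped with a warning rather than injecting noise. Total harmonic power
is invariant under the rotation/start standardization (orthogonal maps per
harmonic), which the tests check to 1e-9.

Standardized coefficients are invariant under translation, uniform scaling
and rotation of the input to ≈10⁻¹⁵ (tested at 10⁻⁶); mirror-symmetric
outlines have bₙ = cₙ = 0, and mirroring negates exactly those columns —
the basis for identifying the asymmetry axis of a fitted shape space by
its b/c loading mass.

Truncation default is 11 harmonics / 44 coefficients at a 0.99 cumulative
power threshold, both overridable; `choose_harmonics` accepts a `max_h`
cap so that "threshold unreachable" is a real condition (power fractions
are normalized over the computed harmonics, so the final fraction is
always 1).

## Shape space

PCA is fitted on the covariance (not correlation) matrix of all 4H
standardized coefficients; near-constant columns fixed by normalization
(b₁, c₁ ≈ 0) contribute ≈0 variance and are harmless. Eigenvector signs
are fixed so each component's largest-magnitude loading is positive, for
reproducible plots and tests. Extreme shapes use the extreme *observed*
scores, as in standard outline-morphometric practice. Projection of an
external sample centers on the fitted mean and multiplies by the fitted
eigenvectors; the space is never refitted.

"Confidence ellipses" are **data ellipses** by default: the 2×2 score
covariance scaled by the χ²(2) quantile at the requested level. A
standard-error ellipse of the centroid (`kind="mean"`) is also available;
the data ellipse is the default because group clouds of hundreds of
specimens with broadly overlapping ellipses — the pattern these analyses
argue from — cannot arise from standard-error ellipses, which shrink with
√n. Ellipse overlap is classified (disjoint / overlapping / nested) on
256-vertex polygonal approximations.

## Reduction statistics

* **Tang/tip partition.** No universally agreed measurement rule exists
  for where a tang ends; the detector takes the largest positive jump of
  the smoothed binned width profile within the left 60% of the length,
  and requires the jump to be preceded by a plateau or notch (gradient
  below 30% of the peak). A smoothly swelling silhouette (ellipse) has a
  monotone-gradient profile and raises a detection error; an explicit
  boundary hint overrides detection. On 100 random generated tools the
  detector recovers the true tang fraction within 0.02 (tolerance 0.03).
* **Welch test.** Standard unequal-variance two-sample t with
  Welch–Satterthwaite df (fractional df expected); the statistic's sign
  follows mean(first) − mean(second). No multiple-testing correction is
  applied anywhere, matching conventional reporting of these analyses.
* **Size regressions.** OLS with intercept via statsmodels; adjusted R²
  and the overall F-test p are reported, with a collinearity flag at
  condition number 10¹⁰.
* **Major-axis allometry.** Slope of the first principal axis of the 2×2
  covariance of the already-logged lengths (natural log; the slope is
  base-invariant). The confidence interval is a seeded percentile
  bootstrap over specimens (default 1000 resamples; degenerate resamples
  with zero x-variance are redrawn); `isometric` records whether 1 lies
  inside it. A closed-form slope test would be possible but the bootstrap
  is distribution-light and reproducible. Both regression orientations
  are available by swapping arguments; the major-axis slope is exactly
  reciprocal under the swap. The default orientation is y = log tang,
  x = log tip.
* **Spread by length.** Equal-n (quantile) or equal-width length bins,
  reporting n, median, IQR and retouched fraction per bin. This is a
  descriptive summary; no formal variance test is attached by default.
* **Cumulative type curves** accumulate percentages by ascending type
  code, optionally re-counting endscraper-tips (30/31) as transverse
  scrapers (22/23) — the orientation-convention correction for tanged
  pieces.

## Synthetic generator: what it emulates

A tool is a half-width profile over its long axis: elliptical butt cap
(10% of the tang), flat tang body, a sinusoidal notch dip of fixed depth
(25% of tang half-width) just below the shoulder, a smoothstep shoulder
blend (5% of the blade), and a superelliptic blade taper with exponent q
(q = 1 straight/pointed, larger q progressively blunter). Asymmetry s
scales the upper half-widths by (1+s) and the lower by (1−s). The notch
and shoulder geometry is fixed, not a free parameter, to keep the truth
vector (elongation, pointedness, asymmetry, tang fraction) identifiable
from the first three PCs.

Edge jitter (sd = 0.01 of the blade half-width by default — visible
texture that stays inside the 0.03 tang-recovery tolerance) is a *shared*
profile perturbation applied to both edges, so asymmetry is controlled by
s alone and the s → −s tool is the exact mirror of its twin. Real
digitized outlines have independent edge noise; the consequence is that
passing symmetry tests at 10⁻⁶ here says nothing about noise robustness
on real material (the similarity-invariance tests, which add arbitrary
rotations/scales/offsets, do carry over).

Resharpening multiplies the tip length by (1 − δ) per step (δ = 0.10
default) while the tang keeps its absolute length — so reduced pieces
have relatively larger tang fractions, and the generated truth is allowed
to exceed the fresh-lineage tang-fraction draw bound (0.1–0.5) once
reduced. Trajectory modes: `edge_left`/`edge_right` drift s by ∓/±0.08
per step (maintaining one lateral edge), `rounding` multiplies q by
(1 + δ) per step, `symmetric_point` changes neither. Assemblages draw a
trajectory per lineage (`mixed`), discard each lineage at a uniform step
in 0..5, and apply tang-length variation only at lineage creation, so
that tang lengths are identically distributed across retouch classes —
which also means the tang-length Welch test is a true null and its p-value
is uniform: about one seed in twenty will reject at 0.05 by construction.

Default distributions (lengths ≈ N(60, 10) mm truncated, blade half-width
12–22% of length, tang 45–65% of the blade half-width, pointedness
log-uniform 1.0–2.2, initial asymmetry N(0, 0.10) clipped to ±0.3) were
chosen to emulate the qualitative variance structure such museum samples
show — a dominant continuum with a prominent, clearly separated asymmetry
axis and a minor tang/roundness axis, and growing asymmetry extremes among
short tools — and are deliberately not tuned further. Under these
conditions, across seeds, the asymmetry truth correlates ≈0.98 with its
PC and elongation ≈0.90–0.94 with its best PC; elongation's ceiling is
real, not numerical: area standardization mixes tapering and tang
fraction into the same first-harmonic coefficients that carry elongation.

The arrowhead-like comparison population (blade half-width 7.5–10.5% of
length, asymmetry sd 0.015, no reduction) emulates a hafting- and
ballistics-constrained projectile sample: strongly elongated, tightly
symmetric.

## Degenerate inputs and tie-breaks

Duplicate consecutive vertices are dropped with a warning (a repeated
closing vertex silently); outlines need ≥8 distinct points. Zero-perimeter
or zero-area outlines, zero-variance coefficient matrices, collinear score
clouds and zero-variance groups all raise typed errors rather than
returning NaNs. Coefficient tables round-trip bit-exactly through text
(`%.17g` writing, round-trip float parsing).

## Known limitations

* Entry point is coordinate tables / binary masks; no photograph
  processing (thresholding, shadow removal, scale bars).
* Tang-side auto-detection and the shoulder detector both assume the tang
  is the narrower, plateaued end; strongly atypical silhouettes need
  hints.
* The generator models outlines only — no flaking mechanics, thickness,
  raw material, or type assignment from morphology (type codes are input
  labels; the synthetic labels are coarse placeholders).
* Between-group mean tests (MANOVA/CVA) are intentionally out of scope;
  the analyses argue from overlap and continuity, not group separation.
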