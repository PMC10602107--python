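# Methods

## Model and assumptions

The package computes the laminar hydraulic resistance per unit length,
ℛ ≡ −(∂p/∂z)/Q, of a duct described by an ordered series of planar,
simple-polygon cross sections positioned by arc length z along a straight
centerline. The flow model is steady Stokes flow (Re ≪ 1) in a slender
duct: the perturbation parameter is the squared transverse-to-axial aspect
ratio, and the leading order makes every cross section behave as an
infinite uniform duct (the series-unidirectional picture). Centerline
curvature is neglected throughout; the package exposes the Dean number
De = Re·√(re/rc) so users can check that assumption — for pial
perivascular flow (Re ~ 10⁻³, re ≈ 6 μm, rc ≥ 100 μm) De ≲ 2.5×10⁻⁴ and
curvature effects are negligible.

Internal units are μm, seconds and Pa·s, so ℛ carries Pa·s/μm⁴. This
keeps exponents benign (an SI-metre formulation of the same numbers spans
~10²⁰). Conversion to the physiological bookkeeping unit mmHg·min/(mL·m)
uses exactly 1 mmHg = 133.322 Pa, 1 mL = 10¹² μm³, 1 m = 10⁶ μm, and
round-trips exactly.

The default viscosity is water at 37 °C, μ = 6.91×10⁻⁴ Pa·s, a standard
stand-in for cerebrospinal fluid; it is configurable and ℛ is exactly
linear in it.

## Per-section Poisson solver (SUN)

On each section the unit-gradient problem ∇²φ = −1, φ|∂Ω = 0 is solved by
finite differences on a Cartesian grid with Shortley–Weller stencils at
boundary-cut links: where a grid link crosses the polygon boundary, the
leg length is shortened to the actual intercept (computed exactly from
the polygon edges), keeping the scheme second-order accurate up to the
boundary. ℛ = μ/∫φ dA with the flux integral computed by midpoint
quadrature, boundary cells clipped to the polygon so the quadrature is
also O(h²).

Resolution policy: by default the grid starts at 1/24 of the narrowest
bounding-box dimension and is halved until two successive solves agree
within 0.2%, with a floor of req/100 on the spacing. A fixed spacing can
be passed instead (profiles of many sections run faster at a fixed
spacing of ~0.1 μm for 100 μm² sections, where the solver error is
~0.1%). Verified accuracy: 0.03% against Hagen–Poiseuille on a 720-gon
circle, 0.02% against the elliptical closed form at b/c = 2, and 0.03%
against the known equilateral-triangle solution — comfortably inside the
0.5% (circle) and 1% (ellipse) contracts the tests enforce. A warning is
raised when fewer than ~10 nodes span the narrowest dimension.

## Shape estimators

*Method I* scales a single reference resistance by (A_ref/A)²; exact for
similarity-scaled families, and the reference is chosen as the largest-
or smallest-area section (ties break to lowest z).

*Method II* multiplies Hagen–Poiseuille at the equivalent radius by
γ = (1/N)Σ(req/dⱼ)⁴ over N = 256 boundary points resampled to equal arc
length (the unweighted vertex mean presupposes uniform spacing; source
section series do not guarantee it). The center minimizing γ is found by
Nelder–Mead multi-started from the centroid plus an interior 5×5 grid,
position tolerance 10⁻⁶·req; the objective is non-convex for concave
crescents, where the minimizer moves ~1 μm away from the centroid and the
returned γ is guaranteed never to exceed the centroid value. dⱼ is the
distance to boundary *vertices* by default (matching the defining polygon
sum); perpendicular edge distance is available as an option and differs
only at the boundary-sagitta level (~10⁻³ relative at N = 128).

*Method III* evaluates the elliptical closed form at the section's area
and equivalent-ellipse aspect ratio β (from diagonalizing the central
second-moment tensor; β ≥ 1 by convention, and every formula using β is
invariant under β → 1/β). *Method IV* uses the centroid polar moment,
16π²μ·Ip/A⁴, and is algebraically exact for ellipses.

Measured on the crescent fixtures (relative to SUN): method II deviates
by ≲ 8% where the minor-to-major ratio 1/β exceeds 0.7 and degrades badly
for oblong sections (≈ +46% at 1/β = 0.2, where the velocity peaks along
a ridge rather than a point); methods III and IV underestimate concave
sections (III ≤ IV ≤ SUN on fixture averages), by roughly −20% and −14%
respectively.

## Extended lubrication theory

For the nonuniform elliptical duct the second-order resistance ℛ2 is a
polynomial in b, c and their first two z-derivatives (see
`lubrication.r2`). Because a flat transcription of that polynomial is
error-prone, it is pinned by four independent checks: it vanishes for a
uniform duct; it is invariant under (b,b′,b″) ↔ (c,c′,c″); it reduces
symbolically to the fixed-β form −μ/(12β²A²)·[3(A′²/A)(1+6β²+β⁴) −
A″(1+14β²+β⁴)] for b = βc at general β; and an independent sympy
derivation of the full axisymmetric second-order system (transverse
velocity from continuity, radial momentum for the pressure correction,
axial momentum and zero net second-order flux) reproduces the β = 1
reduction ℛ2 = (8μ/3πa⁴)(a·a″ − 2a′²) exactly.

Everything is evaluated dimensionally: with all lengths in μm, A′ and A″
are dimensionless and no aspect-ratio bookkeeping appears in the
interface. Sign convention: E > 0 means the true (second-order) resistance
exceeds the uniform-duct estimate, so the series-unidirectional percent
error is −100·E. `elt_profile` reports E = ℛ2/(ℛ0+ℛ2); the closed-form
`error_fraction` is the leading form ℛ2/ℛ0 — the two agree for small
area variation and differ visibly on the strongly modulated test sinusoid
(0.28 vs 0.38 at its constriction), where |E| > 0.5 triggers an
expansion-validity warning. Semi-axis profiles supplied as samples are
interpolated with a C² cubic spline: the second-order term needs b″ and
c″, and a merely C¹ shape-preserving interpolant produces spurious
curvature spikes (its use is confined to area resampling, which is only
ever differentiated through smooth fitted areas).

## λ correction

The percent error of the series-unidirectional estimate correlates with
d²A/dz²; fitting err% = slope·d²A/dz² + intercept against a trusted
reference and applying λ = 1/(1 + err/100) per section inverts the
predicted relative error (the error is defined relative to the reference,
so division — not subtraction — undoes it; λ ≤ 0 is rejected). Two
presets ship verbatim from fits against 3D Navier–Stokes references on
mouse pial PVS segments: `realistic` (−1.8, −3.2) and `circular`
(−4.4, +0.22); re-deriving them requires that external data and solver.
λ is applied per section (the per-section and profile-mean corrected
values are both available from the returned profile). Confidence bands
use equal-count bins (default 10) with 5th/50th/95th percentiles per bin;
the Pearson correlation p-value is reported with the caveat that
neighboring sections are spatially autocorrelated, which the test does
not correct. On the sinusoidal test duct, correcting SUA with the
theory-derived circular fit (slope −100/6π, zero intercept) cuts the RMS
deviation from the ELT reference from ~35% to ~12% and improves ≥ 90% of
stations.

## Synthetic geometry

`sinusoidal_duct` generates the circular test duct r(z) = r0 + a·sin(2πz/λ)
(defaults r0 = 50 μm, a = 1.5 μm, λ = 50 μm, two wavelengths long so
period averages are well defined). `circular_duct_from_area` builds the
circular-equivalent duct r = √(A/π) used to isolate area effects from
shape effects. `ellipse_duct` returns both polygonized sections and the
analytic object for the lubrication module.

`lobe_fixture` emulates segmented pial PVS lobes: a crescent base (disc
minus an offset disc that cuts through its boundary, giving the
"incomplete annulus" lobe), low-order Fourier boundary perturbations with
per-duct phases so slices morph smoothly, smooth axial modulation of area
(±5–10% on 15–45 μm wavelengths about a 100 μm² mean) and of the aspect
ratio (targets drawn within [1.2, 1.9]), and pixel quantization: each
slice is rasterized on a fixed, origin-aligned 0.7 μm grid and its
boundary re-extracted by marching squares, the same operation a mask
segmentation performs. The fixed grid keeps quantization noise axially
correlated the way consecutive slices of a real segmentation are. All
randomness flows from one seeded generator passed explicitly; identical
seeds give bitwise-identical profiles.

Measured fixture statistics (defaults): per-slice β within [1.28, 1.75],
mean areas 97–101 μm², |d²A/dz²| median ≈ 0.75 with ~87% of stations
below 2 (the regime where the unidirectional error stays under ~20%).
Pixel quantization moves the SUN resistance of a smooth circular section
at this scale by ~1.7%; for the horned crescents the median effect is
~3.5% with worst cases near 8% where horn tips are about one pixel wide —
an unavoidable consequence of ℛ ∝ A⁻² at a 0.7 μm pixel on a 100 μm²
section. What the fixtures do *not* emulate: the measured statistics of
any real PVS population (they are a stated emulation target, not data),
out-of-plane section tilt, segmentation topology errors, or axial shape
changes at constant area. Tests passing on fixtures therefore validate
the estimators' mathematics and orderings, not their accuracy on any
particular animal's geometry.

## Numerical and interface choices

- Area functions are resampled at 0.7 μm (the source pixel size) with a
  shape-preserving PCHIP interpolant and differentiated by central
  differences (second-order one-sided at the ends). Smoothing is off by
  default; a symmetric moving-window option exists because pixelized
  boundaries make A″ noisy.
- Polygon orientation is normalized to counter-clockwise; the first
  vertex is not repeated; degenerate or self-intersecting boundaries are
  rejected with the slice index named.
- Outlet trimming (`trim_end`) is available but defaults to 0: excluding
  trailing sections is a post-processing convention for 3D reference
  simulations with exit effects, not a property of the 2D method.
- The solver never needs a flow rate: ℛ is a geometry/viscosity property.
- Test and acceptance problem sizes: 720-gon analytic sections, lobe
  fixtures of 8–20 slices solved at 0.1 μm fixed spacing, sinusoid
  profiles of ≤ 144 stations (analytic per-slice forms). These sizes hold
  the full suite to well under two minutes while keeping solver error an
  order of magnitude below every tolerance being asserted.

## Known limitations

- The series-unidirectional approximation itself underestimates average
  resistance in nonuniform ducts; the λ correction compensates only the
  component predictable from d²A/dz².
- ELT is second order in the slenderness parameter: for strongly
  modulated ducts (|E| > 0.5) it is flagged as unreliable.
- No transient/pulsatile flow, no porous (Darcy) annulus models, no
  curved-centerline corrections, and no centerline extraction from raw
  volumes — input begins at the cross-section polygon series.
- Long-CSV input carries no analytic shape tags, so SUA/ELT on circles
  and ellipses require the JSON format (tags survive JSON round trips).
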