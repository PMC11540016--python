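# Methods

`gelattice` implements the two halves of a lattice-radiotherapy (LRT)
commissioning workflow: a geometric planning aid that fills a target
structure with high-dose sphere vertices, and a polymer-gel dosimetry
readout and comparison suite that verifies a delivered LRT dose
distribution against the plan using cone-beam CT (CBCT) imaging of the
gel. This note records the models, the numerical choices, and what the
synthetic test bed does and does not demonstrate.

## Coordinate conventions

World coordinates are right-handed millimetres (x left–right,
y anterior–posterior, z superior–inferior). A `VolumeGeometry` stores the
world position of the *center* of voxel (0, 0, 0), per-axis spacing and
dims; arrays are indexed `[ix, iy, iz]`, 0-based. A world point belongs to
the voxel whose center is nearest. Two geometries are compatible when
origin, spacing and dims agree within 1e-6 mm; no registration or
resampling between mismatched grids is provided — plan and CBCT volumes
are assumed to share one grid, which is exactly the situation CBCT gel
readout is designed to exploit (plan and readout live in the same DICOM
frame). NRRD is the canonical interchange format (NIfTI-1 supported;
DICOM RT Dose import applies `DoseGridScaling` and requires a regular
`GridFrameOffsetVector`).

## Lattice placement

Vertices are sites of a hexagonal close-packed (HCP) lattice: "A" layers
are triangular lattices with basis `a1 = (s, 0, 0)`,
`a2 = (s/2, s·√3/2, 0)`; layer *k* lies at `z = k·s·√(2/3)` and odd
layers are offset in-plane by `(s/2, s/(2√3))`. Every interior site has
12 nearest neighbours at exactly the center-to-center spacing *s*
(coordination number 12); a rectangular (cubic, coordination 6) pattern
is also available. A user shift `(Δx, Δy)` translates the whole lattice
in-plane; there is no z shift.

Containment: a candidate is kept iff a sphere of the given radius about
it lies fully inside the target, evaluated as *Euclidean distance
transform of the target mask ≥ radius* at the candidate's voxel. The
sub-voxel error of this test is at most half a voxel diagonal; at the
default 1 mm grid this is ±0.87 mm against radial margins of several mm
for the canonical geometry, so the kept set is stable across grid
resolutions (verified from 1 to 3 mm).

Anchor rule: layer 0 is an A layer containing a vertex at the anchor,
which defaults to the target centroid ("built around the center"). On the
cylindrical surrogate target (radius 45 mm, height 90.5 mm — volume
575.7 cm³) with 15 mm spheres at 30 mm spacing this convention yields
7 + 6 + 6 = 19 vertices; anchoring a B layer at the center instead gives
20 and is rejected. The in-plane orientation (`a1` along +x) is a fixed
convention; the 19-count is rotation-invariant for this geometry.
Spacing < diameter (overlapping spheres) is rejected at construction.
A documented manual organ-at-risk filter drops vertices closer than a
chosen distance to a second structure; automatic placement optimization
is out of scope.

## Gel dose response

The gel's measurable response is the change in CBCT number between
averaged post- and pre-irradiation scan groups (six scans each by
default), modelled as

    ΔN(D) = α + β·tanh(γ·D − φ)

with offset α and amplitude β in CBCT numbers, rate γ in 1/Gy and
dimensionless shift φ; β, γ > 0 make the curve strictly increasing, so it
is invertible on (α − β, α + β). Fitting is pixel-by-pixel nonlinear least
squares (`scipy.optimize.curve_fit`, bounded β, γ > 0) over a
self-calibration slice chosen (by default) as the axial slice whose
in-mask plan-dose range is widest — mirroring the use of a central slice
spanning the full 0-to-maximum dose range. Deterministic starts:
α₀ = median ΔN in the lowest dose decile, β₀ = half the ΔN range,
γ₀ = 2/(dose span), φ₀ = γ₀·(dose midpoint). The fit reports the 4×4
parameter covariance (95% CIs derive from it), residual RMSE and the dose
range seen. A dose span below 50% of the maximum dose triggers a
conditioning warning; a zero-span design is an error.

Identifiability caveat: when the sampled doses do not reach both tails of
the tanh, α and β trade off against each other and individual parameters
can wander a few percent while the *curve itself* — and hence the
inverted dose — stays accurate. Tests therefore check parameter recovery
on well-spanning designs and dose recovery (not parameter equality) for
the full pipeline.

Inversion clamps the argument of `atanh` to ±(1 − 1e-6), negative doses
to zero, and — when the curve carries its fitted dose range — saturating
responses to the top of the calibrated range (a dose beyond the
calibrated range is not measurable); the fractions of clamped voxels are
reported.

## Filtering and remnant-artifact removal

*Adaptive mean filter* (default 3×3 pixels, per axial slice): the
local-statistics Wiener form `out = μ + max(σ² − ν², 0)/max(σ², ν²)·(x − μ)`
with μ, σ² the window mean/variance and ν² the slice-wide mean of σ².
Flat regions collapse to the local mean; strong dose edges (σ² ≫ ν²) pass
nearly unchanged. Implemented with edge-replicating windows so a constant
slice is exactly invariant.

*Remnant artifact removal* (default span 7): the residual ring/cupping
pattern that survives background subtraction is estimated per axial slice
as the **angular median** of the image in polar coordinates about the
scanner axis, smoothed radially with a centered moving mean of `span`
radial samples (bin width = the in-plane pixel size), interpolated back
to pixels and subtracted; the correction is mean-removed over the slice
region so the slice mean is preserved. Two robustness extensions:

* pixels more than 4 robust standard deviations (1.4826·MAD) above the
  slice median — vertex peaks — are excluded from the estimate, and bins
  left empty are interpolated radially;
* the estimator cannot distinguish an azimuthally symmetric *dose* field
  from an artifact. An optional `baseline_span` band-passes the remnant
  (protecting broad radial trends), and an optional `exclude_model`
  accepts an expected-signal field that is subtracted before estimation,
  so only structure unexplained by the model is treated as artifact.

The verification pipeline uses a **two-pass self-calibration**: a
first-pass curve fit on the filtered image predicts the expected response
of the plan dose; remnant removal runs on the residual with that model
excluded; the curve is refitted on the cleaned image. Without this, a
cylindrical phantom irradiated with a roughly axisymmetric lattice would
have its genuine radial dose structure subtracted as "artifact".

Properties that follow from the construction (and are tested): the
correction is exactly idempotent for remnants that are locally quadratic
in radius (moving means shift polynomials ≤ 2 by a constant, which the
mean-removal cancels); a ring of period T is attenuated by the factor
`1 − sinc(π·W/T)` with W = span·(pixel size) — ≥ 90% for a 15 mm-period
ring at 0.5 mm pixels. The exact algorithm behind the published
"window span" is not reproducible from public sources; this polar
implementation is a documented surrogate and the interface accepts
alternates.

## Comparison suite

*Profiles*: trilinear interpolation of reference (plan) and evaluated
(gel) volumes at uniform arc-length samples; exact on linear fields.

*Valley metrics*: peaks are local maxima above 50% of the profile maximum
with a minimum separation (default 10 mm ≈ half the lattice spacing, to
reject noise peaks); each adjacent-peak pair contributes the interior
minimum, reported as % of a normalization dose — the volume maximum by
default (valley doses quoted against "maximum peak dose"), with profile-
maximum and prescription options, since published valley percentages do
not state their base unambiguously. Peak full-widths at the prescription
level are reported alongside.

*Isodose volumetrics*: the level mask is `dose ≥ level`; its connected
components under 26-connectivity are matched to planned vertices by
nearest centroid within half the minimum vertex spacing (a component
matching two vertices is an error — impossible while spacing ≥ diameter).
Each component reports the equivalent diameter `d = (6V/π)^(1/3)`;
per-vertex plan/gel tables carry the normalized difference
`|gel − plan|/plan` and a mean ± SD summary.

*3D global gamma*: for each reference voxel above the low-dose threshold
(default 10% of the normalization dose, default = reference maximum),

    γ(r) = min_p √( |p − r|²/dta² + (D_eval(p) − D_ref(r))²/(ΔD%·Dnorm/100)² )

minimised over a sub-voxel Cartesian search grid (step = spacing /
refinement, default refinement 3) inside a ball of radius 3·dta, with the
evaluated dose trilinearly interpolated. Displacements are visited in
shells of increasing length, so a voxel is finalized *exactly* when the
spatial term of the next shell alone exceeds its running γ — an exact
termination rule, not an approximation. Pass = γ ≤ 1 (with a 1e-9
boundary tolerance); the sweep covers the standard 12 criteria
(1/2/3/5% × 1/2/3 mm) and pass rates are provably monotone in both
tolerances. Reference = plan and evaluated = gel by convention
(configurable), since the plan is the intended ground truth.

**Discretization limitation.** Any grid-search gamma carries an error of
order `|∇D|·(step/2)/δ` at voxels whose γ-minimum falls between search
samples (δ = the absolute dose tolerance): with LRT-like penumbra
gradients of 2–3 Gy/mm, refinement 3 on a 1 mm grid can over-estimate
individual γ values by ~0.2 while pass rates remain accurate to better
than 0.1%. The oracle-equivalence test therefore compares the engine at
refinement 6 with an exhaustive refinement-8 brute force on fields whose
gradients both grids resolve, and separately checks pass-rate agreement
on steep fields at the default refinement. Raise `refinement` when
individual γ values (not pass rates) matter.

## Synthetic study (the test bed)

The generator emulates the study conditions so every stage is testable
without clinical data:

* **Phantom**: gel jar = cylinder r = 65 mm, h = 130.5 mm (≈1.7 L fill of
  a nominal 2 L jar); surrogate GTV = the jar contracted 20 mm radially
  and axially → r = 45 mm, h = 90.5 mm, reproducing the printed
  575.7 cm³ exactly. Grids are isotropic 1 mm by default (the physical
  readout used 0.5 mm pixels / 1 mm slices; 1 mm keeps the full 3D
  pipeline inside desk-scale budgets, and every geometric result is
  resolution-stable as noted above).
* **Plan dose**: `D(p) = peak·[f·E(p) + (1 − f)·max_c σ((r₀ − |p − c|)/w)]`
  with σ the logistic function, valley floor fraction f = 0.3, peak
  24.9 Gy, prescription 20 Gy, penumbra w = 1.8 mm, and r₀ chosen in
  closed form so D = 20 Gy at the nominal 7.5 mm sphere radius. The
  logistic profile (rather than a convolved top-hat) gives closed-form
  isodose radii for oracles. `E(p) = σ((28 − d_min)/3)` (d_min = distance
  to the nearest vertex, mm) holds the valley floor inside the lattice
  (inter-vertex midpoints stay at ≈0.32·peak, within the 10–40% valley
  regime) while letting the dose fall below 1 Gy at the jar wall, so the
  self-calibration slice spans the full low-to-high dose range. Resulting
  peaks ≈ 24.8 Gy, valleys ≈ 30% of maximum.
* **Scans**: pre-scan = constant base (50 CBCT numbers) inside the gel +
  i.i.d. Gaussian noise per scan; post-scan adds the forward tanh
  response of the dose, the remnant ring (amplitude 2 CBCT numbers,
  period 15 mm, post-only — it models the residual that *survives*
  subtraction) and independent noise. Defaults: curve
  (α, β, γ, φ) = (40, 60, 0.08 Gy⁻¹, 0.3), noise 0.6 = 1% of β, six scans
  per group, one sequentially-drawn RNG per run (bit-reproducible from
  the seed).

What the synthetic bed does *not* model: CBCT physics (scatter, beam
hardening, reconstruction), gel chemistry and temporal drift,
delivery/setup error, non-axisymmetric artifacts, and the VMAT optimizer
that shapes real LRT dose (real 20 Gy isodose diameters contract below
the nominal sphere size; the generator places them at the nominal
diameter unless configured otherwise via `rx_diameter_mm`). Passing the
closure tests therefore demonstrates that the *readout and analysis
chain* is unbiased and self-consistent under the stated noise model — not
that a physical gel experiment would achieve the same numbers.

## Problem sizes and accuracy under the canonical conditions

End-to-end runs use the 1 mm jar grid (135×135×136 voxels, 12 scans); the
gamma sweep evaluates the GTV region (~5.7×10⁵ voxels). Under the
canonical conditions (1% noise, ring amplitude 2) the chain recovers the
true dose with ≈0.14 Gy RMSE (0.7% of the 20 Gy prescription) inside the
gel excluding a 3-voxel wall margin — wall voxels are excluded because
the in-plane filter support straddles the container boundary, the same
reason the physical protocol contracts the analysis region away from the
jar wall. The 12-criterion gamma sweep passes ≥ 99% everywhere with its
minimum at 1%/1 mm, the qualitative signature reported for the physical
experiment (> 95% everywhere except the 1–2%/1 mm corner).

## Degenerate inputs and tie-breaks

Empty targets filter to empty vertex sets (not errors); an empty scan
list, mismatched geometries/quantities, non-finite values, negative
doses, even filter windows, spans exceeding the radial sample count,
zero-span calibration designs, all-zero gamma references and
out-of-extent profile segments raise typed errors naming the offending
quantity. Vertex ordering is deterministic (sorted by z, y, x);
equal-distance shells in the gamma search are processed as one batch so
results do not depend on enumeration order.
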