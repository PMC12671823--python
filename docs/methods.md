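# Methods

## Model

The lens is modelled in the paraxial (Gaussian) regime: two coaxial
spherical refracting surfaces of signed radii `R_ia` (anterior) and `R_ip`
(posterior), separated by the central thickness `t` inside an optic of
index `n_IOL`, immersed in a homogeneous ambient medium of index `n_a`.
Light travels left to right; a positive radius places the centre of
curvature to the right, so a biconvex lens has `R_ia > 0` and `R_ip < 0`
and both surface powers positive.

The forward model is implemented as a literal three-step y–ν ray trace
(refract at the first surface, transfer by the reduced thickness
`τ = t/n_IOL`, refract at the second surface) on a collimated unit-height
ray; the back-vertex power is `−ν₂/y₂`. The equivalent closed form
`A = P/(1 − τ·P_first)` is used only as a cross-check in the tests, so each
trace step is exercised independently (an independently coded 2×2
refraction/translation matrix cascade serves as a second oracle).

The inverse problem is closed-form. Substituting the two vertex relations
`P1 = (1/τ)(1 − P/A)`, `P2 = (1/τ)(1 − P/B)` into the thick-lens identity
`P = P1 + P2 − τ·P1·P2` gives

    P² + τ·A·B·P − A·B = 0.

For `A·B > 0` the two roots have opposite signs (their product is `−A·B`),
so selecting the root whose sign matches `sign(A + B)` is unambiguous; it
picks the convergent branch for plus lenses and generalises correctly to
biconcave (minus) lenses, which round-trip on the negative root. `A + B = 0`
with a real discriminant is reported as an ambiguous-root error rather than
guessed at.

When the detector sits a spacing `d` downstream of the rear vertex, the
measured vergence is `V_out = V_in / (1 − (d/n_a)·V_in)`; raw readings are
corrected back to the vertex plane by the exact algebraic inverse
`A* = A_meas / (1 + (d/n_a)·A_meas)` before the d = 0 relations are
applied. `d` is treated as a non-negative downstream spacing; the same
spacing applies to both orientations by default.

## Conventions and parameters

- **Units.** Public interfaces take millimetres for lengths and diopters
  for powers. Internally every length is converted to metres so powers are
  exact reciprocal metres; this avoids silent unit drift between the mm
  scale of lens geometry and the D scale of the algebra.
- **Plano surfaces** are represented by an explicit infinite-radius marker
  (`PLANO`, i.e. `math.inf`), never radius 0 or a large finite stand-in.
  This makes the surface-power map total (plano → 0 D) and removes
  division hazards.
- **Plano threshold.** Vertex powers with magnitude below 1e-6 D are
  rejected in division contexts (the inversion divides by A and B).
- **Wet cell.** The default ambient index is 1.334 (aqueous-like medium of
  an ISO-style wet cell); air (`n_a = 1.0`) is equally supported. Radii
  recovered from wet-cell readings are only meaningful with the wet-cell
  index — using `n_a = 1` with wet-cell readings silently rescales all
  radii by a factor ≈ 3.65, which is the most likely operator error this
  package's explicit `MediumSpec` type is designed to prevent.
- **Wavelength** (default 546.07 nm, the mercury e-line customary on
  benches) is carried as metadata only. No dispersion model is applied;
  indices are assumed specified at the bench wavelength.
- **Coddington shape factor.** Fixed as `X = (R2 + R1)/(R2 − R1)`:
  0 for equi-biconvex, +1 for convex-plano, −1 for plano-convex, with the
  plano limits taken analytically. Other sign conventions exist; this one
  is stated here prominently because downstream formulas must match it.
- **Biconvex feasibility** (`P1 > 0` and `P2 > 0`) is a report-level flag,
  never a silent filter. Sweep tables record infeasible or failed rows
  with a reason; `retained()` (or `--biconvex-only`) drops them on request.

## Sensitivity analyses

Three deterministic perturbation studies ship with defaults matching
bench-realistic ranges:

- **Spacing sweep** over d = 0…1.0 mm in 0.1 mm steps — the span of axial
  offsets plausibly induced by haptic angulation (`d = h·sin α` with
  `h = 3 mm` and α between 5° and 15° gives 0.26–0.78 mm).
- **Thickness sweep** over Δt ∈ {−0.10, 0, +0.10, +0.20} mm at d = 0,
  reflecting realistic uncertainty in an assumed central thickness.
- **Index perturbation** of ±0.001 on `n_IOL` at fixed readings; because
  `R ∝ (n_IOL − n_a)/P`, this ≈0.07% index error moves the radii by just
  under 1%.

Table emission rounds radii half-to-even to 3 decimals (µm precision, the
customary tabulation for bench radii); full precision is retained
internally so rounding never accumulates.

## Synthetic bench simulator

The simulator emulates a dual-orientation wet-cell measurement: it traces
the exact paraxial back-vertex powers of a known design, propagates them to
the detector plane at spacing `d`, and adds independent Gaussian noise
(default SD 0.02 D, the repeatability reported for ISO-compliant confocal
measurements of positive IOLs) to each raw reading — at the detector
plane, since that is what a bench reports; the vertex correction then
operates on noisy values. Random lens families sample `n_IOL ∈ [1.43,
1.56]`, `t ∈ [0.5, 1.6] mm`, a target equivalent power and a Coddington
factor in (−0.9, 0.9), solving the thick-lens identity for the curvature
scale on the thin-lens branch. Seeding is per-lens-index (spawn-key
derivation from one root seed), so families are order-independent and
bit-reproducible.

What the simulator does **not** emulate: tilt and decentration of the
optic (which bias real bench vergences at the 0.01–0.1 D level if
uncorrected), aperture effects, non-paraxial ray bundles, aspheric
surfaces, and wavelength dispersion. Passing closed-loop tests therefore
demonstrate the algebraic correctness and noise behaviour of the
inversion, not robustness to misalignment or to model mismatch in real
measurements.

## Numerical choices

- The quadratic is solved with the numerically stable pairing (larger-
  magnitude root from the formula, companion root from the product
  `−A·B`), avoiding cancellation when `τ·A·B` is comparable to the
  discriminant's square root.
- Degenerate configurations raise typed errors rather than returning
  NaNs: zero radius (invalid geometry), front focal point on the back
  vertex or detector at a focus (singular configuration), negative
  discriminant (no real solution), `A + B = 0` (ambiguous root), near-zero
  vertex power (plano measurement), `R1 = R2` or two plano surfaces
  (undefined shape). The retrieval pipeline wraps failures with the stage
  that raised them.
- Internal consistency is enforced by tests at tight tolerances: the
  selected root satisfies its quadratic to 1e-9·|A·B|, the vertex identity
  holds to 1e-12 relative, and the zero-noise simulate→retrieve loop
  recovers generating designs to 1e-9 relative across spacings.

## Known limitations

- Paraxial only; results degrade for very steep surfaces or strongly tilted
  lenses, and the package makes no attempt to model that regime.
- The thickness and optic index are inputs, not estimands: no procedure is
  provided to infer `t` from a nominal power.
- Uncertainty is explored through deterministic sweeps and the simulator's
  noise model; no analytic error propagation is performed.
- The problem sizes used by the test suite and the reproduction script
  (families of 100–1000 synthetic lenses, 2000-replicate noise studies)
  were chosen as comfortably sufficient for the closed-form algebra being
  exercised; everything runs in seconds on one CPU.
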