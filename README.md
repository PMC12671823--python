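# iolgeom

Recover the anterior and posterior curvatures of a thick intraocular lens
(IOL) from two back-vertex power measurements — one in the normal
orientation, one with the lens flipped.

## The problem

An IOL is labelled with a single equivalent power (e.g. 22 D), which says
nothing about how that power is split between its two surfaces. Modern
thick-lens IOL power formulas and ray-tracing pipelines need the individual
radii of curvature (R_ia, R_ip), but manufacturers rarely publish them. A
lensmeter or optical bench, however, reports the *back-vertex* power — and
measuring it twice, once per orientation, is enough to separate the surfaces
when the central thickness `t` and optic index `n_IOL` are known.

This package is for optical engineers, IOL researchers and lens-formula
developers who want that geometry non-invasively from standard wet-cell
bench readings.

## The method

For a thick lens in an ambient medium of index `n_a`, with surface powers
`P1 = (n_IOL − n_a)/R_ia` and `P2 = (n_a − n_IOL)/R_ip` and reduced
thickness `τ = t/n_IOL`, the intrinsic (equivalent) power is

    P = P1 + P2 − τ·P1·P2

and a paraxial y–ν trace gives the back-vertex powers in the two
orientations as

    A = P / (1 − τ·P1)        B = P / (1 − τ·P2).

Inverting these, `P1 = (1/τ)(1 − P/A)` and `P2 = (1/τ)(1 − P/B)`, and
substituting into the thick-lens identity yields a quadratic in `P`,

    P² + τ·A·B·P − A·B = 0,

whose root with the sign of `A + B` is the physical solution. Surface
powers, radii and the Coddington shape factor `X = (R2 + R1)/(R2 − R1)`
then follow in closed form. If the readings were taken a spacing `d`
downstream of the rear vertex (e.g. because haptic angulation displaces a
clamped optic by `h·sin α`), they are first mapped back to the vertex plane
with `A* = A_meas / (1 + (d/n_a)·A_meas)`.

The package provides the forward paraxial model, the closed-form retrieval,
spacing/thickness/index sensitivity sweeps, a synthetic bench simulator
with a Gaussian reading-noise model, CSV batch I/O, and a CLI. See
`docs/methods.md` for conventions, assumptions and numerical choices.

## Worked example

A lens measured on a wet-cell bench (`n_a = 1.334`) reads `A = 22.23 D`
normal and `B = 22.35 D` flipped, with `t = 1.0 mm` and `n_IOL = 1.46`:

```sh
$ iolgeom retrieve --a 22.23 --b 22.35 --t 1.0 --n-iol 1.46 --n-a 1.334 --d 0
P  =   22.1204 D   (intrinsic power, principal planes)
P1 =    7.1970 D   P2 =   14.9973 D
R1 =   17.5072 mm  R2 =   -8.4015 mm
Coddington shape factor X = -0.3515
biconvex: True
quadratic roots: 22.120418, -22.460720 D; discriminant 1987.477805; selected 22.120418
```

The intrinsic power (22.12 D) lands close to a typical 22 D label; about a
third of it sits on the anterior surface (P1 ≈ 7.20 D, R1 ≈ +17.51 mm) and
two thirds on the posterior (P2 ≈ 15.00 D, R2 ≈ −8.40 mm) — a biconvex
design with a mildly posterior-loaded shape (X ≈ −0.35). Both quadratic
roots are printed so the sign-matched selection is auditable.

Sensitivity of the recovered radii to the assumed vertex–detector spacing:

```sh
$ iolgeom sweep-d --a 34.34 --b 33.71 --t 1.45 --n-iol 1.46 --label high
  0.000  high         R1=4.848 mm  R2=-16.450 mm  P=33.4536 D  biconvex=True
  0.100  high         R1=4.860 mm  R2=-16.492 mm  P=33.3699 D  biconvex=True
  ...
```

and to the optic index:

```sh
$ iolgeom index-sens --a 15.72 --b 15.79 --t 0.85 --n-iol 1.46
delta_n = +/-0.001
+delta_n: |dR1|/R1 = 0.8584%  |dR2|/R2 = 0.7710%
-delta_n: |dR1|/R1 = 0.8573%  |dR2|/R2 = 0.7713%
max absolute relative change: 0.8584%
```

An index error of ±0.001 (≈0.07%) moves the recovered radii by just under
1% — radii scale nearly linearly as `(n_IOL − n_a)/P`, so material data at
the bench wavelength matter.

Other commands: `sweep-t` (thickness sweep), `simulate` (synthetic bench
readings from random biconvex designs), `batch-retrieve` (CSV batches).
All lengths are mm, all powers diopters; `--help` on any command lists the
schemas.

## Library use

```python
import iolgeom as g

reading = g.BenchReading(a_meas=22.23, b_meas=22.35, d=0.0,
                         medium=g.WET_CELL, t=1.0, n_iol=1.46)
res = g.retrieve_geometry(reading)
res.p_intrinsic   # 22.120...
res.r_anterior    # 17.507... (mm)
res.biconvex_ok   # True
```

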