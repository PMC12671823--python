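"""Recovering intraocular-lens surface curvatures from dual back-vertex powers.

A thick intraocular lens (IOL) of index ``n_iol``, central thickness ``t`` and
signed surface radii (``Ria``, ``Rip``) has surface powers

    P1 = (n_iol - na) / Ria,        P2 = (na - n_iol) / Rip,

and an intrinsic (equivalent) power, referenced to the principal planes,

    P = P1 + P2 - (t / n_iol) * P1 * P2.

A lensmeter or optical bench reports the *back-vertex* power: the vergence of
the emergent beam at the rear vertex for collimated input.  Measured in the
normal orientation it equals ``A = P / (1 - tau * P1)`` with reduced thickness
``tau = t / n_iol``; flipping the lens gives ``B = P / (1 - tau * P2)``.  A
single reading cannot separate the two surfaces, but the pair (A, B), together
with ``t`` and ``n_iol``, determines them in closed form: substituting

    P1 = (1/tau) (1 - P/A),         P2 = (1/tau) (1 - P/B)

into the thick-lens identity yields the quadratic

    P**2 + tau * A * B * P - A * B = 0,

whose sign-matched root is the intrinsic power, after which surface powers,
radii and the Coddington shape factor follow directly.  When the readings are
taken a spacing ``d`` downstream of the rear vertex (e.g. from haptic
angulation in a clamped bench mount), they are first corrected back to the
vertex plane by inverting the vergence-propagation relation.

Public interfaces take lengths in millimetres and powers in diopters; all
internal computation converts lengths to metres so that powers are exact
reciprocal metres.  The module is organised in the order the method runs:
configuration and domain types, the forward paraxial model, the closed-form
inversion, sensitivity sweeps, the synthetic bench simulator, and file I/O.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "PLANO",
    "PLANO_POWER_THRESHOLD_D",
    "AIR",
    "WET_CELL",
    "IolGeomError",
    "InvalidGeometryError",
    "SingularConfigurationError",
    "NoRealSolutionError",
    "AmbiguousRootError",
    "PlanoMeasurementError",
    "UndefinedShapeError",
    "RetrievalStageError",
    "CsvSchemaError",
    "LensDesign",
    "MediumSpec",
    "SurfacePowers",
    "RayState",
    "VertexPowerPair",
    "BenchReading",
    "RootDiagnostics",
    "RetrievalResult",
    "SweepRow",
    "SweepTable",
    "HapticGeometry",
    "SimConfig",
    "IndexSensitivity",
    "LabelledReading",
    "surface_power",
    "thick_lens_power",
    "back_vertex_power",
    "propagate_vergence",
    "correct_to_vertex",
    "solve_intrinsic_power",
    "surface_powers_from_vertex",
    "radius_from_power",
    "coddington_factor",
    "retrieve_geometry",
    "sweep_offset",
    "sweep_thickness",
    "index_sensitivity",
    "haptic_offset_estimate",
    "simulate_reading",
    "generate_lens_family",
    "child_seed",
    "read_readings_csv",
    "write_readings_csv",
    "write_designs_csv",
    "write_results",
    "plot_sweep",
]

# --------------------------------------------------------------------------
# Configuration: constants, thresholds, logging
# --------------------------------------------------------------------------

logger = logging.getLogger("iolgeom")

#: Marker for a flat (plano) surface: infinite radius, zero surface power.
PLANO: float = math.inf

#: Powers below this magnitude (D) are treated as plano / non-invertible in
#: division contexts (the vertex relations divide by A and B).
PLANO_POWER_THRESHOLD_D: float = 1e-6

_MM_PER_M = 1000.0

#: Attempts per lens before generate_lens_family gives up on a target power.
_MAX_SAMPLE_ATTEMPTS = 100

#: Mercury e-line, the conventional bench wavelength (metadata only).
_BENCH_WAVELENGTH_NM = 546.07

Role = Literal["anterior", "posterior"]
Orientation = Literal["normal", "flipped"]


def _mm_to_m(x_mm: float) -> float:
    return x_mm / _MM_PER_M


def _m_to_mm(x_m: float) -> float:
    return x_m * _MM_PER_M


# --------------------------------------------------------------------------
# Errors
# --------------------------------------------------------------------------


class IolGeomError(Exception):
    """Base class for computation errors in this package."""


class InvalidGeometryError(IolGeomError):
    """A radius of zero (or otherwise impossible geometry) was supplied."""


class SingularConfigurationError(IolGeomError):
    """A focal point coincides with a vertex or detector plane."""


class NoRealSolutionError(IolGeomError):
    """The dual-vertex quadratic has a negative discriminant."""


class AmbiguousRootError(IolGeomError):
    """A + B = 0: the sign-matching root-selection rule cannot decide."""


class PlanoMeasurementError(IolGeomError):
    """A vertex power too close to zero for the inversion formulas."""


class UndefinedShapeError(IolGeomError):
    """Coddington factor undefined (equal radii or both surfaces plano)."""


class CsvSchemaError(IolGeomError):
    """A CSV file does not match the documented schema."""


class RetrievalStageError(IolGeomError):
    """Wraps a sub-operation failure with the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: IolGeomError):
        self.stage = stage
        self.cause = cause
        super().__init__(f"retrieval failed at stage '{stage}': {cause}")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumSpec:
    """Ambient medium around the lens.

    The wavelength is carried as metadata only (indices are assumed to be
    specified at the bench wavelength); it never enters any computation.
    """

    n_ambient: float
    wavelength_nm: float = _BENCH_WAVELENGTH_NM

    def __post_init__(self) -> None:
        if not self.n_ambient >= 1.0:
            raise ValueError(f"n_ambient must be >= 1.0, got {self.n_ambient}")


#: Measurement in air.
AIR = MediumSpec(n_ambient=1.0)

#: ISO-style wet cell: aqueous-like ambient medium.
WET_CELL = MediumSpec(n_ambient=1.334)


@dataclass(frozen=True)
class LensDesign:
    """Physical lens: optic index, central thickness and signed radii.

    Sign convention: light travels left to right; a positive radius puts the
    centre of curvature to the right of the surface.  A biconvex lens thus has
    ``r_anterior > 0`` and ``r_posterior < 0``.  Flat surfaces use the
    :data:`PLANO` marker (infinite radius), never zero.
    """

    n_iol: float
    t: float  # central thickness, mm
    r_anterior: float  # signed radius Ria, mm (PLANO for flat)
    r_posterior: float  # signed radius Rip, mm (PLANO for flat)

    def __post_init__(self) -> None:
        if not self.n_iol > 1.0:
            raise ValueError(f"n_iol must exceed 1.0, got {self.n_iol}")
        if not self.t > 0:
            raise ValueError(f"thickness must be positive, got {self.t}")
        for name, r in (("r_anterior", self.r_anterior), ("r_posterior", self.r_posterior)):
            if r == 0:
                raise InvalidGeometryError(
                    f"{name} = 0 is not a valid radius; use PLANO for a flat surface"
                )

    @property
    def is_biconvex(self) -> bool:
        return (
            math.isfinite(self.r_anterior)
            and math.isfinite(self.r_posterior)
            and self.r_anterior > 0
            and self.r_posterior < 0
        )

    def mirrored(self) -> "LensDesign":
        """The same lens traversed back-to-front (radii swapped, signs negated)."""
        return LensDesign(
            n_iol=self.n_iol,
            t=self.t,
            r_anterior=-self.r_posterior,
            r_posterior=-self.r_anterior,
        )


@dataclass(frozen=True)
class SurfacePowers:
    """Anterior and posterior surface powers, in diopters."""

    p1: float
    p2: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.p1) and math.isfinite(self.p2)):
            raise ValueError("surface powers must be finite")

    @property
    def is_biconvex(self) -> bool:
        return self.p1 > 0 and self.p2 > 0


@dataclass(frozen=True)
class RayState:
    """Paraxial ray state: height y and reduced angle nu = n * u."""

    y: float
    nu: float


@dataclass(frozen=True)
class VertexPowerPair:
    """Back-vertex powers in the two orientations, referenced to the vertex.

    ``a`` is the normal-orientation power, ``b`` the flipped one.  The
    ``at_vertex`` flag asserts the values are referenced to the lens vertex
    plane (d = 0), i.e. offset-corrected if they came from raw readings.
    """

    a: float
    b: float
    at_vertex: bool = True


@dataclass(frozen=True)
class BenchReading:
    """Raw dual-orientation bench readings at a detector spacing ``d``."""

    a_meas: float  # normal-orientation reading, D
    b_meas: float  # flipped-orientation reading, D
    d: float  # vertex-detector spacing, mm
    medium: MediumSpec
    t: float  # lens central thickness, mm
    n_iol: float

    def __post_init__(self) -> None:
        if self.d < 0:
            raise ValueError(f"spacing d must be >= 0, got {self.d}")
        if not self.t > 0:
            raise ValueError(f"thickness must be positive, got {self.t}")
        if not self.n_iol > 1:
            raise ValueError(f"n_iol must exceed 1, got {self.n_iol}")


@dataclass(frozen=True)
class RootDiagnostics:
    """Both roots of the dual-vertex quadratic and how one was selected."""

    roots: tuple[float, float]
    selected: float
    discriminant: float


@dataclass(frozen=True)
class RetrievalResult:
    """Recovered thick-lens geometry plus root diagnostics.

    ``biconvex_ok`` flags physical feasibility (both surface powers
    converging); it is a report-level flag, never a silent filter.
    """

    p_intrinsic: float
    powers: SurfacePowers
    r_anterior: float  # mm, PLANO if surface is flat
    r_posterior: float  # mm
    tau: float  # reduced thickness t / n_iol, metres
    shape_factor: float  # Coddington factor X = (R2 + R1) / (R2 - R1)
    biconvex_ok: bool
    roots: RootDiagnostics


@dataclass(frozen=True)
class SweepRow:
    """One (parameter value, lens) cell of a sensitivity sweep."""

    param_value: float
    lens: str
    r1: float
    r2: float
    p: float
    p1: float
    p2: float
    biconvex_ok: bool
    error: str | None = None


@dataclass(frozen=True)
class SweepTable:
    """Sensitivity-sweep results over a spacing or thickness grid.

    Rows carry full precision; table emission (:meth:`to_csv` /
    :meth:`to_json`) rounds radii half-to-even to 3 decimal places, matching
    the precision at which bench radii are conventionally tabulated.
    """

    parameter_name: Literal["d", "delta_t"]
    grid: tuple[float, ...]
    rows: tuple[SweepRow, ...]

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("sweep grid must be strictly increasing")

    def retained(self) -> tuple[SweepRow, ...]:
        """Rows with a feasible biconvex solution and no stage error."""
        return tuple(r for r in self.rows if r.biconvex_ok and r.error is None)

    def to_records(self, biconvex_only: bool = False) -> list[dict]:
        rows = self.retained() if biconvex_only else self.rows
        return [
            {
                "param": round(r.param_value, 3),
                "lens": r.lens,
                "R1_mm": round(r.r1, 3),
                "R2_mm": round(r.r2, 3),
                "P_D": r.p,
                "P1_D": r.p1,
                "P2_D": r.p2,
                "biconvex": r.biconvex_ok,
            }
            for r in rows
        ]

    def to_csv(self, path: str | Path, biconvex_only: bool = False) -> None:
        records = self.to_records(biconvex_only)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["param", "lens", "R1_mm", "R2_mm", "P_D", "P1_D", "P2_D", "biconvex"])
            for rec in records:
                writer.writerow(
                    [
                        _fmt(rec["param"]),
                        rec["lens"],
                        _fmt(rec["R1_mm"]),
                        _fmt(rec["R2_mm"]),
                        _fmt(rec["P_D"]),
                        _fmt(rec["P1_D"]),
                        _fmt(rec["P2_D"]),
                        rec["biconvex"],
                    ]
                )

    def to_json(self, path: str | Path, biconvex_only: bool = False) -> None:
        payload = {
            "parameter_name": self.parameter_name,
            "grid": list(self.grid),
            "rows": self.to_records(biconvex_only),
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @staticmethod
    def merged(tables: Sequence["SweepTable"]) -> "SweepTable":
        """Concatenate per-lens sweeps that share a parameter and grid."""
        first = tables[0]
        for t in tables[1:]:
            if t.parameter_name != first.parameter_name or t.grid != first.grid:
                raise ValueError("cannot merge sweeps over different parameters or grids")
        rows = tuple(r for t in tables for r in t.rows)
        return SweepTable(first.parameter_name, first.grid, rows)


@dataclass(frozen=True)
class HapticGeometry:
    """Optic half-diameter and haptic angulation for the axial-shift estimate."""

    half_diameter: float = 3.0  # mm; half of a standard 6 mm optic
    angulation: float = 0.0  # degrees

    def __post_init__(self) -> None:
        if not self.half_diameter > 0:
            raise ValueError("half_diameter must be positive")
        if not 0 <= self.angulation < 90:
            raise ValueError("angulation must lie in [0, 90) degrees")


@dataclass(frozen=True)
class SimConfig:
    """Synthetic-bench configuration.

    The default measurement noise of 0.02 D reflects the repeatability of
    ISO-compliant confocal bench measurements of positive IOLs (standard
    deviations below about 0.02 D).  The seed fixes the entire noise stream:
    identical configurations produce bit-identical readings.
    """

    noise_sd: float = 0.02  # D
    seed: int = 0
    d: float = 0.0  # mm
    medium: MediumSpec = WET_CELL

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.d < 0:
            raise ValueError("d must be >= 0")


@dataclass(frozen=True)
class IndexSensitivity:
    """Relative radius changes (%) under an optic-index perturbation."""

    delta_n: float
    r1_pct_plus: float
    r2_pct_plus: float
    r1_pct_minus: float
    r2_pct_minus: float

    @property
    def max_abs_pct(self) -> float:
        return max(self.r1_pct_plus, self.r2_pct_plus, self.r1_pct_minus, self.r2_pct_minus)


@dataclass(frozen=True)
class LabelledReading:
    lens_id: str
    reading: BenchReading


# --------------------------------------------------------------------------
# Forward paraxial model
# --------------------------------------------------------------------------


def surface_power(n_iol: float, n_ambient: float, radius: float, role: Role) -> float:
    """Power of a single refracting surface, in diopters.

    Parameters
    ----------
    n_iol, n_ambient
        Optic and ambient refractive indices.
    radius
        Signed radius of curvature in mm; :data:`PLANO` for a flat surface.
    role
        ``"anterior"`` (light passes ambient -> optic) or ``"posterior"``
        (optic -> ambient); the index difference flips accordingly, so a
        biconvex lens (Ria > 0, Rip < 0) has both powers positive.
    """
    if math.isinf(radius):
        return 0.0
    if radius == 0:
        raise InvalidGeometryError("radius 0 is not valid; use PLANO for a flat surface")
    delta = (n_iol - n_ambient) if role == "anterior" else (n_ambient - n_iol)
    return delta / _mm_to_m(radius)


def thick_lens_power(p: SurfacePowers, t: float, n_iol: float) -> float:
    """Intrinsic (equivalent) power of a thick lens between principal planes.

    P = P1 + P2 - (t / n_iol) * P1 * P2, with thickness ``t`` in mm.
    """
    if not t > 0:
        raise ValueError("thickness must be positive")
    if not n_iol > 1:
        raise ValueError("n_iol must exceed 1")
    tau = _mm_to_m(t) / n_iol
    return p.p1 + p.p2 - tau * p.p1 * p.p2


def _trace_to_back_vertex(p_first: float, p_second: float, tau_m: float) -> tuple[RayState, RayState]:
    """Literal y-nu trace of a collimated unit-height ray through two surfaces.

    Refract at the first surface, transfer by the reduced thickness tau,
    refract at the second surface.  Returns the ray state after each surface.
    """
    y1 = 1.0
    nu1 = -y1 * p_first  # refraction: nu' = nu - y * P, collimated input nu = 0
    after_first = RayState(y=y1, nu=nu1)
    y2 = y1 + tau_m * nu1  # transfer over reduced thickness
    nu2 = nu1 - y2 * p_second  # refraction at second surface
    return after_first, RayState(y=y2, nu=nu2)


def back_vertex_power(
    lens: LensDesign, medium: MediumSpec, orientation: Orientation = "normal"
) -> float:
    """Back-vertex power of a thick lens for collimated input, in diopters.

    Executes the three-step y-nu trace (refract, transfer, refract) and
    returns ``-nu2 / y2``, the emergent vergence at the rear vertex.  The
    flipped orientation presents the posterior surface first; because
    flipping negates the radius while swapping the index difference, the
    surface power values are unchanged and only their order swaps.
    """
    p1 = surface_power(lens.n_iol, medium.n_ambient, lens.r_anterior, "anterior")
    p2 = surface_power(lens.n_iol, medium.n_ambient, lens.r_posterior, "posterior")
    p_first, p_second = (p1, p2) if orientation == "normal" else (p2, p1)
    tau_m = _mm_to_m(lens.t) / lens.n_iol
    _, exit_state = _trace_to_back_vertex(p_first, p_second, tau_m)
    if abs(exit_state.y) < 1e-12:
        raise SingularConfigurationError(
            "front-surface focal point falls on the back vertex (1 - tau*P_first = 0)"
        )
    return -exit_state.nu / exit_state.y


def propagate_vergence(v_in: float, d: float, n_ambient: float) -> float:
    """Vergence after free propagation over a spacing ``d`` (mm) in the medium.

    V_out = V_in / (1 - (d / n_a) * V_in), the downstream transfer of a
    converging or diverging beam; d = 0 is the identity.
    """
    d_m = _mm_to_m(d)
    denom = 1.0 - (d_m / n_ambient) * v_in
    if abs(denom) < PLANO_POWER_THRESHOLD_D * max(1.0, abs(v_in)):
        raise SingularConfigurationError("detector plane coincides with the beam focus")
    return v_in / denom


# --------------------------------------------------------------------------
# Closed-form inversion (the retrieval pipeline)
# --------------------------------------------------------------------------


def correct_to_vertex(reading: BenchReading) -> VertexPowerPair:
    """Map raw detector-plane readings back to the lens vertex plane.

    Inverts the propagation relation:
    A* = A_meas / (1 + (d / n_a) * A_meas), likewise for B*.  Exact inverse
    of :func:`propagate_vergence`; d = 0 is the identity.
    """
    d_m = _mm_to_m(reading.d)
    na = reading.medium.n_ambient

    def _invert(v_meas: float, label: str) -> float:
        denom = 1.0 + (d_m / na) * v_meas
        if abs(denom) <= PLANO_POWER_THRESHOLD_D:
            raise SingularConfigurationError(
                f"offset correction singular for {label} (reading measured at a focus)"
            )
        return v_meas / denom

    return VertexPowerPair(
        a=_invert(reading.a_meas, "A"), b=_invert(reading.b_meas, "B"), at_vertex=True
    )


def solve_intrinsic_power(
    a: float, b: float, t: float, n_iol: float
) -> tuple[float, RootDiagnostics]:
    """Solve the dual-vertex quadratic for the intrinsic power P.

    With tau = t / n_iol, substituting the vertex relations
    P1 = (1/tau)(1 - P/A) and P2 = (1/tau)(1 - P/B) into the thick-lens
    identity gives  P**2 + tau*A*B*P - A*B = 0.  For A*B > 0 the roots have
    opposite signs; the physically convergent one is selected by matching
    sign(A + B).

    Returns the selected root and diagnostics holding both roots and the
    discriminant.
    """
    for label, v in (("A", a), ("B", b)):
        if abs(v) <= PLANO_POWER_THRESHOLD_D:
            raise PlanoMeasurementError(
                f"vertex power {label} = {v} D is below the plano threshold; "
                "the inversion divides by it"
            )
    tau = _mm_to_m(t) / n_iol
    bq = tau * a * b  # linear coefficient
    c = -a * b
    disc = bq * bq - 4.0 * c
    if disc < 0:
        raise NoRealSolutionError(
            f"discriminant {disc:.6g} < 0: no real intrinsic power for A={a}, B={b}"
        )
    sqrt_disc = math.sqrt(disc)
    # Numerically stable pairing: compute the larger-magnitude root first.
    if bq >= 0:
        r_hi = (-bq - sqrt_disc) / 2.0
    else:
        r_hi = (-bq + sqrt_disc) / 2.0
    r_lo = c / r_hi if r_hi != 0 else (-bq + sqrt_disc) / 2.0
    roots = (max(r_lo, r_hi), min(r_lo, r_hi))  # (positive-most, negative-most)

    s = a + b
    if s == 0:
        raise AmbiguousRootError("A + B = 0: sign-matched root selection is ambiguous")
    selected = roots[0] if s > 0 else roots[1]
    diag = RootDiagnostics(roots=roots, selected=selected, discriminant=disc)
    logger.info(
        "dual-vertex quadratic: roots=(%.9g, %.9g) discriminant=%.9g selected=%.9g",
        roots[0], roots[1], disc, selected,
    )
    return selected, diag


def surface_powers_from_vertex(
    a: float, b: float, p: float, t: float, n_iol: float
) -> SurfacePowers:
    """Recover the surface powers from the vertex powers and intrinsic power.

    P1 = (1/tau)(1 - P/A),  P2 = (1/tau)(1 - P/B),  tau = t / n_iol.
    """
    for label, v in (("A", a), ("B", b)):
        if abs(v) <= PLANO_POWER_THRESHOLD_D:
            raise PlanoMeasurementError(f"vertex power {label} too close to zero")
    tau = _mm_to_m(t) / n_iol
    if not tau > 0:
        raise ValueError("tau must be positive")
    return SurfacePowers(p1=(1.0 / tau) * (1.0 - p / a), p2=(1.0 / tau) * (1.0 - p / b))


def radius_from_power(p_surface: float, n_iol: float, n_ambient: float, role: Role) -> float:
    """Signed radius of curvature (mm) from a surface power; plano if P = 0."""
    if abs(p_surface) < PLANO_POWER_THRESHOLD_D:
        return PLANO
    delta = (n_iol - n_ambient) if role == "anterior" else (n_ambient - n_iol)
    return _m_to_mm(delta / p_surface)


def coddington_factor(r_anterior: float, r_posterior: float) -> float:
    """Coddington shape factor X = (R2 + R1) / (R2 - R1).

    Describes how the total power is split between the surfaces: 0 for an
    equi-biconvex lens, +1 for convex-plano (posterior flat), -1 for
    plano-convex (anterior flat).  Plano limits are taken analytically.
    """
    a_inf, p_inf = math.isinf(r_anterior), math.isinf(r_posterior)
    if a_inf and p_inf:
        raise UndefinedShapeError("both surfaces plano: shape factor undefined")
    if p_inf:
        return 1.0
    if a_inf:
        return -1.0
    if r_anterior == r_posterior:
        raise UndefinedShapeError("R1 = R2: degenerate meniscus, shape factor undefined")
    return (r_posterior + r_anterior) / (r_posterior - r_anterior)


def retrieve_geometry(reading: BenchReading) -> RetrievalResult:
    """Full inverse pipeline: bench reading to thick-lens geometry.

    Corrects the readings to the vertex plane, solves the dual-vertex
    quadratic for the intrinsic power, recovers surface powers, converts them
    to radii, and computes the Coddington shape factor.  A non-biconvex
    solution is returned (not rejected) with ``biconvex_ok = False``.

    Raises :class:`RetrievalStageError` identifying the failing stage if any
    sub-operation fails.
    """

    def _stage(name: str, fn, *args):
        try:
            return fn(*args)
        except IolGeomError as exc:
            raise RetrievalStageError(name, exc) from exc

    pair = _stage("correct_to_vertex", correct_to_vertex, reading)
    p, diag = _stage(
        "solve_intrinsic_power", solve_intrinsic_power, pair.a, pair.b, reading.t, reading.n_iol
    )
    powers = _stage(
        "surface_powers_from_vertex",
        surface_powers_from_vertex,
        pair.a, pair.b, p, reading.t, reading.n_iol,
    )
    na = reading.medium.n_ambient
    r1 = _stage("radius_from_power", radius_from_power, powers.p1, reading.n_iol, na, "anterior")
    r2 = _stage("radius_from_power", radius_from_power, powers.p2, reading.n_iol, na, "posterior")
    shape = _stage("coddington_factor", coddington_factor, r1, r2)
    biconvex_ok = powers.is_biconvex
    if not biconvex_ok:
        logger.info("retrieved solution is not biconvex: P1=%.6g D, P2=%.6g D", powers.p1, powers.p2)
    return RetrievalResult(
        p_intrinsic=p,
        powers=powers,
        r_anterior=r1,
        r_posterior=r2,
        tau=_mm_to_m(reading.t) / reading.n_iol,
        shape_factor=shape,
        biconvex_ok=biconvex_ok,
        roots=diag,
    )


# --------------------------------------------------------------------------
# Sensitivity analyses: offset and thickness sweeps, index perturbation
# --------------------------------------------------------------------------

#: Default spacing grid: 0 to 1 mm in 0.1 mm steps.
DEFAULT_D_GRID: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(11))

#: Default thickness-perturbation grid, mm.
DEFAULT_DELTA_T_GRID: tuple[float, ...] = (-0.10, 0.00, 0.10, 0.20)


def _sweep(
    parameter_name: Literal["d", "delta_t"],
    grid: Sequence[float],
    reading_for: "callable",
    label: str,
) -> SweepTable:
    rows = []
    for value in grid:
        try:
            res = retrieve_geometry(reading_for(value))
            rows.append(
                SweepRow(
                    param_value=value,
                    lens=label,
                    r1=res.r_anterior,
                    r2=res.r_posterior,
                    p=res.p_intrinsic,
                    p1=res.powers.p1,
                    p2=res.powers.p2,
                    biconvex_ok=res.biconvex_ok,
                )
            )
        except IolGeomError as exc:
            logger.warning("sweep %s=%g failed for %s: %s", parameter_name, value, label, exc)
            rows.append(
                SweepRow(
                    param_value=value,
                    lens=label,
                    r1=math.nan, r2=math.nan, p=math.nan, p1=math.nan, p2=math.nan,
                    biconvex_ok=False,
                    error=str(exc),
                )
            )
    return SweepTable(parameter_name=parameter_name, grid=tuple(grid), rows=tuple(rows))


def sweep_offset(
    reading: BenchReading,
    d_grid: Sequence[float] = DEFAULT_D_GRID,
    label: str = "lens",
) -> SweepTable:
    """Recovered geometry as the assumed vertex-detector spacing varies.

    For each grid value, the raw readings are reinterpreted as taken at that
    spacing, corrected to the vertex, and the retrieval rerun.  Rows that fail
    or violate the biconvex constraint are recorded with a reason, not
    dropped.
    """
    if any(d < 0 for d in d_grid):
        raise ValueError("spacing grid values must be >= 0")
    return _sweep("d", d_grid, lambda d: replace(reading, d=d), label)


def sweep_thickness(
    reading: BenchReading,
    delta_t_grid: Sequence[float] = DEFAULT_DELTA_T_GRID,
    label: str = "lens",
) -> SweepTable:
    """Recovered geometry as the assumed central thickness varies (d fixed).

    Each grid value is a perturbation delta_t added to the reading's nominal
    thickness.
    """
    if any(reading.t + dt <= 0 for dt in delta_t_grid):
        raise ValueError("t + delta_t must remain positive over the grid")
    return _sweep("delta_t", delta_t_grid, lambda dt: replace(reading, t=reading.t + dt), label)


def index_sensitivity(reading: BenchReading, delta_n: float) -> IndexSensitivity:
    """Relative radius changes (%) when the optic index is perturbed by +/- delta_n.

    Reruns the retrieval at ``n_iol +/- delta_n`` with A, B, t, d fixed and
    reports 100 * |delta R| / |R| for both surfaces and both signs.  Because
    R is proportional to (n_iol - n_a) / P, small index errors map nearly
    linearly onto the radii.
    """
    if not reading.n_iol - abs(delta_n) > 1:
        raise ValueError("n_iol - |delta_n| must exceed 1")
    base = retrieve_geometry(reading)

    def _pct(sign: int) -> tuple[float, float]:
        pert = retrieve_geometry(replace(reading, n_iol=reading.n_iol + sign * delta_n))
        return (
            100.0 * abs(pert.r_anterior - base.r_anterior) / abs(base.r_anterior),
            100.0 * abs(pert.r_posterior - base.r_posterior) / abs(base.r_posterior),
        )

    r1p, r2p = _pct(+1)
    r1m, r2m = _pct(-1)
    return IndexSensitivity(
        delta_n=delta_n,
        r1_pct_plus=r1p, r2_pct_plus=r2p, r1_pct_minus=r1m, r2_pct_minus=r2m,
    )


def haptic_offset_estimate(geom: HapticGeometry) -> float:
    """Axial shift of the optic centre induced by haptic angulation, in mm.

    d = h * sin(alpha): a haptic angle alpha tilts the support loops so the
    optic of half-diameter h sits axially displaced when the lens is clamped
    or flipped.  Typical angulations of 5-15 degrees on a 6 mm optic give
    roughly 0.25-0.8 mm.
    """
    return geom.half_diameter * math.sin(math.radians(geom.angulation))


# --------------------------------------------------------------------------
# Synthetic bench simulator
# --------------------------------------------------------------------------


def simulate_reading(lens: LensDesign, cfg: SimConfig) -> BenchReading:
    """Simulate a dual-orientation bench reading from a known lens design.

    The forward model traces the back-vertex power in each orientation,
    propagates it to the detector plane at spacing ``cfg.d``, and adds
    independent Gaussian noise of standard deviation ``cfg.noise_sd`` to each
    raw reading (noise acts at the detector plane, which is what a bench
    reports; the vertex correction then operates on noisy values).
    Deterministic given the seed.
    """
    a0 = back_vertex_power(lens, cfg.medium, "normal")
    b0 = back_vertex_power(lens, cfg.medium, "flipped")
    a_meas = propagate_vergence(a0, cfg.d, cfg.medium.n_ambient)
    b_meas = propagate_vergence(b0, cfg.d, cfg.medium.n_ambient)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        a_meas += rng.normal(0.0, cfg.noise_sd)
        b_meas += rng.normal(0.0, cfg.noise_sd)
    return BenchReading(
        a_meas=a_meas, b_meas=b_meas, d=cfg.d, medium=cfg.medium, t=lens.t, n_iol=lens.n_iol
    )


def child_seed(root_seed: int, index: int) -> int:
    """Deterministic per-item substream seed derived from a root seed.

    Uses a spawn-key style derivation so item ``index`` gets the same stream
    regardless of how many other items are generated (order independence).
    """
    return int(np.random.SeedSequence([root_seed, index]).generate_state(1)[0])


def generate_lens_family(
    n: int,
    power_range: tuple[float, float],
    seed: int,
    medium: MediumSpec = WET_CELL,
) -> list[LensDesign]:
    """Sample ``n`` random biconvex lens designs with target equivalent powers.

    Each lens draws an optic index in [1.43, 1.56], a thickness in
    [0.5, 1.6] mm, a target intrinsic power uniform over ``power_range`` and
    a Coddington factor uniform in (-0.9, 0.9); the radii follow by solving
    the thick-lens identity for the curvature scale at that shape.  Every
    emitted design is biconvex and hits its target power to well under
    1e-6 D.  Infeasible draws (e.g. a non-positive target power, which no
    biconvex lens can deliver) are resampled; after a bounded number of
    failed attempts an error is raised.

    Sampling uses one substream per lens index derived from ``seed``
    (:func:`child_seed`), so the family is order-independent.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    lo, hi = power_range
    if not (-10.0 <= lo <= hi <= 40.0):
        raise ValueError("power_range must lie within [-10, 40] D")
    na = medium.n_ambient
    designs: list[LensDesign] = []
    for i in range(n):
        rng = np.random.default_rng(child_seed(seed, i))
        lens = None
        for _ in range(_MAX_SAMPLE_ATTEMPTS):
            p_target = rng.uniform(lo, hi)
            n_iol = rng.uniform(1.43, 1.56)
            t = rng.uniform(0.5, 1.6)
            x = rng.uniform(-0.9, 0.9)
            lens = _design_from_power_shape(p_target, x, t, n_iol, na)
            if lens is not None and lens.is_biconvex:
                break
            lens = None
        if lens is None:
            raise IolGeomError(
                f"could not realise a biconvex design in range {power_range} D "
                f"after {_MAX_SAMPLE_ATTEMPTS} attempts (lens index {i})"
            )
        designs.append(lens)
    return designs


def _design_from_power_shape(
    p_target: float, x: float, t: float, n_iol: float, na: float
) -> LensDesign | None:
    """Biconvex design realising a target intrinsic power at a given shape.

    With the shape factor fixing R2 = k * R1 (k = (X+1)/(X-1) < 0 for
    |X| < 1), the thick-lens identity becomes a quadratic in the curvature
    1/R1; the root on the thin-lens branch is taken.  Returns None when no
    real biconvex solution exists.
    """
    if p_target <= 0:
        return None
    k = (x + 1.0) / (x - 1.0)  # R2 / R1, negative for |x| < 1
    c1 = n_iol - na  # P1 = c1 * u with u = 1 / R1 (metres)
    c2 = -(n_iol - na) / k  # P2 = c2 * u
    tau = _mm_to_m(t) / n_iol
    # tau*c1*c2 * u^2 - (c1 + c2) * u + P = 0
    aa = tau * c1 * c2
    bb = -(c1 + c2)
    disc = bb * bb - 4.0 * aa * p_target
    if disc < 0:
        return None
    # Thin-lens branch: the root continuous with u = P / (c1 + c2) as tau -> 0.
    u = (-bb - math.sqrt(disc)) / (2.0 * aa)
    if u <= 0:
        return None
    r1_mm = _m_to_mm(1.0 / u)
    return LensDesign(n_iol=n_iol, t=t, r_anterior=r1_mm, r_posterior=k * r1_mm)


# --------------------------------------------------------------------------
# File I/O
# --------------------------------------------------------------------------

_READINGS_HEADER = ["lens_id", "A_meas_D", "B_meas_D", "d_mm", "t_mm", "n_iol", "n_ambient"]
_DESIGNS_HEADER = ["lens_id", "n_iol", "t_mm", "R1_mm", "R2_mm"]
_RESULTS_HEADER = [
    "lens", "P_D", "P1_D", "P2_D", "R1_mm", "R2_mm", "shape_factor", "biconvex",
]


def _fmt(x) -> str:
    """Shortest decimal text that round-trips the double bit-exactly."""
    if isinstance(x, bool):
        return str(x)
    if isinstance(x, float):
        if math.isinf(x):
            return "inf" if x > 0 else "-inf"
        return repr(x)
    return str(x)


def read_readings_csv(path: str | Path) -> list[LabelledReading]:
    """Read a batch of bench readings from CSV.

    Expected header: ``lens_id,A_meas_D,B_meas_D,d_mm,t_mm,n_iol,n_ambient``
    (lengths in mm, powers in D).  An empty file with a valid header yields an
    empty list.  A malformed row raises :class:`CsvSchemaError` naming the row
    number and column.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise CsvSchemaError(f"{path}: empty file, expected header {_READINGS_HEADER}")
        missing = [c for c in _READINGS_HEADER if c not in reader.fieldnames]
        if missing:
            raise CsvSchemaError(f"{path}: missing column(s) {missing}")
        out: list[LabelledReading] = []
        for row_num, row in enumerate(reader, start=2):
            values = {}
            for col in _READINGS_HEADER[1:]:
                try:
                    values[col] = float(row[col])
                except (TypeError, ValueError):
                    raise CsvSchemaError(
                        f"{path}: row {row_num}, column '{col}': "
                        f"cannot parse {row.get(col)!r} as a number"
                    ) from None
            out.append(
                LabelledReading(
                    lens_id=row["lens_id"],
                    reading=BenchReading(
                        a_meas=values["A_meas_D"],
                        b_meas=values["B_meas_D"],
                        d=values["d_mm"],
                        medium=MediumSpec(n_ambient=values["n_ambient"]),
                        t=values["t_mm"],
                        n_iol=values["n_iol"],
                    ),
                )
            )
    return out


def write_readings_csv(path: str | Path, readings: Iterable[LabelledReading]) -> None:
    """Write bench readings in the schema :func:`read_readings_csv` accepts."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_READINGS_HEADER)
        for lr in readings:
            r = lr.reading
            writer.writerow(
                [lr.lens_id, _fmt(r.a_meas), _fmt(r.b_meas), _fmt(r.d), _fmt(r.t),
                 _fmt(r.n_iol), _fmt(r.medium.n_ambient)]
            )


def write_designs_csv(path: str | Path, designs: Iterable[tuple[str, LensDesign]]) -> None:
    """Write ground-truth lens designs (for scoring simulated recoveries)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_DESIGNS_HEADER)
        for lens_id, d in designs:
            writer.writerow(
                [lens_id, _fmt(d.n_iol), _fmt(d.t), _fmt(d.r_anterior), _fmt(d.r_posterior)]
            )


def _result_record(lens_id: str, res: RetrievalResult) -> dict:
    return {
        "lens": lens_id,
        "P_D": res.p_intrinsic,
        "P1_D": res.powers.p1,
        "P2_D": res.powers.p2,
        "R1_mm": res.r_anterior,
        "R2_mm": res.r_posterior,
        "shape_factor": res.shape_factor,
        "biconvex": res.biconvex_ok,
    }


def write_results(
    path: str | Path,
    results: Sequence[tuple[str, RetrievalResult]],
    fmt: Literal["csv", "json"] = "csv",
) -> None:
    """Write labelled retrieval results as CSV or JSON (same values either way)."""
    records = [_result_record(lens_id, res) for lens_id, res in results]
    if fmt == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(_RESULTS_HEADER)
            for rec in records:
                writer.writerow([_fmt(rec[c]) for c in _RESULTS_HEADER])
    elif fmt == "json":
        Path(path).write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}; use 'csv' or 'json'")


def plot_sweep(table: SweepTable, path: str | Path) -> None:
    """Plot R1 and |R2| against the sweep parameter, one line per lens."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xlabel = "d (mm)" if table.parameter_name == "d" else "delta t (mm)"
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4), sharex=True)
    labels = sorted({r.lens for r in table.rows})
    for lens in labels:
        rows = [r for r in table.rows if r.lens == lens and r.error is None]
        xs = [r.param_value for r in rows]
        ax1.plot(xs, [r.r1 for r in rows], marker="o", label=lens)
        ax2.plot(xs, [abs(r.r2) for r in rows], marker="o", label=lens)
    ax1.set_xlabel(xlabel)
    ax1.set_ylabel("R1 (mm)")
    ax2.set_xlabel(xlabel)
    ax2.set_ylabel("|R2| (mm)")
    ax1.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
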