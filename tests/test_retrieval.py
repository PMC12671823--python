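"""Inverse pipeline: vertex correction, dual-vertex quadratic, geometry."""

import math

import numpy as np
import pytest
from scipy.optimize import fsolve

import iolgeom as g

from paper_tables import N_AMBIENT, N_IOL


def _make_reading(a, b, t, d=0.0, n_iol=N_IOL, na=N_AMBIENT):
    return g.BenchReading(
        a_meas=a, b_meas=b, d=d, medium=g.MediumSpec(n_ambient=na), t=t, n_iol=n_iol
    )


class TestCorrectToVertex:
    def test_zero_spacing_identity(self):
        pair = g.correct_to_vertex(_make_reading(15.72, 15.79, 0.85, d=0.0))
        assert pair.a == 15.72 and pair.b == 15.79 and pair.at_vertex

    def test_one_mm_spacing(self):
        # A/(1 + (d/na) A) at d = 1 mm, na = 1.334
        pair = g.correct_to_vertex(_make_reading(15.72, 15.79, 0.85, d=1.0))
        assert pair.a == pytest.approx(15.536911, abs=1e-5)
        assert pair.b == pytest.approx(15.605287, abs=1e-5)

    def test_inverse_of_propagation(self):
        for v, d in [(22.23, 0.3), (-8.0, 1.0), (34.34, 0.7)]:
            meas = g.propagate_vergence(v, d, 1.334)
            pair = g.correct_to_vertex(_make_reading(meas, meas, 1.0, d=d))
            assert pair.a == pytest.approx(v, rel=1e-12)

    def test_corrected_power_decreases_with_spacing(self):
        """For a positive reading, the vertex-referred power falls as the
        assumed spacing grows."""
        grid = np.linspace(0.0, 1.0, 21)
        vals = [
            g.correct_to_vertex(_make_reading(15.72, 15.79, 0.85, d=float(d))).a for d in grid
        ]
        assert all(x > y for x, y in zip(vals, vals[1:]))


class TestSolveIntrinsicPower:
    @pytest.mark.parametrize(
        "a, b, t, expected",
        [
            (22.23, 22.35, 1.0, 22.1204),  # worked example
            (15.72, 15.79, 0.85, 15.6829),  # low-power example lens
        ],
    )
    def test_examples(self, a, b, t, expected):
        p, diag = g.solve_intrinsic_power(a, b, t, N_IOL)
        assert p == pytest.approx(expected, abs=5e-4)
        assert diag.selected == p

    def test_thin_lens_degenerates_to_geometric_mean(self):
        p, _ = g.solve_intrinsic_power(20.0, 20.0, 1e-9, N_IOL)
        assert p == pytest.approx(20.0, abs=1e-9)

    def test_quadratic_residual(self):
        a, b, t = 22.23, 22.35, 1.0
        p, _ = g.solve_intrinsic_power(a, b, t, N_IOL)
        tau = t / 1000 / N_IOL
        assert abs(p * p + tau * a * b * p - a * b) <= 1e-9 * abs(a * b)

    def test_roots_have_opposite_signs_for_positive_product(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a = rng.uniform(5.0, 35.0)
            b = a + rng.normal(0, 0.5)
            _, diag = g.solve_intrinsic_power(a, b, rng.uniform(0.5, 1.5), 1.46)
            assert diag.roots[0] > 0 > diag.roots[1]

    def test_opposite_sign_pair_is_ambiguous(self):
        # A + B = 0 with a real discriminant requires |A*B| > 4/tau^2,
        # i.e. extreme powers; the sign-matching rule then cannot decide.
        with pytest.raises(g.AmbiguousRootError):
            g.solve_intrinsic_power(3000.0, -3000.0, 1.0, 1.46)

    def test_negative_discriminant_rejected(self):
        with pytest.raises(g.NoRealSolutionError):
            g.solve_intrinsic_power(5.0, -4.0, 1.0, 1.46)

    def test_plano_reading_rejected(self):
        with pytest.raises(g.PlanoMeasurementError):
            g.solve_intrinsic_power(0.0, 20.0, 1.0, 1.46)


class TestSurfacePowersAndRadii:
    def test_case1_surface_powers(self, case1_reading):
        p, _ = g.solve_intrinsic_power(22.23, 22.35, 1.0, N_IOL)
        sp = g.surface_powers_from_vertex(22.23, 22.35, p, 1.0, N_IOL)
        assert sp.p1 == pytest.approx(7.20, abs=5e-3)
        assert sp.p2 == pytest.approx(15.00, abs=5e-3)

    def test_low_power_surface_powers(self):
        p, _ = g.solve_intrinsic_power(15.72, 15.79, 0.85, N_IOL)
        sp = g.surface_powers_from_vertex(15.72, 15.79, p, 0.85, N_IOL)
        assert sp.p1 == pytest.approx(4.0569, abs=5e-4)
        assert sp.p2 == pytest.approx(11.6534, abs=5e-4)

    def test_p_equal_a_gives_plano_anterior(self):
        sp = g.surface_powers_from_vertex(20.0, 21.0, 20.0, 1.0, 1.46)
        assert sp.p1 == 0.0

    @pytest.mark.parametrize(
        "power, role, expected",
        [
            (7.197, "anterior", 17.507),
            (14.997, "posterior", -8.402),
        ],
    )
    def test_radius_examples(self, power, role, expected):
        assert g.radius_from_power(power, N_IOL, N_AMBIENT, role) == pytest.approx(
            expected, abs=5e-3
        )

    def test_zero_power_is_plano(self):
        assert math.isinf(g.radius_from_power(0.0, N_IOL, N_AMBIENT, "anterior"))

    def test_radius_power_round_trip(self):
        for p in (7.197, -3.5, 22.0):
            r = g.radius_from_power(p, N_IOL, N_AMBIENT, "posterior")
            assert g.surface_power(N_IOL, N_AMBIENT, r, "posterior") == pytest.approx(
                p, rel=1e-12
            )


class TestCoddingtonFactor:
    @pytest.mark.parametrize(
        "r1, r2, expected",
        [
            (10.0, -10.0, 0.0),  # equi-biconvex
            (10.0, g.PLANO, 1.0),  # convex-plano
            (g.PLANO, -10.0, -1.0),  # plano-convex
            (17.507219, -8.401504, -0.35145),  # worked-example shape
        ],
    )
    def test_examples(self, r1, r2, expected):
        assert g.coddington_factor(r1, r2) == pytest.approx(expected, abs=5e-5)

    def test_equal_radii_undefined(self):
        with pytest.raises(g.UndefinedShapeError):
            g.coddington_factor(10.0, 10.0)

    def test_both_plano_undefined(self):
        with pytest.raises(g.UndefinedShapeError):
            g.coddington_factor(g.PLANO, g.PLANO)


class TestRetrieveGeometry:
    @pytest.mark.parametrize(
        "label, r1, r2",
        [("low", 31.058, -10.812), ("high", 4.848, -16.450)],
    )
    def test_zero_offset_rows(self, paper_readings, label, r1, r2):
        res = g.retrieve_geometry(paper_readings[label])
        assert res.r_anterior == pytest.approx(r1, abs=5e-4)
        assert res.r_posterior == pytest.approx(r2, abs=5e-4)
        assert res.biconvex_ok

    def test_internal_consistency(self, case1_reading):
        """Stored powers, radii and intrinsic power agree with each other."""
        res = g.retrieve_geometry(case1_reading)
        tau = res.tau
        # vertex relations reproduce the stored surface powers
        assert (1 / tau) * (1 - res.p_intrinsic / 22.23) == pytest.approx(
            res.powers.p1, rel=1e-12
        )
        assert (1 / tau) * (1 - res.p_intrinsic / 22.35) == pytest.approx(
            res.powers.p2, rel=1e-12
        )
        # radii and powers are consistent under the surface-power relation
        assert g.surface_power(N_IOL, N_AMBIENT, res.r_anterior, "anterior") == pytest.approx(
            res.powers.p1, rel=1e-12
        )
        assert g.surface_power(N_IOL, N_AMBIENT, res.r_posterior, "posterior") == pytest.approx(
            res.powers.p2, rel=1e-12
        )

    def test_stage_error_identifies_stage(self):
        with pytest.raises(g.RetrievalStageError) as exc_info:
            g.retrieve_geometry(_make_reading(5.0, -4.0, 1.0))
        assert exc_info.value.stage == "solve_intrinsic_power"

    def test_round_trip_1000_random_biconvex_lenses(self):
        """Zero-noise simulate -> retrieve recovers every generating lens to
        1e-9 relative in P, surface powers and radii, across spacings."""
        lenses = g.generate_lens_family(1000, (5.0, 35.0), seed=11)
        rng = np.random.default_rng(3)
        for i, lens in enumerate(lenses):
            medium = g.WET_CELL if rng.random() < 0.5 else g.AIR
            d = float(rng.choice([0.0, 0.3, 1.0]))
            cfg = g.SimConfig(noise_sd=0.0, seed=0, d=d, medium=medium)
            res = g.retrieve_geometry(g.simulate_reading(lens, cfg))
            na = medium.n_ambient
            p1 = g.surface_power(lens.n_iol, na, lens.r_anterior, "anterior")
            p2 = g.surface_power(lens.n_iol, na, lens.r_posterior, "posterior")
            p = g.thick_lens_power(g.SurfacePowers(p1, p2), lens.t, lens.n_iol)
            assert res.p_intrinsic == pytest.approx(p, rel=1e-9)
            assert res.powers.p1 == pytest.approx(p1, rel=1e-9)
            assert res.powers.p2 == pytest.approx(p2, rel=1e-9)
            assert res.r_anterior == pytest.approx(lens.r_anterior, rel=1e-9)
            assert res.r_posterior == pytest.approx(lens.r_posterior, rel=1e-9)

    def test_quadratic_agrees_with_numeric_root_finder(self):
        """The closed-form root matches a brute-force simultaneous solve of
        the two vertex relations plus the thick-lens identity."""
        lenses = g.generate_lens_family(1000, (5.0, 35.0), seed=23)
        for lens in lenses:
            cfg = g.SimConfig(noise_sd=0.0, seed=0, d=0.0, medium=g.WET_CELL)
            r = g.simulate_reading(lens, cfg)
            a, b = r.a_meas, r.b_meas
            tau = r.t / 1000 / r.n_iol

            def equations(x, a=a, b=b, tau=tau):
                p1, p2 = x
                p = p1 + p2 - tau * p1 * p2
                return [a * (1 - tau * p1) - p, b * (1 - tau * p2) - p]

            sol = fsolve(equations, x0=[a / 2, b / 2], full_output=False)
            p1_o, p2_o = sol
            p_oracle = p1_o + p2_o - tau * p1_o * p2_o
            p_closed, _ = g.solve_intrinsic_power(a, b, r.t, r.n_iol)
            assert p_closed == pytest.approx(p_oracle, abs=1e-8)

    def test_biconcave_lens_round_trips_on_negative_root(self):
        lens = g.LensDesign(n_iol=1.46, t=0.8, r_anterior=-15.0, r_posterior=20.0)
        cfg = g.SimConfig(noise_sd=0.0, seed=0, d=0.0, medium=g.WET_CELL)
        res = g.retrieve_geometry(g.simulate_reading(lens, cfg))
        assert res.p_intrinsic < 0
        assert res.roots.selected == res.roots.roots[1]
        assert not res.biconvex_ok
        assert res.r_anterior == pytest.approx(-15.0, rel=1e-9)
        assert res.r_posterior == pytest.approx(20.0, rel=1e-9)
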