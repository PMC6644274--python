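"""Circle fitting and the equatorial-plane construction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from lenspos import lens_geometry as geom
from _oracles import esd_sampling_oracle, kasa_objective


def _arc_points(center_depth, radius, aperture, n=50, anterior=True, rng=None, noise=0.0):
    half = aperture / 2.0
    h = np.linspace(-half, half, n)
    sign = -1.0 if anterior else 1.0
    z = center_depth + sign * np.sqrt(radius**2 - h**2)
    if noise:
        h = h + rng.normal(0.0, noise, n)
    ap = max(aperture, 2 * np.max(np.abs(h)))
    return geom.SurfaceSamples(points=np.column_stack([z, h]), aperture_mm=ap)


class TestFitCircle:
    def test_three_exact_points(self):
        s = geom.SurfaceSamples(points=[(0, 1), (1, 0), (0, -1)], aperture_mm=2.0)
        c = geom.fit_circle(s)
        assert c.center_depth == pytest.approx(0.0, abs=1e-12)
        assert c.radius == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("aperture", [1.0, 2.0, 4.0])
    def test_noise_free_recovery(self, aperture):
        """Exact recovery of the generating circle from any clean arc."""
        s = _arc_points(13.00, 10.21, aperture)
        c = geom.fit_circle(s)
        assert c.center_depth == pytest.approx(13.00, abs=1e-9)
        assert c.radius == pytest.approx(10.21, abs=1e-9)

    def test_noisy_fit_matches_direct_objective_minimization(self):
        """The linear solve agrees with a general minimizer of the same
        algebraic objective, and lands near the generating radius."""
        rng = np.random.default_rng(11)
        s = _arc_points(13.00, 10.21, 4.0, rng=rng, noise=0.01)
        c = geom.fit_circle(s)
        assert abs(c.radius - 10.21) < 0.15

        def obj(p):
            return kasa_objective(s.points, p[0], p[1], p[2])

        res = minimize(obj, x0=[12.5, 0.05, 9.8], method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        assert c.center_depth == pytest.approx(res.x[0], abs=1e-4)
        assert c.radius == pytest.approx(res.x[2], abs=1e-4)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(geom.DegenerateSamplesError, match="degenerate"):
            geom.fit_circle(
                geom.SurfaceSamples(points=[(0, 0), (1, 1)], aperture_mm=4.0)
            )
        collinear = [(z, 0.5 * z) for z in (0.0, 0.5, 1.0, 1.5)]
        with pytest.raises(geom.DegenerateSamplesError, match="collinear"):
            geom.fit_circle(geom.SurfaceSamples(points=collinear, aperture_mm=4.0))

    def test_tilted_surface_rejected(self):
        """A centre off the axis beyond the tolerance must not be collapsed."""
        s = _arc_points(13.0, 10.21, 4.0)
        tilted = geom.SurfaceSamples(
            points=s.points + np.array([0.0, 0.5]), aperture_mm=5.2
        )
        with pytest.raises(geom.SurfaceTiltError, match="tilt"):
            geom.fit_circle(tilted)
        # ... but passes with a loosened tolerance.
        c = geom.fit_circle(tilted, tilt_tolerance_mm=1.0)
        assert c.radius == pytest.approx(10.21, abs=1e-9)

    def test_smaller_aperture_inflates_radius_variance(self):
        """Shrinking the sampled arc makes the fitted radius noisier."""
        spreads = {}
        for aperture in (2.0, 4.0):
            rng = np.random.default_rng(202)
            radii = [
                geom.fit_circle(
                    _arc_points(13.0, 10.21, aperture, rng=rng, noise=0.01)
                ).radius
                for _ in range(300)
            ]
            spreads[aperture] = np.std(radii)
        assert spreads[2.0] > spreads[4.0]


class TestLensShape:
    def test_mean_cohort_geometry(self):
        anterior = geom.AxisCircle(13.00, 10.21)
        posterior = geom.AxisCircle(1.26, 6.01)
        shape = geom.lens_shape_from_circles(anterior, posterior)
        assert shape.asd_mm == pytest.approx(2.79)
        assert shape.psd_mm == pytest.approx(7.27)
        assert shape.lt_mm == pytest.approx(4.48)

    def test_toy_circles(self):
        shape = geom.lens_shape_from_circles(
            geom.AxisCircle(2, 1), geom.AxisCircle(3.5, 1)
        )
        assert (shape.asd_mm, shape.psd_mm, shape.lt_mm) == (1.0, 4.5, 3.5)

    def test_tangent_circles_have_no_equator(self):
        """Externally tangent surfaces meet in a single on-axis point, not
        an equatorial circle."""
        with pytest.raises(geom.NonIntersectingCirclesError):
            geom.lens_shape_from_circles(geom.AxisCircle(2, 1), geom.AxisCircle(4, 1))

    def test_inverted_geometry_rejected(self):
        with pytest.raises(geom.GeometryError, match="inverted"):
            geom.lens_shape_from_circles(
                geom.AxisCircle(20, 1), geom.AxisCircle(10, 1)
            )

    @given(
        asd=st.floats(1.5, 4.0),
        lt=st.floats(3.5, 5.5),
        acr=st.floats(7.5, 14.0),
        pcr=st.floats(4.7, 7.7),
    )
    @settings(max_examples=200, derandomize=True)
    def test_construction_identity_and_ordering(self, asd, lt, acr, pcr):
        """psd − asd − lt = 0 exactly and asd < esd < psd whenever the
        circles intersect."""
        anterior = geom.AxisCircle(asd + acr, acr)
        posterior = geom.AxisCircle(asd + lt - pcr, pcr)
        try:
            shape = geom.lens_shape_from_circles(anterior, posterior)
        except geom.GeometryError:
            return
        assert shape.psd_mm - shape.asd_mm - shape.lt_mm == pytest.approx(0, abs=1e-12)
        assert shape.asd_mm < shape.esd_mm < shape.psd_mm


class TestEquatorialDepth:
    def test_symmetric_circles_meet_at_midplane(self):
        a = geom.AxisCircle(3.0, 3.5)
        p = geom.AxisCircle(7.0, 3.5)
        assert geom.equatorial_depth(a, p) == pytest.approx(5.0, abs=1e-12)

    def test_concentric_depth_rejected(self):
        with pytest.raises(geom.GeometryError, match="equator undefined"):
            geom.equatorial_depth(geom.AxisCircle(5, 2), geom.AxisCircle(5, 3))

    def test_non_intersecting_rejected(self):
        with pytest.raises(geom.NonIntersectingCirclesError):
            geom.equatorial_depth(geom.AxisCircle(3.79, 1.0), geom.AxisCircle(6.27, 1.0))

    def test_matches_sampling_oracle_on_random_pairs(self):
        """Closed form ≡ dense-sampling/bisection oracle to 1e-6 mm."""
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 1000:
            acr = rng.uniform(7.5, 14.0)
            pcr = rng.uniform(4.7, 7.7)
            asd = rng.uniform(1.7, 3.8)
            lt = rng.uniform(3.6, 5.4)
            a = geom.AxisCircle(asd + acr, acr)
            p = geom.AxisCircle(asd + lt - pcr, pcr)
            try:
                z = geom.equatorial_depth(a, p)
            except geom.GeometryError:
                continue
            expected = esd_sampling_oracle(
                a.center_depth, a.radius, p.center_depth, p.radius
            )
            assert expected is not None
            assert z == pytest.approx(expected, abs=1e-6)
            checked += 1

    def test_batch_agrees_with_scalar(self):
        rng = np.random.default_rng(3)
        acr = rng.uniform(8, 13, 50)
        pcr = rng.uniform(5, 7, 50)
        asd = rng.uniform(2, 3.5, 50)
        psd = asd + rng.uniform(3.8, 5.2, 50)
        z, valid = geom.equatorial_depth_batch(asd + acr, acr, psd - pcr, pcr)
        for i in range(50):
            a = geom.AxisCircle(asd[i] + acr[i], acr[i])
            p = geom.AxisCircle(psd[i] - pcr[i], pcr[i])
            if valid[i]:
                assert z[i] == pytest.approx(geom.equatorial_depth(a, p), abs=1e-12)
            else:
                with pytest.raises(geom.GeometryError):
                    geom.equatorial_depth(a, p)
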