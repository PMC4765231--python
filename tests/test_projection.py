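import numpy as np
import pytest

from molcarto import (
    MILLER_Y_MAX,
    centre_of_mass,
    max_radius,
    miller_latitude,
    miller_project,
    miller_y,
    spherify,
    to_geographic,
)
from molcarto.errors import DegenerateMouldError, MolcartoWarning
from molcarto.projection import GeoPoints

# (5/4) * ln(tan(9*pi/20)) evaluated independently with sympy at 20 digits
POLE_Y = 2.3034125433763912877

TOL = 1e-9


class TestCentreOfMass:
    @pytest.mark.parametrize(
        "points,expected",
        [
            ([(0, 0, 0), (2, 0, 0)], (1, 0, 0)),
            ([(1, 2, 3)], (1, 2, 3)),
            (
                [(x, y, z) for x in (0, 1) for y in (0, 1) for z in (0, 1)],
                (0.5, 0.5, 0.5),
            ),
        ],
    )
    def test_unweighted_mean(self, points, expected):
        np.testing.assert_allclose(centre_of_mass(np.array(points, float)), expected)

    def test_empty_input(self):
        with pytest.raises(ValueError):
            centre_of_mass(np.empty((0, 3)))


class TestMaxRadius:
    def test_hand_euclidean(self):
        pts = np.array([(0, 0, 0), (3, 4, 0)], float)
        assert max_radius(pts, np.array([1.5, 2.0, 0.0])) == pytest.approx(2.5)

    def test_single_point(self):
        assert max_radius(np.array([[0, 0, 7]], float),
                          np.zeros(3)) == pytest.approx(7.0)

    def test_coincident_points_degenerate(self):
        pts = np.ones((4, 3))
        with pytest.raises(DegenerateMouldError, match="degenerate"):
            max_radius(pts, np.ones(3))


class TestSpherify:
    def test_axis_scaling(self):
        c = np.array([2.0, 3.0, 4.0])
        m = spherify(np.array([c + (1, 0, 0)]), c, radius=5.0)
        np.testing.assert_allclose(m.points, [[5.0, 0.0, 0.0]], atol=TOL)

    def test_all_norms_equal_radius(self, rng):
        pts = rng.normal(size=(200, 3))
        c = centre_of_mass(pts)
        r = max_radius(pts, c)
        m = spherify(pts, c, r)
        np.testing.assert_allclose(
            np.linalg.norm(m.points, axis=1) / r, 1.0, rtol=TOL)

    def test_point_at_centre_dropped_with_warning(self):
        c = np.zeros(3)
        pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]])
        with pytest.warns(MolcartoWarning, match="centre of mass"):
            m = spherify(pts, c, 2.0, residues=["ALA", "GLY"])
        assert m.n_dropped == 1
        assert m.residues == ["GLY"]

    def test_all_points_at_centre_errors(self):
        with pytest.raises(DegenerateMouldError):
            with pytest.warns(MolcartoWarning):
                spherify(np.zeros((3, 3)), np.zeros(3), 1.0)


class TestGeographic:
    def _single(self, w):
        from molcarto.projection import SphereMapping

        m = SphereMapping(centre=np.zeros(3), radius=float(np.linalg.norm(w)),
                          points=np.array([w], float), residues=["ALA"])
        g = to_geographic(m)
        return float(g.latitude[0]), float(g.longitude[0])

    @pytest.mark.parametrize(
        "w,lat,lon",
        [
            ((3.0, 0.0, 0.0), 0.0, 0.0),
            ((0.0, 0.0, 3.0), np.pi / 2, 0.0),  # north pole: longitude 0
            ((-3.0, 0.0, 0.0), 0.0, np.pi),  # west hemisphere, not folded to 0
            ((0.0, -3.0, 0.0), 0.0, -np.pi / 2),
            ((0.0, 0.0, -3.0), -np.pi / 2, 0.0),
        ],
    )
    def test_quadrant_aware_angles(self, w, lat, lon):
        got_lat, got_lon = self._single(w)
        assert got_lat == pytest.approx(lat, abs=TOL)
        assert got_lon == pytest.approx(lon, abs=TOL)

    def test_ranges(self, rng):
        from molcarto.projection import SphereMapping

        pts = rng.normal(size=(500, 3))
        pts /= np.linalg.norm(pts, axis=1)[:, None]
        g = to_geographic(SphereMapping(np.zeros(3), 1.0, pts, [""] * 500))
        assert np.all(np.abs(g.latitude) <= np.pi / 2)
        assert np.all((g.longitude > -np.pi) & (g.longitude <= np.pi))


class TestMiller:
    def test_zero_at_equator(self):
        assert miller_y(0.0) == pytest.approx(0.0, abs=TOL)

    def test_odd_in_latitude(self, rng):
        lats = rng.uniform(0, np.pi / 2, 50)
        np.testing.assert_allclose(miller_y(-lats), -np.asarray(miller_y(lats)),
                                   atol=TOL)

    def test_pole_matches_independent_evaluation(self):
        assert miller_y(np.pi / 2) == pytest.approx(POLE_Y, abs=TOL)
        assert MILLER_Y_MAX == pytest.approx(POLE_Y, abs=TOL)

    def test_strictly_increasing(self):
        lats = np.linspace(-np.pi / 2, np.pi / 2, 1001)
        assert np.all(np.diff(miller_y(lats)) > 0)

    def test_inverse_recovers_latitude(self):
        lats = np.linspace(-np.pi / 2, np.pi / 2, 501)
        np.testing.assert_allclose(miller_latitude(miller_y(lats)), lats, atol=TOL)

    def test_project_returns_longitude_abscissa(self, rng):
        g = GeoPoints(latitude=rng.uniform(-1.5, 1.5, 20),
                      longitude=rng.uniform(-np.pi, np.pi, 20),
                      residues=[""] * 20)
        x, y = miller_project(g)
        np.testing.assert_array_equal(x, g.longitude)
        np.testing.assert_allclose(y, miller_y(g.latitude), atol=TOL)


class TestComposedInvariances:
    def _geo_of(self, pts):
        c = centre_of_mass(pts)
        r = max_radius(pts, c)
        return to_geographic(spherify(pts, c, r))

    def test_exact_sphere_round_trips(self, rng):
        """On points already on a sphere, spherify + to_geographic returns
        each point's own (lat, lon)."""
        lat = rng.uniform(-np.pi / 2, np.pi / 2, 300)
        lon = rng.uniform(-np.pi, np.pi, 300)
        r = 7.5
        pts = np.stack([
            r * np.cos(lat) * np.cos(lon),
            r * np.cos(lat) * np.sin(lon),
            r * np.sin(lat),
        ], axis=1)
        # symmetric antipodal pairing keeps the centre of mass at the origin
        pts = np.concatenate([pts, -pts])
        g = self._geo_of(pts)
        np.testing.assert_allclose(g.latitude[:300], lat, atol=1e-7)
        np.testing.assert_allclose(g.longitude[:300], lon, atol=1e-7)

    def test_translation_invariance(self, rng):
        pts = rng.normal(size=(100, 3)) * 5
        g0 = self._geo_of(pts)
        g1 = self._geo_of(pts + np.array([123.0, -45.0, 6.0]))
        np.testing.assert_allclose(g1.latitude, g0.latitude, atol=TOL)
        np.testing.assert_allclose(g1.longitude, g0.longitude, atol=TOL)

    def test_z_rotation_shifts_longitude(self, rng):
        pts = rng.normal(size=(100, 3)) * 5
        phi = 0.7
        rot = np.array([
            [np.cos(phi), -np.sin(phi), 0.0],
            [np.sin(phi), np.cos(phi), 0.0],
            [0.0, 0.0, 1.0],
        ])
        c = centre_of_mass(pts)
        g0 = self._geo_of(pts)
        g1 = self._geo_of((pts - c) @ rot.T + c)
        np.testing.assert_allclose(g1.latitude, g0.latitude, atol=TOL)
        dlon = np.mod(g1.longitude - g0.longitude - phi + np.pi, 2 * np.pi) - np.pi
        np.testing.assert_allclose(dlon, 0.0, atol=TOL)
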