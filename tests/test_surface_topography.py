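"""Dot surfaces, MEP/MHP evaluation, spherical grids, Mollweide projection."""

import numpy as np
import pytest

from confrec import surface_topography as topo
from confrec.structure_io import ScalarGrid
from tests.conftest import make_system


class TestDotSurface:
    def test_isolated_atom_keeps_every_point(self):
        system = make_system(np.zeros((1, 3)), radii=[1.7])
        surf = topo.dot_surface(system, points_per_atom=240)
        assert len(surf.points) == 240
        r = np.linalg.norm(surf.points, axis=1)
        assert np.abs(r - (1.7 + 1.4)).max() < 1e-6

    def test_buried_atom_keeps_nothing(self):
        phi = (1 + 5**0.5) / 2
        ico = np.array([
            [0, 1, phi], [0, -1, phi], [0, 1, -phi], [0, -1, -phi],
            [1, phi, 0], [-1, phi, 0], [1, -phi, 0], [-1, -phi, 0],
            [phi, 0, 1], [-phi, 0, 1], [phi, 0, -1], [-phi, 0, -1],
        ], float)
        shell = 2.0 * ico / np.linalg.norm(ico[0])
        coords = np.vstack([[0, 0, 0], shell])
        system = make_system(coords, radii=[1.5] + [2.0] * 12)
        with pytest.warns(UserWarning, match="fully buried"):
            surf = topo.dot_surface(system, residue_subset=[("A", 1)],
                                    points_per_atom=960)
        assert len(surf.points) == 0

    def test_two_atom_occlusion_matches_brute_force(self):
        from confrec.ensemble_descriptors import _golden_spiral

        coords = np.array([[0, 0, 0], [2.5, 0, 0.0]])
        system = make_system(coords, radii=[1.7, 1.7])
        surf = topo.dot_surface(system, points_per_atom=240)
        sphere = _golden_spiral(240)
        expanded = 1.7 + 1.4
        keep = []
        for a in (0, 1):
            pts = coords[a] + expanded * sphere
            other = coords[1 - a]
            mask = np.linalg.norm(pts - other, axis=1) >= expanded
            keep.append(pts[mask])
        want = np.vstack(keep)
        assert len(surf.points) == len(want)
        assert np.abs(np.sort(surf.points.ravel()) - np.sort(want.ravel())).max() < 1e-9

    def test_empty_subset_rejected(self, receptor):
        with pytest.raises(ValueError, match="empty"):
            topo.dot_surface(receptor, residue_subset=[])


class TestMHP:
    def test_value_at_atom_centre_is_f(self):
        system = make_system(np.zeros((1, 3)), lipophilicity=[1.0])
        assert topo.mhp_at_points(np.zeros((1, 3)), system)[0] == pytest.approx(
            1.0, abs=1e-12)

    def test_gaussian_kernel_at_one_angstrom(self):
        system = make_system(np.zeros((1, 3)), lipophilicity=[1.0])
        got = topo.mhp_at_points(np.array([[1.0, 0, 0]]), system)[0]
        assert got == pytest.approx(np.exp(-1.0), abs=1e-12)

    def test_linear_in_f(self):
        coords = np.zeros((2, 3))
        half = make_system(coords, lipophilicity=[0.5, 0.5])
        one = make_system(np.zeros((1, 3)), lipophilicity=[1.0])
        pts = np.array([[0.7, 0.2, -0.1]])
        assert topo.mhp_at_points(pts, half)[0] == pytest.approx(
            topo.mhp_at_points(pts, one)[0], abs=1e-12)

    def test_missing_f_rejected(self):
        system = make_system(np.zeros((1, 3)), lipophilicity=[np.nan])
        with pytest.raises(ValueError, match="lipophilicity"):
            topo.mhp_at_points(np.zeros((1, 3)), system)


class TestMEP:
    def test_constant_grid(self):
        grid = ScalarGrid(origin=np.full(3, -5.0), spacing=np.ones(3),
                          counts=(11, 11, 11), values=np.full((11, 11, 11), 7.0))
        system = make_system(np.zeros((1, 3)))
        pts = np.array([[0.3, -1.2, 2.5]])
        got = topo.mep_at_points(pts, system, method="external_dx", grid=grid)
        assert got[0] == pytest.approx(7.0, abs=1e-9)

    def test_coulomb_closed_form(self):
        system = make_system(np.zeros((1, 3)), charges=[1.0])
        pts = np.array([[10.0, 0, 0]])  # 1 nm
        got = topo.mep_at_points(pts, system, method="coulomb", eps_eff=1.0)
        assert got[0] == pytest.approx(138.935458, abs=1e-9)
        scr = topo.mep_at_points(pts, system, method="coulomb", eps_eff=78.54)
        assert scr[0] == pytest.approx(138.935458 / 78.54, abs=1e-9)

    def test_zero_charges_zero_potential(self):
        system = make_system(np.random.default_rng(0).normal(size=(5, 3)))
        pts = np.array([[10.0, 10, 10]])
        assert topo.mep_at_points(pts, system, method="coulomb")[0] == 0.0


class TestSphericalProjection:
    def test_north_pole(self):
        lat, lon, _ = topo.spherical_project(np.array([[0, 0, 3.0]]),
                                             centre=(0, 0, 0))
        assert lat[0] == pytest.approx(90.0, abs=1e-12)

    def test_equator_prime_meridian(self):
        lat, lon, _ = topo.spherical_project(np.array([[2.0, 0, 0]]),
                                             centre=(0, 0, 0))
        assert lat[0] == pytest.approx(0.0, abs=1e-12)
        assert lon[0] == pytest.approx(0.0, abs=1e-12)

    def test_positive_y_quadrant(self):
        lat, lon, _ = topo.spherical_project(np.array([[0, 2.0, 0]]),
                                             centre=(0, 0, 0))
        assert lon[0] == pytest.approx(90.0, abs=1e-12)

    def test_centre_coincident_point_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            topo.spherical_project(np.zeros((1, 3)), centre=(0, 0, 0))

    def test_auto_centre_is_centroid(self):
        rng = np.random.default_rng(0)
        pts = rng.normal(size=(50, 3)) + 5
        _, _, centre = topo.spherical_project(pts)
        assert np.abs(centre - pts.mean(axis=0)).max() < 1e-12


class TestEqualAreaGrid:
    def test_constant_field(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-89, 89, 600)
        lon = rng.uniform(-180, 180, 600)
        tmap = topo.interpolate_equal_area_grid(lat, lon, np.full(600, 3.3))
        vals = tmap.values[~tmap.mask]
        assert np.abs(vals - 3.3).max() < 1e-9

    def test_recovers_sin_latitude_field(self):
        """Analytic field sin(latitude) sampled on a 2° grid is reproduced
        with max abs error ≤ 0.02."""
        glat, glon = np.meshgrid(np.arange(-90, 91, 2.0), np.arange(-180, 180, 2.0),
                                 indexing="ij")
        lat = glat.ravel()
        lon = glon.ravel()
        values = np.sin(np.radians(lat))
        tmap = topo.interpolate_equal_area_grid(lat, lon, values)
        want = np.sin(np.radians(tmap.latitudes))[:, None]
        err = np.abs(tmap.values - want)
        assert np.nanmax(err[~tmap.mask]) <= 0.02
        assert not tmap.mask.all()

    def test_longitude_seam_continuous(self):
        lat = np.array([0.0, 10.0, -10.0, 0.0])
        lon = np.array([179.0, 179.0, 179.0, -179.0])
        vals = np.full(4, 2.0)
        tmap = topo.interpolate_equal_area_grid(lat, lon, vals)
        col_180 = np.where(tmap.longitudes == 180.0)[0][0]
        row_0 = np.where(tmap.latitudes == 0.0)[0][0]
        assert not tmap.mask[row_0, col_180]
        assert tmap.values[row_0, col_180] == pytest.approx(2.0, abs=1e-9)

    def test_distant_nodes_masked(self):
        lat = np.zeros(4)
        lon = np.array([0.0, 1.0, -1.0, 2.0])
        tmap = topo.interpolate_equal_area_grid(lat, lon, np.ones(4),
                                                mask_radius_deg=10.0)
        assert tmap.mask[0, 0]  # the south pole is ~90° from every sample

    def test_degenerate_samples_rejected(self):
        with pytest.raises(ValueError, match="one location"):
            topo.interpolate_equal_area_grid(np.zeros(5), np.zeros(5), np.ones(5))


class TestMollweide:
    def test_origin_maps_to_origin(self):
        x, y = topo.mollweide_forward(0.0, 0.0)
        assert float(x) == pytest.approx(0.0, abs=1e-12)
        assert float(y) == pytest.approx(0.0, abs=1e-12)

    def test_poles_collapse(self):
        for lat, sign in ((90.0, 1), (-90.0, -1)):
            x, y = topo.mollweide_forward(lat, 123.0)
            assert float(x) == pytest.approx(0.0, abs=1e-9)
            assert float(y) == pytest.approx(sign * np.sqrt(2.0), abs=1e-9)

    def test_round_trip_off_pole(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(-85, 85, 300)
        lon = rng.uniform(-179, 179, 300)
        x, y = topo.mollweide_forward(lat, lon)
        lat2, lon2 = topo.mollweide_inverse(x, y)
        assert np.abs(lat2 - lat).max() < 1e-6
        assert np.abs(lon2 - lon).max() < 1e-6

    def test_equal_area_property(self):
        """Projected 1°-cell areas are proportional to spherical areas
        (cos-latitude weighting) within 0.5%."""
        lats = np.arange(-60.0, 61.0, 1.0)
        lons = np.arange(0.0, 31.0, 1.0)
        glat, glon = np.meshgrid(lats, lons, indexing="ij")
        x, y = topo.mollweide_forward(glat, glon)
        # per-cell area by the shoelace formula over each quad
        x00, x10, x01, x11 = x[:-1, :-1], x[1:, :-1], x[:-1, 1:], x[1:, 1:]
        y00, y10, y01, y11 = y[:-1, :-1], y[1:, :-1], y[:-1, 1:], y[1:, 1:]
        area = 0.5 * np.abs(
            (x00 * y01 - x01 * y00) + (x01 * y11 - x11 * y01)
            + (x11 * y10 - x10 * y11) + (x10 * y00 - x00 * y10)
        )
        mid_lat = 0.5 * (lats[:-1] + lats[1:])
        want = np.cos(np.radians(mid_lat))[:, None]
        ratio = area / want
        spread = np.abs(ratio / ratio.mean() - 1.0)
        assert spread.max() < 0.005

    def test_render_emits_forward_table(self, tmp_path):
        rng = np.random.default_rng(1)
        lat = rng.uniform(-80, 80, 400)
        lon = rng.uniform(-179, 179, 400)
        tmap = topo.interpolate_equal_area_grid(lat, lon, np.cos(np.radians(lon)))
        table = topo.render_mollweide(tmap, path=tmp_path / "map.png")
        assert len(table) == 181 * 361
        assert (tmp_path / "map.png").exists()
        # table rows are consistent with the forward transform
        i = 10_000
        x, y = topo.mollweide_forward(table.lat[i], table.lon[i])
        assert table.x[i] == pytest.approx(float(x), abs=1e-12)


class TestMapSimilarity:
    def test_identical_maps_correlate_perfectly(self):
        rng = np.random.default_rng(2)
        lat = rng.uniform(-80, 80, 500)
        lon = rng.uniform(-179, 179, 500)
        vals = np.sin(np.radians(lat)) + np.cos(np.radians(lon))
        a = topo.interpolate_equal_area_grid(lat, lon, vals)
        b = topo.interpolate_equal_area_grid(lat, lon, vals)
        assert topo.map_similarity(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_negated_map_anticorrelates(self):
        rng = np.random.default_rng(3)
        lat = rng.uniform(-80, 80, 500)
        lon = rng.uniform(-179, 179, 500)
        vals = np.sin(np.radians(lat))
        a = topo.interpolate_equal_area_grid(lat, lon, vals)
        b = topo.interpolate_equal_area_grid(lat, lon, -vals)
        assert topo.map_similarity(a, b) == pytest.approx(-1.0, abs=1e-12)
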