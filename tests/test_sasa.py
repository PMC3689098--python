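"""Shrake–Rupley engine against analytic and Monte-Carlo oracles."""

import itertools

import numpy as np
import pytest

import helixsurf as hs
from helixsurf.synthetic import make_sphere, make_sphere_pair


def two_sphere_battery():
    """1–2 sphere geometries spanning disjoint, tangent, overlapping, contained."""
    cases = []
    for r in (1.2, 1.52, 1.7, 2.0):
        cases.append(("single", r, r, None, 1.4))
    for r1, r2 in [(1.7, 1.7), (1.2, 2.0), (1.52, 1.8)]:
        for probe in (1.0, 1.4, 2.0):
            a, b = r1 + probe, r2 + probe
            cases.append(("far", r1, r2, a + b + 2.0, probe))
            cases.append(("tangent", r1, r2, a + b, probe))
            cases.append(("overlap", r1, r2, 0.7 * (a + b), probe))
            cases.append(("deep", r1, r2, abs(a - b) + 0.2, probe))
    cases.append(("contained", 0.3, 2.0, 0.2, 1.0))  # expanded: 1.3 inside 3.0
    return cases


class TestSpherePoints:
    def test_unit_norm_and_count(self):
        pts = hs.sample_sphere_points(100)
        assert pts.shape == (100, 3)
        np.testing.assert_allclose(np.linalg.norm(pts, axis=1), 1.0, atol=1e-12)

    def test_centroid_near_origin(self):
        pts = hs.sample_sphere_points(960)
        assert np.linalg.norm(pts.mean(axis=0)) < 2.0 / 960

    def test_deterministic(self):
        a = hs.sample_sphere_points(960)
        b = hs.sample_sphere_points(960)
        assert np.array_equal(a, b)

    def test_quasi_uniform_spacing(self):
        from scipy.spatial import cKDTree

        pts = hs.sample_sphere_points(500)
        d, _ = cKDTree(pts).query(pts, k=2)
        nn = d[:, 1]
        assert nn.max() <= 2.0 * nn.min()

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hs.sample_sphere_points(3)


class TestAnalyticOracle:
    def test_single_sphere_definition(self):
        assert hs.analytic_sasa_spheres([[0, 0, 0]], [1.5], 1.4) == pytest.approx(
            4 * np.pi * 2.9**2
        )

    def test_contained_sphere_contributes_zero(self):
        total = hs.analytic_sasa_spheres([[0, 0, 0], [0.1, 0, 0]], [2.0, 0.2], 1.0)
        assert total == pytest.approx(4 * np.pi * 3.0**2)

    def test_three_spheres_unsupported(self):
        with pytest.raises(NotImplementedError):
            hs.analytic_sasa_spheres(np.zeros((3, 3)), [1, 1, 1], 1.4)

    def test_cap_formula_against_monte_carlo(self):
        r1, r2, d, probe = 1.7, 1.7, 2.0, 1.4
        analytic = hs.analytic_sasa_spheres([[0, 0, 0], [0, 0, d]], [r1, r2], probe)
        rng = np.random.default_rng(0)
        n = 400_000
        total = 0.0
        centers = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, d]])
        exp = np.array([r1 + probe, r2 + probe])
        for i in (0, 1):
            v = rng.normal(size=(n, 3))
            v /= np.linalg.norm(v, axis=1, keepdims=True)
            pts = centers[i] + exp[i] * v
            other = 1 - i
            exposed = np.linalg.norm(pts - centers[other], axis=1) >= exp[other]
            total += exposed.mean() * 4 * np.pi * exp[i] ** 2
        assert total == pytest.approx(analytic, rel=5e-3)


class TestShrakeRupley:
    def test_single_sphere_closed_form(self):
        s = make_sphere(1.5)
        res = hs.shrake_rupley(s, probe_radius=1.4, n_points=960)
        assert res.total_area == pytest.approx(4 * np.pi * 2.9**2, rel=1e-12)
        assert res.per_atom_area.sum() == pytest.approx(res.total_area, rel=1e-6)

    def test_two_distant_spheres_additive(self):
        s = make_sphere_pair(1.7, 1.7, 50.0)
        res = hs.shrake_rupley(s, 1.4, 960)
        assert res.total_area == pytest.approx(2 * 4 * np.pi * 3.1**2, rel=1e-12)

    @pytest.mark.parametrize("kind,r1,r2,d,probe", two_sphere_battery())
    def test_battery_matches_analytic_within_half_percent(self, kind, r1, r2, d, probe):
        if d is None:
            s = make_sphere(r1)
            analytic = hs.analytic_sasa_spheres([[0, 0, 0]], [r1], probe)
        else:
            s = make_sphere_pair(r1, r2, d)
            analytic = hs.analytic_sasa_spheres(
                [[0, 0, 0], [0, 0, d]], [r1, r2], probe
            )
        num = hs.shrake_rupley(s, probe, 960).total_area
        assert abs(num - analytic) / analytic < 5e-3

    def test_refinement_reduces_error_on_average(self):
        geoms = [(1.7, 1.7, 2.0), (1.2, 2.0, 2.5), (1.52, 1.8, 3.0)]
        errors = []
        for n in (240, 960, 3840):
            errs = []
            for r1, r2, d in geoms:
                s = make_sphere_pair(r1, r2, d)
                analytic = hs.analytic_sasa_spheres([[0, 0, 0], [0, 0, d]], [r1, r2], 1.4)
                num = hs.shrake_rupley(s, 1.4, n).total_area
                errs.append(abs(num - analytic) / analytic)
            errors.append(np.mean(errs))
        assert errors[0] >= errors[1] >= errors[2]

    def test_translation_invariance_exact(self):
        s = make_sphere_pair(1.7, 1.52, 2.2)
        moved = s.transformed(translation=np.array([13.7, -8.1, 4.9]))
        a = hs.shrake_rupley(s, 1.4, 960).total_area
        b = hs.shrake_rupley(moved, 1.4, 960).total_area
        assert b == pytest.approx(a, rel=1e-9)

    def test_rotation_invariance_within_lattice_tolerance(self):
        # the point lattice is fixed in space, so rotating the molecule changes
        # the sample-point classification slightly; 960 points keep it < 1%
        from scipy.spatial.transform import Rotation

        s = make_sphere_pair(1.7, 1.52, 2.2)
        R = Rotation.from_euler("zyx", [31.0, -47.0, 112.0], degrees=True).as_matrix()
        a = hs.shrake_rupley(s, 1.4, 960).total_area
        b = hs.shrake_rupley(s.transformed(rotation=R), 1.4, 960).total_area
        assert b == pytest.approx(a, rel=1e-2)

    def test_fully_buried_atom_has_zero_area(self):
        # central atom caged by 12 icosahedron neighbours at 1 Å
        phi = (1 + np.sqrt(5)) / 2
        verts = np.array(list(itertools.product([0], [-1, 1], [-phi, phi])))
        verts = np.vstack([np.roll(verts, k, axis=1) for k in range(3)])
        verts /= np.linalg.norm(verts, axis=1, keepdims=True)
        centers = np.vstack([[0, 0, 0], verts])
        atoms = [
            hs.Atom(i + 1, "CB", "C", "UNK", i + 1, "A", c, radius=1.7)
            for i, c in enumerate(centers)
        ]
        res = hs.shrake_rupley(hs.Structure(atoms), 1.4, 960)
        assert res.per_atom_area[0] == 0.0

    def test_unassigned_radius_is_an_error(self, ala_pdb_text):
        s = hs.parse_structure(ala_pdb_text)  # no radii yet
        with pytest.raises(hs.StructureError):
            hs.shrake_rupley(s, 1.4, 240)

    def test_matches_independent_engine(self, ala_pdb_text):
        """Cross-check against biotite's Shrake–Rupley on a small fragment."""
        biotite_structure = pytest.importorskip("biotite.structure")
        s = hs.assign_radii(hs.parse_structure(ala_pdb_text))
        arr = biotite_structure.AtomArray(len(s))
        arr.coord = s.coords().astype(np.float32)
        for field, value in (("chain_id", "A"), ("res_name", "ALA"), ("atom_name", "X"),
                             ("element", "C")):
            arr.set_annotation(field, [value] * len(s))
        arr.res_id = np.arange(1, len(s) + 1)
        theirs = biotite_structure.sasa(
            arr, probe_radius=1.4, vdw_radii=s.radii(), point_number=1000
        ).sum()
        ours = hs.shrake_rupley(s, 1.4, 960).total_area
        assert ours == pytest.approx(theirs, rel=2e-2)
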