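"""Surface meshing, remeshing, curvature, chemistry and patches."""

import numpy as np
import pytest

from neoasurf import chemdata, fixtures, structure, surface
from neoasurf.structure import Atom
from neoasurf.surface import SurfaceError, SurfaceMesh, SurfacePatch

from conftest import cylinder_mesh, icosphere, plane_mesh


def far_padding_atoms(offset=60.0):
    return [Atom("C", "C", (offset, 0, 0), 2, "ALA", "X"),
            Atom("C", "C", (0, offset, 0), 3, "ALA", "X"),
            Atom("C", "C", (0, 0, offset), 4, "ALA", "X")]


class TestBuildSurface:
    def test_single_atom_sphere_area_and_density(self):
        # the isosurface of one atom is its vdW sphere (S: 1.8 A)
        atoms = [Atom("S", "S", (0, 0, 0), 1, "MET", "X")] + far_padding_atoms()
        mesh = surface.build_surface(atoms, regularize_mesh=False)
        tri = mesh.vertices[mesh.faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        near = np.linalg.norm(tri.mean(axis=1), axis=1) < 5
        sphere_area = areas[near].sum()
        expected = 4 * np.pi * chemdata.vdw_radius("S") ** 2
        assert sphere_area == pytest.approx(expected, rel=0.10)
        regular = surface.build_surface(atoms, regularize_mesh=True)
        n_near = (np.linalg.norm(regular.vertices, axis=1) < 5).sum()
        assert expected / 2 < n_near < expected * 2  # ~ area / resolution^2

    def test_two_far_atoms_give_two_components(self):
        atoms = [Atom("C", "C", (0, 0, 0), 1, "ALA", "X"),
                 Atom("C", "C", (30, 0, 0), 2, "ALA", "X")] + far_padding_atoms()
        mesh = surface.build_surface(atoms, regularize_mesh=False)
        assert mesh.connected_components() >= 2

    def test_peptide_mesh_manifold_with_outward_normals(self, arch_mesh,
                                                        arch_peptide):
        assert arch_mesh.is_edge_manifold()
        xyz = arch_peptide.atom_coords()
        from scipy.spatial import cKDTree
        _, nearest = cKDTree(xyz).query(arch_mesh.vertices)
        outward = ((arch_mesh.vertices - xyz[nearest])
                   * arch_mesh.vertex_normals()).sum(axis=1)
        assert (outward > 0).mean() > 0.99

    def test_too_few_atoms(self):
        with pytest.raises(SurfaceError):
            surface.build_surface([Atom("C", "C", (0, 0, 0), 1, "ALA", "X")])


class TestRegularize:
    def test_regular_icosphere_is_near_fixed_point(self):
        v, f = icosphere(5.0, 3)  # edges ~0.75 A
        mesh = SurfaceMesh(v, f, 1.0)
        out = surface.regularize(mesh, 1.0)
        assert 0.75 <= out.median_edge_length() <= 1.25
        # closed surface of genus 0 stays closed: Euler characteristic 2
        assert (out.n_vertices - len(out.edges()) + len(out.faces)) == 2

    def test_overdense_sphere_decimated(self):
        v, f = icosphere(5.0, 5)  # ~10k vertices, 0.19 A edges
        out = surface.regularize(SurfaceMesh(v, f, 1.0), 1.0)
        assert out.n_vertices <= len(v) / 10
        assert 0.75 <= out.median_edge_length() <= 1.25
        assert out.is_edge_manifold()

    def test_slivers_are_split(self):
        v, f = icosphere(3.0, 2)
        v = v.copy()
        v[0] *= 3.0  # stretch one vertex into long slivers
        out = surface.regularize(SurfaceMesh(v, f, 1.0), 1.0)
        assert out.edge_lengths().max() <= 2.0

    def test_median_edge_near_resolution_on_fixture(self, arch_mesh):
        assert abs(arch_mesh.median_edge_length() - 1.0) <= 0.25

    def test_non_manifold_rejected(self):
        v = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1], [0, 0, -1]],
                     dtype=float)
        f = np.array([[0, 1, 2], [0, 1, 3], [0, 1, 4]])  # 3 faces on one edge
        with pytest.raises(SurfaceError):
            surface.regularize(SurfaceMesh(v, f, 1.0), 1.0)


class TestCurvature:
    def test_sphere_recovery(self):
        v, f = icosphere(5.0, 3)
        k1, k2 = surface.principal_curvatures(SurfaceMesh(v, f, 1.0))
        assert np.nanmax(np.abs(k1 - 0.2)) / 0.2 < 0.15
        assert np.nanmax(np.abs(k2 - 0.2)) / 0.2 < 0.15

    def test_cylinder_recovery(self):
        v, f = cylinder_mesh(2.0, 12, 20.0, 1.0)
        mesh = SurfaceMesh(v, f, 1.0)
        k1, k2 = surface.principal_curvatures(mesh)
        interior = (v[:, 2] > 5) & (v[:, 2] < 15)
        assert np.nanmedian(k1[interior]) == pytest.approx(0.5, rel=0.15)
        assert abs(np.nanmedian(k2[interior])) < 0.075  # 15% of k1
        # ordering invariant
        assert np.all(k1[~np.isnan(k1)] >= k2[~np.isnan(k2)])

    def test_plane_is_flat(self):
        v, f = plane_mesh(10)
        k1, k2 = surface.principal_curvatures(SurfaceMesh(v, f, 1.0))
        assert np.nanmax(np.abs(k1)) < 1e-8
        assert np.nanmax(np.abs(k2)) < 1e-8


class TestShapeIndex:
    @pytest.mark.parametrize("k1,k2,expected", [
        (1.0, 0.0, 0.5),
        (1.0, -1.0, 0.0),
        (0.7, 0.7, 1.0),
        (-0.7, -0.7, -1.0),
        (0.0, 0.0, 0.0),
    ])
    def test_reference_values(self, k1, k2, expected):
        assert surface.shape_index(k1, k2) == pytest.approx(expected)

    def test_bounded_and_antisymmetric(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=500)
        b = rng.normal(size=500)
        k1, k2 = np.maximum(a, b), np.minimum(a, b)
        si = surface.shape_index(k1, k2)
        assert np.all(si >= -1) and np.all(si <= 1)
        np.testing.assert_allclose(si, -surface.shape_index(-k2, -k1),
                                   atol=1e-12)


class TestDDC:
    def test_parallel_normals_vanish(self):
        assert surface.distance_dependent_curvature(
            (0, 0, 0), (0, 0, 1), (2, 0, 0), (0, 0, 1)) == 0.0

    def test_hand_evaluated_convex_case(self):
        # d=2; |r_j+n_j-r_i-n_i| = |(2,0,-2)| = 2.83 > 2 -> theta=+1;
        # |n_j-n_i| = 2 -> value +1.0
        val = surface.distance_dependent_curvature(
            (0, 0, 0), (0, 0, 1), (2, 0, 0), (0, 0, -1))
        assert val == pytest.approx(1.0)

    def test_symmetric_in_pair(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            ri, rj = rng.normal(size=3), rng.normal(size=3)
            ni = rng.normal(size=3)
            ni /= np.linalg.norm(ni)
            nj = rng.normal(size=3)
            nj /= np.linalg.norm(nj)
            assert surface.distance_dependent_curvature(ri, ni, rj, nj) == \
                pytest.approx(surface.distance_dependent_curvature(rj, nj, ri, ni))

    def test_coincident_vertices_rejected(self):
        with pytest.raises(SurfaceError):
            surface.distance_dependent_curvature((0, 0, 0), (0, 0, 1),
                                                 (0, 0, 0), (0, 1, 0))


class TestChemicalFeatures:
    def test_poly_ile_hydropathy_saturates(self):
        pep = fixtures.make_arch_peptide(fixtures.ArchSpec(seed=0),
                                         sequence="IIIIIIIII")
        mesh = surface.build_surface(pep, regularize_mesh=False)
        feats = surface.chemical_features(mesh, pep)
        np.testing.assert_allclose(feats["hydropathy"], 1.0)

    @pytest.mark.parametrize("resname,atom,sign", [("LYS", "NZ", 1),
                                                   ("ASP", "CG", -1)])
    def test_electrostatics_sign_near_charged_atom(self, resname, atom, sign):
        atoms = [Atom(atom, chemdata.element_of(atom), (0, 0, 0), 2,
                      resname, "X")]
        v, f = icosphere(2.0, 2)
        mesh = SurfaceMesh(v, f, 0.5)
        feats = surface.chemical_features(mesh, atoms)
        assert np.all(sign * feats["electrostatics"] > 0)

    def test_no_charges_no_potential(self):
        # CA-only glycines: no charged side chains and no N/C termini atoms
        atoms = [Atom("CA", "C", (i * 3.0, 0, 0), i + 1, "GLY", "X")
                 for i in range(4)]
        v, f = icosphere(2.0, 2)
        feats = surface.chemical_features(SurfaceMesh(v, f, 0.5), atoms)
        np.testing.assert_allclose(feats["electrostatics"], 0.0)

    def test_hbond_sign_near_donor_and_acceptor(self):
        v, f = icosphere(1.5, 2)
        donor = [Atom("NZ", "N", (0, 0, 0), 1, "LYS", "X")]
        acceptor = [Atom("OD1", "O", (0, 0, 0), 1, "ASP", "X")]
        hb_d = surface.chemical_features(SurfaceMesh(v.copy(), f, 0.5),
                                         donor)["hbond"]
        hb_a = surface.chemical_features(SurfaceMesh(v.copy(), f, 0.5),
                                         acceptor)["hbond"]
        assert np.all(hb_d > 0) and np.all(hb_a < 0)

    def test_rigid_transform_invariance(self, arch_peptide):
        from scipy.spatial.transform import Rotation

        mesh = surface.build_surface(arch_peptide, regularize_mesh=False)
        base = surface.chemical_features(mesh, arch_peptide)
        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        t = np.array([5.0, -3.0, 11.0])
        moved_chain = arch_peptide.transformed(R, t)
        moved_mesh = SurfaceMesh(mesh.vertices @ R.T + t, mesh.faces,
                                 mesh.resolution)
        moved = surface.chemical_features(moved_mesh, moved_chain)
        for key in base:
            np.testing.assert_allclose(moved[key], base[key], atol=1e-9)


class TestPatches:
    def test_members_within_radius_on_flat_mesh(self):
        v, f = plane_mesh(30)
        mesh = SurfaceMesh(v, f, 1.0)
        center = 15 * 30 + 15
        patch = surface.decompose_patches(mesh, centers=[center])[0]
        eu = np.linalg.norm(v[patch.members] - v[center], axis=1)
        assert eu.max() <= 6.05  # graph geodesics dominate Euclidean
        # coverage: everything well inside the radius is reached
        inside = np.where(np.linalg.norm(v - v[center], axis=1) <= 4.0)[0]
        assert set(inside) <= set(patch.members)

    def test_center_belongs_with_zero_rho(self, arch_mesh):
        patches = surface.decompose_patches(arch_mesh,
                                            centers=[0, 5, arch_mesh.n_vertices - 1])
        for p in patches:
            assert p.center in p.members
            assert p.rho[list(p.members).index(p.center)] == 0.0

    def test_patch_population_on_regular_mesh(self, arch_mesh):
        centers = list(range(0, arch_mesh.n_vertices, 97))
        patches = surface.decompose_patches(arch_mesh, centers=centers)
        sizes = [len(p.members) for p in patches]
        assert all(30 <= s <= 200 for s in sizes)

    def test_rho_bounded_and_phi_range(self, arch_mesh):
        patches = surface.decompose_patches(arch_mesh,
                                            centers=list(range(0, 50, 7)))
        for p in patches:
            assert np.all(p.rho <= p.radius + 1e-9)
            assert np.all((p.phi >= 0) & (p.phi < 2 * np.pi))


class TestPatchGrid:
    def synthetic_patch(self, rho, phi):
        rho = np.asarray(rho, dtype=float)
        return SurfacePatch(center=0, members=np.arange(len(rho)),
                            radius=6.0, rho=rho,
                            phi=np.asarray(phi, dtype=float))

    def test_uniform_feature_fills_occupied_bins(self):
        rng = np.random.default_rng(0)
        patch = self.synthetic_patch(rng.uniform(0, 6, 40),
                                     rng.uniform(0, 2 * np.pi, 40))
        grids = surface.map_patch_to_grid(patch, {"f": np.full(40, 0.7)})
        occ = grids["occupancy"] > 0
        assert np.all(grids["f"][occ] == pytest.approx(0.7))
        assert np.all(grids["f"][~occ] == 0.0)

    def test_single_member_occupies_one_bin(self):
        patch = self.synthetic_patch([3.1], [0.1])
        grids = surface.map_patch_to_grid(patch, {"f": np.array([2.0])})
        assert grids["occupancy"].sum() == 1

    def test_angular_rotation_shifts_grid_cyclically(self):
        rng = np.random.default_rng(1)
        A = 16
        # bin-centered angles so a 2pi/A rotation maps bins exactly
        phi = (rng.integers(0, A, 60) + 0.5) * (2 * np.pi / A)
        rho = rng.uniform(0, 6, 60)
        vals = rng.normal(size=60)
        g0 = surface.map_patch_to_grid(self.synthetic_patch(rho, phi),
                                       {"f": vals})
        g1 = surface.map_patch_to_grid(
            self.synthetic_patch(rho, np.mod(phi + 2 * np.pi / A, 2 * np.pi)),
            {"f": vals})
        np.testing.assert_allclose(g1["f"], np.roll(g0["f"], 1, axis=1))
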