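import numpy as np
import pytest
import trimesh
from scipy.spatial import Delaunay

from microphase.core import CorrelationCurve, Volume
from microphase.surface import (
    bisect_mesh,
    correlation_length,
    extract_surface,
    geodesic_distances,
    mean_curvature,
    mesh_area,
    mesh_volume,
    normal_correlation,
    vertex_areas,
    vertex_normals,
)
from microphase.synthetic import make_sphere_mesh


def _plane_mesh(n=20, size=20.0):
    x, y = np.meshgrid(np.linspace(0, size, n), np.linspace(0, size, n))
    pts = np.stack([x.ravel(), y.ravel(), np.zeros(x.size)], axis=1)
    return trimesh.Trimesh(pts, Delaunay(pts[:, :2]).simplices, process=False)


def _tube_mesh(rho=5.0, h=30.0, nt=96, nz=40):
    th = np.linspace(0, 2 * np.pi, nt, endpoint=False)
    z = np.linspace(-h / 2, h / 2, nz)
    T, Z = np.meshgrid(th, z, indexing="ij")
    pts = np.stack([rho * np.cos(T).ravel(), rho * np.sin(T).ravel(),
                    Z.ravel()], axis=1)
    faces = []
    for i in range(nt):
        for j in range(nz - 1):
            a = i * nz + j
            b = ((i + 1) % nt) * nz + j
            faces += [[a, b, a + 1], [b, b + 1, a + 1]]
    return trimesh.Trimesh(pts, np.array(faces), process=False)


def _solid_sphere_volume(radius=20.0, n=52, voxel=1.0, noise=0.0, seed=0):
    g = (np.arange(n) + 0.5) * voxel
    zz, yy, xx = np.meshgrid(g, g, g, indexing="ij")
    c = n * voxel / 2
    data = ((zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= radius**2).astype(float)
    if noise > 0:
        rng = np.random.default_rng(seed)
        data = np.maximum(data + rng.normal(0, noise, data.shape), 0)
    return Volume(data, voxel)


class TestExtractSurface:
    def test_clean_sphere_volume_within_5pc(self):
        vol = _solid_sphere_volume()
        mask, mesh = extract_surface(vol, iterations=10)
        assert mesh.is_watertight
        assert mesh_volume(mesh) == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.05)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_noisy_sphere_volume_within_10pc(self, seed):
        vol = _solid_sphere_volume(noise=0.05, seed=seed)
        _, mesh = extract_surface(vol, iterations=10)
        assert mesh_volume(mesh) == pytest.approx(4 / 3 * np.pi * 20**3, rel=0.10)

    def test_flat_volume_rejected(self):
        with pytest.raises(ValueError, match="dynamic range"):
            extract_surface(Volume(np.ones((8, 8, 8)), 1.0))

    def test_mask_stays_near_foreground(self):
        vol = _solid_sphere_volume()
        mask, _ = extract_surface(vol, iterations=5)
        fg = vol.data > 0.5
        import scipy.ndimage

        dilated = scipy.ndimage.binary_dilation(fg, iterations=3)
        assert not (mask & ~dilated).any()


class TestMeshMeasures:
    def test_icosphere_closed_forms(self, icosphere):
        assert mesh_area(icosphere) == pytest.approx(4 * np.pi * 100, rel=0.01)
        assert mesh_volume(icosphere) == pytest.approx(4 / 3 * np.pi * 1000,
                                                       rel=0.01)

    def test_unit_cube_exact(self):
        cube = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
        assert mesh_area(cube) == pytest.approx(6.0, rel=1e-9)
        assert mesh_volume(cube) == pytest.approx(1.0, rel=1e-9)

    def test_subdivision_invariance(self, icosphere):
        fine = icosphere.subdivide()
        assert mesh_area(fine) == pytest.approx(mesh_area(icosphere), rel=1e-6)
        assert mesh_volume(fine) == pytest.approx(mesh_volume(icosphere),
                                                  rel=1e-6)

    def test_rigid_motion_invariance(self, icosphere):
        moved = icosphere.copy()
        rot = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3],
                                                      point=[5, -2, 1])
        moved.apply_transform(rot)
        moved.apply_translation([10.0, -4.0, 2.5])
        assert mesh_area(moved) == pytest.approx(mesh_area(icosphere), rel=1e-9)
        assert mesh_volume(moved) == pytest.approx(mesh_volume(icosphere),
                                                   rel=1e-9)

    def test_open_mesh_volume_refused(self):
        with pytest.raises(ValueError, match="watertight"):
            mesh_volume(_plane_mesh())


class TestNormalsAndCurvature:
    def test_normals_unit_length(self, icosphere):
        n = vertex_normals(icosphere)
        np.testing.assert_allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9)

    def test_vertex_areas_sum_to_mesh_area(self, icosphere):
        assert vertex_areas(icosphere).sum() == pytest.approx(
            mesh_area(icosphere), rel=1e-9)

    def test_sphere_curvature_is_inverse_radius(self):
        for radius, ref in ((10.0, 4), (5.0, 3)):
            h = mean_curvature(make_sphere_mesh(radius, ref))
            assert np.median(h) == pytest.approx(1 / radius, rel=0.05)

    def test_plane_curvature_is_zero(self):
        mesh = _plane_mesh()
        h = mean_curvature(mesh)
        v = mesh.vertices
        interior = ((v[:, 0] > 2) & (v[:, 0] < 18)
                    & (v[:, 1] > 2) & (v[:, 1] < 18))
        assert np.abs(h[interior]).max() < 1e-9

    def test_cylinder_curvature(self):
        mesh = _tube_mesh(rho=5.0)
        h = mean_curvature(mesh)
        interior = np.abs(mesh.vertices[:, 2]) < 12
        assert np.median(h[interior]) == pytest.approx(1 / (2 * 5.0), rel=0.05)


class TestBisect:
    def test_sphere_split_into_equal_hemispheres(self, icosphere):
        top, bottom = bisect_mesh(icosphere)
        half = mesh_area(icosphere) / 2
        assert top.area == pytest.approx(half, rel=0.02)
        assert bottom.area == pytest.approx(half, rel=0.02)

    def test_area_conserved_exactly(self, icosphere):
        top, bottom = bisect_mesh(icosphere)
        assert top.area + bottom.area == pytest.approx(mesh_area(icosphere),
                                                       rel=1e-9)

    def test_slab_splits_top_and_bottom_faces(self):
        slab = trimesh.creation.box(extents=(40.0, 30.0, 2.0))
        slab = slab.subdivide().subdivide()
        a, b = bisect_mesh(slab)
        # all upward-facing triangles land in one half, downward in the
        # other (which half is "top" depends on the eigenvector sign)
        za = a.face_normals[:, 2]
        zb = b.face_normals[:, 2]
        za, zb = za[np.abs(za) > 0.5], zb[np.abs(zb) > 0.5]
        assert len(za) and len(zb)
        assert (np.all(za > 0) and np.all(zb < 0)) or (
            np.all(za < 0) and np.all(zb > 0))


class TestNormalCorrelation:
    def test_flat_plane_fully_correlated(self):
        curve = normal_correlation(_plane_mesh(), np.arange(0, 16, 2.0))
        good = np.isfinite(curve.c)
        np.testing.assert_allclose(curve.c[good], 1.0, atol=1e-9)

    def test_sphere_matches_cosine(self, icosphere):
        """Normals on a sphere separated by geodesic L subtend angle L/R."""
        bins = np.arange(0.0, np.pi * 10 / 2 + 1.0, 1.0)
        curve = normal_correlation(icosphere, bins, seed=0)
        expected = np.cos(curve.lam / 10.0)
        good = np.isfinite(curve.c)
        assert np.abs(curve.c[good] - expected[good]).max() < 0.05
        assert curve.c[0] > 0.99

    def test_sampled_agrees_with_exhaustive(self):
        mesh = make_sphere_mesh(10.0, refinement=3)  # 642 vertices
        bins = np.arange(0.0, 16.0, 2.0)
        full = normal_correlation(mesh, bins)
        sampled = normal_correlation(mesh, bins, n_samples=200, seed=4)
        good = np.isfinite(full.c) & np.isfinite(sampled.c)
        assert np.abs(full.c[good] - sampled.c[good]).max() < 0.02

    def test_bins_beyond_diameter_are_missing_not_zero(self, icosphere):
        bins = np.array([0.0, 5.0, 200.0, 300.0])
        curve = normal_correlation(icosphere, bins)
        assert np.isnan(curve.c[-1])
        assert curve.n_pairs[-1] == 0

    def test_geodesic_at_least_euclidean(self, icosphere):
        d = geodesic_distances(icosphere, np.array([0]))[0]
        eu = np.linalg.norm(icosphere.vertices - icosphere.vertices[0], axis=1)
        assert np.all(d >= eu - 1e-9)

    def test_coarse_mesh_rejected(self):
        tet = trimesh.creation.icosahedron()
        with pytest.raises(ValueError, match="coarse"):
            normal_correlation(tet, np.array([0.0, 1.0]))


class TestCorrelationLength:
    def _curve(self, c, lam=None):
        lam = np.arange(1.0, 30.0, 1.0) if lam is None else lam
        return CorrelationCurve(lam=lam, c=c, n_pairs=np.full(lam.size, 100))

    def test_exact_exponential_recovered(self):
        lam = np.arange(1.0, 30.0, 1.0)
        res = correlation_length(
            self._curve(0.2 + 0.8 * np.exp(-lam / 15.0), lam),
            fit_range=(1.0, 29.0))
        assert res["decaying"]
        assert res["length"] == pytest.approx(15.0, rel=1e-6)
        assert res["plateau"] == pytest.approx(0.2, abs=1e-6)

    def test_constant_curve_flagged_non_decaying(self):
        res = correlation_length(self._curve(np.ones(29)), fit_range=(1.0, 29.0))
        assert not res["decaying"]
        assert np.isinf(res["length"])

    def test_noisy_recovery_within_15pc(self):
        """sigma = 0.02 noise on C sampled out to ~4 decay lengths (which
        pins the plateau): length within 15% across 100 replicates."""
        lam = np.arange(1.0, 60.0, 1.0)
        base = 0.2 + 0.8 * np.exp(-lam / 15.0)
        for seed in range(100):
            rng = np.random.default_rng(seed)
            res = correlation_length(
                self._curve(np.clip(base + rng.normal(0, 0.02, lam.size), -1, 1),
                            lam),
                fit_range=(1.0, 59.0))
            assert res["decaying"]
            assert abs(res["length"] - 15.0) / 15.0 < 0.15

    def test_too_few_bins_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            correlation_length(self._curve(np.ones(29)), fit_range=(1.0, 3.0))
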