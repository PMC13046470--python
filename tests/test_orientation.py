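import numpy as np
import pytest
import trimesh

from epialign import orientation as O
from epialign import synthetic as S


def solid_ellipsoid_inertia(a, b, c, volume=None):
    """Unit-density solid ellipsoid inertia components about its axes."""
    v = volume if volume is not None else 4 / 3 * np.pi * a * b * c
    return v / 5 * np.array([b**2 + c**2, a**2 + c**2, a**2 + b**2])


class TestResampleIsotropic:
    def test_isotropic_input_is_identity(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(size=(10, 12, 14))
        out, vs = O.resample_isotropic(arr, (1.0, 1.0, 1.0), bin_xy=1)
        assert vs == 1.0
        assert np.allclose(out, arr)

    def test_constant_volume_stays_constant(self):
        arr = np.full((8, 16, 16), 3.5)
        out, _ = O.resample_isotropic(arr, (2.0, 1.0, 1.0))
        assert np.allclose(out, 3.5)

    def test_stripe_block_means(self):
        """2x2x1 binning reproduces hand-computed block means."""
        arr = np.zeros((2, 4, 4))
        arr[:, ::2, :] = 1.0           # alternating rows -> mean 0.5
        out, vs = O.resample_isotropic(arr, (1.0, 0.5, 0.5))
        assert vs == 1.0               # binned voxels are already isotropic
        assert out.shape == (2, 2, 2)
        assert np.allclose(out, 0.5)

    def test_channel_summing(self):
        arr = np.ones((4, 4, 4, 2))
        out, _ = O.resample_isotropic(arr, (1, 1, 1), bin_xy=1)
        assert np.allclose(out, 2.0)

    def test_invalid_voxel_size(self):
        with pytest.raises(ValueError):
            O.resample_isotropic(np.ones((2, 2, 2)), (0.0, 1, 1))


class TestExtractMeshes:
    def test_rasterized_sphere_volume(self):
        r_um, vs = 10.0, 0.8
        n = int(2 * (r_um / vs + 4))
        idx = np.indices((n, n, n)) * vs
        center = np.array([n // 2, n // 2, n // 2]) * vs
        d2 = ((idx - center[:, None, None, None]) ** 2).sum(axis=0)
        vol = O.LabelVolume((d2 <= r_um**2).astype(np.int32), vs)
        meshes, tissue = O.extract_meshes(vol)
        v = meshes[1].volume
        assert v == pytest.approx(4 / 3 * np.pi * r_um**3, rel=0.02)

    def test_largest_component_kept(self):
        vox = np.zeros((30, 30, 30), dtype=np.int32)
        vox[2:20, 2:20, 2:20] = 1          # large blob
        vox[24:27, 24:27, 24:27] = 2       # small distant blob
        vol = O.LabelVolume(vox, 1.0)
        _, tissue = O.extract_meshes(vol)
        assert tissue.mesh.volume == pytest.approx(18**3, rel=0.1)

    def test_face_orientation_positive_volume(self, spherical_embryo):
        vol, _, _ = spherical_embryo
        meshes, tissue = O.extract_meshes(vol)
        assert tissue.mesh.volume > 0
        assert all(m.volume > 0 for m in meshes.values())

    def test_tiny_labels_skipped(self):
        vox = np.zeros((12, 12, 12), dtype=np.int32)
        vox[2:8, 2:8, 2:8] = 1
        vox[10, 10, 10] = 2                # single voxel
        with pytest.warns(UserWarning, match="label 2"):
            meshes, _ = O.extract_meshes(O.LabelVolume(vox, 1.0))
        assert 2 not in meshes


class TestInertia:
    def test_sphere_isotropic_spectrum(self):
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=2.0)
        lam, axes, centroid, volume, area = O.inertia_analysis(mesh)
        assert lam[2] / lam[0] == pytest.approx(1.0, rel=0.01)
        assert volume == pytest.approx(4 / 3 * np.pi * 8, rel=0.01)

    def test_prolate_ellipsoid_closed_form(self):
        a, b = 4.0, 1.0
        mesh = trimesh.creation.icosphere(subdivisions=3)
        mesh.apply_scale([a, b, b])
        lam, axes, *_ = O.inertia_analysis(mesh)
        expect = solid_ellipsoid_inertia(a, b, b, volume=mesh.volume)
        assert np.allclose(lam, np.sort(expect), rtol=0.02)
        # long axis belongs to the smallest component
        assert abs(axes[0] @ [1, 0, 0]) > 0.99

    def test_rotation_covariance(self):
        mesh = trimesh.creation.icosphere(subdivisions=3)
        mesh.apply_scale([3.0, 1.2, 0.8])
        lam0, axes0, *_ = O.inertia_analysis(mesh.copy())
        R = trimesh.transformations.rotation_matrix(0.7, [1, 2, 3])
        rotated = mesh.copy()
        rotated.apply_transform(R)
        lam1, axes1, *_ = O.inertia_analysis(rotated)
        assert np.allclose(lam0, lam1, rtol=1e-6)
        for i in range(3):
            assert abs(axes1[i] @ (R[:3, :3] @ axes0[i])) > 1 - 1e-6

    def test_right_handed_axes(self):
        mesh = trimesh.creation.icosphere(subdivisions=2)
        mesh.apply_scale([2.0, 1.0, 0.5])
        _, axes, *_ = O.inertia_analysis(mesh)
        assert np.linalg.det(axes) == pytest.approx(1.0, abs=1e-9)


class TestAnisotropy:
    def test_sphere_is_zero(self):
        assert O.anisotropy(2.0, 2.0, 2.0) == 0.0

    def test_four_to_one_ellipsoid(self):
        assert O.anisotropy(0.4, 3.4, 3.4) == pytest.approx(
            (3.4 - np.sqrt(0.4 * 3.4)) / 3.4)

    def test_monotone_toward_one_with_aspect(self):
        etas = []
        for ratio in (1, 2, 4, 8, 16, 100):
            lam = solid_ellipsoid_inertia(ratio, 1, 1)
            etas.append(O.anisotropy(*np.sort(lam)))
        assert all(b > a for a, b in zip(etas, etas[1:]))
        assert etas[0] == 0.0
        assert etas[-1] > 0.98

    def test_rejects_unsorted(self):
        with pytest.raises(ValueError):
            O.anisotropy(3.0, 2.0, 1.0)


class TestNormalsAndPolarity:
    @pytest.fixture(scope="class")
    def spherical_tissue(self):
        """Spherical tissue mesh whose top patch belongs to label 1."""
        mesh = trimesh.creation.icosphere(subdivisions=3, radius=10.0)
        labels = np.where(mesh.vertices[:, 2] > 8.0, 1,
                          np.where(mesh.vertices[:, 2] < -8.0, 2,
                                   np.where(mesh.vertices[:, 0] > 8.0, 3, 4)))
        return O.TissueMesh(mesh=mesh, vertex_labels=labels)

    def test_top_cap_normal_is_up(self, spherical_tissue):
        n = O.boundary_normal(1, spherical_tissue)
        assert n @ [0, 0, 1] > 0.97

    def test_antipodal_cap_normal_is_down(self, spherical_tissue):
        n = O.boundary_normal(2, spherical_tissue)
        assert n @ [0, 0, -1] > 0.97

    def test_patch_normal_matches_analytic_sphere_mean(self, spherical_tissue):
        sel = spherical_tissue.vertex_labels == 3
        analytic = spherical_tissue.mesh.vertices[sel]
        analytic = (analytic / np.linalg.norm(analytic, axis=1, keepdims=True)
                    ).mean(axis=0)
        analytic /= np.linalg.norm(analytic)
        n = O.boundary_normal(3, spherical_tissue)
        assert np.degrees(np.arccos(np.clip(n @ analytic, -1, 1))) < 2.0

    def test_missing_label_is_interior(self, spherical_tissue):
        assert O.boundary_normal(99, spherical_tissue) is None

    def test_boundary_cell_flip(self):
        pol = O.polarity_vector([0, 0, -1], [0, 0, 9], [0, 0, 0],
                                normal=[0, 0, 1])
        assert np.allclose(pol, [0, 0, 1])

    def test_interior_cell_flip(self):
        pol = O.polarity_vector([0, 0, -1], [0, 0, 5], [0, 0, 0], normal=None)
        assert np.allclose(pol, [0, 0, 1])

    def test_flip_is_idempotent(self):
        first = O.polarity_vector([0.3, -0.2, -1], [1, 2, 5], [0, 0, 0],
                                  normal=[0, 0, 1])
        second = O.polarity_vector(first, [1, 2, 5], [0, 0, 0],
                                   normal=[0, 0, 1])
        assert np.allclose(first, second)


class TestBoundaryAngle:
    @pytest.mark.parametrize("pol,expect", [
        ([0, 0, 1], 0.0),                          # perpendicular to surface
        ([1, 0, 0], 90.0),                         # lying parallel
        ([np.sin(np.radians(30)), 0, np.cos(np.radians(30))], 30.0),
    ])
    def test_angle_convention(self, pol, expect):
        assert O.boundary_angle(pol, [0, 0, 1]) == pytest.approx(expect,
                                                                 abs=1e-9)

    def test_antiparallel_folds_to_zero(self):
        assert O.boundary_angle([0, 0, -1], [0, 0, 1]) == pytest.approx(0.0)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            O.boundary_angle([0, 0, 0], [0, 0, 1])


class TestNeighborAngles:
    @staticmethod
    def _two_ellipsoid_volume(axis2, gap=0):
        vox = np.zeros((52, 28, 28), dtype=np.int32)
        zz, yy, xx = np.indices(vox.shape, dtype=float)
        q1 = ((zz - 12) / 10) ** 2 + ((yy - 14) / 4) ** 2 + ((xx - 14) / 4) ** 2
        vox[q1 <= 1] = 1
        c2 = np.array([24 + gap, 14, 14], float)
        d = np.stack([zz - c2[0], yy - c2[1], xx - c2[2]], -1)
        if axis2 == "z":
            q2 = (d[..., 0] / 10) ** 2 + (d[..., 1] / 4) ** 2 + (d[..., 2] / 4) ** 2
        else:
            q2 = (d[..., 0] / 4) ** 2 + (d[..., 1] / 10) ** 2 + (d[..., 2] / 4) ** 2
        vox[(q2 <= 1) & (vox == 0)] = 2
        return O.LabelVolume(vox, 1.0)

    def test_parallel_neighbors(self):
        vol = self._two_ellipsoid_volume("z")
        axes = {1: np.array([1.0, 0, 0]), 2: np.array([1.0, 0, 0])}
        table = O.neighbor_angles(vol, axes)
        assert len(table) == 1
        assert table.angle_deg.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_orthogonal_neighbors(self):
        vol = self._two_ellipsoid_volume("y")
        axes = {1: np.array([1.0, 0, 0]), 2: np.array([0, 1.0, 0])}
        table = O.neighbor_angles(vol, axes)
        assert len(table) == 1
        assert table.angle_deg.iloc[0] == pytest.approx(90.0, abs=1e-9)

    def test_separated_cells_absent(self):
        vol = self._two_ellipsoid_volume("z", gap=12)
        axes = {1: np.array([1.0, 0, 0]), 2: np.array([1.0, 0, 0])}
        assert len(O.neighbor_angles(vol, axes)) == 0

    def test_small_overlap_excluded(self):
        vol = self._two_ellipsoid_volume("z")
        axes = {1: np.array([1.0, 0, 0]), 2: np.array([1.0, 0, 0])}
        table = O.neighbor_angles(vol, axes, min_overlap=1e5)
        assert len(table) == 0


class TestDetermineAxis:
    def test_synthetic_embryo_axis(self, quantified_spherical):
        table, shapes, tissue, frame, truth = quantified_spherical
        ang = np.degrees(np.arccos(abs(frame.rotation[2] @ [0.0, 0.0, 1.0])))
        assert ang < 3.0

    def test_rotational_equivariance(self):
        rng = np.random.default_rng(4)
        pts = rng.uniform(-10, 10, (6, 3))
        ann = O.AxisAnnotation(pts, [0, 0, -20.0], [[15, 0, 1], [15, 0, -1]])
        c = np.array([0.0, 0.0, 2.0])
        f0 = O.determine_axis(ann, c)
        R = trimesh.transformations.rotation_matrix(1.1, [1, 1, 0])[:3, :3]
        ann_r = O.AxisAnnotation(pts @ R.T, R @ [0, 0, -20.0],
                                 (np.array([[15, 0, 1], [15, 0, -1.0]]) @ R.T))
        f1 = O.determine_axis(ann_r, R @ c)
        assert np.allclose(f1.rotation[2], R @ f0.rotation[2], atol=1e-9)

    def test_noiseless_interface_plane_recovery(self):
        """Least-squares plane through coplanar points is exact."""
        rng = np.random.default_rng(5)
        n = np.array([0.2, -0.3, 0.93])
        n /= np.linalg.norm(n)
        basis = np.linalg.svd(n[None])[2][1:]
        pts = rng.uniform(-5, 5, (8, 2)) @ basis + np.array([1.0, 2.0, 3.0])
        ann = O.AxisAnnotation(pts, [0, 0, -20.0], [[15, 0, 1], [15, 0, -1]])
        frame = O.determine_axis(ann, [0.0, 0.0, 0.0])
        _, fitted_n = frame.interface_plane
        assert abs(fitted_n @ n) > 1 - 1e-9

    def test_tip_at_centroid_rejected(self):
        ann = O.AxisAnnotation(np.zeros((6, 3)), [1.0, 1, 1],
                               [[2, 0, 0], [2, 0, 1]])
        with pytest.raises(ValueError):
            O.determine_axis(ann, [1.0, 1.0, 1.0])


class TestPipelineInvariants:
    def test_every_cell_classified(self, quantified_spherical):
        table, shapes, tissue, frame, truth = quantified_spherical
        assert set(table.label) == set(shapes)
        assert (table.boundary_flag | table.boundary_angle_deg.isna()).all()

    def test_radial_cells_stand_perpendicular(self, quantified_spherical):
        """Radially oriented cells on a spherical tissue meet the boundary
        head-on: the median cell-boundary angle is near 0 deg."""
        table, *_ = quantified_spherical
        bnd = table[table.boundary_flag]
        assert bnd.boundary_angle_deg.median() < 10.0

    def test_measured_axes_match_ground_truth(self, quantified_spherical):
        table, shapes, tissue, frame, truth = quantified_spherical
        errs = []
        for lab, cs in shapes.items():
            gt = truth.orientations[lab - 1]
            c = abs(np.dot(cs.axes[0], gt))
            errs.append(np.degrees(np.arccos(np.clip(c, 0, 1))))
        assert np.median(errs) < 10.0
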