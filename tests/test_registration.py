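"""Normal estimation, voxel downsampling, coarse alignment and ICP."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from radshape import (IcpParams, PointCloud, RegistrationError,
                      RigidTransform, ValidationError, estimate_normals,
                      icp_point_to_plane, initial_align, register_pair,
                      voxel_downsample)


def test_plane_normals_are_vertical(rng):
    pts = np.column_stack([rng.uniform(-5, 5, (60, 2)), np.zeros(60)])
    cloud = estimate_normals(PointCloud(points=pts), k=8)
    np.testing.assert_allclose(np.abs(cloud.normals[:, 2]), 1.0, atol=1e-9)


def test_sphere_normals_near_radial():
    n = 500                       # quasi-uniform Fibonacci sphere, r = 10 mm
    i = np.arange(n)
    golden = np.pi * (3 - np.sqrt(5))
    y = 1 - 2 * i / (n - 1)
    r = np.sqrt(1 - y * y)
    pts = 10 * np.column_stack([np.cos(golden * i) * r, y,
                                np.sin(golden * i) * r])
    cloud = estimate_normals(PointCloud(points=pts), k=10)
    radial = pts / 10.0
    cosang = np.einsum("ij,ij->i", cloud.normals, radial)
    assert np.all(np.degrees(np.arccos(np.clip(np.abs(cosang), 0, 1))) < 5)
    # outward orientation: positive dot with the radial direction
    assert np.all(cosang > 0)


def test_normals_bad_k(tiny_cloud):
    with pytest.raises(ValidationError):
        estimate_normals(tiny_cloud, k=4)
    with pytest.raises(ValidationError):
        estimate_normals(tiny_cloud, k=2)


def test_voxel_single_cell():
    cloud = PointCloud(points=[[0.1, 0.1, 0.1], [0.2, 0.2, 0.2],
                               [5, 5, 5], [6, 6, 6], [7, 7, 7]])
    out = voxel_downsample(cloud, 1.0)
    assert len(out) == 4           # the two sub-voxel points merge
    np.testing.assert_allclose(out.points[0], [0.15, 0.15, 0.15])


def test_voxel_fine_grid_is_identity_up_to_order(rng):
    pts = rng.uniform(0, 10, (50, 3))
    out = voxel_downsample(PointCloud(points=pts), voxel=1e-4)
    assert len(out) == 50
    assert {tuple(np.round(p, 9)) for p in out.points} == \
           {tuple(np.round(p, 9)) for p in pts}


def test_voxel_against_brute_force_binning(rng):
    pts = rng.uniform(0, 2, (100, 3))
    cloud = PointCloud(points=pts)
    out = voxel_downsample(cloud, 1.0)
    origin = np.floor(pts.min(axis=0))
    keys = {tuple(k) for k in np.floor(pts - origin).astype(int)}
    assert len(out) == len(keys)
    # every output point lies inside its voxel
    idx = np.floor(out.points - origin).astype(int)
    assert len(out) <= len(pts)
    assert {tuple(k) for k in idx} == keys


def test_initial_align_identity(template):
    cloud, _, _ = template
    aligned, tf = initial_align(cloud, cloud)
    assert not tf.mirrored
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)
    np.testing.assert_allclose(aligned.points, cloud.points, atol=1e-9)


def test_initial_align_recovers_rotation(template):
    cloud, _, _ = template
    rot = Rotation.from_euler("z", 30, degrees=True).as_matrix()
    moved = cloud.with_points(cloud.points @ rot.T)
    _, tf = initial_align(moved, cloud)
    np.testing.assert_allclose(tf.rotation @ rot, np.eye(3), atol=1e-6)


def test_initial_align_detects_mirror(template):
    cloud, _, _ = template
    mirrored_pts = cloud.points * np.array([-1.0, 1.0, 1.0])
    aligned, tf = initial_align(cloud.with_points(mirrored_pts), cloud,
                                allow_mirror=True)
    assert tf.mirrored
    assert np.linalg.norm(aligned.points.mean(0) - cloud.points.mean(0)) < 1e-6


def test_initial_align_isotropic_raises():
    cube = PointCloud(points=np.array(
        [[x, y, z] for x in (-1, 1) for y in (-1, 1) for z in (-1, 1)],
        dtype=float))              # exactly equal principal variances
    with pytest.raises(RegistrationError):
        initial_align(cube, cube)


@pytest.fixture(scope="module")
def bone_with_normals():
    from radshape import make_template
    cloud, _, _ = make_template(800, seed=3)
    return estimate_normals(cloud, k=20)


def test_icp_identity(bone_with_normals):
    tf, report = icp_point_to_plane(bone_with_normals, bone_with_normals)
    assert report.final_rmse < 1e-9
    assert report.iterations <= 2
    np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-9)


def test_icp_recovers_small_transform(bone_with_normals):
    rot = Rotation.from_euler("z", 10, degrees=True).as_matrix()
    tvec = np.array([1.0, 2.0, 0.0])
    moved = bone_with_normals.with_points(
        bone_with_normals.points @ rot.T + tvec)
    tf, report = icp_point_to_plane(moved, bone_with_normals)
    np.testing.assert_allclose(tf.rotation @ rot, np.eye(3), atol=1e-3)
    np.testing.assert_allclose(tf.rotation @ tvec + tf.translation,
                               np.zeros(3), atol=1e-3)
    assert report.passed_gate


def test_icp_rejects_outlier_pairs(bone_with_normals):
    pts = bone_with_normals.points.copy()
    pts[0] += np.array([0.0, 0.0, 200.0])   # far outlier, > 2.5 mm from all
    moved = bone_with_normals.with_points(pts)
    _, report = icp_point_to_plane(moved, bone_with_normals)
    assert report.rejected_fraction > 0
    assert report.final_rmse < 0.1          # outlier excluded from objective


def test_icp_objective_non_increasing_on_noiseless_input(bone_with_normals):
    rot = Rotation.from_euler("y", 8, degrees=True).as_matrix()
    moved = bone_with_normals.with_points(
        bone_with_normals.points @ rot.T + np.array([1.0, -0.5, 0.5]))
    _, report = icp_point_to_plane(moved, bone_with_normals)
    hist = np.asarray(report.error_history)
    assert len(hist) >= 2
    assert np.all(np.diff(hist) <= 1e-12)


def test_icp_equivariance_under_joint_rotation(bone_with_normals):
    rot = Rotation.from_euler("xyz", [7, -12, 25], degrees=True).as_matrix()
    src = bone_with_normals.with_points(
        bone_with_normals.points + np.array([0.5, -0.3, 0.2]))
    _, rep1 = icp_point_to_plane(src, bone_with_normals)
    src_r = src.with_points(src.points @ rot.T)
    tgt_r = bone_with_normals.with_points(
        bone_with_normals.points @ rot.T,
        bone_with_normals.normals @ rot.T)
    _, rep2 = icp_point_to_plane(src_r, tgt_r)
    assert abs(rep1.final_rmse - rep2.final_rmse) < 1e-9


def test_register_pair_composes_to_identity(bone_with_normals, rng):
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(18) * axis).as_matrix()
    tvec = rng.uniform(-5, 5, 3)
    moved = bone_with_normals.with_points(
        bone_with_normals.points @ rot.T + tvec)
    _, tf, report = register_pair(moved, bone_with_normals)
    np.testing.assert_allclose(tf.rotation @ rot, np.eye(3), atol=1e-3)
    assert report.final_rmse <= 0.5


def test_rigid_transform_validation():
    with pytest.raises(ValidationError):
        RigidTransform(rotation=np.diag([1.0, 1.0, -1.0]),
                       translation=np.zeros(3))
    with pytest.raises(ValidationError):
        IcpParams(max_iters=0)
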