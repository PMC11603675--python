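"""Frame construction, rigid transforms, ROI partition, probe placement."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from palatemap import anatomy
from palatemap.errors import GeometryError, PlacementError


def _landmarks(ans=(0, 50, 0), pns=(0, 0, 0), occ_z=-10.0):
    return anatomy.LandmarkSet(
        ans=ans,
        pns=pns,
        molar_fissure_r=(12, 10, occ_z),
        molar_fissure_l=(-12, 10, occ_z),
        occlusal_points=[(0, 40, occ_z), (8, 10, occ_z), (-8, 10, occ_z)],
    )


class TestBuildFrame:
    def test_axis_aligned_case(self):
        frame = anatomy.build_frame(_landmarks())
        np.testing.assert_allclose(frame.axes[1], [0, 1, 0], atol=1e-12)  # Y
        np.testing.assert_allclose(frame.axes[2], [0, 0, 1], atol=1e-12)  # Z
        np.testing.assert_allclose(frame.axes[0], [1, 0, 0], atol=1e-12)  # X
        assert np.isclose(np.linalg.det(frame.axes), 1.0)
        np.testing.assert_allclose(frame.origin, [0, 25, 0])

    def test_coincident_spines_raise(self):
        with pytest.raises(GeometryError):
            anatomy.build_frame(_landmarks(ans=(0, 0, 0), pns=(0, 0, 0)))

    def test_collinear_occlusal_points_raise(self):
        lm = _landmarks()
        lm.occlusal_points = np.array([[0, 0, -10], [1, 0, -10], [2, 0, -10]])
        with pytest.raises(GeometryError):
            anatomy.build_frame(lm)

    def test_swapped_fissures_raise(self):
        lm = _landmarks()
        lm.molar_fissure_r, lm.molar_fissure_l = (
            lm.molar_fissure_l.copy(),
            lm.molar_fissure_r.copy(),
        )
        with pytest.raises(GeometryError):
            anatomy.build_frame(lm)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_orthonormal_for_random_rigid_poses(self, seed):
        """Axes stay orthonormal/right-handed under arbitrary rigid poses."""
        rng = np.random.default_rng(seed)
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = rng.normal(scale=30.0, size=3)
        lm = _landmarks()
        for name in ("ans", "pns", "molar_fissure_r", "molar_fissure_l"):
            setattr(lm, name, q @ getattr(lm, name) + t)
        lm.occlusal_points = lm.occlusal_points @ q.T + t
        frame = anatomy.build_frame(lm)
        np.testing.assert_allclose(frame.axes @ frame.axes.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(frame.axes) > 0

    def test_scale_free(self):
        f1 = anatomy.build_frame(_landmarks())
        lm2 = _landmarks()
        for name in ("ans", "pns", "molar_fissure_r", "molar_fissure_l"):
            setattr(lm2, name, 2.0 * getattr(lm2, name))
        lm2.occlusal_points = 2.0 * lm2.occlusal_points
        f2 = anatomy.build_frame(lm2)
        np.testing.assert_allclose(f1.axes, f2.axes, atol=1e-12)


class TestTransform:
    def test_roundtrip(self, slab_pair):
        oral, _, truth = slab_pair
        frame = anatomy.build_frame(truth.landmark_set)
        there = anatomy.transform_to_frame(oral, frame)
        back = frame.to_world(there.vertices)
        np.testing.assert_allclose(back, oral.vertices, atol=1e-9)

    def test_isometry(self, slab_pair):
        oral, _, truth = slab_pair
        frame = anatomy.build_frame(truth.landmark_set)
        there = anatomy.transform_to_frame(oral, frame)
        d0 = np.linalg.norm(oral.vertices[0] - oral.vertices[-1])
        d1 = np.linalg.norm(there.vertices[0] - there.vertices[-1])
        assert abs(d0 - d1) < 1e-9

    def test_identity_frame(self, slab_pair):
        oral, _, _ = slab_pair
        out = anatomy.transform_to_frame(oral, anatomy.AnatomicalFrame.identity())
        np.testing.assert_array_equal(out.vertices, oral.vertices)


def _tiny_patch(centroids):
    """One tiny triangle per requested centroid (z = 0 plane)."""
    verts, faces = [], []
    for i, (cx, cy) in enumerate(centroids):
        verts += [
            [cx - 0.1, cy - 0.1, 0.0],
            [cx + 0.2, cy - 0.1, 0.0],
            [cx - 0.1, cy + 0.2, 0.0],
        ]
        faces.append([3 * i, 3 * i + 2, 3 * i + 1])  # normal −Z
    import trimesh

    return trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces), process=False)


@pytest.fixture()
def simple_bands():
    mk = lambda ys: anatomy.ToothBands(
        anchors={"canine_p1": (0, ys[0], 0), "p1_mid": (0, (ys[0] + ys[1]) / 2, 0),
                 "p1_p2": (0, ys[1], 0)},
        roi_bounds=[(0, y, 0) for y in ys],
    )
    return {"r": mk([12.0, 6.0, 0.0, -8.0]), "l": mk([12.0, 6.0, 0.0, -8.0])}


class TestPartition:
    def test_label_by_definition(self, simple_bands):
        patch = _tiny_patch([(5.0, 9.0)])
        part = anatomy.partition_roi(patch, simple_bands)
        assert part.face_labels[0] == "1r"

    def test_beyond_paramedian_limit(self, simple_bands):
        patch = _tiny_patch([(12.0, 9.0), (5.0, 9.0)])
        part = anatomy.partition_roi(patch, simple_bands)
        assert list(part.face_labels) == ["none", "1r"]

    def test_tie_breaks_right_and_anterior(self, simple_bands):
        # centroid exactly at x=0 → right; y exactly at a band boundary → the
        # anterior of the two adjacent bands
        patch = _tiny_patch([(0.0, 9.0), (5.0, 6.0)])
        part = anatomy.partition_roi(patch, simple_bands)
        c = patch.triangles_center
        assert np.isclose(c[0, 0], 0.0) and part.face_labels[0] == "1r"
        assert np.isclose(c[1, 1], 6.0) and part.face_labels[1] == "1r"

    def test_symmetric_phantom_equal_areas(self, slab_pair):
        oral, _, truth = slab_pair
        part = anatomy.partition_roi(oral, truth.landmark_set.tooth_bands)
        areas = {
            roi: oral.area_faces[part.faces_for(roi)].sum()
            for roi in anatomy.ROI_IDS
        }
        for k in ("1", "2", "3"):
            assert np.isclose(areas[f"{k}r"], areas[f"{k}l"], rtol=1e-9)

    def test_roi_area_bounded_by_patch(self, slab_pair):
        oral, _, truth = slab_pair
        part = anatomy.partition_roi(oral, truth.landmark_set.tooth_bands)
        labelled = part.face_labels != "none"
        assert oral.area_faces[labelled].sum() <= oral.area + 1e-9

    def test_rigid_invariance(self, vault_truth):
        """Labels are unchanged when mesh and landmarks move together."""
        oral = vault_truth.meshes["oral"]
        lm = vault_truth.landmark_set
        p0 = anatomy.partition_roi(oral, lm.tooth_bands)

        rng = np.random.default_rng(5)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] = -q[:, 0]
        t = np.array([7.0, -12.0, 4.0])
        import trimesh

        moved = trimesh.Trimesh(vertices=oral.vertices @ q.T + t,
                                faces=oral.faces, process=False)
        lm2 = anatomy.LandmarkSet(
            ans=q @ lm.ans + t, pns=q @ lm.pns + t,
            molar_fissure_r=q @ lm.molar_fissure_r + t,
            molar_fissure_l=q @ lm.molar_fissure_l + t,
            occlusal_points=lm.occlusal_points @ q.T + t,
            tooth_bands={
                side: anatomy.ToothBands(
                    anchors={k: q @ v + t for k, v in tb.anchors.items()},
                    roi_bounds=tb.roi_bounds @ q.T + t,
                )
                for side, tb in lm.tooth_bands.items()
            },
        )
        frame2 = anatomy.build_frame(lm2)
        moved_f = anatomy.transform_to_frame(moved, frame2)
        lm2_f = lm2.transformed(frame2)
        p1 = anatomy.partition_roi(moved_f, lm2_f.tooth_bands)
        # float roundoff may flip faces whose centroid sits exactly on a
        # boundary; everywhere else the labels must agree exactly
        c = oral.triangles_center
        bounds = lm.tooth_bands["r"].bound_ys()
        off_boundary = (
            (np.abs(c[:, 0]) > 1e-6)
            & (np.abs(np.abs(c[:, 0]) - 10.0) > 1e-6)
            & (np.abs(c[:, 1][:, None] - bounds[None, :]).min(axis=1) > 1e-6)
        )
        assert (p0.face_labels[off_boundary] == p1.face_labels[off_boundary]).all()


class TestProbePoints:
    def test_six_points_with_expected_ids(self, vault_probe_setup):
        assert set(vault_probe_setup["points"]) == {"1r", "1l", "2r", "2l", "3r", "3l"}

    def test_mirror_symmetry(self, vault_probe_setup):
        pts = vault_probe_setup["points"]
        for k in ("1", "2", "3"):
            r, l = pts[f"{k}r"], pts[f"{k}l"]
            assert np.isclose(r.position[0], 3.0) and np.isclose(l.position[0], -3.0)
            assert np.isclose(r.position[1], l.position[1])
            assert abs(r.position[2] - l.position[2]) < 1e-6

    def test_points_lie_on_surface(self, vault_probe_setup):
        from palatemap.raycast import closest_point_on_tris

        oral = vault_probe_setup["oral"]
        for p in vault_probe_setup["points"].values():
            d, _, _ = closest_point_on_tris(p.position[None], oral.vertices, oral.faces)
            assert d[0] < 0.1

    def test_normals_face_oral_cavity(self, vault_probe_setup):
        for p in vault_probe_setup["points"].values():
            assert p.surface_normal[2] < 0

    def test_anchor_outside_mesh_raises(self, vault_probe_setup, simple_bands):
        bad = {
            s: anatomy.ToothBands(
                anchors={"canine_p1": (0, 99.0, 0), "p1_mid": (0, 98.0, 0),
                         "p1_p2": (0, 97.0, 0)},
                roi_bounds=tb.roi_bounds,
            )
            for s, tb in simple_bands.items()
        }
        with pytest.raises(PlacementError):
            anatomy.place_probe_points(vault_probe_setup["oral"], bad)


def test_landmarks_json_roundtrip(tmp_path, vault_truth):
    lm = vault_truth.landmark_set
    path = str(tmp_path / "lm.json")
    lm.to_json(path)
    back = anatomy.LandmarkSet.from_json(path)
    np.testing.assert_allclose(back.ans, lm.ans)
    np.testing.assert_allclose(
        back.tooth_bands["r"].roi_bounds, lm.tooth_bands["r"].roi_bounds
    )
    np.testing.assert_allclose(
        back.tooth_bands["l"].anchors["p1_mid"], lm.tooth_bands["l"].anchors["p1_mid"]
    )
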