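"""Shared fixtures: phantoms and their derived meshes, generated at test time."""

import numpy as np
import pytest
import trimesh

from palatemap import anatomy, phantom, segmentation, thickness


@pytest.fixture(scope="session")
def slab_pair():
    """Exact 5 mm slab mesh pair (20×10 mm)."""
    return phantom.make_mesh_pair("slab", thickness_mm=5.0, extent_mm=(20.0, 10.0))


@pytest.fixture(scope="session")
def shell_pair():
    """Concentric spherical shell, inner radius 10 mm, thickness 2 mm."""
    return phantom.make_mesh_pair("spherical_shell", inner_r_mm=10.0, thickness_mm=2.0)


@pytest.fixture(scope="session")
def wedge_pair():
    """Gradient wedge 10→3.5 mm over 30 mm."""
    return phantom.make_mesh_pair("gradient_wedge")


@pytest.fixture(scope="session")
def vault_truth():
    """Analytic vault surfaces + truth (coarse voxel grid, meshes exact)."""
    _, truth = phantom.make_vault_phantom(spacing_mm=1.0)
    return truth


@pytest.fixture(scope="session")
def vault_probe_setup(vault_truth):
    """Probe points on the analytic vault oral surface (world ≡ frame axes)."""
    oral = vault_truth.meshes["oral"]
    nasal = vault_truth.meshes["nasal"]
    teeth = vault_truth.meshes["teeth"]
    bands = vault_truth.landmark_set.tooth_bands
    points = anatomy.place_probe_points(oral, bands)
    return {"oral": oral, "nasal": nasal, "teeth": teeth, "bands": bands,
            "points": {p.id: p for p in points}, "truth": vault_truth}


def _segment_to_frame(vol, truth, lo=400.0, teeth_lo=1500.0):
    """Voxel volume → framed bone mesh, oral patch, nasal target, landmarks."""
    bone_mask = segmentation.largest_component(
        segmentation.segment_threshold(vol, lo, teeth_lo), min_voxels=500
    )
    bone = segmentation.extract_surface(vol, iso_level=lo, mask=bone_mask)
    frame = anatomy.build_frame(truth.landmark_set)
    bone_f = anatomy.transform_to_frame(bone, frame)
    lm_f = truth.landmark_set.transformed(frame)
    oral = anatomy.select_oral_patch(bone_f)
    keep = bone_f.face_normals[:, 2] > 0.2
    nasal = trimesh.Trimesh(
        vertices=bone_f.vertices.copy(), faces=bone_f.faces[keep], process=False
    )
    nasal.remove_unreferenced_vertices()
    return {"frame": frame, "bone": bone_f, "oral": oral, "nasal": nasal,
            "landmarks": lm_f, "bone_mask": bone_mask}


@pytest.fixture(scope="session")
def slab_segmented():
    """5 mm slab voxelized at 0.3 mm, segmented and framed."""
    vol, truth = phantom.make_slab_phantom(5.0, 20.0, 0.3)
    out = _segment_to_frame(vol, truth)
    out["truth"] = truth
    out["vol"] = vol
    return out


@pytest.fixture(scope="session")
def vault_segmented_clean():
    """Vault without roots/canal, voxelized at 0.5 mm, segmented and framed."""
    vol, truth = phantom.make_vault_phantom(
        spacing_mm=0.5, roots_on=False, canal_on=False
    )
    out = _segment_to_frame(vol, truth)
    out["truth"] = truth
    return out


@pytest.fixture(scope="session")
def vault_segmented_full():
    """Vault with roots and canal, voxelized at 0.5 mm, segmented and framed."""
    vol, truth = phantom.make_vault_phantom(spacing_mm=0.5)
    out = _segment_to_frame(vol, truth)
    out["truth"] = truth
    out["vol"] = vol
    return out


@pytest.fixture()
def roi_box_crop():
    """Crop a framed mesh to the paramedian ROI strip (speed helper)."""

    def crop(mesh, bands, limit=10.0, pad=2.0):
        ys = np.concatenate([bands[s].bound_ys() for s in ("r", "l")])
        c = mesh.triangles_center
        keep = (
            (np.abs(c[:, 0]) <= limit + pad)
            & (c[:, 1] >= ys.min() - pad)
            & (c[:, 1] <= ys.max() + pad)
        )
        out = trimesh.Trimesh(
            vertices=mesh.vertices.copy(), faces=mesh.faces[keep], process=False
        )
        out.remove_unreferenced_vertices()
        return out

    return crop
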