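"""HU thresholding, component filtering and surface extraction.

Mirrors the usual CBCT→STL conversion workflow: a global two-sided HU
threshold selects hard tissue, small speckle components are dropped, and a
marching-cubes iso-surface (run on the continuous grey values, not the
binary mask, to reduce staircase bias) produces the triangle mesh in mm.
A second, higher threshold separates the teeth from bone; the two meshes
are then merged by concatenation since they live in the same scanner frame.
"""

from __future__ import annotations

import warnings

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

from .volume import BinaryMask, VoxelVolume

__all__ = [
    "segment_threshold",
    "largest_component",
    "extract_surface",
    "merge_meshes",
    "voxel_volume_of",
    "DEFAULT_BONE_LO_HU",
    "DEFAULT_TEETH_LO_HU",
    "DEFAULT_HI_HU",
]

# Working range follows the usual 50–2000 HU hard-tissue window; the bone and
# teeth passes default to 400 and 1500 HU lower bounds.
DEFAULT_BONE_LO_HU = 400.0
DEFAULT_TEETH_LO_HU = 1500.0
DEFAULT_HI_HU = 2000.0

_CONN26 = np.ones((3, 3, 3), dtype=bool)


def segment_threshold(volume: VoxelVolume, lo_hu: float, hi_hu: float) -> BinaryMask:
    """Binary mask of voxels with ``lo_hu <= value <= hi_hu``."""
    if not lo_hu < hi_hu:
        raise ValueError(f"inverted threshold bounds: lo={lo_hu} >= hi={hi_hu}")
    values = (volume.values >= lo_hu) & (volume.values <= hi_hu)
    return BinaryMask(values=values, spacing=volume.spacing, origin=volume.origin)


def largest_component(mask: BinaryMask, min_voxels: int = 1000) -> BinaryMask:
    """Keep the largest 26-connected component plus any component ≥ min_voxels."""
    labels, n = ndimage.label(mask.values, structure=_CONN26)
    if n == 0:
        warnings.warn("largest_component: empty mask, returning empty result")
        return BinaryMask(
            values=np.zeros_like(mask.values), spacing=mask.spacing, origin=mask.origin
        )
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = np.flatnonzero((counts >= min_voxels) | (counts == counts.max()))
    out = np.isin(labels, keep)
    return BinaryMask(values=out, spacing=mask.spacing, origin=mask.origin)


def extract_surface(
    source,
    iso_level: float | None = None,
    mask: BinaryMask | None = None,
) -> trimesh.Trimesh:
    """Iso-surface mesh in mm coordinates.

    ``source`` may be a :class:`VoxelVolume` (marching cubes at ``iso_level``
    on the grey values; pass ``mask`` to restrict extraction to a tissue
    class by flooring excluded voxels) or a :class:`BinaryMask` (level 0.5 on
    the 0/1 field).  The result is cleaned of degenerate faces and oriented
    with outward normals.
    """
    if isinstance(source, BinaryMask):
        field = source.values.astype(np.float32)
        level = 0.5
        spacing, origin = source.spacing, source.origin
    elif isinstance(source, VoxelVolume):
        if iso_level is None:
            raise ValueError("iso_level is required for a grey-value volume")
        field = np.asarray(source.values, dtype=np.float32)
        if mask is not None:
            floor = min(float(field.min()), iso_level - 1000.0)
            field = np.where(mask.values, field, np.float32(floor))
        level = float(iso_level)
        spacing, origin = source.spacing, source.origin
    else:
        raise TypeError("source must be a VoxelVolume or BinaryMask")

    if field.max() <= level or field.min() >= level:
        raise ValueError("empty mesh: iso level outside the data range")

    verts, faces, _, _ = measure.marching_cubes(field, level=level, spacing=tuple(spacing))
    mesh = trimesh.Trimesh(vertices=verts + origin, faces=faces, process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    # marching-cubes winding follows the gradient; make normals point out of
    # the solid (positive enclosed volume) when the surface is closed.  Flip
    # by rewinding faces: trimesh's invert() can leave stale cached normals.
    flip = False
    if mesh.is_watertight:
        flip = mesh.volume < 0
    else:
        centroid_dirs = mesh.triangles_center - mesh.centroid
        flip = np.einsum("ij,ij->i", mesh.face_normals, centroid_dirs).mean() < 0
    if flip:
        mesh = trimesh.Trimesh(
            vertices=mesh.vertices.copy(), faces=mesh.faces[:, ::-1], process=False
        )
    return mesh


def merge_meshes(bone: trimesh.Trimesh, teeth: trimesh.Trimesh) -> trimesh.Trimesh:
    """Concatenate bone and teeth meshes, tagging faces by component.

    Input vertex coordinates are kept bit-identical; the merged mesh carries
    a per-face label array under ``metadata['face_labels']`` ("bone"/"teeth")
    for downstream collision queries.
    """
    if teeth is None or len(teeth.faces) == 0:
        merged = trimesh.Trimesh(
            vertices=bone.vertices.copy(), faces=bone.faces.copy(), process=False
        )
        merged.metadata["face_labels"] = np.array(["bone"] * len(bone.faces))
        return merged
    vertices = np.vstack([bone.vertices, teeth.vertices])
    faces = np.vstack([bone.faces, teeth.faces + len(bone.vertices)])
    merged = trimesh.Trimesh(vertices=vertices, faces=faces, process=False)
    merged.metadata["face_labels"] = np.array(
        ["bone"] * len(bone.faces) + ["teeth"] * len(teeth.faces)
    )
    return merged


def voxel_volume_of(mask: BinaryMask) -> float:
    """Volume of the mask in mm³ (true-voxel count × voxel volume)."""
    return mask.count() * float(np.prod(mask.spacing))
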