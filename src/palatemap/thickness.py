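"""Per-vertex bone thickness maps and ROI aggregation (AA, MD, Vol).

The thickness at an oral-surface vertex is the ray-cast distance from that
vertex into the bone to the first intersection with the nasal-floor
surface.  ROI aggregates use the barycentric one-third area rule, which
makes the integrated-distance volume an exact surface integral and the
identity Vol = AA × MD hold by construction:

    AA  = Σ_v w_v            (analysis area, mm²)
    MD  = Σ_v w_v d_v / AA   (area-weighted mean thickness, mm)
    Vol = Σ_v w_v d_v        (integrated distance, mm³)

with w_v one third of the labelled-triangle area incident to vertex v,
restricted to vertices with a valid ray hit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .anatomy import ROI_IDS, RoiPartition
from .raycast import closest_point_on_tris, first_hit_mesh

__all__ = ["DistanceMap", "RoiSummary", "compute_distance_map", "summarize_roi",
           "export_color_map"]

DIRECTION_RULES = ("anti_normal", "frame_z", "closest_point")


@dataclass
class DistanceMap:
    """Per-vertex thickness over an oral patch.

    ``distances`` is NaN where the ray missed (no nasal surface within
    ``max_ray_mm``); ``valid`` marks hits.  The mesh the map was computed on
    is kept so ROI aggregation can weight vertices by incident face area.
    """

    distances: np.ndarray
    valid: np.ndarray
    direction_rule: str
    max_ray_mm: float
    mesh: trimesh.Trimesh = None
    metadata: dict = field(default_factory=dict)


def compute_distance_map(
    oral_patch: trimesh.Trimesh,
    nasal_surface: trimesh.Trimesh,
    direction_rule: str = "anti_normal",
    max_ray_mm: float = 40.0,
) -> DistanceMap:
    """Cast one ray per oral vertex and record the distance to the nasal floor.

    Direction rules: ``anti_normal`` (into the bone, opposite the oral
    vertex normal — the default, "relative to the palatal surface"),
    ``frame_z`` (straight superior, +Z of the anatomical frame), or
    ``closest_point`` (unsigned closest distance to the nasal surface,
    no ray involved).
    """
    if nasal_surface is None or len(nasal_surface.faces) == 0:
        raise ValueError("nasal surface is empty")
    if direction_rule not in DIRECTION_RULES:
        raise ValueError(f"unknown direction rule {direction_rule!r}")
    verts = oral_patch.vertices.view(np.ndarray)
    if direction_rule == "closest_point":
        dist, _, _ = closest_point_on_tris(verts, nasal_surface.vertices, nasal_surface.faces)
        valid = dist <= max_ray_mm
        distances = np.where(valid, dist, np.nan)
    else:
        if direction_rule == "anti_normal":
            dirs = -oral_patch.vertex_normals.view(np.ndarray)
            dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        else:
            dirs = np.tile(np.array([0.0, 0.0, 1.0]), (len(verts), 1))
        dist, _ = first_hit_mesh(verts, dirs, nasal_surface, max_dist=max_ray_mm)
        valid = np.isfinite(dist)
        distances = np.where(valid, dist, np.nan)
    return DistanceMap(
        distances=distances,
        valid=valid,
        direction_rule=direction_rule,
        max_ray_mm=float(max_ray_mm),
        mesh=oral_patch,
        metadata={"convention": "mm; X+=right, Y+=anterior, Z+=superior"},
    )


@dataclass
class RoiSummary:
    """ROI aggregate: analysis area, mean thickness, integrated volume."""

    roi: str
    AA: float  # mm²
    MD: float  # mm (NaN when the section holds no valid vertex)
    Vol: float  # mm³
    n_valid_vertices: int
    coverage: float
    flagged: bool = False


def _vertex_weights(mesh: trimesh.Trimesh, face_idx: np.ndarray) -> np.ndarray:
    """One-third incident-area weight per vertex, over the given faces."""
    w = np.zeros(len(mesh.vertices))
    if len(face_idx) == 0:
        return w
    areas = mesh.area_faces[face_idx] / 3.0
    for corner in range(3):
        np.add.at(w, mesh.faces[face_idx, corner], areas)
    return w


def summarize_roi(partition: RoiPartition, dmap: DistanceMap) -> list:
    """AA/MD/Vol per ROI section from a labelled oral patch and its map."""
    mesh = dmap.mesh
    if mesh is None or len(partition.face_labels) != len(mesh.faces):
        raise ValueError("partition and distance map refer to different patches")
    out = []
    for roi in ROI_IDS:
        faces = partition.faces_for(roi)
        w_all = _vertex_weights(mesh, faces)
        total_area = w_all.sum()
        w = np.where(dmap.valid, w_all, 0.0)
        aa = float(w.sum())
        vol = float(np.nansum(w * np.where(dmap.valid, dmap.distances, 0.0)))
        md = vol / aa if aa > 0 else float("nan")
        out.append(
            RoiSummary(
                roi=roi,
                AA=aa,
                MD=md,
                Vol=vol,
                n_valid_vertices=int(((w_all > 0) & dmap.valid).sum()),
                coverage=float(aa / total_area) if total_area > 0 else 0.0,
                flagged=aa == 0.0,
            )
        )
    return out


def export_color_map(
    oral_patch: trimesh.Trimesh,
    dmap: DistanceMap,
    path: str,
    color_scale: str = "viridis",
    bounds: tuple | None = None,
) -> str:
    """Write a PLY with per-vertex colors encoding thickness.

    Colors follow a monotone matplotlib scale between ``bounds`` (default:
    the valid min/max); invalid vertices are grey.  Scale bounds and the
    colormap name go to a sidecar JSON next to the PLY.
    """
    import matplotlib

    d = dmap.distances
    if bounds is None:
        finite = d[np.isfinite(d)]
        bounds = (float(finite.min()), float(finite.max())) if finite.size else (0.0, 1.0)
    vmin, vmax = bounds
    span = vmax - vmin
    if span <= 1e-9 * max(1.0, abs(vmax)):  # constant map → single mid color
        frac = np.full_like(d, 0.5)
    else:
        frac = np.clip((d - vmin) / span, 0.0, 1.0)
    cmap = matplotlib.colormaps[color_scale]
    rgba = (cmap(np.where(np.isfinite(frac), frac, 0.0)) * 255).astype(np.uint8)
    rgba[~dmap.valid] = [128, 128, 128, 255]
    mesh = trimesh.Trimesh(
        vertices=oral_patch.vertices.copy(), faces=oral_patch.faces.copy(), process=False
    )
    mesh.visual.vertex_colors = rgba
    mesh.export(path)
    sidecar = str(path) + ".json"
    with open(sidecar, "w") as fh:
        json.dump(
            {"colormap": color_scale, "vmin": vmin, "vmax": vmax,
             "invalid_color": [128, 128, 128], "unit": "mm"},
            fh, indent=2,
        )
    return str(path)
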