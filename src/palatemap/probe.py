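"""Angulated insertion-corridor probing at the six paramedian points.

Simulates mini-implant insertion at 0°/10°/20°/30° anterior tilt: the 0°
direction is the local surface anti-normal (into the bone); tilting rotates
it about the frame X axis toward anterior.  Thickness is always the
distance to the nasal floor; a tooth-root interception is recorded as a
separate flag with its depth, never by truncating the thickness, so the
two risks (perforating the nasal floor, hitting a root) stay separable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .anatomy import ProbePoint, RoiPartition
from .errors import GeometryError
from .raycast import closest_point_on_tris, first_hit_mesh

__all__ = [
    "ProbeResult",
    "ImplantSpec",
    "CorridorFit",
    "angled_direction",
    "measure_point_thickness",
    "corridor_fit",
    "roots_in_region",
]

PROBE_ANGLES_DEG = (0, 10, 20, 30)


@dataclass
class ImplantSpec:
    """Mini-implant geometry; typical palatal devices are ~2×9 mm."""

    diameter_mm: float = 2.0
    length_mm: float = 9.0

    def __post_init__(self):
        if not 0 < self.diameter_mm <= 5:
            raise ValueError("implant diameter must be in (0, 5] mm")
        if not 0 < self.length_mm <= 20:
            raise ValueError("implant length must be in (0, 20] mm")


@dataclass
class ProbeResult:
    """One (point, angle) measurement."""

    point_id: str
    angle_deg: float
    thickness_mm: float  # NaN when the ray misses the nasal floor
    root_hit: bool
    root_depth_mm: float  # NaN when no root interception
    direction: np.ndarray

    @property
    def valid(self) -> bool:
        return bool(np.isfinite(self.thickness_mm))

    @property
    def usable_depth_mm(self) -> float:
        """Depth available before the first limiting structure."""
        if self.root_hit:
            return float(np.nanmin([self.thickness_mm, self.root_depth_mm]))
        return float(self.thickness_mm)


def angled_direction(surface_normal: np.ndarray, theta_deg: float) -> np.ndarray:
    """Insertion direction: anti-normal tilted toward anterior (+Y).

    The tilt is purely sagittal — a rotation about the frame X axis by
    ``theta_deg`` that carries +Z toward +Y.  Expects frame coordinates.
    """
    n = np.asarray(surface_normal, dtype=float)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise GeometryError("zero surface normal")
    if not 0 <= theta_deg <= 45:
        raise ValueError("tilt must be within [0°, 45°]")
    d0 = -n / norm  # 0° = into the bone
    th = np.deg2rad(theta_deg)
    rot = np.array(
        [[1.0, 0.0, 0.0],
         [0.0, np.cos(th), np.sin(th)],
         [0.0, -np.sin(th), np.cos(th)]]
    )
    return rot @ d0


def measure_point_thickness(
    point: ProbePoint,
    theta_deg: float,
    nasal_surface: trimesh.Trimesh,
    teeth_mesh: trimesh.Trimesh | None = None,
    max_ray_mm: float = 40.0,
) -> ProbeResult:
    """Ray-cast thickness at one probe point and tilt, with root detection.

    A miss (no nasal hit within ``max_ray_mm``) yields NaN thickness, not an
    exception.  ``root_hit`` is true when the teeth mesh is intercepted
    closer than the nasal floor.
    """
    direction = angled_direction(point.surface_normal, theta_deg)
    dist, _ = first_hit_mesh(
        point.position[None], direction[None], nasal_surface, max_dist=max_ray_mm
    )
    thickness = float(dist[0]) if np.isfinite(dist[0]) else float("nan")
    root_hit = False
    root_depth = float("nan")
    if teeth_mesh is not None and len(teeth_mesh.faces) > 0:
        rdist, _ = first_hit_mesh(
            point.position[None], direction[None], teeth_mesh, max_dist=max_ray_mm
        )
        if np.isfinite(rdist[0]) and (not np.isfinite(thickness) or rdist[0] < thickness):
            root_hit = True
            root_depth = float(rdist[0])
    return ProbeResult(
        point_id=point.id,
        angle_deg=float(theta_deg),
        thickness_mm=thickness,
        root_hit=root_hit,
        root_depth_mm=root_depth,
        direction=direction,
    )


@dataclass
class CorridorFit:
    """Does a given implant fit the probed corridor?"""

    fits: bool
    limiting_structure: str  # none | nasal_floor | tooth_root
    min_clearance_mm: float  # shallowest structure across all test rays


def _disc_offsets(direction: np.ndarray, radius: float, n: int) -> np.ndarray:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, direction)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * (np.cos(ang)[:, None] * u + np.sin(ang)[:, None] * v)


def corridor_fit(
    result: ProbeResult,
    implant: ImplantSpec,
    point: ProbePoint | None = None,
    nasal_surface: trimesh.Trimesh | None = None,
    teeth_mesh: trimesh.Trimesh | None = None,
    n_perimeter: int = 8,
) -> CorridorFit:
    """Check an implant cylinder against the probed corridor.

    With geometry supplied, a cylinder of the implant diameter is tested by
    ``n_perimeter`` perimeter rays plus the axial one; otherwise only the
    axial measurement in ``result`` is used.  The implant fits iff its
    length stays short of the nasal floor on every ray and no tooth root is
    intercepted within the length.
    """
    length = implant.length_mm
    nasal_min = result.thickness_mm if result.valid else float("inf")
    root_min = result.root_depth_mm if result.root_hit else float("inf")

    if point is not None and nasal_surface is not None and n_perimeter > 0:
        offsets = _disc_offsets(result.direction, implant.diameter_mm / 2.0, n_perimeter)
        origins = point.position[None] + offsets
        dirs = np.tile(result.direction, (len(origins), 1))
        nd, _ = first_hit_mesh(origins, dirs, nasal_surface, max_dist=40.0)
        if np.isfinite(nd).any():
            nasal_min = min(nasal_min, float(np.nanmin(np.where(np.isfinite(nd), nd, np.inf))))
        if teeth_mesh is not None and len(teeth_mesh.faces) > 0:
            td, _ = first_hit_mesh(origins, dirs, teeth_mesh, max_dist=40.0)
            if np.isfinite(td).any():
                root_min = min(root_min, float(np.min(np.where(np.isfinite(td), td, np.inf))))

    blocked_by_root = root_min < length
    blocked_by_nasal = nasal_min < length
    if blocked_by_root and (root_min <= nasal_min or not blocked_by_nasal):
        limiting = "tooth_root"
    elif blocked_by_nasal:
        limiting = "nasal_floor"
    else:
        limiting = "none"
    return CorridorFit(
        fits=not (blocked_by_root or blocked_by_nasal),
        limiting_structure=limiting,
        min_clearance_mm=float(min(nasal_min, root_min)),
    )


def roots_in_region(
    partition: RoiPartition,
    oral_patch: trimesh.Trimesh,
    teeth_mesh: trimesh.Trimesh | None,
    corridor_depth_mm: float = 8.0,
    lateral_tol_mm: float = 0.5,
) -> dict:
    """Per-ROI flag: do tooth roots extend into the measurement corridor?

    A ROI is flagged when some teeth-mesh vertex lies inside the prism swept
    from the section's oral faces along the 0° (anti-normal) direction to
    ``corridor_depth_mm``.  Evaluated via closest-point queries: a vertex is
    inside a face's sweep iff its offset from the closest surface point is
    (within ``lateral_tol_mm``) purely along that face's anti-normal.
    """
    from .anatomy import ROI_IDS

    out = {roi: False for roi in ROI_IDS}
    if teeth_mesh is None or len(teeth_mesh.vertices) == 0:
        return out
    pts = teeth_mesh.vertices.view(np.ndarray)
    for roi in ROI_IDS:
        faces = partition.faces_for(roi)
        if len(faces) == 0:
            continue
        sub_faces = oral_patch.faces[faces]
        dist, closest, tri = closest_point_on_tris(pts, oral_patch.vertices, sub_faces)
        near = dist <= corridor_depth_mm
        if not near.any():
            continue
        # anti-normal = into the bone (normals point toward the oral cavity)
        into_bone = -oral_patch.face_normals[faces][tri[near]]
        vec = pts[near] - closest[near]
        depth = np.einsum("ij,ij->i", vec, into_bone)
        lateral = np.sqrt(np.maximum(np.einsum("ij,ij->i", vec, vec) - depth**2, 0.0))
        inside = (depth >= 0) & (depth <= corridor_depth_mm) & (lateral <= lateral_tol_mm)
        out[roi] = bool(inside.any())
    return out
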