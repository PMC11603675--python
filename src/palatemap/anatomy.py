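"""Anatomical coordinate frame, ROI partition and paramedian probe points.

Conventions (recorded in every output): millimetres, right-handed frame,
X+ = patient right, Y+ = anterior, Z+ = superior.  The frame is built from
midsagittal and dental landmarks: the Y axis runs from the posterior to the
anterior nasal spine, Z is the occlusal-plane normal orthogonalized against
Y (pointing from the occlusal plane up toward the palate), and X = Y × Z,
its sign checked against the first-molar fissures.

The region of interest is the palatal vault within 10 mm of the midsagittal
suture, cut into three bands per side along tooth levels (first premolar,
second premolar, first molar), giving the six sections 1r/1l … 3r/3l.  The
six probe points sit 3 mm paramedian at the canine–P1 contact, P1 mid and
P1–P2 contact levels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from .errors import GeometryError, PlacementError
from .raycast import first_hit_mesh

__all__ = [
    "ToothBands",
    "LandmarkSet",
    "AnatomicalFrame",
    "RoiPartition",
    "ProbePoint",
    "build_frame",
    "transform_to_frame",
    "select_oral_patch",
    "partition_roi",
    "place_probe_points",
    "ROI_IDS",
    "POINT_IDS",
]

ROI_IDS = ("1r", "1l", "2r", "2l", "3r", "3l")
POINT_IDS = ("1r", "1l", "2r", "2l", "3r", "3l")

#: probe-point index → tooth-level anchor name
POINT_ANCHORS = {1: "canine_p1", 2: "p1_mid", 3: "p1_p2"}


@dataclass
class ToothBands:
    """Tooth-level geometry for one side, as 3D points.

    ``anchors`` holds the probe-point levels (canine–P1 contact, P1 mid,
    P1–P2 contact); ``roi_bounds`` holds the four band boundaries
    anterior→posterior delimiting the P1, P2 and M1 ROI bands.  Points (not
    scalars) so that a rigid frame transform applies uniformly; the
    anatomically meaningful quantity is the Y level after framing.
    """

    anchors: dict
    roi_bounds: np.ndarray  # (4, 3), anterior→posterior

    def __post_init__(self):
        self.anchors = {k: np.asarray(v, dtype=float) for k, v in self.anchors.items()}
        self.roi_bounds = np.asarray(self.roi_bounds, dtype=float)
        if self.roi_bounds.shape != (4, 3):
            raise ValueError("roi_bounds must be four 3D points")

    def anchor_y(self, name: str) -> float:
        return float(self.anchors[name][1])

    def bound_ys(self) -> np.ndarray:
        """Band boundary Y levels, descending (anterior→posterior).

        The ordering is meaningful only in the anatomical frame, so it is
        validated here (at use) rather than at construction: a landmark set
        in an arbitrary scanner pose need not be Y-sorted until framed.
        """
        y = self.roi_bounds[:, 1]
        if not np.all(np.diff(y) < 0):
            raise ValueError(
                "roi band boundaries must be strictly ordered anterior→posterior"
            )
        return y.copy()


@dataclass
class LandmarkSet:
    """Named landmarks: ANS/PNS, molar fissures, occlusal points, tooth bands."""

    ans: np.ndarray
    pns: np.ndarray
    molar_fissure_r: np.ndarray
    molar_fissure_l: np.ndarray
    occlusal_points: np.ndarray  # (k>=3, 3)
    tooth_bands: dict = field(default_factory=dict)  # side -> ToothBands

    def __post_init__(self):
        for name in ("ans", "pns", "molar_fissure_r", "molar_fissure_l"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.occlusal_points = np.atleast_2d(np.asarray(self.occlusal_points, dtype=float))
        if np.allclose(self.ans, self.pns):
            raise GeometryError("ANS and PNS coincide")
        if self.occlusal_points.shape[0] < 3:
            raise GeometryError("need at least 3 occlusal points")

    def transformed(self, frame: "AnatomicalFrame") -> "LandmarkSet":
        f = frame.to_frame
        bands = {
            side: ToothBands(
                anchors={k: f(v) for k, v in tb.anchors.items()},
                roi_bounds=f(tb.roi_bounds),
            )
            for side, tb in self.tooth_bands.items()
        }
        return LandmarkSet(
            ans=f(self.ans),
            pns=f(self.pns),
            molar_fissure_r=f(self.molar_fissure_r),
            molar_fissure_l=f(self.molar_fissure_l),
            occlusal_points=f(self.occlusal_points),
            tooth_bands=bands,
        )

    # ------------------------------------------------------------------ I/O
    def to_json(self, path: str) -> None:
        payload = {
            "convention": "mm, right-handed, X+=right, Y+=anterior, Z+=superior",
            "ANS": self.ans.tolist(),
            "PNS": self.pns.tolist(),
            "molar_fissure_r": self.molar_fissure_r.tolist(),
            "molar_fissure_l": self.molar_fissure_l.tolist(),
            "occlusal_points": self.occlusal_points.tolist(),
            "tooth_bands": {
                side: {
                    "anchors": {k: v.tolist() for k, v in tb.anchors.items()},
                    "roi_bounds": tb.roi_bounds.tolist(),
                }
                for side, tb in self.tooth_bands.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path: str) -> "LandmarkSet":
        with open(path) as fh:
            payload = json.load(fh)
        bands = {
            side: ToothBands(anchors=d["anchors"], roi_bounds=d["roi_bounds"])
            for side, d in payload.get("tooth_bands", {}).items()
        }
        return cls(
            ans=payload["ANS"],
            pns=payload["PNS"],
            molar_fissure_r=payload["molar_fissure_r"],
            molar_fissure_l=payload["molar_fissure_l"],
            occlusal_points=payload["occlusal_points"],
            tooth_bands=bands,
        )


@dataclass
class AnatomicalFrame:
    """Orthonormal anatomical axes (rows X, Y, Z) and origin, in mm."""

    origin: np.ndarray
    axes: np.ndarray  # (3, 3), rows are X, Y, Z unit vectors

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)
        self.axes = np.asarray(self.axes, dtype=float)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-9):
            raise GeometryError("frame axes are not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise GeometryError("frame is left-handed")

    def to_frame(self, points: np.ndarray) -> np.ndarray:
        """World → frame coordinates."""
        return (np.asarray(points, dtype=float) - self.origin) @ self.axes.T

    def to_world(self, points: np.ndarray) -> np.ndarray:
        """Frame → world coordinates."""
        return np.asarray(points, dtype=float) @ self.axes + self.origin

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(origin=np.zeros(3), axes=np.eye(3))


def build_frame(landmarks: LandmarkSet) -> AnatomicalFrame:
    """Anatomical frame from ANS/PNS, the occlusal plane and molar fissures."""
    y = landmarks.ans - landmarks.pns
    ny = np.linalg.norm(y)
    if ny < 1e-9:
        raise GeometryError("ANS and PNS coincide")
    y = y / ny

    occ = landmarks.occlusal_points
    centered = occ - occ.mean(axis=0)
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[-1] > 1e-9 and s[1] < 1e-9:
        raise GeometryError("occlusal points are collinear")
    if occ.shape[0] == 3:
        a, b, c = occ
        normal = np.cross(b - a, c - a)
        if np.linalg.norm(normal) < 1e-9:
            raise GeometryError("occlusal points are collinear")
    else:
        normal = vt[-1]
    normal = normal / np.linalg.norm(normal)
    # superior = from the occlusal plane toward the nasal spines
    midspine = 0.5 * (landmarks.ans + landmarks.pns)
    if np.dot(normal, midspine - occ.mean(axis=0)) < 0:
        normal = -normal

    z = normal - np.dot(normal, y) * y
    nz = np.linalg.norm(z)
    if nz < 1e-9:
        raise GeometryError("occlusal normal is parallel to the ANS–PNS axis")
    z = z / nz
    x = np.cross(y, z)

    fiss = landmarks.molar_fissure_r - landmarks.molar_fissure_l
    if np.dot(fiss, x) < 0:
        raise GeometryError(
            "molar fissures contradict the X axis orientation; check landmark sides"
        )
    origin = 0.5 * (landmarks.ans + landmarks.pns)
    return AnatomicalFrame(origin=origin, axes=np.vstack([x, y, z]))


def transform_to_frame(mesh: trimesh.Trimesh, frame: AnatomicalFrame) -> trimesh.Trimesh:
    """Rigidly transform a mesh into frame coordinates (isometry)."""
    out = trimesh.Trimesh(
        vertices=frame.to_frame(mesh.vertices), faces=mesh.faces.copy(), process=False
    )
    if "face_labels" in mesh.metadata:
        out.metadata["face_labels"] = mesh.metadata["face_labels"].copy()
    return out


def select_oral_patch(mesh: trimesh.Trimesh, z_normal_max: float = -0.2) -> trimesh.Trimesh:
    """Faces whose outward normal faces the oral cavity (normal_z below cutoff).

    Expects a mesh already in the anatomical frame with outward orientation.
    """
    keep = mesh.face_normals[:, 2] < z_normal_max
    patch = trimesh.Trimesh(
        vertices=mesh.vertices.copy(), faces=mesh.faces[keep], process=False
    )
    patch.remove_unreferenced_vertices()
    return patch


@dataclass
class RoiPartition:
    """Per-face ROI labels over the oral patch ('1r'…'3l' or 'none')."""

    face_labels: np.ndarray
    paramedian_limit_mm: float = 10.0
    min_paramedian_mm: float = 0.0

    def faces_for(self, roi_id: str) -> np.ndarray:
        return np.flatnonzero(self.face_labels == roi_id)


def partition_roi(
    oral_patch: trimesh.Trimesh,
    tooth_bands: dict,
    paramedian_limit_mm: float = 10.0,
    min_paramedian_mm: float = 0.0,
) -> RoiPartition:
    """Label oral-patch faces into the six ROI sections.

    A face belongs to section ``k``·side iff its centroid has
    ``min_paramedian ≤ |x| ≤ paramedian_limit`` and its Y lies in band ``k``
    of that side's tooth bands.  Ties at x = 0 go to the right; ties at a
    band boundary go to the anterior band.
    """
    centroids = oral_patch.triangles_center
    labels = np.full(len(centroids), "none", dtype=object)
    x, y = centroids[:, 0], centroids[:, 1]
    absx = np.abs(x)
    in_strip = (absx >= min_paramedian_mm) & (absx <= paramedian_limit_mm)
    for side in ("r", "l"):
        bounds = tooth_bands[side].bound_ys()  # descending
        side_mask = (x >= 0) if side == "r" else (x < 0)
        for k in (1, 2, 3):
            band = (y >= bounds[k]) & (y <= bounds[k - 1])
            sel = in_strip & side_mask & band & (labels == "none")
            labels[sel] = f"{k}{side}"
    if not np.any(labels != "none"):
        warnings.warn("partition_roi: no face fell inside any ROI section")
    return RoiPartition(
        face_labels=labels.astype(str),
        paramedian_limit_mm=paramedian_limit_mm,
        min_paramedian_mm=min_paramedian_mm,
    )


@dataclass
class ProbePoint:
    """A paramedian insertion-simulation point on the oral palatal surface."""

    id: str
    position: np.ndarray
    surface_normal: np.ndarray  # unit, oriented toward the oral cavity
    side: str

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.surface_normal = np.asarray(self.surface_normal, dtype=float)


def place_probe_points(
    oral_patch: trimesh.Trimesh,
    tooth_bands: dict,
    paramedian_offset_mm: float = 3.0,
) -> list:
    """Drop the six probe points onto the oral surface.

    Each point sits at x = ±offset, y = its tooth-level anchor, and is
    projected along −Z onto the oral patch (highest hit).  The surface
    normal is taken from the hit face, oriented toward the oral cavity.
    """
    z_top = float(oral_patch.vertices[:, 2].max()) + 10.0
    points = []
    for idx in (1, 2, 3):
        anchor = POINT_ANCHORS[idx]
        for side in ("r", "l"):
            x = paramedian_offset_mm if side == "r" else -paramedian_offset_mm
            yv = tooth_bands[side].anchor_y(anchor)
            origin = np.array([x, yv, z_top])
            direction = np.array([0.0, 0.0, -1.0])
            dist, tri = first_hit_mesh(origin[None], direction[None], oral_patch)
            if not np.isfinite(dist[0]):
                raise PlacementError(
                    f"probe point {idx}{side}: no oral surface under (x={x}, y={yv})"
                )
            pos = origin + dist[0] * direction
            normal = oral_patch.face_normals[tri[0]].copy()
            if normal[2] > 0:  # must face the oral cavity (downward)
                normal = -normal
            points.append(
                ProbePoint(id=f"{idx}{side}", position=pos, surface_normal=normal, side=side)
            )
    return points
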