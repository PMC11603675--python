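"""Synthetic palatal phantoms with analytic ground truth.

Three families of test objects stand in for patient CBCTs, which are not
publicly available for this kind of study:

* **Voxel phantoms** (:func:`make_slab_phantom`, :func:`make_vault_phantom`)
  — HU-valued grids exercising the full segmentation → surface → thickness
  chain.  The vault is a half-cylindrical bone shell whose wall thickness
  ramps linearly from anterior (≈10 mm) to posterior (≈3.5 mm), the
  dominant anatomical gradient of the palatal process.  Optional incisor
  root analogues (high-HU rods embedded in the anterior corridor, placed so
  that 20°–30° anteriorly tilted rays from the point-1 positions intercept
  them while 0°/10° rays stay clear) and a paramedian canal void emulate
  the structures that limit mini-implant corridors in vivo.

* **Exact mesh pairs** (:func:`make_mesh_pair`) — analytically separated
  oral/nasal surfaces (parallel slab, concentric spherical shell, linear
  gradient wedge) for unit-testing the geometric core to float precision,
  bypassing voxelization entirely.

* **Cohorts** (:func:`sample_cohort`) — long-format measurement tables
  drawn from the same random-intercept linear model the stats layer fits,
  ``y = Xβ + b_patient + ε``, so parameter recovery can be checked end to
  end.  Effect-size defaults are plausible palatal values (mm scale), not
  reproduction targets.

All randomness flows from explicit integer seeds; nothing touches global
RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh

from .anatomy import AnatomicalFrame, LandmarkSet, ToothBands
from .errors import GeometryError, ResolutionError
from .volume import VoxelVolume

__all__ = [
    "DEFAULT_HU_LEVELS",
    "PhantomTruth",
    "CohortSpec",
    "make_slab_phantom",
    "make_vault_phantom",
    "make_mesh_pair",
    "sample_cohort",
]

#: tissue-class HU defaults: air, soft tissue, bone, teeth.  Bone and teeth
#: sit inside the 50–2000 HU hard-tissue working range and are separable by
#: the two-pass thresholding (bone 400–1500, teeth 1500–2000).
DEFAULT_HU_LEVELS = {"air": -1000.0, "soft": 40.0, "bone": 1200.0, "teeth": 1800.0}


@dataclass
class PhantomTruth:
    """Analytic ground truth accompanying a phantom.

    ``thickness_field(points)`` returns the true wall thickness (mm) along
    the inward surface normal at world positions, NaN where undefined (off
    the structure or over a canal void).
    """

    thickness_field: object
    landmark_set: LandmarkSet
    roots_present: dict = field(default_factory=lambda: {"r": False, "l": False})
    canal_present: bool = False
    hu_levels: dict = field(default_factory=lambda: dict(DEFAULT_HU_LEVELS))
    meshes: dict = field(default_factory=dict)  # optional analytic surfaces
    params: dict = field(default_factory=dict)

    def thickness_at(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.asarray(self.thickness_field(pts), dtype=float)


# --------------------------------------------------------------------------
# small mesh builders


def _grid_mesh(positions: np.ndarray, normal_hint: np.ndarray) -> trimesh.Trimesh:
    """Triangulate an (nu, nv, 3) vertex grid; orient faces along the hint."""
    nu, nv, _ = positions.shape
    verts = positions.reshape(-1, 3)
    idx = np.arange(nu * nv).reshape(nu, nv)
    a = idx[:-1, :-1].ravel()
    b = idx[1:, :-1].ravel()
    c = idx[1:, 1:].ravel()
    d = idx[:-1, 1:].ravel()
    faces = np.concatenate([np.stack([a, b, c], 1), np.stack([a, c, d], 1)])
    # orient winding from an explicit cross product; trimesh's invert() can
    # leave stale cached normals on process=False meshes
    n0 = np.cross(verts[faces[0, 1]] - verts[faces[0, 0]],
                  verts[faces[0, 2]] - verts[faces[0, 0]])
    if np.dot(n0, normal_hint) < 0:
        faces = faces[:, ::-1]
    return trimesh.Trimesh(vertices=verts, faces=faces, process=False)


def _plane_mesh(x_range, y_range, z_fn, n=(21, 21), normal_z=-1.0) -> trimesh.Trimesh:
    xs = np.linspace(*x_range, n[0])
    ys = np.linspace(*y_range, n[1])
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    Z = z_fn(X, Y)
    pos = np.stack([X, Y, Z], axis=-1)
    return _grid_mesh(pos, np.array([0.0, 0.0, normal_z]))


def _frustum_mesh(center_xy, z0, z1, r0, r1, sections=48) -> trimesh.Trimesh:
    """Capped vertical frustum (radius r0 at z0 → r1 at z1)."""
    ang = np.linspace(0, 2 * np.pi, sections, endpoint=False)
    ring0 = np.stack(
        [center_xy[0] + r0 * np.cos(ang), center_xy[1] + r0 * np.sin(ang), np.full(sections, z0)], 1
    )
    ring1 = np.stack(
        [center_xy[0] + r1 * np.cos(ang), center_xy[1] + r1 * np.sin(ang), np.full(sections, z1)], 1
    )
    verts = np.vstack([ring0, ring1, [[center_xy[0], center_xy[1], z0]], [[center_xy[0], center_xy[1], z1]]])
    c0, c1 = 2 * sections, 2 * sections + 1
    faces = []
    for i in range(sections):
        j = (i + 1) % sections
        faces += [[i, j, sections + j], [i, sections + j, sections + i]]
        faces += [[c0, j, i], [c1, sections + i, sections + j]]
    return trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)


# --------------------------------------------------------------------------
# slab phantom


def _slab_landmarks(half_x: float, half_y: float, thickness: float) -> LandmarkSet:
    """Synthetic landmark set for the slab (axis-aligned frame by design)."""
    zl = thickness + 5.0
    bands = {}
    for side in ("r", "l"):
        bands[side] = ToothBands(
            anchors={
                "canine_p1": (0.0, 0.5 * half_y, zl),
                "p1_mid": (0.0, 0.3 * half_y, zl),
                "p1_p2": (0.0, 0.1 * half_y, zl),
            },
            roi_bounds=[
                (0.0, 0.6 * half_y, zl),
                (0.0, 0.1 * half_y, zl),
                (0.0, -0.3 * half_y, zl),
                (0.0, -0.7 * half_y, zl),
            ],
        )
    return LandmarkSet(
        ans=(0.0, 0.9 * half_y, zl),
        pns=(0.0, -0.9 * half_y, zl),
        molar_fissure_r=(0.6 * half_x, -0.5 * half_y, -5.0),
        molar_fissure_l=(-0.6 * half_x, -0.5 * half_y, -5.0),
        occlusal_points=[
            (0.0, 0.5 * half_y, -5.0),
            (0.5 * half_x, 0.0, -5.0),
            (-0.5 * half_x, 0.0, -5.0),
            (0.3 * half_x, -0.5 * half_y, -5.0),
        ],
        tooth_bands=bands,
    )


def make_slab_phantom(
    thickness_mm: float,
    lateral_extent_mm: float = 20.0,
    spacing_mm: float = 0.3,
    hu_levels: dict | None = None,
) -> tuple:
    """Flat bone slab of uniform thickness between two air half-spaces.

    The slab spans ``z ∈ [0, thickness]`` over a square lateral extent; the
    oral-facing surface is the lower plane (outward normal −Z).  Truth
    thickness is the constant ``thickness_mm`` over the slab footprint.
    """
    if thickness_mm <= 0:
        raise GeometryError("thickness must be positive")
    if spacing_mm <= 0 or spacing_mm > thickness_mm / 3.0:
        raise ResolutionError(
            f"spacing {spacing_mm} mm cannot resolve a {thickness_mm} mm slab "
            "(needs spacing ≤ thickness/3)"
        )
    hu = dict(DEFAULT_HU_LEVELS, **(hu_levels or {}))
    half = lateral_extent_mm / 2.0
    margin = 3.0
    xs = np.arange(-half - margin, half + margin + spacing_mm / 2, spacing_mm)
    ys = xs.copy()
    zs = np.arange(-margin, thickness_mm + margin + spacing_mm / 2, spacing_mm)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]
    inside = (np.abs(X) <= half) & (np.abs(Y) <= half) & (Z >= 0) & (Z <= thickness_mm)
    values = np.where(inside, hu["bone"], hu["air"]).astype(np.float32)
    vol = VoxelVolume(values=values, spacing=np.full(3, spacing_mm), origin=np.array([xs[0], ys[0], zs[0]]))

    def thickness_field(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        on = (np.abs(pts[:, 0]) <= half) & (np.abs(pts[:, 1]) <= half)
        return np.where(on, thickness_mm, np.nan)

    truth = PhantomTruth(
        thickness_field=thickness_field,
        landmark_set=_slab_landmarks(half, half, thickness_mm),
        hu_levels=hu,
        params={"thickness_mm": thickness_mm, "lateral_extent_mm": lateral_extent_mm,
                "spacing_mm": spacing_mm, "kind": "slab"},
    )
    return vol, truth


# --------------------------------------------------------------------------
# vault phantom

# fixed geometry of the vault family (mm, canonical frame: X right,
# Y anterior, Z superior; cylinder axis along Y at x = 0, z = 0)
_VAULT = {
    "y_range": (-25.0, 20.0),
    "grad_anchors": (-4.0, 9.0),  # posterior / anterior thickness plateaus
    "roi_bounds_y": (12.0, 6.0, 0.0, -8.0),
    "anchors_y": {"canine_p1": 12.0, "p1_mid": 9.0, "p1_p2": 6.0},
    "alpha_max_deg": 75.0,
    # incisor root bundle: mild frustum, one per side
    "incisor_axis": (4.0, 17.0),  # (|x|, y)
    "incisor_z": (14.5, 25.0),
    "incisor_r": (3.0, 2.6),
    # canine root rod
    "canine_axis": (7.5, 11.0),
    "canine_z": (15.0, 20.0),
    "canine_r": (1.8, 1.5),
    # nerve-canal void
    "canal_axis": (2.0, -4.0),
    "canal_r": 1.2,
    "spine_z": 15.0,
    "occlusal_z": -10.0,
}


def _vault_thickness(y: np.ndarray, t_ant: float, t_post: float) -> np.ndarray:
    y0, y1 = _VAULT["grad_anchors"]
    frac = np.clip((np.asarray(y, dtype=float) - y0) / (y1 - y0), 0.0, 1.0)
    return t_post + (t_ant - t_post) * frac


def _vault_landmarks(inner_r: float) -> LandmarkSet:
    zs = _VAULT["spine_z"]
    zo = _VAULT["occlusal_z"]
    b0, b1, b2, b3 = _VAULT["roi_bounds_y"]
    bands = {}
    for side in ("r", "l"):
        bands[side] = ToothBands(
            anchors={k: (0.0, y, zs) for k, y in _VAULT["anchors_y"].items()},
            roi_bounds=[(0.0, b, zs) for b in (b0, b1, b2, b3)],
        )
    return LandmarkSet(
        ans=(0.0, 20.0, zs),
        pns=(0.0, -20.0, zs),
        molar_fissure_r=(12.0, -4.0, zo),
        molar_fissure_l=(-12.0, -4.0, zo),
        occlusal_points=[(0.0, 10.0, zo), (6.0, 0.0, zo), (-6.0, 0.0, zo), (4.0, -8.0, zo)],
        tooth_bands=bands,
    )


def _root_solids(roots_on: bool):
    """Analytic root shapes: list of (axis_xy, z0, z1, r0, r1) per side sign."""
    if not roots_on:
        return []
    solids = []
    for sgn in (+1.0, -1.0):
        ix, iy = _VAULT["incisor_axis"]
        solids.append(((sgn * ix, iy), *_VAULT["incisor_z"], *_VAULT["incisor_r"]))
        cx, cy = _VAULT["canine_axis"]
        solids.append(((sgn * cx, cy), *_VAULT["canine_z"], *_VAULT["canine_r"]))
    return solids


def _inside_frustum(X, Y, Z, axis_xy, z0, z1, r0, r1):
    frac = np.clip((Z - z0) / (z1 - z0), 0.0, 1.0)
    r = r0 + (r1 - r0) * frac
    return ((X - axis_xy[0]) ** 2 + (Y - axis_xy[1]) ** 2 <= r**2) & (Z >= z0) & (Z <= z1)


def _vault_surface_grid(inner_r, radius_fn, n_alpha=161):
    """(alpha, y) parametric grid; y nodes include the gradient kinks."""
    amax = np.deg2rad(_VAULT["alpha_max_deg"])
    alphas = np.linspace(-amax, amax, n_alpha)
    y0, y1 = _VAULT["y_range"]
    k0, k1 = _VAULT["grad_anchors"]
    ys = np.unique(np.concatenate([
        np.linspace(y0, k0, 29), np.linspace(k0, k1, 19), np.linspace(k1, y1, 16)
    ]))
    A, Yg = np.meshgrid(alphas, ys, indexing="ij")
    R = radius_fn(Yg)
    pos = np.stack([R * np.sin(A), Yg, R * np.cos(A)], axis=-1)
    return pos, A


def make_vault_phantom(
    inner_radius_mm: float = 15.0,
    thickness_anterior_mm: float = 10.0,
    thickness_posterior_mm: float = 3.5,
    roots_on: bool = True,
    canal_on: bool = True,
    spacing_mm: float = 0.5,
    hu_levels: dict | None = None,
) -> tuple:
    """Half-cylindrical palatal vault with an anterior→posterior thickness ramp.

    Bone occupies the shell ``inner_r ≤ sqrt(x²+z²) ≤ inner_r + t(y)`` for
    z > 0, where t(y) ramps linearly from the posterior to the anterior
    plateau between the gradient anchors.  The truth thickness along the
    inward surface normal is exactly t(y) (radial rays stay at constant y).
    ``truth.meshes`` carries exact parametric surfaces ("oral", "nasal",
    "teeth") whose oral vertex normals are prescribed exactly radial, for
    voxel-free geometric tests.
    """
    t_ant, t_post = float(thickness_anterior_mm), float(thickness_posterior_mm)
    if not (t_ant >= t_post > 0):
        raise GeometryError("need thickness_anterior ≥ thickness_posterior > 0")
    if inner_radius_mm <= 2 * t_ant / np.pi:
        raise GeometryError("inner radius too small: shell would self-intersect")
    if spacing_mm <= 0 or spacing_mm > t_post / 3.0:
        raise ResolutionError(
            f"spacing {spacing_mm} mm cannot resolve the {t_post} mm posterior wall"
        )
    hu = dict(DEFAULT_HU_LEVELS, **(hu_levels or {}))
    R = float(inner_radius_mm)
    y_lo, y_hi = _VAULT["y_range"]
    r_out_max = R + t_ant

    margin = 2.0
    xs = np.arange(-(r_out_max + margin), r_out_max + margin, spacing_mm)
    ys = np.arange(y_lo - margin, y_hi + margin, spacing_mm)
    zs = np.arange(-3.0, r_out_max + margin, spacing_mm)
    X = xs[:, None, None]
    Y = ys[None, :, None]
    Z = zs[None, None, :]

    r_cyl = np.sqrt(X**2 + Z**2)
    t_of_y = _vault_thickness(Y, t_ant, t_post)
    in_y = (Y >= y_lo) & (Y <= y_hi)
    shell = (Z > 0) & in_y & (r_cyl >= R) & (r_cyl <= R + t_of_y)

    values = np.full(np.broadcast_shapes(X.shape, Y.shape, Z.shape), hu["air"], dtype=np.float32)
    values[np.broadcast_to(Z <= 0, values.shape)] = hu["soft"]
    values[shell] = hu["bone"]

    for axis_xy, z0, z1, r0, r1 in _root_solids(roots_on):
        root = _inside_frustum(X, Y, Z, axis_xy, z0, z1, r0, r1) & shell
        values[root] = hu["teeth"]

    if canal_on:
        cx, cy = _VAULT["canal_axis"]
        canal = ((X - cx) ** 2 + (Y - cy) ** 2 <= _VAULT["canal_r"] ** 2) & shell
        values[canal] = hu["soft"]

    vol = VoxelVolume(
        values=values,
        spacing=np.full(3, spacing_mm),
        origin=np.array([xs[0], ys[0], zs[0]]),
    )

    def thickness_field(pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        x, y = pts[:, 0], pts[:, 1]
        t = _vault_thickness(y, t_ant, t_post)
        t = np.where((y >= y_lo) & (y <= y_hi), t, np.nan)
        amax = np.deg2rad(_VAULT["alpha_max_deg"])
        t = np.where(np.abs(x) <= R * np.sin(amax), t, np.nan)
        if canal_on:
            cx, cy = _VAULT["canal_axis"]
            on_canal = (x - cx) ** 2 + (y - cy) ** 2 <= _VAULT["canal_r"] ** 2
            t = np.where(on_canal, np.nan, t)
        return t

    # exact parametric surfaces sharing the (alpha, y) grid so that a radial
    # ray through an inner vertex meets the outer surface at the matching
    # vertex, at distance exactly t(y)
    inner_pos, A_in = _vault_surface_grid(R, lambda Yg: np.full_like(Yg, R))
    outer_pos, _ = _vault_surface_grid(R, lambda Yg: R + _vault_thickness(Yg, t_ant, t_post))
    oral = _grid_mesh(inner_pos, np.array([0.0, 0.0, -1.0]))
    radial = oral.vertices.copy()
    radial[:, 1] = 0.0
    radial /= np.linalg.norm(radial, axis=1, keepdims=True)
    oral.vertex_normals = -radial  # exact, toward the oral cavity
    nasal = _grid_mesh(outer_pos, np.array([0.0, 0.0, 1.0]))
    teeth_parts = [
        _frustum_mesh(axis_xy, z0, z1, r0, r1)
        for axis_xy, z0, z1, r0, r1 in _root_solids(roots_on)
    ]
    meshes = {"oral": oral, "nasal": nasal}
    if teeth_parts:
        teeth = trimesh.util.concatenate(teeth_parts)
        meshes["teeth"] = teeth

    truth = PhantomTruth(
        thickness_field=thickness_field,
        landmark_set=_vault_landmarks(R),
        roots_present={"r": bool(roots_on), "l": bool(roots_on)},
        canal_present=bool(canal_on),
        hu_levels=hu,
        meshes=meshes,
        params={
            "inner_radius_mm": R,
            "thickness_anterior_mm": t_ant,
            "thickness_posterior_mm": t_post,
            "spacing_mm": spacing_mm,
            "kind": "vault",
            **{k: _VAULT[k] for k in ("y_range", "grad_anchors", "roi_bounds_y", "anchors_y")},
        },
    )
    return vol, truth


# --------------------------------------------------------------------------
# exact mesh pairs


def make_mesh_pair(surface_spec: str, **params) -> tuple:
    """Analytic oral/nasal mesh pairs with exact separation.

    ``surface_spec``:

    - ``"slab"`` (thickness_mm=5, extent_mm=(20, 10)): parallel rectangles;
      the nasal plate is padded laterally so edge rays hit robustly.
    - ``"spherical_shell"`` (inner_r_mm=10, thickness_mm=2): concentric
      icospheres sharing vertex topology; normal-ray thickness is exactly t.
    - ``"gradient_wedge"`` (t_anterior_mm=10, t_posterior_mm=3.5,
      length_mm=30, width_mm=10): flat oral plate under a tilted nasal
      plane; thickness ramps linearly along +Y.
    """
    if surface_spec == "slab":
        t = float(params.get("thickness_mm", 5.0))
        ex, ey = params.get("extent_mm", (20.0, 10.0))
        hx, hy = ex / 2.0, ey / 2.0
        oral = _plane_mesh((-hx, hx), (-hy, hy), lambda X, Y: np.zeros_like(X),
                           n=(21, 11), normal_z=-1.0)
        pad = 2.0
        nasal = _plane_mesh((-hx - pad, hx + pad), (-hy - pad, hy + pad),
                            lambda X, Y: np.full_like(X, t), n=(11, 11), normal_z=1.0)
        field = lambda pts: np.where(
            (np.abs(np.atleast_2d(pts)[:, 0]) <= hx) & (np.abs(np.atleast_2d(pts)[:, 1]) <= hy),
            t, np.nan)
        truth = PhantomTruth(
            thickness_field=field,
            landmark_set=_slab_landmarks(hx, hy, t),
            params={"kind": "slab", "thickness_mm": t, "extent_mm": (ex, ey),
                    "AA_mm2": ex * ey, "MD_mm": t, "Vol_mm3": ex * ey * t},
        )
        return oral, nasal, truth

    if surface_spec == "spherical_shell":
        r = float(params.get("inner_r_mm", 10.0))
        t = float(params.get("thickness_mm", 2.0))
        inner = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
        # flip winding so "outward" faces the enclosed cavity (the oral side)
        oral = trimesh.Trimesh(
            vertices=inner.vertices * r, faces=inner.faces[:, ::-1], process=False
        )
        unit = oral.vertices / np.linalg.norm(oral.vertices, axis=1, keepdims=True)
        oral.vertex_normals = -unit  # exact inward normals
        nasal = trimesh.Trimesh(
            vertices=inner.vertices * (r + t), faces=inner.faces, process=False
        )
        field = lambda pts: np.full(np.atleast_2d(pts).shape[0], t)
        truth = PhantomTruth(
            thickness_field=field,
            landmark_set=_slab_landmarks(r, r, t),
            params={"kind": "spherical_shell", "inner_r_mm": r, "thickness_mm": t},
        )
        return oral, nasal, truth

    if surface_spec == "gradient_wedge":
        t0 = float(params.get("t_anterior_mm", 10.0))
        t1 = float(params.get("t_posterior_mm", 3.5))
        length = float(params.get("length_mm", 30.0))
        width = float(params.get("width_mm", 10.0))
        hw = width / 2.0
        oral = _plane_mesh((-hw, hw), (0.0, length), lambda X, Y: np.zeros_like(X),
                           n=(11, 31), normal_z=-1.0)

        def ramp(Y):
            return t0 + (t1 - t0) * Y / length

        pad = 2.0
        nasal = _plane_mesh((-hw - pad, hw + pad), (0.0 - pad, length + pad),
                            lambda X, Y: ramp(Y), n=(11, 33), normal_z=1.0)
        field = lambda pts: np.where(
            (np.abs(np.atleast_2d(pts)[:, 0]) <= hw)
            & (np.atleast_2d(pts)[:, 1] >= 0)
            & (np.atleast_2d(pts)[:, 1] <= length),
            ramp(np.atleast_2d(pts)[:, 1]), np.nan)
        truth = PhantomTruth(
            thickness_field=field,
            landmark_set=_slab_landmarks(hw, length / 2.0, (t0 + t1) / 2.0),
            params={"kind": "gradient_wedge", "t_anterior_mm": t0, "t_posterior_mm": t1,
                    "length_mm": length, "width_mm": width,
                    "MD_mm": (t0 + t1) / 2.0, "AA_mm2": width * length},
        )
        return oral, nasal, truth

    raise ValueError(f"unknown surface_spec {surface_spec!r}")


# --------------------------------------------------------------------------
# cohort simulation

#: plausible fixed-effect defaults for the mean-thickness (MD, mm) design:
#: intercept at the anterior reference, small age effects, a sex deficit of
#: about −1.1 mm, a tooth-intrusion offset, a negligible side effect and the
#: strong anterior→posterior ROI drop.
MD_ROI_EFFECTS = {
    "intercept": 9.94,
    "age_13_16": 0.52,
    "age_17_20": 0.51,
    "sex_female": -1.12,
    "teeth": 0.73,
    "side_r": 0.04,
    "roi_2": -4.75,
    "roi_3": -6.94,
}

#: angulated point-1 design (anterior corridor: thickness falls with angle)
ANGLE_POINT1_EFFECTS = {
    "intercept": 13.05,
    "age_13_16": 1.60,
    "age_17_20": 1.08,
    "sex_female": -1.81,
    "teeth": -2.15,
    "side_r": -0.04,
    "angle_10": -0.53,
    "angle_20": -1.75,
    "angle_30": -3.04,
}

#: angulated points-2/3 design (posterior slope: thickness rises with angle)
ANGLE_POINT23_EFFECTS = {
    "intercept": 6.67,
    "age_13_16": 1.95,
    "age_17_20": 2.26,
    "sex_female": -1.94,
    "teeth": 2.62,
    "side_r": 0.02,
    "angle_10": 0.31,
    "angle_20": 0.91,
    "angle_30": 1.60,
    "point_3": -3.01,
}

AGE_GROUPS = ("4-12", "13-16", "17-20")
AGE_RANGES = {"4-12": (4, 12), "13-16": (13, 16), "17-20": (17, 20)}


@dataclass
class CohortSpec:
    """Forward-simulation spec for a measurement cohort.

    Defaults mirror a 184-patient cohort: 62/184 female, age groups
    33/42/109, tooth intrusion in 57% of palates, and mm-scale fixed
    effects; ``sigma_b`` and ``sigma_e`` are the between-patient and
    residual SDs of the random-intercept model.
    """

    n_patients: int = 184
    sex_ratio: float = 62.0 / 184.0  # fraction female
    age_group_probs: tuple = (33.0 / 184.0, 42.0 / 184.0, 109.0 / 184.0)
    teeth_prob: float = 105.0 / 184.0
    fixed_effects: dict | None = None
    sigma_b: float = 1.5
    sigma_e: float = 1.0
    design: str = "roi"  # "roi" | "angle_point1" | "angle_point23"
    unit: str = "mm"
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if not np.isclose(sum(self.age_group_probs), 1.0):
            raise ValueError("age_group_probs must sum to 1")
        if self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("sigma_b and sigma_e must be non-negative")
        if self.fixed_effects is None:
            self.fixed_effects = {
                "roi": MD_ROI_EFFECTS,
                "angle_point1": ANGLE_POINT1_EFFECTS,
                "angle_point23": ANGLE_POINT23_EFFECTS,
            }[self.design].copy()


def _design_rows(design: str):
    if design == "roi":
        return [("r", roi, None, None) for roi in (1, 2, 3)] + [
            ("l", roi, None, None) for roi in (1, 2, 3)
        ]
    if design == "angle_point1":
        return [(s, None, 1, a) for s in ("r", "l") for a in (0, 10, 20, 30)]
    if design == "angle_point23":
        return [
            (s, None, p, a) for s in ("r", "l") for p in (2, 3) for a in (0, 10, 20, 30)
        ]
    raise ValueError(f"unknown design {design!r}")


def sample_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Simulate a long-format measurement table from the mixed model.

    Response = fixed effects + per-patient random intercept
    ``b ~ N(0, sigma_b²)`` + residual ``ε ~ N(0, sigma_e²)``.  Identical
    seeds give bitwise-identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    eff = spec.fixed_effects
    rows = []
    conditions = _design_rows(spec.design)
    for pid in range(spec.n_patients):
        sex = "female" if rng.random() < spec.sex_ratio else "male"
        age_group = AGE_GROUPS[rng.choice(3, p=np.asarray(spec.age_group_probs))]
        lo, hi = AGE_RANGES[age_group]
        age_years = int(rng.integers(lo, hi + 1))
        teeth = bool(rng.random() < spec.teeth_prob)
        b = rng.normal(0.0, spec.sigma_b) if spec.sigma_b > 0 else 0.0
        for side, roi, point, angle in conditions:
            mu = eff.get("intercept", 0.0) + b
            if sex == "female":
                mu += eff.get("sex_female", 0.0)
            if age_group == "13-16":
                mu += eff.get("age_13_16", 0.0)
            elif age_group == "17-20":
                mu += eff.get("age_17_20", 0.0)
            if teeth:
                mu += eff.get("teeth", 0.0)
            if side == "r":
                mu += eff.get("side_r", 0.0)
            if roi is not None and roi > 1:
                mu += eff.get(f"roi_{roi}", 0.0)
            if angle is not None and angle > 0:
                mu += eff.get(f"angle_{angle}", 0.0)
            if point is not None and point == 3:
                mu += eff.get("point_3", 0.0)
            y = mu + (rng.normal(0.0, spec.sigma_e) if spec.sigma_e > 0 else 0.0)
            rows.append(
                {
                    "patient_id": f"P{pid:04d}",
                    "sex": sex,
                    "age_group": age_group,
                    "age_years": age_years,
                    "side": side,
                    "roi": roi if roi is not None else "none",
                    "point": point if point is not None else "none",
                    "angle_deg": angle if angle is not None else "none",
                    "teeth": teeth,
                    "response": y,
                    "unit": spec.unit,
                }
            )
    return pd.DataFrame(rows)
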