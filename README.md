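# palatemap

3D cartography of palatal bone thickness for orthodontic mini-implant
planning, built to run end to end on synthetic CBCT-like phantoms with
analytic ground truth.

Palatal mini-implants (temporary anchorage devices, ~2 mm × 7–11 mm) need
enough bone between the oral surface of the hard palate and the floor of
the nasal cavity. Planning asks three questions this package answers
quantitatively from a 3D volume:

1. **Where is the bone?** Per-vertex thickness maps over the palatal vault,
   aggregated over six paramedian regions of interest (ROI 1–3, right/left)
   as analysis area *AA* (mm²), area-weighted mean thickness
   *MD* (mm) and integrated-distance volume *Vol = AA · MD* (mm³).
2. **At what angle can an implant go in?** Ray-cast thickness at six probe
   points 3 mm paramedian of the midpalatal suture, tilted 0°/10°/20°/30°
   anteriorly relative to the palatal surface, with tooth-root
   interceptions flagged separately from nasal-floor distance.
3. **What drives the variation?** A cohort statistics layer: descriptive
   tables (two explicit 1.96-interval conventions), random-intercept linear
   mixed models `y = Xβ + b_patient + ε` fitted by profiled REML,
   pseudoreplication-guarded rank tests, and smoothing-spline age trends.

Because raw patient CBCTs for this kind of study are not shared, the
`phantom` module is first-class: voxel phantoms (flat slab; a
half-cylindrical palatal vault whose wall ramps ≈10 mm anterior → ≈3.5 mm
posterior, with optional incisor-root analogues and a nerve-canal void),
exact analytic mesh pairs, and forward-simulated cohorts — all with known
truth, so every stage of the chain is testable offline.

## Pipeline

```
volume (NRRD, HU) ──► two-pass threshold (bone 400–1500, teeth 1500–2000)
                  ──► marching-cubes surfaces (mm), merged bone+teeth
landmarks (JSON)  ──► anatomical frame: Y = PNS→ANS, Z ⊥ occlusal plane, X = Y×Z
                  ──► oral patch, 6 ROI sections (|x| ≤ 10 mm, tooth-level bands)
                  ──► distance map (anti-normal ray cast) ──► AA / MD / Vol + PLY
                  ──► angulated probes, corridor fit, root conflicts
cohort table      ──► descriptives, REML mixed model, rank tests, age splines
```

Ray–triangle intersection (Möller–Trumbore) and point–triangle projection
are implemented in vectorized numpy in `palatemap.raycast`; they are the
measurement core of the method.

## Worked example

Probe the anterior insertion point (1r) of the root-bearing vault phantom
at increasing anterior tilt, then summarize the six ROI sections:

```python
from palatemap import anatomy, phantom, probe, thickness

_, truth = phantom.make_vault_phantom(spacing_mm=1.0)
oral, nasal, teeth = (truth.meshes[k] for k in ("oral", "nasal", "teeth"))
bands = truth.landmark_set.tooth_bands

points = {p.id: p for p in anatomy.place_probe_points(oral, bands)}
for theta in (0, 10, 20, 30):
    r = probe.measure_point_thickness(points["1r"], theta, nasal, teeth)
    root = f"root at {r.root_depth_mm:.2f} mm" if r.root_hit else "no root"
    print(f"point 1r @ {theta:2d}°: bone {r.thickness_mm:5.2f} mm, {root}, "
          f"usable {r.usable_depth_mm:5.2f} mm")

part = anatomy.partition_roi(oral, bands)
dmap = thickness.compute_distance_map(oral, nasal)
for s in thickness.summarize_roi(part, dmap):
    print(f"ROI {s.roi}: AA={s.AA:6.1f} mm²  MD={s.MD:5.2f} mm  Vol={s.Vol:7.1f} mm³")
```

Output:

```
point 1r @  0°: bone 10.00 mm, no root, usable 10.00 mm
point 1r @ 10°: bone 10.15 mm, no root, usable 10.15 mm
point 1r @ 20°: bone 10.61 mm, root at 6.79 mm, usable  6.79 mm
point 1r @ 30°: bone 11.47 mm, root at 4.41 mm, usable  4.41 mm
ROI 1r: AA=  63.6 mm²  MD= 9.64 mm  Vol=  613.1 mm³
ROI 1l: AA=  63.6 mm²  MD= 9.64 mm  Vol=  613.1 mm³
ROI 2r: AA=  67.1 mm²  MD= 7.02 mm  Vol=  470.9 mm³
ROI 2l: AA=  67.0 mm²  MD= 7.02 mm  Vol=  470.3 mm³
ROI 3r: AA=  88.4 mm²  MD= 3.99 mm  Vol=  352.7 mm³
ROI 3l: AA=  88.4 mm²  MD= 3.99 mm  Vol=  352.8 mm³
```

Reading it: at 0°–10° the anterior point has ~10 mm of bone and no root in
the corridor; tilting to 20°–30° keeps gaining nasal-floor distance but
runs into the incisor-root analogue, collapsing the usable depth to
4.4 mm — while mean thickness falls anterior → posterior (9.6 → 4.0 mm)
across the ROI sections, mirroring the anatomy the phantom encodes.

There is also a CLI: `palate run --seed 3 --out-dir out/` runs the full
phantom → segmentation → maps → probes → statistics chain and writes STL /
PLY / CSV / JSON reports; see `palate --help` for the stage-wise
subcommands (`phantom`, `segment`, `frame`, `stats`, …).

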