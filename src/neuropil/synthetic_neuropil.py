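"""Parametric synthetic neuropil scenes with exact ground truth.

Stand-in for an EM-reconstructed tissue block: dendritic spines (spherical
head + cylindrical neck, built as closed surfaces of revolution) carrying PSD
caps, spherical/ellipsoidal boutons, shaft cylinders, and astrocytic material
as partial spherical shells ("wraps" at a controlled offset and solid-angle
coverage around a target) or as branchlet tubes with attached leaflet sheets.
Every generated object records analytic ground truth (volumes, offsets,
classes, attachment spacings), so each analysis stage can be validated by
parameter recovery.  All randomness flows from a single seed; the same seed
reproduces the scene exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm

from .mesh_core import NeuropilScene, SceneObject, TriMesh


# ----------------------------------------------------------------------
# meshing helpers
def _rotation_to(axis):
    """Rotation matrix sending +z to the given direction."""
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx * (1.0 / (1.0 + c))


def revolve_profile(profile, n_theta=48, label="", max_seg=None):
    """Closed mesh of revolution about the z axis.

    ``profile`` is a polyline of (r, z) pairs traversed so the enclosed solid
    lies to its left; the first and last points must sit on the axis (r = 0).
    Rings of ``n_theta`` vertices are generated for interior points and
    connected by triangle strips; axis endpoints become pole fans.  Profile
    segments longer than ``max_seg`` (default: the ring arc length) are
    resampled so no triangle is much longer than the azimuthal spacing.
    """
    profile = np.asarray(profile, float)
    if abs(profile[0, 0]) > 1e-12 or abs(profile[-1, 0]) > 1e-12:
        raise ValueError("profile must start and end on the axis (r = 0)")
    if max_seg is None:
        max_seg = 2 * np.pi * profile[:, 0].max() / n_theta
    pieces = [profile[:1]]
    for a, b in zip(profile[:-1], profile[1:]):
        seg = np.linalg.norm(b - a)
        n_sub = max(int(np.ceil(seg / max_seg)), 1)
        t = np.linspace(0.0, 1.0, n_sub + 1)[1:, None]
        pieces.append(a[None] + (b - a)[None] * t)
    profile = np.concatenate(pieces)
    theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
    cos, sin = np.cos(theta), np.sin(theta)
    verts = [np.array([[0.0, 0.0, profile[0, 1]]])]
    ring_start = [None]  # vertex offset of each profile row (None for poles)
    for r, z in profile[1:-1]:
        ring_start.append(len(np.concatenate(verts)))
        verts.append(np.stack([r * cos, r * sin, np.full(n_theta, z)], axis=1))
    top = len(np.concatenate(verts))
    verts.append(np.array([[0.0, 0.0, profile[-1, 1]]]))
    V = np.concatenate(verts)

    faces = []
    idx = np.arange(n_theta)
    nxt = (idx + 1) % n_theta
    # bottom pole fan
    s0 = ring_start[1]
    faces.append(np.stack([np.zeros(n_theta, int), s0 + nxt, s0 + idx], axis=1))
    # strips between consecutive rings
    for i in range(1, len(profile) - 2):
        a, b = ring_start[i], ring_start[i + 1]
        faces.append(np.stack([a + idx, a + nxt, b + idx], axis=1))
        faces.append(np.stack([a + nxt, b + nxt, b + idx], axis=1))
    # top pole fan
    sl = ring_start[-1]
    faces.append(np.stack([np.full(n_theta, top), sl + idx, sl + nxt], axis=1))
    return TriMesh(V, np.concatenate(faces), label=label)


# ----------------------------------------------------------------------
# analytic occupancy for primitive shapes (fast exact rasterisation)
def primitive_contains(prim: dict, points):
    points = np.asarray(points, float)
    kind = prim["kind"]
    if kind == "sphere":
        return np.linalg.norm(points - prim["center"], axis=1) <= prim["radius"]
    if kind == "shell":
        d = points - prim["center"]
        r = np.linalg.norm(d, axis=1)
        ok = (r >= prim["r_in"]) & (r <= prim["r_out"])
        if prim.get("cos_theta_min") is not None:
            with np.errstate(invalid="ignore"):
                cos = d @ prim["axis"] / np.where(r == 0, 1.0, r)
            ok &= cos >= prim["cos_theta_min"]
        return ok
    if kind == "cylinder":
        d = points - prim["center"]
        z = d @ prim["axis"]
        rad = np.linalg.norm(d - z[:, None] * prim["axis"], axis=1)
        return (np.abs(z) <= prim["half_len"]) & (rad <= prim["radius"])
    if kind == "box":
        local = (points - prim["center"]) @ prim["rotation"]
        return np.all(np.abs(local) <= np.asarray(prim["extents"]) / 2.0, axis=1)
    raise ValueError(f"unknown primitive kind {kind!r}")


# ----------------------------------------------------------------------
def make_spine(head_radius, neck_len=0.4, neck_radius=0.05,
               psd_cap_angle=np.deg2rad(40.0), n_theta=48, n_arc=40,
               center=None, axis=(0, 0, 1)):
    """Spine (sphere head on cylinder neck, one closed mesh) plus PSD cap.

    Returns ``(spine, psd, truth)``; the PSD is the open spherical-cap
    sub-surface opposite the neck.  Truth records the analytic union volume,
    head centre/radius, PSD centre and edge radius.
    """
    R, a, L = float(head_radius), float(neck_radius), float(neck_len)
    if a >= R:
        raise ValueError("neck_radius must be smaller than head_radius")
    z0 = L + np.sqrt(R * R - a * a)  # head centre height
    # profile: base disc -> neck wall -> head arc -> top pole
    ang_j = np.arcsin(a / R)  # polar angle (from -z of head) of the junction
    arc_t = np.linspace(np.pi - ang_j, 0.0, n_arc)  # polar angle from +z
    arc = np.stack([R * np.sin(arc_t), z0 + R * np.cos(arc_t)], axis=1)
    profile = np.concatenate([[[0.0, 0.0], [a, 0.0], [a, L]], arc])
    spine = revolve_profile(profile, n_theta=n_theta, label="spine")

    # PSD: head faces within psd_cap_angle of the +z pole
    tri_cent = spine.vertices[spine.faces].mean(axis=1)
    d = tri_cent - np.array([0, 0, z0])
    r = np.linalg.norm(d, axis=1)
    with np.errstate(invalid="ignore"):
        cosang = d[:, 2] / np.where(r == 0, 1.0, r)
    on_head = np.abs(r - R) < 0.02 * R
    cap = on_head & (cosang >= np.cos(psd_cap_angle))
    psd = TriMesh(spine.vertices, spine.faces[cap], label="psd", clean=True)

    h = L - (z0 - R)  # height of the sphere cap cut away by the neck region
    vol = np.pi * a * a * L + 4.0 / 3.0 * np.pi * R ** 3 \
        - np.pi * h * h * (R - h / 3.0)
    truth = {"head_radius": R, "head_center": np.array([0.0, 0.0, z0]),
             "neck_radius": a, "neck_len": L,
             "psd_center": np.array([0.0, 0.0,
                                     z0 + R * (1 + np.cos(psd_cap_angle)) / 2]),
             "psd_cap_angle": float(psd_cap_angle),
             "axis": np.array([0.0, 0.0, 1.0]), "base": np.zeros(3),
             "volume": float(vol)}
    if center is not None or not np.allclose(axis, (0, 0, 1)):
        Rm = _rotation_to(axis)
        shift = np.zeros(3) if center is None else np.asarray(center, float)
        for m in (spine, psd):
            m.vertices = m.vertices @ Rm.T + shift
            m._sd = None; m._trimesh = None
        for k in ("head_center", "psd_center", "axis", "base"):
            truth[k] = Rm @ truth[k] + (shift if k != "axis" else 0)
    return spine, psd, truth


def make_sphere(radius, center=(0, 0, 0), subdivisions=3, label="sphere"):
    s = _tm.creation.icosphere(subdivisions=subdivisions, radius=radius)
    m = TriMesh(s.vertices + np.asarray(center, float), s.faces, label=label)
    return m, {"radius": float(radius), "center": np.asarray(center, float),
               "primitive": {"kind": "sphere", "center": np.asarray(center, float),
                             "radius": float(radius)}}


def wrap_astro(target_center, target_radius, offset, thickness, coverage=1.0,
               cap_axis=(0, 0, -1), n_theta=48, n_arc=36, seed=None,
               label="astro_wrap"):
    """Partial spherical astrocytic shell around a spherical target.

    The shell occupies surface distances ``[offset, offset + thickness]`` from
    the target membrane and a polar cap of solid-angle fraction ``coverage``
    centred on ``cap_axis`` (random direction when a ``seed`` is given).
    Returns ``(mesh, truth)``; the true VF profile is available in closed form.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage fraction must be in (0, 1]")
    if offset < 0 or thickness <= 0:
        raise ValueError("offset must be >= 0 and thickness > 0")
    c = np.asarray(target_center, float)
    r_in = target_radius + offset
    r_out = r_in + thickness
    if seed is not None:
        rng = np.random.default_rng(seed)
        v = rng.normal(size=3)
        cap_axis = v / np.linalg.norm(v)
    cap_axis = np.asarray(cap_axis, float)
    cap_axis = cap_axis / np.linalg.norm(cap_axis)

    if coverage >= 1.0:
        outer = _tm.creation.icosphere(subdivisions=3, radius=r_out)
        inner = _tm.creation.icosphere(subdivisions=3, radius=r_in)
        verts = np.concatenate([outer.vertices, inner.vertices]) + c
        faces = np.concatenate([outer.faces,
                                inner.faces[:, ::-1] + len(outer.vertices)])
        mesh = TriMesh(verts, faces, label=label, clean=False)
    else:
        theta_f = np.arccos(1.0 - 2.0 * coverage)
        t_in = np.linspace(0.0, theta_f, n_arc)
        inner_arc = np.stack([r_in * np.sin(t_in), r_in * np.cos(t_in)], axis=1)
        outer_arc = np.stack([r_out * np.sin(t_in[::-1]),
                              r_out * np.cos(t_in[::-1])], axis=1)
        profile = np.concatenate([inner_arc, outer_arc])
        mesh = revolve_profile(profile, n_theta=n_theta, label=label)
        Rm = _rotation_to(cap_axis)
        mesh.vertices = mesh.vertices @ Rm.T + c
        mesh._sd = None; mesh._trimesh = None
    cos_min = None if coverage >= 1.0 else float(1.0 - 2.0 * coverage)
    truth = {"offset": float(offset), "thickness": float(thickness),
             "coverage": float(coverage), "target_radius": float(target_radius),
             "target_center": c, "cap_axis": cap_axis,
             "primitive": {"kind": "shell", "center": c, "r_in": float(r_in),
                           "r_out": float(r_out), "axis": cap_axis,
                           "cos_theta_min": cos_min}}
    return mesh, truth


def make_tube(radius, length, center=(0, 0, 0), axis=(1, 0, 0), sections=48,
              max_edge=0.15, label="branchlet"):
    """Closed cylinder (astrocytic branchlet or dendritic shaft).

    Faces are subdivided to ``max_edge`` so that surface-sampling stages see
    a tessellation finer than the structures they probe.
    """
    cyl = _tm.creation.cylinder(radius=radius, height=length, sections=sections)
    v, f = _tm.remesh.subdivide_to_size(cyl.vertices, cyl.faces,
                                        max_edge=max_edge)
    cyl = _tm.Trimesh(v, f, process=False)
    Rm = _rotation_to(axis)
    verts = cyl.vertices @ Rm.T + np.asarray(center, float)
    mesh = TriMesh(verts, cyl.faces, label=label)
    truth = {"radius": float(radius), "length": float(length),
             "center": np.asarray(center, float),
             "axis": Rm @ np.array([0.0, 0.0, 1.0]),
             "primitive": {"kind": "cylinder", "center": np.asarray(center, float),
                           "axis": Rm @ np.array([0.0, 0.0, 1.0]),
                           "radius": float(radius), "half_len": length / 2.0}}
    return mesh, truth


def make_sheet(extents, center, rotation=np.eye(3), max_edge=0.08,
               label="leaflet"):
    """Thin box (astrocytic leaflet), subdivided to ``max_edge``."""
    box = _tm.creation.box(extents=extents)
    v, f = _tm.remesh.subdivide_to_size(box.vertices, box.faces,
                                        max_edge=max_edge)
    box = _tm.Trimesh(v, f, process=False)
    verts = box.vertices @ np.asarray(rotation).T + np.asarray(center, float)
    mesh = TriMesh(verts, box.faces, label=label)
    truth = {"extents": np.asarray(extents, float),
             "center": np.asarray(center, float),
             "primitive": {"kind": "box", "center": np.asarray(center, float),
                           "rotation": np.asarray(rotation, float),
                           "extents": np.asarray(extents, float)}}
    return mesh, truth


# ----------------------------------------------------------------------
@dataclass
class AstroArbor:
    """Branchlet tube(s) with attached leaflet sheets and per-face truth."""
    composite: TriMesh
    parts: list            # list of (TriMesh, class_name, truth)
    face_class: np.ndarray  # 0 = branchlet, 1 = leaflet, per composite face
    attachment_s: np.ndarray  # leaflet attachment coordinates along the tube
    nn_distances: np.ndarray  # truth nearest-neighbour spacing per leaflet

    def contains(self, points):
        out = np.zeros(len(points), bool)
        for mesh, _, truth in self.parts:
            if "primitive" in truth:
                out |= primitive_contains(truth["primitive"], points)
            else:
                out |= mesh.contains(points)
        return out


def make_astro_arbor(tube_radius=0.25, tube_length=4.0, sheet_extents=(0.04, 0.5, 0.5),
                     spacings=None, n_sheets=5, spacing=0.25, seed=0,
                     center=(0, 0, 0), axis=(1, 0, 0), min_gap=0.06,
                     angles=None):
    """One branchlet tube along +x with leaflet sheets attached at intervals.

    ``spacings`` (gaps between successive attachment points, μm) overrides the
    regular ``n_sheets`` × ``spacing`` layout.  Sheets closer than ``min_gap``
    are rejected and resampled (or an error raised for explicit spacings).
    Sheets stand radially off the tube surface, rotated around the tube axis
    at seeded random angles; each is embedded 0.02 μm into the tube so the
    arbor is a connected solid.
    """
    rng = np.random.default_rng(seed)
    if spacings is None:
        spacings = np.full(max(n_sheets - 1, 0), spacing)
    spacings = np.asarray(spacings, float)
    if (spacings < min_gap).any():
        raise ValueError("sheet spacings below the minimum gap")
    if n_sheets == 0 and len(spacings) == 0:
        s = np.empty(0)
    else:
        s = np.concatenate([[0.0], np.cumsum(spacings)])
    span = (s[-1] - s[0]) if len(s) else 0.0
    if span > tube_length - 2 * max(np.asarray(sheet_extents)[0], 0.1):
        raise ValueError("sheets do not fit on the tube")
    s = s - span / 2.0  # centre the run of sheets on the tube

    center = np.asarray(center, float)
    tube, tube_truth = make_tube(tube_radius, tube_length, center=(0, 0, 0),
                                 axis=(1, 0, 0))
    parts = [(tube, "branchlet", tube_truth)]
    embed = 0.02
    h = np.asarray(sheet_extents, float)  # (thickness_x, radial, lateral)
    if angles is not None:
        angles = np.broadcast_to(np.asarray(angles, float), (len(s),))
    for j, si in enumerate(s):
        phi = rng.uniform(0, 2 * np.pi) if angles is None else angles[j]
        radial = np.array([0.0, np.cos(phi), np.sin(phi)])
        lateral = np.cross([1.0, 0.0, 0.0], radial)
        rot = np.stack([np.array([1.0, 0.0, 0.0]), radial, lateral], axis=1)
        extents_local = np.array([h[0], h[1], h[2]])
        c_sheet = np.array([si, 0.0, 0.0]) \
            + radial * (tube_radius - embed + h[1] / 2.0)
        sheet, sheet_truth = make_sheet(extents_local, c_sheet, rotation=rot)
        parts.append((sheet, "leaflet", sheet_truth))

    # orient the arbor along the requested axis and move it to the centre:
    # _rotation_to maps +z to axis, composed with the +x -> +z rotation
    x_to_z = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
    Rm = _rotation_to(np.asarray(axis, float)) @ x_to_z
    for mesh, _, truth in parts:
        mesh.vertices = mesh.vertices @ Rm.T + center
        mesh._sd = None; mesh._trimesh = None
        prim = truth.get("primitive")
        if prim:
            prim["center"] = Rm @ prim["center"] + center
            if "axis" in prim:
                prim["axis"] = Rm @ prim["axis"]
            if "rotation" in prim:
                prim["rotation"] = Rm @ prim["rotation"]
        for key in ("center", "axis"):
            if key in truth and not np.isscalar(truth[key]):
                truth[key] = Rm @ np.asarray(truth[key], float) \
                    + (center if key == "center" else 0)

    meshes = [p[0] for p in parts]
    verts = np.concatenate([m.vertices for m in meshes])
    offs = np.cumsum([0] + [len(m.vertices) for m in meshes[:-1]])
    faces = np.concatenate([m.faces + o for m, o in zip(meshes, offs)])
    face_class = np.concatenate([
        np.full(len(m.faces), 0 if cls == "branchlet" else 1, np.int8)
        for m, cls, _ in parts])
    composite = TriMesh(verts, faces, label="astro_arbor", clean=False)

    if len(s) > 1:
        gaps = np.diff(s)
        nn = np.array([gaps[0]] + [min(gaps[i - 1], gaps[i])
                                   for i in range(1, len(s) - 1)] + [gaps[-1]])
    else:
        nn = np.full(len(s), np.nan)
    return AstroArbor(composite, parts, face_class, s, nn)


# ----------------------------------------------------------------------
def rasterize(parts, bounds, voxel, min_feature=None, chunk=200_000):
    """Voxelise labelled solids into binary stacks, one per class.

    ``parts`` is a list of (mesh, class_name, truth) — analytic primitives in
    the truth dict are used when available, otherwise the mesh inside test.
    Returns ``(stacks, voxel)`` where each stack is a (z, y, x) uint8 array of
    occupancy at voxel centres.
    """
    if min_feature is not None and voxel > min_feature / 2.0:
        raise ValueError(
            f"voxel size {voxel} too coarse for minimum feature {min_feature}")
    bounds = np.asarray(bounds, float)
    n = np.maximum(np.round((bounds[1] - bounds[0]) / voxel).astype(int), 1)
    axes = [bounds[0][i] + voxel * (np.arange(n[i]) + 0.5) for i in range(3)]
    zz, yy, xx = np.meshgrid(axes[2], axes[1], axes[0], indexing="ij")
    pts = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=1)
    stacks = {}
    for mesh, cls, truth in parts:
        occ = stacks.setdefault(cls, np.zeros(len(pts), bool))
        if truth and "primitive" in truth:
            occ |= primitive_contains(truth["primitive"], pts)
        else:
            for lo in range(0, len(pts), chunk):
                occ[lo:lo + chunk] |= mesh.contains(pts[lo:lo + chunk])
    shape = (n[2], n[1], n[0])
    return ({cls: occ.reshape(shape).astype(np.uint8)
             for cls, occ in stacks.items()}, voxel)


# ----------------------------------------------------------------------
@dataclass
class SceneSpec:
    """Parameters of a synthetic neuropil block (defaults: desk-scale block).

    Head radii follow the uniform 0.05–0.4 μm range of hippocampal spines;
    astrocytic wraps sit at ``wrap_offset`` from their target membrane.
    """
    block_size: float = 3.0
    n_spines: int = 4
    head_radius_range: tuple = (0.05, 0.4)
    neck_len: float = 0.3
    neck_radius_frac: float = 0.35  # neck radius as fraction of head radius
    n_boutons: int = 2
    bouton_radius_range: tuple = (0.15, 0.35)
    shaft_radius: float = 0.25
    wrap_offset: float = 0.0
    wrap_thickness: float = 0.06
    wrap_coverage: float = 0.5
    wrap_fraction: float = 1.0  # fraction of spines receiving a wrap
    include_arbor: bool = True
    seed: int = 0


def make_scene(spec: SceneSpec | None = None, seed=None) -> NeuropilScene:
    """Build a full synthetic scene satisfying the NeuropilScene invariants.

    Objects are placed by rejection sampling on bounding spheres so neuronal
    structures do not interpenetrate; astrocytic wraps deliberately surround
    their target spines.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    half = spec.block_size / 2.0
    bounds = np.array([[-half] * 3, [half] * 3])
    objects = []
    placed = []  # ("sphere", center, r) or ("capsule", p0, p1, r)

    def _seg_seg_dist(p0, p1, q0, q1):
        # closest distance between two segments (Eberly's clamped solution)
        d1, d2 = p1 - p0, q1 - q0
        r = p0 - q0
        a, e, f = d1 @ d1, d2 @ d2, d2 @ r
        c_, b = d1 @ r, d1 @ d2
        denom = a * e - b * b
        s = np.clip((b * f - c_ * e) / denom, 0.0, 1.0) if denom > 1e-15 else 0.0
        t = (b * s + f) / e if e > 1e-15 else 0.0
        if t < 0.0:
            t, s = 0.0, np.clip(-c_ / a, 0.0, 1.0) if a > 1e-15 else 0.0
        elif t > 1.0:
            t, s = 1.0, np.clip((b - c_) / a, 0.0, 1.0) if a > 1e-15 else 0.0
        return np.linalg.norm((p0 + s * d1) - (q0 + t * d2))

    def _clear(entry_new, margin):
        for entry in placed:
            if entry[0] == "sphere" and entry_new[0] == "sphere":
                d = np.linalg.norm(entry_new[1] - entry[1])
                rr = entry_new[2] + entry[2]
            elif entry[0] == "sphere":
                p0, p1, r = entry_new[1], entry_new[2], entry_new[3]
                seg = p1 - p0
                t = np.clip((entry[1] - p0) @ seg / (seg @ seg), 0.0, 1.0)
                d = np.linalg.norm(entry[1] - (p0 + t * seg))
                rr = r + entry[2]
            elif entry_new[0] == "sphere":
                p0, p1, r = entry[1], entry[2], entry[3]
                seg = p1 - p0
                t = np.clip((entry_new[1] - p0) @ seg / (seg @ seg), 0.0, 1.0)
                d = np.linalg.norm(entry_new[1] - (p0 + t * seg))
                rr = r + entry_new[2]
            else:
                d = _seg_seg_dist(entry_new[1], entry_new[2], entry[1], entry[2])
                rr = entry_new[3] + entry[3]
            if d <= rr + margin:
                return False
        return True

    def try_place_sphere(radius, margin=0.04, max_tries=500):
        for _ in range(max_tries):
            c = rng.uniform(-half + radius + margin, half - radius - margin, 3)
            if _clear(("sphere", c, radius), margin):
                placed.append(("sphere", c, radius))
                return c
        raise RuntimeError("could not place object without interpenetration")

    def try_place_capsule(length, radius, margin=0.04, max_tries=2000):
        room = radius + margin
        for _ in range(max_tries):
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            # midpoint range that keeps the whole capsule inside the block
            slack = half - room - np.abs(axis) * length / 2.0
            if (slack <= 0).any():
                continue
            mid = rng.uniform(-slack, slack)
            p0 = mid - axis * length / 2.0
            p1 = mid + axis * length / 2.0
            if _clear(("capsule", p0, p1, radius), margin):
                placed.append(("capsule", p0, p1, radius))
                return p0, axis
        raise RuntimeError("could not place object without interpenetration")

    # dendritic shaft along the bottom-front edge of the block
    ys = zs = -half + spec.shaft_radius + 0.2
    shaft, shaft_truth = make_tube(spec.shaft_radius, spec.block_size - 0.2,
                                   center=(0, ys, zs),
                                   axis=(1, 0, 0), label="shaft")
    placed.append(("capsule", np.array([-half, ys, zs]),
                   np.array([half, ys, zs]), spec.shaft_radius + 0.05))
    objects.append(SceneObject("shaft0", shaft, "shaft", truth=shaft_truth))

    if spec.include_arbor:  # reserve the arbor's corridor before placing spines
        xa = za = half - 0.65
        placed.append(("capsule", np.array([xa, -half, za]),
                       np.array([xa, half, za]), 0.62))

    for i in range(spec.n_spines):
        # packing-conditioned radius draw: a head too large for the remaining
        # free space is redrawn, as in a densely packed block
        for attempt in range(8):
            R = rng.uniform(*spec.head_radius_range)
            extent = spec.neck_len + 2 * R  # base to head top along the axis
            try:
                c, axis = try_place_capsule(extent,
                                            R + spec.wrap_thickness + 0.04)
                break
            except RuntimeError:
                if attempt == 7:
                    raise
        spine, psd, truth = make_spine(
            R, neck_len=spec.neck_len, neck_radius=spec.neck_radius_frac * R,
            center=c, axis=axis)
        truth["spine_class"] = "mushroom" if R >= 0.2 else "thin"
        objects.append(SceneObject(f"spine{i}", spine, "spine", truth=truth))
        objects.append(SceneObject(f"psd{i}", psd, "psd", parent=f"spine{i}"))
        if rng.uniform() < spec.wrap_fraction:
            wrap, wt = wrap_astro(truth["head_center"], R, spec.wrap_offset,
                                  spec.wrap_thickness, spec.wrap_coverage,
                                  cap_axis=-truth["axis"])
            objects.append(SceneObject(f"wrap{i}", wrap, "astrocyte",
                                       process_class="leaflet", truth=wt))

    for i in range(spec.n_boutons):
        r = rng.uniform(*spec.bouton_radius_range)
        c = try_place_sphere(r + 0.08)
        mesh, truth = make_sphere(r, center=c, label=f"bouton{i}")
        objects.append(SceneObject(f"bouton{i}", mesh, "bouton", truth=truth))

    if spec.include_arbor:
        xa = za = half - 0.65
        arbor = make_astro_arbor(
            tube_length=spec.block_size - 0.4, seed=int(rng.integers(2**31)),
            center=(xa, 0, za), axis=(0, 1, 0),
            sheet_extents=(0.04, 0.3, 0.4))
        for j, (mesh, cls, truth) in enumerate(arbor.parts):
            objects.append(SceneObject(f"arbor{j}", mesh, "astrocyte",
                                       process_class=cls, truth=truth))
    scene = NeuropilScene(objects, bounds, provenance="synthetic")
    return scene.validate()
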