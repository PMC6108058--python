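"""Equidistant-surface construction and astrocyte volume-fraction profiles.

The central quantity is the astrocyte volume fraction (VF) inside thin shells
bounded by successive equidistant surfaces around a reference structure: the
PSD centre of mass, the PSD edge, the lateral spine surface, or the full
membrane of a bouton / dendritic-shaft chunk.  Profiles are estimated by
seeded uniform Monte-Carlo sampling: each sample point is assigned a shell by
its distance to the reference and tested for membership in the astrocytic
processes; VF per shell is the astrocytic point fraction, with a binomial
standard error.  Shell parts excluded by the presynaptic / dendritic
half-spaces (or lying inside the reference object) contribute to neither
numerator nor denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _tm

from ._geometry import point_segments_distance
from .mesh_core import MeshError, NeuropilScene, TriMesh

MODES = ("psd_center", "psd_edge", "spine_surface", "object_surface")

#: default distance step Δd between equidistant surfaces (μm)
DEFAULT_STEP = 0.03
#: default profile range (μm)
DEFAULT_DMAX = 0.99
#: tolerance on equidistant-surface vertex distances: Δd / 3
TOL_EQ = DEFAULT_STEP / 3.0


# ----------------------------------------------------------------------
@dataclass
class EquidistantSurface:
    mesh: TriMesh
    reference: str
    d: float
    max_error: float
    flags: set = field(default_factory=set)


def equidistant_surface(ref, d, sphere_subdiv=4, tol=TOL_EQ, max_iter=50,
                        bounds=None) -> EquidistantSurface:
    """Surface at constant distance ``d`` from a reference point or mesh.

    An enclosing triangulated sphere is shrunk onto the offset surface: each
    vertex moves along the line to its closest reference point until its
    distance equals ``d``.  The projection is iterated until the vertex
    distance audit passes ``tol`` (concave references need more than one
    rearrangement) or ``max_iter`` is reached.
    """
    if d <= 0:
        raise ValueError("offset distance d must be positive")
    flags = set()
    ref_is_point = not isinstance(ref, TriMesh)
    if ref_is_point:
        center = np.asarray(ref, float)
        sphere = _tm.creation.icosphere(subdivisions=sphere_subdiv, radius=d)
        verts = sphere.vertices + center
        mesh = TriMesh(verts, sphere.faces, label="equidistant", clean=False)
        surf = EquidistantSurface(mesh, "point", float(d), 0.0, flags)
    else:
        center = ref.centroid
        r0 = np.linalg.norm(ref.vertices - center, axis=1).max() + d
        sphere = _tm.creation.icosphere(subdivisions=sphere_subdiv, radius=r0)
        verts = sphere.vertices + center
        err = np.inf
        for _ in range(max_iter):
            closest, dist, _ = ref.sd.query(verts)
            degenerate = dist < 1e-12
            if degenerate.any():  # vertex exactly on the reference: nudge out
                verts[degenerate] += 1e-9
                closest, dist, _ = ref.sd.query(verts)
            verts = closest + (verts - closest) * (d / dist)[:, None]
            err = float(np.abs(ref.sd.distance(verts) - d).max())
            if err <= tol:
                break
        if err > tol:
            flags.add("not_converged")
        mesh = TriMesh(verts, sphere.faces, label="equidistant", clean=False)
        surf = EquidistantSurface(mesh, ref.label or "mesh", float(d), err, flags)
    if bounds is not None:
        bounds = np.asarray(bounds, float)
        v = surf.mesh.vertices
        if (v < bounds[0]).any() or (v > bounds[1]).any():
            flags.add("out_of_bounds")
    # cheap self-intersection heuristic: non-neighbouring vertices nearly
    # coincident relative to the local edge length
    v = surf.mesh.vertices
    edges = v[surf.mesh.faces[:, 0]] - v[surf.mesh.faces[:, 1]]
    med_edge = np.median(np.linalg.norm(edges, axis=1))
    from scipy.spatial import cKDTree
    tree = cKDTree(v)
    pairs = tree.query_pairs(0.25 * med_edge, output_type="ndarray")
    if len(pairs):
        flags.add("possible_self_intersection")
    return surf


# ----------------------------------------------------------------------
def half_space_planes(spine: TriMesh, psd: TriMesh):
    """Presynaptic and dendritic exclusion half-spaces for a spine.

    The presynaptic plane is the least-squares plane of the PSD mesh, offset
    to the PSD's outermost point, with the bouton side excluded.  The
    dendritic plane is normal to the neck axis at the spine base, with the
    shaft side excluded.  Each plane is returned as ``(point, normal)`` where
    points with ``dot(p - point, normal) > 0`` are excluded.
    """
    c_psd = psd.centroid
    # least-squares plane of PSD vertices
    dv = psd.vertices - psd.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(dv, full_matrices=False)
    n_psd = vt[2]
    body = spine.centroid
    if np.dot(n_psd, c_psd - body) < 0:
        n_psd = -n_psd
    # offset to the outer face of the PSD
    offset = (psd.vertices - c_psd) @ n_psd
    presyn_point = c_psd + n_psd * offset.max()

    # neck axis: from the base (vertex farthest opposite the PSD) to the PSD
    axis0 = c_psd - body
    axis0 /= np.linalg.norm(axis0)
    proj = spine.vertices @ axis0
    base = spine.vertices[np.argmin(proj)]
    axis = c_psd - base
    axis /= np.linalg.norm(axis)
    return (presyn_point, n_psd), (base, -axis)


def exclude_half_spaces(surface: EquidistantSurface, presyn_plane,
                        dendritic_plane):
    """Clip an equidistant surface by the two half-spaces.

    Faces whose centroid lies strictly inside either excluded half-space are
    removed.  Returns ``(clipped_surface, record)`` where the record carries
    the retained/excluded area fractions used by VF renormalisation.
    """
    mesh = surface.mesh
    tri = mesh.vertices[mesh.faces]
    cent = tri.mean(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    excluded = np.zeros(len(cent), bool)
    for plane in (presyn_plane, dendritic_plane):
        if plane is None:
            continue
        point, normal = plane
        excluded |= (cent - np.asarray(point)) @ np.asarray(normal) > 0
    if excluded.all():
        raise ValueError("half-space planes exclude the entire surface")
    total = areas.sum()
    record = {"area_total": float(total),
              "area_excluded": float(areas[excluded].sum()),
              "fraction_retained": float(areas[~excluded].sum() / total)}
    clipped = TriMesh(mesh.vertices, mesh.faces[~excluded],
                      label=mesh.label, clean=False)
    out = EquidistantSurface(clipped, surface.reference, surface.d,
                             surface.max_error, set(surface.flags) | {"clipped"})
    return out, record


def points_excluded_by_planes(points, planes):
    excl = np.zeros(len(points), bool)
    for plane in planes:
        if plane is None:
            continue
        point, normal = plane
        excl |= (points - np.asarray(point)) @ np.asarray(normal) > 0
    return excl


# ----------------------------------------------------------------------
def _boundary_loops(faces):
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, inv, counts = np.unique(edges_sorted, axis=0, return_inverse=True,
                                  return_counts=True)
    boundary = uniq[counts == 1]
    adj = {}
    for a, b in boundary:
        adj.setdefault(int(a), []).append(int(b))
        adj.setdefault(int(b), []).append(int(a))
    used = set()
    loops = []
    for a0, b0 in boundary:
        e0 = (min(a0, b0), max(a0, b0))
        if e0 in used:
            continue
        # claim edges while walking; terminates even on non-manifold pinches
        loop = [int(a0)]
        used.add(e0)
        cur = int(b0)
        for _ in range(len(boundary) + 1):
            loop.append(cur)
            nxt = None
            for v in adj[cur]:
                e = (min(cur, v), max(cur, v))
                if e not in used:
                    nxt = v
                    used.add(e)
                    break
            if nxt is None or nxt == loop[0]:
                break
            cur = nxt
        if len(loop) >= 3:
            loops.append(loop)
    return loops


def _cap_open_mesh(vertices, faces, label=""):
    """Close boundary loops by centroid-fan caps; cap faces are marked."""
    vertices = np.asarray(vertices, float)
    faces = np.asarray(faces, np.int64)
    loops = _boundary_loops(faces)
    new_v = [vertices]
    new_f = [faces]
    n_v = len(vertices)
    cut = []
    fstart = len(faces)
    for loop in loops:
        centroid = vertices[loop].mean(axis=0)
        new_v.append(centroid[None])
        ring = np.array(loop + [loop[0]])
        fan = np.stack([ring[:-1], ring[1:],
                        np.full(len(loop), n_v)], axis=1)
        new_f.append(fan)
        cut.extend(range(fstart, fstart + len(fan)))
        fstart += len(fan)
        n_v += 1
    mesh = TriMesh(np.concatenate(new_v), np.concatenate(new_f), label=label,
                   clean=False, cut_faces=np.array(cut, np.int64))
    if not mesh.is_closed:
        raise MeshError("capping failed to close the mesh")
    if mesh._signed_volume() < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return mesh


def split_shaft(shaft: TriMesh, chunk_len=1.0):
    """Split a dendritic shaft into ~1 μm chunks along its principal axis.

    Each chunk is re-closed with planar caps; cap faces are recorded in
    ``cut_faces`` so downstream analyses treat only the membrane-covered
    lateral surface as reference.  A remainder shorter than ``chunk_len / 2``
    merges into the last chunk, keeping chunk lengths within
    [chunk_len/2, 3·chunk_len/2).
    """
    v = shaft.vertices - shaft.vertices.mean(axis=0)
    _, _, vt = np.linalg.svd(v, full_matrices=False)
    axis = vt[0]
    proj = shaft.vertices @ axis
    lo, hi = proj.min(), proj.max()
    length = hi - lo
    warn = length < chunk_len / 2
    n_full = int(length // chunk_len)
    cuts = [lo + chunk_len * i for i in range(1, n_full + 1)]
    if cuts and (hi - cuts[-1]) < chunk_len / 2:
        cuts.pop()  # merge short remainder into the last chunk
    if cuts and abs(cuts[-1] - hi) < 1e-9:
        cuts.pop()
    edges = [lo] + cuts + [hi]
    base = shaft.as_trimesh()
    chunks = []
    for i in range(len(edges) - 1):
        piece = base
        if i > 0:
            piece = _tm.intersections.slice_mesh_plane(
                piece, plane_normal=axis, plane_origin=axis * edges[i], cap=False)
        if i < len(edges) - 2:
            piece = _tm.intersections.slice_mesh_plane(
                piece, plane_normal=-axis, plane_origin=axis * edges[i + 1],
                cap=False)
        label = f"{shaft.label or 'shaft'}:chunk{i}"
        chunk = TriMesh(piece.vertices, piece.faces, label=label, clean=True)
        if not chunk.is_closed:
            chunk = _cap_open_mesh(chunk.vertices, chunk.faces, label=label)
        chunks.append(chunk)
    if warn and chunks:
        chunks = chunks[:1]
    return chunks


# ----------------------------------------------------------------------
def spine_head_radius(spine: TriMesh, psd: TriMesh, n_stations=60):
    """Equivalent-sphere radius (μm) of the spine head.

    The head is separated from the neck at the locus of minimal cross-section
    (the neck waist) along the base→PSD axis; its volume defines the
    equivalent-sphere radius.  When no waist is found (headless stub) the
    whole-spine volume is used and a warning flag returned.

    Returns ``(radius, info)`` with ``info['warning']`` set for stubs.
    """
    c_psd = psd.centroid
    body = spine.centroid
    axis = c_psd - body
    axis /= np.linalg.norm(axis)
    proj = spine.vertices @ axis
    base = spine.vertices[np.argmin(proj)]
    axis = c_psd - base
    axis /= np.linalg.norm(axis)
    proj = spine.vertices @ axis
    lo, hi = proj.min(), proj.max()

    base_tm = spine.as_trimesh()
    stations = np.linspace(lo + 0.05 * (hi - lo), hi - 0.1 * (hi - lo), n_stations)
    radii = np.full(n_stations, np.nan)
    for i, s in enumerate(stations):
        sections = _tm.intersections.mesh_plane(
            base_tm, plane_normal=axis, plane_origin=axis * s)
        if len(sections):
            pts = sections.reshape(-1, 3)
            d = pts - (pts @ axis)[:, None] * axis
            center = d.mean(axis=0)
            radii[i] = np.linalg.norm(d - center, axis=1).mean()
    ok = np.isfinite(radii)
    info = {"warning": None}
    waist_idx = None
    if ok.sum() >= 5:
        r = radii.copy()
        r[~ok] = np.inf
        # interior minimum that is a genuine waist: clearly below the maximal
        # cross-section further out (the head)
        for i in range(1, n_stations - 1):
            ahead = r[i + 1:][np.isfinite(r[i + 1:])]
            if not len(ahead):
                continue
            if r[i] < 0.8 * ahead.max() and r[i] <= r[:i + 1].min() + 1e-12:
                waist_idx = i
        if waist_idx is not None and not np.isfinite(r[waist_idx]):
            waist_idx = None
    if waist_idx is None:
        volume = spine.volume
        info["warning"] = "no neck waist found; whole-spine equivalent radius"
    else:
        s = stations[waist_idx]
        head = _tm.intersections.slice_mesh_plane(
            base_tm, plane_normal=axis, plane_origin=axis * s, cap=False)
        head = _cap_open_mesh(head.vertices, head.faces, label="head")
        volume = head.volume
        info["waist_position"] = float(s)
    radius = float((3.0 * volume / (4.0 * np.pi)) ** (1.0 / 3.0))
    info["head_volume"] = float(volume)
    return radius, info


#: spine-class boundary: head radius ≥ 0.2 μm is a mushroom spine
SPINE_CLASS_THRESHOLD = 0.2


def classify_spine(radius: float) -> str:
    """'mushroom' for head radius ≥ 0.2 μm, 'thin' below."""
    return "mushroom" if radius >= SPINE_CLASS_THRESHOLD else "thin"


def bouton_radius(bouton: TriMesh) -> float:
    """Equivalent-sphere radius (μm) from the bouton volume."""
    if not bouton.is_closed:
        raise MeshError(
            f"open mesh ({bouton.boundary_edge_count} boundary edges): "
            "bouton radius undefined")
    return float((3.0 * bouton.volume / (4.0 * np.pi)) ** (1.0 / 3.0))


# ----------------------------------------------------------------------
@dataclass
class VFProfile:
    object_id: str
    role: str
    mode: str
    bin_edges: np.ndarray  # (n_bins + 1,)
    vf: np.ndarray         # astrocyte volume fraction per shell (NaN: no data)
    vf_se: np.ndarray
    n_points: np.ndarray
    vf_leaflet: np.ndarray | None = None
    vf_branchlet: np.ndarray | None = None
    spine_class: str | None = None
    flags: set = field(default_factory=set)

    @property
    def bin_centers(self):
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def vf_max(self) -> float:
        ok = np.isfinite(self.vf)
        return float(self.vf[ok].max()) if ok.any() else float("nan")

    @property
    def d_at_vf_max(self) -> float:
        ok = np.isfinite(self.vf)
        if not ok.any():
            return float("nan")
        idx = np.flatnonzero(ok)[np.nanargmax(self.vf[ok])]
        return float(self.bin_centers[idx])


def _reference_distance(scene, obj, mode):
    """Distance function + exclusion function for the requested mode."""
    if mode in ("psd_center", "psd_edge"):
        psd = obj if obj.role == "psd" else scene.psd_of(obj.object_id)
        if mode == "psd_center":
            center = psd.mesh.centroid
            return (lambda p: np.linalg.norm(p - center, axis=1),
                    lambda p: np.zeros(len(p), bool),
                    np.array([center, center]))
        loops = psd.mesh.boundary_edges()
        seg_a = psd.mesh.vertices[loops[:, 0]]
        seg_b = psd.mesh.vertices[loops[:, 1]]
        bounds = np.array([np.minimum(seg_a, seg_b).min(axis=0),
                           np.maximum(seg_a, seg_b).max(axis=0)])
        return (lambda p: point_segments_distance(p, seg_a, seg_b),
                lambda p: np.zeros(len(p), bool), bounds)

    mesh = obj.mesh
    if mode == "spine_surface":
        if obj.role != "spine":
            raise ValueError("spine_surface mode requires a spine object")
        psd = scene.psd_of(obj.object_id)
        planes = half_space_planes(mesh, psd.mesh)

        def excl(p):
            return points_excluded_by_planes(p, planes) | mesh.contains(p)
        return mesh.distance, excl, mesh.bounds

    if mode == "object_surface":
        cut = mesh.cut_faces

        def excl(p):
            inside = mesh.contains(p)
            if len(cut):
                _, _, tri_id = mesh.sd.query(p)
                inside |= np.isin(tri_id, cut)
            return inside
        return mesh.distance, excl, mesh.bounds

    raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")


def vf_profile(scene: NeuropilScene, object_id: str, mode: str,
               step=DEFAULT_STEP, d_max=DEFAULT_DMAX, n_samples=200_000,
               seed=0, by_class=False) -> VFProfile:
    """Astrocyte volume-fraction profile around one object.

    Monte-Carlo points are drawn uniformly in the reference's bounding box
    inflated by ``d_max``; each point is binned by its distance to the
    reference (bin width ``step``) and classified against every astrocytic
    mesh.  ``by_class`` additionally splits VF into leaflet / branchlet
    contributions using the scene's process-class labels.
    """
    obj = scene.get(object_id)
    dist_fn, excl_fn, ref_bounds = _reference_distance(scene, obj, mode)
    rng = np.random.default_rng(seed)
    lo = ref_bounds[0] - d_max
    hi = ref_bounds[1] + d_max
    flags = set()
    if (lo < scene.block_bounds[0]).any() or (hi > scene.block_bounds[1]).any():
        flags.add("boundary_truncated")

    points = rng.uniform(lo, hi, size=(n_samples, 3))
    dist = dist_fn(points)
    keep = dist < d_max
    points, dist = points[keep], dist[keep]
    keep = ~excl_fn(points)
    points, dist = points[keep], dist[keep]

    n_bins = int(np.ceil(d_max / step))
    edges = step * np.arange(n_bins + 1)
    bin_idx = np.minimum((dist // step).astype(int), n_bins - 1)
    denom = np.bincount(bin_idx, minlength=n_bins).astype(float)

    astro_objs = scene.astro()
    in_astro = np.zeros(len(points), bool)
    in_class = {c: np.zeros(len(points), bool) for c in ("leaflet", "branchlet")}
    for a in astro_objs:
        b = a.mesh.bounds
        cand = np.all((points >= b[0] - 1e-12) & (points <= b[1] + 1e-12), axis=1)
        if not cand.any():
            continue
        hit = np.zeros(len(points), bool)
        hit[cand] = a.mesh.contains(points[cand])
        in_astro |= hit
        if by_class and a.process_class in in_class:
            in_class[a.process_class] |= hit

    num = np.bincount(bin_idx[in_astro], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        vf = np.where(denom > 0, num / denom, np.nan)
        se = np.where(denom > 0, np.sqrt(np.clip(vf * (1 - vf), 0, None)
                                         / np.maximum(denom, 1)), np.nan)
    prof = VFProfile(object_id=object_id, role=obj.role, mode=mode,
                     bin_edges=edges, vf=vf, vf_se=se,
                     n_points=denom.astype(int), flags=flags)
    if by_class:
        for cname, attr in (("leaflet", "vf_leaflet"), ("branchlet", "vf_branchlet")):
            numc = np.bincount(bin_idx[in_class[cname]], minlength=n_bins).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                setattr(prof, attr, np.where(denom > 0, numc / denom, np.nan))
    return prof


# ----------------------------------------------------------------------
def min_surface_distance(mesh_a: TriMesh, mesh_b: TriMesh, n_samples=2000,
                         seed=0):
    """Approximate minimal surface-to-surface distance between two meshes."""
    rng = np.random.default_rng(seed)
    pts_a, _ = _tm.sample.sample_surface(mesh_a.as_trimesh(), n_samples,
                                         seed=int(rng.integers(2**31)))
    pts = np.concatenate([pts_a, mesh_a.vertices])
    d1 = mesh_b.distance(pts).min()
    d2 = mesh_a.distance(mesh_b.vertices).min()
    return float(min(d1, d2))


def contact_fraction(scene: NeuropilScene, process_class, spine_class=None,
                     d_contact=0.05, distance_grid=None, n_samples=2000,
                     seed=0):
    """Percentage of spines with a process of ``process_class`` within reach.

    A spine is in contact when its minimal surface-to-surface distance to any
    astrocytic mesh of the given class is ≤ ``d_contact`` (default 50 nm).
    Returns a dict with the percentage, the per-spine minimal distances, and
    the full percentage-vs-distance curve on ``distance_grid``.
    """
    spines = scene.by_role("spine")
    if spine_class is not None:
        selected = []
        for s in spines:
            cls = s.truth.get("spine_class")
            if cls is None:
                r, _ = spine_head_radius(s.mesh, scene.psd_of(s.object_id).mesh)
                cls = classify_spine(r)
            if cls == spine_class:
                selected.append(s)
        spines = selected
    if not spines:
        raise ValueError("no spines to analyse")
    processes = scene.astro(process_class)
    dmin = {}
    for s in spines:
        if processes:
            dmin[s.object_id] = min(
                min_surface_distance(s.mesh, p.mesh, n_samples=n_samples,
                                     seed=seed) for p in processes)
        else:
            dmin[s.object_id] = np.inf
    dvals = np.array(list(dmin.values()))
    if distance_grid is None:
        distance_grid = np.arange(0.0, 0.51, 0.01)
    curve = np.array([(dvals <= g).mean() * 100.0 for g in distance_grid])
    return {"percentage": float((dvals <= d_contact).mean() * 100.0),
            "d_contact": d_contact,
            "min_distances": dmin,
            "distance_grid": np.asarray(distance_grid),
            "percentage_curve": curve}
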