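"""Mesh and scene primitives shared by all analysis stages.

A :class:`TriMesh` is a triangulated surface in micrometres.  Volume-bearing
objects (spines, boutons, shaft chunks, astrocytic processes) must be closed
and consistently oriented; sub-surfaces such as PSD caps are open meshes.
A :class:`NeuropilScene` is a labelled collection of meshes with roles and
parent links (every PSD belongs to a spine, every leaflet to a branchlet)
inside an axis-aligned block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh as _tm

from ._geometry import SurfaceDistance

ROLES = ("astrocyte", "spine", "psd", "bouton", "shaft", "axon")
PROCESS_CLASSES = ("leaflet", "branchlet")

_UNIT_SCALES = {"um": 1.0, "µm": 1.0, "micron": 1.0, "nm": 1e-3, "mm": 1e3}


class MeshError(ValueError):
    """Raised for invalid meshes (open where closed is required, etc.)."""


class SceneError(ValueError):
    """Raised for invalid scene manifests."""


class TriMesh:
    """Triangulated surface with vertices (μm), faces and a free-text label."""

    def __init__(self, vertices, faces, label="", clean=True, cut_faces=None):
        self.vertices = np.asarray(vertices, float).reshape(-1, 3)
        self.faces = np.asarray(faces, np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise MeshError("face indices out of range")
        self.label = label
        # face indices marking artificial cut planes (shaft chunk ends)
        self.cut_faces = np.asarray(cut_faces, np.int64) if cut_faces is not None \
            else np.empty(0, np.int64)
        if clean and len(self.faces):
            self._clean()
        self._sd = None
        self._trimesh = None

    # -- construction -------------------------------------------------
    @classmethod
    def from_trimesh(cls, mesh, label="", clean=True):
        return cls(mesh.vertices, mesh.faces, label=label, clean=clean)

    def _clean(self, tol=1e-6):
        """Merge duplicate vertices (tol in μm), drop degenerate faces and
        unreferenced vertices."""
        used = np.unique(self.faces)
        if len(used) < len(self.vertices):
            remap = np.full(len(self.vertices), -1, np.int64)
            remap[used] = np.arange(len(used))
            self.vertices = self.vertices[used]
            self.faces = remap[self.faces]
        key = np.round(self.vertices / tol).astype(np.int64)
        _, first, inv = np.unique(key, axis=0, return_index=True, return_inverse=True)
        self.vertices = self.vertices[first]
        faces = inv[self.faces]
        tri = self.vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        distinct = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
            & (faces[:, 0] != faces[:, 2])
        keep = distinct & (areas > 0)
        if len(self.cut_faces):
            old2new = np.cumsum(keep) - 1
            kept_cut = self.cut_faces[keep[self.cut_faces]]
            self.cut_faces = old2new[kept_cut]
        self.faces = faces[keep]
        # enforce positive signed volume on closed meshes
        if self.is_closed and self._signed_volume() < 0:
            self.faces = self.faces[:, ::-1]

    # -- cached helpers ------------------------------------------------
    @property
    def sd(self) -> SurfaceDistance:
        if self._sd is None:
            self._sd = SurfaceDistance(self.vertices, self.faces)
        return self._sd

    def as_trimesh(self):
        if self._trimesh is None:
            self._trimesh = _tm.Trimesh(self.vertices, self.faces, process=False)
        return self._trimesh

    # -- topology ------------------------------------------------------
    @property
    def boundary_edge_count(self) -> int:
        if not len(self.faces):
            return 0
        edges = np.sort(np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                        self.faces[:, [0, 2]]]), axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts == 1).sum())

    @property
    def is_closed(self) -> bool:
        return len(self.faces) > 0 and self.boundary_edge_count == 0

    def boundary_edges(self):
        """Vertex index pairs of edges used by exactly one face."""
        edges = np.sort(np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                                        self.faces[:, [0, 2]]]), axis=1)
        uniq, counts = np.unique(edges, axis=0, return_counts=True)
        return uniq[counts == 1]

    # -- measures ------------------------------------------------------
    def _signed_volume(self) -> float:
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0],
                               np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)

    @property
    def area(self) -> float:
        if not len(self.faces):
            return 0.0
        tri = self.vertices[self.faces]
        return float(0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1).sum())

    @property
    def volume(self) -> float:
        if not self.is_closed:
            raise MeshError(
                f"open mesh ({self.boundary_edge_count} boundary edges): "
                "volume undefined")
        return abs(self._signed_volume())

    @property
    def centroid(self):
        """Area-weighted surface centroid."""
        tri = self.vertices[self.faces]
        a = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
        return (tri.mean(axis=1) * a[:, None]).sum(axis=0) / a.sum()

    @property
    def bounds(self):
        return np.array([self.vertices.min(axis=0), self.vertices.max(axis=0)])

    # -- queries -------------------------------------------------------
    def distance(self, points):
        return self.sd.distance(points)

    def signed_distance(self, points):
        return self.sd.signed_distance(points)

    def contains(self, points):
        return self.sd.contains(points)

    def copy(self):
        return TriMesh(self.vertices.copy(), self.faces.copy(), self.label,
                       clean=False, cut_faces=self.cut_faces.copy())

    def __repr__(self):
        return (f"TriMesh({self.label!r}, {len(self.vertices)} vertices, "
                f"{len(self.faces)} faces)")


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume (μm³) by the divergence theorem; mesh must be closed."""
    return mesh.volume


def mesh_area(mesh: TriMesh) -> float:
    """Total surface area (μm²)."""
    return mesh.area


def point_surface_distance(point, mesh: TriMesh) -> float:
    """Exact minimum Euclidean distance (μm) from a point to the surface."""
    return float(mesh.distance(np.atleast_2d(point))[0])


# ----------------------------------------------------------------------
@dataclass
class SceneObject:
    object_id: str
    mesh: TriMesh
    role: str
    parent: str | None = None
    process_class: str | None = None  # leaflet / branchlet for astro meshes
    truth: dict = field(default_factory=dict)


@dataclass
class NeuropilScene:
    objects: list[SceneObject]
    block_bounds: np.ndarray  # (2, 3) min/max corners, μm
    provenance: str = "synthetic"

    def __post_init__(self):
        self.block_bounds = np.asarray(self.block_bounds, float).reshape(2, 3)
        self._index = {o.object_id: o for o in self.objects}
        if len(self._index) != len(self.objects):
            raise SceneError("duplicate object ids")

    def get(self, object_id: str) -> SceneObject:
        try:
            return self._index[object_id]
        except KeyError:
            raise SceneError(f"unknown object id {object_id!r}") from None

    def by_role(self, role: str):
        return [o for o in self.objects if o.role == role]

    def astro(self, process_class=None):
        out = self.by_role("astrocyte")
        if process_class is not None:
            out = [o for o in out if o.process_class == process_class]
        return out

    def psd_of(self, spine_id: str) -> SceneObject:
        for o in self.objects:
            if o.role == "psd" and o.parent == spine_id:
                return o
        raise SceneError(f"spine {spine_id!r} has no PSD")

    def validate(self):
        for o in self.objects:
            if o.role not in ROLES:
                raise SceneError(f"object {o.object_id!r}: unknown role {o.role!r}")
            if o.role == "psd":
                if o.parent is None:
                    raise SceneError(f"psd {o.object_id!r} lacks a parent spine")
                parent = self.get(o.parent)
                if parent.role != "spine":
                    raise SceneError(
                        f"psd {o.object_id!r} parent {o.parent!r} is not a spine")
            if o.process_class is not None and o.process_class not in PROCESS_CLASSES:
                raise SceneError(
                    f"object {o.object_id!r}: unknown process class "
                    f"{o.process_class!r}")
            b = o.mesh.bounds
            if (b[0] < self.block_bounds[0] - 1e-9).any() or \
                    (b[1] > self.block_bounds[1] + 1e-9).any():
                raise SceneError(
                    f"object {o.object_id!r} extends outside block bounds")
        # each spine has at most one psd; each psd exactly one spine (above)
        seen = {}
        for o in self.objects:
            if o.role == "psd":
                if o.parent in seen:
                    raise SceneError(f"spine {o.parent!r} has multiple PSDs")
                seen[o.parent] = o.object_id
        return self


# ----------------------------------------------------------------------
def load_scene(manifest_path) -> NeuropilScene:
    """Load a scene from a JSON manifest.

    Manifest schema::

        {"units": "um" | "nm" | <scale factor>,
         "block_bounds": [[x0,y0,z0],[x1,y1,z1]],
         "objects": [{"id": ..., "file": ..., "role": ...,
                      "parent": ..., "class": ...}, ...]}

    Mesh files (OBJ/PLY) are resolved relative to the manifest; vertex
    coordinates are rescaled to μm by the declared units.
    """
    manifest_path = Path(manifest_path)
    try:
        spec = json.loads(manifest_path.read_text())
    except FileNotFoundError:
        raise SceneError(f"manifest not found: {manifest_path}") from None
    units = spec.get("units", "um")
    scale = float(_UNIT_SCALES[units]) if isinstance(units, str) else float(units)
    objects = []
    for entry in spec.get("objects", []):
        path = manifest_path.parent / entry["file"]
        if not path.exists():
            raise SceneError(f"mesh file not found: {path}")
        raw = _tm.load(str(path), force="mesh", process=False)
        mesh = TriMesh(np.asarray(raw.vertices) * scale, raw.faces,
                       label=entry.get("id", path.stem))
        objects.append(SceneObject(
            object_id=entry["id"], mesh=mesh, role=entry["role"],
            parent=entry.get("parent"), process_class=entry.get("class")))
    if "block_bounds" in spec:
        bounds = np.asarray(spec["block_bounds"], float) * scale
    else:
        lo = np.min([o.mesh.bounds[0] for o in objects], axis=0)
        hi = np.max([o.mesh.bounds[1] for o in objects], axis=0)
        bounds = np.array([lo, hi])
    scene = NeuropilScene(objects, bounds,
                          provenance=spec.get("provenance", str(manifest_path)))
    return scene.validate()


def _write_obj(mesh: TriMesh, path):
    """OBJ writer at full double precision (binary PLY stores float32)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.17g} {v[1]:.17g} {v[2]:.17g}\n")
        for f in mesh.faces + 1:
            fh.write(f"f {f[0]} {f[1]} {f[2]}\n")


def save_scene(scene: NeuropilScene, outdir, mesh_format="obj") -> Path:
    """Write meshes plus a JSON manifest; returns the manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for o in scene.objects:
        fname = f"{o.object_id}.{mesh_format}"
        if mesh_format == "obj":
            _write_obj(o.mesh, outdir / fname)
        else:
            o.mesh.as_trimesh().export(str(outdir / fname))
        entry = {"id": o.object_id, "file": fname, "role": o.role}
        if o.parent is not None:
            entry["parent"] = o.parent
        if o.process_class is not None:
            entry["class"] = o.process_class
        entries.append(entry)
    manifest = {"units": "um",
                "block_bounds": scene.block_bounds.tolist(),
                "provenance": scene.provenance,
                "objects": entries}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1))
    return path


def save_profiles(profiles, csv_path, json_path=None):
    """Write VF profiles as tidy CSV (one row per object × bin) + JSON summary."""
    rows = []
    summary = {}
    for p in profiles:
        for i in range(len(p.vf)):
            row = {"object_id": p.object_id, "role": p.role, "class": p.spine_class,
                   "mode": p.mode, "bin_lo_um": p.bin_edges[i],
                   "bin_hi_um": p.bin_edges[i + 1], "vf": p.vf[i],
                   "vf_se": p.vf_se[i], "n_points": p.n_points[i]}
            if p.vf_leaflet is not None:
                row["vf_leaflet"] = p.vf_leaflet[i]
                row["vf_branchlet"] = p.vf_branchlet[i]
            rows.append(row)
        summary[p.object_id] = {"mode": p.mode, "vf_max": p.vf_max,
                                "d_at_vf_max": p.d_at_vf_max,
                                "flags": sorted(p.flags)}
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    if json_path is not None:
        Path(json_path).write_text(json.dumps(summary, indent=1))
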