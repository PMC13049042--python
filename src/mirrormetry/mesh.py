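"""Triangle-mesh container, mirroring, and PLY/STL input/output.

Meshes are plain vertex/face arrays in millimetres.  Vertices may carry a
per-vertex region label (``head`` vs ``neck-shaft``) so downstream stages can
fit a sphere to the femoral head only, or exclude the fracture fragment from
registration.  Labels survive PLY round-trips via an extra vertex property.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: region-label codes
LABEL_NECK_SHAFT = 0
LABEL_HEAD = 1

LABEL_NAMES = {LABEL_NECK_SHAFT: "neck-shaft", LABEL_HEAD: "head"}


class MeshError(ValueError):
    """Raised for malformed meshes or mesh files."""


@dataclass
class SurfaceMesh:
    """Triangulated surface in mm.

    Parameters
    ----------
    vertices : (n, 3) float array
    faces : (m, 3) int array of vertex indices (counter-clockwise = outward)
    labels : optional (n,) int array of region codes (``LABEL_HEAD`` etc.)
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must be (m, 3)")
        if self.faces.size and (self.faces.min() < 0 or self.faces.max() >= len(self.vertices)):
            raise MeshError("face indices out of range")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int64)
            if self.labels.shape != (len(self.vertices),):
                raise MeshError("labels must be one code per vertex")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(
            self.vertices.copy(),
            self.faces.copy(),
            None if self.labels is None else self.labels.copy(),
        )

    def region_vertices(self, label: int) -> np.ndarray:
        """Vertex coordinates of one labeled region."""
        if self.labels is None:
            raise MeshError("mesh carries no region labels")
        return self.vertices[self.labels == label]

    def face_normals(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        n = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
        norms = np.linalg.norm(n, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        return n / norms

    def face_areas(self) -> np.ndarray:
        tri = self.vertices[self.faces]
        return 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )

    def is_closed(self) -> bool:
        """True when every edge is shared by exactly two faces.

        The phantom is a union of closed primitives, so the test is applied
        per connected component implicitly: the global edge-incidence count
        is 2 everywhere iff every component is closed.
        """
        edges = np.vstack(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        edges = np.sort(edges, axis=1)
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def signed_volume(self) -> float:
        """Total signed volume (positive when faces point outward)."""
        tri = self.vertices[self.faces]
        return float(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum() / 6.0)


def concatenate(meshes: list[SurfaceMesh]) -> SurfaceMesh:
    """Concatenate meshes into one (components stay disjoint)."""
    verts, faces, labels, off = [], [], [], 0
    has_labels = any(m.labels is not None for m in meshes)
    for m in meshes:
        verts.append(m.vertices)
        faces.append(m.faces + off)
        if has_labels:
            labels.append(
                m.labels if m.labels is not None
                else np.full(m.n_vertices, LABEL_NECK_SHAFT, dtype=np.int64)
            )
        off += m.n_vertices
    return SurfaceMesh(
        np.vstack(verts),
        np.vstack(faces),
        np.concatenate(labels) if has_labels else None,
    )


def mirror_mesh(mesh: SurfaceMesh, plane_point, plane_normal) -> SurfaceMesh:
    """Reflect a mesh across the plane through ``plane_point`` with unit ``plane_normal``.

    Face winding is reversed so outward orientation is preserved.  Applying
    the operation twice returns the input exactly (reflection is involutive
    in exact arithmetic; the arithmetic here is a single subtract/add per
    application, so the round trip is exact for representable inputs).
    """
    p = np.asarray(plane_point, dtype=np.float64)
    n = np.asarray(plane_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise MeshError("mirror plane normal must be nonzero")
    n = n / norm
    d = (mesh.vertices - p) @ n
    verts = mesh.vertices - 2.0 * d[:, None] * n[None, :]
    faces = mesh.faces[:, ::-1].copy()
    return SurfaceMesh(verts, faces, None if mesh.labels is None else mesh.labels.copy())


def mirror_points(points, plane_point, plane_normal) -> np.ndarray:
    """Reflect bare points across a plane (same convention as :func:`mirror_mesh`)."""
    p = np.asarray(plane_point, dtype=np.float64)
    n = np.asarray(plane_normal, dtype=np.float64)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise MeshError("mirror plane normal must be nonzero")
    n = n / norm
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    out = pts - 2.0 * ((pts - p) @ n)[:, None] * n[None, :]
    return out if np.ndim(points) == 2 else out[0]


# ---------------------------------------------------------------------------
# I/O — ASCII PLY (with labels), ASCII + binary STL (geometry only)
# ---------------------------------------------------------------------------

def save_ply(mesh: SurfaceMesh, path) -> None:
    path = Path(path)
    with_labels = mesh.labels is not None
    lines = [
        "ply",
        "format ascii 1.0",
        "comment mirrormetry surface mesh (mm)",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
    ]
    if with_labels:
        lines.append("property int region")
    lines += [
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for i, v in enumerate(mesh.vertices):
        row = f"{v[0]:.17g} {v[1]:.17g} {v[2]:.17g}"
        if with_labels:
            row += f" {int(mesh.labels[i])}"
        lines.append(row)
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def load_ply(path) -> SurfaceMesh:
    text = Path(path).read_text().splitlines()
    if not text or text[0].strip() != "ply":
        raise MeshError(f"{path}: not a PLY file")
    n_vert = n_face = 0
    vert_props: list[str] = []
    element = None
    i = 1
    while i < len(text):
        tok = text[i].split()
        i += 1
        if not tok:
            continue
        if tok[0] == "format" and tok[1] != "ascii":
            raise MeshError("only ASCII PLY is supported")
        elif tok[0] == "element":
            element = tok[1]
            if element == "vertex":
                n_vert = int(tok[2])
            elif element == "face":
                n_face = int(tok[2])
        elif tok[0] == "property" and element == "vertex" and tok[1] != "list":
            vert_props.append(tok[-1])
        elif tok[0] == "end_header":
            break
    body = text[i:]
    vdata = np.array([r.split() for r in body[:n_vert]], dtype=np.float64)
    ix, iy, iz = (vert_props.index(c) for c in "xyz")
    verts = vdata[:, [ix, iy, iz]]
    labels = None
    if "region" in vert_props:
        labels = vdata[:, vert_props.index("region")].astype(np.int64)
    faces = np.array([r.split()[1:4] for r in body[n_vert:n_vert + n_face]], dtype=np.int64)
    return SurfaceMesh(verts, faces, labels)


def save_stl(mesh: SurfaceMesh, path, binary: bool = True) -> None:
    path = Path(path)
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    normals = mesh.face_normals().astype(np.float32)
    if binary:
        with open(path, "wb") as fh:
            fh.write(b"mirrormetry binary STL".ljust(80, b" "))
            fh.write(struct.pack("<I", mesh.n_faces))
            rec = np.zeros(mesh.n_faces, dtype=[("n", "<3f4"), ("v", "<9f4"), ("attr", "<u2")])
            rec["n"] = normals
            rec["v"] = tri.reshape(-1, 9)
            fh.write(rec.tobytes())
    else:
        out = ["solid mirrormetry"]
        for n, t in zip(normals, tri):
            out.append(f"  facet normal {n[0]:g} {n[1]:g} {n[2]:g}")
            out.append("    outer loop")
            for v in t:
                out.append(f"      vertex {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}")
            out.append("    endloop")
            out.append("  endfacet")
        out.append("endsolid mirrormetry")
        path.write_text("\n".join(out) + "\n")


def load_stl(path) -> SurfaceMesh:
    """Read ASCII or binary STL; vertices are welded exactly."""
    raw = Path(path).read_bytes()
    if raw[:5] == b"solid" and b"facet" in raw[:1000]:
        tris = []
        for line in raw.decode().splitlines():
            tok = line.split()
            if tok and tok[0] == "vertex":
                tris.append([float(tok[1]), float(tok[2]), float(tok[3])])
        tri = np.array(tris, dtype=np.float64).reshape(-1, 3, 3)
    else:
        n_faces = struct.unpack("<I", raw[80:84])[0]
        rec = np.frombuffer(raw[84:], dtype=[("n", "<3f4"), ("v", "<9f4"), ("attr", "<u2")],
                            count=n_faces)
        tri = rec["v"].reshape(-1, 3, 3).astype(np.float64)
    flat = tri.reshape(-1, 3)
    verts, inverse = np.unique(flat, axis=0, return_inverse=True)
    faces = inverse.reshape(-1, 3)
    return SurfaceMesh(verts, faces)


def load_mesh(path) -> SurfaceMesh:
    path = Path(path)
    if path.suffix.lower() == ".ply":
        return load_ply(path)
    if path.suffix.lower() == ".stl":
        return load_stl(path)
    raise MeshError(f"unsupported mesh format: {path.suffix}")
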