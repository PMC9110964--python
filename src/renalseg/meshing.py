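"""Marching-cubes surface extraction from binary masks and STL export.

Meshes carry vertices in physical millimetre coordinates, ordered (x, y, z)
as mesh consumers expect; the conversion from the package's (z, y, x) grid
convention (and the accompanying winding flip) happens once, at extraction.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .core import BinaryMask, MeshError

__all__ = ["SurfaceMesh", "extract_surface", "mesh_measures", "write_stl", "read_stl"]


@dataclass
class SurfaceMesh:
    """Triangulated surface: float vertices (mm, xyz) and int face index triples."""

    vertices: np.ndarray
    faces: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshError("face index out of range")

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_watertight(self) -> bool:
        """Every directed edge used exactly once (so each edge borders 2 faces)."""
        if not self.faces.size:
            return False
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        fwd = {tuple(e) for e in edges.tolist()}
        if len(fwd) != len(edges):
            return False
        return all((b, a) in fwd for a, b in fwd)


def extract_surface(mask: BinaryMask, iso_level: float = 0.5,
                    smoothing_sigma: float = 0.0) -> SurfaceMesh:
    """Marching Cubes on the 0/1 mask field at ``iso_level``.

    The mask is zero-padded by one voxel so objects touching the grid
    boundary still produce closed surfaces.  Faces are oriented outward
    (positive signed volume).  ``smoothing_sigma`` optionally applies a
    Gaussian to the binary field before extraction (off by default to
    preserve volume fidelity).
    """
    if mask.voxel_count == 0:
        raise MeshError("cannot extract a surface from an empty mask")
    fieldv = np.pad(mask.bits.astype(np.float32), 1)
    if smoothing_sigma > 0:
        from scipy import ndimage

        fieldv = ndimage.gaussian_filter(fieldv, sigma=smoothing_sigma)
    verts, faces, _, _ = measure.marching_cubes(fieldv, level=iso_level)
    verts -= 1.0  # undo padding offset (back to mask index coordinates)

    geom = mask.geometry
    phys_zyx = geom.origin + (geom.direction @ (verts * geom.spacing).T).T
    vertices_xyz = phys_zyx[:, ::-1]
    # zyx -> xyz reverses axis order (det -1): flip winding to preserve orientation
    mesh = SurfaceMesh(vertices=vertices_xyz, faces=faces[:, ::-1], label=mask.label)

    signed = _signed_volume(mesh)
    if signed < 0:
        mesh.faces = mesh.faces[:, ::-1]
    return _drop_degenerate(mesh)


def _drop_degenerate(mesh: SurfaceMesh) -> SurfaceMesh:
    v = mesh.vertices[mesh.faces]
    areas = 0.5 * np.linalg.norm(
        np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1
    )
    keep = areas > 1e-12
    mesh.faces = mesh.faces[keep]
    return mesh


def _signed_volume(mesh: SurfaceMesh) -> float:
    v = mesh.vertices[mesh.faces]
    return float(np.einsum("ij,ij->i", v[:, 0], np.cross(v[:, 1], v[:, 2])).sum() / 6.0)


def mesh_measures(mesh: SurfaceMesh) -> tuple[float, float]:
    """(enclosed volume mm^3, surface area mm^2).

    Volume is the absolute sum of signed tetrahedra over faces — reliable
    only for watertight meshes (a warning-free contract left to callers via
    :meth:`SurfaceMesh.is_watertight`).
    """
    v = mesh.vertices[mesh.faces]
    area = float(
        0.5 * np.linalg.norm(np.cross(v[:, 1] - v[:, 0], v[:, 2] - v[:, 0]), axis=1).sum()
    )
    return abs(_signed_volume(mesh)), area


def write_stl(mesh: SurfaceMesh, file_path: str | Path, dialect: str = "binary") -> None:
    """Write an STL file; facet normals are recomputed from vertex winding.

    Binary layout: 80-byte header, uint32 triangle count, then 50 bytes per
    facet (normal, 3 vertices as float32 triples, uint16 attribute).
    """
    if dialect not in ("binary", "ascii"):
        raise ValueError(f"unknown STL dialect {dialect!r}")
    file_path = Path(file_path)
    tri = mesh.vertices[mesh.faces].astype(np.float32)
    normals = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    lengths = np.linalg.norm(normals, axis=1, keepdims=True)
    normals = np.where(lengths > 0, normals / np.maximum(lengths, 1e-30), 0.0).astype(np.float32)

    if dialect == "ascii":
        lines = [f"solid {mesh.label or 'renalseg'}"]
        for n, t in zip(normals, tri):
            lines.append(f"  facet normal {n[0]:.9e} {n[1]:.9e} {n[2]:.9e}")
            lines.append("    outer loop")
            for p in t:
                lines.append(f"      vertex {p[0]:.9e} {p[1]:.9e} {p[2]:.9e}")
            lines.append("    endloop")
            lines.append("  endfacet")
        lines.append(f"endsolid {mesh.label or 'renalseg'}")
        file_path.write_text("\n".join(lines) + "\n")
        return

    with open(file_path, "wb") as fh:
        header = (mesh.label or "renalseg binary STL").encode("ascii", "replace")[:80]
        fh.write(header.ljust(80, b"\x00"))
        fh.write(struct.pack("<I", len(tri)))
        record = np.zeros(
            len(tri),
            dtype=np.dtype(
                [("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]
            ),
        )
        record["normal"] = normals
        record["v"] = tri
        fh.write(record.tobytes())


def read_stl(file_path: str | Path) -> SurfaceMesh:
    """Read a binary or ASCII STL into a vertex-soup mesh (no deduplication)."""
    file_path = Path(file_path)
    data = file_path.read_bytes()
    if data[:5] == b"solid" and b"facet" in data[:1024]:
        return _read_stl_ascii(data.decode("ascii"))
    if len(data) < 84:
        raise MeshError(f"{file_path.name}: too short for a binary STL")
    (count,) = struct.unpack_from("<I", data, 80)
    expected = 84 + 50 * count
    if len(data) < expected:
        raise MeshError(f"{file_path.name}: truncated binary STL")
    record = np.frombuffer(
        data, offset=84, count=count,
        dtype=np.dtype([("normal", "<f4", 3), ("v", "<f4", (3, 3)), ("attr", "<u2")]),
    )
    vertices = record["v"].reshape(-1, 3).astype(float)
    faces = np.arange(3 * count, dtype=np.int64).reshape(-1, 3)
    return SurfaceMesh(vertices=vertices, faces=faces)


def _read_stl_ascii(text: str) -> SurfaceMesh:
    vertices = []
    for line in text.splitlines():
        parts = line.split()
        if parts and parts[0] == "vertex":
            vertices.append([float(x) for x in parts[1:4]])
    vertices = np.array(vertices, dtype=float).reshape(-1, 3)
    faces = np.arange(len(vertices), dtype=np.int64).reshape(-1, 3)
    return SurfaceMesh(vertices=vertices, faces=faces)
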