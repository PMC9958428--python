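"""Stage S5: bone isosurface extraction and STL export.

The isosurface of the trilinearly interpolated HU field at the bone
threshold is triangulated with topology-consistent (Lewiner) marching
cubes, vertices are mapped into world millimetres through the volume
affine, and the triangle soup is written as binary (default) or ASCII STL.

Binary STL layout (little-endian): 80-byte header, uint32 triangle count,
then 50 bytes per facet — 12 float32 (normal, v1, v2, v3) + uint16
attribute. File size is therefore exactly 84 + 50·T bytes.

No smoothing or decimation is applied by default; surfaces where the
iso-set exits the grid remain open (no capping).
"""

from __future__ import annotations

import logging
import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from skimage import measure

from .export_volume import Volume, stack_series
from .noise_removal import ThresholdSpec

log = logging.getLogger(__name__)

_DEGENERATE_AREA = 1e-9  # mm^2
_HEADER = b"ctprep STL export".ljust(80, b"\x00")


@dataclass
class TriangleMesh:
    """Triangle soup: vertices in world mm, index triples, unit facet normals."""

    vertices: np.ndarray  # (V, 3) float64
    triangles: np.ndarray  # (T, 3) int64
    normals: np.ndarray  # (T, 3) float64

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def is_empty(self) -> bool:
        return self.n_triangles == 0

    def edges(self) -> np.ndarray:
        """Unique undirected edges, shape (E, 2)."""
        if self.is_empty():
            return np.empty((0, 2), dtype=np.int64)
        tri = self.triangles
        e = np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]])
        return np.unique(np.sort(e, axis=1), axis=0)

    def euler_characteristic(self) -> int:
        """V − E + F counted on referenced vertices (2 for a closed genus-0 surface)."""
        if self.is_empty():
            return 0
        v = len(np.unique(self.triangles))
        return v - len(self.edges()) + self.n_triangles

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two triangles."""
        if self.is_empty():
            return False
        tri = self.triangles
        e = np.sort(
            np.vstack([tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]]), axis=1
        )
        _, counts = np.unique(e, axis=0, return_counts=True)
        return bool(np.all(counts == 2))

    def surface_area(self) -> float:
        """Total triangle area, mm²."""
        if self.is_empty():
            return 0.0
        v = self.vertices
        t = self.triangles
        cross = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        return float(np.linalg.norm(cross, axis=1).sum() / 2.0)

    def enclosed_volume(self) -> float:
        """Signed volume by the divergence theorem, mm³ (meaningful when closed)."""
        if self.is_empty():
            return 0.0
        v = self.vertices
        t = self.triangles
        return float(
            np.einsum("ij,ij->i", v[t[:, 0]], np.cross(v[t[:, 1]], v[t[:, 2]])).sum()
            / 6.0
        )

    def n_components(self) -> int:
        """Connected components over shared vertices."""
        if self.is_empty():
            return 0
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        e = self.edges()
        nv = int(self.triangles.max()) + 1
        adj = coo_matrix(
            (np.ones(len(e)), (e[:, 0], e[:, 1])), shape=(nv, nv)
        )
        n, labels = connected_components(adj, directed=False)
        return len(np.unique(labels[np.unique(self.triangles)]))


def _accumulate_normals(
    vnormals: np.ndarray, inverse: np.ndarray, n: int
) -> np.ndarray:
    out = np.zeros((n, 3))
    for d in range(3):
        out[:, d] = np.bincount(inverse, weights=vnormals[:, d], minlength=n)
    return out


def _empty_mesh() -> TriangleMesh:
    return TriangleMesh(
        vertices=np.empty((0, 3)),
        triangles=np.empty((0, 3), dtype=np.int64),
        normals=np.empty((0, 3)),
    )


def extract_isosurface(volume: Volume, iso: float) -> TriangleMesh:
    """Marching-cubes triangulation of the HU iso-level set, in world mm.

    Returns an empty mesh when the field never crosses ``iso``.
    """
    vox = np.asarray(volume.voxels, dtype=np.float64)
    if min(vox.shape) < 2:
        raise ValueError("volume needs at least 2 voxels per axis")
    if not (vox.min() < iso < vox.max()):
        return _empty_mesh()

    verts, faces, vnormals, _ = measure.marching_cubes(vox, level=iso)
    # Weld coincident vertices (marching cubes can emit exact duplicates,
    # which show up as zero-area slivers and break edge pairing).
    uniq, inverse = np.unique(verts, axis=0, return_inverse=True)
    vnormals = _accumulate_normals(vnormals, inverse, len(uniq))
    verts = uniq
    faces = inverse[faces]

    # Index space → world mm.
    world = (volume.affine[:3, :3] @ verts.T).T + volume.affine[:3, 3]
    # Normals transform with the inverse-transpose of the linear part.
    nmat = np.linalg.inv(volume.affine[:3, :3]).T
    vnorm_world = (nmat @ vnormals.T).T

    tri = faces.astype(np.int64)
    tri = tri[
        (tri[:, 0] != tri[:, 1]) & (tri[:, 1] != tri[:, 2]) & (tri[:, 0] != tri[:, 2])
    ]
    cross = np.cross(
        world[tri[:, 1]] - world[tri[:, 0]], world[tri[:, 2]] - world[tri[:, 0]]
    )
    areas2 = np.linalg.norm(cross, axis=1)
    keep = areas2 / 2.0 > _DEGENERATE_AREA
    tri, cross = tri[keep], cross[keep]
    if len(tri) == 0:
        return _empty_mesh()

    # Make winding agree with the outward (descending-HU) vertex normals:
    # flip all faces if the majority of facet normals oppose them.
    facet_ref = (
        vnorm_world[tri[:, 0]] + vnorm_world[tri[:, 1]] + vnorm_world[tri[:, 2]]
    )
    agree = np.einsum("ij,ij->i", cross, facet_ref)
    if np.sum(agree < 0) > len(agree) / 2:
        tri = tri[:, [0, 2, 1]]
        cross = -cross
    normals = cross / np.linalg.norm(cross, axis=1, keepdims=True)
    return TriangleMesh(vertices=world, triangles=tri, normals=normals)


def write_stl(
    mesh: TriangleMesh,
    out_path: str | Path,
    mode: Literal["binary", "ascii"] = "binary",
) -> Path:
    """Write the mesh as STL. An empty mesh yields a valid 0-triangle file."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    if mode == "binary":
        _write_binary(mesh, out_path)
    elif mode == "ascii":
        _write_ascii(mesh, out_path)
    else:
        raise ValueError(f"unknown STL mode {mode!r}")
    return out_path


def _write_binary(mesh: TriangleMesh, out_path: Path) -> None:
    t = mesh.n_triangles
    # 50-byte facet records via a packed structured dtype.
    rec = np.zeros(
        t,
        dtype=np.dtype(
            [("normal", "<f4", 3), ("verts", "<f4", (3, 3)), ("attr", "<u2")],
            align=False,
        ),
    )
    if t:
        rec["normal"] = mesh.normals.astype(np.float32)
        rec["verts"] = mesh.vertices[mesh.triangles].astype(np.float32)
    with open(out_path, "wb") as fh:
        fh.write(_HEADER)
        fh.write(struct.pack("<I", t))
        fh.write(rec.tobytes())


def _write_ascii(mesh: TriangleMesh, out_path: Path) -> None:
    lines = ["solid ctprep"]
    v32 = mesh.vertices.astype(np.float32)
    n32 = mesh.normals.astype(np.float32)
    for i, tri in enumerate(mesh.triangles):
        n = n32[i]
        lines.append(f"  facet normal {n[0]:e} {n[1]:e} {n[2]:e}")
        lines.append("    outer loop")
        for vi in tri:
            v = v32[vi]
            lines.append(f"      vertex {v[0]:e} {v[1]:e} {v[2]:e}")
        lines.append("    endloop")
        lines.append("  endfacet")
    lines.append("endsolid ctprep")
    out_path.write_text("\n".join(lines) + "\n")


def decimate(mesh: TriangleMesh, fraction: float) -> TriangleMesh:
    """Crude vertex-clustering decimation to ~``fraction`` of the triangles.

    Vertices are snapped to a uniform grid sized so the expected triangle
    count shrinks by ``fraction``; collapsed triangles vanish. Intended as
    an opt-in size reducer, not a quality simplifier.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    if mesh.is_empty():
        return mesh
    span = mesh.vertices.max(axis=0) - mesh.vertices.min(axis=0)
    # Triangle count scales roughly with (span/cell)^2 for a surface.
    target_cells = max(2.0, np.sqrt(mesh.n_triangles * fraction / 2.0))
    cell = float(span.max()) / target_cells
    keys = np.floor((mesh.vertices - mesh.vertices.min(axis=0)) / cell).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    new_verts = np.zeros((len(uniq), 3))
    counts = np.bincount(inverse)
    for d in range(3):
        new_verts[:, d] = np.bincount(inverse, weights=mesh.vertices[:, d]) / counts
    tri = inverse[mesh.triangles]
    keep = (tri[:, 0] != tri[:, 1]) & (tri[:, 1] != tri[:, 2]) & (tri[:, 0] != tri[:, 2])
    tri = tri[keep]
    if len(tri) == 0:
        return _empty_mesh()
    cross = np.cross(
        new_verts[tri[:, 1]] - new_verts[tri[:, 0]],
        new_verts[tri[:, 2]] - new_verts[tri[:, 0]],
    )
    norms = np.linalg.norm(cross, axis=1)
    ok = norms / 2.0 > _DEGENERATE_AREA
    tri, cross, norms = tri[ok], cross[ok], norms[ok]
    return TriangleMesh(new_verts, tri, cross / norms[:, None])


def series_to_stl(
    series_dir: str | Path,
    spec: ThresholdSpec,
    out_path: str | Path,
    mode: Literal["binary", "ascii"] = "binary",
    decimate_fraction: float | None = None,
) -> Path:
    """stack_series → isosurface at the bone threshold → STL file."""
    volume = stack_series(series_dir)
    mesh = extract_isosurface(volume, spec.bone_lower)
    if decimate_fraction is not None:
        mesh = decimate(mesh, decimate_fraction)
    log.info(
        "%s: %d triangles at iso %.0f HU", series_dir, mesh.n_triangles, spec.bone_lower
    )
    return write_stl(mesh, out_path, mode=mode)
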