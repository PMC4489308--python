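"""Star-shaped scattering envelope built from a subdivided icosahedron.

The envelope separates the "inside" region — solute plus hydration
shell — from bulk solvent; only atoms inside it enter the scattering
amplitudes.  It is built once, from all frames of the solute
trajectory, by pushing each icosphere vertex radially outward until it
is at least a distance d (7 Å by default) from every solute atom of
every frame, and the same surface is then reused for the whole
downstream calculation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, cKDTree

__all__ = [
    "TriangulatedSphere",
    "Envelope",
    "build_icosphere",
    "build_envelope",
    "DEFAULT_ENVELOPE_DISTANCE",
    "DEFAULT_ICOSPHERE_DEPTH",
]

DEFAULT_ENVELOPE_DISTANCE = 7.0  # Å
DEFAULT_ICOSPHERE_DEPTH = 4  # 2562 vertices
_MIN_RADIUS = 1e-3  # Å, floor for rays that see no atom


@dataclass(frozen=True)
class TriangulatedSphere:
    """Unit-sphere triangle mesh: vertices (V,3) with |v|=1, faces (F,3)."""

    vertices: np.ndarray
    faces: np.ndarray

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def euler_characteristic(self) -> int:
        edges = set()
        for f in self.faces:
            for i in range(3):
                e = (min(f[i], f[(i + 1) % 3]), max(f[i], f[(i + 1) % 3]))
                edges.add(e)
        return self.n_vertices - len(edges) + self.n_faces


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=int,
    )
    return verts, faces


def _orient_outward(verts: np.ndarray, faces: np.ndarray) -> np.ndarray:
    v0, v1, v2 = verts[faces[:, 0]], verts[faces[:, 1]], verts[faces[:, 2]]
    normals = np.cross(v1 - v0, v2 - v0)
    centers = (v0 + v1 + v2) / 3.0
    flip = np.einsum("ij,ij->i", normals, centers) < 0
    faces = faces.copy()
    faces[flip] = faces[flip][:, [0, 2, 1]]
    return faces


def build_icosphere(depth: int) -> TriangulatedSphere:
    """Recursively subdivide an icosahedron ``depth`` times.

    Each subdivision splits every triangle into four by inserting edge
    midpoints projected back onto the unit sphere, giving 10·4^depth + 2
    vertices and 20·4^depth faces.
    """
    if depth < 0:
        raise ValueError("subdivision depth must be non-negative")
    if depth > 8:
        raise ValueError("subdivision depth > 8 is not supported (resource guard)")
    verts, faces = _icosahedron()
    for _ in range(depth):
        verts_list = list(verts)
        midpoint_cache: dict[tuple[int, int], int] = {}

        def midpoint(i: int, j: int) -> int:
            key = (min(i, j), max(i, j))
            if key not in midpoint_cache:
                m = verts_list[i] + verts_list[j]
                m /= np.linalg.norm(m)
                midpoint_cache[key] = len(verts_list)
                verts_list.append(m)
            return midpoint_cache[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca = midpoint(a, b), midpoint(b, c), midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        verts = np.array(verts_list)
        faces = np.array(new_faces, dtype=int)
    verts /= np.linalg.norm(verts, axis=1, keepdims=True)
    return TriangulatedSphere(vertices=verts, faces=_orient_outward(verts, faces))


class Envelope:
    """The built envelope: center, per-vertex directions/radii, faces.

    The surface point along vertex direction u_k is center + r_k u_k;
    between vertices the surface is the planar triangle through the
    three surface points, so point containment is exact ray–mesh
    containment for the star-shaped mesh.
    """

    def __init__(
        self,
        center: np.ndarray,
        directions: np.ndarray,
        radii: np.ndarray,
        faces: np.ndarray,
        build_distance: float,
    ):
        self.center = np.asarray(center, dtype=float)
        self.directions = np.asarray(directions, dtype=float)
        self.radii = np.asarray(radii, dtype=float)
        self.faces = np.asarray(faces, dtype=int)
        self.build_distance = float(build_distance)
        if np.any(self.radii <= 0):
            raise ValueError("all envelope radii must be positive")
        self._surface = self.center + self.radii[:, None] * self.directions
        # Per-face inverse vertex matrices: for direction u, s = M_f u has
        # all components >= 0 iff u falls in face f's cone, and the
        # surface distance along u is 1 / sum(s).
        tri = self._surface[self.faces] - self.center  # (F, 3, 3) rows=verts
        self._face_inv = np.linalg.inv(np.transpose(tri, (0, 2, 1)))
        centers = tri.mean(axis=1)
        self._face_tree = cKDTree(centers / np.linalg.norm(centers, axis=1, keepdims=True))
        self._dir_tree = cKDTree(self.directions)

    # -- geometry ----------------------------------------------------------

    @property
    def surface_vertices(self) -> np.ndarray:
        """(V, 3) absolute surface-vertex positions in Å."""
        return self._surface

    def surface_radius(self, points: np.ndarray) -> np.ndarray:
        """Distance from the center to the surface along each point's
        direction (the point's own radius is irrelevant)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float)) - self.center
        r = np.linalg.norm(pts, axis=1)
        out = np.empty(len(pts))
        zero = r < 1e-12
        out[zero] = np.min(self.radii)
        idx = np.nonzero(~zero)[0]
        if len(idx):
            dirs = pts[idx] / r[idx, None]
            out[idx] = self._radius_along(dirs)
        return out

    def _radius_along(self, dirs: np.ndarray, k: int = 24) -> np.ndarray:
        k = min(k, len(self.faces))
        _, cand = self._face_tree.query(dirs, k=k)
        cand = np.atleast_2d(cand)
        # s[i, j, :] = M_{face cand[i,j]} @ dirs[i]
        s = np.einsum("ijkl,il->ijk", self._face_inv[cand], dirs)
        ok = np.all(s >= -1e-9, axis=2)
        out = np.full(len(dirs), -1.0)
        hit_any = ok.any(axis=1)
        first = np.argmax(ok, axis=1)
        rows = np.nonzero(hit_any)[0]
        ssum = s[rows, first[rows]].sum(axis=1)
        out[rows] = 1.0 / ssum
        miss = np.nonzero(~hit_any)[0]
        for i in miss:  # rare: fall back to a full scan
            s_all = np.einsum("jkl,l->jk", self._face_inv, dirs[i])
            ok_all = np.all(s_all >= -1e-9, axis=1)
            j = int(np.argmax(ok_all))
            if not ok_all[j]:
                j = int(np.argmin(np.max(np.maximum(-s_all, 0.0), axis=1)))
            out[i] = 1.0 / s_all[j].sum()
        return out

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorised inside-test; ties on the surface resolve to inside."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts - self.center, axis=1)
        inside = r <= self.surface_radius(pts) + 1e-9
        if np.asarray(points).ndim == 1:
            return bool(inside[0])
        return inside

    def select_inside(self, frame_coords: np.ndarray) -> np.ndarray:
        """Indices of atoms whose coordinates lie inside the envelope.

        Selection is atom-wise: a water molecule may be split by the
        boundary, mirroring a density (not molecule) partition.
        """
        return np.nonzero(self.contains(frame_coords))[0]

    def diameter(self) -> float:
        """Maximum pairwise distance between surface vertices (Å)."""
        pts = self._surface
        if len(pts) > 16:
            try:
                pts = pts[ConvexHull(pts).vertices]
            except Exception:
                pass
        d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))

    def volume(self) -> float:
        """Mesh volume (Å³) as a sum of signed tetrahedra from the center."""
        tri = self._surface[self.faces] - self.center
        return float(np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)

    def export_obj(self, path) -> None:
        """Write the surface as a Wavefront OBJ mesh for visualisation."""
        with open(path, "w") as fh:
            fh.write("# solvaxs envelope mesh\n")
            for v in self._surface:
                fh.write(f"v {v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
            for f in self.faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")


def build_envelope(
    solute_frames: np.ndarray,
    d: float = DEFAULT_ENVELOPE_DISTANCE,
    depth: int = DEFAULT_ICOSPHERE_DEPTH,
) -> Envelope:
    """Build the envelope from solute coordinates of all frames.

    Parameters
    ----------
    solute_frames : (n_frames, n_atoms, 3) or (n_atoms, 3) array, Å
    d : minimum vertex distance from every solute atom, Å
    depth : icosphere subdivision depth (4 ≈ 2562 vertices by default)

    For each vertex direction u the radius is the largest
    t_a + sqrt(d² − ρ_a²) over atoms whose perpendicular distance ρ_a to
    the ray is < d (t_a the along-ray coordinate) — the exit point of
    the ray from the union of atom-centered spheres of radius d.  This
    guarantees every vertex is ≥ d from every atom of every frame.
    """
    frames = np.asarray(solute_frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3 or frames.shape[0] == 0:
        raise ValueError("solute_frames must be (n_frames, n_atoms, 3) with ≥ 1 frame")
    if d <= 0:
        raise ValueError("envelope distance d must be positive")
    sphere = build_icosphere(depth)
    atoms = frames.reshape(-1, 3)
    center = atoms.mean(axis=0)
    rel = atoms - center  # (N, 3)
    radii = np.full(sphere.n_vertices, _MIN_RADIUS)
    # chunk over vertices to bound memory at O(chunk * N)
    chunk = max(1, int(5e7 // max(len(rel), 1)))
    for lo in range(0, sphere.n_vertices, chunk):
        u = sphere.vertices[lo : lo + chunk]  # (V, 3)
        t = u @ rel.T  # (V, N) along-ray coordinate
        rho2 = np.maximum(np.sum(rel ** 2, axis=1)[None, :] - t ** 2, 0.0)
        close = rho2 < d * d
        cand = np.where(close, t + np.sqrt(np.maximum(d * d - rho2, 0.0)), -np.inf)
        radii[lo : lo + chunk] = np.maximum(cand.max(axis=1), _MIN_RADIUS)
    return Envelope(
        center=center,
        directions=sphere.vertices,
        radii=radii,
        faces=sphere.faces,
        build_distance=d,
    )
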