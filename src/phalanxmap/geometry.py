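"""Canonical anatomical frame, mesh ingestion, orientation and length measurement.

All downstream analysis assumes a bone expressed in a canonical right-handed
frame: ``u`` (x) runs proximal → distal, ``v`` (y) points dorsal, and
``w = u × v`` (z) points radial for a right-side bone.  The origin sits at the
proximal extreme of the outer (periosteal) surface, so the u-coordinate of any
point is its distance from the proximal end.

Phalanges bow palmarly: cross-section centroids deviate toward the palm
relative to the proximodistal chord.  Automatic orientation exploits this to
sign the dorsal axis, and uses the broader metaphyseal base (versus the
narrower trochlea) to sign the proximodistal axis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import trimesh

__all__ = [
    "TriSurface",
    "AnatomicalFrame",
    "BoneSurfacePair",
    "FormatError",
    "OrientationError",
    "load_surface",
    "orient_anatomical",
    "max_length",
    "mirror_to_right",
]

#: minimum ratio of first to second principal extent below which a mesh is
#: considered too isotropic to orient automatically
ELONGATION_RATIO_MIN = 1.2


class FormatError(ValueError):
    """Raised when a mesh file cannot be parsed as a triangle mesh."""


class OrientationError(ValueError):
    """Raised when automatic anatomical orientation is impossible."""


@dataclass
class TriSurface:
    """A cleaned triangle mesh (vertices in mm)."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be an (n, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be an (m, 3) array of vertex triples")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise FormatError("face references a vertex that does not exist")

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "TriSurface":
        """Return the surface with vertices mapped ``x -> R x + t``."""
        return TriSurface(self.vertices @ np.asarray(rotation).T + translation, self.faces)

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.faces.copy())


@dataclass
class AnatomicalFrame:
    """Right-handed orthonormal frame: u proximal→distal, v dorsal, w = u × v."""

    origin: np.ndarray
    u_prox_dist: np.ndarray
    v_dorsal: np.ndarray
    w_radial: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.u_prox_dist = np.asarray(self.u_prox_dist, dtype=float)
        self.v_dorsal = np.asarray(self.v_dorsal, dtype=float)
        self.w_radial = np.asarray(self.w_radial, dtype=float)
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("frame axes must be orthonormal")
        if not np.allclose(np.cross(self.u_prox_dist, self.v_dorsal), self.w_radial, atol=1e-6):
            raise ValueError("frame must be right-handed (u × v = w)")

    @property
    def rotation(self) -> np.ndarray:
        """Rows are the frame axes: maps world coords to frame coords."""
        return np.vstack([self.u_prox_dist, self.v_dorsal, self.w_radial])

    @classmethod
    def identity(cls) -> "AnatomicalFrame":
        return cls(np.zeros(3), np.array([1.0, 0, 0]), np.array([0, 1.0, 0]), np.array([0, 0, 1.0]))


@dataclass
class BoneSurfacePair:
    """A specimen: paired outer (periosteal) and inner (endosteal) surfaces.

    After :func:`orient_anatomical` the vertex coordinates are expressed in the
    canonical frame directly (x = u, y = v, z = w, origin at the proximal
    extreme); ``frame`` records the frame in the original input coordinates.
    """

    outer: TriSurface
    inner: TriSurface
    frame: Optional[AnatomicalFrame] = None
    side: Optional[str] = None          # "left" | "right"
    label: str = ""
    element: str = "PP"                 # "PP" | "IP"
    digit: Optional[int] = None
    specimen_id: str = ""
    oriented: bool = False
    meta: dict = field(default_factory=dict)

    def copy(self) -> "BoneSurfacePair":
        return dataclasses.replace(self, outer=self.outer.copy(), inner=self.inner.copy(),
                                   meta=dict(self.meta))

    def check_nested(self, n_samples: int = 200, seed: int = 0) -> bool:
        """Verify the inner surface lies inside the outer by point containment."""
        rng = np.random.default_rng(seed)
        mesh = self.outer.to_trimesh()
        if not mesh.is_watertight:
            return True  # cropped/open surfaces cannot be tested this way
        idx = rng.choice(len(self.inner.vertices), size=min(n_samples, len(self.inner.vertices)),
                         replace=False)
        # pull sample points slightly toward the inner centroid to dodge
        # coincident-surface edge cases
        pts = self.inner.vertices[idx]
        pts = pts + 1e-6 * (pts.mean(axis=0) - pts)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        tri = self.outer.vertices[self.outer.faces]
        return all(_ray_crossings(p, direction, tri) % 2 == 1 for p in pts)


def _ray_crossings(origin: np.ndarray, direction: np.ndarray, triangles: np.ndarray) -> int:
    """Number of ray–triangle crossings (vectorized Möller–Trumbore)."""
    v0, v1, v2 = triangles[:, 0], triangles[:, 1], triangles[:, 2]
    e1, e2 = v1 - v0, v2 - v0
    p = np.cross(direction, e2)
    det = np.einsum("ij,ij->i", e1, p)
    ok = np.abs(det) > 1e-12
    inv = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)
    tvec = origin - v0
    u = np.einsum("ij,ij->i", tvec, p) * inv
    q = np.cross(tvec, e1)
    v = np.einsum("ij,j->i", q, direction) * inv
    t = np.einsum("ij,ij->i", q, e2) * inv
    hit = ok & (u >= 0) & (v >= 0) & (u + v <= 1) & (t > 1e-9)
    return int(hit.sum())


# ---------------------------------------------------------------------------
# ingestion


def load_surface(path: str | Path, format: Optional[str] = None) -> TriSurface:
    """Load a triangle mesh (PLY/OBJ/STL), merging duplicate vertices and
    dropping degenerate (zero-area) faces.

    Raises :class:`FormatError` if the file is unreadable or not a triangle mesh.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), file_type=format.lower() if format else None)
    except Exception as exc:  # noqa: BLE001 — trimesh raises many types
        raise FormatError(f"could not parse {path.name} as a triangle mesh: {exc}") from exc
    if isinstance(mesh, trimesh.Scene):
        geoms = list(mesh.geometry.values())
        if not geoms:
            raise FormatError(f"{path.name}: file contains no mesh geometry")
        mesh = trimesh.util.concatenate(geoms)
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise FormatError(f"{path.name}: no triangulated faces found")
    mesh.merge_vertices()
    areas = mesh.area_faces
    mesh.update_faces(areas > 1e-12)
    mesh.remove_unreferenced_vertices()
    if len(mesh.faces) == 0:
        raise FormatError(f"{path.name}: all faces degenerate after cleanup")
    return TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces))


def save_surface(surface: TriSurface, path: str | Path) -> None:
    """Write a surface to PLY/OBJ/STL (chosen by extension)."""
    surface.to_trimesh().export(str(path))


# ---------------------------------------------------------------------------
# orientation


def _principal_axes(vertices: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decomposition of the vertex scatter; axes as rows, descending."""
    centered = vertices - vertices.mean(axis=0)
    cov = centered.T @ centered / len(centered)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order].T


def _slice_spread(coords_u: np.ndarray, radial: np.ndarray, lo: float, hi: float) -> float:
    """RMS radial distance from the axis for vertices with u in [lo, hi] quantile span."""
    u0, u1 = coords_u.min(), coords_u.max()
    mask = (coords_u >= u0 + lo * (u1 - u0)) & (coords_u <= u0 + hi * (u1 - u0))
    if not mask.any():
        return 0.0
    return float(np.sqrt(np.mean(radial[mask] ** 2)))


def orient_anatomical(pair: BoneSurfacePair,
                      hints: Optional[dict] = None) -> BoneSurfacePair:
    """Reorient a bone into the canonical anatomical frame.

    The proximodistal axis ``u`` is the dominant principal axis of the outer
    vertex scatter, signed so the broader end (larger RMS section spread over
    the end decile) is proximal.  The dorsal axis ``v`` is the second principal
    axis, signed away from the mean palmar deviation of per-slice centroids
    from the chord (phalanges bow palmarly).  Both signs can be overridden via
    ``hints`` (keys ``"u"`` and/or ``"v"``: approximate world-space directions).

    Raises :class:`OrientationError` for near-isotropic vertex scatter
    (elongation ratio < ``ELONGATION_RATIO_MIN``).
    """
    hints = hints or {}
    verts = pair.outer.vertices
    if len(verts) < 4:
        raise OrientationError("need at least 4 outer vertices")
    evals, axes = _principal_axes(verts)
    if evals[1] <= 0 or np.sqrt(evals[0] / max(evals[1], 1e-300)) < ELONGATION_RATIO_MIN:
        raise OrientationError(
            f"vertex scatter too isotropic to orient (elongation ratio "
            f"{np.sqrt(evals[0] / max(evals[1], 1e-300)):.3f} < {ELONGATION_RATIO_MIN})")

    u = axes[0]
    if "u" in hints:
        if np.dot(u, np.asarray(hints["u"], dtype=float)) < 0:
            u = -u
    else:
        cu = verts @ u
        radial = np.linalg.norm(verts - verts.mean(axis=0)
                                - np.outer(cu - cu.mean(), u), axis=1)
        # broader metaphyseal base is proximal: want spread(min end) > spread(max end)
        if _slice_spread(cu, radial, 0.0, 0.1) < _slice_spread(cu, radial, 0.9, 1.0):
            u = -u

    v = axes[1]
    v = v - np.dot(v, u) * u
    v /= np.linalg.norm(v)
    if "v" in hints:
        if np.dot(v, np.asarray(hints["v"], dtype=float)) < 0:
            v = -v
    else:
        # per-slice centroid deviation from the chord, projected on v;
        # centroids deviate palmarly, so dorsal is the opposite sign
        cu = verts @ u
        nbins = 20
        edges = np.linspace(cu.min(), cu.max(), nbins + 1)
        which = np.clip(np.searchsorted(edges, cu, side="right") - 1, 0, nbins - 1)
        devs = []
        cv = verts @ v
        for b in range(nbins):
            m = which == b
            if m.sum() >= 3:
                devs.append(cv[m].mean())
        devs = np.asarray(devs)
        if devs.size >= 3:
            # deviation relative to the line joining end-bin centroids
            trend = np.linspace(devs[0], devs[-1], devs.size)
            palmar_dev = float(np.mean(devs - trend))
            if palmar_dev > 0:
                v = -v
    w = np.cross(u, v)

    R = np.vstack([u, v, w])  # world -> canonical
    out_v = pair.outer.vertices @ R.T
    in_v = pair.inner.vertices @ R.T
    origin_u = out_v[:, 0].min()
    shift = np.array([origin_u, 0.0, 0.0])
    out_v = out_v - shift
    in_v = in_v - shift
    origin_world = R.T @ shift  # frame origin expressed in input coordinates
    frame = AnatomicalFrame(origin=origin_world, u_prox_dist=u, v_dorsal=v, w_radial=w)
    new = pair.copy()
    new.outer = TriSurface(out_v, pair.outer.faces.copy())
    new.inner = TriSurface(in_v, pair.inner.faces.copy())
    new.frame = frame
    new.oriented = True
    return new


def max_length(pair: BoneSurfacePair) -> float:
    """Maximum proximodistal length: extent of the outer surface along u (mm)."""
    if not pair.oriented:
        raise ValueError("pair must be oriented before measuring max length")
    cu = pair.outer.vertices[:, 0]
    return float(cu.max() - cu.min())


def mirror_to_right(pair: BoneSurfacePair) -> BoneSurfacePair:
    """Reflect left-side bones across the sagittal (u–v) plane so that all
    bones share the right-side map convention; right bones pass through
    unchanged."""
    if pair.side not in ("left", "right"):
        raise ValueError("side is unknown; assign side='left' or 'right' explicitly")
    if pair.side == "right":
        return pair
    new = pair.copy()
    for surf in (new.outer, new.inner):
        surf.vertices[:, 2] *= -1.0
        # flip winding to keep outward normals after reflection
        surf.faces = surf.faces[:, ::-1].copy()
    new.side = "right"
    new.meta["mirrored_from_left"] = True
    return new
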