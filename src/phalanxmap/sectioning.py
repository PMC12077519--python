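"""Shaft definition, cross-sectioning, equiangular semi-landmarks, thickness maps.

The analysis window (the "defined shaft", by default 20–80% of maximum bone
length) is sliced into 97 cross-sections at 1% intervals from 2% to 98% of
shaft length.  On each section, 50 rays are cast outward from the area
centroid of the outer contour at equal angular spacing starting mid-dorsally;
the semi-landmark pair on a ray is the farthest ray–contour intersection on
the outer and inner contour, and cortical thickness is the distance between
them.  Stacking the 97 sections × 50 rays produces the unrolled morphometric
map of cortical bone distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import trimesh

from .geometry import BoneSurfacePair, TriSurface, max_length

__all__ = [
    "ShaftWindow",
    "CrossSection",
    "LandmarkedSection",
    "ThicknessMap",
    "SectioningError",
    "LandmarkError",
    "define_shaft",
    "extract_sections",
    "place_landmarks",
    "build_thickness_map",
    "compute_thickness_map",
]

log = logging.getLogger("phalanxmap")

N_LEVELS = 97
N_ANGLES = 50
LEVEL_SPAN = (0.02, 0.98)
DEFAULT_WINDOW = (0.20, 0.80)


class SectioningError(RuntimeError):
    pass


class LandmarkError(RuntimeError):
    pass


@dataclass(frozen=True)
class ShaftWindow:
    """Analysis window as fractions of maximum bone length from the proximal end."""

    start_frac: float = DEFAULT_WINDOW[0]
    end_frac: float = DEFAULT_WINDOW[1]

    def __post_init__(self) -> None:
        if not (0.0 <= self.start_frac < self.end_frac <= 1.0):
            raise ValueError(
                f"invalid shaft window ({self.start_frac}, {self.end_frac}): "
                "need 0 <= start < end <= 1")


@dataclass
class CrossSection:
    """One planar slice: closed outer contour, optional inner contour, in (v, w) mm."""

    level_frac: float               # fraction of shaft length, proximal origin
    x: float                        # u-coordinate of the slicing plane (mm)
    outer_contour: np.ndarray       # (n, 2) CCW closed polygon (v, w)
    inner_contour: Optional[np.ndarray]
    centroid: np.ndarray            # area centroid of outer contour
    n_outer_loops: int = 1
    n_inner_loops: int = 0


@dataclass
class LandmarkedSection:
    level_frac: float
    angles: np.ndarray              # (k,) radians from mid-dorsal
    outer_pts: np.ndarray           # (k, 2)
    inner_pts: np.ndarray           # (k, 2)
    thickness: np.ndarray           # (k,) mm
    solid: np.ndarray               # (k,) bool — inner contour absent/missed


@dataclass
class ThicknessMap:
    """Unrolled level × angle matrix of cortical thickness.

    Rows run proximal → distal over shaft-length fractions; columns start at
    mid-dorsal and advance toward the radial side (right-bone convention).
    ``mask`` marks cells where the cortex filled the whole ray (no endosteal
    hit) and the centroid-to-outer distance was recorded instead.
    """

    values: np.ndarray              # (n_levels, n_angles)
    mask: np.ndarray                # bool, True = flagged (solid) cell
    levels: np.ndarray              # shaft-length fractions
    angles: np.ndarray              # radians from mid-dorsal
    bone_length: float              # maximum bone length, mm
    standardized: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")
        if np.any(self.values < 0):
            raise ValueError("thickness values must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "ThicknessMap":
        return ThicknessMap(self.values.copy(), self.mask.copy(), self.levels.copy(),
                            self.angles.copy(), self.bone_length, self.standardized,
                            dict(self.meta))

    # -- plain-text round trip ------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the map as CSV (header: angles in degrees; index: level fractions),
        with the mask and metadata in sidecar files."""
        import json
        import pandas as pd
        path = Path(path)
        df = pd.DataFrame(self.values,
                          index=np.round(self.levels, 6),
                          columns=np.round(np.degrees(self.angles), 4))
        df.index.name = "level_frac"
        df.to_csv(path, float_format="%.9g")
        pd.DataFrame(self.mask.astype(int), index=df.index, columns=df.columns) \
            .to_csv(path.with_suffix(".mask.csv"))
        meta = {"bone_length": self.bone_length, "standardized": self.standardized,
                **self.meta}
        path.with_suffix(".meta.json").write_text(json.dumps(meta, indent=2, default=str))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ThicknessMap":
        import json
        import pandas as pd
        path = Path(path)
        df = pd.read_csv(path, index_col=0)
        meta = json.loads(path.with_suffix(".meta.json").read_text())
        mask_path = path.with_suffix(".mask.csv")
        mask = (pd.read_csv(mask_path, index_col=0).to_numpy().astype(bool)
                if mask_path.exists() else np.zeros(df.shape, dtype=bool))
        length = float(meta.pop("bone_length"))
        std = bool(meta.pop("standardized"))
        return cls(df.to_numpy(), mask, df.index.to_numpy(dtype=float),
                   np.radians(df.columns.to_numpy(dtype=float)), length, std, meta)


# ---------------------------------------------------------------------------
# shaft cropping


def define_shaft(pair: BoneSurfacePair,
                 window: ShaftWindow = ShaftWindow()) -> tuple[BoneSurfacePair, ShaftWindow]:
    """Crop both surfaces to the analysis window along u.

    Returns the cropped pair (crop planes recorded in ``meta``) and the
    resolved window.  Raises :class:`SectioningError` if a cut empties a
    surface.
    """
    if not pair.oriented:
        raise ValueError("pair must be oriented before shaft definition")
    L = max_length(pair)
    u0 = float(pair.outer.vertices[:, 0].min())
    x0 = u0 + window.start_frac * L
    x1 = u0 + window.end_frac * L
    new = pair.copy()
    for name in ("outer", "inner"):
        surf: TriSurface = getattr(new, name)
        mesh = surf.to_trimesh()
        if window.start_frac > 0.0:
            mesh = trimesh.intersections.slice_mesh_plane(mesh, [1, 0, 0], [x0, 0, 0])
        if window.end_frac < 1.0:
            mesh = trimesh.intersections.slice_mesh_plane(mesh, [-1, 0, 0], [x1, 0, 0])
        if mesh is None or len(mesh.faces) == 0:
            raise SectioningError(f"cropping removed the whole {name} surface")
        setattr(new, name, TriSurface(np.asarray(mesh.vertices), np.asarray(mesh.faces)))
    new.meta.update(shaft_window=(window.start_frac, window.end_frac),
                    shaft_x0=x0, shaft_x1=x1, bone_length=L)
    return new, window


# ---------------------------------------------------------------------------
# plane sections


def _stitch_loops(segments: np.ndarray, decimals: int = 7) -> list[np.ndarray]:
    """Join (n, 2, 3) intersection segments into closed 3D loops."""
    if len(segments) == 0:
        return []
    keys = np.round(segments, decimals)
    keymap: dict[tuple, list[int]] = {}
    for i, seg in enumerate(keys):
        for end in (0, 1):
            keymap.setdefault(tuple(seg[end]), []).append(2 * i + end)
    used = np.zeros(len(segments), dtype=bool)
    loops = []
    for start in range(len(segments)):
        if used[start]:
            continue
        used[start] = True
        loop = [segments[start][0], segments[start][1]]
        loop_keys = [tuple(keys[start][0]), tuple(keys[start][1])]
        while True:
            tail = loop_keys[-1]
            nxt = None
            for code in keymap.get(tail, []):
                i, end = code // 2, code % 2
                if not used[i]:
                    nxt = (i, end)
                    break
            if nxt is None:
                break
            i, end = nxt
            used[i] = True
            loop.append(segments[i][1 - end])
            loop_keys.append(tuple(keys[i][1 - end]))
            if loop_keys[-1] == loop_keys[0]:
                break
        if len(loop) >= 4 and loop_keys[-1] == loop_keys[0]:
            loops.append(np.asarray(loop[:-1]))
    return loops


def _signed_area(poly: np.ndarray) -> float:
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def _slice_contours(mesh_verts: np.ndarray, mesh_faces: np.ndarray,
                    x: float) -> list[np.ndarray]:
    """All closed contours of the plane u = x with the mesh, as (n, 2) CCW
    polygons in (v, w) coordinates, sorted by descending |area|."""
    mesh = trimesh.Trimesh(mesh_verts, mesh_faces, process=False)
    segs = trimesh.intersections.mesh_plane(mesh, np.array([1.0, 0, 0]),
                                            np.array([x, 0.0, 0.0]))
    loops = _stitch_loops(np.asarray(segs))
    polys = []
    for loop in loops:
        p = loop[:, 1:3]
        a = _signed_area(p)
        if abs(a) < 1e-9:
            continue
        if a < 0:
            p = p[::-1]
        polys.append(p)
    polys.sort(key=lambda p: -abs(_signed_area(p)))
    return polys


def _area_centroid(poly: np.ndarray) -> np.ndarray:
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    a = 0.5 * cross.sum()
    cx = np.sum((x + x1) * cross) / (6 * a)
    cy = np.sum((y + y1) * cross) / (6 * a)
    return np.array([cx, cy])


def extract_sections(shaft: BoneSurfacePair, n_levels: int = N_LEVELS,
                     span: tuple[float, float] = LEVEL_SPAN) -> list[CrossSection]:
    """Slice the cropped shaft into ``n_levels`` sections over ``span`` of
    shaft length (defaults: 97 sections from 2% to 98% at 1% intervals).

    For each surface the largest closed loop is kept; extra loops are counted
    and logged.  Raises :class:`SectioningError` if any level yields no closed
    outer contour.
    """
    if "shaft_x0" not in shaft.meta:
        raise ValueError("shaft must come from define_shaft (crop planes missing)")
    x0, x1 = shaft.meta["shaft_x0"], shaft.meta["shaft_x1"]
    if n_levels == N_LEVELS and span == LEVEL_SPAN:
        levels = 0.02 + 0.01 * np.arange(N_LEVELS)
    else:
        levels = np.linspace(span[0], span[1], n_levels)
    sections = []
    for f in levels:
        x = x0 + f * (x1 - x0)
        outer_polys = _slice_contours(shaft.outer.vertices, shaft.outer.faces, x)
        if not outer_polys:
            raise SectioningError(f"no closed outer contour at shaft level {f:.2f}")
        inner_polys = _slice_contours(shaft.inner.vertices, shaft.inner.faces, x)
        if len(inner_polys) > 1:
            log.warning("level %.2f: %d inner loops, keeping largest", f, len(inner_polys))
        outer = outer_polys[0]
        sections.append(CrossSection(
            level_frac=float(f), x=float(x), outer_contour=outer,
            inner_contour=inner_polys[0] if inner_polys else None,
            centroid=_area_centroid(outer),
            n_outer_loops=len(outer_polys), n_inner_loops=len(inner_polys)))
    return sections


# ---------------------------------------------------------------------------
# semi-landmarks


def _ray_farthest_hit(origin: np.ndarray, direction: np.ndarray,
                      poly: np.ndarray) -> Optional[np.ndarray]:
    """Farthest intersection of a ray with a closed polygon (None if no hit)."""
    p1 = poly
    p2 = np.roll(poly, -1, axis=0)
    e = p2 - p1
    rel = p1 - origin
    denom = direction[0] * e[:, 1] - direction[1] * e[:, 0]
    ok = np.abs(denom) > 1e-14
    t = np.where(ok, (rel[:, 0] * e[:, 1] - rel[:, 1] * e[:, 0]) / np.where(ok, denom, 1.0),
                 -1.0)
    s = np.where(ok, (rel[:, 0] * direction[1] - rel[:, 1] * direction[0])
                 / np.where(ok, denom, 1.0), -1.0)
    # epsilon on both ends so rays through a polygon vertex still register
    hit = ok & (t > 1e-9) & (s >= -1e-9) & (s <= 1.0 + 1e-9)
    if not hit.any():
        return None
    tmax = t[hit].max()
    return origin + tmax * direction


def place_landmarks(section: CrossSection, k: int = N_ANGLES) -> LandmarkedSection:
    """Cast ``k`` equiangular rays from the outer-contour area centroid and
    place the semi-landmark pair on each.

    The outer landmark is the farthest ray–outer-contour intersection; the
    inner landmark the farthest ray–inner-contour intersection.  If the inner
    contour is absent or the ray misses it (solid section), the inner landmark
    is the centroid itself and the cell is flagged.
    """
    import shapely.geometry as sg
    origin = section.centroid
    if not sg.Polygon(section.outer_contour).buffer(1e-9).contains(sg.Point(origin)):
        raise LandmarkError(
            f"centroid outside outer contour at level {section.level_frac:.2f}")
    angles = 2 * np.pi * np.arange(k) / k
    outer_pts = np.empty((k, 2))
    inner_pts = np.empty((k, 2))
    solid = np.zeros(k, dtype=bool)
    for j, th in enumerate(angles):
        d = np.array([np.cos(th), np.sin(th)])
        hit_o = _ray_farthest_hit(origin, d, section.outer_contour)
        if hit_o is None:
            raise LandmarkError(
                f"ray {j} missed the outer contour at level {section.level_frac:.2f}")
        outer_pts[j] = hit_o
        hit_i = (None if section.inner_contour is None
                 else _ray_farthest_hit(origin, d, section.inner_contour))
        if hit_i is None:
            inner_pts[j] = origin
            solid[j] = True
        else:
            inner_pts[j] = hit_i
    thickness = np.linalg.norm(outer_pts - inner_pts, axis=1)
    return LandmarkedSection(section.level_frac, angles, outer_pts, inner_pts,
                             thickness, solid)


def build_thickness_map(sections: Sequence[LandmarkedSection], bone_length: float,
                        n_levels: int = N_LEVELS, meta: Optional[dict] = None,
                        ) -> ThicknessMap:
    """Assemble landmarked sections into the level × angle thickness matrix."""
    if len(sections) != n_levels:
        raise ValueError(f"expected {n_levels} sections, got {len(sections)}")
    k = len(sections[0].thickness)
    values = np.vstack([s.thickness for s in sections])
    mask = np.vstack([s.solid for s in sections])
    if values.shape != (n_levels, k):
        raise ValueError("inconsistent landmark counts across sections")
    levels = np.array([s.level_frac for s in sections])
    if np.any(np.diff(levels) <= 0):
        raise ValueError("sections must be ordered proximal to distal")
    return ThicknessMap(values, mask, levels, sections[0].angles.copy(),
                        bone_length, False, dict(meta or {}))


def compute_thickness_map(pair: BoneSurfacePair,
                          window: ShaftWindow = ShaftWindow(),
                          n_levels: int = N_LEVELS, n_angles: int = N_ANGLES,
                          span: tuple[float, float] = LEVEL_SPAN) -> ThicknessMap:
    """Full chain: crop shaft → 97 sections → 50 landmarks each → map."""
    shaft, win = define_shaft(pair, window)
    sections = extract_sections(shaft, n_levels=n_levels, span=span)
    landmarked = [place_landmarks(s, k=n_angles) for s in sections]
    meta = {"specimen_id": pair.specimen_id, "label": pair.label,
            "element": pair.element, "digit": pair.digit, "side": pair.side,
            "shaft_window": (win.start_frac, win.end_frac)}
    return build_thickness_map(landmarked, shaft.meta["bone_length"],
                               n_levels=n_levels, meta=meta)
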