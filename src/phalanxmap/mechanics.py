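"""Cross-sectional geometric properties and longitudinal curvature.

The polar second moment of area J = Ixx + Iyy of the cortical annulus is a
standard proxy for bending and torsional rigidity of a long-bone shaft.  It is
computed in closed form from the boundary polygons (Green's theorem), with the
inner (endosteal) polygon subtracted from the outer (periosteal) one and the
moments transferred to the combined cortical-area centroid by the
parallel-axis theorem.  By default J is evaluated at 35, 50 and 65% of maximum
bone length (fractions of *bone* length, not of the cropped shaft), and
standardized by length to the fourth power for dimensional homogeneity.

Longitudinal curvature is summarized by the included angle: section centroids
are projected to the sagittal plane, a circle is fitted (algebraic Kåsa fit
plus one Gauss–Newton refinement), and the angle subtended at the fitted
center between the proximal-most and distal-most centroids is reported in
degrees.  Bones whose fitted radius exceeds 50× the shaft length are reported
as straight (0°).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import BoneSurfacePair, max_length
from .sectioning import (LandmarkError, SectioningError, ShaftWindow, ThicknessMap,
                         _area_centroid, _slice_contours, define_shaft,
                         extract_sections, place_landmarks)

__all__ = [
    "SectionGeometry",
    "CurvatureResult",
    "GeometryError",
    "polygon_moments",
    "section_J",
    "J_at_levels",
    "standardize_J",
    "mean_cortical_thickness",
    "included_angle",
]

J_LEVELS_DEFAULT = (0.35, 0.50, 0.65)
J_STD_EXPONENT = 4           # J / L**4 is dimensionless
STRAIGHT_RADIUS_FACTOR = 50.0


class GeometryError(ValueError):
    pass


@dataclass
class SectionGeometry:
    """Closed-form properties of one cortical cross-section.

    Moments are about the cortical-area centroid with x = w (radial) and
    y = v (dorsal); J = Ixx + Iyy exactly by construction.
    """

    level_frac: float
    cortical_area: float        # mm^2
    centroid: np.ndarray        # (v, w) mm
    Ixx: float                  # mm^4, about x (radial) axis
    Iyy: float                  # mm^4, about y (dorsal) axis
    Ixy: float                  # mm^4
    J: float                    # mm^4 = Ixx + Iyy
    mean_thickness: float       # mm, mean of the 50 ray thicknesses
    meta: dict = field(default_factory=dict)


@dataclass
class CurvatureResult:
    included_angle: float       # degrees
    fit_radius: float           # mm (inf for straight bones)
    fit_rmse: float             # mm


# ---------------------------------------------------------------------------
# polygon moments (Green's theorem closed forms)


def _is_simple(poly: np.ndarray) -> bool:
    import shapely.geometry as sg
    return sg.LinearRing(poly).is_simple


def polygon_moments(poly: np.ndarray, check_simple: bool = True,
                    ) -> tuple[float, np.ndarray, float, float, float]:
    """Area, centroid and second moments about the ORIGIN of a simple closed
    polygon, from the boundary alone (exact closed forms, no quadrature).

    Returns ``(area, centroid, Ixx, Iyy, Ixy)`` with Ixx = ∫y²dA,
    Iyy = ∫x²dA, Ixy = ∫xy dA.  Orientation is normalized so area > 0.
    """
    poly = np.asarray(poly, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 3:
        raise GeometryError("polygon must be an (n>=3, 2) array")
    if check_simple and not _is_simple(poly):
        raise GeometryError("polygon is self-intersecting")
    x, y = poly[:, 0], poly[:, 1]
    x1, y1 = np.roll(x, -1), np.roll(y, -1)
    cross = x * y1 - x1 * y
    area = 0.5 * cross.sum()
    if area == 0:
        raise GeometryError("polygon has zero area")
    sign = 1.0 if area > 0 else -1.0
    area *= sign
    cross *= sign
    cx = np.sum((x + x1) * cross) / (6 * area)
    cy = np.sum((y + y1) * cross) / (6 * area)
    Ixx = np.sum((y * y + y * y1 + y1 * y1) * cross) / 12.0
    Iyy = np.sum((x * x + x * x1 + x1 * x1) * cross) / 12.0
    Ixy = np.sum((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross) / 24.0
    return float(area), np.array([cx, cy]), float(Ixx), float(Iyy), float(Ixy)


def section_J(outer_contour: np.ndarray, inner_contour: Optional[np.ndarray],
              level_frac: float = np.nan,
              ray_thicknesses: Optional[np.ndarray] = None) -> SectionGeometry:
    """Annular section properties: outer polygon minus inner polygon.

    Contours are given in (v, w) map coordinates; the moment axes follow the
    x = w, y = v convention.  Moments are transferred to the cortical-area
    centroid via the parallel-axis theorem and J = Ixx + Iyy.
    """
    def moments_xw(poly_vw):
        # swap to (x=w, y=v) for the moment convention
        return polygon_moments(poly_vw[:, ::-1])

    a_o, c_o, ixx_o, iyy_o, ixy_o = moments_xw(np.asarray(outer_contour, dtype=float))
    if inner_contour is not None:
        import shapely.geometry as sg
        p_out = sg.Polygon(np.asarray(outer_contour))
        p_in = sg.Polygon(np.asarray(inner_contour))
        if not p_out.buffer(1e-9).contains(p_in):
            raise GeometryError("inner contour is not contained in the outer contour")
        a_i, c_i, ixx_i, iyy_i, ixy_i = moments_xw(np.asarray(inner_contour, dtype=float))
    else:
        a_i = ixx_i = iyy_i = ixy_i = 0.0
        c_i = np.zeros(2)
    area = a_o - a_i
    if area <= 0:
        raise GeometryError("cortical area is not positive")
    cx = (a_o * c_o[0] - a_i * c_i[0]) / area
    cy = (a_o * c_o[1] - a_i * c_i[1]) / area
    # origin moments of the annulus, then parallel-axis to the combined centroid
    Ixx = (ixx_o - ixx_i) - area * cy * cy
    Iyy = (iyy_o - iyy_i) - area * cx * cx
    Ixy = (ixy_o - ixy_i) - area * cx * cy
    mean_t = float(np.mean(ray_thicknesses)) if ray_thicknesses is not None else np.nan
    return SectionGeometry(level_frac=float(level_frac), cortical_area=float(area),
                           centroid=np.array([cy, cx]),  # back to (v, w) order
                           Ixx=float(Ixx), Iyy=float(Iyy), Ixy=float(Ixy),
                           J=float(Ixx + Iyy), mean_thickness=mean_t)


def J_at_levels(pair: BoneSurfacePair,
                levels: Sequence[float] = J_LEVELS_DEFAULT) -> list[SectionGeometry]:
    """Section properties at fractions of maximum BONE length from the
    proximal end (default 35, 50, 65%) — a different reference frame from the
    map grid, which uses fractions of the cropped shaft."""
    if not pair.oriented:
        raise ValueError("pair must be oriented")
    L = max_length(pair)
    u0 = float(pair.outer.vertices[:, 0].min())
    out = []
    for f in levels:
        if not 0.0 < f < 1.0:
            raise ValueError(f"level {f} outside (0, 1)")
        x = u0 + f * L
        outer_polys = _slice_contours(pair.outer.vertices, pair.outer.faces, x)
        if not outer_polys:
            raise SectioningError(f"no closed outer contour at bone level {f:.2f}")
        inner_polys = _slice_contours(pair.inner.vertices, pair.inner.faces, x)
        from .sectioning import CrossSection
        cs = CrossSection(level_frac=float(f), x=float(x),
                          outer_contour=outer_polys[0],
                          inner_contour=inner_polys[0] if inner_polys else None,
                          centroid=_area_centroid(outer_polys[0]))
        try:
            lm = place_landmarks(cs)
            thick = lm.thickness
        except LandmarkError:
            thick = None
        geom = section_J(cs.outer_contour, cs.inner_contour, level_frac=float(f),
                         ray_thicknesses=thick)
        geom.meta.update(level_reference="max_bone_length", bone_length=L)
        out.append(geom)
    return out


def standardize_J(geom: SectionGeometry, bone_length: float,
                  exponent: int = J_STD_EXPONENT) -> float:
    """Length-standardized J: J / L**exponent (default exponent 4, so the
    result is dimensionless).  The exponent used is recorded in ``geom.meta``."""
    if not bone_length > 0:
        raise ValueError("bone_length must be positive")
    geom.meta["J_std_exponent"] = exponent
    return float(geom.J / bone_length ** exponent)


def mean_cortical_thickness(tmap: ThicknessMap) -> float:
    """Whole-shaft mean thickness over all non-flagged map cells."""
    ok = ~tmap.mask
    if not ok.any():
        raise ValueError("all map cells are flagged; no measurable thickness")
    return float(tmap.values[ok].mean())


# ---------------------------------------------------------------------------
# curvature via included angle


def _fit_circle(pts: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Least-squares circle: Kåsa algebraic fit + one Gauss–Newton pass.

    Returns (center, radius, rmse of radial residuals).
    """
    x, y = pts[:, 0], pts[:, 1]
    A = np.column_stack([2 * x, 2 * y, np.ones(len(x))])
    b = x * x + y * y
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    cx, cy = sol[0], sol[1]
    r = np.sqrt(max(sol[2] + cx * cx + cy * cy, 0.0))
    # one geometric refinement step on (cx, cy, r)
    for _ in range(1):
        dx, dy = x - cx, y - cy
        d = np.hypot(dx, dy)
        d = np.where(d < 1e-12, 1e-12, d)
        res = d - r
        Jac = np.column_stack([-dx / d, -dy / d, -np.ones(len(x))])
        try:
            step, *_ = np.linalg.lstsq(Jac, -res, rcond=None)
            cx, cy, r = cx + step[0], cy + step[1], r + step[2]
        except np.linalg.LinAlgError:
            break
    d = np.hypot(x - cx, y - cy)
    rmse = float(np.sqrt(np.mean((d - r) ** 2)))
    return np.array([cx, cy]), float(r), rmse


def included_angle_from_points(pts: np.ndarray,
                               chord_length: Optional[float] = None,
                               straight_scale: Optional[float] = None,
                               ) -> CurvatureResult:
    """Included angle from sagittal-plane midline points.

    A circle is fitted to the points and the included angle is the arc
    subtended on it by a chord of length ``chord_length`` (by default the
    chord between the first and last points): 2·arcsin(chord / 2R).  If the
    fitted radius exceeds ``STRAIGHT_RADIUS_FACTOR`` times ``straight_scale``
    (default: the chord), the midline is deemed straight and 0° is returned.
    """
    pts = np.asarray(pts, dtype=float)
    if len(pts) < 10:
        raise ValueError("need at least 10 midline points for curvature")
    if chord_length is None:
        chord_length = float(np.linalg.norm(pts[-1] - pts[0]))
    if straight_scale is None:
        straight_scale = chord_length
    # guard: almost-collinear points make the algebraic fit ill-conditioned
    chord_dir = (pts[-1] - pts[0]) / max(np.linalg.norm(pts[-1] - pts[0]), 1e-12)
    offsets = (pts - pts[0]) @ np.array([-chord_dir[1], chord_dir[0]])
    if offsets.max() - offsets.min() < 1e-7 * straight_scale:
        return CurvatureResult(0.0, np.inf, float(np.std(offsets)))
    center, radius, rmse = _fit_circle(pts)
    if not np.isfinite(radius) or radius > STRAIGHT_RADIUS_FACTOR * straight_scale:
        return CurvatureResult(0.0, float(radius), rmse)
    half_sin = np.clip(chord_length / (2 * radius), 0.0, 1.0)
    ang = float(np.degrees(2 * np.arcsin(half_sin)))
    return CurvatureResult(ang, radius, rmse)


def included_angle(pair: BoneSurfacePair,
                   window: ShaftWindow = ShaftWindow(),
                   n_levels: int = 49) -> CurvatureResult:
    """Included angle of longitudinal shaft curvature, in degrees.

    Section centroids over the shaft window are projected to the sagittal
    (u–v) plane and a circle is fitted (Kåsa + one Gauss–Newton pass); the
    included angle is the arc the whole bone subtends on that circle,
    2·arcsin(L / 2R) with L the maximum bone length — the field's standard
    included-angle measure.  Nearly straight bones (fit radius > 50× shaft
    length) are reported as exactly 0°.
    """
    L = max_length(pair)
    shaft, _ = define_shaft(pair, window)
    sections = extract_sections(shaft, n_levels=n_levels)
    pts = np.array([[s.x, s.centroid[0]] for s in sections])  # (u, v) sagittal
    shaft_len = shaft.meta["shaft_x1"] - shaft.meta["shaft_x0"]
    return included_angle_from_points(pts, chord_length=L, straight_scale=shaft_len)
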