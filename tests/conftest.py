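"""Shared fixtures: synthetic bones, cohorts, and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pytest

import phalanxmap as pm
from phalanxmap.synthetic import BlendedThicknessField


def circle_polygon(r: float, n: int = 4096, center=(0.0, 0.0)) -> np.ndarray:
    th = 2 * np.pi * np.arange(n) / n
    return np.column_stack([center[0] + r * np.cos(th), center[1] + r * np.sin(th)])


def star_polygon(rng: np.random.Generator, n: int = 2000,
                 r0: float = 5.0, wobble: float = 0.25) -> np.ndarray:
    """Random star-shaped simple polygon: positive radius Fourier series."""
    th = 2 * np.pi * np.arange(n) / n
    r = np.full(n, r0)
    for k in range(1, 6):
        a, b = rng.normal(0, wobble * r0 / k, 2)
        r += a * np.cos(k * th) + b * np.sin(k * th)
    r = np.clip(r, 0.2 * r0, None)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def raster_moments(poly: np.ndarray, resolution: int = 4000):
    """Pixel-rasterization oracle for area/centroid/second moments.

    Scan-line fills the polygon on a ``resolution``² grid and accumulates the
    contribution of every pixel center inside it (column sums are evaluated
    with exact integer-power-sum formulas).  Independent of the Green's
    theorem closed forms.
    """
    lo = poly.min(axis=0)
    span = (poly.max(axis=0) - lo).max() * 1.02
    px = span / resolution
    x0 = lo[0] - 0.01 * span / 2
    y0 = lo[1] - 0.01 * span / 2
    xs1, ys1 = poly[:, 0], poly[:, 1]
    xs2, ys2 = np.roll(xs1, -1), np.roll(ys1, -1)
    keep = ys1 != ys2
    xs1, ys1, xs2, ys2 = xs1[keep], ys1[keep], xs2[keep], ys2[keep]
    dA = px * px
    area = Sx = Sy = Ixx = Iyy = Ixy = 0.0
    for row in range(resolution):
        y = y0 + (row + 0.5) * px
        m = (np.minimum(ys1, ys2) <= y) & (y < np.maximum(ys1, ys2))
        if not m.any():
            continue
        xc = np.sort(xs1[m] + (y - ys1[m]) * (xs2[m] - xs1[m]) / (ys2[m] - ys1[m]))
        for a, b in zip(xc[0::2], xc[1::2]):
            i_lo = int(np.ceil((a - x0) / px - 0.5))
            i_hi = int(np.floor((b - x0) / px - 0.5 - 1e-12))
            if i_hi < i_lo:
                continue
            n = i_hi - i_lo + 1
            s1 = (i_lo + i_hi) * n / 2.0

            def cube_sum(k):  # sum of i^2 for i = 0..k
                return k * (k + 1) * (2 * k + 1) / 6.0 if k >= 0 else 0.0

            s2 = cube_sum(i_hi) - cube_sum(i_lo - 1)
            sum_x = px * (s1 + 0.5 * n) + n * x0
            sum_x2 = (px * px * (s2 + s1 + 0.25 * n) + 2 * x0 * px * (s1 + 0.5 * n)
                      + n * x0 * x0)
            area += n * dA
            Sx += sum_x * dA
            Sy += y * n * dA
            Ixx += y * y * n * dA
            Iyy += sum_x2 * dA
            Ixy += y * sum_x * dA
    return area, np.array([Sx / area, Sy / area]), Ixx, Iyy, Ixy


# ---------------------------------------------------------------------------
# canonical cohort study conditions: an "ape-like" morphotype (strong palmar
# flexor-sheath ridges, monotonically increasing axial gradient) versus a
# "human-like" one (dorsal-shaft thickening, mid-distal peak at 65% of shaft)


def ape_like_spec(**kw) -> pm.SyntheticPhalanxSpec:
    return pm.SyntheticPhalanxSpec(thickness_field=pm.ThicknessFieldSpec(
        t0=1.2, axial_profile=("monotone_increase",), axial_amp=1.0,
        ridge_amp=1.5, dorsal_amp=0.2), **kw)


def human_like_spec(**kw) -> pm.SyntheticPhalanxSpec:
    return pm.SyntheticPhalanxSpec(thickness_field=pm.ThicknessFieldSpec(
        t0=1.2, axial_profile=("mid_peak", 0.65, 0.6), axial_amp=1.0,
        ridge_amp=0.4, dorsal_amp=1.0), **kw)


COHORT_SDS = {"t0": 0.1, "axial_amp": 0.1, "ridge_amp": 0.1,
              "dorsal_amp": 0.1, "peak_frac": 0.05}
COHORT_SEED = 20260925


@pytest.fixture(scope="session")
def straight_tube():
    """Straight circular tube: outer r = 5 mm, constant cortex t = 2 mm."""
    spec = pm.SyntheticPhalanxSpec(
        included_angle_deg=0.0, base_radius=5.0, mid_radius=5.0, troch_radius=5.0,
        aspect=1.0, thickness_field=pm.ThicknessFieldSpec(t0=2.0, axial_amp=0.0),
        mesh_resolution=(400, 200))
    pair, truth = pm.generate_phalanx(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def default_phalanx():
    spec = pm.SyntheticPhalanxSpec()
    pair, truth = pm.generate_phalanx(spec)
    return spec, pair, truth


@pytest.fixture(scope="session")
def default_sections(default_phalanx):
    _, pair, _ = default_phalanx
    shaft, _ = pm.define_shaft(pair)
    return pm.extract_sections(shaft)


@pytest.fixture(scope="session")
def cohort():
    """Two synthetic cohorts, n = 15 each, effect sizes >> within-group noise."""
    return pm.generate_cohort(
        [("ape", ape_like_spec(), COHORT_SDS), ("human", human_like_spec(), COHORT_SDS)],
        n_per_group=15, seed=COHORT_SEED)


@pytest.fixture(scope="session")
def cohort_maps(cohort):
    maps, labels = [], []
    for pair, _truth, label in cohort:
        maps.append(pm.standardize_map(pm.compute_thickness_map(pair)))
        labels.append(label)
    return maps, labels


@pytest.fixture(scope="session")
def blended_specimen():
    """A 50/50 morphological intermediate between the two cohort morphotypes."""
    blend = BlendedThicknessField(ape_like_spec().thickness_field,
                                  human_like_spec().thickness_field, weight=0.5)
    spec = pm.SyntheticPhalanxSpec(thickness_field=blend)
    pair, _ = pm.generate_phalanx(spec)
    return pm.standardize_map(pm.compute_thickness_map(pair))
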