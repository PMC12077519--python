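"""Parametric synthetic phalanx generator with known cortical-thickness field.

The generator sweeps elliptical cross-sections along a circular centerline arc
(longitudinal palmar bowing, parameterized by its included angle) and offsets
the inner (endosteal) surface inward from the outer (periosteal) one by a
prescribed thickness field t(s, θ).  Because the field is known in closed form,
every downstream quantity — the 97×50 thickness map, mean profiles, peak
location, curvature — has an exact ground truth, which is what makes the
generator usable as an oracle for the full cartography pipeline.

The thickness field emulates the qualitative contrasts seen in hominid
phalanges: palmar flexor-sheath-ridge thickening (two angular Gaussian crests),
dorsal-shaft thickening (raised-cosine window around mid-dorsal), and
proximodistal gradients that either increase monotonically ("ape-like") or
peak at ~60–75% of shaft length and then fall ("human-like").

Conventions match the analysis modules: s is the axial fraction of bone length
(0 proximal, 1 distal), θ is the ray angle from mid-dorsal (+v) increasing
toward +w, and the axial thickness profile is parameterized in fractions of the
*shaft* window (default 20–80% of bone length) so that a peak_frac of 0.65
lands at map row 65%.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

from .geometry import BoneSurfacePair, TriSurface

__all__ = [
    "ThicknessFieldSpec",
    "SyntheticPhalanxSpec",
    "GroundTruthField",
    "GenerationError",
    "generate_phalanx",
    "generate_cohort",
]

DEFAULT_SHAFT_WINDOW = (0.20, 0.80)
N_LEVELS, N_ANGLES = 97, 50


class GenerationError(ValueError):
    """Raised when a spec cannot produce a valid bone."""


# ---------------------------------------------------------------------------
# thickness field


@dataclass
class ThicknessFieldSpec:
    """Closed-form cortical thickness field t(s, θ) in mm.

    axial_profile: ``("monotone_increase",)`` or ``("mid_peak", peak_frac,
    fall_frac)``; ``axial_amp`` scales it.  ``fall_frac`` is the fraction of
    the peak amplitude lost between the peak and the distal end of the shaft.
    """

    t0: float = 1.2
    axial_profile: tuple = ("monotone_increase",)
    axial_amp: float = 0.8
    dorsal_amp: float = 0.0
    ridge_amp: float = 0.0
    # palmar-ulnar and palmar-radial crests, symmetric about the sagittal plane
    ridge_angles: tuple[float, float] = (np.pi - 0.7, np.pi + 0.7)
    ridge_angular_sd: float = 0.35
    ridge_axial_window: tuple[float, float] = (0.15, 0.95)
    shaft_window: tuple[float, float] = DEFAULT_SHAFT_WINDOW

    def validate(self) -> None:
        if self.t0 <= 0:
            raise GenerationError("t0 must be positive")
        kind = self.axial_profile[0]
        if kind not in ("monotone_increase", "mid_peak"):
            raise GenerationError(f"unknown axial profile {kind!r}")
        if kind == "mid_peak":
            peak = self.axial_profile[1]
            if not 0.0 < peak < 1.0:
                raise GenerationError("mid_peak peak_frac must be in (0, 1)")
        # positivity over a fine grid
        s = np.linspace(0, 1, 201)
        th = np.linspace(0, 2 * np.pi, 181)
        if np.min(self(s[:, None], th[None, :])) <= 0:
            raise GenerationError("thickness field must be strictly positive")

    def _axial(self, ss: np.ndarray) -> np.ndarray:
        kind = self.axial_profile[0]
        if kind == "monotone_increase":
            return self.axial_amp * ss
        peak, fall = self.axial_profile[1], self.axial_profile[2]
        up = np.clip(ss / peak, 0, 1)
        down = np.clip((ss - peak) / max(1 - peak, 1e-9), 0, 1)
        return self.axial_amp * np.where(ss <= peak, up, 1.0 - fall * down)

    def __call__(self, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Evaluate t(s, θ) (broadcasting); s is a fraction of bone length."""
        s = np.asarray(s, dtype=float)
        theta = np.asarray(theta, dtype=float)
        w0, w1 = self.shaft_window
        ss = np.clip((s - w0) / (w1 - w0), 0.0, 1.0)
        t = self.t0 + self._axial(ss)
        if self.dorsal_amp:
            d = _wrap(theta)
            win = np.where(np.abs(d) <= np.pi / 3, 0.5 * (1 + np.cos(3 * d)), 0.0)
            t = t + self.dorsal_amp * win
        if self.ridge_amp:
            a0, a1 = self.ridge_axial_window
            ramp = _smoothstep((ss - a0) / 0.05) * _smoothstep((a1 - ss) / 0.05)
            crest = sum(np.exp(-_wrap(theta - c) ** 2 / (2 * self.ridge_angular_sd ** 2))
                        for c in self.ridge_angles)
            t = t + self.ridge_amp * crest * ramp
        return np.broadcast_to(t, np.broadcast_shapes(s.shape, theta.shape)).copy()


@dataclass
class BlendedThicknessField:
    """Convex combination of two thickness fields (an "intermediate" morphology).

    Drop-in replacement for :class:`ThicknessFieldSpec` in a phalanx spec;
    used to synthesize specimens lying between two group morphotypes.
    """

    first: "ThicknessFieldSpec"
    second: "ThicknessFieldSpec"
    weight: float = 0.5          # weight on ``first``

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise GenerationError("blend weight must be in [0, 1]")

    @property
    def shaft_window(self) -> tuple[float, float]:
        return self.first.shaft_window

    def validate(self) -> None:
        self.first.validate()
        self.second.validate()

    def __call__(self, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
        return (self.weight * self.first(s, theta)
                + (1.0 - self.weight) * self.second(s, theta))


def _wrap(a: np.ndarray) -> np.ndarray:
    """Wrap angles to (-π, π]."""
    return (np.asarray(a) + np.pi) % (2 * np.pi) - np.pi


def _smoothstep(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3 - 2 * x)


# ---------------------------------------------------------------------------
# bone spec


@dataclass
class SyntheticPhalanxSpec:
    """Geometric ground truth for one synthetic phalanx."""

    length: float = 40.0                 # chord length along u, mm
    base_radius: float = 6.0             # radioulnar semi-axis at proximal end
    mid_radius: float = 4.5
    troch_radius: float = 5.0
    aspect: float = 1.15                 # dorsopalmar/radioulnar semi-axis ratio
    included_angle_deg: float = 30.0     # longitudinal arc of the centerline
    thickness_field: ThicknessFieldSpec = field(default_factory=ThicknessFieldSpec)
    mesh_resolution: tuple[int, int] = (200, 100)   # (n_axial, n_circumferential)
    noise_sd: float = 0.0                # mm of i.i.d. radial vertex jitter
    seed: int = 0

    def validate(self) -> None:
        if self.length <= 0:
            raise GenerationError("length must be positive")
        for name in ("base_radius", "mid_radius", "troch_radius"):
            if getattr(self, name) <= 0:
                raise GenerationError(f"{name} must be positive")
        if self.included_angle_deg < 0:
            raise GenerationError("included_angle_deg must be >= 0")
        if self.noise_sd < 0:
            raise GenerationError("noise_sd must be >= 0")
        na, nc = self.mesh_resolution
        if na < 10 or nc < 12:
            raise GenerationError("mesh_resolution too coarse")
        self.thickness_field.validate()
        # thickness must leave a cavity everywhere: t < min polar radius
        s = np.linspace(0, 1, 201)
        th = np.linspace(0, 2 * np.pi, 181)
        rho = self._outer_radius(s[:, None], th[None, :])
        t = self.thickness_field(s[:, None], th[None, :])
        bad = t >= rho
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise GenerationError(
                f"thickness {t[i, j]:.3f} mm >= local radius {rho[i, j]:.3f} mm "
                f"at s={s[i]:.3f}, theta={th[j]:.3f}")

    # -- closed-form geometry ------------------------------------------------

    def _radius_profile(self, s: np.ndarray) -> np.ndarray:
        """Radioulnar semi-axis: quadratic through base, mid, trochlear radii."""
        b, m, t = self.base_radius, self.mid_radius, self.troch_radius
        # Lagrange on nodes 0, 0.5, 1
        return (b * (2 * (s - 0.5) * (s - 1))
                + m * (-4 * s * (s - 1))
                + t * (2 * s * (s - 0.5)))

    def _outer_radius(self, s: np.ndarray, theta: np.ndarray) -> np.ndarray:
        """Polar radius of the outer ellipse at ray angle θ from mid-dorsal."""
        r = self._radius_profile(np.asarray(s, dtype=float))
        av, aw = self.aspect * r, r
        th = np.asarray(theta, dtype=float)
        return av * aw / np.sqrt((aw * np.cos(th)) ** 2 + (av * np.sin(th)) ** 2)

    def _centerline_v(self, s: np.ndarray) -> np.ndarray:
        """Sagittal (dorsal +) offset of the centerline at axial fraction s."""
        s = np.asarray(s, dtype=float)
        phi = np.deg2rad(self.included_angle_deg)
        if phi < 1e-9:
            return np.zeros_like(s)
        L = self.length
        R = (L / 2) / np.sin(phi / 2)
        h = R * np.cos(phi / 2)
        x = s * L
        return h - np.sqrt(R ** 2 - (x - L / 2) ** 2)  # ≤ 0: bows palmarly

    def arc_length(self) -> float:
        """Centerline arc length (exceeds chord length when curved)."""
        phi = np.deg2rad(self.included_angle_deg)
        if phi < 1e-9:
            return self.length
        return phi * (self.length / 2) / np.sin(phi / 2)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class GroundTruthField:
    """The generator's exact thickness field plus its 97×50 grid sample."""

    func: Callable[[np.ndarray, np.ndarray], np.ndarray]
    values: np.ndarray          # (97, 50) mm on the analysis grid
    levels: np.ndarray          # shaft-length fractions 0.02 … 0.98
    angles: np.ndarray          # ray angles from mid-dorsal
    shaft_window: tuple[float, float]
    bone_length: float

    @classmethod
    def from_spec(cls, spec: SyntheticPhalanxSpec,
                  n_levels: int = N_LEVELS, n_angles: int = N_ANGLES) -> "GroundTruthField":
        w0, w1 = spec.thickness_field.shaft_window
        levels = 0.02 + 0.01 * np.arange(n_levels) if n_levels == N_LEVELS else \
            np.linspace(0.02, 0.98, n_levels)
        angles = 2 * np.pi * np.arange(n_angles) / n_angles
        s_bone = w0 + levels * (w1 - w0)
        values = spec.thickness_field(s_bone[:, None], angles[None, :])
        return cls(spec.thickness_field, values, levels, angles,
                   spec.thickness_field.shaft_window, spec.length)


# ---------------------------------------------------------------------------
# mesh construction


def _tube_mesh(points: np.ndarray, n_axial: int, n_circ: int) -> TriSurface:
    """Triangulate an (n_axial, n_circ, 3) vertex grid as a capped tube."""
    verts = points.reshape(-1, 3)
    faces = []
    for i in range(n_axial - 1):
        for j in range(n_circ):
            a = i * n_circ + j
            b = i * n_circ + (j + 1) % n_circ
            c = (i + 1) * n_circ + j
            d = (i + 1) * n_circ + (j + 1) % n_circ
            faces.append((a, b, d))
            faces.append((a, d, c))
    # end caps: fan to ring centers
    c0 = points[0].mean(axis=0)
    c1 = points[-1].mean(axis=0)
    verts = np.vstack([verts, c0[None], c1[None]])
    i0, i1 = len(verts) - 2, len(verts) - 1
    for j in range(n_circ):
        faces.append((i0, (j + 1) % n_circ, j))
        base = (n_axial - 1) * n_circ
        faces.append((i1, base + j, base + (j + 1) % n_circ))
    return TriSurface(verts, np.asarray(faces, dtype=np.int64))


def generate_phalanx(spec: SyntheticPhalanxSpec) -> tuple[BoneSurfacePair, GroundTruthField]:
    """Build the outer/inner surface pair and its exact thickness ground truth.

    The mesh is deterministic given ``spec.seed``; radial jitter of sd
    ``noise_sd`` is applied independently to outer and inner vertices.
    Vertices are emitted directly in the canonical anatomical frame.
    """
    spec.validate()
    na, nc = spec.mesh_resolution
    s = np.linspace(0.0, 1.0, na)
    theta = 2 * np.pi * np.arange(nc) / nc
    rho_out = spec._outer_radius(s[:, None], theta[None, :])          # (na, nc)
    t = spec.thickness_field(s[:, None], theta[None, :])
    rho_in = rho_out - t
    if np.min(rho_in) <= 0:
        i, j = np.argwhere(rho_in <= 0)[0]
        raise GenerationError(f"inner surface self-intersects at s={s[i]:.3f}, "
                              f"theta={theta[j]:.3f}")
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        rho_out = rho_out + rng.normal(0, spec.noise_sd, rho_out.shape)
        rho_in = np.minimum(rho_in + rng.normal(0, spec.noise_sd, rho_in.shape),
                            rho_out - 1e-3)

    cx = s * spec.length
    cv = spec._centerline_v(s)
    dir_v, dir_w = np.cos(theta), np.sin(theta)

    def grid(rho):
        pts = np.empty((na, nc, 3))
        pts[:, :, 0] = cx[:, None]
        pts[:, :, 1] = cv[:, None] + rho * dir_v[None, :]
        pts[:, :, 2] = rho * dir_w[None, :]
        return pts

    outer = _tube_mesh(grid(rho_out), na, nc)
    inner = _tube_mesh(grid(rho_in), na, nc)
    pair = BoneSurfacePair(outer=outer, inner=inner, side="right",
                           oriented=True, meta={"synthetic_spec": _spec_dict(spec)})
    from .geometry import AnatomicalFrame
    pair.frame = AnatomicalFrame.identity()
    return pair, GroundTruthField.from_spec(spec)


# ---------------------------------------------------------------------------
# cohorts

# fields perturbed multiplicatively (log-normal, keeps positivity) vs additively
_LOG_FIELDS = {"t0", "axial_amp", "dorsal_amp", "ridge_amp", "length",
               "base_radius", "mid_radius", "troch_radius", "included_angle_deg"}
_ADD_FIELDS = {"ridge_angles", "peak_frac", "ridge_angular_sd", "aspect"}


def _spec_dict(spec: SyntheticPhalanxSpec) -> dict:
    d = dataclasses.asdict(spec)
    tf = d.get("thickness_field", {})
    if "axial_profile" in tf:
        tf["axial_profile"] = list(tf["axial_profile"])
    else:  # blended field: nested sub-fields
        for key in ("first", "second"):
            if key in tf and "axial_profile" in tf[key]:
                tf[key]["axial_profile"] = list(tf[key]["axial_profile"])
    return d


def perturb_spec(base: SyntheticPhalanxSpec, sds: dict, rng: np.random.Generator,
                 seed: int) -> SyntheticPhalanxSpec:
    """Draw one individual's spec around a group base spec.

    ``sds`` maps field names to dispersions: log-normal sigma (relative sd) for
    amplitude/size fields, additive normal sd for angular/positional fields.
    """
    spec = dataclasses.replace(base, thickness_field=dataclasses.replace(base.thickness_field))
    tf = spec.thickness_field
    for name, sd in sds.items():
        if sd == 0:
            continue
        if name in ("t0", "axial_amp", "dorsal_amp", "ridge_amp"):
            val = getattr(tf, name)
            if val != 0:
                setattr(tf, name, val * rng.lognormal(0.0, sd))
        elif name == "peak_frac":
            if tf.axial_profile[0] == "mid_peak":
                kind, peak, fall = tf.axial_profile
                tf.axial_profile = (kind, float(np.clip(peak + rng.normal(0, sd), 0.05, 0.95)),
                                    fall)
            else:
                rng.normal(0, sd)  # keep the draw sequence aligned across profiles
        elif name == "ridge_angles":
            tf.ridge_angles = tuple(a + rng.normal(0, sd) for a in tf.ridge_angles)
        elif name == "ridge_angular_sd":
            tf.ridge_angular_sd = tf.ridge_angular_sd * rng.lognormal(0.0, sd)
        elif name in _LOG_FIELDS:
            setattr(spec, name, getattr(spec, name) * rng.lognormal(0.0, sd))
        elif name == "aspect":
            spec.aspect = spec.aspect + rng.normal(0, sd)
        else:
            raise GenerationError(f"unknown perturbation field {name!r}")
    spec.seed = seed
    return spec


def generate_cohort(group_specs: Sequence[tuple[str, SyntheticPhalanxSpec, dict]],
                    n_per_group: int, seed: int,
                    ) -> list[tuple[BoneSurfacePair, GroundTruthField, str]]:
    """Generate group-structured cohorts of synthetic phalanges.

    Each individual perturbs the group base spec (log-normal on amplitudes,
    normal on angular positions).  Invalid draws are resampled up to 100
    times.  Fully reproducible given ``seed``.
    """
    if n_per_group < 2:
        raise GenerationError("n_per_group must be >= 2")
    ss = np.random.SeedSequence(seed)
    out: list[tuple[BoneSurfacePair, GroundTruthField, str]] = []
    for g, (label, base, sds) in enumerate(group_specs):
        base.validate()
        for i in range(n_per_group):
            child = ss.spawn(1)[0]
            rng = np.random.default_rng(child)
            ind_seed = int(child.generate_state(1)[0] % (2 ** 31))
            for attempt in range(100):
                spec = perturb_spec(base, sds, rng, ind_seed)
                try:
                    spec.validate()
                    break
                except GenerationError:
                    continue
            else:
                raise GenerationError(
                    f"could not draw a valid spec for group {label!r} after 100 tries")
            pair, truth = generate_phalanx(spec)
            pair.label = label
            pair.specimen_id = f"{label}_{i:03d}"
            out.append((pair, truth, label))
    return out


def spec_to_json(spec: SyntheticPhalanxSpec, path) -> None:
    with open(path, "w") as fh:
        json.dump(_spec_dict(spec), fh, indent=2)


def spec_from_json(path_or_dict) -> SyntheticPhalanxSpec:
    if isinstance(path_or_dict, dict):
        d = dict(path_or_dict)
    else:
        with open(path_or_dict) as fh:
            d = json.load(fh)
    tf = d.pop("thickness_field", {})
    tf = dict(tf)
    if "axial_profile" in tf:
        tf["axial_profile"] = tuple(tf["axial_profile"])
    if "ridge_angles" in tf:
        tf["ridge_angles"] = tuple(tf["ridge_angles"])
    if "ridge_axial_window" in tf:
        tf["ridge_axial_window"] = tuple(tf["ridge_axial_window"])
    if "shaft_window" in tf:
        tf["shaft_window"] = tuple(tf["shaft_window"])
    if "mesh_resolution" in d:
        d["mesh_resolution"] = tuple(d["mesh_resolution"])
    return SyntheticPhalanxSpec(thickness_field=ThicknessFieldSpec(**tf), **d)
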