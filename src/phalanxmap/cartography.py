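"""Map standardization, mean models, proximodistal profiles, and export.

Cortical thickness is made size-free by dividing every map cell by the bone's
maximum proximodistal length, so specimens of different body size can share
one morphospace.  Mean models average standardized maps cell-wise (per-taxon
mean maps, or the per-individual mean across an individual's digits 2–5).
The proximodistal profile is the per-level mean over the 50 angular cells,
plotted 0% (proximal) to 100% (distal) of shaft length; its peak location
separates a monotonically increasing "ape-like" gradient from the mid-distal
peak seen in humans.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .sectioning import ThicknessMap

__all__ = [
    "ThicknessProfile",
    "standardize_map",
    "mean_map",
    "digit_mean",
    "thickness_profile",
    "profile_peak",
    "export_map_image",
]

PEAK_SMOOTH_WINDOW = 5  # rows (~5% of shaft length)


@dataclass
class ThicknessProfile:
    """Per-level mean thickness from proximal (0) to distal (100% of shaft)."""

    levels: np.ndarray          # shaft-length fractions
    mean_thickness: np.ndarray  # mm, or dimensionless if standardized; NaN = missing
    standardized: bool = False

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd
        pd.DataFrame({"level_percent": 100 * self.levels,
                      "mean_thickness": self.mean_thickness}).to_csv(path, index=False)


def standardize_map(tmap: ThicknessMap) -> ThicknessMap:
    """Divide every cell by the bone's maximum length (size correction).

    Raises if the map is already standardized (guards double division) or the
    recorded length is not positive.
    """
    if tmap.standardized:
        raise ValueError("map is already standardized; refusing to divide twice")
    if not tmap.bone_length > 0:
        raise ValueError("bone_length must be positive to standardize")
    out = tmap.copy()
    out.values = out.values / tmap.bone_length
    out.standardized = True
    return out


def _check_same_grid(maps: Sequence[ThicknessMap]) -> None:
    ref = maps[0]
    for m in maps[1:]:
        if m.shape != ref.shape or not np.allclose(m.levels, ref.levels) \
                or not np.allclose(m.angles, ref.angles):
            raise ValueError("maps are on different grids")
        if m.standardized != ref.standardized:
            raise ValueError("cannot mix standardized and unstandardized maps")


def mean_map(maps: Sequence[ThicknessMap], require_standardized: bool = True) -> ThicknessMap:
    """Cell-wise arithmetic mean of maps; flagged cells are excluded per cell.

    A cell flagged in every input stays flagged in the output with value 0;
    ``meta['mean_cell_counts']`` records contributing counts.
    """
    if not maps:
        raise ValueError("need at least one map")
    if require_standardized and not maps[0].standardized:
        raise ValueError("maps must be standardized before averaging")
    _check_same_grid(maps)
    stack = np.stack([m.values for m in maps])
    ok = ~np.stack([m.mask for m in maps])
    counts = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        vals = np.where(counts > 0, (stack * ok).sum(axis=0) / np.maximum(counts, 1), 0.0)
    out = maps[0].copy()
    out.values = vals
    out.mask = counts == 0
    out.bone_length = float(np.mean([m.bone_length for m in maps]))
    out.meta = {"n_maps": len(maps),
                "mean_cell_counts_min": int(counts.min()),
                "source_ids": [m.meta.get("specimen_id", "") for m in maps]}
    return out


def digit_mean(maps: Sequence[ThicknessMap]) -> ThicknessMap:
    """Mean map across one individual's phalanges of one element type
    (digits 2–5; individuals with missing digits contribute fewer maps)."""
    if not 1 <= len(maps) <= 4:
        raise ValueError("digit_mean expects 1-4 maps from one individual")
    elements = {m.meta.get("element") for m in maps}
    if len(elements) > 1:
        raise ValueError(f"cannot mix element types in a digit mean: {sorted(elements)}")
    out = mean_map(maps, require_standardized=True)
    out.meta["element"] = elements.pop()
    out.meta["digits"] = sorted(m.meta.get("digit") for m in maps
                                if m.meta.get("digit") is not None)
    return out


def thickness_profile(tmap: ThicknessMap) -> ThicknessProfile:
    """Per-level mean over the angular cells, excluding flagged cells.

    Fully-flagged rows are reported as NaN (missing), never as zero.
    """
    ok = ~tmap.mask
    counts = ok.sum(axis=1)
    sums = (tmap.values * ok).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return ThicknessProfile(tmap.levels.copy(), means, tmap.standardized)


def profile_peak(profile: ThicknessProfile,
                 smooth_window: int = PEAK_SMOOTH_WINDOW) -> float:
    """Shaft-length fraction of the profile maximum.

    The profile is smoothed with a centered moving average (window
    ``smooth_window`` rows, shrinking symmetrically at the ends) before taking
    the argmax; ties break toward the proximal-most maximizer.
    """
    y = profile.mean_thickness
    valid = ~np.isnan(y)
    if valid.sum() < 3:
        raise ValueError("need at least 3 non-missing profile values")
    ys = _centered_moving_average(y, smooth_window)
    ys = np.where(valid, ys, -np.inf)
    # smoothing can flatten a sharp peak into a plateau of equal smoothed
    # values: break smoothed ties by the raw profile, then proximally
    tie = np.flatnonzero(ys >= ys.max() - 1e-12)
    raw = np.where(valid, y, -np.inf)[tie]
    idx = int(tie[np.argmax(raw)])  # argmax takes the first (proximal-most) tie
    return float(profile.levels[idx])


def _centered_moving_average(y: np.ndarray, window: int) -> np.ndarray:
    half = window // 2
    out = np.empty_like(y, dtype=float)
    n = len(y)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        seg = y[lo:hi]
        seg = seg[~np.isnan(seg)]
        out[i] = seg.mean() if seg.size else np.nan
    return out


def export_map_image(tmap: ThicknessMap, path: str | Path,
                     vmin: Optional[float] = None, vmax: Optional[float] = None,
                     cmap: str = "viridis") -> dict:
    """Render the unrolled map as a PNG heat map and write the CSV alongside.

    Returns the metadata block (including the color-scale limits actually
    used); pass explicit ``vmin``/``vmax`` to share a scale across maps.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    path = Path(path)
    lo = float(np.nanmin(tmap.values)) if vmin is None else float(vmin)
    hi = float(np.nanmax(tmap.values)) if vmax is None else float(vmax)
    fig, ax = plt.subplots(figsize=(6, 8))
    shown = np.where(tmap.mask, np.nan, tmap.values)
    im = ax.imshow(shown, origin="lower", aspect="auto", cmap=cmap,
                   vmin=lo, vmax=hi,
                   extent=(0, 360, 100 * tmap.levels[0], 100 * tmap.levels[-1]))
    ax.set_xlabel("angle from mid-dorsal (deg)")
    ax.set_ylabel("shaft length (%)")
    unit = "t / L" if tmap.standardized else "thickness (mm)"
    fig.colorbar(im, ax=ax, label=unit)
    title = tmap.meta.get("specimen_id") or tmap.meta.get("label") or ""
    if title:
        ax.set_title(str(title))
    try:
        fig.savefig(path, dpi=110)
    except OSError as exc:
        raise OSError(f"cannot write map image to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    tmap.to_csv(path.with_suffix(".csv"))
    meta = {"vmin": lo, "vmax": hi, "cmap": cmap, "png": str(path),
            "csv": str(path.with_suffix(".csv"))}
    return meta
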