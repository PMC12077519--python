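"""Configuration-driven end-to-end runner.

One :class:`RunConfig` (JSON-serializable) drives the whole analysis:
specimen input (a mesh manifest CSV or a synthetic cohort spec), shaft window
and map grid, mechanics levels, standardization exponents, and the
statistical options.  Every run writes its resolved config next to the
outputs, so a run is reproducible from that file alone; a single seed governs
the only stochastic stage (cohort generation).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import cartography, geometry, groupstats, mechanics, sectioning, synthetic

log = logging.getLogger("phalanxmap")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved options for one pipeline run (protocol defaults built in)."""

    output_dir: str = "phalanxmap_out"
    manifest: Optional[str] = None          # CSV: id,group,element,digit,side,outer,inner
    synthetic: Optional[dict] = None        # {"groups": [{label, spec, sds}], "n_per_group": int}
    shaft_window: tuple[float, float] = sectioning.DEFAULT_WINDOW
    n_levels: int = sectioning.N_LEVELS
    n_angles: int = sectioning.N_ANGLES
    level_span: tuple[float, float] = sectioning.LEVEL_SPAN
    j_levels: tuple[float, ...] = mechanics.J_LEVELS_DEFAULT
    j_std_exponent: int = mechanics.J_STD_EXPONENT
    n_pcs: int = 3
    typicality_variant: str = "chi2"
    export_images: bool = False
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(json.dumps(d, indent=2, default=str))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        d = json.loads(Path(path).read_text())
        for key in ("shaft_window", "level_span", "j_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _load_specimens(config: RunConfig,
                    ) -> tuple[list[tuple[geometry.BoneSurfacePair, str]], list[dict]]:
    """Resolve specimens from the synthetic spec or the mesh manifest.

    Ingestion failures are isolated per specimen and returned alongside the
    successfully loaded pairs.
    """
    pairs: list[tuple[geometry.BoneSurfacePair, str]] = []
    failures: list[dict] = []
    if config.synthetic is not None:
        groups = []
        for gspec in config.synthetic["groups"]:
            base = synthetic.spec_from_json(gspec["spec"])
            groups.append((gspec["label"], base, dict(gspec.get("sds", {}))))
        cohort = synthetic.generate_cohort(groups, config.synthetic["n_per_group"],
                                           seed=config.seed)
        for pair, _truth, label in cohort:
            pairs.append((pair, label))
    elif config.manifest is not None:
        table = pd.read_csv(config.manifest)
        root = Path(config.manifest).parent
        for _, row in table.iterrows():
            try:
                outer = geometry.load_surface(root / row["outer"])
                inner = geometry.load_surface(root / row["inner"])
                pair = geometry.BoneSurfacePair(
                    outer=outer, inner=inner, side=str(row.get("side", "right")),
                    label=str(row["group"]), element=str(row.get("element", "PP")),
                    digit=int(row["digit"]) if not pd.isna(row.get("digit")) else None,
                    specimen_id=str(row["id"]))
                pair = geometry.orient_anatomical(pair)
                pair = geometry.mirror_to_right(pair)
                pairs.append((pair, str(row["group"])))
            except Exception as exc:  # noqa: BLE001 — isolate per-specimen failures
                failures.append({"id": str(row.get("id", "?")), "stage": "ingest",
                                 "error": f"{type(exc).__name__}: {exc}"})
    else:
        raise ValueError("config must provide either a manifest or a synthetic cohort")
    return pairs, failures


def run_pipeline(config: RunConfig) -> dict:
    """Run generation/ingestion → maps → mechanics → group statistics.

    Per-specimen failures are isolated: the failing specimen is recorded in
    the report and the rest of the cohort completes.  Returns the report
    dict (also written as ``report.json``).
    """
    t_start = time.perf_counter()
    outdir = Path(config.output_dir)
    (outdir / "maps").mkdir(parents=True, exist_ok=True)
    config.to_json(outdir / "config.resolved.json")
    report: dict = {"stages": {}, "failures": [], "warnings": [], "n_specimens": 0}

    t0 = time.perf_counter()
    pairs, load_failures = _load_specimens(config)
    report["failures"].extend(load_failures)
    report["stages"]["load_or_generate_s"] = round(time.perf_counter() - t0, 3)
    report["n_specimens"] = len(pairs)

    window = sectioning.ShaftWindow(*config.shaft_window)
    maps, labels, mech_rows = [], [], []
    t0 = time.perf_counter()
    for pair, label in pairs:
        sid = pair.specimen_id or f"s{len(maps)}"
        try:
            tmap = sectioning.compute_thickness_map(
                pair, window=window, n_levels=config.n_levels,
                n_angles=config.n_angles, span=config.level_span)
            if (config.n_levels, config.n_angles) != (sectioning.N_LEVELS,
                                                      sectioning.N_ANGLES):
                tmap.meta["grid_deviates_from_protocol"] = True
            smap = cartography.standardize_map(tmap)
            smap.to_csv(outdir / "maps" / f"{sid}.csv")
            if config.export_images:
                cartography.export_map_image(smap, outdir / "maps" / f"{sid}.png")
            profile = cartography.thickness_profile(smap)
            profile.to_csv(outdir / "maps" / f"{sid}.profile.csv")

            L = geometry.max_length(pair)
            curv = mechanics.included_angle(pair, window=window)
            for geom in mechanics.J_at_levels(pair, levels=config.j_levels):
                j_std = mechanics.standardize_J(geom, L, exponent=config.j_std_exponent)
                mech_rows.append({
                    "id": sid, "group": label, "element": pair.element,
                    "digit": pair.digit, "level_frac": geom.level_frac,
                    "cortical_area": geom.cortical_area, "Ixx": geom.Ixx,
                    "Iyy": geom.Iyy, "Ixy": geom.Ixy, "J": geom.J, "J_std": j_std,
                    "mean_thickness": geom.mean_thickness,
                    "mean_thickness_std": geom.mean_thickness / L,
                    "included_angle_deg": curv.included_angle,
                    "max_length": L,
                })
            maps.append(smap)
            labels.append(label)
        except Exception as exc:  # noqa: BLE001 — isolate per-specimen failures
            report["failures"].append({"id": sid, "stage": "map/mechanics",
                                       "error": f"{type(exc).__name__}: {exc}"})
    report["stages"]["maps_mechanics_s"] = round(time.perf_counter() - t0, 3)

    mech_df = pd.DataFrame(mech_rows)
    mech_df.to_csv(outdir / "mechanics.csv", index=False)

    if len(maps) >= 3 and len(set(labels)) >= 2:
        t0 = time.perf_counter()
        sample = groupstats.assemble_matrix(maps, labels)
        report["n_imputed_cells"] = sample.n_imputed
        r = min(len(maps) - 1, max(config.n_pcs, 10))
        model = groupstats.pca(sample, r=r)
        scores = pd.DataFrame(model.scores, columns=[f"PC{i+1}" for i in range(r)])
        scores.insert(0, "id", sample.ids)
        scores.insert(1, "group", sample.labels)
        scores.to_csv(outdir / "pc_scores.csv", index=False)

        pcs = model.scores[:, :config.n_pcs]
        counts = {g: labels.count(g) for g in set(labels)}
        if min(counts.values()) >= 3:
            cva_model = groupstats.cva(pcs, labels)
            canon = cva_model.transform(pcs)
            cv_df = pd.DataFrame(canon, columns=[f"CV{i+1}" for i in range(cva_model.n_axes)])
            cv_df.insert(0, "id", sample.ids)
            cv_df.insert(1, "group", sample.labels)
            cv_df.to_csv(outdir / "cv_scores.csv", index=False)

            typ = {
                g: [groupstats.typicality(cva_model, pcs[i], g,
                                          variant=config.typicality_variant).probability
                    for i in range(len(pcs))]
                for g in cva_model.group_names}
            typ_df = pd.DataFrame(typ)
            typ_df.insert(0, "id", sample.ids)
            typ_df.to_csv(outdir / "typicality.csv", index=False)

            loo = groupstats.loo_classification(pcs, labels, ids=sample.ids)
            loo["confusion"].to_csv(outdir / "confusion.csv")
            report["loo_overall_accuracy"] = loo["overall_accuracy"]
            report["loo_per_group"] = loo["per_group_accuracy"]
        report["stages"]["stats_s"] = round(time.perf_counter() - t0, 3)

    report["total_s"] = round(time.perf_counter() - t_start, 3)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
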