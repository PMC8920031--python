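"""End-to-end orchestration.

One seeded run goes: simulate colony -> extract features -> fit/decode
the HMM -> time-activity budgets -> DEE -> utilization distribution ->
stage statistics -> plain-text report, with a manifest recording the
config hash, seed and every file written.  The same (config, seed) pair
reproduces the run byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import BEHAVIOURS, STAGES, ColonyConfig, validate_config
from .containers import (
    BirdRecord,
    FeatureSeries,
    StatePath,
    TimeActivityBudget,
    write_metadata,
)
from .energetics import compute_dee
from .features import build_features
from .hmm import HmmModel, canonicalize, compute_budget, decode, fit_em
from .simulate import simulate_colony, write_deployment
from .spaceuse import kernel_ud, select_foraging_points
from .stagestats import (
    build_outcome_table,
    fit_lm_anova,
    lsm_pairwise,
    paired_t,
    stage_summary,
)

log = logging.getLogger("colonyflux")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: dict = field(default_factory=dict)  # stage -> [paths]
    timestamps: dict = field(default_factory=dict)

    def record(self, stage: str, paths) -> None:
        self.outputs[stage] = [str(p) for p in paths]
        self.timestamps[stage] = pd.Timestamp.now().isoformat()
        for p in paths:
            p = Path(p)
            if not (p.exists() and p.stat().st_size > 0):
                raise RuntimeError(f"stage {stage!r} output missing or empty: {p}")

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def config_hash(config: ColonyConfig) -> str:
    blob = yaml.safe_dump(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---- in-memory stage functions (also used by the CLI) --------------------


def extract_features(deployments: dict, config: ColonyConfig) -> dict:
    colony = (config.colony_lat, config.colony_lon)
    out = {}
    for bid, (_, accel, gps) in deployments.items():
        out[bid] = build_features(
            accel,
            gps,
            colony,
            window_s=config.window_s,
            band=config.band_hz,
            dominance_min=config.dominance_min,
            gps_period=config.gps_period_s,
        )
    return out


def classify(features: dict, init: Optional[HmmModel] = None,
             max_iter: int = 200, tol: float = 1e-6):
    """Pooled EM fit, canonical state labelling, per-bird Viterbi paths
    and budgets."""
    series = list(features.values())
    model, trace = fit_em(series, init=init, max_iter=max_iter, tol=tol)
    model = canonicalize(model)
    paths = {bid: decode(model, fs, bird_id=bid) for bid, fs in features.items()}
    budgets = [compute_budget(p) for p in paths.values()]
    return model, trace, paths, budgets


def analyse_colony(config: ColonyConfig, seed: Optional[int] = None,
                   duration_days: Optional[float] = None):
    """Generate and fully classify one colony in memory.

    Returns (birds, deployments, features, model, paths, budgets)."""
    birds, deployments = simulate_colony(config, seed=seed, duration_days=duration_days)
    features = extract_features(deployments, config)
    model, _, paths, budgets = classify(features)
    return birds, deployments, features, model, paths, budgets


def _budget_frame(budgets) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {"bird_id": b.bird_id, **{f"T_{beh}": b.proportions[i]
                                      for i, beh in enumerate(BEHAVIOURS)}}
            for b in budgets
        ]
    )


def stats_report(table: pd.DataFrame) -> str:
    """Plain-text summary mirroring the study's results structure:
    budgets, DEE and T3 by stage and sex."""
    lines = ["Stage summaries (mean +/- s.d.)", "=" * 34]
    summ = stage_summary(table)
    for _, r in summ.iterrows():
        sd = f"{r['sd']:.3f}" if np.isfinite(r["sd"]) else "NA"
        lines.append(f"{r['stage']:>14} {r['variable']:>9}: "
                     f"{r['mean']:.3f} +/- {sd} (n={int(r['n'])})")
    for resp in ("T_flight", "T_colony", "T_water", "dee_act", "t3"):
        if resp not in table.columns or table[resp].dropna().empty:
            continue
        lines.append("")
        lines.append(f"--- {resp} ~ sex * stage ---")
        try:
            a3 = fit_lm_anova(table, resp, interaction=True)
            a2 = fit_lm_anova(table, resp, interaction=False)
        except ValueError as e:
            lines.append(f"model not estimable: {e}")
            continue
        lines.append("type III (interaction): " + "; ".join(
            f"{t} p={a3.table.loc[t, 'PR(>F)']:.4g}"
            for t in a3.table.index if t not in ("Residual", "Intercept")))
        lines.append("type II (main effects): " + "; ".join(
            f"{t} p={a2.table.loc[t, 'PR(>F)']:.4g}"
            for t in a2.table.index if t != "Residual"))
        lsm = lsm_pairwise(a2, "stage")
        for _, c in lsm.contrasts.iterrows():
            lines.append(f"  LSM {c['a']} - {c['b']}: {c['diff']:+.4f} "
                         f"(SE {c['se']:.4f}, Tukey p={c['p_adj']:.4g})")
    t, df, p = paired_t(table["mass_pre"], table["mass_post"])
    lines.append("")
    lines.append(f"Paired t-test, mass change over deployment: t({df}) = {t:.3f}, p = {p:.4g}")
    return "\n".join(lines) + "\n"


# ---- full run ------------------------------------------------------------


def run_pipeline(config: ColonyConfig, seed: int, outdir,
                 duration_days: Optional[float] = None) -> RunManifest:
    """Execute every stage in order under ``outdir``; returns the manifest.

    Any stage failure aborts with the failing stage named; partial
    outputs are retained for inspection.
    """
    config = validate_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=seed, version=__version__)
    stage = "simulate"
    try:
        log.info("simulating colony (seed %d)", seed)
        birds, deployments = simulate_colony(config, seed=seed, duration_days=duration_days)
        raw = outdir / "raw"
        paths = [raw / "metadata.csv"]
        raw.mkdir(exist_ok=True)
        write_metadata(birds, paths[0])
        for b in birds:
            _, accel, gps = deployments[b.bird_id]
            paths.extend(write_deployment(b, accel, gps, raw).values())
        manifest.record("simulate", paths)

        stage = "features"
        features = extract_features(deployments, config)
        fdir = outdir / "features"
        fdir.mkdir(exist_ok=True)
        paths = []
        for bid, fs in features.items():
            p = fdir / f"{bid}_features.csv"
            fs.write(p)
            paths.append(p)
        manifest.record("features", paths)

        stage = "classify"
        model, trace, spaths, budgets = classify(features)
        log.info("EM converged after %d iterations (loglik %.2f)", len(trace), trace[-1])
        sdir = outdir / "states"
        sdir.mkdir(exist_ok=True)
        paths = [outdir / "hmm_model.yaml", outdir / "budgets.csv"]
        model.to_yaml(paths[0])
        _budget_frame(budgets).to_csv(paths[1], index=False)
        for bid, sp in spaths.items():
            p = sdir / f"{bid}_states.csv"
            sp.write(p)
            paths.append(p)
        manifest.record("classify", paths)

        stage = "energetics"
        dees = [compute_dee(b, config.mr) for b in budgets]
        p = outdir / "dee.csv"
        pd.DataFrame(
            [{"bird_id": d.bird_id, "dee_act_kj_g_day": d.dee_act} for d in dees]
        ).to_csv(p, index=False)
        manifest.record("energetics", [p])

        stage = "ud"
        colony = (config.colony_lat, config.colony_lon)
        pts = [
            select_foraging_points(deployments[bid][2], spaths[bid], colony,
                                   window_s=config.window_s)
            for bid in spaths
        ]
        points = np.vstack([p_ for p_ in pts if len(p_)]) if any(len(p_) for p_ in pts) \
            else np.empty((0, 2))
        paths = [outdir / "ud_areas.csv"]
        if len(points) >= 5:
            _, iso = kernel_ud(points, cell_m=config.ud_cell_m, levels=config.ud_levels)
            pd.DataFrame(
                [{"level": lv, "area_km2": iso.areas_km2[lv], "mass": iso.masses[lv]}
                 for lv in iso.levels]
            ).to_csv(paths[0], index=False)
            iso.write_geojson(outdir / "isopleths.geojson", colony)
            paths.append(outdir / "isopleths.geojson")
        else:
            pd.DataFrame([{"level": np.nan, "area_km2": np.nan, "mass": np.nan}]).to_csv(
                paths[0], index=False
            )
            log.warning("too few at-sea fixes for a UD")
        manifest.record("ud", paths)

        stage = "stats"
        tab = build_outcome_table(birds, budgets, dees)
        paths = [outdir / "outcomes.csv", outdir / "stage_summary.csv"]
        tab.to_csv(paths[0], index=False)
        stage_summary(tab).to_csv(paths[1], index=False)
        manifest.record("stats", paths)

        stage = "report"
        p = outdir / "report.txt"
        p.write_text(stats_report(tab))
        manifest.record("report", [p])
    except Exception as e:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {e}") from e
    manifest.write(outdir / "manifest.json")
    return manifest
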