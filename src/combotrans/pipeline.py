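"""End-to-end analysis stages gluing the library into file-driven workflows.

Each stage reads what it needs (config blocks, upstream CSVs), runs the
corresponding library computation, writes its artifacts plus a provenance
manifest, and returns the paths it wrote. Stages are independently runnable;
a stage missing its upstream artifact raises DependencyError naming the
stage to run first.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import gr, io, mapk, pk, projection, synth, tgi
from .dose_response import synergy_analysis
from .errors import DependencyError, ParameterError

__all__ = ["run_stage", "STAGES"]


def _outdir(config):
    d = Path(config.get("out_dir", "combotrans_out"))
    d.mkdir(parents=True, exist_ok=True)
    return d


def _require(config, *keys):
    missing = [k for k in keys if k not in config]
    if missing:
        raise ParameterError(f"config missing required keys: {missing}")


def _seed(config, default=0):
    return int(config.get("seed", default))


def stage_synth(config: dict) -> list:
    """Generate the synthetic screen panel and write per-line wide CSVs."""
    out = _outdir(config)
    seed = _seed(config)
    spec = synth.DEFAULT_PANEL_SPEC
    if "n_lines" in config:  # optional downscaling, e.g. {"BRAF_V600": 2, ...}
        from dataclasses import replace
        groups = {g: replace(sp, n_lines=int(config["n_lines"].get(g, sp.n_lines)))
                  for g, sp in spec.groups.items()}
        spec = replace(spec, groups=groups)
    matrices, truth = synth.generate_screen_panel(spec, seed=seed)
    paths = []
    panel_dir = out / "panel"
    panel_dir.mkdir(exist_ok=True)
    for m in matrices:
        p = panel_dir / f"{m.cell_line}.csv"
        io.write_combination_csv(m, p)
        paths.append(p)
    truth_path = out / "panel_truth.json"
    with open(truth_path, "w") as fh:
        json.dump({"groups": [t["group"] for t in truth.per_item],
                   "cell_lines": [t["cell_line"] for t in truth.per_item],
                   "bump_amplitudes": [t["bump_amplitude"] for t in truth.per_item]},
                  fh, indent=2)
    paths.append(truth_path)
    io.write_manifest(out, "synth", {}, {"seed": seed}, paths)
    return paths


def stage_score(config: dict) -> list:
    """Score every panel matrix: Bliss/HSA scores JSON + excess CSVs."""
    out = _outdir(config)
    panel_dir = out / "panel"
    if not panel_dir.exists():
        raise DependencyError("no panel/ directory found; run the 'synth' stage first")
    rows = []
    paths = []
    for p in sorted(panel_dir.glob("*.csv")):
        m = io.read_combination_csv(p, "wide", cell_line=p.stem)
        res = synergy_analysis(m)
        rows.append({"cell_line": p.stem, "bliss_score": res.bliss_score,
                     "hsa_score": res.hsa_score})
    scores_path = out / "scores.csv"
    pd.DataFrame(rows).to_csv(scores_path, index=False)
    paths.append(scores_path)
    io.write_manifest(out, "score", {"panel": panel_dir}, {}, paths)
    return paths


def stage_gr(config: dict) -> list:
    """Convert a viability matrix to a GR surface on free-dose axes."""
    out = _outdir(config)
    _require(config, "matrix_csv")
    m = io.read_combination_csv(config["matrix_csv"], "wide")
    constants = gr.AssayConstants(**config.get("assay_constants", {}))
    syn = synergy_analysis(m)
    surface = gr.gr_surface_from_matrix(m, constants, bliss_excess=syn.bliss_excess)
    df = pd.DataFrame(surface.gr, index=surface.free_doses_a,
                      columns=surface.free_doses_b)
    df.index.name = "free_dose_a_uM"
    p = out / "gr_surface.csv"
    df.to_csv(p)
    io.write_manifest(out, "gr", {"matrix_csv": config["matrix_csv"]}, {}, [p])
    return [p]


def stage_xeno_predict(config: dict) -> list:
    """Predict xenograft volumes from a GR surface and per-arm free exposures."""
    out = _outdir(config)
    _require(config, "matrix_csv", "arms")
    m = io.read_combination_csv(config["matrix_csv"], "wide")
    constants = gr.AssayConstants(**config.get("assay_constants", {}))
    surface = gr.gr_surface_from_matrix(m, constants)
    pred_cfg = config.get("prediction", {})
    v0 = float(pred_cfg.get("initial_volume_mm3", 240.0))
    td = float(pred_cfg.get("doubling_time_in_vivo_days",
                            constants.doubling_time_in_vivo))
    times = np.asarray(pred_cfg.get("times_days", list(range(0, 22))), dtype=float)
    k = gr.baseline_rate_from_doubling(td)
    rows = []
    summary = {}
    for arm in config["arms"]:
        # per-arm exposures given in nM free drug; µM internally
        fa = float(arm.get("free_a_nM", 0.0)) * 1e-3
        fb = float(arm.get("free_b_nM", 0.0)) * 1e-3
        r_norm = surface.normalized_rate_at(fa, fb)
        pred = gr.predict_tumor_growth(v0, k, r_norm, times)
        summary[arm["name"]] = {"gr": surface.gr_at(fa, fb),
                                "normalized_rate": r_norm}
        for t, v in zip(pred.times, pred.predicted_volumes):
            rows.append({"arm": arm["name"], "day": t, "volume_mm3": v})
    vol_path = out / "predicted_volumes.csv"
    pd.DataFrame(rows).to_csv(vol_path, index=False)
    sum_path = out / "xeno_summary.json"
    with open(sum_path, "w") as fh:
        json.dump(summary, fh, indent=2)
    io.write_manifest(out, "xeno-predict", {"matrix_csv": config["matrix_csv"]},
                      {}, [vol_path, sum_path])
    return [vol_path, sum_path]


def stage_pk_sim(config: dict) -> list:
    """Simulate the standard population PK regimens; write long CSV summaries."""
    out = _outdir(config)
    seed = _seed(config)
    n = int(config.get("n_individuals", 500))
    rows = []
    for d, (drug, regimens) in enumerate(pk.STANDARD_REGIMENS.items()):
        model = pk.DEFAULT_MODELS[drug]
        for r, regimen in enumerate(regimens):
            profiles = pk.simulate_population_pk(model, regimen, n=n,
                                                 seed=seed + 1000 * d + r)
            summary = pk.exposure_summary(profiles)
            rows.append({"drug": drug, "regimen": regimen.label,
                         "mean_free_uM": summary["mean"], "sd_free_uM": summary["sd"],
                         "n": summary["n"]})
    p = out / "pk_exposure_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    io.write_manifest(out, "pk-sim", {}, {"seed": seed}, [p])
    return [p]


def stage_project(config: dict) -> list:
    """Project a virtual population onto the GR/Bliss surfaces of a matrix."""
    out = _outdir(config)
    _require(config, "matrix_csv")
    seed = _seed(config)
    m = io.read_combination_csv(config["matrix_csv"], "wide")
    constants = gr.AssayConstants(**config.get("assay_constants", {}))
    syn = synergy_analysis(m)
    surface = gr.gr_surface_from_matrix(m, constants, bliss_excess=syn.bliss_excess)
    n = int(config.get("n_individuals", 100))
    n_patients = int(config.get("n_patients", 75))
    reg_a = pk.Regimen("belvarafenib", float(config.get("belva_mg", 100.0)),
                       config.get("belva_schedule", "BID"))
    reg_b = pk.Regimen("cobimetinib", float(config.get("cobi_mg", 40.0)),
                       config.get("cobi_schedule", "QD"))
    pa = pk.simulate_population_pk(pk.DEFAULT_MODELS["belvarafenib"], reg_a,
                                   n=n, seed=seed)
    pb = pk.simulate_population_pk(pk.DEFAULT_MODELS["cobimetinib"], reg_b,
                                   n=n, seed=seed + 1)
    dist = projection.project_population(pa, pb, surface, n_patients=n_patients,
                                         seed=seed + 2)
    rows = [{"regimen_a": dist.regimen_a, "regimen_b": dist.regimen_b,
             "statistic": f"gr_q{int(q * 100)}", "value": v}
            for q, v in dist.gr_quantiles.items()]
    rows += [{"regimen_a": dist.regimen_a, "regimen_b": dist.regimen_b,
              "statistic": f"bliss_q{int(q * 100)}", "value": v}
             for q, v in dist.bliss_quantiles.items()]
    p = out / "effect_distribution.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    pooled = out / "effect_samples.csv"
    pd.DataFrame({"gr": dist.gr_samples, "bliss_excess": dist.bliss_samples}
                 ).to_csv(pooled, index=False)
    io.write_manifest(out, "project", {"matrix_csv": config["matrix_csv"]},
                      {"seed": seed}, [p, pooled])
    return [p, pooled]


def stage_mapk_sim(config: dict) -> list:
    """Run the MAPK surrogate dose matrices for all three variants."""
    out = _outdir(config)
    variants = {"BRAF_V600E": mapk.braf_v600e(), "NRAS_Q61": mapk.nras_q61(),
                "NRAS_Q61_NO_FEEDBACK": mapk.nras_q61_no_feedback()}
    paths = []
    summary = {}
    for name, variant in variants.items():
        dm = mapk.dose_matrix(variant)
        for key in ("pmek_rel", "perk_rel", "bliss_excess_perk"):
            df = pd.DataFrame(dm[key], index=dm["belva_doses"],
                              columns=dm["cobi_doses"])
            df.index.name = "belvarafenib_uM"
            p = out / f"mapk_{name}_{key}.csv"
            df.to_csv(p)
            paths.append(p)
        summary[name] = {"max_bliss_excess_perk": dm["max_bliss_excess_perk"],
                         "bliss_score_perk": dm["bliss_score_perk"]}
    sp = out / "mapk_summary.json"
    with open(sp, "w") as fh:
        json.dump(summary, fh, indent=2)
    paths.append(sp)
    io.write_manifest(out, "mapk-sim", {}, {}, paths)
    return paths


def stage_tgi(config: dict) -> list:
    """Fit per-subject TGI parameters from a long CSV and simulate cohorts."""
    out = _outdir(config)
    _require(config, "tgi_csv")
    df = pd.read_csv(config["tgi_csv"])
    fits = []
    for sid, sub in df.groupby("subject_id"):
        p = tgi.fit_tgi(sub["week"].to_numpy(), sub["tumor_size"].to_numpy())
        fits.append({"subject_id": sid, "group": sub["group"].iloc[0],
                     "ts0": p.ts0, "kg": p.kg, "ks": p.ks})
    fit_df = pd.DataFrame(fits)
    fit_path = out / "tgi_fits.json"
    fit_df.to_json(fit_path, orient="records", indent=2)
    group_params = {g: (sub["kg"].mean(), sub["ks"].mean())
                    for g, sub in fit_df.groupby("group")}
    cohort = tgi.simulate_cohort(group_params,
                                 ts0=float(config.get("ts0", 50.0)))
    rows = [{"group": g, "week": t, "tumor_size": s}
            for g, tr in cohort.items()
            for t, s in zip(tr["times_weeks"], tr["sizes"])]
    traj_path = out / "tgi_trajectories.csv"
    pd.DataFrame(rows).to_csv(traj_path, index=False)
    io.write_manifest(out, "tgi", {"tgi_csv": config["tgi_csv"]}, {},
                      [fit_path, traj_path])
    return [fit_path, traj_path]


STAGES = {
    "synth": stage_synth,
    "score": stage_score,
    "gr": stage_gr,
    "xeno-predict": stage_xeno_predict,
    "pk-sim": stage_pk_sim,
    "project": stage_project,
    "mapk-sim": stage_mapk_sim,
    "tgi": stage_tgi,
}


def run_stage(stage: str, config: dict) -> list:
    """Run one named pipeline stage; returns the paths it wrote."""
    if stage not in STAGES:
        raise ParameterError(f"unknown stage {stage!r}; choose from {sorted(STAGES)}")
    return STAGES[stage](config)
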