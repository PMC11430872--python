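"""Config-driven orchestration of the full analysis chain.

Stages: synthetic data (or CSV ingest) -> moisture-ratio kinetics and
thin-layer model ranking -> Fick-slab diffusivity and Arrhenius activation
energy -> transition-state thermodynamics -> energy/emission accounting ->
quality panels -> LM-trained MLP and ANN-vs-kinetic comparison.  All
tables are written as CSV, headline numbers land in a JSON report, and a
fixed global seed makes the whole run byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, datasets
from .ann import AnnTopology, MLPRegressor, compare_models, search_report, topology_search, train_lm
from .config import RunConfig
from .diffusion import arrhenius_fit, deff_from_series
from .energy import emission_intensity, energy_record, percent_change
from .kinetics import fit_all_models, moisture_ratio
from .quality import chroma, delta_e, ColorReading, summarize_panel
from .synthetic import generate_experiment, read_drying_runs, write_bundle
from .thermodynamics import thermo_table

__all__ = ["run_pipeline", "PipelineError"]

_FLOAT_FMT = "%.6g"


class PipelineError(RuntimeError):
    """Stage-named failure with a manifest of outputs written so far."""

    def __init__(self, stage: str, cause: Exception, manifest: dict):
        self.stage = stage
        self.manifest = manifest
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")


def _stage_seed(global_seed: int, stage: str) -> int:
    # stable hash of the stage name; reordering config keys never changes it
    return (int(global_seed) ^ zlib.crc32(stage.encode())) & 0x7FFFFFFF


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run report (also written to
    ``report.json`` in the output directory)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    report: dict = {"rwdry_version": __version__, "seed": config.seed, "mode": config.mode}
    stage = "setup"
    try:
        # ---- data ------------------------------------------------------
        stage = "synthetic_data" if config.mode == "synthetic" else "ingest"
        if config.mode == "synthetic":
            syn = dataclasses.replace(config.synthetic,
                                      seed=_stage_seed(config.seed, "synthetic_data"))
            bundle = generate_experiment(syn)
            for name, path in write_bundle(bundle, out / "data").items():
                files[name] = path
            runs = bundle.drying_runs
        else:
            bundle = None
            runs = read_drying_runs(config.csv_paths["drying_runs"])

        # ---- kinetics ---------------------------------------------------
        stage = "kinetics"
        fit_rows = []
        series_by_run = {}
        for run in runs:
            series = moisture_ratio(run, clip=True)
            series_by_run[run.run_id] = series
            for f in fit_all_models(series, seed=_stage_seed(config.seed, "kinetics")):
                fit_rows.append({"run_id": run.run_id, "temperature_C": run.temperature_C,
                                 "model": f.model_name,
                                 **{f"param_{k}": v for k, v in f.params.items()},
                                 "r2": f.r2, "mse": f.mse, "converged": f.converged})
        fits_df = pd.DataFrame(fit_rows)
        files["model_fits"] = str(out / "model_fits.csv")
        fits_df.to_csv(files["model_fits"], index=False, float_format=_FLOAT_FMT)
        mean_r2 = fits_df.groupby("model")["r2"].mean().sort_values(ascending=False)
        best_model = str(mean_r2.index[0])
        report["best_kinetic_model"] = best_model
        report["kinetic_mean_r2"] = {m: float(v) for m, v in mean_r2.items()}

        # ---- diffusion + Arrhenius --------------------------------------
        stage = "diffusion"
        drows = []
        for run in runs:
            d = deff_from_series(series_by_run[run.run_id], config.diffusion)
            drows.append({"run_id": run.run_id, "temperature_C": run.temperature_C,
                          "K1_per_s": d.k1_per_s, "deff_m2_s": d.deff_m2_s,
                          "r2_line": d.r2_line, "n_points": d.n_points})
        diff_df = pd.DataFrame(drows)
        files["diffusivity"] = str(out / "diffusivity.csv")
        diff_df.to_csv(files["diffusivity"], index=False, float_format=_FLOAT_FMT)
        per_T = diff_df.groupby("temperature_C")["deff_m2_s"].mean()
        arr = arrhenius_fit(list(per_T.items()))
        report["Ea_kJ_per_mol"] = arr.Ea_kJ_per_mol
        report["D0_m2_s"] = arr.D0_m2_s
        report["arrhenius_r2"] = arr.r2
        report["deff_m2_s"] = {f"{t:g}": float(v) for t, v in per_T.items()}

        # ---- thermodynamics ---------------------------------------------
        stage = "thermodynamics"
        thermo = thermo_table(arr.Ea_J_per_mol, arr.D0_m2_s, sorted(per_T.index))
        files["thermodynamics"] = str(out / "thermodynamics.csv")
        thermo.to_csv(files["thermodynamics"], index=False, float_format=_FLOAT_FMT)
        report["thermodynamics"] = {
            f"{row.temperature_C:g}": {"dH": row.dH_kJ_per_mol, "dS": row.dS_kJ_per_molK,
                                       "dG": row.dG_kJ_per_mol}
            for row in thermo.itertuples()
        }

        # ---- energy & emissions -----------------------------------------
        stage = "energy_emissions"
        erows = []
        if bundle is not None:
            for run in runs:
                total_kWh = float(bundle.energy_series[run.run_id]["cum_kWh"].iloc[-1])
                water_kg = float(run.mass_g[0] - run.mass_g[-1]) / 1000.0
                rec = energy_record(run.temperature_C, total_kWh, water_kg, config.emissions)
                erows.append(dataclasses.asdict(rec))
        elif "energy" in config.csv_paths:
            edf = pd.read_csv(config.csv_paths["energy"])
            for run in runs:
                g = edf[edf["run_id"] == run.run_id]
                if g.empty:
                    continue
                total_kWh = float(g.sort_values("time_min")["cum_kWh"].iloc[-1])
                water_kg = float(run.mass_g[0] - run.mass_g[-1]) / 1000.0
                rec = energy_record(run.temperature_C, total_kWh, water_kg, config.emissions)
                erows.append(dataclasses.asdict(rec))
        if erows:
            energy_df = pd.DataFrame(erows).groupby("temperature_C", as_index=False).mean()
            files["energy_summary"] = str(out / "energy_summary.csv")
            energy_df.to_csv(files["energy_summary"], index=False, float_format=_FLOAT_FMT)
            lo = energy_df.iloc[0]
            hi = energy_df.iloc[-1]
            report["sec_kWh_per_kg"] = {f"{r.temperature_C:g}": r.sec_kWh_per_kg
                                        for r in energy_df.itertuples()}
            report["percent_change_low_to_high_T"] = {
                "sec": percent_change(lo.sec_kWh_per_kg, hi.sec_kWh_per_kg),
                "co2": percent_change(lo.co2_kg_per_kg, hi.co2_kg_per_kg),
                "nox": percent_change(lo.nox_kg_per_kg, hi.nox_kg_per_kg),
            }

        # drying time per temperature (first sample at/below the stop MR)
        times = {}
        for run in runs:
            times.setdefault(run.temperature_C, []).append(float(run.time_min[-1]))
        tmean = {T: float(np.mean(v)) for T, v in sorted(times.items())}
        report["drying_time_min"] = {f"{t:g}": v for t, v in tmean.items()}
        T_lo, T_hi = min(tmean), max(tmean)
        report.setdefault("percent_change_low_to_high_T", {})["drying_time"] = \
            percent_change(tmean[T_lo], tmean[T_hi])

        # ---- quality -----------------------------------------------------
        stage = "quality"
        if bundle is not None:
            cp = bundle.color_panel
            fresh_mean = cp[cp["label"] == "fresh"][["L", "a", "b"]].mean()
            fresh = ColorReading(fresh_mean["L"], fresh_mean["a"], fresh_mean["b"], "fresh")
            qrows = []
            for label, g in cp[cp["label"] != "fresh"].groupby("label", sort=False):
                des = [delta_e(fresh, ColorReading(r.L, r.a, r.b, label))
                       for r in g.itertuples()]
                qrows.append({"label": label,
                              "delta_e": float(np.mean(des)),
                              "chroma": float(np.mean([chroma(r.a, r.b) for r in g.itertuples()]))})
            color_df = pd.DataFrame(qrows)
            files["color_metrics"] = str(out / "color_metrics.csv")
            color_df.to_csv(files["color_metrics"], index=False, float_format=_FLOAT_FMT)

            panel = summarize_panel(bundle.quality_panel)
            files["quality_summary"] = str(out / "quality_summary.csv")
            panel.to_csv(files["quality_summary"], index=False, float_format=_FLOAT_FMT)
            eo = panel.set_index("label")["eo_pct_mean"].dropna()
            if "80" in eo.index and "90" in eo.index:
                report["percent_change_low_to_high_T"]["eo_80_to_90"] = \
                    percent_change(float(eo["80"]), float(eo["90"]))

        # ---- ANN ---------------------------------------------------------
        stage = "ann"
        X = np.vstack([
            np.column_stack([np.full(s.time_min.size, s.temperature_C), s.time_min])
            for s in series_by_run.values()
        ])
        y = np.concatenate([s.mr for s in series_by_run.values()])
        tcfg = dataclasses.replace(config.train, seed=_stage_seed(config.seed, "ann"))
        if config.run_topology_search:
            results = topology_search(X, y, config=tcfg)
            files["ann_search"] = str(out / "ann_search.csv")
            search_report(results).to_csv(files["ann_search"], index=False,
                                          float_format=_FLOAT_FMT)
            ann = results[0]
        else:
            topo = AnnTopology((2, 15, 14, 1), ("tansig", "logsig", "purelin"))
            ann = train_lm(MLPRegressor(topo, seed=tcfg.seed), X, y, tcfg)
        files["ann_model"] = str(out / "ann_model.json")
        Path(files["ann_model"]).write_text(ann.network.to_json())
        report["ann"] = {"topology": str(ann.topology),
                         "activations": list(ann.topology.activations),
                         "test_mse": ann.mse, "test_r2": ann.r2, "epochs": ann.epoch}

        # ---- comparison --------------------------------------------------
        stage = "comparison"
        best_series = max(series_by_run.values(), key=lambda s: s.time_min.size)
        best_fit = fit_all_models(best_series, seed=_stage_seed(config.seed, "kinetics"))[0]
        Xc = np.column_stack([np.full(best_series.time_min.size, best_series.temperature_C),
                              best_series.time_min])
        report["ann_vs_kinetic"] = compare_models(ann, best_fit, Xc, best_series.mr)

    except Exception as exc:
        raise PipelineError(stage, exc, files) from exc

    report["files"] = {k: str(Path(v).relative_to(out)) for k, v in files.items()}
    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=2, sort_keys=True, default=float))
    report["report_path"] = str(report_path)
    return report


def reference_tables_report(settings=None) -> dict:
    """Recompute the derived columns of the shipped reference tables:
    Arrhenius chain, thermodynamic identities, Chroma, and the headline
    percent changes.  Pure desk calculation; no randomness."""
    drying = datasets.load_drying_summary()
    thermo = datasets.load_thermo_summary()
    color = datasets.load_color_summary()
    qual = datasets.load_quality_summary()

    arr = arrhenius_fit(list(zip(drying["temperature_C"], drying["deff_m2_s"])))
    from .thermodynamics import enthalpy, gibbs
    t90 = thermo[thermo["temperature_C"] == 90].iloc[0]
    dried = color[color["label"] != "fresh"]
    eo = qual.set_index("label")["eo_pct"]
    first, last = drying.iloc[0], drying.iloc[-1]
    return {
        "Ea_kJ_per_mol": arr.Ea_kJ_per_mol,
        "arrhenius_r2": arr.r2,
        "dH90_kJ_per_mol": enthalpy(arr.Ea_J_per_mol, 90.0),
        "dG90_kJ_per_mol": gibbs(float(t90["dH_kJ_per_mol"]), float(t90["dS_kJ_per_molK"]), 90.0),
        "chroma": {str(int(r.label) if str(r.label).isdigit() else r.label): chroma(r.a, r.b)
                   for r in dried.itertuples()},
        "percent_change": {
            "drying_time": percent_change(first["drying_time_min"], last["drying_time_min"]),
            "sec": percent_change(first["sec_kWh_per_kg"], last["sec_kWh_per_kg"]),
            "co2": percent_change(first["co2_kg_per_kg"], last["co2_kg_per_kg"]),
            "nox": percent_change(first["nox_kg_per_kg"], last["nox_kg_per_kg"]),
            "eo_80_to_90": percent_change(float(eo.loc["80"]), float(eo.loc["90"])),
        },
    }
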