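"""Pipeline orchestration: simulate, fit, summarize, report.

Ties the stages together into the reproducible study run: synthetic trial
generation at the published truth values, population PK fit, per-run HCVR
fits, per-biomarker effect-compartment EMAX fits, population summaries,
potency ratios, dose-effect comparison and the dynamics likelihood-ratio
test.  All randomness flows from one root seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from .emax import (
    BiomarkerSeries,
    compare_dynamics,
    fit_pd_panel,
    peak_fractional_effects,
)
from .hcvr import fit_run
from .physiology import PhysiologyConstants
from .pk import DoseEvent, concentration_fn, fit_pk_population
from .population import (
    compute_cv,
    dose_effect_table,
    potency_ratios,
    summarize_biomarker,
)
from .study import TABLE1_TRUTH, TrialDataset, TrialDesign, generate_trial, load_trial

log = logging.getLogger("ventpkpd")

BIOMARKERS = ("resting_ve", "resting_petco2", "vrt", "slope", "ve55")
RESTING_CLASS = ("resting_ve", "resting_petco2", "vrt")
DIRECTIONS = {"resting_ve": "depressed", "resting_petco2": "elevated",
              "vrt": "elevated", "slope": "depressed", "ve55": "depressed"}


@dataclass(frozen=True)
class PipelineConfig:
    """Validated configuration of a pipeline run; unknown keys rejected."""

    seed: int = 0
    out_dir: str = "results"
    n_per_arm: int = 12
    doses: tuple = (100.0, 200.0)
    bootstrap_b: int = 200
    alpha: float = 0.01
    backend: str = "two-stage"
    noise_scale: float = 1.0
    bsv_scale: float = 1.0
    run_dynamics_test: bool = True

    def __post_init__(self) -> None:
        if self.backend not in ("two-stage",):
            raise ValueError(f"unknown estimation backend '{self.backend}'")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.bootstrap_b < 2:
            raise ValueError("bootstrap_b must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "doses" in raw:
            raw["doses"] = tuple(raw["doses"])
        return cls(**raw)

    def design(self) -> TrialDesign:
        return TrialDesign(seed=self.seed, n_per_arm=self.n_per_arm,
                           doses=self.doses, noise_scale=self.noise_scale,
                           bsv_scale=self.bsv_scale)


@dataclass
class FitResults:
    """Everything the fitting stage produces for one trial."""

    run_table: pd.DataFrame           # per-run biomarker estimates
    pk_population: object             # PopulationPKResult
    pd_fits: Dict[str, object]        # biomarker/panel name -> PDPanelFit
    summaries: Dict[str, object]      # name -> PopulationSummary
    table1: pd.DataFrame
    ratio_table: pd.DataFrame
    dose_effect: Optional[pd.DataFrame]
    dynamics_test: Optional[object]
    recovery: Optional[pd.DataFrame]


def cmd_simulate(config: PipelineConfig, truth: dict = TABLE1_TRUTH) -> Path:
    """Generate a trial bundle on disk; returns the manifest path."""
    out = Path(config.out_dir)
    t0 = time.perf_counter()
    ds = generate_trial(config.design(), truth=truth, out_dir=out)
    log.info("simulate: %d subjects, %d runs, %d PK samples in %.1f s",
             ds.n_subjects, ds.n_runs, ds.n_pk_samples, time.perf_counter() - t0)
    return out / "manifest.json"


def fit_all_runs(trial: TrialDataset,
                 constants: PhysiologyConstants = PhysiologyConstants()) -> pd.DataFrame:
    """Fit every HCVR run; returns the per-run biomarker table."""
    rows = []
    for s in trial.subjects:
        for rec in s.runs:
            try:
                fr = fit_run(rec, constants)
            except ValueError as exc:
                log.warning("run %s t=%.0f h failed: %s", s.subject_id,
                            rec.run_time, exc)
                continue
            p = fr.params
            rows.append({
                "subject_id": s.subject_id, "dose_mg": s.dose_mg,
                "run_time_h": rec.run_time,
                "resting_ve": p.baseline_ve, "resting_petco2": p.resting_petco2,
                "vrt": p.vrt, "slope": p.slope_s, "ve55": fr.ve55,
                "apneic_threshold": fr.apneic_threshold,
                "converged": fr.converged, "flagged": fr.flagged,
            })
    return pd.DataFrame(rows)


def _biomarker_panel(run_table: pd.DataFrame, names) -> Dict[str, List[BiomarkerSeries]]:
    panel: Dict[str, List[BiomarkerSeries]] = {}
    for name in names:
        series = []
        for sid, grp in run_table.groupby("subject_id"):
            grp = grp.sort_values("run_time_h")
            series.append(BiomarkerSeries(subject_id=str(sid),
                                          times=grp["run_time_h"].to_numpy(float),
                                          values=grp[name].to_numpy(float)))
        panel[name] = series
    return panel


def cmd_fit(config: PipelineConfig, trial: TrialDataset,
            out_dir: Optional[Path] = None) -> FitResults:
    """Run the full estimation pipeline on a trial dataset."""
    t0 = time.perf_counter()
    pk_pop = fit_pk_population(trial.pk_subjects(), bootstrap_b=config.bootstrap_b,
                               bootstrap_seed=config.seed)
    log.info("fit: population PK done in %.1f s (CL=%.1f L/h, converged=%s)",
             time.perf_counter() - t0, pk_pop.params.cl, pk_pop.converged)

    t0 = time.perf_counter()
    run_table = fit_all_runs(trial)
    n_flag = int(run_table["flagged"].sum()) if not run_table.empty else 0
    log.info("fit: %d HCVR runs fitted in %.1f s (%d flagged)",
             len(run_table), time.perf_counter() - t0, n_flag)

    cp_fns = {}
    for s in trial.subjects:
        params_i = dataclasses.replace(pk_pop.params,
                                       cl=pk_pop.cl_by_subject[s.subject_id])
        cp_fns[s.subject_id] = concentration_fn(params_i,
                                                DoseEvent(dose_mg=s.dose_mg),
                                                s.weight)

    sigmas = TABLE1_TRUTH["sigma"]
    t0 = time.perf_counter()
    pd_fits: Dict[str, object] = {}
    panel_rest = _biomarker_panel(run_table, RESTING_CLASS)
    pd_fits["resting_class"] = fit_pd_panel(
        panel_rest, cp_fns, DIRECTIONS, sigmas=sigmas, share_dynamics=True)
    for name in ("slope", "ve55"):
        panel = _biomarker_panel(run_table, [name])
        pd_fits[name] = fit_pd_panel(panel, cp_fns, DIRECTIONS, sigmas=sigmas)
    log.info("fit: PD EMAX fits done in %.1f s", time.perf_counter() - t0)

    dynamics = None
    if config.run_dynamics_test:
        panel_all = _biomarker_panel(run_table, BIOMARKERS)
        shared = fit_pd_panel(panel_all, cp_fns, DIRECTIONS, sigmas=sigmas,
                              share_dynamics=True)
        separate = fit_pd_panel(panel_all, cp_fns, DIRECTIONS, sigmas=sigmas,
                                share_dynamics=False)
        dynamics = compare_dynamics(shared, separate, alpha=config.alpha)
        log.info("fit: dynamics LR test stat=%.1f df=%d p=%.3g",
                 dynamics.statistic, dynamics.df, dynamics.pvalue)

    # population summaries of the pre-drug (t = 0) biomarkers
    base_rows = run_table[run_table.run_time_h == 0.0]
    summaries = {}
    for name in BIOMARKERS:
        summaries[name] = summarize_biomarker(
            name, base_rows[name].to_numpy(float), sigma=sigmas[name],
            b=config.bootstrap_b, seed=config.seed)

    table1 = _table1(summaries, pd_fits)
    c50s = {"resting_class": pd_fits["resting_class"].biomarkers["resting_ve"].c50,
            "slope": pd_fits["slope"].biomarkers["slope"].c50,
            "ve55": pd_fits["ve55"].biomarkers["ve55"].c50}
    ratios = potency_ratios(c50s)

    dose_eff = None
    arms = sorted(run_table["dose_mg"].unique())
    if len(arms) == 2:
        dose_eff = _dose_effect(run_table, cp_fns, sigmas, arms)

    recovery = _recovery_report(trial, summaries, pk_pop, c50s, pd_fits)

    results = FitResults(run_table=run_table, pk_population=pk_pop,
                         pd_fits=pd_fits, summaries=summaries, table1=table1,
                         ratio_table=ratios, dose_effect=dose_eff,
                         dynamics_test=dynamics, recovery=recovery)
    if out_dir is not None:
        _write_results(results, Path(out_dir), config)
    return results


def _dose_effect(run_table, cp_fns, sigmas, arms):
    per_arm = []
    for dose in arms:
        sub = run_table[run_table.dose_mg == dose]
        n_arm = sub["subject_id"].nunique()
        k = max(1, min(4, n_arm))
        effects = {}
        rest = fit_pd_panel(_biomarker_panel(sub, RESTING_CLASS), cp_fns,
                            DIRECTIONS, sigmas=sigmas, share_dynamics=True,
                            min_subjects=k)
        for name in RESTING_CLASS:
            effects[name] = list(peak_fractional_effects(rest, name, cp_fns).values())
        for name in ("slope", "ve55"):
            f = fit_pd_panel(_biomarker_panel(sub, [name]), cp_fns, DIRECTIONS,
                             sigmas=sigmas, min_subjects=k)
            effects[name] = list(peak_fractional_effects(f, name, cp_fns).values())
        per_arm.append(effects)
    return dose_effect_table(per_arm[0], per_arm[1])


def _table1(summaries, pd_fits) -> pd.DataFrame:
    rows = []
    for name, s in summaries.items():
        rows.append({"parameter": f"{name} at t=0", "estimate": s.estimate,
                     "se": s.se, "omega2": s.omega2, "cv_percent": s.cv_percent,
                     "sigma": s.sigma})
    for key, label in (("resting_class", "resting class"), ("slope", "S"),
                       ("ve55", "VE55")):
        fit = pd_fits[key]
        bf = next(iter(fit.biomarkers.values()))
        rows.append({"parameter": f"C50 {label}", "estimate": bf.c50,
                     "se": np.nan, "omega2": np.nan, "cv_percent": np.nan,
                     "sigma": np.nan})
        rows.append({"parameter": f"h1/2 {label}", "estimate": bf.h_half,
                     "se": np.nan, "omega2": np.nan, "cv_percent": np.nan,
                     "sigma": np.nan})
    return pd.DataFrame(rows)


def _recovery_report(trial, summaries, pk_pop, c50s, pd_fits) -> Optional[pd.DataFrame]:
    truth = trial.truth
    if not truth:
        return None
    rows = []

    def add(name, est, tru):
        rows.append({"parameter": name, "estimate": est, "truth": tru,
                     "rel_error": (est - tru) / tru if tru else np.nan})

    add("population CL (L/h/70kg)", pk_pop.params.cl, truth["pk"]["cl"])
    key_map = {"resting_ve": "resting_ve", "resting_petco2": "resting_petco2",
               "vrt": "vrt", "slope": "slope"}
    for name, s in summaries.items():
        if name in key_map:
            add(f"baseline {name}", s.estimate, truth["baseline"][key_map[name]])
    add("baseline ve55", summaries["ve55"].estimate, truth["ve55"])
    add("C50 slope", c50s["slope"], truth["c50"]["slope"])
    add("C50 ve55", c50s["ve55"], truth["c50"]["ve55"])
    add("C50 resting class", c50s["resting_class"], truth["c50"]["resting_class"])
    bf = pd_fits["resting_class"].biomarkers["resting_ve"]
    add("h1/2 resting class", bf.h_half, truth["h_half"]["resting_class"])
    add("h1/2 slope", pd_fits["slope"].biomarkers["slope"].h_half,
        truth["h_half"]["slope"])
    add("h1/2 ve55", pd_fits["ve55"].biomarkers["ve55"].h_half,
        truth["h_half"]["ve55"])
    return pd.DataFrame(rows)


def _write_results(results: FitResults, out: Path, config: PipelineConfig) -> None:
    out.mkdir(parents=True, exist_ok=True)
    results.table1.to_csv(out / "table1.csv", index=False)
    results.run_table.to_csv(out / "run_estimates.csv", index=False)
    results.ratio_table.to_csv(out / "potency_ratios.csv", index=False)
    if results.dose_effect is not None:
        results.dose_effect.to_csv(out / "fig4f.csv", index=False)
    if results.recovery is not None:
        results.recovery.to_csv(out / "recovery_report.csv", index=False)
    manifest = {"seed": config.seed, "config": asdict(config)}
    if results.dynamics_test is not None:
        d = results.dynamics_test
        manifest["dynamics_test"] = {"statistic": d.statistic, "df": d.df,
                                     "pvalue": d.pvalue,
                                     "significant": d.significant}
    (out / "fit_manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      default=float))


def cmd_report(results: FitResults) -> str:
    """Render a plain-text summary of a results bundle."""
    lines = ["Population estimates (pre-drug biomarkers and drug potency)",
             "=" * 60]
    lines.append(results.table1.to_string(index=False,
                                          float_format=lambda x: f"{x:.3g}"))
    lines.append("")
    lines.append("Potency ratios (resting-class C50 over S / VE55 C50)")
    lines.append(results.ratio_table.to_string(index=False,
                                               float_format=lambda x: f"{x:.3g}"))
    if results.dose_effect is not None:
        lines.append("")
        lines.append("Dose effect (peak fractional effect, % per arm)")
        lines.append(results.dose_effect.to_string(
            index=False, float_format=lambda x: f"{x:.1f}"))
    if results.dynamics_test is not None:
        d = results.dynamics_test
        verdict = "distinct" if d.significant else "not distinguishable"
        lines.append("")
        lines.append(f"Dynamics LR test: stat={d.statistic:.1f}, df={d.df}, "
                     f"p={d.pvalue:.2e} -> biomarker dynamics {verdict} "
                     f"at alpha={d.alpha}")
    if results.recovery is not None:
        lines.append("")
        lines.append("Recovery versus generator truth")
        lines.append(results.recovery.to_string(
            index=False, float_format=lambda x: f"{x:.3g}"))
    return "\n".join(lines)


def paper_run(seed: int, n_per_arm: int = 12, bootstrap_b: int = 200,
              run_dynamics_test: bool = False,
              out_dir: Optional[Path] = None) -> dict:
    """Simulate the study at the published truth and fit it end to end.

    Returns the scalar quantities of interest (population CL, pre-drug
    biomarkers, potencies, hysteresis) for one seed.
    """
    config = PipelineConfig(seed=seed, n_per_arm=n_per_arm,
                            bootstrap_b=bootstrap_b,
                            run_dynamics_test=run_dynamics_test)
    trial = generate_trial(config.design())
    results = cmd_fit(config, trial, out_dir=out_dir)
    s = results.summaries
    out = {
        "pop_cl": results.pk_population.params.cl,
        "baseline_resting_ve": s["resting_ve"].estimate,
        "baseline_resting_petco2": s["resting_petco2"].estimate,
        "baseline_vrt": s["vrt"].estimate,
        "baseline_slope": s["slope"].estimate,
        "baseline_ve55": s["ve55"].estimate,
        "c50_resting_class": results.pd_fits["resting_class"]
                                    .biomarkers["resting_ve"].c50,
        "c50_slope": results.pd_fits["slope"].biomarkers["slope"].c50,
        "c50_ve55": results.pd_fits["ve55"].biomarkers["ve55"].c50,
        "h_half_resting_class": results.pd_fits["resting_class"]
                                       .biomarkers["resting_ve"].h_half,
        "h_half_slope": results.pd_fits["slope"].biomarkers["slope"].h_half,
        "h_half_ve55": results.pd_fits["ve55"].biomarkers["ve55"].h_half,
        "n_subjects": trial.n_subjects,
        "n_runs": int(len(results.run_table)),
    }
    if results.dynamics_test is not None:
        out["dynamics_pvalue"] = results.dynamics_test.pvalue
    return out
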