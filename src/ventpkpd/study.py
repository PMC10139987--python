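"""Synthetic trial generator.

Emulates the tapentadol HCVR study: 24 healthy adults (12 per oral dose
arm, 100/200 mg), one pre-drug HCVR run plus hourly runs for 8 h, hourly
plasma samples 0-7 h.  Subject-level parameters are drawn log-normally
around the population values with the published between-subject
variances; observation noise uses the published within-subject SDs.  The
drug acts through per-pathway effect compartments and EMAX laws on the
subject's instantaneous HCVR parameters, which are held constant within a
run (a run lasts ~27 min; intra-run drug drift is second order).  True
individual parameters are stored alongside the observations so recovery
can be scored.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .emax import effect_site_concentration
from .hcvr import HCVRParameters
from .physiology import ForcingProtocol, PhysiologyConstants, RunRecord, simulate_run
from .pk import DoseEvent, PKParameters, PlasmaSample, SubjectPK, concentration_fn

__all__ = [
    "TABLE1_TRUTH",
    "TrialDesign",
    "SubjectRecord",
    "TrialDataset",
    "generate_subject",
    "draw_individual",
    "generate_trial",
    "load_trial",
]

# Published population truth used as the generator default: PK parameters,
# per-biomarker baselines with between-subject variances (omega2, log
# scale), potencies (C50, mg/L) and hysteresis half-lives (h) per pathway,
# and within-subject SDs (sigma, parameter units).  The resting-class
# biomarkers (resting VE, resting PETCO2, VRT) share one potency/hysteresis
# pathway; VE55 = 37.1 L/min is the implied baseline, not an input.
TABLE1_TRUTH: dict = {
    "pk": {"v1": 90.0, "v2": 557.0, "cl": 197.0, "cl2": 726.0, "tabs": 1.2,
           "sigma2_prop": 0.015, "omega2_cl": 0.06},
    "baseline": {"resting_ve": 8.3, "resting_petco2": 41.0, "vrt": 44.0,
                 "slope": 2.5},
    "omega2_baseline": {"resting_ve": 0.017, "resting_petco2": 0.007,
                        "vrt": 0.005, "slope": 0.134},
    "c50": {"resting_class": 0.81, "slope": 0.23, "ve55": 0.08},
    "omega2_c50": {"resting_class": 0.066, "slope": 0.589, "ve55": 0.105},
    "h_half": {"resting_class": 1.3, "slope": 0.6, "ve55": 0.9},
    "sigma": {"resting_ve": 0.44, "resting_petco2": 1.50, "vrt": 1.90,
              "slope": 0.49, "ve55": 3.46},
    "ve55": 37.1,
}

# Correlation of the subject-level log deviations of VRT and resting
# PETCO2 (the threshold rides on the resting operating point).
VRT_PETCO2_RHO = 0.9


@dataclass(frozen=True)
class TrialDesign:
    n_per_arm: int = 12
    doses: Sequence[float] = (100.0, 200.0)
    run_times: Sequence[float] = tuple(float(t) for t in range(9))   # h
    pk_times: Sequence[float] = tuple(float(t) for t in range(8))    # h
    weight_mean: float = 74.0
    weight_sd: float = 10.0
    weight_range: Sequence[float] = (57.0, 103.0)
    seed: int = 0
    # noise switches (1.0 = study conditions, 0.0 = deterministic)
    bsv_scale: float = 1.0        # between-subject variability
    noise_scale: float = 1.0      # run-level jitter + 1-min VE + PK noise
    ve_noise_ref: float = 0.44    # 1-min VE noise SD at the reference resting VE
    ve_noise_ref_ve: float = 8.3  # reference VE for the linear noise scaling

    def __post_init__(self) -> None:
        if self.n_per_arm < 1:
            raise ValueError("n_per_arm must be >= 1")
        if 0.0 not in self.run_times:
            raise ValueError("run_times must include the pre-drug control (0)")


@dataclass
class SubjectRecord:
    subject_id: str
    dose_mg: float
    weight: float
    truth: dict
    pk_samples: List[PlasmaSample]
    runs: List[RunRecord]

    def pk_subject(self) -> SubjectPK:
        return SubjectPK(subject_id=self.subject_id,
                         dose=DoseEvent(dose_mg=self.dose_mg),
                         weight=self.weight, samples=self.pk_samples)


@dataclass
class TrialDataset:
    design: TrialDesign
    subjects: List[SubjectRecord]
    truth: dict

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_runs(self) -> int:
        return sum(len(s.runs) for s in self.subjects)

    @property
    def n_pk_samples(self) -> int:
        return sum(len(s.pk_samples) for s in self.subjects)

    def pk_subjects(self) -> List[SubjectPK]:
        return [s.pk_subject() for s in self.subjects]

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        (out / "runs").mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [{"subject_id": s.subject_id, "dose_mg": s.dose_mg,
              "weight_kg": s.weight} for s in self.subjects]
        ).to_csv(out / "subjects.csv", index=False)
        pk_rows = [
            {"subject_id": s.subject_id, "dose_mg": s.dose_mg,
             "weight_kg": s.weight, "time_h": p.time, "conc_mg_l": p.concentration}
            for s in self.subjects for p in s.pk_samples
        ]
        pd.DataFrame(pk_rows).to_csv(out / "pk_samples.csv", index=False)
        for s in self.subjects:
            for k, run in enumerate(s.runs):
                run.to_csv(out / "runs" / f"{s.subject_id}_{k}.csv")
        truth = dict(self.truth)
        truth["subjects"] = {s.subject_id: s.truth for s in self.subjects}
        (out / "truth.json").write_text(json.dumps(truth, indent=1))
        manifest = {"seed": self.design.seed, "version": __version__,
                    "n_subjects": self.n_subjects, "n_runs": self.n_runs,
                    "n_pk_samples": self.n_pk_samples}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return out / "manifest.json"


def load_trial(in_dir) -> TrialDataset:
    """Re-read a written trial bundle (truth attached when present)."""
    src = Path(in_dir)
    if not (src / "runs").is_dir():
        raise FileNotFoundError(f"no runs/ directory under {src}")
    subj_df = pd.read_csv(src / "subjects.csv",
                          dtype={"subject_id": str})
    pk_df = pd.read_csv(src / "pk_samples.csv", dtype={"subject_id": str})
    truth = {}
    if (src / "truth.json").exists():
        truth = json.loads((src / "truth.json").read_text())
    subj_truth = truth.pop("subjects", {})
    subjects = []
    for _, row in subj_df.iterrows():
        sid = str(row["subject_id"])
        pk = [PlasmaSample(time=float(r.time_h), concentration=float(r.conc_mg_l))
              for r in pk_df[pk_df.subject_id == sid].itertuples()]
        runs = []
        k = 0
        while (src / "runs" / f"{sid}_{k}.csv").exists():
            runs.append(RunRecord.from_csv(src / "runs" / f"{sid}_{k}.csv"))
            k += 1
        subjects.append(SubjectRecord(subject_id=sid, dose_mg=float(row["dose_mg"]),
                                      weight=float(row["weight_kg"]),
                                      truth=subj_truth.get(sid, {}),
                                      pk_samples=pk, runs=runs))
    return TrialDataset(design=TrialDesign(), subjects=subjects, truth=truth)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError("truncated normal draw failed")


def draw_individual(design: TrialDesign, truth: dict,
                    rng: np.random.Generator) -> dict:
    """Draw one subject's true individual parameters (no simulation)."""
    bsv = design.bsv_scale
    t = truth

    weight = _truncated_normal(rng, design.weight_mean,
                               max(design.weight_sd * bsv, 1e-9),
                               *design.weight_range) if bsv > 0 else design.weight_mean

    def lognorm(median: float, omega2: float) -> float:
        return float(median * np.exp(np.sqrt(omega2) * bsv * rng.standard_normal()))

    # The recruitment threshold tracks each subject's resting PETCO2 (the
    # dog-leg sits a few mmHg above the resting point), so their log
    # deviations are drawn with correlation VRT_PETCO2_RHO while keeping
    # the printed marginal variances.
    z_pet = rng.standard_normal()
    z_vrt = (VRT_PETCO2_RHO * z_pet
             + np.sqrt(1.0 - VRT_PETCO2_RHO ** 2) * rng.standard_normal())
    petco2_i = float(t["baseline"]["resting_petco2"]
                     * np.exp(np.sqrt(t["omega2_baseline"]["resting_petco2"])
                              * bsv * z_pet))
    vrt_i = float(t["baseline"]["vrt"]
                  * np.exp(np.sqrt(t["omega2_baseline"]["vrt"]) * bsv * z_vrt))

    indiv = {
        "cl": lognorm(t["pk"]["cl"], t["pk"]["omega2_cl"]),
        "resting_ve": lognorm(t["baseline"]["resting_ve"],
                              t["omega2_baseline"]["resting_ve"]),
        "resting_petco2": petco2_i,
        "vrt": vrt_i,
        "slope": lognorm(t["baseline"]["slope"], t["omega2_baseline"]["slope"]),
        "c50_resting": lognorm(t["c50"]["resting_class"],
                               t["omega2_c50"]["resting_class"]),
        "c50_slope": lognorm(t["c50"]["slope"], t["omega2_c50"]["slope"]),
        "c50_ve55": lognorm(t["c50"]["ve55"], t["omega2_c50"]["ve55"]),
        "weight": weight,
    }
    return indiv


def generate_subject(design: TrialDesign, truth: dict, dose_mg: float,
                     rng: np.random.Generator, subject_id: str,
                     protocol: ForcingProtocol = ForcingProtocol(),
                     constants: PhysiologyConstants = PhysiologyConstants(),
                     max_redraws: int = 10) -> SubjectRecord:
    """Draw one subject and simulate their PK samples and all HCVR runs."""
    nz = design.noise_scale
    t = truth
    indiv = draw_individual(design, truth, rng)
    weight = indiv["weight"]

    pk_pop = PKParameters(**t["pk"])
    pk_ind = PKParameters(v1=pk_pop.v1, v2=pk_pop.v2, cl=indiv["cl"],
                          cl2=pk_pop.cl2, tabs=pk_pop.tabs,
                          sigma2_prop=pk_pop.sigma2_prop,
                          omega2_cl=pk_pop.omega2_cl)
    dose = DoseEvent(dose_mg=dose_mg)
    cp = concentration_fn(pk_ind, dose, weight)

    pk_samples = []
    sd_prop = np.sqrt(pk_pop.sigma2_prop) * nz
    for tt in design.pk_times:
        c = float(cp(np.array([tt]))[0])
        if c > 0 and sd_prop > 0:
            c = max(c * (1.0 + sd_prop * rng.standard_normal()), 0.0)
        pk_samples.append(PlasmaSample(time=float(tt), concentration=c))

    run_times = np.asarray(design.run_times, dtype=float)
    ce_rest = effect_site_concentration(cp, t["h_half"]["resting_class"], run_times)
    ce_slope = effect_site_concentration(cp, t["h_half"]["slope"], run_times)

    sig = t["sigma"]
    runs = []
    for j, rt in enumerate(run_times):
        fr = indiv["c50_resting"] / (indiv["c50_resting"] + ce_rest[j])
        fe = 1.0 / fr
        fs = indiv["c50_slope"] / (indiv["c50_slope"] + ce_slope[j])
        base_d = indiv["resting_ve"] * fr
        petco2_d = indiv["resting_petco2"] * fe
        vrt_d = indiv["vrt"] * fe
        slope_d = indiv["slope"] * fs
        # run-level jitter: the VRT jitter shares the resting-PETCO2
        # component (the two move together within a session) plus an
        # independent remainder sized to preserve the printed sigma
        sig_vrt_ind = np.sqrt(max(sig["vrt"] ** 2 - sig["resting_petco2"] ** 2, 0.0))
        for attempt in range(max_redraws + 1):
            e_pet = rng.standard_normal()
            base_r = base_d + nz * sig["resting_ve"] * rng.standard_normal()
            petco2_r = petco2_d + nz * sig["resting_petco2"] * e_pet
            vrt_r = (vrt_d + nz * (sig["resting_petco2"] * e_pet
                                   + sig_vrt_ind * rng.standard_normal()))
            slope_r = slope_d + nz * sig["slope"] * rng.standard_normal()
            feasible = (base_r > constants.vd + 0.5 and slope_r > 0.02
                        and petco2_r > 20.0)
            if feasible:
                break
        else:
            raise RuntimeError(
                f"{subject_id}: no feasible run parameters at t={rt} h "
                f"after {max_redraws} redraws")
        hcvr = HCVRParameters(baseline_ve=base_r, resting_petco2=petco2_r,
                              vrt=vrt_r, slope_s=slope_r, run_time=rt)
        rec = simulate_run(hcvr, constants, protocol,
                           subject_id=subject_id, run_time=rt)
        if nz > 0:
            sd = design.ve_noise_ref * rec.ve_min / design.ve_noise_ref_ve
            rec.ve_min = rec.ve_min + nz * sd * rng.standard_normal(rec.n_minutes)
            rec.ve_min = np.maximum(rec.ve_min, 0.0)
        runs.append(rec)

    return SubjectRecord(subject_id=subject_id, dose_mg=dose_mg, weight=weight,
                         truth=indiv, pk_samples=pk_samples, runs=runs)


def generate_trial(design: TrialDesign = TrialDesign(),
                   truth: dict = TABLE1_TRUTH,
                   out_dir=None) -> TrialDataset:
    """Generate the full two-arm trial; optionally write the CSV bundle."""
    root = np.random.SeedSequence(design.seed)
    n_total = design.n_per_arm * len(design.doses)
    streams = root.spawn(n_total)
    subjects = []
    k = 0
    for dose in design.doses:
        for _ in range(design.n_per_arm):
            sid = f"S{k + 1:03d}"
            rng = np.random.default_rng(streams[k])
            subjects.append(generate_subject(design, truth, dose, rng, sid))
            k += 1
    ds = TrialDataset(design=design, subjects=subjects, truth=dict(truth))
    if out_dir is not None:
        try:
            ds.write(out_dir)
        except OSError as exc:
            raise OSError(f"failed writing trial bundle under {out_dir}: {exc}")
    return ds
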