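"""Per-run HCVR biomarker estimation.

Each hypercapnic-ventilatory-response run yields four parameters —
resting ventilation, resting end-tidal PCO2, the ventilatory recruitment
threshold (VRT) and the slope S of the linear limb — plus two derived
quantities: the extrapolated ventilation at an effect-site PCO2 of
55 mmHg (VE55) and the classical apneic threshold B (zero-ventilation
intercept, B = 55 - VE55/S).

Estimation fits the kinetic forward model of :mod:`ventpkpd.physiology`
(lung/tissue/brain CO2 balances driven by the recorded inspired PCO2)
to the 1-min ventilation averages by nonlinear least squares.  Resting
end-tidal PCO2 is taken directly from the resting-phase minutes, which
pins the absolute PCO2 level and makes the estimator exactly equivariant
under a common shift of all PCO2 channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.optimize import least_squares

from .physiology import (
    PhysiologyConstants,
    RunRecord,
    calibrate_vco2,
    hinge,
    simulate_driven,
)

__all__ = [
    "HCVRParameters",
    "HCVRFitResult",
    "InsufficientExcitationError",
    "fit_run",
    "compute_ve55",
    "compute_apneic_threshold",
]

# Minutes with mean inspired PCO2 below this are treated as CO2-free.
RESTING_PICO2_THRESHOLD = 0.5  # mmHg


class InsufficientExcitationError(ValueError):
    """Run lacks the resting minutes or CO2 steps needed for estimation."""


@dataclass(frozen=True)
class HCVRParameters:
    """Biomarker set of one HCVR run."""

    baseline_ve: float         # L/min
    resting_petco2: float      # mmHg
    vrt: float                 # mmHg
    slope_s: float             # L/min/mmHg
    run_time: float = 0.0      # h since dosing

    def __post_init__(self) -> None:
        if self.baseline_ve < 0:
            raise ValueError("baseline_ve must be nonnegative")
        if self.slope_s < 0:
            raise ValueError("slope_s must be nonnegative")

    @property
    def vrt_below_resting(self) -> bool:
        """Diagnostic: VRT is normally at or above resting PETCO2."""
        return self.vrt < self.resting_petco2


@dataclass(frozen=True)
class HCVRFitResult:
    params: HCVRParameters
    ve55: float
    apneic_threshold: Optional[float]
    rss: float
    n_obs: int
    converged: bool
    flagged: bool
    message: str = ""


def compute_ve55(hcvr: HCVRParameters, delta: float = 0.1) -> float:
    """Extrapolated ventilation at an effect-site PCO2 of 55 mmHg."""
    return float(hcvr.baseline_ve + hcvr.slope_s * hinge(55.0 - hcvr.vrt, delta))


def compute_apneic_threshold(hcvr: HCVRParameters, delta: float = 0.1) -> Optional[float]:
    """Zero-ventilation intercept B of the extrapolated linear limb.

    B = 55 - VE55/S; undefined (None) when the slope is zero.
    """
    if hcvr.slope_s == 0:
        return None
    return 55.0 - compute_ve55(hcvr, delta) / hcvr.slope_s


def _split_resting(record: RunRecord) -> int:
    """Length of the CO2-free prefix of the run, in minutes.

    Thresholded relative to the run minimum so a common offset on the
    inspired channel does not change the segmentation.
    """
    below = record.pico2_min < record.pico2_min.min() + RESTING_PICO2_THRESHOLD
    n = 0
    for flag in below:
        if not flag:
            break
        n += 1
    return n


def _count_steps(petco2_elev: np.ndarray) -> int:
    """Distinct CO2 plateau levels among the elevated minutes (2-mmHg gaps)."""
    if petco2_elev.size == 0:
        return 0
    levels = np.sort(petco2_elev)
    return int(1 + np.sum(np.diff(levels) > 2.0))


def fit_run(record: RunRecord, constants: PhysiologyConstants = PhysiologyConstants(),
            delta55: float = 0.1) -> HCVRFitResult:
    """Estimate (baseline VE, resting PETCO2, VRT, S) from one run.

    Requires at least 3 resting minutes and at least 2 CO2 steps.  The
    forward model is driven by the recorded inspired PCO2 (the 1-s trace
    when the record carries one, otherwise the 1-min averages interpolated
    at minute midpoints) and compared with the 1-min ventilation averages
    under uniform weighting.
    """
    n_rest = _split_resting(record)
    if n_rest < 3:
        raise InsufficientExcitationError(
            f"need >= 3 resting (CO2-free) minutes, found {n_rest}")
    elev_pet = record.petco2_min[n_rest:]
    n_steps = _count_steps(elev_pet)
    if n_steps < 2:
        raise InsufficientExcitationError(
            f"need >= 2 CO2 steps, found {n_steps}")

    resting_petco2 = float(np.mean(record.petco2_min[:n_rest]))
    pi_rest = float(np.mean(record.pico2_min[:n_rest]))
    base0 = float(np.mean(record.ve_min[:n_rest]))

    # Deterministic, data-driven starts: S from ordinary regression of the
    # elevated minutes, VRT from that line's intersection with resting VE.
    elev_ve = record.ve_min[n_rest:]
    mask = elev_pet > resting_petco2 + 2.0
    if mask.sum() >= 2 and np.ptp(elev_pet[mask]) > 0.5:
        b, a = np.polyfit(elev_pet[mask], elev_ve[mask], 1)
    else:
        b, a = 0.0, base0
    s0 = max(b, 0.05)
    vrt0 = (base0 - a) / b if b > 0.05 else resting_petco2 + 3.0
    vrt0 = float(np.clip(vrt0, resting_petco2 - 5.0, 58.0))

    duration = float(record.n_minutes)
    obs = record.ve_min
    if record.pico2_substep is not None:
        from .physiology import RK4_STEP_MIN
        drive = record.pico2_substep
        drive_t = np.arange(len(drive)) * RK4_STEP_MIN
    elif record.time_s is not None and record.pico2_s is not None:
        drive_t = record.time_s / 60.0
        drive = record.pico2_s
    else:
        drive_t = record.minute_index - record.minute_index[0] + 0.5
        drive = record.pico2_min

    lam12 = constants.lambda1 * constants.lambda2

    def residuals(theta: np.ndarray) -> np.ndarray:
        base, vrt, s = theta
        hc = HCVRParameters(baseline_ve=base, resting_petco2=resting_petco2,
                            vrt=vrt, slope_s=s, run_time=record.run_time)
        # hinge-aware calibration keeps the family self-consistent when the
        # recruitment threshold sits below resting PETCO2
        ve_rest = base + s * float(hinge(resting_petco2 - vrt, constants.delta))
        vco2 = (ve_rest - constants.vd) * (resting_petco2 - pi_rest) / lam12
        cons = constants.with_vco2(vco2)
        _, _, _, ve = simulate_driven(hc, cons, drive_t, drive,
                                      duration, pa0=resting_petco2)
        n_min = record.n_minutes
        model_min = ve[: n_min * 60].reshape(n_min, 60).mean(axis=1)
        return model_min - obs

    lb = [constants.vd + 0.3, resting_petco2 - 15.0, 1e-3]
    ub = [40.0, 65.0, 25.0]
    x0 = np.clip([base0, vrt0, s0], np.asarray(lb) + 1e-6, np.asarray(ub) - 1e-6)
    sol = least_squares(residuals, x0, bounds=(lb, ub),
                        x_scale=[1.0, 1.0, 0.2], ftol=1e-10, xtol=1e-10, gtol=1e-10)

    base, vrt, s = sol.x
    params = HCVRParameters(baseline_ve=float(base), resting_petco2=resting_petco2,
                            vrt=float(vrt), slope_s=float(s),
                            run_time=record.run_time)
    pinned = s <= lb[2] * 1.01
    converged = bool(sol.success)
    flagged = pinned or not converged
    msg = ""
    if pinned:
        msg = "slope pinned at zero"
    elif not converged:
        msg = f"optimizer did not converge: {sol.message}"
    if flagged:
        warnings.warn(f"flagged HCVR run fit ({record.subject_id}, "
                      f"t={record.run_time} h): {msg}", stacklevel=2)
    return HCVRFitResult(
        params=params,
        ve55=compute_ve55(params, delta55),
        apneic_threshold=compute_apneic_threshold(params, delta55),
        rss=float(2.0 * sol.cost),
        n_obs=record.n_minutes,
        converged=converged,
        flagged=flagged,
        message=msg,
    )
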