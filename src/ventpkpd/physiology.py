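"""Closed-loop CO2 chemoreflex physiology.

Forward model of the ventilatory control system used throughout the
package: alveolar and tissue CO2 mass balances, a first-order brain-tissue
(effect-site) PCO2 lag, and a hinge-function ventilation law

    VE = baseline_VE + S * H(brain_PCO2 - VRT),   H(x) = delta*log(1+exp(x/delta)).

End-tidal PCO2 is reported equal to arterial/alveolar PCO2 (no
alveolar-arterial gradient is modelled).  A dynamic end-tidal forcing
controller (proportional-integral action on inspired PCO2) steers the
end-tidal pressure through the step protocol of a hypercapnic-ventilatory-
response (HCVR) run.

Pressures are mmHg, ventilation L/min, volumes L, time minutes unless a
function says otherwise.  CO2 production (``vco2``) is expressed in the
model units defined by the lambda bookkeeping and is normally obtained by
calibration from a resting (VE, PETCO2) pair rather than given directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "PhysiologyConstants",
    "GasState",
    "ForcingProtocol",
    "RunRecord",
    "SteadyState",
    "hinge",
    "ventilation_from_brain_pco2",
    "calibrate_vco2",
    "vco2_for_resting_state",
    "closed_loop_steady_state",
    "simulate_run",
    "brain_step_halftime",
]

# Fixed-step RK4 substep, minutes (0.25 s).  Small compared with the
# fastest time constant of the loop (alveolar washout, a few seconds).
RK4_STEP_MIN = 0.25 / 60.0

# Dynamic end-tidal forcing controller gains: inspired PCO2 (mmHg) per
# mmHg of end-tidal error (proportional) and per mmHg*min (integral).
FORCING_KP = 10.0
FORCING_KI = 5.0
# Inspired PCO2 actuator limits, mmHg.
PICO2_MAX = 90.0


@dataclass(frozen=True)
class PhysiologyConstants:
    """Constants of the CO2 loop.

    lambda0 is the blood CO2 pressure/content slope (mmHg per mL CO2/100 mL
    blood); lambda1 the lung transfer constant; lambda2 = 100*lambda0 is
    enforced at construction.  ``vco2`` is the CO2 production in model
    units; when None it must be calibrated from a resting state before the
    loop can be simulated (see :func:`calibrate_vco2`).
    """

    lambda0: float = 0.115
    lambda1: float = 10.0
    valv: float = 3.0          # alveolar volume, L
    vd: float = 1.8            # dead-space ventilation, L/min
    vts: float = 10.0          # apparent tissue CO2 distribution volume, L
    q: float = 4.0             # cardiac output, L/min
    tau: float = 2.5           # brain-tissue time constant, min
    delta: float = 0.1         # hinge smoothness, mmHg
    vco2: Optional[float] = None
    lambda2: float = field(init=False)

    def __post_init__(self) -> None:
        for name in ("lambda0", "lambda1", "valv", "vd", "vts", "q", "tau", "delta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.vco2 is not None and self.vco2 <= 0:
            raise ValueError("vco2 must be strictly positive when given")
        object.__setattr__(self, "lambda2", 100.0 * self.lambda0)

    def with_vco2(self, vco2: float) -> "PhysiologyConstants":
        return replace(self, vco2=vco2)


@dataclass(frozen=True)
class GasState:
    arterial_pco2: float
    venous_pco2: float
    brain_pco2: float
    inspired_pco2: float
    end_tidal_pco2: float

    def __post_init__(self) -> None:
        for name in ("arterial_pco2", "venous_pco2", "brain_pco2",
                     "inspired_pco2", "end_tidal_pco2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass(frozen=True)
class SteadyState:
    """Closed-loop fixed point; ``feasible`` False means no solution (apnea)."""

    feasible: bool
    gas: Optional[GasState] = None
    ve: Optional[float] = None


@dataclass(frozen=True)
class ForcingProtocol:
    """End-tidal forcing schedule of one HCVR run.

    Step increments are mmHg above the run's resting end-tidal PCO2.  If the
    steps before the last would together exceed ``max_total`` minutes, the
    final (largest) step is omitted; with the default 7-min steps the
    18-mmHg step is always dropped and a run has three CO2 steps.
    """

    resting_duration: float = 6.0
    step_increments: Sequence[float] = (4.5, 9.0, 13.5, 18.0)
    step_duration: float = 7.0
    max_total: float = 20.0

    def __post_init__(self) -> None:
        if self.resting_duration <= 0 or self.step_duration <= 0 or self.max_total <= 0:
            raise ValueError("durations must be positive")
        incs = tuple(float(x) for x in self.step_increments)
        if len(incs) == 0 or any(b <= a for a, b in zip(incs, incs[1:])):
            raise ValueError("step_increments must be strictly increasing and non-empty")
        object.__setattr__(self, "step_increments", incs)

    def effective_increments(self) -> tuple:
        incs = self.step_increments
        if len(incs) > 1 and (len(incs) - 1) * self.step_duration > self.max_total:
            incs = incs[:-1]
        return incs

    @property
    def total_duration(self) -> float:
        return self.resting_duration + len(self.effective_increments()) * self.step_duration


@dataclass
class RunRecord:
    """One HCVR run: 1-s traces plus 1-min block averages.

    The 1-min table (``minute_index``, ``ve_min``, ``petco2_min``,
    ``pico2_min``) is the external data product; the 1-s traces are kept
    when the record was produced by :func:`simulate_run` and are absent
    after a CSV round trip.
    """

    subject_id: str
    run_time: float            # h since dosing
    minute_index: np.ndarray
    ve_min: np.ndarray
    petco2_min: np.ndarray
    pico2_min: np.ndarray
    time_s: Optional[np.ndarray] = None
    ve_s: Optional[np.ndarray] = None
    petco2_s: Optional[np.ndarray] = None
    pico2_s: Optional[np.ndarray] = None
    brain_s: Optional[np.ndarray] = None
    pico2_substep: Optional[np.ndarray] = None  # controller output per RK4 substep

    def __post_init__(self) -> None:
        n = len(self.minute_index)
        if not (len(self.ve_min) == len(self.petco2_min) == len(self.pico2_min) == n):
            raise ValueError("minute channels must have equal length")
        idx = np.asarray(self.minute_index)
        if n and not np.array_equal(idx, np.arange(idx[0], idx[0] + n)):
            raise ValueError("minutes must be contiguous")

    @property
    def n_minutes(self) -> int:
        return len(self.minute_index)

    def minute_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "run_time_h": self.run_time,
                "minute_index": np.asarray(self.minute_index, dtype=int),
                "ve_l_min": self.ve_min,
                "petco2_mmhg": self.petco2_min,
                "pico2_mmhg": self.pico2_min,
            }
        )

    def to_csv(self, path) -> None:
        self.minute_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "RunRecord":
        df = pd.read_csv(path)
        return cls.from_frame(df)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RunRecord":
        return cls(
            subject_id=str(df["subject_id"].iloc[0]),
            run_time=float(df["run_time_h"].iloc[0]),
            minute_index=df["minute_index"].to_numpy(),
            ve_min=df["ve_l_min"].to_numpy(float),
            petco2_min=df["petco2_mmhg"].to_numpy(float),
            pico2_min=df["pico2_mmhg"].to_numpy(float),
        )


def hinge(x, delta: float = 0.1):
    """Smooth hinge H(x) = delta*log(1+exp(x/delta)); overflow-safe."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    return delta * np.logaddexp(0.0, np.asarray(x, dtype=float) / delta)


def ventilation_from_brain_pco2(hcvr, brain_pco2, constants: PhysiologyConstants):
    """Ventilation law VE = baseline + S*H(brain_PCO2 - VRT), clamped at >= 0."""
    ve = hcvr.baseline_ve + hcvr.slope_s * hinge(brain_pco2 - hcvr.vrt, constants.delta)
    return np.maximum(ve, 0.0)


def calibrate_vco2(baseline_ve: float, baseline_pco2: float,
                   constants: PhysiologyConstants,
                   inspired_pco2: float = 0.0) -> float:
    """CO2 production (model units) that makes (baseline_ve, baseline_pco2)
    the closed-loop resting state at the given inspired PCO2."""
    if baseline_ve <= constants.vd:
        raise ValueError("baseline ventilation must exceed dead-space ventilation")
    if baseline_pco2 <= inspired_pco2:
        raise ValueError("resting PCO2 must exceed inspired PCO2")
    return ((baseline_ve - constants.vd) * (baseline_pco2 - inspired_pco2)
            / (constants.lambda1 * constants.lambda2))


def vco2_for_resting_state(hcvr, constants: PhysiologyConstants,
                           inspired_pco2: float = 0.0) -> float:
    """Hinge-aware calibration: CO2 production that puts the closed-loop
    resting arterial PCO2 exactly at ``hcvr.resting_petco2``.

    Uses the full ventilation law at the resting point, so it remains
    consistent when the recruitment threshold sits below resting PETCO2
    (hinge partially active at rest); reduces to :func:`calibrate_vco2`
    with the baseline ventilation otherwise.
    """
    ve_rest = float(ventilation_from_brain_pco2(hcvr, hcvr.resting_petco2, constants))
    return calibrate_vco2(ve_rest, hcvr.resting_petco2, constants, inspired_pco2)


def _require_vco2(constants: PhysiologyConstants) -> float:
    if constants.vco2 is None:
        raise ValueError("constants.vco2 is not set; calibrate it first "
                         "(calibrate_vco2 / PhysiologyConstants.with_vco2)")
    return constants.vco2


def closed_loop_steady_state(hcvr, constants: PhysiologyConstants,
                             inspired_pco2: float = 0.0) -> SteadyState:
    """Fixed point of the closed loop at a given inspired PCO2.

    Solves (VE(Pa) - VD)*(Pa - PI) = lambda1*lambda2*VCO2 with
    VE(Pa) = baseline + S*H(Pa - VRT); brain and arterial PCO2 coincide at
    steady state and venous PCO2 exceeds arterial by lambda2*VCO2/Q.
    """
    from scipy.optimize import brentq

    vco2 = _require_vco2(constants)
    rhs = constants.lambda1 * constants.lambda2 * vco2
    pi = float(inspired_pco2)

    def gap(pa: float) -> float:
        ve = float(ventilation_from_brain_pco2(hcvr, pa, constants))
        return (ve - constants.vd) * (pa - pi) - rhs

    # Bracket: gap -> -rhs < 0 as Pa -> PI+ provided VE stays finite; the
    # hinge makes VE (hence gap) increase without bound in Pa.
    lo = pi + 1e-9
    hi = max(pi + 1.0, hcvr.vrt + 1.0)
    for _ in range(80):
        if gap(hi) > 0:
            break
        hi *= 1.5
    else:
        return SteadyState(feasible=False)
    if gap(lo) >= 0:
        return SteadyState(feasible=False)
    pa = brentq(gap, lo, hi, xtol=1e-12, rtol=8.9e-16, maxiter=200)
    ve = float(ventilation_from_brain_pco2(hcvr, pa, constants))
    if ve <= constants.vd:
        return SteadyState(feasible=False)
    gas = GasState(
        arterial_pco2=pa,
        venous_pco2=pa + constants.lambda2 * vco2 / constants.q,
        brain_pco2=pa,
        inspired_pco2=pi,
        end_tidal_pco2=pa,
    )
    return SteadyState(feasible=True, gas=gas, ve=ve)


# ----------------------------------------------------------------------
# Numba kernels: fixed-step RK4 on the state (Pa, Pv, Pb, controller
# integral).  mode 0 drives the loop with a prescribed inspired-PCO2 trace
# (node values, linearly interpolated within a substep); mode 1 runs the
# end-tidal forcing controller toward a target trace (NaN target = no
# forcing, inspired PCO2 held at 0).
# ----------------------------------------------------------------------

@njit(cache=True)
def _hinge_nb(x: float, delta: float) -> float:
    z = x / delta
    if z > 30.0:
        return x
    if z < -30.0:
        return delta * np.exp(z)
    return delta * np.log1p(np.exp(z))


@njit(cache=True)
def _pic_from_controller(pa: float, target: float, integ: float,
                         kp: float, ki: float, pic_max: float):
    if np.isnan(target):
        return 0.0, 0.0
    e = target - pa
    u = kp * e + ki * integ
    pic = u
    dinteg = e
    if pic < 0.0:
        pic = 0.0
        if e < 0.0:
            dinteg = 0.0
    elif pic > pic_max:
        pic = pic_max
        if e > 0.0:
            dinteg = 0.0
    return pic, dinteg


@njit(cache=True)
def _deriv(pa, pv, pb, pic, base, slope, vrt, delta,
           valv, vd, vts, q, tau, lam1, lam2, vco2):
    ve = base + slope * _hinge_nb(pb - vrt, delta)
    if ve < 0.0:
        ve = 0.0
    va = ve - vd
    if va < 0.0:
        va = 0.0
    dpa = (va * (pic - pa) + lam1 * q * (pv - pa)) / valv
    dpv = (q * (pa - pv) + lam2 * vco2) / vts
    dpb = (pa - pb) / tau
    return dpa, dpv, dpb, ve


@njit(cache=True)
def _integrate_loop(h, n_steps, keep, mode, drive, kp, ki, pic_max,
                    base, slope, vrt, delta, valv, vd, vts, q, tau,
                    lam1, lam2, vco2, pa0, pv0, pb0):
    """RK4 integration of the loop with sampled-data inspired PCO2.

    Inspired PCO2 is held constant across each substep (the forcing
    controller updates once per substep, like the breath-paced gas mixer
    it idealizes), so a run can be reproduced exactly by re-driving the
    model with the recorded substep trace.

    drive: length n_steps+1 node array — inspired PCO2 (mode 0) or
    end-tidal target (mode 1, NaN = forcing off).  Returns arrays sampled
    every ``keep`` substeps (Pa, Pb, VE, inspired PCO2) plus the full
    substep inspired-PCO2 trace.
    """
    n_out = n_steps // keep + 1
    out_pa = np.empty(n_out)
    out_pb = np.empty(n_out)
    out_ve = np.empty(n_out)
    out_pic = np.empty(n_out)
    pic_fine = np.empty(n_steps + 1)

    pa, pv, pb, integ = pa0, pv0, pb0, 0.0
    j = 0
    for k in range(n_steps + 1):
        if mode == 0:
            pic = drive[k]
            dinteg = 0.0
        else:
            pic, dinteg = _pic_from_controller(pa, drive[k], integ, kp, ki, pic_max)
        pic_fine[k] = pic
        if k % keep == 0:
            ve_node = base + slope * _hinge_nb(pb - vrt, delta)
            if ve_node < 0.0:
                ve_node = 0.0
            out_pa[j] = pa
            out_pb[j] = pb
            out_ve[j] = ve_node
            out_pic[j] = pic
            j += 1
        if k == n_steps:
            break

        k1a, k1v, k1b, _ = _deriv(pa, pv, pb, pic, base, slope, vrt, delta,
                                  valv, vd, vts, q, tau, lam1, lam2, vco2)
        k2a, k2v, k2b, _ = _deriv(pa + 0.5 * h * k1a, pv + 0.5 * h * k1v,
                                  pb + 0.5 * h * k1b, pic, base, slope, vrt, delta,
                                  valv, vd, vts, q, tau, lam1, lam2, vco2)
        k3a, k3v, k3b, _ = _deriv(pa + 0.5 * h * k2a, pv + 0.5 * h * k2v,
                                  pb + 0.5 * h * k2b, pic, base, slope, vrt, delta,
                                  valv, vd, vts, q, tau, lam1, lam2, vco2)
        k4a, k4v, k4b, _ = _deriv(pa + h * k3a, pv + h * k3v,
                                  pb + h * k3b, pic, base, slope, vrt, delta,
                                  valv, vd, vts, q, tau, lam1, lam2, vco2)

        pa += h / 6.0 * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
        pv += h / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        pb += h / 6.0 * (k1b + 2.0 * k2b + 2.0 * k3b + k4b)
        integ += h * dinteg

    return out_pa, out_pb, out_ve, out_pic, pic_fine


def _minute_means(x: np.ndarray, per_min: int) -> np.ndarray:
    n_min = (len(x) - 1) // per_min
    return x[: n_min * per_min].reshape(n_min, per_min).mean(axis=1)


def simulate_run(hcvr, constants: PhysiologyConstants,
                 protocol: ForcingProtocol = ForcingProtocol(),
                 dt_out: float = 1.0,
                 subject_id: str = "sim", run_time: float = 0.0) -> RunRecord:
    """Simulate one forced HCVR run from the closed-loop resting state.

    The run starts at the steady state for inspired PCO2 = 0 (resting
    phase, no forcing), then the controller steps end-tidal PCO2 through
    the protocol increments above resting.  ``dt_out`` is the output grid
    spacing in seconds; 1-min block averages are arithmetic means of the
    output samples in each minute.
    """
    if constants.vco2 is None:
        constants = constants.with_vco2(vco2_for_resting_state(hcvr, constants))
    vco2 = constants.vco2
    rest = closed_loop_steady_state(hcvr, constants, inspired_pco2=0.0)
    if not rest.feasible:
        raise ValueError("no feasible resting steady state (apneic baseline?)")
    pa0 = rest.gas.arterial_pco2

    h = RK4_STEP_MIN
    keep = max(1, int(round(dt_out / 60.0 / h)))
    incs = protocol.effective_increments()
    seg_min = [protocol.resting_duration] + [protocol.step_duration] * len(incs)
    # NaN target = forcing off (resting phase, inspired PCO2 held at 0)
    seg_tgt = [np.nan] + [pa0 + inc for inc in incs]
    n_steps = int(round(sum(seg_min) / h))
    target = np.empty(n_steps + 1)
    pos = 0
    for dur, tgt in zip(seg_min, seg_tgt):
        n_seg = int(round(dur / h))
        target[pos: pos + n_seg] = tgt
        pos += n_seg
    target[pos:] = seg_tgt[-1]

    out_pa, out_pb, out_ve, out_pic, pic_fine = _integrate_loop(
        h, n_steps, keep, 1, target, FORCING_KP, FORCING_KI, PICO2_MAX,
        hcvr.baseline_ve, hcvr.slope_s, hcvr.vrt, constants.delta,
        constants.valv, constants.vd, constants.vts, constants.q,
        constants.tau, constants.lambda1, constants.lambda2, vco2,
        pa0, rest.gas.venous_pco2, pa0)

    per_min = int(round(60.0 / dt_out))
    time_s = np.arange(len(out_pa)) * dt_out
    n_min = (len(out_pa) - 1) // per_min
    return RunRecord(
        subject_id=subject_id,
        run_time=run_time,
        minute_index=np.arange(n_min),
        ve_min=_minute_means(out_ve, per_min),
        petco2_min=_minute_means(out_pa, per_min),
        pico2_min=_minute_means(out_pic, per_min),
        time_s=time_s,
        ve_s=out_ve,
        petco2_s=out_pa,
        pico2_s=out_pic,
        brain_s=out_pb,
        pico2_substep=pic_fine,
    )


def simulate_driven(hcvr, constants: PhysiologyConstants,
                    pico2_t: np.ndarray, pico2: np.ndarray,
                    duration_min: float, pa0: float,
                    dt_out: float = 1.0):
    """Integrate the loop driven by a recorded inspired-PCO2 trace.

    ``pico2_t``/``pico2`` give the trace nodes (minutes, mmHg); values are
    interpolated onto the integration substep grid and held constant over
    each substep, matching the sampled-data forcing of
    :func:`simulate_run` (a substep-resolution trace is reproduced
    exactly).  Initial state is the resting steady state at arterial PCO2
    ``pa0``.  Returns (time_s, Pa, Pb, VE) on the ``dt_out``-second output
    grid.  Used by the run estimator, which needs many cheap forward
    solves.
    """
    vco2 = _require_vco2(constants)
    h = RK4_STEP_MIN
    keep = max(1, int(round(dt_out / 60.0 / h)))
    n_steps = int(round(duration_min / h))
    grid = np.arange(n_steps + 1) * h
    drive = np.interp(grid, pico2_t, pico2)
    pv0 = pa0 + constants.lambda2 * vco2 / constants.q
    out_pa, out_pb, out_ve, _, _ = _integrate_loop(
        h, n_steps, keep, 0, drive, 0.0, 0.0, PICO2_MAX,
        hcvr.baseline_ve, hcvr.slope_s, hcvr.vrt, constants.delta,
        constants.valv, constants.vd, constants.vts, constants.q,
        constants.tau, constants.lambda1, constants.lambda2, vco2,
        pa0, pv0, pa0)
    time_s = np.arange(len(out_pa)) * dt_out
    return time_s, out_pa, out_pb, out_ve


def brain_step_halftime(constants: PhysiologyConstants, dt: float = 1e-3) -> float:
    """Measured 50%-rise time of brain PCO2 after an arterial step (open loop).

    Integrates tau*dPb/dt = Pa - Pb for a unit arterial step with RK4 and
    locates the half-rise by linear interpolation; expected tau*ln 2.
    """
    tau = constants.tau
    t, pb = 0.0, 0.0
    prev_t, prev_pb = t, pb
    while pb < 0.5:
        prev_t, prev_pb = t, pb
        k1 = (1.0 - pb) / tau
        k2 = (1.0 - (pb + 0.5 * dt * k1)) / tau
        k3 = (1.0 - (pb + 0.5 * dt * k2)) / tau
        k4 = (1.0 - (pb + dt * k3)) / tau
        pb += dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return prev_t + (0.5 - prev_pb) / (pb - prev_pb) * (t - prev_t)
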