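"""Population summaries: between-subject variability, potency ratios,
dose-effect comparison and bootstrap standard errors.

The between-subject coefficient of variation follows the log-normal
convention %CV = 100*sqrt(exp(omega2) - 1), where omega2 is the variance
of the log-scale parameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSummary",
    "compute_cv",
    "invert_cv",
    "potency_ratios",
    "dose_effect_table",
    "bootstrap_se",
    "summarize_biomarker",
]


@dataclass(frozen=True)
class PopulationSummary:
    """Population row for one parameter (Table-1 shape)."""

    name: str
    estimate: float              # median across subjects
    se: float                    # bootstrap SE of the median
    omega2: float                # between-subject variance of log parameter
    cv_percent: float
    sigma: Optional[float] = None  # within-subject residual SD, parameter units

    def __post_init__(self) -> None:
        if self.omega2 < 0:
            raise ValueError("omega2 must be nonnegative")


def compute_cv(omega2: float) -> float:
    """%CV of a log-normal parameter from its log-scale variance."""
    if omega2 < 0:
        raise ValueError("omega2 must be nonnegative")
    return 100.0 * np.sqrt(np.expm1(omega2))


def invert_cv(cv_percent: float) -> float:
    """Inverse of :func:`compute_cv`: omega2 = log(1 + (cv/100)^2)."""
    return float(np.log1p((cv_percent / 100.0) ** 2))


def _round_sig(x: float, sig: int = 2) -> float:
    if x == 0:
        return 0.0
    k = sig - 1 - int(np.floor(np.log10(abs(x))))
    return round(x, k)


def potency_ratios(c50: Mapping[str, float]) -> pd.DataFrame:
    """C50 ratios of the resting-class biomarkers over S and VE55.

    ``c50`` must contain 'resting_class', 'slope' and 've55' entries.
    Returns raw ratios and values rounded to two significant figures.
    """
    for key in ("resting_class", "slope", "ve55"):
        if key not in c50:
            raise KeyError(f"missing C50 entry '{key}'")
    rows = []
    for denom in ("slope", "ve55"):
        raw = c50["resting_class"] / c50[denom]
        rows.append({"ratio": f"resting_class/{denom}", "raw": raw,
                     "rounded": _round_sig(raw, 2)})
    return pd.DataFrame(rows)


def bootstrap_se(estimates: Sequence[float], b: int = 1000, seed: int = 0,
                 statistic: Callable = np.median) -> float:
    """Nonparametric bootstrap SE of a statistic of per-subject estimates."""
    x = np.asarray(estimates, dtype=float)
    if len(x) < 2 or np.ptp(x) == 0:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(x), size=(b, len(x)))
    stats = statistic(x[idx], axis=1)
    return float(np.std(stats, ddof=1))


def summarize_biomarker(name: str, values: Sequence[float],
                        sigma: Optional[float] = None,
                        b: int = 1000, seed: int = 0) -> PopulationSummary:
    """Stage-2 summary of per-subject estimates of one parameter.

    Median point estimate, bootstrap SE, and omega2 from the variance of
    the log estimates (values must be positive for omega2; otherwise
    omega2 is reported as 0 with a warning).
    """
    x = np.asarray(values, dtype=float)
    est = float(np.median(x))
    se = bootstrap_se(x, b=b, seed=seed)
    if np.all(x > 0):
        omega2 = float(np.var(np.log(x), ddof=1)) if len(x) > 1 else 0.0
    else:
        warnings.warn(f"nonpositive estimates for {name}; omega2 set to 0",
                      stacklevel=2)
        omega2 = 0.0
    return PopulationSummary(name=name, estimate=est, se=se, omega2=omega2,
                             cv_percent=float(compute_cv(omega2)), sigma=sigma)


def dose_effect_table(fits_low: Mapping[str, Sequence[float]],
                      fits_high: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dose-effect comparison between the 100- and 200-mg arms.

    Inputs map biomarker name -> per-subject peak fractional drug effects
    (|extremum - e0|/e0, dimensionless; see
    :func:`ventpkpd.emax.peak_fractional_effects`).  Reports the median
    peak effect per arm in percent and the change between arms in
    percentage points, sorted by decreasing dose effect.  Biomarkers
    missing from either arm are omitted with a warning.
    """
    if not fits_low or not fits_high:
        raise ValueError("both dose arms must be non-empty")
    rows = []
    for name in fits_low:
        if name not in fits_high:
            warnings.warn(f"biomarker {name} missing in high-dose arm; omitted",
                          stacklevel=2)
            continue
        lo = 100.0 * float(np.median(np.asarray(fits_low[name], dtype=float)))
        hi = 100.0 * float(np.median(np.asarray(fits_high[name], dtype=float)))
        rows.append({"biomarker": name, "peak_effect_low_pct": lo,
                     "peak_effect_high_pct": hi, "dose_effect_points": hi - lo})
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values("dose_effect_points", ascending=False,
                            ignore_index=True)
    return df
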