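"""Phenotype-microarray kinetic curves: parameters, sigmoid fits,
activity areas and per-plate categorization.

An OmniLog-style phenotype microarray records one colour-development
curve per well, sampled every 15 minutes for 72 hours (289 points).
Each curve is summarised by nine characteristic parameters:

====================  =========================================================
``y0``                baseline signal (mean of the first 3 points)
``min_s``, ``max_s``  raw signal extremes
``span``              ``max_s - min_s``
``avg_height``        mean raw signal
``lag_lambda``        lag time in hours (tangent construction at max slope)
``max_slope_mu``      maximum smoothed first difference, units/hour
``plateau``           mean of the trailing points
``auc``               trapezoidal area under the baseline-subtracted curve
====================  =========================================================

Three sigmoid models (logistic, Gompertz, Richards) can be least-squares
fitted for diagnostics, but the *activity* of a well is always the
directly computed area under the curve — truncated curves make
model-estimated activities unreliable, so fitted parameters never feed
the activity statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Dict, List, MutableMapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .models import MODEL_NPARAMS, MODELS

__all__ = [
    "DEFAULT_GRID",
    "KineticCurve",
    "CurveParameters",
    "SigmoidFit",
    "ActivityRecord",
    "read_kinetics",
    "write_kinetics",
    "curve_parameters",
    "fit_sigmoid",
    "best_fit",
    "activity",
    "categorize_activities",
    "normalize_heatmap",
    "ACTIVITY_LEVELS",
]

# 15-minute sampling over 72 h
DEFAULT_GRID = np.arange(289) * 0.25

ACTIVITY_LEVELS = ("low", "lower-middle", "upper-middle", "high")


@dataclass
class KineticCurve:
    strain_id: str
    plate_id: str
    well_id: str
    substrate: str
    replicate: int
    times: np.ndarray
    signals: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.times.shape != self.signals.shape:
            raise ValueError("times and signals differ in length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")

    @property
    def column_id(self) -> str:
        return f"{self.strain_id}:{self.plate_id}:{self.well_id}:{self.replicate}"


@dataclass
class CurveParameters:
    y0: float
    min_s: float
    max_s: float
    span: float
    avg_height: float
    lag_lambda: float
    max_slope_mu: float
    plateau: float
    auc: float

    def as_dict(self) -> Dict[str, float]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}


@dataclass
class SigmoidFit:
    model: str
    params: Dict[str, float]
    rss: float
    converged: bool
    n_params: int = 0

    def __post_init__(self):
        if not self.n_params:
            self.n_params = MODEL_NPARAMS[self.model]


@dataclass
class ActivityRecord:
    strain_id: str
    plate_id: str
    well_id: str
    substrate: str
    activity: float
    consistent: bool
    level: Optional[str] = None
    replicate_aucs: List[float] = field(default_factory=list)


# ------------------------------------------------------------------- file IO


def read_kinetics(
    csv_path,
    manifest_path=None,
    warning_counts: Optional[MutableMapping[str, int]] = None,
) -> List[KineticCurve]:
    """Read curves from a CSV with a ``time_h`` column and one column per well.

    The optional manifest TSV maps well columns to strain/plate/well/
    substrate/replicate; without it those fields are parsed from the
    column id (``strain:plate:well:replicate``) or defaulted.  Negative
    signals are clipped to zero and counted in ``warning_counts``.
    """
    df = pd.read_csv(csv_path)
    if "time_h" not in df.columns:
        raise ValueError(f"{csv_path}: missing 'time_h' column")
    times = df["time_h"].to_numpy(dtype=float)
    if len(times) >= 2 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{csv_path}: time column is not strictly increasing")

    manifest: Dict[str, Dict[str, str]] = {}
    if manifest_path is not None:
        mdf = pd.read_csv(manifest_path, sep="\t", dtype=str)
        required = {"column", "strain_id", "plate_id", "well_id", "substrate", "replicate"}
        missing = required - set(mdf.columns)
        if missing:
            raise ValueError(f"{manifest_path}: missing manifest columns {sorted(missing)}")
        manifest = {row["column"]: dict(row) for _, row in mdf.iterrows()}

    curves = []
    for col in df.columns:
        if col == "time_h":
            continue
        signals = df[col].to_numpy(dtype=float)
        n_neg = int((signals < 0).sum())
        if n_neg and warning_counts is not None:
            warning_counts["negative_signals_clipped"] = (
                warning_counts.get("negative_signals_clipped", 0) + n_neg
            )
        signals = np.clip(signals, 0, None)
        if col in manifest:
            m = manifest[col]
            curves.append(
                KineticCurve(
                    m["strain_id"], m["plate_id"], m["well_id"], m["substrate"],
                    int(m["replicate"]), times, signals,
                )
            )
        else:
            parts = col.split(":")
            if len(parts) == 4:
                curves.append(
                    KineticCurve(parts[0], parts[1], parts[2], parts[2],
                                 int(parts[3]), times, signals)
                )
            else:
                curves.append(KineticCurve("strain", "plate", col, col, 1, times, signals))
    return curves


def write_kinetics(curves: Sequence[KineticCurve], csv_path, manifest_path=None) -> None:
    if not curves:
        raise ValueError("no curves to write")
    times = curves[0].times
    for c in curves:
        if not np.array_equal(c.times, times):
            raise ValueError("all curves must share one time grid to share a CSV")
    data = {"time_h": times}
    for c in curves:
        data[c.column_id] = c.signals
    pd.DataFrame(data).to_csv(csv_path, index=False)
    if manifest_path is not None:
        rows = [
            {
                "column": c.column_id,
                "strain_id": c.strain_id,
                "plate_id": c.plate_id,
                "well_id": c.well_id,
                "substrate": c.substrate,
                "replicate": c.replicate,
            }
            for c in curves
        ]
        pd.DataFrame(rows).to_csv(manifest_path, sep="\t", index=False)


# ------------------------------------------------------- curve parameters


def curve_parameters(
    curve: KineticCurve, smooth_window: int = 5, plateau_tail: int = 8
) -> CurveParameters:
    """Nine-parameter summary of one kinetic curve.

    The maximum slope is taken from first differences of a centered
    moving average (window ``smooth_window`` points); the lag is the
    intercept of the tangent at the maximum-slope point with the
    baseline, clamped to the observed time range.
    """
    t, y = curve.times, curve.signals
    n = len(t)
    if smooth_window % 2 == 0 or smooth_window < 1:
        raise ValueError("smooth_window must be odd and positive")
    if n < max(smooth_window + 1, 4):
        raise ValueError(f"curve too short ({n} points) for smoothing window {smooth_window}")

    y0 = float(np.mean(y[:3]))
    min_s = float(np.min(y))
    max_s = float(np.max(y))
    span = max_s - min_s
    avg_height = float(np.mean(y))

    half = smooth_window // 2
    kernel = np.ones(smooth_window) / smooth_window
    sm = np.convolve(y, kernel, mode="valid")  # length n - 2*half
    t_sm = t[half : n - half]
    slopes = np.diff(sm) / np.diff(t_sm)
    i_max = int(np.argmax(slopes))
    mu = float(max(slopes[i_max], 0.0))

    t_last = float(t[-1])
    if mu > 0:
        t_star = 0.5 * (t_sm[i_max] + t_sm[i_max + 1])
        y_star = 0.5 * (sm[i_max] + sm[i_max + 1])
        lag = t_star - (y_star - y0) / mu
        lag = float(min(max(lag, 0.0), t_last))
    else:
        lag = t_last

    plateau = float(np.mean(y[-plateau_tail:]))
    auc = float(np.trapezoid(np.clip(y - y0, 0, None), t))

    return CurveParameters(y0, min_s, max_s, span, avg_height, lag, mu, plateau, auc)


# -------------------------------------------------------------- model fits


def fit_sigmoid(curve: KineticCurve, model: str) -> SigmoidFit:
    """Least-squares fit of one sigmoid model, seeded from curve_parameters."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    t, y = curve.times, curve.signals
    n_par = MODEL_NPARAMS[model]
    if len(t) <= n_par:
        raise ValueError(f"curve has {len(t)} points, need > {n_par} for {model}")

    cp = curve_parameters(curve, smooth_window=5 if len(t) >= 6 else 3)
    span = max(cp.span, 1e-6)
    p0 = [span, max(cp.max_slope_mu, 1e-3), min(max(cp.lag_lambda, 0.0), float(t[-1])),
          max(cp.y0, 0.0)]
    lower = [0.0, 0.0, 0.0, 0.0]
    upper = [np.inf, np.inf, float(t[-1]) * 2 + 1, max(float(np.max(y)), 1e-6)]
    if model == "richards":
        p0.append(1.0)
        lower.append(1e-3)
        upper.append(100.0)

    func = MODELS[model]
    try:
        with np.errstate(over="ignore", invalid="ignore"):
            popt, _ = curve_fit(
                func, t, y, p0=p0, bounds=(lower, upper), maxfev=5000, method="trf"
            )
        resid = y - func(t, *popt)
        rss = float(np.sum(resid**2))
        if not math.isfinite(rss):
            raise RuntimeError("non-finite residual")
        names = ["A", "mu", "lambda", "y0"] + (["nu"] if model == "richards" else [])
        return SigmoidFit(model, dict(zip(names, map(float, popt))), rss, True)
    except (RuntimeError, ValueError):
        return SigmoidFit(model, {}, float("inf"), False)


_MODEL_ORDER = ("logistic", "gompertz", "richards")


def best_fit(curve: KineticCurve, rel_tol: float = 1e-6, abs_tol: float = 1e-9) -> SigmoidFit:
    """Lowest-RSS converged model; near-ties go to the simpler model.

    Two fits are tied when their RSS values agree within ``rel_tol``
    relatively or ``abs_tol`` absolutely (a Richards fit reproduces any
    logistic curve exactly at nu = 1, so exact comparison would be
    decided by floating-point noise).  Ties break toward fewer
    parameters, then the fixed model order logistic, gompertz, richards.
    """
    fits = [fit_sigmoid(curve, m) for m in _MODEL_ORDER]
    converged = [f for f in fits if f.converged]
    if not converged:
        return min(fits, key=lambda f: _MODEL_ORDER.index(f.model))
    best_rss = min(f.rss for f in converged)
    tied = [
        f for f in converged
        if f.rss <= best_rss + abs_tol or f.rss <= best_rss * (1 + rel_tol)
    ]
    return min(tied, key=lambda f: (f.n_params, _MODEL_ORDER.index(f.model)))


# ---------------------------------------------------------------- activity


def activity(
    replicate_curves: Sequence[KineticCurve], consistency_tol: float = 0.25
) -> ActivityRecord:
    """Mean replicate AUC for one strain x substrate, with a consistency flag.

    Replicates are inconsistent when their AUC spread (max - min) exceeds
    ``consistency_tol`` of the mean.
    """
    if not replicate_curves:
        raise ValueError("need at least one replicate curve")
    first = replicate_curves[0]
    aucs = [curve_parameters(c).auc for c in replicate_curves]
    mean = float(np.mean(aucs))
    if mean > 0:
        consistent = (max(aucs) - min(aucs)) / mean <= consistency_tol
    else:
        consistent = True
    return ActivityRecord(
        first.strain_id, first.plate_id, first.well_id, first.substrate,
        mean, consistent, replicate_aucs=[float(a) for a in aucs],
    )


def categorize_activities(
    activities: Dict[str, float],
    cutpoints: Tuple[float, float, float] = (0.25, 0.50, 0.75),
) -> Dict[str, str]:
    """Four-level per-plate categorization by fraction of the plate maximum.

    Levels: low (< c1*max), lower-middle (< c2*max), upper-middle
    (< c3*max), high (rest).  An all-zero plate is all low.
    """
    if not activities:
        raise ValueError("no activities to categorize")
    c1, c2, c3 = cutpoints
    if not (0 < c1 < c2 < c3 <= 1):
        raise ValueError(f"cutpoints must be increasing in (0, 1], got {cutpoints}")
    m = max(activities.values())
    levels = {}
    for well, a in activities.items():
        if m <= 0:
            levels[well] = "low"
        elif a < c1 * m:
            levels[well] = "low"
        elif a < c2 * m:
            levels[well] = "lower-middle"
        elif a < c3 * m:
            levels[well] = "upper-middle"
        else:
            levels[well] = "high"
    return levels


def normalize_heatmap(values: Sequence[float]) -> np.ndarray:
    """Min-max normalization to [0, 1]; constant input maps to all zeros."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("no values to normalize")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
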