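"""ThT aggregation-curve processing and two-baseline sigmoid fitting.

The central model is a sigmoidal transition between two straight lines,

    F(t) = (m1*t + n1) * (1 - L(t)) + (m2*t + n2) * L(t),
    L(t) = 1 / (1 + exp(-k*(t - t05))),

where (m1, n1) are the slope and intercept of the pre-transition baseline,
(m2, n2) those of the post-transition baseline, t05 the transition midpoint
(the aggregation half-time) and k the transition slope in 1/h.  At t = t05
the curve equals the mean of the two baselines for any k.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

PARAM_NAMES = ("m1", "n1", "m2", "n2", "k", "t05")

# Smallest positive subnormal double; used as a printable lower bound when a
# p-value underflows.
_P_FLOOR = 5e-324


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TimeCourse:
    """One well's fluorescence trace plus its condition metadata."""

    times: np.ndarray            # hours, strictly increasing
    fluorescence: np.ndarray     # arbitrary units
    tau_conc: float              # uM
    inhibitor_id: str | None = None
    inhibitor_conc: float = 0.0  # uM
    heparin: bool = True
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.times.size != self.fluorescence.size:
            raise ValueError("times and fluorescence must have equal length")
        if self.times.size < 4:
            raise ValueError("a time course needs at least 4 points")
        if not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if self.tau_conc < 0:
            raise ValueError("tau_conc must be >= 0")

    @property
    def condition_key(self) -> tuple:
        return (self.tau_conc, self.inhibitor_id, self.inhibitor_conc,
                self.heparin)


@dataclass
class AveragedCurve:
    """Replicate-averaged curve, optionally control-subtracted/normalized."""

    times: np.ndarray
    mean_fluorescence: np.ndarray
    n_replicates: int = 1
    control_subtracted: bool = False
    normalized: bool = False
    norm_reference: tuple[float, float] | None = None  # (F_min, F_max)
    condition: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.mean_fluorescence = np.asarray(self.mean_fluorescence,
                                            dtype=float)
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.normalized:
            if self.norm_reference is None:
                raise ValueError("normalized curve requires norm_reference")
            fmin, fmax = self.norm_reference
            if not fmax > fmin:
                raise ValueError("norm_reference requires F_max > F_min")


@dataclass
class SigmoidFit:
    """Fitted two-baseline sigmoid parameters with uncertainties."""

    m1: float = 0.0
    n1: float = 0.0
    m2: float = 0.0
    n2: float = 1.0
    k: float = 1.0           # 1/h (often reported with hour units; see
    #                          k_reciprocal for the inverse reading)
    t05: float = 0.0         # h
    se: dict = field(default_factory=dict)
    covariance: np.ndarray | None = None
    rmse: float = float("nan")
    converged: bool = True
    message: str = ""

    @property
    def params(self) -> dict:
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @property
    def k_reciprocal(self) -> float:
        """1/k in hours, emitted because the source units are ambiguous."""
        return 1.0 / self.k if self.k != 0 else float("inf")


@dataclass
class ScalingFit:
    """log-log regression of half-time on monomer concentration."""

    log_conc: np.ndarray
    log_t05: np.ndarray
    slope: float
    slope_se: float
    intercept: float
    r_squared: float

    def __post_init__(self) -> None:
        self.log_conc = np.asarray(self.log_conc, dtype=float)
        self.log_t05 = np.asarray(self.log_t05, dtype=float)
        if self.log_conc.size != self.log_t05.size or self.log_conc.size < 3:
            raise ValueError("need >= 3 matched (conc, t05) points")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared must lie in [0, 1]")


# ---------------------------------------------------------------------------
# plate i/o
# ---------------------------------------------------------------------------

def load_plate(plate_file, meta_file) -> list[TimeCourse]:
    """Read a delimited plate file plus its well-metadata companion.

    The plate file has a ``time_h`` column followed by one column per well;
    the metadata file has columns ``well, tau_conc_uM, inhibitor,
    inhibitor_conc_uM, heparin, replicate``.
    """
    plate = pd.read_csv(plate_file, sep=None, engine="python")
    meta = pd.read_csv(meta_file, sep=None, engine="python")
    time_col = plate.columns[0]
    times = plate[time_col].to_numpy(dtype=float)
    if not np.all(np.diff(times) > 0):
        raise ValueError(f"time column {time_col!r} is not strictly "
                         "increasing (duplicate or unsorted values)")
    meta = meta.set_index(meta["well"].astype(str))
    curves = []
    for well in plate.columns[1:]:
        if str(well) not in meta.index:
            raise ValueError(f"no metadata for well {well!r}")
        row = meta.loc[str(well)]
        inhibitor = row["inhibitor"]
        if pd.isna(inhibitor) or str(inhibitor).lower() in ("", "none"):
            inhibitor = None
        curves.append(TimeCourse(
            times=times,
            fluorescence=plate[well].to_numpy(dtype=float),
            tau_conc=float(row["tau_conc_uM"]),
            inhibitor_id=inhibitor,
            inhibitor_conc=float(row["inhibitor_conc_uM"]),
            heparin=bool(row["heparin"]),
            replicate_id=str(row["replicate"]),
        ))
    return curves


# ---------------------------------------------------------------------------
# averaging / normalization
# ---------------------------------------------------------------------------

def average_replicates(curves: list[TimeCourse]) -> AveragedCurve:
    """Pointwise mean of replicate wells sharing one condition and grid."""
    if not curves:
        raise ValueError("no curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if c.times.size != ref.times.size or not np.array_equal(c.times,
                                                                ref.times):
            raise ValueError("replicates must share an identical time grid")
        if c.condition_key != ref.condition_key:
            raise ValueError("cannot average curves from mixed conditions: "
                             f"{c.condition_key} vs {ref.condition_key}")
    mean = np.mean([c.fluorescence for c in curves], axis=0)
    return AveragedCurve(
        times=ref.times.copy(),
        mean_fluorescence=mean,
        n_replicates=len(curves),
        condition={
            "tau_conc": ref.tau_conc,
            "inhibitor_id": ref.inhibitor_id,
            "inhibitor_conc": ref.inhibitor_conc,
            "heparin": ref.heparin,
        },
    )


def subtract_control(avg: AveragedCurve,
                     control: AveragedCurve) -> AveragedCurve:
    """Subtract the matching heparin-free control, pointwise."""
    if not np.array_equal(avg.times, control.times):
        raise ValueError("control curve is on a different time grid")
    return replace(
        avg,
        mean_fluorescence=avg.mean_fluorescence - control.mean_fluorescence,
        control_subtracted=True,
    )


def normalize_curve(avg: AveragedCurve,
                    reference: AveragedCurve | None = None) -> AveragedCurve:
    """Map fluorescence to (F - F_min) / (F_max - F_min).

    Self-normalization (``reference=None``) takes F_min as the curve's
    initial (minimum) value and F_max as its plateau (maximum).  Curves
    measured in the presence of an inhibitor are normalized with the
    (F_min, F_max) of the inhibitor-free reference curve, so a suppressed
    plateau stays below 1.
    """
    src = reference if reference is not None else avg
    fmin = float(np.min(src.mean_fluorescence))
    fmax = float(np.max(src.mean_fluorescence))
    if fmax == fmin:
        raise ValueError("degenerate normalization range: F_max == F_min")
    return replace(
        avg,
        mean_fluorescence=(avg.mean_fluorescence - fmin) / (fmax - fmin),
        normalized=True,
        norm_reference=(fmin, fmax),
    )


# ---------------------------------------------------------------------------
# sigmoid model
# ---------------------------------------------------------------------------

def sigmoid(t, m1, n1, m2, n2, k, t05):
    """Two-baseline sigmoid, overflow-safe (the logistic saturates)."""
    t = np.asarray(t, dtype=float)
    z = np.clip(k * (t - t05), -700.0, 700.0)
    logistic = 1.0 / (1.0 + np.exp(-z))
    # saturate exactly where the logistic is flat to double precision
    logistic = np.where(z < -37.0, 0.0, np.where(z > 37.0, 1.0, logistic))
    return (m1 * t + n1) * (1.0 - logistic) + (m2 * t + n2) * logistic


def eval_sigmoid(params, t):
    """Evaluate the sigmoid from a SigmoidFit or a mapping of parameters."""
    if isinstance(params, SigmoidFit):
        p = params.params
    else:
        p = dict(params)
    return sigmoid(t, *(p[name] for name in PARAM_NAMES))


def _initial_guess(times: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Data-driven starting point: baselines from the first/last 10% of
    points, t05 at half-maximal normalized signal, k from the steepest
    finite-difference slope of the normalized signal."""
    n = times.size
    edge = max(2, n // 10)
    m1, n1 = np.polyfit(times[:edge], y[:edge], 1)
    m2, n2 = np.polyfit(times[-edge:], y[-edge:], 1)
    lo, hi = float(np.min(y)), float(np.max(y))
    span = hi - lo if hi > lo else 1.0
    yn = (y - lo) / span
    i_half = int(np.argmin(np.abs(yn - 0.5)))
    t05 = float(times[i_half])
    dy = np.gradient(yn, times)
    # logistic max slope = k/4 on the unit-amplitude transition
    k = 4.0 * float(np.max(np.abs(dy)))
    k = max(k, 1e-3)
    return np.array([m1, n1, m2, n2, k, t05])


def fit_sigmoid(curve: AveragedCurve,
                init: np.ndarray | dict | None = None,
                max_restarts: int = 3,
                seed: int = 0) -> SigmoidFit:
    """Nonlinear least squares of the two-baseline sigmoid.

    Standard errors come from the Jacobian-based covariance scaled by the
    residual variance.  Non-convergence is reported via ``converged=False``
    after ``max_restarts`` jittered restarts, never as an exception.
    """
    times = curve.times
    y = curve.mean_fluorescence
    if times.size < 7:
        raise ValueError("need at least 7 points to fit the sigmoid")

    if init is None:
        x0 = _initial_guess(times, y)
    elif isinstance(init, dict):
        x0 = np.array([init[name] for name in PARAM_NAMES], dtype=float)
    else:
        x0 = np.asarray(init, dtype=float)

    def residuals(x):
        return sigmoid(times, *x) - y

    rng = np.random.default_rng(seed)
    best = None
    start = x0.copy()
    for attempt in range(max_restarts + 1):
        res = optimize.least_squares(residuals, start, method="lm",
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14,
                                     max_nfev=20000)
        ok = (res.success and res.x[4] > 0
              and times[0] <= res.x[5] <= times[-1])
        if best is None or res.cost < best[0].cost:
            best = (res, ok)
        if ok:
            best = (res, ok)
            break
        start = x0 * (1.0 + 0.2 * rng.standard_normal(6))
        start[4] = abs(start[4]) or 0.1

    res, ok = best
    x = res.x
    n, p = times.size, 6
    ssr = float(2.0 * res.cost)
    rmse = math.sqrt(ssr / n)
    jac = res.jac
    try:
        jtj_inv = np.linalg.pinv(jac.T @ jac)
        s2 = ssr / max(n - p, 1)
        cov = jtj_inv * s2
        se = {name: float(math.sqrt(max(cov[i, i], 0.0)))
              for i, name in enumerate(PARAM_NAMES)}
    except np.linalg.LinAlgError:  # pragma: no cover - pinv rarely fails
        cov = None
        se = {name: float("nan") for name in PARAM_NAMES}
        ok = False

    return SigmoidFit(
        m1=x[0], n1=x[1], m2=x[2], n2=x[3], k=x[4], t05=x[5],
        se=se, covariance=cov, rmse=rmse, converged=bool(ok),
        message=res.message,
    )


# ---------------------------------------------------------------------------
# comparisons
# ---------------------------------------------------------------------------

def compare_halftimes(fit_a: SigmoidFit,
                      fit_b: SigmoidFit) -> tuple[float, float]:
    """Two-sample Z statistic on the fitted half-times.

    Z = |t05_a - t05_b| / sqrt(se_a^2 + se_b^2) with a two-sided p-value
    under a standard normal null.  A p-value below the smallest positive
    double is reported as that bound.
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("both fits must have converged")
    se_a = fit_a.se.get("t05", 0.0)
    se_b = fit_b.se.get("t05", 0.0)
    pooled = math.hypot(se_a, se_b)
    if pooled == 0.0:
        if fit_a.t05 == fit_b.t05:
            return 0.0, 1.0
        raise ValueError("zero standard errors on both half-times")
    z = abs(fit_a.t05 - fit_b.t05) / pooled
    p = math.erfc(z / math.sqrt(2.0))
    if p == 0.0:
        p = _P_FLOOR  # underflow: report the printable bound
    return z, p


def halftime_scaling(fits: list[tuple[float, SigmoidFit]]) -> ScalingFit:
    """OLS of log10(t05) on log10(monomer concentration)."""
    if len(fits) < 3:
        raise ValueError("need fits at >= 3 distinct concentrations")
    concs = np.array([c for c, _ in fits], dtype=float)
    t05s = np.array([f.t05 for _, f in fits], dtype=float)
    for _, f in fits:
        if not f.converged:
            raise ValueError("all fits must have converged")
    if np.any(concs <= 0) or np.any(t05s <= 0):
        raise ValueError("concentrations and half-times must be positive")
    if np.unique(concs).size < 3:
        raise ValueError("need >= 3 distinct concentrations")
    lx, ly = np.log10(concs), np.log10(t05s)
    reg = stats.linregress(lx, ly)
    r2 = float(reg.rvalue ** 2)
    if not np.isfinite(r2):
        # constant half-times: zero total variance, the flat fit is exact
        r2 = 1.0
    return ScalingFit(
        log_conc=lx, log_t05=ly,
        slope=float(reg.slope), slope_se=float(reg.stderr),
        intercept=float(reg.intercept),
        r_squared=r2,
    )


def halftime_from_curve(times: np.ndarray, y: np.ndarray) -> float:
    """Linear-interpolated time at which a normalized curve crosses 0.5."""
    times = np.asarray(times, dtype=float)
    y = np.asarray(y, dtype=float)
    above = np.nonzero(y >= 0.5)[0]
    if above.size == 0 or above[0] == 0:
        raise ValueError("curve does not cross 0.5 inside the time range")
    i = above[0]
    t0, t1 = times[i - 1], times[i]
    y0, y1 = y[i - 1], y[i]
    return float(t0 + (0.5 - y0) * (t1 - t0) / (y1 - y0))
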