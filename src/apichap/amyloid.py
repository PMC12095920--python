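"""Moment-equation amyloid growth models, global fitting and model selection.

Each mechanism is a two-moment ODE system in the fibril number concentration
P(t) and fibril mass concentration M(t), with monomer m(t) = m0 - M(t):

    dP/dt = kn * m^nc                      (primary nucleation, all models)
            + kminus * M                   (fragmentation variants)
            + k2 * m^n2 * M                (secondary nucleation)
    dM/dt = 2 * kplus * m * P              (elongation)
            / (1 + m / KS)                 (saturating variant)

Forward simulation returns the normalized mass curve M(t)/m0.  The
identifiable combination under fragmentation is kappa =
sqrt(2*kplus*kminus*m0); individual kplus/kminus trade off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.integrate import solve_ivp

MODEL_NAMES = (
    "nucleation_elongation",
    "secondary_nucleation",
    "fragmentation",
    "saturating_elongation_fragmentation",
)

# free (fitted) rate parameters per mechanism; nucleus sizes stay fixed
_FREE_PARAMS = {
    "nucleation_elongation": ("kn", "kplus"),
    "secondary_nucleation": ("kn", "kplus", "k2"),
    "fragmentation": ("kn", "kplus", "kminus"),
    "saturating_elongation_fragmentation": ("kn", "kplus", "kminus", "KS"),
}


@dataclass
class KineticModel:
    """A named mechanism with its rate constants and nucleus sizes.

    Units assume concentrations in uM and time in hours: kn in
    uM^(1-nc)/h, kplus in 1/(uM h), kminus in 1/h, k2 in uM^(-n2)/h,
    KS in uM.
    """

    name: str
    kn: float = 0.0
    kplus: float = 0.0
    nc: int = 2
    kminus: float | None = None
    k2: float | None = None
    n2: int | None = None
    KS: float | None = None

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; "
                             f"expected one of {MODEL_NAMES}")
        if self.kn < 0 or self.kplus < 0 or self.nc < 1:
            raise ValueError("rate constants must be >= 0 and nc >= 1")
        needs_frag = self.name in ("fragmentation",
                                   "saturating_elongation_fragmentation")
        if needs_frag and self.kminus is None:
            raise ValueError(f"{self.name} requires kminus")
        if self.name == "secondary_nucleation":
            if self.k2 is None:
                raise ValueError("secondary_nucleation requires k2")
            if self.n2 is None:
                self.n2 = 2
        if (self.name == "saturating_elongation_fragmentation"
                and self.KS is None):
            raise ValueError("saturating model requires KS")
        # reject parameters that do not belong to the named mechanism
        if not needs_frag and self.kminus is not None:
            raise ValueError(f"kminus is not a parameter of {self.name}")
        if self.name != "secondary_nucleation" and self.k2 is not None:
            raise ValueError(f"k2 is not a parameter of {self.name}")
        if (self.name != "saturating_elongation_fragmentation"
                and self.KS is not None):
            raise ValueError(f"KS is not a parameter of {self.name}")


@dataclass
class GlobalFitResult:
    model: KineticModel
    fitted_params: dict            # name -> (value, standard error)
    mre: float                     # mean squared residual over all points
    per_curve_residuals: list[np.ndarray]
    converged: bool = True

    def __post_init__(self) -> None:
        if self.mre < 0:
            raise ValueError("mre must be >= 0")


def _rhs(model: KineticModel, m0: float):
    kn, kplus, nc = model.kn, model.kplus, model.nc
    kminus = model.kminus or 0.0
    k2 = model.k2 or 0.0
    n2 = model.n2 or 2
    KS = model.KS
    frag = model.name in ("fragmentation",
                          "saturating_elongation_fragmentation")
    secondary = model.name == "secondary_nucleation"
    saturating = model.name == "saturating_elongation_fragmentation"

    def rhs(t, y):
        P, M = y
        m = m0 - M
        if m < 0.0:
            m = 0.0
        dP = kn * m ** nc
        if frag:
            dP += kminus * M
        if secondary:
            dP += k2 * m ** n2 * M
        dM = 2.0 * kplus * m * P
        if saturating:
            dM /= 1.0 + m / KS
        return (dP, dM)

    return rhs


def simulate_model(model: KineticModel, m0: float, times,
                   rtol: float = 1e-8, dense: bool = False):
    """Integrate the moment equations; return M(t)/m0 on ``times``.

    With ``dense=True`` also returns the solver object (dense output) for
    root finding on the mass curve.
    """
    times = np.asarray(times, dtype=float)
    if m0 <= 0:
        raise ValueError("m0 must be positive")
    if times.size < 2 or not np.all(np.diff(times) > 0) or times[0] < 0:
        raise ValueError("times must increase from >= 0")
    sol = solve_ivp(_rhs(model, m0), (times[0], times[-1]), (0.0, 0.0),
                    method="LSODA", t_eval=times, rtol=rtol,
                    atol=rtol * m0 * 1e-4, dense_output=dense)
    if not sol.success:  # pragma: no cover - LSODA handles these systems
        raise RuntimeError(f"integration failed: {sol.message}")
    frac = np.clip(sol.y[1] / m0, 0.0, 1.0)
    if dense:
        return frac, sol
    return frac


def model_halftime(model: KineticModel, m0: float, t_max: float,
                   rtol: float = 1e-8) -> float:
    """Time at which M(t)/m0 crosses 0.5, via dense output + bisection."""
    grid = np.linspace(0.0, t_max, 200)
    frac, sol = simulate_model(model, m0, grid, rtol=rtol, dense=True)
    if frac[-1] < 0.5:
        raise ValueError("mass fraction does not reach 0.5 by t_max; "
                         "increase t_max")
    i = int(np.nonzero(frac >= 0.5)[0][0])
    lo = grid[max(i - 1, 0)]
    hi = grid[i]
    if lo == hi:
        return float(hi)
    f = lambda t: sol.sol(t)[1] / m0 - 0.5
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def halftime_scaling_exponent(model: KineticModel, m0_values,
                              t_max: float = 2000.0) -> tuple[float, float]:
    """Slope (and r^2) of log10 t05 vs log10 m0 from forward simulations."""
    m0_values = np.asarray(m0_values, dtype=float)
    t05 = np.array([model_halftime(model, m0, t_max) for m0 in m0_values])
    from scipy import stats
    reg = stats.linregress(np.log10(m0_values), np.log10(t05))
    return float(reg.slope), float(reg.rvalue ** 2)


# ---------------------------------------------------------------------------
# global fitting
# ---------------------------------------------------------------------------

def _model_from_log(name: str, logx: np.ndarray, nc: int,
                    n2: int) -> KineticModel:
    vals = dict(zip(_FREE_PARAMS[name], 10.0 ** np.asarray(logx)))
    kwargs = dict(name=name, nc=nc, **vals)
    if name == "secondary_nucleation":
        kwargs["n2"] = n2
    return KineticModel(**kwargs)


def global_fit(model_name: str, curves, nc: int = 2, n2: int = 2,
               n_starts: int = 20, seed: int = 0,
               rtol: float = 1e-6) -> GlobalFitResult:
    """Fit one shared parameter set to curves at several concentrations.

    ``curves`` is a list of ``(m0, times, mass_fraction)`` triples with the
    mass fraction normalized to a final plateau of 1.  Optimization is
    multi-start local least squares in log10 parameter space: one
    data-driven start plus ``n_starts - 1`` draws log-uniform over six
    decades, with a fixed RNG seed.
    """
    if model_name not in MODEL_NAMES:
        raise ValueError(f"unknown model {model_name!r}")
    curves = [(float(m0), np.asarray(t, float), np.asarray(y, float))
              for m0, t, y in curves]
    if len(curves) < 3:
        raise ValueError("global fitting needs >= 3 concentrations")
    if all(np.ptp(y) < 1e-12 for _, _, y in curves):
        free = _FREE_PARAMS[model_name]
        return GlobalFitResult(
            model=_model_from_log(model_name, np.zeros(len(free)), nc, n2),
            fitted_params={p: (float("nan"), float("nan")) for p in free},
            mre=float("nan"),
            per_curve_residuals=[np.zeros_like(y) for _, _, y in curves],
            converged=False)

    free = _FREE_PARAMS[model_name]
    n_points = sum(y.size for _, _, y in curves)

    def residuals(logx):
        if np.any(np.abs(logx) > 12):
            return np.full(n_points, 1e3)
        try:
            model = _model_from_log(model_name, logx, nc, n2)
            parts = [simulate_model(model, m0, t, rtol=rtol) - y
                     for m0, t, y in curves]
            return np.concatenate(parts)
        except (RuntimeError, OverflowError, FloatingPointError):
            return np.full(n_points, 1e3)

    # heuristic start: pick rates so the mid-concentration half-time lands
    # near the middle of its observed time window
    mid_m0, mid_t, _ = curves[len(curves) // 2]
    t_scale = max(float(mid_t[-1]) / 2.0, 1e-6)
    start0 = []
    for p in free:
        if p == "kn":
            start0.append(np.log10(0.1 / (t_scale * mid_m0 ** nc)))
        elif p == "kplus":
            start0.append(np.log10(10.0 / (t_scale * mid_m0)))
        elif p in ("kminus", "k2"):
            start0.append(np.log10(0.1 / t_scale))
        elif p == "KS":
            start0.append(np.log10(mid_m0))
    start0 = np.asarray(start0)

    rng = np.random.default_rng(seed)
    starts = [start0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(start0 + rng.uniform(-3.0, 3.0, size=len(free)))

    best = None
    for x0 in starts:
        try:
            res = optimize.least_squares(residuals, x0, method="lm",
                                         xtol=1e-12, ftol=1e-12,
                                         max_nfev=400 * len(free))
        except Exception:  # pragma: no cover - LM rarely raises
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:  # pragma: no cover
        raise RuntimeError("all optimization starts failed")

    model = _model_from_log(model_name, best.x, nc, n2)
    resid = residuals(best.x)
    mre = float(np.mean(resid ** 2))
    # parameter SEs in log10 space, propagated to linear scale
    try:
        jtj_inv = np.linalg.pinv(best.jac.T @ best.jac)
        dof = max(n_points - len(free), 1)
        s2 = float(np.sum(resid ** 2)) / dof
        log_se = np.sqrt(np.clip(np.diag(jtj_inv) * s2, 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        log_se = np.full(len(free), float("nan"))
    fitted = {}
    for i, p in enumerate(free):
        val = 10.0 ** best.x[i]
        fitted[p] = (float(val), float(val * np.log(10.0) * log_se[i]))

    per_curve = []
    off = 0
    for _, _, y in curves:
        per_curve.append(resid[off:off + y.size])
        off += y.size
    return GlobalFitResult(model=model, fitted_params=fitted, mre=mre,
                           per_curve_residuals=per_curve,
                           converged=bool(best.success))


def select_model(results: list[GlobalFitResult]) -> str:
    """Return the mechanism with the lowest mean residual error."""
    if not results:
        raise ValueError("no fit results to select from")
    mres = [r.mre for r in results]
    order = np.argsort(mres)
    if len(results) > 1 and mres[order[0]] == mres[order[1]]:
        tied = sorted(results[i].model.name for i in order[:2])
        raise ValueError("tie in mean residual error between "
                         f"{tied[0]} and {tied[1]}; report both")
    return results[int(order[0])].model.name
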