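"""Per-curve estimation of Vcmax and Jmax from A/Ci measurements.

Each curve is fitted at its own leaf temperature: the estimated Vcmax and
Jmax are rates *at that temperature*, with the measured dark respiration
held fixed as an input.  The default method is nonlinear least squares of
observed A against the FvCB model; when it fails to converge a bilinear
fallback linearizes the two limitation branches.  A four-criterion quality
screen then decides whether the curve enters downstream analyses: a curve
is excluded when at least two of (1) max Ci < 700 ppm, (2) no plateau at
high Ci, (3) RMSE > 6 umol m-2 s-1, (4) bilinear method used, are true.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .fvcb import FvCBParams, KineticParams, assimilation_curve, kinetic_constants_at

__all__ = [
    "GasExchangePoint",
    "ACiCurve",
    "ACiFitResult",
    "QCReport",
    "FitOptions",
    "UnfittableCurveError",
    "MissingStepError",
    "fit_aci",
    "bilinear_fit",
    "qc_evaluate",
    "extract_anet",
]


class UnfittableCurveError(ValueError):
    """Raised when a curve cannot support a two-parameter FvCB fit."""


class MissingStepError(KeyError):
    """Raised when a required CO2 step is absent from a curve."""


@dataclass(frozen=True)
class GasExchangePoint:
    """One gas-exchange observation within an A/Ci curve."""

    Ca: float  # ambient CO2, umol/mol
    Ci: float  # intercellular CO2, umol/mol
    A: float  # net assimilation, umol m-2 s-1
    gs: float = float("nan")  # stomatal conductance to water, mol m-2 s-1
    Tleaf: float = float("nan")  # degC
    D: float = float("nan")  # vapor pressure deficit, kPa
    PAR: float = 1500.0  # umol m-2 s-1

    def __post_init__(self) -> None:
        if self.Ca < 0 or self.Ci < 0:
            raise ValueError("Ca and Ci must be non-negative")


@dataclass(frozen=True)
class ACiCurve:
    """An A/Ci response for one tussock at one target leaf temperature.

    Point order is preserved as measured: the CO2 step sequence starts and
    ends at 400 ppm, and the *final* 400-ppm step is the one used for
    steady-state Anet extraction.  ``Rd_measured`` is the dark respiration
    measured after the curve, stored as a positive magnitude.
    """

    curve_id: str
    ecotype: str
    garden: str
    treatment: str
    tleaf_target: float
    points: tuple[GasExchangePoint, ...]
    Rd_measured: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "points", tuple(self.points))

    @property
    def ci(self) -> np.ndarray:
        return np.array([p.Ci for p in self.points])

    @property
    def a(self) -> np.ndarray:
        return np.array([p.A for p in self.points])

    @property
    def tleaf_mean(self) -> float:
        t = np.array([p.Tleaf for p in self.points])
        return float(np.nanmean(t)) if np.any(np.isfinite(t)) else self.tleaf_target

    @property
    def fittable(self) -> bool:
        return len(self.points) >= 5 and np.ptp(self.ci) > 1e-9


@dataclass(frozen=True)
class ACiFitResult:
    """Estimated Vcmax and Jmax (at the curve's Tleaf) with diagnostics."""

    Vcmax: float
    Jmax: float
    Vcmax_se: float
    Jmax_se: float
    rmse: float
    method: str  # "default" | "bilinear"
    converged: bool
    residuals: np.ndarray
    tleaf: float


@dataclass(frozen=True)
class QCReport:
    """Two-of-four exclusion verdict for a fitted curve."""

    c1_max_ci_below_700: bool
    c2_no_plateau: bool
    c3_rmse_above_6: bool
    c4_bilinear: bool

    @property
    def n_criteria(self) -> int:
        return int(self.c1_max_ci_below_700) + int(self.c2_no_plateau) + \
            int(self.c3_rmse_above_6) + int(self.c4_bilinear)

    @property
    def excluded(self) -> bool:
        return self.n_criteria >= 2


@dataclass(frozen=True)
class FitOptions:
    """Tunable fitting and QC thresholds."""

    ci_cutoff: float = 700.0  # QC criterion 1, umol/mol
    rmse_cutoff: float = 6.0  # QC criterion 3, umol m-2 s-1
    plateau_slope: float = 0.005  # umol m-2 s-1 per umol/mol, QC criterion 2
    plateau_points: int = 3
    bound_upper: float = 1000.0
    alpha: float = 0.24
    theta: float = 0.85
    saturating_light: bool = False
    ca_tolerance: float = 5.0  # matching window for the 400-ppm step


def _model_params(vcmax: float, jmax: float, curve: ACiCurve,
                  opts: FitOptions, par: float) -> FvCBParams:
    # EaV = EaJ = 0: the fitted rates are at the curve's own temperature.
    return FvCBParams(
        Vcmax25=vcmax, Jmax25=jmax, EaV=0.0, EaJ=0.0, Rd=curve.Rd_measured,
        alpha=opts.alpha, theta=opts.theta, PAR=par,
        saturating_light=opts.saturating_light,
    )


def _predict(curve: ACiCurve, vcmax: float, jmax: float,
             ctx: KineticParams, opts: FitOptions) -> np.ndarray:
    par = float(np.nanmedian([p.PAR for p in curve.points]))
    p = _model_params(vcmax, jmax, curve, opts, par)
    return assimilation_curve(curve.ci, curve.tleaf_target, p, ctx)


def bilinear_fit(curve: ACiCurve, ctx: KineticParams | None = None,
                 opts: FitOptions | None = None) -> tuple[float, float]:
    """Branch-wise linearized estimate of (Vcmax, Jmax at Tleaf).

    Gross assimilation A + Rd is regressed through the origin on
    x1 = (Ci - Gstar)/(Ci + Km) over candidate Rubisco-limited low-Ci
    subsets and on x2 = (Ci - Gstar)/(4 Ci + 8 Gstar) over the remaining
    high-Ci points; the Ci-rank split minimizing total SSE wins.  The x2
    slope estimates J, which is inverted through the light response to
    Jmax.  When one branch is empty its parameter is taken from the other
    branch's slope (Jmax = 2 Vcmax as a field-typical prior ratio).
    """
    ctx = ctx or KineticParams()
    opts = opts or FitOptions()
    kin = kinetic_constants_at(curve.tleaf_target, ctx)
    gstar, km = kin["Gstar"], kin["Km"]
    order = np.argsort(curve.ci, kind="stable")
    ci = curve.ci[order]
    gross = (curve.a + curve.Rd_measured)[order]
    x1 = (ci - gstar) / (ci + km)
    x2 = (ci - gstar) / (4.0 * ci + 8.0 * gstar)
    n = len(ci)

    def slope_through_origin(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        denom = float(x @ x)
        if denom <= 0:
            return 0.0, float(y @ y)
        s = float(x @ y) / denom
        r = y - s * x
        return s, float(r @ r)

    best: tuple[float, float, float] | None = None  # (sse, vcmax, j)
    for split in range(2, n + 1):  # at least two points on the Rubisco branch
        v, sse1 = slope_through_origin(x1[:split], gross[:split])
        if split < n:
            j, sse2 = slope_through_origin(x2[split:], gross[split:])
        else:
            j, sse2 = float("nan"), 0.0
        sse = sse1 + sse2
        if best is None or sse < best[0]:
            best = (sse, v, j)
    assert best is not None
    _, vcmax, j = best
    vcmax = max(vcmax, 1e-6)
    if not np.isfinite(j) or j <= 0:
        jmax = 2.0 * vcmax
    elif opts.saturating_light:
        jmax = j
    else:
        par = float(np.nanmedian([p.PAR for p in curve.points]))
        i2 = opts.alpha * par
        # invert theta J^2 - (i2 + Jmax) J + i2 Jmax = 0 for Jmax given J
        jmax = j * (opts.theta * j - i2) / (j - i2) if abs(j - i2) > 1e-9 else j
        if jmax <= 0 or not np.isfinite(jmax):
            jmax = j
    return float(vcmax), float(min(jmax, opts.bound_upper))


def _fit_default(curve: ACiCurve, ctx: KineticParams, opts: FitOptions,
                 p0: tuple[float, float]) -> tuple[np.ndarray, np.ndarray, bool]:
    def resid(theta: np.ndarray) -> np.ndarray:
        return _predict(curve, theta[0], theta[1], ctx, opts) - curve.a

    sol = optimize.least_squares(
        resid, x0=np.clip(p0, 1e-3, opts.bound_upper),
        bounds=([1e-6, 1e-6], [opts.bound_upper, opts.bound_upper]),
        xtol=1e-12, ftol=1e-12, gtol=1e-12,
    )
    # asymptotic covariance from the Jacobian at the solution
    dof = max(len(curve.points) - 2, 1)
    s2 = float(sol.fun @ sol.fun) / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
        identifiable = np.all(np.isfinite(se)) and np.linalg.cond(jtj) < 1e8
    except np.linalg.LinAlgError:
        se = np.full(2, np.nan)
        identifiable = False
    converged = bool(sol.success) and identifiable and \
        not np.any(np.isclose(sol.x, opts.bound_upper, rtol=1e-3))
    return sol.x, se, converged


def fit_aci(curve: ACiCurve, ctx: KineticParams | None = None,
            opts: FitOptions | None = None) -> tuple[ACiFitResult, QCReport]:
    """Fit one A/Ci curve and evaluate its quality screen.

    The nonlinear fit is initialized from the bilinear estimates; if it
    does not converge (solver failure, an unidentifiable parameter, or a
    boundary solution) the bilinear estimates themselves are reported and
    the method is recorded as ``bilinear`` — which also trips QC
    criterion 4.
    """
    ctx = ctx or KineticParams()
    opts = opts or FitOptions()
    if not curve.fittable:
        raise UnfittableCurveError(
            f"curve {curve.curve_id}: needs >= 5 points spanning a Ci range"
        )
    p0 = bilinear_fit(curve, ctx, opts)
    try:
        x, se, converged = _fit_default(curve, ctx, opts, p0)
    except Exception:
        x, se, converged = np.array(p0), np.full(2, np.nan), False

    if converged:
        method = "default"
        vcmax, jmax = float(x[0]), float(x[1])
        vse, jse = float(se[0]), float(se[1])
    else:
        method = "bilinear"
        vcmax, jmax = p0
        vse, jse = float("nan"), float("nan")
        if vcmax <= 0 or jmax <= 0:
            raise UnfittableCurveError(
                f"curve {curve.curve_id}: both fit methods failed "
                f"(bilinear gave Vcmax={vcmax:.3g}, Jmax={jmax:.3g})"
            )
    resid = _predict(curve, vcmax, jmax, ctx, opts) - curve.a
    rmse = float(np.sqrt(np.mean(resid**2)))
    fit = ACiFitResult(
        Vcmax=vcmax, Jmax=jmax, Vcmax_se=vse, Jmax_se=jse, rmse=rmse,
        method=method, converged=converged, residuals=resid,
        tleaf=curve.tleaf_target,
    )
    return fit, qc_evaluate(curve, fit, opts)


def qc_evaluate(curve: ACiCurve, fit: ACiFitResult,
                opts: FitOptions | None = None) -> QCReport:
    """Apply the four-criterion screen; excluded iff two or more are met.

    The plateau criterion is operationalized as the OLS slope of A on Ci
    over the ``plateau_points`` highest-Ci points: a slope above
    ``plateau_slope`` means assimilation was still rising, i.e. no
    plateau.
    """
    opts = opts or FitOptions()
    ci = curve.ci
    c1 = bool(np.max(ci) < opts.ci_cutoff)
    k = min(opts.plateau_points, len(ci))
    top = np.argsort(ci, kind="stable")[-k:]
    slope = float(np.polyfit(ci[top], curve.a[top], 1)[0]) if k >= 2 else 0.0
    c2 = slope > opts.plateau_slope
    c3 = fit.rmse > opts.rmse_cutoff
    c4 = fit.method == "bilinear"
    return QCReport(c1, c2, c3, c4)


def extract_anet(curve: ACiCurve,
                 opts: FitOptions | None = None) -> dict[str, float]:
    """Steady-state values at the final 400-ppm CO2 step.

    Returns the last point whose Ca is within the matching tolerance of
    400 ppm; with the standard step sequence this is the second of the
    two 400-ppm steps that follow the low-CO2 ramp.
    """
    opts = opts or FitOptions()
    matches = [p for p in curve.points if abs(p.Ca - 400.0) <= opts.ca_tolerance]
    if not matches:
        raise MissingStepError(
            f"curve {curve.curve_id}: no point at Ca = 400 +/- "
            f"{opts.ca_tolerance} umol/mol"
        )
    p = matches[-1]
    return {"Anet": p.A, "gs": p.gs, "D": p.D}
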