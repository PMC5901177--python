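"""Group-level temperature responses of photosynthetic capacity and respiration.

Vcmax and Jmax estimated per curve at 15, 20 and 25 degC are pooled per
ecotype x treatment x garden cell and modelled with a non-peaked Arrhenius
function

    f(Tk) = k25 exp[ Ea (Tk - Tref) / (Tref R Tk) ]

whose parameters are the rate at 25 degC (k25) and the activation energy
(Ea).  Over a 10-degC span below the thermal optimum the peaked form is
not identifiable, so deactivation is deliberately omitted.  Dark
respiration is modelled per cell as Rd = a exp(b Tleaf), and its
temperature sensitivity summarized as Q10 = exp(10 b).  Fit summaries
(model SE, adjusted R2, regression F and p) follow the conventions of
standard nonlinear-regression software so the output tables read like the
field's parameter tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .fvcb import KineticParams

__all__ = [
    "ArrheniusFit",
    "RespFit",
    "RegressionResult",
    "fit_arrhenius_group",
    "fit_rd_exponential",
    "q10_from_b",
    "jmax_vcmax_ratio_analysis",
]


class UnidentifiableFitError(ValueError):
    """Raised when the data cannot separate the model's parameters."""


@dataclass(frozen=True)
class ArrheniusFit:
    """Arrhenius parameters for one design cell.

    ``k25``/``k25_se`` in the rate's own units; ``Ea``/``Ea_se`` in kJ/mol
    at this reporting surface (J/mol are used internally).
    """

    k25: float
    k25_se: float
    Ea: float
    Ea_se: float
    model_se: float
    r2_adj: float
    F: float
    p: float
    n: int
    single_temperature: bool
    _cov: np.ndarray  # (k25, Ea[J/mol]) covariance, for confidence bands
    Tref: float = 298.15
    Rgas: float = 8.314

    def predict(self, tleaf_c: np.ndarray) -> np.ndarray:
        tk = np.asarray(tleaf_c, dtype=float) + 273.15
        ea_j = self.Ea * 1000.0
        return self.k25 * np.exp(
            ea_j * (tk - self.Tref) / (self.Tref * self.Rgas * tk))

    def confidence_band(self, tleaf_c: np.ndarray,
                        level: float = 0.95) -> pd.DataFrame:
        """Pointwise delta-method confidence band over a temperature grid."""
        tleaf_c = np.asarray(tleaf_c, dtype=float)
        tk = tleaf_c + 273.15
        ea_j = self.Ea * 1000.0
        x = (tk - self.Tref) / (self.Tref * self.Rgas * tk)
        f = self.k25 * np.exp(ea_j * x)
        grad = np.stack([f / max(self.k25, 1e-300), f * x])  # d/dk25, d/dEa
        var = np.einsum("ij,ik,kj->j", grad, self._cov, grad)
        dof = max(self.n - 2, 1)
        t = stats.t.ppf(0.5 + level / 2.0, dof)
        half = t * np.sqrt(np.clip(var, 0.0, None))
        return pd.DataFrame(
            {"tleaf": tleaf_c, "fit": f, "lower": f - half, "upper": f + half})


@dataclass(frozen=True)
class RespFit:
    """Exponential respiration fit Rd = a exp(b Tleaf) with its Q10."""

    a: float
    a_se: float
    b: float
    b_se: float
    Q10: float
    model_se: float
    r2_adj: float
    F: float
    p: float
    n: int

    def predict(self, tleaf_c: np.ndarray) -> np.ndarray:
        return self.a * np.exp(self.b * np.asarray(tleaf_c, dtype=float))


@dataclass(frozen=True)
class RegressionResult:
    """Ordinary least-squares line with standard errors."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    r2_adj: float
    n: int


def _fit_summary(y: np.ndarray, resid: np.ndarray,
                 n_params: int) -> tuple[float, float, float, float]:
    """(model_se, r2_adj, F, p) for a nonlinear least-squares fit.

    F compares the regression against the mean-only model with
    (n_params - 1, n - n_params) degrees of freedom, the convention of
    nonlinear-regression reports.
    """
    n = len(y)
    sse = float(resid @ resid)
    sst = float(np.sum((y - y.mean()) ** 2))
    dof = max(n - n_params, 1)
    model_se = np.sqrt(sse / dof)
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / dof
    df1 = max(n_params - 1, 1)
    if sse <= 0:
        return model_se, r2_adj, float("inf"), 0.0
    F = ((sst - sse) / df1) / (sse / dof)
    p = float(stats.f.sf(F, df1, dof)) if np.isfinite(F) else 0.0
    return model_se, r2_adj, float(F), p


def fit_arrhenius_group(points: list[tuple[float, float]],
                        ctx: KineticParams | None = None) -> ArrheniusFit:
    """Fit (k25, Ea) by nonlinear least squares to (Tleaf degC, rate) pairs.

    Requires at least three points with positive rates.  With all points
    at a single temperature Ea is unidentifiable and an error is raised;
    fewer than three distinct temperatures is allowed but flagged on the
    result.
    """
    ctx = ctx or KineticParams()
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need at least three (Tleaf, value) points")
    t_c, y = pts[:, 0], pts[:, 1]
    if np.any(y <= 0):
        raise ValueError("rates must be positive for an Arrhenius fit")
    n_temps = len(np.unique(np.round(t_c, 6)))
    if n_temps < 2:
        raise UnidentifiableFitError(
            "all observations at one temperature: Ea is unidentifiable")
    tk = t_c + 273.15
    x = (tk - ctx.Tref) / (ctx.Tref * ctx.Rgas * tk)

    def model(xv: np.ndarray, k25: float, ea: float) -> np.ndarray:
        return k25 * np.exp(ea * xv)

    # log-linear start: log y = log k25 + Ea x
    beta = np.polyfit(x, np.log(y), 1)
    p0 = [float(np.exp(beta[1])), float(beta[0])]
    popt, pcov = optimize.curve_fit(
        model, x, y, p0=p0, maxfev=20000,
        bounds=([1e-9, -1e7], [1e6, 1e7]))
    resid = model(x, *popt) - y
    model_se, r2_adj, F, p = _fit_summary(y, resid, 2)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return ArrheniusFit(
        k25=float(popt[0]), k25_se=float(se[0]),
        Ea=float(popt[1]) / 1000.0, Ea_se=float(se[1]) / 1000.0,
        model_se=model_se, r2_adj=r2_adj, F=F, p=p, n=len(y),
        single_temperature=n_temps < 3, _cov=pcov,
        Tref=ctx.Tref, Rgas=ctx.Rgas)


def q10_from_b(b: float) -> float:
    """Temperature sensitivity over a 10-degC interval: Q10 = exp(10 b)."""
    if not np.isfinite(b):
        raise ValueError("b must be finite")
    return float(np.exp(10.0 * b))


def fit_rd_exponential(points: list[tuple[float, float]]) -> RespFit:
    """Fit Rd = a exp(b Tleaf) to (Tleaf degC, Rd) pairs.

    Rd values must be positive magnitudes; the log-linear regression that
    seeds the nonlinear solver is impossible otherwise.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 3:
        raise ValueError("need at least three (Tleaf, Rd) points")
    t_c, y = pts[:, 0], pts[:, 1]
    if np.any(y <= 0):
        raise ValueError("Rd must be positive (stored as magnitudes)")

    def model(t: np.ndarray, a: float, b: float) -> np.ndarray:
        return a * np.exp(b * t)

    beta = np.polyfit(t_c, np.log(y), 1)
    p0 = [float(np.exp(beta[1])), float(beta[0])]
    popt, pcov = optimize.curve_fit(model, t_c, y, p0=p0, maxfev=20000)
    resid = model(t_c, *popt) - y
    model_se, r2_adj, F, p = _fit_summary(y, resid, 2)
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return RespFit(
        a=float(popt[0]), a_se=float(se[0]),
        b=float(popt[1]), b_se=float(se[1]),
        Q10=q10_from_b(float(popt[1])),
        model_se=model_se, r2_adj=r2_adj, F=F, p=p, n=len(y))


def jmax_vcmax_ratio_analysis(
    pairs: pd.DataFrame,
) -> dict[str, object]:
    """Jmax25:Vcmax25 ratio per tussock, its design ANOVA, and the pooled line.

    ``pairs`` needs columns vcmax25, jmax25, ecotype, garden, treatment
    (one row per tussock).  The ratio is analysed with a three-way ANOVA
    over garden x ecotype x treatment; the pooled relationship is an OLS
    regression of Jmax25 on Vcmax25 across all tussocks.
    """
    import statsmodels.api as sm

    from .stats import factorial_anova

    required = {"vcmax25", "jmax25", "ecotype", "garden", "treatment"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if len(pairs) < 3:
        raise ValueError("need at least three tussocks for the pooled regression")
    df = pairs.copy()
    df["ratio"] = df["jmax25"] / df["vcmax25"]

    anova = factorial_anova(
        df, response="ratio", factors=["garden", "ecotype", "treatment"])

    X = sm.add_constant(df["vcmax25"].to_numpy())
    fit = sm.OLS(df["jmax25"].to_numpy(), X).fit()
    reg = RegressionResult(
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        r2_adj=float(fit.rsquared_adj), n=int(fit.nobs))
    return {"ratios": df[["ratio"]].assign(**{
        c: df[c] for c in ("ecotype", "garden", "treatment")}),
        "anova": anova, "regression": reg}
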