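"""Design-based statistics: factorial ANOVAs, outlier screening, gs-D lines.

The experiment is a factorial design (ecotype x treatment within garden,
plus garden itself for pooled analyses), analysed with fixed-effect
ANOVAs.  Responses that violate normality are power-transformed before
analysis (reciprocal, inverse-square or inverse-square-root, as recorded
per analysis), and the transform used is carried through to the output so
means are never silently back-transformed.  Type II sums of squares are
used because quality-control exclusions leave the design mildly
unbalanced; for balanced data Type II coincides with Type I/III for the
terms tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from .thermal import RegressionResult

__all__ = [
    "LeafTraits",
    "AnovaTable",
    "DegenerateDesignError",
    "TRANSFORMS",
    "factorial_anova",
    "remove_outliers",
    "gs_vpd_regression",
    "narea_from_traits",
]


class DegenerateDesignError(ValueError):
    """Raised when empty design cells make a model term inestimable."""


#: Named response transforms used before ANOVA.
TRANSFORMS = {
    "none": lambda y: y,
    "inv": lambda y: 1.0 / y,
    "inv_sq": lambda y: y ** -2.0,
    "inv_sqrt": lambda y: y ** -0.5,
}


@dataclass(frozen=True)
class LeafTraits:
    """Leaf morphology and nitrogen for one tussock."""

    tussock_id: str
    ecotype: str
    garden: str
    treatment: str
    SLA: float  # specific leaf area, cm2/g
    percentN: float  # leaf nitrogen, % of dry mass

    def __post_init__(self) -> None:
        if self.SLA <= 0:
            raise ValueError("SLA must be positive")
        if not 0.0 <= self.percentN <= 100.0:
            raise ValueError("percentN must lie in [0, 100]")

    @property
    def Narea(self) -> float:
        """Leaf nitrogen per unit area, g N/m2."""
        return narea_from_traits(self.SLA, self.percentN)


def narea_from_traits(sla_cm2_per_g: float, percent_n: float) -> float:
    """Narea (g N/m2) from SLA (cm2/g) and %N: (N fraction)/(SLA in m2/g)."""
    sla_m2_per_g = sla_cm2_per_g / 1e4
    return (percent_n / 100.0) / sla_m2_per_g


@dataclass(frozen=True)
class AnovaTable:
    """Per-term ANOVA results with the transform that produced them."""

    table: pd.DataFrame  # index: term; columns: df, sum_sq, F, p
    transform: str
    ss_type: int

    def term(self, name: str) -> pd.Series:
        return self.table.loc[name]


def factorial_anova(data: pd.DataFrame, response: str, factors: list[str],
                    transform: str = "none", ss_type: int = 2) -> AnovaTable:
    """Full-factorial fixed-effects ANOVA of ``response`` on ``factors``.

    The transform is applied to the response before fitting.  Every cell
    of the full cross must be occupied; an empty cell is reported by name
    rather than silently dropping the interaction.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    for f in factors:
        if data[f].nunique() < 2:
            raise DegenerateDesignError(f"factor {f!r} has fewer than 2 levels")
    counts = data.groupby(factors, observed=True).size()
    full = pd.MultiIndex.from_product(
        [sorted(data[f].unique()) for f in factors], names=factors)
    missing = full.difference(counts.index)
    if len(missing) > 0:
        raise DegenerateDesignError(
            f"empty design cell(s): {list(missing[:5])}")
    df = data.copy()
    df["_y"] = TRANSFORMS[transform](df[response].astype(float))
    rhs = " * ".join(f"C({f})" for f in factors)
    model = smf.ols(f"_y ~ {rhs}", data=df).fit()
    if model.df_resid < 1:
        raise DegenerateDesignError("no residual degrees of freedom")
    raw = anova_lm(model, typ=ss_type)
    table = raw.rename(columns={"sum_sq": "sum_sq", "PR(>F)": "p"})
    table = table[["df", "sum_sq", "F", "p"]]
    # human-readable term labels: C(ecotype) -> ecotype, ':' -> ' x '
    def clean(term: str) -> str:
        return term.replace("C(", "").replace(")", "").replace(":", " x ")
    table.index = [clean(t) for t in table.index]
    return AnovaTable(table=table, transform=transform, ss_type=ss_type)


def remove_outliers(values, k: float = 2.0) -> tuple[list[float], list[float]]:
    """Single-pass screen: drop values more than ``k`` SD from the mean.

    Mean and (sample) SD are those of the full input; the screen is not
    re-applied to the survivors.  Returns (kept, removed) in input order.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        return [], []
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    mask = np.abs(arr - mean) <= k * sd
    return list(arr[mask]), list(arr[~mask])


def gs_vpd_regression(records: pd.DataFrame | list[tuple[float, float]],
                      ) -> RegressionResult:
    """OLS of stomatal conductance on vapor pressure deficit.

    ``records`` is a DataFrame with columns gs and D, or (gs, D) pairs.
    A negative slope indicates stomatal closure as the air dries.
    """
    if isinstance(records, pd.DataFrame):
        gs = records["gs"].to_numpy(dtype=float)
        d = records["D"].to_numpy(dtype=float)
    else:
        arr = np.asarray(records, dtype=float)
        gs, d = arr[:, 0], arr[:, 1]
    if len(gs) < 3:
        raise ValueError("need at least three (gs, D) pairs")
    if np.ptp(d) <= 0:
        raise DegenerateDesignError("D is constant: regression is singular")
    X = sm.add_constant(d)
    fit = sm.OLS(gs, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]), slope_se=float(fit.bse[1]),
        intercept=float(fit.params[0]), intercept_se=float(fit.bse[0]),
        r2_adj=float(fit.rsquared_adj), n=int(fit.nobs))
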