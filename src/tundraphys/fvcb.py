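"""Farquhar–von Caemmerer–Berry (FvCB) leaf biochemistry core.

Net CO2 assimilation of a C3 leaf is modelled as the minimum of a
Rubisco-limited rate and an RuBP-regeneration (electron-transport) limited
rate, minus mitochondrial respiration:

    Ac = Vcmax (Ci - Gstar) / (Ci + Km)
    Aj = J (Ci - Gstar) / (4 Ci + 8 Gstar)
    A  = min(Ac, Aj) - Rd

Kinetic constants (Kc, Ko, Gstar) follow the Bernacchi in-vivo
parameterization and are scaled with leaf temperature by a non-peaked
Arrhenius function.  The same Arrhenius form scales Vcmax and Jmax.  TPU
limitation is deliberately not modelled: over the 15-25 degC measurement
range used here only the two classic limitations are identifiable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "FvCBParams",
    "arrhenius_scale",
    "kinetic_constants_at",
    "net_assimilation",
    "assimilation_curve",
    "electron_transport_rate",
]

R_GAS = 8.314  # J mol-1 K-1


@dataclass(frozen=True)
class KineticParams:
    """Rubisco kinetic constants at the reference temperature.

    Defaults are the Bernacchi in-vivo values widely used for C3 A/Ci
    fitting.  Concentrations are mole fractions: Kc and Gstar in umol/mol,
    Ko and O in mmol/mol (so O/Ko is dimensionless).  Activation energies
    in J/mol.
    """

    Kc25: float = 404.9
    EaKc: float = 79430.0
    Ko25: float = 278.4
    EaKo: float = 36380.0
    Gstar25: float = 42.75
    EaGstar: float = 37830.0
    O: float = 210.0
    Tref: float = 298.15  # K; base rates are indexed at 25 degC exactly
    Rgas: float = R_GAS

    def __post_init__(self) -> None:
        for name in ("Kc25", "Ko25", "Gstar25", "O"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (293.0 <= self.Tref <= 303.0):
            raise ValueError("Tref must lie in [293, 303] K")


@dataclass(frozen=True)
class FvCBParams:
    """Leaf-level FvCB parameters.

    Vcmax25 / Jmax25 are the maximum carboxylation and electron-transport
    rates at 25 degC (umol m-2 s-1); EaV / EaJ their activation energies
    (J/mol).  Rd is dark respiration, supplied as a positive magnitude and
    never fitted.  alpha (apparent quantum yield, mol e- per mol photons)
    and theta (curvature) shape the non-rectangular hyperbola of the light
    response; with ``saturating_light`` the hyperbola is bypassed and
    J = Jmax(T).
    """

    Vcmax25: float
    Jmax25: float
    EaV: float = 0.0
    EaJ: float = 0.0
    Rd: float = 0.0
    alpha: float = 0.24
    theta: float = 0.85
    PAR: float = 1500.0
    saturating_light: bool = False

    def __post_init__(self) -> None:
        if self.Vcmax25 < 0 or self.Jmax25 < 0 or self.Rd < 0:
            raise ValueError("Vcmax25, Jmax25 and Rd must be non-negative")
        if not 0.0 < self.theta < 1.0:
            raise ValueError("theta must lie in (0, 1)")
        if not 0.0 < self.alpha < 0.5:
            raise ValueError("alpha must lie in (0, 0.5)")


def arrhenius_scale(
    k25: float, Ea: float, Tk: float, ctx: KineticParams | None = None
) -> float:
    """Scale a rate from the reference temperature to ``Tk`` (Kelvin).

    f(Tk) = k25 * exp[ Ea (Tk - Tref) / (Tref R Tk) ]

    Exactly ``k25`` at Tk = Tref, strictly increasing in Tk for Ea > 0.
    """
    ctx = ctx or KineticParams()
    if np.any(np.asarray(Tk) <= 0):
        raise ValueError("absolute temperature Tk must be positive")
    if np.any(np.asarray(k25) < 0):
        raise ValueError("k25 must be non-negative")
    return k25 * np.exp(Ea * (Tk - ctx.Tref) / (ctx.Tref * ctx.Rgas * Tk))


def kinetic_constants_at(
    Tleaf: float, ctx: KineticParams | None = None
) -> dict[str, float]:
    """Kinetic constants at a leaf temperature in degC.

    Returns Kc, Gstar and Km in umol/mol and Ko in mmol/mol, with
    Km = Kc (1 + O/Ko) the effective Michaelis constant under O2
    competition.
    """
    ctx = ctx or KineticParams()
    if not -10.0 <= Tleaf <= 50.0:
        raise ValueError("Tleaf outside the supported -10..50 degC range")
    Tk = Tleaf + 273.15
    Kc = arrhenius_scale(ctx.Kc25, ctx.EaKc, Tk, ctx)
    Ko = arrhenius_scale(ctx.Ko25, ctx.EaKo, Tk, ctx)
    Gstar = arrhenius_scale(ctx.Gstar25, ctx.EaGstar, Tk, ctx)
    Km = Kc * (1.0 + ctx.O / Ko)
    return {"Kc": Kc, "Ko": Ko, "Gstar": Gstar, "Km": Km}


def electron_transport_rate(p: FvCBParams, jmax_t: float) -> float:
    """Potential electron transport rate J at the leaf's irradiance.

    Smaller root of the non-rectangular hyperbola
    theta J^2 - (alpha PAR + Jmax) J + alpha PAR Jmax = 0,
    or J = Jmax when saturating light is assumed.
    """
    if p.saturating_light:
        return jmax_t
    i2 = p.alpha * p.PAR
    b = i2 + jmax_t
    disc = b * b - 4.0 * p.theta * i2 * jmax_t
    return (b - math.sqrt(max(disc, 0.0))) / (2.0 * p.theta)


def net_assimilation(
    Ci: float, Tleaf: float, p: FvCBParams, ctx: KineticParams | None = None
) -> dict[str, object]:
    """Net assimilation at one intercellular CO2 concentration.

    Returns ``{"A": umol m-2 s-1, "limitation": "rubisco" | "rubp"}``.
    Below the compensation point Gstar, gross assimilation is zero and
    A = -Rd (Rubisco branch by convention); ties also go to Rubisco.
    """
    ctx = ctx or KineticParams()
    if Ci < 0:
        raise ValueError("Ci must be non-negative")
    kin = kinetic_constants_at(Tleaf, ctx)
    Tk = Tleaf + 273.15
    vcmax_t = arrhenius_scale(p.Vcmax25, p.EaV, Tk, ctx)
    jmax_t = arrhenius_scale(p.Jmax25, p.EaJ, Tk, ctx)
    gstar = kin["Gstar"]
    if Ci <= gstar:
        return {"A": -p.Rd, "limitation": "rubisco"}
    ac = vcmax_t * (Ci - gstar) / (Ci + kin["Km"])
    j = electron_transport_rate(p, jmax_t)
    aj = j * (Ci - gstar) / (4.0 * Ci + 8.0 * gstar)
    if ac <= aj:
        return {"A": ac - p.Rd, "limitation": "rubisco"}
    return {"A": aj - p.Rd, "limitation": "rubp"}


def assimilation_curve(
    Ci: np.ndarray,
    Tleaf: float,
    p: FvCBParams,
    ctx: KineticParams | None = None,
) -> np.ndarray:
    """Vectorized net assimilation over an array of Ci values.

    Same model as :func:`net_assimilation` without the limitation labels;
    used by the curve fitter and the synthetic-curve generator.
    """
    ctx = ctx or KineticParams()
    Ci = np.asarray(Ci, dtype=float)
    if np.any(Ci < 0):
        raise ValueError("Ci must be non-negative")
    kin = kinetic_constants_at(Tleaf, ctx)
    Tk = Tleaf + 273.15
    vcmax_t = arrhenius_scale(p.Vcmax25, p.EaV, Tk, ctx)
    jmax_t = arrhenius_scale(p.Jmax25, p.EaJ, Tk, ctx)
    gstar = kin["Gstar"]
    j = electron_transport_rate(p, jmax_t)
    with np.errstate(divide="ignore", invalid="ignore"):
        ac = vcmax_t * (Ci - gstar) / (Ci + kin["Km"])
        aj = j * (Ci - gstar) / (4.0 * Ci + 8.0 * gstar)
    gross = np.minimum(ac, aj)
    gross = np.where(Ci <= gstar, 0.0, gross)
    return gross - p.Rd
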