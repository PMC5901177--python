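"""Synthetic gas-exchange, trait and microclimate data with known truth.

Emulates a reciprocal-transplant warming experiment on tussock sedges:
three source ecotypes (CF, TL, SAG) x two treatments (ambient, OTC) x two
common gardens (TL, SAG), five tussocks per cell, each measured with an
A/Ci curve and a dark-respiration reading at leaf temperatures of 15, 20
and 25 degC over the instrument's stepped CO2 sequence.  Every generated
quantity derives from an explicit per-cell truth (Vcmax25, Jmax25,
activation energies, respiration coefficients), so parameter-recovery and
round-trip tests can compare pipeline output against the generating
values.

Physical consistency is enforced by construction: intercellular CO2 is
not sampled but solved from the supply-demand balance A = gc (Ca - Ci)
with a fixed per-curve CO2 transfer conductance, so (Ca, Ci, A) triplets
always lie on both the biochemical demand curve and the diffusive supply
line.  Randomness is split per entity by stable hashing of identifiers:
adding a tussock never reshuffles the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize

from .aci import ACiCurve, GasExchangePoint
from .fvcb import FvCBParams, KineticParams, assimilation_curve

__all__ = [
    "CA_SEQUENCE",
    "CellTruth",
    "SyntheticTruth",
    "GardenConfig",
    "default_truth",
    "default_garden_configs",
    "generate_aci_curve",
    "generate_garden_dataset",
    "generate_met_series",
]

#: instrument CO2 step sequence (ppm): start/end checks at 400, a downward
#: ramp, a return to 400, then an upward ramp
CA_SEQUENCE = (400, 400, 300, 200, 100, 50, 400, 400, 600, 800, 1000, 1200)

ECOTYPES = ("CF", "TL", "SAG")
TREATMENTS = ("ambient", "OTC")
GARDENS = ("TL", "SAG")


@dataclass(frozen=True)
class CellTruth:
    """Generating parameters for one ecotype x treatment x garden cell."""

    vcmax25: float  # umol m-2 s-1
    ea_v: float  # J/mol
    jmax25: float
    ea_j: float
    rd25: float  # umol m-2 s-1, positive magnitude
    rd_b: float  # per degC; Q10 = exp(10 b)

    @property
    def rd_a(self) -> float:
        """Pre-exponential of Rd = a exp(b T), anchored at rd25."""
        return self.rd25 * np.exp(-self.rd_b * 25.0)

    def rd_at(self, tleaf: float) -> float:
        return self.rd_a * np.exp(self.rd_b * tleaf)


@dataclass(frozen=True)
class SyntheticTruth:
    """Full generating configuration for the gas-exchange side of the study."""

    seed: int
    cells: dict[tuple[str, str, str], CellTruth]  # (garden, ecotype, treatment)
    tussocks_per_cell: int = 5
    leaf_temperatures: tuple[float, ...] = (15.0, 20.0, 25.0)
    sigma_A: float = 0.5  # additive noise on assimilation, umol m-2 s-1
    sigma_rd: float = 0.10  # fractional noise on measured Rd
    tussock_cv: float = 0.10  # between-tussock CV on Vcmax25
    ratio_sd: float = 0.05  # tussock Jmax25 scatter about the cell ratio
    gs_lines: dict[str, tuple[float, float]] = field(default_factory=lambda: {
        # gs (mmol m-2 s-1) = intercept + slope * D (kPa), per ecotype
        "CF": (-60.67, 232.0),
        "TL": (-62.97, 267.0),
        "SAG": (-40.48, 194.0),
    })
    gs_noise_sd: float = 55.0  # mmol m-2 s-1
    d_means: dict[float, float] = field(default_factory=lambda: {
        15.0: 1.00, 20.0: 1.30, 25.0: 1.89})  # cuvette VPD by Tleaf, kPa
    d_sd: float = 0.08
    gsc: float = 0.15  # CO2 transfer conductance of the supply line, mol m-2 s-1
    gsc_temp_slope: float = 0.002  # mild decline per degC above 15
    par: float = 1500.0
    # leaf traits per (garden, ecotype, treatment): (SLA cm2/g, Narea g/m2)
    trait_means: dict[tuple[str, str, str], tuple[float, float]] = field(
        default_factory=dict)
    sla_sd: float = 7.0
    percent_n_sd: float = 0.15

    def cell(self, garden: str, ecotype: str, treatment: str) -> CellTruth:
        return self.cells[(garden, ecotype, treatment)]


# Cell-level truth follows the magnitudes typical of Arctic sedges in
# warming gardens: Vcmax25 of 53-77 umol m-2 s-1 with activation energies
# of 42-57 kJ/mol, Jmax25 at 2.09 x Vcmax25, and respiration Q10 of
# 1.2-1.7 around Rd25 ~ 1.2 umol m-2 s-1.
_VCMAX25 = {
    ("TL", "CF", "ambient"): (60.8, 56.8), ("TL", "CF", "OTC"): (63.1, 57.3),
    ("TL", "TL", "ambient"): (68.9, 49.6), ("TL", "TL", "OTC"): (76.5, 52.1),
    ("TL", "SAG", "ambient"): (55.0, 42.7), ("TL", "SAG", "OTC"): (76.5, 54.9),
    ("SAG", "CF", "ambient"): (53.5, 51.3), ("SAG", "CF", "OTC"): (56.1, 54.0),
    ("SAG", "TL", "ambient"): (74.7, 50.2), ("SAG", "TL", "OTC"): (56.6, 42.4),
    ("SAG", "SAG", "ambient"): (69.4, 51.0), ("SAG", "SAG", "OTC"): (64.2, 50.5),
}
_Q10 = {
    ("TL", "CF", "ambient"): 1.58, ("TL", "CF", "OTC"): 1.23,
    ("TL", "TL", "ambient"): 1.42, ("TL", "TL", "OTC"): 1.45,
    ("TL", "SAG", "ambient"): 1.42, ("TL", "SAG", "OTC"): 1.46,
    ("SAG", "CF", "ambient"): 1.26, ("SAG", "CF", "OTC"): 1.70,
    ("SAG", "TL", "ambient"): 1.34, ("SAG", "TL", "OTC"): 1.63,
    ("SAG", "SAG", "ambient"): 1.32, ("SAG", "SAG", "OTC"): 1.52,
}
_SLA_NAREA = {
    ("TL", "CF", "ambient"): (100.37, 1.90), ("TL", "CF", "OTC"): (97.19, 1.88),
    ("TL", "TL", "ambient"): (95.74, 1.88), ("TL", "TL", "OTC"): (99.39, 1.81),
    ("TL", "SAG", "ambient"): (91.85, 1.74), ("TL", "SAG", "OTC"): (96.80, 1.72),
    ("SAG", "CF", "ambient"): (103.96, 1.59), ("SAG", "CF", "OTC"): (96.44, 1.66),
    ("SAG", "TL", "ambient"): (96.28, 1.88), ("SAG", "TL", "OTC"): (94.00, 1.72),
    ("SAG", "SAG", "ambient"): (91.71, 1.87), ("SAG", "SAG", "OTC"): (93.81, 1.64),
}

JMAX_VCMAX_SLOPE = 2.09  # pooled Jmax25 : Vcmax25 relationship
EA_JMAX = 43000.0  # J/mol; electron transport is less temperature-sensitive


def default_truth(seed: int = 0, **overrides) -> SyntheticTruth:
    """The study-design truth: 12 cells with realistic Arctic-sedge values."""
    cells = {}
    for key, (v25, ea_kj) in _VCMAX25.items():
        cells[key] = CellTruth(
            vcmax25=v25, ea_v=ea_kj * 1000.0,
            jmax25=JMAX_VCMAX_SLOPE * v25, ea_j=EA_JMAX,
            rd25=1.2, rd_b=np.log(_Q10[key]) / 10.0)
    return SyntheticTruth(seed=seed, cells=cells, trait_means=dict(_SLA_NAREA),
                          **overrides)


def _entity_rng(base_seed: int, entity: str) -> np.random.Generator:
    """Independent stream per entity: stable across dataset composition."""
    return np.random.default_rng(
        np.random.SeedSequence([int(base_seed), zlib.crc32(entity.encode())]))


def _solve_ci(ca: float, gsc: float, tleaf: float, p: FvCBParams,
              ctx: KineticParams) -> float:
    """Intersect the demand curve A(Ci) with the supply line gc (Ca - Ci).

    The mismatch f(Ci) = A(Ci) - gc (Ca - Ci) is strictly increasing, so
    the intersection is unique; Ci may exceed Ca when the leaf respires
    more than it assimilates.
    """
    def f(ci: float) -> float:
        a = float(assimilation_curve(np.array([ci]), tleaf, p, ctx)[0])
        return a - gsc * (ca - ci)

    lo, hi = 1e-9, ca + 5000.0
    if f(lo) >= 0:
        raise ValueError(f"no supply-demand intersection for Ca={ca}")
    return float(optimize.brentq(f, lo, hi, xtol=1e-10))


def generate_aci_curve(
    truth: SyntheticTruth,
    garden: str, ecotype: str, treatment: str,
    tussock: int, tleaf: float,
    vcmax25: float | None = None, jmax25: float | None = None,
    ca_sequence: tuple[float, ...] = CA_SEQUENCE,
    ctx: KineticParams | None = None,
) -> ACiCurve:
    """One synthetic A/Ci curve with its dark-respiration reading.

    Tussock-level Vcmax25/Jmax25 may be passed explicitly (as
    :func:`generate_garden_dataset` does); otherwise the cell means are
    used.  Reproducible per curve: the stream is keyed by (seed, curve id).
    """
    ctx = ctx or KineticParams()
    cell = truth.cell(garden, ecotype, treatment)
    v25 = cell.vcmax25 if vcmax25 is None else vcmax25
    j25 = cell.jmax25 if jmax25 is None else jmax25
    curve_id = f"{garden}-{ecotype}-{treatment}-t{tussock}-T{tleaf:g}"
    rng = _entity_rng(truth.seed, curve_id)
    rd_true = cell.rd_at(tleaf)
    p = FvCBParams(Vcmax25=v25, Jmax25=j25, EaV=cell.ea_v, EaJ=cell.ea_j,
                   Rd=rd_true, PAR=truth.par)
    gsc = max(truth.gsc - truth.gsc_temp_slope * (tleaf - 15.0), 0.02)
    slope, intercept = truth.gs_lines[ecotype]
    points = []
    for ca in ca_sequence:
        ci = _solve_ci(float(ca), gsc, tleaf, p, ctx)
        a_clean = float(assimilation_curve(np.array([ci]), tleaf, p, ctx)[0])
        a_obs = a_clean + rng.normal(0.0, truth.sigma_A) if truth.sigma_A > 0 \
            else a_clean
        d = max(truth.d_means.get(tleaf, 1.3) + rng.normal(0.0, truth.d_sd), 0.05)
        gs_mmol = intercept + slope * d + rng.normal(0.0, truth.gs_noise_sd)
        gs = max(gs_mmol, 20.0) / 1000.0  # mol m-2 s-1, floored at 20 mmol
        points.append(GasExchangePoint(
            Ca=float(ca), Ci=ci, A=a_obs, gs=gs, Tleaf=tleaf, D=d,
            PAR=truth.par))
    rd_meas = rd_true * (1.0 + rng.normal(0.0, truth.sigma_rd)) \
        if truth.sigma_rd > 0 else rd_true
    rd_meas = max(rd_meas, 0.01)
    return ACiCurve(
        curve_id=curve_id, ecotype=ecotype, garden=garden,
        treatment=treatment, tleaf_target=tleaf, points=tuple(points),
        Rd_measured=rd_meas)


def _tussock_params(truth: SyntheticTruth, garden: str, ecotype: str,
                    treatment: str, tussock: int) -> tuple[float, float]:
    """Tussock-level (Vcmax25, Jmax25) around the cell means.

    Jmax25 scatters about the cell's Jmax:Vcmax ratio so the pooled
    regression across tussocks recovers that ratio as its slope.
    """
    cell = truth.cell(garden, ecotype, treatment)
    rng = _entity_rng(truth.seed, f"tussock-{garden}-{ecotype}-{treatment}-{tussock}")
    v25 = cell.vcmax25 * max(1.0 + rng.normal(0.0, truth.tussock_cv), 0.3)
    ratio = cell.jmax25 / cell.vcmax25
    j25 = v25 * ratio * max(1.0 + rng.normal(0.0, truth.ratio_sd), 0.3)
    return v25, j25


def generate_garden_dataset(
    truth: SyntheticTruth, garden: str,
    include_qc_fixtures: bool = False,
    ctx: KineticParams | None = None,
) -> dict[str, object]:
    """All synthetic inputs for one garden.

    Returns ``curves`` (30 tussocks x 3 leaf temperatures = 90 A/Ci
    curves with the default design), ``traits`` (per-tussock SLA / %N /
    Narea), and ``truth_table`` (the per-tussock generating parameters,
    for recovery tests).  With ``include_qc_fixtures``, four deliberately
    degenerate extra curves exercise each quality-control criterion:
    a truncated-Ci curve, a non-plateauing curve, a high-noise curve and
    a low-CO2-only curve that forces the bilinear method.
    """
    ctx = ctx or KineticParams()
    curves: list[ACiCurve] = []
    trait_rows = []
    truth_rows = []
    for ecotype in ECOTYPES:
        for treatment in TREATMENTS:
            cell = truth.cell(garden, ecotype, treatment)
            sla_mu, narea_mu = truth.trait_means.get(
                (garden, ecotype, treatment), (96.0, 1.8))
            for tussock in range(1, truth.tussocks_per_cell + 1):
                v25, j25 = _tussock_params(truth, garden, ecotype, treatment,
                                           tussock)
                for tleaf in truth.leaf_temperatures:
                    curves.append(generate_aci_curve(
                        truth, garden, ecotype, treatment, tussock, tleaf,
                        vcmax25=v25, jmax25=j25, ctx=ctx))
                trng = _entity_rng(
                    truth.seed, f"trait-{garden}-{ecotype}-{treatment}-{tussock}")
                sla = max(sla_mu + trng.normal(0.0, truth.sla_sd), 40.0)
                # %N chosen so Narea = %N/100 / (SLA/1e4) centres on its target
                pn_mu = narea_mu * sla_mu / 100.0
                pn = float(np.clip(pn_mu + trng.normal(0.0, truth.percent_n_sd),
                                   0.3, 6.0))
                tid = f"{garden}-{ecotype}-{treatment}-t{tussock}"
                trait_rows.append({
                    "tussock_id": tid, "garden": garden, "ecotype": ecotype,
                    "treatment": treatment, "sla": sla, "percent_n": pn,
                    "narea": (pn / 100.0) / (sla / 1e4)})
                truth_rows.append({
                    "tussock_id": tid, "garden": garden, "ecotype": ecotype,
                    "treatment": treatment, "vcmax25": v25, "jmax25": j25,
                    "ea_v": cell.ea_v, "ea_j": cell.ea_j,
                    "rd25": cell.rd25, "rd_b": cell.rd_b})
    if include_qc_fixtures:
        curves.extend(_qc_fixture_curves(truth, garden, ctx))
    return {
        "curves": curves,
        "traits": pd.DataFrame(trait_rows),
        "truth_table": pd.DataFrame(truth_rows),
    }


def _qc_fixture_curves(truth: SyntheticTruth, garden: str,
                       ctx: KineticParams) -> list[ACiCurve]:
    """Degenerate curves that each trip a known quality-control criterion."""
    fixtures = []
    base = dict(garden=garden, ecotype="CF", treatment="ambient", tleaf=25.0)
    # truncated: CO2 ramp stops at 600 ppm -> max Ci < 700
    c = generate_aci_curve(truth, tussock=901, ca_sequence=(400, 400, 300, 200, 100, 50, 400, 400, 600), **base)
    fixtures.append(replace(c, curve_id=c.curve_id + "-qc-trunc"))
    # non-plateau: electron transport so high the curve stays Rubisco-limited
    c = generate_aci_curve(truth, tussock=902, jmax25=6.0 * truth.cell(garden, "CF", "ambient").vcmax25, **base)
    fixtures.append(replace(c, curve_id=c.curve_id + "-qc-noplateau"))
    # high noise: alternating +/-8 deviations that no smooth A/Ci model can
    # absorb, so the fitted RMSE exceeds 6 by construction
    clean = replace(truth, sigma_A=0.0)
    c = generate_aci_curve(clean, tussock=903, **base)
    bumped = tuple(
        replace(p, A=p.A + (8.0 if i % 2 == 0 else -8.0))
        for i, p in enumerate(c.points))
    fixtures.append(replace(c, curve_id=c.curve_id + "-qc-noisy",
                            points=bumped))
    # low-CO2 only (max Ca 300), fully noise-free (including Rd) so the
    # Jmax likelihood is exactly flat over the Rubisco-limited points ->
    # bilinear fallback
    exact = replace(truth, sigma_A=0.0, sigma_rd=0.0)
    c = generate_aci_curve(exact, tussock=904, ca_sequence=(300, 300, 250, 200, 150, 100, 50), **base)
    fixtures.append(replace(c, curve_id=c.curve_id + "-qc-lowco2"))
    return fixtures


@dataclass(frozen=True)
class GardenConfig:
    """Microclimate generating configuration for one garden.

    Monthly ambient means and OTC warming offsets set the treatment
    contrast; the OTC PAR attenuation (fraction removed above the bright
    threshold) sets the chamber-shading signal.
    """

    garden: str
    monthly_tair: dict[int, float]  # ambient monthly mean, degC
    otc_offset: dict[int, float]  # OTC - ambient, degC (>= 0)
    par_attenuation: dict[int, float]  # fraction of bright-hour PAR removed
    diurnal_amplitude: float = 4.0  # degC, half peak-to-trough
    noise_sd: float = 1.5  # AR(1) innovation SD, degC
    ar1: float = 0.8
    par_max: float = 1400.0  # clear-sky midday PAR, umol m-2 s-1
    sensors_per_treatment: int = 2
    start: str = "2016-06-01"
    end: str = "2016-08-31"

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.otc_offset.values()):
            raise ValueError("OTC offsets must be non-negative")


def default_garden_configs() -> dict[str, GardenConfig]:
    """Warming contrasts of 1.0-1.9 degC at TL and 0.3-0.8 degC at SAG."""
    return {
        "TL": GardenConfig(
            garden="TL",
            monthly_tair={6: 9.2, 7: 12.1, 8: 8.6},
            otc_offset={6: 1.8, 7: 1.9, 8: 1.0},
            par_attenuation={6: 0.25, 7: 0.16, 8: 0.09}),
        "SAG": GardenConfig(
            garden="SAG",
            monthly_tair={6: 9.9, 7: 12.8, 8: 8.7},
            otc_offset={6: 0.8, 7: 0.6, 8: 0.3},
            par_attenuation={6: 0.10, 7: 0.08, 8: 0.05}),
    }


def generate_met_series(config: GardenConfig, seed: int,
                        ) -> dict[str, pd.DataFrame]:
    """Hourly Tair and PAR series per treatment and sensor.

    Tair is a monthly baseline plus a diurnal sinusoid plus AR(1) noise
    shared within a treatment, with small independent sensor noise; the
    OTC series adds the monthly warming offset.  PAR follows a clear-sky
    half-sinusoid with multiplicative weather noise; the OTC series is
    attenuated by the configured monthly fraction.  Returns ``tair`` and
    ``par`` DataFrames with columns timestamp, value, garden, treatment,
    sensor.
    """
    idx = pd.date_range(config.start, pd.Timestamp(config.end) +
                        pd.Timedelta(hours=23), freq="h")
    hours = idx.hour.to_numpy()
    months = idx.month.to_numpy()
    n = len(idx)
    rng = _entity_rng(seed, f"met-{config.garden}")
    base = np.array([config.monthly_tair.get(m, 8.0) for m in months])
    diurnal = config.diurnal_amplitude * np.sin(2 * np.pi * (hours - 9) / 24.0)
    # one shared weather realization; treatments differ by offset only
    if config.noise_sd > 0:
        innov = rng.normal(0.0, config.noise_sd, size=n)
        weather = np.empty(n)
        weather[0] = innov[0]
        for i in range(1, n):
            weather[i] = config.ar1 * weather[i - 1] + innov[i]
    else:
        weather = np.zeros(n)
    offset = np.array([config.otc_offset.get(m, 0.0) for m in months])
    tair_rows = []
    par_rows = []
    sunlight = np.clip(np.sin(np.pi * (hours - 4) / 16.0), 0.0, None)
    cloud = np.clip(1.0 - np.abs(rng.normal(0.0, 0.25, size=n)), 0.05, 1.0) \
        if config.noise_sd > 0 else np.ones(n)
    atten = np.array([config.par_attenuation.get(m, 0.0) for m in months])
    for treatment in TREATMENTS:
        t_base = base + diurnal + weather + (offset if treatment == "OTC" else 0.0)
        par_base = config.par_max * sunlight * cloud
        if treatment == "OTC":
            par_base = par_base * (1.0 - atten)
        for sensor in range(1, config.sensors_per_treatment + 1):
            srng = _entity_rng(seed, f"met-{config.garden}-{treatment}-{sensor}")
            s_noise = srng.normal(0.0, 0.1, size=n) if config.noise_sd > 0 else 0.0
            tair_rows.append(pd.DataFrame({
                "timestamp": idx, "value": t_base + s_noise,
                "garden": config.garden, "treatment": treatment,
                "sensor": f"{treatment}-{sensor}"}))
        par_rows.append(pd.DataFrame({
            "timestamp": idx, "value": par_base,
            "garden": config.garden, "treatment": treatment,
            "sensor": f"{treatment}-par"}))
    return {"tair": pd.concat(tair_rows, ignore_index=True),
            "par": pd.concat(par_rows, ignore_index=True)}
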