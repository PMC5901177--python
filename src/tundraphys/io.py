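"""CSV interchange, pipeline configuration and the end-to-end driver.

All interchange is plain CSV (instrument exports are tabular).  The
gas-exchange dialect is long-format: one row per observation with the
curve's metadata repeated, grouped by ``curve_id`` with measurement order
preserved (or restored from an explicit ``step`` column).  Temperatures
are degC at every interface; Kelvin appears only inside the Arrhenius
math.  ``run_pipeline`` executes the full analysis in a fixed stage
order and writes one CSV per output surface plus a JSON manifest with
the config hash, seed and exclusion counts, so identical (config, seed,
inputs) yield byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import met as met_mod
from . import synth
from .aci import (ACiCurve, FitOptions, GasExchangePoint, extract_anet,
                  fit_aci)
from .fvcb import KineticParams
from .stats import DegenerateDesignError, factorial_anova, gs_vpd_regression, remove_outliers
from .thermal import fit_arrhenius_group, fit_rd_exponential, jmax_vcmax_ratio_analysis

__all__ = [
    "PipelineConfig",
    "SchemaError",
    "IntegrityError",
    "read_gasexchange_csv",
    "write_gasexchange_csv",
    "read_met_csv",
    "run_pipeline",
]

log = logging.getLogger("tundraphys")

GASEX_COLUMNS = ["curve_id", "ecotype", "garden", "treatment", "tleaf_target",
                 "ca", "ci", "a", "gs", "d", "par", "rd"]


class SchemaError(ValueError):
    """A required column is missing or a value is out of range."""


class IntegrityError(ValueError):
    """Rows within one curve disagree on the curve's metadata."""


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs, serializable to YAML losslessly."""

    outdir: str = "results"
    curves_csv: str | None = None  # None -> simulate from the default truth
    traits_csv: str | None = None
    met_csv: str | None = None
    seed: int = 0
    # kinetic-constant overrides (field name -> value), applied to defaults
    kinetics: dict = field(default_factory=dict)
    # QC / fit thresholds
    ci_cutoff: float = 700.0
    rmse_cutoff: float = 6.0
    plateau_slope: float = 0.005
    # response transforms per analysis surface
    transforms: dict = field(default_factory=lambda: {
        "sla": {"TL": "inv", "SAG": "inv_sq"},
        "narea": {"TL": "none", "SAG": "none"},
        "anet": {"CF": "none", "TL": "inv_sqrt", "SAG": "none"},
    })
    # Narea outlier screening (>k SD), applied per listed garden
    narea_outlier_gardens: list = field(default_factory=lambda: ["SAG"])
    narea_outlier_k: float = 2.0
    # curve ids excluded by hand (e.g. anomalous measurement conditions)
    blacklist: list = field(default_factory=list)
    include_qc_fixtures: bool = False

    def __post_init__(self) -> None:
        if min(self.ci_cutoff, self.rmse_cutoff, self.plateau_slope) <= 0:
            raise ValueError("thresholds must be positive")

    def kinetic_params(self) -> KineticParams:
        return KineticParams(**self.kinetics)

    def fit_options(self) -> FitOptions:
        return FitOptions(ci_cutoff=self.ci_cutoff,
                          rmse_cutoff=self.rmse_cutoff,
                          plateau_slope=self.plateau_slope)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                             sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise SchemaError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def content_hash(self) -> str:
        """Hash of the analysis configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def write_gasexchange_csv(curves: list[ACiCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for step, p in enumerate(c.points, start=1):
            rows.append({
                "curve_id": c.curve_id, "ecotype": c.ecotype,
                "garden": c.garden, "treatment": c.treatment,
                "tleaf_target": c.tleaf_target, "step": step,
                "ca": p.Ca, "ci": p.Ci, "a": p.A, "gs": p.gs, "d": p.D,
                "par": p.PAR, "rd": c.Rd_measured})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_gasexchange_csv(path: str | Path) -> list[ACiCurve]:
    """Parse the long-format gas-exchange dialect into curves.

    Row order within a curve is preserved; if a ``step`` column is present
    and rows arrive shuffled they are restored by it (with a warning).
    Malformed rows are reported with their line numbers.
    """
    df = pd.read_csv(path)
    missing = [c for c in GASEX_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    bad = df.index[(df["ca"] < 0) | (df["ci"] < 0) | (df["gs"] < 0) |
                   (df["d"] < 0) | (df["rd"] < 0)].tolist()
    if bad:
        lines = [i + 2 for i in bad[:10]]  # +2: header + 1-based
        raise SchemaError(f"{path}: negative values on line(s) {lines}")
    curves = []
    for cid, g in df.groupby("curve_id", sort=False):
        meta = g[["ecotype", "garden", "treatment", "tleaf_target", "rd"]]
        if (meta.nunique() > 1).any():
            cols = meta.columns[(meta.nunique() > 1)].tolist()
            raise IntegrityError(f"curve {cid}: inconsistent metadata {cols}")
        if "step" in g.columns and not g["step"].is_monotonic_increasing:
            warnings.warn(f"curve {cid}: rows out of order; sorted by step")
            g = g.sort_values("step", kind="stable")
        first = g.iloc[0]
        pts = tuple(GasExchangePoint(Ca=r.ca, Ci=r.ci, A=r.a, gs=r.gs,
                                     Tleaf=first.tleaf_target, D=r.d,
                                     PAR=r.par)
                    for r in g.itertuples())
        curves.append(ACiCurve(
            curve_id=str(cid), ecotype=first.ecotype, garden=first.garden,
            treatment=first.treatment, tleaf_target=float(first.tleaf_target),
            points=pts, Rd_measured=float(first.rd)))
    return curves


def read_met_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    missing = [c for c in ("timestamp", "value", "garden", "treatment", "sensor")
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    return df


def _anova_rows(table, garden: str, response: str) -> list[dict]:
    rows = []
    for term, r in table.table.iterrows():
        rows.append({"garden": garden, "response": response, "term": term,
                     "df": r["df"], "sum_sq": r["sum_sq"], "F": r["F"],
                     "p": r["p"], "transform": table.transform})
    return rows


def run_pipeline(config: PipelineConfig) -> dict[str, object]:
    """Execute the full analysis and write its output tables.

    Stages, in order: load or simulate inputs; per-curve FvCB fits with
    quality control; blacklist filter; per-cell Arrhenius fits of Vcmax
    and Jmax; per-cell exponential Rd fits with Q10; Jmax:Vcmax ratio
    analysis; trait ANOVAs with outlier screening; Anet ANOVAs at the
    stronger-warming garden; gs-D regressions per ecotype; met summaries.
    Returns the result tables keyed by name and writes them under
    ``config.outdir`` together with ``manifest.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = config.kinetic_params()
    opts = config.fit_options()
    results: dict[str, object] = {}

    # --- stage: inputs ---------------------------------------------------
    if config.curves_csv:
        curves = read_gasexchange_csv(config.curves_csv)
        traits = pd.read_csv(config.traits_csv) if config.traits_csv else None
        met_df = read_met_csv(config.met_csv) if config.met_csv else None
        par_df = None
    else:
        truth = synth.default_truth(seed=config.seed)
        curves, trait_frames = [], []
        for garden in synth.GARDENS:
            ds = synth.generate_garden_dataset(
                truth, garden, include_qc_fixtures=config.include_qc_fixtures,
                ctx=ctx)
            curves.extend(ds["curves"])
            trait_frames.append(ds["traits"])
        traits = pd.concat(trait_frames, ignore_index=True)
        met_parts = {g: synth.generate_met_series(cfg, config.seed)
                     for g, cfg in synth.default_garden_configs().items()}
        met_df = pd.concat([m["tair"] for m in met_parts.values()],
                           ignore_index=True)
        par_df = pd.concat([m["par"] for m in met_parts.values()],
                           ignore_index=True)
    log.info("loaded %d curves", len(curves))

    # --- stage: per-curve fits + QC --------------------------------------
    fit_rows = []
    anet_rows = []
    n_unfittable = 0
    for curve in curves:
        try:
            fit, qc = fit_aci(curve, ctx, opts)
        except Exception as exc:
            n_unfittable += 1
            log.warning("curve %s unfittable: %s", curve.curve_id, exc)
            continue
        fit_rows.append({
            "curve_id": curve.curve_id, "ecotype": curve.ecotype,
            "garden": curve.garden, "treatment": curve.treatment,
            "tleaf": curve.tleaf_target, "vcmax": fit.Vcmax,
            "vcmax_se": fit.Vcmax_se, "jmax": fit.Jmax,
            "jmax_se": fit.Jmax_se, "rmse": fit.rmse, "method": fit.method,
            "rd": curve.Rd_measured,
            "c1": qc.c1_max_ci_below_700, "c2": qc.c2_no_plateau,
            "c3": qc.c3_rmse_above_6, "c4": qc.c4_bilinear,
            "n_criteria": qc.n_criteria, "excluded": qc.excluded,
            "blacklisted": curve.curve_id in config.blacklist})
        try:
            an = extract_anet(curve, opts)
            anet_rows.append({
                "curve_id": curve.curve_id, "ecotype": curve.ecotype,
                "garden": curve.garden, "treatment": curve.treatment,
                "tleaf": curve.tleaf_target, "anet": an["Anet"],
                "gs": an["gs"], "d": an["D"]})
        except KeyError:
            pass
    fits = pd.DataFrame(fit_rows)
    anet = pd.DataFrame(anet_rows)
    results["fits"] = fits
    results["anet"] = anet
    retained = fits[~fits["excluded"] & ~fits["blacklisted"]]
    exclusion_counts = (
        fits[fits["excluded"]].groupby("garden").size().to_dict()
        if len(fits) else {})

    # --- stage: group Arrhenius fits --------------------------------------
    arr_rows = []
    for param in ("vcmax", "jmax"):
        for (garden, ecotype, treatment), g in retained.groupby(
                ["garden", "ecotype", "treatment"]):
            pts = list(zip(g["tleaf"], g[param]))
            try:
                f = fit_arrhenius_group(pts, ctx)
            except (ValueError, RuntimeError) as exc:
                log.warning("arrhenius %s %s/%s/%s failed: %s", param,
                            garden, ecotype, treatment, exc)
                continue
            arr_rows.append({
                "parameter": param, "garden": garden, "ecotype": ecotype,
                "treatment": treatment, "k25": f.k25, "k25_se": f.k25_se,
                "ea_kj": f.Ea, "ea_se_kj": f.Ea_se, "model_se": f.model_se,
                "r2_adj": f.r2_adj, "F": f.F, "p": f.p, "n": f.n})
    results["arrhenius"] = pd.DataFrame(arr_rows)

    # --- stage: respiration fits -----------------------------------------
    rd_rows = []
    for (garden, ecotype, treatment), g in retained.groupby(
            ["garden", "ecotype", "treatment"]):
        pts = list(zip(g["tleaf"], g["rd"]))
        try:
            f = fit_rd_exponential(pts)
        except (ValueError, RuntimeError) as exc:
            log.warning("respiration %s/%s/%s failed: %s", garden, ecotype,
                        treatment, exc)
            continue
        rd_rows.append({
            "garden": garden, "ecotype": ecotype, "treatment": treatment,
            "a": f.a, "a_se": f.a_se, "b": f.b, "b_se": f.b_se,
            "q10": f.Q10, "model_se": f.model_se, "r2_adj": f.r2_adj,
            "F": f.F, "p": f.p, "n": f.n})
    results["respiration"] = pd.DataFrame(rd_rows)

    # --- stage: Jmax:Vcmax ratio ------------------------------------------
    at25 = retained[np.isclose(retained["tleaf"], 25.0)]
    if len(at25) >= 3:
        pairs = at25.rename(columns={"vcmax": "vcmax25", "jmax": "jmax25"})[
            ["vcmax25", "jmax25", "ecotype", "garden", "treatment"]]
        try:
            ratio = jmax_vcmax_ratio_analysis(pairs)
            reg = ratio["regression"]
            results["ratio_regression"] = pd.DataFrame([{
                "slope": reg.slope, "slope_se": reg.slope_se,
                "intercept": reg.intercept, "intercept_se": reg.intercept_se,
                "r2_adj": reg.r2_adj, "n": reg.n}])
            results["ratio_anova"] = ratio["anova"].table.reset_index(
                names="term")
        except (ValueError, DegenerateDesignError) as exc:
            log.warning("ratio analysis skipped: %s", exc)

    # --- stage: trait ANOVAs ----------------------------------------------
    if traits is not None and len(traits):
        anova_rows = []
        for garden, g in traits.groupby("garden"):
            tr = config.transforms.get("sla", {}).get(garden, "none")
            try:
                t = factorial_anova(g, "sla", ["ecotype", "treatment"],
                                    transform=tr)
                anova_rows += _anova_rows(t, garden, "sla")
            except DegenerateDesignError as exc:
                log.warning("SLA ANOVA at %s skipped: %s", garden, exc)
            gn = g.copy()
            if garden in config.narea_outlier_gardens:
                kept, removed = remove_outliers(gn["narea"],
                                                k=config.narea_outlier_k)
                if removed:
                    log.info("Narea outliers removed at %s: %s", garden,
                             removed)
                    gn = gn[~gn["narea"].isin(removed)]
            tr = config.transforms.get("narea", {}).get(garden, "none")
            try:
                t = factorial_anova(gn, "narea", ["ecotype", "treatment"],
                                    transform=tr)
                anova_rows += _anova_rows(t, garden, "narea")
            except DegenerateDesignError as exc:
                log.warning("Narea ANOVA at %s skipped: %s", garden, exc)
        results["trait_anova"] = pd.DataFrame(anova_rows)

    # --- stage: Anet ANOVAs (garden with the stronger warming) ------------
    if len(anet):
        anet_tl = anet[anet["garden"] == "TL"].copy()
        anet_tl["tleaf_f"] = anet_tl["tleaf"].astype(str)
        rows = []
        for ecotype, g in anet_tl.groupby("ecotype"):
            tr = config.transforms.get("anet", {}).get(ecotype, "none")
            try:
                t = factorial_anova(g, "anet", ["treatment", "tleaf_f"],
                                    transform=tr)
                for term, r in t.table.iterrows():
                    rows.append({"ecotype": ecotype, "term": term,
                                 "df": r["df"], "F": r["F"], "p": r["p"],
                                 "transform": t.transform})
            except DegenerateDesignError as exc:
                log.warning("Anet ANOVA for %s skipped: %s", ecotype, exc)
        results["anet_anova"] = pd.DataFrame(rows)

        # --- stage: gs-D regressions per ecotype --------------------------
        gs_rows = []
        for ecotype, g in anet.groupby("ecotype"):
            sub = pd.DataFrame({"gs": g["gs"] * 1000.0, "D": g["d"]})  # mmol
            try:
                r = gs_vpd_regression(sub)
            except (ValueError, DegenerateDesignError) as exc:
                log.warning("gs-D regression for %s skipped: %s", ecotype, exc)
                continue
            gs_rows.append({"ecotype": ecotype, "slope": r.slope,
                            "slope_se": r.slope_se, "intercept": r.intercept,
                            "intercept_se": r.intercept_se,
                            "r2_adj": r.r2_adj, "n": r.n})
        results["gs_vpd"] = pd.DataFrame(gs_rows)

    # --- stage: met summaries ---------------------------------------------
    if met_df is not None and len(met_df):
        met_rows = []
        tdd_rows = []
        for garden, g in met_df.groupby("garden"):
            for s in met_mod.monthly_stats(g):
                met_rows.append({
                    "garden": garden, "month": str(s.month),
                    "tmean_ambient": s.tmean.get("ambient"),
                    "tmean_ambient_se": s.tmean_se.get("ambient"),
                    "tmean_otc": s.tmean.get("OTC"),
                    "tmean_otc_se": s.tmean_se.get("OTC"),
                    "tmin_ambient": s.tmin.get("ambient"),
                    "tmax_ambient": s.tmax.get("ambient"),
                    "difference": s.difference})
            for treatment, gt in g.groupby("treatment"):
                dm = met_mod.daily_means(gt)
                tdd_rows.append({"garden": garden, "treatment": treatment,
                                 "tdd": met_mod.thawing_degree_days(dm)})
        results["met_monthly"] = pd.DataFrame(met_rows)
        results["tdd"] = pd.DataFrame(tdd_rows)
    if par_df is not None and len(par_df):
        par_rows = []
        for garden, g in par_df.groupby("garden"):
            wide = (g.groupby(["treatment", "timestamp"])["value"].mean()
                     .unstack("treatment").sort_index())
            pct = met_mod.par_percent_difference(wide["ambient"], wide["OTC"])
            for month, v in pct.items():
                par_rows.append({"garden": garden, "month": str(month),
                                 "par_pct_difference": v})
        results["par_difference"] = pd.DataFrame(par_rows)

    # --- stage: outputs ----------------------------------------------------
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(outdir / f"{name}.csv", index=False)
    manifest = {
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "n_curves": len(curves),
        "n_fitted": len(fits),
        "n_unfittable": n_unfittable,
        "n_retained": len(retained),
        "exclusions_by_garden": exclusion_counts,
        "n_blacklisted": int(fits["blacklisted"].sum()) if len(fits) else 0,
        "outputs": sorted(n for n, o in results.items()
                          if isinstance(o, pd.DataFrame)),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    results["manifest"] = manifest
    return results
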