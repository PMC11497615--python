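"""End-to-end study pipeline: derive, impute, stratify, fit, pool, report.

Orchestrates the full analysis from one configuration object:

1.  derive per-cycle statistics (mean peak luteal P4, ovulation flag,
    season label) and winsorize haemoglobin across the analytic sample;
2.  multiply impute missing covariates;
3.  z-scale continuous covariates on the full analytic sample (so a
    coefficient means "per SD of the whole sample" in every stratum), then
    fit each model on all cycles and separately on better-season and
    arduous-season cycles;
4.  pool across imputations with Rubin's rules and emit four result tables:
    descriptives by season (table 1), traditional-economy -> haemoglobin
    linear mixed models (table 2), haemoglobin -> ovulation odds ratios
    (table 3), and haemoglobin -> log mean peak luteal P4 restricted to
    ovulatory cycles (table 4).

No multiple-testing correction is applied, matching the analysis design
this pipeline reproduces.
"""

from __future__ import annotations

import logging
import math
import platform
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .cycle_data import Dataset, read_cycle_table, validate_dataset, write_cycle_table
from .ecology import (
    ARDUOUS,
    BETTER,
    DEFAULT_ANAEMIA_CUTOFFS,
    DEFAULT_CALENDAR,
    AnaemiaCutoffs,
    SeasonCalendar,
    assign_season,
    winsorize,
    z_standardize,
)
from .hormone_profiles import classify_ovulation, mean_peak_luteal_p4
from .imputation import (
    DEFAULT_IMPUTABLE,
    DEFAULT_PREDICTORS,
    impute_chained_pmm,
    pool_rubin,
)
from .mixed_models import ModelSpec, fit_lmm_ri, fit_logistic_ri

__all__ = [
    "StudyConfig",
    "DRYAD_REFERENCE_TARGETS",
    "derive_cycle_statistics",
    "build_table1",
    "run_model_suite",
    "run_study",
]

logger = logging.getLogger("alticycle")

#: Published estimates from the original altiplano study whose deposited data
#: (Dryad doi:10.5061/dryad.tqjq2bw7f) this pipeline is designed to analyse.
#: They are accession-gated reference values: reproducing them requires that
#: deposit and the exact stochastic imputation stream, so they are recorded
#: here for users who obtain the data (see docs/dryad_mapping.md), not
#: asserted by the test suite.
DRYAD_REFERENCE_TARGETS = {
    "hb_season_beta": 0.76,          # g/dl, better minus arduous, crude
    "hb_trad_arduous_beta": -0.42,   # g/dl per SD trad-econ, arduous stratum
    "ovulation_or_crude_arduous": 2.59,
    "ovulation_or_adjusted_arduous": 3.27,
    "predicted_hb_arduous": 14.85,   # g/dl
    "predicted_hb_better": 15.61,    # g/dl
    "median_hb": 15.6,               # g/dl
    "hb_cap_lower": 11.8,            # 5th centile, g/dl
    "hb_cap_upper": 17.5,            # 95th centile, g/dl
}


@dataclass
class StudyConfig:
    """One configuration object for the whole analysis."""

    cycles_csv: str | None = None
    samples_csv: str | None = None
    output_dir: str = "results"
    calendar: SeasonCalendar = field(default_factory=lambda: DEFAULT_CALENDAR)
    cutoffs: AnaemiaCutoffs = field(default_factory=lambda: DEFAULT_ANAEMIA_CUTOFFS)
    ovul_threshold: float | None = 100.0  # pmol/l; assumed value, see docs/methods.md
    winsor_lo_pct: float = 5.0
    winsor_hi_pct: float = 95.0
    min_peak_coverage: float = 0.5
    imputation_m: int = 5
    imputation_max_iter: int = 10
    imputation_k_donors: int = 5
    imputation_seed: int = 20240912
    imputable_columns: tuple[str, ...] = DEFAULT_IMPUTABLE
    imputation_predictors: tuple[str, ...] = DEFAULT_PREDICTORS
    scale_within_stratum: bool = False

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "calendar" in raw:
            cal = raw["calendar"]
            raw["calendar"] = SeasonCalendar(
                arduous_ranges=tuple(map(tuple, cal["arduous_ranges"])),
                better_ranges=tuple(map(tuple, cal["better_ranges"])),
                year_length=cal.get("year_length", 366),
            )
        if "cutoffs" in raw:
            raw["cutoffs"] = AnaemiaCutoffs(**raw["cutoffs"])
        for key in ("imputable_columns", "imputation_predictors"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = {
            "cycles_csv": self.cycles_csv,
            "samples_csv": self.samples_csv,
            "output_dir": self.output_dir,
            "calendar": {
                "arduous_ranges": [list(r) for r in self.calendar.arduous_ranges],
                "better_ranges": [list(r) for r in self.calendar.better_ranges],
                "year_length": self.calendar.year_length,
            },
            "cutoffs": {
                "anaemia_threshold": self.cutoffs.anaemia_threshold,
                "mild_lower": self.cutoffs.mild_lower,
                "moderate_lower": self.cutoffs.moderate_lower,
            },
            "ovul_threshold": self.ovul_threshold,
            "winsor_lo_pct": self.winsor_lo_pct,
            "winsor_hi_pct": self.winsor_hi_pct,
            "min_peak_coverage": self.min_peak_coverage,
            "imputation_m": self.imputation_m,
            "imputation_max_iter": self.imputation_max_iter,
            "imputation_k_donors": self.imputation_k_donors,
            "imputation_seed": self.imputation_seed,
            "imputable_columns": list(self.imputable_columns),
            "imputation_predictors": list(self.imputation_predictors),
            "scale_within_stratum": self.scale_within_stratum,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Derivation
# ---------------------------------------------------------------------------

def derive_cycle_statistics(ds: Dataset, cfg: StudyConfig) -> Dataset:
    """Fill mpl_p4, ovulatory and season for every cycle; winsorize haemoglobin.

    Haemoglobin capping is done across the whole analytic sample and every
    capped value is logged.  The input dataset is not mutated.
    """
    out = ds.copy()
    for rec in out.records:
        res = mean_peak_luteal_p4(rec.series, min_coverage=cfg.min_peak_coverage)
        rec.mpl_p4 = res.mpl_p4
        if not res.reliable:
            logger.warning(
                "low peak-window coverage %.2f for (%s, %d)",
                res.coverage_fraction, rec.woman_id, rec.cycle_index,
            )
        rec.ovulatory = classify_ovulation(rec.mpl_p4, cfg.ovul_threshold)
        rec.season = assign_season(rec.hb_day_of_year, cfg.calendar)
    hb = np.array([rec.hb for rec in out.records])
    capped, lo_cap, hi_cap = winsorize(hb, cfg.winsor_lo_pct, cfg.winsor_hi_pct)
    for rec, old, new in zip(out.records, hb, capped):
        if new != old:
            logger.info(
                "winsorized hb %.2f -> %.2f for (%s, %d)",
                old, new, rec.woman_id, rec.cycle_index,
            )
            rec.hb = float(new)
    logger.info("hb winsorize caps: lo=%.4f hi=%.4f", lo_cap, hi_cap)
    return out


# ---------------------------------------------------------------------------
# Table 1: descriptives by season
# ---------------------------------------------------------------------------

def _median_iqr(values: np.ndarray) -> tuple[float, float, float]:
    v = values[np.isfinite(values)]
    if v.size == 0:
        return (math.nan, math.nan, math.nan)
    return (
        float(np.median(v)),
        float(np.percentile(v, 25)),
        float(np.percentile(v, 75)),
    )


def build_table1(ds: Dataset) -> pd.DataFrame:
    """Descriptive statistics by season: median (IQR) for continuous
    variables, n (%) for categorical.  Empty strata are reported with NaN
    rather than raising."""
    cycles, _ = ds.to_frames()
    rows = []
    strata = [(ARDUOUS, cycles[cycles["season"] == ARDUOUS]),
              (BETTER, cycles[cycles["season"] == BETTER])]
    for name, sub in strata:
        n = len(sub)
        for var in ("hb", "mpl_p4", "trad_econ", "age", "body_fat"):
            med, q1, q3 = _median_iqr(sub[var].to_numpy(dtype=float))
            rows.append(
                dict(variable=var, stratum=name, n=int(sub[var].notna().sum()),
                     median=med, q1=q1, q3=q3, count=math.nan, pct=math.nan)
            )
        for var, level in (("ovulatory", 1), ("ovulatory", 0), ("breastfeeding", 1)):
            count = int((sub[var] == level).sum())
            pct = float(round(100.0 * count / n)) if n else math.nan
            label = {("ovulatory", 1): "ovulatory", ("ovulatory", 0): "anovulatory"}.get(
                (var, level), "breastfeeding"
            )
            rows.append(
                dict(variable=label, stratum=name, n=n, median=math.nan,
                     q1=math.nan, q3=math.nan, count=count, pct=pct)
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Model suite: tables 2-4
# ---------------------------------------------------------------------------

# (table, family, response, focal term, adjustment sets)
MODEL_FAMILIES = {
    "table2": dict(
        family="gaussian", response="hb", focal="trad_z",
        adjustments={"crude": (), "adjusted": ("age_z",)},
        exponentiate=False, ovulatory_only=False,
    ),
    "table3": dict(
        family="binomial", response="ovulatory", focal="hb_z",
        adjustments={"crude": (), "adjusted": ("age_z", "body_fat_z", "breastfeeding")},
        exponentiate=True, ovulatory_only=False,
    ),
    "table4": dict(
        family="gaussian", response="log_mpl", focal="hb_z",
        adjustments={"crude": (), "adjusted": ("age_z", "body_fat_z", "breastfeeding")},
        exponentiate=False, ovulatory_only=True,
    ),
}
STRATA = ("all", BETTER, ARDUOUS)


def _analytic_frame(ds: Dataset, scale_reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Cycle-level modelling frame with z-scaled covariates.

    Continuous covariates are standardized against ``scale_reference``
    (default: the frame itself, i.e. the full analytic sample) so that
    stratified fits keep full-sample SD units.
    """
    cycles, _ = ds.to_frames()
    ref = cycles if scale_reference is None else scale_reference
    frame = cycles.copy()
    frame["hb_z"] = z_standardize(cycles["hb"], ref["hb"])
    for col, zcol in (("trad_econ", "trad_z"), ("age", "age_z"), ("body_fat", "body_fat_z")):
        vals = cycles[col].to_numpy(dtype=float)
        rvals = ref[col].to_numpy(dtype=float)
        rvals = rvals[np.isfinite(rvals)]
        frame[zcol] = (vals - rvals.mean()) / rvals.std(ddof=1)
    with np.errstate(divide="ignore"):
        frame["log_mpl"] = np.log(frame["mpl_p4"].to_numpy(dtype=float))
    return frame


def _pooled_row(fits: list, term: str, exponentiate: bool) -> dict:
    """Rubin-pool one coefficient across imputed-data fits (t-based inference)."""
    from scipy import stats

    if any(not f.converged for f in fits):
        msgs = "; ".join(f.message for f in fits if not f.converged)
        raise RuntimeError(f"unconverged member fit(s): {msgs}")
    est = [float(f.params[term]) for f in fits]
    var = [float(f.bse[term]) ** 2 for f in fits]
    if len(fits) == 1:
        qbar, se, df = est[0], math.sqrt(var[0]), math.inf
    else:
        pooled = pool_rubin(est, var)
        qbar, se, df = pooled.qbar, pooled.se, pooled.df
    if math.isinf(df):
        crit = stats.norm.ppf(0.975)
        p = 2 * stats.norm.sf(abs(qbar / se))
    else:
        crit = stats.t.ppf(0.975, df)
        p = 2 * stats.t.sf(abs(qbar / se), df)
    lo, hi = qbar - crit * se, qbar + crit * se
    if exponentiate:
        qbar, lo, hi = math.exp(qbar), math.exp(lo), math.exp(hi)
    return dict(estimate=qbar, ci_low=lo, ci_high=hi, se=se, p=p,
                n_fits=len(fits), sigma_u=float(np.mean([f.sigma_u for f in fits])))


def run_model_suite(
    ds: Dataset, cfg: StudyConfig, quad_points: int = 15
) -> dict[str, pd.DataFrame]:
    """Fit the six model blocks of each family on imputed data and pool.

    Returns ``{"table2": ..., "table3": ..., "table4": ...}``, one row per
    (stratum, adjustment) with the focal-term estimate, CI, SE and p.  With
    no missing covariates a single fit is used (the pooled result with zero
    between-imputation variance is identical).
    """
    cycles, _ = ds.to_frames()
    has_missing = any(cycles[c].isna().any() for c in cfg.imputable_columns)
    if has_missing:
        imp = impute_chained_pmm(
            ds, m=cfg.imputation_m, max_iter=cfg.imputation_max_iter,
            k_donors=cfg.imputation_k_donors, seed=cfg.imputation_seed,
            columns=cfg.imputable_columns, predictors=cfg.imputation_predictors,
        )
        completed = imp.datasets
    else:
        completed = [ds]

    frames = [_analytic_frame(d) for d in completed]
    out: dict[str, pd.DataFrame] = {}
    for table, mdef in MODEL_FAMILIES.items():
        rows = []
        for stratum in STRATA:
            for adj_name, adj_terms in mdef["adjustments"].items():
                fits = []
                n_used = None
                for frame in frames:
                    sub = frame if stratum == "all" else frame[frame["season"] == stratum]
                    if mdef["ovulatory_only"]:
                        sub = sub[sub["ovulatory"] == 1]
                    if cfg.scale_within_stratum and stratum != "all":
                        sub = sub.copy()
                        for z in ("hb_z", "trad_z", "age_z", "body_fat_z"):
                            v = sub[z].to_numpy(dtype=float)
                            sub[z] = (v - v.mean()) / v.std(ddof=1)
                    spec = ModelSpec(
                        response=mdef["response"],
                        fixed_terms=(mdef["focal"], *adj_terms),
                        group="woman_id",
                        family=mdef["family"],
                    )
                    if mdef["family"] == "gaussian":
                        fit = fit_lmm_ri(spec, sub)
                    else:
                        fit = fit_logistic_ri(spec, sub, quad_points=quad_points)
                    fits.append(fit)
                    n_used = fit.n_obs
                row = _pooled_row(fits, mdef["focal"], mdef["exponentiate"])
                row.update(stratum=stratum, adjustment=adj_name, term=mdef["focal"],
                           n=n_used)
                rows.append(row)
        out[table] = pd.DataFrame(rows)[
            ["stratum", "adjustment", "term", "n", "estimate",
             "ci_low", "ci_high", "se", "p", "sigma_u", "n_fits"]
        ]
    return out


# ---------------------------------------------------------------------------
# Full study run
# ---------------------------------------------------------------------------

def run_study(
    cfg: StudyConfig, ds: Dataset | None = None, make_plots: bool = False
) -> dict:
    """Execute read -> validate -> derive -> impute -> tables 1-4 and write outputs.

    Returns the report bundle (tables, validation issues, caps, log path).
    Any stage failure aborts with a stage-named error.
    """
    import pathlib

    outdir = pathlib.Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info(
            "alticycle run: python=%s numpy=%s pandas=%s scipy=%s",
            platform.python_version(), np.__version__, pd.__version__,
            __import__("scipy").__version__,
        )
        logger.info("imputation seed=%d m=%d max_iter=%d",
                    cfg.imputation_seed, cfg.imputation_m, cfg.imputation_max_iter)
        if ds is None:
            if not (cfg.cycles_csv and cfg.samples_csv):
                raise RuntimeError("read stage: no dataset and no input CSV paths")
            ds = read_cycle_table(cfg.cycles_csv, cfg.samples_csv)
        issues = validate_dataset(ds)
        for issue in issues:
            logger.warning("validation issue: %s", issue)
        try:
            derived = derive_cycle_statistics(ds, cfg)
        except Exception as exc:  # pragma: no cover - stage naming
            raise RuntimeError(f"derive stage failed: {exc}") from exc
        table1 = build_table1(derived)
        try:
            tables = run_model_suite(derived, cfg)
        except Exception as exc:
            raise RuntimeError(f"model stage failed: {exc}") from exc
        table1.to_csv(outdir / "table1.csv", index=False)
        for name, tab in tables.items():
            tab.to_csv(outdir / f"{name}.csv", index=False)
        derived_paths = (outdir / "derived_cycles.csv", outdir / "derived_p4_samples.csv")
        write_cycle_table(derived, *derived_paths)
        if make_plots:
            _plot_hb_by_season(derived, cfg, outdir / "hb_by_season.png")
        logger.info("wrote tables to %s", outdir)
        return {
            "dataset": derived,
            "issues": issues,
            "table1": table1,
            **tables,
            "output_dir": str(outdir),
            "log": str(log_path),
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def _plot_hb_by_season(ds: Dataset, cfg: StudyConfig, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    cycles, _ = ds.to_frames()
    fig, ax = plt.subplots(figsize=(6, 4))
    for name, color in ((ARDUOUS, "#c0392b"), (BETTER, "#2980b9")):
        vals = cycles.loc[cycles["season"] == name, "hb"].dropna()
        ax.hist(vals, bins=15, alpha=0.55, label=name, color=color)
    ax.axvline(cfg.cutoffs.anaemia_threshold, ls="--", c="k",
               label=f"anaemia cutoff {cfg.cutoffs.anaemia_threshold} g/dl")
    ax.set_xlabel("haemoglobin (g/dl)")
    ax.set_ylabel("cycles")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
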