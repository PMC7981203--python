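"""End-to-end study orchestration: tables, fits, comparisons, reports.

Runs the full analysis for each of the five vital rates in each resource
treatment: build the response table and its lagged composition, select the
model (knots, smooth term, colony intercepts), fit the colony-age smooth for
the confounding screen, compare treatments by pooled-versus-separate AIC,
and emit machine-readable CSV analogs of the study's summary tables plus
coefficient-function and predicted-response tables for plotting.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .brood_data import apply_exclusion_rules, brood_cells_from_frame
from .flm import (
    FLMConvergenceError,
    age_shape_label,
    classify_shape,
    coefficient_function,
    fit_age_model,
    is_unimodal,
)
from .selection import compare_treatments, select_model
from .vital_rates import (
    build_size_grid,
    callow_size_tables,
    development_time_table,
    lagged_composition,
    survival_table,
    weekly_compositions,
    weekly_egg_production,
    workers_from_frame,
)

__all__ = ["RunConfig", "build_rate_inputs", "run_study", "plot_results"]

logger = logging.getLogger(__name__)

RATE_FAMILIES = {
    "egg_production": "negative_binomial",
    "development_time": "negative_binomial",
    "larval_survival": "binomial",
    "mean_callow_size": "gaussian",
    "cv_callow_size": "gaussian",
}

#: lag convention pairing each vital rate with its composition
RATE_LAGS = {
    "egg_production": "previous_week",
    "larval_survival": "previous_week",
    "development_time": "development_window_mean",
    "mean_callow_size": "development_window_mean",
    "cv_callow_size": "development_window_mean",
}

#: spans (mm) at which predicted-response lines are drawn
REPORT_SPANS = (2.5, 3.5, 4.5)


@dataclass
class RunConfig:
    """Configuration of one full analysis run."""

    brood_path: str
    workers_path: str
    treatment_map: dict  # colony_id -> treatment label
    years: dict = field(default_factory=dict)  # treatment -> year label
    n_bins: dict = field(default_factory=lambda: {
        "low": 14, "high_low": 14, "high": 17})
    n_bins_default: int = 14
    max_knots: int = 5
    alpha_parametric: float = 0.05
    alpha_smooth: float = 0.01
    max_gap_days: int = 8
    smoothing: str = "gcv"  # or "reml"
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self):
        for a in (self.alpha_parametric, self.alpha_smooth):
            if not 0 < a < 1:
                raise ValueError("significance cutoffs must be in (0, 1)")
        for t, nb in self.n_bins.items():
            if nb < 2:
                raise ValueError(f"n_bins for {t!r} must be >= 2")
        if not self.treatment_map:
            raise ValueError("treatment_map must assign every colony")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def build_rate_inputs(
    brood: pd.DataFrame,
    workers: pd.DataFrame,
    rate: str,
    n_bins: int = 14,
    max_gap_days: int = 8,
    grid=None,
):
    """Vital-rate table plus aligned lagged composition from raw frames.

    The worker survey schedule doubles as the photo schedule (both are
    weekly censuses of the same colonies).  Returns ``(table, comp)`` with
    rows aligned one-to-one.
    """
    if rate not in RATE_FAMILIES:
        raise ValueError(f"unknown vital rate {rate!r}")
    cells = brood_cells_from_frame(brood)
    wrecs = workers_from_frame(workers)
    survey_days = {
        str(c): sorted(int(d) for d in g["survey_day"].unique())
        for c, g in workers.groupby("colony_id")
    }
    if grid is None:
        grid = build_size_grid(workers["it_span_mm"].astype(float), n_bins)
    weekly = weekly_compositions(wrecs, grid, survey_days)
    survival_set, devtime_set, _ = apply_exclusion_rules(cells, max_gap_days)

    if rate == "egg_production":
        table = weekly_egg_production(cells, survey_days)
    elif rate == "development_time":
        table = development_time_table(devtime_set)
    elif rate == "larval_survival":
        table = survival_table(survival_set)
    else:
        mean_t, cv_t = callow_size_tables(wrecs, survey_days)
        table = mean_t if rate == "mean_callow_size" else cv_t
    if table.n == 0:
        raise ValueError(f"no rows for vital rate {rate!r}")
    comp, table = lagged_composition(weekly, table, RATE_LAGS[rate])
    if table.n == 0:
        raise ValueError(f"no composition-matched rows for {rate!r}")
    return table, comp


def _row_ages(table) -> np.ndarray:
    """Colony age covariate (days since study start) for each row."""
    df = table.df
    if "week" in df.columns:
        ages = df["week"].to_numpy(float)
    else:
        ages = df["window_end"].to_numpy(float)
    return np.maximum(ages, 1.0)


def _predicted_lines(fit, grid, rate, treatment) -> list[dict]:
    """Figure-style predicted responses versus workers of one size.

    Intercepts are averaged on the link scale; counts are per day (unit
    offset).  Spans outside the fitted grid are clamped to its range.
    """
    cf = coefficient_function(fit)
    b0 = float(np.mean(list(fit.colony_intercepts.values())))
    lo, hi = grid.bin_edges[0], grid.bin_edges[-1]
    rows = []
    for span in REPORT_SPANS:
        s = min(max(span, lo), hi)
        slope = float(cf(np.array([s]))[0]) if fit.spline_coefficients.size \
            else 0.0
        for n in range(0, 21):
            eta = b0 + slope * n
            if fit.family == "gaussian":
                mu = eta
            elif fit.family == "binomial":
                mu = 1.0 / (1.0 + np.exp(-eta))
            else:
                mu = float(np.exp(np.clip(eta, -20, 20)))
            rows.append({"vital_rate": rate, "treatment": treatment,
                         "span_mm": span, "n_workers": n, "predicted": mu})
    return rows


def run_study(config: RunConfig, brood: pd.DataFrame | None = None,
              workers: pd.DataFrame | None = None) -> dict:
    """Run the full analysis and write the result bundle to ``out_dir``.

    Any failing vital-rate-by-treatment cell is logged and recorded in the
    bundle's ``errors`` without aborting the rest of the run.
    """
    if brood is None:
        brood = pd.read_csv(config.brood_path,
                            dtype={"cell_id": str, "colony_id": str,
                                   "clump_id": str})
    if workers is None:
        workers = pd.read_csv(config.workers_path,
                              dtype={"worker_id": str, "colony_id": str})

    tmap = {str(k): str(v) for k, v in config.treatment_map.items()}
    brood = brood.assign(_treatment=brood["colony_id"].astype(str).map(tmap))
    workers = workers.assign(
        _treatment=workers["colony_id"].astype(str).map(tmap))
    if brood["_treatment"].isna().any() or workers["_treatment"].isna().any():
        missing = sorted(
            set(brood.loc[brood["_treatment"].isna(), "colony_id"])
            | set(workers.loc[workers["_treatment"].isna(), "colony_id"]))
        raise ValueError(f"colonies without a treatment mapping: {missing}")
    treatments = sorted(set(tmap.values()))

    fits: dict[tuple[str, str], object] = {}
    age_fits: dict[tuple[str, str], object] = {}
    summary_rows, coef_rows, line_rows, table2_rows = [], [], [], []
    errors: dict[str, str] = {}

    for treatment in treatments:
        b_t = brood[brood["_treatment"] == treatment].drop(columns="_treatment")
        w_t = workers[workers["_treatment"] == treatment].drop(
            columns="_treatment")
        nb = config.n_bins.get(treatment, config.n_bins_default)
        for rate, family in RATE_FAMILIES.items():
            key = f"{rate}/{treatment}"
            try:
                table, comp = build_rate_inputs(
                    b_t, w_t, rate, n_bins=nb,
                    max_gap_days=config.max_gap_days)
                fit = select_model(
                    table, comp, family=family,
                    max_knots=config.max_knots,
                    alpha_parametric=config.alpha_parametric,
                    alpha_smooth=config.alpha_smooth,
                    lam=config.smoothing)
                fits[(rate, treatment)] = fit
                cf = coefficient_function(fit)
                has_smooth = fit.spline_coefficients.size > 0
                summary_rows.append({
                    "vital_rate": rate, "treatment": treatment,
                    "family": fit.family, "n_knots": fit.n_knots,
                    "edf": fit.edf, "loglik": fit.loglik, "aic": fit.aic,
                    "smooth_p": fit.smooth_pvalue,
                    "parametric_p": fit.parametric_pvalue,
                    "unimodal": bool(is_unimodal(cf, comp.grid))
                    if has_smooth else True,
                    "n": fit.n_obs,
                })
                if has_smooth:
                    for c, b, se in zip(comp.grid.bin_centers,
                                        cf.grid_values, cf.pointwise_se):
                        coef_rows.append({
                            "vital_rate": rate, "treatment": treatment,
                            "bin_center_mm": c, "beta": b, "se": se})
                line_rows.extend(_predicted_lines(fit, comp.grid, rate,
                                                  treatment))

                sign, trend = (classify_shape(cf, comp.grid)
                               if has_smooth else ("none", "none"))
                comp_sig = has_smooth and fit.smooth_pvalue < config.alpha_smooth
                try:
                    age_fit = fit_age_model(table, _row_ages(table),
                                            family=family,
                                            lam=config.smoothing)
                    age_fits[(rate, treatment)] = age_fit
                    age_label = age_shape_label(age_fit, config.alpha_smooth)
                    age_sig = age_fit.smooth_pvalue < config.alpha_smooth
                except (FLMConvergenceError, ValueError) as exc:
                    logger.warning("age model %s failed: %s", key, exc)
                    errors[f"age/{key}"] = str(exc)
                    age_label, age_sig = "unavailable", False
                table2_rows.append({
                    "vital_rate": rate, "treatment": treatment,
                    "n": fit.n_obs,
                    "age_shape": age_label,
                    "wsc_sign": sign, "wsc_trend": trend,
                    # conservative flag: both smooths separately significant
                    "confounded": bool(comp_sig and age_sig),
                })
            except (FLMConvergenceError, ValueError) as exc:
                logger.warning("cell %s failed: %s", key, exc)
                errors[key] = str(exc)

    # -- pooled-vs-separate treatment comparisons on a shared grid ---------
    table1_rows = []
    if len(treatments) > 1:
        shared_grid = build_size_grid(workers["it_span_mm"].astype(float),
                                      config.n_bins_default)
        for rate, family in RATE_FAMILIES.items():
            data = {}
            for treatment in treatments:
                b_t = brood[brood["_treatment"] == treatment].drop(
                    columns="_treatment")
                w_t = workers[workers["_treatment"] == treatment].drop(
                    columns="_treatment")
                try:
                    data[treatment] = build_rate_inputs(
                        b_t, w_t, rate, grid=shared_grid,
                        max_gap_days=config.max_gap_days)
                except ValueError as exc:
                    errors[f"table1/{rate}/{treatment}"] = str(exc)
            if len(data) < 2:
                continue
            comparisons = compare_treatments(
                data, family=family,
                years={t: config.years.get(t, "") for t in data}
                if config.years else None,
                max_knots=config.max_knots,
                alpha_parametric=config.alpha_parametric,
                alpha_smooth=config.alpha_smooth,
                lam=config.smoothing)
            row = {"vital_rate": rate}
            for cmp_ in comparisons:
                row[f"daic_{cmp_.label}"] = cmp_.daic
            table1_rows.append(row)

    bundle = {
        "config": dataclasses.asdict(config),
        "manifest": {"config_digest": config.digest(), "seed": config.seed},
        "fits": fits,
        "age_fits": age_fits,
        "fit_summary": pd.DataFrame(summary_rows),
        "coefficient_functions": pd.DataFrame(coef_rows),
        "predicted_lines": pd.DataFrame(line_rows),
        "table1": pd.DataFrame(table1_rows),
        "table2": pd.DataFrame(table2_rows),
        "errors": errors,
        "treatments": treatments,
        "mean_span": {
            t: float(workers.loc[workers["_treatment"] == t,
                                 "it_span_mm"].mean())
            for t in treatments},
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in ("fit_summary", "coefficient_functions", "predicted_lines",
                 "table1", "table2"):
        bundle[name].to_csv(out / f"{name}.csv", index=False)
    (out / "manifest.json").write_text(json.dumps(
        {**bundle["manifest"], "errors": errors}, indent=2))
    return bundle


def plot_results(bundle: dict, out_dir: str | Path | None = None) -> list[Path]:
    """Coefficient-function panels and predicted-response lines as PNGs.

    Each panel shows the fitted beta(s) with a +/-2 SE band, a dashed zero
    line, and a grey dashed marker at the treatment's mean worker size.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coef = bundle["coefficient_functions"]
    out = Path(out_dir or bundle["config"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if coef.empty and bundle["predicted_lines"].empty:
        logger.warning("empty bundle: nothing to plot")
        return written

    rates = list(RATE_FAMILIES)
    treatments = bundle["treatments"]
    if not coef.empty or bundle["fit_summary"].shape[0]:
        fig, axes = plt.subplots(len(rates), len(treatments),
                                 figsize=(3.2 * len(treatments),
                                          2.4 * len(rates)),
                                 squeeze=False)
        for i, rate in enumerate(rates):
            for j, t in enumerate(treatments):
                ax = axes[i][j]
                sub = coef[(coef["vital_rate"] == rate)
                           & (coef["treatment"] == t)]
                if not sub.empty:
                    ax.plot(sub["bin_center_mm"], sub["beta"], color="k")
                    ax.fill_between(sub["bin_center_mm"],
                                    sub["beta"] - 2 * sub["se"],
                                    sub["beta"] + 2 * sub["se"],
                                    alpha=0.25, color="grey")
                ax.axhline(0.0, ls="--", lw=0.8, color="k")
                ms = bundle["mean_span"].get(t)
                if ms is not None:
                    ax.axvline(ms, ls="--", lw=0.8, color="grey")
                if i == 0:
                    ax.set_title(t)
                if j == 0:
                    ax.set_ylabel(rate, fontsize=7)
        fig.tight_layout()
        path = out / "coefficient_functions.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)

    lines = bundle["predicted_lines"]
    if not lines.empty:
        fig, axes = plt.subplots(len(rates), len(treatments),
                                 figsize=(3.2 * len(treatments),
                                          2.4 * len(rates)),
                                 squeeze=False)
        shades = {2.5: "0.75", 3.5: "0.45", 4.5: "0.0"}
        for i, rate in enumerate(rates):
            for j, t in enumerate(treatments):
                ax = axes[i][j]
                sub = lines[(lines["vital_rate"] == rate)
                            & (lines["treatment"] == t)]
                for span, g in sub.groupby("span_mm"):
                    ax.plot(g["n_workers"], g["predicted"],
                            color=shades.get(span, "k"),
                            label=f"{span} mm")
                if i == 0:
                    ax.set_title(t)
                if j == 0:
                    ax.set_ylabel(rate, fontsize=7)
                if i == 0 and j == 0:
                    ax.legend(fontsize=6)
        fig.tight_layout()
        path = out / "predicted_lines.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
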