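"""Likelihood-ratio term tests, knot selection, and pooled-vs-separate AIC.

Model structure is chosen by likelihood-ratio testing: colony intercepts are
retained when the parametric LR test has p < .05, and the smooth
size-composition term when its LR test has p < .01 (smooth-term p-values are
approximate and typically too small, hence the stricter cutoff).  Candidate
smooths run from two to five knots and any candidate whose fitted
coefficient function is not unimodal is rejected before testing.

Treatment differences are assessed by comparing the AIC of a model fit to
pooled data against the summed AIC of group-wise fits,
``AIC_sep = 2 * sum(k_g) - 2 * sum(LL_g)``; a positive difference
(pooled minus separate) flags a group difference.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .flm import (
    FLMConvergenceError,
    SmoothFit,
    build_basis,
    coefficient_function,
    fit_flm,
    is_unimodal,
)
from .vital_rates import CompositionMatrix, VitalRateTable

__all__ = [
    "ModelComparison",
    "lr_test",
    "select_model",
    "aic_separate",
    "compare_treatments",
    "compare_group_means",
]

_LL_TOL = 1e-6


@dataclass
class ModelComparison:
    """One pooled-versus-separate AIC comparison (a group-difference flag)."""

    label: str
    aic_combined: float
    aic_separate: float
    groups: tuple[str, ...]
    available: bool = True
    reason: str = ""

    @property
    def daic(self) -> float:
        return self.aic_combined - self.aic_separate

    @property
    def groups_differ(self) -> bool:
        # literal sign rule: positive dAIC flags a difference
        return self.available and self.daic > 0


def lr_test(fit_null: SmoothFit, fit_alt: SmoothFit) -> tuple[float, float, float]:
    """Likelihood-ratio test of nested fits on the same rows.

    Returns ``(statistic, df, p)`` with ``statistic = 2 (LL_alt - LL_null)``
    and ``df`` the difference in effective parameter counts (rounded EDFs
    for smooth terms).  Identical fits give a zero statistic and p = 1.
    """
    if fit_null.n_obs != fit_alt.n_obs:
        raise ValueError("fits must use the same data rows")
    stat = 2.0 * (fit_alt.loglik - fit_null.loglik)
    if stat < -_LL_TOL * (abs(fit_null.loglik) + 1.0):
        raise ValueError(
            "alternative log-likelihood below the null: models are not nested "
            "or a fit did not converge"
        )
    stat = max(stat, 0.0)
    df = round(fit_alt.k) - round(fit_null.k)
    if stat <= _LL_TOL:
        return stat, float(max(df, 0)), 1.0
    if df <= 0:
        raise ValueError("alternative model has no extra effective parameters")
    return stat, float(df), float(chi2_dist.sf(stat, df))


def _null_fit(table: VitalRateTable, comp: CompositionMatrix, family: str,
              include_colony_intercepts: bool, lam, nb_alpha) -> SmoothFit:
    """Intercept-only structure: the smooth term pinned at zero."""
    basis = build_basis(comp.grid, 2)
    return fit_flm(table, comp, basis, family=family,
                   include_colony_intercepts=include_colony_intercepts,
                   lam=0.0, nb_alpha=nb_alpha, include_smooth=False)


def select_model(
    table: VitalRateTable,
    comp: CompositionMatrix,
    family: str | None = None,
    max_knots: int = 5,
    alpha_parametric: float = 0.05,
    alpha_smooth: float = 0.01,
    lam="gcv",
    nb_alpha=None,
) -> SmoothFit:
    """Select knots and terms for one vital rate by LR testing.

    Candidates with 2..max_knots knots are fit; non-unimodal fitted
    coefficient functions are rejected.  Among the survivors, the fewest
    knots not significantly improved upon (sequential LR at
    ``alpha_smooth``) wins; the smooth is kept only if it beats the
    intercept-only null at ``alpha_smooth``, and colony intercepts are kept
    only if they beat a shared intercept at ``alpha_parametric``.
    """
    family = family or table.family
    if max_knots > 5:
        raise ValueError("max_knots may not exceed 5")

    diagnostics: dict[int, str] = {}
    candidates: list[SmoothFit] = []
    for kn in range(2, min(max_knots, comp.grid.n_bins) + 1):
        basis = build_basis(comp.grid, kn)
        try:
            fit = fit_flm(table, comp, basis, family=family,
                          include_colony_intercepts=True, lam=lam,
                          nb_alpha=nb_alpha)
        except (FLMConvergenceError, ValueError) as exc:
            diagnostics[kn] = f"fit failed: {exc}"
            continue
        cf = coefficient_function(fit)
        if not is_unimodal(cf, comp.grid):
            diagnostics[kn] = "rejected: multimodal coefficient function"
            continue
        candidates.append(fit)

    null = _null_fit(table, comp, family, True, lam, nb_alpha)
    if not candidates:
        if diagnostics and all("failed" in v for v in diagnostics.values()):
            raise FLMConvergenceError(
                "no converged smooth candidate; diagnostics: "
                + "; ".join(f"{k} knots: {v}" for k, v in diagnostics.items()))
        chosen = null
    else:
        # fewest knots not significantly improved upon
        chosen = candidates[0]
        for bigger in candidates[1:]:
            try:
                _, _, p = lr_test(chosen, bigger)
            except ValueError:
                continue
            if p < alpha_smooth:
                chosen = bigger
        # keep the smooth only if it beats the null
        try:
            _, _, p_smooth = lr_test(null, chosen)
        except ValueError:
            p_smooth = 1.0
        if not (p_smooth < alpha_smooth):
            chosen = null

    # parametric term: colony intercepts vs a shared intercept
    if len(set(table.df["colony_id"])) > 1:
        if chosen is null or len(chosen.spline_coefficients) == 0 or \
                np.allclose(chosen.spline_coefficients, 0):
            reduced = _null_fit(table, comp, family, False, lam, nb_alpha)
            full = null
        else:
            basis = chosen.basis
            reduced = fit_flm(table, comp, basis, family=family,
                              include_colony_intercepts=False,
                              lam=chosen.smoothing_parameter, nb_alpha=nb_alpha)
            full = chosen
        try:
            _, _, p_par = lr_test(reduced, full)
        except ValueError:
            p_par = 1.0
        if not (p_par < alpha_parametric):
            chosen = reduced if full is chosen else _null_fit(
                table, comp, family, False, lam, nb_alpha)
    return chosen


def aic_separate(fits: list[SmoothFit]) -> float:
    """AIC of a set of group-wise fits: ``2 * sum(k) - 2 * sum(LL)``."""
    if not fits:
        raise ValueError("fits must be nonempty")
    return 2.0 * sum(f.k for f in fits) - 2.0 * sum(f.loglik for f in fits)


def _pool(groups: dict[str, tuple[VitalRateTable, CompositionMatrix]]
          ) -> tuple[VitalRateTable, CompositionMatrix]:
    tables, mats, units = [], [], []
    rate = family = None
    grid = None
    for g, (t, c) in groups.items():
        rate, family, grid = t.rate, t.family, c.grid
        df = t.df.copy()
        df["unit_id"] = g + "|" + df["unit_id"].astype(str)
        df["colony_id"] = g + "|" + df["colony_id"].astype(str)
        tables.append(df)
        mats.append(c.counts)
        units.extend(g + "|" + u for u in c.unit_ids)
    table = VitalRateTable(rate, family, pd.concat(tables, ignore_index=True))
    comp = CompositionMatrix(units, np.vstack(mats), grid, "pooled")
    return table, comp


def compare_treatments(
    data: dict[str, tuple[VitalRateTable, CompositionMatrix]],
    family: str | None = None,
    years: dict[str, str] | None = None,
    **select_kw,
) -> list[ModelComparison]:
    """Pooled-vs-separate AIC comparisons across treatment groups.

    ``data`` maps each treatment label to its (table, composition) pair on a
    common size grid.  Emits the combined-vs-by-treatment comparison, a
    combined-vs-by-year comparison when ``years`` maps treatments to years,
    and all pairwise comparisons.  Groups too small to fit are marked
    unavailable with the failure reason.
    """
    labels = sorted(data)
    if len(labels) < 2:
        return []
    max_knots = select_kw.get("max_knots", 5)
    lam = select_kw.get("lam", "gcv")
    nb_alpha = select_kw.get("nb_alpha")

    # the comparison holds the model structure fixed (full smooth, colony
    # intercepts) and shares the pooled fit's smoothness with the group
    # fits, so the dAIC reflects the data split rather than re-selection
    # or smoothing-adaptation noise
    def fixed_fit(t: VitalRateTable, c: CompositionMatrix,
                  lam_fixed=None) -> SmoothFit:
        basis = build_basis(c.grid, min(max_knots, c.grid.n_bins))
        return fit_flm(t, c, basis, family=family,
                       lam=lam if lam_fixed is None else lam_fixed,
                       nb_alpha=nb_alpha)

    out: list[ModelComparison] = []

    def comparison(label: str, subset: tuple[str, ...],
                   partition: list[tuple[str, ...]]) -> ModelComparison:
        try:
            pooled = fixed_fit(*_pool({g: data[g] for g in subset}))
            parts = [fixed_fit(*_pool({g: data[g] for g in block}),
                               lam_fixed=pooled.smoothing_parameter)
                     for block in partition]
            return ModelComparison(label, pooled.aic, aic_separate(parts),
                                   subset)
        except (FLMConvergenceError, ValueError) as exc:
            return ModelComparison(label, math.nan, math.nan, subset, False,
                                   str(exc))

    out.append(comparison("by_treatment", tuple(labels),
                          [(g,) for g in labels]))
    if years:
        blocks: dict[str, list[str]] = {}
        for g in labels:
            blocks.setdefault(str(years[g]), []).append(g)
        if len(blocks) > 1:
            out.append(comparison("by_year", tuple(labels),
                                  [tuple(v) for v in blocks.values()]))
    for a, b in itertools.combinations(labels, 2):
        out.append(comparison(f"{a}_vs_{b}", (a, b), [(a,), (b,)]))
    return out


def compare_group_means(values, groups) -> pd.DataFrame:
    """All-pairs comparison of group means with a single-step adjustment.

    A one-way linear model on the group labels with Tukey HSD contrasts;
    returns a frame with columns ``group1, group2, estimate, statistic,
    p_adj`` where ``estimate`` is the difference in means (group2 - group1).
    """
    values = np.asarray(values, float)
    groups = np.asarray([str(g) for g in groups])
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    small = uniq[counts < 2]
    if len(small):
        raise ValueError(f"groups with fewer than 2 values: {list(small)}")
    res = pairwise_tukeyhsd(values, groups)
    frame = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    frame = frame.rename(columns={"meandiff": "estimate", "p-adj": "p_adj"})
    frame["estimate"] = frame["estimate"].astype(float)
    frame["p_adj"] = np.asarray(res.pvalues, float)
    frame["statistic"] = np.asarray(res.meandiffs, float) / np.asarray(
        res.std_pairs, float)
    return frame[["group1", "group2", "estimate", "statistic", "p_adj"]]
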