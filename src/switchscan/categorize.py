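"""Temporal-response categories for genes after a diet switch.

With S(c) the event "comparison c is significant at the chosen FDR" and
D = S(RF_vs_CF) marking diet-dependent genes, the main categories are

* I   (switching):   D and S(SF_vs_CF) and not S(SF_vs_RF) — the SF cohort
  left the CF level and is indistinguishable from RF;
* II  (refractory):  D and not S(SF_vs_CF) and S(SF_vs_RF) — expression is
  pinned to the cohort's nutritional history;
* III (responsive, non-switching): D and S(SF_vs_CF) and S(SF_vs_RF) —
  moved off CF but never reached RF;
* IV  (deviating):   not D and S(SF_vs_CF) — responds to the switch event
  itself, not to the diet level;
* V   (null): nothing significant.

Diet-dependent genes with neither SF comparison significant, and the residual
diet-independent pattern, are statistically indeterminate and get routed to
VI (non-responding), VII (slow/partial switch) or VIII (too variable) by
substitute rules exposed in :class:`IndeterminateRules`; no formal published
criteria exist for these residual classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .expression import COMPARISONS, ExpressionMatrix, run_comparisons

CATEGORIES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
MAIN_CATEGORIES = ("I", "II", "III", "IV")


class CategorizeError(ValueError):
    """Invalid categorization input."""


@dataclass
class IndeterminateRules:
    """Substitute routing rules for statistically indeterminate genes.

    A gene is VIII when its pooled within-(cohort, time) replicate SD exceeds
    ``variability_sd_multiple`` times the median over genes. Otherwise the SF
    late-time mean's position in the CF→RF gap decides: within
    ``nonresponding_max_frac`` of CF → VI (non-responding); farther along →
    VII (slow / partial switch). ``late_hours`` counts how many of the last
    sampled hours define "late". Without an expression matrix the fallback is
    VI for diet-dependent and VIII for diet-independent patterns.
    """

    nonresponding_max_frac: float = 0.25
    variability_sd_multiple: float = 3.0
    late_hours: int = 3


def _pivot(comparisons: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = comparisons.pivot(index="gene_id", columns="comparison", values=column)
    missing_cols = set(COMPARISONS) - set(wide.columns)
    if missing_cols:
        raise CategorizeError(f"missing comparisons: {sorted(missing_cols)}")
    incomplete = wide.index[wide[list(COMPARISONS)].isna().any(axis=1)]
    if len(incomplete):
        raise CategorizeError(
            f"genes lacking a comparison row: {list(incomplete[:10])}")
    return wide[list(COMPARISONS)]


def assign_categories(comparisons: pd.DataFrame, fdr: float = 0.05,
                      rules: IndeterminateRules | None = None,
                      matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
    """Assign every gene exactly one category and a direction.

    Parameters
    ----------
    comparisons : DataFrame
        Long comparison table from :func:`switchscan.expression.run_comparisons`
        (one row per gene per comparison, with ``q`` and ``mean_diff_log2``).
    fdr : float
        Significance threshold on the pooled q-values.
    rules : IndeterminateRules, optional
        Routing for indeterminate genes (VI/VII/VIII).
    matrix : ExpressionMatrix, optional
        When given, enables the late-time-gap and variability rules and the
        per-gene switch-completion time for Category I genes.

    Returns a DataFrame with columns ``gene_id, category, direction,
    switch_time_h`` where direction is up/down for categories I-IV (sign of
    the RF-CF difference for I-III, of SF-CF for IV) and none otherwise.
    """
    if not (0 < fdr < 1):
        raise CategorizeError("fdr must lie in (0, 1)")
    rules = rules or IndeterminateRules()
    q = _pivot(comparisons, "q")
    diff = _pivot(comparisons, "mean_diff_log2")
    sig = q < fdr
    d = sig["RF_vs_CF"]
    sfc = sig["SF_vs_CF"]
    sfr = sig["SF_vs_RF"]

    category = pd.Series("", index=q.index, dtype=object)
    category[d & sfc & ~sfr] = "I"
    category[d & ~sfc & sfr] = "II"
    category[d & sfc & sfr] = "III"
    category[~d & sfc] = "IV"
    category[~d & ~sfc & ~sfr] = "V"
    indeterminate = category == ""  # (D, ~sfc, ~sfr) or (~D, ~sfc, sfr)
    if indeterminate.any():
        category[indeterminate] = _route_indeterminate(
            q.index[indeterminate], d[indeterminate], rules, matrix)

    direction = pd.Series("none", index=q.index, dtype=object)
    in_i_iii = category.isin(("I", "II", "III"))
    direction[in_i_iii] = np.where(diff.loc[in_i_iii, "RF_vs_CF"] > 0, "up", "down")
    is_iv = category == "IV"
    direction[is_iv] = np.where(diff.loc[is_iv, "SF_vs_CF"] > 0, "up", "down")

    switch_time = pd.Series(np.nan, index=q.index, dtype=float)
    if matrix is not None:
        switch_time = _switch_times(category, matrix)

    out = pd.DataFrame({
        "gene_id": q.index,
        "category": category.to_numpy(),
        "direction": direction.to_numpy(),
        "switch_time_h": switch_time.to_numpy(),
    }).reset_index(drop=True)
    return out


def _route_indeterminate(genes: pd.Index, diet_dependent: pd.Series,
                         rules: IndeterminateRules,
                         matrix: ExpressionMatrix | None) -> pd.Series:
    if matrix is None:
        return pd.Series(np.where(diet_dependent, "VI", "VIII"), index=genes)
    sd = matrix.replicate_residual_sd()
    med = float(np.nanmedian(sd))
    hours = np.sort(matrix.timepoints("SF"))[-rules.late_hours:]
    cf = matrix.time_means("CF").loc[genes]
    rf = matrix.time_means("RF").loc[genes]
    sf = matrix.time_means("SF").loc[genes]
    cf_level = cf.mean(axis=1)
    rf_level = rf.mean(axis=1)
    sf_late = sf[hours].mean(axis=1)
    gap = rf_level - cf_level
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = (sf_late - cf_level) / gap
    out = pd.Series("VI", index=genes, dtype=object)
    out[np.abs(frac) > rules.nonresponding_max_frac] = "VII"
    out[gap == 0] = "VI"
    if np.isfinite(med) and med > 0:
        out[sd.loc[genes] > rules.variability_sd_multiple * med] = "VIII"
    return out


def _switch_times(category: pd.Series, matrix: ExpressionMatrix) -> pd.Series:
    cf = matrix.time_means("CF").mean(axis=1)
    rf = matrix.time_means("RF").mean(axis=1)
    sf = matrix.time_means("SF")
    times = pd.Series(np.nan, index=category.index, dtype=float)
    for gene in category.index[category == "I"]:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            t = estimate_switch_time(sf.loc[gene], cf.loc[gene], rf.loc[gene])
        times.loc[gene] = np.nan if t is None else t
    return times


def estimate_switch_time(sf_series: pd.Series, cf_level: float, rf_level: float,
                         completion_fraction: float = 0.9,
                         gap_tol: float = 1e-8) -> float | None:
    """Earliest sampled hour at which the SF trajectory has completed.

    Completion at hour t means the SF time-mean has crossed
    ``completion_fraction`` of the CF→RF gap and stays within
    ``1 - completion_fraction`` of the RF level at every later sampled hour.
    Returns None when the series never completes or the gap is degenerate.
    """
    if not (0 < completion_fraction < 1):
        raise CategorizeError("completion_fraction must lie in (0, 1)")
    gap = rf_level - cf_level
    if abs(gap) <= gap_tol:
        warnings.warn("degenerate CF-RF gap; switch time undefined")
        return None
    series = sf_series.sort_index()
    within = (np.abs(series - rf_level) <=
              (1.0 - completion_fraction) * abs(gap)).to_numpy()
    # earliest hour from which the trajectory stays within tolerance of RF
    ok_from = np.logical_and.accumulate(within[::-1])[::-1]
    if not ok_from.any():
        return None
    return float(series.index[np.argmax(ok_from)])


def curate_fast_switchers(assignments: pd.DataFrame,
                          switch_times: pd.Series | None = None,
                          cutoff_h: float = 8.0) -> tuple[list[str], list[str]]:
    """Category I genes completing the switch by ``cutoff_h``, split by direction.

    Returns ``(up_genes, down_genes)``. ``switch_times`` (gene_id → hour)
    overrides the assignment table's ``switch_time_h`` column when given.
    """
    frame = assignments.set_index("gene_id")
    times = frame["switch_time_h"] if switch_times is None else \
        switch_times.reindex(frame.index)
    fast = frame[(frame["category"] == "I") & times.notna() & (times <= cutoff_h)]
    up = sorted(fast.index[fast["direction"] == "up"])
    down = sorted(fast.index[fast["direction"] == "down"])
    return up, down


def category_counts(assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-category totals with up/down splits (the study's summary shape)."""
    rows = []
    for cat in CATEGORIES:
        sub = assignments[assignments["category"] == cat]
        rows.append({
            "category": cat,
            "n_genes": len(sub),
            "n_down": int((sub["direction"] == "down").sum()),
            "n_up": int((sub["direction"] == "up").sum()),
        })
    return pd.DataFrame(rows)


class SwitchCategorizer(BaseEstimator):
    """Estimator wrapping the full comparison + categorization step.

    ``fit`` takes an :class:`~switchscan.expression.ExpressionMatrix`, runs the
    three time-paired cohort comparisons with pooled BH FDR, and assigns every
    gene a temporal-response category.

    Attributes (after fit)
    ----------------------
    comparisons_ : DataFrame
        Long per-gene, per-comparison statistics table.
    assignments_ : DataFrame
        gene_id, category, direction, switch_time_h.
    summary_ : DataFrame
        Per-category gene counts with up/down splits.
    """

    def __init__(self, fdr: float = 0.05, nonresponding_max_frac: float = 0.25,
                 variability_sd_multiple: float = 3.0, late_hours: int = 3):
        self.fdr = fdr
        self.nonresponding_max_frac = nonresponding_max_frac
        self.variability_sd_multiple = variability_sd_multiple
        self.late_hours = late_hours

    def fit(self, X: ExpressionMatrix, y=None):
        rules = IndeterminateRules(
            nonresponding_max_frac=self.nonresponding_max_frac,
            variability_sd_multiple=self.variability_sd_multiple,
            late_hours=self.late_hours)
        self.comparisons_ = run_comparisons(X)
        self.assignments_ = assign_categories(
            self.comparisons_, fdr=self.fdr, rules=rules, matrix=X)
        self.summary_ = category_counts(self.assignments_)
        return self


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    assignments.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
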