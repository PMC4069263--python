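"""Expression-matrix handling and the core differential-expression statistics.

The experimental design compares three cohorts of flies sampled at the same
post-switch hours: CF (control food), RF (restricted food, chronic dietary
restriction) and SF (switched from CF to RF at the mortality-separation day).
Differential expression between any two cohorts is assessed with a two-sided
paired t-test, pairing the cohorts' per-time-point mean log2 expression by
time of collection; a single Benjamini-Hochberg correction is then applied to
the pooled p-values from all genes and all three comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

COHORTS = ("CF", "RF", "SF")

#: ordered (numerator, reference) cohort pairs tested per gene
COMPARISON_PAIRS = (("RF", "CF"), ("SF", "CF"), ("SF", "RF"))
COMPARISONS = tuple(f"{a}_vs_{b}" for a, b in COMPARISON_PAIRS)


class ExpressionError(ValueError):
    """Invalid expression matrix, metadata, or statistical input."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2 expression scores with sample metadata.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene id, columns by sample id, entries log2 scores.
    metadata : DataFrame
        Indexed by sample id with columns ``cohort`` (CF/RF/SF), ``time_h``
        (positive hours since the diet switch) and ``replicate``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        dup = self.values.index[self.values.index.duplicated()].unique()
        if len(dup):
            raise ExpressionError(f"duplicate gene ids: {sorted(map(str, dup))}")
        missing = [s for s in self.values.columns if s not in self.metadata.index]
        if missing:
            raise ExpressionError(f"samples missing from metadata: {missing}")
        required = {"cohort", "time_h", "replicate"}
        absent = required - set(self.metadata.columns)
        if absent:
            raise ExpressionError(f"metadata lacks columns: {sorted(absent)}")
        bad_cohort = set(self.metadata["cohort"]) - set(COHORTS)
        if bad_cohort:
            raise ExpressionError(f"unknown cohorts: {sorted(bad_cohort)}")
        if (self.metadata["time_h"] <= 0).any():
            raise ExpressionError("time_h must be positive hours")
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all():
            bad = self.values.index[~np.isfinite(vals).all(axis=1)]
            raise ExpressionError(f"non-finite values in genes: {list(bad[:10])}")
        # keep metadata aligned and restricted to the matrix columns
        self.metadata = self.metadata.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def n_genes(self) -> int:
        return len(self.values.index)

    def cohorts(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.metadata["cohort"])))

    def timepoints(self, cohort: str) -> np.ndarray:
        t = self.metadata.loc[self.metadata["cohort"] == cohort, "time_h"]
        return np.sort(t.unique())

    def time_means(self, cohort: str) -> pd.DataFrame:
        """Per-gene mean log2 score at each time point (replicates averaged).

        Returns a genes x times DataFrame with time-ordered columns.
        """
        meta = self.metadata[self.metadata["cohort"] == cohort]
        if meta.empty:
            raise ExpressionError(f"cohort {cohort!r} absent from matrix")
        sub = self.values[meta.index]
        grouped = sub.T.groupby(meta["time_h"]).mean().T
        return grouped[np.sort(grouped.columns)]

    def replicate_residual_sd(self) -> pd.Series:
        """Pooled within-(cohort, time) SD per gene, NaN if no replication."""
        key = list(zip(self.metadata["cohort"], self.metadata["time_h"]))
        groups = pd.Series(key, index=self.values.columns)
        sq_sum = pd.Series(0.0, index=self.values.index)
        dof = 0
        for _, cols in groups.groupby(groups).groups.items():
            block = self.values[list(cols)]
            if block.shape[1] < 2:
                continue
            centered = block.sub(block.mean(axis=1), axis=0)
            sq_sum += (centered**2).sum(axis=1)
            dof += block.shape[1] - 1
        if dof == 0:
            return pd.Series(np.nan, index=self.values.index)
        return np.sqrt(sq_sum / dof)


def read_expression(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a log2 expression TSV (first column gene_id) and its metadata TSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    non_numeric = values.columns[values.dtypes == object]
    if len(non_numeric):
        raise ExpressionError(f"non-numeric expression columns: {list(non_numeric)}")
    metadata = pd.read_csv(metadata_path, sep="\t", index_col=0)
    return ExpressionMatrix(values, metadata)


def write_expression(matrix: ExpressionMatrix, matrix_path: str | Path,
                     metadata_path: str | Path) -> None:
    matrix.values.rename_axis("gene_id").to_csv(matrix_path, sep="\t")
    matrix.metadata.rename_axis("sample_id").to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# quantile normalization


def quantile_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Force every column onto the common distribution of sorted-row means.

    Ties within a column receive the mean of the quantile values they span.
    A single-column input is returned unchanged with a warning.
    """
    if values.shape[1] < 2:
        warnings.warn("quantile normalization needs >= 2 samples; returning input")
        return values.copy()
    arr = values.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    return _map_to_reference(values, reference)


def _map_to_reference(values: pd.DataFrame, reference: np.ndarray) -> pd.DataFrame:
    n = values.shape[0]
    if len(reference) != n:
        raise ExpressionError(
            f"reference distribution has {len(reference)} values, matrix has {n} rows")
    out = np.empty(values.shape)
    for j, col in enumerate(values.columns):
        ranks = values[col].rank(method="average").to_numpy()  # 1..n, .5 on ties
        lo = np.floor(ranks).astype(int) - 1
        hi = np.ceil(ranks).astype(int) - 1
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


class QuantileNormalizer(TransformerMixin, BaseEstimator):
    """Sklearn-style transformer mapping columns onto a reference distribution.

    ``fit`` learns the reference (row-wise mean of the sorted training
    columns); ``transform`` replaces each column's values by the reference
    value at the corresponding rank, averaging quantiles across ties.
    """

    def fit(self, X, y=None):
        X = self._as_frame(X)
        if X.shape[1] < 2:
            warnings.warn("fitting a quantile reference from < 2 samples")
        self.reference_ = np.sort(X.to_numpy(dtype=float), axis=0).mean(axis=1)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        if not hasattr(self, "reference_"):
            raise ExpressionError("QuantileNormalizer is not fitted")
        X = self._as_frame(X)
        return _map_to_reference(X, self.reference_)

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X, dtype=float)
        return pd.DataFrame(X)


# ---------------------------------------------------------------------------
# paired tests


def _as_time_means(series: Mapping[float, float | Iterable[float]]) -> pd.Series:
    out = {}
    for t, v in dict(series).items():
        arr = np.atleast_1d(np.asarray(v, dtype=float))
        out[float(t)] = float(arr.mean())
    return pd.Series(out).sort_index()


def paired_t(values_a_by_time: Mapping, values_b_by_time: Mapping) -> tuple[float, float, float]:
    """Two-sided paired t-test of two cohorts matched by collection time.

    Replicates are averaged within each (cohort, time) cell before pairing, so
    the differences are one per shared time point. Returns ``(t, p,
    mean_diff)`` with ``mean_diff`` the mean log2 difference A - B.

    Zero-variance conventions: identical series give ``p = 1``; a constant
    nonzero difference gives the ``p -> 0`` limit (t is signed infinity).
    """
    a = _as_time_means(values_a_by_time)
    b = _as_time_means(values_b_by_time)
    if set(a.index) != set(b.index):
        raise ExpressionError(
            f"time grids differ: {sorted(set(a.index) ^ set(b.index))}")
    if len(a) < 2:
        raise ExpressionError("paired t-test needs >= 2 matched time points")
    diffs = (a - b.loc[a.index]).to_numpy()
    t, p, mean, _ = _t_from_diffs(diffs[None, :])
    return float(t[0]), float(p[0]), float(mean[0])


def _t_from_diffs(diffs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized one-sample t on rows of paired differences.

    Returns (t, p, mean, zero_variance_flag); the flag marks rows where the
    p-value came from the degenerate zero-variance convention.
    """
    n = diffs.shape[1]
    mean = diffs.mean(axis=1)
    sd = diffs.std(axis=1, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    # conventions for degenerate inputs
    with np.errstate(invalid="ignore"):
        t = np.where(zero_var & (mean == 0), 0.0, t)
        t = np.where(zero_var & (mean != 0), np.sign(mean) * np.inf, t)
    p = np.where(zero_var & (mean == 0), 1.0, p)
    p = np.where(zero_var & (mean != 0), 0.0, p)
    flagged = zero_var & (mean != 0)
    return t, p, mean, flagged


def run_comparisons(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Paired tests for RF-vs-CF, SF-vs-CF and SF-vs-RF with pooled BH FDR.

    All three comparisons are computed per gene over the shared time grid and
    the q-values come from one Benjamini-Hochberg step-up over the pooled
    vector of all 3 x n_genes p-values.

    Returns a long DataFrame with columns ``gene_id, comparison,
    mean_diff_log2, fold_change, t, p, q, zero_variance``.
    """
    present = matrix.cohorts()
    for cohort in COHORTS:
        if cohort not in present:
            raise ExpressionError(f"cohort {cohort!r} missing from matrix")
    grids = {c: tuple(matrix.timepoints(c)) for c in COHORTS}
    if len(set(grids.values())) != 1:
        raise ExpressionError(f"cohort time grids differ: {grids}")

    means = {c: matrix.time_means(c).to_numpy() for c in COHORTS}
    frames = []
    for (num, ref), name in zip(COMPARISON_PAIRS, COMPARISONS):
        diffs = means[num] - means[ref]
        t, p, mean, flagged = _t_from_diffs(diffs)
        frames.append(pd.DataFrame({
            "gene_id": matrix.genes,
            "comparison": name,
            "mean_diff_log2": mean,
            "fold_change": np.exp2(mean),
            "t": t,
            "p": p,
            "zero_variance": flagged,
        }))
    table = pd.concat(frames, ignore_index=True)
    table["q"] = bh_fdr(table["p"].to_numpy())
    return table


def bh_fdr(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min_{j : p_j >= p_i} m * p_j / rank_j`` capped at 1; monotone in p.
    """
    p = np.asarray(list(p_values) if not isinstance(p_values, np.ndarray) else p_values,
                   dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ExpressionError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def variance_filter(matrix: ExpressionMatrix, min_sd: float) -> ExpressionMatrix:
    """Drop genes whose overall SD falls below ``min_sd`` (off by default).

    A coarse expressed-gene filter for gene-level matrices; probe-level
    filtering of raw arrays is out of scope.
    """
    sd = matrix.values.std(axis=1, ddof=1)
    keep = sd >= min_sd
    return ExpressionMatrix(matrix.values.loc[keep], matrix.metadata.copy())


def write_comparisons(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_comparisons(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
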