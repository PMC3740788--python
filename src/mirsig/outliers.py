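"""Cancer-outlier detection statistics and the consensus accuracy benchmark.

Five per-feature statistics are implemented — the classical two-sample t and
four outlier statistics designed for heterogeneous activation (a shift in
only a subset of tumour samples): COPA, OS (outlier sum), ORT (outlier-robust
t) and MOST (maximum ordered subset t).  All statistics are computed on both
tails (original and negated values) and the larger kept with its direction,
since disease signatures contain both up- and down-regulated features.

Conventions fixed here because the source methods differ:

* MAD is scaled by 1.4826 (consistency with the normal SD).
* Quartiles/percentiles use linear interpolation (numpy default).
* Undefined statistics (zero MAD / zero variance) are flagged, ranked after
  all defined values and never selected.
"""

from __future__ import annotations

import logging
import math
import warnings
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datasets import ExpressionDataset, NORMAL, TUMOR

log = logging.getLogger(__name__)

MAD_SCALE = 1.4826
METHODS = ("t", "COPA", "OS", "ORT", "MOST")

DEFAULT_NULL_B = 20_000
DEFAULT_NULL_SEED = 2024


@dataclass
class BenchmarkConfig:
    """Selection fraction and consensus rule for the accuracy benchmark."""

    selection_fraction: float = 0.05
    min_methods: int = 3
    copa_percentile: float = 90.0

    def __post_init__(self) -> None:
        if not (0.0 < self.selection_fraction < 1.0):
            raise ValueError("selection_fraction must be in (0, 1)")
        if not (1 <= self.min_methods <= len(METHODS)):
            raise ValueError("min_methods must be between 1 and 5")


# ---------------------------------------------------------------------------
# MOST null moments
# ---------------------------------------------------------------------------

@dataclass
class MostNullTable:
    """Monte-Carlo moments of the sum of the top-k order statistics of
    ``n_tumor`` standard normals, for k = 1..n_tumor."""

    n_tumor: int
    mu: np.ndarray
    sigma: np.ndarray
    B: int
    seed: int


_NULL_CACHE: dict[tuple[int, int, int], MostNullTable] = {}


def most_null_moments(n_tumor: int, B: int = DEFAULT_NULL_B, seed: int = DEFAULT_NULL_SEED) -> MostNullTable:
    """Estimate (mu_k, sigma_k) for the MOST standardization by simulation."""
    if n_tumor < 1:
        raise ValueError("n_tumor must be >= 1")
    if B < 1000:
        raise ValueError("B must be >= 1000")
    key = (n_tumor, B, seed)
    if key in _NULL_CACHE:
        return _NULL_CACHE[key]
    rng = np.random.default_rng(seed)
    draws = rng.standard_normal((B, n_tumor))
    draws.sort(axis=1)
    cum = np.cumsum(draws[:, ::-1], axis=1)  # sum of top-k
    table = MostNullTable(
        n_tumor=n_tumor,
        mu=cum.mean(axis=0),
        sigma=cum.std(axis=0, ddof=1),
        B=B,
        seed=seed,
    )
    _NULL_CACHE[key] = table
    return table


# ---------------------------------------------------------------------------
# matrix statistics (NaN-aware, one value per feature; NaN = undefined)
# ---------------------------------------------------------------------------

@contextmanager
def _quiet_nan():
    """Rows flagged undefined (zero MAD) legitimately produce all-NaN slices."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="All-NaN slice", category=RuntimeWarning)
        warnings.filterwarnings("ignore", message="Mean of empty slice", category=RuntimeWarning)
        yield


def _t_matrix(X: np.ndarray, normal: np.ndarray, tumor: np.ndarray, welch: bool = False) -> np.ndarray:
    Xn, Xt = X[:, normal], X[:, tumor]
    n1 = np.isfinite(Xn).sum(axis=1).astype(float)
    n2 = np.isfinite(Xt).sum(axis=1).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m2 = np.nanmean(Xn, axis=1), np.nanmean(Xt, axis=1)
        v1 = np.nanvar(Xn, axis=1, ddof=1)
        v2 = np.nanvar(Xt, axis=1, ddof=1)
        if welch:
            se2 = v1 / n1 + v2 / n2
        else:
            s2p = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
            se2 = s2p * (1 / n1 + 1 / n2)
        t = (m2 - m1) / np.sqrt(se2)
    t[(n1 < 2) | (n2 < 2) | ~(se2 > 0)] = np.nan
    return t


def _standardize_all(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median/MAD standardization over all samples; returns (Z, mad)."""
    med = np.nanmedian(X, axis=1, keepdims=True)
    mad = MAD_SCALE * np.nanmedian(np.abs(X - med), axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - med) / mad
    return Z, mad[:, 0]


def _copa_matrix(X: np.ndarray, normal: np.ndarray, tumor: np.ndarray, r: float = 90.0) -> np.ndarray:
    Z, mad = _standardize_all(X)
    with np.errstate(invalid="ignore"), _quiet_nan():
        stat = np.nanpercentile(Z[:, tumor], r, axis=1)
    stat[~(mad > 0)] = np.nan
    return stat


def _os_matrix(X: np.ndarray, normal: np.ndarray, tumor: np.ndarray) -> np.ndarray:
    Z, mad = _standardize_all(X)
    with _quiet_nan():
        q75 = np.nanpercentile(Z, 75, axis=1)
        q25 = np.nanpercentile(Z, 25, axis=1)
    cutoff = q75 + (q75 - q25)
    Zt = Z[:, tumor]
    with np.errstate(invalid="ignore"):
        over = Zt > cutoff[:, None]
    stat = np.where(over, Zt, 0.0)
    stat = np.nansum(stat, axis=1)
    stat[~(mad > 0)] = np.nan
    return stat


def _ort_matrix(X: np.ndarray, normal: np.ndarray, tumor: np.ndarray) -> np.ndarray:
    Xn, Xt = X[:, normal], X[:, tumor]
    med_n = np.nanmedian(Xn, axis=1)
    med_t = np.nanmedian(Xt, axis=1)
    q75n = np.nanpercentile(Xn, 75, axis=1)
    q25n = np.nanpercentile(Xn, 25, axis=1)
    cutoff = q75n + (q75n - q25n)
    # pooled robust scale: median of |x - own-group median| over every sample
    res_n = np.abs(Xn - med_n[:, None])
    res_t = np.abs(Xt - med_t[:, None])
    scale = MAD_SCALE * np.nanmedian(np.concatenate([res_n, res_t], axis=1), axis=1)
    with np.errstate(invalid="ignore"):
        over = Xt > cutoff[:, None]
        contrib = np.where(over, Xt - med_n[:, None], 0.0)
    stat = np.nansum(contrib, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = stat / scale
    stat[~(scale > 0)] = np.nan
    return stat


def _most_matrix(
    X: np.ndarray,
    normal: np.ndarray,
    tumor: np.ndarray,
    null_B: int = DEFAULT_NULL_B,
    null_seed: int = DEFAULT_NULL_SEED,
    scale: str = "normal",
) -> np.ndarray:
    Xn, Xt = X[:, normal], X[:, tumor]
    med_n = np.nanmedian(Xn, axis=1)
    if scale == "normal":
        mad_n = MAD_SCALE * np.nanmedian(np.abs(Xn - med_n[:, None]), axis=1)
    elif scale == "pooled":
        # ORT-style robust scale from both groups' residuals (more stable at
        # small n; the normal-only MAD is the default reference behaviour)
        med_t = np.nanmedian(Xt, axis=1)
        res = np.concatenate(
            [np.abs(Xn - med_n[:, None]), np.abs(Xt - med_t[:, None])], axis=1
        )
        mad_n = MAD_SCALE * np.nanmedian(res, axis=1)
    else:
        raise ValueError(f"unknown MOST scale {scale!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        Zt = (Xt - med_n[:, None]) / mad_n[:, None]
    n_obs = np.isfinite(Zt).sum(axis=1)
    # descending sort, NaNs pushed to the back
    desc = -np.sort(-Zt, axis=1)
    stat = np.full(X.shape[0], np.nan)
    for m in np.unique(n_obs):
        if m < 1:
            continue
        rows = np.flatnonzero((n_obs == m) & (mad_n > 0))
        if rows.size == 0:
            continue
        table = most_null_moments(int(m), B=null_B, seed=null_seed)
        M = np.cumsum(desc[rows, : int(m)], axis=1)
        stat[rows] = ((M - table.mu) / table.sigma).max(axis=1)
    return stat


_MATRIX_FUNCS = {
    "t": _t_matrix,
    "COPA": _copa_matrix,
    "OS": _os_matrix,
    "ORT": _ort_matrix,
    "MOST": _most_matrix,
}


# ---------------------------------------------------------------------------
# single-feature wrappers (reference entry points; the pipeline uses matrices)
# ---------------------------------------------------------------------------

def _as_matrix(values: Sequence[float], groups: Sequence[str]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    x = np.asarray(values, dtype=float)[None, :]
    g = np.asarray(groups)
    return x, g == NORMAL, g == TUMOR


def stat_t(values: Sequence[float], groups: Sequence[str], welch: bool = False) -> float:
    """Two-sample t statistic (pooled variance by default), tumour minus normal."""
    X, n, t = _as_matrix(values, groups)
    return float(_t_matrix(X, n, t, welch=welch)[0])


def stat_copa(values: Sequence[float], groups: Sequence[str], r: float = 90.0) -> float:
    """COPA: r-th percentile of median/MAD-standardized tumour values."""
    X, n, t = _as_matrix(values, groups)
    return float(_copa_matrix(X, n, t, r=r)[0])


def stat_os(values: Sequence[float], groups: Sequence[str]) -> float:
    """Outlier sum: sum of standardized tumour values above q75+IQR of all samples."""
    X, n, t = _as_matrix(values, groups)
    return float(_os_matrix(X, n, t)[0])


def stat_ort(values: Sequence[float], groups: Sequence[str]) -> float:
    """Outlier-robust t: normal-referenced outlier sum over a pooled robust scale."""
    X, n, t = _as_matrix(values, groups)
    return float(_ort_matrix(X, n, t)[0])


def stat_most(values: Sequence[float], groups: Sequence[str], null_table: MostNullTable) -> float:
    """MOST: max over k of the null-standardized sum of the top-k tumour values."""
    X, n, t = _as_matrix(values, groups)
    n_obs = int(np.isfinite(X[0, t]).sum())
    if n_obs != null_table.n_tumor:
        raise ValueError("null table does not match the number of observed tumour samples")
    return float(
        _most_matrix(X, n, t, null_B=null_table.B, null_seed=null_table.seed)[0]
    )


# ---------------------------------------------------------------------------
# scoring, selection, consensus, benchmark
# ---------------------------------------------------------------------------

@dataclass
class OutlierScoreTable:
    """Per-feature statistic, direction, rank and selection flag for one method."""

    dataset_id: str
    method: str
    table: pd.DataFrame  # columns: statistic, direction, rank, selected

    @property
    def selected(self) -> set[str]:
        return set(self.table.index[self.table["selected"]])

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out.insert(0, "method", self.method)
        return out


def score_dataset(
    data: ExpressionDataset,
    method: str,
    selection_fraction: float = 0.05,
    copa_percentile: float = 90.0,
    welch: bool = False,
    null_B: int = DEFAULT_NULL_B,
    null_seed: int = DEFAULT_NULL_SEED,
) -> OutlierScoreTable:
    """Score every feature with one method, two-sided, and select the top fraction.

    The statistic is computed on the original and the negated values; the
    larger is kept with direction ``up``/``down``.  Features rank by
    decreasing statistic (undefined last, ties broken by feature id) and the
    top ``ceil(fraction * n)`` defined features are selected.
    """
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {METHODS}")
    if not (0.0 < selection_fraction < 1.0):
        raise ValueError("selection_fraction must be in (0, 1)")
    data.require_min_group_size(2)
    X = data.matrix()
    normal = data.group_mask(NORMAL)
    tumor = data.group_mask(TUMOR)

    kwargs: dict = {}
    if method == "COPA":
        kwargs["r"] = copa_percentile
    elif method == "t":
        kwargs["welch"] = welch
    elif method == "MOST":
        kwargs["null_B"] = null_B
        kwargs["null_seed"] = null_seed
    func = _MATRIX_FUNCS[method]
    up = func(X, normal, tumor, **kwargs)
    down = func(-X, normal, tumor, **kwargs)

    both_nan = np.isnan(up) & np.isnan(down)
    up_f = np.where(np.isnan(up), -np.inf, up)
    down_f = np.where(np.isnan(down), -np.inf, down)
    stat = np.where(up_f >= down_f, up_f, down_f)
    direction = np.where(up_f >= down_f, "up", "down")
    stat = np.where(both_nan, np.nan, stat)

    n = len(stat)
    order = sorted(
        range(n),
        key=lambda i: (np.isnan(stat[i]), -(stat[i] if not np.isnan(stat[i]) else 0.0), data.feature_ids[i]),
    )
    rank = np.empty(n, dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    cutoff = math.ceil(selection_fraction * n)
    selected = (rank <= cutoff) & ~np.isnan(stat)

    table = pd.DataFrame(
        {
            "statistic": stat,
            "direction": direction,
            "rank": rank,
            "selected": selected,
        },
        index=pd.Index(data.feature_ids, name="feature_id"),
    )
    return OutlierScoreTable(dataset_id=data.dataset_id, method=method, table=table)


def score_all_methods(data: ExpressionDataset, config: BenchmarkConfig | None = None) -> dict[str, OutlierScoreTable]:
    config = config or BenchmarkConfig()
    return {
        m: score_dataset(
            data, m,
            selection_fraction=config.selection_fraction,
            copa_percentile=config.copa_percentile,
        )
        for m in METHODS
    }


def consensus_putative(score_tables: Iterable[OutlierScoreTable], min_methods: int = 3) -> set[str]:
    """Features selected by at least ``min_methods`` methods (the putative list)."""
    tables = list(score_tables)
    if not tables:
        raise ValueError("no score tables supplied")
    universes = {frozenset(t.table.index) for t in tables}
    if len(universes) != 1:
        raise ValueError("score tables cover different feature universes")
    counts: dict[str, int] = {}
    for t in tables:
        for f in t.selected:
            counts[f] = counts.get(f, 0) + 1
    return {f for f, c in counts.items() if c >= min_methods}


def method_accuracy(
    datasets: Sequence[ExpressionDataset],
    config: BenchmarkConfig | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus accuracy benchmark across datasets.

    For each dataset the five methods are scored, the putative list is the
    >= ``min_methods`` consensus, and each method's proportion is the share
    of its selections that are putative.  A method's accuracy is the median
    proportion across datasets.  Returns ``(accuracy, per_dataset_table)``.
    """
    config = config or BenchmarkConfig()
    if not datasets:
        raise ValueError("need at least one dataset")
    rows: dict[str, dict[str, float]] = {m: {} for m in METHODS}
    for ds in datasets:
        tables = score_all_methods(ds, config)
        putative = consensus_putative(tables.values(), config.min_methods)
        for m, tab in tables.items():
            sel = tab.selected
            if not sel:
                log.warning("method %s selected nothing on %s; excluded from median", m, ds.dataset_id)
                rows[m][ds.dataset_id] = np.nan
            else:
                rows[m][ds.dataset_id] = len(sel & putative) / len(sel)
    per_dataset = pd.DataFrame(rows).T
    per_dataset.index.name = "method"
    accuracy = per_dataset.median(axis=1, skipna=True)
    accuracy.name = "accuracy"
    return accuracy, per_dataset
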