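"""Array-style preprocessing: normexp background correction, quantile
normalization, probe averaging/collapsing, and kNN missing-value imputation.

The default chain (mirroring standard two-colour/bead array practice) is
normexp -> quantile -> probe averaging -> kNN imputation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import log_ndtr
from scipy.stats import norm

from .datasets import ExpressionDataset

log = logging.getLogger(__name__)


@dataclass
class NormexpParams:
    """Parameters of the normal + exponential convolution model.

    Observed intensity X = B + S with background B ~ Normal(mu, sigma^2) and
    signal S ~ Exponential(mean alpha_exp).  The corrected value is the
    posterior mean E[S | X = x] (+ offset), which is strictly positive.
    """

    mu: float
    sigma: float
    alpha_exp: float
    offset: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma > 0):
            raise ValueError("sigma must be > 0")
        if not (self.alpha_exp > 0):
            raise ValueError("alpha_exp must be > 0")


@dataclass
class PreprocessConfig:
    knn_k: int = 5
    offset: float = 0.0
    probe_map: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        if self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")


# ---------------------------------------------------------------------------
# normexp background correction
# ---------------------------------------------------------------------------

def normexp_signal(x: np.ndarray, params: NormexpParams) -> np.ndarray:
    """Posterior-mean signal E[S | X = x] + offset under the convolution model.

    With m = x - mu - sigma^2/alpha, the posterior mean is
    m + sigma * phi(m/sigma) / Phi(m/sigma); computed in log space so the
    deep-background tail (m/sigma << 0) stays finite and positive.
    """
    x = np.asarray(x, dtype=float)
    m = x - params.mu - params.sigma**2 / params.alpha_exp
    z = m / params.sigma
    # phi(z)/Phi(z) via logs; for z -> -inf the ratio ~ -z so the sum ~ -1/z > 0
    ratio = np.exp(norm.logpdf(z) - log_ndtr(z))
    return m + params.sigma * ratio + params.offset


def normexp_loglik(x: np.ndarray, mu: float, sigma: float, alpha: float) -> float:
    """Log-likelihood of the normal+exponential convolution density."""
    z = (x - mu) / sigma - sigma / alpha
    ll = -math.log(alpha) + (mu - x) / alpha + sigma**2 / (2 * alpha**2) + log_ndtr(z)
    return float(np.sum(ll))


def fit_normexp(x: np.ndarray) -> NormexpParams:
    """Maximum-likelihood fit of (mu, sigma, alpha_exp) to one sample's values."""
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise ValueError("need at least 50 observed values to estimate normexp parameters")

    mu0 = float(np.quantile(x, 0.05))
    low = x[x <= np.quantile(x, 0.25)]
    sigma0 = max(float(np.std(low)), 1e-2)
    alpha0 = max(float(np.mean(x) - mu0), 1e-2)

    def nll(theta: np.ndarray) -> float:
        mu, log_sigma, log_alpha = theta
        return -normexp_loglik(x, mu, math.exp(log_sigma), math.exp(log_alpha))

    theta0 = np.array([mu0, math.log(sigma0), math.log(alpha0)])
    res = optimize.minimize(nll, theta0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
    if not res.success:
        raise RuntimeError(f"normexp estimation did not converge: {res.message}")
    mu, log_sigma, log_alpha = res.x
    return NormexpParams(mu=float(mu), sigma=float(math.exp(log_sigma)),
                         alpha_exp=float(math.exp(log_alpha)))


def normexp_correct(
    raw: ExpressionDataset,
    params_per_sample: NormexpParams | Mapping[str, NormexpParams] | str = "estimate",
    offset: float = 0.0,
) -> ExpressionDataset:
    """Background-correct every sample with the normexp posterior mean.

    ``params_per_sample`` may be a single :class:`NormexpParams` applied to all
    samples, a mapping sample id -> params, or ``"estimate"`` to fit each
    sample by maximum likelihood.
    """
    vals = raw.values.to_numpy(dtype=float)
    obs = np.isfinite(vals)
    if not obs.all() and np.isinf(vals[~np.isnan(vals)]).any():
        raise ValueError("non-finite (infinite) intensities in input")
    out = np.full_like(vals, np.nan)
    for j, sample in enumerate(raw.sample_ids):
        col = vals[:, j]
        mask = np.isfinite(col)
        if isinstance(params_per_sample, str):
            if params_per_sample != "estimate":
                raise ValueError(f"unknown parameter mode {params_per_sample!r}")
            try:
                p = fit_normexp(col[mask])
            except RuntimeError as err:
                raise RuntimeError(f"normexp estimation failed for sample {sample}: {err}")
            p = NormexpParams(p.mu, p.sigma, p.alpha_exp, offset=offset)
        elif isinstance(params_per_sample, NormexpParams):
            p = params_per_sample
        else:
            p = params_per_sample[sample]
        out[mask, j] = normexp_signal(col[mask], p)
    return raw.with_values(pd.DataFrame(out, index=raw.feature_ids, columns=raw.sample_ids))


# ---------------------------------------------------------------------------
# quantile normalization
# ---------------------------------------------------------------------------

def quantile_normalize(data: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the mean empirical distribution.

    The reference is the across-sample mean of each column's sorted observed
    values, interpolated onto a common grid of ``n_feature`` quantiles so
    columns with missing entries contribute too.  Within-column rank order is
    preserved; ties get stable (first-occurrence-first) ranks; missing entries
    stay missing.  On complete data the usual post-condition holds exactly:
    every column's sorted values equal the reference.
    """
    if data.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    X = data.matrix()
    n_feat, n_samp = X.shape
    grid = np.linspace(0.0, 1.0, n_feat)
    per_col_quantiles = np.empty((n_feat, n_samp))
    for j in range(n_samp):
        obs = X[np.isfinite(X[:, j]), j]
        if obs.size < 2:
            raise ValueError(f"sample {data.sample_ids[j]} has fewer than 2 observed values")
        per_col_quantiles[:, j] = np.quantile(obs, grid)
    reference = per_col_quantiles.mean(axis=1)

    out = np.full_like(X, np.nan)
    for j in range(n_samp):
        idx = np.flatnonzero(np.isfinite(X[:, j]))
        m = idx.size
        targets = reference if m == n_feat else np.interp(np.linspace(0.0, 1.0, m), grid, reference)
        order = np.argsort(X[idx, j], kind="stable")
        col = np.empty(m)
        col[order] = targets
        out[idx, j] = col
    return data.with_values(pd.DataFrame(out, index=data.feature_ids, columns=data.sample_ids))


# ---------------------------------------------------------------------------
# probe handling
# ---------------------------------------------------------------------------

def average_probes(data: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Average all probes of each feature, per sample, ignoring missing entries.

    Probes absent from ``probe_map`` are dropped (count logged).
    """
    if not probe_map:
        raise ValueError("empty probe map")
    mapped = [p for p in data.feature_ids if p in probe_map]
    dropped = data.n_features - len(mapped)
    if dropped:
        log.info("average_probes: dropping %d unmapped probes", dropped)
    sub = data.values.loc[mapped]
    grouped = sub.groupby([probe_map[p] for p in mapped], sort=True).mean()
    grouped.index.name = None
    return data.with_values(grouped)


def collapse_multiprobe_genes(data: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Keep only genes measured by exactly one probe; rename probe -> gene."""
    if probe_map is None:
        raise ValueError("probe_map must be provided")
    present = [p for p in data.feature_ids if p in probe_map]
    counts: dict[str, int] = {}
    for p in present:
        counts[probe_map[p]] = counts.get(probe_map[p], 0) + 1
    keep = [p for p in present if counts[probe_map[p]] == 1]
    removed_genes = sum(1 for g, c in counts.items() if c > 1)
    if removed_genes:
        log.info("collapse_multiprobe_genes: removed %d multi-probe genes", removed_genes)
    if not keep:
        log.warning("collapse_multiprobe_genes: no single-probe genes remain; empty dataset")
    out = data.values.loc[keep].copy()
    out.index = [probe_map[p] for p in keep]
    return data.with_values(out)


# ---------------------------------------------------------------------------
# kNN imputation
# ---------------------------------------------------------------------------

def knn_impute(data: ExpressionDataset, k: int = 5) -> ExpressionDataset:
    """Fill missing cells from the k nearest features (expression profiles).

    Distance between two features is the root-mean-square difference over the
    samples observed in both.  For a missing cell (f, s) the candidate
    neighbours are features observed at sample s that share at least one
    observed sample with f; the cell gets the mean of the k nearest
    candidates' values at s (all candidates when fewer than k exist).
    Observed cells are never modified.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = data.matrix()
    obs = np.isfinite(X)
    fully_missing = [data.feature_ids[i] for i in np.flatnonzero(~obs.any(axis=1))]
    if fully_missing:
        raise ValueError(f"features with no observed values: {fully_missing}")
    if obs.all():
        return data.with_values(data.values.copy())

    out = X.copy()
    ids = data.feature_ids
    need = np.flatnonzero(~obs.all(axis=1))
    for i in need:
        # distances from feature i to all others over shared observed samples
        shared = obs[i] & obs  # (n_feat, n_samp)
        n_shared = shared.sum(axis=1)
        diff = np.where(shared, X[i] - np.where(obs, X, 0.0), 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dist = np.sqrt(np.where(n_shared > 0, (diff**2).sum(axis=1) / np.maximum(n_shared, 1), np.inf))
        dist[i] = np.inf
        dist[n_shared == 0] = np.inf
        for s in np.flatnonzero(~obs[i]):
            cand = np.flatnonzero(obs[:, s] & np.isfinite(dist))
            if cand.size == 0:
                raise ValueError(
                    f"no imputation candidates for feature {ids[i]} at sample {data.sample_ids[s]}"
                )
            ranked = sorted(cand, key=lambda c: (dist[c], ids[c]))
            chosen = ranked[: min(k, len(ranked))]
            out[i, s] = float(np.mean([X[c, s] for c in chosen]))
    return data.with_values(pd.DataFrame(out, index=ids, columns=data.sample_ids))


def preprocess_pipeline(
    raw: ExpressionDataset,
    config: PreprocessConfig | None = None,
    background: str | NormexpParams | Mapping[str, NormexpParams] | None = None,
) -> ExpressionDataset:
    """Run the default chain: normexp -> quantile -> average probes -> impute.

    ``background=None`` skips background correction (data already on a
    corrected/log scale); pass ``"estimate"`` or explicit parameters to apply
    normexp first.
    """
    config = config or PreprocessConfig()
    ds = raw
    if background is not None:
        ds = normexp_correct(ds, background, offset=config.offset)
    ds = quantile_normalize(ds)
    if config.probe_map:
        ds = average_probes(ds, config.probe_map)
    if not np.isfinite(ds.matrix()).all():
        ds = knn_impute(ds, k=config.knn_k)
    return ds
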