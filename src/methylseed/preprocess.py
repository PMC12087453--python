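"""Probe filtering, β↔M transforms, and empirical-Bayes batch adjustment.

Matrices are pandas DataFrames with probes as rows and samples as columns.
β values live in [0, 1]; M values are log2 odds, ``M = log2(β/(1−β))``,
preferred for linear modelling because they are closer to homoskedastic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EPSILON = 1e-6  # logit clip keeping M finite for β∈{0,1}

#: Order in which filter reasons are applied; a probe is counted once,
#: under the first reason that removes it.
FILTER_ORDER = ("detection", "snp", "xy", "cross_hybridizing")


@dataclass
class ProbeMask:
    """Probe sets to exclude, plus an optional probe x sample detection-failure matrix.

    IDs not present in the target matrix are ignored (counted in the report's
    ``unknown_ids``).
    """

    snp_probes: set[str] = field(default_factory=set)
    xy_probes: set[str] = field(default_factory=set)
    cross_hybridizing: set[str] = field(default_factory=set)
    detection_fail: pd.DataFrame | None = None  # boolean, True = failed


@dataclass
class FilterReport:
    removed: dict[str, int]
    n_in: int
    n_out: int
    unknown_ids: int

    def to_dict(self) -> dict:
        return {
            "removed": dict(self.removed),
            "n_in": self.n_in,
            "n_out": self.n_out,
            "unknown_ids": self.unknown_ids,
        }


def filter_probes(
    beta: pd.DataFrame,
    mask: ProbeMask,
    detection_alpha: float = 0.05,
    max_fail_fraction: float = 0.0,
) -> tuple[pd.DataFrame, FilterReport]:
    """Remove masked probes from a β matrix.

    Reasons are applied in the fixed order detection → SNP → XY →
    cross-hybridizing, and each removed probe is attributed to the first
    reason that hits it, so reports are deterministic.  A probe fails
    detection when its failure fraction across samples exceeds
    ``max_fail_fraction`` (default 0: one failing sample is enough).
    ``detection_alpha`` is applied when ``mask.detection_fail`` holds
    p-values rather than booleans.
    """
    if beta.shape[0] == 0:
        raise ValueError("empty β matrix")
    universe = set(beta.index)
    unknown = 0
    reason_sets: dict[str, set[str]] = {}

    det: set[str] = set()
    if mask.detection_fail is not None:
        d = mask.detection_fail.reindex(index=beta.index, columns=beta.columns)
        if d.dtypes.apply(pd.api.types.is_bool_dtype).all():
            fail = d.fillna(False)
        else:
            fail = d.astype(float) > detection_alpha
            fail = fail.fillna(False)
        frac = fail.mean(axis=1)
        det = set(beta.index[frac > max_fail_fraction])
    reason_sets["detection"] = det
    for reason, ids in (
        ("snp", mask.snp_probes),
        ("xy", mask.xy_probes),
        ("cross_hybridizing", mask.cross_hybridizing),
    ):
        unknown += len(set(ids) - universe)
        reason_sets[reason] = set(ids) & universe

    removed: dict[str, int] = {}
    dropped: set[str] = set()
    for reason in FILTER_ORDER:
        new = reason_sets[reason] - dropped
        removed[reason] = len(new)
        dropped |= new

    kept = beta.loc[[p for p in beta.index if p not in dropped]]
    if kept.shape[0] == 0:
        raise ValueError("all probes removed by filtering")
    report = FilterReport(removed=removed, n_in=beta.shape[0], n_out=kept.shape[0], unknown_ids=unknown)
    return kept, report


def beta_to_m(beta: pd.DataFrame, epsilon: float = EPSILON) -> pd.DataFrame:
    """M = log2(β′/(1−β′)) with β clipped into [epsilon, 1−epsilon]."""
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    m = np.log2(b / (1.0 - b))
    return pd.DataFrame(m, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    """Inverse logit: β = 2^M / (1 + 2^M), computed stably for large |M|."""
    x = np.asarray(m, dtype=float)
    b = np.where(x >= 0, 1.0 / (1.0 + np.exp2(-x)), np.exp2(x) / (1.0 + np.exp2(x)))
    return pd.DataFrame(b, index=m.index, columns=m.columns)


def _design(covariates: pd.DataFrame | None, n: int) -> np.ndarray:
    """Intercept + covariate columns (categoricals one-hot, first level dropped)."""
    cols = [np.ones(n)]
    if covariates is not None:
        for c in covariates.columns:
            col = covariates[c]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
            else:
                dummies = pd.get_dummies(col, drop_first=True)
                for dc in dummies.columns:
                    cols.append(dummies[dc].to_numpy(dtype=float))
    return np.column_stack(cols)


def batch_adjust(
    m: pd.DataFrame,
    batch: pd.Series | list,
    covariates_to_preserve: pd.DataFrame | None = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Parametric empirical-Bayes location/scale batch adjustment of M-values.

    Per probe the model is standardised against a design that carries batch
    indicators plus any covariates to protect; per-batch locations γ and
    scales δ² are estimated, shrunk toward batch-level priors (normal prior
    for γ, inverse-gamma for δ² with method-of-moments hyperparameters,
    solved by the standard iterative conditional updates), then removed.
    The grand location/scale and protected covariate effects are restored.

    A single batch is a no-op.  Every batch must contain ≥2 samples.
    """
    batch = pd.Series(list(batch), index=m.columns)
    levels = sorted(batch.unique(), key=str)
    if len(levels) == 1:
        return m.copy()
    counts = batch.value_counts()
    small = [str(b) for b in levels if counts[b] < 2]
    if small:
        raise ValueError(f"batches with <2 samples: {small}")

    Y = np.asarray(m, dtype=float)  # probes x samples
    G, n = Y.shape
    # cell-means batch design + protected covariates
    B = np.column_stack([(batch == b).to_numpy(dtype=float) for b in levels])
    X = B
    if covariates_to_preserve is not None:
        C = _design(covariates_to_preserve, n)[:, 1:]  # intercept absorbed by batch block
        if C.shape[1]:
            X = np.column_stack([B, C])
    beta_hat, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, G)
    n_batches = len(levels)
    batch_sizes = np.array([counts[b] for b in levels], dtype=float)
    # grand (batch-size weighted) location per probe
    grand = (batch_sizes / n) @ beta_hat[:n_batches]  # (G,)
    fitted = X @ beta_hat  # n x G
    resid = Y.T - fitted
    var_pooled = (resid**2).sum(axis=0) / n  # (G,)
    var_pooled = np.maximum(var_pooled, 1e-12)
    sd = np.sqrt(var_pooled)

    stand_mean = np.tile(grand, (n, 1))
    if X.shape[1] > n_batches:
        stand_mean = stand_mean + X[:, n_batches:] @ beta_hat[n_batches:]
    Z = (Y.T - stand_mean) / sd  # n x G standardised

    Z_adj = Z.copy()
    for j, b in enumerate(levels):
        idx = (batch == b).to_numpy()
        nb = int(idx.sum())
        Zb = Z[idx]  # nb x G
        gamma_hat = Zb.mean(axis=0)
        # population (ddof=0) variance, consistent with the /n pooled variance:
        # keeps the adjustment an exact fixed point once batch effects are gone
        delta_hat = Zb.var(axis=0, ddof=0)
        # hyperpriors by method of moments across probes
        gamma_bar = gamma_hat.mean()
        tau2 = gamma_hat.var(ddof=1)
        d_mean = delta_hat.mean()
        d_var = delta_hat.var(ddof=1)
        lam = (2 * d_var + d_mean**2) / max(d_var, 1e-12)  # inverse-gamma shape
        theta = (d_mean * d_var + d_mean**3) / max(d_var, 1e-12)  # inverse-gamma scale
        gamma_star = gamma_hat.copy()
        delta_star = np.maximum(delta_hat.copy(), 1e-12)
        for _ in range(max_iter):
            g_new = (tau2 * nb * gamma_hat + delta_star * gamma_bar) / (tau2 * nb + delta_star)
            ssq = ((Zb - g_new) ** 2).sum(axis=0)
            d_new = (theta + 0.5 * ssq) / (nb / 2 + lam - 1)
            d_new = np.maximum(d_new, 1e-12)
            change = max(
                np.abs(g_new - gamma_star).max(initial=0),
                np.abs(d_new - delta_star).max(initial=0),
            )
            gamma_star, delta_star = g_new, d_new
            if change < tol:
                break
        Z_adj[idx] = (Zb - gamma_star) / np.sqrt(delta_star)

    out = Z_adj * sd + stand_mean
    return pd.DataFrame(out.T, index=m.index, columns=m.columns)
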