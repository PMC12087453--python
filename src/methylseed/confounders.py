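"""Source-of-variation analysis, confounder adjustment, and inflation diagnostics.

The source-of-variation (SOV) screen fits, per probe, one linear model
containing all declared clinical factors and computes each factor's marginal
(type-III) F statistic — the variance-explained ratio when that factor's
columns are dropped from the joint model.  Averaging F over probes ranks the
factors against the error reference of 1: a pure-noise factor's mean F
converges to ~1, so factors with mean F > 1 are flagged as confounders
(the group label itself is reported but never auto-selected).

Adjustment is residual-based: M-values are regressed on the confounder
design only (group deliberately excluded), and the residuals — with the
grand mean restored — carry forward to differential testing.  When
confounders correlate with group this residualisation can absorb part of
the group effect; the diagnostics here report, they never auto-correct.

Genomic inflation λ is the classic genomic-control estimate: the median of
the χ²₁ quantiles of the observed p-values divided by the χ²₁ median
(≈0.4549).  λ≈1 indicates calibrated tests; the permuted-label null λ
distribution shows what the test statistic does when the group association
is destroyed while everything else is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CHI2_1_MEDIAN = stats.chi2.ppf(0.5, 1)  # 0.45493642...


@dataclass
class SOVResult:
    """Per-factor mean marginal F statistics and the F>1 confounder flags."""

    mean_f: dict[str, float]
    selected: list[str]  # factors with mean F > 1, excluding `group`
    n_probes: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "factor": list(self.mean_f),
                "mean_F": [self.mean_f[f] for f in self.mean_f],
                "selected": [f in self.selected for f in self.mean_f],
            }
        )


@dataclass
class InflationEstimate:
    lambda_: float
    n_tests: int
    null_lambdas: list[float] | None = None


def _factor_columns(
    metadata: pd.DataFrame, factor: str, ftype: str
) -> np.ndarray:
    """Design columns for one factor: one-hot (reference level dropped) or
    a standardized continuous column."""
    col = metadata[factor]
    if ftype == "categorical" or not pd.api.types.is_numeric_dtype(col):
        levels = sorted(pd.unique(col.astype(str)))
        if len(levels) < 2:
            raise ValueError(f"factor {factor!r} is constant")
        return np.column_stack(
            [(col.astype(str) == lv).to_numpy(dtype=float) for lv in levels[1:]]
        )
    x = col.to_numpy(dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError(f"factor {factor!r} is constant")
    return ((x - x.mean()) / sd)[:, None]


def _build_design(
    metadata: pd.DataFrame, factors: list[str], factor_types: dict[str, str]
) -> tuple[np.ndarray, dict[str, slice]]:
    missing = [f for f in factors if f not in metadata.columns]
    if missing:
        raise ValueError(f"factors not in metadata: {missing}")
    n = metadata.shape[0]
    blocks = [np.ones((n, 1))]
    spans: dict[str, slice] = {}
    start = 1
    for f in factors:
        B = _factor_columns(metadata, f, factor_types.get(f, ""))
        blocks.append(B)
        spans[f] = slice(start, start + B.shape[1])
        start += B.shape[1]
    X = np.hstack(blocks)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        collinear = []
        for f in factors:
            keep = [i for i in range(X.shape[1]) if not (spans[f].start <= i < spans[f].stop)]
            if np.linalg.matrix_rank(X[:, keep]) == np.linalg.matrix_rank(X):
                collinear.append(f)
        raise ValueError(f"rank-deficient design; collinear factors: {collinear or factors}")
    return X, spans


def _rss(Y: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Residual sum of squares per probe (rows of Y) under design X."""
    Q, _ = np.linalg.qr(X)
    fitted = (Y @ Q) @ Q.T
    return ((Y - fitted) ** 2).sum(axis=1)


def sov_analysis(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    factors: list[str],
    factor_types: dict[str, str] | None = None,
) -> SOVResult:
    """Mean marginal F per factor over probes, with the F>1 selection rule."""
    factor_types = factor_types or {}
    if len(set(factors)) < len(factors):
        raise ValueError("duplicate factors passed (rank-deficient design)")
    meta = metadata.loc[m.columns]
    X, spans = _build_design(meta, factors, factor_types)
    Y = np.asarray(m, dtype=float)
    n, p = X.shape
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom in the joint model")
    rss_full = _rss(Y, X)
    rss_full = np.maximum(rss_full, 1e-300)
    mean_f: dict[str, float] = {}
    for f in factors:
        keep = [i for i in range(p) if not (spans[f].start <= i < spans[f].stop)]
        rss_red = _rss(Y, X[:, keep])
        q = spans[f].stop - spans[f].start
        F = (rss_red - rss_full) / q / (rss_full / df_resid)
        mean_f[f] = float(np.mean(F))
    selected = [f for f in factors if f != "group" and mean_f[f] > 1.0]
    return SOVResult(mean_f=mean_f, selected=selected, n_probes=m.shape[0])


def residualize(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    confounders: list[str],
    factor_types: dict[str, str] | None = None,
) -> pd.DataFrame:
    """OLS residuals of M on intercept + confounder design, grand mean restored.

    Refuses ``group`` among the confounders: regressing the effect of
    interest out would erase it.
    """
    if "group" in confounders:
        raise ValueError("'group' may not be residualized out (effect of interest)")
    if not confounders:
        return m.copy()
    meta = metadata.loc[m.columns]
    X, _ = _build_design(meta, list(confounders), factor_types or {})
    Y = np.asarray(m, dtype=float)
    Q, _ = np.linalg.qr(X)
    resid = Y - (Y @ Q) @ Q.T
    resid += Y.mean(axis=1, keepdims=True)
    return pd.DataFrame(resid, index=m.index, columns=m.columns)


def genomic_inflation(pvalues) -> InflationEstimate:
    """Classic genomic-control λ: median observed χ²₁ quantile / χ²₁ median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size < 10:
        raise ValueError("need at least 10 p-values")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, 1)
    lam = float(np.median(chi2) / CHI2_1_MEDIAN)
    return InflationEstimate(lambda_=lam, n_tests=int(p.size))


def shuffled_null_lambda(
    m: pd.DataFrame,
    metadata: pd.DataFrame,
    n_perm: int = 20,
    seed: int = 0,
) -> InflationEstimate:
    """λ distribution under permuted group labels.

    Each permutation shuffles the group assignment across samples, reruns the
    moderated t-test, and records the genomic-control λ of the raw p-values.
    Permutation breaks the group-methylation association, so the null λ
    concentrates near 1 whatever the true effect.
    """
    from .diffmeth import moderated_ttest

    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    groups = metadata.loc[m.columns, "group"].to_numpy()
    lambdas = []
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        res = moderated_ttest(m, pd.Series(perm, index=m.columns))
        lambdas.append(genomic_inflation(res["p_raw"].to_numpy()).lambda_)
    med = float(np.median(lambdas))
    return InflationEstimate(lambda_=med, n_tests=m.shape[0], null_lambdas=lambdas)
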