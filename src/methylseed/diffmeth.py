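"""Moderated t-test differential methylation, BH FDR, direction calls,
gestational-DMR exclusion, and CpG feature-distribution statistics.

The moderated t-test shrinks each probe's residual variance toward a common
prior estimated from the whole ensemble (empirical Bayes).  With per-probe
pooled variance s² on d = n₁+n₂−2 degrees of freedom, the prior (d₀, s₀²)
is obtained by moment matching on log s²: since log s² is distributed as a
scaled log-χ², its mean and variance involve digamma/trigamma functions of
d/2 and d₀/2, and d₀ follows from inverting the trigamma function (Newton's
method).  The posterior variance s̃² = (d₀s₀² + d·s²)/(d₀+d) then yields
t = Δ/(s̃·√(1/n₁+1/n₂)) on d₀+d degrees of freedom.  d₀→0 recovers the
ordinary pooled t; d₀→∞ uses the common prior variance for every probe.

Direction calls follow the sign of the log2 fold change of M-values
(case − control): hypermethylated if positive, hypomethylated if negative,
among probes passing the BH FDR threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma


@dataclass
class DMRTrack:
    """Genomic intervals (0-based half-open) of coordinated methylation change."""

    intervals: pd.DataFrame  # columns chrom, start, end [, name]
    source: str = ""

    def __post_init__(self) -> None:
        iv = self.intervals
        if len(iv) and not (iv["start"] < iv["end"]).all():
            raise ValueError("DMR intervals must satisfy start < end")


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


def _trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration on 1/y."""
    if x <= 0:
        return np.inf
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < tol * y:
            break
    return float(y)


def estimate_prior(s2: np.ndarray, d: float) -> tuple[float, float]:
    """Empirical-Bayes prior (d0, s0²) by moment matching on log s².

    Zero variances are excluded from moment estimation (they carry no
    information about the spread of log s²); the returned prior then pools
    them safely.  Returns d0 = inf when the observed spread of log s² is no
    larger than the sampling spread of a χ² log-variance.
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2[s2 > 0]
    if pos.size < 2:
        raise ValueError("need >=2 probes with positive variance to pool")
    z = np.log(pos)
    e = z - digamma(d / 2.0) + np.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(polygamma(1, d / 2.0))
    if e_var <= 0:
        return np.inf, float(np.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_2 = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def moderated_ttest(
    m_adj: pd.DataFrame,
    groups: pd.Series | list,
    case_label=None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-probe moderated two-sample t-test on (adjusted) M-values.

    ``groups`` holds two labels; ``case_label`` names the case group
    (default: 'case' if present, else the lexicographically larger label).
    log2FC = mean(M_case) − mean(M_control).  ``prior_df`` overrides the
    estimated d₀ (0 → ordinary pooled t; inf → fully pooled variance).

    Returns a DataFrame indexed by probe with columns log2FC, t_mod,
    p_raw, df_total, and the prior (d0, s0_2) in ``attrs``.
    """
    groups = pd.Series(list(groups), index=m_adj.columns)
    labels = sorted(groups.unique(), key=str)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, got {labels}")
    if case_label is None:
        case_label = "case" if "case" in labels else labels[1]
    control_label = [l for l in labels if l != case_label][0]
    idx1 = (groups == case_label).to_numpy()
    idx0 = (groups == control_label).to_numpy()
    n1, n0 = int(idx1.sum()), int(idx0.sum())
    if n1 < 2 or n0 < 2:
        raise ValueError("each group needs >=2 samples")
    if m_adj.shape[0] < 2:
        raise ValueError("variance pooling needs >=2 probes")

    Y = np.asarray(m_adj, dtype=float)
    mean1 = Y[:, idx1].mean(axis=1)
    mean0 = Y[:, idx0].mean(axis=1)
    fc = mean1 - mean0
    ss = ((Y[:, idx1] - mean1[:, None]) ** 2).sum(axis=1) + (
        (Y[:, idx0] - mean0[:, None]) ** 2
    ).sum(axis=1)
    d = n1 + n0 - 2
    s2 = ss / d

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, d)
    elif prior_df == 0:
        d0, s0_2 = 0.0, float(np.nan)
    elif np.isinf(prior_df):
        _, s0_2 = estimate_prior(s2, d)
        d0 = np.inf
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, d)

    if d0 == 0:
        s2_post = s2
        df_total = float(d)
    elif np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * s2) / (d0 + d)
        df_total = d0 + d

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, fc / se, 0.0)
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df_total)

    out = pd.DataFrame(
        {"log2FC": fc, "t_mod": t, "p_raw": p},
        index=m_adj.index,
    )
    out.attrs["d0"] = d0
    out.attrs["s0_2"] = s0_2
    out.attrs["df_total"] = df_total
    out.attrs["case_label"] = case_label
    return out


def bh_adjust(p_raw) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_raw, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def call_dm(results: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Attach BH-adjusted p-values and hyper/hypo/none direction calls.

    Significant probes (p_adj < alpha) are hypermethylated when log2FC > 0
    and hypomethylated when log2FC < 0; a log2FC of exactly 0 stays 'none'.
    """
    out = results.copy()
    if "p_adj" not in out.columns:
        out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    sig = out["p_adj"] < alpha
    direction = np.where(
        sig & (out["log2FC"] > 0),
        "hyper",
        np.where(sig & (out["log2FC"] < 0), "hypo", "none"),
    )
    out["direction"] = direction
    return out


def probes_in_dmrs(
    annotation: pd.DataFrame, dmrs: DMRTrack
) -> pd.Index:
    """Probes whose annotated position falls inside any DMR interval.

    BED intervals are 0-based half-open; annotation positions are 1-based.
    A probe at 1-based position ``pos`` is inside [start, end) exactly when
    start < pos + 1 <= end.  Chromosome names are normalised so 'chr1' ≡ '1'.
    """
    if len(dmrs.intervals) == 0:
        return pd.Index([])
    chrom = annotation["chrom"].map(_norm_chrom)
    pos = annotation["pos"].to_numpy()
    inside = np.zeros(len(annotation), dtype=bool)
    for _, iv in dmrs.intervals.iterrows():
        c = _norm_chrom(iv["chrom"])
        hit = (chrom == c).to_numpy() & (iv["start"] < pos + 1) & (pos + 1 <= iv["end"])
        inside |= hit
    return annotation.index[inside]


def exclude_dmr_cpgs(
    results: pd.DataFrame, dmrs: DMRTrack, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, dict]:
    """Flag and demote probes inside gestational-age DMR intervals.

    Probes located in a DMR are marked ``in_gestational_dmr`` and removed
    from the significant set (direction reset to 'none').  Probes missing
    from the annotation are skipped with a warning count.
    """
    out = results.copy()
    known = out.index.intersection(annotation.index)
    n_missing = len(out.index) - len(known)
    inside = probes_in_dmrs(annotation.loc[known], dmrs)
    out["in_gestational_dmr"] = out.index.isin(inside)
    n_excluded = 0
    if "direction" in out.columns:
        was_sig = out["direction"] != "none"
        n_excluded = int((was_sig & out["in_gestational_dmr"]).sum())
        out.loc[out["in_gestational_dmr"], "direction"] = "none"
    log = {
        "n_in_dmr": int(out["in_gestational_dmr"].sum()),
        "n_excluded_from_significant": n_excluded,
        "n_missing_coordinates": n_missing,
    }
    return out, log


ISLAND_CATEGORIES = ("Island", "N_Shore", "S_Shore", "N_Shelf", "S_Shelf", "OpenSea")
REGION_CATEGORIES = ("TSS200", "TSS1500", "5'UTR", "Body", "3'UTR", "intergenic")


def region_distribution(
    significant: set[str] | pd.Index,
    annotation: pd.DataFrame,
    background: set[str] | pd.Index | None = None,
) -> dict:
    """Feature-category composition of significant probes vs the background.

    Returns proportions of the significant set per island-relation and per
    gene-region category, the matching background proportions, and a
    chi-square goodness-of-fit p-value of the significant composition
    against the background composition.
    """
    sig = pd.Index(sorted(significant))
    if len(sig) == 0:
        raise ValueError("empty significant set")
    bg = pd.Index(sorted(background)) if background is not None else annotation.index
    if not sig.isin(bg).all():
        raise ValueError("significant set must be a subset of the background")
    out: dict = {}
    for key, cats in (("island", ISLAND_CATEGORIES), ("region", REGION_CATEGORIES)):
        col = "island" if key == "island" else "region"
        sig_counts = annotation.loc[sig, col].value_counts().reindex(cats, fill_value=0)
        bg_counts = annotation.loc[bg, col].value_counts().reindex(cats, fill_value=0)
        used = bg_counts > 0
        expected = bg_counts[used] / bg_counts[used].sum() * sig_counts[used].sum()
        chi2, p = stats.chisquare(sig_counts[used], expected)
        out[key] = {
            "proportions": (sig_counts / sig_counts.sum()).to_dict(),
            "background_proportions": (bg_counts / bg_counts.sum()).to_dict(),
            "chi2": float(chi2),
            "p": float(p),
        }
    return out
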