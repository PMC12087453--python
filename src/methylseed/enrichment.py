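"""Hypergeometric pathway enrichment of significant CpGs and pathway β-scores.

Enrichment asks whether a pathway's CpGs are over-represented among the
significant set.  With N CpGs in the (region-filtered) array universe, K of
them in the pathway, and n significant overall, the chance of seeing k or
more significant CpGs in the pathway is the upper hypergeometric tail

    P(X >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n),

computed exactly in integer arithmetic for N <= 1000 and in log-gamma space
otherwise.  BH correction is applied across the pathways of one collection.

Pathway methylation scores are per-sample unweighted means of β over the
pathway's promoter (TSS200/TSS1500) CpGs, compared between groups with a
Wilcoxon rank-sum test (exact enumeration for small tie-free inputs, normal
approximation with tie and continuity corrections otherwise).
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .diffmeth import bh_adjust

PROMOTER_REGIONS = ("TSS200", "TSS1500")


def _log_comb(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_tail(k: int, N: int, K: int, n: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    k: significant CpGs observed in the pathway; N: CpGs in the universe;
    K: CpGs in the pathway; n: significant CpGs overall.
    """
    for name, v in (("k", k), ("N", N), ("K", K), ("n", n)):
        if v < 0 or int(v) != v:
            raise ValueError(f"{name} must be a nonnegative integer")
    if K > N or n > N or k > min(K, n):
        raise ValueError(f"impossible configuration k={k} N={N} K={K} n={n}")
    if k == 0:
        return 1.0
    hi = min(K, n)
    if N <= 1000:
        denom = math.comb(N, n)
        num = sum(math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, hi + 1))
        return num / denom
    log_denom = _log_comb(N, n)
    terms = [
        _log_comb(K, i) + _log_comb(N - K, n - i) - log_denom for i in range(k, hi + 1)
    ]
    mx = max(terms)
    return float(min(1.0, math.exp(mx) * sum(math.exp(t - mx) for t in terms)))


def map_cpgs_to_pathways(
    annotation: pd.DataFrame,
    genesets: dict[str, list[str]],
    region_filter: str = "promoter",
) -> tuple[dict[str, set[str]], set[str]]:
    """Map gene sets to CpG universes.

    Returns (pathway -> CpG ID set, filtered probe universe).  With
    ``region_filter='promoter'`` only TSS200/TSS1500 probes count, matching
    the promoter-centric usage downstream; ``'all'`` keeps every annotated
    probe.  Pathways mapping to zero probes are retained with an empty set.
    """
    if region_filter not in ("promoter", "all"):
        raise ValueError("region_filter must be 'promoter' or 'all'")
    ann = annotation
    if region_filter == "promoter":
        ann = ann[ann["region"].isin(PROMOTER_REGIONS)]
    universe = set(ann.index)
    by_gene: dict[str, list[str]] = {}
    for probe, gene in ann["gene"].items():
        if isinstance(gene, str) and gene:
            for g in gene.split(";"):
                by_gene.setdefault(g, []).append(probe)
    universes = {
        name: {p for g in genes for p in by_gene.get(g, [])}
        for name, genes in genesets.items()
    }
    return universes, universe


def enrich_pathways(
    significant: set[str],
    universes: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric enrichment table with BH correction across pathways.

    Rows are sorted by p_adj, then p_raw, then pathway name.  A pathway with
    K=0 gets p=1 by convention (nothing to observe) and is flagged.
    """
    sig = set(significant) & universe
    if not sig:
        raise ValueError("empty significant set (after universe intersection)")
    N, n = len(universe), len(sig)
    rows = []
    for name in sorted(universes):
        members = universes[name] & universe
        K = len(members)
        k = len(sig & members)
        p = 1.0 if K == 0 else hypergeom_tail(k, N, K, n)
        rows.append({"pathway": name, "N": N, "K": K, "n": n, "k": k, "p_raw": p, "empty": K == 0})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(["p_adj", "p_raw", "pathway"], kind="mergesort").reset_index(drop=True)
    return table


def pathway_beta_score(
    beta: pd.DataFrame, universes: dict[str, set[str]], pathway: str
) -> pd.Series:
    """Per-sample mean β over the pathway's (promoter-filtered) CpGs."""
    members = sorted(universes[pathway] & set(beta.index))
    if not members:
        raise ValueError(f"pathway {pathway!r} has no CpGs in the matrix")
    return beta.loc[members].mean(axis=0)


def rank_sum_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Rank sum of the first sample within the pooled ranking (midranks for ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    return float(ranks[: len(x)].sum())


def compare_groups_wilcoxon(scores, groups) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact null enumeration when n₁+n₂ <= 12 with no ties; otherwise the
    normal approximation with tie correction and a 0.5 continuity
    correction.  Returns (rank-sum statistic of the first-label group,
    two-sided p).  Degenerate input (all values identical) yields p = 1.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups), key=str)
    if len(labels) != 2:
        raise ValueError("need exactly two groups")
    x = scores[groups == labels[0]]
    y = scores[groups == labels[1]]
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs >=1 sample")
    if np.all(scores == scores[0]):
        return rank_sum_statistic(x, y), 1.0
    w = rank_sum_statistic(x, y)
    n1, n2 = len(x), len(y)
    n = n1 + n2
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n
    if n <= 12 and not has_ties:
        ranks = stats.rankdata(pooled)
        sums = np.fromiter(
            (sum(c) for c in combinations(ranks, n1)), dtype=float, count=math.comb(n, n1)
        )
        lo = float(np.mean(sums <= w))
        hi = float(np.mean(sums >= w))
        return w, min(1.0, 2.0 * min(lo, hi))
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1.0))
    sigma2 = n1 * n2 / 12.0 * ((n + 1.0) - tie_term)
    if sigma2 <= 0:
        return w, 1.0
    z = (abs(w - mu) - 0.5) / math.sqrt(sigma2)
    return w, float(min(1.0, 2.0 * stats.norm.sf(max(z, 0.0))))
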