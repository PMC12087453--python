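"""Shannon-entropy stemness scoring of methylomes.

A sample's β profile is treated as a discrete distribution over CpGs:
p_i = β_i / Σβ.  Its normalized Shannon entropy,

    Entropy = Σ_i −p_i·log(p_i) / log(N),

lies in [0, 1]: 1 for a perfectly uniform profile, 0 for a degenerate one
(all methylation on a single CpG).  Higher entropy is read as greater
epigenetic plasticity.  The stemness score min-max scales the entropies
across the scored cohort:

    Stemness = (Entropy − min) / (max − min),

so it is cohort-relative — scores from separately scored cohorts are NOT
comparable.  Any logarithm base cancels between numerator and the log N
normalizer, and scaling the β vector by a positive constant cancels in
p_i, so entropy depends only on the shape of the profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import compare_groups_wilcoxon


@dataclass
class StemnessScores:
    entropy: pd.Series  # per-sample normalized Shannon entropy, in [0,1]
    stemness: pd.Series  # min-max scaled entropy over the cohort, in [0,1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"entropy": self.entropy, "stemness": self.stemness})


def shannon_entropy(beta_vector) -> float:
    """Normalized Shannon entropy of one sample's β profile (0·log 0 ≡ 0)."""
    b = np.asarray(beta_vector, dtype=float)
    if b.size < 2:
        raise ValueError("need at least 2 CpGs")
    if np.any(b < 0):
        raise ValueError("negative β values")
    total = b.sum()
    if total <= 0:
        raise ValueError("all-zero β vector: entropy undefined")
    p = b / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(b.size))


def stemness_scores(beta: pd.DataFrame) -> StemnessScores:
    """Entropy per sample and cohort-relative min-max stemness scores."""
    if beta.shape[1] < 2:
        raise ValueError("need >=2 samples to min-max scale")
    ent = beta.apply(lambda col: shannon_entropy(col.to_numpy()), axis=0)
    lo, hi = float(ent.min()), float(ent.max())
    if hi == lo:
        raise ValueError("all entropies identical: min-max scaling undefined")
    stem = (ent - lo) / (hi - lo)
    return StemnessScores(entropy=ent, stemness=stem)


def compare_stemness(scores: StemnessScores, groups) -> dict:
    """Wilcoxon rank-sum comparison of stemness between the two groups."""
    groups = pd.Series(list(groups), index=scores.stemness.index)
    labels = sorted(groups.unique(), key=str)
    stat, p = compare_groups_wilcoxon(scores.stemness.to_numpy(), groups.to_numpy())
    medians = {str(l): float(scores.stemness[groups == l].median()) for l in labels}
    higher = max(medians, key=lambda l: medians[l])
    return {"statistic": stat, "p": p, "medians": medians, "higher_group": higher}
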