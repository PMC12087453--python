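"""Promoter-level gene aggregation of methylation and expression correlation.

Gene-level methylation is the unweighted mean β over a gene's promoter
(TSS200/TSS1500) probes.  Against a matched expression matrix, each gene
gets a Pearson correlation across the shared samples and a case/control
expression fold change; promoter methylation is expected to repress, so
candidate genes are screened by negative correlation:

* enrichment set: PCC < −0.2
* top set:        |FC| > 1.5 (i.e. FC > 1.5 or FC < 1/1.5) and PCC < −0.3
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .enrichment import PROMOTER_REGIONS
from .preprocess import beta_to_m

#: pseudocount added to group mean expression before the fold-change ratio
FC_OFFSET = 0.5


def promoter_gene_beta(
    beta: pd.DataFrame, annotation: pd.DataFrame
) -> tuple[pd.DataFrame, pd.Series]:
    """Mean promoter β per gene and sample.

    A probe annotated to several genes (';'-separated) contributes to each.
    Genes with no promoter probe are omitted.  Returns (gene x sample
    matrix, per-gene contributing probe count).
    """
    ann = annotation.loc[annotation.index.intersection(beta.index)]
    prom = ann[ann["region"].isin(PROMOTER_REGIONS)]
    gene_probes: dict[str, list[str]] = {}
    for probe, gene in prom["gene"].items():
        if isinstance(gene, str) and gene:
            for g in gene.split(";"):
                gene_probes.setdefault(g, []).append(probe)
    if not gene_probes:
        raise ValueError("no gene has promoter probes")
    genes = sorted(gene_probes)
    mat = pd.DataFrame(np.empty((len(genes), beta.shape[1])), index=genes, columns=beta.columns)
    counts = pd.Series({g: len(gene_probes[g]) for g in genes})
    for g in genes:
        mat.loc[g] = beta.loc[gene_probes[g]].mean(axis=0)
    return mat, counts


def promoter_gene_m(gene_beta: pd.DataFrame) -> pd.DataFrame:
    """M transform of the gene-level promoter β matrix."""
    return beta_to_m(gene_beta)


def gene_methyl_correlation(
    gene_meth: pd.DataFrame,
    expression: pd.DataFrame,
    groups: pd.Series,
    matched_samples: list[str] | None = None,
) -> pd.DataFrame:
    """Per-gene Pearson correlation of expression vs promoter β, plus FC flags.

    ``groups`` (indexed by sample) supplies case/control labels for the
    expression fold change (mean case + offset)/(mean control + offset).
    Genes with zero variance in either modality are kept but flagged
    ``undefined`` and excluded from selection.
    """
    samples = [s for s in gene_meth.columns if s in expression.columns]
    if matched_samples is not None:
        samples = [s for s in matched_samples if s in samples]
    if len(samples) < 3:
        raise ValueError("need >=3 matched samples")
    genes = gene_meth.index.intersection(expression.index)
    g = groups.loc[samples]
    case = g == "case"
    ctrl = g == "control"
    rows = []
    for gene in genes:
        x = gene_meth.loc[gene, samples].to_numpy(dtype=float)
        y = expression.loc[gene, samples].to_numpy(dtype=float)
        undefined = x.std() == 0 or y.std() == 0
        pcc = np.nan if undefined else float(np.corrcoef(x, y)[0, 1])
        fc = float((y[case.to_numpy()].mean() + FC_OFFSET) / (y[ctrl.to_numpy()].mean() + FC_OFFSET))
        abs_fc_pass = fc > 1.5 or fc < 1 / 1.5
        rows.append(
            {
                "gene": gene,
                "pcc": pcc,
                "expr_fc": fc,
                "undefined": undefined,
                "selected_enrichment": (not undefined) and pcc < -0.2,
                "selected_top": (not undefined) and abs_fc_pass and pcc < -0.3,
            }
        )
    return pd.DataFrame(rows).set_index("gene")


def select_candidates(rows: pd.DataFrame, mode: str) -> list[str]:
    """Gene lists from the two printed screening rules."""
    if mode == "enrichment_set":
        sel = rows["selected_enrichment"]
    elif mode == "top_set":
        sel = rows["selected_top"]
    else:
        raise ValueError("mode must be 'enrichment_set' or 'top_set'")
    return sorted(rows.index[sel.fillna(False)])
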