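"""Synthetic 450K-style cohorts with planted, recoverable structure.

The generator emulates a two-group umbilical-cord methylation cohort
(default 38 controls vs 34 cases) so every downstream stage is testable
without any download:

* per-probe baseline β drawn from a bimodal mixture — Beta(3,17) (mean
  ~0.15) for the hypomethylated mode and Beta(17,3) (mean ~0.85) for the
  hypermethylated mode; promoter probes are preferentially hypomethylated,
  as promoters are in real methylomes;
* per-sample variation is normal on the M scale (where linear models
  operate); clinical confounders and slide/array batch effects are likewise
  added on the M scale;
* the group effect is an additive β-scale shift (+delta_beta, default 0.15)
  at the truth CpGs, which sit preferentially in the promoter probes of a
  designated set of truth genes — the genes that later populate the truth
  pathways — with the remainder in non-promoter probes of those genes or
  intergenic probes, so the truth pathways contain every gene hosting a
  planted CpG;
* β values are clipped into (0.01, 0.99) so the logit stays finite.

Everything is driven by a single integer seed and is bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffmeth import DMRTrack
from .preprocess import beta_to_m, m_to_beta

BETA_CLIP = (0.01, 0.99)
#: mixture components for baseline per-probe mean β
LOW_BETA = (3.0, 17.0)
HIGH_BETA = (17.0, 3.0)
#: probability that a promoter / non-promoter probe sits in the low mode
P_LOW_PROMOTER = 0.85
P_LOW_OTHER = 0.45
#: per-sample biological + technical noise on the M scale
M_NOISE_SD = 0.35

ISLAND_PROBS = {
    "Island": 0.31,
    "N_Shore": 0.12,
    "S_Shore": 0.10,
    "N_Shelf": 0.05,
    "S_Shelf": 0.05,
    "OpenSea": 0.37,
}
REGION_PROBS = {
    "TSS200": 0.12,
    "TSS1500": 0.13,
    "5'UTR": 0.12,
    "Body": 0.45,
    "3'UTR": 0.18,
}


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_control: int = 38
    n_case: int = 34
    n_cpg: int = 10_000
    n_gene: int = 1_000
    n_pathway: int = 10
    frac_affected_cpg: float = 0.05
    delta_beta: float = 0.15
    #: (factor name, 'categorical'|'continuous', effect size on the M scale)
    confounder_spec: list[tuple[str, str, float]] = field(
        default_factory=lambda: [
            ("baby_sex", "categorical", 0.4),
            ("gestational_age", "continuous", 0.4),
            ("maternal_age", "continuous", 0.3),
        ]
    )
    #: (number of batches, additive M-scale shift scale, multiplicative noise scale)
    batch_spec: tuple[int, float, float] = (2, 0.3, 1.1)
    expr_rho: float = -0.5
    seed: int = 0
    #: fraction of truth CpGs planted as hypomethylation instead
    frac_hypo: float = 0.0

    def validate(self) -> None:
        for name in ("n_control", "n_case", "n_cpg", "n_gene", "n_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0.0 <= self.frac_affected_cpg <= 1.0:
            raise ValueError("frac_affected_cpg must lie in [0, 1]")
        if 0 < self.frac_affected_cpg and self.frac_affected_cpg * self.n_cpg < 1:
            raise ValueError("frac_affected_cpg * n_cpg must be >= 1 when nonzero")
        if not 0.0 <= self.delta_beta < 1.0:
            raise ValueError("delta_beta must lie in [0, 1)")
        if not -1.0 <= self.expr_rho <= 0.0:
            raise ValueError("expr_rho must lie in [-1, 0]")
        if self.batch_spec[0] < 1:
            raise ValueError("need >= 1 batch")


@dataclass
class SyntheticCohort:
    beta: pd.DataFrame  # probes x samples
    metadata: pd.DataFrame  # indexed by sample_id; includes 'group', 'batch'
    factor_types: dict[str, str]
    annotation: pd.DataFrame
    truth_cpg: dict[str, str]  # probe -> 'hyper' | 'hypo'
    truth_genes: list[str]
    truth_pathways: list[str] = field(default_factory=list)
    expression: pd.DataFrame | None = None
    config: SimulationConfig | None = None


def generate_annotation(n_cpg: int, n_gene: int, seed: int) -> pd.DataFrame:
    """Manifest-style probe annotation with guaranteed promoter coverage.

    Every gene receives at least one promoter (TSS200) probe; remaining
    probes are spread over genes and gene regions, with ~15% intergenic.
    Positions are strictly increasing within each chromosome.
    """
    if n_gene > n_cpg:
        raise ValueError("n_gene may not exceed n_cpg")
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i:05d}" for i in range(1, n_gene + 1)]
    gene_col: list[str] = list(genes)  # one promoter probe per gene, by construction
    region_col: list[str] = ["TSS200"] * n_gene
    n_rest = n_cpg - n_gene
    regions = list(REGION_PROBS)
    probs = np.array(list(REGION_PROBS.values()))
    for _ in range(n_rest):
        if rng.random() < 0.15:
            gene_col.append("")
            region_col.append("intergenic")
        else:
            gene_col.append(genes[rng.integers(0, n_gene)])
            region_col.append(regions[rng.choice(len(regions), p=probs)])
    order = rng.permutation(n_cpg)
    gene_col = [gene_col[i] for i in order]
    region_col = [region_col[i] for i in order]

    chroms = [str(c) for c in rng.integers(1, 23, size=n_cpg)]
    islands = rng.choice(list(ISLAND_PROBS), size=n_cpg, p=list(ISLAND_PROBS.values()))
    pos = np.zeros(n_cpg, dtype=int)
    df = pd.DataFrame(
        {
            "chrom": chroms,
            "pos": pos,
            "gene": gene_col,
            "region": region_col,
            "island": islands,
        },
        index=[f"cg{i:08d}" for i in range(1, n_cpg + 1)],
    )
    for c in df["chrom"].unique():
        idx = df.index[df["chrom"] == c]
        gaps = rng.integers(100, 10_000, size=len(idx))
        df.loc[idx, "pos"] = np.cumsum(gaps)
    df.index.name = "probe_id"
    return df


def _place_truth_cpgs(
    annotation: pd.DataFrame, n_truth: int, rng: np.random.Generator,
    promoter_frac: float = 0.8,
) -> tuple[list[str], list[str]]:
    """Pick truth CpGs concentrated in promoters of a set of truth genes.

    Returns (truth probes, truth genes).  Non-promoter truth probes come
    from the truth genes' other probes or intergenic probes, so the genes
    hosting truth CpGs are exactly the truth genes.
    """
    prom = annotation[annotation["region"].isin(("TSS200", "TSS1500")) & (annotation["gene"] != "")]
    genes = pd.unique(prom["gene"])
    genes = genes[rng.permutation(len(genes))]
    quota = int(round(promoter_frac * n_truth))
    chosen_probes: list[str] = []
    chosen_genes: list[str] = []
    for g in genes:
        if len(chosen_probes) >= quota:
            break
        probes = list(prom.index[prom["gene"] == g])
        chosen_probes.extend(probes[: quota - len(chosen_probes)])
        chosen_genes.append(g)
    rest_pool = annotation.index[
        (
            annotation["gene"].isin(chosen_genes)
            & ~annotation["region"].isin(("TSS200", "TSS1500"))
        )
        | (annotation["gene"] == "")
    ]
    rest_pool = [p for p in rest_pool if p not in set(chosen_probes)]
    n_rest = min(n_truth - len(chosen_probes), len(rest_pool))
    rest = list(rng.choice(rest_pool, size=n_rest, replace=False)) if n_rest else []
    return chosen_probes + rest, sorted(chosen_genes)


def _simulate_metadata(cfg: SimulationConfig, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, str]]:
    n = cfg.n_control + cfg.n_case
    sample_ids = [f"ctrl{i:03d}" for i in range(1, cfg.n_control + 1)] + [
        f"case{i:03d}" for i in range(1, cfg.n_case + 1)
    ]
    n_batches = cfg.batch_spec[0]
    batch = np.array([f"slide{1 + (i % n_batches)}" for i in range(n)])
    batch = batch[rng.permutation(n)]
    meta = pd.DataFrame(
        {
            "group": ["control"] * cfg.n_control + ["case"] * cfg.n_case,
            "baby_sex": rng.choice(["F", "M"], size=n),
            "maternal_age": np.round(rng.normal(29.0, 5.0, size=n), 1),
            "maternal_ethnicity": rng.choice(["asian", "caucasian", "pacific"], size=n, p=[0.4, 0.35, 0.25]),
            "paternal_ethnicity": rng.choice(["asian", "caucasian", "pacific"], size=n, p=[0.4, 0.35, 0.25]),
            "gravidity": rng.integers(1, 5, size=n),
            "parity": rng.integers(0, 4, size=n),
            "gestational_age": np.round(rng.normal(39.0, 1.0, size=n), 1),
            "net_weight_gain": np.round(rng.normal(12.0, 5.0, size=n), 1),
            "batch": batch,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    ftypes = {
        "baby_sex": "categorical",
        "maternal_age": "continuous",
        "maternal_ethnicity": "categorical",
        "paternal_ethnicity": "categorical",
        "gravidity": "continuous",
        "parity": "continuous",
        "gestational_age": "continuous",
        "net_weight_gain": "continuous",
        "batch": "categorical",
    }
    return meta, ftypes


def generate_cohort(
    config: SimulationConfig, annotation: pd.DataFrame | None = None
) -> SyntheticCohort:
    """Simulate a two-group β matrix with planted effects and recorded truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    if annotation is None:
        annotation = generate_annotation(config.n_cpg, config.n_gene, seed=config.seed + 1)
    n_cpg = annotation.shape[0]
    meta, ftypes = _simulate_metadata(config, rng)
    n = meta.shape[0]

    is_prom = annotation["region"].isin(("TSS200", "TSS1500")).to_numpy()
    p_low = np.where(is_prom, P_LOW_PROMOTER, P_LOW_OTHER)
    low = rng.random(n_cpg) < p_low
    base = np.where(
        low,
        rng.beta(*LOW_BETA, size=n_cpg),
        rng.beta(*HIGH_BETA, size=n_cpg),
    )
    base = np.clip(base, *BETA_CLIP)
    mu_m = np.log2(base / (1 - base))

    M = mu_m[:, None] + rng.normal(0.0, M_NOISE_SD, size=(n_cpg, n))

    # confounder effects, additive on the M scale
    for name, ftype, effect in config.confounder_spec:
        if name not in meta.columns:
            raise ValueError(f"confounder_spec names unknown factor {name!r}")
        if effect == 0:
            continue
        if ftype == "continuous":
            x = meta[name].to_numpy(dtype=float)
            x = (x - x.mean()) / x.std(ddof=1)
            coef = rng.normal(0.0, effect, size=n_cpg)
            M += coef[:, None] * x[None, :]
        else:
            levels = sorted(pd.unique(meta[name].astype(str)))
            for lv in levels[1:]:
                mask = (meta[name].astype(str) == lv).to_numpy()
                offs = rng.normal(0.0, effect, size=n_cpg)
                M[:, mask] += offs[:, None]

    # slide/array batch effects: additive location + multiplicative noise scale
    n_batches, add_sd, mult = config.batch_spec
    if n_batches > 1 and (add_sd > 0 or mult != 1):
        batches = sorted(meta["batch"].unique())
        for j, b in enumerate(batches):
            mask = (meta["batch"] == b).to_numpy()
            gamma = rng.normal(0.0, add_sd, size=n_cpg)
            delta = mult ** (j - (len(batches) - 1) / 2.0)
            noise_part = M[:, mask] - mu_m[:, None]
            M[:, mask] = mu_m[:, None] + delta * noise_part + gamma[:, None]

    beta = 1.0 / (1.0 + np.exp2(-M))

    # planted group effect, additive on the β scale
    n_truth = int(round(config.frac_affected_cpg * n_cpg))
    truth_cpg: dict[str, str] = {}
    if n_truth > 0 and config.delta_beta > 0:
        probes, truth_genes = _place_truth_cpgs(annotation, n_truth, rng)
        n_hypo = int(round(config.frac_hypo * len(probes)))
        directions = ["hypo"] * n_hypo + ["hyper"] * (len(probes) - n_hypo)
        case_mask = (meta["group"] == "case").to_numpy()
        probe_pos = {p: i for i, p in enumerate(annotation.index)}
        shifted = beta.copy()
        for p, direc in zip(probes, directions):
            i = probe_pos[p]
            sign = 1.0 if direc == "hyper" else -1.0
            shifted[i, case_mask] = beta[i, case_mask] + sign * config.delta_beta
            truth_cpg[p] = direc
        truth_rows = np.array([probe_pos[p] for p in probes])
        cells = shifted[np.ix_(truth_rows, np.where(case_mask)[0])]
        n_clipped = int(((cells < BETA_CLIP[0]) | (cells > BETA_CLIP[1])).sum())
        if n_clipped:
            warnings.warn(f"{n_clipped} β values clipped into {BETA_CLIP}", stacklevel=2)
        beta = shifted
    else:
        truth_genes = []

    beta = np.clip(beta, *BETA_CLIP)
    beta_df = pd.DataFrame(beta, index=annotation.index, columns=meta.index)
    declared_types = {name: ftype for name, ftype, _ in config.confounder_spec}
    ftypes.update({k: v for k, v in declared_types.items() if k in ftypes})
    return SyntheticCohort(
        beta=beta_df,
        metadata=meta,
        factor_types=ftypes,
        annotation=annotation,
        truth_cpg=truth_cpg,
        truth_genes=truth_genes,
        config=config,
    )


def generate_pathways(
    annotation: pd.DataFrame,
    n_pathway: int,
    size_range: tuple[int, int] = (10, 50),
    seed: int = 0,
    truth_genes: list[str] | None = None,
) -> tuple[dict[str, list[str]], list[str]]:
    """Named gene sets; designated truth pathways absorb the truth genes.

    Truth genes are chunked into as many truth pathways as needed (chunk
    size ≤ max size), each padded with random non-truth genes up to a size
    in range; the remaining pathways draw only from non-truth genes, so a
    decoy pathway never enriches through planted genes.  Returns
    (name -> gene list, truth pathway names).
    """
    rng = np.random.default_rng(seed)
    genes = sorted(g for g in pd.unique(annotation["gene"]) if g)
    lo, hi = size_range
    if not 1 <= lo <= hi or hi > len(genes):
        raise ValueError(f"size_range {size_range} infeasible for {len(genes)} genes")
    truth_genes = list(truth_genes or [])
    non_truth = [g for g in genes if g not in set(truth_genes)]
    sets: dict[str, list[str]] = {}
    truth_names: list[str] = []
    shuffled_truth = list(truth_genes)
    rng.shuffle(shuffled_truth)
    chunks = [shuffled_truth[i : i + hi] for i in range(0, len(shuffled_truth), hi)]
    if len(chunks) >= n_pathway:
        raise ValueError("n_pathway too small to hold the truth genes plus decoys")
    for ci, chunk in enumerate(chunks, start=1):
        size = int(rng.integers(lo, hi + 1))
        pad = max(0, size - len(chunk))
        pad_genes = list(rng.choice(non_truth, size=min(pad, len(non_truth)), replace=False))
        name = f"PATHWAY{ci:03d}"
        sets[name] = sorted(chunk + pad_genes)
        truth_names.append(name)
    for ci in range(len(chunks) + 1, n_pathway + 1):
        size = int(rng.integers(lo, hi + 1))
        sets[f"PATHWAY{ci:03d}"] = sorted(rng.choice(non_truth, size=size, replace=False))
    return sets, truth_names


def generate_dmr_track(
    annotation: pd.DataFrame, n_dmr: int, seed: int = 0, halfwidth: int = 500
) -> tuple[DMRTrack, set[str]]:
    """Random intervals, each anchored on a probe so it overlaps ≥1 position.

    Returns (track, probes inside under the documented containment rule).
    """
    if n_dmr < 0:
        raise ValueError("n_dmr must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    if n_dmr > 0:
        anchors = rng.choice(annotation.index, size=min(n_dmr, len(annotation)), replace=False)
        for i, p in enumerate(sorted(anchors), start=1):
            chrom = annotation.loc[p, "chrom"]
            pos = int(annotation.loc[p, "pos"])
            start = max(0, pos - 1 - halfwidth)
            end = pos + halfwidth
            rows.append({"chrom": chrom, "start": start, "end": end, "name": f"DMR{i:04d}"})
    track = DMRTrack(pd.DataFrame(rows, columns=["chrom", "start", "end", "name"]), source="synthetic")
    from .diffmeth import probes_in_dmrs

    inside = set(probes_in_dmrs(annotation, track)) if rows else set()
    return track, inside


def generate_expression(
    cohort: SyntheticCohort, rho: float = -0.5, seed: int = 0
) -> pd.DataFrame:
    """Gene x sample expression negatively coupled to promoter methylation.

    For each gene with promoter probes, expression is an affine function of
    −(mean promoter β) plus Gaussian noise calibrated so the expected
    Pearson correlation is ``rho``; values are shifted to a positive range.
    ``rho = 0`` gives independent noise; positive targets are refused.
    """
    if not -1.0 <= rho <= 0.0:
        raise ValueError("rho must lie in [-1, 0]")
    from .integration import promoter_gene_beta

    rng = np.random.default_rng(seed)
    gene_beta, _ = promoter_gene_beta(cohort.beta, cohort.annotation)
    n = gene_beta.shape[1]
    out = np.empty_like(gene_beta.to_numpy())
    for gi in range(gene_beta.shape[0]):
        x = gene_beta.iloc[gi].to_numpy(dtype=float)
        sd = x.std()
        if rho == 0.0 or sd == 0.0:
            raw = rng.normal(0.0, 1.0, size=n)
        elif rho == -1.0:
            raw = -x
        else:
            sigma_e = sd * np.sqrt(1.0 / rho**2 - 1.0)
            raw = -x + rng.normal(0.0, sigma_e, size=n)
        out[gi] = 50.0 + 40.0 * raw
    out = np.maximum(out, 0.0)
    return pd.DataFrame(out, index=gene_beta.index, columns=gene_beta.columns)


def generate_external_cohort(
    markers: list[str],
    n_pos: int,
    n_neg: int,
    shift: float = 0.2,
    seed: int = 0,
    n_background: int = 200,
    noise_sd: float = 0.05,
) -> tuple[pd.DataFrame, pd.Series]:
    """Two-class external methylome sharing a marker-level β shift.

    Positive-class samples (label 1, e.g. tumor) carry +shift at the marker
    CpGs; background CpGs are i.i.d. between classes.  Marker baselines are
    promoter-like (hypomethylated) so the shift survives clipping.
    """
    if not markers:
        raise ValueError("markers must be nonempty")
    rng = np.random.default_rng(seed)
    probes = list(markers) + [f"bg{i:06d}" for i in range(1, n_background + 1)]
    n = n_pos + n_neg
    base_markers = np.clip(rng.beta(*LOW_BETA, size=len(markers)), *BETA_CLIP)
    low = rng.random(n_background) < 0.5
    base_bg = np.where(low, rng.beta(*LOW_BETA, size=n_background), rng.beta(*HIGH_BETA, size=n_background))
    base = np.concatenate([base_markers, base_bg])
    beta = base[:, None] + rng.normal(0.0, noise_sd, size=(len(probes), n))
    labels = pd.Series(
        [1] * n_pos + [0] * n_neg,
        index=[f"pos{i:04d}" for i in range(1, n_pos + 1)]
        + [f"neg{i:04d}" for i in range(1, n_neg + 1)],
        name="label",
    )
    beta[: len(markers), : n_pos] += shift
    beta = np.clip(beta, *BETA_CLIP)
    return pd.DataFrame(beta, index=probes, columns=labels.index), labels


def simulate_all(config: SimulationConfig, size_range: tuple[int, int] | None = None, n_dmr: int = 20) -> SyntheticCohort:
    """Full study bundle: cohort + pathways + DMR track + expression.

    The DMR track and expression matrix are attached as attributes
    ``dmr_track`` / ``dmr_probes`` and ``expression``; pathway sets as
    ``pathways`` with ``truth_pathways`` recorded.
    """
    cohort = generate_cohort(config)
    if size_range is None:
        size_range = (min(10, config.n_gene), min(50, config.n_gene))
    sets, truth_names = generate_pathways(
        cohort.annotation, config.n_pathway, size_range, seed=config.seed + 2,
        truth_genes=cohort.truth_genes,
    )
    cohort.truth_pathways = truth_names
    cohort.pathways = sets  # type: ignore[attr-defined]
    track, inside = generate_dmr_track(cohort.annotation, n_dmr, seed=config.seed + 3)
    cohort.dmr_track = track  # type: ignore[attr-defined]
    cohort.dmr_probes = inside  # type: ignore[attr-defined]
    cohort.expression = generate_expression(cohort, rho=config.expr_rho, seed=config.seed + 4)
    return cohort
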