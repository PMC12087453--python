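"""Marker selection from top enriched pathways and random-forest transfer.

Markers are hypermethylated, significant (BH FDR < alpha), promoter-region
CpGs of genes in the union of the top-k enriched pathways, optionally
intersected with an external platform's probe set.  A random forest is
trained on the cohort's marker β values (β rather than M: bounded features
transfer across cohorts without per-cohort variance rescaling) with a
stratified 80/20 split and 5-fold cross-validation on the training portion,
then refit on all samples for transfer to external tumor/normal methylomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split

#: random-forest defaults: 500 trees, sqrt(p) features per split, unlimited depth
RF_PARAMS = {"n_estimators": 500, "max_features": "sqrt", "max_depth": None}


@dataclass
class MarkerPanel:
    markers: list[str]
    provenance: pd.DataFrame  # per marker: gene, pathway, log2FC, p_adj
    availability_applied: bool = False

    def __len__(self) -> int:
        return len(self.markers)


@dataclass
class TransferMetrics:
    accuracy: float
    balanced_accuracy: float
    f1: float
    auc: float | None
    tp: int
    fp: int
    tn: int
    fn: int
    dataset: str = ""

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in ("dataset", "accuracy", "balanced_accuracy", "f1", "auc", "tp", "fp", "tn", "fn")}


def confusion_metrics(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray | None = None, dataset: str = "") -> TransferMetrics:
    """Accuracy, balanced accuracy ((sens+spec)/2) and F1 (positive = 1/case)."""
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    acc = (tp + tn) / max(len(y_true), 1)
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    auc = None
    if scores is not None and len(np.unique(y_true)) == 2:
        _, auc = roc_curve(scores, y_true)
    return TransferMetrics(
        accuracy=acc, balanced_accuracy=(sens + spec) / 2, f1=f1, auc=auc,
        tp=tp, fp=fp, tn=tn, fn=fn, dataset=dataset,
    )


def select_markers(
    dm: pd.DataFrame,
    enr: pd.DataFrame,
    annotation: pd.DataFrame,
    genesets: dict[str, list[str]],
    top_k: int = 5,
    alpha: float = 0.05,
    availability: set[str] | None = None,
) -> MarkerPanel:
    """Hypermethylated promoter markers from the top-k enriched pathways.

    Pathways are ranked by p_adj ascending (ties broken by p_raw, then
    name).  On an empty result the error names the filter that emptied it.
    """
    if enr.shape[0] < top_k:
        raise ValueError(f"only {enr.shape[0]} pathways enriched, need top_k={top_k}")
    ranked = enr.sort_values(["p_adj", "p_raw", "pathway"], kind="mergesort")
    top = list(ranked["pathway"].head(top_k))
    genes = {g for pw in top for g in genesets.get(pw, [])}

    steps: list[tuple[str, pd.Index]] = []
    sig = dm.index[(dm["p_adj"] < alpha) & (dm["direction"] == "hyper")]
    steps.append(("significant-hypermethylated", sig))
    ann = annotation.loc[annotation.index.intersection(sig)]
    prom = ann.index[ann["region"].isin(("TSS200", "TSS1500"))]
    steps.append(("promoter-region", prom))
    gene_of = annotation["gene"]
    in_path = pd.Index(
        [p for p in prom if isinstance(gene_of.get(p), str) and set(str(gene_of[p]).split(";")) & genes]
    )
    steps.append(("gene-in-top-pathways", in_path))
    final = in_path
    applied = availability is not None
    if applied:
        final = pd.Index([p for p in in_path if p in availability])
        steps.append(("availability", final))
    if len(final) == 0:
        trail = " -> ".join(f"{name}:{len(ids)}" for name, ids in steps)
        raise ValueError(f"empty marker panel; filter funnel: {trail}")
    markers = sorted(final)
    prov = pd.DataFrame(
        {
            "gene": [gene_of[p] for p in markers],
            "log2FC": dm.loc[markers, "log2FC"].to_numpy(),
            "p_adj": dm.loc[markers, "p_adj"].to_numpy(),
            "pathways": [
                ";".join(pw for pw in top if set(str(gene_of[p]).split(";")) & set(genesets.get(pw, [])))
                for p in markers
            ],
        },
        index=pd.Index(markers, name="probe_id"),
    )
    return MarkerPanel(markers=markers, provenance=prov, availability_applied=applied)


def _label01(labels) -> np.ndarray:
    lab = pd.Series(list(labels))
    if set(lab.unique()) <= {0, 1}:
        return lab.to_numpy(dtype=int)
    uniq = sorted(lab.astype(str).unique())
    if len(uniq) != 2:
        raise ValueError(f"need binary labels, got {uniq}")
    pos = "case" if "case" in uniq else ("tumor" if "tumor" in uniq else uniq[1])
    return (lab.astype(str) == pos).to_numpy(dtype=int)


def train_obesity_model(
    beta_markers: pd.DataFrame,
    labels,
    split: float = 0.8,
    folds: int = 5,
    seed: int = 0,
):
    """Train the marker random forest: stratified 80/20 split, 5-fold CV on
    the training portion, hold-out evaluation, final refit on all samples.

    ``beta_markers`` is samples x markers.  Returns (final refit model,
    cv_metrics, holdout_metrics).
    """
    X = np.asarray(beta_markers, dtype=float)
    y = _label01(labels)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=split, stratify=y, random_state=seed
    )
    if min(np.bincount(y_tr)) < folds:
        raise ValueError("too few samples per class for stratified CV")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cv_pred = np.empty_like(y_tr)
    cv_score = np.empty(len(y_tr), dtype=float)
    for tr_idx, va_idx in skf.split(X_tr, y_tr):
        rf = RandomForestClassifier(**RF_PARAMS, random_state=seed)
        rf.fit(X_tr[tr_idx], y_tr[tr_idx])
        cv_pred[va_idx] = rf.predict(X_tr[va_idx])
        cv_score[va_idx] = rf.predict_proba(X_tr[va_idx])[:, 1]
    cv_metrics = confusion_metrics(y_tr, cv_pred, cv_score, dataset="cv")

    model = RandomForestClassifier(**RF_PARAMS, random_state=seed)
    model.fit(X_tr, y_tr)
    holdout_metrics = confusion_metrics(
        y_te, model.predict(X_te), model.predict_proba(X_te)[:, 1], dataset="holdout"
    )
    final = RandomForestClassifier(**RF_PARAMS, random_state=seed)
    final.fit(X, y)
    return final, cv_metrics, holdout_metrics


def evaluate_transfer(
    model,
    external_beta: pd.DataFrame,
    external_labels,
    panel: MarkerPanel,
    dataset: str = "external",
) -> TransferMetrics:
    """Apply the trained marker model to an external β matrix.

    ``external_beta`` is probes x samples; every panel marker must be
    present (the availability filter at selection time is how missing
    markers are meant to be avoided).
    """
    missing = [p for p in panel.markers if p not in external_beta.index]
    if missing:
        raise ValueError(f"markers missing from external matrix: {missing}")
    X = external_beta.loc[panel.markers].T.to_numpy(dtype=float)
    y = _label01(external_labels)
    if len(np.unique(y)) < 2:
        raise ValueError("external labels contain a single class; AUC undefined")
    pred = model.predict(X)
    scores = model.predict_proba(X)[:, 1]
    return confusion_metrics(y, pred, scores, dataset=dataset)


def roc_curve(scores, labels) -> tuple[np.ndarray, float]:
    """ROC points from a sweep over unique score thresholds + trapezoid AUC.

    Returns (array of (fpr, tpr) points, auc).  The trapezoid AUC equals
    the Mann–Whitney statistic U/(n1·n2) with midrank tie handling.
    """
    s = np.asarray(scores, dtype=float)
    y = _label01(labels)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    order = np.argsort(-s, kind="mergesort")
    s_sorted = s[order]
    y_sorted = y[order]
    tps = np.cumsum(y_sorted)
    fps = np.cumsum(1 - y_sorted)
    last = np.r_[s_sorted[1:] != s_sorted[:-1], True]  # end of each tie block
    tpr = np.r_[0.0, tps[last] / n1]
    fpr = np.r_[0.0, fps[last] / n0]
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc
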