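"""Metrics, seed ensembling, naïve accessibility predictor, variant effects
and paired one-sided Wilcoxon comparisons.

Per-fold performance is reported for the *seed ensemble*: the arithmetic
mean of the five seed replicates' predictions for each held-out gene.
Fold statistics are mean ± SD across folds. Undefined correlations
(constant vectors) are reported as NaN with a warning and excluded from
fold means, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

METRIC_NAMES = ("pearson", "spearman", "mse", "r2")


def metrics(y_true, y_pred) -> dict:
    """Pearson, Spearman (average ranks on ties), MSE and R^2
    (= 1 - SSres/SStot, not the squared correlation)."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape:
        raise ValueError(f"length mismatch: {y_true.shape} vs {y_pred.shape}")
    if y_true.size < 2:
        raise ValueError("need at least 2 observations")
    out = {"mse": float(np.mean((y_true - y_pred) ** 2))}
    sstot = float(np.sum((y_true - y_true.mean()) ** 2))
    ssres = float(np.sum((y_true - y_pred) ** 2))
    out["r2"] = 1.0 - ssres / sstot if sstot > 0 else np.nan
    if np.ptp(y_true) == 0 or np.ptp(y_pred) == 0:
        warnings.warn("constant vector: correlations undefined, reporting NaN")
        out["pearson"] = out["spearman"] = np.nan
    else:
        out["pearson"] = float(stats.pearsonr(y_true, y_pred).statistic)
        out["spearman"] = float(stats.spearmanr(y_true, y_pred).statistic)
    return out


@dataclass
class MetricReport:
    """Per-fold metric table with across-fold mean and SD."""

    per_fold: pd.DataFrame  # index fold, columns METRIC_NAMES + n_genes

    @classmethod
    def from_folds(cls, fold_metrics: dict) -> "MetricReport":
        df = pd.DataFrame(fold_metrics).T
        df.index.name = "fold"
        return cls(df)

    @property
    def mean(self) -> pd.Series:
        nan_counts = self.per_fold[list(METRIC_NAMES)].isna().sum()
        if nan_counts.any():
            warnings.warn(f"NaN metrics excluded from fold means: {dict(nan_counts[nan_counts > 0])}")
        return self.per_fold[list(METRIC_NAMES)].mean(skipna=True)

    @property
    def std(self) -> pd.Series:
        return self.per_fold[list(METRIC_NAMES)].std(skipna=True)

    def to_tsv(self, path) -> None:
        self.per_fold.to_csv(path, sep="\t")


def ensemble_predict(models, x: np.ndarray, gene_ids=None, model_gene_ids=None) -> np.ndarray:
    """Mean prediction across seed-replicate models of one fold.

    ``models`` are built networks or checkpoints; if per-model gene-id
    lists are supplied they must all match ``gene_ids``.
    """
    if model_gene_ids is not None:
        for mg in model_gene_ids:
            if list(mg) != list(gene_ids):
                raise ValueError("checkpoints evaluated on mismatched gene sets")
    preds = []
    for m in models:
        net = m.build() if hasattr(m, "build") else m
        preds.append(net.predict(np.asarray(x, dtype=np.float32)))
    return np.mean(preds, axis=0)


def evaluate_fold_ensemble(checkpoints, test_data) -> dict:
    """Ensemble the fold's seed replicates and score against the fold's
    held-out targets."""
    pred = ensemble_predict(checkpoints, test_data.x)
    out = metrics(test_data.y, pred)
    out["n_genes"] = test_data.n
    return out


def naive_predict(auatac: pd.Series | dict, test_genes) -> np.ndarray:
    """The accessibility-only baseline: the prediction for a gene is its
    auATAC. Scored by Spearman against GEx per fold."""
    s = pd.Series(auatac)
    missing = [g for g in test_genes if g not in s.index]
    if missing:
        raise KeyError(f"auATAC missing for genes: {missing[:5]}")
    return s.loc[list(test_genes)].to_numpy(dtype=np.float64)


def naive_eval(auatac, gex, test_genes) -> float:
    pred = naive_predict(auatac, test_genes)
    y = pd.Series(gex).loc[list(test_genes)].to_numpy(dtype=np.float64)
    return metrics(y, pred)["spearman"]


def cross_cell_type_eval(checkpoints_by_fold: dict, datasets_by_fold: dict) -> MetricReport:
    """Score models trained on cell type *a* against another cell type's
    inputs and targets, fold by fold (fold gene sets must match)."""
    folds = sorted(checkpoints_by_fold)
    if sorted(datasets_by_fold) != folds:
        raise ValueError("fold mismatch between checkpoints and datasets")
    out = {}
    for fold in folds:
        out[fold] = evaluate_fold_ensemble(checkpoints_by_fold[fold], datasets_by_fold[fold])
    return MetricReport.from_folds(out)


def subset_eval(y_true_by_fold: dict, y_pred_by_fold: dict, gene_ids_by_fold: dict,
                subset) -> MetricReport:
    """Recompute fold metrics on the intersection with a gene subset
    (e.g. highly-variable genes); empty or singleton intersections yield
    NaN correlations with a warning."""
    subset = set(subset)
    out = {}
    for fold in sorted(gene_ids_by_fold):
        genes = list(gene_ids_by_fold[fold])
        idx = [i for i, g in enumerate(genes) if g in subset]
        if len(idx) == 0:
            warnings.warn(f"fold {fold}: empty intersection with subset")
            out[fold] = {m: np.nan for m in METRIC_NAMES} | {"n_genes": 0}
            continue
        yt = np.asarray(y_true_by_fold[fold])[idx]
        yp = np.asarray(y_pred_by_fold[fold])[idx]
        if len(idx) < 2:
            warnings.warn(f"fold {fold}: subset of size 1, correlations undefined")
            out[fold] = {
                "pearson": np.nan, "spearman": np.nan,
                "mse": float(np.mean((yt - yp) ** 2)), "r2": np.nan, "n_genes": 1,
            }
            continue
        out[fold] = metrics(yt, yp) | {"n_genes": len(idx)}
    return MetricReport.from_folds(out)


def variant_effect(model, ref_sample: np.ndarray, alt_sequence) -> float:
    """Predicted GEx change of an alternative promoter sequence.

    The alternative sample reuses the reference ATAC track (when present):
    only the DNA rows change. Returns predict(alt) - predict(ref).
    """
    from .genome_io import one_hot_encode

    ref_sample = np.asarray(ref_sample, dtype=np.float32)
    C, L = ref_sample.shape
    if isinstance(alt_sequence, str):
        alt_dna = one_hot_encode(alt_sequence)
    else:
        alt_dna = np.asarray(alt_sequence, dtype=np.float32)
    if alt_dna.shape[1] != L:
        raise ValueError(f"alt length {alt_dna.shape[1]} != ref length {L}")
    alt = ref_sample.copy()
    alt[:4] = alt_dna
    net = model.build() if hasattr(model, "build") else model
    both = np.stack([alt, ref_sample])
    pred = net.predict(both)
    return float(pred[0] - pred[1])


def auroc(scores, labels) -> float:
    """Probability a random positive outscores a random negative (ties
    count 1/2); both classes must be present."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("auROC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=np.float64)))


def wilcoxon_one_sided(x, y, alternative: str = "greater") -> float:
    """One-sided Wilcoxon signed-rank test on paired samples.

    Zero differences are dropped before ranking (signed-rank convention);
    ties in |difference| get average ranks. The p-value is exact (full
    null distribution of the positive-rank sum, computed by dynamic
    programming — identical to 2^n sign enumeration) for n <= 25 nonzero
    differences, and a tie-corrected normal approximation with continuity
    correction beyond that.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = stats.rankdata(np.abs(d))  # average ranks; multiples of 0.5
    w_plus = float(ranks[d > 0].sum())
    if alternative == "less":
        # P(W+ <= w) == P(W+ >= n(n+1)/2 - w) by symmetry of the null
        w_plus = n * (n + 1) / 2.0 - w_plus
    if n <= 25:
        r2 = np.rint(2 * ranks).astype(np.int64)  # doubled ranks are integers
        total = int(r2.sum())
        counts = np.zeros(total + 1, dtype=np.float64)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[: total + 1 - r]
        w2 = int(np.ceil(2 * w_plus - 1e-9))
        return float(counts[w2:].sum() / 2.0**n)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float(((tie_counts**3 - tie_counts).sum())) / 48.0
    z = (w_plus - mean - 0.5) / np.sqrt(var)
    return float(stats.norm.sf(z))
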