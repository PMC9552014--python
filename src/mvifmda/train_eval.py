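"""Cross-validation protocol, training loop, metrics, and candidate ranking.

Evaluation follows the masked-link-prediction convention: the known positive
pairs are split into five near-equal folds; for each fold the held-out
positives are removed from the association matrix, the heterogeneous networks
are rebuilt from the masked matrix, the model is trained on it, and every
pair that is not a *training* positive is scored.  Test positives are the
positives of that candidate set and all other unobserved pairs count as
negatives — no negative subsampling, which is why AUPR lives on a small scale
at realistic sparsity.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import MVIFMDA, Adam, ModelConfig
from .netbuild import AssociationMatrix, assemble_hetero_networks, mask_associations
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FoldSplit",
    "MetricReport",
    "make_folds",
    "train_model",
    "compute_metrics",
    "run_cv",
    "fit_full",
    "rank_disease_candidates",
    "paired_metric_ttest",
]

N_FOLDS = 5
DEFAULT_KS = (0.05, 0.10)


@dataclass
class FoldSplit:
    """Partition of the known positives into disjoint test folds."""

    folds: list[list[tuple[str, str]]]
    seed: int

    def __post_init__(self):
        sizes = [len(f) for f in self.folds]
        if max(sizes) - min(sizes) > 1:
            raise ValueError(f"folds are not near-equal: sizes {sizes}")


@dataclass
class MetricReport:
    """Classification and ranking metrics on one scored candidate set."""

    auc: float
    aupr: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    precision_at_k: dict[float, float]
    recall_at_k: dict[float, float]
    n_candidates: int = 0
    n_positives: int = 0

    def to_dict(self) -> dict:
        d = {
            "AUC": self.auc, "AUPR": self.aupr, "accuracy": self.accuracy,
            "precision": self.precision, "recall": self.recall, "F1": self.f1,
            "n_candidates": self.n_candidates, "n_positives": self.n_positives,
        }
        for k, v in self.precision_at_k.items():
            d[f"precision@{k:.0%}"] = v
        for k, v in self.recall_at_k.items():
            d[f"recall@{k:.0%}"] = v
        return d


def make_folds(
    positives: list[tuple[str, str]], seed: int, n_folds: int = N_FOLDS
) -> FoldSplit:
    """Seeded shuffle of the positive pairs into near-equal disjoint folds."""
    if len(positives) < n_folds:
        raise ValueError(
            f"need at least {n_folds} positive pairs, got {len(positives)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(positives))
    parts = np.array_split(order, n_folds)
    return FoldSplit(
        folds=[[positives[i] for i in part] for part in parts], seed=seed
    )


def train_model(
    config: ModelConfig,
    masked_assoc: AssociationMatrix,
    mirna_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
) -> tuple[MVIFMDA, list[float]]:
    """Train the network on a (possibly masked) association matrix.

    Heterogeneous views are assembled from the masked matrix, so held-out
    positives are invisible to both the GCN branch and the loss.  Returns the
    trained model and the per-epoch loss trace.
    """
    networks = assemble_hetero_networks(masked_assoc, mirna_sims, disease_sims)
    model = MVIFMDA(config, masked_assoc.n_mirna, masked_assoc.n_disease,
                    n_views=len(networks))
    inputs = model.prepare_inputs(networks, mirna_sims, disease_sims)
    opt = Adam(model.parameters(), lr=config.lr)
    trace: list[float] = []
    best = np.inf
    stale = 0
    for epoch in range(config.epochs):
        opt.zero_grad()
        loss = model.loss(inputs, masked_assoc.A)
        value = float(loss.data)
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite training loss at epoch {epoch}: {value}"
            )
        loss.backward()
        opt.step()
        trace.append(value)
        if config.early_stop_patience:
            if value < best * (1.0 - config.early_stop_min_delta):
                best, stale = value, 0
            else:
                stale += 1
                if stale >= config.early_stop_patience:
                    logger.info("early stop at epoch %d (loss %.4f)", epoch, value)
                    break
    model._inputs = inputs  # cache for prediction on the same networks
    return model, trace


def _top_k_counts(order_labels: np.ndarray, k: float) -> tuple[float, float]:
    n_top = max(1, int(np.floor(k * order_labels.size)))
    hits = float(order_labels[:n_top].sum())
    total_pos = float(order_labels.sum())
    precision = hits / n_top
    recall = hits / total_pos if total_pos else 0.0
    return precision, recall


def compute_metrics(
    scores,
    labels,
    threshold: float = 0.5,
    ks: tuple[float, ...] = DEFAULT_KS,
) -> MetricReport:
    """Full metric suite on one ranking of scored candidates.

    AUC is the rank-statistic ROC area (ties rank-averaged), AUPR the
    precision-recall step integral; confusion metrics use the given score
    threshold; precision@k%/recall@k% take the top k-percent slice of the
    descending ranking.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D arrays")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present for AUC/AUPR")
    auc = float(roc_auc_score(labels, scores))
    aupr = float(average_precision_score(labels, scores))
    pred = (scores >= threshold).astype(int)
    tp = int(((pred == 1) & (labels == 1)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    accuracy = (tp + tn) / labels.size
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    order = np.argsort(-scores, kind="stable")
    ordered = labels[order]
    p_at, r_at = {}, {}
    for k in ks:
        p_at[k], r_at[k] = _top_k_counts(ordered, k)
    return MetricReport(
        auc=auc, aupr=aupr, accuracy=accuracy, precision=precision,
        recall=recall, f1=f1, precision_at_k=p_at, recall_at_k=r_at,
        n_candidates=labels.size, n_positives=int(labels.sum()),
    )


def _evaluate_fold(
    model: MVIFMDA,
    masked_assoc: AssociationMatrix,
    test_pairs: list[tuple[str, str]],
    ks: tuple[float, ...],
) -> MetricReport:
    """Score all pairs that are not training positives; test positives are 1."""
    scores_matrix = model.predict(model._inputs)
    candidate_mask = masked_assoc.A == 0  # everything except training positives
    mi = {m: i for i, m in enumerate(masked_assoc.mirna_ids)}
    di = {d: j for j, d in enumerate(masked_assoc.disease_ids)}
    labels_matrix = np.zeros_like(masked_assoc.A)
    for m, d in test_pairs:
        labels_matrix[mi[m], di[d]] = 1.0
    assert (labels_matrix[~candidate_mask] == 0).all(), \
        "test positives leaked into the training matrix"
    return compute_metrics(
        scores_matrix[candidate_mask], labels_matrix[candidate_mask], ks=ks
    )


@dataclass
class CVResult:
    """Per-fold, per-repeat, and aggregate metrics of a cross-validation run."""

    per_fold: list[dict]            # one dict per (repeat, fold)
    per_repeat: list[dict]          # fold-mean per repeat
    aggregate: dict                 # mean/std over repeats and over all folds
    fold_seeds: list[int]
    config: dict
    elapsed_seconds: float = 0.0

    def to_dict(self) -> dict:
        return {
            "aggregate": self.aggregate,
            "per_repeat": self.per_repeat,
            "per_fold": self.per_fold,
            "fold_seeds": self.fold_seeds,
            "config": self.config,
            "elapsed_seconds": self.elapsed_seconds,
        }


def run_cv(
    config: ModelConfig,
    assoc: AssociationMatrix,
    mirna_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    repeats: int = 1,
    seed: int = 0,
    ks: tuple[float, ...] = DEFAULT_KS,
) -> CVResult:
    """Repeated 5-fold cross-validation over the known positives.

    Each repeat reshuffles the folds with its own derived seed; the model seed
    is likewise re-derived per fold so repeats are independent.  Reports mean
    and standard deviation both over repeat-level means and over all
    fold-level values.
    """
    t0 = time.time()
    positives = assoc.positives()
    per_fold, per_repeat, fold_seeds = [], [], []
    rng = np.random.default_rng(seed)
    for rep in range(repeats):
        fold_seed = int(rng.integers(0, 2**31 - 1))
        fold_seeds.append(fold_seed)
        split = make_folds(positives, seed=fold_seed)
        rep_metrics = []
        for fold_idx, test_pairs in enumerate(split.folds):
            masked = mask_associations(assoc, set(test_pairs))
            fold_config = ModelConfig(**{
                **config.to_dict(), "seed": fold_seed + fold_idx + 1
            })
            model, trace = train_model(fold_config, masked, mirna_sims,
                                       disease_sims)
            report = _evaluate_fold(model, masked, test_pairs, ks)
            entry = {"repeat": rep, "fold": fold_idx,
                     "final_loss": trace[-1], "epochs_run": len(trace),
                     **report.to_dict()}
            per_fold.append(entry)
            rep_metrics.append(report.to_dict())
            logger.info("repeat %d fold %d: AUC=%.4f AUPR=%.4f",
                        rep, fold_idx, report.auc, report.aupr)
        keys = [k for k in rep_metrics[0] if isinstance(rep_metrics[0][k], float)]
        per_repeat.append(
            {k: float(np.mean([m[k] for m in rep_metrics])) for k in keys}
        )
    metric_keys = list(per_repeat[0])
    aggregate = {}
    for k in metric_keys:
        rep_vals = np.array([r[k] for r in per_repeat])
        fold_vals = np.array([f[k] for f in per_fold if k in f])
        aggregate[k] = {
            "mean": float(rep_vals.mean()),
            "std_over_repeats": float(rep_vals.std(ddof=0)),
            "std_over_folds": float(fold_vals.std(ddof=0)),
        }
    return CVResult(per_fold=per_fold, per_repeat=per_repeat,
                    aggregate=aggregate, fold_seeds=fold_seeds,
                    config=config.to_dict(),
                    elapsed_seconds=time.time() - t0)


def fit_full(
    config: ModelConfig,
    assoc: AssociationMatrix,
    mirna_sims: list[SimilarityMatrix],
    disease_sims: list[SimilarityMatrix],
    exclude_disease: str | None = None,
) -> tuple[MVIFMDA, AssociationMatrix]:
    """Train on all known positives (case-study mode).

    With ``exclude_disease`` the associations of that disease are withheld
    before training (novel-disease mode: the disease is scored purely from
    the similarity signal of the remaining network).
    """
    training_assoc = assoc
    if exclude_disease is not None:
        if exclude_disease not in assoc.disease_ids:
            raise KeyError(f"unknown disease id: {exclude_disease!r}")
        withheld = {(m, d) for m, d in assoc.positives() if d == exclude_disease}
        training_assoc = mask_associations(assoc, withheld)
    model, _ = train_model(config, training_assoc, mirna_sims, disease_sims)
    return model, training_assoc


def rank_disease_candidates(
    scores: np.ndarray,
    assoc: AssociationMatrix,
    disease_id: str,
    exclude: set[str] | None = None,
    top: int | None = None,
) -> list[tuple[str, float]]:
    """Descending-score candidate miRNAs for one disease.

    ``exclude`` removes miRNAs (typically those already known for the
    disease) from the ranking; ties break by miRNA identifier for
    reproducibility.
    """
    if disease_id not in assoc.disease_ids:
        raise KeyError(f"unknown disease id: {disease_id!r}")
    j = assoc.disease_ids.index(disease_id)
    exclude = exclude or set()
    items = [
        (m, float(scores[i, j]))
        for i, m in enumerate(assoc.mirna_ids)
        if m not in exclude
    ]
    items.sort(key=lambda t: (-t[1], t[0]))
    return items[:top] if top is not None else items


def paired_metric_ttest(values_a, values_b) -> tuple[float, float]:
    """Two-sided paired t-test over repeat-level metric vectors.

    Utility for comparing this model against externally computed baselines;
    no baseline predictors ship with the package.
    """
    from scipy import stats

    res = stats.ttest_rel(np.asarray(values_a), np.asarray(values_b))
    return float(res.statistic), float(res.pvalue)
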