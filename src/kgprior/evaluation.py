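"""Link-deletion k-fold cross-validation and its metric suite.

Unlike a conventional cross-validation, the held-out genes are not removed
from the data: only their association edge to the target disease is deleted
from the graph, so during training they are effectively labelled as *not*
linked.  The model's job in each fold is to re-predict the deleted links —
an exact simulation of the intended use (predicting genes whose link is
genuinely missing from today's databases).  A fold is significantly
enriched when the hypergeometric probability of predicting at least as many
held-out genes correctly by chance is below 0.05.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .graph import DiseaseDefinition, KnowledgeGraph, delete_disease_links
from .model import ProfilePrioritizer, UntrainableModelError
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "CVFoldResult",
    "CVReport",
    "kfold_split",
    "run_fold",
    "expected_random_precision",
    "fold_significance",
    "summarize_cv",
    "cross_validate",
]

SIGNIFICANCE_LEVEL = 0.05

_METRICS = (
    "precision_train",
    "recall_train",
    "precision_valid",
    "recall_valid",
    "fold_change",
)


@dataclass
class CVFoldResult:
    """Metrics for one link-deletion fold (one row behind the summary table)."""

    fold_index: int
    n_train: int
    n_valid: int
    precision_train: float
    recall_train: float
    precision_valid: float
    recall_valid: float
    expected_random_precision: float
    fold_change: float
    p_fold: float
    significant: bool
    n_predicted_new: int
    n_correct: int
    seed: int
    failed: bool = False
    no_predictions: bool = False


@dataclass
class CVReport:
    """Per-fold results plus mean/standard-deviation summary."""

    folds: list[CVFoldResult]
    mean: dict[str, float]
    std: dict[str, float]
    n_significant_folds: int
    k: int = 0
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "k": self.k,
                "seed": self.seed,
                "folds": [asdict(f) for f in self.folds],
                "mean": self.mean,
                "std": self.std,
                "n_significant_folds": self.n_significant_folds,
            },
            sort_keys=True,
            indent=2,
        )


def kfold_split(genes: Sequence[str], k: int, seed: int) -> list[list[str]]:
    """Random partition into k folds with sizes differing by at most one.

    Deterministic given the seed; e.g. 27 genes at k=5 give fold sizes
    {6, 6, 5, 5, 5} (validation 5–6, training 21–22).
    """
    genes = list(genes)
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if len(genes) < k:
        raise ValueError(f"cannot split {len(genes)} genes into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(genes))
    return [[genes[i] for i in part] for part in np.array_split(order, k)]


def expected_random_precision(n_valid: int, n_candidates: int) -> float:
    """Precision of a random guesser: held-out positives over candidate genes.

    Candidates are the universe genes minus the training positives — the
    genes the model was allowed to predict.
    """
    if n_candidates <= 0:
        raise ValueError("no candidate genes")
    if n_valid > n_candidates:
        raise ValueError(f"n_valid={n_valid} exceeds n_candidates={n_candidates}")
    return n_valid / n_candidates


def fold_significance(
    n_correct: int, n_predicted: int, n_valid: int, n_candidates: int
) -> float:
    """P(random predictions of the same size hit at least n_correct held-out genes)."""
    return hypergeom_tail(k=n_correct, K=n_valid, n=n_predicted, N=n_candidates)


def _derive_fold_seeds(seed: int, k: int) -> list[int]:
    """Per-fold seeds from one master seed (fixed splitmix-style stream)."""
    state = np.random.SeedSequence(seed).generate_state(k)
    return [int(s) % 2**31 for s in state]


def run_fold(
    graph: KnowledgeGraph,
    disease: str,
    train_genes: Sequence[str],
    valid_genes: Sequence[str],
    fold_index: int = 0,
    seed: int = 0,
    model_params: dict | None = None,
    shuffle_scores: bool = False,
) -> CVFoldResult:
    """Train on the graph with the validation genes' disease links deleted.

    Training positives are ``train_genes``; the held-out genes stay in the
    graph with all their other edges, so they are scored as ordinary
    candidates.  Validation precision/recall count only *new* predictions
    (training positives excluded from the prediction set); training
    precision/recall are computed over all genes at the threshold.

    ``shuffle_scores=True`` permutes the fitted score vector across genes
    before thresholding — the null calibration mode, which keeps the number
    of predictions but destroys their association with the held-out set.
    """
    train = set(train_genes) & set(valid_genes)
    if train:
        raise ValueError(f"train and validation sets overlap: {sorted(train)}")
    pruned = delete_disease_links(graph, disease, valid_genes)
    params = dict(model_params or {})
    params.setdefault("random_state", seed)
    try:
        est = ProfilePrioritizer(**params).fit(pruned, train_genes, disease=disease)
    except UntrainableModelError as exc:
        logger.warning("fold %d failed: %s", fold_index, exc)
        return CVFoldResult(
            fold_index=fold_index,
            n_train=len(set(train_genes)),
            n_valid=len(set(valid_genes)),
            precision_train=0.0,
            recall_train=0.0,
            precision_valid=0.0,
            recall_valid=0.0,
            expected_random_precision=0.0,
            fold_change=0.0,
            p_fold=1.0,
            significant=False,
            n_predicted_new=0,
            n_correct=0,
            seed=seed,
            failed=True,
        )

    scored = est.predict()
    if shuffle_scores:
        rng = np.random.default_rng(seed + 1)
        scored = scored.copy()
        scored["score"] = rng.permutation(scored["score"].to_numpy())
        pos = set(est.positives_used_)
        scored["predicted"] = (scored["score"] >= est.threshold_) & ~scored[
            "gene"
        ].isin(pos)

    universe = set(est.universe_)
    train_used = set(est.positives_used_)
    valid = {g if g.startswith("gene:") else f"gene:{g.upper()}" for g in valid_genes}
    valid &= universe
    candidates = universe - train_used

    above = set(scored.loc[scored["score"] >= est.threshold_, "gene"])
    predicted_new = set(scored.loc[scored["predicted"], "gene"])
    n_correct = len(predicted_new & valid)

    precision_train = len(above & train_used) / len(above) if above else 0.0
    recall_train = len(above & train_used) / len(train_used) if train_used else 0.0
    precision_valid = n_correct / len(predicted_new) if predicted_new else 0.0
    recall_valid = n_correct / len(valid) if valid else 0.0
    erp = expected_random_precision(len(valid), len(candidates))
    fold_change = precision_valid / erp if erp > 0 else 0.0
    p_fold = fold_significance(n_correct, len(predicted_new), len(valid), len(candidates))

    return CVFoldResult(
        fold_index=fold_index,
        n_train=len(train_used),
        n_valid=len(valid),
        precision_train=precision_train,
        recall_train=recall_train,
        precision_valid=precision_valid,
        recall_valid=recall_valid,
        expected_random_precision=erp,
        fold_change=fold_change,
        p_fold=p_fold,
        significant=p_fold < SIGNIFICANCE_LEVEL,
        n_predicted_new=len(predicted_new),
        n_correct=n_correct,
        seed=seed,
        no_predictions=not predicted_new,
    )


def summarize_cv(folds: Iterable[CVFoldResult], k: int = 0, seed: int = 0) -> CVReport:
    """Mean and sample (n−1) standard deviation of each metric over folds.

    Failed folds are kept in the report but excluded from the summary
    statistics; a single fold yields std 0 by convention.
    """
    folds = list(folds)
    if not folds:
        raise ValueError("no folds to summarize")
    ok = [f for f in folds if not f.failed]
    mean: dict[str, float] = {}
    std: dict[str, float] = {}
    for m in _METRICS:
        vals = np.array([getattr(f, m) for f in ok]) if ok else np.array([0.0])
        mean[m] = float(vals.mean())
        std[m] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return CVReport(
        folds=folds,
        mean=mean,
        std=std,
        n_significant_folds=sum(f.significant for f in ok),
        k=k or len(folds),
        seed=seed,
    )


def cross_validate(
    graph: KnowledgeGraph,
    definition: DiseaseDefinition,
    k: int = 5,
    seed: int = 0,
    model_params: dict | None = None,
    shuffle_scores: bool = False,
) -> CVReport:
    """Full link-deletion k-fold cross-validation for one gene-list definition.

    Genes absent from the graph are dropped before splitting (with a logged
    count), so fold sizes reflect the usable genes.  Per-fold seeds are
    derived from the master seed and recorded in each fold result.
    """
    usable = definition.present_in(graph)
    n_missing = len(definition) - len(usable)
    if n_missing:
        logger.info(
            "cross_validate(%s): %d genes absent from the graph", definition.name, n_missing
        )
    folds = kfold_split(usable, k, seed)
    fold_seeds = _derive_fold_seeds(seed, k)
    results = []
    for i, valid in enumerate(folds):
        train = [g for g in usable if g not in set(valid)]
        results.append(
            run_fold(
                graph,
                definition.disease_node,
                train,
                valid,
                fold_index=i,
                seed=fold_seeds[i],
                model_params=model_params,
                shuffle_scores=shuffle_scores,
            )
        )
    return summarize_cv(results, k=k, seed=seed)
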