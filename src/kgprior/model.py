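"""Enrichment-profile link prediction: the gene-prioritisation model.

Given a knowledge graph and a set of genes known to be linked to a disease
(the positives), the model

1. collects every node in the positives' local neighbourhood — annotation
   terms, other diseases, and interaction-partner genes — as candidate
   features, tagged by the edge type through which they are reached;
2. keeps the features significantly over-represented among positives
   relative to the whole gene universe (one-sided hypergeometric test,
   Bonferroni-corrected by default) — the *predictive profile*;
3. scores every gene by its overlap with the profile: per edge type, the
   fraction of that type's profile features the gene carries, combined by a
   convex weight vector over edge types;
4. learns the weights and a decision threshold by grid search, maximising
   the mean F1 over an inner cross-validation split of the positives;
5. predicts as new candidates every gene scoring at or above the threshold
   that is not itself an input positive.

This is a guilt-by-association model on the local neighbourhood; it is
deliberately not a diffusion or random-walk scorer.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import asdict, dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .graph import DiseaseDefinition, EdgeType, KnowledgeGraph, gene_node
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureStat",
    "ProfilePrioritizer",
    "UntrainableModelError",
    "candidate_features",
    "select_profile",
    "score_gene",
    "learn_weights_and_threshold",
    "predict",
]

MODEL_SCHEMA_VERSION = 1

#: deterministic ordering of edge types in weight vectors
_TYPE_ORDER = (EdgeType.INTERACTS_WITH, EdgeType.ANNOTATED_WITH, EdgeType.ASSOCIATED_WITH)


class UntrainableModelError(RuntimeError):
    """The positives yield no enriched features; no model can be fitted."""


@dataclass(frozen=True)
class FeatureStat:
    """Enrichment record for one profile feature.

    ``k`` of the ``n`` positives carry the feature, against ``K`` carriers in
    the ``N``-gene universe; ``p_enrich`` is the one-sided hypergeometric
    tail P(X >= k).
    """

    feature: str
    edge_type: EdgeType
    k: int
    K: int
    p_enrich: float


def _as_gene_nodes(positives: Iterable[str] | DiseaseDefinition) -> list[str]:
    if isinstance(positives, DiseaseDefinition):
        return positives.gene_nodes()
    out = []
    for g in positives:
        out.append(g if g.startswith("gene:") else gene_node(g))
    return out


def candidate_features(
    graph: KnowledgeGraph,
    positives: Iterable[str] | DiseaseDefinition,
    disease: str | None = None,
) -> list[tuple[str, EdgeType]]:
    """Every neighbourhood node of the positives, tagged by edge type.

    Annotation terms, other diseases, and interaction-partner genes adjacent
    to at least one positive all qualify; the target disease node itself is
    excluded (it would trivially separate positives from the rest).  Order is
    deterministic: by edge type, then feature id.
    """
    pos = [p for p in _as_gene_nodes(positives) if p in graph]
    if not pos:
        raise UntrainableModelError("no usable positives")
    feats: set[tuple[str, EdgeType]] = set()
    for p in pos:
        for t in _TYPE_ORDER:
            for nb in graph.neighbors(p, t):
                if disease is not None and nb == disease:
                    continue
                feats.add((nb, t))
    return sorted(feats, key=lambda ft: (ft[1].value, ft[0]))


def select_profile(
    graph: KnowledgeGraph,
    positives: Iterable[str] | DiseaseDefinition,
    alpha: float = 0.05,
    correction: str = "bonferroni",
    disease: str | None = None,
) -> list[FeatureStat]:
    """Hypergeometric enrichment test over all candidate features.

    For each candidate feature, ``k`` positives out of ``n`` carry it versus
    ``K`` carriers among all ``N`` universe genes; the feature enters the
    profile iff its one-sided tail p-value passes ``alpha / m`` (Bonferroni
    over the ``m`` candidates) or plain ``alpha`` with ``correction="none"``.
    """
    if correction not in ("bonferroni", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    if isinstance(positives, DiseaseDefinition):
        if disease is None:
            disease = positives.disease_node
        positives = positives.gene_nodes()
    pos = sorted({p for p in _as_gene_nodes(positives) if p in graph})
    if not pos:
        raise UntrainableModelError("no usable positives")
    if len(pos) < 2:
        raise UntrainableModelError("need at least 2 usable positives")
    universe = graph.gene_universe
    N, n = len(universe), len(pos)
    pos_set = set(pos)
    cands = candidate_features(graph, pos, disease=disease)
    m = len(cands)
    cutoff = alpha / m if (correction == "bonferroni" and m) else alpha
    profile = []
    for feat, t in cands:
        carriers = graph.neighbors(feat, t) & universe
        K = len(carriers)
        k = len(carriers & pos_set)
        p = hypergeom_tail(k, K, n, N)
        if p <= cutoff:
            profile.append(FeatureStat(feat, t, k, K, p))
    return profile


def _overlap_fractions(
    graph: KnowledgeGraph,
    genes: Sequence[str],
    profile: Sequence[FeatureStat],
    active_types: Sequence[EdgeType],
) -> np.ndarray:
    """Per-gene, per-edge-type fraction of profile features carried.

    Shape (len(genes), len(active_types)); each column is the count of
    type-t profile features adjacent to the gene over the number of type-t
    features.
    """
    idx = {g: i for i, g in enumerate(genes)}
    frac = np.zeros((len(genes), len(active_types)))
    for j, t in enumerate(active_types):
        feats = [fs.feature for fs in profile if fs.edge_type == t]
        if not feats:
            continue
        counts = np.zeros(len(genes))
        for f in feats:
            for nb in graph.neighbors(f, t):
                i = idx.get(nb)
                if i is not None:
                    counts[i] += 1
        frac[:, j] = counts / len(feats)
    return frac


class ProfilePrioritizer(BaseEstimator):
    """Guilt-by-association gene prioritiser over a knowledge graph.

    Parameters
    ----------
    alpha : significance level for profile feature selection (default 0.05).
    correction : ``"bonferroni"`` (default) or ``"none"`` — multiple-testing
        control over the candidate features.
    weight_grid : candidate per-edge-type weights; the grid of convex weight
        vectors is every normalised combination of these values over the
        edge types present in the profile.
    inner_folds : folds of the inner cross-validation used to pick weights
        and threshold by mean F1 (default 3; clipped to the number of
        positives when smaller lists are fitted).
    random_state : seed for the inner-fold assignment; fitting is fully
        deterministic given graph, positives, and this seed.

    Fitted attributes
    -----------------
    profile_ : list[FeatureStat] — the enriched features.
    type_weights_ : dict[EdgeType, float] — convex weights over edge types
        with at least one profile feature.
    threshold_ : float — decision threshold on the similarity score.
    positives_used_ : tuple[str, ...] — gene node ids the model trained on.
    disease_ : str | None — target disease node, excluded from features.
    universe_ : tuple[str, ...] — gene universe at fit time (sorted).
    """

    def __init__(
        self,
        alpha: float = 0.05,
        correction: str = "bonferroni",
        weight_grid: Sequence[float] = (0.0, 0.25, 0.5, 0.75, 1.0),
        inner_folds: int = 3,
        random_state: int = 0,
    ) -> None:
        self.alpha = alpha
        self.correction = correction
        self.weight_grid = weight_grid
        self.inner_folds = inner_folds
        self.random_state = random_state

    # -- fitting ----------------------------------------------------------

    def fit(
        self,
        graph: KnowledgeGraph,
        positives: Iterable[str] | DiseaseDefinition,
        disease: str | None = None,
    ) -> "ProfilePrioritizer":
        if not (0 < self.alpha < 1):
            raise ValueError(f"alpha must be in (0,1), got {self.alpha}")
        grid = sorted({float(w) for w in self.weight_grid})
        if not grid or all(w == 0 for w in grid):
            raise ValueError("weight_grid must contain a nonzero weight")
        if isinstance(positives, DiseaseDefinition) and disease is None:
            disease = positives.disease_node
        requested = _as_gene_nodes(positives)
        pos = sorted({p for p in requested if p in graph})
        n_dropped = len(set(requested)) - len(pos)
        if n_dropped:
            logger.info("fit: %d positives absent from the graph were dropped", n_dropped)
        profile = select_profile(
            graph, pos, alpha=self.alpha, correction=self.correction, disease=disease
        )
        if not profile:
            raise UntrainableModelError("untrainable: no enriched features")
        active = [t for t in _TYPE_ORDER if any(fs.edge_type == t for fs in profile)]
        universe = tuple(sorted(graph.gene_universe))
        frac = _overlap_fractions(graph, universe, profile, active)
        uidx = {g: i for i, g in enumerate(universe)}
        pos_idx = np.array([uidx[p] for p in pos])

        weights, threshold = self._search(frac, pos_idx, len(active))

        self.graph_ = graph
        self.disease_ = disease
        self.positives_used_ = tuple(pos)
        self.profile_ = profile
        self.active_types_ = tuple(active)
        self.type_weights_ = dict(zip(active, weights))
        self.threshold_ = float(threshold)
        self.universe_ = universe
        self._frac = frac
        return self

    def _weight_vectors(self, n_types: int) -> list[tuple[float, ...]]:
        grid = sorted({float(w) for w in self.weight_grid})
        if n_types == 1:
            return [(1.0,)]
        seen: dict[tuple[float, ...], None] = {}
        for combo in itertools.product(grid, repeat=n_types):
            s = sum(combo)
            if s == 0:
                continue
            seen.setdefault(tuple(round(w / s, 9) for w in combo), None)
        return list(seen)

    def _search(
        self, frac: np.ndarray, pos_idx: np.ndarray, n_types: int
    ) -> tuple[tuple[float, ...], float]:
        """Grid search over weight vectors and observed-score thresholds.

        For each convex weight vector the positives are split into inner
        folds and every observed score is tried as the threshold.  The fold
        F1 follows the positive-unlabeled convention: precision is the share
        of known positives among all genes at or above the threshold (genes
        without a disease link are unlabeled, not confirmed negatives, so
        precision is estimated against the labels we have), while recall is
        measured on the held-out inner fold only, so the threshold must
        generalise to positives it was not tuned on.  The pair maximising
        mean inner F1 wins, ties resolved toward the higher threshold (fewer
        predictions), then first weight vector in enumeration order.
        """
        n_folds = min(self.inner_folds, len(pos_idx))
        if n_folds < 1:
            raise UntrainableModelError("no usable positives")
        rng = np.random.default_rng(self.random_state)
        folds = np.array_split(rng.permutation(pos_idx), n_folds)

        best = (-1.0, -1.0, None)  # (mean F1, threshold, weights)
        for w in self._weight_vectors(n_types):
            s = frac @ np.asarray(w)
            # candidate thresholds are the positives' observed scores: a cut
            # between two positives only drops unlabeled genes, which inflates
            # the measured precision without evidence
            thresholds = np.unique(s[pos_idx])  # ascending
            npred = len(s) - np.searchsorted(np.sort(s), thresholds, side="left")
            ps = np.sort(s[pos_idx])
            tp_all = len(ps) - np.searchsorted(ps, thresholds, side="left")
            prec = np.where(npred > 0, tp_all / np.maximum(npred, 1), 0.0)
            f1 = np.zeros(len(thresholds))
            for fold in folds:
                fs = np.sort(s[fold])
                tp = len(fs) - np.searchsorted(fs, thresholds, side="left")
                rec = tp / len(fold)
                denom = prec + rec
                f1 += np.where(denom > 0, 2 * prec * rec / np.maximum(denom, 1e-300), 0.0)
            f1 /= len(folds)
            i = int(np.flatnonzero(f1 >= f1.max() - 1e-12)[-1])  # highest threshold
            cand = (float(f1[i]), float(thresholds[i]))
            if cand[0] > best[0] + 1e-12 or (
                abs(cand[0] - best[0]) <= 1e-12 and cand[1] > best[1] + 1e-12
            ):
                best = (cand[0], cand[1], w)
        assert best[2] is not None
        return best[2], best[1]

    # -- inference --------------------------------------------------------

    def _check_fitted(self) -> None:
        if not hasattr(self, "profile_"):
            raise RuntimeError("model is not fitted")

    def decision_function(
        self, graph: KnowledgeGraph | None = None, genes: Sequence[str] | None = None
    ) -> np.ndarray:
        """Similarity score in [0, 1] for each gene (default: fit universe)."""
        self._check_fitted()
        if graph is None and genes is None and self._frac is not None:
            frac = self._frac
        else:
            graph = graph if graph is not None else self.graph_
            genes = tuple(genes) if genes is not None else tuple(sorted(graph.gene_universe))
            frac = _overlap_fractions(graph, genes, self.profile_, self.active_types_)
        w = np.array([self.type_weights_[t] for t in self.active_types_])
        return frac @ w

    def score_gene(self, gene: str, graph: KnowledgeGraph | None = None) -> float:
        node = gene if gene.startswith("gene:") else gene_node(gene)
        g = graph if graph is not None else self.graph_
        return float(self.decision_function(graph=g, genes=[node])[0])

    def predict(self, graph: KnowledgeGraph | None = None) -> pd.DataFrame:
        """Score every universe gene and flag the predicted candidates.

        ``predicted`` is true iff the score reaches the learned threshold and
        the gene was not an input positive — a model can only *predict* genes
        it was not told about.  Rows are sorted by descending score, ties
        broken lexicographically by gene id.
        """
        self._check_fitted()
        if graph is None:
            genes, scores = self.universe_, self.decision_function()
        else:
            genes = tuple(sorted(graph.gene_universe))
            scores = self.decision_function(graph=graph, genes=genes)
        pos = set(self.positives_used_)
        df = pd.DataFrame({"gene": genes, "score": scores})
        df["predicted"] = (df["score"] >= self.threshold_) & ~df["gene"].isin(pos)
        df = df.sort_values(["score", "gene"], ascending=[False, True], kind="mergesort")
        return df.reset_index(drop=True)

    def predicted_genes(self, graph: KnowledgeGraph | None = None) -> list[str]:
        df = self.predict(graph)
        return df.loc[df["predicted"], "gene"].tolist()

    # -- serialisation ----------------------------------------------------

    def to_json(self) -> str:
        self._check_fitted()
        payload = {
            "schema_version": MODEL_SCHEMA_VERSION,
            "disease": self.disease_,
            "positives_used": list(self.positives_used_),
            "profile": [
                {**asdict(fs), "edge_type": fs.edge_type.value} for fs in self.profile_
            ],
            "type_weights": {t.value: w for t, w in self.type_weights_.items()},
            "threshold": self.threshold_,
            "params": self.get_params(),
        }
        payload["params"]["weight_grid"] = list(payload["params"]["weight_grid"])
        return json.dumps(payload, sort_keys=True, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ProfilePrioritizer":
        payload = json.loads(text)
        if payload.get("schema_version") != MODEL_SCHEMA_VERSION:
            raise ValueError(f"unsupported model schema {payload.get('schema_version')!r}")
        est = cls(**payload["params"])
        est.disease_ = payload["disease"]
        est.positives_used_ = tuple(payload["positives_used"])
        est.profile_ = [
            FeatureStat(
                feature=d["feature"],
                edge_type=EdgeType(d["edge_type"]),
                k=d["k"],
                K=d["K"],
                p_enrich=d["p_enrich"],
            )
            for d in payload["profile"]
        ]
        est.active_types_ = tuple(
            t for t in _TYPE_ORDER if t.value in payload["type_weights"]
        )
        est.type_weights_ = {
            t: payload["type_weights"][t.value] for t in est.active_types_
        }
        est.threshold_ = payload["threshold"]
        est.graph_ = None
        est._frac = None
        est.universe_ = ()
        return est


# -- thin functional wrappers --------------------------------------------


def score_gene(graph: KnowledgeGraph, gene: str, model: ProfilePrioritizer) -> float:
    """Similarity of one gene to the model's profile (convex overlap score)."""
    return model.score_gene(gene, graph=graph)


def learn_weights_and_threshold(
    graph: KnowledgeGraph,
    positives: Iterable[str] | DiseaseDefinition,
    disease: str | None = None,
    **params,
) -> ProfilePrioritizer:
    """Fit a :class:`ProfilePrioritizer` (profile, weights, and threshold)."""
    return ProfilePrioritizer(**params).fit(graph, positives, disease=disease)


def predict(graph: KnowledgeGraph, model: ProfilePrioritizer) -> pd.DataFrame:
    """Score all universe genes with a fitted model; see
    :meth:`ProfilePrioritizer.predict`."""
    return model.predict(graph)
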