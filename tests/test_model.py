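"""Profile selection, gene scoring, weight/threshold learning, prediction."""

import numpy as np
import pytest

from kgprior.graph import EdgeRecord, EdgeType, build_graph
from kgprior.model import (
    ProfilePrioritizer,
    UntrainableModelError,
    candidate_features,
    select_profile,
)
from kgprior.stats import hypergeom_tail
from kgprior.synthetic import SyntheticSpec, generate_kg


class TestCandidateFeatures:
    def test_direct_neighbourhood_with_partner_genes(self, tiny_graph):
        feats = set(candidate_features(tiny_graph, ["A", "B"], disease="disease:D1"))
        assert feats == {
            ("go:GO:1", EdgeType.ANNOTATED_WITH),
            ("gene:A", EdgeType.INTERACTS_WITH),
            ("gene:B", EdgeType.INTERACTS_WITH),
        }

    def test_isolated_positives_have_no_features(self):
        g = build_graph([EdgeRecord("gene:X", "go:GO:9", EdgeType.ANNOTATED_WITH)])
        g.add_node("gene:A")
        g.add_node("gene:B")
        assert candidate_features(g, ["A", "B"]) == []

    def test_target_disease_node_excluded(self, tiny_graph):
        feats = candidate_features(tiny_graph, ["A", "B"], disease="disease:D1")
        assert all(f != "disease:D1" for f, _ in feats)
        # without exclusion it would be a feature
        assert any(
            f == "disease:D1" for f, _ in candidate_features(tiny_graph, ["A", "B"])
        )

    def test_no_usable_positives_raises(self, tiny_graph):
        with pytest.raises(UntrainableModelError, match="no usable positives"):
            candidate_features(tiny_graph, ["ZZZ"])


class TestSelectProfile:
    def test_planted_feature_survives_bonferroni_among_noise(self, planted_graph):
        """Only the feature carried by all positives and nobody else is kept.

        Oracle: recompute each candidate's hypergeometric tail directly and
        apply the alpha/m cut-off independently of the implementation path.
        """
        g, positives, disease = planted_graph
        profile = select_profile(g, positives, alpha=0.05, disease=disease)
        assert [fs.feature for fs in profile] == ["go:GO:PLANTED"]
        fs = profile[0]
        assert (fs.k, fs.K) == (10, 10)
        N = len(g.gene_universe)
        cands = candidate_features(g, positives, disease=disease)
        m = len(cands)
        for feat, t in cands:
            carriers = g.neighbors(feat, t) & g.gene_universe
            p = hypergeom_tail(len(carriers & set(positives)), len(carriers), 10, N)
            assert (p <= 0.05 / m) == (feat == "go:GO:PLANTED")

    def test_universal_feature_is_discarded(self):
        edges = [
            EdgeRecord(f"gene:G{i}", "go:GO:ALL", EdgeType.ANNOTATED_WITH)
            for i in range(20)
        ]
        g = build_graph(edges)
        profile = select_profile(g, ["G0", "G1"], correction="none")
        assert profile == []  # p_enrich = 1 for a feature every gene carries

    def test_fewer_than_two_positives_rejected(self, tiny_graph):
        with pytest.raises(UntrainableModelError):
            select_profile(tiny_graph, ["A"])


class TestScoring:
    @pytest.fixture
    def fitted(self, planted_graph):
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease)
        return g, est

    def test_gene_with_every_profile_feature_scores_one(self, fitted):
        g, est = fitted
        assert est.score_gene("P0") == 1.0

    def test_gene_with_no_profile_feature_scores_zero(self, fitted):
        g, est = fitted
        assert est.score_gene("N00") == 0.0

    def test_two_types_half_weight_half_overlap(self):
        # A carries the annotation feature but interacts with nobody
        est = ProfilePrioritizer.from_json(
            _manual_model_json(
                profile=[
                    ("go:GO:1", "annotated_with"),
                    ("gene:H", "interacts_with"),
                ],
                weights={"annotated_with": 0.5, "interacts_with": 0.5},
            )
        )
        g = build_graph(
            [
                EdgeRecord("gene:A", "go:GO:1", EdgeType.ANNOTATED_WITH),
                EdgeRecord("gene:B", "gene:H", EdgeType.INTERACTS_WITH),
            ]
        )
        assert est.score_gene("A", graph=g) == 0.5

    def test_scores_bounded(self, fitted):
        g, est = fitted
        s = est.decision_function()
        assert np.all(s >= 0) and np.all(s <= 1)

    def test_adding_profile_feature_never_decreases_score(self, fitted):
        g, est = fitted
        before = est.score_gene("N05", graph=g)
        g2 = g.copy()
        g2.add_edge(EdgeRecord("gene:N05", "go:GO:PLANTED", EdgeType.ANNOTATED_WITH))
        assert est.score_gene("N05", graph=g2) >= before


def _manual_model_json(profile, weights, threshold=0.5):
    """Hand-assembled serialised model for forced-formula score checks."""
    import json

    return json.dumps(
        {
            "schema_version": 1,
            "disease": None,
            "positives_used": [],
            "profile": [
                {"feature": f, "edge_type": t, "k": 1, "K": 1, "p_enrich": 0.01}
                for f, t in profile
            ],
            "type_weights": weights,
            "threshold": threshold,
            "params": {},
        }
    )


class TestLearning:
    def test_separable_case_threshold_between_classes(self):
        """Two high-scoring positives, all negatives far below: training F1 = 1."""
        edges = [
            EdgeRecord("gene:A", "go:GO:F", EdgeType.ANNOTATED_WITH),
            EdgeRecord("gene:B", "go:GO:F", EdgeType.ANNOTATED_WITH),
        ]
        edges += [
            EdgeRecord(f"gene:N{i}", "go:GO:OTHER", EdgeType.ANNOTATED_WITH)
            for i in range(20)
        ]
        g = build_graph(edges)
        est = ProfilePrioritizer(random_state=0).fit(g, ["A", "B"])
        s = est.decision_function()
        pos = {"gene:A", "gene:B"}
        pos_scores = [x for gn, x in zip(est.universe_, s) if gn in pos]
        neg_scores = [x for gn, x in zip(est.universe_, s) if gn not in pos]
        assert max(neg_scores) < est.threshold_ <= min(pos_scores)

    def test_single_edge_type_forces_unit_weight(self, planted_graph):
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease)
        assert est.type_weights_ == {EdgeType.ANNOTATED_WITH: 1.0}

    def test_learned_threshold_keeps_most_positives(self):
        g, truth = generate_kg(SyntheticSpec(p_in=0.9, p_out=0.05, seed=7))
        d = truth.visible_definition()
        est = ProfilePrioritizer(random_state=7).fit(g, d)
        s = est.decision_function(genes=[f for f in d.present_in(g)])
        assert np.mean(s >= est.threshold_) >= 0.8

    def test_returned_threshold_maximises_inner_objective(self, planted_graph):
        """Oracle: sweep every observed positive score by hand and verify no
        threshold beats the returned one under the same weights."""
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=3).fit(g, positives, disease=disease)
        s = est.decision_function()
        pos_set = set(est.positives_used_)
        pos_scores = np.array([x for gn, x in zip(est.universe_, s) if gn in pos_set])
        rng = np.random.default_rng(3)
        uidx = {gn: i for i, gn in enumerate(est.universe_)}
        pos_idx = np.array([uidx[p] for p in sorted(pos_set)])
        folds = np.array_split(rng.permutation(pos_idx), 3)

        def mean_f1(theta):
            npred = int(np.sum(s >= theta))
            prec = float(np.sum(pos_scores >= theta)) / npred if npred else 0.0
            f1s = []
            for fold in folds:
                rec = float(np.mean(s[fold] >= theta))
                f1s.append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            return float(np.mean(f1s))

        best = max(mean_f1(t) for t in np.unique(pos_scores))
        assert mean_f1(est.threshold_) == pytest.approx(best, abs=1e-12)

    def test_untrainable_when_no_enriched_features(self):
        edges = [
            EdgeRecord(f"gene:G{i}", "go:GO:ALL", EdgeType.ANNOTATED_WITH)
            for i in range(10)
        ]
        with pytest.raises(UntrainableModelError, match="no enriched"):
            ProfilePrioritizer().fit(build_graph(edges), ["G0", "G1"])

    def test_degenerate_weight_grid_rejected(self, planted_graph):
        g, positives, disease = planted_graph
        with pytest.raises(ValueError, match="weight_grid"):
            ProfilePrioritizer(weight_grid=(0.0,)).fit(g, positives, disease=disease)


class TestPredict:
    def test_positives_never_predicted(self, planted_graph):
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease)
        df = est.predict()
        assert not df.loc[df["gene"].isin(positives), "predicted"].any()

    def test_threshold_above_all_scores_gives_no_predictions(self, planted_graph):
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease)
        est.threshold_ = 1.0 + 1e-9
        assert est.predict()["predicted"].sum() == 0

    def test_hidden_planted_genes_outrank_noise(self):
        g, truth = generate_kg(SyntheticSpec(seed=11))
        est = ProfilePrioritizer(random_state=11).fit(g, truth.visible_definition())
        df = est.predict()
        sc = dict(zip(df["gene"], df["score"]))
        noise = [
            s
            for gn, s in sc.items()
            if gn not in truth.planted and gn not in est.positives_used_
        ]
        assert all(sc[h] > np.median(noise) for h in truth.planted_hidden)

    def test_sorted_by_score_then_gene(self, planted_graph):
        g, positives, disease = planted_graph
        df = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease).predict()
        keys = list(zip(-df["score"], df["gene"]))
        assert keys == sorted(keys)


class TestInvariances:
    def test_gene_relabelling_permutes_scores(self):
        g, truth = generate_kg(SyntheticSpec(n_genes=60, n_planted=10, seed=4))
        d = truth.visible_definition()
        est = ProfilePrioritizer(random_state=4).fit(g, d)
        base = dict(zip(est.universe_, est.decision_function()))

        relabel = {
            n: (f"gene:Z{n[5:]}" if n.startswith("gene:") else n) for n in g.nodes()
        }
        g2 = build_graph(
            [
                EdgeRecord(relabel[e.a], relabel[e.b], e.edge_type, e.provenance)
                for e in g.edges()
            ]
        )
        d2 = type(d)(d.name, d.disease_node, tuple("Z" + x for x in d.genes))
        est2 = ProfilePrioritizer(random_state=4).fit(g2, d2)
        perm = dict(zip(est2.universe_, est2.decision_function()))
        for gn, s in base.items():
            assert perm[relabel[gn]] == pytest.approx(s)

    def test_fit_is_deterministic_given_seed(self):
        g, truth = generate_kg(SyntheticSpec(seed=9))
        d = truth.visible_definition()
        a = ProfilePrioritizer(random_state=9).fit(g, d)
        b = ProfilePrioritizer(random_state=9).fit(g, d)
        assert a.to_json() == b.to_json()
        assert a.predict().equals(b.predict())

    def test_json_round_trip_scores_identically(self, planted_graph):
        g, positives, disease = planted_graph
        est = ProfilePrioritizer(random_state=0).fit(g, positives, disease=disease)
        clone = ProfilePrioritizer.from_json(est.to_json())
        assert clone.predict(g).equals(est.predict())

    def test_sklearn_params_round_trip(self):
        est = ProfilePrioritizer(alpha=0.01, inner_folds=4)
        clone = ProfilePrioritizer(**est.get_params())
        assert clone.get_params() == est.get_params()
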