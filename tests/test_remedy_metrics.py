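import math

import numpy as np
import pytest

from oracles import simrank_double_loop
from tcmnorm.corpus_io import RemedyBag
from tcmnorm.remedy_metrics import (
    BipartiteGraph,
    RemedyContext,
    cosine_similarity,
    fit_tfidf,
    jaccard_similarity,
    remedy_similarity,
    simrank,
)


def bag(owner, counts):
    return RemedyBag(owner=owner, counts=counts)


class TestJaccard:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ({"r1", "r2"}, {"r1", "r2"}, 1.0),
            ({"r1"}, {"r2"}, 0.0),
            ({"r1", "r2", "r3"}, {"r2", "r3", "r4"}, 0.5),
            (set(), set(), 0.0),
            (set(), {"r1"}, 0.0),
        ],
    )
    def test_known_values(self, a, b, expected):
        assert jaccard_similarity(a, b) == expected


class TestTfidf:
    def test_rare_remedy_weight_is_log_n(self):
        bags = {f"s{i}": bag(f"s{i}", {"common": 1}) for i in range(9)}
        bags["s9"] = bag("s9", {"common": 1, "rare": 1})
        model = fit_tfidf(bags)
        j = model.remedy_index["rare"]
        assert model.vector("s9")[j] == pytest.approx(math.log(10))

    def test_ubiquitous_remedy_carries_no_weight(self):
        bags = {f"s{i}": bag(f"s{i}", {"common": 2, f"own{i}": 1}) for i in range(5)}
        model = fit_tfidf(bags)
        j = model.remedy_index["common"]
        assert np.all(model.matrix[:, j] == 0.0)

    def test_absent_remedy_has_zero_weight(self):
        bags = {"a": bag("a", {"r1": 1}), "b": bag("b", {"r2": 1})}
        model = fit_tfidf(bags)
        assert model.vector("a")[model.remedy_index["r2"]] == 0.0

    def test_self_cosine_is_one_with_informative_remedy(self):
        bags = {"a": bag("a", {"r1": 2, "r2": 1}), "b": bag("b", {"r2": 3})}
        model = fit_tfidf(bags)
        assert model.cosine("a", "a") == pytest.approx(1.0)

    def test_remedy_count_idf_base_uses_vocabulary_size(self):
        bags = {"a": bag("a", {"r1": 1, "r2": 1}), "b": bag("b", {"r2": 1})}
        model = fit_tfidf(bags, idf_base="remedy_count")
        # |R| = 2 remedies; df(r1) = 1 -> idf = ln 2; df(r2) = 2 -> idf = 0
        assert model.vector("a")[model.remedy_index["r1"]] == pytest.approx(math.log(2))
        assert model.vector("a")[model.remedy_index["r2"]] == 0.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            fit_tfidf({})


class TestCosine:
    def test_known_values(self):
        assert cosine_similarity([1, 1, 0], [1, 0, 1]) == pytest.approx(0.5)
        assert cosine_similarity([1, 0], [0, 1]) == 0.0
        assert cosine_similarity([0, 0], [1, 1]) == 0.0
        assert cosine_similarity([2, 3], [2, 3]) == pytest.approx(1.0)


class TestSimRank:
    def test_decay_validation(self):
        graph = BipartiteGraph.from_bags({"a": bag("a", {"r": 1})})
        for bad in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                simrank(graph, C=bad)

    def test_diagonal_pinned_every_iteration(self):
        bags = {f"s{i}": bag(f"s{i}", {f"r{i % 2}": 1, "shared": 1}) for i in range(4)}
        graph = BipartiteGraph.from_bags(bags)
        for k in range(5):
            state = simrank(graph, C=0.8, k_max=k)
            assert np.all(np.diag(state.sim_s) == 1.0)
            assert np.all(np.diag(state.sim_r) == 1.0)

    def test_twin_singleton_bags_score_decay_factor(self):
        bags = {"a": bag("a", {"r": 1}), "b": bag("b", {"r": 1})}
        state = simrank(BipartiteGraph.from_bags(bags), C=0.8, k_max=1)
        assert state.symptom_similarity("a", "b") == pytest.approx(0.8)

    def test_disconnected_components_stay_zero(self):
        bags = {"a": bag("a", {"r1": 1}), "b": bag("b", {"r2": 1})}
        for k in range(5):
            state = simrank(BipartiteGraph.from_bags(bags), C=0.8, k_max=k)
            assert state.symptom_similarity("a", "b") == 0.0

    def test_matches_double_loop_transcription_on_random_graphs(self):
        rng = np.random.default_rng(1234)
        for _ in range(25):
            n_s = int(rng.integers(2, 7))
            n_r = int(rng.integers(2, 7))
            neighbors = [
                set(rng.choice(n_r, size=rng.integers(0, n_r + 1), replace=False).tolist())
                for _ in range(n_s)
            ]
            bags = {
                f"s{i}": bag(f"s{i}", {f"r{j}": 1 for j in neighbors[i]})
                for i in range(n_s)
                if neighbors[i]
            }
            if not bags:
                continue
            graph = BipartiteGraph.from_bags(bags)
            state = simrank(graph, C=0.7, k_max=4)
            idx = {r: j for j, r in enumerate(graph.remedies)}
            oracle_neighbors = [
                {idx[r] for r in bags[key].counts} for key in graph.symptoms
            ]
            sim_s, sim_r = simrank_double_loop(oracle_neighbors, len(graph.remedies), 0.7, 4)
            assert np.allclose(state.sim_s, np.array(sim_s), atol=1e-12)
            assert np.allclose(state.sim_r, np.array(sim_r), atol=1e-12)

    def test_offdiagonals_bounded_by_decay_and_monotone_in_k(self, default_bundle):
        from tcmnorm.corpus_io import build_remedy_bags

        bags = build_remedy_bags(default_bundle.corpus)
        graph = BipartiteGraph.from_bags(bags)
        prev = None
        for k in range(1, 5):
            state = simrank(graph, C=0.8, k_max=k)
            off = state.sim_s[~np.eye(len(state.symptoms), dtype=bool)]
            assert off.max() <= 0.8 + 1e-12
            if prev is not None:
                assert np.all(state.sim_s >= prev - 1e-12)
            prev = state.sim_s

    def test_symptom_order_permutation_leaves_scores_unchanged(self):
        rng = np.random.default_rng(5)
        bags = {
            f"s{i}": bag(f"s{i}", {f"r{j}": 1 for j in rng.choice(6, size=3, replace=False)})
            for i in range(5)
        }
        state = simrank(BipartiteGraph.from_bags(bags), C=0.8, k_max=4)
        shuffled = {k: bags[k] for k in reversed(list(bags))}
        state2 = simrank(BipartiteGraph.from_bags(shuffled), C=0.8, k_max=4)
        for a in bags:
            for b in bags:
                assert state.symptom_similarity(a, b) == pytest.approx(
                    state2.symptom_similarity(a, b), abs=1e-12
                )


class TestFacade:
    def setup_method(self):
        self.bags = {
            "a": bag("a", {"r1": 1, "r2": 2}),
            "b": bag("b", {"r1": 1, "r2": 1}),
            "c": bag("c", {"r3": 1}),
        }
        self.ctx = RemedyContext.fit(self.bags)

    def test_dispatch_matches_direct_calls(self):
        assert remedy_similarity("a", "b", "set", self.ctx) == pytest.approx(1.0)
        assert remedy_similarity("a", "c", "vsm_tfidf", self.ctx) == 0.0
        assert remedy_similarity("a", "a", "simrank", self.ctx) == 1.0

    def test_unknown_method_and_unfitted_context_raise(self):
        with pytest.raises(ValueError):
            remedy_similarity("a", "b", "euclid", self.ctx)
        bare = RemedyContext(bags=self.bags)
        with pytest.raises(RuntimeError):
            remedy_similarity("a", "b", "vsm_tfidf", bare)
        with pytest.raises(RuntimeError):
            remedy_similarity("a", "b", "simrank", bare)

    def test_missing_name_scores_zero(self):
        assert remedy_similarity("a", "ghost", "set", self.ctx) == 0.0
        assert remedy_similarity("ghost", "ghost2", "simrank", self.ctx) == 0.0
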