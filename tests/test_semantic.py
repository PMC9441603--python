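"""Semantic similarity: contribution profiles, Wang, IC and Xuan measures."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mirlink import (
    DiseaseDAG,
    combined_semantic_similarity,
    information_content,
    semantic_profile,
    wang_similarity,
    xuan_similarity,
)
from conftest import random_dag

THETA = 0.5

# Exact hand evaluations of the recursive contribution/IC formulas.
WANG_CHAIN = 2.25 / 3.25
XUAN_XZ = 2 * math.log(1.5) / (2 * math.log(1.5) + math.log(3))


def brute_contribution(dag: DiseaseDAG, theta: float, term: str) -> float:
    """Direct recursion on the DAG edges, independent of the module."""
    if term == dag.disease_term:
        return 1.0
    kids = [c for (p, c) in dag.edges if p == term]
    return theta * max(brute_contribution(dag, theta, c) for c in kids)


class TestSemanticProfile:
    @pytest.mark.parametrize(
        "dag, expected, value",
        [
            (
                DiseaseDAG("c", "C", frozenset("ABC"), frozenset({("A", "B"), ("B", "C")})),
                {"C": 1.0, "B": 0.5, "A": 0.25},
                1.75,
            ),
            (
                DiseaseDAG(
                    "dia",
                    "D",
                    frozenset({"R", "P1", "P2", "D"}),
                    frozenset({("R", "P1"), ("R", "P2"), ("P1", "D"), ("P2", "D")}),
                ),
                {"D": 1.0, "P1": 0.5, "P2": 0.5, "R": 0.25},
                2.25,
            ),
            (DiseaseDAG("solo", "D", frozenset({"D"}), frozenset()), {"D": 1.0}, 1.0),
        ],
        ids=["chain", "diamond", "single-node"],
    )
    def test_contributions(self, dag, expected, value):
        profile = semantic_profile(dag, THETA)
        assert profile.contributions == pytest.approx(expected)
        assert profile.semantic_value == pytest.approx(value)

    def test_own_term_contributes_one_and_sum_matches(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            dag = random_dag(rng, int(rng.integers(2, 10)))
            profile = semantic_profile(dag, THETA)
            assert profile.contributions[dag.disease_term] == 1.0
            assert profile.semantic_value == pytest.approx(
                sum(profile.contributions.values())
            )

    def test_contributions_decay_toward_ancestors(self):
        """Each ancestor's contribution is theta times its best child's,
        so it never exceeds any child's by more than the decay allows
        and is strictly below the maximum over its children."""
        rng = np.random.default_rng(5)
        for _ in range(30):
            dag = random_dag(rng, int(rng.integers(2, 10)))
            profile = semantic_profile(dag, THETA)
            children = {}
            for parent, child in dag.edges:
                children.setdefault(parent, []).append(child)
            for term, kids in children.items():
                if term == dag.disease_term:
                    continue
                best = max(profile.contributions[c] for c in kids)
                assert profile.contributions[term] == pytest.approx(THETA * best)
                assert profile.contributions[term] < best
                for c in kids:
                    assert profile.contributions[term] >= THETA * profile.contributions[c]

    @pytest.mark.parametrize("theta", [0.0, 1.0, -0.5, 2.0])
    def test_theta_out_of_range_rejected(self, theta):
        dag = DiseaseDAG("d", "D", frozenset({"D"}), frozenset())
        with pytest.raises(ValueError):
            semantic_profile(dag, theta)

    def test_cyclic_dag_rejected(self):
        with pytest.raises(ValueError, match="cycle"):
            DiseaseDAG("d", "B", frozenset("AB"), frozenset({("A", "B"), ("B", "A")}))

    def test_unreachable_term_rejected(self):
        with pytest.raises(ValueError, match="path"):
            DiseaseDAG("d", "B", frozenset("ABX"), frozenset({("A", "B")}))


class TestWangSimilarity:
    def test_identical_dags_give_one(self, chain_dags):
        d_i, _ = chain_dags
        p = semantic_profile(d_i, THETA)
        assert wang_similarity(p, p) == pytest.approx(1.0)

    def test_disjoint_term_sets_give_zero(self):
        a = semantic_profile(DiseaseDAG("a", "A", frozenset({"A"}), frozenset()), THETA)
        b = semantic_profile(DiseaseDAG("b", "B", frozenset({"B"}), frozenset()), THETA)
        assert wang_similarity(a, b) == 0.0

    def test_chain_pair_matches_hand_evaluation(self, chain_dags):
        d_i, d_j = chain_dags
        sim = wang_similarity(semantic_profile(d_i, THETA), semantic_profile(d_j, THETA))
        assert sim == pytest.approx(WANG_CHAIN, abs=1e-9)

    def test_mismatched_theta_rejected(self, chain_dags):
        d_i, d_j = chain_dags
        with pytest.raises(ValueError):
            wang_similarity(semantic_profile(d_i, 0.5), semantic_profile(d_j, 0.4))


class TestInformationContent:
    def test_tiny_corpus_counts(self, tiny_corpus):
        ic = information_content(tiny_corpus)
        assert ic.values["R"] == pytest.approx(0.0)
        assert ic.values["X"] == pytest.approx(-math.log(2 / 3))
        assert ic.values["Y"] == pytest.approx(math.log(3))
        assert ic.values["Z"] == pytest.approx(math.log(3))

    def test_base_changes_raw_values(self, tiny_corpus):
        nat = information_content(tiny_corpus)
        b10 = information_content(tiny_corpus, log_base=10)
        assert b10.values["Y"] == pytest.approx(nat.values["Y"] / math.log(10))

    def test_empty_corpus_rejected(self):
        with pytest.raises(ValueError):
            information_content([])


class TestXuanSimilarity:
    def test_identical_dags_give_one(self, tiny_corpus):
        ic = information_content(tiny_corpus)
        assert xuan_similarity(tiny_corpus[0], tiny_corpus[0], ic) == pytest.approx(1.0)

    def test_hand_evaluated_pair(self, tiny_corpus):
        ic = information_content(tiny_corpus)
        x, _, z = tiny_corpus
        assert xuan_similarity(x, z, ic) == pytest.approx(XUAN_XZ, abs=1e-9)

    def test_base_invariance(self, tiny_corpus):
        x, _, z = tiny_corpus
        nat = xuan_similarity(x, z, information_content(tiny_corpus))
        b10 = xuan_similarity(x, z, information_content(tiny_corpus, log_base=10))
        assert b10 == pytest.approx(nat, abs=1e-12)

    def test_all_ubiquitous_terms_return_zero_with_warning(self):
        same = [
            DiseaseDAG(f"d{i}", "X", frozenset({"R", "X"}), frozenset({("R", "X")}))
            for i in range(3)
        ]
        ic = information_content(same)
        with pytest.warns(UserWarning, match="ubiquitous"):
            assert xuan_similarity(same[0], same[1], ic) == 0.0

    def test_zero_numerator_positive_denominator(self):
        # Shared terms ubiquitous (IC 0), private terms informative.
        a = DiseaseDAG("a", "A", frozenset({"R", "A"}), frozenset({("R", "A")}))
        b = DiseaseDAG("b", "B", frozenset({"R", "B"}), frozenset({("R", "B")}))
        ic = information_content([a, b])
        assert xuan_similarity(a, b, ic) == 0.0

    def test_missing_term_rejected(self, tiny_corpus):
        ic = information_content(tiny_corpus[:2])
        with pytest.raises(ValueError, match="absent"):
            xuan_similarity(tiny_corpus[0], tiny_corpus[2], ic)


class TestCombinedSimilarity:
    def test_average_of_the_two_measures(self, chain_dags, tiny_corpus):
        # Pair with known SS1 and SS2 values computed from the oracles.
        sim = combined_semantic_similarity(tiny_corpus, THETA)
        ic = information_content(tiny_corpus)
        profiles = {d.disease_id: semantic_profile(d, THETA) for d in tiny_corpus}
        i, j = 0, 2
        expected = (
            wang_similarity(profiles["X"], profiles["Z"])
            + xuan_similarity(tiny_corpus[i], tiny_corpus[j], ic)
        ) / 2.0
        assert sim.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_identical_diseases_on_diagonal(self, tiny_corpus):
        sim = combined_semantic_similarity(tiny_corpus, THETA)
        assert np.allclose(np.diag(sim.values), 1.0)

    def test_symmetric_and_bounded(self, tiny_corpus):
        sim = combined_semantic_similarity(tiny_corpus, THETA)
        assert np.abs(sim.values - sim.values.T).max() <= 1e-12
        assert sim.values.min() >= 0.0 and sim.values.max() <= 1.0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1), n_terms=st.integers(2, 10))
def test_profile_matches_brute_force_recursion(seed, n_terms):
    """Memoized children-first evaluation equals the naive recursion."""
    rng = np.random.default_rng(seed)
    dag = random_dag(rng, n_terms)
    profile = semantic_profile(dag, THETA)
    for term in dag.terms:
        assert profile.contributions[term] == pytest.approx(
            brute_contribution(dag, THETA, term), abs=1e-12
        )


@settings(max_examples=30, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2**31 - 1))
def test_pairwise_similarity_matches_brute_force(seed):
    """Wang/Xuan over a random corpus match set-arithmetic re-evaluation."""
    rng = np.random.default_rng(seed)
    corpus = [random_dag(rng, int(rng.integers(2, 10)), f"d{k}") for k in range(4)]
    ic = information_content(corpus)
    profiles = [semantic_profile(d, THETA) for d in corpus]
    for i in range(4):
        for j in range(4):
            shared = corpus[i].terms & corpus[j].terms
            num = sum(
                brute_contribution(corpus[i], THETA, t)
                + brute_contribution(corpus[j], THETA, t)
                for t in shared
            )
            den = sum(brute_contribution(corpus[i], THETA, t) for t in corpus[i].terms)
            den += sum(brute_contribution(corpus[j], THETA, t) for t in corpus[j].terms)
            assert wang_similarity(profiles[i], profiles[j]) == pytest.approx(
                num / den, abs=1e-12
            )
            denom_ic = sum(ic.values[t] for t in corpus[i].terms) + sum(
                ic.values[t] for t in corpus[j].terms
            )
            if denom_ic > 0:
                expected = 2 * sum(ic.values[t] for t in shared) / denom_ic
                assert xuan_similarity(corpus[i], corpus[j], ic) == pytest.approx(
                    expected, abs=1e-12
                )
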