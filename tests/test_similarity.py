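import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from dmccda import (
    AssociationData,
    DiseaseOntology,
    GipParams,
    SequenceRecord,
    gip_bandwidth,
    gip_similarity_matrix,
    levenshtein_distance,
    semantic_contributions,
    semantic_similarity_matrix,
    sequence_similarity_matrix,
)
from dmccda.similarity import validate_similarity_matrix

from _oracles import dp_levenshtein

dna = st.text(alphabet="ACGT", max_size=6)


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", 0),
            ("AC", "A", 1),
            ("ACGT", "AGCT", 2),  # matches the DP oracle on length-4 strings
            ("", "", 0),
            ("", "ACG", 3),
        ],
    )
    def test_known_distances(self, a, b, expected):
        assert levenshtein_distance(a, b) == expected
        assert dp_levenshtein(a, b) == expected

    @given(dna, dna)
    def test_matches_dp_oracle_and_symmetry(self, a, b):
        d = levenshtein_distance(a, b)
        assert d == dp_levenshtein(a, b)
        assert d == levenshtein_distance(b, a)

    @given(dna, dna, dna)
    def test_triangle_inequality(self, a, b, c):
        assert levenshtein_distance(a, c) <= (
            levenshtein_distance(a, b) + levenshtein_distance(b, c)
        )


class TestSequenceSimilarity:
    def test_identical_sequences_score_one(self):
        recs = [SequenceRecord("c1", "ACGT"), SequenceRecord("c2", "ACGT")]
        CC = sequence_similarity_matrix(recs, ["c1", "c2"])
        np.testing.assert_allclose(CC, 1.0)

    def test_single_deletion(self):
        recs = [SequenceRecord("c1", "AC"), SequenceRecord("c2", "A")]
        CC = sequence_similarity_matrix(recs, ["c1", "c2"])
        np.testing.assert_allclose(CC[0, 1], 1 - 1 / 3)

    def test_disjoint_alphabets_give_half(self):
        # substitution-only edit script: dis = L, so 1 - L/(2L) = 0.5
        recs = [SequenceRecord("c1", "AAAA"), SequenceRecord("c2", "GGGG")]
        CC = sequence_similarity_matrix(recs, ["c1", "c2"])
        np.testing.assert_allclose(CC[0, 1], 0.5)

    def test_missing_sequence_names_the_id(self):
        with pytest.raises(KeyError, match="c2"):
            sequence_similarity_matrix([SequenceRecord("c1", "AC")], ["c1", "c2"])

    def test_is_valid_similarity_matrix(self, rng):
        recs = [
            SequenceRecord(f"c{i}", "".join(rng.choice(list("ACGT"), size=30)))
            for i in range(8)
        ]
        CC = sequence_similarity_matrix(recs, [f"c{i}" for i in range(8)])
        validate_similarity_matrix(CC, "CC")


class TestSemanticContributions:
    def test_self_contribution_is_one(self, sibling_dag):
        assert semantic_contributions(sibling_dag, "d1")["d1"] == 1.0

    def test_parent_gets_decay(self, sibling_dag):
        assert semantic_contributions(sibling_dag, "d1")["root"] == 0.5

    def test_max_rule_picks_shorter_path(self, diamond_dag):
        # g is reachable in 2 hops (via p) and 3 hops (via q, r): max wins
        S = semantic_contributions(diamond_dag, "d")
        assert S["g"] == 0.25
        assert S["r"] == 0.25 and S["q"] == 0.5 and S["p"] == 0.5

    def test_keys_equal_ancestor_closure(self, diamond_dag):
        S = semantic_contributions(diamond_dag, "d")
        assert set(S) == diamond_dag.ancestors("d")

    def test_unknown_term_errors(self, sibling_dag):
        with pytest.raises(KeyError):
            semantic_contributions(sibling_dag, "nope")

    def test_non_increasing_along_edges(self, diamond_dag):
        S = semantic_contributions(diamond_dag, "d")
        for child, parents in diamond_dag.parents.items():
            for p in parents:
                assert S[p] <= S[child]


class TestSemanticSimilarity:
    def test_self_similarity_is_one(self, sibling_dag):
        DD = semantic_similarity_matrix(sibling_dag, ["d1"])
        assert DD[0, 0] == 1.0

    def test_siblings_share_a_third(self, sibling_dag):
        DD = semantic_similarity_matrix(sibling_dag, ["d1", "d2"])
        np.testing.assert_allclose(DD[0, 1], 1 / 3)

    def test_disjoint_closures_score_zero(self):
        ont = DiseaseOntology(
            terms={"r1", "r2", "a", "b"},
            parents={"a": {"r1"}, "b": {"r2"}},
        )
        DD = semantic_similarity_matrix(ont, ["a", "b"])
        assert DD[0, 1] == 0.0

    def test_valid_similarity_matrix(self, diamond_dag):
        DD = semantic_similarity_matrix(diamond_dag, ["d", "p", "q", "g"])
        validate_similarity_matrix(DD, "DD")


class TestGip:
    def test_identity_matrix_bandwidth_is_one(self):
        A = np.eye(2)
        assert gip_bandwidth(A, axis="disease") == 1.0

    def test_bandwidth_scales_inversely_with_profile_mass(self):
        assert gip_bandwidth(np.ones((2, 2)), axis="disease") == 0.5

    def test_default_beta_prime_is_one(self):
        assert GipParams().beta_prime == 1.0

    def test_identity_off_diagonal(self):
        KC = gip_similarity_matrix(np.eye(2), axis="circ")
        np.testing.assert_allclose(KC[0, 1], np.exp(-2.0))
        np.testing.assert_allclose(np.diag(KC), 1.0)

    def test_axis_shapes(self):
        A = np.zeros((4, 3))
        A[0, 0] = A[1, 1] = A[2, 2] = 1
        assert gip_similarity_matrix(A, axis="circ").shape == (4, 4)
        assert gip_similarity_matrix(A, axis="disease").shape == (3, 3)

    def test_empty_profile_conventions(self):
        A = np.array([[1.0, 0.0], [0.0, 0.0], [0.0, 0.0]])
        KC = gip_similarity_matrix(A, axis="circ")
        beta = gip_bandwidth(A, axis="circ")
        assert KC[1, 2] == 1.0  # two empty profiles
        np.testing.assert_allclose(KC[0, 1], np.exp(-beta * 1.0))

    def test_all_zero_matrix_errors(self):
        with pytest.raises(ValueError, match="no known pairs"):
            gip_bandwidth(np.zeros((3, 2)), axis="circ")

    def test_kernel_contract_on_random_matrices(self, rng):
        for _ in range(10):
            A = (rng.uniform(size=(8, 5)) < 0.3).astype(float)
            if A.sum() == 0:
                A[0, 0] = 1
            for axis in ("circ", "disease"):
                K = gip_similarity_matrix(A, axis=axis)
                validate_similarity_matrix(K, f"GIP-{axis}")
                assert K.min() > 0.0
                assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_accepts_association_data(self):
        data = AssociationData(["c1", "c2"], ["d1", "d2"], np.eye(2))
        np.testing.assert_allclose(
            gip_similarity_matrix(data, "circ"), gip_similarity_matrix(np.eye(2), "circ")
        )
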