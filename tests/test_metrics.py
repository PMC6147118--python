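import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from conftest import random_count_matrix
from oracles import (
    cq_oracle,
    d_prime_oracle,
    h2prime_oracle,
    ie_oracle,
    strength_oracle,
    wnodf_oracle,
)
from traitwebs.metrics import (
    d_prime,
    h2prime,
    interaction_evenness,
    metric_report,
    strength,
    weighted_connectance,
    wnodf,
)

matrices = arrays(
    np.int64,
    st.tuples(st.integers(2, 5), st.integers(2, 5)),
    elements=st.integers(0, 9),
).filter(lambda M: (M.sum(axis=1) > 0).all() and (M.sum(axis=0) > 0).all())


class TestWeightedConnectance:
    def test_single_cell(self):
        assert weighted_connectance(np.array([[5]])) == pytest.approx(0.5)

    def test_uniform_2x2(self):
        assert weighted_connectance(np.array([[1, 1], [1, 1]])) == pytest.approx(0.5)

    def test_diagonal_2x2(self):
        assert weighted_connectance(np.array([[2, 0], [0, 2]])) == pytest.approx(0.25)


class TestWnodf:
    def test_fully_nested(self):
        M = np.array([[3, 2, 1], [2, 1, 0], [1, 0, 0]])
        assert wnodf(M) == pytest.approx(100.0)

    def test_equal_margins_score_zero(self):
        assert wnodf(np.array([[1, 0], [0, 1]])) == 0.0

    def test_too_small(self):
        with pytest.raises(ValueError):
            wnodf(np.array([[1, 2]]))


class TestInteractionEvenness:
    def test_uniform(self):
        assert interaction_evenness(np.array([[1, 1], [1, 1]])) == pytest.approx(1.0)

    def test_single_link(self):
        # one nonzero cell: H = 0 regardless of denominator
        assert interaction_evenness(np.array([[4, 0], [0, 0]])) == 0.0

    def test_hand_value(self):
        M = np.array([[2, 1], [1, 0]])
        expected = -(0.5 * np.log(0.5) + 2 * 0.25 * np.log(0.25)) / np.log(4)
        assert interaction_evenness(M) == pytest.approx(expected)
        assert interaction_evenness(M) == pytest.approx(0.75, abs=0.001)

    def test_unknown_denominator(self):
        with pytest.raises(ValueError):
            interaction_evenness(np.array([[1, 1], [1, 1]]), "links")


class TestH2prime:
    def test_diagonal_fully_specialized(self):
        assert h2prime(np.array([[2, 0], [0, 2]])) == pytest.approx(1.0)

    def test_proportional_table_zero(self):
        # outer(margins)/m exactly integer: [[1,2],[2,4]]
        assert h2prime(np.array([[1, 2], [2, 4]])) == pytest.approx(0.0, abs=1e-12)

    def test_single_node_both_sides(self):
        assert h2prime(np.array([[7]])) == 0.0


class TestDPrime:
    def test_proportional_node_zero(self):
        # plant row proportional to column availability
        M = np.array([[2, 4], [1, 2]])
        vals = d_prime(M, "plant")
        assert vals == pytest.approx([0.0, 0.0], abs=1e-12)

    def test_extreme_specialist_one(self):
        # bee 0 puts all visits on the rarest plant, integer-feasible
        M = np.array([[2, 0], [0, 9]])
        vals = d_prime(M, "bee")
        assert vals[0] == pytest.approx(1.0)

    def test_range(self, rng):
        for _ in range(20):
            M = random_count_matrix(rng)
            for side in ("bee", "plant"):
                vals = d_prime(M, side)
                assert np.all(vals >= 0) and np.all(vals <= 1)


class TestStrength:
    def test_sole_partners(self):
        M = np.array([[2, 0], [0, 2]])
        assert strength(M, "bee") == pytest.approx([1.0, 1.0])
        assert strength(M, "plant") == pytest.approx([1.0, 1.0])

    def test_hand_case(self):
        M = np.array([[1, 1], [0, 2]])
        assert strength(M, "bee") == pytest.approx([0.5, 1.5])
        assert strength(M, "plant") == pytest.approx([4 / 3, 2 / 3])

    @given(matrices)
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, M):
        P, A = M.shape
        assert strength(M, "bee").sum() == pytest.approx(P, abs=1e-12)
        assert strength(M, "plant").sum() == pytest.approx(A, abs=1e-12)

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            strength(np.array([[1, 0], [0, 0]]), "bee")


class TestOracleEquivalence:
    def test_all_metrics_random_matrices(self, rng):
        for _ in range(60):
            M = random_count_matrix(rng)
            L = M.tolist()
            assert wnodf(M) == pytest.approx(wnodf_oracle(L))
            assert weighted_connectance(M) == pytest.approx(cq_oracle(L))
            for denom in ("all_cells", "realized_links"):
                assert interaction_evenness(M, denom) == pytest.approx(
                    ie_oracle(L, denom)
                )
            assert h2prime(M) == pytest.approx(h2prime_oracle(L))
            for side in ("bee", "plant"):
                assert strength(M, side) == pytest.approx(strength_oracle(L, side))
                assert d_prime(M, side) == pytest.approx(d_prime_oracle(L, side))


class TestInvariances:
    @given(matrices, st.randoms(use_true_random=False))
    @settings(max_examples=40, deadline=None)
    def test_permutation_invariance(self, M, rnd):
        P, A = M.shape
        rp = list(range(P))
        ca = list(range(A))
        rnd.shuffle(rp)
        rnd.shuffle(ca)
        Mp = M[np.ix_(rp, ca)]
        assert wnodf(Mp) == pytest.approx(wnodf(M))
        assert h2prime(Mp) == pytest.approx(h2prime(M))
        assert interaction_evenness(Mp) == pytest.approx(interaction_evenness(M))
        assert weighted_connectance(Mp) == pytest.approx(weighted_connectance(M))
        assert sorted(d_prime(Mp, "bee")) == pytest.approx(sorted(d_prime(M, "bee")))

    @given(matrices, st.integers(2, 5))
    @settings(max_examples=40, deadline=None)
    def test_integer_scaling_invariance(self, M, c):
        assert wnodf(c * M) == pytest.approx(wnodf(M))
        assert interaction_evenness(c * M) == pytest.approx(interaction_evenness(M))
        assert weighted_connectance(c * M) == pytest.approx(weighted_connectance(M))
        assert strength(c * M, "bee") == pytest.approx(strength(M, "bee"))

    def test_zero_padding_invariance(self):
        M = np.array([[4, 1, 0], [0, 2, 3]])
        padded = np.zeros((3, 4), dtype=int)
        padded[:2, :3] = M
        assert wnodf(padded) == pytest.approx(wnodf(M))
        assert h2prime(padded) == pytest.approx(h2prime(M))
        assert interaction_evenness(padded) == pytest.approx(interaction_evenness(M))
        assert weighted_connectance(padded) == pytest.approx(weighted_connectance(M))


class TestMetricReport:
    def test_summary_keys_and_ranges(self, rng):
        M = random_count_matrix(rng, max_rows=8, max_cols=8)
        rep = metric_report(M)
        s = rep.summary()
        assert 0 < s["Cq"] <= 1
        assert 0 <= s["WNODF"] <= 100
        assert 0 <= s["IE"] <= 1
        assert 0 <= s["H2prime"] <= 1
        assert s["strength_bee_mean"] * M.shape[1] == pytest.approx(M.shape[0])
        assert s["strength_plant_mean"] * M.shape[0] == pytest.approx(M.shape[1])
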