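import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from gapscore import DecisionMatrix, gap_scores, normalize, reference_points
from gapscore.mcdm import DegenerateColumnError

from oracle_topsis import brute_force_topsis


def make_matrix(values, directions=None, weights=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return DecisionMatrix(
        alternatives=[f"a{i}" for i in range(n)],
        criteria=[f"c{j}" for j in range(m)],
        values=values,
        directions=directions or ["gap_increasing"] * m,
        weights=np.asarray(weights if weights is not None else np.ones(m)),
    )


class TestNormalize:
    def test_vector_column(self):
        m = make_matrix([[3.0], [4.0]])
        assert normalize(m, "vector")[:, 0] == pytest.approx([0.6, 0.8])

    def test_minmax_constant_column_maps_to_half(self):
        m = make_matrix([[2.0], [2.0], [2.0]])
        assert normalize(m, "minmax")[:, 0] == pytest.approx([0.5, 0.5, 0.5])

    def test_minmax_spans_unit_interval(self):
        m = make_matrix([[1.0], [3.0], [5.0]])
        assert normalize(m, "minmax")[:, 0] == pytest.approx([0.0, 0.5, 1.0])

    def test_all_zero_column_under_vector_is_degenerate(self):
        m = make_matrix([[0.0], [0.0]])
        with pytest.raises(DegenerateColumnError):
            normalize(m, "vector")


class TestReferencePoints:
    def test_gap_increasing_best_is_minimum(self):
        v = np.array([[0.2], [0.8]])
        best, worst = reference_points(v, ["gap_increasing"])
        assert (best[0], worst[0]) == (0.2, 0.8)

    def test_gap_decreasing_best_is_maximum(self):
        v = np.array([[0.2], [0.8]])
        best, worst = reference_points(v, ["gap_decreasing"])
        assert (best[0], worst[0]) == (0.8, 0.2)

    def test_mixed_directions_combine_componentwise(self):
        v = np.array([[0.2, 0.1], [0.8, 0.9]])
        best, worst = reference_points(v, ["gap_increasing", "gap_decreasing"])
        assert best == pytest.approx([0.2, 0.9])
        assert worst == pytest.approx([0.8, 0.1])


class TestGapScores:
    def test_single_criterion_endpoints(self):
        trace = gap_scores(make_matrix([[0.0], [1.0]]))
        assert trace.gap == pytest.approx([0.0, 1.0])

    def test_arithmetic_progression_midpoint(self):
        # rows (1,2), (3,4), (5,6): first is ideal, last anti-ideal, middle
        # exactly equidistant from both
        trace = gap_scores(make_matrix([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]))
        assert trace.gap == pytest.approx([0.0, 0.5, 1.0], abs=1e-12)

    def test_duplicated_rows_get_identical_scores(self):
        trace = gap_scores(make_matrix([[1.0, 5.0], [2.0, 3.0], [2.0, 3.0]]))
        assert trace.gap[1] == trace.gap[2]

    def test_identical_alternatives_all_half(self):
        trace = gap_scores(make_matrix([[2.0, 3.0], [2.0, 3.0]]))
        assert trace.gap == pytest.approx([0.5, 0.5])

    def test_fewer_than_two_alternatives_rejected(self):
        with pytest.raises(ValueError, match="2 alternatives"):
            make_matrix([[1.0]])

    def test_nonpositive_weights_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            make_matrix([[1.0], [2.0]], weights=[0.0])

    def test_identity_between_gap_and_separations(self):
        trace = gap_scores(make_matrix(np.random.default_rng(0).uniform(1, 9, (5, 3))))
        expected = trace.d_best / (trace.d_best + trace.d_worst)
        assert trace.gap == pytest.approx(expected)
        assert np.all((trace.gap >= 0) & (trace.gap <= 1))


matrix_strategy = st.integers(min_value=0, max_value=10_000)


@settings(derandomize=True, max_examples=300)
@given(seed=matrix_strategy)
def test_matches_bruteforce_oracle(seed):
    """Vectorised TOPSIS equals the naive-loop oracle on random matrices."""
    rng = np.random.default_rng(seed)
    n, m = int(rng.integers(2, 9)), int(rng.integers(1, 7))
    values = rng.uniform(0.01, 100.0, (n, m))
    directions = [
        "gap_increasing" if b else "gap_decreasing" for b in rng.integers(0, 2, m)
    ]
    weights = rng.uniform(0.1, 5.0, m)
    norm = "vector" if seed % 2 == 0 else "minmax"
    trace = gap_scores(make_matrix(values, directions, weights), normalization=norm)
    oracle = brute_force_topsis(values.tolist(), directions, weights.tolist(), norm)
    assert np.max(np.abs(trace.gap - np.array(oracle))) < 1e-12


@settings(derandomize=True, max_examples=100)
@given(seed=matrix_strategy, c=st.floats(min_value=1e-3, max_value=1e3))
def test_weight_rescaling_invariance(seed, c):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 100.0, (5, 3))
    weights = rng.uniform(0.1, 5.0, 3)
    g1 = gap_scores(make_matrix(values, weights=weights)).gap
    g2 = gap_scores(make_matrix(values, weights=weights * c)).gap
    assert g1 == pytest.approx(g2, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(seed=matrix_strategy, c=st.floats(min_value=1e-3, max_value=1e3))
def test_column_unit_invariance_under_vector_norm(seed, c):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 100.0, (5, 3))
    scaled = values.copy()
    scaled[:, 1] *= c
    g1 = gap_scores(make_matrix(values), normalization="vector").gap
    g2 = gap_scores(make_matrix(scaled), normalization="vector").gap
    assert g1 == pytest.approx(g2, abs=1e-10)


@settings(derandomize=True, max_examples=100)
@given(seed=matrix_strategy)
def test_alternative_permutation_equivariance(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 100.0, (6, 3))
    perm = rng.permutation(6)
    g1 = gap_scores(make_matrix(values)).gap
    g2 = gap_scores(make_matrix(values[perm])).gap
    assert g2 == pytest.approx(g1[perm], abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(seed=matrix_strategy)
def test_criteria_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 100.0, (5, 4))
    weights = rng.uniform(0.1, 5.0, 4)
    directions = [
        "gap_increasing" if b else "gap_decreasing" for b in rng.integers(0, 2, 4)
    ]
    perm = rng.permutation(4)
    g1 = gap_scores(make_matrix(values, directions, weights)).gap
    g2 = gap_scores(
        make_matrix(
            values[:, perm], [directions[j] for j in perm], weights[perm]
        )
    ).gap
    assert g1 == pytest.approx(g2, abs=1e-12)


@settings(derandomize=True, max_examples=100)
@given(seed=matrix_strategy)
def test_direction_flip_complements_scores(seed):
    """Flipping every direction swaps ideal and anti-ideal: G -> 1 - G."""
    rng = np.random.default_rng(seed)
    values = rng.uniform(0.01, 100.0, (5, 3))
    directions = ["gap_increasing"] * 3
    flipped = ["gap_decreasing"] * 3
    g1 = gap_scores(make_matrix(values, directions)).gap
    g2 = gap_scores(make_matrix(values, flipped)).gap
    assert g2 == pytest.approx(1.0 - g1, abs=1e-12)
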