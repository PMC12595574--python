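import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from dematelkit import (
    ComputationError,
    FactorCatalog,
    ValidationError,
    analyze,
    classify_group,
    compute_threshold,
    normalize,
    prominence_relation,
    total_relation,
    validate_direct_matrix,
)
from dematelkit.core import NormalizedDirectMatrix, TotalRelationMatrix


def direct(values, ids=None):
    values = np.asarray(values, dtype=float)
    catalog = FactorCatalog.from_ids(ids or [f"F{i+1}" for i in range(values.shape[0])])
    return validate_direct_matrix(values, catalog)


def random_direct(rng, n):
    """Random direct-relation matrix with 0-3 scale entries, zero diagonal."""
    values = rng.uniform(0.0, 3.0, size=(n, n))
    np.fill_diagonal(values, 0.0)
    return direct(values)


class TestNormalize:
    def test_two_factor_example(self):
        X = normalize(direct([[0, 2], [1, 0]]))
        assert X.normalizing_constant == 2
        np.testing.assert_allclose(X.values, [[0, 1], [0.5, 0]])

    def test_constant_is_max_row_sum_of_study_matrix(self, fpt_matrix):
        X = normalize(fpt_matrix)
        row_sums = fpt_matrix.values.sum(axis=1)
        assert X.normalizing_constant == pytest.approx(row_sums.max())
        # the max row sum is attained by F10
        assert fpt_matrix.catalog.ids[int(row_sums.argmax())] == "F10"
        # the maximal row of X sums to 1
        assert X.values.sum(axis=1).max() == pytest.approx(1.0)
        assert X.values.min() >= 0 and X.values.max() <= 1

    def test_single_nonzero_entry_normalizes_to_one(self):
        X = normalize(direct([[0, 0, 0.7], [0, 0, 0], [0, 0, 0]]))
        np.testing.assert_allclose(X.values, [[0, 0, 1], [0, 0, 0], [0, 0, 0]])

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(ComputationError, match="degenerate"):
            normalize(direct(np.zeros((3, 3))))


class TestTotalRelation:
    def test_zero_influence_gives_zero_total(self, catalog2):
        X = NormalizedDirectMatrix(
            catalog=catalog2, values=np.zeros((2, 2)), normalizing_constant=1.0
        )
        assert not total_relation(X).values.any()

    def test_closed_form_2x2(self, catalog2):
        # X = [[0, 1/2], [1/4, 0]] -> T = [[1/7, 4/7], [2/7, 1/7]]
        X = NormalizedDirectMatrix(
            catalog=catalog2,
            values=np.array([[0, 0.5], [0.25, 0]]),
            normalizing_constant=4.0,
        )
        T = total_relation(X)
        np.testing.assert_allclose(T.values, [[1 / 7, 4 / 7], [2 / 7, 1 / 7]], atol=1e-12)
        np.testing.assert_allclose(T.values, X.values + X.values @ T.values, atol=1e-12)

    def test_row_stochastic_normalization_is_non_convergent(self):
        # every row sum equal -> X row-stochastic -> I-X singular
        A = direct([[0, 1, 1], [1, 0, 1], [1, 1, 0]])
        with pytest.raises(ComputationError, match="non-convergent"):
            total_relation(normalize(A))

    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 6))
    @settings(max_examples=40, deadline=None)
    def test_neumann_series_oracle(self, seed, n):
        """T from the linear solve equals the truncated influence series
        X + X^2 + ... on random small systems with spectral radius < 0.9
        (the regime where 200 terms converge well past the tolerance)."""
        rng = np.random.default_rng(seed)
        X = normalize(random_direct(rng, n))
        assume(np.abs(np.linalg.eigvals(X.values)).max() < 0.9)
        T = total_relation(X)
        series = np.zeros((n, n))
        power = np.eye(n)
        for _ in range(200):
            power = power @ X.values
            series += power
        assert np.abs(T.values - series).max() < 1e-8

    @given(seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_fixed_point_identity(self, seed):
        rng = np.random.default_rng(seed)
        X = normalize(random_direct(rng, 5))
        T = total_relation(X)
        assert np.abs(T.values - (X.values + X.values @ T.values)).max() < 1e-9


class TestProfiles:
    def test_hand_summed_2x2(self, catalog2):
        T = TotalRelationMatrix(catalog=catalog2, values=np.array([[0.1, 0.6], [0.2, 0.1]]))
        p, q = prominence_relation(T)
        assert (p.R, p.C, p.relation) == pytest.approx((0.7, 0.3, 0.4))
        assert (q.R, q.C, q.relation) == pytest.approx((0.3, 0.7, -0.4))
        assert p.group == "Cause" and q.group == "Effect"
        assert p.prominence == pytest.approx(1.0)

    def test_symmetric_total_matrix_has_zero_relations(self, catalog4):
        values = np.full((4, 4), 0.3)
        T = TotalRelationMatrix(catalog=catalog4, values=values)
        for p in prominence_relation(T):
            assert p.relation == pytest.approx(0.0, abs=1e-12)
            assert p.group == "Effect"

    @pytest.mark.parametrize(
        "relation,group", [(0.31, "Cause"), (-0.07, "Effect"), (1e-9, "Cause")]
    )
    def test_classification_by_sign(self, relation, group):
        assert classify_group(relation) == group

    def test_zero_relation_ties_to_effect_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="dematelkit.core"):
            assert classify_group(0.0) == "Effect"
        assert any("tie rule" in r.message for r in caplog.records)

    def test_non_finite_relation_rejected(self):
        with pytest.raises(ValidationError):
            classify_group(float("nan"))


class TestThreshold:
    def test_mean_includes_diagonal(self, catalog2):
        T = TotalRelationMatrix(catalog=catalog2, values=np.array([[0.1, 0.6], [0.2, 0.1]]))
        assert compute_threshold(T) == pytest.approx(0.25)

    def test_constant_matrix_threshold_is_the_constant(self, catalog4):
        T = TotalRelationMatrix(catalog=catalog4, values=np.full((4, 4), 0.37))
        assert compute_threshold(T) == pytest.approx(0.37)


class TestAnalyze:
    def test_single_influence_edge_has_sole_cause(self):
        A = direct([[0, 2.0, 0], [0, 0, 0], [0, 0, 0]], ids=["S", "T", "U"])
        result = analyze(A)
        groups = {p.factor_id: p.group for p in result.profiles}
        assert groups["S"] == "Cause"
        assert groups["T"] == "Effect"
        # U neither dispatches nor receives: zero relation, Effect by tie rule
        by_id = {p.factor_id: p for p in result.profiles}
        assert by_id["U"].prominence == pytest.approx(0.0)

    def test_permutation_equivariance(self, rng):
        A = random_direct(rng, 5)
        result = analyze(A)
        perm = rng.permutation(5)
        cat_p = FactorCatalog.from_pairs([A.catalog.factors[i] for i in perm])
        A_p = validate_direct_matrix(A.values[np.ix_(perm, perm)], cat_p)
        result_p = analyze(A_p)
        orig = {p.factor_id: p for p in result.profiles}
        for p in result_p.profiles:
            q = orig[p.factor_id]
            assert p.R == pytest.approx(q.R)
            assert p.relation == pytest.approx(q.relation)
            assert p.group == q.group
        assert result_p.threshold == pytest.approx(result.threshold)

    @given(scale=st.floats(0.1, 50), seed=st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_scale_invariance(self, scale, seed):
        """Multiplying A by a positive constant leaves X, T, profiles and
        threshold unchanged."""
        rng = np.random.default_rng(seed)
        A = random_direct(rng, 4)
        base = analyze(A)
        scaled = analyze(direct(A.values * scale, ids=A.catalog.ids))
        np.testing.assert_allclose(scaled.normalized.values, base.normalized.values)
        np.testing.assert_allclose(scaled.total.values, base.total.values, atol=1e-9)
        assert scaled.threshold == pytest.approx(base.threshold)
        assert [p.group for p in scaled.profiles] == [p.group for p in base.profiles]

    def test_conservation_of_influence(self, fpt_result):
        T = fpt_result.total.values
        R = T.sum(axis=1)
        C = T.sum(axis=0)
        assert R.sum() == pytest.approx(C.sum(), abs=1e-9)
        assert R.sum() == pytest.approx(T.sum(), abs=1e-9)
        assert sum(p.relation for p in fpt_result.profiles) == pytest.approx(0.0, abs=1e-9)

    def test_monotonicity_in_direct_influence(self, rng):
        """Increasing one off-diagonal entry of A (with the normalizing row
        max held fixed) does not decrease the corresponding total influence."""
        A = random_direct(rng, 5)
        values = A.values.copy()
        row_sums = values.sum(axis=1)
        i, j = 1, 3  # ensure row 1 is not the max row even after the bump
        values[i, j] += 0.5 * (row_sums.max() - row_sums[1])
        bumped = direct(values, ids=A.catalog.ids)
        assert np.isclose(
            bumped.values.sum(axis=1).max(), A.values.sum(axis=1).max()
        )
        t_before = analyze(A).total.values[i, j]
        t_after = analyze(bumped).total.values[i, j]
        assert t_after >= t_before

    def test_stage_errors_carry_stage_name(self):
        with pytest.raises(ComputationError, match="normalize:"):
            analyze(direct(np.zeros((3, 3))))
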