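"""Ranking metrics against independent brute-force formula evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from sklearn.metrics import (
    coverage_error,
    label_ranking_average_precision_score,
    label_ranking_loss,
    roc_auc_score,
)

from icam.metrics import (
    average_precision,
    coverage,
    evaluate,
    one_error,
    ranking_loss,
    ranks_from_scores,
    roc_auc,
)

# ---------------------------------------------------------------------------
# brute-force oracles, written directly from the printed metric definitions


def _oracle_ranks(row):
    """rank 1 = highest score, ties to lower class index."""
    order = sorted(range(len(row)), key=lambda l: (-row[l], l))
    ranks = [0] * len(row)
    for pos, l in enumerate(order, start=1):
        ranks[l] = pos
    return ranks


def _oracle_metrics(S, Y):
    cov, rloss, oe, ap = [], [], [], []
    for row, y in zip(S, Y):
        true = [l for l in range(len(y)) if y[l]]
        false = [l for l in range(len(y)) if not y[l]]
        ranks = _oracle_ranks(row)
        cov.append(max(ranks[l] for l in true) - 1)
        if false:
            bad = sum(1 for l1 in true for l2 in false if row[l1] <= row[l2])
            rloss.append(bad / (len(true) * len(false)))
        top = min(range(len(y)), key=lambda l: ranks[l])
        oe.append(0 if y[top] else 1)
        ap.append(
            np.mean(
                [sum(1 for l2 in true if ranks[l2] <= ranks[l]) / ranks[l] for l in true]
            )
        )
    return (
        float(np.mean(cov)),
        float(np.mean(rloss)) if rloss else None,
        float(np.mean(oe)),
        float(np.mean(ap)),
    )


def _exhaustive_cases():
    """All truth patterns x a coarse score grid, single instances, c = 2..4."""
    grid = (0.0, 0.5, 1.0)
    for c in (2, 3, 4):
        for y in itertools.product((0, 1), repeat=c):
            if sum(y) == 0:
                continue
            for s in itertools.product(grid, repeat=c):
                yield np.array([s]), np.array([y])


class TestAgainstBruteForce:
    def test_exhaustive_single_instances(self):
        """Every metric equals direct formula evaluation on all small cases."""
        n = 0
        for S, Y in _exhaustive_cases():
            cov, rloss, oe, ap = _oracle_metrics(S, Y)
            assert coverage(S, Y) == cov
            assert one_error(S, Y) == oe
            assert average_precision(S, Y) == pytest.approx(ap, abs=1e-12)
            if rloss is not None:
                assert ranking_loss(S, Y) == pytest.approx(rloss, abs=1e-12)
            n += 1
        assert n > 500

    @pytest.mark.parametrize("trial", range(20))
    def test_random_small_matrices(self, trial):
        rg = np.random.default_rng(1000 + trial)
        m, c = rg.integers(2, 6), rg.integers(2, 5)
        S = rg.random((m, c)).round(1)  # rounding forces occasional ties
        Y = np.zeros((m, c), dtype=int)
        for i in range(m):
            k = rg.integers(1, c)
            Y[i, rg.choice(c, size=k, replace=False)] = 1
        cov, rloss, oe, ap = _oracle_metrics(S, Y)
        assert coverage(S, Y) == pytest.approx(cov, abs=1e-12)
        assert ranking_loss(S, Y) == pytest.approx(rloss, abs=1e-12)
        assert one_error(S, Y) == pytest.approx(oe, abs=1e-12)
        assert average_precision(S, Y) == pytest.approx(ap, abs=1e-12)


class TestConventions:
    def test_rank_assignment_and_tie_rule(self):
        assert ranks_from_scores(np.array([[0.5, 0.2, 0.3]])).tolist() == [[1, 3, 2]]
        assert ranks_from_scores(np.array([[0.4, 0.4, 0.2]])).tolist() == [[1, 2, 3]]

    def test_ranks_invariant_to_monotone_transform(self, rng):
        S = rng.random((6, 5))
        assert np.array_equal(ranks_from_scores(S), ranks_from_scores(np.exp(3 * S)))

    def test_perfect_and_reversed_rankings(self):
        S = np.array([[0.9, 0.7, 0.1, 0.05]])
        Y = np.array([[1, 1, 0, 0]])
        assert ranking_loss(S, Y) == 0.0
        assert one_error(S, Y) == 0.0
        assert average_precision(S, Y) == 1.0
        assert coverage(S, Y) == 1.0  # both true labels within top 2
        Yrev = np.array([[0, 0, 1, 1]])
        assert ranking_loss(S, Yrev) == 1.0
        assert one_error(S, Yrev) == 1.0

    def test_coverage_worked_example(self):
        # single instance with true labels at ranks 1 and 3 -> coverage 2
        S = np.array([[0.9, 0.5, 0.7]])
        Y = np.array([[1, 1, 0]])
        assert coverage(S, Y) == 2.0

    def test_single_true_label_ranked_second_gives_ap_half(self):
        S = np.array([[0.3, 0.7]])
        Y = np.array([[1, 0]])
        assert average_precision(S, Y) == 0.5

    def test_single_label_one_error_is_classification_error(self, rng):
        m, c = 40, 5
        S = rng.random((m, c))
        true_class = rng.integers(c, size=m)
        Y = np.eye(c, dtype=int)[true_class]
        err = float(np.mean(np.argmax(S, axis=1) != true_class))
        assert one_error(S, Y) == pytest.approx(err)

    def test_ties_count_against_ranking_loss(self):
        S = np.array([[0.5, 0.5]])
        assert ranking_loss(S, np.array([[1, 0]])) == 1.0


class TestAgainstSklearn:
    """Cross-checks on tie-free scores, where conventions coincide."""

    @pytest.mark.parametrize("trial", range(5))
    def test_tie_free_agreement(self, trial):
        rg = np.random.default_rng(50 + trial)
        m, c = 30, 6
        S = rg.random((m, c))  # continuous -> ties have probability zero
        Y = (rg.random((m, c)) < 0.4).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        Y[Y.sum(axis=1) == c, -1] = 0
        assert coverage(S, Y) == pytest.approx(coverage_error(Y, S) - 1.0)
        assert ranking_loss(S, Y) == pytest.approx(label_ranking_loss(Y, S))
        assert average_precision(S, Y) == pytest.approx(
            label_ranking_average_precision_score(Y, S)
        )


class TestRocAuc:
    def test_separated_and_constant_scores(self):
        y = np.array([0, 0, 1, 1])
        assert roc_auc(np.array([0.1, 0.2, 0.8, 0.9]), y) == 1.0
        assert roc_auc(np.full(4, 0.5), y) == 0.5

    @pytest.mark.parametrize("trial", range(10))
    def test_matches_trapezoid_oracle(self, trial):
        rg = np.random.default_rng(200 + trial)
        s = rg.random(20).round(1)  # ties exercised
        y = rg.random(20) < 0.4
        if y.all() or not y.any():
            y[0] = ~y[0]
        assert roc_auc(s, y) == pytest.approx(roc_auc_score(y, s), abs=1e-12)

    def test_rejects_single_class(self):
        with pytest.raises(ValueError):
            roc_auc(np.array([0.1, 0.9]), np.array([1, 1]))


class TestProperties:
    """Invariants over randomly drawn score/truth matrices."""

    score_matrices = arrays(
        float,
        st.tuples(st.integers(2, 6), st.integers(2, 5)),
        elements=st.floats(0, 1, width=32),
    )

    @staticmethod
    def _valid_truth(shape, seed):
        rg = np.random.default_rng(seed)
        Y = (rg.random(shape) < 0.5).astype(int)
        Y[Y.sum(axis=1) == 0, 0] = 1
        Y[Y.sum(axis=1) == shape[1], -1] = 0
        return Y

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(S=score_matrices, seed=st.integers(0, 2**16))
    def test_metrics_invariant_to_monotone_transform(self, S, seed):
        Y = self._valid_truth(S.shape, seed)
        T = np.expm1(2.0 * S)  # strictly increasing
        assert coverage(S, Y) == coverage(T, Y)
        assert one_error(S, Y) == one_error(T, Y)
        assert ranking_loss(S, Y) == pytest.approx(ranking_loss(T, Y))
        assert average_precision(S, Y) == pytest.approx(average_precision(T, Y))

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(seed=st.integers(0, 2**16), m=st.integers(2, 6), c=st.integers(2, 5))
    def test_loss_plus_correct_fraction_is_one_without_ties(self, seed, m, c):
        rg = np.random.default_rng(seed)
        S = rg.random((m, c))  # continuous: ties have measure zero
        Y = self._valid_truth((m, c), seed + 1)
        correct = []
        for i in range(m):
            t, f = S[i, Y[i] == 1], S[i, Y[i] == 0]
            correct.append((t[:, None] > f[None, :]).mean())
        assert ranking_loss(S, Y) + np.mean(correct) == pytest.approx(1.0)


def test_evaluate_excludes_rows_without_true_labels(rng):
    S = rng.random((5, 3))
    Y = np.array([[1, 0, 0], [0, 0, 0], [1, 1, 0], [0, 0, 0], [0, 1, 0]])
    res = evaluate(S, Y)
    assert res.n == 3
    assert res.n_excluded == 2
    assert 0.0 <= res.one_minus_avg_precision <= 1.0


def test_evaluate_per_instance_table(rng):
    S = rng.random((4, 3))
    Y = np.array([[1, 0, 0], [0, 1, 1], [1, 1, 1], [0, 0, 1]])
    res, table = evaluate(S, Y, per_instance=True)
    assert len(table) == 4
    assert np.isnan(table.loc[table.instance == 2, "ranking_loss"]).all()  # all-true row
    assert res.coverage == pytest.approx(table.coverage.mean())
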