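"""Metrics and the Friedman/Nemenyi comparison layer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from tsdax import (
    aggregate_ranks,
    bonferroni_threshold,
    classification_metrics,
    friedman_test,
    nemenyi_posthoc,
    rank_table,
)


def test_perfect_prediction_scores_one_everywhere():
    report = classification_metrics([0, 1, 2, 1], [0, 1, 2, 1], c=3)
    assert report.accuracy == 1.0 and report.af1 == 1.0
    assert np.all(report.f1 == 1.0)


def test_confusion_arithmetic_on_a_known_class():
    # class 0: tp=5, fp=5, fn=0 -> p=0.5, r=1, F1=2/3
    y_true = [0] * 5 + [1] * 5
    y_pred = [0] * 10
    report = classification_metrics(y_true, y_pred, c=2)
    assert report.tp[0] == 5 and report.fp[0] == 5 and report.fn[0] == 0
    assert report.precision[0] == 0.5 and report.recall[0] == 1.0
    assert report.f1[0] == pytest.approx(2 / 3)


def test_all_predicted_one_class_on_balanced_truth():
    report = classification_metrics([0] * 5 + [1] * 5, [0] * 10, c=2)
    assert report.accuracy == 0.5
    assert report.f1[0] == pytest.approx(2 / 3)
    assert report.f1[1] == 0.0
    assert report.af1 == pytest.approx(1 / 3)


def test_metrics_reject_degenerate_inputs():
    with pytest.raises(ValueError):
        classification_metrics([], [], c=2)
    with pytest.raises(ValueError):
        classification_metrics([0, 1], [0], c=2)
    with pytest.raises(ValueError):
        classification_metrics([0, 3], [0, 0], c=2)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(seed=st.integers(0, 2**16), c=st.integers(2, 5), n=st.integers(5, 60))
def test_af1_is_the_unweighted_mean_of_per_class_f1(seed, c, n):
    rng = np.random.default_rng(seed)
    y_true = rng.integers(0, c, size=n)
    y_pred = rng.integers(0, c, size=n)
    report = classification_metrics(y_true, y_pred, c=c)
    assert report.af1 == pytest.approx(report.f1.mean(), abs=1e-12)
    # cross-check against scikit-learn's macro F1
    from sklearn.metrics import f1_score

    assert report.af1 == pytest.approx(
        f1_score(y_true, y_pred, labels=range(c), average="macro", zero_division=0.0),
        abs=1e-12,
    )


def test_friedman_matches_scipy_on_random_matrices():
    rng = np.random.default_rng(1)
    for _ in range(20):
        perf = rng.normal(size=(int(rng.integers(3, 10)), int(rng.integers(3, 8))))
        stat, p = friedman_test(perf)
        ref = sps.friedmanchisquare(*perf.T)
        assert stat == pytest.approx(ref.statistic, abs=1e-8)
        assert p == pytest.approx(ref.pvalue, abs=1e-8)


def test_friedman_identical_columns_yield_zero_statistic():
    perf = np.tile(np.arange(4.0)[:, None], (1, 5))
    stat, p = friedman_test(perf)
    assert stat == 0.0 and p == 1.0


def test_friedman_unanimous_orderings_hit_the_closed_form_maximum():
    """3 methods x 4 runs, all runs agreeing: rank sums 4, 8, 12 give
    chi2 = 12/(4*3*4) * (16 + 64 + 144) - 3*4*4 = 8."""
    perf = np.tile([0.1, 0.2, 0.3], (4, 1))
    stat, _ = friedman_test(perf)
    assert stat == pytest.approx(8.0, abs=1e-12)


def test_friedman_is_invariant_to_monotone_row_transforms():
    rng = np.random.default_rng(2)
    perf = rng.normal(size=(6, 5))
    stat_a, _ = friedman_test(perf)
    stat_b, _ = friedman_test(np.exp(perf) * 3.0 + 1.0)
    assert stat_a == pytest.approx(stat_b, abs=1e-12)


def _reference_nemenyi(perf: np.ndarray) -> np.ndarray:
    """Independent reimplementation: pandas ranking + explicit loops."""
    n, k = perf.shape
    avg = pd.DataFrame(perf).rank(axis=1).mean(axis=0).to_numpy()
    out = np.ones((k, k))
    for i in range(k):
        for j in range(k):
            if i != j:
                q = abs(avg[i] - avg[j]) / np.sqrt(k * (k + 1) / (6.0 * n)) * np.sqrt(2.0)
                out[i, j] = min(1.0, float(sps.studentized_range.sf(q, k, np.inf)))
    return out


def test_nemenyi_matches_the_reference_implementation():
    rng = np.random.default_rng(3)
    for _ in range(20):
        perf = rng.normal(size=(5, 13))
        assert np.allclose(nemenyi_posthoc(perf), _reference_nemenyi(perf), atol=1e-6)


def test_nemenyi_identical_columns_give_all_ones():
    perf = np.tile(np.arange(5.0)[:, None], (1, 4))
    assert np.all(nemenyi_posthoc(perf) == 1.0)


def test_nemenyi_matrix_is_symmetric_with_unit_diagonal():
    perf = np.random.default_rng(4).normal(size=(6, 7))
    p = nemenyi_posthoc(perf)
    assert np.allclose(p, p.T)
    assert np.all(np.diag(p) == 1.0)
    assert np.all((p >= 0) & (p <= 1))


def test_bonferroni_pairwise_comparisons():
    assert bonferroni_threshold(13, 0.05) == (78, pytest.approx(6.41e-4, rel=1e-2))
    assert bonferroni_threshold(2, 0.05) == (1, 0.05)
    assert bonferroni_threshold(4, 0.05)[0] == 6
    with pytest.raises(ValueError):
        bonferroni_threshold(1)


def test_rank_table_ranks_descending_af1_with_tie_averaging():
    scores = pd.DataFrame(
        {"a": [0.9, 0.8], "b": [0.8, 0.8], "c": [0.7, 0.9]},
        index=["d1", "d2"],
    )
    matrix = rank_table(scores)
    assert matrix.ranks.loc["d1"].tolist() == [1.0, 2.0, 3.0]
    assert matrix.ranks.loc["d2"].tolist() == [2.5, 2.5, 1.0]
    # each row's ranks sum to k(k+1)/2
    assert np.allclose(matrix.ranks.sum(axis=1), 6.0)
    assert matrix.average["a"] == pytest.approx(1.75)


def test_single_dataset_average_rank_is_that_rows_rank():
    scores = pd.DataFrame({"a": [0.5], "b": [0.9]}, index=["only"])
    matrix = rank_table(scores)
    assert matrix.average.tolist() == matrix.ranks.loc["only"].tolist()


def test_average_ranks_are_invariant_to_row_order():
    rng = np.random.default_rng(5)
    scores = pd.DataFrame(rng.normal(size=(5, 6)))
    forward = rank_table(scores).average
    shuffled = rank_table(scores.iloc[::-1]).average
    assert np.allclose(forward, shuffled)


def test_aggregate_ranks_averages_prestated_rank_rows():
    ranks = pd.DataFrame({"m1": [1, 2], "m2": [2, 1]})
    assert aggregate_ranks(ranks).tolist() == [1.5, 1.5]
    with pytest.raises(ValueError):
        aggregate_ranks(pd.DataFrame({"m1": [1.0, np.nan]}))
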