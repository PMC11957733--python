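"""Strategy engine: factor arithmetic, class caps, harness bookkeeping."""

import numpy as np
import pytest

from tsdax import (
    PROVENANCE_SYNTHETIC,
    AugmentationPlan,
    FactorGrid,
    FoldScheme,
    LabeledWindowSet,
    NearestCentroidClassifier,
    OneNNDtwClassifier,
    ParameterError,
    SynthSpec,
    augment_balanced,
    augment_imbalanced,
    compute_nmax,
    generate_synthetic,
    round_half_away,
    run_benchmark,
    separable_fixture,
)


def test_plan_validates_method_factor_and_mode():
    with pytest.raises(ParameterError):
        AugmentationPlan(method="no_such_method", factor=1.0)
    with pytest.raises(ParameterError):
        AugmentationPlan(method="jitter", factor=0.0)
    with pytest.raises(ParameterError):
        AugmentationPlan(method="jitter", factor=1.0, mode="sideways")


@pytest.mark.parametrize("factor", [0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0])
def test_balanced_mode_adds_round_n_times_m_windows(fixture_set, factor):
    plan = AugmentationPlan(method="scaling", factor=factor, seed=1)
    augmented = augment_balanced(fixture_set, plan)
    m = fixture_set.n_windows
    assert augmented.n_windows == m + round_half_away(factor * m)
    added = augmented.provenance == PROVENANCE_SYNTHETIC
    assert added.sum() == round_half_away(factor * m)


def test_balanced_factor_one_doubles_the_training_set(fixture_set):
    plan = AugmentationPlan(method="jitter", factor=1.0, seed=2)
    assert augment_balanced(fixture_set, plan).n_windows == 2 * fixture_set.n_windows


def test_synthetic_windows_copy_their_source_labels(fixture_set):
    plan = AugmentationPlan(method="time_warp", factor=0.5, seed=3)
    augmented = augment_balanced(fixture_set, plan)
    synth = augmented.provenance == PROVENANCE_SYNTHETIC
    # labels of synthetic windows are drawn from the existing label set
    assert set(np.unique(augmented.labels[synth])) <= set(np.unique(fixture_set.labels))


def test_augmentation_is_reproducible_per_seed(fixture_set):
    plan = AugmentationPlan(method="magnitude_warp", factor=0.5, seed=7)
    a = augment_balanced(fixture_set, plan)
    b = augment_balanced(fixture_set, plan)
    assert np.array_equal(a.data, b.data)


def test_compute_nmax_is_floor_of_majority_over_minority():
    assert compute_nmax({0: 100, 1: 1000}) == 10
    assert compute_nmax({0: 300, 1: 1000}) == 3
    assert compute_nmax({0: 1000, 1: 1000}) == 1
    with pytest.raises(ParameterError):
        compute_nmax({0: 100})
    with pytest.raises(ParameterError):
        compute_nmax({0: 0, 1: 10})


def test_compute_nmax_matches_floor_arithmetic_on_random_vectors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        counts = rng.integers(1, 2000, size=int(rng.integers(2, 6)))
        assert compute_nmax(list(counts)) == int(max(counts)) // int(min(counts))


def _imbalanced_set(counts=(8, 40), seed=0):
    return generate_synthetic(
        SynthSpec(n_per_class=tuple(counts), n_timesteps=16, n_channels=1,
                  noise_sd=0.05, seed=seed)
    )


def test_imbalanced_mode_grows_minorities_only():
    data = _imbalanced_set((8, 40))
    plan = AugmentationPlan(method="jitter", factor=0.5, mode="imbalanced", seed=4)
    augmented = augment_imbalanced(data, plan)
    counts = augmented.class_counts()
    assert counts[1] == 40  # majority untouched
    assert counts[0] == 8 + round_half_away(0.5 * 8)
    synth = augmented.provenance == PROVENANCE_SYNTHETIC
    assert set(np.unique(augmented.labels[synth])) == {0}


def test_imbalanced_mode_never_exceeds_the_majority_count():
    data = _imbalanced_set((8, 40))
    for factor in (0.2, 1.0, 4.0, 10.0, 25.0):
        plan = AugmentationPlan(method="jitter", factor=factor, mode="imbalanced", seed=5)
        counts = augment_imbalanced(data, plan).class_counts()
        assert counts[0] <= counts[1] == 40


def test_imbalanced_mode_needs_at_least_two_classes():
    single = _imbalanced_set((10,))
    plan = AugmentationPlan(method="jitter", factor=1.0, mode="imbalanced", seed=6)
    with pytest.raises(ParameterError):
        augment_imbalanced(single, plan)


def test_factor_grids_match_the_published_sweeps():
    assert FactorGrid.balanced_default().factors == (0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0)
    grid10 = FactorGrid.imbalanced_default(10)
    assert grid10.factors == (0.2, 0.4, 0.6, 0.8, 1.0) + tuple(float(v) for v in range(2, 11))
    grid4 = FactorGrid.imbalanced_default(4)
    assert grid4.factors == (0.2, 0.4, 0.6, 0.8, 1.0, 2.0, 3.0, 4.0)
    with pytest.raises(ParameterError):
        FactorGrid((0.0, 1.0))


def test_loso_assigns_every_subject_to_exactly_one_test_fold(fixture_set):
    scheme = FoldScheme(kind="loso")
    seen = []
    for train_idx, test_idx in scheme.folds(fixture_set, seed=0):
        subjects = np.unique(fixture_set.groups[test_idx])
        assert len(subjects) == 1
        seen.append(int(subjects[0]))
        assert not set(test_idx) & set(train_idx)
    assert sorted(seen) == sorted(np.unique(fixture_set.groups))


def test_benchmark_bookkeeping_is_complete(fixture_set):
    result = run_benchmark(
        fixture_set,
        methods=("scaling",),
        grid=FactorGrid((1.0,)),
        scheme=FoldScheme(kind="stratified_kfold", k=2),
        repeats=2,
        seed=0,
    )
    table = result.table
    # 2 repeats x 2 folds x (1 baseline + 1 cell)
    assert len(table) == 8
    assert set(table["method"]) == {"baseline", "scaling"}
    assert (table["status"] == "ok").all()
    assert result.mean_af1().loc["scaling", 1.0] >= 0.0


def test_benchmark_rejects_synthetic_windows_in_the_input():
    data = separable_fixture(seed=1)
    data.provenance[:5] = PROVENANCE_SYNTHETIC
    with pytest.raises(AssertionError, match="synthetic test window"):
        run_benchmark(data, methods=("scaling",), grid=FactorGrid((1.0,)),
                      scheme=FoldScheme(kind="stratified_kfold", k=2), repeats=1, seed=0)


def test_failed_cells_are_marked_and_the_sweep_continues(fixture_set):
    # rgw with an impossible parameter -> per-cell failure, run completes
    result = run_benchmark(
        fixture_set,
        methods=("jitter", "slicing"),
        grid=FactorGrid((0.5,)),
        scheme=FoldScheme(kind="stratified_kfold", k=2),
        repeats=1,
        seed=0,
        method_params={"slicing": {"keep_fraction": 2.0}},
    )
    table = result.table
    assert (table.loc[table.method == "slicing", "status"] == "failed").all()
    assert (table.loc[table.method == "jitter", "status"] == "ok").all()


def test_noop_augmentation_matches_the_baseline(fixture_set):
    """sigma-zero jitter only duplicates windows; with a nearest-centroid
    classifier the decision rule barely moves, so AF1 tracks baseline."""
    result = run_benchmark(
        fixture_set,
        methods=("jitter",),
        grid=FactorGrid((1.0,)),
        scheme=FoldScheme(kind="stratified_kfold", k=2),
        repeats=2,
        seed=0,
        method_params={"jitter": {"sigma": 0.0}},
    )
    diff = abs(result.mean_af1().loc["jitter", 1.0] - result.baseline_af1())
    assert diff < 0.05


def test_one_nn_dtw_classifier_separates_the_fixture(fixture_set):
    train = fixture_set.subset(np.arange(0, 60, 2))
    test = fixture_set.subset(np.arange(1, 60, 12))
    clf = OneNNDtwClassifier().fit(train)
    predictions = clf.predict(test.data)
    assert np.mean(predictions == test.labels) >= 0.8


def test_nearest_centroid_predicts_classes_it_saw(fixture_set):
    clf = NearestCentroidClassifier().fit(fixture_set)
    predictions = clf.predict(fixture_set.data)
    assert set(np.unique(predictions)) <= set(np.unique(fixture_set.labels))
    assert np.mean(predictions == fixture_set.labels) > 0.9
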