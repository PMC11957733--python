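"""Pattern mixing: SMOTE interpolation, guided warping, SPAWNER."""

import numpy as np
import pytest

from tsdax import (
    SYMMETRIC,
    GuidedWarpParams,
    LabeledWindowSet,
    ParameterError,
    ShapeDescriptorParams,
    SmoteParams,
    SpawnerParams,
    discriminative_guided_warp,
    random_guided_warp,
    smote,
    spawner,
)
from tsdax.pattern_mixing import _teacher_scores


def _pool(windows, labels=None):
    windows = np.asarray(windows, dtype=float)
    labels = np.zeros(len(windows), dtype=int) if labels is None else np.asarray(labels)
    return LabeledWindowSet(data=windows, labels=labels)


def test_smote_endpoints_and_midpoint(stub_rng_factory):
    x = np.zeros((2, 1))
    pool = _pool([[[2.0], [2.0]]])
    # lambda = 0 -> x; lambda = 1 -> neighbour; lambda = 0.5 -> midpoint
    assert np.array_equal(smote(x, pool, SmoteParams(k_neighbors=1), stub_rng_factory(uniform=0.0, choice=0)), x)
    assert np.allclose(smote(x, pool, SmoteParams(k_neighbors=1), stub_rng_factory(uniform=1.0, choice=0)), 2.0)
    assert np.allclose(smote(x, pool, SmoteParams(k_neighbors=1), stub_rng_factory(uniform=0.5, choice=0)), 1.0)


def test_smote_output_lies_between_input_and_neighbour():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(6, 2))
    pool = _pool(rng.normal(size=(5, 6, 2)))
    for seed in range(20):
        out = smote(x, pool, SmoteParams(k_neighbors=3), np.random.default_rng(seed))
        lo = np.minimum.reduce([x] + list(pool.data))
        hi = np.maximum.reduce([x] + list(pool.data))
        assert np.all(out >= lo - 1e-12) and np.all(out <= hi + 1e-12)


def test_smote_k1_uses_the_single_nearest_neighbour(stub_rng_factory):
    x = np.zeros((2, 1))
    pool = _pool([[[9.0], [9.0]], [[1.0], [1.0]], [[5.0], [5.0]]])
    out = smote(x, pool, SmoteParams(k_neighbors=1), stub_rng_factory(uniform=1.0, choice=1))
    assert np.allclose(out, 1.0)  # lambda=1 lands exactly on the nearest


def test_smote_empty_pool_is_an_error():
    with pytest.raises(ParameterError):
        smote(np.zeros((2, 1)), _pool(np.zeros((0, 2, 1))), SmoteParams(), np.random.default_rng(0))


def test_rgw_with_identical_reference_is_identity():
    x = np.random.default_rng(1).normal(size=(10, 2))
    out = random_guided_warp(x, _pool(x[None]), rng=np.random.default_rng(2))
    assert np.allclose(out, x, atol=1e-12)


def test_rgw_single_reference_pool_is_deterministic():
    rng = np.random.default_rng(3)
    x = rng.normal(size=(12, 1))
    ref = rng.normal(size=(12, 1))
    a = random_guided_warp(x, _pool(ref[None]), rng=np.random.default_rng(0))
    b = random_guided_warp(x, _pool(ref[None]), rng=np.random.default_rng(99))
    assert np.array_equal(a, b)


def test_rgw_moves_a_spike_to_the_reference_location():
    t = np.arange(24.0)
    x = np.exp(-0.5 * ((t - 6.0) / 1.5) ** 2)[:, None]
    ref = np.exp(-0.5 * ((t - 16.0) / 1.5) ** 2)[:, None]
    out = random_guided_warp(x, _pool(ref[None]), rng=np.random.default_rng(0))
    assert abs(int(np.argmax(out[:, 0])) - 16) <= 2
    # output is a resampling of x's values: range bounded by x's range
    assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12


def test_rgw_requires_a_reference():
    with pytest.raises(ParameterError):
        random_guided_warp(np.zeros((4, 1)), _pool(np.zeros((0, 4, 1))),
                           rng=np.random.default_rng(0))


def test_dgw_teacher_scores_match_hand_computation():
    """Constant sequences make every ShapeDTW cost a closed form.

    With unit descriptors, aligning constant sequences a and b of length 4
    costs 4 (a - b)^2.  For positives {5, 1} and negative {0}:
    score(5) = 4*25 - 4*16 = 36, score(1) = 4*1 - 4*16 = -60.
    """
    positives = np.array([[[5.0]] * 4, [[1.0]] * 4])
    negatives = np.array([[[0.0]] * 4])
    scores = _teacher_scores(
        positives, negatives, step=SYMMETRIC, desc=ShapeDescriptorParams(descriptor_len=1)
    )
    assert np.allclose(scores, [36.0, -60.0])


def test_dgw_selects_the_higher_scoring_teacher_and_keeps_the_label():
    rng = np.random.default_rng(4)
    t = np.arange(16.0)
    far_pos = 3.0 + 0.1 * rng.normal(size=(16, 1))          # far from negatives
    near_pos = 0.2 + 0.1 * rng.normal(size=(16, 1))         # close to negatives
    neg = 0.0 + 0.1 * rng.normal(size=(16, 1))
    pool = _pool(np.stack([far_pos, near_pos, neg]), labels=[0, 0, 1])
    x = np.sin(2 * np.pi * t / 16)[:, None]
    params = GuidedWarpParams(variant="dgw", bootstrap_size=3,
                              descriptor=ShapeDescriptorParams(descriptor_len=1))
    out = discriminative_guided_warp(x, 0, pool, params, np.random.default_rng(5))
    assert out.shape == x.shape
    # warped output is a resampling of x's values
    assert out.min() >= x.min() - 1e-9 and out.max() <= x.max() + 1e-9


def test_dgw_teacher_choice_is_invariant_to_subset_order():
    positives = np.array([[[5.0]] * 4, [[1.0]] * 4])
    negatives = np.array([[[0.0]] * 4])
    desc = ShapeDescriptorParams(descriptor_len=1)
    forward = _teacher_scores(positives, negatives, SYMMETRIC, desc)
    backward = _teacher_scores(positives[::-1].copy(), negatives, SYMMETRIC, desc)
    assert int(np.argmax(forward)) == len(forward) - 1 - int(np.argmax(backward))


def test_dgw_falls_back_to_rgw_without_negatives():
    rng = np.random.default_rng(6)
    pool = _pool(rng.normal(size=(3, 8, 1)), labels=[0, 0, 0])
    x = rng.normal(size=(8, 1))
    with pytest.warns(UserWarning, match="falling back"):
        out = discriminative_guided_warp(
            x, 0, pool, GuidedWarpParams(variant="dgw"), np.random.default_rng(7)
        )
    assert out.shape == x.shape


def test_spawner_self_pair_with_zero_noise_is_identity():
    x = np.random.default_rng(8).normal(size=(12, 2))
    out = spawner(x, x, SpawnerParams(mu=0.5, sigma=0.0), np.random.default_rng(9))
    assert np.allclose(out, x, atol=1e-12)


def test_spawner_weight_degeneracy_returns_first_partner_warped():
    """mu = 1 keeps only x1's values (on the joint time base)."""
    rng = np.random.default_rng(10)
    x1 = rng.normal(size=(10, 1))
    x2 = rng.normal(size=(10, 1))
    out = spawner(x1, x2, SpawnerParams(mu=1.0, sigma=0.0), np.random.default_rng(11))
    # all output values lie within x1's per-channel range (resampled x1 values)
    assert out.min() >= x1.min() - 1e-12 and out.max() <= x1.max() + 1e-12


def test_spawner_rejects_mismatched_partners():
    with pytest.raises(ParameterError):
        spawner(np.zeros((8, 1)), np.zeros((9, 1)), SpawnerParams(), np.random.default_rng(0))
    with pytest.raises(ParameterError):
        spawner(np.zeros((8, 1)), np.zeros((8, 1)), SpawnerParams(),
                np.random.default_rng(0), label1=0, label2=1)


def test_spawner_preserves_shape_with_noise():
    x1 = np.random.default_rng(12).normal(size=(20, 3))
    x2 = np.random.default_rng(13).normal(size=(20, 3))
    out = spawner(x1, x2, SpawnerParams(mu=0.5, sigma=0.05), np.random.default_rng(14))
    assert out.shape == (20, 3)
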