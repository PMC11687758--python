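from collections import Counter

import numpy as np
import pytest

from nasalkit.features import FeatureWindow
from nasalkit.model import (
    KernelConfig,
    TrainConfig,
    WindowClassifier,
    assign_folds,
    build_cnn,
    classify_kernel,
    crossvalidate,
    enumerate_kernel_grid,
    plan_grid_runs,
    train_model,
)

SMALL_SHAPE = (2, 8, 10)  # small stacks keep training tests fast


def _toy_windows(n_per_speaker, speakers, nprng, separation=3.0):
    """Linearly separable toy stacks: class means at +/- separation/2."""
    windows = []
    for s_idx, spk in enumerate(speakers):
        for k in range(n_per_speaker):
            label = "nasal" if (k + s_idx) % 2 else "oral"
            mean = separation / 2 if label == "nasal" else -separation / 2
            stack = mean + nprng.standard_normal(SMALL_SHAPE)
            windows.append(FeatureWindow(stack=stack, start_ms=0.0,
                                         speaker_id=spk, label=label))
    return windows


@pytest.fixture()
def nprng():
    return np.random.default_rng(7)


def test_kernel_grid_census():
    grid = enumerate_kernel_grid()
    assert len(grid) == 126
    assert sum(k.pointwise_first for k in grid) == 63
    tally = Counter(k.shape_class for k in grid)
    assert tally == {"spectral": 14, "temporal": 14, "spectral_temporal": 98}


def test_kernel_grid_is_bijective_and_ordered():
    grid = enumerate_kernel_grid()
    keys = [(k.pointwise_first, *k.second_shape) for k in grid]
    assert len(set(keys)) == 126
    assert keys == sorted(keys)  # pointwise flag, then i, then j
    ids = [k.config_id for k in grid]
    assert len(set(ids)) == 126


@pytest.mark.parametrize(
    "shape,expected",
    [((3, 1), "spectral"), ((2, 1), "spectral"), ((1, 4), "temporal"),
     ((1, 2), "temporal"), ((2, 4), "spectral_temporal"), ((8, 8), "spectral_temporal")],
)
def test_classify_kernel(shape, expected):
    assert classify_kernel(shape) == expected


def test_classify_kernel_rejects_pointwise_and_out_of_range():
    with pytest.raises(ValueError):
        classify_kernel((1, 1))
    with pytest.raises(ValueError):
        classify_kernel((9, 2))


def test_grid_times_folds_plans_630_runs():
    plan = plan_grid_runs()
    assert len(plan) == 630
    assert len(set(plan)) == 630


def test_build_cnn_parameter_census():
    # layer-1 conv for a same-kernel 3x3 config: 3*3*2*16 weights + 16 biases
    net = build_cnn(KernelConfig(False, (3, 3)), TrainConfig(seed=0))
    conv1 = net.layers[0]
    assert conv1.w.size == 3 * 3 * 2 * 16 == 288
    assert conv1.b.size == 16
    conv2 = net.layers[4]
    assert conv2.w.shape == (16, 16, 3, 3)


def test_build_cnn_pointwise_first_layer():
    net = build_cnn(KernelConfig(True, (5, 2)), TrainConfig(seed=0))
    assert (net.layers[0].kh, net.layers[0].kw) == (1, 1)
    assert (net.layers[4].kh, net.layers[4].kw) == (5, 2)


def test_build_cnn_seeded_determinism():
    a = build_cnn(KernelConfig(True, (3, 3)), TrainConfig(seed=5))
    b = build_cnn(KernelConfig(True, (3, 3)), TrainConfig(seed=5))
    for pa, pb in zip(a.params, b.params):
        assert np.array_equal(pa, pb)


def test_build_cnn_kernel_exceeding_input_rejected():
    with pytest.raises(ValueError):
        build_cnn(KernelConfig(False, (8, 8)), TrainConfig(), input_shape=(2, 5, 26))


def test_posteriors_sum_to_one(nprng):
    tc = TrainConfig.reduced(seed=1, epochs=1)
    windows = _toy_windows(8, ["a", "b"], nprng)
    from nasalkit.model import windows_to_arrays
    X, y, _ = windows_to_arrays(windows)
    m = train_model(X, y, KernelConfig(True, (2, 2)), tc)
    post = m.predict_posterior(nprng.standard_normal((7, *SMALL_SHAPE)))
    assert post.shape == (7, 2)
    assert np.allclose(post.sum(axis=1), 1.0, atol=1e-6)


def test_training_learns_separable_toy_data(nprng):
    windows = _toy_windows(20, ["a", "b", "c", "d", "e"], nprng)
    tc = TrainConfig(epochs=8, learning_rate=1e-2, batch_size=32, n_folds=5, seed=2)
    res = WindowClassifier(windows, KernelConfig(False, (2, 2)), tc).fit()
    assert res.mean_val_accuracy > 0.9
    assert "mean validation accuracy" in res.summary()


def test_fold_partition_properties(nprng):
    speakers = np.array([f"s{i}" for i in range(10) for _ in range(3)])
    folds = assign_folds(speakers, n_folds=5, seed=0)
    flat = np.concatenate(folds)
    assert len(flat) == 10 and len(set(flat)) == 10  # disjoint cover
    assert all(len(f) == 2 for f in folds)


def test_crossvalidate_is_speaker_disjoint(nprng):
    windows = _toy_windows(6, [f"s{i}" for i in range(5)], nprng)
    tc = TrainConfig.reduced(seed=3, epochs=1)
    models = crossvalidate(windows, KernelConfig(True, (2, 2)), tc)
    assert len(models) == 5
    val_sets = [set(m.metadata["val_speakers"]) for m in models]
    for m in models:
        assert not set(m.metadata["val_speakers"]) & set(m.metadata["train_speakers"])
    assert set().union(*val_sets) == {f"s{i}" for i in range(5)}


def test_crossvalidate_too_few_speakers(nprng):
    windows = _toy_windows(6, ["a", "b", "c"], nprng)
    with pytest.raises(ValueError, match="at least 5 speakers"):
        crossvalidate(windows, KernelConfig(True, (2, 2)), TrainConfig.reduced(seed=0))


def test_crossvalidate_single_class_split_named(nprng):
    # one speaker all-nasal, others all-nasal too except validation fold
    windows = []
    for spk in ["a", "b", "c", "d", "e"]:
        for k in range(4):
            label = "oral" if spk == "a" else "nasal"
            windows.append(FeatureWindow(stack=nprng.standard_normal(SMALL_SHAPE),
                                         start_ms=0.0, speaker_id=spk, label=label))
    with pytest.raises(ValueError, match="fold"):
        crossvalidate(windows, KernelConfig(True, (2, 2)), TrainConfig.reduced(seed=0))


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0)
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
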