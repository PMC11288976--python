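"""Ensemble algebra, losses, weighting, and the training loop."""

import numpy as np
import pytest

from stargardt_oct.ensemble_model import (ComponentUNet, ComponentUNetConfig,
                                          EnsembleConfig, EnsembleNetwork, TrainConfig,
                                          _loss_and_grad, _max_routing,
                                          boundary_weight_map, combine_max, dice_loss,
                                          overall_loss, softmax2, train,
                                          weight_penalty, weighted_logloss)

TINY = ComponentUNetConfig(input_shape=(8, 8), depth=2, widths=(3, 4), kernel_size=3)


@pytest.fixture()
def tiny_net():
    return EnsembleNetwork(EnsembleConfig(("mean", "std"), TINY), seed=1, dtype=np.float64)


def test_component_preserves_spatial_dims_and_outputs_two_channels(rng):
    unet = ComponentUNet(TINY, rng, dtype=np.float64)
    y = unet.forward(rng.random((2, 1, 8, 8)))
    assert y.shape == (2, 2, 8, 8)
    cfg128 = ComponentUNetConfig()  # paper-scale default
    assert cfg128.input_shape == (128, 128) and cfg128.kernel_size == 5


def test_zeroed_head_gives_zero_activations(rng):
    unet = ComponentUNet(TINY, rng, dtype=np.float64)
    unet.head.weight.value[...] = 0.0
    unet.head.bias.value[...] = 0.0
    y = unet.forward(rng.random((1, 1, 8, 8)), train=False)
    assert np.allclose(y, 0.0)


def test_inference_forward_is_deterministic(rng):
    unet = ComponentUNet(TINY, rng, dtype=np.float64)
    x = rng.random((1, 1, 8, 8))
    assert np.array_equal(unet.forward(x, train=False), unet.forward(x, train=False))


def test_indivisible_input_rejected(rng):
    cfg = ComponentUNetConfig(input_shape=(10, 10), depth=2, widths=(2, 2))
    with pytest.raises(ValueError, match="divisible"):
        ComponentUNet(cfg, rng)


def test_combine_max_examples_and_brute_force(rng):
    single = rng.random((1, 2, 4, 4))
    assert np.array_equal(combine_max([single]), single)
    a = np.zeros((1, 2, 1, 1))
    b = np.zeros((1, 2, 1, 1))
    a[0, :, 0, 0] = (1, 3)
    b[0, :, 0, 0] = (2, 0)
    assert combine_max([a, b])[0, :, 0, 0].tolist() == [2, 3]
    grids = [rng.standard_normal((2, 2, 6, 6)) for _ in range(5)]
    combined = combine_max(grids)
    for _ in range(100):
        n, c, i, j = (int(rng.integers(s)) for s in combined.shape)
        assert combined[n, c, i, j] == max(g[n, c, i, j] for g in grids)
    with pytest.raises(ValueError, match="dimensions"):
        combine_max([grids[0], grids[1][:, :, :4]])


def test_combine_max_permutation_invariant_and_idempotent(rng):
    grids = [rng.standard_normal((1, 2, 4, 4)) for _ in range(3)]
    assert np.array_equal(combine_max(grids), combine_max(grids[::-1]))
    assert np.array_equal(combine_max(grids), combine_max(grids + [grids[0]]))


def test_max_routing_zeroes_dominated_components_and_splits_ties(rng):
    a = rng.standard_normal((1, 2, 4, 4))
    b = a - 1.0          # strictly dominated everywhere
    combined = combine_max([a, b])
    ra, rb = _max_routing([a, b], combined)
    assert np.allclose(ra, 1.0) and np.allclose(rb, 0.0)
    rc, rd = _max_routing([a, a.copy()], a)
    assert np.allclose(rc, 0.5) and np.allclose(rd, 0.5)


def test_softmax_normalizes_and_single_component_identity(rng, tiny_net):
    x = rng.random((6, 8, 8)).astype(np.float64)
    net1 = EnsembleNetwork(EnsembleConfig(("mean",), TINY), seed=3, dtype=np.float64)
    res = net1.predict(x[:1])
    assert np.allclose(res.probabilities.sum(axis=0), 1.0, atol=1e-12)
    comp = net1.components[0].forward(x[:1][None, 0:1], train=False)
    assert np.allclose(res.probabilities, softmax2(comp, axis=1)[0], atol=1e-12)
    # equal activations -> p = 0.5 everywhere
    z = np.ones((1, 2, 4, 4))
    assert np.allclose(softmax2(z, axis=1), 0.5)


def test_prediction_result_fields(tiny_net, rng):
    x = rng.random((2, 8, 8)).astype(np.float64)
    res = tiny_net.predict(x)
    assert res.probabilities.shape == (2, 8, 8)
    assert (res.probabilities >= 0).all()
    assert np.allclose(res.probabilities.sum(0), 1.0)
    assert set(np.unique(res.mask)) <= {0, 1}
    assert res.component_activations.shape == (2, 2, 8, 8)
    assert res.component_sigmoids.shape == (2, 8, 8)
    assert ((res.component_sigmoids > 0) & (res.component_sigmoids < 1)).all()
    assert res.features == ("mean", "std")


def test_boundary_weight_map_cases():
    all_bg = np.zeros((5, 5), dtype=np.uint8)
    assert np.allclose(boundary_weight_map(all_bg), 6.0)
    single = np.zeros((5, 5), dtype=np.uint8)
    single[2, 2] = 1
    w = boundary_weight_map(single)
    expect = np.full((5, 5), 6.0)
    expect[1:4, 1:4] = 15.0
    assert np.array_equal(w, expect)
    half = np.zeros((6, 8), dtype=np.uint8)
    half[3:, :] = 1
    w = boundary_weight_map(half)
    expect = np.full((6, 8), 6.0)
    expect[2:4, :] = 15.0
    assert np.array_equal(w, expect)
    with pytest.raises(ValueError, match="binary"):
        boundary_weight_map(np.array([[0, 2]]))


def test_weighted_logloss_closed_forms():
    # perfect one-hot prediction -> 0
    p = np.zeros((2, 2, 2))
    gt = np.array([[0, 1], [1, 0]], dtype=np.uint8)
    p[1] = gt
    p[0] = 1 - gt
    w = np.full((2, 2), 6.0)
    assert weighted_logloss(p, gt, w, reduction="sum") == pytest.approx(0.0, abs=1e-5)
    # single pixel, w = 6, true-class probability 0.5 -> 6 ln 2
    p1 = np.full((2, 1, 1), 0.5)
    g1 = np.ones((1, 1), dtype=np.uint8)
    got = weighted_logloss(p1, g1, np.full((1, 1), 6.0), reduction="sum")
    assert got == pytest.approx(6 * np.log(2), rel=1e-12)
    # linearity in the weights
    half = weighted_logloss(p1, g1, np.full((1, 1), 3.0), reduction="sum")
    assert half == pytest.approx(got / 2)


def test_dice_loss_closed_forms():
    g = np.zeros((4, 4))
    g[:2] = 1.0
    assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-6)
    disjoint = 1.0 - g
    assert dice_loss(disjoint, g) == pytest.approx(1.0, abs=1e-6)
    assert dice_loss(np.full((4, 4), 0.5), g) == pytest.approx(1 / 3, abs=1e-6)
    with pytest.raises(ValueError, match="mismatch"):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_overall_loss_components(tiny_net):
    g = np.zeros((8, 8), dtype=np.uint8)
    g[2:5, 2:5] = 1
    p = np.stack([1.0 - g, g.astype(float)])
    w = boundary_weight_map(g)
    perfect = overall_loss(p, g, w, params=[], weight_decay=0.0)
    assert perfect == pytest.approx(0.0, abs=1e-5)
    lam0 = overall_loss(p, g, w, tiny_net.params(), weight_decay=0.0)
    lam1 = overall_loss(p, g, w, tiny_net.params(), weight_decay=1e-4)
    assert lam1 - lam0 == pytest.approx(1e-4 * weight_penalty(tiny_net.params()), rel=1e-9)


def test_full_loss_gradients_match_central_differences(rng, tiny_net):
    """Analytic gradients of logloss+Dice+decay through the whole ensemble."""
    from conftest import ensemble_grad_rel_error

    x = rng.random((2, 2, 8, 8))
    gt = (rng.random((2, 8, 8)) > 0.6).astype(np.int8)
    w = boundary_weight_map(gt)
    worst, n_checked, n_skipped = ensemble_grad_rel_error(tiny_net, x, gt, w)
    assert worst < 1e-4
    assert n_checked >= 4 * n_skipped  # kink exclusions stay rare


def test_train_config_schedule_and_validation():
    cfg = TrainConfig()
    assert cfg.epochs == 60
    assert cfg.lr_at(0) == cfg.lr_at(39) == 1e-2
    assert cfg.lr_at(40) == cfg.lr_at(59) == 1e-3
    with pytest.raises(ValueError, match="boundary"):
        TrainConfig(region_weight=15, boundary_weight=6).validate()


def _toy_data(rng, n=4):
    stacks, masks = [], []
    for _ in range(n):
        g = np.zeros((8, 8), dtype=np.uint8)
        r0, c0 = rng.integers(0, 4, size=2)
        g[r0:r0 + 4, c0:c0 + 4] = 1
        x = np.stack([g + 0.1 * rng.random((8, 8)),
                      0.5 * g + 0.1 * rng.random((8, 8))]).astype(np.float32)
        stacks.append(x)
        masks.append(g)
    return stacks, masks


def test_zero_learning_rate_leaves_weights_unchanged(rng, tiny_net):
    stacks, masks = _toy_data(rng)
    before = [p.value.copy() for p in tiny_net.params()]
    train(tiny_net, stacks, masks,
          TrainConfig(lr_schedule=((1, 0.0),), batch_size=2, seed=0))
    for b, p in zip(before, tiny_net.params()):
        assert np.array_equal(b, p.value)


def test_training_is_deterministic_and_reduces_loss(rng):
    stacks, masks = _toy_data(rng, n=6)
    cfg = TrainConfig(lr_schedule=((6, 1e-2), (2, 1e-3)), batch_size=2, seed=3)
    h1 = train(EnsembleNetwork(EnsembleConfig(("mean", "std"), TINY), seed=2), stacks, masks, cfg)
    h2 = train(EnsembleNetwork(EnsembleConfig(("mean", "std"), TINY), seed=2), stacks, masks, cfg)
    assert h1[-1]["loss"] == h2[-1]["loss"]
    assert h1[-1]["loss"] < h1[0]["loss"]


def test_training_rejects_nonbinary_masks(tiny_net, rng):
    stacks, masks = _toy_data(rng)
    masks[0] = masks[0] * 3
    with pytest.raises(ValueError, match="binary"):
        train(tiny_net, stacks, masks, TrainConfig(lr_schedule=((1, 1e-2),)))
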