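"""Training: objective arithmetic oracles, lambda degeneracies, the
alternating-update partition contract, warm-up schedule, determinism, and
augmentation geometry."""

import numpy as np
import pytest

from mscfnet.network import (DiscConfig, FiLMConfig, GateConfig, MSCFNet,
                             NetworkConfig, PatchDiscriminator)
from mscfnet.nn import Tensor
from mscfnet.synthetic import SynthParams, generate_dataset
from mscfnet.training import (AugmentSpec, PerceptualEncoder, TrainConfig,
                              Trainer, augment, cross_entropy,
                              generator_objective, segmentation_objective)


def tiny_cfg(**kw):
    base = dict(depth=2, base_width=4,
                discriminator=DiscConfig(n_layers=2, width=8))
    base.update(kw)
    return NetworkConfig(**base)


def tiny_data(n=4, seed=0):
    return generate_dataset(SynthParams(tile_size=32, n_nuclei=4,
                                        radius_range=(3.0, 5.0)), n, seed=seed)


def make_trainer(steps=4, warmup=0.0, seed=0, cfg=None, train_cfg=None):
    cfg = cfg or tiny_cfg()
    model = MSCFNet(cfg, seed=seed + 1)
    disc = PatchDiscriminator(3, 2, cfg.discriminator, seed=seed + 2)
    tc = train_cfg or TrainConfig(steps=steps, warmup_fraction=warmup,
                                  seed=seed, batch_size=2)
    return Trainer(model, disc, tiny_data(seed=seed), tc)


# -- objective oracles --------------------------------------------------------

def test_generator_objective_perfect_reconstruction(rng):
    y = rng.random((1, 2, 8, 8)).astype(np.float32)
    total, f = generator_objective(Tensor(y.copy()), y, None,
                                   TrainConfig(), PerceptualEncoder())
    assert f["l_rec"] == 0.0 and f["l_perc"] == pytest.approx(0.0, abs=1e-10)


def test_generator_objective_weight_degeneracy(rng):
    y = rng.random((1, 2, 8, 8)).astype(np.float32)
    pred = Tensor(rng.random((1, 2, 8, 8)).astype(np.float32))
    scores = Tensor(rng.standard_normal((1, 1, 3, 3)))
    cfg0 = TrainConfig(lambda_rec=0.0, lambda_perc=0.0)
    total, f = generator_objective(pred, y, scores, cfg0, PerceptualEncoder())
    assert float(total.data) == pytest.approx(f["l_adv"], abs=1e-7)


def test_l_rec_elementwise_oracle():
    pred = Tensor(np.array([[[[0.2, 0.8], [0.5, 0.0]]]], np.float32))
    target = np.array([[[[0.0, 1.0], [0.5, 0.5]]]], np.float32)
    _, f = generator_objective(pred, target, None, TrainConfig())
    assert f["l_rec"] == pytest.approx((0.2 + 0.2 + 0.0 + 0.5) / 4, abs=1e-7)


def test_total_gen_affine_in_lambda_rec(rng):
    """total_gen is affine in lambda_rec with slope l_rec."""
    y = rng.random((1, 2, 8, 8)).astype(np.float32)
    pred = Tensor(rng.random((1, 2, 8, 8)).astype(np.float32))
    t1, f1 = generator_objective(pred, y, None, TrainConfig(lambda_rec=10.0))
    t2, f2 = generator_objective(pred, y, None, TrainConfig(lambda_rec=30.0))
    slope = (float(t2.data) - float(t1.data)) / 20.0
    assert slope == pytest.approx(f1["l_rec"], rel=1e-4)


def test_cross_entropy_hand_oracle():
    probs = np.array([[[[0.8, 0.4]], [[0.2, 0.6]]]], np.float32)  # (1,2,1,2)
    logp = Tensor(np.log(probs))
    target = np.array([[[0, 1]]], np.int64)
    expected = -(np.log(0.8) + np.log(0.6)) / 2
    assert float(cross_entropy(logp, target).data) == pytest.approx(expected, abs=1e-6)


def test_segmentation_objective_confident_perfect_prediction(rng):
    """One-hot-correct prediction: Dice term ~0 and cross-entropy ~0."""
    net = MSCFNet(tiny_cfg(tradesgate=GateConfig(epsilon=0.0),
                           atfilm=FiLMConfig(epsilon=0.0)), seed=0)
    x = Tensor(rng.random((1, 3, 16, 16)).astype(np.float32))
    out = net(x, mode="train")
    gt = np.argmax(out.seg_logp.data, axis=1)
    # overwrite prediction with a near-one-hot version of itself
    sharp = np.where(np.eye(2, dtype=np.float32)[gt].transpose(0, 3, 1, 2) > 0,
                     0.0, -30.0)
    out.seg_logp = Tensor(sharp) + out.seg_logp * 0.0
    total, f = segmentation_objective(out, gt, TrainConfig(lambda_cons=0.0,
                                                           lambda_tv=0.0))
    assert f["l_seg"] == pytest.approx(0.0, abs=1e-3)


def test_segmentation_objective_lambda_degeneracy(rng):
    net = MSCFNet(tiny_cfg(), seed=0)
    x = Tensor(rng.random((1, 3, 16, 16)).astype(np.float32))
    out = net(x, mode="train")
    gt = (rng.random((1, 16, 16)) > 0.5).astype(np.int64)
    cfg = TrainConfig(lambda_cons=0.0, lambda_tv=0.5)
    total, f = segmentation_objective(out, gt, cfg)
    assert float(total.data) - 0.5 * f["l_tv"] == pytest.approx(f["l_seg"], rel=1e-5)


def test_consistency_zero_when_epsilons_zero(rng):
    cfg = tiny_cfg(tradesgate=GateConfig(epsilon=0.0),
                   atfilm=FiLMConfig(epsilon=0.0))
    net = MSCFNet(cfg, seed=0)
    out = net(Tensor(rng.random((1, 3, 16, 16)).astype(np.float32)), mode="train")
    gt = np.zeros((1, 16, 16), np.int64)
    _, f = segmentation_objective(out, gt, TrainConfig())
    assert f["l_cons_gate"] == 0.0 and f["l_cons_film"] == 0.0


# -- alternating updates ------------------------------------------------------

def test_partition_contract_phase3_leaves_gen_and_disc_untouched():
    tr = make_trainer(steps=2, warmup=0.0)
    tr.train_step()           # past any warm-up concerns
    gen_before = [p.data.copy() for p in tr.gen_params]
    disc_before = [p.data.copy() for p in tr.disc.parameters()]
    seg_before = [p.data.copy() for p in tr.seg_params]
    # run only phase 3 by replaying a full step and checking relative change:
    # generator/disc change in phases 1-2, so instead freeze a fresh step and
    # verify the seg optimizer's parameter list is disjoint from the others
    gen_ids = {id(p) for p in tr.gen_params}
    seg_ids = {id(p) for p in tr.seg_params}
    disc_ids = {id(p) for p in tr.disc.parameters()}
    assert not (gen_ids & seg_ids) and not (gen_ids & disc_ids) \
        and not (seg_ids & disc_ids)
    # and that a direct seg-objective update does not move gen/disc params
    x, y_aux, y_mask = tr._sample_batch()
    from mscfnet.nn import frozen
    with frozen(tr.gen_params):
        out = tr.model(Tensor(x), mode="train")
    total, _ = segmentation_objective(out, y_mask, tr.cfg)
    tr._zero_all()
    total.backward()
    tr.opt_seg.step()
    for p, before in zip(tr.gen_params, gen_before):
        np.testing.assert_array_equal(p.data, before)
    for p, before in zip(tr.disc.parameters(), disc_before):
        np.testing.assert_array_equal(p.data, before)
    assert any(not np.array_equal(p.data, b)
               for p, b in zip(tr.seg_params, seg_before))


def test_warmup_keeps_segmentation_parameters_fixed():
    tr = make_trainer(steps=10, warmup=0.5)
    assert tr.warmup_steps == 5
    seg_before = [p.data.copy() for p in tr.seg_params]
    for _ in range(tr.warmup_steps):
        b = tr.train_step()
        assert b.total_seg == 0.0
    for p, before in zip(tr.seg_params, seg_before):
        np.testing.assert_array_equal(p.data, before)
    tr.train_step()
    assert any(not np.array_equal(p.data, b)
               for p, b in zip(tr.seg_params, seg_before))


def test_train_step_run_twice_is_deterministic():
    b1 = [b.row() for b in make_trainer(steps=3, seed=5).run()]
    b2 = [b.row() for b in make_trainer(steps=3, seed=5).run()]
    assert b1 == b2


def test_losses_finite_and_signs():
    tr = make_trainer(steps=3)
    for _ in range(3):
        b = tr.train_step()
        row = np.array(b.row())
        assert np.isfinite(row).all()
        assert b.l_rec >= 0 and b.l_tv >= 0
        assert b.l_cons_gate >= -1e-7 and b.l_cons_film >= -1e-7


# -- augmentation -------------------------------------------------------------

def sample_for_aug(seed=0):
    return generate_dataset(SynthParams(tile_size=32, n_nuclei=4,
                                        radius_range=(3.0, 5.0)), 1, seed=seed)[0]


def test_flip_twice_is_identity():
    s = sample_for_aug()
    spec = AugmentSpec(flip_prob=1.0, jitter_strength=0.0, elastic_alpha=0.0, seed=0)
    twice = augment(augment(s, spec), spec)
    np.testing.assert_array_equal(twice.image, s.image)
    np.testing.assert_array_equal(twice.instances, s.instances)
    assert twice.classes == s.classes


def test_zero_magnitudes_are_identity():
    s = sample_for_aug()
    spec = AugmentSpec(flip_prob=0.0, jitter_strength=0.0, elastic_alpha=0.0, seed=0)
    out = augment(s, spec)
    np.testing.assert_array_equal(out.image, s.image)
    np.testing.assert_array_equal(out.aux_pos, s.aux_pos)
    np.testing.assert_array_equal(out.instances, s.instances)


def test_flip_moves_image_and_labels_together():
    """After a flip the aux-channel support equals the transformed foreground
    exactly (Dice 1): mask and image moved together."""
    s = sample_for_aug(seed=3)
    spec = AugmentSpec(flip_prob=1.0, jitter_strength=0.0, elastic_alpha=0.0, seed=9)
    out = augment(s, spec)
    fg = out.instances > 0
    aux_fg = (out.aux_pos > 0) | (out.aux_neg > 0)
    assert 2 * (fg & aux_fg).sum() / (fg.sum() + aux_fg.sum()) == 1.0


def test_elastic_warp_keeps_labels_and_channels_aligned():
    """Under an elastic warp, labels (nearest-neighbor) and aux channels
    (bilinear) may differ on a thin edge band, but every foreground pixel
    must still carry auxiliary signal."""
    s = sample_for_aug(seed=3)
    spec = AugmentSpec(flip_prob=1.0, jitter_strength=0.1, elastic_alpha=6.0,
                       elastic_sigma=3.0, seed=9)
    out = augment(s, spec)
    fg = out.instances > 0
    aux_fg = (out.aux_pos > 0) | (out.aux_neg > 0)
    recall = (fg & aux_fg).sum() / fg.sum()
    assert recall > 0.99
    assert set(out.classes) <= set(s.classes)


def test_jitter_touches_image_only():
    s = sample_for_aug()
    spec = AugmentSpec(flip_prob=0.0, jitter_strength=0.3, elastic_alpha=0.0, seed=2)
    out = augment(s, spec)
    assert not np.array_equal(out.image, s.image)
    np.testing.assert_array_equal(out.instances, s.instances)
    np.testing.assert_array_equal(out.aux_pos, s.aux_pos)
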