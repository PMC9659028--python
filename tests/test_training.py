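"""Schedule logic, augmentation, patch sampling, training, strategies."""

import numpy as np
import pytest

from lymphmet.augment import AugmentParams, augment, augment_random
from lymphmet.network import NetworkConfig, build_network
from lymphmet.synthetic import CODE_HARD_NEGATIVE, CODE_HEALTHY, CODE_TUMOR
from lymphmet.training import (
    PlateauSchedule,
    SlideSource,
    StrategyConfig,
    TrainConfig,
    run_schedule,
    run_strategy,
    sample_epoch,
    train,
)


def tconfig(**kw):
    base = dict(max_epochs=200, lr_patience_epochs=4, early_stop_patience=20)
    base.update(kw)
    return TrainConfig(**base)


class TestPlateauSchedule:
    def test_strict_improvement_runs_to_max_epochs(self):
        cfg = tconfig(max_epochs=30)
        hist = run_schedule([0.5 + 0.01 * e for e in range(30)], cfg)
        assert len(hist) == 30
        assert (hist.lr == cfg.lr_init).all()
        assert hist.stop.iloc[-1]  # max_epochs reached

    def test_constant_sequence_stops_after_patience(self):
        cfg = tconfig()
        hist = run_schedule([0.7] * 100, cfg)
        assert len(hist) == 1 + cfg.early_stop_patience

    def test_lr_drops_after_patience_epochs(self):
        cfg = tconfig()
        hist = run_schedule([0.7] + [0.6] * 10, cfg)
        # epochs 2-5 without improvement -> drop announced at epoch 5
        assert hist.lr.iloc[4] == cfg.lr_init
        assert hist.lr.iloc[5] == pytest.approx(cfg.lr_init / 10)
        # counter resets: second drop 4 epochs later
        assert hist.lr.iloc[9] == pytest.approx(cfg.lr_init / 100)

    def test_equal_value_is_not_improvement(self):
        cfg = tconfig(early_stop_patience=3)
        hist = run_schedule([0.8, 0.8, 0.8, 0.8, 0.9], cfg)
        assert len(hist) == 4  # stopped before the late improvement

    def test_improvement_resets_both_counters(self):
        cfg = tconfig()
        seq = [0.5, 0.4, 0.4, 0.4, 0.6] + [0.5] * 30
        hist = run_schedule(seq, cfg)
        assert hist.lr.iloc[4] == cfg.lr_init  # no drop before improvement
        assert len(hist) == 5 + cfg.early_stop_patience

    def test_pure_function_of_sequence(self):
        cfg = tconfig()
        seq = list(np.random.default_rng(0).uniform(0.4, 0.9, size=40))
        a = run_schedule(seq, cfg)
        b = run_schedule(seq, cfg)
        assert a.equals(b)

    def test_invalid_patience(self):
        with pytest.raises(ValueError, match="patience"):
            TrainConfig(max_epochs=10, early_stop_patience=20)


class TestAugment:
    def test_identity_parameters_identity_output(self):
        patch = np.random.default_rng(0).uniform(size=(21, 21, 3)).astype(np.float32)
        assert np.array_equal(augment(patch, AugmentParams()), patch)

    def test_four_quarter_rotations_identity(self):
        patch = np.random.default_rng(1).uniform(size=(15, 15, 3)).astype(np.float32)
        out = patch
        for _ in range(4):
            out = augment(out, AugmentParams(rot_quarters=1))
        assert np.allclose(out, patch, atol=1e-6)

    def test_double_flip_identity(self):
        patch = np.random.default_rng(2).uniform(size=(9, 9, 3)).astype(np.float32)
        out = augment(augment(patch, AugmentParams(flip=True)),
                      AugmentParams(flip=True))
        assert np.array_equal(out, patch)

    def test_shape_and_range_preserved_under_random_draws(self):
        rng = np.random.default_rng(3)
        patch = rng.uniform(size=(17, 17, 3)).astype(np.float32)
        for _ in range(25):
            out, params = augment_random(patch, rng)
            assert out.shape == patch.shape
            assert out.min() >= 0.0 and out.max() <= 1.0

    def test_deterministic_given_seed(self):
        patch = np.random.default_rng(4).uniform(size=(13, 13, 3)).astype(np.float32)
        a, pa = augment_random(patch, np.random.default_rng(99))
        b, pb = augment_random(patch, np.random.default_rng(99))
        assert pa == pb
        assert np.array_equal(a, b)

    def test_single_channel_patch_supported(self):
        patch = np.random.default_rng(5).uniform(size=(11, 11)).astype(np.float32)
        out, _ = augment_random(patch, np.random.default_rng(0))
        assert out.shape == patch.shape

    def test_parameter_ranges(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = AugmentParams.draw(rng)
            assert p.rot_quarters in (0, 1, 2, 3)
            assert 0.9 <= p.scale <= 1.1
            assert -0.1 <= p.hue <= 0.1
            assert -0.25 <= p.saturation <= 0.25
            assert -0.25 <= p.brightness <= 0.25
            assert -0.25 <= p.contrast <= 0.25
            assert 0.0 <= p.noise_sd <= 0.05
            assert 0.0 <= p.blur_sd <= 1.0


def make_source(slide_id, seed, local=False, n=96, hard_frac=0.0):
    rng = np.random.default_rng(seed)
    tissue = rng.uniform(0.4, 0.9, size=(n, n)).astype(np.float32)
    mask = np.full((n, n), CODE_HEALTHY, dtype=np.uint8)
    mask[: n // 4] = CODE_TUMOR
    if hard_frac > 0:
        k = int(hard_frac * n)
        mask[n - k:, :] = CODE_HARD_NEGATIVE
    return SlideSource(slide_id=slide_id, tissue=tissue, mask=mask, local=local)


class TestSampleEpoch:
    CFG = dict(patch_px=9, augment=False)

    def test_tumor_fraction_binomial(self):
        cfg = tconfig(tumor_fraction=0.2, **self.CFG)
        sources = [make_source("a", 0), make_source("b", 1)]
        n = 5000
        _, labels = sample_epoch(sources, cfg, StrategyConfig(), seed=0,
                                 n_patches=n)
        sd = np.sqrt(n * 0.2 * 0.8)
        assert abs(labels.sum() - n * 0.2) < 3 * sd

    def test_uniform_sources_balanced(self):
        cfg = tconfig(tumor_fraction=0.0, **self.CFG)
        sources = [make_source("a", 0), make_source("b", 1)]
        rng_counts = {"a": 0, "b": 0}
        # track slide of each patch via distinguishable tissue values
        sources[0].tissue[:] = 0.25
        sources[1].tissue[:] = 0.75
        patches, _ = sample_epoch(sources, cfg, StrategyConfig(), seed=1,
                                  n_patches=2000)
        from_a = (patches[:, 0, 0] == 0.25).sum()
        sd = np.sqrt(2000 * 0.25)
        assert abs(from_a - 1000) < 3 * sd

    def test_local_upweight_ratio(self):
        cfg = tconfig(tumor_fraction=0.0, **self.CFG)
        sources = [make_source("local", 0, local=True),
                   make_source("other", 1)]
        sources[0].tissue[:] = 0.25
        sources[1].tissue[:] = 0.75
        strategy = StrategyConfig(sampling_mode="local_upweighted",
                                  local_upweight_factor=4.0)
        n = 4000
        patches, _ = sample_epoch(sources, cfg, strategy, seed=2, n_patches=n)
        from_local = (patches[:, 0, 0] == 0.25).sum()
        expect = n * 4.0 / 5.0
        sd = np.sqrt(n * 0.8 * 0.2)
        assert abs(from_local - expect) < 3 * sd

    def test_hnm_weight_prefers_code3(self):
        """Healthy draws land on code-3 pixels at the weighted rate."""
        cfg = tconfig(tumor_fraction=0.0, **self.CFG)
        src = make_source("a", 0, hard_frac=0.5, n=64)
        # fingerprint the hard-negative band through the tissue values
        src.tissue[:] = 0.3
        src.tissue[src.mask == CODE_HARD_NEGATIVE] = 0.8
        w = 6.0
        strategy = StrategyConfig(hnm_enabled=True, hnm_code_sampling_weight=w)
        n = 4000
        half = cfg.patch_px // 2
        patches, _ = sample_epoch([src], cfg, strategy, seed=3, n_patches=n)
        hit3 = (patches[:, half, half] == np.float32(0.8)).sum()
        interior = np.zeros_like(src.mask, dtype=bool)
        interior[half:-half, half:-half] = True
        i1 = ((src.mask == CODE_HEALTHY) & interior).sum()
        i3 = ((src.mask == CODE_HARD_NEGATIVE) & interior).sum()
        p3 = w * i3 / (i1 + w * i3)
        sd = np.sqrt(n * p3 * (1 - p3))
        assert abs(hit3 - n * p3) < 3 * sd

    def test_hnm_disabled_equals_no_code3_weighting(self):
        cfg = tconfig(tumor_fraction=0.0, **self.CFG)
        src = make_source("a", 0, hard_frac=0.0)
        a, _ = sample_epoch([src], cfg, StrategyConfig(hnm_enabled=True),
                            seed=4, n_patches=50)
        b, _ = sample_epoch([src], cfg, StrategyConfig(hnm_enabled=False),
                            seed=4, n_patches=50)
        assert np.array_equal(a, b)

    def test_seed_reproducible(self):
        cfg = tconfig(**self.CFG)
        src = make_source("a", 0)
        a = sample_epoch([src], cfg, StrategyConfig(), seed=5, n_patches=30)
        b = sample_epoch([src], cfg, StrategyConfig(), seed=5, n_patches=30)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_no_tumor_pixels_error(self):
        cfg = tconfig(tumor_fraction=0.5, **self.CFG)
        src = make_source("a", 0)
        src.mask[src.mask == CODE_TUMOR] = CODE_HEALTHY
        with pytest.raises(ValueError, match="no tumor"):
            sample_epoch([src], cfg, StrategyConfig(), seed=0, n_patches=10)


def separable_patches(fov, n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = rng.integers(0, 2, size=n)
    x = rng.normal(0.35, 0.08, size=(n, fov, fov)).astype(np.float32)
    x += 0.3 * y[:, None, None]
    return np.clip(x, 0, 1), y


class TestTrain:
    def net_and_cfg(self):
        net_cfg = NetworkConfig(n_dense_blocks=1, convs_1x1_per_block=3,
                                convs_3x3_per_block=2, channels_1x1=8,
                                channels_3x3=4, patch_px=9, in_channels=1)
        net = build_network(net_cfg, seed=1)
        return net, net_cfg

    def test_toy_convergence(self):
        net, _ = self.net_and_cfg()
        x, y = separable_patches(net.min_input)
        cfg = tconfig(lr_init=3e-3, max_epochs=60, patches_per_epoch=len(x),
                      patch_px=net.min_input, batch_size=10, augment=False,
                      early_stop_patience=50, lr_patience_epochs=10)
        net, hist = train(net, lambda e: (x, y), lambda e: (x, y), cfg)
        assert hist.train_acc.iloc[-1] >= 0.95
        assert {"epoch", "lr", "train_acc", "val_acc"} <= set(hist.columns)

    def test_empty_stream_rejected(self):
        net, _ = self.net_and_cfg()
        cfg = tconfig(max_epochs=3, patch_px=net.min_input,
                      lr_patience_epochs=1, early_stop_patience=2)
        empty = np.empty((0, net.min_input, net.min_input), dtype=np.float32)
        with pytest.raises(ValueError, match="empty"):
            train(net, lambda e: (empty, np.empty(0, dtype=int)),
                  lambda e: (empty, np.empty(0, dtype=int)), cfg)

    def test_best_checkpoint_returned(self):
        """After training, the kept weights reproduce the best val acc."""
        net, _ = self.net_and_cfg()
        x, y = separable_patches(net.min_input, n=30, seed=3)
        cfg = tconfig(lr_init=3e-3, max_epochs=15, patch_px=net.min_input,
                      batch_size=10, augment=False, early_stop_patience=12,
                      lr_patience_epochs=5)
        net, hist = train(net, lambda e: (x, y), lambda e: (x, y), cfg)
        from lymphmet.network.layers import softmax

        logits = net.forward_logits(x[..., None])
        probs = softmax(logits[:, logits.shape[1] // 2, logits.shape[2] // 2])
        acc = (probs.argmax(-1) == y).mean()
        assert acc == pytest.approx(hist.val_acc.max(), abs=1e-9)


class TestRunStrategy:
    def sources(self):
        return [make_source("local", 0, local=True, n=48),
                make_source("other", 1, n=48)]

    def strategy_cfg(self, **kw):
        return tconfig(max_epochs=2, patches_per_epoch=20, patch_px=9,
                       batch_size=10, augment=False, early_stop_patience=1,
                       lr_patience_epochs=1)

    def net_cfg(self):
        return NetworkConfig(n_dense_blocks=1, convs_1x1_per_block=2,
                             convs_3x3_per_block=1, channels_1x1=4,
                             channels_3x3=2, patch_px=9, in_channels=1)

    def test_finetune_requires_checkpoint(self):
        with pytest.raises(ValueError, match="base checkpoint"):
            run_strategy(None, self.sources(),
                         StrategyConfig(transfer_mode="finetune_local"),
                         self.strategy_cfg(), self.net_cfg())

    def test_finetune_starts_from_base_weights(self):
        base = build_network(self.net_cfg(), seed=77)
        base_state = base.get_state()
        cfg = self.strategy_cfg()
        cfg.max_epochs = 1

        captured = {}
        import lymphmet.training as tr

        orig_train = tr.train

        def spy(network, a, b, c):
            captured["init"] = [v.copy() for v in network.get_state()]
            return orig_train(network, a, b, c)

        tr.train, restore = spy, orig_train
        try:
            run_strategy(base_state, self.sources(),
                         StrategyConfig(transfer_mode="finetune_local"),
                         cfg, self.net_cfg())
        finally:
            tr.train = restore
        n_params = len(build_network(self.net_cfg()).params())
        assert all(np.array_equal(a, b) for a, b in
                   zip(captured["init"][:n_params], base_state[:n_params]))

    def test_scratch_pooled_trains(self):
        net, hist = run_strategy(None, self.sources(), StrategyConfig(),
                                 self.strategy_cfg(), self.net_cfg())
        assert len(hist) >= 1
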