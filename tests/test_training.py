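"""Loss formulas, early stopping, determinism, and weight transfer."""

import numpy as np
import pytest

from qsmseg.network import NetworkConfig, build_network, is_output_param
from qsmseg.nn import Tensor
from qsmseg.preprocess import AugmentRanges, SliceSample
from qsmseg.training import (LossWeights, PreprocessConfig, TrainConfig,
                             combine_branch_losses, cross_entropy_loss,
                             dice_loss, total_loss, train_fold,
                             transfer_weights)


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        g = np.array([1.0, 1.0, 0.0, 0.0])
        assert dice_loss(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_all_zero_prediction_is_one(self):
        g = np.array([1.0, 1.0, 0.0])
        assert dice_loss(np.zeros(3), g) == pytest.approx(1.0, abs=1e-5)

    def test_half_probability_hand_case(self):
        # N=4, g=(1,1,0,0), p=0.5 everywhere -> 1 - 2*1.0/(2+2) = 0.5
        g = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.full(4, 0.5)
        assert dice_loss(p, g) == pytest.approx(0.5, abs=1e-6)

    def test_empty_empty_defined_as_zero(self):
        assert dice_loss(np.zeros(8), np.zeros(8)) == 0.0

    def test_matches_brute_force_formula(self, rng):
        for _ in range(50):
            n = rng.integers(4, 64)
            p = rng.random(n)
            g = (rng.random(n) > 0.5).astype(float)
            num = 2 * sum(pi * gi for pi, gi in zip(p, g))
            den = sum(p) + sum(g)
            expected = 1 - num / den if den else 0.0
            assert dice_loss(p, g) == pytest.approx(expected, abs=1e-5)

    def test_tensor_and_array_paths_agree(self, rng):
        p = rng.random(32).astype(np.float32)
        g = (rng.random(32) > 0.5).astype(np.float32)
        assert dice_loss(Tensor(p), g).item() == pytest.approx(dice_loss(p, g), abs=1e-5)


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        g = np.array([1.0, 0.0, 1.0])
        assert cross_entropy_loss(g, g) == pytest.approx(0.0, abs=1e-5)

    def test_uniform_half_is_ln2(self):
        g = np.array([1.0, 0.0, 1.0, 0.0])
        assert cross_entropy_loss(np.full(4, 0.5), g) == pytest.approx(np.log(2), abs=1e-9)

    def test_wrong_prediction_is_maximal(self):
        g = np.array([1.0, 0.0])
        worst = cross_entropy_loss(1.0 - g, g)
        assert worst == pytest.approx(-np.log(1e-7), rel=1e-3)

    def test_matches_brute_force_formula(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 64))
            p = np.clip(rng.random(n), 1e-6, 1 - 1e-6)
            g = (rng.random(n) > 0.5).astype(float)
            expected = -sum(gi * np.log(pi) + (1 - gi) * np.log(1 - pi)
                            for pi, gi in zip(p, g)) / n
            assert cross_entropy_loss(p, g) == pytest.approx(expected, abs=1e-6)


class TestTotalLoss:
    def test_branch_weighting(self):
        assert combine_branch_losses([1.0, 1.0, 1.0]) == pytest.approx(1.0)
        assert combine_branch_losses([1.0, 0.0, 0.0]) == pytest.approx(0.6)

    def test_single_branch_weight_renormalized(self):
        assert combine_branch_losses([0.7]) == pytest.approx(0.7)

    def test_mismatched_counts_rejected(self):
        with pytest.raises(ValueError):
            combine_branch_losses([1.0, 1.0])

    def test_weights_validated(self):
        with pytest.raises(ValueError):
            LossWeights(-0.1, 0.5, 0.6)
        with pytest.raises(ValueError):
            LossWeights(0.0, 0.0, 0.0)
        assert LossWeights().as_tuple() == (0.6, 0.3, 0.1)

    def test_perfect_branches_give_near_zero_total(self, rng):
        g = (rng.random((2, 8, 8, 3)) > 0.8).astype(np.float32)
        branches = [Tensor(g) for _ in range(3)]
        assert total_loss(branches, g).item() < 1e-3

    def test_linear_in_branch_losses(self, rng):
        g = (rng.random((1, 8, 8, 2)) > 0.7).astype(np.float32)
        p = rng.random((1, 8, 8, 2)).astype(np.float32)
        per_branch = total_loss([Tensor(p)] * 3, g).item()
        single = total_loss([Tensor(p)], g).item()
        assert per_branch == pytest.approx(single * (0.6 + 0.3 + 0.1), rel=1e-5)


# --------------------------------------------------------------- training loop
class _ScriptedModel:
    """Stub with a prescribed per-epoch output probability schedule."""

    def __init__(self, schedule):
        self.schedule = schedule
        self.epoch = -1
        self.config = NetworkConfig(n_classes=1, base_filters=1,
                                    use_deep_supervision=False,
                                    use_multiscale_inputs=False)
        self._state = {"w": np.array([0.0])}

    def parameters(self):
        t = Tensor(np.zeros(1), requires_grad=True)
        return [t]

    def train(self, mode=True):
        if mode:
            self.epoch += 1
        return self

    def eval(self):
        return self

    def forward(self, scales):
        x = scales[0]
        p = self.schedule[min(self.epoch, len(self.schedule) - 1)]
        out = Tensor(np.full(x.shape[:3] + (1,), p, dtype=np.float32),
                     requires_grad=True, parents=())
        out._backward = None
        return [out]

    def state_dict(self):
        return {"w": np.array([float(self.epoch)])}

    def load_state_dict(self, state):
        self._state = state


def _toy_samples(n=4, size=8):
    samples = []
    truth = np.ones((size, size), dtype=np.uint8)
    for i in range(n):
        samples.append(SliceSample(np.zeros((3, size, size), np.float32),
                                   truth, f"s{i}", i))
    return samples


def test_early_stopping_on_plateau_keeps_best_epoch():
    # val loss improves through epoch 3, then plateaus -> with patience 2 the
    # run stops at epoch 5 and the best checkpoint is epoch 3's
    schedule = [0.6, 0.7, 0.8, 0.8, 0.8, 0.8, 0.8, 0.8]
    model = _ScriptedModel(schedule)
    preproc = PreprocessConfig(crop_size=8, class_ids=(1,), normalize_range=None)
    cfg = TrainConfig(batch_size=4, patience=2, max_epochs=20, seed=0)
    tf = train_fold(model, _toy_samples(), _toy_samples(), cfg, preproc)
    assert len(tf.epoch_log) == 5
    assert tf.state["w"][0] == 2.0  # state captured in epoch 3 (0-based 2)
    val = [e["val_loss"] for e in tf.epoch_log]
    assert tf.best_val_loss == pytest.approx(min(val))


def test_default_patience_is_twenty():
    assert TrainConfig().patience == 20
    assert TrainConfig().initial_lr == pytest.approx(1e-4)
    assert TrainConfig().batch_size == 32


def _tiny_real_setup(rng, n_subjects=2):
    cfg = NetworkConfig(n_classes=2, base_filters=4, depth=2,
                        use_multiscale_inputs=False, use_attention=True,
                        use_deep_supervision=False)
    preproc = PreprocessConfig(crop_size=16, class_ids=(1, 2),
                               normalize_range=None,
                               augment=AugmentRanges(shift=2, rotation=5,
                                                     shear=(0.95, 1.05)))
    samples = []
    for i in range(8):
        stack = rng.normal(0, 0.05, size=(3, 16, 16)).astype(np.float32)
        truth = np.zeros((16, 16), dtype=np.uint8)
        truth[4:8, 4:8] = 1
        truth[9:13, 9:13] = 2
        stack[:, truth == 1] += 1.0
        stack[:, truth == 2] += 0.6
        samples.append(SliceSample(stack, truth, f"s{i % n_subjects}", i))
    return cfg, preproc, samples


def test_training_loss_decreases_on_separable_task(rng):
    cfg, preproc, samples = _tiny_real_setup(rng)
    model = build_network(cfg, seed=0)
    tc = TrainConfig(batch_size=4, initial_lr=3e-3, patience=10, max_epochs=5, seed=0)
    tf = train_fold(model, samples, samples[:4], tc, preproc)
    losses = [e["train_loss"] for e in tf.epoch_log]
    assert losses[-1] < losses[0]


def test_training_is_reproducible(rng):
    cfg, preproc, samples = _tiny_real_setup(rng)

    def run():
        model = build_network(cfg, seed=1)
        tc = TrainConfig(batch_size=4, initial_lr=1e-3, patience=10,
                         max_epochs=3, seed=5)
        return train_fold(model, samples, samples[:4], tc, preproc).epoch_log

    log1, log2 = run(), run()
    assert log1 == log2


# ------------------------------------------------------------------- transfer
def test_transfer_copies_all_non_output_tensors_bit_exact():
    src_cfg = NetworkConfig(n_classes=2, base_filters=4)
    tgt_cfg = NetworkConfig(n_classes=3, base_filters=4)
    source = build_network(src_cfg, seed=0)
    state = source.state_dict()
    model = transfer_weights(state, tgt_cfg, seed=99)
    fresh = build_network(tgt_cfg, seed=99)
    for name, p in model.named_parameters():
        if is_output_param(name):
            assert p.data.shape[-1] == 3
            np.testing.assert_array_equal(
                p.data, dict(fresh.named_parameters())[name].data)
        else:
            np.testing.assert_array_equal(p.data, state[name])


def test_transfer_same_class_count_reproduces_forward(rng):
    cfg = NetworkConfig(n_classes=2, base_filters=4)
    source = build_network(cfg, seed=0)
    # make running stats non-trivial before transfer
    from qsmseg.training import multiscale_batch
    x = rng.normal(size=(2, 32, 32, 3)).astype(np.float32)
    source.forward(multiscale_batch(x))
    target = transfer_weights(source.state_dict(), cfg, seed=42)
    source.eval()
    target.eval()
    np.testing.assert_array_equal(source.forward(multiscale_batch(x))[0].data,
                                  target.forward(multiscale_batch(x))[0].data)


def test_transfer_rejects_architecture_mismatch():
    state = build_network(NetworkConfig(n_classes=2, base_filters=4), seed=0).state_dict()
    tampered = dict(state)
    tampered["enc0.conv1.weight"] = state["enc0.conv1.weight"].reshape(3, 3, -1, 2)
    with pytest.raises(ValueError, match="enc0.conv1.weight"):
        transfer_weights(tampered, NetworkConfig(n_classes=3, base_filters=4))
    with pytest.raises(ValueError, match="mismatch"):
        transfer_weights(state, NetworkConfig(n_classes=3, base_filters=8))
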