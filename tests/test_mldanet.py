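"""Group trainer: fusion, pseudo-labels, loss bookkeeping, determinism."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cobci.benchmark import default_train_config
from cobci.exceptions import ConfigurationError, DataError
from cobci.mldanet import (
    LossBundle,
    evaluate_group,
    fuse_and_binarize,
    plateau_epoch,
    predict_group,
    target_class_loss,
    train_group,
)
from cobci.p3_ssda import source_class_loss


class TestFuseAndBinarize:
    @pytest.mark.parametrize(
        "probs,expected_mean,expected_label",
        [((0.9, 0.6, 0.3), 0.6, 1), ((0.4, 0.4, 0.4), 0.4, 0), ((0.5,), 0.5, 1)],
    )
    def test_mean_and_threshold(self, probs, expected_mean, expected_label):
        pl = fuse_and_binarize(np.array(probs)[:, None], (1.0,) * len(probs))
        assert pl.provenance[0] == pytest.approx(expected_mean)
        assert pl.labels[0] == expected_label

    def test_single_network_reduces_to_self_training(self, rng):
        p = rng.uniform(size=20)
        pl = fuse_and_binarize(p[None, :], (1.0,))
        np.testing.assert_array_equal(pl.labels, (p >= 0.5).astype(int))

    def test_degenerate_weights_select_one_network(self, rng):
        probs = rng.uniform(size=(3, 15))
        pl = fuse_and_binarize(probs, (1.0, 0.0, 0.0))
        np.testing.assert_allclose(pl.provenance, probs[0])

    def test_invalid_weights_rejected(self, rng):
        probs = rng.uniform(size=(2, 4))
        with pytest.raises(DataError):
            fuse_and_binarize(probs, (0.0, 0.0))
        with pytest.raises(DataError):
            fuse_and_binarize(probs, (1.0,))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(0, 1), min_size=3, max_size=3),
        st.lists(st.floats(0.01, 5), min_size=3, max_size=3),
    )
    def test_fused_mean_within_member_range(self, probs, weights):
        pl = fuse_and_binarize(np.array(probs)[:, None], tuple(weights))
        assert min(probs) - 1e-12 <= pl.provenance[0] <= max(probs) + 1e-12


class TestTargetClassLoss:
    def test_equals_source_loss_formula_on_shared_labels(self, rng):
        p1 = rng.uniform(0.05, 0.95, size=6)
        probs = np.column_stack([1 - p1, p1])
        labels = rng.integers(0, 2, size=6)
        pl = fuse_and_binarize(labels[None, :].astype(float), (1.0,))
        assert target_class_loss(probs, pl) == source_class_loss(probs, labels)

    def test_closed_form_quarter_probability(self):
        pl = fuse_and_binarize(np.array([[1.0]]), (1.0,))
        loss = target_class_loss(np.array([[0.75, 0.25]]), pl)
        assert loss == pytest.approx(-math.log(0.25), abs=1e-12)


class TestLossBundle:
    def test_total_decomposition_exact(self, rng):
        a, s, t = rng.uniform(size=(3, 3))
        b = LossBundle(tuple(a), tuple(s), tuple(t), alpha=0.4, gamma=0.8, beta=0.2)
        manual = sum(0.4 * ai + 0.8 * si + 0.2 * ti for ai, si, ti in zip(a, s, t))
        assert b.total == pytest.approx(manual, abs=1e-9)


class TestPlateauDetection:
    def test_flat_curve_plateaus_at_first_full_window(self):
        assert plateau_epoch([100.0] * 30, window=10) == 9

    def test_steady_decline_never_plateaus(self):
        losses = list(np.linspace(100, 50, 40))
        assert plateau_epoch(losses, window=10) is None

    def test_transient_crossing_not_mistaken_for_convergence(self):
        rise_fall = list(np.linspace(100, 120, 15)) + list(np.linspace(120, 40, 30))
        flat = [40.0] * 20
        pe = plateau_epoch(rise_fall + flat, window=10)
        assert pe is not None and pe >= len(rise_fall)


@pytest.fixture(scope="module")
def short_cfg():
    return default_train_config(seed=7, epochs=4, warmup_epochs=2)


class TestTrainGroup:
    def test_identical_seeds_give_identical_runs(self, tiny_benchmark, short_cfg):
        nets1, h1 = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        nets2, h2 = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        for n1, n2 in zip(nets1, nets2):
            for k in n1.params:
                np.testing.assert_array_equal(n1.params[k], n2.params[k])
        assert h1["epoch_loss"] == h2["epoch_loss"]

    def test_history_totals_match_components(self, tiny_benchmark, short_cfg):
        _, hist = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        for b in hist["iterations"]:
            manual = sum(
                b.alpha * a + b.gamma * s + b.beta * t
                for a, s, t in zip(b.l_adv, b.l_class_s, b.l_class_t)
            )
            assert b.total == pytest.approx(manual, abs=1e-9)

    def test_selection_shared_across_subjects_in_mutual_mode(
        self, tiny_benchmark, short_cfg
    ):
        _, hist = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        sels = list(hist["selections"].values())
        assert hist["mode"] == "mutual"
        for sel in sels[1:]:
            np.testing.assert_array_equal(sel.trial_index, sels[0].trial_index)

    def test_network_count_mismatch_rejected(self, tiny_benchmark, short_cfg):
        with pytest.raises(ConfigurationError):
            train_group(tiny_benchmark.source, tiny_benchmark.targets[:2], short_cfg)

    def test_beta_zero_equals_independent_unit_training(self, tiny_benchmark):
        """Uncoupled group training is bit-identical to training each unit alone."""
        cfg3 = default_train_config(seed=7, epochs=3, beta=0.0, n_networks=3)
        joint, _ = train_group(tiny_benchmark.source, tiny_benchmark.targets, cfg3)
        for i, tgt in enumerate(tiny_benchmark.targets):
            cfg1 = replace(cfg3, n_networks=1)
            solo, _ = train_group(tiny_benchmark.source, [tgt], cfg1)
            for k in joint[i].params:
                np.testing.assert_array_equal(joint[i].params[k], solo[0].params[k])


class TestPredictGroup:
    def test_weights_one_zero_zero_equal_first_network(self, tiny_benchmark, short_cfg):
        nets, _ = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        pred = predict_group(nets, tiny_benchmark.targets, (1.0, 0.0, 0.0))
        np.testing.assert_allclose(pred.fused_probs, pred.per_net_probs[0])
        np.testing.assert_array_equal(
            pred.fused_labels, (pred.per_net_probs[0] >= 0.5).astype(int)
        )

    def test_fused_labels_recomputable_from_stored_probabilities(
        self, tiny_benchmark, short_cfg
    ):
        nets, _ = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        w = np.array([1.0, 1.0, 1.0])
        pred = predict_group(nets, tiny_benchmark.targets, w)
        manual = (w @ pred.per_net_probs / w.sum() >= 0.5).astype(int)
        np.testing.assert_array_equal(pred.fused_labels, manual)

    def test_evaluation_is_deterministic(self, tiny_benchmark, short_cfg):
        nets, _ = train_group(tiny_benchmark.source, tiny_benchmark.targets, short_cfg)
        m1, _, _ = evaluate_group(nets, tiny_benchmark.targets)
        m2, _, _ = evaluate_group(nets, tiny_benchmark.targets)
        assert m1 == m2
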