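"""Network unit: forward contracts, loss oracles, gradients, sample selection."""

import math

import numpy as np
import pytest

from cobci import nn
from cobci.erp_align import AlignedTrialSet
from cobci.exceptions import DataError
from cobci.nn import Arch
from cobci.p3_ssda import (
    NetworkUnit,
    domain_adv_loss,
    select_by_scores,
    select_target_samples,
    source_class_loss,
)

SMALL_ARCH = Arch(n_temporal=3, kernel=7, n_spatial=3, pool=4, embed=10, hidden=5)


class TestForward:
    def test_probability_rows_sum_to_one(self, rng):
        net = NetworkUnit(seed=0)
        x = rng.standard_normal((40, 16, 100))
        cp, dp = net.forward(x)
        assert cp.shape == dp.shape == (40, 2)
        np.testing.assert_allclose(cp.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(dp.sum(axis=1), 1.0, atol=1e-6)
        assert (cp > 0).all() and (cp < 1).all()

    def test_duplicated_sample_gets_identical_rows(self, rng):
        net = NetworkUnit(seed=1)
        x = rng.standard_normal((1, 16, 100))
        cp, dp = net.forward(np.concatenate([x, x]))
        np.testing.assert_array_equal(cp[0], cp[1])
        np.testing.assert_array_equal(dp[0], dp[1])

    def test_shape_mismatch_rejected(self, rng):
        net = NetworkUnit(seed=0)
        with pytest.raises(DataError):
            net.forward(rng.standard_normal((4, 16, 150)))


class TestLossOracles:
    def test_source_class_loss_matches_scalar_arithmetic(self, rng):
        for _ in range(20):
            m = rng.integers(1, 6)
            probs1 = rng.uniform(0.05, 0.95, size=m)
            probs = np.column_stack([1 - probs1, probs1])
            labels = rng.integers(0, 2, size=m)
            expected = -sum(
                math.log(probs[k, labels[k]]) for k in range(m)
            )
            assert source_class_loss(probs, labels) == pytest.approx(expected, abs=1e-9)

    def test_domain_loss_matches_scalar_arithmetic(self, rng):
        for _ in range(20):
            ms, mt = rng.integers(1, 6, size=2)
            ps = rng.uniform(0.05, 0.95, size=ms)
            pt = rng.uniform(0.05, 0.95, size=mt)
            dps = np.column_stack([ps, 1 - ps])      # P(source domain) = ps
            dpt = np.column_stack([1 - pt, pt])      # P(target domain) = pt
            expected = -sum(math.log(p) for p in ps) - sum(math.log(p) for p in pt)
            assert domain_adv_loss(dps, dpt) == pytest.approx(expected, abs=1e-9)

    def test_closed_form_values(self):
        # labels [1,0] with target-class probs [0.8, 0.3]
        probs = np.array([[0.2, 0.8], [0.7, 0.3]])
        assert source_class_loss(probs, np.array([1, 0])) == pytest.approx(
            -(math.log(0.8) + math.log(0.7)), abs=1e-12
        )
        # perfect predictions -> 0
        assert source_class_loss(np.array([[0.0, 1.0]]), np.array([1])) == 0.0
        # uniform 0.5, m=2 -> 2 ln 2
        half = np.full((2, 2), 0.5)
        assert source_class_loss(half, np.array([0, 1])) == pytest.approx(2 * math.log(2))
        # uniform domain probs, one sample per domain -> 2 ln 2
        assert domain_adv_loss(half[:1], half[:1]) == pytest.approx(2 * math.log(2))
        # confident correct discriminator -> 0
        assert domain_adv_loss(np.array([[1.0, 0.0]]), np.array([[0.0, 1.0]])) == 0.0

    def test_epsilon_clamp_guards_zero_probabilities(self):
        loss = source_class_loss(np.array([[1.0, 0.0]]), np.array([1]))
        assert np.isfinite(loss) and loss == pytest.approx(-math.log(1e-12))


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        arch = SMALL_ARCH
        params = nn.init_params(arch, rng)
        xs = rng.standard_normal((3, 16, 100))
        ys = np.array([1, 0, 1])
        alpha, gamma = 0.4, 0.8

        def loss_fn():
            f, _ = nn.feature_forward(params, arch, xs)
            cp, _ = nn.head_forward(params, "clf", f)
            dp, _ = nn.head_forward(params, "dom", f)
            return gamma * nn.cross_entropy_sum(cp, ys) + alpha * nn.cross_entropy_sum(
                dp, np.zeros(3, dtype=int)
            )

        f, cache = nn.feature_forward(params, arch, xs)
        cp, ccache = nn.head_forward(params, "clf", f)
        dp, dcache = nn.head_forward(params, "dom", f)
        gc, dfc = nn.head_backward(params, "clf", ccache, gamma * (cp - nn.one_hot(ys)))
        gd, dfd = nn.head_backward(
            params, "dom", dcache, alpha * (dp - nn.one_hot(np.zeros(3, dtype=int)))
        )
        grads = nn.accumulate(nn.feature_backward(params, arch, cache, dfc + dfd), gc, gd)

        eps = 1e-6
        for key in ("W1", "W2", "W3", "clf_W1", "dom_W2"):
            flat = params[key].ravel()
            for i in rng.choice(flat.size, size=4, replace=False):
                old = flat[i]
                flat[i] = old + eps
                lp = loss_fn()
                flat[i] = old - eps
                lm = loss_fn()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = grads[key].ravel()[i]
                assert ana == pytest.approx(num, rel=1e-4, abs=1e-7)

    def test_gradient_reversal_flips_extractor_domain_gradient(self, rng):
        """The extractor ascends the domain loss while the discriminator descends it."""
        arch = SMALL_ARCH
        params = nn.init_params(arch, rng)
        xs = rng.standard_normal((4, 16, 100))
        f, cache = nn.feature_forward(params, arch, xs)
        dp, dcache = nn.head_forward(params, "dom", f)
        dlog = dp - nn.one_hot(np.zeros(4, dtype=int))
        gd, df = nn.head_backward(params, "dom", dcache, dlog)
        g_plain = nn.feature_backward(params, arch, cache, df)
        g_reversed = nn.feature_backward(params, arch, cache, -df)
        for k in g_plain:
            np.testing.assert_allclose(g_reversed[k], -g_plain[k])

    def test_adversarial_training_confuses_discriminator(self, rng):
        """On domain-shifted toy data the discriminator drifts toward chance."""
        arch = SMALL_ARCH
        net = NetworkUnit(arch=arch, seed=3)
        xs = rng.standard_normal((200, 16, 100))
        xt = rng.standard_normal((200, 16, 100)) * 1.8 + 0.7  # shifted domain
        ys = rng.integers(0, 2, size=200)

        def domain_accuracy():
            _, ds = net.forward(xs)
            _, dt = net.forward(xt)
            return 0.5 * ((ds[:, 0] > 0.5).mean() + (dt[:, 1] > 0.5).mean())

        accs = [domain_accuracy()]
        for epoch in range(30):
            order = rng.permutation(200)
            for it in range(5):
                rows = order[it * 40 : (it + 1) * 40]
                net.train_step(xs[rows], ys[rows], xt[rows], None,
                               alpha=0.4, gamma=0.8, beta=0.0, lr=3e-4)
            accs.append(domain_accuracy())
        # late-phase accuracy sits nearer chance than any early peak
        assert min(abs(a - 0.5) for a in accs[-5:]) <= 0.15


def _aligned_for_selection(n_valid=621, n_invalid=10):
    n = n_valid + n_invalid
    rng = np.random.default_rng(0)
    return AlignedTrialSet(
        subject_id="s",
        trials=rng.standard_normal((n, 16, 100)),
        offsets=np.zeros(n, dtype=int),
        labels=np.zeros(n, dtype=np.int8),
        validity=np.array([True] * n_valid + [False] * n_invalid),
        trial_index=np.arange(n),
    )


class TestTargetSelection:
    def test_80_percent_of_621_valid_trials_is_496(self):
        a = _aligned_for_selection()
        scores = np.linspace(1, 0, 621)
        td = select_by_scores(a, scores, 0.8)
        assert len(td.trial_index) == 496
        assert td.n_valid == 621

    def test_fraction_one_keeps_all_valid(self):
        a = _aligned_for_selection(50, 5)
        td = select_by_scores(a, np.zeros(50), 1.0)
        assert len(td.trial_index) == 50
        assert not np.isin(np.arange(50, 55), td.trial_index).any()

    def test_selection_is_permutation_equivariant(self, rng):
        a = _aligned_for_selection(40, 0)
        scores = rng.uniform(size=40).round(1)  # force ties
        td1 = select_by_scores(a, scores, 0.5)
        perm = rng.permutation(40)
        shuffled = AlignedTrialSet(
            subject_id="s",
            trials=a.trials[perm],
            offsets=a.offsets[perm],
            labels=a.labels[perm],
            validity=a.validity[perm],
            trial_index=a.trial_index[perm],
        )
        td2 = select_by_scores(shuffled, scores[perm], 0.5)
        np.testing.assert_array_equal(td1.trial_index, td2.trial_index)

    def test_confident_targets_all_retained_on_separable_data(self, tiny_benchmark, rng):
        """After brief training on clean-ish data, targets rank above the cut."""
        src = tiny_benchmark.source
        a = tiny_benchmark.targets[0]
        net = NetworkUnit(seed=5)
        pos = np.flatnonzero(src.labels == 1)
        neg = np.flatnonzero(src.labels == 0)
        for epoch in range(30):
            rows = np.concatenate(
                [rng.choice(pos, 20, replace=False), rng.choice(neg, 20, replace=False)]
            )
            net.train_step(src.trials[rows], src.labels[rows],
                           a.trials[rng.choice(a.n_trials, 40, replace=False)],
                           None, alpha=0.0, gamma=0.8, beta=0.0, lr=3e-4)
        td = select_target_samples(a, net, fraction=0.8)
        target_idx = a.trial_index[(a.labels == 1) & a.validity]
        kept = np.isin(target_idx, td.trial_index).mean()
        assert kept >= 0.9
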