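"""CSP fitting, template building, and latency alignment."""

import numpy as np
import pytest

from cobci.erp_align import (
    SpatialFilter,
    align_trials,
    build_template,
    fit_csp,
)
from cobci.exceptions import DataError
from cobci.preprocess import TrialSet


def _trials_with_direction(rng, n, direction, signal_sd, noise_sd=1.0, t=150):
    """Trials whose extra variance lies along one spatial direction."""
    base = rng.standard_normal((n, 16, t)) * noise_sd
    comp = rng.standard_normal((n, 1, t)) * signal_sd
    return base + comp * direction[None, :, None]


def _csp_oracle(target, nontarget, shrinkage=1e-6):
    """Independent eigensolve route: eig of inv(Ct+Cn) @ Ct."""

    def cov(trials):
        c = np.zeros((16, 16))
        for x in trials:
            xc = x - x.mean(axis=1, keepdims=True)
            ci = xc @ xc.T / (x.shape[1] - 1)
            c += ci / np.trace(ci)
        return c / len(trials)

    ct, cn = cov(target), cov(nontarget)
    pooled = ct + cn
    pooled += (shrinkage * np.trace(pooled) / 16) * np.eye(16)
    ct_r = ct + (shrinkage * np.trace(ct) / 16) * np.eye(16)
    vals, vecs = np.linalg.eig(np.linalg.solve(pooled, ct_r))
    order = np.argsort(vals.real)
    return vecs[:, order].real


def _abs_cos(a, b):
    return abs(a @ b) / (np.linalg.norm(a) * np.linalg.norm(b))


class TestFitCsp:
    def test_matches_generalized_eigen_oracle_on_random_problems(self, rng):
        for _ in range(10):
            d = rng.standard_normal(16)
            d /= np.linalg.norm(d)
            tgt = _trials_with_direction(rng, 12, d, signal_sd=3.0)
            non = _trials_with_direction(rng, 12, d, signal_sd=0.0)
            w = fit_csp(tgt, non).weights
            oracle_top = _csp_oracle(tgt, non)[:, -1]
            assert _abs_cos(w, oracle_top) >= 0.999

    def test_recovers_planted_spatial_direction(self, rng):
        d = np.zeros(16)
        d[[10, 11, 12]] = [0.5, 0.7, 0.5]
        d /= np.linalg.norm(d)
        tgt = _trials_with_direction(rng, 30, d, signal_sd=5.0, noise_sd=0.5)
        non = _trials_with_direction(rng, 30, d, signal_sd=0.0, noise_sd=0.5)
        assert _abs_cos(fit_csp(tgt, non).weights, d) >= 0.95

    def test_swapping_classes_returns_opposite_extreme(self, rng):
        d = rng.standard_normal(16)
        d /= np.linalg.norm(d)
        tgt = _trials_with_direction(rng, 15, d, signal_sd=4.0)
        non = _trials_with_direction(rng, 15, d, signal_sd=0.0)
        w_swapped = fit_csp(non, tgt).weights
        oracle_bottom = _csp_oracle(non, tgt)[:, -1]
        assert _abs_cos(w_swapped, oracle_bottom) >= 0.999

    def test_degenerate_identical_covariances_still_deterministic(self, rng):
        x = rng.standard_normal((10, 16, 150))
        w1 = fit_csp(x, x.copy()).weights
        w2 = fit_csp(x, x.copy()).weights
        np.testing.assert_array_equal(w1, w2)
        assert np.linalg.norm(w1) == pytest.approx(1.0)

    def test_requires_two_trials_per_class(self, rng):
        x = rng.standard_normal((1, 16, 150))
        with pytest.raises(DataError):
            fit_csp(x, x)


def _bump_trials(n, peak_sample, topo, amp=10.0, width=30, t=150, noise=0.0, rng=None):
    trials = np.zeros((n, 16, t)) if rng is None else rng.standard_normal((n, 16, t)) * noise
    idx = np.arange(max(peak_sample - width // 2, 0), min(peak_sample + width // 2 + 1, t))
    bump = amp * np.cos(np.pi * (idx - peak_sample) / width)
    trials[:, :, idx] += topo[:, None] * bump[None, :]
    return trials


class TestBuildTemplate:
    topo = np.linspace(0.1, 1.0, 16)

    def test_identical_noise_free_trials_give_projected_crop(self):
        trials = _bump_trials(5, 70, self.topo)
        filt = SpatialFilter(weights=np.eye(16)[15])
        tpl = build_template(filt, trials)
        proj = filt.project(trials[0])
        np.testing.assert_allclose(
            tpl.series, proj[tpl.crop_start : tpl.crop_start + 100]
        )

    def test_planted_peak_recovered_within_20ms(self, rng):
        trials = _bump_trials(30, 50, self.topo, noise=0.5, rng=rng)
        filt = fit_csp(trials, rng.standard_normal((30, 16, 150)) * 0.5)
        tpl = build_template(filt, trials)
        peak_in_template = int(np.argmax(tpl.series))
        assert abs((peak_in_template + tpl.crop_start) - 50) <= 2  # +/- 20 ms

    def test_zero_trials_give_flat_template(self):
        filt = SpatialFilter(weights=np.ones(16) / 4.0)
        tpl = build_template(filt, np.zeros((4, 16, 150)))
        np.testing.assert_allclose(tpl.series, 0.0)


class TestAlignTrials:
    topo = np.linspace(0.1, 1.0, 16)

    def _template(self):
        trials = _bump_trials(5, 50, self.topo)
        filt = SpatialFilter(weights=np.eye(16)[15])
        return build_template(filt, trials)

    def _ts(self, trials):
        n = len(trials)
        return TrialSet(
            subject_id="s",
            trials=trials,
            labels=np.ones(n, dtype=np.int8),
            validity=np.ones(n, dtype=bool),
            trial_index=np.arange(n),
        )

    def test_embedded_template_found_at_its_offset(self):
        tpl = self._template()
        trial = np.zeros((1, 16, 150))
        trial[0, :, 20:120] = self.topo[:, None] * tpl.series[None, :]
        out = align_trials(self._ts(trial), tpl)
        assert out.offsets[0] == 20
        assert out.trials.shape == (1, 16, 100)

    def test_flat_trial_defaults_to_offset_zero(self):
        out = align_trials(self._ts(np.zeros((1, 16, 150))), tpl := self._template())
        assert out.offsets[0] == 0

    def test_alignment_idempotent_on_padded_aligned_data(self):
        tpl = self._template()
        # peaks within the recoverable offset range of the template
        jittered = np.concatenate(
            [_bump_trials(1, p, self.topo) for p in (40, 55, 65, 70)]
        )
        first = align_trials(self._ts(jittered), tpl)
        padded = np.zeros((first.n_trials, 16, 150))
        padded[:, :, :100] = first.trials
        second = align_trials(self._ts(padded), tpl)
        assert (second.offsets == 0).all()
        np.testing.assert_allclose(second.trials, first.trials)

    def test_output_shape_and_offset_bounds(self, tiny_benchmark):
        a = tiny_benchmark.targets[0]
        assert a.trials.shape[1:] == (16, 100)
        assert (a.offsets >= 0).all() and (a.offsets + 100 <= 150).all()
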