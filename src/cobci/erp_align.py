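"""CSP-based ERP template construction and latency alignment.

Because the target can appear at an unpredictable moment inside each video,
the P300 latency jitters by hundreds of milliseconds from trial to trial.
Averaging jittered trials smears the component, so trials are first aligned
to a one-dimensional target ERP template:

1. a single common-spatial-patterns (CSP) filter ``w`` is fitted to maximize
   the target/nontarget variance ratio of the spatial projection;
2. projected target trials are averaged and cropped to the 1000 ms
   (100-sample) window with maximal energy — the template;
3. every 1500 ms trial is projected to 1-D, a 100-sample window slides over
   the 150-sample series (51 candidate offsets), and the offset maximizing
   Pearson correlation with the template wins (ties -> smallest offset).

The aligned output is the full 16-channel data inside the chosen window, so
every downstream consumer sees uniform 16 x 100 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .exceptions import DataError
from .preprocess import TrialSet

TEMPLATE_SAMPLES = 100  # 1000 ms at 100 Hz


@dataclass(frozen=True)
class SpatialFilter:
    """Unit-norm CSP spatial filter for the (target, nontarget) pair."""

    weights: np.ndarray  # (16,)
    source_class_pair: tuple[int, int] = (1, 0)

    def project(self, trials: np.ndarray) -> np.ndarray:
        """Project (n, 16, t) or (16, t) trials to 1-D time series."""
        return np.tensordot(trials, self.weights, axes=([-2], [0]))


@dataclass(frozen=True)
class ErpTemplate:
    """1000 ms one-dimensional target ERP template plus its filter."""

    series: np.ndarray  # (100,)
    filter: SpatialFilter
    crop_start: int = 0

    def __post_init__(self) -> None:
        if self.series.shape != (TEMPLATE_SAMPLES,):
            raise DataError(f"template must have {TEMPLATE_SAMPLES} samples")


@dataclass
class AlignedTrialSet:
    """Latency-aligned 16 x 100 trials with parent TrialSet metadata."""

    subject_id: str
    trials: np.ndarray       # (n, 16, 100)
    offsets: np.ndarray      # (n,) chosen window starts in samples
    labels: np.ndarray
    validity: np.ndarray
    trial_index: np.ndarray

    def __post_init__(self) -> None:
        if self.trials.ndim != 3 or self.trials.shape[1:] != (16, TEMPLATE_SAMPLES):
            raise DataError(f"aligned trials must be (n, 16, 100), got {self.trials.shape}")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def _class_covariance(trials: np.ndarray) -> np.ndarray:
    """Trace-normalized average spatial covariance of (n, 16, t) trials."""
    cov = np.zeros((16, 16))
    for x in trials:
        xc = x - x.mean(axis=1, keepdims=True)
        c = xc @ xc.T / max(x.shape[1] - 1, 1)
        tr = np.trace(c)
        if tr > 0:
            c = c / tr
        cov += c
    return cov / len(trials)


def fit_csp(
    target_trials: np.ndarray,
    nontarget_trials: np.ndarray,
    shrinkage: float = 1e-6,
) -> SpatialFilter:
    """Fit the single CSP component maximizing target-class variance ratio.

    Solves the generalized eigenproblem ``C_t w = lambda (C_t + C_n) w`` and
    returns the unit-normalized eigenvector of the largest eigenvalue, sign
    fixed so the mean projected target trial peaks positive.  Covariances are
    shrunk by ``shrinkage * trace / 16`` for small-sample stability.
    """
    if len(target_trials) < 2 or len(nontarget_trials) < 2:
        raise DataError("CSP needs at least two trials per class")
    ct = _class_covariance(np.asarray(target_trials))
    cn = _class_covariance(np.asarray(nontarget_trials))
    pooled = ct + cn
    reg = shrinkage * np.trace(pooled) / 16.0
    pooled = pooled + reg * np.eye(16)
    ct = ct + (shrinkage * np.trace(ct) / 16.0) * np.eye(16)
    if np.linalg.matrix_rank(pooled) < 16:
        raise DataError("pooled covariance is rank-deficient even after regularization")
    # eigh returns ascending eigenvalues with deterministic ordering
    _vals, vecs = scipy.linalg.eigh(ct, pooled)
    w = vecs[:, -1]
    w = w / np.linalg.norm(w)
    # sign convention: mean projected target trial peaks positive
    mean_proj = np.tensordot(np.asarray(target_trials).mean(axis=0), w, axes=([0], [0]))
    extremum = mean_proj[np.argmax(np.abs(mean_proj))]
    if extremum < 0:
        w = -w
    return SpatialFilter(weights=w)


def build_template(filt: SpatialFilter, target_trials: np.ndarray) -> ErpTemplate:
    """Average the projected target trials and crop a 100-sample window.

    The window is anchored a quarter-length (25 samples = 250 ms) before the
    peak of the averaged projection, clipped to the trial bounds.  Anchoring
    the peak at the window's first quarter rather than its center matters
    for alignment: a trial whose P300 sits *earlier* than the template peak
    can only be matched if the peak is not too deep inside the window, so
    this placement keeps roughly -250/+750 ms of latency jitter inside the
    recoverable offset range.
    """
    proj = filt.project(np.asarray(target_trials))  # (n, 150)
    avg = proj.mean(axis=0)
    n_off = avg.shape[0] - TEMPLATE_SAMPLES + 1
    if n_off < 1:
        raise DataError("trials shorter than the template length")
    peak = int(np.argmax(avg))  # first maximum
    start = int(np.clip(peak - TEMPLATE_SAMPLES // 4, 0, n_off - 1))
    return ErpTemplate(series=avg[start : start + TEMPLATE_SAMPLES].copy(),
                       filter=filt, crop_start=start)


def _window_correlations(series: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Pearson correlation of every sliding window of ``series`` vs template.

    Degenerate windows (zero variance, or a degenerate template) score -2 —
    strictly below any real correlation — so the smallest-offset tie-break
    picks offset 0 when nothing matches.
    """
    win = np.lib.stride_tricks.sliding_window_view(series, TEMPLATE_SAMPLES)
    wc = win - win.mean(axis=1, keepdims=True)
    tc = template - template.mean()
    wn = np.linalg.norm(wc, axis=1)
    tn = np.linalg.norm(tc)
    scores = np.full(win.shape[0], -2.0)
    ok = (wn > 0) & (tn > 0)
    if tn > 0:
        scores[ok] = (wc[ok] @ tc) / (wn[ok] * tn)
    return scores


def align_trials(ts: TrialSet, template: ErpTemplate) -> AlignedTrialSet:
    """Align every trial of a TrialSet to the template.

    All trials — target and nontarget, valid and invalid — are aligned so the
    network input is uniformly 16 x 100 and trial indices stay intact.
    """
    n, _c, t = ts.trials.shape
    if t < TEMPLATE_SAMPLES:
        raise DataError("trials shorter than the template")
    proj = template.filter.project(ts.trials)  # (n, 150)
    aligned = np.empty((n, 16, TEMPLATE_SAMPLES))
    offsets = np.empty(n, dtype=int)
    for i in range(n):
        scores = _window_correlations(proj[i], template.series)
        off = int(np.argmax(scores))  # first max == smallest offset on ties
        offsets[i] = off
        aligned[i] = ts.trials[i, :, off : off + TEMPLATE_SAMPLES]
    return AlignedTrialSet(
        subject_id=ts.subject_id,
        trials=aligned,
        offsets=offsets,
        labels=ts.labels.copy(),
        validity=ts.validity.copy(),
        trial_index=ts.trial_index.copy(),
    )
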