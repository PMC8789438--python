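"""Raw recordings -> filtered, downsampled, epoched, amplitude-screened trials.

The pipeline is: 0.1-10 Hz zero-phase band-pass, downsample to 100 Hz,
segment into 1500 ms trials (one per target video from target onset;
nontarget videos tiled without overlap), then flag trials whose absolute
amplitude exceeds +/-120 uV as invalid.  Screening only flags; nothing is
removed, so trial indices stay aligned across the subjects of a group.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .events import trial_windows
from .exceptions import DataError, ParameterError
from .synthetic import RawRecording

logger = logging.getLogger(__name__)

TRIAL_SAMPLES = 150  # 1500 ms at 100 Hz
DEFAULT_THRESHOLD_UV = 120.0


@dataclass
class TrialSet:
    """Epoched trials for one subject at 100 Hz.

    ``trial_index`` is the position in the shared stimulus stream; it is
    identical across the subjects of a synchronized group and is the key
    used to keep group batches aligned downstream.
    """

    subject_id: str
    trials: np.ndarray       # (n, 16, 150) uV
    labels: np.ndarray       # (n,) int, target=1 / nontarget=0
    validity: np.ndarray     # (n,) bool
    trial_index: np.ndarray  # (n,) int
    fs: float = 100.0

    def __post_init__(self) -> None:
        n = self.trials.shape[0]
        if self.trials.ndim != 3 or self.trials.shape[1] != 16:
            raise DataError(f"trials must be (n, 16, t), got {self.trials.shape}")
        if not (len(self.labels) == len(self.validity) == len(self.trial_index) == n):
            raise DataError("labels/validity/trial_index must match trial count")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def bandpass_downsample(
    rec: RawRecording,
    low: float = 0.1,
    high: float = 10.0,
    fs_out: float = 100.0,
    order: int = 4,
) -> RawRecording:
    """Zero-phase Butterworth band-pass, then downsample.

    The filter is applied forward-backward (``sosfiltfilt``) so P3 latency is
    not shifted.  When the rate ratio is an integer the signal is decimated
    by slicing (the band-pass has already removed energy above ``high``, far
    below the new Nyquist); otherwise polyphase resampling is used.
    """
    if not (0 < low < high):
        raise ParameterError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= rec.fs / 2:
        raise ParameterError(f"high={high} Hz must be below Nyquist ({rec.fs / 2} Hz)")
    if fs_out <= 2 * high:
        raise ParameterError(f"fs_out={fs_out} Hz cannot represent the {high} Hz band edge")

    sos = signal.butter(order, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=1)

    ratio = rec.fs / fs_out
    if abs(ratio - round(ratio)) < 1e-9:
        out = filtered[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(fs_out / rec.fs).limit_denominator(1000)
        out = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return RawRecording(subject_id=rec.subject_id, samples=np.ascontiguousarray(out),
                        fs=fs_out, events=rec.events, channels=rec.channels)


def epoch_trials(rec: RawRecording, trial_s: float = 1.5) -> TrialSet:
    """Segment a (100 Hz) recording into 1500 ms trials.

    Exactly one target trial per target video, starting at target onset;
    nontarget videos tiled from video onset, partial tails discarded.
    """
    if rec.events is None or len(rec.events) == 0:
        raise DataError("recording has no events to epoch")
    n_samp = int(round(trial_s * rec.fs))
    windows = trial_windows(rec.events, trial_s)
    trials = np.empty((len(windows), 16, n_samp))
    labels = np.empty(len(windows), dtype=np.int8)
    for i, (start, label, _vid) in enumerate(windows):
        s0 = int(round(start * rec.fs))
        if s0 < 0 or s0 + n_samp > rec.samples.shape[1]:
            raise DataError(
                f"trial at t={start:.3f}s exceeds recording bounds for {rec.subject_id}"
            )
        trials[i] = rec.samples[:, s0 : s0 + n_samp]
        labels[i] = label
    return TrialSet(
        subject_id=rec.subject_id,
        trials=trials,
        labels=labels,
        validity=np.ones(len(windows), dtype=bool),
        trial_index=np.arange(len(windows)),
        fs=rec.fs,
    )


def screen_validity(ts: TrialSet, threshold: float = DEFAULT_THRESHOLD_UV) -> TrialSet:
    """Flag trials whose peak absolute amplitude exceeds ``threshold``.

    The comparison is inclusive: a trial peaking at exactly the threshold is
    valid.  Flags only — no trials are dropped.
    """
    if threshold <= 0:
        raise ParameterError("threshold must be positive")
    peaks = np.abs(ts.trials).max(axis=(1, 2))
    return replace(ts, validity=peaks <= threshold)


def remove_eog(rec: RawRecording, enabled: bool = False) -> RawRecording:
    """Ocular-artifact removal hook.

    No ICA is implemented in this toolkit (the synthetic data carries no
    electrooculogram); when enabled this is an identity transform with a
    warning, kept so real-data pipelines have a slot to plug into.
    """
    if enabled:
        logger.warning(
            "EOG removal requested but no ICA backend is implemented; "
            "returning the recording unchanged"
        )
    return rec


def preprocess_recording(
    rec: RawRecording,
    low: float = 0.1,
    high: float = 10.0,
    fs_out: float = 100.0,
    threshold: float = DEFAULT_THRESHOLD_UV,
) -> TrialSet:
    """Full per-subject chain: filter, downsample, epoch, screen."""
    return screen_validity(epoch_trials(bandpass_downsample(rec, low, high, fs_out)), threshold)
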