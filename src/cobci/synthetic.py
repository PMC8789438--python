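"""Synthetic multi-subject EEG with planted P300 structure.

This module generates the study conditions the rest of the pipeline assumes:
groups of time-synchronized subjects watching an identical stream of short
videos (4-10 s, preceded by a 2 s fixation cross), where target videos
contain one vehicle appearing no earlier than 1 s into the clip.  Each
target elicits a P300-like deflection whose latency jitters from trial to
trial and whose scalp topography is concentrated over parieto-occipital
electrodes, scaled per subject ("strong" vs "weak" P3 responders).

The signal model is deliberately simple and fully parameterized:

* background = 1/f (pink) noise per channel plus a low-amplitude 10 Hz
  oscillation, so the 0.1-10 Hz band-pass stage is exercised meaningfully;
* P300 = positive half-cosine bump (default width 300 ms) times a fixed
  posterior topography, peak drawn uniformly 0.3-0.7 s after target onset;
* amplitude artifacts = step offsets of +/-150 uV injected into a
  configurable fraction of (future) trials so the +/-120 uV validity screen
  has something to reject.

All randomness flows from ``SimConfig.seed`` through spawned child
generators; output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .events import NONTARGET, TARGET, TRIAL_SECONDS, VideoEvent, trial_windows
from .exceptions import ConfigurationError
from .montage import CHANNELS_16

__all__ = [
    "SimConfig",
    "RawRecording",
    "GroundTruth",
    "base_topography",
    "simulate_group",
    "simulate_subject_pool",
]

#: Relative P3 scalp weights (peak channel Pz = 1), posterior-dominant.
_TOPO_WEIGHTS = {
    "Fp1": 0.05, "Fp2": 0.05, "F3": 0.10, "Fz": 0.15, "F4": 0.10,
    "C3": 0.25, "Cz": 0.45, "C4": 0.25, "T7": 0.10, "T8": 0.10,
    "P3": 0.80, "Pz": 1.00, "P4": 0.80, "PO7": 0.65, "PO8": 0.65,
    "Oz": 0.55,
}


def base_topography(channels=CHANNELS_16) -> np.ndarray:
    """Unit-peak P3 topography over ``channels`` (posterior-dominant)."""
    return np.array([_TOPO_WEIGHTS.get(ch, 0.05) for ch in channels])


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synchronized-group simulation.

    Amplitudes are in microvolts.  ``p3_latency_jitter`` is the range of the
    P3 *peak* time relative to target onset; the target onset itself is drawn
    uniformly in ``[target_onset_min, duration - 1.5 s]`` within each target
    video so the full trial fits inside the clip.
    """

    n_subjects: int = 3
    n_target_videos: int = 100
    n_nontarget_videos: int = 100
    video_length_range: tuple[float, float] = (4.0, 10.0)
    channels: tuple[str, ...] = CHANNELS_16
    fs_raw: float = 600.0
    p3_amplitude_per_subject: tuple[float, ...] | None = None
    p3_latency_jitter: tuple[float, float] = (0.3, 0.7)
    target_onset_min: float = 1.0
    p3_width: float = 0.3
    noise_sd: float = 5.0
    osc_amplitude: float | None = None  # default 0.2 * noise_sd
    artifact_rate: float = 0.0
    artifact_amplitude: float = 150.0
    fixation_s: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.video_length_range
        if not (4.0 <= lo <= hi <= 10.0):
            raise ConfigurationError(
                f"video_length_range must lie within [4, 10] s, got {self.video_length_range}"
            )
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if not 0.0 <= self.artifact_rate <= 1.0:
            raise ConfigurationError("artifact_rate must be in [0, 1]")
        if len(self.channels) != 16:
            raise ConfigurationError("montage must have 16 channels")
        jlo, jhi = self.p3_latency_jitter
        if not 0.0 <= jlo <= jhi:
            raise ConfigurationError("invalid p3_latency_jitter range")
        if self.target_onset_min < 1.0:
            raise ConfigurationError("targets may not appear before 1 s into a video")
        if self.p3_amplitude_per_subject is not None and len(
            self.p3_amplitude_per_subject
        ) != self.n_subjects:
            raise ConfigurationError("need one P3 amplitude per subject")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")

    @property
    def amplitudes(self) -> tuple[float, ...]:
        if self.p3_amplitude_per_subject is None:
            return (10.0,) * self.n_subjects
        return self.p3_amplitude_per_subject

    @property
    def osc_amp(self) -> float:
        return 0.2 * self.noise_sd if self.osc_amplitude is None else self.osc_amplitude


@dataclass
class RawRecording:
    """One subject's continuous recording plus its event stream."""

    subject_id: str
    samples: np.ndarray  # (16, n_samples) in uV
    fs: float
    events: list[VideoEvent]
    channels: tuple[str, ...] = CHANNELS_16

    def __post_init__(self) -> None:
        if self.samples.shape[0] != 16:
            raise ConfigurationError("recordings carry exactly 16 channels")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.fs


@dataclass
class GroundTruth:
    """What the simulator planted, for evaluating recovery downstream."""

    topographies: np.ndarray      # (n_subjects, 16) uV at P3 peak
    peak_latencies: np.ndarray    # (n_subjects, n_target_videos) s after target onset
    validity: np.ndarray          # (n_subjects, n_trials) bool, trial_index order
    trial_labels: np.ndarray      # (n_trials,) shared labels in trial_index order
    subject_ids: list[str] = field(default_factory=list)


def _draw_events(cfg: SimConfig, rng: np.random.Generator) -> list[VideoEvent]:
    """One shared stimulus stream: shuffled target/nontarget videos."""
    n = cfg.n_target_videos + cfg.n_nontarget_videos
    classes = np.array([TARGET] * cfg.n_target_videos + [NONTARGET] * cfg.n_nontarget_videos)
    rng.shuffle(classes)
    lo, hi = cfg.video_length_range
    durations = rng.uniform(lo, hi, size=n)
    events: list[VideoEvent] = []
    t = 0.0
    for vid, (cls, dur) in enumerate(zip(classes, durations)):
        t += cfg.fixation_s
        target_onset = None
        if cls == TARGET:
            latest = dur - TRIAL_SECONDS
            target_onset = t + rng.uniform(cfg.target_onset_min, latest)
        events.append(
            VideoEvent(onset=t, video_id=vid, video_class=int(cls),
                       duration=float(dur), target_onset=target_onset)
        )
        t += dur
    return events


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance 1/f noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n)
    scale = np.zeros_like(freqs)
    scale[1:] = 1.0 / np.sqrt(freqs[1:])
    spec = (rng.standard_normal(freqs.size) + 1j * rng.standard_normal(freqs.size)) * scale
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _render_subject(
    cfg: SimConfig,
    events: list[VideoEvent],
    amplitude: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render one subject's continuous signal.

    Returns (samples, peak_latencies_per_target_video, validity_per_trial).
    """
    fs = cfg.fs_raw
    total = events[-1].onset + events[-1].duration + cfg.fixation_s
    n = int(round(total * fs))
    x = np.zeros((16, n))

    if cfg.noise_sd > 0:
        for ch in range(16):
            x[ch] = cfg.noise_sd * _pink_noise(n, rng)
    if cfg.osc_amp > 0:
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=16)
        x += cfg.osc_amp * np.sin(2 * np.pi * 10.0 * t[None, :] + phases[:, None])

    # plant one P3 bump per target video
    topo = amplitude * base_topography(cfg.channels)
    jlo, jhi = cfg.p3_latency_jitter
    target_events = [ev for ev in events if ev.video_class == TARGET]
    latencies = rng.uniform(jlo, jhi, size=len(target_events))
    half = cfg.p3_width / 2.0
    for ev, lat in zip(target_events, latencies):
        peak = ev.target_onset + lat
        i0 = int(np.ceil((peak - half) * fs))
        i1 = int(np.floor((peak + half) * fs))
        idx = np.arange(max(i0, 0), min(i1 + 1, n))
        bump = np.cos(np.pi * (idx / fs - peak) / cfg.p3_width)
        x[:, idx] += topo[:, None] * bump[None, :]

    # artifacts: step offsets inside a fraction of future trials
    windows = trial_windows(events)
    n_trials = len(windows)
    hit = rng.random(n_trials) < cfg.artifact_rate
    for (start, _label, _vid), is_hit in zip(windows, hit):
        if not is_hit:
            continue
        ch = rng.integers(0, 16)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        s0 = int(round(start * fs))
        s1 = int(round((start + TRIAL_SECONDS) * fs))
        # step begins somewhere in the first half of the trial, runs to its end
        step_at = s0 + rng.integers(0, max((s1 - s0) // 2, 1))
        x[ch, step_at:s1] += sign * cfg.artifact_amplitude
    return x, latencies, ~hit


def simulate_group(cfg: SimConfig) -> tuple[list[RawRecording], GroundTruth]:
    """Simulate one synchronized group.

    All subjects share a bit-identical event stream (the synchronization
    contract); signals differ per subject (independent noise, latencies,
    artifacts, P3 amplitude scale).
    """
    master = np.random.SeedSequence(cfg.seed)
    ev_seq, *subject_seqs = master.spawn(cfg.n_subjects + 1)
    events = _draw_events(cfg, np.random.default_rng(ev_seq))
    windows = trial_windows(events)
    labels = np.array([label for _, label, _ in windows], dtype=np.int8)

    recs: list[RawRecording] = []
    topos = np.zeros((cfg.n_subjects, 16))
    lats = np.zeros((cfg.n_subjects, cfg.n_target_videos))
    valid = np.zeros((cfg.n_subjects, len(windows)), dtype=bool)
    ids = []
    for s, (amp, seq) in enumerate(zip(cfg.amplitudes, subject_seqs)):
        rng = np.random.default_rng(seq)
        x, latencies, validity = _render_subject(cfg, events, amp, rng)
        sid = f"sub{s + 1:02d}"
        ids.append(sid)
        recs.append(RawRecording(subject_id=sid, samples=x, fs=cfg.fs_raw,
                                 events=events, channels=cfg.channels))
        topos[s] = amp * base_topography(cfg.channels)
        lats[s] = latencies
        valid[s] = validity
    truth = GroundTruth(topographies=topos, peak_latencies=lats, validity=valid,
                        trial_labels=labels, subject_ids=ids)
    return recs, truth


def simulate_subject_pool(
    cfg: SimConfig,
    n_strong: int,
    n_weak: int,
    *,
    strong_amplitude: float = 9.0,
    weak_amplitude: float = 3.0,
) -> tuple[list[RawRecording], list[GroundTruth], np.ndarray]:
    """Independent single-subject sessions with a strong/weak amplitude split.

    Each pool member views their own stimulus stream (single-mind sessions
    are not synchronized).  Returns the recordings, per-subject ground
    truths, and the boolean strong-membership mask used to grade source
    selection downstream.
    """
    if n_strong + n_weak < 2:
        raise ConfigurationError("a pool needs at least two subjects")
    amps = [strong_amplitude] * n_strong + [weak_amplitude] * n_weak
    seqs = np.random.SeedSequence(cfg.seed).spawn(len(amps))
    recs: list[RawRecording] = []
    truths: list[GroundTruth] = []
    for i, (amp, seq) in enumerate(zip(amps, seqs)):
        sub_cfg = replace(
            cfg,
            n_subjects=1,
            p3_amplitude_per_subject=(amp,),
            seed=int(seq.generate_state(1)[0] % (2**31)),
        )
        rec, truth = simulate_group(sub_cfg)
        sid = f"pool{i + 1:02d}"
        rec[0].subject_id = sid
        truth.subject_ids = [sid]
        recs.append(rec[0])
        truths.append(truth)
    return recs, truths, np.array([True] * n_strong + [False] * n_weak)
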