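"""The synthetic study conditions used by tests and the acceptance script.

Two named configurations:

* ``medium`` — the mutual-learning benchmark: a 3-subject group with
  heterogeneous P3 amplitudes (10, 7, 4 uV — one clearly weak responder)
  against pink noise of 6 uV, 5% artifact trials, and a source pool of
  4 strong + 2 weak single-session subjects.  Hard enough that the weak
  subject's unit benefits from the group's pseudo-labels.
* ``easy`` — a separable sanity benchmark: homogeneous 10 uV responders at
  3 uV noise, for "the pipeline should essentially solve this" checks.

Problem sizes are scaled to desk hardware: 40 target + 40 nontarget videos
per session (4-10 s clips) instead of 100 + 100, preserving the ~1:4.6
class imbalance of the full paradigm.  Epochs default to 30 at batch 40.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .erp_align import AlignedTrialSet, align_trials, build_template, fit_csp
from .exceptions import ConfigurationError
from .mldanet import TrainConfig
from .p3_select import (
    SourceDomain,
    build_source_domain,
    cluster_p3_maps,
    extract_p3_map,
)
from .preprocess import preprocess_recording
from .synthetic import SimConfig, simulate_group, simulate_subject_pool


@dataclass(frozen=True)
class BenchmarkData:
    """Everything a framework run needs, plus ground truth for grading."""

    source: SourceDomain
    targets: list[AlignedTrialSet]
    group_truth: object
    strong_ids: list[str]


def group_sim_config(level: str, seed: int) -> SimConfig:
    if level == "medium":
        return SimConfig(
            n_subjects=3,
            n_target_videos=40,
            n_nontarget_videos=40,
            p3_amplitude_per_subject=(10.0, 7.0, 4.0),
            noise_sd=6.0,
            artifact_rate=0.05,
            seed=seed,
        )
    if level == "easy":
        return SimConfig(
            n_subjects=3,
            n_target_videos=40,
            n_nontarget_videos=40,
            p3_amplitude_per_subject=(10.0, 10.0, 10.0),
            noise_sd=3.0,
            artifact_rate=0.05,
            seed=seed,
        )
    if level == "tiny":  # smoke-scale: structure over statistics
        return SimConfig(
            n_subjects=3,
            n_target_videos=12,
            n_nontarget_videos=12,
            video_length_range=(4.0, 6.0),
            p3_amplitude_per_subject=(10.0, 8.0, 6.0),
            noise_sd=4.0,
            artifact_rate=0.05,
            seed=seed,
        )
    raise ConfigurationError(f"unknown benchmark level {level!r}")


def pool_sim_config(level: str, seed: int) -> SimConfig:
    cfg = group_sim_config(level, seed)
    return replace(cfg, n_subjects=1, p3_amplitude_per_subject=None)


def default_train_config(seed: int, epochs: int = 30, **overrides) -> TrainConfig:
    return TrainConfig(epochs=epochs, seed=seed, **overrides)


def build_source_from_pool(
    pool_cfg: SimConfig,
    n_strong: int = 4,
    n_weak: int = 2,
    cluster_seed: int = 0,
) -> tuple[SourceDomain, list[str], list[AlignedTrialSet]]:
    """Simulate the labeled pool, build the template, cluster, pool the strong."""
    recs, _truths, _mask = simulate_subject_pool(pool_cfg, n_strong, n_weak)
    trialsets = [preprocess_recording(r) for r in recs]
    # template from the pool's valid target/nontarget trials
    tgt = np.concatenate(
        [ts.trials[(ts.labels == 1) & ts.validity] for ts in trialsets]
    )
    non = np.concatenate(
        [ts.trials[(ts.labels == 0) & ts.validity] for ts in trialsets]
    )
    template = build_template(fit_csp(tgt, non), tgt)
    aligned = [align_trials(ts, template) for ts in trialsets]
    maps = [extract_p3_map(a, template) for a in aligned]
    strong_ids, _weak = cluster_p3_maps(maps, seed=cluster_seed)
    source = build_source_domain(aligned, sorted(strong_ids), template)
    return source, sorted(strong_ids), aligned


#: Source-pool composition per benchmark level (strong, weak).
POOL_SPLIT = {"medium": (4, 2), "easy": (4, 2), "tiny": (2, 1)}


def make_benchmark(level: str, seed: int) -> BenchmarkData:
    """Simulate pool + group, preprocess, align, select: ready to train."""
    seed = int(seed) % (2**31)
    n_strong, n_weak = POOL_SPLIT[level]
    source, strong_ids, _pool_aligned = build_source_from_pool(
        pool_sim_config(level, seed + 10_000), n_strong=n_strong, n_weak=n_weak
    )
    group_recs, truth = simulate_group(group_sim_config(level, seed))
    targets = [
        align_trials(preprocess_recording(rec), source.template)
        for rec in group_recs
    ]
    return BenchmarkData(
        source=source, targets=targets, group_truth=truth, strong_ids=strong_ids
    )
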