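"""The four detection frameworks under comparison.

* **sBCI** — one subject, one adversarial unit, no fusion.
* **SC-cBCI** — signal-level fusion: the group's aligned trials are averaged
  sample-wise into one pseudo-subject, classified by a single unit.
* **MC-cBCI** — decision-level fusion: N independently trained units, their
  target probabilities weighted-averaged and binarized at evaluation only.
* **MLDANet-cBCI** — decision-level fusion *plus* mutual learning: the fused
  pseudo-labels feed back into every unit during training.

All four consume the same preprocessed, aligned inputs, so differences in
metrics are attributable to the fusion/learning strategy alone.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .erp_align import AlignedTrialSet
from .exceptions import ConfigurationError, DataError
from .metrics import DetectionMetrics
from .mldanet import TrainConfig, evaluate_group, train_group
from .p3_select import SourceDomain

FRAMEWORK_NAMES = ("sbci", "sc-cbci", "mc-cbci", "mldanet")

#: Published adversarial-loss weights per framework.
DEFAULT_ALPHA = {"sbci": 0.2, "sc-cbci": 0.2, "mc-cbci": 0.2, "mldanet": 0.4}


@dataclass(frozen=True)
class FrameworkSpec:
    """Taxonomy of a framework: unit count, fusion level, mutual learning."""

    name: str
    n_networks: int
    fusion: str  # none | signal | decision
    mutual_learning: bool

    def __post_init__(self) -> None:
        if self.name not in FRAMEWORK_NAMES:
            raise ConfigurationError(f"unknown framework {self.name!r}")
        ok = {
            "sbci": self.fusion == "none" and not self.mutual_learning,
            "sc-cbci": self.fusion == "signal"
            and self.n_networks == 1
            and not self.mutual_learning,
            "mc-cbci": self.fusion == "decision" and not self.mutual_learning,
            "mldanet": self.fusion == "decision" and self.mutual_learning,
        }[self.name]
        if not ok:
            raise ConfigurationError(f"inconsistent framework spec: {self}")


def framework_spec(name: str, n_networks: int = 3) -> FrameworkSpec:
    return {
        "sbci": FrameworkSpec("sbci", 1, "none", False),
        "sc-cbci": FrameworkSpec("sc-cbci", 1, "signal", False),
        "mc-cbci": FrameworkSpec("mc-cbci", n_networks, "decision", False),
        "mldanet": FrameworkSpec("mldanet", n_networks, "decision", True),
    }[name]


@dataclass
class FrameworkResult:
    """Metrics and artifacts of one framework run on one group."""

    spec: FrameworkSpec
    fused: DetectionMetrics
    per_network: list[DetectionMetrics]
    history: dict
    nets: list


def _cfg_for(name: str, cfg: TrainConfig, n_networks: int) -> TrainConfig:
    beta = cfg.beta if name == "mldanet" else 0.0
    alpha = cfg.alpha if name == "mldanet" else min(cfg.alpha, DEFAULT_ALPHA[name])
    return replace(cfg, n_networks=n_networks, beta=beta, alpha=alpha)


def run_sbci(
    source: SourceDomain, target: AlignedTrialSet, cfg: TrainConfig
) -> FrameworkResult:
    """Single-mind baseline: one unit, no pseudo-label coupling."""
    run_cfg = _cfg_for("sbci", cfg, 1)
    nets, history = train_group(source, [target], run_cfg)
    fused, per_net, _ = evaluate_group(nets, [target], (1.0,))
    return FrameworkResult(framework_spec("sbci"), fused, per_net, history, nets)


def average_group_signals(targets: list[AlignedTrialSet]) -> AlignedTrialSet:
    """Sample-wise average of the group's aligned trials (signal fusion).

    Trials are matched by stimulus ``trial_index``; validity is the logical
    AND of member validity.  Averaging after alignment (rather than on raw
    signals) keeps each subject's P300 at the same latency so the component
    is reinforced instead of smeared.
    """
    ref = targets[0]
    for t in targets[1:]:
        if not np.array_equal(t.trial_index, ref.trial_index):
            raise DataError("cannot average desynchronized trial sets")
        if not np.array_equal(t.labels, ref.labels):
            raise DataError("label streams disagree across the group")
    avg = np.mean([t.trials for t in targets], axis=0)
    validity = np.logical_and.reduce([t.validity for t in targets])
    return AlignedTrialSet(
        subject_id="+".join(t.subject_id for t in targets),
        trials=avg,
        offsets=ref.offsets.copy(),
        labels=ref.labels.copy(),
        validity=validity,
        trial_index=ref.trial_index.copy(),
    )


def run_sc_cbci(
    source: SourceDomain, targets: list[AlignedTrialSet], cfg: TrainConfig
) -> FrameworkResult:
    """Signal-level fusion: classify the group-averaged pseudo-subject."""
    pseudo_subject = average_group_signals(targets)
    run_cfg = _cfg_for("sc-cbci", cfg, 1)
    nets, history = train_group(source, [pseudo_subject], run_cfg)
    fused, per_net, _ = evaluate_group(nets, [pseudo_subject], (1.0,))
    return FrameworkResult(framework_spec("sc-cbci"), fused, per_net, history, nets)


def run_mc_cbci(
    source: SourceDomain, targets: list[AlignedTrialSet], cfg: TrainConfig
) -> FrameworkResult:
    """Decision-level fusion of independently trained units (no mutual learning)."""
    run_cfg = _cfg_for("mc-cbci", cfg, len(targets))
    nets, history = train_group(source, targets, run_cfg)
    fused, per_net, _ = evaluate_group(nets, targets, run_cfg.weights())
    return FrameworkResult(
        framework_spec("mc-cbci", len(targets)), fused, per_net, history, nets
    )


def run_mldanet(
    source: SourceDomain, targets: list[AlignedTrialSet], cfg: TrainConfig
) -> FrameworkResult:
    """Decision-level fusion with mutual pseudo-label learning."""
    run_cfg = _cfg_for("mldanet", cfg, len(targets))
    if run_cfg.beta <= 0:
        raise ConfigurationError("the mutual-learning framework requires beta > 0")
    nets, history = train_group(source, targets, run_cfg)
    fused, per_net, _ = evaluate_group(nets, targets, run_cfg.weights())
    return FrameworkResult(
        framework_spec("mldanet", len(targets)), fused, per_net, history, nets
    )


def run_framework(
    name: str,
    source: SourceDomain,
    targets: list[AlignedTrialSet],
    cfg: TrainConfig,
) -> FrameworkResult | list[FrameworkResult]:
    """Dispatch by framework name; sBCI returns one result per subject."""
    if name == "sbci":
        return [run_sbci(source, t, cfg) for t in targets]
    if name == "sc-cbci":
        return run_sc_cbci(source, targets, cfg)
    if name == "mc-cbci":
        return run_mc_cbci(source, targets, cfg)
    if name == "mldanet":
        return run_mldanet(source, targets, cfg)
    raise ConfigurationError(f"unknown framework {name!r}")
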