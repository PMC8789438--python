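"""Mutual-learning group trainer: N adversarial units coupled by pseudo-labels.

N network units — one per subject of a synchronized group — are trained
jointly.  Every iteration each unit sees the shared labeled source batch and
its own subject's target batch, drawn at *identical* stimulus trial indices
across subjects.  The units' target-class probabilities are weighted-averaged
and binarized into a single pseudo-label vector, which is fed back to every
unit as its target category loss.  The optimized objective per iteration is

    sum_n  alpha * L_adv^(s,t_n)  +  gamma * L_class^(s,t_n)  +  beta * L_class^(t_n)

(minimized by Adam; the domain term reaches the feature extractors through
gradient reversal).  With ``beta = 0`` the coupling vanishes and the trainer
degenerates to N independently trained units — which is exactly how the
non-mutual baselines are defined.

Training schedule: the first ``warmup_epochs`` (default half of the epochs)
run with the pseudo-label term off and the full valid trial pool; then the
target-domain selection (top 80% by predicted target probability — group-
averaged in the mutual setting, per-unit otherwise) is computed once and
frozen, and the pseudo-label feedback engages.  Engaging the feedback only
after the units have stabilized matters: pseudo-labels binarized from
still-majority-biased probabilities suppress the minority (target) class
and the loop ratchets the hit rate down instead of up.  Source mini-batches
are class-balanced by default for the same reason.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .erp_align import AlignedTrialSet
from .exceptions import ConfigurationError, DataError
from .metrics import DetectionMetrics, compute_metrics
from .nn import Arch
from .p3_select import SourceDomain
from .p3_ssda import NetworkUnit, TargetDomain, select_by_scores, source_class_loss

DEFAULT_SELECT_FRACTION = 0.8


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters (defaults follow the published settings).

    ``alpha`` weighs the adversarial domain loss (0.2 for the non-mutual
    frameworks, 0.4 with mutual learning), ``gamma`` the source category
    loss, ``beta`` the pseudo-label target category loss.
    """

    n_networks: int = 3
    batch_size: int = 40
    learning_rate: float = 3e-4
    epochs: int = 100
    alpha: float = 0.4
    gamma: float = 0.8
    beta: float = 0.2
    fusion_weights: tuple[float, ...] | None = None  # default (1, ..., 1)
    select_fraction: float = DEFAULT_SELECT_FRACTION
    balanced_source: bool = True  # class-balanced source mini-batches
    warmup_epochs: int | None = None  # default: half of epochs
    grl_lambda: float = 1.0
    seed: int = 0
    eval_every: int = 0  # 0: no per-epoch evaluation
    track_epoch_loss: bool = False  # full-pool loss at each epoch end
    arch: Arch = field(default_factory=Arch)

    def __post_init__(self) -> None:
        if min(self.alpha, self.gamma, self.beta) < 0:
            raise ConfigurationError("alpha, gamma, beta must be >= 0")
        if self.n_networks < 1:
            raise ConfigurationError("need at least one network")

    @property
    def n_warmup(self) -> int:
        # Units need a fixed number of epochs to stabilize before their
        # pseudo-labels are trustworthy, so the default is half the run but
        # capped: long runs should not postpone the coupled phase.
        if self.warmup_epochs is not None:
            return self.warmup_epochs
        return min(max(1, round(0.5 * self.epochs)), 20)

    def weights(self) -> np.ndarray:
        w = self.fusion_weights
        if w is None:
            w = (1.0,) * self.n_networks
        w = np.asarray(w, dtype=float)
        if w.min() < 0 or w.sum() == 0:
            raise ConfigurationError("fusion weights must be nonnegative, not all zero")
        return w


@dataclass(frozen=True)
class PseudoLabels:
    """Binarized group-averaged target-class probabilities."""

    labels: np.ndarray       # (m,) in {0, 1}
    provenance: np.ndarray   # (m,) the weighted-mean probability


@dataclass(frozen=True)
class LossBundle:
    """Per-iteration losses of all networks plus the optimized total."""

    l_adv: tuple[float, ...]
    l_class_s: tuple[float, ...]
    l_class_t: tuple[float, ...]
    alpha: float
    gamma: float
    beta: float

    @property
    def total(self) -> float:
        return float(
            sum(
                self.alpha * a + self.gamma * s + self.beta * t
                for a, s, t in zip(self.l_adv, self.l_class_s, self.l_class_t)
            )
        )


@dataclass
class GroupBatch:
    """One synchronized iteration batch (internal)."""

    source_trials: np.ndarray
    source_labels: np.ndarray
    target_trials: list[np.ndarray]  # per subject, same trial_index rows
    trial_index: np.ndarray


@dataclass
class GroupPrediction:
    """Evaluation-mode group output on the common valid trial set."""

    per_net_probs: np.ndarray  # (N, n) target-class probabilities
    fused_probs: np.ndarray    # (n,)
    fused_labels: np.ndarray   # (n,)
    trial_index: np.ndarray
    true_labels: np.ndarray


def fuse_and_binarize(
    probs: np.ndarray, weights: np.ndarray | tuple | None = None
) -> PseudoLabels:
    """Weighted-average N networks' target probabilities; binarize at 0.5.

    ``probs`` is (N, m).  Ties (mean exactly 0.5) go to the target class.
    """
    probs = np.atleast_2d(np.asarray(probs, dtype=float))
    if weights is None:
        weights = np.ones(probs.shape[0])
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != probs.shape[0]:
        raise DataError("one fusion weight per network required")
    if w.min() < 0 or w.sum() == 0:
        raise DataError("fusion weights must be nonnegative, not all zero")
    mean = (w[:, None] * probs).sum(axis=0) / w.sum()
    return PseudoLabels(labels=(mean >= 0.5).astype(np.int8), provenance=mean)


def target_class_loss(class_probs_t: np.ndarray, pseudo: PseudoLabels) -> float:
    """Cross-entropy of one network's target predictions vs the shared pseudo-labels."""
    return source_class_loss(class_probs_t, pseudo.labels)


def _net_seed(base_seed: int, subject_id: str) -> int:
    """Subject-keyed seed so a unit's stream is identical alone or in a group."""
    return (zlib.crc32(subject_id.encode()) ^ (base_seed * 2654435761)) % (2**31)


def _epoch_rng(seed: int, epoch: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed % (2**31), epoch, tag])


def _permuted_draw(n_pool: int, n_draw: int, rng: np.random.Generator) -> np.ndarray:
    """n_draw indices from a pool by concatenated permutations (no short batch)."""
    out = []
    got = 0
    while got < n_draw:
        perm = rng.permutation(n_pool)
        out.append(perm[: n_draw - got])
        got += len(out[-1])
    return np.concatenate(out)


def _source_draw(
    source: SourceDomain, n_iter: int, m: int, rng: np.random.Generator, balanced: bool
) -> np.ndarray:
    """Source row indices for one epoch: (n_iter * m,).

    Balanced mode draws half of each batch from the target class and half
    from the nontarget class (cycling through permutations), so the category
    classifier is not dominated by the ~5:1 nontarget majority.
    """
    if not balanced:
        return _permuted_draw(source.n_trials, n_iter * m, rng)
    pos = np.flatnonzero(source.labels == 1)
    neg = np.flatnonzero(source.labels == 0)
    if pos.size == 0 or neg.size == 0:
        return _permuted_draw(source.n_trials, n_iter * m, rng)
    half = m // 2
    pos_draw = pos[_permuted_draw(pos.size, n_iter * half, rng)]
    neg_draw = neg[_permuted_draw(neg.size, n_iter * (m - half), rng)]
    rows = np.empty((n_iter, m), dtype=int)
    for it in range(n_iter):
        batch = np.concatenate(
            [pos_draw[it * half : (it + 1) * half],
             neg_draw[it * (m - half) : (it + 1) * (m - half)]]
        )
        rows[it] = batch[rng.permutation(m)]
    return rows.ravel()


def _common_valid_index(targets: list[AlignedTrialSet]) -> np.ndarray:
    """Stimulus trial indices valid for every subject of the group."""
    if not targets:
        raise ConfigurationError("empty target group")
    ref = targets[0].trial_index
    for t in targets[1:]:
        if not np.array_equal(t.trial_index, ref):
            raise DataError("group subjects are not stimulus-synchronized")
    common = np.ones(len(ref), dtype=bool)
    for t in targets:
        common &= t.validity
    return ref[common]


def _rows_for(aligned: AlignedTrialSet, wanted: np.ndarray) -> np.ndarray:
    pos = {ti: i for i, ti in enumerate(aligned.trial_index)}
    return np.array([pos[ti] for ti in wanted], dtype=int)


def _unit_full_loss(
    net: NetworkUnit,
    source: SourceDomain,
    target_trials: np.ndarray,
    pseudo_labels: np.ndarray | None,
    cfg: TrainConfig,
    chunk: int = 256,
) -> float:
    """Deterministic end-of-epoch loss over the full source + target pools.

    The running batch average fluctuates with mini-batch resampling; this
    full-pool evaluation gives a smooth curve suitable for convergence
    detection.  Scaled to a per-``batch_size`` basis so its magnitude is
    comparable to the per-iteration bundles.
    """
    from . import nn as _nn

    def _probs(trials):
        cp = np.empty((len(trials), 2))
        dp = np.empty((len(trials), 2))
        for i in range(0, len(trials), chunk):
            c, d = net.forward(trials[i : i + chunk])
            cp[i : i + chunk], dp[i : i + chunk] = c, d
        return cp, dp

    cps, dps = _probs(source.trials)
    cpt, dpt = _probs(target_trials)
    ns, nt = len(source.trials), len(target_trials)
    l_s = _nn.cross_entropy_sum(cps, source.labels) / ns
    l_adv = (
        _nn.cross_entropy_sum(dps, np.zeros(ns, dtype=int)) / ns
        + _nn.cross_entropy_sum(dpt, np.ones(nt, dtype=int)) / nt
    ) / 2
    l_t = 0.0
    if pseudo_labels is not None and cfg.beta > 0:
        l_t = _nn.cross_entropy_sum(cpt, pseudo_labels) / nt
    m = cfg.batch_size
    return m * (cfg.alpha * 2 * l_adv + cfg.gamma * l_s + cfg.beta * l_t)


def plateau_epoch(epoch_losses, window: int = 20, rel_tol: float = 0.01) -> int | None:
    """First epoch at which training loss has stopped changing.

    The per-epoch loss fluctuates with mini-batch resampling even after
    convergence, so the change is measured as a trend: the relative
    difference between the mean of the first and second halves of a
    ``window``-epoch window.  Returns the index of the first epoch closing a
    window whose trend is below ``rel_tol``, or None.
    """
    losses = np.asarray(epoch_losses, dtype=float)
    half = window // 2
    run_min = np.minimum.accumulate(losses)
    for e in range(window, len(losses) + 1):
        seg = losses[e - window : e]
        a, b = seg[:half].mean(), seg[half:].mean()
        mean = abs(seg.mean())
        flat = mean == 0 or abs(b - a) / mean < rel_tol
        # the flat window must sit at the best level reached so far: a
        # transient rise-fall crossing is flat but above the running
        # minimum, so it does not count as convergence
        at_floor = mean == 0 or seg.mean() <= run_min[e - 1] * (1 + rel_tol)
        if flat and at_floor:
            return e - 1
    return None


def train_group(
    source: SourceDomain,
    targets: list[AlignedTrialSet],
    cfg: TrainConfig,
) -> tuple[list[NetworkUnit], dict]:
    """Train the N-unit group on a shared source domain.

    ``targets`` are the full aligned trial sets (selection happens inside,
    after warm-up).  Returns the trained units and a history dict with
    per-iteration :class:`LossBundle` records, per-epoch group loss, the
    frozen :class:`TargetDomain` selections, and (if ``cfg.eval_every > 0``)
    per-epoch fused metrics.
    """
    n = len(targets)
    if n != cfg.n_networks:
        raise ConfigurationError(
            f"config expects {cfg.n_networks} networks, got {n} target subjects"
        )
    if cfg.beta == 0:
        return _train_independent(source, targets, cfg)
    return _train_mutual(source, targets, cfg)


# --------------------------------------------------------------------------
# beta == 0: the units are uncoupled; train each exactly as if it were alone.
# --------------------------------------------------------------------------


def _train_independent(source, targets, cfg) -> tuple[list[NetworkUnit], dict]:
    nets, selections = [], {}
    iters: list[LossBundle] = []
    per_net_epoch_losses = []
    for aligned in targets:
        net, sel, ep_losses, unit_iters = _train_single(source, aligned, cfg)
        nets.append(net)
        selections[aligned.subject_id] = sel
        per_net_epoch_losses.append(ep_losses)
        iters.append(unit_iters)
    # merge per-unit iteration logs into group-level bundles
    bundles = [
        LossBundle(
            l_adv=tuple(u[i]["l_adv"] for u in iters),
            l_class_s=tuple(u[i]["l_class_s"] for u in iters),
            l_class_t=tuple(u[i]["l_class_t"] for u in iters),
            alpha=cfg.alpha,
            gamma=cfg.gamma,
            beta=cfg.beta,
        )
        for i in range(min(len(u) for u in iters))
    ]
    n_ep = min(len(e) for e in per_net_epoch_losses)
    epoch_loss = [sum(e[i] for e in per_net_epoch_losses) for i in range(n_ep)]
    history = {
        "iterations": bundles,
        "epoch_loss": epoch_loss,
        "selections": selections,
        "epoch_metrics": [],
        "mode": "independent",
    }
    return nets, history


def _train_single(source, aligned: AlignedTrialSet, cfg: TrainConfig):
    net = NetworkUnit(arch=cfg.arch, seed=_net_seed(cfg.seed, aligned.subject_id))
    nseed = net.seed
    valid_rows = np.flatnonzero(aligned.validity)
    pool_rows = valid_rows
    selection: TargetDomain | None = None
    ep_losses: list[float] = []
    unit_iters: list[dict] = []
    m = cfg.batch_size
    for epoch in range(cfg.epochs):
        if epoch == cfg.n_warmup:
            scores = net.predict_target_prob(aligned.trials[valid_rows])
            selection = select_by_scores(aligned, scores, cfg.select_fraction)
            pool_rows = _rows_for(aligned, selection.trial_index)
        rng_t = _epoch_rng(nseed, epoch, 2)
        rng_s = _epoch_rng(cfg.seed, epoch, 1)
        n_iter = max(len(pool_rows) // m, 1)
        t_order = rng_t.permutation(len(pool_rows))
        s_draw = _source_draw(source, n_iter, m, rng_s, cfg.balanced_source)
        ep_total = 0.0
        for it in range(n_iter):
            t_rows = pool_rows[t_order[it * m : (it + 1) * m]]
            s_rows = s_draw[it * m : (it + 1) * m]
            losses = net.train_step(
                xs=source.trials[s_rows],
                ys=source.labels[s_rows],
                xt=aligned.trials[t_rows],
                pseudo_labels=None,
                alpha=cfg.alpha,
                gamma=cfg.gamma,
                beta=0.0,
                lr=cfg.learning_rate,
                grl_lambda=cfg.grl_lambda,
            )
            unit_iters.append(losses)
            ep_total += losses["total"]
        if cfg.track_epoch_loss:
            ep_losses.append(
                _unit_full_loss(net, source, aligned.trials[pool_rows], None, cfg)
            )
        else:
            ep_losses.append(ep_total / n_iter)
    if selection is None:  # all epochs were warm-up
        scores = net.predict_target_prob(aligned.trials[valid_rows])
        selection = select_by_scores(aligned, scores, cfg.select_fraction)
    return net, selection, ep_losses, unit_iters


# --------------------------------------------------------------------------
# beta > 0: synchronized batches + pseudo-label feedback.
# --------------------------------------------------------------------------


def _train_mutual(source, targets, cfg) -> tuple[list[NetworkUnit], dict]:
    n = len(targets)
    weights = cfg.weights()
    nets = [
        NetworkUnit(arch=cfg.arch, seed=_net_seed(cfg.seed, t.subject_id))
        for t in targets
    ]
    common = _common_valid_index(targets)  # shared stimulus indices
    rows = [_rows_for(t, common) for t in targets]
    pool = np.arange(len(common))  # positions into `common`
    selections: dict[str, TargetDomain] = {}
    m = cfg.batch_size
    iters: list[LossBundle] = []
    epoch_loss: list[float] = []
    epoch_metrics: list[dict] = []

    for epoch in range(cfg.epochs):
        warm = epoch < cfg.n_warmup
        if epoch == cfg.n_warmup:
            # group-averaged ranking over the common valid pool, frozen
            probs = np.stack(
                [net.predict_target_prob(t.trials[r]) for net, t, r in zip(nets, targets, rows)]
            )
            fused = fuse_and_binarize(probs, weights).provenance
            order = np.lexsort((common, -fused))
            n_keep = int(cfg.select_fraction * len(common))
            pool = np.sort(order[:n_keep])
            for t, r in zip(targets, rows):
                sel_rows = r[pool]
                selections[t.subject_id] = TargetDomain(
                    subject_id=t.subject_id,
                    trials=t.trials[sel_rows],
                    trial_index=common[pool],
                    eval_labels=t.labels[sel_rows],
                    n_valid=len(common),
                )
        rng_t = _epoch_rng(cfg.seed, epoch, 2)
        rng_s = _epoch_rng(cfg.seed, epoch, 1)
        n_iter = max(len(pool) // m, 1)
        t_order = rng_t.permutation(len(pool))
        s_draw = _source_draw(source, n_iter, m, rng_s, cfg.balanced_source)
        ep_total = 0.0
        for it in range(n_iter):
            batch_pos = pool[t_order[it * m : (it + 1) * m]]
            s_rows = s_draw[it * m : (it + 1) * m]
            xs, ys = source.trials[s_rows], source.labels[s_rows]
            xts = [t.trials[r[batch_pos]] for t, r in zip(targets, rows)]

            if warm:
                pseudo = None
            else:
                probs = np.stack(
                    [net.forward(xt)[0][:, 1] for net, xt in zip(nets, xts)]
                )
                pseudo = fuse_and_binarize(probs, weights)

            l_adv, l_s, l_t = [], [], []
            for net, xt in zip(nets, xts):
                losses = net.train_step(
                    xs=xs,
                    ys=ys,
                    xt=xt,
                    pseudo_labels=None if pseudo is None else pseudo.labels,
                    alpha=cfg.alpha,
                    gamma=cfg.gamma,
                    beta=0.0 if warm else cfg.beta,
                    lr=cfg.learning_rate,
                    grl_lambda=cfg.grl_lambda,
                )
                l_adv.append(losses["l_adv"])
                l_s.append(losses["l_class_s"])
                l_t.append(losses["l_class_t"])
            bundle = LossBundle(
                l_adv=tuple(l_adv),
                l_class_s=tuple(l_s),
                l_class_t=tuple(l_t),
                alpha=cfg.alpha,
                gamma=cfg.gamma,
                beta=0.0 if warm else cfg.beta,
            )
            iters.append(bundle)
            ep_total += bundle.total
        if cfg.track_epoch_loss:
            pool_trials = [t.trials[r[pool]] for t, r in zip(targets, rows)]
            if warm:
                pl = None
            else:
                probs = np.stack(
                    [net.predict_target_prob(x) for net, x in zip(nets, pool_trials)]
                )
                pl = fuse_and_binarize(probs, weights).labels
            epoch_loss.append(
                sum(
                    _unit_full_loss(net, source, x, pl, cfg)
                    for net, x in zip(nets, pool_trials)
                )
            )
        else:
            epoch_loss.append(ep_total / n_iter)
        if cfg.eval_every and (epoch + 1) % cfg.eval_every == 0:
            pred = predict_group(nets, targets, weights)
            epoch_metrics.append(
                {"epoch": epoch, "fused": compute_metrics(pred.fused_labels, pred.true_labels)}
            )
    history = {
        "iterations": iters,
        "epoch_loss": epoch_loss,
        "selections": selections,
        "epoch_metrics": epoch_metrics,
        "mode": "mutual",
    }
    return nets, history


def history_to_frame(history: dict):
    """Per-iteration loss log as a flat table (for TSV export).

    Columns: iteration, per-network l_adv/l_class_s/l_class_t, and the
    optimized total.
    """
    import pandas as pd

    rows = []
    for i, b in enumerate(history["iterations"]):
        row = {"iteration": i}
        for n, (a, s, t) in enumerate(zip(b.l_adv, b.l_class_s, b.l_class_t), 1):
            row[f"net{n}_l_adv"] = a
            row[f"net{n}_l_class_s"] = s
            row[f"net{n}_l_class_t"] = t
        row["total"] = b.total
        rows.append(row)
    return pd.DataFrame(rows)


def predict_group(
    nets: list[NetworkUnit],
    targets: list[AlignedTrialSet],
    weights: np.ndarray | tuple | None = None,
) -> GroupPrediction:
    """Evaluation-mode group prediction on the common valid trials."""
    common = _common_valid_index(targets)
    rows = [_rows_for(t, common) for t in targets]
    per_net = np.stack(
        [net.predict_target_prob(t.trials[r]) for net, t, r in zip(nets, targets, rows)]
    )
    pseudo = fuse_and_binarize(per_net, weights)
    return GroupPrediction(
        per_net_probs=per_net,
        fused_probs=pseudo.provenance,
        fused_labels=pseudo.labels,
        trial_index=common,
        true_labels=targets[0].labels[rows[0]],
    )


def evaluate_group(
    nets: list[NetworkUnit],
    targets: list[AlignedTrialSet],
    weights: np.ndarray | tuple | None = None,
) -> tuple[DetectionMetrics, list[DetectionMetrics], GroupPrediction]:
    """Fused and per-network detection metrics on the common valid trials."""
    pred = predict_group(nets, targets, weights)
    fused = compute_metrics(pred.fused_labels, pred.true_labels)
    per_net = [
        compute_metrics((p >= 0.5).astype(int), pred.true_labels)
        for p in pred.per_net_probs
    ]
    return fused, per_net, pred
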