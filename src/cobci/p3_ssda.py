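"""The individual network unit: adversarial single-source domain adaptation.

One unit per observed subject.  It is trained on labeled source-domain
trials (pooled strong-P3 subjects) while adapting, without labels, to the
subject's own target-domain trials: a domain discriminator tries to tell
source features from target features, and a gradient-reversal layer makes
the feature extractor maximize that confusion.  A target-domain sample
selector keeps the trials most confidently predicted as targets (plus the
rest of the ranking down to 80%), which counteracts the heavy class
imbalance of the detection task.

Losses (summed over the batch, epsilon-clamped logs):

* source category loss   L_class^s = -sum_k l_k^s log p^{s,k}
* domain loss            L_adv     = -sum_k [ l^{d,s} log p^{d,s,k} + l^{d,t} log p^{d,t,k} ]

The discriminator descends L_adv; the extractor receives the reversed
gradient (coefficient ``grl_lambda``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .erp_align import AlignedTrialSet
from .exceptions import DataError
from .nn import Arch

SOURCE_DOMAIN_LABEL = 0
TARGET_DOMAIN_LABEL = 1
DEFAULT_SELECT_FRACTION = 0.8


@dataclass
class TargetDomain:
    """The selected (unlabeled) adaptation pool for one subject.

    ``eval_labels`` are the true labels, carried only for evaluation — the
    trainer never reads them.
    """

    subject_id: str
    trials: np.ndarray        # (k, 16, 100)
    trial_index: np.ndarray   # (k,) ascending
    eval_labels: np.ndarray   # (k,)
    n_valid: int


class NetworkUnit:
    """Feature extractor + category classifier + domain discriminator."""

    def __init__(self, arch: Arch | None = None, seed: int = 0):
        self.arch = arch or Arch()
        self.params = nn.init_params(self.arch, np.random.default_rng(seed))
        self.opt = nn.Adam()
        self.seed = seed

    # ---- inference ----------------------------------------------------

    def forward(self, batch: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Eval-mode forward pass: (class_probs (m,2), domain_probs (m,2))."""
        batch = np.asarray(batch)
        if batch.ndim != 3 or batch.shape[1:] != (self.arch.n_channels, self.arch.n_samples):
            raise DataError(
                f"batch must be (m, {self.arch.n_channels}, {self.arch.n_samples}), "
                f"got {batch.shape}"
            )
        f, _ = nn.feature_forward(self.params, self.arch, batch)
        class_probs, _ = nn.head_forward(self.params, "clf", f)
        domain_probs, _ = nn.head_forward(self.params, "dom", f)
        return class_probs, domain_probs

    def predict_target_prob(self, trials: np.ndarray, chunk: int = 256) -> np.ndarray:
        """Target-class probability for each trial, chunked for memory."""
        out = np.empty(len(trials))
        for i in range(0, len(trials), chunk):
            probs, _ = self.forward(trials[i : i + chunk])
            out[i : i + chunk] = probs[:, 1]
        return out

    # ---- one adversarial training step --------------------------------

    def train_step(
        self,
        xs: np.ndarray,
        ys: np.ndarray,
        xt: np.ndarray,
        pseudo_labels: np.ndarray | None,
        alpha: float,
        gamma: float,
        beta: float,
        lr: float,
        grl_lambda: float = 1.0,
    ) -> dict[str, float]:
        """One Adam step on  alpha*L_adv + gamma*L_class^s + beta*L_class^t.

        ``pseudo_labels`` (or ``beta == 0``) gates the target category term.
        Returns the loss components actually optimized.
        """
        p, arch = self.params, self.arch
        fs, cache_s = nn.feature_forward(p, arch, xs)
        ft, cache_t = nn.feature_forward(p, arch, xt)

        ps, ccache_s = nn.head_forward(p, "clf", fs)
        pt, ccache_t = nn.head_forward(p, "clf", ft)
        ds, dcache_s = nn.head_forward(p, "dom", fs)
        dt, dcache_t = nn.head_forward(p, "dom", ft)

        m_s, m_t = len(xs), len(xt)
        dom_s = np.full(m_s, SOURCE_DOMAIN_LABEL)
        dom_t = np.full(m_t, TARGET_DOMAIN_LABEL)

        l_class_s = source_class_loss(ps, ys)
        l_adv = domain_adv_loss(ds, dt)
        use_pseudo = beta > 0 and pseudo_labels is not None
        l_class_t = source_class_loss(pt, pseudo_labels) if use_pseudo else 0.0

        # gradients wrt logits of summed cross-entropy: (probs - onehot)
        dlog_ps = gamma * (ps - nn.one_hot(ys))
        dlog_ds = alpha * (ds - nn.one_hot(dom_s))
        dlog_dt = alpha * (dt - nn.one_hot(dom_t))

        gclf_s, dfs_c = nn.head_backward(p, "clf", ccache_s, dlog_ps)
        gdom_s, dfs_d = nn.head_backward(p, "dom", dcache_s, dlog_ds)
        gdom_t, dft_d = nn.head_backward(p, "dom", dcache_t, dlog_dt)

        if use_pseudo:
            dlog_pt = beta * (pt - nn.one_hot(pseudo_labels))
            gclf_t, dft_c = nn.head_backward(p, "clf", ccache_t, dlog_pt)
        else:
            gclf_t, dft_c = {}, np.zeros_like(ft)

        # gradient reversal: the extractor ascends the domain loss
        dfs = dfs_c - grl_lambda * dfs_d
        dft = dft_c - grl_lambda * dft_d
        gfeat = nn.accumulate(
            nn.feature_backward(p, arch, cache_s, dfs),
            nn.feature_backward(p, arch, cache_t, dft),
        )
        grads = nn.accumulate(gfeat, gclf_s, gclf_t, gdom_s, gdom_t)
        self.opt.lr = lr
        self.opt.step(p, grads)
        total = alpha * l_adv + gamma * l_class_s + beta * l_class_t
        return {
            "l_adv": l_adv,
            "l_class_s": l_class_s,
            "l_class_t": l_class_t,
            "total": total,
        }

    # ---- persistence ---------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, **self.params, _seed=self.seed)

    @classmethod
    def load(cls, path, arch: Arch | None = None) -> "NetworkUnit":
        data = np.load(path)
        unit = cls(arch=arch, seed=int(data["_seed"]))
        for k in unit.params:
            unit.params[k] = data[k]
        return unit


def source_class_loss(class_probs: np.ndarray, labels: np.ndarray) -> float:
    """Summed category cross-entropy against (pseudo-)labels."""
    if len(class_probs) != len(labels):
        raise DataError("probabilities and labels disagree in length")
    return nn.cross_entropy_sum(class_probs, labels)


def domain_adv_loss(domain_probs_s: np.ndarray, domain_probs_t: np.ndarray) -> float:
    """Summed domain cross-entropy: source rows labeled 0, target rows 1."""
    ls = np.full(len(domain_probs_s), SOURCE_DOMAIN_LABEL)
    lt = np.full(len(domain_probs_t), TARGET_DOMAIN_LABEL)
    return nn.cross_entropy_sum(domain_probs_s, ls) + nn.cross_entropy_sum(
        domain_probs_t, lt
    )


def select_target_samples(
    aligned: AlignedTrialSet,
    net: NetworkUnit,
    fraction: float = DEFAULT_SELECT_FRACTION,
) -> TargetDomain:
    """Keep the top ``floor(fraction * n_valid)`` trials by target probability.

    Ranking is over the subject's *valid* trials by descending predicted
    target-class probability, ties broken by ascending trial_index, so the
    selected set is invariant to trial order.
    """
    return select_by_scores(
        aligned, net.predict_target_prob(aligned.trials[aligned.validity]), fraction
    )


def select_by_scores(
    aligned: AlignedTrialSet, scores: np.ndarray, fraction: float
) -> TargetDomain:
    """Selection core shared with the group trainer (which averages scores)."""
    if not 0 < fraction <= 1:
        raise DataError("fraction must be in (0, 1]")
    valid_idx = np.flatnonzero(aligned.validity)
    if len(scores) != len(valid_idx):
        raise DataError("one score per valid trial required")
    n_keep = int(fraction * len(valid_idx))
    order = np.lexsort((aligned.trial_index[valid_idx], -scores))
    keep = valid_idx[order[:n_keep]]
    keep = keep[np.argsort(aligned.trial_index[keep])]  # ascending stimulus order
    return TargetDomain(
        subject_id=aligned.subject_id,
        trials=aligned.trials[keep],
        trial_index=aligned.trial_index[keep],
        eval_labels=aligned.labels[keep],
        n_valid=len(valid_idx),
    )
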