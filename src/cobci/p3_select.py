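"""Individual P3 maps, strong/weak clustering, and source-domain assembly.

Subjects differ widely in P300 expression.  Training the detector on
subjects with strong, posterior-focused P3 topographies yields better
transfer, so the pool of labeled single-subject sessions is clustered into a
"strong P3" and a "weak P3" group on their 16-channel topographies at the
P3 peak, and the strong group becomes the source domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from sklearn.cluster import KMeans

from .erp_align import AlignedTrialSet, ErpTemplate
from .exceptions import ConfigurationError, DataError
from .montage import CHANNELS_16, posterior_indices


@dataclass(frozen=True)
class P3Map:
    """One subject's 16-channel scalp topography at the P3 peak."""

    subject_id: str
    topography: np.ndarray  # (16,) uV
    peak_latency_ms: float


@dataclass
class SourceDomain:
    """Pooled labeled trials of the selected (strong-P3) subjects."""

    trials: np.ndarray       # (n, 16, 100)
    labels: np.ndarray       # (n,)
    member_ids: list[str]
    template: ErpTemplate
    subject_of_trial: np.ndarray  # (n,) index into member_ids

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]


def extract_p3_map(aligned: AlignedTrialSet, template: ErpTemplate) -> P3Map:
    """Average the valid aligned target trials; read the topography at the peak.

    The peak is the first maximum of the template-filter projection of the
    average; the map is the 16-channel slice at that sample.
    """
    mask = (aligned.labels == 1) & aligned.validity
    if not mask.any():
        raise DataError(f"{aligned.subject_id}: no valid target trials to average")
    avg = aligned.trials[mask].mean(axis=0)  # (16, 100)
    proj = template.filter.project(avg)
    peak = int(np.argmax(proj))
    return P3Map(
        subject_id=aligned.subject_id,
        topography=avg[:, peak].copy(),
        peak_latency_ms=peak * 10.0,
    )


def cluster_p3_maps(
    maps: list[P3Map],
    k: int = 2,
    seed: int = 0,
    n_init: int = 10,
    channels=CHANNELS_16,
) -> tuple[list[str], list[str]]:
    """K-means (k=2) on raw 16-vectors; the posterior-stronger cluster is "strong".

    Returns (strong_ids, weak_ids).  Seeded with restarts so source selection
    is deterministic.
    """
    if len(maps) < 2:
        raise DataError("need at least two P3 maps to cluster")
    X = np.stack([m.topography for m in maps])
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    post = posterior_indices(channels)
    strength = [km.cluster_centers_[c][post].mean() for c in range(k)]
    strong_cluster = int(np.argmax(strength))
    strong = [m.subject_id for m, lab in zip(maps, km.labels_) if lab == strong_cluster]
    weak = [m.subject_id for m, lab in zip(maps, km.labels_) if lab != strong_cluster]
    return strong, weak


def p3_strength(p3map: P3Map, channels=CHANNELS_16) -> float:
    """Scalar P3 strength: mean topography over parieto-occipital channels."""
    return float(p3map.topography[posterior_indices(channels)].mean())


def rank_by_strength(maps: list[P3Map], channels=CHANNELS_16) -> list[str]:
    """Subject ids in descending P3 strength (ties broken by subject_id).

    This is the total order behind "first m subjects" source-size sweeps.
    """
    return [
        m.subject_id
        for m in sorted(maps, key=lambda m: (-p3_strength(m, channels), m.subject_id))
    ]


def build_source_domain(
    pool: list[AlignedTrialSet],
    selected_ids: list[str],
    template: ErpTemplate,
) -> SourceDomain:
    """Concatenate the valid labeled trials of the selected subjects.

    Order is (subject as listed in ``selected_ids``, then trial_index).
    """
    if not selected_ids:
        raise ConfigurationError("source selection is empty")
    by_id = {a.subject_id: a for a in pool}
    missing = [s for s in selected_ids if s not in by_id]
    if missing:
        raise DataError(f"selected subjects not in pool: {missing}")
    chunks, label_chunks, owner = [], [], []
    for si, sid in enumerate(selected_ids):
        a = by_id[sid]
        order = np.argsort(a.trial_index, kind="stable")
        keep = order[a.validity[order]]
        chunks.append(a.trials[keep])
        label_chunks.append(a.labels[keep])
        owner.append(np.full(keep.size, si))
    return SourceDomain(
        trials=np.concatenate(chunks),
        labels=np.concatenate(label_chunks).astype(np.int8),
        member_ids=list(selected_ids),
        template=template,
        subject_of_trial=np.concatenate(owner),
    )


def brute_force_two_partition(X: np.ndarray) -> np.ndarray:
    """Exhaustive best 2-partition by K-means objective (within-cluster SSE).

    Exponential in n — an independent oracle for small clustering problems,
    not a production path.
    """
    n = X.shape[0]
    if n > 16:
        raise ValueError("brute force limited to n <= 16")
    best, best_labels = np.inf, None
    idx = np.arange(n)
    for r in range(1, n // 2 + 1):
        for combo in combinations(idx, r):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            sse = 0.0
            for m in (mask, ~mask):
                c = X[m].mean(axis=0)
                sse += ((X[m] - c) ** 2).sum()
            if sse < best - 1e-12:
                best, best_labels = sse, mask.copy()
    return best_labels
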