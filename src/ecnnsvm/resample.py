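"""Hybrid class balancing: SMOTE oversampling followed by TomekLink cleaning.

With tens of patients and a death/survival imbalance, a classifier trained on
the raw data inflates accuracy by favouring the majority class. Phase 1
synthesizes minority samples by interpolation toward minority nearest
neighbors until the two classes are equal in size; phase 2 removes
cross-class mutual-nearest-neighbor pairs (TomekLinks) to clean overlapping
boundary samples. Both members of a link are removed by default; a
``majority_only`` switch restores the more common convention of dropping only
the majority member.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.distance import cdist

from .fusion import FusedDataset

__all__ = ["SmoteParams", "TomekPair", "smote_generate", "find_tomek_links",
           "hybrid_balance"]


@dataclass
class SmoteParams:
    """Knobs of the SMOTE phase.

    k_neighbors is the size of the minority neighborhood a synthetic point
    interpolates into (must be smaller than the minority count);
    target_count is the minority size to reach (None = majority count).
    """

    k_neighbors: int = 5
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class TomekPair:
    """A mutual-nearest pair of opposite-class samples."""

    i: int          # index into the majority class
    j: int          # index into the minority class
    distance: float


def _knn_indices(dist_row: np.ndarray, self_idx: int, k: int) -> np.ndarray:
    """Indices of the k nearest points, excluding self; ties by ascending index."""
    order = np.argsort(dist_row, kind="stable")
    order = order[order != self_idx]
    return order[:k]


def smote_generate(minority: np.ndarray, params: SmoteParams,
                   rng: np.random.Generator) -> np.ndarray:
    """Synthesize minority samples by convex interpolation.

    Each new row is ``X_i + u * (X_nn - X_i)`` with ``u ~ Uniform(0, 1)``,
    where ``X_nn`` is one of ``X_i``'s k nearest minority neighbors under
    Euclidean distance. Exactly ``target_count - len(minority)`` rows are
    returned, every one on the closed segment between its seed point and a
    true minority neighbor.
    """
    minority = np.asarray(minority, dtype=float)
    m = minority.shape[0]
    if m <= params.k_neighbors:
        raise ValueError(
            f"minority count {m} must exceed k_neighbors={params.k_neighbors}; "
            "use a smaller k"
        )
    if params.target_count is None:
        raise ValueError("target_count must be set")
    need = params.target_count - m
    if need < 0:
        raise ValueError("target_count below current minority count")
    if need == 0:
        return np.empty((0, minority.shape[1]))
    dists = cdist(minority, minority)
    neighbors = np.stack([_knn_indices(dists[i], i, params.k_neighbors)
                          for i in range(m)])
    seeds = rng.integers(0, m, size=need)
    picks = rng.integers(0, params.k_neighbors, size=need)
    u = rng.random(size=need)
    xi = minority[seeds]
    xnn = minority[neighbors[seeds, picks]]
    return xi + u[:, None] * (xnn - xi)


def find_tomek_links(X: np.ndarray, y: np.ndarray) -> list[TomekPair]:
    """Enumerate all TomekLink pairs of a labelled sample set.

    A pair (a, b) of opposite-class samples is a link when no third sample —
    of any class — is strictly closer to a than b is, nor strictly closer to
    b than a is. Pairs are oriented (majority member first) and sorted by
    ascending member indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = X.shape[0]
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or n < 2:
        return []
    majority_label = classes[np.argmax(counts)]  # argmax ties -> first label
    dists = cdist(X, X)
    np.fill_diagonal(dists, np.inf)
    nearest = dists.min(axis=1)
    links: list[TomekPair] = []
    for a in range(n):
        for b in range(a + 1, n):
            if y[a] == y[b]:
                continue
            d = dists[a, b]
            if d <= nearest[a] and d <= nearest[b]:
                i, j = (a, b) if y[a] == majority_label else (b, a)
                links.append(TomekPair(i, j, float(d)))
    return links


def hybrid_balance(
    data: FusedDataset,
    params: SmoteParams,
    majority_only: bool = False,
) -> tuple[FusedDataset, dict]:
    """Balance a fused dataset: SMOTE to class parity, then remove TomekLinks.

    Phase 1 raises the minority class to the majority count with synthetic
    interpolated rows (flagged in ``synthetic``); phase 2 detects TomekLinks
    on the augmented data and removes both members of every link (or only the
    majority member when ``majority_only``). Surviving original rows are
    passed through bit-for-bit. Returns the cleaned dataset and a report with
    class counts before/after each phase.
    """
    y = data.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValueError("hybrid_balance needs exactly two classes")
    report: dict = {"counts_before": {int(c): int(k) for c, k in zip(classes, counts)}}

    minority_label = int(classes[np.argmin(counts)])
    majority_count = int(counts.max())
    min_mask = y == minority_label
    rng = np.random.default_rng(params.seed)
    p1 = replace(params, target_count=majority_count)
    synth = smote_generate(data.values[min_mask], p1, rng)

    values = np.vstack([data.values, synth])
    labels = np.concatenate([y, np.full(synth.shape[0], minority_label)])
    synthetic = np.concatenate([data.synthetic,
                                np.ones(synth.shape[0], dtype=bool)])
    sample_ids = data.sample_ids + [f"synth_{i}" for i in range(synth.shape[0])]
    report["counts_after_smote"] = {
        int(c): int((labels == c).sum()) for c in classes
    }

    links = find_tomek_links(values, labels)
    drop: set[int] = set()
    for pair in links:
        drop.add(pair.i)
        if not majority_only:
            drop.add(pair.j)
    keep = np.array([i for i in range(values.shape[0]) if i not in drop], dtype=int)
    report["n_tomek_links"] = len(links)
    report["n_removed"] = len(drop)
    report["majority_only"] = majority_only
    report["counts_after_clean"] = {
        int(c): int((labels[keep] == c).sum()) for c in classes
    }

    out = FusedDataset(values[keep], labels[keep], list(data.feature_provenance),
                       [sample_ids[i] for i in keep], synthetic[keep])
    return out, report
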