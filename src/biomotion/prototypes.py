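"""Action prototypes: five representative form snapshots per class.

Each action is abstracted into five primitive pose snapshots ("action
prototypes") extracted from training descriptors by a two-stage reduction:
project the frames onto their leading eigenimages (principal components
capturing >= 95% variance), cluster the projections into five groups, and
return the real training frame nearest each cluster centroid, unit
normalised.  This eigendecomposition + clustering construction stands in
for the synergetic-network "melting" abstraction of this model family; the
nearest-real-frame step keeps prototypes physically realisable poses
rather than blurred means.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .classifiers import PrototypeSet

__all__ = ["extract_prototypes", "build_prototype_bank", "train_split"]


def extract_prototypes(frames, k: int = 5, seed: int = 0) -> np.ndarray:
    """Extract ``k`` prototype frames from one class's descriptors.

    Returns a ``(k, ...)`` array of unit-norm prototypes, each an actual
    (normalised) input frame — the one nearest its cluster centroid in
    eigenimage space.  Prototype indices are pairwise distinct.
    Deterministic given ``seed``; permutation-invariant up to prototype
    order.
    """
    X = np.asarray(frames, dtype=float)
    if X.ndim < 2 or X.shape[0] < k:
        raise ValueError(f"need at least k={k} frames")
    n = X.shape[0]
    flat = X.reshape(n, -1)
    order = np.lexsort(flat.T[::-1])  # canonical order: frame-order invariance
    flat_sorted = flat[order]

    centred = flat_sorted - flat_sorted.mean(axis=0)
    total_var = float((centred**2).sum())
    if total_var < 1e-18:
        # degenerate: all frames identical
        proto = flat_sorted[:1].repeat(k, axis=0)
        norms = np.linalg.norm(proto, axis=1, keepdims=True)
        proto = proto / np.maximum(norms, 1e-12)
        return proto.reshape((k,) + X.shape[1:])

    n_comp = min(n - 1, flat.shape[1], 32)
    pca = PCA(n_components=n_comp, svd_solver="full")
    Z = pca.fit_transform(flat_sorted)
    cum = np.cumsum(pca.explained_variance_ratio_)
    keep = int(np.searchsorted(cum, 0.95) + 1)
    Z = Z[:, :keep]

    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    km.fit(Z)
    chosen: list[int] = []
    for centre in km.cluster_centers_:
        d = np.linalg.norm(Z - centre, axis=1)
        for idx in np.argsort(d, kind="stable"):
            if idx not in chosen:
                chosen.append(int(idx))
                break
    proto = flat_sorted[chosen]
    norms = np.linalg.norm(proto, axis=1, keepdims=True)
    proto = proto / np.maximum(norms, 1e-12)
    return proto.reshape((k,) + X.shape[1:])


def build_prototype_bank(descriptors_by_class: dict, k: int = 5, seed: int = 0) -> PrototypeSet:
    """Extract prototypes for every class and wrap them as a PrototypeSet."""
    names = tuple(sorted(descriptors_by_class))
    protos = {
        name: extract_prototypes(descriptors_by_class[name], k=k, seed=seed + i)
        for i, name in enumerate(names)
    }
    return PrototypeSet(prototypes=protos, class_names=names)


def train_split(videos, n_train_subjects: int = 5, seed: int = 0):
    """Subject-disjoint train/test split of a labelled video collection.

    ``videos`` is any iterable of objects with a ``subject_id`` attribute.
    ``n_train_subjects`` subjects are drawn without replacement with the
    seeded generator; every video of a drawn subject goes to the training
    set, all others to test.  Reproducible for a fixed seed.
    """
    videos = list(videos)
    subjects = sorted({v.subject_id for v in videos})
    if len(subjects) < n_train_subjects:
        raise ValueError("not enough subjects for the requested split")
    rng = np.random.default_rng(seed)
    train_subjects = set(
        np.asarray(subjects)[rng.choice(len(subjects), size=n_train_subjects, replace=False)]
        .tolist()
    )
    train = [v for v in videos if v.subject_id in train_subjects]
    test = [v for v in videos if v.subject_id not in train_subjects]
    return train, test
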