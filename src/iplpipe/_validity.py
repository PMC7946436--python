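"""Cluster validity indices used in the majority vote over candidate k.

Twelve indices spanning maximization, minimization, and successive-k
("elbow") optimum rules.  Each scalar index takes the feature matrix, a
label vector, and a precomputed square pairwise-distance matrix; it
returns ``nan`` when undefined for the given partition (the vote logic
treats that as an abstention).

Index values are plain functions of (features, partition) so they can be
checked against hand computation on tiny fixtures.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform
from sklearn import metrics as _skm


def pairwise_distances(X: np.ndarray) -> np.ndarray:
    return squareform(pdist(X))


def _cluster_stats(X, labels):
    ks = np.unique(labels)
    centroids = np.stack([X[labels == k].mean(axis=0) for k in ks])
    return ks, centroids


def _within_between_masks(labels, D):
    n = len(labels)
    iu = np.triu_indices(n, 1)
    same = labels[iu[0]] == labels[iu[1]]
    d = D[iu]
    return d[same], d[~same], d


def calinski_harabasz(X, labels, D=None):
    try:
        return float(_skm.calinski_harabasz_score(X, labels))
    except ValueError:
        return np.nan


def silhouette(X, labels, D=None):
    try:
        return float(_skm.silhouette_score(X, labels))
    except ValueError:
        return np.nan


def davies_bouldin(X, labels, D=None):
    try:
        return float(_skm.davies_bouldin_score(X, labels))
    except ValueError:
        return np.nan


def dunn(X, labels, D):
    ks = np.unique(labels)
    if len(ks) < 2:
        return np.nan
    diam = 0.0
    for k in ks:
        idx = np.flatnonzero(labels == k)
        if len(idx) > 1:
            diam = max(diam, D[np.ix_(idx, idx)].max())
    if diam == 0:
        return np.nan
    min_between = np.inf
    for i, a in enumerate(ks):
        for b in ks[i + 1:]:
            ia, ib = np.flatnonzero(labels == a), np.flatnonzero(labels == b)
            min_between = min(min_between, D[np.ix_(ia, ib)].min())
    return float(min_between / diam)


def c_index(X, labels, D):
    dw, db, dall = _within_between_masks(labels, D)
    nw = len(dw)
    if nw == 0 or nw == len(dall):
        return np.nan
    sorted_d = np.sort(dall)
    s = dw.sum()
    smin = sorted_d[:nw].sum()
    smax = sorted_d[-nw:].sum()
    if smax == smin:
        return np.nan
    return float((s - smin) / (smax - smin))


def mcclain_rao(X, labels, D):
    dw, db, _ = _within_between_masks(labels, D)
    if len(dw) == 0 or len(db) == 0 or db.mean() == 0:
        return np.nan
    return float(dw.mean() / db.mean())


def point_biserial(X, labels, D):
    dw, db, dall = _within_between_masks(labels, D)
    nw, nb, nt = len(dw), len(db), len(dall)
    sd = dall.std()
    if nw == 0 or nb == 0 or sd == 0:
        return np.nan
    return float((db.mean() - dw.mean()) * np.sqrt(nw * nb) / nt / sd)


def pbm(X, labels, D=None):
    ks, centroids = _cluster_stats(X, labels)
    k = len(ks)
    if k < 2:
        return np.nan
    grand = X.mean(axis=0)
    e1 = np.linalg.norm(X - grand, axis=1).sum()
    ew = sum(
        np.linalg.norm(X[labels == lab] - c, axis=1).sum()
        for lab, c in zip(ks, centroids)
    )
    if ew == 0:
        return np.nan
    dmax = max(
        np.linalg.norm(centroids[i] - centroids[j])
        for i in range(k) for j in range(i + 1, k)
    )
    return float((e1 * dmax / (k * ew)) ** 2)


def ratkowsky_lance(X, labels, D=None):
    ks, centroids = _cluster_stats(X, labels)
    k = len(ks)
    if k < 2:
        return np.nan
    grand = X.mean(axis=0)
    sizes = np.array([(labels == lab).sum() for lab in ks])
    tss = ((X - grand) ** 2).sum(axis=0)
    bgss = (sizes[:, None] * (centroids - grand) ** 2).sum(axis=0)
    ok = tss > 0
    if not ok.any():
        return np.nan
    cbar = np.sqrt(bgss[ok] / tss[ok]).mean()
    return float(cbar / np.sqrt(k))


def xie_beni(X, labels, D=None):
    ks, centroids = _cluster_stats(X, labels)
    k = len(ks)
    if k < 2:
        return np.nan
    wss = 0.0
    for lab, c in zip(ks, centroids):
        wss += ((X[labels == lab] - c) ** 2).sum()
    dmin2 = min(
        ((centroids[i] - centroids[j]) ** 2).sum()
        for i in range(k) for j in range(i + 1, k)
    )
    if dmin2 == 0:
        return np.nan
    return float(wss / (len(X) * dmin2))


#: scalar indices with a simple per-k optimum rule
SCALAR_INDICES = {
    "calinski_harabasz": (calinski_harabasz, "max"),
    "silhouette": (silhouette, "max"),
    "davies_bouldin": (davies_bouldin, "min"),
    "dunn": (dunn, "max"),
    "c_index": (c_index, "min"),
    "mcclain_rao": (mcclain_rao, "min"),
    "point_biserial": (point_biserial, "max"),
    "pbm": (pbm, "max"),
    "ratkowsky_lance": (ratkowsky_lance, "max"),
    "xie_beni": (xie_beni, "min"),
}


def hartigan_votes(wcss: dict[int, float], k_range: range, n: int, threshold: float = 10.0):
    """Hartigan rule over successive k.

    H(k) = (W_k / W_{k+1} - 1) * (n - k - 1).  Vote: the smallest k in the
    range with H(k) <= threshold; if none qualifies, the k with the largest
    drop H(k-1) - H(k) (the elbow).  Requires W at k_max + 1.
    """
    H = {}
    for k in k_range:
        if k + 1 not in wcss or wcss[k + 1] <= 0:
            return None, H
        H[k] = (wcss[k] / wcss[k + 1] - 1.0) * (n - k - 1)
    for k in k_range:
        if H[k] <= threshold:
            return k, H
    ks = [k for k in k_range if k - 1 in H]
    if not ks:
        return None, H
    drops = {k: H[k - 1] - H[k] for k in ks}
    return max(drops, key=lambda k: (drops[k], -k)), H


def krzanowski_lai_votes(wcss: dict[int, float], k_range: range, p: int):
    """Krzanowski-Lai rule: KL(k) = |DIFF(k)| / |DIFF(k+1)| with
    DIFF(k) = (k-1)^{2/p} W_{k-1} - k^{2/p} W_k; vote for the k maximizing
    KL.  Requires W at k_min - 1 and k_max + 1."""
    def diff(k):
        return (k - 1) ** (2.0 / p) * wcss[k - 1] - k ** (2.0 / p) * wcss[k]

    KL = {}
    for k in k_range:
        if not {k - 1, k, k + 1} <= set(wcss):
            return None, KL
        denom = diff(k + 1)
        if denom == 0:
            KL[k] = np.nan
        else:
            KL[k] = abs(diff(k)) / abs(denom)
    finite = {k: v for k, v in KL.items() if np.isfinite(v)}
    if not finite:
        return None, KL
    best = max(finite.values())
    return min(k for k, v in finite.items() if v == best), KL
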